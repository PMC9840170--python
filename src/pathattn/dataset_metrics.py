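"""Dataset-difficulty statistics for a reference/query annotation task.

Four per-dataset numbers: log10 cell count, number of cell types, Shannon
entropy (bits) of the reference label proportions, and the Kullback-Leibler
divergence (bits) of the reference proportions from the query proportions.
An uneven reference (low entropy) and a reference/query label-composition
mismatch (high KL) both make annotation transfer harder; KL is the
strongest difficulty predictor.

Entropy and KL use the standard non-negative conventions
H(p) = -sum p_i log2 p_i and D_KL(p||q) = sum p_i log2(p_i / q_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class DatasetStats:
    log_size: float
    n_types: int
    entropy: float   # bits
    d_kl: float      # bits, reference vs query label proportions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def label_distribution(labels: np.ndarray, classes: list[str] | None = None) -> pd.Series:
    """Proportion of cells per cell type, over ``classes`` when given."""
    counts = pd.Series(labels).astype(str).value_counts()
    if classes is not None:
        counts = counts.reindex(classes, fill_value=0)
    return counts / counts.sum()


def log_size(x: ExpressionMatrix | int) -> float:
    """log10 of the number of cells."""
    n = x if isinstance(x, (int, np.integer)) else x.n_cells
    if n < 1:
        raise ValueError("dataset is empty")
    return float(np.log10(n))


def _validate(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    return p


def shannon_entropy(p) -> float:
    """Shannon entropy in bits, with 0 * log 0 = 0."""
    p = _validate(np.asarray(p, dtype=np.float64))
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def kl_divergence(p, q, pseudo: float = 1e-9) -> float:
    """D_KL(p || q) in bits after pseudo-count smoothing and renormalization.

    ``p`` and ``q`` must share support ordering (use the union of label sets,
    absent labels at proportion 0); the additive pseudo-count keeps the
    divergence finite when a reference type is missing from the query.
    """
    p = _validate(p)
    q = _validate(q)
    if p.shape != q.shape:
        raise ValueError("p and q must be over the same (union) label set")
    p = (p + pseudo) / (p + pseudo).sum()
    q = (q + pseudo) / (q + pseudo).sum()
    return float((p * np.log2(p / q)).sum())


def dataset_stats(
    ref: ExpressionMatrix, query: ExpressionMatrix | None = None, pseudo: float = 1e-9
) -> DatasetStats:
    """Compute all four statistics for a labeled reference (and labeled query)."""
    if ref.labels is None:
        raise ValueError("reference must carry labels")
    p = label_distribution(ref.labels)
    d_kl = float("nan")
    if query is not None and query.labels is not None:
        classes = sorted(set(p.index) | set(pd.Series(query.labels).astype(str)))
        p_full = label_distribution(ref.labels, classes)
        q_full = label_distribution(query.labels, classes)
        d_kl = kl_divergence(p_full.to_numpy(), q_full.to_numpy(), pseudo)
    return DatasetStats(
        log_size=log_size(ref),
        n_types=int(len(p)),
        entropy=shannon_entropy(p.to_numpy()),
        d_kl=d_kl,
    )
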