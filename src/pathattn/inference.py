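"""Query prediction with Unknown rejection, and attention-embedding export.

A cell whose maximum class probability falls below the cutoff (default 0.95)
is annotated "Unknown" — the mechanism behind novel-cell-type discovery.
Queries are processed in chunks so large matrices stream through; results
are independent of the chunk size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix
from .model import ModelState, _forward_batch

UNKNOWN = "Unknown"


@dataclass
class PredictionResult:
    cell_ids: tuple[str, ...]
    class_names: tuple[str, ...]
    probabilities: np.ndarray       # (cells, nc), rows sum to 1
    predicted: np.ndarray           # label or "Unknown"
    max_prob: np.ndarray

    def __post_init__(self) -> None:
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("probability rows must sum to 1")


@dataclass
class AttentionEmbedding:
    """Cells x gene-sets CLS attention scores: the interpretable latent space.

    Entries are post-softmax attention weights in [0, 1]; each row sums to
    at most 1 (the CLS-to-CLS weight is excluded).
    """

    values: np.ndarray
    set_names: tuple[str, ...]
    cell_ids: tuple[str, ...]


def _run(query: ExpressionMatrix, state: ModelState, chunk_size: int):
    if tuple(query.gene_names.names) != tuple(state.mask.gene_names.names):
        raise ValueError("query is not aligned to the model's gene vocabulary")
    probs = np.empty((query.n_cells, state.n_classes))
    attn = np.empty((query.n_cells, state.n_sets))
    for start in range(0, query.n_cells, chunk_size):
        sl = slice(start, start + chunk_size)
        p, a, _ = _forward_batch(query.values[sl], state)
        probs[sl], attn[sl] = p, a
    return probs, attn


def predict(
    query: ExpressionMatrix,
    state: ModelState,
    cutoff: float | None = None,
    chunk_size: int = 512,
) -> PredictionResult:
    """Per-cell argmax label, replaced by "Unknown" below the probability cutoff.

    Ties are broken by label order (first label wins), so predictions are
    deterministic.  ``cutoff=None`` uses the model config's cutoff.
    """
    if cutoff is None:
        cutoff = state.config.unknown_cutoff
    probs, _ = _run(query, state, chunk_size)
    idx = probs.argmax(axis=1)
    max_prob = probs[np.arange(len(idx)), idx]
    labels = np.array(state.labels, dtype=object)[idx]
    labels[max_prob < cutoff] = UNKNOWN
    return PredictionResult(
        cell_ids=query.cell_ids,
        class_names=state.labels,
        probabilities=probs,
        predicted=labels,
        max_prob=max_prob,
    )


def attention_embedding(
    query: ExpressionMatrix, state: ModelState, chunk_size: int = 512
) -> AttentionEmbedding:
    """Head-averaged final-block CLS->token attention, one row per cell."""
    _, attn, = _run(query, state, chunk_size)
    return AttentionEmbedding(
        values=attn, set_names=state.mask.set_names, cell_ids=query.cell_ids
    )
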