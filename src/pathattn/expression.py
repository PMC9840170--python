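"""Expression-matrix I/O, normalization and gene alignment.

Cells are rows, genes are columns everywhere.  A query is aligned to the
reference gene vocabulary by NAME (case-insensitive), never by position;
vocabulary genes missing from the query become zero columns, which the
masked embedding treats the same as an unmeasured gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gene_sets import GeneVocabulary


@dataclass
class ExpressionMatrix:
    """Non-negative cells x genes matrix with per-cell metadata.

    ``labels`` (cell types) and ``batch`` are optional per-cell categories;
    batch is never consumed by the model, only by evaluation code.
    """

    values: np.ndarray
    gene_names: GeneVocabulary
    cell_ids: tuple[str, ...]
    labels: np.ndarray | None = None
    batch: np.ndarray | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=np.float64)
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (cells x genes)")
        if self.values.shape[1] != len(self.gene_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.gene_names)} gene names"
            )
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match row count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative entries")
        for attr in ("labels", "batch"):
            vec = getattr(self, attr)
            if vec is not None:
                vec = np.asarray(vec, dtype=object)
                if vec.shape != (self.values.shape[0],):
                    raise ValueError(f"{attr} must have one entry per cell")
                setattr(self, attr, vec)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            values=self.values[rows],
            gene_names=self.gene_names,
            cell_ids=tuple(np.asarray(self.cell_ids, dtype=object)[rows]),
            labels=None if self.labels is None else self.labels[rows],
            batch=None if self.batch is None else self.batch[rows],
            normalized=self.normalized,
        )


def _load_h5ad(path: Path, label_key: str | None, batch_key: str | None) -> ExpressionMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    x = adata.X
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise KeyError(f"label column {label_key!r} not found in obs")
        labels = adata.obs[label_key].astype(str).to_numpy()
    batch = None
    if batch_key is not None and batch_key in adata.obs:
        batch = adata.obs[batch_key].astype(str).to_numpy()
    return ExpressionMatrix(
        values=x,
        gene_names=GeneVocabulary(tuple(str(g) for g in adata.var_names)),
        cell_ids=tuple(str(c) for c in adata.obs_names),
        labels=labels,
        batch=batch,
    )


def _load_mtx_dir(path: Path, label_key: str | None) -> ExpressionMatrix:
    from scipy.io import mmread

    mtx = mmread(path / "matrix.mtx")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    values = np.asarray(sp.csr_matrix(mtx).todense(), dtype=np.float64)
    # 10x convention stores genes x cells; transpose if shapes say so
    if values.shape == (len(features), len(barcodes)) and values.shape[0] != values.shape[1]:
        values = values.T
    labels = None
    if label_key is not None:
        meta_path = path / "labels.tsv"
        if not meta_path.exists():
            raise KeyError(f"label file {meta_path} not found for MTX input")
        labels = pd.read_csv(meta_path, sep="\t", header=None)[0].astype(str).to_numpy()
    return ExpressionMatrix(
        values=values,
        gene_names=GeneVocabulary(tuple(str(g) for g in features[0])),
        cell_ids=tuple(str(b) for b in barcodes[0]),
        labels=labels,
    )


def _load_csv(path: Path, label_key: str | None, transpose: bool) -> ExpressionMatrix:
    import csv

    with open(path, newline="") as fh:  # pandas mangles duplicate headers
        header = next(csv.reader(fh))[1:]
    if not transpose:
        dupes = sorted({h for h in header if header.count(h) > 1})
        if dupes:
            raise ValueError(f"duplicate gene names: {dupes[:10]}")
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    labels = None
    if label_key is not None:
        if label_key not in df.columns:
            raise KeyError(f"label column {label_key!r} not found in CSV header")
        labels = df[label_key].astype(str).to_numpy()
        df = df.drop(columns=[label_key])
    genes = tuple(str(c) for c in df.columns)
    dupes = [g for g in set(genes) if list(genes).count(g) > 1]
    if dupes:
        raise ValueError(f"duplicate gene names: {sorted(dupes)[:10]}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_names=GeneVocabulary(genes),
        cell_ids=tuple(str(i) for i in df.index),
        labels=labels,
    )


def load_expression(
    path: str | Path,
    label_key: str | None = None,
    batch_key: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix from h5ad, an MTX triplet directory, or CSV.

    Raw counts are accepted; values are only checked for non-negativity.
    ``label_key`` names the per-cell annotation column (h5ad obs / CSV column)
    or requests ``labels.tsv`` next to an MTX triplet.
    """
    path = Path(path)
    if path.is_dir():
        return _load_mtx_dir(path, label_key)
    if path.suffix == ".h5ad":
        return _load_h5ad(path, label_key, batch_key)
    if path.suffix in (".csv", ".txt", ".gz"):
        return _load_csv(path, label_key, transpose)
    raise ValueError(f"unrecognized expression input: {path}")


def normalize(
    x: ExpressionMatrix, size_factor: float = 1e4, log: bool = True
) -> ExpressionMatrix:
    """Library-size normalize each cell to ``size_factor`` total, then log1p.

    ``log=False`` skips the log transform (pure library-size scaling).
    All-zero cells are left as zeros with a warning.
    """
    totals = x.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s) left unnormalized")
    safe = np.where(zero, 1.0, totals)
    scaled = x.values * (size_factor / safe)[:, None]
    return ExpressionMatrix(
        values=np.log1p(scaled) if log else scaled,
        gene_names=x.gene_names,
        cell_ids=x.cell_ids,
        labels=x.labels,
        batch=x.batch,
        normalized=True,
    )


def prepare_model_input(x: ExpressionMatrix, mode: str = "linear") -> ExpressionMatrix:
    """Normalize raw counts for the classifier.

    ``linear`` (default) scales each cell to a total of 100 without a log
    transform, so pathway-token magnitudes stay proportional to pathway
    count shares — the signal the attention layer reads.  ``log1p`` applies
    the 1e4 library-size + log1p convention instead; ``none`` passes counts
    through unchanged.
    """
    if mode == "linear":
        return normalize(x, size_factor=100.0, log=False)
    if mode == "log1p":
        return normalize(x, size_factor=1e4, log=True)
    if mode == "none":
        return x
    raise ValueError("mode must be 'linear', 'log1p' or 'none'")


def align_to_vocabulary(
    x: ExpressionMatrix,
    vocabulary: GeneVocabulary,
    min_overlap: float = 0.10,
) -> ExpressionMatrix:
    """Reorder/zero-fill columns of ``x`` to match ``vocabulary``.

    Genes absent from ``x`` become zero columns; extra genes are dropped.
    An overlap below ``min_overlap`` of the vocabulary aborts: almost-disjoint
    gene spaces signal a species or identifier-scheme mismatch.
    """
    source = x.gene_names.index()
    n_vocab = len(vocabulary)
    values = np.zeros((x.n_cells, n_vocab), dtype=np.float64)
    found = 0
    for j, gene in enumerate(vocabulary.names):
        i = source.get(gene.lower())
        if i is not None:
            values[:, j] = x.values[:, i]
            found += 1
    fraction = found / n_vocab
    if fraction < min_overlap:
        raise ValueError(
            f"only {found}/{n_vocab} vocabulary genes found in input "
            f"({fraction:.1%} < {min_overlap:.0%}); gene spaces look disjoint"
        )
    if fraction < 1.0:
        warnings.warn(f"{n_vocab - found} vocabulary gene(s) missing; zero-filled")
    return ExpressionMatrix(
        values=values,
        gene_names=vocabulary,
        cell_ids=x.cell_ids,
        labels=x.labels,
        batch=x.batch,
        normalized=x.normalized,
    )


def write_predictions(path: str | Path, result) -> None:
    """Write predictions as CSV: cell_id, predicted_label, max_probability, per-class columns."""
    df = pd.DataFrame(result.probabilities, columns=list(result.class_names))
    df.insert(0, "max_probability", result.max_prob)
    df.insert(0, "predicted_label", result.predicted)
    df.insert(0, "cell_id", list(result.cell_ids))
    df.to_csv(path, index=False)
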