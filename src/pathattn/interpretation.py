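"""Interpretability downstream of the attention embedding.

The attention matrix is treated like a small expression matrix: library-size
normalized to 1e4, log1p-transformed, PCA-reduced for neighbor graphs.
Signature ("marker") attentions per cell type come from one-vs-rest Wilcoxon
rank-sum tests with Benjamini-Hochberg correction; sub-clusters come from
Louvain community detection on a kNN graph at resolution 0.3; and a token's
signal is traced back to genes via the mean absolute masked embedding weight
across the m embedding dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests

from .inference import AttentionEmbedding
from .model import ModelState


def preprocess_attention(
    a: AttentionEmbedding | np.ndarray,
    size_factor: float = 1e4,
    n_pcs: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize attention rows to ``size_factor``, log1p, then PCA.

    Returns (processed matrix, PC scores).  The PC count defaults to
    min(50, k - 1, cells - 1).  All-zero rows stay zero with a warning.
    """
    values = a.values if isinstance(a, AttentionEmbedding) else np.asarray(a, dtype=float)
    if (values < 0).any():
        raise ValueError("attention scores must be non-negative")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero attention row(s) left as zeros")
    processed = np.log1p(values * (size_factor / np.where(zero, 1.0, totals))[:, None])
    n_cells, k = processed.shape
    if n_pcs is None:
        n_pcs = min(50, k - 1, n_cells - 1)
    n_pcs = max(1, min(n_pcs, k, n_cells - 1))
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(processed)
    return processed, pcs


def rank_attentions(
    a: AttentionEmbedding,
    groups: np.ndarray,
    preprocess: bool = True,
    bh_scope: str = "per_group",
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum test per (cell type, token).

    Returns a tidy table with columns group, token, statistic, pvalue,
    pvalue_adj (BH within each group across tokens, or globally with
    ``bh_scope="global"``), direction, and rank (by statistic, descending).
    """
    groups = np.asarray(groups).astype(str)
    if groups.shape[0] != a.values.shape[0]:
        raise ValueError("one group label per cell required")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with <2 cells: {list(small.index)}")
    values = preprocess_attention(a)[0] if preprocess else a.values
    rows = []
    for group in uniq:
        in_g = groups == group
        x, y = values[in_g], values[~in_g]
        stats = np.empty(values.shape[1])
        pvals = np.empty(values.shape[1])
        # exact U distribution when cheap and tie-free; normal approx otherwise
        for j in range(values.shape[1]):
            if np.ptp(values[:, j]) == 0:  # constant token: no discrimination
                stats[j], pvals[j] = x.shape[0] * y.shape[0] / 2.0, 1.0
                continue
            small = x.shape[0] * y.shape[0] <= 400
            ties = len(np.unique(values[:, j])) < values.shape[0]
            method = "exact" if small and not ties else "asymptotic"
            stats[j], pvals[j] = mannwhitneyu(
                x[:, j], y[:, j], alternative="two-sided", method=method
            )
        if bh_scope == "per_group":
            padj = multipletests(pvals, method="fdr_bh")[1]
        else:
            padj = pvals  # adjusted globally below
        direction = np.where(
            x.mean(axis=0) >= y.mean(axis=0), "up", "down"
        )
        order = np.argsort(-stats, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        for j, name in enumerate(a.set_names):
            rows.append(
                dict(group=group, token=name, statistic=stats[j], pvalue=pvals[j],
                     pvalue_adj=padj[j], direction=direction[j], rank=int(rank[j]))
            )
    table = pd.DataFrame(rows)
    if bh_scope == "global":
        table["pvalue_adj"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    return table


def subcluster(
    a: AttentionEmbedding,
    cell_subset: np.ndarray | None = None,
    resolution: float = 0.3,
    n_neighbors: int = 15,
    n_pcs: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Louvain sub-clusters of a cell subset in attention space.

    The subset is re-normalized and log-transformed alone, PCA-reduced, a
    kNN graph is built on the PCs, and igraph's multilevel (Louvain)
    community detection runs at the given resolution with a seeded RNG.
    Returns integer cluster labels for the subset cells.
    """
    import igraph
    import random as _random

    values = a.values if cell_subset is None else a.values[np.asarray(cell_subset)]
    if values.shape[0] < 10:
        raise ValueError(f"subset has {values.shape[0]} cells; need >= 10")
    _, pcs = preprocess_attention(values, n_pcs=n_pcs)
    knn = kneighbors_graph(
        pcs, n_neighbors=min(n_neighbors, values.shape[0] - 1), mode="connectivity"
    )
    knn = knn.maximum(knn.T)  # symmetrize
    sources, targets = knn.nonzero()
    keep = sources < targets
    graph = igraph.Graph(
        n=values.shape[0], edges=list(zip(sources[keep], targets[keep]))
    )
    igraph.set_random_number_generator(_random.Random(seed))
    try:
        communities = graph.community_multilevel(resolution=resolution)
    finally:
        igraph.set_random_number_generator(_random)
    return np.asarray(communities.membership, dtype=int)


@dataclass
class GeneImportance:
    token: str
    table: pd.DataFrame  # columns: gene, importance; sorted descending


def gene_importance(state: ModelState, token: str) -> GeneImportance:
    """Rank a token's member genes by mean |masked embedding weight|.

    importance_i = (1/m) * sum_d |W'[i, token, d]|; off-mask genes have
    exactly zero importance and are omitted from the ranking.
    """
    if token not in state.mask.set_names:
        raise KeyError(f"unknown token {token!r}")
    j = state.mask.set_names.index(token)
    scores = np.abs(state.effective_embedding()[:, j, :]).mean(axis=1)
    members = state.mask.values[:, j] == 1
    table = pd.DataFrame(
        {
            "gene": np.asarray(state.mask.gene_names.names)[members],
            "importance": scores[members],
        }
    ).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    return GeneImportance(token=token, table=table)
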