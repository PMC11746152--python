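"""Cell-level QC, normalization, embedding, clustering and marker ranking.

The typing contract upstream of every analysis: cells failing the volume or
transcript-count cutoffs are removed, counts are scaled to the median
library size and log2 transformed, sequencing depth is regressed out per
gene, the standardized residuals are projected onto principal components,
and cells are clustered on a k-nearest-neighbour graph with a seeded
modularity-style partition.  Batch integration is a pluggable hook with an
identity default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .config import AnalysisThresholds

__all__ = [
    "qc_filter_cells", "normalize_log", "embed_cells", "cluster_cells",
    "rank_markers", "drop_contaminated_subclusters",
]


def qc_filter_cells(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
):
    """Drop cells with volume above or transcript count below the cutoffs.

    Both inequalities are strict, so a cell at exactly the volume cutoff or
    exactly the minimum transcript count is retained.  Idempotent.
    """
    thresholds = thresholds or AnalysisThresholds()
    total = counts.sum(axis=1).to_numpy()
    keep = ~(
        (cells["volume"].to_numpy() > thresholds.max_cell_volume)
        | (total < thresholds.min_transcripts_per_cell)
    )
    cells_f = cells.loc[keep].reset_index(drop=True)
    counts_f = counts.loc[keep]
    cells_f = cells_f.assign(total_transcripts=counts_f.sum(axis=1).to_numpy())
    return cells_f, counts_f


def normalize_log(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell to the median library size, then log2(1 + x).

    All-zero cells stay all-zero.  Raises on an all-zero matrix (no usable
    library size).
    """
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    nonzero = lib > 0
    if not nonzero.any():
        raise ValueError("all-zero count matrix cannot be normalized")
    target = float(np.median(lib[nonzero]))
    factor = np.zeros_like(lib)
    factor[nonzero] = target / lib[nonzero]
    vals = counts.to_numpy(dtype=float) * factor[:, None]
    return pd.DataFrame(np.log2(1.0 + vals), index=counts.index, columns=counts.columns)


def embed_cells(
    norm: pd.DataFrame,
    cells: pd.DataFrame,
    n_pcs: int = 20,
    integrate=None,
) -> np.ndarray:
    """Depth-regressed, scaled PCA embedding of normalized expression.

    Per gene, a univariate least-squares fit on total_transcripts is removed
    (residuals are exactly orthogonal to depth), residuals are standardized,
    and the top ``n_pcs`` principal components are returned in order of
    decreasing explained variance.  ``integrate(embedding, cells)`` may
    adjust the result per batch; the default is the identity.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs > norm.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds the number of genes {norm.shape[1]}")
    Y = norm.to_numpy(dtype=float)
    t = cells["total_transcripts"].to_numpy(dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom > 0:
        slope = (tc @ (Y - Y.mean(axis=0))) / denom
        Y = Y - Y.mean(axis=0) - np.outer(tc, slope)
    else:
        Y = Y - Y.mean(axis=0)
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    Y = Y / sd
    n_pcs = min(n_pcs, min(Y.shape) - 1) or 1
    emb = PCA(n_components=n_pcs, svd_solver="full", random_state=0).fit_transform(Y)
    if integrate is not None:
        emb = integrate(emb, cells)
    return emb


def cluster_cells(embedding: np.ndarray, seed: int = 0, resolution: float = 1.0,
                  n_neighbors: int = 15) -> np.ndarray:
    """Leiden community detection on a k-nearest-neighbour graph.

    Deterministic for a fixed seed.  Returns integer labels 0..K-1.
    """
    import igraph
    import leidenalg

    embedding = np.asarray(embedding, dtype=float)
    if len(embedding) < 2:
        raise ValueError("need at least 2 cells to cluster")
    if not np.isfinite(embedding).all():
        raise ValueError("embedding contains non-finite values")
    k = min(n_neighbors, len(embedding) - 1)
    adj = kneighbors_graph(embedding, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=len(embedding), edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def rank_markers(norm: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster marker table by two-sided Wilcoxon rank-sum vs rest.

    BH adjustment is applied within each cluster; genes are ranked by the
    rank-sum z statistic (most upregulated first).
    """
    from .de import bh_adjust

    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("marker ranking needs at least 2 clusters")
    Y = norm.to_numpy(dtype=float)
    rows = []
    for cl in clusters:
        mask = labels == cl
        a, b = Y[mask], Y[~mask]
        stat, p = stats.ranksums(a, b, axis=0)
        stat = np.nan_to_num(stat, nan=0.0)
        p = np.nan_to_num(p, nan=1.0)
        p_adj = bh_adjust(p)
        order = np.argsort(-stat, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        for j, gene in enumerate(norm.columns):
            rows.append({
                "cluster": cl, "gene": gene, "statistic": float(stat[j]),
                "p": float(p[j]), "p_adj": float(p_adj[j]),
                "direction": "up" if stat[j] > 0 else "down",
                "rank": int(rank[j]),
            })
    return pd.DataFrame(rows)


def drop_contaminated_subclusters(
    labels,
    markers: pd.DataFrame,
    atlas: pd.DataFrame,
    host_type: str,
    top_n: int = 10,
    min_foreign: int = 2,
):
    """Exclude subclusters whose top markers belong to a different cell type.

    A subcluster is flagged as contaminated when at least ``min_foreign`` of
    its ``top_n`` top-ranked markers are atlas-annotated as exclusive to a
    major cell type other than ``host_type``.  Returns the filtered label
    array (excluded cells set to -1) and an exclusion report.
    """
    if host_type not in set("|".join(atlas["expressed_in"]).split("|")):
        raise ValueError(f"host type {host_type!r} not present in atlas annotation")
    exclusive = atlas.set_index("gene")["exclusive_to"].to_dict()
    labels = np.asarray(labels)
    report = {}
    out = labels.copy()
    for cl in np.unique(labels):
        top = markers[(markers["cluster"] == cl) & (markers["rank"] <= top_n)]
        foreign = [
            g for g in top["gene"]
            if exclusive.get(g, "") not in ("", host_type)
        ]
        if len(foreign) >= min_foreign:
            report[cl] = sorted(foreign)
            out[labels == cl] = -1
    return out, report
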