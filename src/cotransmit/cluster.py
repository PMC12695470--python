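"""Neighbor-graph clustering, modularity, marker AUC and resolution selection.

The resolution of the Leiden partition is chosen by a dual criterion:

* **plateau** — sweep resolutions (default 0.1..1.0 step 0.1), record the
  Newman-Girvan modularity Q of each partition, and take the smallest
  resolution where the Q increase to the next resolution drops below a
  fraction (default 0.1) of the largest per-step increase;
* **marker validity** — a resolution is *valid* when every one of its
  clusters still has at least one marker gene with cluster-vs-rest
  AUC > 0.6 (after the min.pct / log-FC pre-filters); the maximum valid
  resolution is the largest prefix of the sweep that stays valid.

The chosen resolution is the smaller of the two, so the AUC criterion caps
over-splitting. Q is always reported at unit gamma so values are comparable
across the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph
from sklearn.neighbors import NearestNeighbors

from cotransmit.errors import CotransmitError
from cotransmit.io_qc import Embedding, NormalizedMatrix

__all__ = [
    "NeighborGraph",
    "ResolutionSweep",
    "ResolutionChoice",
    "build_knn_graph",
    "cluster_sweep",
    "modularity_q",
    "marker_stats",
    "select_resolution",
    "cluster_similarity",
]


@dataclass
class NeighborGraph:
    """Symmetric weighted kNN graph without self-loops."""

    adjacency: sparse.csr_matrix  # symmetric, zero diagonal
    k: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_components(self) -> int:
        return int(csgraph.connected_components(self.adjacency, directed=False)[0])

    def to_igraph(self) -> ig.Graph:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        g = ig.Graph(
            n=self.n_nodes,
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        return g


@dataclass
class ResolutionSweep:
    resolutions: np.ndarray
    labels: dict[float, np.ndarray]
    n_clusters: dict[float, int]
    modularity: dict[float, float]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resolution": self.resolutions,
                "n_clusters": [self.n_clusters[r] for r in self.resolutions],
                "modularity_q": [self.modularity[r] for r in self.resolutions],
            }
        )


@dataclass
class ResolutionChoice:
    chosen_resolution: float
    plateau_candidate: float
    max_valid_resolution: float
    validity: dict[float, bool]
    rationale: str


def build_knn_graph(embedding: Embedding, k: int = 20) -> NeighborGraph:
    """k-nearest-neighbor graph with shared-neighbor (Jaccard) edge weights.

    Neighbor sets include the node itself, so every kNN edge has weight
    >= 1/(2k+1); symmetrization is by union, so every node keeps at least
    k neighbors.
    """
    X = embedding.coordinates
    n = X.shape[0]
    if k >= n:
        raise CotransmitError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    indices = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([np.c_[np.arange(n), indices].ravel()])
    # A: n x n boolean "j is in i's neighbor set (incl self)"
    A = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    A.data[:] = 1.0  # collapse duplicates
    E = A.maximum(A.T)  # union-symmetrized edge support (incl diagonal)
    inter = (A @ A.T).multiply(E)  # shared-neighbor counts on supported pairs
    inter = inter.tocoo()
    union = 2.0 * (k + 1) - inter.data
    W = sparse.csr_matrix((inter.data / union, (inter.row, inter.col)), shape=(n, n))
    W.setdiag(0.0)
    W.eliminate_zeros()
    W = W.maximum(W.T)
    return NeighborGraph(adjacency=W, k=k)


def modularity_q(graph: NeighborGraph, labels: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity Q = sum_c [w_in,c/W - (deg_c/2W)^2]."""
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_nodes:
        raise CotransmitError(
            f"labels cover {labels.shape[0]} nodes but graph has {graph.n_nodes}"
        )
    A = graph.adjacency
    two_w = A.sum()
    if two_w == 0:
        return 0.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    _, inv = np.unique(labels, return_inverse=True)
    k = inv.max() + 1
    S = sparse.csr_matrix(
        (np.ones(labels.size), (np.arange(labels.size), inv)), shape=(labels.size, k)
    )
    intra = np.asarray((S.T @ A @ S).diagonal())  # counts both triangles
    deg_c = S.T @ deg
    return float(np.sum(intra / two_w - (deg_c / two_w) ** 2))


def cluster_sweep(
    graph: NeighborGraph,
    resolutions=None,
    seed: int = 0,
) -> ResolutionSweep:
    """Leiden partitions (RB-configuration objective) over a resolution sweep."""
    if graph.n_nodes == 0:
        raise CotransmitError("cannot cluster an empty graph")
    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 1.01, 0.1), 10)
    resolutions = np.asarray(sorted(float(r) for r in resolutions))
    if len(resolutions) != len(set(resolutions)):
        raise CotransmitError("resolutions must be strictly increasing")
    g = graph.to_igraph()
    weights = g.es["weight"] if g.ecount() else None
    labels: dict[float, np.ndarray] = {}
    n_clusters: dict[float, int] = {}
    modularity: dict[float, float] = {}
    for r in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=float(r),
            seed=seed,
            n_iterations=2,
        )
        memb = np.asarray(part.membership)
        labels[r] = memb
        n_clusters[r] = int(memb.max() + 1)
        modularity[r] = modularity_q(graph, memb)
    return ResolutionSweep(
        resolutions=resolutions,
        labels=labels,
        n_clusters=n_clusters,
        modularity=modularity,
        seed=seed,
    )


def marker_stats(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    cluster,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
) -> pd.DataFrame:
    """Cluster-vs-rest marker statistics for one cluster.

    Genes are tested when expressed in at least ``min_pct`` of the in- or
    out-group and the absolute log fold change (difference of
    ``ln(1 + mean(expm1 x))``) is at least ``logfc_min``. For tested genes:
    two-sided rank-sum p (asymptotic, tie-corrected), AUC = U/(n_in*n_out)
    with midranks, and a Bonferroni adjustment whose multiplier is the
    number of genes tested for this cluster.
    """
    labels = np.asarray(labels)
    in_mask = labels == cluster
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise CotransmitError(
            f"cluster {cluster!r} needs >=3 cells inside and outside "
            f"(has {n_in} / {n_out})"
        )
    X = norm.values
    pct_in = np.asarray((X[:, in_mask] > 0).mean(axis=1)).ravel()
    pct_out = np.asarray((X[:, ~in_mask] > 0).mean(axis=1)).ravel()
    mean_in = np.asarray(X[:, in_mask].expm1().mean(axis=1)).ravel()
    mean_out = np.asarray(X[:, ~in_mask].expm1().mean(axis=1)).ravel()
    log_fc = np.log1p(mean_in) - np.log1p(mean_out)
    tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (np.abs(log_fc) >= logfc_min)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene", "auc", "log_fc", "pct_in", "pct_out", "p_value", "p_adj"]
        )
    dense = np.asarray(X[idx].todense())
    res = stats.mannwhitneyu(
        dense[:, in_mask], dense[:, ~in_mask], axis=1, method="asymptotic"
    )
    auc = res.statistic / (n_in * n_out)
    p = res.pvalue
    out = pd.DataFrame(
        {
            "gene": norm.gene_ids[idx],
            "auc": auc,
            "log_fc": log_fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p_value": p,
            "p_adj": np.minimum(1.0, p * idx.size),
        }
    )
    out.attrs["n_tested"] = int(idx.size)
    out.attrs["bonferroni_multiplier"] = int(idx.size)
    return out.sort_values("auc", ascending=False, kind="mergesort").reset_index(drop=True)


def _resolution_valid(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    auc_threshold: float,
    min_pct: float,
    logfc_min: float,
) -> bool:
    """Every cluster has >=1 pre-filter-passing marker with AUC > threshold.

    A single-cluster partition is vacuously valid (there is no "rest" to
    discriminate against); a cluster too small to test (<3 cells either
    side) makes the resolution invalid.
    """
    uniq = np.unique(labels)
    if uniq.size == 1:
        return True
    for cluster in uniq:
        n_in = int((labels == cluster).sum())
        if n_in < 3 or labels.size - n_in < 3:
            return False
        ms = marker_stats(norm, labels, cluster, min_pct=min_pct, logfc_min=logfc_min)
        if ms.empty or not (ms["auc"] > auc_threshold).any():
            return False
    return True


def select_resolution(
    sweep: ResolutionSweep,
    norm: NormalizedMatrix,
    auc_threshold: float = 0.6,
    plateau_frac: float = 0.1,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
) -> ResolutionChoice:
    """Dual-criterion resolution choice: min(plateau candidate, max valid).

    ``max_valid_resolution`` is the largest resolution r such that every
    resolution up to and including r is marker-valid; the plateau candidate
    is the smallest resolution whose Q increase to the next one falls below
    ``plateau_frac`` times the largest increase over the sweep (the last
    resolution when no step qualifies, the first when Q never increases).
    """
    res = sweep.resolutions
    validity = {
        float(r): _resolution_valid(norm, sweep.labels[r], auc_threshold, min_pct, logfc_min)
        for r in res
    }
    max_valid = None
    for r in res:
        if validity[float(r)]:
            max_valid = float(r)
        else:
            break
    if max_valid is None:
        raise CotransmitError(
            "no resolution in the sweep is marker-valid; lower the sweep range "
            "or the AUC threshold"
        )
    q = np.array([sweep.modularity[r] for r in res])
    dq = np.diff(q)
    if dq.size == 0:
        plateau = float(res[0])
    else:
        max_dq = dq.max()
        if max_dq <= 0:
            plateau = float(res[0])
        else:
            below = np.flatnonzero(dq < plateau_frac * max_dq)
            plateau = float(res[below[0]]) if below.size else float(res[-1])
    chosen = min(plateau, max_valid)
    rationale = (
        f"plateau candidate {plateau} (dQ < {plateau_frac} * max dQ rule), "
        f"max marker-valid resolution {max_valid} (every cluster keeps a marker "
        f"with AUC > {auc_threshold}); chosen = min = {chosen}"
    )
    return ResolutionChoice(
        chosen_resolution=chosen,
        plateau_candidate=plateau,
        max_valid_resolution=max_valid,
        validity=validity,
        rationale=rationale,
    )


def cluster_similarity(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    conditions: np.ndarray,
    flag_below: float = 0.8,
) -> dict[str, pd.DataFrame]:
    """Pearson correlation of mean whole-transcriptome profiles between clusters.

    Computed within each condition; a cluster with no cells in a condition
    yields NaN rows (marked missing) rather than an error. Pairs with
    r < ``flag_below`` are listed in ``attrs["low_similarity_pairs"]``.
    """
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    clusters = list(pd.unique(labels))
    out: dict[str, pd.DataFrame] = {}
    X = norm.values
    for cond in pd.unique(conditions):
        profiles = np.full((len(clusters), norm.values.shape[0]), np.nan)
        for i, cl in enumerate(clusters):
            mask = (labels == cl) & (conditions == cond)
            if mask.any():
                profiles[i] = np.asarray(X[:, mask].mean(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(profiles)
        mat = pd.DataFrame(corr, index=clusters, columns=clusters)
        np.fill_diagonal(mat.values, [1.0 if not np.isnan(profiles[i]).all() else np.nan for i in range(len(clusters))])
        low = [
            (clusters[i], clusters[j], float(mat.iat[i, j]))
            for i in range(len(clusters))
            for j in range(i + 1, len(clusters))
            if np.isfinite(mat.iat[i, j]) and mat.iat[i, j] < flag_below
        ]
        mat.attrs["low_similarity_pairs"] = low
        out[cond] = mat
    return out
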