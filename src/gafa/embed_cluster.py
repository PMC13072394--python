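"""Batch-aware embedding, kNN graph, Leiden clustering, NK gating, markers.

The embedding stage is specified as a contract rather than an
architecture: it must produce a cells x d latent matrix that mixes
batches better than an embedding ignoring the batch covariate.  The
mandatory deterministic backend ("linear") centers genes within each
batch and applies a truncated SVD; a VAE backend would satisfy the same
contract but is not shipped.

Clustering is Leiden community detection (RB-configuration modularity)
on a max-symmetrized Euclidean kNN graph with a Gaussian connectivity
kernel.  Cluster ids are relabeled by decreasing cluster size so they
are stable across runs with the same seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io_qc import NormalizedMatrix

__all__ = [
    "LatentEmbedding",
    "NeighborGraph",
    "ClusterLabels",
    "embed_batch_aware",
    "build_knn_graph",
    "leiden_cluster",
    "gene_set_score",
    "identify_nk_clusters",
    "rank_marker_genes",
    "differential_expression",
    "batch_mixing_score",
]


@dataclass
class LatentEmbedding:
    coords: np.ndarray  # cells x d
    backend: str = "linear"
    batch_key: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite values")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    adjacency: sp.csr_matrix  # symmetric, weights in [0, 1], no self-loops
    k: int = 15
    distances: sp.csr_matrix | None = None


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-cell int, 0..n_clusters-1
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cluster_ids(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())


def embed_batch_aware(
    x: NormalizedMatrix | np.ndarray,
    batches: np.ndarray | None = None,
    d: int = 20,
    backend: str = "linear",
    seed: int = 0,
) -> LatentEmbedding:
    """Latent embedding with the batch covariate regressed out.

    Linear backend: per-batch gene centering followed by truncated SVD
    to ``d`` components, fully deterministic given ``seed``.  With a
    single batch (or ``batches=None``) this reduces to plain truncated
    SVD of the globally centered matrix.
    """
    if backend != "linear":
        raise NotImplementedError(
            f"backend {backend!r} not available; the deterministic 'linear' backend is mandatory"
        )
    dense = x.dense() if isinstance(x, NormalizedMatrix) else np.asarray(x, dtype=float)
    n_cells, n_genes = dense.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells to embed")
    if d >= n_genes:
        raise ValueError(f"d={d} must be < n_genes={n_genes}")

    centered = dense.copy()
    if batches is None:
        centered -= centered.mean(axis=0, keepdims=True)
        batch_key = None
    else:
        batches = np.asarray(batches)
        for b in np.unique(batches):
            mask = batches == b
            centered[mask] -= centered[mask].mean(axis=0, keepdims=True)
        batch_key = "batch"
    svd = TruncatedSVD(n_components=d, algorithm="randomized", random_state=seed)
    coords = svd.fit_transform(centered)
    return LatentEmbedding(coords=coords, backend="linear", batch_key=batch_key)


def _knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k nearest neighbors (self excluded)."""
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean")
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    return idx[:, 1:], dist[:, 1:]


def build_knn_graph(e: LatentEmbedding, k: int = 15) -> NeighborGraph:
    """Euclidean kNN graph, max-symmetrized, Gaussian connectivity weights.

    Edge weight = exp(-d_ij^2 / (sigma_i * sigma_j)) with local scale
    sigma_i = distance to the k-th neighbor (Zelnik-Manor/Perona style),
    so weights lie in (0, 1].
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    n = e.coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    idx, dist = _knn(e.coords, k)
    sigma = np.maximum(dist[:, -1], 1e-12)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    adj = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)
    adj.setdiag(0)
    adj.eliminate_zeros()
    dmat = sp.csr_matrix((dist.ravel(), (rows, cols)), shape=(n, n))
    dmat = dmat.maximum(dmat.T)
    return NeighborGraph(adjacency=adj, k=k, distances=dmat)


def leiden_cluster(
    g: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterLabels:
    """Leiden partition of the neighbor graph (RB-configuration modularity).

    Deterministic given the seed; cluster ids are assigned by
    decreasing cluster size (ties broken by smallest member index).
    """
    adj = sp.triu(g.adjacency, format="coo")
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    graph = ig.Graph(
        n=adj.shape[0],
        edges=list(zip(adj.row.tolist(), adj.col.tolist())),
        edge_attrs={"weight": adj.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    return ClusterLabels(labels=labels, resolution=resolution, seed=seed)


def gene_set_score(x: NormalizedMatrix, genes: list[str]) -> np.ndarray:
    """Per-cell mean of z-scored expression over a gene set.

    A simple signature score (e.g. for cell-cycle gene sets used as
    integration diagnostics); no correction is performed with it.
    """
    cols = x.gene_index(list(genes))
    vals = np.asarray(x.values[:, cols].todense())
    mean = vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return ((vals - mean) / sd).mean(axis=1)


def identify_nk_clusters(
    x: NormalizedMatrix,
    labels: ClusterLabels,
    markers: tuple[str, ...] = ("NCAM1", "FCGR3A"),
    quantile: float = 0.75,
) -> set[int]:
    """Flag clusters with high mean z-scored marker expression.

    A cluster is NK-flagged when its mean marker score reaches the
    ``quantile`` threshold across clusters and is positive.  Returns the
    empty set (with a warning) if no cluster qualifies.
    """
    score = gene_set_score(x, list(markers))  # raises listing missing genes
    cluster_score = {c: score[labels.labels == c].mean() for c in labels.cluster_ids()}
    cutoff = np.quantile(list(cluster_score.values()), quantile)
    flagged = {c for c, s in cluster_score.items() if s >= cutoff and s > 0}
    if not flagged:
        warnings.warn("no cluster passed the NK marker score threshold")
    return flagged


def differential_expression(
    values: np.ndarray, in_group: np.ndarray, eps: float = 1e-9
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of one cell group against the rest.

    ``values`` are log1p-normalized (cells x genes).  logFC is
    log2((mean expm1 in-group + eps) / (mean expm1 rest + eps)); p-values
    are two-sided Mann-Whitney (exact for small untied samples), BH
    adjusted across genes.
    """
    in_group = np.asarray(in_group, dtype=bool)
    a, b = values[in_group], values[~in_group]
    with np.errstate(over="ignore"):
        mean_a = np.expm1(a).mean(axis=0)
        mean_b = np.expm1(b).mean(axis=0)
    logfc = np.log2((mean_a + eps) / (mean_b + eps))
    res = mannwhitneyu(a, b, axis=0, alternative="two-sided", method="auto")
    pvals = np.atleast_1d(res.pvalue)
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"logFC": logfc, "p_value": pvals, "p_adj": p_adj})


def rank_marker_genes(x: NormalizedMatrix, labels: ClusterLabels) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker statistics per cluster.

    Returns rows (gene, cluster, logFC, p_value, p_adj) with BH
    adjustment within each cluster's gene list.  Clusters of size 1 are
    skipped with a warning.
    """
    if labels.n_clusters < 2:
        raise ValueError("need at least 2 clusters for marker ranking")
    dense = x.dense()
    tables = []
    for c in labels.cluster_ids():
        mask = labels.labels == c
        if mask.sum() < 2:
            warnings.warn(f"cluster {c} has fewer than 2 cells; skipped")
            continue
        tab = differential_expression(dense, mask)
        tab.insert(0, "cluster", c)
        tab.insert(0, "gene", x.gene_ids)
        tables.append(tab.sort_values("logFC", ascending=False, kind="stable"))
    return pd.concat(tables, ignore_index=True)


def batch_mixing_score(
    e: LatentEmbedding, batches: np.ndarray, k: int = 15
) -> float:
    """Mean normalized Shannon entropy of batch labels among k neighbors.

    1 means batches are perfectly interleaved in the latent space, 0
    means each neighborhood is single-batch.  A single batch scores 1.0
    by convention (with a warning).
    """
    batches = np.asarray(batches)
    uniq = np.unique(batches)
    if len(uniq) < 2:
        warnings.warn("single batch; mixing score defined as 1.0")
        return 1.0
    idx, _ = _knn(e.coords, k)
    codes = np.searchsorted(uniq, batches)
    neigh = codes[idx]  # cells x k
    ent = np.zeros(len(codes))
    for b in range(len(uniq)):
        p = (neigh == b).mean(axis=1)
        nz = p > 0
        ent[nz] -= p[nz] * np.log(p[nz])
    return float(np.mean(ent / np.log(len(uniq))))
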