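"""Diffusion maps, diffusion pseudotime (DPT), lineages and occupancy stats.

The manifold is modeled as a kNN graph with a locally scaled Gaussian
kernel.  Density effects are removed with the anisotropic
normalization at exponent 1 (Coifman-Lafon), and the spectrum of the
resulting Markov transition operator is obtained through its symmetric
conjugate.  DPT distance of a cell from the root is the Euclidean norm
over nontrivial components of (lambda/(1-lambda)) * (psi(cell) -
psi(root)), min-max scaled to [0, 1].

Lineages are cluster paths: cells in the clusters shared by two paths
belong to both lineages; a terminal cluster's cells belong only to its
own lineage.  Occupancy profiles bin each outcome group's lineage cells
over equal-width pseudotime intervals; group differences are tested
with Mann-Whitney U (exact for small samples) and Kruskal-Wallis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import kruskal, mannwhitneyu

from .embed_cluster import ClusterLabels, LatentEmbedding, NeighborGraph, build_knn_graph

__all__ = [
    "DiffusionMap",
    "PseudotimeAssignment",
    "OccupancyProfile",
    "compute_diffusion_map",
    "compute_dpt",
    "assign_lineages",
    "lineage_pseudotime",
    "branch_occupancy",
    "compare_occupancy",
    "DEFAULT_LINEAGE_MAP",
]

#: cluster paths of the two lineages: maturation 5->0->1, cytotoxic 5->0->3
DEFAULT_LINEAGE_MAP: dict[str, list[int]] = {"L501": [5, 0, 1], "L503": [5, 0, 3]}


@dataclass
class DiffusionMap:
    eigenvalues: np.ndarray  # nontrivial, descending
    eigenvectors: np.ndarray  # cells x n_comps (psi, density-corrected)
    provenance: dict = field(default_factory=dict)


@dataclass
class PseudotimeAssignment:
    pseudotime: dict[str, np.ndarray]  # lineage -> per-cell values, NaN off-lineage
    membership: dict[str, np.ndarray]  # lineage -> boolean mask
    root_cluster: int
    root_cell: int
    dpt: np.ndarray  # global DPT before per-lineage rescaling


@dataclass
class OccupancyProfile:
    lineage: str
    bin_edges: np.ndarray
    fractions: pd.DataFrame  # rows = groups, cols = bins; each row sums to 1
    smoothed: pd.DataFrame


def _kernel_from_embedding(e: LatentEmbedding, k: int) -> sp.csr_matrix:
    g = build_knn_graph(e, k=k)
    return g.adjacency


def compute_diffusion_map(
    e: LatentEmbedding | NeighborGraph, n_comps: int = 15, k: int = 15
) -> DiffusionMap:
    """Spectral decomposition of the density-corrected diffusion operator."""
    if isinstance(e, NeighborGraph):
        K = e.adjacency.copy()
    else:
        K = _kernel_from_embedding(e, k)
    n = K.shape[0]
    if n_comps >= n:
        raise ValueError(f"n_comps={n_comps} must be < n_cells={n}")
    n_comp_graph, _ = connected_components(K, directed=False)
    if n_comp_graph > 1:
        warnings.warn(
            f"neighbor graph has {n_comp_graph} connected components; "
            "pseudotime is only meaningful within the root's component"
        )

    # anisotropic normalization, exponent 1: K' = K / (q_i q_j)
    q = np.asarray(K.sum(axis=1)).ravel()
    q[q == 0] = 1.0
    Dq = sp.diags(1.0 / q)
    K1 = Dq @ K @ Dq
    d = np.asarray(K1.sum(axis=1)).ravel()
    d[d == 0] = 1.0
    Dhalf = sp.diags(1.0 / np.sqrt(d))
    S = Dhalf @ K1 @ Dhalf  # symmetric conjugate of the transition matrix

    if n <= 200:  # dense path: exact and handles tiny graphs
        evals_all, evecs_all = np.linalg.eigh(S.toarray())
        order = np.argsort(evals_all)[::-1][: n_comps + 1]
        evals, evecs = evals_all[order], evecs_all[:, order]
    else:
        k_eig = min(n_comps + 1, n - 1)
        v0 = np.full(n, 1.0 / np.sqrt(n))  # fixed start vector: deterministic ARPACK
        evals, evecs = sp.linalg.eigsh(S, k=k_eig, which="LA", v0=v0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    # sign convention: largest-|.| entry of each eigenvector is positive
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1
    psi = (Dhalf @ evecs)  # right eigenvectors of the transition matrix
    # normalize each psi to unit norm under the stationary-distribution weight
    pi = d / d.sum()
    norms = np.sqrt((pi[:, None] * psi**2).sum(axis=0))
    norms[norms == 0] = 1.0
    psi = psi / norms
    # drop the trivial (constant, lambda=1) component
    return DiffusionMap(
        eigenvalues=evals[1 : n_comps + 1],
        eigenvectors=psi[:, 1 : n_comps + 1],
        provenance={
            "kernel": "gaussian, local scaling (k-th neighbor)",
            "anisotropy_exponent": 1,
            "k": k if isinstance(e, LatentEmbedding) else e.k,
            "n_comps": n_comps,
        },
    )


def compute_dpt(dm: DiffusionMap, root_cells: np.ndarray) -> tuple[np.ndarray, int]:
    """Diffusion pseudotime from a root population.

    The representative root is the member cell with the extremal first
    diffusion component (farthest from the overall median, i.e. an
    endpoint of the dominant axis).  Components with eigenvalue >= 1
    are dropped with a warning.  Returns (pseudotime scaled to [0, 1],
    root cell index).
    """
    root_cells = np.asarray(root_cells)
    if root_cells.dtype == bool:
        root_cells = np.flatnonzero(root_cells)
    if root_cells.size == 0:
        raise ValueError("root_cells is empty")
    psi1 = dm.eigenvectors[:, 0]
    root = int(root_cells[np.argmax(np.abs(psi1[root_cells] - np.median(psi1)))])

    lam = dm.eigenvalues
    keep = lam < 1.0 - 1e-12
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} diffusion components with eigenvalue >= 1 dropped"
        )
    lam = lam[keep]
    psi = dm.eigenvectors[:, keep]
    scale = lam / (1.0 - lam)
    delta = (psi - psi[root]) * scale
    dpt = np.linalg.norm(delta, axis=1)
    rng = dpt.max() - dpt.min()
    if rng > 0:
        dpt = (dpt - dpt.min()) / rng
    return dpt, root


def assign_lineages(
    labels: ClusterLabels, mapping: dict[str, list[int]] | None = None
) -> dict[str, np.ndarray]:
    """Boolean lineage membership from cluster paths.

    Cells in clusters shared by several paths belong to all of them;
    cells in clusters outside every path belong to no lineage.
    """
    mapping = mapping or DEFAULT_LINEAGE_MAP
    present = set(labels.cluster_ids())
    for lin, clusters in mapping.items():
        missing = [c for c in clusters if c not in present]
        if missing:
            raise ValueError(f"lineage {lin} references missing clusters {missing}")
    return {
        lin: np.isin(labels.labels, clusters) for lin, clusters in mapping.items()
    }


def lineage_pseudotime(
    dpt: np.ndarray,
    membership: dict[str, np.ndarray],
    root_cluster: int,
    root_cell: int,
) -> PseudotimeAssignment:
    """Min-max rescale global DPT within each lineage; NaN off-lineage."""
    pseudotime: dict[str, np.ndarray] = {}
    for lin, mask in membership.items():
        pt = np.full(len(dpt), np.nan)
        vals = dpt[mask]
        rng = vals.max() - vals.min() if vals.size else 0.0
        pt[mask] = (dpt[mask] - vals.min()) / rng if rng > 0 else 0.0
        pseudotime[lin] = pt
    return PseudotimeAssignment(
        pseudotime=pseudotime,
        membership=membership,
        root_cluster=root_cluster,
        root_cell=root_cell,
        dpt=dpt,
    )


def branch_occupancy(
    pt: np.ndarray,
    groups: np.ndarray,
    n_bins: int = 10,
    smoothing_window: int = 3,
    lineage: str = "",
) -> OccupancyProfile:
    """Per-group histogram fractions over equal-width pseudotime bins.

    Each group's fractions sum to 1.  Smoothing is a centered moving
    average over bins (window 1 = raw histogram).
    """
    pt = np.asarray(pt, dtype=float)
    groups = np.asarray(groups)
    member = np.isfinite(pt)
    if not member.any():
        raise ValueError("empty lineage: no cells with finite pseudotime")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = {}
    for g in np.unique(groups[member]):
        vals = pt[member & (groups == g)]
        if vals.size == 0:
            continue
        hist, _ = np.histogram(np.clip(vals, 0, 1), bins=edges)
        rows[g] = hist / hist.sum()
    frac = pd.DataFrame(rows).T
    frac.columns = [f"bin{i}" for i in range(n_bins)]
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    smooth = frac.T.rolling(smoothing_window, center=True, min_periods=1).mean().T
    return OccupancyProfile(lineage=lineage, bin_edges=edges, fractions=frac, smoothed=smooth)


def compare_occupancy(pt: np.ndarray, groups: np.ndarray) -> dict:
    """Mann-Whitney U per group pair and a global Kruskal-Wallis test.

    Pseudotime distributions are compared between outcome groups over
    the lineage's member cells.  Exact Mann-Whitney p-values when the
    smaller sample has <= 8 cells (and no ties), normal approximation
    with tie correction otherwise.  Groups with < 2 cells are excluded
    with a warning.
    """
    pt = np.asarray(pt, dtype=float)
    groups = np.asarray(groups)
    member = np.isfinite(pt)
    samples: dict[str, np.ndarray] = {}
    for g in np.unique(groups[member]):
        vals = pt[member & (groups == g)]
        if vals.size < 2:
            warnings.warn(f"group {g!r} has fewer than 2 cells; excluded")
            continue
        samples[str(g)] = vals
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 cells")

    pairwise = {}
    for a, b in combinations(sorted(samples), 2):
        x, y = samples[a], samples[b]
        method = "exact" if min(len(x), len(y)) <= 8 else "asymptotic"
        if method == "exact" and len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
            method = "asymptotic"  # ties: exact distribution not applicable
        res = mannwhitneyu(x, y, alternative="two-sided", method=method)
        pairwise[f"{a}_vs_{b}"] = {
            "U": float(res.statistic),
            "p": float(res.pvalue),
            "n1": len(x),
            "n2": len(y),
        }
    try:
        H, p = kruskal(*samples.values())
    except ValueError:  # every observation identical: no rank variation
        H, p = 0.0, 1.0
    global_test = {"H": float(H), "p": float(p)}
    return {"pairwise": pairwise, "kruskal_wallis": global_test}
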