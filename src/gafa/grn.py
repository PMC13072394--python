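"""Prior-constrained message-passing gene regulatory network inference.

The inference follows the PANDA family of message-passing schemes: a
TF x gene prior W0 (curated TF-target evidence), a TF x TF
protein-cooperativity prior P (high-confidence PPI, combined score >=
700, scaled to [0, 1]) and a gene x gene co-expression matrix C are
iteratively reconciled.  Agreement between two evidence vectors is
measured by a continuous Tanimoto similarity

    T(x, y) = <x, y> / (||x||^2 + ||y||^2 - |<x, y>|),

applied row/column-wise.  Each iteration computes a responsibility
R = T(P, W) (does the TF's cooperativity profile explain the gene's
regulator profile?) and an availability A = T(W, C) (does the TF's
target profile explain the gene's co-expression profile?), then blends

    W <- (1 - alpha) W + alpha (R + A) / 2,

followed by multiplicative L2 shrinkage by (1 - alpha * lambda).  P
and C are co-updated toward their W-implied estimates and every matrix
is z-normalized per iteration.  alpha = 0 is an exact fixed point: the
(normalized) prior is returned unchanged.

Downstream: edge filtering (absolute-weight or top-fraction), PageRank /
out-strength / betweenness centralities on the directed TF -> gene
graph, Markov clustering (MCL) modules on the symmetrized edge graph,
outcome-bias annotation of targets from a condition DE table, regulon
activity scores, and SIF/GraphML export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PriorNetwork",
    "MessagePassingParams",
    "WeightedGRN",
    "assemble_prior",
    "compute_coexpression",
    "message_passing",
    "filter_edges",
    "compute_centralities",
    "mcl_modules",
    "annotate_outcome_bias",
    "regulon_activity",
    "export_graph",
    "read_graphml_edges",
]


@dataclass
class PriorNetwork:
    W0: np.ndarray  # TF x gene, 1/0 or weighted
    P: np.ndarray  # TF x TF symmetric, unit diagonal, scores scaled to [0, 1]
    gene_ids: list[str]
    tf_ids: list[str]

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        n_tf, n_g = self.W0.shape
        if n_tf != len(self.tf_ids) or n_g != len(self.gene_ids):
            raise ValueError("W0 dimensions inconsistent with tf_ids/gene_ids")
        if self.P.shape != (n_tf, n_tf):
            raise ValueError("P must be TF x TF")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("P must be symmetric")


@dataclass(frozen=True)
class MessagePassingParams:
    alpha: float = 0.05
    lambda_l2: float = 0.1
    n_iter: int = 150
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class WeightedGRN:
    W: np.ndarray  # refined TF x gene weights
    C: np.ndarray  # co-expression as used (possibly co-updated)
    gene_ids: list[str]
    tf_ids: list[str]
    params: MessagePassingParams
    trace: list[float] = field(default_factory=list)  # per-iteration update norm


def _read_edge_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    return df


def assemble_prior(
    tf_target_files: list[str | Path],
    ppi_file: str | Path,
    gene_universe: list[str],
    min_string_score: float = 700.0,
) -> PriorNetwork:
    """Union of curated TF-target sources + high-confidence PPI prior.

    TF-target files are 2-column TSVs (tf, target); an edge present in
    several sources still contributes W0 = 1 (idempotent union).  The
    PPI file is a 3-column STRING-dialect TSV (a, b, combined_score in
    [0, 1000]); edges below ``min_string_score`` are discarded, kept
    edges are scaled by /1000, symmetrized, with unit diagonal.
    Gene symbols are harmonized to (intersected with) the expression
    universe.
    """
    universe = set(gene_universe)
    edges: set[tuple[str, str]] = set()
    for path in tf_target_files:
        df = _read_edge_tsv(path)
        for tf, tg in df.iloc[:, :2].itertuples(index=False):
            if tg in universe:
                edges.add((str(tf), str(tg)))
    tf_ids = sorted({tf for tf, _ in edges} & universe)
    if not tf_ids:
        raise ValueError("no TF left after harmonization with the gene universe")
    gene_ids = list(gene_universe)
    gcol = {g: i for i, g in enumerate(gene_ids)}
    trow = {t: i for i, t in enumerate(tf_ids)}
    W0 = np.zeros((len(tf_ids), len(gene_ids)))
    for tf, tg in edges:
        if tf in trow:
            W0[trow[tf], gcol[tg]] = 1.0

    P = np.zeros((len(tf_ids), len(tf_ids)))
    ppi = _read_edge_tsv(ppi_file)
    if ppi.shape[1] < 3:
        raise ValueError(f"{ppi_file}: PPI file needs 3 columns (a, b, combined_score)")
    for a, b, score in ppi.iloc[:, :3].itertuples(index=False):
        if float(score) < min_string_score:
            continue
        if a in trow and b in trow:
            w = float(score) / 1000.0
            P[trow[a], trow[b]] = max(P[trow[a], trow[b]], w)
            P[trow[b], trow[a]] = P[trow[a], trow[b]]
    np.fill_diagonal(P, 1.0)
    return PriorNetwork(W0=W0, P=P, gene_ids=gene_ids, tf_ids=tf_ids)


def compute_coexpression(values: np.ndarray, cells: np.ndarray | None = None) -> np.ndarray:
    """Pearson gene-gene correlation over cells (diagonal 1).

    Zero-variance genes get zero off-diagonal correlations with a
    warning.  Requires at least 3 cells.
    """
    X = np.asarray(values, dtype=float)
    if cells is not None:
        X = X[np.asarray(cells)]
    if X.shape[0] < 3:
        raise ValueError(f"need >= 3 cells for co-expression, got {X.shape[0]}")
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} zero-variance genes: co-expression set to 0")
    Xc = X - X.mean(axis=0)
    denom = sd.copy()
    denom[const] = 1.0
    Z = Xc / denom
    C = (Z.T @ Z) / X.shape[0]
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def _znorm(M: np.ndarray) -> np.ndarray:
    sd = M.std()
    if sd == 0:
        return M - M.mean()
    return (M - M.mean()) / sd


def _tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """T[i, j] = <A[i, :], B[:, j]> / (||A[i]||^2 + ||B[:, j]||^2 - |<.,.>|)."""
    num = A @ B
    a2 = (A**2).sum(axis=1)[:, None]
    b2 = (B**2).sum(axis=0)[None, :]
    den = a2 + b2 - np.abs(num)
    den[den == 0] = 1.0
    return num / den


def message_passing(
    prior: PriorNetwork,
    C: np.ndarray,
    params: MessagePassingParams | None = None,
) -> WeightedGRN:
    """Refine the TF-target prior against PPI and co-expression evidence."""
    params = params or MessagePassingParams()
    n_tf, n_g = prior.W0.shape
    C = np.asarray(C, dtype=float)
    if C.shape != (n_g, n_g):
        raise ValueError(f"co-expression shape {C.shape} != ({n_g}, {n_g})")

    W = _znorm(prior.W0.copy())
    P = _znorm(prior.P.copy())
    Cm = _znorm(C.copy())
    trace: list[float] = []

    if params.alpha == 0:  # exact fixed point: no information flows
        trace = [0.0] * params.n_iter
        return WeightedGRN(W=W, C=Cm, gene_ids=list(prior.gene_ids),
                           tf_ids=list(prior.tf_ids), params=params, trace=trace)

    a = params.alpha
    shrink = 1.0 - a * params.lambda_l2
    for it in range(params.n_iter):
        R = _tanimoto(P, W)  # responsibility: PPI profile vs regulator profile
        A = _tanimoto(W, Cm)  # availability: target profile vs co-expression
        W_new = (1 - a) * W + a * 0.5 * (R + A)
        W_new *= shrink
        if not np.isfinite(W_new).all():
            raise FloatingPointError(f"NaN/inf in W at iteration {it}")

        # co-update P and C toward their W-implied estimates; the evidence
        # matrices are re-standardized every iteration while W itself is
        # left on the message scale (bounded by the Tanimoto kernel), which
        # keeps the update norm monotonically shrinking
        P_imp = _tanimoto(W, W.T)
        P_new = (1 - a) * P + a * 0.5 * (P_imp + P_imp.T)
        C_imp = _tanimoto(W.T, W)
        C_new = (1 - a) * Cm + a * 0.5 * (C_imp + C_imp.T)

        delta = float(np.abs(W_new - W).mean())
        trace.append(delta)
        W, P, Cm = W_new, _znorm(P_new), _znorm(C_new)
        if delta < params.tol:
            break
    return WeightedGRN(
        W=W, C=Cm, gene_ids=list(prior.gene_ids), tf_ids=list(prior.tf_ids),
        params=params, trace=trace,
    )


def filter_edges(
    grn: WeightedGRN, mode: str = "abs_threshold", value: float = 0.3
) -> pd.DataFrame:
    """Retain high-weight edges.

    ``abs_threshold`` keeps edges with |weight| > value (the usual cut
    of 0.3 corresponds to roughly the top 1.5% of weights);
    ``top_fraction`` keeps exactly ceil(value * n_edges) edges by
    |weight|, ties broken deterministically by (tf, gene) order.
    Self-pairs (a TF as its own target) are excluded.
    """
    if not np.isfinite(grn.W).all():
        raise ValueError("GRN weights contain non-finite values")
    tfs = np.repeat(grn.tf_ids, len(grn.gene_ids))
    genes = np.tile(grn.gene_ids, len(grn.tf_ids))
    weights = grn.W.ravel()
    df = pd.DataFrame({"tf": tfs, "gene": genes, "weight": weights})
    df = df[df["tf"] != df["gene"]].reset_index(drop=True)
    df["sign"] = np.sign(df["weight"]).astype(int)
    if mode == "abs_threshold":
        kept = df[df["weight"].abs() > value]
    elif mode == "top_fraction":
        if not (0 < value <= 1):
            raise ValueError("top_fraction value must be in (0, 1]")
        n_keep = int(np.ceil(value * len(df)))
        order = df.assign(absw=df["weight"].abs()).sort_values(
            ["absw", "tf", "gene"], ascending=[False, True, True], kind="stable"
        )
        kept = order.head(n_keep).drop(columns="absw")
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if kept.empty:
        warnings.warn("edge filter retained no edges")
    kept = kept.sort_values(["tf", "gene"], kind="stable").reset_index(drop=True)
    kept.attrs["retention"] = {"mode": mode, "value": value}
    return kept


def _edge_graph(edges: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    for tf, gene, w in edges[["tf", "gene", "weight"]].itertuples(index=False):
        g.add_edge(tf, gene, weight=abs(float(w)), sign=int(np.sign(w)))
    return g


def compute_centralities(edges: pd.DataFrame, tf_ids: list[str] | None = None) -> pd.DataFrame:
    """PageRank (damping 0.85), weighted out-degree and betweenness.

    Edge weights are |regulatory weight|; betweenness uses inverted
    weights as distances.  ``high_centrality`` flags TFs at or above
    the 90th percentile of TF PageRank scores.
    """
    if edges.empty:
        raise ValueError("empty edge list")
    g = _edge_graph(edges)
    pagerank = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-13, max_iter=2000)
    out_deg = dict(g.out_degree(weight="weight"))
    inv = nx.DiGraph()
    for u, v, d in g.edges(data=True):
        inv.add_edge(u, v, dist=1.0 / d["weight"] if d["weight"] > 0 else np.inf)
    betweenness = nx.betweenness_centrality(inv, weight="dist")
    tf_set = set(tf_ids) if tf_ids is not None else set(edges["tf"])
    table = pd.DataFrame(
        {
            "node": list(g.nodes),
            "pagerank": [pagerank[n] for n in g.nodes],
            "out_degree": [out_deg.get(n, 0.0) for n in g.nodes],
            "betweenness": [betweenness.get(n, 0.0) for n in g.nodes],
            "is_tf": [n in tf_set for n in g.nodes],
        }
    )
    tf_pr = table.loc[table["is_tf"], "pagerank"]
    cutoff = np.percentile(tf_pr, 90) if len(tf_pr) else np.inf
    table["high_centrality"] = table["is_tf"] & (table["pagerank"] >= cutoff)
    return table.sort_values("pagerank", ascending=False, kind="stable").reset_index(drop=True)


def mcl_modules(
    edges: pd.DataFrame,
    inflation: float = 2.2,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune: float = 1e-9,
) -> dict[str, int]:
    """Markov clustering on the symmetrized |weight| graph with self-loops.

    Alternates expansion (matrix squaring) and inflation (elementwise
    power + column normalization) to convergence; attractor rows define
    the modules, which partition the nodes of the filtered graph.
    """
    if edges.empty:
        raise ValueError("empty edge list")
    nodes = sorted(set(edges["tf"]) | set(edges["gene"]))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for tf, gene, w in edges[["tf", "gene", "weight"]].itertuples(index=False):
        i, j = idx[tf], idx[gene]
        w = abs(float(w))
        M[i, j] = max(M[i, j], w)
        M[j, i] = M[i, j]
    np.fill_diagonal(M, M.max(axis=1))  # self-loops at each node's max weight
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        M_new = M @ M  # expansion
        M_new = M_new**inflation  # inflation
        M_new[M_new < prune] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new /= colsum
        change = np.abs(M_new - M).max()
        M = M_new
        if change < tol:
            break
    else:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations (residual {change:.2e})")

    # attractor rows -> clusters; merge overlapping supports
    clusters: list[set[int]] = []
    for i in range(n):
        support = set(np.flatnonzero(M[i] > 1e-6).tolist())
        if not support:
            continue
        merged = [c for c in clusters if c & support]
        for c in merged:
            support |= c
            clusters.remove(c)
        clusters.append(support)
    assigned: dict[str, int] = {}
    clusters.sort(key=lambda c: (-len(c), min(c)))
    for mod_id, members in enumerate(clusters):
        for m in members:
            assigned.setdefault(nodes[m], mod_id)
    for node in nodes:  # isolated columns: singleton modules
        if node not in assigned:
            assigned[node] = len(set(assigned.values()))
    return assigned


def annotate_outcome_bias(
    edges: pd.DataFrame,
    de_table: pd.DataFrame,
    p_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each target gene by its condition DE direction.

    ``de_table`` must be indexed by gene with columns logFC (positive =
    up in the first condition, e.g. TFR) and p_adj.  Targets with
    logFC > 0 and p_adj < cutoff are ``TFR_up``, logFC < 0 significant
    are ``Relapse_up``, everything else ``unchanged``.  Targets missing
    from the DE table are ``unchanged`` with a warning.  Returns
    (per-target labels, per-TF label counts).
    """
    targets = sorted(set(edges["gene"]))
    missing = [t for t in targets if t not in de_table.index]
    if missing:
        warnings.warn(f"{len(missing)} targets missing from DE table, labeled unchanged")
    labels = {}
    for t in targets:
        if t not in de_table.index:
            labels[t] = "unchanged"
            continue
        row = de_table.loc[t]
        if row["p_adj"] < p_cutoff and row["logFC"] > 0:
            labels[t] = "TFR_up"
        elif row["p_adj"] < p_cutoff and row["logFC"] < 0:
            labels[t] = "Relapse_up"
        else:
            labels[t] = "unchanged"
    ann = pd.DataFrame({"gene": targets, "outcome": [labels[t] for t in targets]})
    per_tf = (
        edges.assign(outcome=edges["gene"].map(labels))
        .groupby(["tf", "outcome"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["TFR_up", "Relapse_up", "unchanged"], fill_value=0)
    )
    return ann, per_tf


def regulon_activity(
    values: np.ndarray,
    gene_ids: list[str],
    edges: pd.DataFrame,
    group_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell (or per-group) TF regulon activity.

    Activity = weighted mean of z-scored target expression using the
    filtered edge weights, then min-max scaled per TF across cells or
    groups.
    """
    X = np.asarray(values, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    col = {g: i for i, g in enumerate(gene_ids)}
    rows = {}
    for tf, sub in edges.groupby("tf"):
        cols = [col[g] for g in sub["gene"] if g in col]
        w = np.abs(sub.loc[sub["gene"].isin(col), "weight"].to_numpy())
        if not cols or w.sum() == 0:
            continue
        act = Z[:, cols] @ (w / w.sum())
        rows[tf] = act
    df = pd.DataFrame(rows)
    if group_labels is not None:
        df = df.groupby(np.asarray(group_labels)).mean()
    rng = df.max() - df.min()
    rng[rng == 0] = 1.0
    return (df - df.min()) / rng


def export_graph(
    edges: pd.DataFrame,
    path: str | Path,
    fmt: str = "SIF",
    centralities: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> Path:
    """Write the filtered network as SIF triplets or attribute-rich GraphML."""
    if edges.empty:
        raise ValueError("cannot export an empty edge list")
    path = Path(path)
    if fmt.upper() == "SIF":
        lines = [f"{tf}\tregulates\t{gene}" for tf, gene in edges[["tf", "gene"]].itertuples(index=False)]
        path.write_text("\n".join(lines) + "\n")
    elif fmt.upper() == "GRAPHML":
        g = nx.DiGraph()
        for tf, gene, w, s in edges[["tf", "gene", "weight", "sign"]].itertuples(index=False):
            g.add_edge(tf, gene, weight=float(w), sign=int(s))
        if centralities is not None:
            for row in centralities.itertuples(index=False):
                if row.node in g:
                    g.nodes[row.node]["pagerank"] = float(row.pagerank)
                    g.nodes[row.node]["high_centrality"] = bool(row.high_centrality)
        if annotations is not None:
            for gene, outcome in annotations[["gene", "outcome"]].itertuples(index=False):
                if gene in g:
                    g.nodes[gene]["outcome"] = str(outcome)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_graphml_edges(path: str | Path) -> pd.DataFrame:
    """Re-import a GraphML export as an edge list (round-trip helper)."""
    g = nx.read_graphml(path)
    rows = [
        (u, v, float(d.get("weight", np.nan)), int(d.get("sign", 0)))
        for u, v, d in g.edges(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=["tf", "gene", "weight", "sign"])
        .sort_values(["tf", "gene"], kind="stable")
        .reset_index(drop=True)
    )
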