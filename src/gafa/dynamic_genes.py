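"""Spline (GAM) scoring of gene expression dynamics along pseudotime.

Each gene's log-normalized expression is regressed on lineage
pseudotime with a penalized cubic B-spline (identity link — a "linear
GAM"): 10 basis functions by default, a second-difference penalty on
the coefficients, and the penalty weight chosen per gene by generalized
cross-validation over a log-spaced grid.  The fit quality
(``raw_score``) is the explained deviance relative to the
intercept-only model, i.e. a pseudo-R^2 in [0, 1].

Scores are then normalized across genes within a lineage
(``score_norm`` = z-score of ``raw_score``), and genes with positive
``score_norm`` — better-than-average pseudotime dependence — are
called dynamic.  The pooled pseudotime gene set is the union of both
lineages' dynamic genes, optionally extended with transcription
factors dynamic in *both* lineages.

Because the pseudotime vector is shared by all genes of a lineage, the
basis and the per-lambda solver factorizations are computed once and
every gene is scored by vectorized linear algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "PooledGeneSet",
    "bspline_basis",
    "fit_gene_gam",
    "score_genes",
    "normalize_scores",
    "pool_dynamic_sets",
]

DEFAULT_LAMBDAS = np.logspace(-3.0, 3.0, 7)
MIN_CELLS = 20


@dataclass
class PooledGeneSet:
    genes_501: set[str]
    genes_503: set[str]
    appended_tfs: set[str] = field(default_factory=set)

    @property
    def pooled(self) -> set[str]:
        return self.genes_501 | self.genes_503 | self.appended_tfs


def bspline_basis(t: np.ndarray, n_splines: int = 10, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with ``n_splines`` basis functions.

    Interior knots are equally spaced over the observed pseudotime
    range; boundary knots are repeated ``degree + 1`` times.
    """
    t = np.asarray(t, dtype=float)
    if n_splines <= degree:
        raise ValueError(f"n_splines={n_splines} must exceed degree={degree}")
    lo, hi = float(t.min()), float(t.max())
    if hi <= lo:
        hi = lo + 1e-9
    n_interior = n_splines - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    # clip to the open support so boundary points evaluate cleanly
    tc = np.clip(t, lo, hi - 1e-12 * max(1.0, abs(hi)))
    return BSpline.design_matrix(tc, knots, degree).toarray()


def _second_diff_penalty(m: int) -> np.ndarray:
    D = np.diff(np.eye(m), n=2, axis=0)
    return D.T @ D


def score_genes(
    Y: np.ndarray,
    pt: np.ndarray,
    n_splines: int = 10,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
) -> np.ndarray:
    """Pseudo-R^2 of the penalized spline fit for each column of ``Y``.

    GCV(lambda) = n * RSS / (n - edf)^2 per gene; the best lambda is
    chosen per gene.  Constant genes score 0.
    """
    pt = np.asarray(pt, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != pt.shape[0]:
        Y = Y.T
    n, n_genes = Y.shape
    if n < MIN_CELLS:
        raise ValueError(f"need >= {MIN_CELLS} cells, got {n}")
    if not np.isfinite(pt).all():
        raise ValueError("pseudotime contains non-finite values")

    B = bspline_basis(pt, n_splines=n_splines)
    m = B.shape[1]
    P = _second_diff_penalty(m)
    BtB = B.T @ B
    BtY = B.T @ Y
    tss = ((Y - Y.mean(axis=0, keepdims=True)) ** 2).sum(axis=0)

    best_gcv = np.full(n_genes, np.inf)
    best_rss = np.zeros(n_genes)
    for lam in np.atleast_1d(lambdas):
        M = BtB + lam * P
        coef = np.linalg.solve(M, BtY)
        fitted = B @ coef
        rss = ((Y - fitted) ** 2).sum(axis=0)
        edf = np.trace(np.linalg.solve(M, BtB))
        denom = max(n - edf, 1e-8) ** 2
        gcv = n * rss / denom
        better = gcv < best_gcv
        best_gcv[better] = gcv[better]
        best_rss[better] = rss[better]

    raw = np.zeros(n_genes)
    nonconst = tss > 0
    raw[nonconst] = 1.0 - best_rss[nonconst] / tss[nonconst]
    return np.clip(raw, 0.0, 1.0)


def fit_gene_gam(
    expr: np.ndarray,
    pt: np.ndarray,
    n_splines: int = 10,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
) -> float:
    """Spline fit quality (pseudo-R^2) for a single gene."""
    return float(score_genes(np.asarray(expr)[:, None], pt, n_splines, lambdas)[0])


def normalize_scores(
    raw_scores: dict[str, float] | pd.Series, lineage: str
) -> pd.DataFrame:
    """Across-gene z-score of raw scores; dynamic = score_norm > 0."""
    s = pd.Series(raw_scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need raw scores for at least 2 genes")
    sd = s.std(ddof=0)
    if sd == 0:
        warnings.warn(
            f"lineage {lineage}: zero variance across gene scores; no gene is dynamic"
        )
        norm = pd.Series(0.0, index=s.index)
    else:
        norm = (s - s.mean()) / sd
    out = pd.DataFrame(
        {
            "gene": s.index,
            "lineage": lineage,
            "raw_score": s.to_numpy(),
            "score_norm": norm.to_numpy(),
        }
    )
    out["dynamic"] = out["score_norm"] > 0
    return out.reset_index(drop=True)


def pool_dynamic_sets(
    scores_501: pd.DataFrame,
    scores_503: pd.DataFrame,
    tf_list: list[str] | None = None,
) -> PooledGeneSet:
    """Union of the two lineages' dynamic genes, plus TFs dynamic in both."""
    g501 = set(scores_501.loc[scores_501["dynamic"], "gene"])
    g503 = set(scores_503.loc[scores_503["dynamic"], "gene"])
    appended: set[str] = set()
    if tf_list:
        appended = (g501 & g503) & set(tf_list)
    return PooledGeneSet(genes_501=g501, genes_503=g503, appended_tfs=appended)
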