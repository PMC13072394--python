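"""Stability gene-panel selection with patient-level leave-pair-out folds.

Cells are the observations but cross-validation is at the sample
level: each fold holds out exactly one relapse-arm sample and one
control-arm sample, training on all samples from other patients.  A
random forest (500 trees, balanced class weights) classifies cells as
relapse vs control; per fold the top-k genes by mean-decrease-in-
impurity importance are recorded, and the panel is the set of genes
whose selection frequency across folds reaches a threshold (default
half of the folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score

from .embed_cluster import ClusterLabels
from .io_qc import NormalizedMatrix

__all__ = [
    "FoldSpec",
    "FoldResult",
    "PanelTable",
    "enumerate_patient_folds",
    "prepare_features",
    "train_eval_fold",
    "build_panel",
    "run_panel_selection",
]

DEFAULT_FEATURE_CLUSTERS = (0, 1, 3, 5)


@dataclass(frozen=True)
class FoldSpec:
    fold_id: int
    train_samples: tuple[str, ...]
    test_samples: tuple[str, ...]  # exactly one relapse + one control sample


@dataclass
class FoldResult:
    fold_id: int
    accuracy: float
    roc_auc: float
    top_k_genes: list[str]
    seed: int


@dataclass
class PanelTable:
    table: pd.DataFrame  # gene, count_in_topk, n_validations, frequency
    selected_panel: list[str]
    threshold: float


def enumerate_patient_folds(
    samples: pd.DataFrame,
    relapse_arm: str = "relapse",
    control_arm: str = "control",
) -> list[FoldSpec]:
    """One fold per (held-out relapse sample x held-out control sample).

    ``samples`` needs columns sample_id, patient, arm.  The training
    set of each fold excludes every sample from the held-out patients,
    so no patient appears on both sides.  4 relapse x 2 control samples
    yield 8 folds.
    """
    required = {"sample_id", "patient", "arm"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    rel = samples[samples["arm"] == relapse_arm]
    ctl = samples[samples["arm"] == control_arm]
    for name, df in (("relapse", rel), ("control", ctl)):
        if len(df) < 2:
            raise ValueError(
                f"need at least 2 samples in the {name} arm to hold one out, got {len(df)}"
            )
    patient_of = dict(zip(samples["sample_id"], samples["patient"]))
    folds = []
    for fold_id, (r, c) in enumerate(
        product(rel["sample_id"].tolist(), ctl["sample_id"].tolist())
    ):
        held_patients = {patient_of[r], patient_of[c]}
        train = tuple(
            s for s in samples["sample_id"] if patient_of[s] not in held_patients
        )
        folds.append(FoldSpec(fold_id=fold_id, train_samples=train, test_samples=(r, c)))
    return folds


def _batch_quantile_normalize(X: np.ndarray, batches: np.ndarray) -> np.ndarray:
    """Map each batch's per-gene value distribution onto the pooled one.

    Rank-based and label-free; removes batch differences in both
    location and shape (additive shifts interact non-additively with
    dropout and the log transform, so mean-centering alone is not
    enough).  Within-batch orderings — and hence any within-batch
    biological contrast — are preserved exactly.
    """
    Xn = X.copy()
    uniq = np.unique(batches)
    if len(uniq) < 2:
        return Xn
    for g in range(X.shape[1]):
        pooled = np.sort(X[:, g])
        for b in uniq:
            mask = batches == b
            q = (rankdata(X[mask, g], method="average") - 0.5) / mask.sum()
            Xn[mask, g] = np.quantile(pooled, q)
    return Xn


def prepare_features(
    x: NormalizedMatrix,
    pooled_genes: list[str] | set[str],
    labels: ClusterLabels | None = None,
    clusters: tuple[int, ...] = DEFAULT_FEATURE_CLUSTERS,
    batch_correction: str = "quantile",
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Feature matrix (cells x pooled genes) restricted to lineage clusters.

    Returns (features, per-cell outcome, per-cell sample id).  Genes in
    the pooled set that are absent from the matrix are dropped with a
    warning.  ``batch_correction`` ("quantile", "center" or "none")
    applies a label-free per-batch correction; without it a fold whose
    training arm is dominated by one sequencing batch lets the
    classifier exploit the batch effect instead of outcome biology.
    z-scoring is deferred to fold training so that only training-fold
    statistics are used.
    """
    pooled = sorted(set(pooled_genes))
    if not pooled:
        raise ValueError("pooled gene set is empty")
    present = [g for g in pooled if g in set(x.gene_ids)]
    missing = sorted(set(pooled) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} pooled genes absent from matrix, dropped: {missing[:5]}...")
    if not present:
        raise ValueError("no pooled gene present in the matrix")

    if labels is not None:
        mask = np.isin(labels.labels, list(clusters))
        if not mask.any():
            raise ValueError(f"no cells in clusters {clusters}")
        x = x.subset_cells(mask)
    cols = x.gene_index(present)
    values = np.asarray(x.values[:, cols].todense())
    if batch_correction != "none" and "batch" in x.cell_meta.columns:
        batches = x.cell_meta["batch"].to_numpy()
        if batch_correction == "quantile":
            values = _batch_quantile_normalize(values, batches)
        elif batch_correction == "center":
            for b in np.unique(batches):
                mask = batches == b
                values[mask] -= values[mask].mean(axis=0, keepdims=True)
        else:
            raise ValueError(f"unknown batch_correction {batch_correction!r}")
    feat = pd.DataFrame(values, index=x.cell_ids, columns=present)
    return feat, x.cell_meta["outcome"].copy(), x.cell_meta["sample"].copy()


def train_eval_fold(
    features: pd.DataFrame,
    arms: pd.Series,
    cell_samples: pd.Series,
    fold: FoldSpec,
    k: int = 15,
    n_trees: int = 500,
    seed: int = 0,
) -> FoldResult:
    """Fit a seeded random forest on the fold's training cells.

    Features are z-scored with training-fold statistics (applied
    unchanged to test cells).  Importance is mean decrease in impurity;
    ties in the top-k ranking break lexicographically by gene id.
    """
    train_mask = cell_samples.isin(fold.train_samples).to_numpy()
    test_mask = cell_samples.isin(fold.test_samples).to_numpy()
    y = arms.to_numpy()
    if len(np.unique(y[train_mask])) < 2:
        raise ValueError(f"fold {fold.fold_id}: training cells contain a single class")

    X = features.to_numpy(dtype=float)
    mu = X[train_mask].mean(axis=0)
    sd = X[train_mask].std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    clf = RandomForestClassifier(
        n_estimators=n_trees,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(Xz[train_mask], y[train_mask])
    pred = clf.predict(Xz[test_mask])
    acc = accuracy_score(y[test_mask], pred)
    classes = clf.classes_
    proba = clf.predict_proba(Xz[test_mask])[:, 1]
    if len(np.unique(y[test_mask])) < 2:
        warnings.warn(f"fold {fold.fold_id}: single-class test set, AUC undefined (0.5)")
        auc = 0.5
    else:
        auc = roc_auc_score(y[test_mask] == classes[1], proba)

    imp = clf.feature_importances_
    genes = features.columns.to_numpy()
    order = np.lexsort((genes, -imp))  # importance desc, gene id asc on ties
    top_k = genes[order[:k]].tolist()
    return FoldResult(
        fold_id=fold.fold_id,
        accuracy=float(acc),
        roc_auc=float(auc),
        top_k_genes=top_k,
        seed=seed,
    )


def build_panel(
    fold_results: list[FoldResult] | list[list[str]],
    n_validations: int | None = None,
    threshold: float = 0.5,
) -> PanelTable:
    """Cross-fold selection counts and the frequency-thresholded panel.

    frequency = count_in_topk / n_validations exactly; the panel keeps
    genes with frequency >= threshold, sorted by frequency descending
    then gene id.
    """
    if not fold_results:
        raise ValueError("need at least one fold result")
    top_lists = [
        fr.top_k_genes if isinstance(fr, FoldResult) else list(fr)
        for fr in fold_results
    ]
    n = n_validations if n_validations is not None else len(top_lists)
    counts: dict[str, int] = {}
    for genes in top_lists:
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    table = pd.DataFrame(
        {
            "gene": list(counts),
            "count_in_topk": list(counts.values()),
            "n_validations": n,
        }
    )
    table["frequency"] = table["count_in_topk"] / n
    table = table.sort_values(
        ["frequency", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    selected = table.loc[table["frequency"] >= threshold, "gene"].tolist()
    return PanelTable(table=table, selected_panel=selected, threshold=threshold)


def run_panel_selection(
    x: NormalizedMatrix,
    pooled_genes: list[str] | set[str],
    labels: ClusterLabels | None = None,
    clusters: tuple[int, ...] = DEFAULT_FEATURE_CLUSTERS,
    relapse_outcomes: tuple[str, ...] = ("early_relapse", "late_relapse"),
    control_outcomes: tuple[str, ...] = ("TFR", "control"),
    k: int = 15,
    n_trees: int = 500,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[PanelTable, list[FoldResult]]:
    """End-to-end stability selection: folds, per-fold forests, panel.

    Outcome labels from cell metadata are collapsed into two arms; the
    per-fold forest seed is ``seed + fold_id`` so folds differ but the
    run is reproducible.
    """
    feat, outcomes, cell_samples = prepare_features(x, pooled_genes, labels, clusters)
    arm = pd.Series(
        np.select(
            [outcomes.isin(relapse_outcomes), outcomes.isin(control_outcomes)],
            ["relapse", "control"],
            default="other",
        ),
        index=outcomes.index,
    )
    keep = (arm != "other").to_numpy()
    patients = x.cell_meta["patient"].reindex(cell_samples.index)
    feat, arm = feat[keep], arm[keep]
    cell_samples, patients = cell_samples[keep], patients[keep]
    sample_table = (
        pd.DataFrame(
            {
                "sample_id": cell_samples.to_numpy(),
                "patient": patients.to_numpy(),
                "arm": arm.to_numpy(),
            }
        )
        .drop_duplicates("sample_id")
        .reset_index(drop=True)
    )
    folds = enumerate_patient_folds(sample_table)
    results = [
        train_eval_fold(feat, arm, cell_samples, f, k=k, n_trees=n_trees, seed=seed + f.fold_id)
        for f in folds
    ]
    panel = build_panel(results, threshold=threshold)
    return panel, results
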