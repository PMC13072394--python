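"""Seeded synthetic single-cell data with planted branching-lineage structure.

The generator emulates the shape of a small longitudinal immune-cell
cohort: multiple samples from multiple patients across three clinical
outcome arms (treatment-free remission as the control arm, early and
late relapse), sequenced in batches, with cells drawn from a two-branch
differentiation tree (root -> shared intermediate -> two terminal
states) plus a small off-path population — six discrete states in all.

Counts follow a negative-binomial droplet model: a per-cell gene
program on the log scale is passed through a softmax, scaled by a
log-normally distributed library size, and sampled with gene-level
dispersion; an optional Bernoulli dropout thins the counts (the mean is
compensated so per-cell totals keep the configured library-size law).

Planted signal, all recorded in :class:`GroundTruth`:

* pseudotime-dynamic genes per lineage — half monotone (sigmoid in
  pseudotime), half transient (Gaussian bump), so downstream spline
  fits are exercised on non-linear shapes;
* outcome-discriminative genes with a configured log2 fold change
  between the relapse and control arms;
* a TF -> target bipartite network realized through shared per-cell
  TF activity factors, so that co-expression carries evidence of the
  planted regulatory edges;
* an additive gene-wise log-mean batch shift, the simplest confounder a
  batch-aware embedding must remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .io_qc import ExpressionMatrix, write_10x

__all__ = [
    "SampleSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_prior_networks",
    "write_dataset",
    "default_samples",
]

LINEAGES = ("L501", "L503")
#: state codes: 0 root, 1 early, 2 intermediate, 3 terminal A, 4 terminal B, 5 off-path
STATE_NAMES = ("root", "early", "intermediate", "terminal_A", "terminal_B", "off_path")
OUTCOMES = ("TFR", "early_relapse", "late_relapse", "control")
#: arms whose samples count as "relapse" for discriminative effects / folds
RELAPSE_OUTCOMES = ("early_relapse", "late_relapse")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    patient_id: str
    batch_id: str
    outcome: str


def default_samples() -> list[SampleSpec]:
    """Six-patient cohort: 2 control-arm (TFR) and 4 relapse samples."""
    return [
        SampleSpec("S1", "P1", "B1", "late_relapse"),
        SampleSpec("S2", "P2", "B2", "late_relapse"),
        SampleSpec("S3", "P3", "B1", "early_relapse"),
        SampleSpec("S4", "P4", "B2", "early_relapse"),
        SampleSpec("S5", "P5", "B1", "TFR"),
        SampleSpec("S6", "P6", "B2", "TFR"),
    ]


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_cells: int = 800
    n_genes: int = 500
    n_tfs: int = 20
    samples: list[SampleSpec] = field(default_factory=default_samples)
    n_dynamic_genes_per_lineage: int = 25
    n_discriminative_genes: int = 5
    effect_size_logfc: float = 1.0
    dropout_rate: float = 0.3
    library_size_lognormal: tuple[float, float] = (np.log(5000.0), 0.35)
    batch_shift_sd: float = 0.2
    seed: int = 0
    noise_seed: int | None = None  # regenerate sampling noise, keep structure
    # secondary shape parameters (fixed study conditions, rarely touched)
    off_path_fraction: float = 0.08
    n_state_markers: int = 8
    marker_strength: float = 2.5
    dynamic_amplitude: float = 4.0
    dynamic_baseline: float = 0.8
    tf_amplitude: float = 0.9
    tf_target_coupling: float = 0.6
    targets_per_tf: int = 10
    n_mito_genes: int = 10

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_tfs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("n_dynamic_genes_per_lineage", "n_discriminative_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if not self.samples:
            raise ValueError("samples must be non-empty")
        for s in self.samples:
            if s.outcome not in OUTCOMES:
                raise ValueError(
                    f"samples: outcome {s.outcome!r} of {s.sample_id} not in {OUTCOMES}"
                )
        reserved = (
            self.n_mito_genes
            + 4  # gating + root markers
            + 6 * self.n_state_markers
            + self.n_tfs
            + 2 * self.n_dynamic_genes_per_lineage
            + self.n_discriminative_genes
        )
        if self.n_genes < reserved + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the planted structure "
                f"(needs >= {reserved + 10})"
            )


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery tests."""

    true_pseudotime: np.ndarray  # per-cell, in [0, 1]
    true_branch: np.ndarray  # per-cell in {"root", "A", "B"}
    true_state: np.ndarray  # per-cell int in 0..5
    dynamic_gene_ids: dict[str, list[str]]  # per lineage
    dynamic_gene_shapes: dict[str, str]  # gene -> monotone | transient
    discriminative_genes: dict[str, int]  # gene -> sign (+1 up in relapse)
    planted_edges: list[tuple[str, str, int]]  # (tf, gene, sign)
    tf_ids: list[str]

    def lineage_mask(self, lineage: str) -> np.ndarray:
        """Cells belonging to a lineage: root cells plus its branch's cells."""
        branch = {"L501": "A", "L503": "B"}[lineage]
        on_path = self.true_state != 5
        return on_path & np.isin(self.true_branch, ["root", branch])

    def to_json(self) -> dict:
        return {
            "true_pseudotime": self.true_pseudotime.tolist(),
            "true_branch": self.true_branch.tolist(),
            "true_state": self.true_state.tolist(),
            "dynamic_gene_ids": self.dynamic_gene_ids,
            "dynamic_gene_shapes": self.dynamic_gene_shapes,
            "discriminative_genes": self.discriminative_genes,
            "planted_edges": [list(e) for e in self.planted_edges],
            "tf_ids": self.tf_ids,
        }


def _gene_names(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Partition the gene universe into named blocks."""
    names: dict[str, list[str]] = {}
    names["mito"] = [f"MT-G{i + 1:02d}" for i in range(cfg.n_mito_genes)]
    names["gating"] = ["NCAM1", "FCGR3A"]
    names["root_markers"] = ["SELL", "XCL1"]
    names["state_markers"] = [
        f"ST{s}M{j + 1:02d}" for s in range(6) for j in range(cfg.n_state_markers)
    ]
    names["tfs"] = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]
    n_special = sum(len(v) for v in names.values())
    n_background = cfg.n_genes - n_special
    names["background"] = [f"G{i + 1:04d}" for i in range(n_background)]
    return names


def generate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one seeded dataset; identical config => byte-identical output.

    ``seed`` drives the structural draws (which genes are dynamic, bump
    centers, regulatory wiring, batch shift vectors, dispersions);
    ``noise_seed`` (default: same as ``seed``) drives the cell-level
    sampling noise, so the same planted structure can be re-observed
    under fresh noise.
    """
    rng = np.random.default_rng(cfg.seed)
    rngn = np.random.default_rng(cfg.seed if cfg.noise_seed is None else cfg.noise_seed)
    n, G = cfg.n_cells, cfg.n_genes
    blocks = _gene_names(cfg)
    gene_ids = (
        blocks["mito"]
        + blocks["gating"]
        + blocks["root_markers"]
        + blocks["state_markers"]
        + blocks["tfs"]
        + blocks["background"]
    )
    col = {g: i for i, g in enumerate(gene_ids)}

    # --- cell-level structure -------------------------------------------------
    sample_idx = np.repeat(np.arange(len(cfg.samples)), int(np.ceil(n / len(cfg.samples))))[:n]
    meta = pd.DataFrame(
        {
            "patient": [cfg.samples[i].patient_id for i in sample_idx],
            "sample": [cfg.samples[i].sample_id for i in sample_idx],
            "timepoint": [
                "baseline" if c % 2 == 0 else "followup" for c in range(n)
            ],
            "batch": [cfg.samples[i].batch_id for i in sample_idx],
            "outcome": [cfg.samples[i].outcome for i in sample_idx],
        }
    )
    cell_ids = [f"CELL{i + 1:05d}" for i in range(n)]

    off_path = rngn.random(n) < cfg.off_path_fraction
    t = rngn.random(n)
    branch = np.where(t < 0.15, "root", np.where(rngn.random(n) < 0.5, "A", "B"))
    state = np.select(
        [t < 0.15, t < 0.45, t < 0.70],
        [0, 1, 2],
        default=-1,
    )
    state = np.where(state == -1, np.where(branch == "A", 3, 4), state)
    state[off_path] = 5
    branch = branch.astype("<U4")
    branch[off_path] = "root"
    t[off_path] = 0.0

    # --- gene program on the log scale ---------------------------------------
    z = rngn.normal(0.0, 0.5, size=(n, G))  # baseline heterogeneity

    for s in range(6):
        cells = state == s
        markers = blocks["state_markers"][s * cfg.n_state_markers : (s + 1) * cfg.n_state_markers]
        z[np.ix_(cells, [col[g] for g in markers])] += cfg.marker_strength
    on_path = state != 5
    z[np.ix_(on_path, [col[g] for g in blocks["gating"]])] += 2.0
    z[np.ix_(state == 0, [col[g] for g in blocks["root_markers"]])] += cfg.marker_strength

    # pseudotime-dynamic genes (disjoint between lineages)
    bg_pool = list(blocks["background"])
    dynamic_ids: dict[str, list[str]] = {}
    shapes: dict[str, str] = {}
    for lin, br in (("L501", "A"), ("L503", "B")):
        genes = bg_pool[: cfg.n_dynamic_genes_per_lineage]
        bg_pool = bg_pool[cfg.n_dynamic_genes_per_lineage :]
        dynamic_ids[lin] = genes
        z[:, [col[g] for g in genes]] += cfg.dynamic_baseline  # lift off the noise floor
        members = on_path & np.isin(branch, ["root", br])
        tm = t[members]
        for j, g in enumerate(genes):
            if j % 2 == 0:
                shapes[g] = "monotone"
                profile = expit(4.0 * (tm - 0.5))
            else:
                shapes[g] = "transient"
                center = rng.uniform(0.3, 0.7)
                profile = np.exp(-((tm - center) ** 2) / (2 * 0.15**2))
            z[members, col[g]] += cfg.dynamic_amplitude * profile

    # outcome-discriminative genes
    disc_genes = bg_pool[: cfg.n_discriminative_genes]
    bg_pool = bg_pool[cfg.n_discriminative_genes :]
    relapse_cells = meta["outcome"].isin(RELAPSE_OUTCOMES).to_numpy()
    disc_signs: dict[str, int] = {}
    for j, g in enumerate(disc_genes):
        sign = 1 if j % 2 == 0 else -1
        disc_signs[g] = sign
        shift = np.log(2.0) * cfg.effect_size_logfc
        if sign > 0:
            z[relapse_cells, col[g]] += shift
        else:
            z[~relapse_cells, col[g]] += shift

    # planted TF -> target network via shared per-cell activity factors.
    # Regulatory targets are drawn outside the dynamic sets so the two kinds
    # of planted signal stay orthogonal.  Consecutive TF pairs are
    # cooperative partners: they share half of their targets, emulating
    # co-binding complexes that a PPI prior can report.
    target_pool = bg_pool + disc_genes
    planted_edges: list[tuple[str, str, int]] = []
    tf_targets: dict[str, list[str]] = {}
    for j, tf in enumerate(blocks["tfs"]):
        eta = rngn.normal(0.0, 1.0, size=n)
        z[:, col[tf]] += cfg.tf_amplitude * eta
        own = rng.choice(
            len(target_pool), size=min(cfg.targets_per_tf, len(target_pool)), replace=False
        )
        targets = [target_pool[i] for i in own]
        if j % 2 == 1:  # partner of the previous TF: share half its targets
            partner = blocks["tfs"][j - 1]
            n_shared = cfg.targets_per_tf // 2
            shared = tf_targets[partner][:n_shared]
            targets = shared + [g for g in targets if g not in shared][: cfg.targets_per_tf - n_shared]
        tf_targets[tf] = targets
        for g in targets:
            sign = 1 if rng.random() < 0.7 else -1
            planted_edges.append((tf, g, sign))
            z[:, col[g]] += sign * cfg.tf_target_coupling * cfg.tf_amplitude * eta

    # batch shift: additive gene-wise log-mean offset per batch
    for b in meta["batch"].unique():
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=G)
        z[(meta["batch"] == b).to_numpy()] += shift

    # mitochondrial content: moderate baseline so QC is exercisable
    z[:, [col[g] for g in blocks["mito"]]] += 1.0

    # --- negative-binomial sampling ------------------------------------------
    p = np.exp(z - z.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    mean_log, sd_log = cfg.library_size_lognormal
    lib = rngn.lognormal(mean_log, sd_log, size=n)
    mu = lib[:, None] * p
    theta = rng.uniform(2.0, 8.0, size=G)  # gene property: structural
    if cfg.dropout_rate > 0:
        # mean-dependent dropout: lowly expressed entries vanish preferentially
        # (droplet-style zero inflation); means are compensated so per-cell
        # totals keep the configured library-size law in expectation
        p_drop = cfg.dropout_rate * np.exp(-mu / 5.0)
        mu_adj = mu / (1.0 - p_drop)
        lam = rngn.gamma(shape=theta[None, :], scale=mu_adj / theta[None, :])
        counts = rngn.poisson(lam).astype(np.int64)
        counts *= (rngn.random(size=counts.shape) >= p_drop).astype(np.int64)
    else:
        lam = rngn.gamma(shape=theta[None, :], scale=mu / theta[None, :])
        counts = rngn.poisson(lam).astype(np.int64)

    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=meta,
    )
    truth = GroundTruth(
        true_pseudotime=t,
        true_branch=branch,
        true_state=state,
        dynamic_gene_ids=dynamic_ids,
        dynamic_gene_shapes=shapes,
        discriminative_genes=disc_signs,
        planted_edges=planted_edges,
        tf_ids=list(blocks["tfs"]),
    )
    return matrix, truth


def generate_prior_networks(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    fraction: float = 0.6,
    n_decoys: int | None = None,
):
    """Build a TF-target prior (a fraction of planted edges plus decoys)
    and a symmetric PPI prior with STRING-style scores in [0, 1000].

    Returns a :class:`gafa.grn.PriorNetwork` over the full gene universe.
    """
    from .grn import PriorNetwork  # local import: grn does not depend on synthetic

    if cfg.n_tfs == 0:
        raise ValueError("n_tfs must be > 0 to build prior networks")
    if not truth.planted_edges:
        raise ValueError("truth contains no planted edges")
    rng = np.random.default_rng(cfg.seed + 10_007)

    blocks = _gene_names(cfg)
    gene_ids = (
        blocks["mito"]
        + blocks["gating"]
        + blocks["root_markers"]
        + blocks["state_markers"]
        + blocks["tfs"]
        + blocks["background"]
    )
    tf_ids = truth.tf_ids
    gcol = {g: i for i, g in enumerate(gene_ids)}
    trow = {tf: i for i, tf in enumerate(tf_ids)}

    n_planted = len(truth.planted_edges)
    n_keep = int(round(fraction * n_planted))
    keep_idx = rng.choice(n_planted, size=n_keep, replace=False)
    kept = [truth.planted_edges[i] for i in sorted(keep_idx)]

    if n_decoys is None:
        n_decoys = int(round(0.5 * n_planted))
    planted_set = {(tf, g) for tf, g, _ in truth.planted_edges}
    decoys: set[tuple[str, str]] = set()
    candidates = blocks["background"]
    while len(decoys) < n_decoys:
        tf = tf_ids[rng.integers(len(tf_ids))]
        g = candidates[rng.integers(len(candidates))]
        if (tf, g) not in planted_set:
            decoys.add((tf, g))

    W0 = np.zeros((len(tf_ids), len(gene_ids)))
    for tf, g, _sign in kept:
        W0[trow[tf], gcol[g]] = 1.0
    for tf, g in sorted(decoys):
        W0[trow[tf], gcol[g]] = 1.0

    # PPI: cooperative TF pairs (shared planted targets) get high-confidence
    # scores scaling with target overlap, plus a sprinkling of random
    # high-score decoy interactions; unit diagonal
    targets_of: dict[str, set[str]] = {tf: set() for tf in tf_ids}
    for tf, g, _sign in truth.planted_edges:
        targets_of[tf].add(g)
    scores = np.zeros((len(tf_ids), len(tf_ids)))
    for i in range(len(tf_ids)):
        for j in range(i + 1, len(tf_ids)):
            a, b = targets_of[tf_ids[i]], targets_of[tf_ids[j]]
            jac = len(a & b) / len(a | b) if (a | b) else 0.0
            if jac > 0:
                scores[i, j] = scores[j, i] = 700 + 300 * min(1.0, 2.0 * jac)
            elif rng.random() < 0.05:
                scores[i, j] = scores[j, i] = rng.uniform(700, 1000)
    P = scores / 1000.0
    np.fill_diagonal(P, 1.0)
    return PriorNetwork(W0=W0, P=P, gene_ids=list(gene_ids), tf_ids=list(tf_ids))


def write_dataset(
    m: ExpressionMatrix,
    truth: GroundTruth,
    dir_path: str | Path,
    prior=None,
) -> Path:
    """Write MTX + barcodes/features/metadata TSV, truth JSON and priors TSV."""
    dir_path = Path(dir_path)
    write_10x(m, dir_path)
    (dir_path / "truth.json").write_text(json.dumps(truth.to_json()))
    if prior is not None:
        rows = []
        for i, tf in enumerate(prior.tf_ids):
            for j in np.flatnonzero(prior.W0[i]):
                rows.append((tf, prior.gene_ids[j]))
        pd.DataFrame(rows, columns=["tf", "target"]).to_csv(
            dir_path / "tf_target_prior.tsv", sep="\t", index=False
        )
        ppi_rows = []
        for i, a in enumerate(prior.tf_ids):
            for j in range(i + 1, len(prior.tf_ids)):
                if prior.P[i, j] > 0:
                    ppi_rows.append((a, prior.tf_ids[j], int(round(prior.P[i, j] * 1000))))
        pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
            dir_path / "ppi_prior.tsv", sep="\t", index=False
        )
    return dir_path
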