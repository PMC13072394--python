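# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic benchmark does and does not emulate,
and the known limitations.

## Synthetic data model

Cells are drawn from a two-branch differentiation tree: a latent
pseudotime *t* ~ U(0,1) per cell, a root segment (*t* < 0.15), a shared
early/intermediate segment, and a 50/50 branch assignment (A or B) realized
as terminal states for *t* ≥ 0.7.  A small off-path population (8% of
cells) carries its own expression program and belongs to no lineage, for
six discrete states in total.  The default cohort has six samples from six
patients in two sequencing batches: two control-arm (TFR) samples and four
relapse samples (two early, two late) — the smallest design that supports
the 4 × 2 leave-pair-out fold scheme.

Expression is generated on the log scale as a per-cell gene program *z*,
passed through a softmax and scaled by a log-normal library size
(mean log 5000, σ = 0.35).  Counts are negative binomial via a
gamma–Poisson mixture with gene-level dispersion θ ~ U(2, 8).  Planted
structure:

* **State markers** — 8 genes per state at +2.5 log-units, plus NK gating
  markers (*NCAM1*, *FCGR3A*, elevated in all on-path states) and root
  markers (*SELL*, *XCL1*).
* **Dynamic genes** — 25 per lineage (disjoint between lineages), half
  monotone (sigmoid in *t*, slope 4, amplitude 4 log-units over a +0.8
  baseline) and half transient (Gaussian bump, σ = 0.15, random center in
  [0.3, 0.7]), so the spline stage is exercised on non-linear shapes.  The
  gentle slope and large amplitude are needed for the planted rank signal
  to survive counting noise and dropout (see below).
* **Discriminative genes** — 5 genes shifted by ±log2FC (default 1.0)
  between the relapse and control arms, alternating sign.
* **Regulatory network** — each of 20 TFs has a per-cell activity factor
  η ~ N(0,1); the TF's own gene and its ~10 targets (signed, drawn outside
  the dynamic/marker sets so the two planted signals stay orthogonal) load
  on η, which creates the co-expression evidence message passing needs.
  Consecutive TF pairs share half their targets — cooperative complexes —
  and the synthetic PPI prior scores TF pairs by the Jaccard overlap of
  their target sets (scaled into the 700–1000 high-confidence range), with
  a 5% sprinkling of high-score decoys.
* **Batch effect** — an additive gene-wise log-mean shift per batch,
  N(0, 0.2²), applied before sampling: the simplest confounder a
  batch-aware embedding must remove.

**Dropout.**  Dropout is mean-dependent (probability
`rate · exp(−μ/5)` per matrix entry, mean-compensated so per-cell totals
keep the configured library-size law).  This choice is forced, not
cosmetic: uniform Bernoulli dropout at rate 0.3 caps the Spearman
correlation between pseudotime and *any* gene at ≈ 0.52 even for a
noiseless monotone profile, which would make planted-signal recovery
meaningless.  Mean-dependent zero inflation is also what droplet data
actually shows.

**Structure vs noise seeds.**  `seed` fixes the structural draws (which
genes are dynamic, bump centers, wiring, batch shift vectors,
dispersions); an optional `noise_seed` redraws only the cell-level
sampling, so the same planted structure can be observed under fresh noise
— used by the score-stability tests.

What the generator does **not** emulate: ambient RNA and doublets,
realistic gene names beyond the gating markers, per-sample (as opposed to
per-batch) technical effects, UMI saturation, and transcriptional bursting
beyond NB dispersion.  Passing recovery tests therefore show the pipeline
is correct and calibrated under a faithful droplet-count model with known
truth — not that it is robust to every artifact of real libraries.

## QC and normalization

"Fewer than 200 genes" is interpreted as strictly fewer than 200 genes
with count > 0; "> 10% mitochondrial" as strictly greater, with
mitochondrial genes identified by a case-insensitive `MT-` prefix (both
configurable).  Normalization scales each cell to `target_sum` = 10⁴ and
applies log1p.  No gene-level filter is applied.

## Embedding and clustering

The mandatory embedding backend is linear: genes are mean-centered within
each batch and the centered matrix is reduced by truncated SVD to *d* = 20
components (seeded randomized solver, fully deterministic).  This is a
contract, not an architecture: any backend producing a batch-mixed
cells × d latent matrix can replace it, and the batch-mixing score (mean
normalized Shannon entropy of batch labels among *k* = 15 latent
neighbors) quantifies the contract.

The kNN graph uses Euclidean distances in the latent space, a
locally-scaled Gaussian kernel `exp(−d²/(σᵢσⱼ))` with σᵢ the distance to
the *k*-th neighbor, and max-symmetrization.  Leiden optimizes
RB-configuration modularity at the given resolution with a fixed seed;
cluster ids are relabeled by decreasing size so they are reproducible.

NK gating flags clusters whose mean z-scored marker expression (*NCAM1*,
*FCGR3A*) reaches a quantile threshold and is positive.  The op-level
default (top 25% of clusters) suits PBMC-like mixtures where NK cells are
a minority; the pipeline config default is permissive (quantile 0.25)
because the synthetic benchmark is NK-dominated.

Marker statistics are one-vs-rest two-sided Wilcoxon rank-sum tests (exact
for small untied samples), BH-adjusted within each cluster, with
`logFC = log2((mean expm1 in + ε)/(mean expm1 rest + ε))`, ε = 10⁻⁹.

## Diffusion pseudotime

The diffusion kernel applies the anisotropic normalization at exponent 1
(dividing the kernel by the outer product of its row sums) before forming
the Markov operator, removing sampling-density effects.  The spectrum is
taken from the symmetric conjugate (dense `eigh` for ≤ 200 cells, ARPACK
with a fixed start vector and a sign convention otherwise — both
deterministic).  DPT is the Euclidean norm of
`(λ/(1−λ))·(ψ(cell) − ψ(root))` over nontrivial components (default 15);
components with λ ≥ 1 (extra connected components) are dropped with a
warning.  The representative root cell is the root-cluster member with the
most extremal first diffusion component.  Lineages are cluster paths —
cells of shared clusters belong to both lineages — and pseudotime is
min-max scaled within each lineage.  Occupancy uses 10 equal-width bins by
default with an optional centered moving average (window 3); group
comparisons use exact Mann–Whitney when the smaller group has ≤ 8 untied
observations, the tie-corrected normal approximation otherwise, and
Kruskal–Wallis globally.

## Dynamic-gene scoring

Per gene and lineage the model is a Gaussian identity-link GAM:
a cubic B-spline basis with 10 basis functions over the observed
pseudotime range, a second-difference penalty on the coefficients, and the
penalty weight chosen per gene by GCV over λ ∈ 10^{−3..3} (7 grid points).
`raw_score` is the explained deviance against the intercept-only model,
clipped to [0, 1]; constant genes score 0.  Because all genes of a lineage
share the pseudotime vector, the basis and per-λ factorizations are
computed once and all genes are scored by vectorized linear algebra.
`score_norm` is the across-gene z-score of `raw_score` within a lineage:
z-scoring is the one normalization for which "positive score" is a
meaningful selector (a min–max scaling would retain everything).  The
pooled set is the union of both lineages' dynamic genes plus user-supplied
TFs dynamic in both.

## Panel selection

Folds are the full product of held-out (relapse sample × control sample)
pairs; the training set excludes every sample of a held-out patient, so no
patient appears on both sides.  Features are the pooled genes over cells
of the lineage clusters.  Before fold-wise z-scoring (training statistics
only), features undergo a **per-batch quantile normalization** — each
batch's per-gene value distribution is mapped, rank-wise, onto the pooled
distribution.  This label-free correction is required because the batch
shift interacts non-additively with dropout and the log transform: the
realized between-arm contrast then differs by batch, and since half the
folds train their control arm on a single sample from a single batch, the
classifier otherwise inverts confidently on cross-batch test pairs
(observed fold AUCs of 0.01–0.26 with true labels; 0.74–0.88 after
quantile normalization).  Mean-centering alone does not fix this.

The classifier is a random forest with 500 trees and balanced class
weights; per-fold seed = global seed + fold id.  Importance is mean
decrease in impurity; top-*k* (k = 15) ties break lexicographically.  The
panel keeps genes appearing in ≥ 50% of folds (exact rational
frequencies).

**Permutation null.**  With six samples in a 4 v 2 design, every
arm-size-preserving relabeling that keeps the true control samples
together retains genuine planted signal (measured mean fold AUC ≈ 0.62),
so the null relabels the control role onto *mixed* pairs — one true
control plus one true relapse sample — which carries no outcome
information; the machinery is judged calibrated if the mean held-out AUC
over these relabelings is near chance (measured ≈ 0.51).

## GRN inference

The prior `W0` is the idempotent union of curated TF→target edge lists,
harmonized to the expression universe; the PPI prior keeps combined scores
≥ 700, scaled by 1/1000, symmetrized with unit diagonal.  Co-expression is
the Pearson gene–gene correlation over cells (zero-variance genes zeroed
with a warning).

Message passing follows the PANDA scheme with a continuous Tanimoto
kernel, `T(x,y) = ⟨x,y⟩ / (‖x‖² + ‖y‖² − |⟨x,y⟩|)` applied
row/column-wise: responsibility `R = T(P, W)` asks whether a TF's
cooperativity profile explains a gene's regulator profile, availability
`A = T(W, C)` whether the TF's target profile explains the gene's
co-expression profile, and `W ← (1−α)·W + α·(R+A)/2` followed by
multiplicative shrinkage `(1 − αλ)`, with α = 0.05, λ = 0.1, 150
iterations and an early-stop tolerance on the mean absolute update.  P and
C are co-updated toward their W-implied estimates and re-standardized
every iteration.  **W itself is z-normalized once at initialization and
then left on the message scale**: re-standardizing W every iteration makes
the update norm rise after ~50 iterations and, run long enough, collapses
the network toward a degenerate consensus (planted-edge AUROC 0.72 at 600
iterations versus 0.90 without in-loop W normalization), whereas the
chosen scheme converges monotonically and improves on the prior in 10/10
planted replicates.  α = 0 short-circuits the loop: the normalized prior
is an exact fixed point.

Edge filtering offers an absolute-|w| threshold and a top-fraction mode
(exactly ⌈q·n⌉ edges, deterministic tie-breaking); the pipeline default is
the top 1.5% because on the z-scored message scale an absolute 0.3 cut
does not correspond to that quantile.  Centralities: PageRank with damping
0.85 (tight tolerance so it matches a power-iteration oracle to < 10⁻⁸),
weighted out-degree, and betweenness on inverse-|w| distances;
high-centrality TFs are those at or above the 90th percentile of TF
PageRank.  Markov clustering alternates expansion (squaring) and inflation
(elementwise power 2.2 + column normalization) on the symmetrized |w|
matrix with per-node self-loops, pruning entries < 10⁻⁹, until the update
is < 10⁻⁸; attractor rows define modules, merged over overlapping
supports.  Outcome annotation labels targets `TFR_up` / `Relapse_up` by
the sign of a significant (BH p < 0.05) condition contrast, `unchanged`
otherwise.  Regulon activity is the |w|-weighted mean of z-scored target
expression, min–max scaled per TF.

## Enrichment

One-sided hypergeometric upper-tail p-values against each GMT set, with
the universe defined as the genes surviving QC (standard ORA practice),
BH-adjusted across sets.

## Pipeline, determinism and problem sizes

The orchestrator runs QC → embedding/clustering/gating → trajectory →
dynamics → panel → GRN → (optional) enrichment, writing each stage's
outputs as it completes and a manifest of parameters, seeds and SHA-256
hashes.  All backends are deterministic given the config seed, so two
identical runs produce byte-identical outputs.  The auto mode for lineage
mapping takes the marker-selected root cluster, calls the two non-root
clusters with the highest mean DPT terminal, and treats the remaining
clusters as shared.

The standard benchmark is 800 cells × 500 genes (dropout 0.3); the
message-passing replicate studies use 400 cells × 300 genes × 10 seeds.
These sizes were chosen so the full validation cycle runs in minutes on a
laptop core while every recovery margin stays wide (pseudotime ρ ≈ 0.96
against a 0.8 requirement; dynamic-gene AUROC ≈ 0.95 against 0.9).

## Limitations

* The linear embedding removes additive batch effects only; a VAE-class
  backend would be needed for non-linear integration (the contract and
  tests accommodate one, none is shipped).
* Lineage membership is cluster-path-based and deterministic; there is no
  probabilistic branch assignment, RNA velocity or fate mapping.
* Cell-level classification treats cells as observations; with six
  samples the panels are exploratory and carry no patient-level predictive
  claim.
* The GRN is correlational: message passing reconciles priors with
  co-expression and infers no causality; condition-specific networks can
  be produced either by re-running inference on condition cells
  (recommended, since masking a global network cannot change weights) or
  by subsetting edges.
* MCL is run on the filtered (hence sparse) graph; module granularity
  depends on the edge filter as much as on the inflation parameter.
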