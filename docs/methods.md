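# Methods

## Overview

`omicsgat` implements a multi-omics integration framework in four stages:
(1) per-omics patient similarity graphs, (2) per-omics graph attention
network (GAT) embeddings, (3) embedding fusion with an MLP subtype
classifier, and (4) a Cox-based risk-stratification pipeline that compares
embeddings against raw features. A synthetic cohort generator provides
subtype-structured data with subtype-dependent survival so that every stage
is exercisable without controlled-access data.

## Patient similarity graphs

Similarity is metric-dispatched by data type: Pearson correlation between
sample feature vectors for continuous layers (EXP, LNC, MIR, MET, CNA, COE),
Jaccard similarity of mutated-gene sets for the binary MUT layer, and Gower
similarity for the mixed clinical table (per attribute, `1 − |Δ|/range` for
continuous and exact match for categorical, averaged over attributes
observed in both records). Gower runs on the raw clinical table; one-hot
encoding is reserved for node features, since the metric exists precisely to
handle mixed kinds.

Each patient is linked to its k most similar peers (default k = 3) and the
directed top-k lists are symmetrized by union, giving an undirected graph
whose edge count lies in `[⌈nk/2⌉, nk]` and whose minimum degree is ≥ k.
Design choices, all for determinism or by standard practice:

- Pearson is used as the signed correlation — "most similar" means highest
  correlation, not highest |correlation|.
- Ties in the top-k ranking break by ascending sample ID.
- Degenerate inputs get explicit conventions with warnings: zero-variance
  sample rows correlate 0 with everything; two all-zero mutation profiles
  have Jaccard 0; zero-range clinical attributes are excluded pairwise.
- Graphs are unweighted downstream (attention learns edge weights);
  similarity weights are exported for inspection only.

## Graph attention networks

Each omics layer gets its own two-layer GAT, trained transductively as a
node classifier on subtype labels. The node feature matrix is shared across
layers: the concatenation of all processed omics blocks, so each
per-omics graph views an integrated feature space. With neighborhood
N(i) = graph neighbors of i plus a self-loop:

- attention score `c_ij = LeakyReLU(aᵀ[Wx_i ‖ Wx_j])`, negative slope 0.2;
- normalization `α_ij = softmax_{j∈N(i)}(c_ij)`, computed with
  max-subtraction for overflow safety;
- aggregation `h_i = σ(Σ_j α_ij W x_j)` — the *neighbor's* transformed
  features enter the sum. The self-loop keeps each node's own term in the
  aggregation. An alternative reading that puts `Wx_i` inside the sum
  collapses to `h_i = Wx_i` for any α (since Σα = 1) and makes attention
  vacuous, so the package deliberately implements the neighbor form.

Layer 1 runs H heads (default 1) whose outputs are concatenated to a total
width of `hidden_dim` (so H must divide `hidden_dim`), followed by ELU.
Layer 2 maps to class scores with no nonlinearity before softmax
cross-entropy; with several output heads their outputs are averaged.
Dropout is 0 by default.

The implementation is pure numpy with hand-derived reverse-mode gradients
(segment reductions over destination-sorted edge lists); the test suite
verifies them against central finite differences at 1e-6. Optimization is
full-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8); parameters use Glorot
uniform initialization from a seeded generator, so fixed seeds reproduce
loss trajectories bit for bit. Model selection keeps the epoch with the best
validation macro-F1. The per-omics training objective (supervised node
classification) follows the convention of the GCN-based integration
frameworks this design extends; an unsupervised variant is out of scope.

Tunable parameters and grids (defaults in bold): hidden width
[128, 256, **512**, 1024], learning rate [0.01, **0.001**, 0.0001], epochs
[100, **200**, 500], heads [**1**, 2, 4, 8]. Grid search, when requested,
selects by validation macro-F1 per omics.

## Fusion and classification

Per-omics embeddings are concatenated in canonical (alphabetical) code
order — CLI, CNA, COE, EXP, LNC, MET, MIR, MUT — regardless of input order,
and fed to an MLP (scikit-learn `MLPClassifier`; default architecture
(64, 32), learning rate 0.001, 1000 epochs; optional randomized search over
the grids with 20 sampled configurations). Metrics are accuracy, weighted-F1
and macro-F1; classes absent from both truth and prediction are excluded,
and a class with no true and no predicted members scores F1 = 0.

The combination sweep evaluates all 2^T − 1 non-empty omics subsets over
repeated runs (default 10), each run drawing a fresh stratified 70/10/20
train/validation/test split; resampling splits (rather than re-seeding one
fixed split) gives the more conservative variance estimate. Feature
selection and all model selection see only train+validation nodes; test
nodes never influence any choice. A leave-one-omics-out view ("All except
X" rows plus "All Datatypes") is derived from the same sweep.

## Preprocessing

- **Low-expression filter** (raw FPKM/RPM-like scale, before any
  normalization): keep features with value ≥ 1 in ≥ 15% of samples for
  EXP/LNC, ≥ 30% for MIR. Idempotent by construction.
- **Duplicate samples**: continuous layers merge patient replicates by the
  feature-wise mean, MUT by Boolean OR; clinical duplicates must be resolved
  upstream (first record wins).
- **Clinical encoding**: categoricals expand to one indicator per observed
  category (missing gets its own indicator); age and other continuous
  attributes pass through unscaled.
- **Common samples**: all inputs are restricted to the intersection of
  sample IDs and re-ordered to one sorted canonical order; alignment is
  always by ID string, never by row position.
- **Feature selection**: a label-aware univariate ranking (one-way ANOVA F
  across subtypes, ties broken by feature ID) with per-omics default counts
  EXP 1000, LNC 500, MET 1000, CNA 500, MUT 200 (MIR/COE/CLI unfiltered),
  mirroring the dimensionality profile of a real breast-cancer cohort. The
  scorer is pluggable — any `(values, labels) -> scores` callable can
  replace it. Label-aware selection must run on training folds only; the
  pipeline enforces this.
- **Normalization**: per-feature z-score (population SD) for CNA, EXP, LNC,
  MIR, MET; zero-variance columns map to zeros rather than NaN so downstream
  linear algebra stays finite. MUT (binary), CLI (one-hot) and COE
  (eigengenes) are not normalized.

## Survival pipeline

The selection stage is an L1-penalized *linear* regression of observed
survival time on predictors — censoring deliberately enters only at the
later stages, reproducing the framework's stated protocol; a penalized-Cox
selection would be the statistically cleaner alternative and is noted as a
limitation. The α grid is {0.001, 0.002, 0.005, 0.01, 0.05, 1.0}, chosen by
cross-validated MSE.

Selected predictors go into a multivariate Cox proportional hazards fit
(statsmodels `PHReg`, Breslow tie handling, Wald p-values). Predictors with
p < 0.05 contribute to the risk score `Σ X_i·Coef_i`; the cohort splits at
the median score with "score ≤ median" defining the low-risk group, so for
101 distinct scores the split is 51/49+1 = 51/50. Kaplan–Meier curves
(lifelines), the two-group log-rank test and a univariate-Cox hazard ratio
summarize the separation. Rank-deficient predictor matrices, constant
predictors, event-free tables and empty significant sets raise typed errors;
in the paired raw-vs-embedding comparison an input for which the chain
leaves zero significant predictors reports p = 1.0 (no stratification
achievable) so the comparison stays well-defined.

Note that, as in the original protocol, the risk model is fitted and
evaluated on the same cohort; log-rank p-values are therefore optimistic in
both arms of the comparison, which is exactly why the package evaluates
embeddings *against* a same-shape noise matrix rather than against an
absolute threshold.

## Synthetic cohorts

The generator emulates a breast-cancer-like cohort with five subtypes at
prevalences 17.24 / 8.02 / 50.65 / 20.39 / 3.68 % (the common-sample
distribution of a real cohort). Continuous layers are Gaussian with unit
within-subtype SD; an informative fraction of features (default 0.2)
receives subtype-specific mean shifts of magnitude `effect_size` (default
3) in SD units. Subtype prototypes are drawn from a structure seed that does
not involve `effect_size`, so raising the effect scales a fixed geometry and
between-subtype separation is monotone in it. The MUT layer is Bernoulli
with logit-shifted subtype-dependent rates around a base rate of 0.1; the
clinical table carries age (years, subtype-shifted around 60 ± 10) and
three categorical attributes with subtype-skewed frequencies. A raw
"FPKM-like" exponentiated variant of any continuous layer feeds the
low-expression filter realistically.

Survival times are exponential with per-subtype rate
`(ln 2 / 60 months) · exp(log_hazard)`, default per-subtype log hazards
(0.8, 0.5, 0.0, 0.4, −0.2) — poor prognosis for the Basal-like and
HER2-like subtypes relative to LumA-like, hazard ratios up to e ≈ 2.7,
realistic for intrinsic-subtype contrasts. Censoring is independent uniform
`U(0, u)` with `u` solved (Brent's method) so the expected censored fraction
matches `censoring_rate` (default 0.3); survival depends on subtype only,
matching the evaluation question "do embeddings that capture subtype
stratify risk". All draws derive from named, CRC-keyed child seeds of the
spec seed, so cohorts are reproducible across processes.

What the generator does **not** emulate: real marginal distributions
(FPKM/beta-value shapes), batch and platform effects, feature–feature
correlation beyond subtype structure, within-omics missingness, or direct
feature→hazard effects. Passing tests therefore demonstrate correctness of
the machinery and sensible behavior under clean subtype structure — not
performance claims on real cohorts.

## Problem sizes

The default demo cohort is n = 400 with four layers (EXP 200, MET 150, MUT
100 features, plus clinical) and 64-dimensional GAT embeddings — with a few
hundred input features, 512-wide embeddings would be wider than the data,
so the demo uses a width commensurate with the synthetic feature space
(the 512 default remains for full-scale configurations). Classification
results average ten runs. The embedding-versus-noise survival comparison
uses n = 800 cohorts over 20 seeds: the in-sample log-rank advantage of
true subtype signal over Cox overfitting grows with n, and at n = 800 the
comparison has adequate power to be a stable property rather than a coin
flip. Calibration checks use 200 null Cox fits and 1000 null log-rank
trials.

## Known limitations

- Full-batch training only; no neighbor sampling or GPU path. Intended for
  cohorts up to a few thousand patients.
- The LASSO stage regresses observed time, ignoring censoring (protocol
  fidelity; see above).
- Grid search is exhaustive per omics and can be slow at full Table-scale
  grids; the pipeline defaults to the single tuned configuration.
- COE enters as a precomputed eigengene matrix; module detection itself is
  out of scope, as are differential-expression-based cleaning and
  random-forest feature selection, for which the ANOVA-F ranking is a
  documented stand-in behind the pluggable scorer interface.
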