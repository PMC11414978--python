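# Methods

This note documents the models, estimators and numerical choices behind
`pathsurv`, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Setting and notation

The data are a genes × samples matrix X of continuous log2-scale
expression, a collection of named gene sets (pathways) J ⊆ genes, and per
sample a right-censored survival outcome: observed time T̃_i = min(T_i,
C_i) in months and event indicator δ_i = 1{T_i ≤ C_i}. Expression is
assumed already normalised; the toolkit never touches raw intensities
(readers warn when values exceed 30, which suggests a non-log scale).
Missing expression values are representable only in prediction-time
inputs; every training path requires complete data.

## Pathway scores

All three scorers map expression to a pathways × samples matrix; rank
ties are always broken by lexicographic gene id so results are
deterministic across runs and platforms.

**z-score.** Each gene is standardised across samples (ddof = 1);
Z_iJ = Σ_{j∈J} z_ij / D. The combined z-score convention D = √|J| is the
default; D = |J| (the mean) is available via `denominator="count"` and is
recorded in `method_params`. Zero-variance genes are dropped from all
sets with a warning; a set losing all its genes this way is an error.

**ssGSEA.** Per sample, genes are ranked by expression descending; the
gene at 1-based position k gets rank score s = N − k + 1. Walking the
ranked list, P_in accumulates s^α (α = 0.25 by default) over in-set
genes, normalised by the in-set total, and P_out accumulates the uniform
step 1/(N − |J|); the enrichment score is Σ_i (P_in(i) − P_out(i)) over
all N positions. Because only ranks enter, any strictly monotone
per-sample transform of expression leaves scores bitwise unchanged, and
one sample can be scored without a background cohort. With
`normalize=True` (default) the final score matrix is divided by its range.

**GSVA.** (1) Each expression value is converted to a Gaussian-kernel CDF
estimate against its gene's cohort distribution, bandwidth h_g = sd_g/4;
zero-variance genes are pinned at 0.5. (2) Per sample the CDF values are
ranked descending and symmetrised, r = |N/2 − ρ|^τ (τ = 1). (3) A
KS-like walk with in-set steps r/Σr and uniform out-of-set steps yields
the deviations v_i; `max_diff` (default) reports max(v,0) + min(v,0),
`max_abs` the signed extreme. Scores lie in (−1, 1). Both GSVA and
z-score depend on the background cohort, so scoring new samples requires
the stored training reference; ssGSEA does not.

Set-size filtering before scoring defaults to [5, 500] genes after
intersection with the measured universe.

## Distinct-pathway selection

Collections larger than `n_select` (default 100) are reduced before
group-lasso fitting: average-linkage hierarchical clustering on the
Jaccard distance 1 − |A∩B|/|A∪B| between gene memberships, the tree cut
into exactly `n_select` clusters (scipy's `cut_tree`, which guarantees
the count even under tied merge heights), one representative per cluster
= the medoid (minimum summed within-cluster distance, ties by name).
Distance, linkage and representative rule are the minimal standard
completions of "hierarchical clustering"; all three are configurable.
Representatives are always original sets, never merged ones.

## Penalized Cox model

The fit minimises

    (1/n) · NLL(β) + λ P(β),
    P(β) = Σ_j |β_j|  (lasso)   or   Σ_g m_g ‖β_g‖₂  (group lasso)

with NLL the negative log partial likelihood under the Breslow treatment
of tied event times. Group weights default to m_g = √T_g (T_g = group
cardinality); with singleton groups and m_g = 1 the group penalty
reduces exactly to the lasso, which the tests verify numerically. The
printed linear-model form of these objectives (squared-error loss with an
intercept β₀) is also implemented (`loss="squared_error"`) for continuous
outcomes; the Cox form has no intercept.

Pathways overlap, but the group penalty requires a partition of the
predictor indices, so grouped designs are built by column duplication: a
gene in k selected pathways contributes k columns (named
`pathway::gene`), one per group. Selected-variable counts therefore
count gene-pathway pairs.

*Solver.* Monotone FISTA: proximal gradient steps from the extrapolated
point with backtracking line search (sufficient-decrease condition,
halving), the accelerated iterate accepted only when it does not increase
the objective, momentum restarted otherwise; two consecutive
no-progress restarts mean the objective is flat to working precision and
the solver stops. Convergence is declared when the relative objective
change falls below 1e-7 (configurable), with a hard cap of 1e5
iterations. Predictors are standardised internally (the penalty acts on
the standardised scale); coefficients are returned on the original
scale. The objective path is stored and is non-increasing by
construction; KKT residuals at the solution are available via
`kkt_violation()`. Samples are internally ordered by time, which makes
the fit invariant to the order samples arrive in (bitwise, for tie-free
times).

*Regularisation path.* λ_max (the smallest λ with an all-zero solution)
comes from the null-model gradient in closed form; the default grid is
100 log-spaced values from λ_max down to 0.01·λ_max. Paths are
warm-started and screened with sequential strong rules; every screened-out
feature/group is KKT-checked at the candidate solution and re-admitted on
violation, so screening changes speed, never solutions.

*λ selection.* 10-fold cross-validation, folds stratified by the event
indicator, scored by the Verweij–van Houwelingen cross-validated
partial-likelihood deviance 2·[NLL_all(β_{−k}) − NLL_{−k}(β_{−k})]; the
chosen λ minimises the summed deviance (the minimum rather than a 1-SE
rule: the models are built for prediction). Same seed → same folds →
same λ.

*Baseline hazard and absolute risk.* The Breslow cumulative baseline
hazard H₀(t) = Σ_{t_k ≤ t} d_k / Σ_{j∈R(t_k)} e^{lp_j} is fitted on the
training data and stored with the model; π(x, t) = exp(−H₀(t) e^{lp(x)}).
Beyond the last training event time the hazard is extrapolated flat with
a warning — transporting a baseline hazard to a population with a
different one is an approximation, which is also why the integrated
Brier score on external cohorts should be read cautiously.

## Evaluation

**Censoring model.** Ĝ(t) is the reverse Kaplan–Meier estimate (events
and censorings swapped), implemented as an explicit product-limit step
function so that left limits are available. The product-limit estimator
is hand-rolled (≈30 lines) precisely to control Ĝ(T⁻); lifelines serves
as an independent oracle in the tests.

**IPCW Brier score.** BS(t*) = (1/n) Σ W_i (1{T̃_i > t*} − π_i)², with
W = 1/Ĝ(T̃_i⁻) for events before t*, 1/Ĝ(t*) for survivors, 0 for
subjects censored before t*. The left limit at the subject's own time
avoids weighting an observation by its own censoring step; evaluating
Ĝ(T̃_i) instead is available via `left_limit=False`. With no censoring
the score reduces exactly to the uncensored Brier score. The integrated
Brier score averages BS over [0, t_max] by the trapezoidal rule on the
grid of unique observed event times; t_max defaults to the largest
observed event time of the evaluation set (capped at the training
baseline's support inside the validation harnesses).

**Concordance index.** All ordered pairs are enumerated; a pair is
usable iff the strictly smaller observed time belongs to an event.
Pairs with tied observed times are excluded: two tied event times never
establish the order, and a subject censored exactly at T_i is not known
to outlive i. Risk ties among usable pairs count 0.5 (Harrell
convention). The estimate and the usable-pair count are both reported.
No small-sample bias correction is applied — comparisons are always
within-dataset.

**Corrected resampled t-test.** For J repeated random train/test splits
with paired metric differences d_j, t = d̄ / √[(1/J + n_test/n_train)
s²_d], p two-sided from Student t with J−1 df. The n_test/n_train term
inflates the variance to account for the overlap between training sets
that makes the d_j dependent; the package verifies by simulation that
the test's null rejection rate stays near (at or below) the nominal
level. Degenerate inputs: zero variance with zero mean → p = 1; zero
variance with non-zero mean → p = 0 with a warning.

**Bootstrap CIs.** Percentile intervals over B resamples (default 1000)
of evaluation subjects; resamples on which a metric is undefined (e.g.
no usable pairs) are redrawn and counted. Deterministic under a seed.

**Risk groups.** high = risk > median, low = risk ≤ median (the median
sample goes low), with per-group KM curves; all-equal risks are an error.

## Validation harnesses

*Internal validation* repeats a stratified 70/30 split (stratified by
event indicator so every validation split retains events) `n_repeats`
times (default 100). Within each repeat, everything that uses background
statistics — z-score means/sds, the GSVA kernel CDF reference, predictor
standardisation, CV of λ — is fitted on the training split only and
replayed on the validation split. The harness exposes
`leak_validation_statistics=True` purely as an audit hook: it rebuilds
held-out features from held-out statistics, and the tests assert this
changes results while the shipped path scores held-out samples
identically whether they arrive alone or in a batch.

*External validation* replays the stored training statistics on a new
cohort, optionally after per-gene location/scale alignment to the
training reference (each gene rescaled to the reference gene's mean and
sd; zero-variance genes shifted only). This alignment is a deliberately
simple batch-adjustment contract — it is not an empirical-Bayes
batch-correction method and does not pool information across genes.

*Missing data.* New samples with missing genes are imputed from the
training reference: gene-gene Euclidean distances on the reference
matrix, and each missing gene takes the inverse-distance-weighted
average (w = 1/(d + 1e-6)) of its K = 10 nearest neighbour genes that
are observed in that sample (all observed genes if fewer than K exist).
Subject-neighbour imputation is intentionally not implemented. A warning
is issued beyond 5% missingness per sample — the recommended allowance;
the robustness experiment (mask → impute → predict → C-index across
missing fractions) quantifies the degradation beyond it.

*Model report.* A JSON report with the feature space, selected
pathways/genes and coefficients, λ and the CV curve, evaluation metrics,
the missing-data policy and software versions; models round-trip through
JSON with bitwise-identical predictions.

## Synthetic data generator

The generator provides ground truth for every stage. Gene sets are drawn
with sizes uniform in a range and a controllable fraction of members
re-drawn from previously used genes (creating the overlap that motivates
distinct-pathway selection). Per sample, each pathway has a latent
activity A_p ~ N(0,1); expression is x_gj = μ_g + Σ_p λ_gp A_pj + ε with
μ_g ~ N(8, 2) (log2-intensity-like), loadings 1 for member genes and
ε ~ N(0, 1). Survival follows a Weibull proportional-hazards model with
shape ρ = 1.5 and scale set so median survival at lp = 0 is 90 months,
under lp_j = Σ_{p active} γ_p A_pj with effect sizes of magnitude 1 and
alternating sign. Censoring is uniform on (0, c_max) with c_max
calibrated by bisection so the realised event rate lands within ±3
percentage points of the target 0.44 — event rate, follow-up scale and
median survival are chosen to resemble a typical newly-diagnosed
multiple-myeloma cohort.

Two presets: `tiny` (50 genes × 30 samples × 6 sets, 2 active) for fast
unit tests, and `default` (2000 genes × 400 samples × 60 sets, 3 active)
for recovery and robustness experiments. The recorded seed alone
regenerates a bundle bitwise.

*What the generator does not emulate:* probe-level artifacts, batch
structure beyond a global location/scale shift, heavy-tailed or
platform-specific noise, gene-gene correlation beyond the shared latent
activities, informative censoring, and the sheer pathway counts of real
collections (thousands of sets). Tests passing on this generator
demonstrate the machinery is correct and the pipeline leak-free under
the stated model; they do not by themselves establish predictive
performance on real cohorts.

## Problem sizes used in the shipped checks

The heaviest shipped checks run the study-scale preset (2000 genes,
n = 400, 70/30 split) over 20 simulation seeds for pathway recovery, 20
mask/impute replicates at 5% missingness for robustness, and 200
simulated cohorts × 100 splits for the t-test calibration; scoring and
metric oracles use exhaustive brute-force enumeration at small n. These
sizes were chosen so each property is measured with comfortable
Monte-Carlo margin while the whole suite stays desk-scale.

## Known limitations

* The Cox solver is first-order; at λ = 0 on ill-conditioned designs a
  Newton method would converge faster (agreement with Newton solutions
  is verified to 1e-3 at the tested sizes).
* Overlap handling by column duplication means a shared gene's total
  effect is split across its pathways; overlap-aware group penalties are
  out of scope.
* The corrected resampled t-test is known to be conservative; it is used
  for pairwise model screening, not confirmatory inference.
* IBS on external cohorts inherits the training baseline hazard.
* Wilcoxon signed-rank comparison between models on bootstrap replicates
  is not implemented; the corrected resampled t-test covers the
  internal-validation comparisons.
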