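# Methods

This note documents the statistical models, defaults and design choices
behind `gliostrat`, in the order the pipeline runs.

## Synthetic cohorts

The generator emulates the statistical shape of a log2-scale microarray
cohort, not its chemistry. Expression marginals are Gaussian (mean 8, sd 1 —
the conventional post-normalization scale for U133A-class arrays); there is
no probe-level chemistry, batch structure or RMA preprocessing. Survival
follows a proportional-hazards model: each planted probe contributes
`β · 1[x > cohort median]` to the linear predictor, and event times are drawn
from an exponential (default rate 1/400 days) or Weibull baseline scaled by
`exp(lp)`. "High" is defined against the cohort median to mirror the 0/1
output coding used throughout the pipeline.

Censoring is independent exponential; its rate is solved numerically
(Brent's method) so that the expected censored fraction, conditional on the
realized event times, equals the requested `censoring_rate`. This achieves
the target within ±0.05 at n ≥ 1000 and keeps the mechanism simple and
reproducible.

Hub blocks plant `target = link(coupling · hub) + N(0, noise_sd)` with
linear, quadratic or sigmoid links; the DE block shifts a probe set by a
fixed amount in one of two classes. Everything is deterministic given the
spec seed.

Desk-scale defaults are 2,000 probes and 200–500 samples per cohort; tests
and examples use smaller probe panels still. Because the generator satisfies
the proportional-hazards and independence assumptions exactly, passing tests
demonstrate correctness of the machinery under those assumptions — they say
nothing about violations (informative censoring, batch effects, non-PH
hazards) found in real cohorts.

## Survival primitives

Kaplan–Meier estimation, the k-sample log-rank test and Cox regression are
delegated to `lifelines`, pinned to these conventions:

- **Ties**: Efron's approximation (lifelines' only method). It is more
  accurate than Breslow's, which some legacy software defaults to; with the
  near-continuous survival times this package deals in, the difference is
  negligible.
- **Inference**: Wald tests and 95% CIs `exp(β ± 1.96·se)`, matching the
  "HR (95% CI)" reporting convention of the field.
- **Convergence**: lifelines' Newton solver, 50 step cap; constant
  covariates are rejected before fitting, and fits require at least as many
  events as covariates.

Multiplicity adjustment (`BH`, `Bonferroni`) wraps
`statsmodels.stats.multitest.multipletests`.

## Optimal-cutpoint screening

`optimal_cutpoint` scans every unique expression value inside the 10th–90th
percentile band as a candidate split (`x > c` = high), computes the
two-group log-rank chi-square for all candidates in one vectorized pass, and
returns the maximizing split. Ties among equally maximal splits break toward
the split closest to the cohort median (the most balanced choice). The
reported direction is the level with more observed than expected deaths.

The selected minimum p-value is anti-conservative — the classic bias of
cutpoint optimization. The Miller–Siegmund correction for a minimum p
selected over a quantile band is therefore computed, and **the panel-wide BH
step is applied to the corrected p by default**. An earlier design applied
BH to the uncorrected minimum p; that cannot control the panel error rate
under the null (the uncorrected minimum p is far from uniform), so the
corrected p was made the screening input. The uncorrected p is still
reported alongside. The correction's asymptotic formula degenerates for
large p and is clipped into `[p_min, 1]`.

Whether a shared or per-cohort cutpoint should carry across cohorts is
genuinely open; the default uses per-cohort cutpoints and requires only
concordance of direction for consensus.

## Cox model reduction

Backward elimination is **batch**: all covariates with Wald p > α are
dropped at once and the model refit, repeating until a fixed point. With two
cohorts, each converges separately, the survivor sets are intersected, and
both models are refit once on the common set. This terminates in at most
(number of probes) rounds per cohort. An empty final model is returned with
a flag rather than raised.

## Prognostic index

`β̄_g` is the arithmetic mean of the two cohorts' final-model log hazard
ratios; the patient score is `Σ 1[x_g > c_g] · β̄_g`, so attainable scores
lie between the sum of negative and the sum of positive coefficients. Risk
groups are score tertiles (quantile bins, tied scores kept together,
relabeled 1..k by ascending median); an alternative cut-optimization mode
was considered and not implemented — quantile binning is parameter-free,
permutation-invariant, and no standard grouping rule exists to match.

Year-survival curves read percent survival at the horizon from each group's
KM life table and solve the 3×3 Vandermonde system exactly, so the quadratic
passes through its three anchors to machine precision. Predictions are
clamped to [0, 100] and flagged when the score lies outside the anchor
range. The quadratic is a reporting device, not a calibrated survival model;
no calibration statistics are computed.

## MLP interactome

The MLP is fixed: one hidden layer (2 sigmoid units), sigmoid output, mean
squared error, full-batch gradient descent with learning rate 0.5 and
momentum 0.1, weights initialized uniform(−0.5, 0.5) from a seeded
generator. Batch (per-epoch) updates, 500-epoch default cap, and early
stopping with patience 25 on a held-out test split (best-epoch weights are
restored). Gradients are verified against central finite differences in the
test suite. Inputs are standardized; screening targets are 0/1 median
splits, interaction targets are the continuous standardized probe min-max
scaled into [0, 1] on the training split (the sigmoid output range).

Screening ranks candidates by mean validation RMSE over Monte-Carlo 60/20/20
resamples (default 50; the same resample splits are reused across candidates
so ranking differences are not resampling noise). Misclassification rate at
0.5 is reported as a secondary column; RMSE is the primary criterion.

The pairwise influence of probe *i* on target *j* is the resample-mean
connection-weight product `Σ_h w(i→h) · w(h→out)` from an MLP trained on the
remaining m−1 inputs — a standard, testable influence measure for one-hidden-
layer networks; the interface isolates it so a perturbation-based measure
could be swapped in. All m(m−1) ordered pairs are evaluated. Hub rules: keep
the top-k (default 100) edges by |weight|; hubs are nodes with ≥5 incident
retained edges (in or out), ranked by summed |weight|, top 3 flagged.

Desk-scale defaults screen ~2,000 probes and infer over the top m = 20–50;
the full-size m = 200 run is a configuration change, and the m = 200 pair
count (39,800) is exercised in the tests with a reduced epoch budget.

## Moderated t and the ensemble classifier

The per-gene two-class contrast uses empirical-Bayes variance shrinkage:
`s̃² = (d₀s₀² + d·s²)/(d₀ + d)` with residual df `d = n − 2`, and p-values on
`d + d₀` df. The prior `(d₀, s₀²)` is moment-matched on `log s²` against the
scaled-F marginal (mean and variance of `log s²` corrected by digamma/
trigamma terms; the trigamma inverse is solved by Newton iteration), with
`d₀` capped at 10⁶ as "effectively infinite". The implementation reproduces
limma's `eBayes` to machine precision on shared input, which the test suite
checks by running limma through Rscript as an independent oracle. `d₀ = 0`
recovers the ordinary pooled t-test.

LOOCV: every fold selects genes (moderated-t p < 0.05) on its training
portion only; a fold selecting nothing falls back to the top-10 genes by
|t| (logged). Learner grids: linear SVM `C ∈ {0.01, 0.1, 1, 10}`; kNN
`k ∈ {1, 3, 5, 7}`; nearest shrunken centroid with shrinkage over 10
quantiles of the standardized centroid offsets (computed per fold); all
tuned by grid search in stratified 5-fold inner CV. The random forest is
fixed at 100 trees with default feature subsampling and no tuned grid —
forest size is not a regularization parameter, and tuning it in the nested
loop multiplied runtime several-fold for no expected gain. Majority-vote
ties go to the class with the higher mean predicted score across learners,
then lexicographically; the vote is invariant to learner order. Gene
ranking is selection frequency across folds, ties broken by smaller mean
fold p.

Desk-scale defaults are 60–100 samples and a few hundred genes; a
508 × 22,277 LOOCV is a configuration change and long-running.

A known property of leave-one-out under label permutation: removing the
held-out sample depletes its class in the training set, biasing null
accuracy slightly below 50%. At n = 60 the effect is mild and the mean null
accuracy stays inside the 95% binomial band around 0.5, which the tests
check.

## IHC scoring

`H = 1·p1 + 2·p2 + 3·p3` with percentages summing to 100 (±0.5 tolerance
for pathologist rounding); repeat sections of one sample are averaged.
Dichotomization is strict-greater-than against a configurable threshold
table whose defaults are the glioma-cohort values (APE1 160, NBN 85,
nuclear PTEN 50, cytoplasmic PTEN 10, PMS2 120); new cohorts can re-derive
thresholds with `optimal_cutpoint`.

## Pipeline and reproducibility

`run_full_analysis` executes intersect → screen → consensus → reduction → PI
(groups, year curves) → optional treatment-stratified KM re-analysis (fixed
cutpoints, no re-derivation per stratum) → per-gene ANN screening and
interactome → ensemble ranking, writing TSV/JSON/SIF artifacts plus a
manifest (version, seeds, config). Identical config and seed give
bit-identical outputs; each stage's files suffice to resume later stages.
An empty consensus or final model short-circuits the downstream stages with
a logged notice rather than failing.

## Known limitations

- The generator's idealized assumptions (see above) mean test passes bound
  correctness, not real-data robustness.
- The Miller–Siegmund correction is asymptotic and conservative at small n.
- Only Efron tie handling is available for Cox fits.
- The interaction weights are influence scores, not causal estimates;
  direction reflects predictive asymmetry under the trained networks.
- The year-survival quadratic extrapolates poorly outside its anchors
  (predictions there are flagged and clamped).
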