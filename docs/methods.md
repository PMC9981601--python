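# Methods

## Signal model and relaxometry

Multi-echo gradient-echo signal in each voxel is modelled as a
mono-exponential decay, S(TE) = S₀·exp(−TE/T2\*), with additive Gaussian
noise. Two fitting routes are provided:

* `log_linear` — ordinary least squares of ln S against TE. Exact on
  noiseless data; biased at low SNR (log transform); a voxel with any
  non-positive intensity cannot be fitted on this route and is flagged.
* `nonlinear` (default) — Levenberg–Marquardt least squares on the
  exponential itself, initialized from the log-linear solution, with tight
  (1e−12) convergence tolerances so noiseless data are recovered to well
  below 1e−6 ms.

Voxels whose fitted decay rate is non-positive, or whose T2\* reaches the
ceiling (default 100 ms — twice the top feature-bin edge, so runaway fits
cannot dominate region means), are treated as non-physical: they are
removed from the output mask and counted, not imputed, so downstream
region statistics remain well defined. Fit quality is the coefficient of
determination against the measured intensities (defined as 1 for an exact
fit to a constant). No Rician/magnitude-bias correction is applied,
consistent with the Gaussian noise model of the synthetic data; on real
magnitude images at low SNR the log-linear route would be biased upward.

Both methods fit in-mask voxels only. Multi-compartment decay, B0
correction and motion are out of scope.

## Features

Eleven continuous candidates per ligament plus dichotomous limb type
(surgical = 1, contralateral = 0, never z-scored):

* Median, mean, SD, skew, Q1, Q3 of the in-mask T2\* values. Quartiles use
  linear interpolation; skew is the adjusted Fisher–Pearson coefficient,
  defined as 0 for a zero-variance sample.
* Average cross-sectional area CSA = ligament volume / ligament length
  (mm²). Length defaults to the mask extent along its principal axis
  (SVD of voxel coordinates) plus one voxel; a measured anatomical length
  can be passed instead.
* Sub-volume proportions Prop 1–4: fractions of in-mask voxels with T2\*
  in [0, 12.5), [12.5, 25), [25, 37.5), [37.5, 50] ms. Bins are half-open
  with the top bin closed; voxels above 50 ms count in the denominator but
  in no bin, so Σ Prop may be < 1. (The four-bin reading resolves an
  ambiguity in how the bin list is usually quoted; "Prop 1–4" forces it.)

**Standardization.** All continuous features are z-scored. A
`StandardizationReference` freezes per-feature means/SDs from the training
table and travels with the fitted model, so a later (e.g. clinical) cohort
is mapped onto the training scale before prediction.

**Scanner harmonization.** Cohorts acquired on scanners with different
echo trains carry per-scanner feature offsets. The stand-in harmonization
is per-scanner z-scoring; by default the z-scores are rescaled to the
pooled cohort mean/SD. The rescaling matters: plain per-scanner z-scores
live on a unit scale, and standardizing *those* against a porcine
reference would push the whole cohort several SD outside the training
range, where tree ensembles predict a constant. Removing scanner
location/scale while preserving the pooled physical scale is what
reference-based harmonization methods effectively do. This stand-in
removes location/scale effects only; real harmonization also addresses
covariance and site-by-feature interactions.

## Model lab

* **Split**: random, grouped by subject (both limbs together), test
  fraction 0.2 (65 subjects → 52 train / 13 test).
* **RFE-CV**: at each round a random forest (300 trees, m-try = p/3) is
  fitted on each of 5 CV folds; feature importance is *permutation
  importance on the held-out fold* (mean increase in validation MSE over 5
  shuffles, batched into a single predict call per fold), averaged over
  folds; the least important feature is dropped until 3 remain.
  Permutation-on-validation is used instead of impurity importance because
  impurity importance dilutes across correlated proxies and cannot
  distinguish an exact determinant from its correlates — with it,
  elimination keeps compound summary features (the in-mask mean) over the
  true inputs of a planted signal. A redundant proxy scores ≈ 0 under
  validation permutation once the determinants are in the model.
* **Hyperparameter search**: random search (default 60 draws, 20 in the
  runtime-reduced suites) over per-family lattices spanning the declared
  ranges — log-spaced for scale parameters (SVM C 0.1–1000, gamma
  1e−4–1, tree counts 100–2000, XGBoost learning rate 0.01–0.7), linear
  otherwise, categoricals verbatim — scored by 5-fold CV mean absolute
  error with folds shared across candidates; then a grid search over the
  axis-aligned ±1-notch neighbourhood of the winner (ordered numeric axes
  only; a "notch" is undefined for kernels/losses/booleans). A full
  Cartesian ±1 grid over 7 hyperparameters would cost 3⁷ × 5 fits and buy
  nothing. Final model refit on the full training set. The scikit-learn
  backend names the RF criteria `squared_error`/`absolute_error` and has
  no `max_features="auto"`; "Auto" maps to 1.0 (all features).
* **LM benchmark**: OLS (statsmodels) on the fixed feature set
  {Prop 1, Prop 4, CSA, limb type}; no search.
* **Evaluation**: MAE on the withheld test set; 95% CI by percentile
  bootstrap (2000 resamples, seeded). Paired model comparison: two-sided
  Wilcoxon signed-rank on per-sample absolute errors (exact distribution
  when n ≤ 25 with no ties/zeros, zero differences dropped), plus the
  percent MAE decrease with a paired-bootstrap CI.

## Risk stratification

Predicted failure loads are min-max scored:
score = (F − F_min)/(F_max − F_min). Subjects with score ≤ t form the low
group (predicted positive). The threshold sweeps every distinct score;
J = TPR − FPR is maximized, ties broken toward the smallest threshold
(fewest subjects labelled at-risk). The ROC is traced by the same sweep
and integrated by trapezoid. Incidences are reported per group; the
percent risk increase is primarily computed from incidences rounded to one
decimal — the only arithmetic consistent with how such figures are usually
quoted (the raw-count value is also reported). A zero-incidence or empty
group leaves the increase undefined (reported as such, never infinite).
Association is tested with the likelihood-ratio chi-square
G = 2·Σ O·ln(O/E), 0·ln 0 ≡ 0, against χ²(1); no continuity correction.

One caveat found while testing: the tempting invariant
"AUC ≥ (TPR − FPR + 1)/2 at the Youden point" is false for empirical
staircase ROCs (the curve need not lie above the chord); the true bound
AUC ≥ TPR·(1 − FPR) is asserted instead.

## Synthetic cohorts

The generators emulate the statistical structure the analysis assumes,
not MRI physics (mono-exponential decay only; no B0 inhomogeneity,
partial volume or motion; Gaussian rather than Rician noise, adequate at
the SNRs used and keeping the fits unbiased).

* **Tissue**: per-voxel T2\* inside a discretized ellipsoid (semi-axes
  ≈ 4 × 4 × 11 mm with ~10 % lognormal subject jitter on girth and
  length) is a two-component mixture: organized N(10, 3²) ms and
  disorganized N(35, 6²) ms. Per subject, the component means shift
  (truncated normal, ±2 SD; SD 0.7 ms organized, 1.75 ms disorganized by
  default) and the component SDs scale (lognormal, SD 0.45 in log), so
  quantile features and tail-mass features vary with partially independent
  latent factors. The disorganized voxel fraction is Beta-distributed —
  surgical Beta(12, 20) (mean 0.375), contralateral Beta(3, 34)
  (mean 0.08) — clipped to [0.02, 0.6]; surgical limbs therefore have
  higher mean T2\*, higher Prop 4 and slightly higher Q1, and a thicker
  ellipsoid. Values are truncated to (0.5, 80) ms.
* **Load model** (defaults): F = 6200 − 1100·limb − 230·Q1 − 2400·Prop4
  + 4·CSA − 2000·limb·Prop4 + ε, ε ~ N(0, 150²) N. Coefficients were set
  so that (i) contralateral limbs land at ≈ 3000–4500 N and surgical limbs
  at ≈ 800–2500 N, spanning the hundreds-to-≈4000 N range reported for
  porcine tensile tests; (ii) Q1 and Prop 4 — the quantities tied to the
  most and least organized tissue — are genuine drivers, not passengers;
  and (iii) the limb × Prop4 interaction provides the nonlinearity that
  separates tree ensembles from the linear benchmark. Signs are validated
  (load must decrease with Q1, Prop 4 and surgical status); the expected
  load is checked positive at typical features at configuration time, and
  rare joint-extreme subjects are floored at 50 N at draw time.
* **Outcome model**: revision ~ Bernoulli(σ(a − 0.004·F)). When the
  intercept is not given it is solved per cohort so the mean probability
  equals the target incidence (default 6/46 ≈ 13 %), matching the
  low-incidence clinical setting.
* **Clinical cohort**: 46 surgical limbs, 10 on a "prisma"-like scanner
  (first echo 2.5 ms) and 36 on a "trio"-like scanner (first echo 3.4 ms,
  +2 ms additive T2\* bias) — the offset the harmonization step must
  remove.
* **Seeding**: one cohort-level `SeedSequence` spawns one child per
  subject and grandchildren per limb/draw, so any subset of a cohort is
  bit-reproducible and adding subjects never perturbs earlier ones.

**The planted-recovery configuration** (`planted_cohort_config`) exists to
validate the selection machinery, not to mimic biology: both limb types
share one tissue distribution (limb enters the load only through its own
term), the disorganized fraction is nearly constant (Beta(60, 100)), and
subject variation flows through the component spreads and the disorganized
mean. This makes limb type, Q1 and Prop 4 the only features carrying their
respective load components, i.e. the planted signal is identifiable — a
precondition for demanding that RFE-CV recover it. On the default
biology-like cohort the features are deliberately collinear (one latent
healing factor drives most of them), and there selection legitimately
returns compound summaries instead.

**What passing these tests does and does not show.** The synthetic cohorts
have exactly the structure the models assume: mono-exponential decay,
mixture tissue, a low-dimensional load model. Passing shows the pipeline's
operations are correct and the protocol can find planted structure at
these sample sizes; it does not show that real healing ligaments follow
this load model, that real feature–load relations are this strong, or that
the reported clinical threshold would transfer.

## Problem sizes and numerical choices

Test suites run the study-scale conditions (65 limb-pairs, 46-subject
clinical cohorts, 20-seed Monte-Carlo repetitions) but scale down costs
orthogonal to what is being checked: synthetic volumes are 24×24×40 at
0.5×0.5×0.8 mm (≈ 4000 in-mask voxels — ample for stable region
statistics), feature tables are computed from the ground-truth maps except
where the render → refit round trip is itself under test, the
model-ordering suite uses the reduced search (20 random draws,
squared-error criterion — the absolute-error criterion is an O(n²)
outlier in fit cost and orthogonal to the RF-vs-LM comparison), and its
RFE uses a 100-tree forest. Percentile bootstraps use 2000 resamples
(200 where only the point estimate is asserted). All tolerances asserted
in tests are stated there: 1e−6 ms for noiseless relaxometry, 1e−10 for
likelihood identities, 0.05 for permutation-null AUC.

## Known limitations

* The harmonization stand-in ignores feature covariance across scanners.
* Permutation-importance RFE needs its validation folds to be informative;
  with very small cohorts (< ~20 subjects) the importance estimates get
  noisy and selection degrades gracefully toward arbitrary 3-subsets.
* The AdaBoost and XGBoost families are exercised functionally but the
  headline ordering property is only asserted for RF vs LM.
* The score threshold and AUC on a synthetic clinical cohort depend on the
  generator's outcome model; they are demonstrations, not predictions.
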