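# Methods

## The model

`normap` implements normative modelling for mass-univariate biological
data: instead of comparing group means, it charts the expected value *and*
the expected variation of a response across a reference cohort as a
function of clinical covariates — the statistical analogue of a
paediatric growth chart — and then scores individuals against that chart.

For each response location *j* (a voxel, vertex, or region; any column of
a subjects × locations matrix) the response is modelled as

    y = f(x) + ε,   f ~ GP(0, k),   ε ~ N(0, σ²_nj)

where *x* are the covariates. The kernel is a squared-exponential with
one length-scale per covariate (automatic relevance determination, so the
model learns how much each covariate matters) — optionally summed with a
linear kernel. Hyperparameters (length-scales, signal variance, noise
variance σ²_nj) are estimated by type-II maximum likelihood: L-BFGS-B in
log-parameter space with analytic gradients and seeded multi-restart
initialization. Responses are centred and covariates standardized on the
training subjects only; constants are restored at prediction.

Predictions at a query point return an expected response ŷ_ij and a
noise-free posterior function variance σ²_ij that grows when
extrapolating beyond the training covariates. The deviation of subject
*i* at location *j* is the Z-score

    z_ij = (y_ij − ŷ_ij) / sqrt(σ²_ij + σ²_nj)

combining prediction error, predictive uncertainty and normative noise.
The subjects × locations matrix of z_ij is the subject's normative
probability map (NPM). Centile surfaces for charts are
ŷ + Φ⁻¹(c)·sqrt(σ²_ij + σ²_nj), non-crossing by construction.

Estimation runs under grouped k-fold cross-validation (default k = 10):
families are assigned to folds atomically by a seeded greedy balancing of
subject counts, so related subjects never straddle a train/test split and
every z_ij comes from a model that never saw subject *i*. A final
all-data model per location is kept for charts and for scoring new
cohorts ("transfer" mode). Predictive quality is summarized by the
standardized mean squared error (SMSE = cross-validated MSE divided by
the variance of the test targets, averaged over folds); values below 1
mean the covariates carry signal at that location.

## Subject-level abnormality and localization

A subject's multivariate deviation is compressed by a block-maxima
device: the subject is one block, and their summary deviance is a
trimmed mean of the extreme tail of their Z values — by default the 90%
trimmed mean of the top 1% (tail size = ceil of 1% of the valid
locations; 45% of the tail block is removed from each end, floored, with
at least one survivor). Positive, negative (top 1% of −Z, reported with
negative sign) and absolute variants are available, because over- and
under-expression relative to the norm carry different information. The
trimming convention removes `trim_total` of the *tail block*; the
alternative reading (keep 90% of the block) is one configuration change
(`trim_total = 0.10`).

Across the cohort these block summaries follow an extreme value
distribution. A GEV is fitted by maximum likelihood (Gumbel enforced
below n = 30; Gumbel fallback if the GEV fit degenerates), and each
subject's upper-tail probability under the fitted EVD is their outlier
p-value. By default the fit includes the subject under test (cohort-level
usage); a leave-one-out option exists for strict inference. The fit is
per deviance mode, since the three tails answer different questions.

Spatial localization is separate: per subject, two-sided normal p-values
at each location are thresholded by Benjamini–Hochberg FDR (default
q = 0.05), giving the individualized map of deviating locations; a
per-location count of deviating subjects is provided as an overlap
summary. Two-sided testing is used because deviations in both directions
are meaningful.

Tail correlations relate deviance to a symptom score: subjects are ranked
by deviance *magnitude* (for the negative mode, by the negated negative
deviance, so "more deviant" sorts first) and a Pearson correlation
between magnitude and symptom is computed within the top 1–20% subsets.
Correlating the magnitude rather than the signed score makes "more
deviant ↔ more symptomatic" appear as a positive r in every mode. A
constant symptom vector within a subset yields r = NaN (undefined), never
zero.

## Synthetic cohorts

The generator (`normap.synthetic`) produces cohorts with exactly the
structure the method assumes, so every stage is testable without any
data download:

* two correlated bounded covariates drawn via a Gaussian copula with Beta
  marginals (right-skewed, mimicking area-under-curve trait scores on
  [0, 1]);
* families of size 1–3 sharing a random intercept per location
  (sd 0.3), so grouped cross-validation demonstrably matters;
* a fraction (default 30%) of locations carrying a smooth random
  cubic-polynomial surface of the covariates (unit sd), the rest pure
  noise (unit sd);
* planted outlier subjects (default 5%) receiving additive shifts at a
  sparse idiosyncratic location set (default 1% of locations), of
  magnitude 4 total-SD scaled by a log-normal factor (sd 0.9 in log
  space; 0 plants the magnitude exactly). The heavy-tailed spread makes
  the most deviant subjects spread out rather than piled at a ceiling,
  emulating the near-deterministic extreme-tail deviance–symptom link
  the method is designed to expose;
* symptoms under four mechanisms: `null`; `extreme-of-normal` (symptoms
  track the position along the covariate principal axis — high symptoms
  within the normal spectrum); `deviance-linked` (symptoms track the
  injected deviation magnitude, noise sd 0.15); and `mixture`, in which
  the two subpopulations coexist — the scenario where only the
  deviance-linked subjects should drive deviance–symptom tail
  correlations while extreme-of-normal subjects pass every outlier test.

`generate_prior_cohort` additionally simulates responses directly from
the GP prior (shared uniform covariates, SE-ARD kernel, length-scale 0.3,
unit signal and noise variance): the model class then matches the
generator exactly, which is the reference condition for calibration
checks of the cross-validated Z-scores.

What the generator does **not** emulate: realistic acquisition noise or
spatial correlation between locations, task-level signal generation,
motion artifacts, non-Gaussian heavy-tailed measurement noise, or
covariate measurement error. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under its own
assumptions, not that any particular real dataset satisfies them.

## Numerical choices

* Cholesky factorization with a jitter ladder (0 → 1e−4 of the mean
  kernel diagonal in decade steps); exhausting the ladder raises, never
  silently degrades.
* Hyperparameters live in a log-space box (|log θ| ≤ 25) to keep
  exponentials finite.
* **Length-scale floor.** Length-scales are bounded below at the median
  nearest-neighbour spacing of the standardized training inputs.
  Maximum-likelihood SE-ARD fits possess degenerate optima in which
  length-scales fall below the data's resolution and the kernel
  interpolates observation noise: the fitted noise variance collapses
  toward zero and held-out deviation scores explode at exactly the
  noise-dominated locations a mass-univariate analysis is full of.
  Structure finer than the input spacing is unidentifiable from the data,
  so the floor removes only that degenerate family. It can be overridden
  or disabled per fit (`length_scale_floor`).
* Per-location fit failures are flagged and excluded downstream (never
  imputed); a run with more than 5% failed locations aborts.
* Deviance tail bookkeeping uses ceil for the tail size and floor for
  per-side trim counts, always retaining at least one value.
* All randomness (restart jitter, fold assignment, cohort generation)
  flows from explicit integer seeds; every pipeline stage is reproducible
  bit-for-bit given (inputs, config, seed).

## Design choices where the design was open

* Kernel family: SE-ARD by default (the hyperparameters must encode both
  the scale of the function and per-covariate relevance); a linear+SE sum
  is available by configuration.
* Covariates are standardized before kernel evaluation by default; the
  choice is recorded in the model state.
* Cross-validated deviance scores use each fold's own learned noise
  variance for its held-out subjects.
* The EVD is fitted per deviance mode on the full cohort's
  cross-validated scores.
* Chart anchor points ("reference subjects") are placed along the first
  principal axis of the covariates relative to a configurable baseline
  point; the default rectangular chart grid spans observed covariate
  ranges with 50 points per axis.
* Tabular I/O is TSV/CSV with a `subject_id` column; responses may be a
  wide matrix file or a 4D NIfTI plus mask (maps are written back into
  the mask geometry). CIFTI input is not currently supported — surface
  data can be supplied through the matrix route.

## Problem sizes used in tests and the acceptance script

The package's reference desk-scale condition is 500 subjects × 2000
locations. The shipped test suite and `scripts/acceptance.py` run the
same checks at reduced sizes chosen to preserve the feature each check
depends on while keeping a laptop run in minutes:

* Z calibration: GP-prior cohorts, 300 subjects × 12 locations, k = 4,
  6 seeds (pooled mean and variance of ~21k cross-validated Z values).
* Outlier-rate calibration: 160 × 110 null cohorts, 4 seeds.
* Detection power: 120 subjects × 1000 locations with +4 SD planted at
  10 locations (1%), k = 3 — the tail block then averages ≈10 planted
  cells, the feature that gives the test its power at full scale.
* Mixture tail correlations: 200 × 100 cohorts, 10 seeds; the smallest
  top fraction is 2.5% so the extreme-tail subset keeps five subjects,
  the tail count of the reference analysis. "Positive-deviance
  correlations are null" is operationalized as the pooled share of
  nominally significant positive-mode correlations staying ≤ 0.15 and
  the pooled mean r staying within ±0.15 — a calibration statement that
  is robust to the strong dependence between nested subsets, rather than
  a per-seed "no p < 0.05 anywhere" rule, which even a true null fails
  too often.

## Known limitations

* Type-II ML ignores hyperparameter uncertainty; cross-validated Z
  variance runs a few percent above 1 at small training sizes (the bias
  shrinks with n; approximate hyperparameter marginalization is out of
  scope).
* The residual miscalibration is not uniform over covariate space: it is
  largest where the covariate density is thin (the extremes of skewed
  covariates), so at small cohort sizes a subject's deviance tail is
  weakly correlated with how extreme their covariates are. Any symptom
  that also tracks covariate extremeness then acquires a weak genuine
  correlation with deviance in *both* tails. In our mixture simulations
  this coupling falls from r ≈ 0.1–0.25 at 200 subjects (k = 3) to
  ≈ 0.06 at 300 subjects (k = 4) and is expected to be near-nominal at
  the reference scale; "null" positive-tail behaviour at desk scale is
  therefore approximate, not exact.
* Exact GP inference is O(n³) per location per fold; the toolkit targets
  cohort sizes in the hundreds to low thousands, not biobank scale.
* Locations are modelled independently; no spatial regularization or
  smoothing across locations.
* Non-Gaussian response likelihoods, multi-output GPs and longitudinal
  trajectories are out of scope.
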