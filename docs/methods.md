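# Methods

## The two-step extraction procedure

The package distills an arbitrary black-box risk scorer
`f : R^d -> [0, 1]` into an axis-aligned binary tree in two steps.

**Step 1 — the black box.** Any conforming scorer is accepted; the shipped
references are an L2 logistic regression and a small feed-forward network
(scikit-learn `MLPClassifier`). Training follows the protocol used
throughout the package for imbalanced readmission labels: stratified k-fold
cross-validation for hyperparameter choice (default k = 5) with up- or
down-sampling applied to the training folds only (default "up", which
discards no information). Features enter every model unscaled.

**Step 2 — the surrogate.** A diagonal-covariance Gaussian mixture

    p(x) = Σ_{i=1..K} φ_i N(x; μ_i, diag σ_i²)

is fitted to the training features by EM, synthetic vectors `x̃ ~ P` are
drawn, and each is labeled with the scorer's *continuous* score
`ỹ = f(x̃)`. A CART regression tree fitted to `(x̃, ỹ)` is the proposed
surrogate. The comparison arm binarizes `ỹ` at a threshold (0.5 by default;
a score exactly at the threshold maps to 1) and fits a Gini classification
tree — the classic distillation recipe, retained here to quantify the
information it loses.

Because labeled pairs are free, `m` defaults to 10x the training size
(capped at 100,000). Every extraction returns a fidelity report computed on
a fresh synthetic batch: squared correlation between tree and scorer
predictions, AUC of tree scores against the scorer's binarized labels, and
quantiles of the absolute prediction gap. A zero-variance pair (constant
scorer matched by a single leaf) reports R² = 1 with a `zero_variance` flag.

## The mixture model

* EM with responsibility-weighted M-steps; the log-likelihood path is
  recorded and asserted non-decreasing (up to 1e-9 slack) in tests.
* Convergence on absolute log-likelihood gain below `tol` (default 1e-6),
  `max_iter` 500.
* Initialization: k-means centers (scikit-learn `KMeans`, one start, seeded)
  by default; `random` picks K data rows. Variances start at column
  variances, weights uniform.
* Variance floor: 1e-6 x column variance (minimum 1e-12). Binary and one-hot
  columns are fitted as continuous coordinates; without the floor they
  collapse into zero-width spikes. Sampled values are *not* rounded before
  scoring — the scorer sees raw reals, and clipping to physical ranges is
  available but off by default (`ExtractionConfig.clip_ranges`): the
  surrogate should approximate `f` wherever `P` puts mass.
* K is a free parameter; `select_K` picks it by BIC
  (−2·loglik + [(K−1) + 2Kd]·log n, ties to the smaller K) over 1..10 when
  not given. The distillation benchmarks fix K = 10 for speed and
  determinism of the study configuration.
* The GMM is fitted on the *raw* training-split features — never test rows,
  and never the rebalanced (minority-duplicated) matrix, which would distort
  the sampling distribution toward the minority class's feature profile.

## The tree learner

Hand-implemented CART, kept free of scikit-learn so that the split search,
tie-breaking, and rendering semantics are pinned down in one file (sklearn
trees appear in the test-suite as an independent cross-check only).

* Candidate thresholds: midpoints between consecutive distinct sorted
  values — on 0/1 columns this yields exactly the 0.5 cutoff.
* Criterion: summed child squared deviation (regression) or n x Gini
  (classification; for binary targets the two rank splits identically).
* Tie-break: lowest feature index, then smallest threshold. "Tied" means
  within 1e-9·(Σy²+1) — far above summation-order noise (~1e-15 relative)
  and far below any real cost difference — so fits are deterministic
  regardless of vectorization.
* Stopping: `max_depth`, `min_leaf` per child, and a minimum cost reduction
  `min_gain` (default 1e-7). Defaults `max_depth=4, min_leaf=50` produce a
  tree readable at a glance; the distillation benchmarks deepen to 8–10
  because a depth-4 surrogate underfits a smooth scorer (held-out fidelity
  R² ~0.4 vs ~0.75), trading some readability for fidelity. Both settings
  are ordinary configuration; depth selection by cross-validation is left to
  the caller.
* Routing: `feature <= threshold` goes left; recorded in the JSON
  serialization so renders are unambiguous. DOT output shades each node in
  proportion to its mean predicted risk.

## Evaluation machinery

* Metrics: accuracy, precision, recall, F1 (reported as "F-value"), MCC
  (0 when any confusion-matrix margin is empty), midrank Mann–Whitney AUC
  (ties get half-credit; undefined and rejected on single-class labels), and
  AUPRC as average precision with descending-score ties processed as blocks.
  Average precision — not trapezoidal interpolation — is used deliberately:
  its no-skill baseline equals the positive prevalence exactly, a property
  the tests verify by simulation (mean AP of random scorers at 14.3%
  prevalence → 0.143).
* Replication protocol: R stratified 70–30 train/test splits (default
  R = 50), training-portion rebalancing, full metric panel per replication.
  Stratification is a deliberate refinement of a plain random split so that
  every test set contains positives.
* Conservative standard errors: sample SD (denominator R−1) times
  `sqrt((R−1)/χ²_{α,R−1})` — the one-sided upper confidence limit on a
  normal population SD — equal to 1.2017 at R = 50, α = 0.05. A candidate
  model is flagged `*` when its mean exceeds the baseline's by strictly more
  than 2 baseline adjusted SEs, `**` beyond 3 (one-sided; a deficit is never
  flagged). With the measured baseline SDs of 0.0093 (accuracy) and 0.0088
  (AUC), these rules give thresholds 0.0224 and 0.0212 at four decimals. The
  analogous AUPRC computation gives 2 x 1.2017 x 0.0049 = 0.0118, not the
  0.0116 sometimes quoted from rounding the adjusted SD first
  (2 x 0.0058 = 0.0116); the implementation always works from unrounded SDs.

## The synthetic cohort generator

The generator emulates the administrative admission tables this method is
aimed at: one row per visit with patient/visit ids, admission and discharge
dates, and a feature roster of age, Charlson and van Walraven comorbidity
indices, length of stay, secondary-diagnosis count, emergency-admission,
nursing-home-discharge, public-insurance, surgery and ICU flags, transfer
count, specialty (7 levels, shares dominated by medicine/surgery/
orthopedics/cardiology), and admission month/year/day-of-week. Prior-visit
counts are *emergent* from each patient's simulated history, not drawn.

Per patient: an initial admission date, then a chain of visits. Each visit
draws features from configurable marginals, computes its true 30-day
readmission probability `p = σ(β₀ + Σ βⱼ xⱼ)`, and draws the gap to the next
admission: uniform on [1, 30] days with probability p; else uniform on
[31, 90] with probability `late_readmit_prob`; else 91 days plus an
exponential tail (`interarrival_scale`, default 150 days). The chain stops
at `max_visits_per_patient` or the end of the observation window. This link
makes 30-/90-day labels consistent with gaps by construction and gives
`y30 <= y90` row-wise identically.

**Calibration.** A patient's last recorded visit is always labeled 0, so
the realized per-visit prevalence sits below the mechanism's mean risk.
`calibrate_mechanism` therefore bisects the intercept (then
`late_readmit_prob`) against the *realized* label means of seeded pilot
cohorts, followed by a one-step correction on fresh pilot seeds (realized
30-day prevalence scales ≈ e^intercept at low risk; the 31–90-day excess
scales linearly in `late_readmit_prob`) — the correction exists because
bisection against a noisy pilot average stops as soon as noise dips inside
tolerance, which biases the constant by up to the pilot SE. The shipped
default mechanism is the output of this procedure against the 14.3%/24.4%
targets; held-out cohorts realize 0.142/0.242 on average with per-cohort
binomial noise of ~0.003.

Prevalence targets are calibrated *per visit*. Quoted readmission rates are
sometimes per patient; with a mean of ~3 visits per patient the two differ,
and the per-visit convention matches how the labels enter every model.

Randomness: one root seed, split per patient by a counter-based sub-seed
(`default_rng([seed, patient_index])`), so enlarging a cohort never perturbs
earlier patients' draws and identical configs reproduce tables byte for
byte. Age and insurance class are held constant within a patient; the other
features redraw per visit.

**What the generator does not emulate** — and hence what a green test does
not establish: real joint dependence between features (marginals are
independent given the visit), disease progression across visits, seasonal
admission patterns, coding noise in comorbidity indices, and informative
censoring. Tests on this world demonstrate that the machinery is correct
and that the regression-over-decision distillation advantage holds under a
known logistic truth; they cannot certify performance on any real cohort.

## Label and feature conventions

* 30-/90-day labels: visit k is positive iff visit k+1 exists and
  `admit_{k+1} − discharge_k <= window`, boundary inclusive, whole-day
  arithmetic. The last visit is 0.
* Prior visits: count of strictly earlier visits with
  `0 <= admit_k − discharge_j <= 180`, boundary inclusive. The literal
  running-sum form that includes the always-true j = k term is available via
  `include_self=True`; the default counts previous hospitalizations only.
* Visits admitted within 90 days of the table's last admission date are
  flagged `censored` (their labels may be truncated zeros); they are kept by
  default and can be dropped with a switch.
* Rows missing any roster feature are dropped and counted; no imputation.
* Categoricals are one-hot encoded over the full observed level set (no
  reference level dropped — trees are indifferent to collinearity, and full
  encoding keeps every level nameable in renders). Admission month and
  day-of-week stay ordinal integers to limit design-matrix width.
* Specialty filtering: mode "all" excludes pediatrics and
  obstetrics/gynecology; mode "main" keeps medicine, surgery, orthopedics,
  cardiology. Labels and history features are computed on the full visit
  history *before* filtering, so removing a specialty cannot sever the
  visit pair that defines an earlier visit's label.

## Known limitations

* The diagonal GMM cannot represent feature correlation within a component;
  with few components, synthetic samples can land in regions the scorer
  never saw, and surrogate fidelity on real-world-shaped data is capped by
  this mismatch (held-out R² ~0.75 in the benchmark configuration).
* Trees are unpruned; depth is the only capacity control.
* The headline significance rule compares against the baseline's adjusted
  SE; a paired-difference alternative (`significance_flags(..., paired=True)`)
  exists but is off by default.
* `replicate` re-trains the black box and refits the GMM per replication,
  which is honest but makes R = 50 with an MLP scorer computationally
  noticeable (~minutes at 10⁴ visits).
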