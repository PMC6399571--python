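# Methods note

This note records the model, the assumptions behind the synthetic cohort
generator, every default parameter with its rationale, and the numerical
choices made in the implementation. No empirical claim here goes beyond
what the code in this repository computes.

## 1. Model

A discrete Bayesian network `B = (Pr, G)`: a directed acyclic graph `G`
over finitely-valued nodes plus one conditional probability table (CPT) per
node. The joint factorizes as `Pr(x) = Π_v Pr(x_v | x_parents(v))`.

**CPT row order.** A node with parents `(p1, …, pk)` has one CPT row per
parent configuration, ordered lexicographically by the parents' declared
state lists — exactly NumPy's C-order `ravel_multi_index` over the parent
cardinalities. `BayesNet.row_index` is the single authority for this
mapping; sampling, counting, and inference all go through it.

**Estimation.** Each CPT row is the Dirichlet-weighted blend
`p̂ = (n·P_D + n0·θ) / (n + n0)` of the empirical row frequencies `P_D`
(from `n` matching windows) and a prior distribution `θ` with equivalent
sample size `n0`. Defaults: uniform `θ`, `n0 = 1` — one pseudo-observation
spread over the states, enough to keep every rare row strictly positive
without visibly biasing well-populated rows. `n0 = 0` gives pure maximum
likelihood and raises on empty rows.

**Missing data (EM).** Windows with missing evidence are handled by exact
expectation-maximization. A window's completions are full joint
assignments, so the E-step needs no message passing: each unique
observation pattern is expanded into its completions, weighted by their
joint probability under the current parameters, and the expected counts are
accumulated; the M-step is the Dirichlet re-estimate above. Iteration stops
when the observed-data log-likelihood gains less than `tol = 1e-4` (a
negligible fraction of typical data log-likelihoods of order 10⁴–10⁵) or at
`max_iter = 100`; non-convergence is reported on the result object, not
raised. Patterns with more than `max_completions = 4096` completions are
refused — exact enumeration is the design, and that bound keeps one
pattern's expansion small relative to the data.

Because the M-step uses the posterior-mean (Dirichlet-smoothed) update
rather than the MAP update, the observed-data log-likelihood is not
guaranteed monotone in theory; with `n ≫ n0` the smoothing perturbation is
O(n0/n) and the sequence is monotone in every scenario the test suite runs
(asserted to −10⁻⁶ slack at 50,000 windows).

**Inference.** Exact variable elimination with the min-degree heuristic
(ties broken by declaration order). The daily risk is the posterior of the
fall node given all non-missing window evidence; missing variables are
marginalized by the elimination itself, never imputed, and the fall node is
never accepted as evidence. A brute-force joint-enumeration oracle
(`joint_enumerate`, refusing state spaces beyond 2²⁰) exists solely for
verification; the test suite asserts agreement within 10⁻⁹ on 200 random
networks.

**Sensitivity.** One-variable-at-a-time: entropy reduction is the exact
mutual information (bits) between the fall node and each other node under
the fitted joint; variance reduction is the expected drop in the target's
variance over its declared numeric state values. Per-node values are summed
by subgroup tag (demographics, administrative, assessment/diagnosis,
intervention, KPCS, medication, risk tool).

## 2. Windowing

- Nonfaller admissions contribute one negative window per whole hospital
  day, anchored at admission: `[d, d+1)` for day `d`.
- Faller admissions contribute exactly one positive window per fall — the
  24 hours ending at the fall time — and nothing else; days after the final
  fall are dropped (`keep_post_fall=True` restores them as negatives).
- Evidence is last-observation-carried-forward. Observations are indexed at
  the start of their day; a window ending at `end_day` may use observations
  through day `floor(end_day − 1e-9)` (an observation charted on day `d`
  enters windows extending past time `d`; the epsilon keeps a negative
  window of day `d` from seeing day `d+1`'s chart). The cutoff is clamped
  at day 0: admission assessments are charted at admission and precede
  every window, including one ending in the first charted hour of the stay.
- Splits are by **patient**; the 90/10 folds are repeated random
  subsampling (`mode="kfold"` gives a true partition instead). Training
  positives are oversampled to class balance by whole-copy duplication plus
  a randomly assigned remainder; test folds are never resampled.
- Derived seeds use `fold_seed(master, i) = (master·1_000_003 + i) mod 2³¹`.

## 3. Synthetic cohort generator

The generator emulates the *structure* of a two-hospital longitudinal EMR
extract, not any real patient data.

What it emulates:

- **Admission-level traits** (sex, age bin, diagnosis group, secondary
  diagnosis, KPCS nursing-intensity group) drawn from configurable
  marginals; the two site presets use the published two-site marginal
  proportions so the synthetic sites differ the way the real ones did.
- **Length of stay**: 1 + a negative binomial matched to the published
  mean/SD (8.54/11.52 development, 8.15/11.28 validation), truncated at 120
  days. Moment matching reproduces the heavy right tail; truncation caps
  pathological draws.
- **Daily contributing factors** (mobility impairment, elimination problem,
  cognitive impairment, fall history, sedative use, fall precaution,
  toileting assistance) with first-order day-to-day persistence 0.8 — a
  state is kept with probability 0.8 and redrawn from its
  marginal-preserving conditional otherwise — so charts change slowly, as
  real ones do. Factor baselines depend on the planted parent traits via
  multipliers normalized to preserve the marginal rate.
- **Risk-tool score** (Hendrich-style in the development preset,
  STRATIFY-style in validation) as a noisy deterministic summary of its
  subscales, which are themselves noisy copies (noise 0.1) of the
  underlying factors.
- **Falls**: per-day Bernoulli from a logistic CPT over the planted risk
  factors. Default log-odds are ln 20 per contributing factor and −ln 4 per
  mitigating intervention — a deliberately strong planted signal, since the
  generator's purpose is to verify that the pipeline *recovers* structure,
  not to estimate realistic effect sizes. The intercept is solved by Brent's
  method against the enumerated parent joint so that the marginal fall
  probability is exactly `target_fall_rate / 1000` (1.95 development, 1.69
  validation). Injury levels follow the published injurious and minor
  fractions (54/238 and 49/54).
- **Missingness**: MCAR per-variable daily drop rates (the validation
  preset drops the risk-tool score at the published unscored-day fraction,
  0.6465), or a policy mode emulating reassessment schedules.

What it does **not** emulate: real covariance between diagnoses and
demographics beyond the planted arcs, ward/unit structure, seasonal or
time-of-day effects, informative (non-MCAR beyond the policy mode)
missingness, transfers, or any real patient record. Its parameter values
are published marginal summaries of the two cohorts, nothing more.

## 4. Evaluation

- **Error rate** at threshold 0.5; the no-information rate is the
  majority-class share, which for rare events is near 1 and easy to beat —
  discrimination is therefore judged by AUC.
- **Log loss** with natural logarithm, probabilities clipped at 10⁻¹².
- **Spherical payoff** `P_correct / sqrt(Σ_j P_j²)`, averaged over cases.
- **AUC** via the Mann–Whitney rank statistic (ties counted ½), verified
  against the explicit pairwise oracle and against the trapezoidal area
  under the ROC polyline (scikit-learn's `roc_curve`).
- **Calibration**: equal-count deciles of the sorted predictions with tied
  predictions kept in one bin, Wilson 95% intervals on the observed rates.

Two-site cohort statistics use the uncorrected Pearson chi-square
(`scipy.stats.chi2_contingency(correction=False)`), the pooled two-sample t
from summary statistics (Welch optional), and rates per 1000 hospital days
compared by the 2×2 chi-square of event-days vs non-event-days.

## 5. Problem sizes and limitations

The acceptance checks run at: 200 random networks (inference), 50,000
windows (parameter recovery, complete and 20% MCAR), 100,000 predictions
(calibration), 50,000 admissions (realized fall rate), and 5,000 admissions
× 10 folds (end-to-end cross-validation); everything completes in well
under a minute on one CPU.

Limitations: exact EM refuses windows with too much joint missingness;
variable elimination is exact but intended for the tens-of-nodes scale of
these models, not hundreds; the cross-validated metrics on synthetic
cohorts verify the machinery and say nothing about performance on real
hospital data; and the generator's strong default signal makes
discrimination easier than any clinical deployment would be.
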