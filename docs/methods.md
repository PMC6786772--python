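# Methods

## Model and estimators

The package works in the model-based (prediction) view of survey
sampling: the finite population's outcomes are one realisation of a
superpopulation model, and estimating the total *T_y = W'y* means
predicting the outcomes of every unit that was not observed. Unit
non-response is treated as *non-ignorable*: the population is stratified
by a response indicator *R* that is related to the outcome, and the two
strata follow separate linear regimes with coefficients β_r, β_nr and
error variances σ₁², σ₂². Errors are independent across units with mean
zero; normality is not required for the bias/variance results, only for
small-sample inference (which the package does not perform — no
confidence intervals are produced).

Three predictors are implemented:

1. **Full-response predictor** — observed sample sum plus model
   predictions of all non-sampled units from a single fit.
2. **Respondent-only predictor** T̂_y1 — fits the respondent regime on
   *s₁* and extrapolates it to all unobserved units including the whole
   non-respondent stratum. Its model bias, conditional on the draw, is
   W₂' x₂ (β_r − β_nr); its model variance is
   σ₁²(n₁ + a₁'H_{s₁}⁻¹a₁) + σ₂²(a₂'H_{s₁}⁻¹a₂). It is retained as
   the comparison baseline and never uses second-call data.
3. **Sub-sampling predictor** T̂* — additionally observes a SRSWOR
   sub-sample *s′₂* of the first-call non-respondents (size
   round(n₂/k), at least 1; round-half-to-even), fits the
   non-respondent regime on it, and predicts only the remaining
   non-respondent units from that fit. Under the OLS assumptions for
   both regimes it is model-unbiased.

The reported closed-form variance of T̂*,

    V_m(T̂*) = n₁σ₁² + n′₂σ₂² + σ₁² a₁'H_{s₁}⁻¹a₁ + σ₂² a₂'H_{s′₂}⁻¹a₂,

is the variance of the estimator itself; the variance of the *prediction
error* T̂* − T_y differs in its leading terms because the observed sums
appear in both the estimator and the estimand. Both views are surfaced:
the closed form verbatim in `theory.var_subsampling`, and the empirical
prediction-error moments in `theory.empirical_prediction_moments`. No
silent correction is applied to the printed formula. Design-averaged
variances are Monte-Carlo means over fresh SRSWOR draws (explicit `reps`
and `seed`), since no closed form over the design is available.

## Ridge (PRR) fitting under super-collinearity

With aggressive sub-sampling the second-call sample can be smaller than
the regressor count (n′₂ ≤ p), making H_{s′₂} = x'x singular. The
non-respondent fit then uses ridge augmentation H(v) = H + vI, defined
for any v > 0 regardless of rank; using the ridge coefficients for the
non-respondent regime only gives the partially-ridge (PRR) total
predictor. Choices made here:

- **Penalty covers the intercept.** H(v) adds v to all p+1 diagonal
  entries, intercept included, matching the estimator's definition; an
  intercept-free penalty is deliberately not the default.
- **Tuning selection.** The admissible range 0 < v < 2[−min(0, ψ₂)]
  is stated in terms of the unknown β₂ and σ₂², so operationally v is
  chosen by leave-one-out cross-validation on the sub-sample over a
  log-spaced grid (default 10⁻⁴…10⁴, 17 points; ties resolve to the
  smallest value). A plug-in admissible cap can truncate the grid. With
  a single observation no cross-validation is possible and the lightest
  grid penalty is used.
- **Error variance for ridge fits** uses divisor n and is flagged
  approximate (`sigma_sq_approx`); ridge has no exact residual degrees
  of freedom.
- **Numerical singularity criterion.** OLS/WLS solve the normal
  equations by Cholesky factorisation and treat cond(H) > 10¹² as
  super-collinear. The automatic policy falls back to ridge both when
  n′₂ ≤ p+1 and when a formally overdetermined system trips the
  condition threshold (the simulation DGP's mean-100 covariates make
  near-saturated fits numerically singular). Every fallback is recorded
  in the estimate's method metadata.

Known heteroscedastic structures (per-unit variances as functions of the
covariates) are handled by WLS with *known* V; iterative/feasible GLS
with an estimated variance structure is out of scope.

## Synthetic data generators

**Two-regime generator** (`make_two_regime_population`): draws covariates
from a configurable law (standard normal by default), assigns the first
N₁ units to the respondent regime and the rest to the non-respondent
regime, and adds regime-specific homoscedastic or heteroscedastic noise.
The generating truth (coefficients, per-unit error SDs, conditional
means) is stored on the population so the Monte-Carlo auditors can
redraw errors from exactly the generating law.

**Simulation DGP** (`generate_simulation_population`): a latent N×p
matrix z ~ N(100, 1) i.i.d. Two covariate constructions are provided
because the defining formula admits two readings:

- `literal` (default): x_ij = (1−ρ)^0.5·z_ij + ρ·z_ij. This is a pure
  per-column rescaling — ρ acts as a scale factor and induces no
  cross-column correlation.
- `latent`: x_ij = (1−ρ²)^0.5·z_ij + ρ·z_{i,p+1} with one shared extra
  latent column — the standard construction that makes ρ a genuine
  collinearity dial.

The coefficient vector γ is the element-wise average of the unit-norm
eigenvectors of H = x'x (covariate columns only, no intercept) whose
eigenvalues exceed 1, after fixing each eigenvector's sign so that its
largest-magnitude entry is positive (eigenvector orientation is
otherwise arbitrary and would make γ ill-defined). If no eigenvalue
exceeds 1 a degenerate-γ error is raised rather than silently zeroing.
The outcome is y = xγ + ε, ε ~ N(0, σ²I).

**NMAR response assignment** (`assign_response_by_quantile`): respondents
are the fraction 1−λ₂ of units in one tail of the *outcome*
distribution — missingness depends on the unobserved outcome, which is
precisely what makes it non-ignorable. `tail="lower"` marks the
low-outcome units as respondents; `tail="upper"` the high-outcome ones.
Both conventions appear in the survey literature; they are exposed as a
parameter rather than hard-wired. The respondent count is
⌈(1−λ₂)N⌉; units exactly at the threshold join the respondent stratum,
and ties heavy enough to swallow the whole population raise a
tie-degenerate error instead of randomising.

**Donor-registry emulator** (`emulate_blood_population`): a synthetic
748-row stand-in for the blood-transfusion donor registry used in the
resampling study, for fully offline runs. It generates donor tenure
(months since first donation), donation count, recency (months since
last donation) and the outcome — total volume donated, a fixed 250 c.c.
per donation — calibrated to the published marginal moments of the real
registry (tenure ≈ 34 ± 24 months, recency ≈ 9.5 ± 8, frequency
≈ 5.5 ± 5.8, heavily right-skewed) and to its dependence structure
(outcome exactly proportional to frequency, strongly correlated with
tenure, weakly and negatively with recency). What it does *not*
emulate: the discrete clumping of real inter-donation intervals, the
registry's exact joint distribution, and any covariate measurement
error. Passing tests on the emulator therefore demonstrate the
estimators' behaviour on registry-*like* NMAR structure, not conclusions
about the actual registry; the real table can be substituted at any time
through `load_population_csv`.

## Evaluation protocols

**Fixed-population resampling** (`bootstrap_protocol`): assign R by
outcome quantile at rate λ₂; repeatedly draw first-call SRSWOR samples
(outer loop, default 300); within each, repeatedly redraw the
second-call sub-sample (inner loop, default 300) and average the
sub-sampling estimate (the respondent-only estimate depends only on the
first call and is computed once per outer draw). Metrics are the
relative bias mean((T̂−T_y)/T_y) and relative MSE mean(((T̂−T_y)/T_y)²)
over outer draws. Outer draws with n₁ ≤ p, with no non-respondents
despite λ₂ > 0, or with a singular respondent fit are rejected,
redrawn and counted.

**Simulation study** (`run_simulation_study`): generates one population
from the DGP per study, runs the same nested loop, and reports
*absolute* bias and MSE (the generated outcomes are already on a
standardised scale), optionally alongside a forced-PRR variant whose
tuning is re-selected from each sub-sample.

**Replication streams.** Every outer replicate runs on a substream
seeded deterministically by (seed, attempt index). This makes runs
bit-reproducible regardless of rejected draws, and gives common random
numbers across configurations that differ only in k or in the ridge
policy — the first-call samples coincide, so k-comparisons are paired
and resolvable at desk-scale replication counts.

**Problem sizes.** Default desk-scale runs use 300×300 resampling
replicates on the 748-unit registry and a 2000-unit simulation
population with 100×50 replicates and p = 5 covariates; these keep the
full evaluation in minutes while leaving the Monte-Carlo error well
below the effect sizes being measured. Full-scale counts (5000×2000 and
2000×500 on N = 10000) are available via `--full` in the CLI or
explicitly through the config objects.

## Numerical and design choices

- Sub-sample size: round(n₂/k) with Python's round-half-to-even, floored
  at 1 when n₂ > 0; k = 1 returns the whole non-respondent sample.
- Quadratic forms a'H⁻¹a are evaluated by Cholesky solves with the same
  10¹² condition criterion as the fitting engines; design-averaging
  rejects (and logs) draws whose fitting matrices fail it, since the
  closed-form variance is unbounded as the sub-sample approaches
  saturation.
- Homogeneous-population special case p = 0 (intercept-only fits) is
  supported throughout; the variance formulas then reduce to the
  classical (N₁−n₁)²/n₁-type scalar forms, which the tests verify.
- Weight vectors: totals use W ≡ 1, means W ≡ 1/N. No
  prediction-variance-optimal weight selection is implemented.
- The respondent-only predictor never borrows second-call information
  even when it is available, preserving its role as the biased baseline.

## Limitations

- λ₁, λ₂ are taken as known (or implied by the assigned R); estimating
  them, e.g. by two-phase sampling, is out of scope, as is modelling a
  response-propensity mechanism.
- Design-based estimators (Horvitz–Thompson / Hansen–Hurwitz weighting)
  and confidence intervals are not provided.
- The ridge tuning criterion is LOOCV prediction error; generalised
  cross-validation and ridge effective-degrees-of-freedom corrections
  are not implemented.
- Polynomial or otherwise nonlinear-in-variables regimes are not
  implemented (the fits are linear in the supplied design matrix, so a
  caller can supply transformed covariates).
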