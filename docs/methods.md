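# Methods

## Measurement-error model

All methods assume classical (random, nondifferential) measurement
error in a single continuous exposure: the observed measure is
W = X + e with e ⟂ X, E[e] = 0, Var(e) = τ². Under this model the naive
coefficient of W in a linear outcome model with covariates C is the true
coefficient multiplied by the attenuation factor
λ = σ²_{X|C}/(σ²_{X|C} + τ²). Two distinct variance ratios matter and
are deliberately kept apart in the API:

- `attenuation_factor(var_x_given_c, tau2)` — the *conditional* ratio,
  which governs the bias of the adjusted coefficient;
- `reliability(scenario)` — the *marginal* ratio Var(X)/Var(W), which
  equals the attenuation only when exposure and covariates are
  independent. The covariate-dependency scenarios exist precisely to
  separate the two: raising the exposure–covariate association raises
  reliability while the attenuation (and hence the bias) stays fixed.

## Estimators

**Naive** (`fit_naive`): OLS or maximum-likelihood logistic regression
of the outcome on the *first* replicate plus covariates, with a Wald
interval. The first replicate is the designated "single measurement";
the remaining replicates are used only to estimate τ².

**Error-variance estimation** (`estimate_tau2_replicates`): per-person
sample variance across the k replicates (denominator k−1), averaged over
persons. Invariant to replicate relabelling and location shifts.

**Regression calibration** (`rc_correct`): naive estimate ×
σ̂²_{W|C}/(σ̂²_{W|C} − τ²), where σ̂²_{W|C} is the residual variance of an
OLS of W on the covariates with denominator n − c − 1 (unbiased under
the linear calibration model). The identical ratio is applied to the
logistic log-odds coefficient; this Rosner-style correction is
approximate — adequate for small-to-moderate effects and/or small τ² —
and documented as such, not as a defect. When σ̂²_{W|C} − τ² ≤ 0 the
correction raises an error carrying both values: a near-null calibration
factor is the known instability of RC and must never be clipped
silently. Covariate coefficients are not corrected.

**SIMEX** (`simex_correct`): defaults follow standard practice — ζ grid
(0.5, 1, 1.5, 2), 100 refits per ζ with independent pseudo-error draws
W + sqrt(ζτ²)·ε, quadratic extrapolation to ζ = −1. Three choices were
genuinely open and are fixed as follows: (i) the naive point ζ = 0
participates in the extrapolation fit — without it a quadratic through
four points is nearly saturated and unstable; (ii) the polynomial fit is
ordinary unweighted least squares on the averaged points; (iii) noise
draws are independent across grid points and repetitions (no common
random numbers). A linear extrapolant is available for diagnostics;
quartic is out of scope. On the exact attenuation curve of the linear
base design the quadratic extrapolant returns 0.17326 — strictly between
the naive 0.125 and the true 0.2 — which is the mechanism behind SIMEX's
systematic residual attenuation at low reliability.

**Bootstrap** (`bootstrap_ci`): percentile intervals from resampling
individuals (rows) with replacement, re-running the full pipeline per
resample, 999 resamples by default. Percentile was chosen as the
least-assumption default; the type and count are otherwise
unconstrained. τ² is re-estimated inside each resample when it came from
replicates (so the interval reflects τ² uncertainty) and held fixed when
user-supplied. Resample failures are dropped and counted up to 10%,
beyond which the interval is refused. In coverage experiments the
resample count matters: percentile intervals at 99–199 resamples
visibly under-cover from quantile granularity alone, so coverage runs
use ≥ 299 resamples.

## Synthetic study designs

The generator emulates two fully parameterised designs; their defaults
are the base conditions of the comparison study this package operationalises.

*Linear (blood pressure → creatinine):* Age ~ N(32, 25);
BP | Age ~ N(120 + γ·Age, 50); k replicates BP* ~ N(BP, τ²);
Creatinine | BP, Age ~ N(30 + 0.2·BP + 0.2·Age, σ²). Base: n = 500,
k = 3, τ² = 30, σ² = 100, γ = 0; estimand 0.2. Closed forms:
reliability (25γ² + 50)/(25γ² + 50 + τ²); attenuation 50/(50 + τ²);
crude (age-omitted) effect 0.2 + 5γ/(25γ² + 50).

*Logistic (sodium intake → hypertension):* Age ~ U(18, 80);
Na | Age ~ N(4 + γ·Age, 1); replicates Na* ~ N(Na, τ²);
Hypertension ~ Bern(expit(−7 + 0.1·Na + φ·Age)). Base: n = 4000, k = 2,
τ² = 2, φ = 0.1, γ = 0; estimand 0.1. Reliability
(γ²(80−18)²/12 + 1)/(γ²(80−18)²/12 + 1 + τ²); the Nagelkerke pseudo-R²
of the true-exposure model at base parameters is ≈ 0.43 by simulation.

`scenario_grid` returns each design's 22 published one-factor-at-a-time
scenarios (8 error-variance, 4 sample-size, 3 replicate-count, 3
residual-variance/age-effect, 3 covariate-dependency variations around
the base). Two accounting conventions for the linear design's explained
variance circulate and disagree (the generating coefficients imply
R² = 0.03 at base; an alternative explained-variance bookkeeping of
0.4×50 + 10 = 30 implies 0.23); `r_squared` reports both and scenarios
are labelled by σ², not by a claimed R².

What the generator does **not** emulate: skewed or heavy-tailed error,
systematic or differential error, heteroscedastic error, missing data,
multiple error-prone exposures, or real covariate structure beyond a
single age summary. Passing tests therefore certify the estimators
under classical normal error with a correctly specified outcome model —
not robustness to violations of those assumptions.

## Simulation-study engine

`run_scenario` generates R datasets per scenario, applies each method,
and summarises bias, percentage bias, MSE and (optionally) bootstrap
coverage with Monte Carlo standard errors: MCSE(bias) = sd/√R,
MCSE(MSE) = sqrt(Σ((θ̂ᵢ−θ)² − MSE)²/(R(R−1))),
MCSE(coverage) = sqrt(p(1−p)/R). Seeding is hierarchical
(SeedSequence spawning: scenario → repetition → data/method/bootstrap),
so every repetition is independently reproducible and runs are
bit-identical for a fixed seed. Coverage is opt-in because
bootstrap-inside-Monte-Carlo dominates cost. Study-level summaries
report median and IQR (linear-interpolation quantiles) per method,
pooled and per family; the signed percentage bias is reported
(attenuation is negative).

Performance: the inner loops refit the same small design thousands of
times, so fits run on dedicated numpy kernels (closed-form OLS;
step-halved Newton/IRLS for logistic regression, batched least squares
across SIMEX pseudo-datasets). The test suite pins these kernels to
statsmodels on fixed datasets (coefficients and standard errors) —
statsmodels remains the independent oracle, not the implementation.

Default problem sizes in the shipped tests and acceptance script are
desk-scale choices: 1000–2000 repetitions for bias/MSE quantities
(3-MCSE comparisons absorb the extra Monte Carlo noise relative to the
5000-repetition reference values), 150–200 repetitions with 299–399
bootstrap resamples for coverage, and reduced SIMEX refits (20–50)
inside grids and bootstrap loops. One quantity needs more: the mean of
the calibrated logistic estimator at n = 500 is heavy-tailed (the
calibration factor σ̂²_{W|C} − τ̂² ≈ 1 with sd ≈ 0.15 occasionally comes
close to zero), so its percentage bias is computed at 10⁵ repetitions to
bring the MCSE below one point; it converges to ≈ +5%, versus ≈ −2% at
n = 4000 — small-sample upward bias of RC, the same instability that
produces its hard-error policy.

## Sensitivity analysis

`TauPrior` + `run_sensitivity` implement the five-step bias-analysis
loop: (1–2) quantify τ² and specify its distribution (point, uniform,
triangular, trapezoidal; all sampled by inverse CDF, the trapezoid's
plateau spanning its two modes); (3) correct once per draw with
ErrorModel(source="known"); (4) visualise estimate vs τ²
(`plot_sensitivity`); (5) summarise (median, range, failure count —
draws exceeding σ̂²_{W|C} are recorded as failed, never dropped
silently). For RC the corrected estimate is a deterministic, strictly
increasing function of the drawn τ²; SIMEX adds its own simulation
noise, so each draw gets an independent RNG stream and the τ²-trend
scatter is genuine method noise, not seed reuse. Per-draw bootstrap CIs
are optional (expensive); with them, `probabilistic_bias_summary` pools
one normal deviate per draw (mean = estimate, sd = bootstrap SE) and
reports median and 2.5/97.5 percentiles.

## Numerical notes and limitations

- Logistic fits: Newton with intercept warm start, step-halving, and
  divergence detection (|β| > 10⁴ → separation error); tolerance 1e−10.
- Degenerate inputs fail loudly: collinear designs, one-class outcomes,
  k < 2 for replicate-based τ², τ² ≥ σ̂²_{W|C}, truth = 0 for percentage
  bias.
- Percentile intervals are clipped, when necessary, to bracket the
  point estimate (rare, skewed-resample edge case).
- The n = 10,000 scenarios exist in the grids but are excluded from
  default runs (`include_heavy=False`): they dominate runtime without
  changing the qualitative comparison.
- Exact reproduction of the 5000-repetition, 999-resample reference
  study is possible through the same API (`run_grid(..., n_reps=5000,
  compute_coverage=True)`) but is not part of the shipped test suite.
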