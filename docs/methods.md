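# Methods

## Model

The data-generating process is a stationary zero-mean CVAR(1) — the
multivariate Ornstein-Uhlenbeck process. It is parameterized here by the
drift matrix **B** (all eigenvalues with negative real part) and the
stationary covariance **Σ**<sub>y</sub>, because those are the quantities
the bias study manipulates and reports; the diffusion matrix GG′ of the
underlying stochastic differential equation is available as
`diffusion_of` (GG′ = −(BΣ<sub>y</sub> + Σ<sub>y</sub>B′), the closed-form
solution of the continuous Lyapunov equation) but is never needed by the
pipeline. The Wiener process is never discretized: observations at times
t₁ < t₂ < … are generated and modeled with the exact transition law

    y_i | y_{i-1} ~ N( exp(B Δ_i) y_{i-1},  Σ_y − exp(B Δ_i) Σ_y exp(B′ Δ_i) ),

with Δ_i the elapsed interval and y₁ ~ N(0, Σ_y). Because there is no
observation noise, this Markov factorization *is* the likelihood — no
Kalman filtering is required, and simulation at the beep times is exact at
any interval length.

All internal times are in block units (Δ = 1 ≡ one design block; 90 min
in the simulation design, 105 min in the empirical-like design), with
t = 0 at the start of day 1. Unit conversion happens only at I/O.

## Measurement designs emulated

**Simulation design.** Ten back-to-back 90-min blocks fill a 15-h waking
day (default 8:00–23:00); one beep is placed uniformly in each block; the
night is unobserved but the process keeps evolving, so the expected
overnight gap is 7 blocks (½ + 6 + ½). The interval between beeps in
consecutive blocks is therefore triangular on [0, 2] blocks with mode 1
(mean 1 block = 90 min, variance 1/6 block² = 1,350 min²). An optional
minimum same-day interval m < 1 block (default variant: 1/6 ≡ 15 min) is
enforced by redrawing the *later* beep within its own block until the
constraint holds, which preserves per-block uniformity conditional on
feasibility; the rule applies within days only, since overnight gaps are
always long. The generator was validated against the analytic law
(moment match within Monte-Carlo error; Kolmogorov distance < 0.02 at
10⁵ gaps) and truncation behaves as theory requires (mean up, variance
down).

**Empirical-like design.** Seven days with at most eight beeps: one in
8–10 AM, six in equal blocks between 10 AM and 8 PM, one in 8–10 PM.
Recorded times are *response* times: beep plus a nonnegative delay, drawn
from an exponential (default mean 15 min — quick but imperfect compliance)
truncated at the block's response window (1.5 h daytime, 2 h morning, 4 h
evening), with a default 5% per-beep nonresponse rate. These defaults give
a mean realized within-day interval of ~105 min, the design's nominal
block length, while producing occasional very short intervals (a late
response followed quickly by the next beep) — the feature that
distinguishes real response data from clean beep data. The true delay
distribution of any real study is unknown, so the delay law is exposed as
configuration rather than asserted; a beep whose response cannot be placed
after the previous response within its window is treated as missed.

What the generators do *not* emulate: measurement error on top of the
latent process, systematic diurnal cycles, trends, floor/ceiling effects
of rating scales, or informative (mood-dependent) nonresponse. Passing
tests therefore demonstrate correctness of interval handling under the
model's own assumptions, not robustness to these real-data features.

## The four interval handlings

`assign_intervals` produces the Δ sequence each implementation feeds the
(single, shared) likelihood:

* **MI1** — Δ ≡ 1 everywhere, nights included.
* **MI2** — Δ = 1 within days, Δ = 7 overnight (the design's nominal
  expected overnight gap; configurable for other designs).
* **MI3** — each observation *time* is assigned to the 1/6-block grid cell
  containing it (floor onto the grid) and the grid times are differenced.
  This is the mechanism the phantom-variable device induces — an
  observation occupies the slot of the missing-data grid it falls in — and
  it reproduces the published worked table exactly, which per-interval
  nearest-rounding does not. An interval whose endpoints share a grid cell
  would be zero, so it is promoted to one grid unit (a zero-length
  transition density is degenerate).
* **MI4** — the exact intervals: the true model.

Because all four run through the same ML machinery, differences in their
estimates are attributable purely to interval handling.

## Estimation

Maximum likelihood on a stationarity-enforcing parameterization:
univariate drift B = −exp(θ); multivariate drift unconstrained with a
hard barrier on the largest eigenvalue real part; Σ<sub>y</sub> through a
log-Cholesky factor. Optimization is L-BFGS-B from the within-day OLS
slope mapped through the matrix logarithm (fallback B = −I), with up to 5
jittered restarts; a result whose central-difference gradient is
numerically zero is accepted even if the line search ends abnormally, and
a fit that never converges is returned flagged rather than raised. Data
are per-person mean-centered by default with the intercept fixed at zero;
the stationary density of the first observation is included (an option to
condition on it exists). For two-variable processes the transition
matrices for all unique intervals are computed at once from the
eigendecomposition of B, with closed-form 2×2 determinants/inverses, so a
10,000-observation exact-interval fit costs ~1–2 s; other handlings and
the univariate case are much cheaper.

Confidence intervals for phi(Δ) = exp(BΔ) use the delta method on the
unconstrained scale. Univariate, the Wald interval for θ = log(−B) is
mapped through the monotone transform phi = exp(−exp(θ)Δ), so bounds
always lie in [0, 1): negative autocorrelations are impossible in this
model, and intervals can approach but never cross zero. When the
likelihood drives phi to its zero boundary the surface is flat in θ and a
Wald interval is meaningless; the fit then reports an exact 0 with a
degenerate interval, mirroring how boundary fits surface in practice.
Coverage of the 95% interval was checked by simulation at a realistic
series length (50 observations, phi = 0.39): ~98%, i.e. mildly
conservative. The delta method was chosen over profile likelihood as the
standard, testable construction; the discrete-time OLS baseline instead
reports classical intervals, which can include negative values.

The OLS baseline (`fit_ar_ols`) regresses y_i on y_{i−1} per equation
with an intercept, after marking each day's first observation as having a
missing lagged predictor — one day's first measurement is never regressed
on the previous day's last.

## Bias study

For each condition (true parameters × series length × minimum-interval
rule), fresh schedules and series are drawn per replicate from seeds
derived deterministically from the condition seed, all four handlings are
fit, and the implied one-block matrix Φ(1) is compared with the truth.
Long-series cells (one replicate of 1,000 days) report a
*single-realization estimation error*, labeled as such — a replicated
long-series mode exists to separate estimand bias from realization noise,
and the package's own acceptance checks use it. Short-series cells
(many replicates of 10 days) report the *median* error, because the error
distribution is skewed near the phi boundaries. Relative measures divide
by |true entry| and warn when a true entry is (near) zero — the bivariate
cross-coefficients (−0.0482, −0.0679) make relative bias numerically
unstable. Nonconverged replicates are excluded with a reported count; a
cell under 90% convergence is flagged invalid. The averaged-over-truths
summary is emitted both ways the averaging can be read (absolute values
taken before or after averaging).

Default grids mirror the full study design (nine phi values 0.1–0.9;
1,000-day long series; 1,000 ten-day replicates; minimum interval 0 and
1/6; a bivariate truth taken from published standardized positive-affect /
worrying VAR estimates). Tests and the acceptance checks run reduced
grids; replicate counts there were sized from pilot standard errors so
that each asserted sign or ordering has adequate power: 3 × 1,000-day
replicates for the univariate long-series sign patterns (smallest margin
+0.013 at phi = 0.6 against a per-replicate SE of ~0.008), 1,000 ten-day
replicates per phi for the short-series medians (smallest median −0.006
at phi = 0.1), 25 × 1,000-day replicates for the bivariate means, and 500
replicates for interval coverage.

## Numerical choices

* Matrix logarithm: principal branch only; a Φ with an eigenvalue on the
  closed negative real axis, or whose logarithm is not a stable real
  matrix, raises a typed no-continuous-time-representation error rather
  than returning a complex drift.
* Innovation covariances are symmetrized and eigenvalue-clipped at a
  −10⁻¹⁰ relative tolerance before factorization; larger negativity is an
  error, not silently repaired.
* Per-unique-interval caching of transition matrices and innovation
  Cholesky factors in the simulator (intervals keyed at 12 decimals).
* Seeding: every study seed deterministically derives per-replicate
  (schedule, series) sub-seeds via seed sequences, so any replicate is
  reproducible in isolation; identical configuration and seed reproduce
  outputs bitwise.
* Series CSVs round-trip at 12 significant digits.

## Known limitations

* Single-person (N = 1) models only: no multilevel/random-effects or
  Bayesian estimation, and no measurement-error (latent state) filtering.
* The published bivariate long-series sign pattern is a single-realization
  statement; under replication the equal-everything handling (MI1) shows a
  genuinely negative asymptotic bias in the first autoregressive
  coefficient, and the exact-interval model's cross-coefficient bias is
  zero to within Monte-Carlo precision. The package's replicated bivariate
  check measures the estimand and documents this; the robust facts are
  the all-positive bias of MI2 and the total-bias ordering
  MI3/MI4 ≪ MI1/MI2.
* Long-series "bias" at one replicate conflates estimand bias with
  realization noise (~±0.01 per entry at 10,000 observations); the
  replicated mode is preferred for inference.
* OLS and ML agree only asymptotically on equally spaced data; at short
  lengths both carry the classic negative autoregression bias.
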