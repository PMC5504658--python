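# Methods

## Problem and data model

The package forecasts a univariate daily count series — outpatient visits
of one department — seven days ahead. The series is assumed contiguous
(one value per calendar day), non-negative, and dominated by four
features: a weekly profile with weekend troughs, mild annual seasonality,
occasional holiday collapses, and autocorrelated day-to-day noise. All
computation is positional once dates are validated on ingest; weeks are
Monday-aligned by default (configurable), and the public indexing is
1-based: week t′ = 1..W, weekday τ = 1..7. Day τ of week t′ sits at daily
position t = 7(t′−1) + τ. (The source material prints this map with a
fixed "+1" in place of "+τ", which would pin every week to its Monday;
the τ-dependent form is the only one that aligns the two arms day by day
and is what the package implements.)

## Preprocessing

Holiday outliers ("singularities") are detected per weekday: within each
weekday's weekly sub-series, a value farther than 2 sample standard
deviations (denominator n−1) from that weekday's mean is flagged. The
statistics include the candidate value itself and use the full training
window — the simplest reading of a per-weekday rule, recorded here because
other windows are defensible. Replacement is a single pass: a flagged cell
becomes the mean of the same weekday in the previous and following weeks
(single neighbour at the panel edges), always using *original* neighbour
values, so adjacent flags do not contaminate each other and the pass is
idempotent on its own output support. Cleaning is applied to the training
window only at every rolling origin; observed test values are never
modified, since evaluation must be against real demand.

## Seasonal-ARIMA arm

"Weekly differencing" is one application of (1 − B⁷): d = 0, one seasonal
difference of lag 7. The printed shorthand ARIMA(1,1,7) is read as (AR
order, one lag-7 difference, MA order); a regular difference remains one
flag away (`DifferencingSpec(d=1, ...)`) since the shorthand is ambiguous.

Estimation is conditional least squares: the recursion conditions on the
first max-AR-lag observations and sets presample errors to zero, and the
error vector is minimised with scipy's trust-region least-squares
(`least_squares`, TRF) from a zero start. TRF was chosen over a generic
quasi-Newton minimiser because the CSS surface has near-flat directions in
the MA parameters on weekly-differenced count data, where curvature-based
line searches can stall with precision-loss failures; the sum-of-squares
structure makes a Gauss–Newton-type method both faster and robust. The
non-invertible MA region, where the error recursion explodes, is handled
by capping non-finite residuals at a large finite value so the trust
region backs away from it.

Standard errors come from the numerical Hessian H of the CSS objective,
cov(β̂) = 2σ̂²H⁻¹ with σ̂² = RSS/n_effective (the linear-model identity
H ≈ 2XᵀX applied at the optimum). Order selection fits all contiguous
ARMA(p, q) with p ≤ p_max, q ≤ q_max and ranks by
BIC = n·ln(RSS/n) + (p+q+1)·ln(n) — the innovation variance counts as a
parameter, constant terms are omitted as they shift every candidate
equally, and n is the differenced-series length for all candidates so the
penalty is comparable. Ties break toward smaller p+q, then smaller p. RSS
is floored at 1e−12 inside the logarithm so an exactly periodic
(zero-residual) series degenerates gracefully to the empty model via the
tie-break. Sparse lag sets then arise by pruning: repeatedly drop the
coefficient with the smallest |t| below 1.96 (no pruning α is stated in
the source; 1.96 is the two-sided 5% normal point) and refit.

Sign convention throughout: φ(B) = 1 − Σφ_k B^k and Θ(B) = 1 − Σθ_k B^k,
so a reported AR coefficient of −0.514 corresponds to the factor
(1 + 0.514B) in the transfer form. Tests pin this convention against
statsmodels' opposite MA sign.

Forecasting runs the ARMA recursion on the differenced scale with future
errors zero and in-sample conditional residuals for past errors, then
inverts the differencing against observed history (and previously
inverted steps beyond lag 7). Forecasts are real-valued and not clipped;
`clip_zero` is an explicit option. Diagnostics use the Ljung–Box statistic
Q(m) = n(n+2)Σ r_k²/(n−k) with df = m − (number of ARMA coefficients),
floored at 1, at default lags {6, 12, 18, 24} capped by the sample.

## Day-of-week SES arm

Each weekday's weekly sub-series gets one smoother with the level
recursion above, initialised with the mean of its first three weeks. The
smoothing constant is searched on the grid 0.01..0.99 (step 0.01 — finer
resolution than the two decimals any reported constant could carry).
One-step errors are scored from week 4 on, so the initialisation window
does not score itself. The stated dual criterion "MSE and MAPE" is
resolved as a total order: MSE first, MAPE as tie-break, then the smaller
α. The smoothing constant is re-optimised at every rolling origin.

## Combination and rolling protocol

Per weekday, each arm's training residuals give E_i = √(Σe²) and weights
l_i = E_i⁻¹/ΣE_j⁻¹, so l₁+l₂ = 1 and both lie in (0,1) whenever both
energies are positive. The ARIMA arm's per-weekday residuals are its daily
one-step conditional residuals sliced at that weekday's positions
(warm-up prefix excluded); the SES arm's are its per-weekday one-step
errors. The residual window is the full expanding training window at each
origin — the weights visibly vary by weekday, which requires
weekday-specific energies, and no narrower window is specified anywhere.
If exactly one energy is zero that arm takes weight 1; if both are zero
(a noise-free, exactly periodic input that both arms fit perfectly) the
driver uses an even 0.5/0.5 split — the combination is indifferent there,
and a hard failure would make the degenerate-but-legitimate case
unusable. The low-level `combine_weights(0, 0)` still raises, as the
ratio itself is undefined.

Rolling protocol: with W training weeks and k test weeks, origin o runs
from W to W+k−1; at each origin the training window is weeks 1..o
(cleaned), both arms are refitted, weights recomputed, and week o+1 is
forecast in full. ARMA lag *sets* are frozen after the first origin
(one model form across all test weeks); coefficients are re-estimated
every origin. The driver is deterministic: identical inputs give
byte-identical record CSVs.

## Evaluation

APE = |x − x̂|/x × 100; MAPE is the plain mean of daily APEs — the overall
figure is the mean over all days, not the mean of the workday and weekend
sub-MAPEs. Workdays are τ = 1..5, weekends τ = 6..7. Residual mean and
sample SD (n−1) complete the report. MAPE is undefined at a zero observed
count: the default policy raises, and `zero_policy="skip"` /
`--skip-zero-days` drops such days explicitly, because silently skipping
materially changes results.

## Synthetic generator

`generate` draws x_t = round(max(0, μ_τ(1−holiday depression) +
trend·t′ + A·sin(2πt/365) + η_t)) with AR(1) noise η. The shipped presets
mirror the structure of real outpatient series: `eov_like` uses the
weekday profile (206, 193, 182, 171, 150, 86, 34) — a published observed
week of an endocrinology department — with noise SD 15, AR coefficient
0.5, annual amplitude 20 and four holiday collapses over 51 weeks;
`rov_like` does the same for a respiratory-like profile with near-empty
weekends; `flat_control` is a noise-free constant. Noise SD 15 and AR 0.5
are judgement calls at the scale of day-to-day variation such series show
after their weekly profile is removed; the annual amplitude is kept mild
so the weekly cycle dominates, as it does in the real data the presets
emulate. Generated observations are rounded to integer counts; model
predictions stay real-valued.

What the generator does *not* emulate: closure-driven zero-service days,
long vacation regimes (the February/August troughs of real Chinese
hospital data), slow case-mix trends, and doctor-roster changes. Passing
tests therefore show the pipeline recovers structure of this idealised
process, not that the accuracy figures transfer to any particular
hospital.

`generate_ses_truth` produces weekday panels from the local-level process
(ARIMA(0,1,1) with θ = 1−α) whose optimal one-step smoother is SES with
exactly the generating constant — the ground truth for α-recovery tests.
At 40 weeks the sampling SE of a single-series α̂ is about 0.11, so the
recovery check asserts the panel mean of the seven per-weekday estimates
within ±0.1 of truth; a per-series bound at that length is not a property
the estimator has.

## Problem sizes and numerical notes

The shipped presets use 51 weeks with a 43/8 train/test split (301 and 56
daily observations), the canonical one-year layout for this protocol;
simulation-based tests use n = 500–3000 for parameter recovery and 500
replicates for the Ljung–Box size check — sizes at which the asymptotics
the tests assert are visibly in force while the whole suite stays fast.
Order search defaults to p_max = 3, q_max = 7 in the rolling driver:
MA terms up to a full week capture the seasonal-difference signature,
while AR beyond 3 is never selected on series of this length.

## Known limitations

* Exact-likelihood estimation and multiplicative seasonal polynomials are
  out of scope; CSS with one seasonal difference is the whole ARIMA arm.
* The combination has exactly two arms and static per-origin weights; no
  regret-based or time-varying weighting.
* A published ROV-ARIMA weekly MAPE of 25.44% is not reproducible from
  the same published per-day rows (they give 24.52%); the package asserts
  only the three internally consistent figures and treats the fourth as a
  printing inconsistency.
* Forecast horizons other than 7 days are supported by the ARMA arm but
  the combination and evaluation are built around whole weeks.
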