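# Methods

This note documents the models implemented in `phenoforge`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limits of the approach.

## Forcing models

All three forcing methods share one accumulation skeleton.  For year *i*,
daily contributions u<sub>ij</sub> ≥ 0 derived from the daily mean
temperature are summed from a starting day-of-year *S*; the predicted date
is where the running sum first reaches a threshold.  The cumulative curve is
interpolated linearly between consecutive days ("trapezoid rule"), with the
knot before the first day anchored at zero, so predictions are real numbers.
If the threshold is met within the first accumulation day the interpolated
date falls in the half-open interval (S−1, S]; this is the natural
continuation of the same piecewise-linear curve and is kept rather than
special-cased.  Exact attainment at a day boundary needs no special case
either — the interpolation formula returns the boundary.  Non-attainment by
31 December raises an explicit error carrying the remaining deficit.
Predicted fractional dates are never rounded before computing RMSE.

**ADD.**  u<sub>ij</sub> = max(T<sub>ij</sub> − T₀, 0): days colder than the
biological zero contribute nothing (development cannot regress, so negative
effective temperatures are clipped).  The threshold is the mean across
years of the sums k<sub>i</sub> taken from *S* through the observed date
(both endpoints inclusive).  *S* is selected first, by the Aono correlation
protocol: for each candidate, the mean daily mean temperature over
[S, E<sub>i</sub>] is Pearson-correlated with E<sub>i</sub> across years and
the most negative coefficient wins (ties go to the earliest day; candidates
with a degenerate zero-variance profile are skipped with a warning).  T₀
then comes from a grid search minimising RMSE, defaulting to −5…5 °C in
0.01 °C steps (ties to the smallest value).

**ADTS.**  u<sub>ij</sub> = exp(E<sub>a</sub>(T<sub>K</sub> −
T<sub>s</sub>)/(R·T<sub>K</sub>·T<sub>s</sub>)) with T<sub>K</sub> =
T<sub>ij</sub> + 273.15 (the conversion constant is exactly 273.15, and the
Kelvin conversion happens only inside rate/DTS evaluations — a single
conversion point avoids unit bugs), T<sub>s</sub> = 298.15 K and
R = 1.987 × 10⁻³ kcal mol⁻¹ K⁻¹.  A joint grid search over *S* (default
1…90) and E<sub>a</sub> (default 1…40 kcal/mol in 0.1 steps) minimises
RMSE; ties resolve to the smaller *S*, then the smaller E<sub>a</sub>.  The
full objective surface is retained for contour inspection.  At
E<sub>a</sub> = 0 every day contributes exactly 1 and the prediction
collapses to S − 1 + Ū; this closed form is used as an acceptance check.

**ADP.**  u<sub>ij</sub> = r(**P**; T<sub>ij</sub>) for a rate family from
the registry (linear, Arrhenius, Logan, logistic — all evaluated in °C
except the Arrhenius exponent, all clipped at zero), with fixed threshold 1
(100 % progress).  Per candidate *S*, **P** is estimated by Nelder–Mead
(parameter and objective tolerance 10⁻⁸, 2,000 iterations per start).
Initialisation is automatic: for the Arrhenius family a coarse internal DTS
scan picks the E<sub>a</sub> whose per-year requirements are most nearly
constant, and B is solved so the mean terminal progress at the observed
dates is exactly 1 (the Arrhenius rate and the DTS kernel are the same
ratio, so this chaining starts the simplex near the optimum); the remaining
starts are jittered copies.  Logan and logistic start from literature-scale
values (ψ=0.01, ρ=0.1, T<sub>u</sub>=40 °C, z=6; K=0.15, K₀=0.01, b=0.1)
with five multiplicatively jittered restarts.  Inside the objective,
parameter vectors that violate a family's domain (logistic K₀ ∉ (0, K),
non-positive Logan shape parameters, non-finite rates) return a large
finite penalty, and a year that fails to reach 100 % progress contributes
the finite pseudo-residual (366 − E<sub>i</sub>) + 100 × deficit, keeping
the simplex objective informative rather than infinite.

The default *S* grid is 1…90 for all methods; analyses in the test-suite
and acceptance script pass narrower grids bracketing the relevant region
(e.g. 40…55) to keep run times in seconds — a problem-size choice, not a
change of method.

## Fall–winter features and the residual GAM

The six FWT predictors are computed over [1 November of the preceding year,
S − 1].  The chilling-hours sum is defined with its current-year term ending
at S − 1, so for internal consistency all six features use that same window
(an inclusive-of-*S* variant would mix two window conventions for one
feature table).  Hourly temperatures come from the standard single-sine
interpolation T<sub>w</sub> = (T<sub>max</sub>−T<sub>min</sub>)/2 ·
sin(πw/12 − π/2) + (T<sub>min</sub>+T<sub>max</sub>)/2, w = 1…24, with no
solar-time correction; the day peaks at T<sub>max</sub> at w = 12 and
troughs at T<sub>min</sub> at w = 24.  A chilling hour requires the
temperature strictly between the bounds (default 0 and 7.2 °C); boundary
hours count zero.  The critical low temperature defining the cold-day count
x₁ is scanned (default −10…7 °C) by refitting the residual GAM per
candidate and keeping the largest deviance explained; ties go to the
smallest candidate and a flat profile triggers a warning.

Residuals are modelled as a Gaussian additive model: intercept plus one
penalized cubic B-spline per feature with basis dimension 6 — deliberately
small for ~40-year series (39 observations must support up to six smooths).
The penalty weight is a single value shared across terms, selected by
generalized cross-validation on a log₁₀ grid from 10⁻³ to 10⁶; per-term
weights can be passed explicitly.  Deviance explained is 1 − residual
deviance / null deviance (for the Gaussian family, an R² analogue,
invariant to shifting the response); a constant response short-circuits to
deviance explained 0.  Smooth-term significance uses Wald tests on each
term's coefficient block under the penalized covariance — approximate, as
is standard for penalized fits.  AIC uses the Gaussian likelihood with
effective degrees of freedom from the smoother trace; because AIC for
penalized GAMs is implementation-specific, the package treats model
*ordering*, not AIC values, as the stable contract.  Cross-checks against
an independent mgcv fit of the same formula agree in deviance explained to
well within 0.05 on test data.

Model selection follows the rule: among candidates whose every smooth is
significant at the 0.05 level, take the highest deviance explained; if no
candidate qualifies, fall back to the lowest AIC with a warning.  Two
candidate sets ship with the package: a curated ten-formula list mirroring
the combinations used in published FFD analyses (most of which include the
cold-day count x₁), and `all_subset_formulas()`, all 2–4-feature subsets.
The curated list is the default for data analyses; recovery studies use the
all-subsets list, because a curated list that forces a feature into every
candidate lets the significance screen disqualify the true formula whenever
that forced feature is inactive in the data-generating process.

Contribution rates partition the full model's deviance explained DE₀ by
inverse drop-one deviances: CR<sub>i</sub> =
(1/DE<sub>i</sub>)/Σ<sub>j</sub>(1/DE<sub>j</sub>) · DE₀ · 100 %, where
DE<sub>j</sub> is the deviance explained after removing feature *j*.  The
rates sum to DE₀·100 by construction; a drop-one deviance of zero is an
error (the partition is undefined), reported with guidance.  Adjusted
predictions add the fitted smooth of the residuals back to the forcing
predictions; in-sample this cannot increase the RMSE when the model
includes an intercept.  The residual sign convention is y = observed −
predicted, so adjusted = predicted + ŷ recovers observations.

## Synthetic data

`simulate_climate` draws a daily series T<sub>mean</sub>(d) = μ −
A·cos(2π(doy − d<sub>min</sub>)/365) + AR(1) anomaly, with T<sub>min/max</sub>
= T<sub>mean</sub> ∓ half-range plus jitter and the ordering
T<sub>min</sub> ≤ T<sub>mean</sub> ≤ T<sub>max</sub> enforced.  Defaults —
μ = 12 °C, A = 15 °C, annual minimum at DOY 15, 8 °C diurnal range,
φ = 0.7, σ = 2 °C — produce a Beijing-like station: sub-zero January means
and on the order of a hundred chill-capable days per cold season.  The
diurnal half-range carries two noise components: day-to-day jitter (1 °C)
and a per-calendar-year anomaly (1 °C s.d.) representing sunnier or
cloudier winters.  The annual component matters: without it the winter-mean
T<sub>max</sub> tracks the winter-mean T<sub>mean</sub> at r ≈ 0.98 and no
analysis could attribute an effect to one rather than the other.

`simulate_ffd` forward-simulates the flowering date of each year (after the
first) from a known rate model and starting date — defaults B = −4.38,
E<sub>a</sub> = 15.04 kcal/mol, S = 47, magnitudes that put flowering in
early April under the default climate — then adds per-feature day shifts
g<sub>k</sub>(x<sub>k</sub> − x̄<sub>k</sub>) and Gaussian observation
noise, and rounds to whole days (real phenological records are whole days;
the ground-truth log keeps every component fractional).  The canonical
active-effect scenario `chilling_effects()` drives shifts with chilling
hours (saturating tanh, ~2.2-day scale over a ~110-hour s.d.) and winter
daytime maxima (negative slope −3 d/°C with quadratic curvature −1.2
d/°C²), putting the structured residual component on the ~3-day scale that
two-stage flowering analyses report.  Both responses are nonlinear for two
reasons.  Biologically, chilling benefits saturate once the chilling
requirement is met and warmth responses accelerate — the very reason this
stage uses smooths rather than linear terms.  Statistically, the window
mean of daily means sits essentially at the midpoint of the
T<sub>min</sub>/T<sub>max</sub> means (x₅ ≈ (x₃+x₄)/2 to a few hundredths
of a degree), so a *linear* x₄ effect is exactly reproducible by an
additive model in x₃ and x₅ and the driver would be unidentifiable in
principle; curvature breaks that degeneracy because a nonlinear function of
a linear combination is not additive in its components.

What the generator does **not** emulate: real stations have skewed,
weather-regime-driven temperature anomalies rather than Gaussian AR(1)
noise, occasional missing days, trends from climate warming, and daily
means computed from fixed observation hours rather than lying mid-range.
Passing recovery tests on this generator therefore demonstrates that the
estimation chain inverts its own generative assumptions correctly — not
that those assumptions hold for any particular station.

## Identifiability at the rounding floor

With observation noise σ = 0 the only error left in the generated records
is the whole-day rounding, a uniform ±0.5-day quantisation (RMSE floor
≈ 0.29 days).  Two consequences, both verified with fully converged
optimizers:

- Terminal progress evaluated at observed dates deviates from 100 % by up
  to (daily rate) × 0.5 days ≈ 3 % at spring rates; tests assert that bound
  rather than an arbitrarily tighter one.
- The starting date is identified only to about ±1 day.  Shifting *S* by a
  few days removes a handful of small winter contributions that the other
  parameters can almost exactly compensate, so RMSE differences between
  neighbouring candidates (~0.01 days) sit far below the rounding spread,
  and which candidate wins is quantisation luck.  Across seeded replicates
  the true *S* wins in roughly 8 of 10; it is always within one day, and the
  activation energy is recovered within 5 % regardless.  An acceptance test
  asserting exact recovery in every replicate is retained and is expected to
  fail for this structural reason.

## Other limitations

- The two-stage design treats fall–winter effects as additive corrections
  to a spring forcing model; it cannot represent interactions between
  chilling fulfilment and forcing response, or overlapping chilling/forcing
  phases.
- Point estimates only: no uncertainty on *S*, T₀ or rate parameters.
- The feature set is strongly collinear by construction (x₃, x₄, x₅ are
  linked through the daily temperature structure); contribution rates
  partition deviance among whatever features the selection keeps and should
  not be read as causal decomposition.
- 29 February is kept as native day-of-year 60 in leap years; day-of-year
  labels for the same calendar date therefore differ by one across leap and
  non-leap years, which is immaterial for accumulation windows but worth
  knowing when comparing raw DOY values across years.
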