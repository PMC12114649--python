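# phenoforge

Thermal-time models of spring flowering phenology, with residual correction
by fall–winter temperatures.

Long phenological series — e.g. the first flowering date (FFD) of a fruit
tree observed every spring for decades alongside daily air temperatures —
are classically modelled by accumulating a temperature-driven quantity from
a starting date *S* until a requirement is met. `phenoforge` implements
three such forcing methods, and then a second stage that explains the
remaining per-year residuals with fall–winter temperature (FWT) summaries,
for researchers in plant phenology and thermal biology who want the whole
chain as tested, scriptable Python.

## Models

**Forcing stage.** With T<sub>ij</sub> the daily mean temperature of day
*j* in year *i* and E<sub>i</sub> the observed date (day-of-year):

- **ADD** (accumulated degree-days): k<sub>i</sub> = Σ<sub>j=S..Ei</sub>
  max(T<sub>ij</sub> − T₀, 0); the event is predicted when the accumulation
  reaches the across-year mean k̄.  *S* is chosen by the Aono protocol (most
  negative Pearson correlation between the spring mean temperature and the
  observed date) and the biological zero T₀ by a grid search on RMSE.
- **ADTS** (accumulated days transferred to a standard temperature): each
  day contributes the Arrhenius ratio
  exp(E<sub>a</sub>(T−T<sub>s</sub>)/(R·T·T<sub>s</sub>)) (temperatures in
  K, T<sub>s</sub> = 298.15 K), i.e. its equivalent number of days at 25 °C;
  *S* and the activation energy E<sub>a</sub> come from a joint grid search.
- **ADP** (accumulated developmental progress): daily developmental rates
  r(**P**; T) from any registered rate equation — linear, Arrhenius
  (r = 10¹²·exp(B − E<sub>a</sub>/RT)), Logan, or three-parameter logistic —
  are summed until 100 % progress; **P** is estimated per candidate *S* by
  Nelder–Mead minimisation of the RMSE between observed and predicted dates.

All three interpolate the cumulative curve linearly between days (the
trapezoid rule), so predictions are fractional days and RMSEs are computed
without rounding.

**Residual stage.** The per-year residuals y<sub>i</sub> = E<sub>i</sub> −
Ê<sub>i</sub> are regressed on six FWT summaries of the window from 1
November of the preceding year to the day before *S*: cold-day count x₁
(days with T<sub>min</sub> ≤ a critical temperature, scanned for the best
deviance explained), Chilling Hours x₂ (hours with sine-interpolated
temperature strictly between 0 and 7.2 °C), window means of
T<sub>min</sub>/T<sub>max</sub>/T<sub>mean</sub> (x₃, x₄, x₅), and the
window minimum x₆.  Candidate Gaussian GAMs (one penalized spline per
feature) are compared; the winner is the formula with the highest deviance
explained among those whose every smooth is significant at the 0.05 level.
Its deviance explained is partitioned into per-feature contribution rates
CR<sub>i</sub> = (1/DE<sub>i</sub>)/Σ<sub>j</sub>(1/DE<sub>j</sub>) ·
DE₀ · 100 % from drop-one refits, and the smoothed residuals are added back
to the forcing predictions to give adjusted dates.

A seeded synthetic-data module generates Beijing-like daily climates
(seasonal sinusoid + AR(1) noise + diurnal spread) and forward-simulated
flowering dates with known ground truth, so the full chain is testable
without any data download.

## Worked example

```python
import warnings
from phenoforge import (ClimateGenSpec, PhenoGenSpec, simulate_climate, simulate_ffd,
                        fit_adp, fwt_table, select_best_gam, contribution_rates,
                        adjust_predictions)
from phenoforge.synthetic import chilling_effects
from phenoforge.gam import all_subset_formulas

climate = simulate_climate(ClimateGenSpec(seed=8))
pheno, truth = simulate_ffd(
    climate, PhenoGenSpec(sigma_obs=1.0, seed=9, effects=chilling_effects()))

fit = fit_adp(climate, pheno, s_candidates=range(40, 56), family="arrhenius", seed=0)
print(f"ADP-Arrhenius: S = {fit.s_start}, B = {fit.params['B']:.2f}, "
      f"Ea = {fit.params['Ea']:.2f} kcal/mol, RMSE = {fit.rmse:.4f} d")

features = fwt_table(climate, fit.residuals.index, fit.s_start, critical_low=2.9)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    best, table = select_best_gam(fit.residuals, features, all_subset_formulas())
    rates = contribution_rates(fit.residuals, features, best.terms_)
    adjusted, rmse_adj = adjust_predictions(fit, best)
print(f"best GAM: y ~ {' + '.join('s(%s)' % t for t in best.terms_)}, "
      f"deviance explained = {best.deviance_explained_:.1%}")
print("contribution rates (%):", {k: round(v, 1) for k, v in rates.items()})
print(f"RMSE: {fit.rmse:.4f} -> {rmse_adj:.4f} days after FWT adjustment")
```

prints

```
ADP-Arrhenius: S = 44, B = -1.18, Ea = 16.82 kcal/mol, RMSE = 3.3300 d
best GAM: y ~ s(x2) + s(x4), deviance explained = 89.2%
contribution rates (%): {'x2': 34.4, 'x4': 54.7}
RMSE: 3.3300 -> 1.0960 days after FWT adjustment
```

The forcing stage alone predicts flowering to about 3.3 days RMSE because
the generator also shifted dates with two fall–winter drivers (chilling
hours and winter daytime maxima, plus 1 day of observation noise); the
residual stage identifies exactly those two features, attributes 34 % and
55 % of the 89 % deviance explained to them, and cuts the RMSE to 1.1 days.

The same chain runs from the shell against CSV inputs:

```sh
phenoforge simulate --years 41 --seed 8 --out-dir data/
phenoforge fit --method adp --family arrhenius \
    --climate data/climate.csv --pheno data/phenology.csv --s-min 40 --s-max 55
phenoforge run --config config.yaml --out results/
```

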