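"""Fall--winter temperature (FWT) predictors.

Six per-year summaries of the cold season preceding flowering, computed over
the window from 1 November of the preceding year through the day before the
spring starting date S (both endpoints inclusive; the S-1 endpoint keeps the
window consistent with the chilling-hours sum, whose current-year term is
explicitly exclusive of S):

* x1 — number of days with daily minimum temperature <= a critical low
  temperature (the critical value is selected by scanning candidates for the
  largest GAM deviance explained);
* x2 — accumulated chilling hours (ACH): hours with sine-interpolated
  temperature strictly between the chilling bounds (default 0 and 7.2 degC);
* x3/x4/x5 — window means of daily minimum / maximum / mean temperature;
* x6 — window minimum of the daily minimum temperature.

Hourly temperatures come from the standard single-sine interpolation of the
daily extremes: T_w = (Tmax - Tmin)/2 * sin(pi/12 * w - pi/2) + (Tmin+Tmax)/2
for hour w = 1..24 (peak Tmax at w = 12, trough Tmin at w = 24).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .climate import ClimateSeries, days_in_year

__all__ = [
    "CHILL_LOWER_DEFAULT",
    "CHILL_UPPER_DEFAULT",
    "hourly_temps",
    "daily_chill_hours",
    "accumulated_chill_hours",
    "fwt_summary",
    "fwt_table",
    "scan_critical_temperature",
]

CHILL_LOWER_DEFAULT = 0.0
CHILL_UPPER_DEFAULT = 7.2

_HOURS = np.arange(1, 25)
_SINE = np.sin(np.pi / 12.0 * _HOURS - np.pi / 2.0)


def hourly_temps(t_min: float, t_max: float) -> np.ndarray:
    """24 sine-interpolated hourly temperatures for one day (hour w = 1..24)."""
    if t_min > t_max:
        raise ValueError(f"t_min {t_min} > t_max {t_max}")
    half = (t_max - t_min) / 2.0
    mid = (t_max + t_min) / 2.0
    return half * _SINE + mid


def daily_chill_hours(
    t_min,
    t_max,
    lower: float = CHILL_LOWER_DEFAULT,
    upper: float = CHILL_UPPER_DEFAULT,
):
    """Hours of one day (0..24) with interpolated temperature strictly inside
    (lower, upper).  Boundary hours do not count.  Vectorises over arrays of
    (t_min, t_max) pairs."""
    t_min = np.asarray(t_min, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    if np.any(t_min > t_max):
        raise ValueError("t_min > t_max")
    if not lower < upper:
        raise ValueError("chilling bounds require lower < upper")
    half = (t_max - t_min) / 2.0
    mid = (t_max + t_min) / 2.0
    tw = half[..., None] * _SINE + mid[..., None]
    counts = np.sum((tw > lower) & (tw < upper), axis=-1)
    return counts if counts.ndim else int(counts)


def _window_frame(climate: ClimateSeries, year: int, s_start: int) -> pd.DataFrame:
    """Daily records from 1 Nov of ``year-1`` through DOY ``s_start - 1``."""
    nov1 = 306 if days_in_year(year - 1) == 366 else 305
    return climate.window(year, start=(-1, nov1), end=(0, s_start - 1))


def accumulated_chill_hours(
    climate: ClimateSeries,
    year: int,
    s_start: int,
    lower: float = CHILL_LOWER_DEFAULT,
    upper: float = CHILL_UPPER_DEFAULT,
) -> int:
    """Accumulated chilling hours from 1 Nov of the preceding year through the
    day before the starting date."""
    w = _window_frame(climate, year, s_start)
    return int(np.sum(daily_chill_hours(
        w["t_min"].to_numpy(), w["t_max"].to_numpy(), lower, upper)))


def fwt_summary(
    climate: ClimateSeries,
    year: int,
    s_start: int,
    critical_low: float,
    chill_lower: float = CHILL_LOWER_DEFAULT,
    chill_upper: float = CHILL_UPPER_DEFAULT,
) -> dict:
    """The six FWT predictors x1..x6 for one year (see module docstring)."""
    w = _window_frame(climate, year, s_start)
    t_min = w["t_min"].to_numpy()
    t_max = w["t_max"].to_numpy()
    return {
        "year": int(year),
        "x1": int(np.sum(t_min <= critical_low)),
        "x2": int(np.sum(daily_chill_hours(t_min, t_max, chill_lower, chill_upper))),
        "x3": float(np.mean(t_min)),
        "x4": float(np.mean(t_max)),
        "x5": float(np.mean(w["t_mean"].to_numpy())),
        "x6": float(np.min(t_min)),
    }


def fwt_table(
    climate: ClimateSeries,
    years,
    s_start: int,
    critical_low: float,
    chill_lower: float = CHILL_LOWER_DEFAULT,
    chill_upper: float = CHILL_UPPER_DEFAULT,
) -> pd.DataFrame:
    """FWT feature table (one row per year, columns year, x1..x6)."""
    rows = [
        fwt_summary(climate, int(y), s_start, critical_low, chill_lower, chill_upper)
        for y in years
    ]
    return pd.DataFrame(rows).set_index("year")


def scan_critical_temperature(
    residuals: pd.Series,
    climate: ClimateSeries,
    s_start: int,
    candidates,
    formula=("x1", "x2", "x4", "x5"),
    chill_lower: float = CHILL_LOWER_DEFAULT,
    chill_upper: float = CHILL_UPPER_DEFAULT,
    gam_kwargs: dict | None = None,
) -> tuple[float, pd.DataFrame]:
    """Select the critical low temperature for x1 by deviance explained.

    For each candidate critical temperature, x1 is recomputed, the residual
    GAM with the given formula is refit, and the deviance explained recorded;
    the candidate with the largest deviance explained wins (ties to the
    smallest candidate).  A flat profile (spread < 1e-6) triggers a warning.
    Returns (best candidate, profile DataFrame with columns critical,
    deviance_explained).
    """
    from .gam import ResidualGAM  # deferred: avoids an import cycle

    years = residuals.index.to_numpy()
    base = fwt_table(climate, years, s_start, critical_low=0.0,
                     chill_lower=chill_lower, chill_upper=chill_upper)
    tmins = {int(y): _window_frame(climate, int(y), s_start)["t_min"].to_numpy()
             for y in years}
    rows = []
    for crit in candidates:
        feats = base.copy()
        feats["x1"] = [int(np.sum(tmins[int(y)] <= crit)) for y in years]
        try:
            gam = ResidualGAM(terms=list(formula), **(gam_kwargs or {}))
            gam.fit(feats, residuals)
            rows.append((float(crit), gam.deviance_explained_))
        except Exception as exc:  # noqa: BLE001 - record and move on
            warnings.warn(f"critical candidate {crit}: GAM fit failed ({exc})")
            rows.append((float(crit), np.nan))
    profile = pd.DataFrame(rows, columns=["critical", "deviance_explained"])
    de = profile["deviance_explained"]
    if de.notna().sum() == 0:
        raise RuntimeError("no critical-temperature candidate could be fitted")
    if np.nanmax(de) - np.nanmin(de) < 1e-6:
        warnings.warn("deviance profile is flat: the critical temperature is "
                      "not identified by these residuals")
    best = float(profile.loc[de.idxmax(), "critical"])
    return best, profile
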