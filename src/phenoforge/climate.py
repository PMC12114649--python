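"""Daily climate and phenology tables.

Containers and I/O for the two inputs every downstream stage consumes: a
daily air-temperature series (Tmin/Tmax/Tmean in degC, one row per calendar
day) and a phenology series (one observed first-flowering day-of-year per
year).  Day-of-year is 1-based everywhere (1 Jan = 1); windows are inclusive
of both endpoints unless a caller states otherwise.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "ClimateValidationError",
    "MissingDataError",
    "doy",
    "days_in_year",
    "read_climate_csv",
    "read_phenology_csv",
]


class ClimateValidationError(ValueError):
    """A climate table violates a structural invariant (e.g. t_min > t_max)."""


class MissingDataError(KeyError):
    """A requested date or window is not covered by the series."""


def doy(date: _dt.date) -> int:
    """1-based day-of-year of a Gregorian date (1 Jan -> 1, 31 Dec -> 365/366)."""
    return date.timetuple().tm_yday


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


@dataclass
class ClimateSeries:
    """An ordered daily climate table indexed by (year, day-of-year).

    Parameters
    ----------
    frame : DataFrame with columns ``date`` (datetime64), ``t_min``, ``t_max``,
        ``t_mean`` (degC).  Rows must be unique by date; they are sorted on
        construction.  ``year``/``doy`` columns are derived.
    """

    frame: pd.DataFrame
    gaps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = self.frame.copy()
        f["date"] = pd.to_datetime(f["date"])
        if f["date"].duplicated().any():
            dup = f.loc[f["date"].duplicated(), "date"].iloc[0]
            raise ClimateValidationError(f"duplicate date in climate series: {dup.date()}")
        f = f.sort_values("date").reset_index(drop=True)
        f["year"] = f["date"].dt.year.astype(int)
        f["doy"] = f["date"].dt.dayofyear.astype(int)
        bad = f["t_min"] > f["t_max"]
        if bad.any():
            d = f.loc[bad, "date"].iloc[0]
            raise ClimateValidationError(f"t_min > t_max on {d.date()}")
        self.frame = f
        self.gaps = self.gaps + self._find_gaps(f)
        self._by_year: dict[int, pd.DataFrame] = {
            int(y): g.set_index("doy") for y, g in f.groupby("year")
        }

    @staticmethod
    def _find_gaps(f: pd.DataFrame) -> list[str]:
        gaps = []
        deltas = f["date"].diff().dt.days
        for i in np.nonzero((deltas > 1).to_numpy())[0]:
            a = f["date"].iloc[i - 1].date() if i > 0 else None
            gaps.append(f"gap of {int(deltas.iloc[i]) - 1} day(s) after {a}")
        return gaps

    @property
    def years(self) -> list[int]:
        return sorted(self._by_year)

    def complete_years(self) -> list[int]:
        """Years with every calendar day present."""
        return [y for y, g in sorted(self._by_year.items()) if len(g) == days_in_year(y)]

    def has_day(self, year: int, day: int) -> bool:
        return year in self._by_year and day in self._by_year[year].index

    def year_values(self, year: int, column: str = "t_mean") -> np.ndarray:
        """Array of a temperature column for one year, index 0 == DOY 1.

        Raises :class:`MissingDataError` if the year is absent or incomplete.
        """
        if year not in self._by_year:
            raise MissingDataError(f"year {year} not covered by climate series")
        g = self._by_year[year]
        n = days_in_year(year)
        if len(g) != n:
            raise MissingDataError(f"year {year} incomplete: {len(g)}/{n} days")
        return g[column].to_numpy()

    def window(
        self,
        year: int,
        start: tuple[int, int],
        end: tuple[int, int],
    ) -> pd.DataFrame:
        """Inclusive daily slice between two (year-offset, DOY) endpoints.

        ``start``/``end`` are (offset, day-of-year) pairs where offset is added
        to ``year`` — e.g. ``start=(-1, 305)`` is 1 Nov of the preceding
        (non-leap) year.  The slice may cross the year boundary.
        """
        y0, d0 = year + start[0], start[1]
        y1, d1 = year + end[0], end[1]
        t0 = _dt.date(y0, 1, 1) + _dt.timedelta(days=d0 - 1)
        t1 = _dt.date(y1, 1, 1) + _dt.timedelta(days=d1 - 1)
        if t1 < t0:
            raise ValueError(f"window end {t1} precedes start {t0}")
        f = self.frame
        mask = (f["date"] >= pd.Timestamp(t0)) & (f["date"] <= pd.Timestamp(t1))
        out = f.loc[mask].reset_index(drop=True)
        expected = (t1 - t0).days + 1
        if len(out) != expected:
            raise MissingDataError(
                f"window {t0}..{t1} for year {year}: {len(out)}/{expected} days present"
            )
        return out

    def validation_report(self) -> dict:
        f = self.frame
        return {
            "n_days": int(len(f)),
            "years": self.years,
            "complete_years": self.complete_years(),
            "gaps": list(self.gaps),
            "t_mean_outside_bounds": int(
                ((f["t_mean"] < f["t_min"]) | (f["t_mean"] > f["t_max"])).sum()
            ),
        }

    def to_csv(self, path) -> None:
        out = self.frame[["date", "t_min", "t_max", "t_mean"]].copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        # %.17g round-trips any float64 bit-exactly
        out.to_csv(path, index=False, float_format="%.17g")


_DEFAULT_COLUMNS = {"date": "date", "t_min": "t_min", "t_max": "t_max", "t_mean": "t_mean"}


def read_climate_csv(
    path,
    column_map: dict | None = None,
    date_format: str | None = None,
    strict: bool = True,
    impute_mean: bool = False,
) -> ClimateSeries:
    """Read a daily climate CSV into a validated :class:`ClimateSeries`.

    ``column_map`` maps the canonical names (date, t_min, t_max, t_mean) to the
    file's column headers.  A missing t_mean column is imputed as
    (t_min + t_max)/2 only when ``impute_mean`` is set; otherwise it is an
    error, because downstream models use recorded daily means.  In non-strict
    mode rows with t_min > t_max are dropped (and reported) instead of raising.
    """
    cols = dict(_DEFAULT_COLUMNS)
    cols.update(column_map or {})
    raw = pd.read_csv(path, float_precision="round_trip")
    for key in ("date", "t_min", "t_max"):
        if cols[key] not in raw.columns:
            raise ClimateValidationError(f"column {cols[key]!r} (for {key}) not in {path}")
    f = pd.DataFrame(
        {
            "date": pd.to_datetime(raw[cols["date"]], format=date_format),
            "t_min": pd.to_numeric(raw[cols["t_min"]]),
            "t_max": pd.to_numeric(raw[cols["t_max"]]),
        }
    )
    imputed = False
    if cols["t_mean"] in raw.columns:
        f["t_mean"] = pd.to_numeric(raw[cols["t_mean"]])
    elif impute_mean:
        f["t_mean"] = (f["t_min"] + f["t_max"]) / 2.0
        imputed = True
    else:
        raise ClimateValidationError(
            f"no t_mean column {cols['t_mean']!r}; pass impute_mean=True to use (t_min+t_max)/2"
        )
    gaps = []
    bad = f["t_min"] > f["t_max"]
    if bad.any() and not strict:
        gaps.append(f"dropped {int(bad.sum())} row(s) with t_min > t_max")
        f = f.loc[~bad]
    series = ClimateSeries(f, gaps=gaps)
    if imputed:
        series.gaps.append("t_mean imputed as (t_min+t_max)/2")
    return series


def read_phenology_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a phenology CSV with columns year, ffd_doy (1-based day-of-year)."""
    cols = {"year": "year", "ffd_doy": "ffd_doy"}
    cols.update(column_map or {})
    raw = pd.read_csv(path)
    for key in cols.values():
        if key not in raw.columns:
            raise ClimateValidationError(f"column {key!r} not in {path}")
    out = pd.DataFrame(
        {
            "year": pd.to_numeric(raw[cols["year"]]).astype(int),
            "ffd_doy": pd.to_numeric(raw[cols["ffd_doy"]]),
        }
    )
    if out["year"].duplicated().any():
        raise ClimateValidationError("duplicate years in phenology table")
    if ((out["ffd_doy"] < 1) | (out["ffd_doy"] > 366)).any():
        raise ClimateValidationError("ffd_doy outside 1..366")
    return out.sort_values("year").reset_index(drop=True)


def write_validation_report(series: ClimateSeries, path) -> None:
    with open(path, "w") as fh:
        json.dump(series.validation_report(), fh, indent=2)
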