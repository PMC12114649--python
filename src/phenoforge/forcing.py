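"""Spring forcing-accumulation methods for predicting flowering dates.

Three estimation protocols share one skeleton: starting at a day-of-year S,
daily contributions derived from the daily mean temperature are accumulated
until a threshold is reached; the (fractional) day of attainment is the
predicted event date.

* ADD (:class:`DegreeDayModel`) — contributions are effective temperatures
  max(T - T0, 0); the threshold is the mean across years of the degree-day
  sums k_i from S to the observed date.  S comes from the Aono protocol
  (most negative correlation between spring mean temperature and observed
  date); T0 from a grid search minimising RMSE.
* ADTS (:class:`StandardizedDaysModel`) — each day contributes its DTS
  factor, the Arrhenius-ratio equivalent number of days at 25 degC; S and
  the activation energy Ea are estimated by a joint grid search on RMSE.
* ADP (:class:`DevelopmentalProgressModel`) — each day contributes the
  developmental rate r(P; T) of any registered rate family, the threshold is
  100% progress (1.0), and P is estimated per candidate S by Nelder--Mead
  on RMSE; the best (S, P) pair wins.

Predicted dates are kept fractional via trapezoid (linear) interpolation of
the cumulative curve between consecutive days; RMSEs are computed on the
unrounded predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .climate import ClimateSeries
from .rates import R_KCAL, T_STANDARD_K, PRE_EXP_SCALE, RateModel, dts, celsius_to_kelvin

__all__ = [
    "NonAttainmentError",
    "MethodFit",
    "accumulate_until",
    "select_start_date_add",
    "DegreeDayModel",
    "StandardizedDaysModel",
    "DevelopmentalProgressModel",
    "fit_add",
    "fit_adts",
    "fit_adp",
    "predict_years",
]

DEFAULT_S_CANDIDATES = tuple(range(1, 91))
DEFAULT_T0_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 2)
DEFAULT_EA_GRID = np.round(np.arange(1.0, 40.0 + 1e-9, 0.1), 1)


class NonAttainmentError(RuntimeError):
    """The running accumulation never reached the threshold.

    Carries the final ``deficit`` (threshold minus the achieved total).
    """

    def __init__(self, deficit: float):
        super().__init__(f"threshold not attained; deficit {deficit:g}")
        self.deficit = float(deficit)


def accumulate_until(daily_increments, threshold: float, s_start: int = 1) -> float:
    """Fractional day-of-year at which the running sum first reaches a threshold.

    ``daily_increments`` are the nonnegative contributions of days
    ``s_start, s_start+1, ...``.  With C_F the cumulative total through day F,
    attainment between F and F+1 is interpolated linearly:
    F + (threshold - C_F) / (C_{F+1} - C_F).  Exact attainment at day F
    returns F.  If the threshold is reached within the first day the result
    lies in the open-left interval (s_start - 1, s_start].

    Raises :class:`NonAttainmentError` (with the final deficit) if the total
    never reaches the threshold.
    """
    inc = np.asarray(daily_increments, dtype=float)
    if inc.ndim != 1 or inc.size == 0:
        raise ValueError("daily_increments must be a non-empty 1-d sequence")
    if np.any(inc < 0):
        raise ValueError("daily increments must be >= 0")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    ccum = np.concatenate([[0.0], np.cumsum(inc)])
    if threshold > ccum[-1]:
        raise NonAttainmentError(threshold - ccum[-1])
    idx = int(np.searchsorted(ccum, threshold, side="left"))
    prev = ccum[idx - 1]
    step = ccum[idx] - prev
    return s_start + idx - 2 + (threshold - prev) / step


@dataclass
class MethodFit:
    """A fitted forcing method: parameters, per-year predictions, RMSE."""

    method: str
    family: str | None
    s_start: int
    params: dict[str, float]
    threshold: float
    per_year: pd.DataFrame  # columns: year, observed, predicted, residual
    rmse: float
    search_trace: pd.DataFrame | None = None

    @property
    def residuals(self) -> pd.Series:
        return self.per_year.set_index("year")["residual"]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_year"] = self.per_year.to_dict(orient="records")
        if self.search_trace is not None:
            d["search_trace"] = self.search_trace.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# shared machinery


def _year_matrix(climate: ClimateSeries, years, column: str = "t_mean") -> np.ndarray:
    """(n_years, 366) daily temperatures; 365-day years padded with 31 Dec."""
    rows = []
    for y in years:
        v = climate.year_values(int(y), column)
        if v.size == 365:
            v = np.concatenate([v, v[-1:]])
        rows.append(v)
    return np.vstack(rows)


def _predict_rows(ccum: np.ndarray, s_start: int, thresholds: np.ndarray):
    """Vectorised trapezoid attainment over rows of cumulative matrices.

    ``ccum`` has shape (n, 367) with ccum[:, d] the total through day d
    (column 0 is zero).  Returns (pred, attained); pred is NaN where the
    threshold is not attained by day 366.
    """
    base = ccum[:, s_start - 1]
    target = base + thresholds
    attained = ccum[:, -1] >= target
    d = np.argmax(ccum >= target[:, None], axis=1)
    d = np.where(attained, d, ccum.shape[1] - 1)
    rows = np.arange(ccum.shape[0])
    prev = ccum[rows, d - 1]
    step = ccum[rows, d] - prev
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (d - 1) + (target - prev) / step
    pred = np.where(attained, pred, np.nan)
    return pred, attained


def _ccum(inc: np.ndarray) -> np.ndarray:
    """Prepend a zero column and cumulative-sum along days."""
    z = np.zeros((inc.shape[0], 1))
    return np.hstack([z, np.cumsum(inc, axis=1)])


def _rmse(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residuals))))


def select_start_date_add(
    climate: ClimateSeries,
    pheno: pd.DataFrame,
    candidates=DEFAULT_S_CANDIDATES,
) -> tuple[int, pd.DataFrame]:
    """Aono starting-date selection for the degree-day method.

    For each candidate S, the mean daily mean temperature over [S, E_i] is
    correlated (Pearson) with the observed dates E_i across years; the S with
    the most negative coefficient is returned together with the full profile.
    Ties break to the earliest day; zero-variance candidates are skipped.
    """
    years = pheno["year"].to_numpy()
    if years.size < 3:
        raise ValueError("need at least 3 years to select a starting date")
    e_obs = pheno["ffd_doy"].to_numpy(dtype=float)
    e_int = np.asarray(np.floor(e_obs), dtype=int)
    if not all(c < e_int.min() for c in candidates):
        raise ValueError("every candidate S must precede the earliest observed date")
    tm = _year_matrix(climate, years)
    ccum = _ccum(tm)  # plain sums (no clipping) for window means
    rows = np.arange(len(years))
    out = []
    for s in candidates:
        span = e_int - s + 1
        means = (ccum[rows, e_int] - ccum[rows, s - 1]) / span
        if np.ptp(means) == 0 or np.ptp(e_obs) == 0:
            warnings.warn(f"candidate S={s} skipped: zero variance")
            continue
        r = float(np.corrcoef(means, e_obs)[0, 1])
        out.append((int(s), r))
    if not out:
        raise ValueError("no usable starting-date candidate")
    profile = pd.DataFrame(out, columns=["s", "correlation"])
    best = int(profile.loc[profile["correlation"].idxmin(), "s"])
    return best, profile


class _ForcingModel(BaseEstimator):
    """Common fitted-attribute plumbing for the three forcing estimators."""

    method: str = ""

    def _finalize(self, years, e_obs, pred, s_start, params, threshold, family, trace):
        residual = e_obs - pred
        per_year = pd.DataFrame(
            {"year": years, "observed": e_obs, "predicted": pred, "residual": residual}
        )
        self.s_start_ = int(s_start)
        self.params_ = dict(params)
        self.threshold_ = float(threshold)
        self.rmse_ = _rmse(residual)
        self.per_year_ = per_year
        self.fit_result_ = MethodFit(
            method=self.method,
            family=family,
            s_start=self.s_start_,
            params=self.params_,
            threshold=self.threshold_,
            per_year=per_year,
            rmse=self.rmse_,
            search_trace=trace,
        )
        return self

    def _increments(self, tm: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, climate: ClimateSeries, years) -> pd.Series:
        """Fractional predicted day-of-year per requested year (NaN + warning
        for years where the threshold is not attained)."""
        years = list(int(y) for y in years)
        tm = _year_matrix(climate, years)
        ccum = _ccum(self._increments(tm))
        pred, attained = _predict_rows(ccum, self.s_start_, np.full(len(years), self.threshold_))
        for y, ok in zip(years, attained):
            if not ok:
                warnings.warn(f"year {y}: threshold not attained by 31 Dec")
        return pd.Series(pred, index=pd.Index(years, name="year"), name="predicted")


class DegreeDayModel(_ForcingModel):
    """Accumulated degree-days (ADD) with Aono starting-date selection.

    Parameters
    ----------
    s_start : fixed starting day-of-year, or None to select it with the Aono
        correlation protocol over ``s_candidates``.
    t0_grid : candidate base temperatures T0 (degC); the value minimising
        RMSE between observed and trapezoid-interpolated predicted dates wins
        (ties to the smallest T0).
    """

    method = "ADD"

    def __init__(self, s_start=None, s_candidates=DEFAULT_S_CANDIDATES, t0_grid=None):
        self.s_start = s_start
        self.s_candidates = s_candidates
        self.t0_grid = t0_grid

    def _increments(self, tm):
        return np.clip(tm - self.t0_, 0.0, None)

    def fit(self, climate: ClimateSeries, pheno: pd.DataFrame):
        t0_grid = DEFAULT_T0_GRID if self.t0_grid is None else np.asarray(self.t0_grid, float)
        if self.s_start is None:
            s_start, self.start_profile_ = select_start_date_add(
                climate, pheno, self.s_candidates
            )
        else:
            s_start = int(self.s_start)
            self.start_profile_ = None
        years = pheno["year"].to_numpy()
        e_obs = pheno["ffd_doy"].to_numpy(dtype=float)
        e_int = np.asarray(np.floor(e_obs), dtype=int)
        tm = _year_matrix(climate, years)
        rows = np.arange(len(years))
        rmses, kbars, preds = [], [], []
        for t0 in t0_grid:
            ccum = _ccum(np.clip(tm - t0, 0.0, None))
            k = ccum[rows, e_int] - ccum[rows, s_start - 1]
            kbar = float(np.mean(k))
            if kbar <= 0:
                rmses.append(np.inf)
                kbars.append(kbar)
                preds.append(None)
                continue
            pred, attained = _predict_rows(ccum, s_start, np.full(len(years), kbar))
            if not attained.all():
                rmses.append(np.inf)
                kbars.append(kbar)
                preds.append(None)
                continue
            rmses.append(_rmse(e_obs - pred))
            kbars.append(kbar)
            preds.append(pred)
        rmses = np.asarray(rmses)
        if not np.isfinite(rmses).any():
            raise NonAttainmentError(np.nan)
        best = int(np.argmin(rmses))  # first minimum -> smallest T0
        self.t0_ = float(t0_grid[best])
        trace = pd.DataFrame({"t0": t0_grid, "rmse": rmses})
        return self._finalize(
            years, e_obs, preds[best], s_start,
            {"T0": self.t0_}, kbars[best], None, trace,
        )


class StandardizedDaysModel(_ForcingModel):
    """Accumulated days transferred to a standard temperature (ADTS).

    Joint grid search over the starting date S and the Arrhenius activation
    energy Ea (kcal/mol): each day contributes its DTS factor
    exp(Ea*(T_K - T_s)/(R*T_K*T_s)); the per-year sums from S to the observed
    date define the mean requirement; the (S, Ea) pair minimising RMSE wins
    (ties to smaller S, then smaller Ea).
    """

    method = "ADTS"

    def __init__(self, s_candidates=DEFAULT_S_CANDIDATES, ea_grid=None,
                 t_standard=T_STANDARD_K):
        self.s_candidates = s_candidates
        self.ea_grid = ea_grid
        self.t_standard = t_standard

    def _increments(self, tm):
        return dts(tm, self.ea_, self.t_standard)

    def fit(self, climate: ClimateSeries, pheno: pd.DataFrame):
        ea_grid = DEFAULT_EA_GRID if self.ea_grid is None else np.asarray(self.ea_grid, float)
        s_candidates = list(self.s_candidates)
        years = pheno["year"].to_numpy()
        e_obs = pheno["ffd_doy"].to_numpy(dtype=float)
        e_int = np.asarray(np.floor(e_obs), dtype=int)
        tm = _year_matrix(climate, years)
        t_k = celsius_to_kelvin(tm)
        f = (t_k - self.t_standard) / (R_KCAL * t_k * self.t_standard)
        rows = np.arange(len(years))
        best = None  # (rmse, s, ea, ubar, pred)
        records = []
        for ea in ea_grid:
            ccum = _ccum(np.exp(ea * f))
            cc_at_e = ccum[rows, e_int]
            for s in s_candidates:
                u = cc_at_e - ccum[:, s - 1]
                ubar = float(np.mean(u))
                pred, attained = _predict_rows(ccum, s, np.full(len(years), ubar))
                if not attained.all():
                    records.append((s, ea, np.inf))
                    continue
                rmse = _rmse(e_obs - pred)
                records.append((s, ea, rmse))
                key = (rmse, s, ea)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (rmse, s, ea, ubar, pred)
        if best is None or not np.isfinite(best[0]):
            raise NonAttainmentError(np.nan)
        _, s, ea, ubar, pred = best
        self.ea_ = float(ea)
        trace = pd.DataFrame(records, columns=["s", "ea", "rmse"])
        return self._finalize(
            years, e_obs, pred, s, {"Ea": self.ea_}, ubar, None, trace,
        )


_ADP_BASE_INITS = {
    "logan": {"psi": 0.01, "rho": 0.1, "Tu": 40.0, "z": 6.0},
    "logistic": {"K": 0.15, "K0": 0.01, "b": 0.1},
    "linear": {"a": 0.005, "b": 0.002},
}

_INVALID_OBJECTIVE = 1e6


class DevelopmentalProgressModel(_ForcingModel):
    """Accumulated developmental progress (ADP) with any rate family.

    For each candidate starting date S, the rate-equation parameters are
    estimated by Nelder--Mead minimisation of the RMSE between observed dates
    and the (fractional) dates at which accumulated daily rates reach 100%
    progress; the (S, parameters) pair with the global minimum RMSE is kept.

    ``init='auto'`` seeds the Arrhenius family from an internal coarse DTS
    scan (Ea from the scan; B set so the mean terminal progress at the
    observed dates is exactly 1) and the other families from literature-scale
    values with jittered restarts.  Years where a parameter trial fails to
    attain 100% are penalised with a large finite residual
    (366 - E_i + 100*deficit) to keep the simplex objective informative.
    """

    method = "ADP"

    def __init__(self, family="arrhenius", s_candidates=DEFAULT_S_CANDIDATES,
                 init="auto", n_restarts=5, tol=1e-8, max_iter=2000, seed=0):
        self.family = family
        self.s_candidates = s_candidates
        self.init = init
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _increments(self, tm):
        return self.rate_model_.rate(tm)

    def _objective(self, vec, template, tm, e_obs, e_int, s):
        try:
            model = template.with_params(vec)
        except ValueError:
            return _INVALID_OBJECTIVE
        p = model.params
        if model.family == "logistic" and not (0.0 < p["K0"] < p["K"]):
            return _INVALID_OBJECTIVE
        if model.family == "logan" and (p["z"] <= 0 or p["rho"] <= 0 or p["psi"] <= 0):
            return _INVALID_OBJECTIVE
        with np.errstate(over="ignore"):
            inc = model.rate(tm)
        if not np.all(np.isfinite(inc)):
            return _INVALID_OBJECTIVE
        ccum = _ccum(inc)
        pred, attained = _predict_rows(ccum, s, np.ones(len(e_obs)))
        resid = np.where(
            attained,
            e_obs - np.nan_to_num(pred),
            (366.0 - e_obs) + 100.0 * (1.0 - (ccum[:, -1] - ccum[:, s - 1])),
        )
        return _rmse(resid)

    def _auto_inits(self, tm, e_int, s, rng):
        """Start vectors for the Nelder--Mead runs at one candidate S."""
        if self.family == "arrhenius":
            t_k = celsius_to_kelvin(tm)
            f = (t_k - T_STANDARD_K) / (R_KCAL * t_k * T_STANDARD_K)
            rows = np.arange(tm.shape[0])
            best_ea, best_spread = None, np.inf
            for ea in np.arange(5.0, 30.0 + 1e-9, 1.0):
                ccum = _ccum(np.exp(ea * f))
                u = ccum[rows, e_int] - ccum[:, s - 1]
                spread = np.std(u) / np.mean(u)
                if spread < best_spread:
                    best_ea, best_spread = float(ea), float(spread)
            # B such that mean terminal progress at observed dates is 1
            g = PRE_EXP_SCALE * np.exp(-best_ea / (R_KCAL * celsius_to_kelvin(tm)))
            ccum = _ccum(g)
            mean_v = float(np.mean(ccum[np.arange(tm.shape[0]), e_int] - ccum[:, s - 1]))
            b0 = -np.log(mean_v)
            base = np.array([b0, best_ea])
            jitter = rng.normal(scale=[0.2, 1.0], size=(max(self.n_restarts - 1, 0), 2))
            return [base] + [base + j for j in jitter]
        base = np.array(
            [_ADP_BASE_INITS[self.family][k]
             for k in RateModel(self.family, _ADP_BASE_INITS[self.family]).params]
        )
        starts = [base]
        for _ in range(max(self.n_restarts - 1, 0)):
            starts.append(base * np.exp(rng.normal(scale=0.3, size=base.size)))
        return starts

    def fit(self, climate: ClimateSeries, pheno: pd.DataFrame):
        rng = np.random.default_rng(self.seed)
        years = pheno["year"].to_numpy()
        e_obs = pheno["ffd_doy"].to_numpy(dtype=float)
        e_int = np.asarray(np.floor(e_obs), dtype=int)
        tm = _year_matrix(climate, years)
        template = RateModel(self.family, dict(_ADP_BASE_INITS.get(
            self.family, {"B": -4.0, "Ea": 15.0})))
        best = None  # (rmse, s, vec)
        records = []
        for s in self.s_candidates:
            if self.init == "auto":
                starts = self._auto_inits(tm, e_int, int(s), rng)
            else:
                starts = [np.asarray(self.init, float)]
            s_best = None
            for x0 in starts:
                res = minimize(
                    self._objective, x0,
                    args=(template, tm, e_obs, e_int, int(s)),
                    method="Nelder-Mead",
                    options={"xatol": self.tol, "fatol": self.tol,
                             "maxiter": self.max_iter, "maxfev": 2 * self.max_iter},
                )
                if s_best is None or res.fun < s_best.fun:
                    s_best = res
            records.append((int(s), float(s_best.fun)))
            key = (float(s_best.fun), int(s))
            if best is None or key < (best[0], best[1]):
                best = (float(s_best.fun), int(s), np.array(s_best.x))
        rmse, s, vec = best
        self.rate_model_ = template.with_params(vec)
        ccum = _ccum(self.rate_model_.rate(tm))
        pred, attained = _predict_rows(ccum, s, np.ones(len(years)))
        if not attained.all():
            bad = [int(y) for y, ok in zip(years, attained) if not ok]
            raise NonAttainmentError(float("nan")) from RuntimeError(
                f"best ADP parameters do not attain 100% progress in years {bad}"
            )
        rows = np.arange(len(years))
        self.terminal_progress_ = pd.Series(
            ccum[rows, e_int] - ccum[:, s - 1],
            index=pd.Index(years, name="year"), name="terminal_progress",
        )
        trace = pd.DataFrame(records, columns=["s", "rmse"])
        return self._finalize(
            years, e_obs, pred, s, dict(self.rate_model_.params), 1.0,
            self.family, trace,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_add(climate, pheno, s_start=None, t0_candidates=None,
            s_candidates=DEFAULT_S_CANDIDATES) -> MethodFit:
    est = DegreeDayModel(s_start=s_start, s_candidates=s_candidates, t0_grid=t0_candidates)
    return est.fit(climate, pheno).fit_result_


def fit_adts(climate, pheno, s_candidates=DEFAULT_S_CANDIDATES, ea_candidates=None) -> MethodFit:
    est = StandardizedDaysModel(s_candidates=s_candidates, ea_grid=ea_candidates)
    return est.fit(climate, pheno).fit_result_


def fit_adp(climate, pheno, s_candidates=DEFAULT_S_CANDIDATES, family="arrhenius",
            init="auto", seed=0) -> MethodFit:
    est = DevelopmentalProgressModel(family=family, s_candidates=s_candidates,
                                     init=init, seed=seed)
    return est.fit(climate, pheno).fit_result_


def predict_years(fit: MethodFit, climate: ClimateSeries, years) -> pd.Series:
    """Apply a fitted method to (possibly new) years; NaN where not attained."""
    if fit.method == "ADD":
        est = DegreeDayModel(s_start=fit.s_start)
        est.t0_ = fit.params["T0"]
    elif fit.method == "ADTS":
        est = StandardizedDaysModel()
        est.ea_ = fit.params["Ea"]
    elif fit.method == "ADP":
        est = DevelopmentalProgressModel(family=fit.family)
        est.rate_model_ = RateModel(fit.family, dict(fit.params))
    else:
        raise ValueError(f"unknown method {fit.method!r}")
    est.s_start_ = fit.s_start
    est.threshold_ = fit.threshold
    return est.predict(climate, years)
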