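"""Generalized additive modelling of forcing-method residuals.

The residuals y_i = E_i - Ehat_i of the best spring-forcing fit are regressed
on the fall--winter temperature features x1..x6 with a Gaussian-family
additive model: one univariate penalized B-spline smooth per feature plus an
intercept.  Candidate formulas (subsets of features) are compared on the
percentage of deviance explained, subject to every smooth term being
significant at a stated level; AIC is reported alongside.  The deviance
explained of the winning model is partitioned into per-feature contribution
rates via inverse drop-one deviances, and the smoothed residuals are added
back to the forcing predictions to give adjusted flowering dates.

Smoothing uses a basis dimension of 6 per term (cubic B-splines) and a single
shared penalty weight selected by generalized cross-validation on a log-spaced
grid — deliberately small-basis for the ~40-year series this targets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.gam.api import GLMGam, BSplines

from .forcing import MethodFit

__all__ = [
    "TABLE_CANDIDATE_FORMULAS",
    "ResidualGAM",
    "fit_residual_gam",
    "select_best_gam",
    "contribution_rates",
    "adjust_predictions",
]

#: default candidate set: feature subsets of the six FWT predictors compared
#: in the residual analysis (full model, each leave-one-out, and three
#: reduced models around the chilling/cold-day core).
TABLE_CANDIDATE_FORMULAS = (
    ("x1", "x2", "x3", "x4", "x5", "x6"),
    ("x2", "x3", "x4", "x5", "x6"),
    ("x1", "x3", "x4", "x5", "x6"),
    ("x1", "x2", "x4", "x5", "x6"),
    ("x1", "x2", "x3", "x5", "x6"),
    ("x1", "x2", "x3", "x4", "x6"),
    ("x1", "x2", "x3", "x4", "x5"),
    ("x1", "x2", "x4", "x5"),
    ("x1", "x2", "x5"),
    ("x1", "x2", "x4"),
)

_ALPHA_GRID = 10.0 ** np.arange(-3.0, 7.0)


def all_subset_formulas(features=("x1", "x2", "x3", "x4", "x5", "x6"),
                        min_size: int = 2, max_size: int = 4):
    """All feature subsets of the given sizes, as candidate formulas.

    Useful for recovery studies where no prior candidate list exists: unlike
    a hand-curated list, it does not force any feature into every model, so
    the significance screen cannot disqualify the true subset."""
    from itertools import combinations

    out = []
    for k in range(min_size, max_size + 1):
        out.extend(combinations(features, k))
    return tuple(out)


class ResidualGAM(BaseEstimator):
    """Gaussian additive model of residuals on FWT features.

    Parameters
    ----------
    terms : feature names to smooth (default: all columns of X).
    df : basis dimension per smooth (default 6; keep small relative to the
        number of years).
    degree : B-spline degree (default 3, cubic).
    alpha : penalty weight; a float/sequence is used as-is, the default
        ``"gcv"`` selects a single shared weight from a log-spaced grid by
        generalized cross-validation.

    Fitted attributes: ``results_`` (statsmodels GLMGamResults),
    ``deviance_explained_``, ``aic_``, ``term_pvalues_`` (approximate Wald
    p-value per smooth), ``fitted_values_``, ``alpha_``, ``edf_``.
    """

    def __init__(self, terms=None, df=6, degree=3, alpha="gcv"):
        self.terms = terms
        self.df = df
        self.degree = degree
        self.alpha = alpha

    # -- internal -----------------------------------------------------------

    def _design(self, X: pd.DataFrame):
        terms = list(self.terms) if self.terms is not None else list(X.columns)
        missing = [t for t in terms if t not in X.columns]
        if missing:
            raise KeyError(f"features {missing} not in table columns {list(X.columns)}")
        mat = X[terms].to_numpy(dtype=float)
        return terms, mat

    def _make_model(self, y, mat, alpha_vec, terms):
        bs = BSplines(mat, df=[self.df] * len(terms), degree=[self.degree] * len(terms),
                      variable_names=terms)
        n = len(y)
        if bs.basis.shape[1] + 1 >= n:
            raise ValueError(
                f"{bs.basis.shape[1] + 1} coefficients for {n} observations; "
                "reduce the basis dimension (df) or the number of terms"
            )
        intercept = np.ones((n, 1))
        return GLMGam(y, exog=intercept, smoother=bs, alpha=alpha_vec), bs

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(y).astype(float)
        if isinstance(y.index, pd.RangeIndex) and isinstance(X.index, pd.Index):
            y.index = X.index
        if len(y) != len(X):
            raise ValueError("X and y must have the same number of rows")
        if len(y) < 10:
            raise ValueError("need at least 10 years to fit a residual GAM")
        terms, mat = self._design(X)
        yv = y.to_numpy()
        if np.ptp(yv) == 0.0:
            # constant response: the additive model is the constant itself
            return self._fit_constant(X, yv, terms, mat)
        if self.alpha == "gcv":
            best = None
            for a in _ALPHA_GRID:
                model, _ = self._make_model(yv, mat, [a] * len(terms), terms)
                res = model.fit()
                if best is None or res.gcv < best[0]:
                    best = (res.gcv, a)
            alpha_vec = [best[1]] * len(terms)
        elif np.isscalar(self.alpha):
            alpha_vec = [float(self.alpha)] * len(terms)
        else:
            alpha_vec = [float(a) for a in self.alpha]
        model, bs = self._make_model(yv, mat, alpha_vec, terms)
        res = model.fit()
        null_dev = float(np.sum((yv - yv.mean()) ** 2))
        de = 1.0 - res.deviance / null_dev if null_dev > 0 else 0.0
        pvals = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            for i, t in enumerate(terms):
                try:
                    pvals[t] = float(np.squeeze(res.test_significance(i).pvalue))
                except Exception:  # degenerate smooth (e.g. fully penalised)
                    pvals[t] = float("nan")
        self.terms_ = terms
        self.alpha_ = alpha_vec
        self.smoother_ = bs
        self.model_ = model
        self.results_ = res
        self.deviance_explained_ = float(max(de, 0.0))
        self.aic_ = float(res.aic)
        self.edf_ = float(res.hat_matrix_trace)
        self.term_pvalues_ = pvals
        self.fitted_values_ = pd.Series(np.asarray(res.fittedvalues), index=X.index,
                                        name="fitted_residual")
        return self

    def _fit_constant(self, X, yv, terms, mat):
        """Degenerate fit for a constant response (null deviance is zero)."""
        _, bs = self._make_model(np.zeros_like(yv) + yv, mat,
                                 [_ALPHA_GRID[-1]] * len(terms), terms)
        self.terms_ = terms
        self.alpha_ = [_ALPHA_GRID[-1]] * len(terms)
        self.smoother_ = bs
        self.model_ = None
        self.results_ = None
        self.deviance_explained_ = 0.0
        self.aic_ = float("nan")
        self.edf_ = 1.0
        self.term_pvalues_ = {t: float("nan") for t in terms}
        self.fitted_values_ = pd.Series(np.full(len(yv), yv.mean()), index=X.index,
                                        name="fitted_residual")
        self._constant_ = float(yv.mean())
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        terms, mat = self._design(X)
        if terms != self.terms_:
            raise ValueError("prediction features differ from the fitted terms")
        if self.results_ is None:  # constant-response degenerate fit
            return pd.Series(np.full(len(X), self._constant_), index=X.index,
                             name="fitted_residual")
        pred = self.results_.predict(exog=np.ones((len(X), 1)), exog_smooth=mat)
        return pd.Series(np.asarray(pred), index=X.index, name="fitted_residual")

    def nonsignificant_terms(self, alpha_level: float = 0.05) -> list[str]:
        return [t for t, p in self.term_pvalues_.items()
                if not (np.isfinite(p) and p < alpha_level)]

    def partial_residual_data(self, term: str) -> pd.DataFrame:
        """Per-year partial residuals and smooth component for one term
        (plot-ready: columns value, smooth, partial_residual)."""
        i = self.terms_.index(term)
        smoother = self.smoother_.smoothers[i]
        k_lin = self.results_.model.exog_linear.shape[1]
        start = k_lin + sum(s.dim_basis for s in self.smoother_.smoothers[:i])
        coef = self.results_.params[start:start + smoother.dim_basis]
        component = smoother.basis @ coef
        resid = (np.asarray(self.results_.model.endog)
                 - np.asarray(self.results_.fittedvalues))
        return pd.DataFrame(
            {"value": smoother.x, "smooth": component,
             "partial_residual": component + resid},
            index=self.fitted_values_.index,
        )


def fit_residual_gam(y, features: pd.DataFrame, formula, **kwargs) -> ResidualGAM:
    """Fit one residual GAM with the given feature subset (thin wrapper)."""
    return ResidualGAM(terms=list(formula), **kwargs).fit(features, y)


def select_best_gam(
    y,
    features: pd.DataFrame,
    candidate_formulas=TABLE_CANDIDATE_FORMULAS,
    alpha_level: float = 0.05,
    **gam_kwargs,
) -> tuple[ResidualGAM, pd.DataFrame]:
    """Pick the candidate with the highest deviance explained among those
    whose every smooth term is significant at ``alpha_level``.

    Returns the winning fitted model and a comparison table (formula, aic,
    deviance_explained, nonsignificant terms).  If no candidate has all terms
    significant, the lowest-AIC fit is returned with a warning.
    """
    if not candidate_formulas:
        raise ValueError("candidate_formulas must be non-empty")
    rows, fits = [], []
    for formula in candidate_formulas:
        label = " + ".join(f"s({t})" for t in formula)
        try:
            g = fit_residual_gam(y, features, formula, **gam_kwargs)
        except Exception as exc:  # noqa: BLE001 - selection proceeds over the rest
            warnings.warn(f"candidate {label} failed: {exc}")
            rows.append({"formula": label, "aic": np.nan, "deviance_explained": np.nan,
                         "nonsignificant": "fit failed"})
            fits.append(None)
            continue
        ns = g.nonsignificant_terms(alpha_level)
        rows.append({
            "formula": label,
            "aic": g.aic_,
            "deviance_explained": g.deviance_explained_,
            "nonsignificant": ", ".join(f"s({t})" for t in ns) if ns else "-",
        })
        fits.append(g)
    table = pd.DataFrame(rows)
    qualified = [
        (g.deviance_explained_, -i)
        for i, g in enumerate(fits)
        if g is not None and not g.nonsignificant_terms(alpha_level)
    ]
    if qualified:
        best_idx = -max(qualified)[1]
    else:
        warnings.warn("no candidate has all smooth terms significant; "
                      "returning the lowest-AIC model")
        aics = [g.aic_ if g is not None else np.inf for g in fits]
        best_idx = int(np.argmin(aics))
    return fits[best_idx], table


def contribution_rates(
    y,
    features: pd.DataFrame,
    formula,
    **gam_kwargs,
) -> pd.Series:
    """Partition the full model's deviance explained across its features.

    With DE_0 the deviance explained by the model using all z features and
    DE_j that of the model dropping feature j, the contribution rate of
    feature i is (1/DE_i) / sum_j (1/DE_j) * DE_0 * 100 (percent).  The rates
    sum to DE_0 * 100 by construction.
    """
    formula = list(formula)
    if len(formula) < 2:
        raise ValueError("contribution rates need at least 2 features")
    de0 = fit_residual_gam(y, features, formula, **gam_kwargs).deviance_explained_
    de_drop = {}
    for term in formula:
        reduced = [t for t in formula if t != term]
        de_drop[term] = fit_residual_gam(y, features, reduced, **gam_kwargs).deviance_explained_
        if de_drop[term] == 0:
            raise ZeroDivisionError(
                f"deviance explained dropping {term} is zero; contribution "
                "rates are undefined (refit with a different candidate set)"
            )
    return combine_drop_one_deviances(de0, de_drop)


def combine_drop_one_deviances(de0: float, de_drop: dict) -> pd.Series:
    """Inverse-deviance partition: CR_i = (1/DE_i) / sum_j (1/DE_j) * DE_0 * 100.

    ``de_drop[t]`` is the deviance explained by the model *without* feature t;
    a feature whose removal hurts more (smaller DE) gets a larger share.  The
    rates sum to ``de0 * 100`` by construction."""
    inv = {t: 1.0 / d for t, d in de_drop.items()}
    total = sum(inv.values())
    return pd.Series({t: inv[t] / total * de0 * 100.0 for t in de_drop},
                     name="contribution_rate_pct")


def adjust_predictions(adp_fit: MethodFit, gam: ResidualGAM) -> tuple[pd.DataFrame, float]:
    """Add the smoothed residuals back to the forcing predictions.

    Returns a per-year table (observed, predicted, fitted_residual, adjusted)
    and the adjusted RMSE.  The GAM must have been fitted on this method fit's
    residuals (year indices must match).
    """
    per_year = adp_fit.per_year.set_index("year")
    yhat = gam.fitted_values_
    if not per_year.index.equals(yhat.index):
        raise ValueError("GAM years do not match the method fit's years")
    adjusted = per_year["predicted"] + yhat
    rmse_adj = float(np.sqrt(np.mean((per_year["observed"] - adjusted) ** 2)))
    out = pd.DataFrame({
        "observed": per_year["observed"],
        "predicted": per_year["predicted"],
        "fitted_residual": yhat,
        "adjusted": adjusted,
    })
    return out, rmse_adj
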