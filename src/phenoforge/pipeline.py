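"""End-to-end orchestration: forcing fit -> residual GAM -> adjusted dates.

A single config (YAML mapping or dict) drives the full chain:

1. load climate + phenology CSVs (or simulate both from generator specs);
2. fit the requested forcing method (ADD / ADTS / ADP) and take its
   per-year residuals;
3. compute the fall--winter features and scan the critical low temperature
   for x1 by GAM deviance explained;
4. select the best candidate GAM (highest deviance explained with all
   smooths significant);
5. compute per-feature contribution rates and adjusted predictions.

Every stage's outputs (method fit JSON, features CSV, GAM report JSON,
adjusted predictions CSV, run log) are written under ``out_dir``; re-running
the same config reproduces them bit-exactly.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import read_climate_csv, read_phenology_csv
from .forcing import DegreeDayModel, StandardizedDaysModel, DevelopmentalProgressModel
from .fwt import fwt_table, scan_critical_temperature, CHILL_LOWER_DEFAULT, CHILL_UPPER_DEFAULT
from .gam import (TABLE_CANDIDATE_FORMULAS, select_best_gam, contribution_rates,
                  adjust_predictions)
from .rates import RateModel
from .synthetic import ClimateGenSpec, PhenoGenSpec, simulate_climate, simulate_ffd

__all__ = ["load_config", "run_pipeline"]

_METHODS = {"add", "adts", "adp"}
_FAMILIES = {"linear", "arrhenius", "logan", "logistic"}

DEFAULT_CONFIG = {
    "method": "adp",
    "family": "arrhenius",
    "s_candidates": list(range(30, 71)),
    "t0_grid": None,
    "ea_grid": None,
    "seed": 0,
    "fwt": {
        "chill_lower": CHILL_LOWER_DEFAULT,
        "chill_upper": CHILL_UPPER_DEFAULT,
        "critical_candidates": [round(c, 1) for c in np.arange(-10.0, 7.0 + 1e-9, 0.5)],
    },
    "gam": {
        "candidates": "default",
        "alpha_level": 0.05,
        "df": 6,
        "degree": 3,
        "alpha": "gcv",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def validate_config(user: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, user)
    if cfg["method"] not in _METHODS:
        raise ValueError(f"unknown method {cfg['method']!r}; choose from {sorted(_METHODS)}")
    if cfg["family"] not in _FAMILIES:
        raise ValueError(f"unknown rate family {cfg['family']!r}")
    has_files = "climate_csv" in cfg and "pheno_csv" in cfg
    has_sim = "simulate" in cfg
    if not (has_files or has_sim):
        raise ValueError("config must provide climate_csv+pheno_csv or a simulate block")
    if has_files:
        for key in ("climate_csv", "pheno_csv"):
            if not Path(cfg[key]).exists():
                raise FileNotFoundError(cfg[key])
    return cfg


def _load_inputs(cfg: dict):
    if "climate_csv" in cfg and "pheno_csv" in cfg:
        climate = read_climate_csv(cfg["climate_csv"])
        pheno = read_phenology_csv(cfg["pheno_csv"])
        truth = None
    else:
        sim = cfg["simulate"]
        cspec = ClimateGenSpec(**{**sim.get("climate", {}), "seed": cfg["seed"]})
        climate = simulate_climate(cspec)
        pkw = dict(sim.get("pheno", {}))
        if "rate_model" in pkw:
            pkw["rate_model"] = RateModel.from_dict(pkw["rate_model"])
        pspec = PhenoGenSpec(**{**pkw, "seed": cfg["seed"] + 1})
        pheno, truth = simulate_ffd(climate, pspec)
    return climate, pheno, truth


def _fit_method(cfg: dict, climate, pheno):
    if cfg["method"] == "add":
        est = DegreeDayModel(s_candidates=cfg["s_candidates"], t0_grid=cfg["t0_grid"])
    elif cfg["method"] == "adts":
        est = StandardizedDaysModel(s_candidates=cfg["s_candidates"], ea_grid=cfg["ea_grid"])
    else:
        est = DevelopmentalProgressModel(
            family=cfg["family"], s_candidates=cfg["s_candidates"], seed=cfg["seed"]
        )
    return est.fit(climate, pheno)


def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """Run the full chain under one config; returns the report dict.

    ``config`` may be a dict or a YAML path.  ``out_dir`` (or
    ``config['out_dir']``) selects where reports are written; with neither
    set, nothing is written and the report is only returned.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else validate_config(config)
    out = Path(out_dir or cfg.get("out_dir")) if (out_dir or cfg.get("out_dir")) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception:
            print(f"pipeline stage failed: {name}", file=sys.stderr)
            raise

    climate, pheno, truth = _stage("load_inputs", lambda: _load_inputs(cfg))
    est = _stage("forcing_fit", lambda: _fit_method(cfg, climate, pheno))
    fit = est.fit_result_
    residuals = fit.residuals

    fcfg = cfg["fwt"]
    gcfg = cfg["gam"]
    gam_kwargs = {"df": gcfg["df"], "degree": gcfg["degree"], "alpha": gcfg["alpha"]}
    candidates = (TABLE_CANDIDATE_FORMULAS if gcfg["candidates"] == "default"
                  else [tuple(c) for c in gcfg["candidates"]])

    critical, crit_profile = _stage("critical_scan", lambda: scan_critical_temperature(
        residuals, climate, fit.s_start, fcfg["critical_candidates"],
        chill_lower=fcfg["chill_lower"], chill_upper=fcfg["chill_upper"],
        gam_kwargs=gam_kwargs,
    ))
    features = _stage("fwt_features", lambda: fwt_table(
        climate, residuals.index, fit.s_start, critical,
        fcfg["chill_lower"], fcfg["chill_upper"],
    ))
    best_gam, gam_table = _stage("gam_selection", lambda: select_best_gam(
        residuals, features, candidates, gcfg["alpha_level"], **gam_kwargs,
    ))
    rates_ = _stage("contribution_rates", lambda: contribution_rates(
        residuals, features, best_gam.terms_, **gam_kwargs,
    ))
    adjusted, rmse_adj = _stage("adjust", lambda: adjust_predictions(fit, best_gam))

    report = {
        "phenoforge_version": __version__,
        "config": _jsonable(cfg),
        "method_fit": fit.to_dict(),
        "critical_low": critical,
        "critical_profile": crit_profile.to_dict(orient="records"),
        "gam_table": gam_table.to_dict(orient="records"),
        "best_formula": list(best_gam.terms_),
        "best_gam": {
            "deviance_explained": best_gam.deviance_explained_,
            "aic": best_gam.aic_,
            "edf": best_gam.edf_,
            "term_pvalues": best_gam.term_pvalues_,
            "alpha": list(best_gam.alpha_),
        },
        "contribution_rates_pct": rates_.to_dict(),
        "rmse_unadjusted": fit.rmse,
        "rmse_adjusted": rmse_adj,
    }

    if out:
        with open(out / "method_fit.json", "w") as fh:
            json.dump(_jsonable(fit.to_dict()), fh, indent=2)
        features.to_csv(out / "features.csv")
        adjusted.to_csv(out / "adjusted_predictions.csv")
        with open(out / "gam_report.json", "w") as fh:
            json.dump(_jsonable({k: report[k] for k in (
                "critical_low", "critical_profile", "gam_table", "best_formula",
                "best_gam", "contribution_rates_pct", "rmse_unadjusted",
                "rmse_adjusted")}), fh, indent=2)
        with open(out / "run_log.json", "w") as fh:
            json.dump(_jsonable({
                "phenoforge_version": __version__,
                "config": cfg,
                "n_years": int(len(pheno)),
                "climate_report": climate.validation_report(),
            }), fh, indent=2)
        if truth is not None:
            truth.to_csv(out / "ground_truth.csv")

    report["features"] = features
    report["adjusted"] = adjusted
    report["truth"] = truth
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
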