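import pandas as pd
import pytest

from phenoforge import ClimateGenSpec, PhenoGenSpec, simulate_climate, simulate_ffd


@pytest.fixture(scope="session")
def climate_default():
    """One Beijing-like 41-year synthetic climate, shared across tests."""
    return simulate_climate(ClimateGenSpec(seed=11))


@pytest.fixture(scope="session")
def clean_phenology(climate_default):
    """Noiseless phenology forward-simulated from the default ground truth."""
    pheno, truth = simulate_ffd(climate_default, PhenoGenSpec(sigma_obs=0.0, seed=12))
    return pheno, truth


@pytest.fixture(scope="session")
def adp_fit_clean(climate_default, clean_phenology):
    from phenoforge import fit_adp

    pheno, _ = clean_phenology
    return fit_adp(climate_default, pheno, s_candidates=range(42, 53), seed=0)


@pytest.fixture()
def climate_csv(tmp_path, climate_default):
    path = tmp_path / "climate.csv"
    climate_default.to_csv(path)
    return path


@pytest.fixture()
def pheno_csv(tmp_path, clean_phenology):
    path = tmp_path / "phenology.csv"
    clean_phenology[0].to_csv(path, index=False)
    return path


def constant_climate(t_min, t_max, t_mean, years=(2001, 2004)):
    """A flat climate series covering calendar years [years[0], years[1])."""
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1] - 1}-12-31", freq="D")
    from phenoforge import ClimateSeries

    return ClimateSeries(pd.DataFrame({
        "date": dates,
        "t_min": t_min,
        "t_max": t_max,
        "t_mean": t_mean,
    }))
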