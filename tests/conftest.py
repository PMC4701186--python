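import numpy as np
import pandas as pd
import pytest

from chwvitals.synthetic_data import (
    CaptureModel,
    SimulationConfig,
    SurveyModel,
    simulate_ledger,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but event-rich simulation: ~30 births/month for 24 months."""
    return SimulationConfig(
        n_catchments=5,
        households_per_catchment=60,
        women_per_household=2,
        monthly_birth_prob=0.05,
        hazard_neonatal=0.05,
        hazard_postneonatal=0.05,
        hazard_child=0.06,
        stillbirth_prob=0.03,
        sim_start_cmc=1345,   # Jan 2012
        sim_end_cmc=1368,     # Dec 2013
        seed=7,
    )


@pytest.fixture
def small_ledger(small_config):
    return simulate_ledger(small_config)


@pytest.fixture
def perfect_capture():
    return CaptureModel()


@pytest.fixture
def faithful_census(small_config):
    return SurveyModel(design="census", interview_cmc=small_config.sim_end_cmc + 1)


def random_reports(rng, n_rows=200, n_catchments=4, start_cmc=1300, n_months=24):
    """Random monthly-report rows with valid nested death counts."""
    neo = rng.integers(0, 3, n_rows)
    extra_inf = rng.integers(0, 3, n_rows)
    extra_u5 = rng.integers(0, 3, n_rows)
    return pd.DataFrame({
        "catchment_id": rng.integers(0, n_catchments, n_rows),
        "cmc": rng.integers(start_cmc, start_cmc + n_months, n_rows),
        "births_male": rng.integers(0, 5, n_rows),
        "births_female": rng.integers(0, 5, n_rows),
        "deaths_neonatal": neo,
        "deaths_infant": neo + extra_inf,
        "deaths_under5": neo + extra_inf + extra_u5,
    })


def random_histories(rng, n_rows=150, start_cmc=1300, n_months=36):
    """Random birth-history rows: mixed survivors and deaths at varied ages."""
    birth_cmc = rng.integers(start_cmc, start_cmc + n_months, n_rows)
    died = rng.random(n_rows) < 0.4
    kind = rng.integers(0, 3, n_rows)  # 0 neonatal, 1 postneonatal, 2 child
    age_m = np.where(kind == 0, 0,
                     np.where(kind == 1, rng.integers(1, 12, n_rows),
                              rng.integers(12, 60, n_rows))).astype(float)
    age_d = np.where(kind == 0, rng.integers(0, 28, n_rows), np.nan).astype(float)
    age_m[~died] = np.nan
    age_d[~died] = np.nan
    death_cmc = np.where(died, birth_cmc + np.nan_to_num(age_m), np.nan)
    return pd.DataFrame({
        "mother_id": np.arange(n_rows),
        "child_id": np.arange(n_rows),
        "household_id": np.arange(n_rows),
        "catchment_id": rng.integers(0, 4, n_rows),
        "birth_cmc": birth_cmc.astype(float),
        "sex": np.where(rng.random(n_rows) < 0.5, "M", "F"),
        "died": died,
        "age_at_death_days": age_d,
        "age_at_death_months": age_m,
        "death_cmc": death_cmc,
        "interview_cmc": start_cmc + n_months + 12,
    })
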