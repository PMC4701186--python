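"""Synthetic vital-events data with explicit observation error models.

Three layers:

1. :func:`simulate_ledger` — ground-truth pregnancies, live births and
   under-five deaths for a grid of catchment areas over a monthly horizon.
2. :func:`apply_chw_observation` — what community health workers (CHWs)
   actually submit: per-event capture probabilities by event type,
   stillbirth misclassification, and wholesale loss of catchment-month
   reports.
3. :func:`apply_survey_observation` — a retrospective full-birth-history
   style survey: census or household sample, recall omission of dead
   children growing with time since death, age-at-death heaping onto 12
   months, and date displacement.

Time is discretized to months in century month code (CMC); neonatal deaths
additionally carry an age in days (uniform 0-27 given neonatal death).
Women's fertility is a constant per-woman-month probability over the short
(<= 48 month) horizon; multiple births are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .demography import NEONATAL_MAX_DAYS

__all__ = [
    "SimulationConfig",
    "CaptureModel",
    "SurveyModel",
    "simulate_ledger",
    "apply_chw_observation",
    "apply_survey_observation",
    "LEDGER_COLUMNS",
    "REPORT_COLUMNS",
    "HISTORY_COLUMNS",
]

#: EventLedger CSV header (one row per conception outcome).
LEDGER_COLUMNS = [
    "child_id", "mother_id", "household_id", "catchment_id",
    "birth_cmc", "sex", "stillbirth", "died",
    "age_at_death_days", "age_at_death_months", "death_cmc",
]

#: MonthlyReport CSV header (one row per *submitted* catchment-month).
REPORT_COLUMNS = [
    "catchment_id", "cmc",
    "births_male", "births_female",
    "deaths_neonatal", "deaths_infant", "deaths_under5",
]

#: BirthHistoryDataset CSV header (one row per live birth recalled).
HISTORY_COLUMNS = [
    "mother_id", "child_id", "household_id", "catchment_id",
    "birth_cmc", "sex", "died",
    "age_at_death_days", "age_at_death_months", "death_cmc",
    "interview_cmc",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Demographic regime and horizon for the ground-truth simulator."""

    n_catchments: int = 10
    households_per_catchment: int = 50
    women_per_household: int = 1
    monthly_birth_prob: float = 0.02
    srb_true: float = 105.0            # male births per 100 female
    hazard_neonatal: float = 0.03      # death prob in days 0-27
    hazard_postneonatal: float = 0.03  # death prob months 1-11 given survival
    hazard_child: float = 0.04         # death prob months 12-59 given survival
    stillbirth_prob: float = 0.02      # per pregnancy
    sim_start_cmc: int = 1345          # Jan 2012
    sim_end_cmc: int = 1380            # Dec 2014
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("monthly_birth_prob", "hazard_neonatal",
                     "hazard_postneonatal", "hazard_child", "stillbirth_prob"):
            _check_prob(name, getattr(self, name))
        for name in ("n_catchments", "households_per_catchment", "women_per_household"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.srb_true < 0:
            raise ValueError("srb_true must be non-negative")
        if self.sim_start_cmc >= self.sim_end_cmc:
            raise ValueError("sim_start_cmc must precede sim_end_cmc")

    @property
    def n_women(self) -> int:
        return self.n_catchments * self.households_per_catchment * self.women_per_household

    @property
    def population(self) -> int:
        """Fixed catchment-population denominator: women plus one adult each."""
        return 2 * self.n_women

    @property
    def true_u5_death_prob(self) -> float:
        """Cohort probability of dying before 60 months implied by the hazards."""
        return 1.0 - (1.0 - self.hazard_neonatal) * (1.0 - self.hazard_postneonatal) \
            * (1.0 - self.hazard_child)


@dataclass(frozen=True)
class CaptureModel:
    """How CHW monthly reports distort the ground truth."""

    p_capture_birth: float = 1.0
    p_capture_death_neonatal: float = 1.0
    p_capture_death_postneonatal: float = 1.0
    p_capture_death_child: float = 1.0
    p_monthly_report_missing: float = 0.0
    p_stillbirth_as_neonatal: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _check_prob(name, getattr(self, name))


@dataclass(frozen=True)
class SurveyModel:
    """How a retrospective birth/pregnancy history distorts the ground truth."""

    design: str = "census"             # "census" or "household_sample"
    sample_fraction: float = 1.0
    interview_cmc: int = 1381
    p_omit_per_year_recall: float = 0.0
    p_heap_to_12m: float = 0.0
    date_displacement_sd: float = 0.0  # months

    def __post_init__(self) -> None:
        if self.design not in ("census", "household_sample"):
            raise ValueError(f"design must be census or household_sample, got {self.design!r}")
        _check_prob("sample_fraction", self.sample_fraction)
        _check_prob("p_omit_per_year_recall", self.p_omit_per_year_recall)
        _check_prob("p_heap_to_12m", self.p_heap_to_12m)
        if self.date_displacement_sd < 0:
            raise ValueError("date_displacement_sd must be non-negative")


def simulate_ledger(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the ground-truth event ledger.

    Every woman contributes an independent Bernoulli pregnancy draw each
    month of the horizon; pregnancies end in stillbirth with
    ``stillbirth_prob``, otherwise in a live birth with sex drawn at odds
    ``srb_true : 100``.  Live births then pass sequentially through the
    neonatal, post-neonatal and child death hazards.  Deaths occurring
    after ``sim_end_cmc`` are retained in the ledger (they are ground
    truth); observation layers decide what falls inside a reporting or
    recall horizon.

    Returns a DataFrame with :data:`LEDGER_COLUMNS`; reproducible given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    months = np.arange(config.sim_start_cmc, config.sim_end_cmc + 1)
    n_women = config.n_women
    women_per_catch = config.households_per_catchment * config.women_per_household

    woman_ids = np.arange(n_women)
    household_ids = woman_ids // config.women_per_household
    catchment_ids = woman_ids // women_per_catch

    # woman-month pregnancy draws, vectorized over the full grid
    draws = rng.random((n_women, months.size)) < config.monthly_birth_prob
    w_idx, m_idx = np.nonzero(draws)
    n_events = w_idx.size

    birth_cmc = months[m_idx]
    stillbirth = rng.random(n_events) < config.stillbirth_prob
    p_male = config.srb_true / (config.srb_true + 100.0)
    sex = np.where(rng.random(n_events) < p_male, "M", "F")

    live = ~stillbirth
    died = np.zeros(n_events, dtype=bool)
    age_days = np.full(n_events, np.nan)
    age_months = np.full(n_events, np.nan)

    u = rng.random(n_events)
    neonatal = live & (u < config.hazard_neonatal)
    u2 = rng.random(n_events)
    postneo = live & ~neonatal & (u2 < config.hazard_postneonatal)
    u3 = rng.random(n_events)
    child = live & ~neonatal & ~postneo & (u3 < config.hazard_child)

    died = neonatal | postneo | child
    age_days[neonatal] = rng.integers(0, NEONATAL_MAX_DAYS, size=int(neonatal.sum()))
    age_months[neonatal] = 0
    age_months[postneo] = rng.integers(1, 12, size=int(postneo.sum()))
    age_months[child] = rng.integers(12, 60, size=int(child.sum()))

    death_cmc = np.full(n_events, np.nan)
    death_cmc[died] = birth_cmc[died] + age_months[died]

    ledger = pd.DataFrame({
        "child_id": np.arange(n_events),
        "mother_id": w_idx,
        "household_id": household_ids[w_idx],
        "catchment_id": catchment_ids[w_idx],
        "birth_cmc": birth_cmc,
        "sex": sex,
        "stillbirth": stillbirth,
        "died": died,
        "age_at_death_days": age_days,
        "age_at_death_months": age_months,
        "death_cmc": death_cmc,
    })
    return ledger[LEDGER_COLUMNS]


def apply_chw_observation(
    ledger: pd.DataFrame,
    model: CaptureModel,
    seed: int,
    period_start_cmc: Optional[int] = None,
    period_end_cmc: Optional[int] = None,
    n_catchments: Optional[int] = None,
) -> pd.DataFrame:
    """Derive CHW monthly reports from the ground-truth ledger.

    Each true event inside the reporting period is captured independently
    with its type-specific probability; stillbirths are added as spurious
    neonatal deaths with ``p_stillbirth_as_neonatal``.  Each catchment-month
    report is then suppressed wholesale with ``p_monthly_report_missing``;
    captured events in a suppressed month are lost — downstream tabulation
    makes no adjustment for missing reports.

    Returns one row per *submitted* catchment-month (:data:`REPORT_COLUMNS`);
    suppressed months have no row.
    """
    if period_start_cmc is None:
        period_start_cmc = int(ledger["birth_cmc"].min()) if len(ledger) else 0
    if period_end_cmc is None:
        hi = [ledger["birth_cmc"].max()] if len(ledger) else [0]
        if len(ledger) and ledger["death_cmc"].notna().any():
            hi.append(ledger["death_cmc"].max())
        period_end_cmc = int(max(hi))
    if n_catchments is None:
        n_catchments = int(ledger["catchment_id"].max()) + 1 if len(ledger) else 1

    rng = np.random.default_rng(seed)
    months = np.arange(period_start_cmc, period_end_cmc + 1)
    n_months = months.size

    # count grids: catchment x month
    shape = (n_catchments, n_months)
    births_m = np.zeros(shape, dtype=np.int64)
    births_f = np.zeros(shape, dtype=np.int64)
    d_neo = np.zeros(shape, dtype=np.int64)
    d_inf = np.zeros(shape, dtype=np.int64)
    d_u5 = np.zeros(shape, dtype=np.int64)

    def _accumulate(grid, catchments, cmcs, captured):
        keep = captured & (cmcs >= period_start_cmc) & (cmcs <= period_end_cmc)
        np.add.at(grid, (catchments[keep], cmcs[keep] - period_start_cmc), 1)

    live = ~ledger["stillbirth"].to_numpy(dtype=bool)
    catch = ledger["catchment_id"].to_numpy(dtype=np.int64)
    bcmc = ledger["birth_cmc"].to_numpy(dtype=np.int64)
    n = len(ledger)

    cap_birth = live & (rng.random(n) < model.p_capture_birth)
    is_male = (ledger["sex"] == "M").to_numpy()
    _accumulate(births_m, catch, bcmc, cap_birth & is_male)
    _accumulate(births_f, catch, bcmc, cap_birth & ~is_male)

    died = ledger["died"].to_numpy(dtype=bool)
    age_m = ledger["age_at_death_months"].to_numpy()
    dcmc = np.where(died, ledger["death_cmc"].to_numpy(), 0).astype(np.int64)
    neo = died & (age_m == 0)
    postneo = died & (age_m >= 1) & (age_m < 12)
    child = died & (age_m >= 12)

    u = rng.random(n)
    cap_neo = neo & (u < model.p_capture_death_neonatal)
    cap_postneo = postneo & (u < model.p_capture_death_postneonatal)
    cap_child = child & (u < model.p_capture_death_child)

    _accumulate(d_neo, catch, dcmc, cap_neo)
    for cap in (cap_neo, cap_postneo):
        _accumulate(d_inf, catch, dcmc, cap)
    for cap in (cap_neo, cap_postneo, cap_child):
        _accumulate(d_u5, catch, dcmc, cap)

    # stillbirths misreported as neonatal deaths in the birth month
    still = ledger["stillbirth"].to_numpy(dtype=bool)
    mis = still & (rng.random(n) < model.p_stillbirth_as_neonatal)
    for grid in (d_neo, d_inf, d_u5):
        _accumulate(grid, catch, bcmc, mis)

    submitted = rng.random(shape) >= model.p_monthly_report_missing

    c_idx, m_idx = np.nonzero(submitted)
    reports = pd.DataFrame({
        "catchment_id": c_idx,
        "cmc": months[m_idx],
        "births_male": births_m[c_idx, m_idx],
        "births_female": births_f[c_idx, m_idx],
        "deaths_neonatal": d_neo[c_idx, m_idx],
        "deaths_infant": d_inf[c_idx, m_idx],
        "deaths_under5": d_u5[c_idx, m_idx],
    })
    return reports[REPORT_COLUMNS]


def apply_survey_observation(
    ledger: pd.DataFrame,
    model: SurveyModel,
    seed: int,
) -> pd.DataFrame:
    """Derive a retrospective birth-history dataset from the ledger.

    Households are selected per the survey design (census keeps all, a
    household sample keeps each with ``sample_fraction``).  Stillbirths are
    excluded — birth histories record live births only.  Each dead child is
    omitted with probability ``1 - (1 - p_omit_per_year_recall)**years``
    where years is the (fractional) time from death to interview.  Deaths
    at true ages 10-14 months are relabeled to exactly 12 months with
    ``p_heap_to_12m``.  Birth dates are jittered by a rounded normal
    displacement; death dates follow the (possibly relabeled) age at death.
    """
    if len(ledger) and int(ledger["birth_cmc"].max()) > model.interview_cmc:
        raise ValueError("interview_cmc predates some simulated events")

    rng = np.random.default_rng(seed)
    live = ledger[~ledger["stillbirth"].astype(bool)].copy()

    if model.design == "household_sample":
        households = live["household_id"].unique()
        kept = households[rng.random(households.size) < model.sample_fraction]
        live = live[live["household_id"].isin(kept)]
        if live.empty:
            raise ValueError("household sample selected no children; "
                             "increase sample_fraction or population")

    died = live["died"].to_numpy(dtype=bool)
    years_since_death = np.where(
        died,
        (model.interview_cmc - live["death_cmc"].to_numpy()) / 12.0,
        0.0,
    ).clip(min=0.0)
    p_omit = np.where(died, 1.0 - (1.0 - model.p_omit_per_year_recall) ** years_since_death, 0.0)
    omitted = rng.random(len(live)) < p_omit
    live = live[~omitted]

    out = live.copy()
    died = out["died"].to_numpy(dtype=bool)
    age_m = out["age_at_death_months"].to_numpy(dtype=float)

    heapable = died & (age_m >= 10) & (age_m <= 14)
    heaped = heapable & (rng.random(len(out)) < model.p_heap_to_12m)
    age_m[heaped] = 12.0
    # a heaped 12-month death is no longer an infant death
    days = out["age_at_death_days"].to_numpy(dtype=float)
    days[heaped] = np.nan

    if model.date_displacement_sd > 0:
        jitter = np.rint(rng.normal(0.0, model.date_displacement_sd, len(out))).astype(int)
    else:
        jitter = np.zeros(len(out), dtype=int)
    birth_cmc = out["birth_cmc"].to_numpy(dtype=int) + jitter
    birth_cmc = np.minimum(birth_cmc, model.interview_cmc)
    death_cmc = np.where(died, birth_cmc + np.nan_to_num(age_m), np.nan)

    histories = pd.DataFrame({
        "mother_id": out["mother_id"].to_numpy(),
        "child_id": out["child_id"].to_numpy(),
        "household_id": out["household_id"].to_numpy(),
        "catchment_id": out["catchment_id"].to_numpy(),
        "birth_cmc": birth_cmc,
        "sex": out["sex"].to_numpy(),
        "died": died,
        "age_at_death_days": days,
        "age_at_death_months": age_m if len(out) else np.array([]),
        "death_cmc": death_cmc,
        "interview_cmc": model.interview_cmc,
    })
    histories.loc[~histories["died"], ["age_at_death_days", "age_at_death_months"]] = np.nan
    return histories[HISTORY_COLUMNS]
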