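"""Date arithmetic, rolling analysis windows, event tabulation, and period rates.

All event dating uses the century month code (CMC), the DHS convention:
``cmc = (year - 1900) * 12 + month`` with months 1-based, so January 1900
is CMC 1.

Rates here are *period ratios*: deaths whose death date falls inside a
12-month window divided by births whose birth date falls inside the same
window, scaled per 1,000.  This is deliberately not the synthetic-cohort
estimator used by DHS reports; under changing fertility the period ratio is
biased relative to cohort q(5), and callers should only interpret it under
approximate demographic stationarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AnalysisWindow",
    "EventCounts",
    "RateSet",
    "ZeroBirthsError",
    "cmc",
    "cmc_to_year_month",
    "rolling_windows",
    "tabulate_chw",
    "tabulate_fbh",
    "period_rates",
]

logger = logging.getLogger(__name__)

NEONATAL_MAX_DAYS = 28       # neonatal: died before 28 completed days
INFANT_MAX_MONTHS = 12       # infant: died before 12 completed months
UNDER5_MAX_MONTHS = 60       # under-five: died before 60 completed months

#: Column map for ingesting DHS-style birth-recode exports.
DHS_COLUMN_MAP = {
    "b3": "birth_cmc",        # date of birth (CMC)
    "b4": "sex",              # sex of child
    "b5": "alive",            # child alive at interview
    "b7": "age_at_death_months",
}


class ZeroBirthsError(ValueError):
    """Raised when mortality rates are requested for a window with no births."""


def cmc(year: int, month: int) -> int:
    """Century month code for a calendar (year, month).

    >>> cmc(1900, 1)
    1
    >>> cmc(2012, 1)
    1345
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return (year - 1900) * 12 + month


def cmc_to_year_month(code: int) -> tuple[int, int]:
    """Inverse of :func:`cmc`: returns (year, month)."""
    year, month0 = divmod(int(code) - 1, 12)
    return 1900 + year, month0 + 1


@dataclass(frozen=True)
class AnalysisWindow:
    """A 12-month analysis window, inclusive of both endpoint months."""

    start_cmc: int
    end_cmc: int

    def __post_init__(self) -> None:
        if self.end_cmc - self.start_cmc != 11:
            raise ValueError(
                f"window must span exactly 12 months, got "
                f"[{self.start_cmc}, {self.end_cmc}]"
            )

    def contains(self, code: int) -> bool:
        return self.start_cmc <= code <= self.end_cmc

    @property
    def months(self) -> range:
        return range(self.start_cmc, self.end_cmc + 1)


def rolling_windows(period_start_cmc: int, period_end_cmc: int) -> list[AnalysisWindow]:
    """Rolling 12-month windows with starts 3 months apart.

    Windows start at ``period_start_cmc``, then every 3 months, for as long
    as the full 12 months fit inside the period (both endpoints inclusive).
    """
    span = period_end_cmc - period_start_cmc + 1
    if span < 12:
        raise ValueError(f"period spans {span} months; need at least 12")
    windows = []
    start = period_start_cmc
    while start + 11 <= period_end_cmc:
        windows.append(AnalysisWindow(start, start + 11))
        start += 3
    return windows


@dataclass(frozen=True)
class EventCounts:
    """Births by sex and nested death counts for one window.

    Death classes are nested: every neonatal death is an infant death and
    every infant death is an under-five death.
    """

    births_male: int = 0
    births_female: int = 0
    deaths_neonatal: int = 0
    deaths_infant: int = 0
    deaths_under5: int = 0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.deaths_neonatal <= self.deaths_infant <= self.deaths_under5:
            raise ValueError(
                "death classes must nest: neonatal <= infant <= under5 "
                f"(got {self.deaths_neonatal}, {self.deaths_infant}, "
                f"{self.deaths_under5})"
            )

    @property
    def births(self) -> int:
        return self.births_male + self.births_female

    def __add__(self, other: "EventCounts") -> "EventCounts":
        return EventCounts(
            self.births_male + other.births_male,
            self.births_female + other.births_female,
            self.deaths_neonatal + other.deaths_neonatal,
            self.deaths_infant + other.deaths_infant,
            self.deaths_under5 + other.deaths_under5,
        )


@dataclass(frozen=True)
class RateSet:
    """Crude birth rate and period mortality rates for one window.

    cbr is births per 1,000 population per year; nmr/imr/u5mr are deaths
    per 1,000 births *in the same window* (period ratios).
    """

    cbr: float
    nmr: float
    imr: float
    u5mr: float

    def __post_init__(self) -> None:
        for name in ("cbr", "nmr", "imr", "u5mr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def tabulate_chw(reports: pd.DataFrame, window: AnalysisWindow) -> EventCounts:
    """Sum CHW monthly-report counts over a window.

    ``reports`` is the monthly-report table written by
    :mod:`chwvitals.synthetic_data` (one row per submitted catchment-month,
    columns ``cmc, births_male, births_female, deaths_neonatal,
    deaths_infant, deaths_under5``).  Missing catchment-months simply have
    no row and therefore contribute zero — no imputation.
    """
    if reports.empty:
        return EventCounts()
    sub = reports[(reports["cmc"] >= window.start_cmc) & (reports["cmc"] <= window.end_cmc)]
    return EventCounts(
        births_male=int(sub["births_male"].sum()),
        births_female=int(sub["births_female"].sum()),
        deaths_neonatal=int(sub["deaths_neonatal"].sum()),
        deaths_infant=int(sub["deaths_infant"].sum()),
        deaths_under5=int(sub["deaths_under5"].sum()),
    )


def tabulate_fbh(histories: pd.DataFrame, window: AnalysisWindow) -> EventCounts:
    """Tabulate a birth-history dataset over a window.

    Births are allocated by ``birth_cmc`` and deaths by ``death_cmc``; a
    death can be counted in a window where its birth is not.  Age classes:
    neonatal <28 days, infant <12 completed months, under-five <60
    completed months.  Records missing the relevant date are skipped with a
    logged count.
    """
    if histories.empty:
        return EventCounts()

    h = histories
    bad_birth = h["birth_cmc"].isna()
    if bad_birth.any():
        logger.warning("skipping %d records with missing birth_cmc", int(bad_birth.sum()))
        h = h[~bad_birth]

    in_birth = (h["birth_cmc"] >= window.start_cmc) & (h["birth_cmc"] <= window.end_cmc)
    births_male = int((in_birth & (h["sex"] == "M")).sum())
    births_female = int((in_birth & (h["sex"] == "F")).sum())

    died = h["died"].astype(bool)
    bad_death = died & h["death_cmc"].isna()
    if bad_death.any():
        logger.warning("skipping %d deaths with missing death_cmc", int(bad_death.sum()))
        died = died & ~bad_death
    d = h[died]
    in_death = (d["death_cmc"] >= window.start_cmc) & (d["death_cmc"] <= window.end_cmc)
    d = d[in_death]

    age_m = d["age_at_death_months"]
    neonatal = d["age_at_death_days"].notna() & (d["age_at_death_days"] < NEONATAL_MAX_DAYS)
    infant = neonatal | (age_m < INFANT_MAX_MONTHS)
    under5 = age_m < UNDER5_MAX_MONTHS

    return EventCounts(
        births_male=births_male,
        births_female=births_female,
        deaths_neonatal=int(neonatal.sum()),
        deaths_infant=int(infant.sum()),
        deaths_under5=int(under5.sum()),
    )


def period_rates(counts: EventCounts, population: int) -> RateSet:
    """Period rates from one window's counts.

    u5mr = 1000 * deaths_under5 / births (likewise nmr, imr);
    cbr = 1000 * births / population.

    Raises :class:`ZeroBirthsError` if the window has no births — mortality
    rates are undefined and the caller must handle the window explicitly
    rather than receive NaN.
    """
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    births = counts.births
    if births == 0:
        raise ZeroBirthsError("no births in window; mortality rates undefined")
    return RateSet(
        cbr=1000.0 * births / population,
        nmr=1000.0 * counts.deaths_neonatal / births,
        imr=1000.0 * counts.deaths_infant / births,
        u5mr=1000.0 * counts.deaths_under5 / births,
    )


def rates_by_window(
    tabulate,
    data: pd.DataFrame,
    windows: Sequence[AnalysisWindow],
    population: int,
) -> list[RateSet]:
    """Apply one tabulator over a list of windows and convert to rates."""
    return [period_rates(tabulate(data, w), population) for w in windows]
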