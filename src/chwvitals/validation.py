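"""Completeness, accuracy, data-quality, and register-verification metrics.

Conventions:

* "Expected" event counts come from the reference (survey/census) crude
  birth rate and under-five mortality rate applied to the fixed catchment
  population, not from raw survey counts — the two coincide under a census
  design.
* "Average annual ratio" is the unweighted mean of per-window percent
  ratios.
* Internal values keep full precision; :func:`round_half_up` is applied
  only when rendering tables (one decimal, round half up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .demography import RateSet

__all__ = [
    "CompletenessResult",
    "AccuracyResult",
    "QualityMetrics",
    "MatchReport",
    "expected_births",
    "expected_under5_deaths",
    "completeness",
    "accuracy_ratios",
    "sex_ratio_at_birth",
    "death_ratio",
    "heaping_index_12m",
    "reporting_coverage",
    "match_registers",
    "quality_metrics",
    "round_half_up",
]

SRB_BAND = (102.0, 107.0)  # plausible male births per 100 female

RATE_NAMES = ("cbr", "nmr", "imr", "u5mr")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (table-presentation rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompletenessResult:
    documented: int
    expected: float

    def __post_init__(self) -> None:
        if self.expected <= 0:
            raise ValueError(f"expected count must be positive, got {self.expected}")
        if self.documented < 0:
            raise ValueError("documented count must be non-negative")

    @property
    def percent(self) -> float:
        return 100.0 * self.documented / self.expected


@dataclass(frozen=True)
class AccuracyResult:
    """Per-window percent ratios (monitored rate / reference rate) and means."""

    per_window: Mapping[str, tuple[float, ...]]   # rate name -> window ratios
    annual_average: Mapping[str, float]           # rate name -> mean ratio

    def __post_init__(self) -> None:
        for name, ratios in self.per_window.items():
            avg = self.annual_average[name]
            if not min(ratios) <= avg <= max(ratios):
                raise ValueError(f"annual average for {name} outside per-window range")


@dataclass(frozen=True)
class QualityMetrics:
    srb: float
    pct_neonatal_of_infant: float
    pct_infant_of_under5: float
    heaping_index_12m: Optional[float]

    @property
    def srb_in_reference_band(self) -> bool:
        return SRB_BAND[0] <= self.srb <= SRB_BAND[1]


@dataclass(frozen=True)
class MatchReport:
    n_sampled: int
    n_matched: int
    pct_matched: Optional[float]         # None when nothing was sampled
    pct_date_consistent: Optional[float]  # None when nothing matched

    def __post_init__(self) -> None:
        if self.n_matched > self.n_sampled:
            raise ValueError("n_matched cannot exceed n_sampled")


def expected_births(cbr_reference: float, population: int) -> float:
    """Expected births = reference CBR x population / 1000."""
    if cbr_reference <= 0 or population <= 0:
        raise ValueError("cbr_reference and population must be positive")
    return cbr_reference * population / 1000.0


def expected_under5_deaths(u5mr_reference: float, expected_births_: float) -> float:
    """Expected under-five deaths = reference U5MR x expected births / 1000."""
    if u5mr_reference <= 0 or expected_births_ <= 0:
        raise ValueError("u5mr_reference and expected_births must be positive")
    return u5mr_reference * expected_births_ / 1000.0


def completeness(documented: int, expected: float) -> CompletenessResult:
    """Documented over expected; percent may exceed 100 (not clipped)."""
    return CompletenessResult(documented=documented, expected=expected)


def accuracy_ratios(
    monitored: Sequence[RateSet],
    reference: Sequence[RateSet],
) -> AccuracyResult:
    """Per-window percent ratios of monitored to reference rates, plus the
    unweighted mean across windows ("average annual ratio")."""
    if len(monitored) != len(reference):
        raise ValueError(
            f"window mismatch: {len(monitored)} monitored vs {len(reference)} reference"
        )
    if not monitored:
        raise ValueError("need at least one window")
    per_window: dict[str, tuple[float, ...]] = {}
    for name in RATE_NAMES:
        ratios = []
        for m, r in zip(monitored, reference):
            ref = getattr(r, name)
            if ref == 0:
                raise ZeroDivisionError(f"reference {name} is zero in one window")
            ratios.append(100.0 * getattr(m, name) / ref)
        per_window[name] = tuple(ratios)
    annual = {name: float(np.mean(r)) for name, r in per_window.items()}
    return AccuracyResult(per_window=per_window, annual_average=annual)


def sex_ratio_at_birth(births_male: int, births_female: int) -> tuple[float, bool]:
    """Male births per 100 female, and whether it falls in the 102-107 band."""
    if births_female <= 0:
        raise ValueError("need at least one female birth")
    srb = 100.0 * births_male / births_female
    return srb, SRB_BAND[0] <= srb <= SRB_BAND[1]


def death_ratio(numerator_deaths: int, denominator_deaths: int) -> float:
    """Percent ratio of nested death counts (e.g. neonatal:infant)."""
    if denominator_deaths <= 0:
        raise ValueError("denominator deaths must be positive")
    if numerator_deaths < 0:
        raise ValueError("numerator deaths must be non-negative")
    return 100.0 * numerator_deaths / denominator_deaths


def heaping_index_12m(ages_at_death_months: Iterable[float]) -> float:
    """Heaping index for reported age at death at exactly 12 months.

    index = 5 * d(12) / [d(10) + d(11) + d(12) + d(13) + d(14)];
    1.0 means no digit preference, 5.0 maximal heaping on 12.
    """
    ages = np.asarray(list(ages_at_death_months), dtype=float)
    band = ages[(ages >= 10) & (ages <= 14)]
    if band.size == 0:
        raise ValueError("no deaths with age at death in 10-14 months")
    return 5.0 * float((band == 12).sum()) / band.size


def reporting_coverage(
    reports: pd.DataFrame,
    n_catchments: int,
    months: Sequence[int],
) -> float:
    """Mean over months of the percent of catchments that submitted a report."""
    if n_catchments <= 0 or len(months) == 0:
        raise ValueError("n_catchments and months must be non-empty/positive")
    if reports.empty:
        return 0.0
    per_month = [
        100.0 * reports.loc[reports["cmc"] == m, "catchment_id"].nunique() / n_catchments
        for m in months
    ]
    return float(np.mean(per_month))


def match_registers(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    date_tolerance_months: int = 1,
) -> MatchReport:
    """Greedy one-to-one matching of sampled events against a reference register.

    Events match within the same catchment and event type, to the nearest
    reference event month within tolerance; ties break toward the earliest
    reference event.  ``pct_date_consistent`` is the share of matched pairs
    with exact month agreement.  Both frames need columns
    ``catchment_id, event_type, cmc``.
    """
    n_sampled = len(sample)
    if n_sampled == 0:
        return MatchReport(0, 0, None, None)

    n_matched = 0
    n_exact = 0
    ref_groups = {
        key: sorted(grp["cmc"].tolist())
        for key, grp in reference.groupby(["catchment_id", "event_type"])
    }
    for key, grp in sample.groupby(["catchment_id", "event_type"]):
        avail = ref_groups.get(key, [])[:]
        for cmc_s in sorted(grp["cmc"].tolist()):
            best_i, best_d = None, None
            for i, cmc_r in enumerate(avail):
                d = abs(cmc_r - cmc_s)
                if d <= date_tolerance_months and (best_d is None or d < best_d):
                    best_i, best_d = i, d  # earliest ref wins ties (sorted order)
            if best_i is not None:
                n_matched += 1
                if best_d == 0:
                    n_exact += 1
                avail.pop(best_i)

    pct_matched = 100.0 * n_matched / n_sampled
    pct_exact = 100.0 * n_exact / n_matched if n_matched else None
    return MatchReport(n_sampled, n_matched, pct_matched, pct_exact)


def quality_metrics(
    births_male: int,
    births_female: int,
    deaths_neonatal: int,
    deaths_infant: int,
    deaths_under5: int,
    ages_at_death_months: Optional[Iterable[float]] = None,
) -> QualityMetrics:
    """Standard demographic data-quality battery for one data source."""
    srb, _ = sex_ratio_at_birth(births_male, births_female)
    heaping = None
    if ages_at_death_months is not None:
        ages = np.asarray(list(ages_at_death_months), dtype=float)
        if ((ages >= 10) & (ages <= 14)).any():
            heaping = heaping_index_12m(ages)
    return QualityMetrics(
        srb=srb,
        pct_neonatal_of_infant=death_ratio(deaths_neonatal, deaths_infant),
        pct_infant_of_under5=death_ratio(deaths_infant, deaths_under5),
        heaping_index_12m=heaping,
    )
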