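"""Prospective cost-ledger accounting.

Costs are tracked in local currency by calendar year, inflated to a base
year with a local consumer-price-index series, converted to USD at the
base-year exchange rate, and summarized as total, average annual cost per
1,000 population, and cost per vital event reported.

Annualization is ``total * 12 / observation_months`` (exact when the
observation span is a whole number of years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = ["CostLedger", "CostMetrics", "adjust_costs", "cost_metrics"]

LEDGER_CSV_COLUMNS = ["category", "amount", "currency", "year"]


@dataclass(frozen=True)
class CostLedger:
    """Line items in local currency plus the deflator/exchange context.

    ``items`` columns: category, amount (local currency), year; optionally
    currency (informational).  ``cpi_series`` maps calendar year to index
    value; ``fx_rate`` is local currency units per USD at ``base_year``.
    """

    items: pd.DataFrame
    cpi_series: Mapping[int, float]
    fx_rate: float
    base_year: int

    def __post_init__(self) -> None:
        if self.fx_rate <= 0:
            raise ValueError(f"fx_rate must be positive, got {self.fx_rate}")
        if self.base_year not in self.cpi_series:
            raise ValueError(f"base_year {self.base_year} missing from cpi_series")
        for year, cpi in self.cpi_series.items():
            if cpi <= 0:
                raise ValueError(f"CPI for {year} must be positive, got {cpi}")
        if len(self.items) and (self.items["amount"] < 0).any():
            raise ValueError("cost amounts must be non-negative")


@dataclass(frozen=True)
class CostMetrics:
    total: float
    annual_per_1000: float
    per_event: float


def adjust_costs(ledger: CostLedger) -> float:
    """Total cost in base-year USD.

    Each line item is scaled by cpi(base)/cpi(year) and converted at the
    base-year exchange rate.
    """
    if ledger.items.empty:
        return 0.0
    missing = set(ledger.items["year"]) - set(ledger.cpi_series)
    if missing:
        raise ValueError(f"CPI missing for years: {sorted(missing)}")
    cpi_base = ledger.cpi_series[ledger.base_year]
    scaled = ledger.items["amount"] * ledger.items["year"].map(
        lambda y: cpi_base / ledger.cpi_series[y]
    )
    return float(scaled.sum() / ledger.fx_rate)


def cost_metrics(
    total_usd: float,
    population: int,
    months: int,
    n_events: int,
) -> CostMetrics:
    """The three summary cost metrics.

    annual_per_1000 = total * (12 / months) / (population / 1000);
    per_event = total / n_events.
    """
    if population <= 0 or months <= 0 or n_events <= 0:
        raise ValueError("population, months and n_events must be positive")
    return CostMetrics(
        total=total_usd,
        annual_per_1000=total_usd * (12.0 / months) / (population / 1000.0),
        per_event=total_usd / n_events,
    )
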