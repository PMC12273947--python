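"""Stratified mortality rates per 100,000 and closed-form summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RateSeries

__all__ = [
    "compute_rate",
    "percent_change",
    "sex_rate_ratio",
    "RateSummary",
    "rate_series_from_counts",
]


def compute_rate(deaths: float, population: float) -> float:
    """Deaths per 100,000 person-years.  Fractional deaths are allowed."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if deaths < 0:
        raise ValueError(f"deaths must be non-negative, got {deaths}")
    return 1e5 * deaths / population


def percent_change(first: float, last: float) -> float:
    """Percent change from the first to the last value: 100*(last-first)/first."""
    if first <= 0:
        raise ValueError("percent change is undefined for a non-positive baseline")
    return 100.0 * (last - first) / first


@dataclass(frozen=True)
class RateSummary:
    """Per-year male-to-female rate ratios and their arithmetic mean.

    Yearly ratios are reported rounded to 2 decimals and the mean ratio to
    1 decimal, matching surveillance-table conventions; the mean is taken
    over the unrounded yearly ratios.
    """

    years: tuple
    ratios: tuple
    mean_ratio: float


def sex_rate_ratio(series_m: RateSeries, series_f: RateSeries) -> RateSummary:
    """Male:female rate ratio per year plus the period mean."""
    if not np.array_equal(series_m.years, series_f.years):
        raise ValueError("male and female series must cover the same years")
    if np.any(series_f.rates <= 0):
        raise ValueError("female rates must be positive to form ratios")
    raw = series_m.rates / series_f.rates
    return RateSummary(
        years=tuple(int(y) for y in series_m.years),
        ratios=tuple(round(float(r), 2) for r in raw),
        mean_ratio=round(float(raw.mean()), 1),
    )


def rate_series_from_counts(counts: pd.DataFrame, population: pd.DataFrame,
                            sex: str, age_group: str,
                            method: str | None = None,
                            cause_group: str = "suicide") -> RateSeries:
    """Build a yearly rate series for one stratum from corrected counts.

    ``counts`` is the long corrected-counts frame (year, sex, age_group,
    cause_group, method, count); ``population`` the denominator frame.
    ``sex`` and ``age_group`` may be ``"total"`` to aggregate over that
    dimension; ``method=None`` sums all suicide methods.
    """
    df = counts[counts["cause_group"] == cause_group]
    pop = population.copy()
    if sex != "total":
        df = df[df["sex"] == sex]
        pop = pop[pop["sex"] == sex]
    if age_group != "total":
        ags = [age_group] if age_group != "10-19" else ["10-14", "15-19"]
        df = df[df["age_group"].isin(ags)]
        pop = pop[pop["age_group"].isin(ags)]
    if method is not None:
        df = df[df["method"] == method]
    dead = df.groupby("year")["count"].sum()
    denom = pop.groupby("year")["population"].sum()
    years = sorted(denom.index)
    dead = dead.reindex(years, fill_value=0.0)
    denom = denom.loc[years]
    rates = 1e5 * dead.to_numpy() / denom.to_numpy()
    label = f"{sex} {age_group}" + (f" {method}" if method else "")
    return RateSeries(label, np.asarray(years), rates,
                      counts=dead.to_numpy(), population=denom.to_numpy())
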