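"""Synthetic vital-registration data with known ground truth.

The generator emulates the structure of a national death registry: for
each (year, sex, age-group) cell, suicide deaths are drawn as Poisson
counts around a piecewise log-linear true rate path, split across
mechanism groups by a multinomial mixture and assigned concrete ICD-10
codes; deaths from other defined cause groups are drawn around constant
rates.  Data-quality degradation is then applied at the record level:
with configurable (possibly year-varying) probabilities a record's code
is replaced by a code from a garbage-code group, and sex/age are masked
independently.  Degradation never creates or removes records, so the
total count is preserved and every corruption is recorded in the
returned ground truth.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import RateSeries

__all__ = [
    "TrendPhase",
    "StratumConfig",
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "true_rate_series",
    "brazil_study_config",
    "channels_from_weights",
]

# concrete codes drawn for each cause group / mechanism
_CODE_POOLS = {
    "hanging": ["X70"],
    "firearm": ["X72", "X73", "X74"],
    "poisoning": ["X60", "X61", "X64", "X68", "X69"],
    "other_method": ["X71", "X78", "X80", "X81", "X83"],
    "homicide": ["X93", "X95", "X99", "Y00"],
    "road_traffic": ["V03", "V23", "V43", "V89"],
    "other_accident": ["W19", "W65", "W74", "X09"],
    "natural": ["A41", "C71", "I21", "J18", "G40"],
    "undetermined_intent": ["Y10", "Y20", "Y24", "Y30", "Y34"],
    "ill_defined": ["R98", "R99"],
    "unspecified_accident": ["X59"],
}


@dataclass(frozen=True)
class TrendPhase:
    """One phase of a piecewise log-linear rate path."""

    start_year: int
    apc: float  # percent change per year within the phase


@dataclass
class StratumConfig:
    """True suicide process for one sex x age-group stratum."""

    baseline_rate: float              # per 100,000 in the first year
    trend: list[TrendPhase]
    population: dict[int, int]        # year -> person-years


@dataclass
class SimConfig:
    """Full generator configuration; the seed makes runs reproducible."""

    years: Sequence[int]
    strata: dict[tuple[str, str], StratumConfig]
    method_mix: dict[str, float] = field(default_factory=lambda: {
        "hanging": 0.66, "poisoning": 0.16, "firearm": 0.11, "other_method": 0.07})
    other_cause_rates: dict[str, float] = field(default_factory=dict)
    gc_channels: Optional[pd.DataFrame] = None  # sex, age_group, year, cause_group, gc_group, prob
    missing_sex: float = 0.0
    missing_age: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        mix_sum = sum(self.method_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"method mixture must sum to 1, got {mix_sum}")
        for p in (self.missing_sex, self.missing_age):
            if not (0.0 <= p <= 1.0):
                raise ValueError("missingness probabilities must be in [0, 1]")
        for key, sc in self.strata.items():
            if any(v <= 0 for v in sc.population.values()):
                raise ValueError(f"populations must be positive in stratum {key}")
            if sc.trend and sc.trend[0].start_year > min(self.years):
                raise ValueError(f"trend for {key} must start at or before the first year")


def simple_channels(probs: dict[tuple[str, str], float], config: SimConfig) -> pd.DataFrame:
    """Expand constant ``{(cause_group, gc_group): prob}`` channels to the cell level."""
    rows = []
    for (sex, ag) in config.strata:
        for year in config.years:
            for (cause, gc), p in probs.items():
                rows.append({"sex": sex, "age_group": ag, "year": year,
                             "cause_group": cause, "gc_group": gc, "prob": p})
    return pd.DataFrame(rows)


def _true_rate(sc: StratumConfig, years: Sequence[int]) -> np.ndarray:
    """Expected rate path: geometric compounding within each phase."""
    phases = sorted(sc.trend, key=lambda p: p.start_year)
    rates = np.empty(len(years))
    rate = sc.baseline_rate
    prev_year = years[0]
    for i, year in enumerate(years):
        for _ in range(year - prev_year):
            apc = 0.0
            for ph in phases:
                if ph.start_year <= prev_year:
                    apc = ph.apc
            rate *= 1 + apc / 100.0
            prev_year += 1
        rates[i] = rate
    return rates


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    config: SimConfig
    expected_rates: pd.DataFrame   # sex, age_group, year, rate
    true_counts: pd.DataFrame      # sex, age_group, year, cause_group, method, count
    mislabelled: pd.DataFrame      # sex, age_group, year, cause_group, gc_group, count
    masked: pd.DataFrame           # sex, age_group, year, masked_sex, masked_age counts


def true_rate_series(truth: SyntheticTruth, stratum: tuple[str, str]) -> RateSeries:
    """Noiseless expected suicide rates for one stratum (not realised counts)."""
    sex, ag = stratum
    df = truth.expected_rates
    sub = df[(df["sex"] == sex) & (df["age_group"] == ag)].sort_values("year")
    if sub.empty:
        raise KeyError(f"unknown stratum {stratum}")
    return RateSeries(f"{sex} {ag} (truth)", sub["year"].to_numpy(), sub["rate"].to_numpy())


def generate_dataset(config: SimConfig):
    """Generate (records, populations, truth) from a :class:`SimConfig`.

    Records follow the canonical record-frame layout of
    :func:`mortrend.io.read_death_records`.
    """
    rng = np.random.default_rng(config.seed)
    years = list(config.years)
    methods = list(config.method_mix)
    mix = np.array([config.method_mix[m] for m in methods])
    channels = config.gc_channels
    channel_index: dict = {}
    if channels is not None:
        for key, grp in channels.groupby(["sex", "age_group", "year", "cause_group"]):
            channel_index[key] = (list(grp["gc_group"]), grp["prob"].to_numpy())

    col_year, col_sex, col_age, col_cause = [], [], [], []
    pop_rows, rate_rows, count_rows, mis_rows, mask_rows = [], [], [], [], []

    for (sex, ag), sc in config.strata.items():
        rates = _true_rate(sc, years)
        age_lo, age_hi = (int(x) for x in ag.split("-"))
        for year, rate in zip(years, rates):
            pop = sc.population[year]
            pop_rows.append({"year": year, "sex": sex, "age_group": ag, "population": pop})
            rate_rows.append({"sex": sex, "age_group": ag, "year": year, "rate": rate})

            # realised deaths per cause group (suicide split by mechanism)
            groups: list[tuple[str, Optional[str], int]] = []
            n_sui = rng.poisson(rate * pop / 1e5)
            for m, n in zip(methods, rng.multinomial(n_sui, mix)):
                groups.append(("suicide", m, int(n)))
            for tg, r in config.other_cause_rates.items():
                groups.append((tg, None, int(rng.poisson(r * pop / 1e5))))

            for cause_group, method, n in groups:
                if n == 0:
                    continue
                count_rows.append({"sex": sex, "age_group": ag, "year": year,
                                   "cause_group": cause_group, "method": method,
                                   "count": n})
                pool = _CODE_POOLS[method or cause_group]
                if not pool:
                    raise ValueError(f"no codes available for group {cause_group}")
                codes = rng.choice(pool, size=n)
                key = (sex, ag, year, cause_group)
                if key in channel_index:
                    gcs, probs = channel_index[key]
                    if probs.sum() > 1 + 1e-9:
                        raise ValueError("channel probabilities exceed 1 for "
                                         f"({sex}, {ag}, {year}, {cause_group})")
                    dest = rng.choice(len(gcs) + 1, size=n,
                                      p=np.append(probs, 1 - probs.sum()))
                    for j, g in enumerate(gcs):
                        hit = dest == j
                        if hit.any():
                            codes[hit] = rng.choice(_CODE_POOLS[g], size=int(hit.sum()))
                            mis_rows.append({"sex": sex, "age_group": ag,
                                             "year": year, "cause_group": cause_group,
                                             "gc_group": g, "count": int(hit.sum())})
                ages = rng.integers(age_lo, age_hi + 1, size=n).astype(float)
                sexes = np.full(n, sex, dtype=object)
                mask_s = rng.random(n) < config.missing_sex
                mask_a = rng.random(n) < config.missing_age
                sexes[mask_s] = "unknown"
                ages[mask_a] = np.nan
                if mask_s.any() or mask_a.any():
                    mask_rows.append({"sex": sex, "age_group": ag, "year": year,
                                      "masked_sex": int(mask_s.sum()),
                                      "masked_age": int(mask_a.sum())})
                col_year.append(np.full(n, year))
                col_sex.append(sexes)
                col_age.append(ages)
                col_cause.append(codes)

    from .io import age_group_of
    if col_year:
        records = pd.DataFrame({
            "year": np.concatenate(col_year),
            "sex": np.concatenate(col_sex),
            "age_years": np.concatenate(col_age),
            "cause": np.concatenate(col_cause),
            "weight": 1.0,
        })
    else:
        records = pd.DataFrame(columns=["year", "sex", "age_years", "cause", "weight"])
    records["age_group"] = records["age_years"].map(age_group_of)
    records = records[["year", "sex", "age_years", "age_group", "cause", "weight"]]

    populations = pd.DataFrame(pop_rows)
    truth = SyntheticTruth(
        config=config,
        expected_rates=pd.DataFrame(rate_rows),
        true_counts=pd.DataFrame(count_rows),
        mislabelled=pd.DataFrame(mis_rows, columns=["sex", "age_group", "year",
                                                    "cause_group", "gc_group", "count"]),
        masked=pd.DataFrame(mask_rows, columns=["sex", "age_group", "year",
                                                "masked_sex", "masked_age"]),
    )
    return records, populations, truth


def channels_from_weights(weights: pd.DataFrame, config: SimConfig,
                          gc_group: str, gc_deaths_per_cell: float) -> pd.DataFrame:
    """Mislabelling channels whose garbage-code composition matches a weight table.

    For each cell the channel probability from true cause ``c`` into
    ``gc_group`` is chosen so the expected mislabelled count equals
    ``gc_deaths_per_cell * w(gc_group, stratum, c)``; among the resulting
    garbage deaths the expected share from cause ``c`` is then exactly
    the table weight, so redistributing with the same table recovers the
    true counts in expectation.
    """
    rows = []
    for (sex, ag), sc in config.strata.items():
        rates = _true_rate(sc, list(config.years))
        wsub = weights[(weights["gc_group"] == gc_group) & (weights["sex"] == sex)
                       & (weights["age_group"] == ag)]
        if wsub.empty:
            raise ValueError(f"no weights for ({gc_group}, {sex}, {ag})")
        for year, rate in zip(config.years, rates):
            pop = sc.population[year]
            for _, wrow in wsub.iterrows():
                cause = wrow["target_group"]
                lam = (rate * pop / 1e5 if cause == "suicide"
                       else config.other_cause_rates[cause] * pop / 1e5)
                prob = gc_deaths_per_cell * wrow["weight"] / lam
                if prob > 1:
                    raise ValueError(
                        f"infeasible channel: expected {cause} deaths {lam:.1f} cannot "
                        f"supply {gc_deaths_per_cell * wrow['weight']:.1f} garbage deaths")
                if prob > 0:
                    rows.append({"sex": sex, "age_group": ag, "year": year,
                                 "cause_group": cause, "gc_group": gc_group,
                                 "prob": prob})
    return pd.DataFrame(rows)


def brazil_study_config(seed: int = 0) -> SimConfig:
    """A configuration mimicking the shape of the Brazilian adolescent study.

    23 years (2000-2022), four sex x age-group strata with populations
    near 8.5 million, baseline suicide rates near the observed 2000
    values, a single trend break near 2012-2013 in each stratum, and an
    undetermined-intent mislabelling probability drifting down from ~0.34
    to ~0.20 (2017) and back up to ~0.25 (2022), mirroring the U-shaped
    garbage-code fraction of the study period.
    """
    years = range(2000, 2023)
    pops = {
        ("male", "10-14"): 8.7e6, ("female", "10-14"): 8.4e6,
        ("male", "15-19"): 8.6e6, ("female", "15-19"): 8.4e6,
    }
    trends = {
        ("male", "10-14"): (0.70, [TrendPhase(2000, 1.0), TrendPhase(2009, 4.8)]),
        ("female", "10-14"): (0.61, [TrendPhase(2000, -1.0), TrendPhase(2012, 10.6)]),
        ("male", "15-19"): (4.65, [TrendPhase(2000, 0.8), TrendPhase(2013, 6.8)]),
        ("female", "15-19"): (2.41, [TrendPhase(2000, -0.7), TrendPhase(2014, 9.5)]),
    }
    strata = {}
    for key, (base, trend) in trends.items():
        # slow population decline, roughly matching projection behaviour
        population = {y: int(pops[key] * (1 - 0.004 * (y - 2000))) for y in years}
        strata[key] = StratumConfig(baseline_rate=base, trend=trend,
                                    population=population)
    config = SimConfig(
        years=years,
        strata=strata,
        other_cause_rates={"homicide": 12.0, "road_traffic": 8.0,
                           "other_accident": 6.0, "natural": 18.0},
        missing_sex=0.005,
        missing_age=0.01,
        seed=seed,
    )

    def gc_prob(year: int) -> float:
        if year <= 2017:
            return 0.34 + (0.20 - 0.34) * (year - 2000) / 17
        return 0.20 + (0.25 - 0.20) * (year - 2017) / 5

    rows = []
    for (sex, ag) in strata:
        for y in years:
            p = gc_prob(y)
            for cause in ("suicide", "homicide", "other_accident"):
                rows.append({"sex": sex, "age_group": ag, "year": y,
                             "cause_group": cause, "gc_group": "undetermined_intent",
                             "prob": p * 0.5})
            rows.append({"sex": sex, "age_group": ag, "year": y,
                         "cause_group": "natural", "gc_group": "ill_defined",
                         "prob": p})
    config.gc_channels = pd.DataFrame(rows)
    return config
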