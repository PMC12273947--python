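"""Reading and validation of death-record and population files.

Death records arrive as delimited text with one row per registered death
(year, sex, age in completed years, ICD-10 underlying cause).  A
:class:`Dialect` maps file columns and encodings onto the package's
canonical fields; the default accepts both plain labels (``M``/``F``) and
SIM-style numeric codes (``1``/``2``, with ``9`` or blank meaning ignored).
Unknown sex or age is preserved — records are never dropped for
missingness, since downstream redistribution handles them.

Also packaged here: the corrected adolescent suicide rate series for
Brazil 2000-2022 (nine sex x age-group strata, rates per 100,000 as
printed to two decimals), used as the reference input for the trend
engine.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .icd import parse_icd10

__all__ = [
    "Dialect",
    "RateSeries",
    "read_death_records",
    "read_population",
    "brazil_adolescent_rates",
    "write_rate_table",
    "write_trend_table",
    "AGE_GROUPS",
    "age_group_of",
]

AGE_GROUPS = ("10-14", "15-19")


def age_group_of(age_years) -> str:
    """Map completed years of age to an analysis age group.

    Inclusive bounds: 10-14 covers ages 10..14, 15-19 covers 15..19.
    Ages outside 10-19 map to ``"other"``; missing age to ``"unknown"``.
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    a = int(age_years)
    if 10 <= a <= 14:
        return "10-14"
    if 15 <= a <= 19:
        return "15-19"
    return "other"


@dataclass
class Dialect:
    """Column mapping and value encodings for a death-record file."""

    year_col: str = "year"
    sex_col: str = "sex"
    age_col: str = "age"
    cause_col: str = "cause"
    sex_codes: dict = field(default_factory=lambda: {
        "M": "male", "F": "female", "1": "male", "2": "female",
        "9": "unknown", "0": "unknown", "": "unknown",
    })
    age_unknown: tuple = ("", "999", "NA")
    delimiter: str = ","

    def required_columns(self) -> list[str]:
        return [self.year_col, self.sex_col, self.age_col, self.cause_col]


#: Dialect matching SIM public-use extract column names.
SIM_DIALECT = Dialect(year_col="ANOOBITO", sex_col="SEXO", age_col="IDADE",
                      cause_col="CAUSABAS")


@dataclass
class RateSeries:
    """Yearly rates per 100,000 person-years for one stratum.

    Years must be consecutive; optional aligned fractional death counts
    and populations must satisfy ``rate = 1e5 * count / population``.
    """

    label: str
    years: np.ndarray
    rates: np.ndarray
    counts: Optional[np.ndarray] = None
    population: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.years.shape != self.rates.shape:
            raise ValueError("years and rates must align")
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError(f"{self.label}: years must be consecutive")
        if np.any(self.rates < 0):
            raise ValueError(f"{self.label}: rates must be non-negative")
        if self.counts is not None and self.population is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            self.population = np.asarray(self.population, dtype=float)
            implied = 1e5 * self.counts / self.population
            if not np.allclose(implied, self.rates, atol=5e-3):
                raise ValueError(f"{self.label}: rates inconsistent with counts/population")

    def __len__(self) -> int:
        return len(self.years)

    def __getitem__(self, year: int) -> float:
        idx = np.where(self.years == year)[0]
        if not len(idx):
            raise KeyError(f"{self.label}: no rate for year {year}")
        return float(self.rates[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"stratum": self.label, "year": self.years, "rate": self.rates})
        if self.counts is not None:
            out["deaths"] = self.counts
        if self.population is not None:
            out["population"] = self.population
        return out


class RecordValidationError(ValueError):
    """Raised when rows of a record file fail validation; carries row diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:5])
        more = "" if len(problems) <= 5 else f" (+{len(problems) - 5} more)"
        super().__init__(f"{len(problems)} invalid rows: {preview}{more}")


def read_death_records(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read a delimited death-record file into the canonical record frame.

    Returns a DataFrame with columns ``year`` (int), ``sex``
    (male/female/unknown), ``age_years`` (float, NaN when unknown),
    ``age_group``, ``cause`` (canonical ICD-10 string) and ``weight``
    (1.0).  Unknown sex/age is preserved, never dropped.

    Raises
    ------
    KeyError
        If a mandatory column is absent (configuration error).
    RecordValidationError
        If rows carry unparseable years or causes; the message lists
        offending row numbers.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required_columns() if c not in raw.columns]
    if missing:
        raise KeyError(f"record file {path} lacks mandatory column(s): {missing}")

    problems: list[str] = []
    years = pd.to_numeric(raw[dialect.year_col], errors="coerce")
    for i in np.where(years.isna())[0]:
        problems.append(f"row {i + 2}: bad year {raw[dialect.year_col].iloc[i]!r}")

    sex = raw[dialect.sex_col].str.strip().map(
        lambda v: dialect.sex_codes.get(v, dialect.sex_codes.get(v.upper(), None)))
    for i in np.where(sex.isna())[0]:
        problems.append(f"row {i + 2}: bad sex code {raw[dialect.sex_col].iloc[i]!r}")

    age_txt = raw[dialect.age_col].str.strip()
    age = pd.to_numeric(age_txt.where(~age_txt.isin(dialect.age_unknown), other=None),
                        errors="coerce")
    bad_age = age.isna() & ~age_txt.isin(dialect.age_unknown)
    for i in np.where(bad_age)[0]:
        problems.append(f"row {i + 2}: bad age {age_txt.iloc[i]!r}")

    causes = []
    for i, c in enumerate(raw[dialect.cause_col]):
        try:
            causes.append(str(parse_icd10(c)))
        except ValueError as exc:
            problems.append(f"row {i + 2}: {exc}")
            causes.append(None)
    if problems:
        raise RecordValidationError(problems)

    return pd.DataFrame({
        "year": years.astype(int),
        "sex": sex,
        "age_years": age.astype(float),
        "age_group": [age_group_of(a) for a in age],
        "cause": causes,
        "weight": 1.0,
    })


def write_death_records(records: pd.DataFrame, path: str | Path,
                        dialect: Dialect | None = None) -> None:
    """Write a canonical record frame back to the dialect's column layout."""
    dialect = dialect or Dialect()
    inv_sex = {"male": "M", "female": "F", "unknown": "9"}
    out = pd.DataFrame({
        dialect.year_col: records["year"].astype(int),
        dialect.sex_col: records["sex"].map(inv_sex),
        dialect.age_col: records["age_years"].map(
            lambda a: "" if pd.isna(a) else str(int(a))),
        dialect.cause_col: records["cause"],
    })
    out.to_csv(path, sep=dialect.delimiter, index=False)


def read_population(path: str | Path, years: Optional[range] = None,
                    sexes=("male", "female"), age_groups=AGE_GROUPS) -> pd.DataFrame:
    """Read population denominators (year, sex, age_group, population).

    Validates positivity and, when ``years`` is given, completeness of the
    years x sexes x age-groups rectangle; the error names missing cells.
    """
    pop = pd.read_csv(path)
    required = {"year", "sex", "age_group", "population"}
    if not required.issubset(pop.columns):
        raise KeyError(f"population file lacks column(s): {sorted(required - set(pop.columns))}")
    if (pop["population"] <= 0).any():
        bad = pop.loc[pop["population"] <= 0].iloc[0]
        raise ValueError(f"non-positive population in cell "
                         f"({bad['year']}, {bad['sex']}, {bad['age_group']})")
    if pop.duplicated(["year", "sex", "age_group"]).any():
        raise ValueError("duplicate (year, sex, age_group) cells in population file")
    if years is not None:
        have = set(map(tuple, pop[["year", "sex", "age_group"]].itertuples(index=False)))
        missing = [(y, s, a) for y in years for s in sexes for a in age_groups
                   if (y, s, a) not in have]
        if missing:
            raise ValueError(f"population file missing cells: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
    return pop.astype({"year": int, "population": int})


def brazil_adolescent_rates() -> dict[tuple[str, str], RateSeries]:
    """The packaged corrected adolescent suicide rate series (2000-2022).

    Returns the nine strata keyed by ``(sex, age_group)`` with sex in
    total/male/female and age group in 10-19/10-14/15-19, 23 yearly rates
    per 100,000 each, exactly as printed (two decimals).
    """
    ref = importlib.resources.files("mortrend.data") / "corrected_rates_2000_2022.csv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    out: dict[tuple[str, str], RateSeries] = {}
    for (sex, ag), grp in df.groupby(["sex", "age_group"]):
        grp = grp.sort_values("year")
        out[(sex, ag)] = RateSeries(f"{sex} {ag}", grp["year"].to_numpy(),
                                    grp["rate"].to_numpy())
    return out


def write_rate_table(series: list[RateSeries], path: str | Path) -> None:
    """Write rate series as CSV (stratum, year, deaths, population, rate_per_100k)."""
    frames = []
    for s in series:
        f = s.to_frame().rename(columns={"rate": "rate_per_100k"})
        for col in ("deaths", "population"):
            if col not in f:
                f[col] = np.nan
        frames.append(f[["stratum", "year", "deaths", "population", "rate_per_100k"]])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trend_table(rows: list[dict], path: str | Path) -> None:
    """Write per-segment trend results mirroring the published table layout."""
    cols = ["stratum", "segment_start", "segment_end", "apc", "apc_ci_low",
            "apc_ci_high", "p_value", "significance", "trend", "aapc",
            "aapc_ci_low", "aapc_ci_high", "overall_trend"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
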