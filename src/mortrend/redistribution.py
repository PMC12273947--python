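"""Correction of cause-of-death counts by garbage-code redistribution.

The correction runs in the order the source registry's quality problems
arise: first records with missing sex or age are reassigned
proportionally to the observed demographic mix of fully specified
records (same year and cause category, with year-level and uniform
fallbacks for sparse strata); then garbage-coded deaths are moved to
their target cause groups, either by empirical weights estimated from
death investigations or proportionally to the observed mix of target
causes in the same stratum.  Total weight is conserved exactly at every
step, and corrected suicide counts can only gain mass relative to the
directly coded counts.

Both steps are transformer-style estimators operating on the canonical
record frame (year, sex, age_years, age_group, cause, weight); the
redistributor's output is a long frame of weighted cell counts, with
redistributed suicide mass tracked separately from directly coded
suicides until :func:`assign_methods_to_redistributed` splits it across
mechanism groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .icd import GCMap, SUICIDE_METHODS, classify_cause, parse_icd10
from .io import AGE_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "classify_records",
    "MissingDemographicsImputer",
    "GarbageCodeRedistributor",
    "assign_methods_to_redistributed",
    "load_weight_table",
    "redistribute_missing_demographics",
    "redistribute_garbage_codes",
]


def classify_records(records: pd.DataFrame, gc_map: GCMap) -> pd.DataFrame:
    """Attach classification columns (kind, method, gc_group, cause_category).

    ``cause_category`` is the single label used to stratify
    redistribution: ``suicide``, the garbage-code group, the defined
    target group, or ``other``.
    """
    out = records.copy()
    cats = {c: classify_cause(parse_icd10(c), gc_map) for c in out["cause"].unique()}
    out["kind"] = out["cause"].map({c: v.kind for c, v in cats.items()})
    out["method"] = out["cause"].map({c: v.method for c, v in cats.items()})
    out["gc_group"] = out["cause"].map({c: v.gc_group for c, v in cats.items()})
    out["target_group"] = out["cause"].map({c: v.target_group for c, v in cats.items()})
    category = {c: ("suicide" if v.kind == "suicide"
                    else v.gc_group if v.kind == "garbage"
                    else (v.target_group or "other")) for c, v in cats.items()}
    out["cause_category"] = out["cause"].map(category)
    return out


def load_weight_table(path) -> pd.DataFrame:
    """Load and validate a redistribution weight table.

    Columns: gc_group, sex, age_group, target_group, weight.  Within each
    (gc_group, sex, age_group) the weights must be non-negative and sum
    to one.
    """
    w = pd.read_csv(path)
    required = {"gc_group", "sex", "age_group", "target_group", "weight"}
    if not required.issubset(w.columns):
        raise KeyError(f"weight table lacks column(s): {sorted(required - set(w.columns))}")
    if (w["weight"] < 0).any():
        raise ValueError("redistribution weights must be non-negative")
    sums = w.groupby(["gc_group", "sex", "age_group"])["weight"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValueError(f"weights do not sum to 1 for strata: {list(bad.index[:5])}")
    return w


class MissingDemographicsImputer(TransformerMixin, BaseEstimator):
    """Reassign records with unknown sex and/or age group proportionally.

    Each unknown record's weight is split across the fully specified
    (sex, age_group) cells observed among records of the same year and
    cause category, proportionally to their weight, conditioning on
    whichever of sex/age the record does carry.  Strata with no fully
    specified records fall back to the year-level mix, then to a uniform
    split over male/female x the analysis age groups (logged).
    """

    def __init__(self, gc_map: GCMap | None = None):
        self.gc_map = gc_map

    def fit(self, X, y=None):
        self.fallback_counts_ = {"year_level": 0, "uniform": 0}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "fallback_counts_"):
            self.fit(X)
        records = X
        if "cause_category" not in records.columns:
            if self.gc_map is None:
                raise ValueError("records are unclassified and no gc_map was given")
            records = classify_records(records, self.gc_map)
        unknown = (records["sex"].eq("unknown")) | (records["age_group"].eq("unknown"))
        known = records.loc[~unknown]
        if not unknown.any():
            return records.copy()

        # weight of fully specified records per cell, at the cause-category
        # level and at the year level (first fallback)
        def _cells(df, keys):
            d = df.groupby(keys + ["sex", "age_group"], observed=True)["weight"] \
                  .sum().reset_index()
            return d.rename(columns={"sex": "cell_sex", "age_group": "cell_ag",
                                     "weight": "cell_w"})

        dist_cat = _cells(known, ["year", "cause_category"])
        dist_year = _cells(known, ["year"])

        unk = records.loc[unknown].reset_index(drop=True)
        unk["_rid"] = np.arange(len(unk))

        def _split(rows: pd.DataFrame, dist: pd.DataFrame, keys: list[str]):
            merged = rows.merge(dist, on=keys, how="inner")
            keep = ((merged["sex"].eq("unknown") | merged["cell_sex"].eq(merged["sex"]))
                    & (merged["age_group"].eq("unknown")
                       | merged["cell_ag"].eq(merged["age_group"])))
            merged = merged[keep]
            if merged.empty:
                return merged, rows
            share = merged["cell_w"] / merged.groupby("_rid")["cell_w"].transform("sum")
            merged = merged.assign(weight=merged["weight"] * share)
            resolved_ids = merged["_rid"].unique()
            return merged, rows[~rows["_rid"].isin(resolved_ids)]

        merged_cat, rest = _split(unk, dist_cat, ["year", "cause_category"])
        merged_year, rest = _split(rest, dist_year, ["year"])
        if len(merged_year):
            self.fallback_counts_["year_level"] += int(merged_year["_rid"].nunique())
            logger.warning("%d unknown record(s) had no specified records in their "
                           "cause category; used the year-level mix",
                           merged_year["_rid"].nunique())

        uniform_parts = []
        for _, row in rest.iterrows():
            self.fallback_counts_["uniform"] += 1
            logger.warning("no specified records to guide (%s, %s); splitting "
                           "uniformly", row["year"], row["cause_category"])
            sexes = [row["sex"]] if row["sex"] != "unknown" else ["male", "female"]
            ags = [row["age_group"]] if row["age_group"] != "unknown" else list(AGE_GROUPS)
            for s in sexes:
                for a in ags:
                    r = row.copy()
                    r["cell_sex"], r["cell_ag"] = s, a
                    r["weight"] = row["weight"] / (len(sexes) * len(ags))
                    uniform_parts.append(r)
        parts = [m for m in (merged_cat, merged_year) if len(m)]
        if uniform_parts:
            parts.append(pd.DataFrame(uniform_parts))
        split = pd.concat(parts, ignore_index=True)
        split["age_years"] = np.where(split["age_group"].eq("unknown"),
                                      np.nan, split["age_years"])
        split["sex"] = split["cell_sex"]
        split["age_group"] = split["cell_ag"]
        out = pd.concat([known, split[records.columns]], ignore_index=True)
        assert abs(out["weight"].sum() - records["weight"].sum()) \
            < 1e-9 * max(records["weight"].sum(), 1.0)
        return out


class GarbageCodeRedistributor(TransformerMixin, BaseEstimator):
    """Aggregate records and move garbage-coded mass to target causes.

    Directly coded records aggregate into (year, sex, age_group,
    cause_group) cells; garbage-coded weight in each cell is then spread
    over the garbage group's target causes, by the empirical weight table
    (``mode=empirical``; a stratum absent from the table falls back to
    the group's all-strata marginal weights) or proportionally to the
    directly observed target mix in the same cell (``mode=proportional``;
    an all-zero mix falls back to a uniform split).  The output is a long
    frame with columns year, sex, age_group, cause_group, method, source
    (direct/redistributed) and count; redistributed suicide mass carries
    no method until :func:`assign_methods_to_redistributed`.
    """

    def __init__(self, gc_map: GCMap | None = None,
                 weights: pd.DataFrame | None = None,
                 age_groups: tuple = AGE_GROUPS):
        self.gc_map = gc_map
        self.weights = weights
        self.age_groups = age_groups

    def fit(self, X, y=None):
        self.fallback_counts_ = {"marginal_weights": 0, "uniform_targets": 0}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "fallback_counts_"):
            self.fit(X)
        records = X
        if "cause_category" not in records.columns:
            if self.gc_map is None:
                raise ValueError("records are unclassified and no gc_map was given")
            records = classify_records(records, self.gc_map)
        if records["sex"].eq("unknown").any() or records["age_group"].eq("unknown").any():
            raise ValueError("records still carry unknown demographics; "
                             "apply MissingDemographicsImputer first")
        records = records[records["age_group"].isin(self.age_groups)]

        cell = ["year", "sex", "age_group"]
        direct = records[records["kind"] != "garbage"].copy()
        direct["cause_group"] = np.where(direct["kind"].eq("suicide"), "suicide",
                                         direct["cause_category"])
        agg = (direct.groupby(cell + ["cause_group", "method"], dropna=False)["weight"]
               .sum().reset_index().rename(columns={"weight": "count"}))
        agg["source"] = "direct"

        garbage = (records[records["kind"] == "garbage"]
                   .groupby(cell + ["gc_group"])["weight"].sum().reset_index())
        redistributed = []
        for _, row in garbage.iterrows():
            g = row["gc_group"]
            targets = self.gc_map.targets.get(g)
            if not targets:
                raise ValueError(f"garbage-code group {g!r} has no targets in the map")
            mode = self.gc_map.modes.get(g, "proportional")
            shares = (self._empirical_shares(g, targets, row["sex"], row["age_group"])
                      if mode == "empirical"
                      else self._proportional_shares(agg, targets, row))
            for target, share in shares.items():
                if share > 0:
                    redistributed.append({
                        "year": row["year"], "sex": row["sex"],
                        "age_group": row["age_group"], "cause_group": target,
                        "method": None, "source": "redistributed",
                        "count": row["weight"] * share,
                    })
        frames = [agg]
        if redistributed:
            frames.append(pd.DataFrame(redistributed))
        out = pd.concat(frames, ignore_index=True)
        out = (out.groupby(cell + ["cause_group", "method", "source"], dropna=False)
               ["count"].sum().reset_index())
        total_in = records["weight"].sum()
        assert abs(out["count"].sum() - total_in) < 1e-9 * max(total_in, 1.0)
        return out

    def _empirical_shares(self, g, targets, sex, age_group) -> dict:
        if self.weights is None:
            raise ValueError(f"group {g!r} is empirical but no weight table was given")
        w = self.weights
        rows = w[(w["gc_group"] == g) & (w["sex"] == sex) & (w["age_group"] == age_group)]
        if rows.empty:
            rows = w[w["gc_group"] == g]
            if rows.empty:
                raise ValueError(f"weight table has no rows for group {g!r}")
            self.fallback_counts_["marginal_weights"] += 1
            logger.warning("no weights for (%s, %s, %s); using the group's "
                           "marginal weights", g, sex, age_group)
            rows = rows.groupby("target_group", as_index=False)["weight"].mean()
        shares = dict(zip(rows["target_group"], rows["weight"]))
        total = sum(shares.values())
        return {t: shares.get(t, 0.0) / total for t in targets}

    def _proportional_shares(self, agg, targets, row) -> dict:
        pool = agg[(agg["year"] == row["year"]) & (agg["sex"] == row["sex"])
                   & (agg["age_group"] == row["age_group"])
                   & (agg["cause_group"].isin(targets))]
        observed = pool.groupby("cause_group")["count"].sum()
        total = observed.sum()
        if total <= 0:
            self.fallback_counts_["uniform_targets"] += 1
            logger.warning("no observed target mass for %s in (%s, %s, %s); "
                           "splitting uniformly", targets, row["year"], row["sex"],
                           row["age_group"])
            return {t: 1.0 / len(targets) for t in targets}
        return {t: observed.get(t, 0.0) / total for t in targets}


def assign_methods_to_redistributed(corrected: pd.DataFrame,
                                    methods: tuple = SUICIDE_METHODS) -> pd.DataFrame:
    """Split redistributed suicide mass across mechanism groups.

    The split follows the directly coded method distribution of the same
    (year, sex, age_group) cell; a cell with no directly coded suicides
    borrows the year-level distribution, and failing that splits
    uniformly.  All non-suicide rows pass through unchanged.
    """
    is_pending = (corrected["cause_group"].eq("suicide")
                  & corrected["source"].eq("redistributed")
                  & corrected["method"].isna())
    if not is_pending.any():
        return corrected.copy()
    direct = corrected[corrected["cause_group"].eq("suicide")
                       & corrected["source"].eq("direct")]
    cell_dist = direct.groupby(["year", "sex", "age_group", "method"])["count"].sum()
    year_dist = direct.groupby(["year", "method"])["count"].sum()

    rows = [corrected[~is_pending]]
    for _, row in corrected[is_pending].iterrows():
        key = (row["year"], row["sex"], row["age_group"])
        try:
            dist = cell_dist.xs(key)
        except KeyError:
            dist = pd.Series(dtype=float)
        if dist.sum() <= 0:
            try:
                dist = year_dist.xs(row["year"])
            except KeyError:
                dist = pd.Series(dtype=float)
        if dist.sum() <= 0:
            logger.warning("no directly coded suicides to guide method split in "
                           "(%s, %s, %s); splitting uniformly", *key)
            dist = pd.Series(1.0, index=list(methods))
        dist = dist / dist.sum()
        for m, share in dist.items():
            if share > 0:
                r = row.copy()
                r["method"] = m
                r["count"] = row["count"] * share
                rows.append(r.to_frame().T)
    out = pd.concat(rows, ignore_index=True)
    out = (out.groupby(["year", "sex", "age_group", "cause_group", "method", "source"],
                       dropna=False)["count"].sum().reset_index())
    total_in = corrected["count"].sum()
    assert abs(out["count"].sum() - total_in) < 1e-9 * max(total_in, 1.0)
    return out


# -- thin functional wrappers -----------------------------------------------

def redistribute_missing_demographics(records: pd.DataFrame,
                                      gc_map: GCMap) -> pd.DataFrame:
    """Functional form of :class:`MissingDemographicsImputer`."""
    return MissingDemographicsImputer(gc_map=gc_map).fit(records).transform(records)


def redistribute_garbage_codes(records: pd.DataFrame, gc_map: GCMap,
                               weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Functional form of :class:`GarbageCodeRedistributor`."""
    return GarbageCodeRedistributor(gc_map=gc_map, weights=weights).fit(records).transform(records)
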