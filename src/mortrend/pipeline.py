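"""End-to-end orchestration: read, correct, estimate rates, fit trends."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .icd import GCMap, SUICIDE_METHODS
from .io import AGE_GROUPS, Dialect, read_death_records, read_population, \
    write_rate_table, write_trend_table
from .joinpoint import fit_joinpoint
from .rates import rate_series_from_counts
from .redistribution import (GarbageCodeRedistributor, MissingDemographicsImputer,
                             assign_methods_to_redistributed, classify_records,
                             load_weight_table)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and settings for a full analysis run."""

    records_path: str
    population_path: str
    gc_map_path: str
    weights_path: Optional[str]
    output_dir: str
    years: Optional[tuple[int, int]] = None      # analysis window (inclusive)
    by_method: bool = True
    max_joinpoints: Optional[int] = None
    min_obs_per_segment: int = 4
    weighting: str = "count"
    confidence: float = 0.95
    zero_rate: str = "error"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.records_path, self.population_path, self.gc_map_path,
                  self.weights_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.years is not None and self.years[0] > self.years[1]:
            raise ValueError("analysis window is empty")


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run read -> classify -> redistribute -> rates -> trends.

    Writes the corrected-count table, the per-stratum (and per-method)
    rate tables, the trend table and a run manifest into the output
    directory, and returns the output paths together with in-memory
    results.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config_hash": _config_hash(config),
                "config": asdict(config), "warnings": {}, "valid": False}

    gc_map = GCMap.from_yaml(config.gc_map_path)
    weights = (load_weight_table(config.weights_path)
               if config.weights_path else None)
    records = read_death_records(config.records_path, Dialect())
    if config.years is not None:
        records = records[records["year"].between(*config.years)]
    population = read_population(config.population_path)

    records = classify_records(records, gc_map)
    total_in = records["weight"].sum()

    imputer = MissingDemographicsImputer(gc_map=gc_map).fit(records)
    records = imputer.transform(records)
    redistributor = GarbageCodeRedistributor(gc_map=gc_map, weights=weights).fit(records)
    corrected = redistributor.transform(records)
    corrected = assign_methods_to_redistributed(corrected)
    manifest["warnings"]["imputer_fallbacks"] = imputer.fallback_counts_
    manifest["warnings"]["redistribution_fallbacks"] = redistributor.fallback_counts_
    adolescent_weight = records[records["age_group"].isin(AGE_GROUPS)]["weight"].sum()
    if abs(corrected["count"].sum() - adolescent_weight) > 1e-6 * max(total_in, 1.0):
        raise RuntimeError("conservation violated between input records and "
                           "corrected counts")

    corrected_path = out_dir / "corrected_counts.csv"
    corrected.to_csv(corrected_path, index=False)

    strata = [(s, a) for s in ("total", "male", "female")
              for a in ("10-19", *AGE_GROUPS)]
    series = [rate_series_from_counts(corrected, population, s, a) for s, a in strata]
    if config.by_method:
        series += [rate_series_from_counts(corrected, population, "total", "10-19",
                                           method=m) for m in SUICIDE_METHODS]
    rates_path = out_dir / "rates.csv"
    write_rate_table(series, rates_path)

    trend_rows = []
    fits = {}
    for s in series:
        if (s.rates <= 0).any() and config.zero_rate == "error":
            logger.warning("skipping trend fit for %s: zero rates", s.label)
            continue
        fit = fit_joinpoint(s, max_joinpoints=config.max_joinpoints,
                            min_obs_per_segment=config.min_obs_per_segment,
                            weighting=config.weighting, confidence=config.confidence,
                            zero_rate=config.zero_rate)
        fits[s.label] = fit
        trend_rows += fit.summary_rows(s.label)
    trends_path = out_dir / "trends.csv"
    write_trend_table(trend_rows, trends_path)

    manifest["valid"] = True
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return {"corrected": corrected, "series": series, "fits": fits,
            "paths": {"corrected": corrected_path, "rates": rates_path,
                      "trends": trends_path, "manifest": manifest_path}}
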