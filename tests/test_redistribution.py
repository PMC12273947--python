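"""Missing-demographics imputation and garbage-code redistribution."""

import numpy as np
import pandas as pd
import pytest

from mortrend.redistribution import (GarbageCodeRedistributor,
                                     MissingDemographicsImputer,
                                     assign_methods_to_redistributed,
                                     classify_records, load_weight_table,
                                     redistribute_missing_demographics)

from conftest import make_records, random_records


def total_weight(df):
    col = "weight" if "weight" in df else "count"
    return df[col].sum()


class TestMissingDemographics:
    def test_single_unknown_sex_split_proportionally(self, gc_map):
        rec = make_records(sexes=["male"] * 30 + ["female"] * 10 + ["unknown"],
                           ages=[16], causes=["X70"])
        out = redistribute_missing_demographics(rec, gc_map)
        by_sex = out.groupby("sex")["weight"].sum()
        assert by_sex["male"] == pytest.approx(30.75)
        assert by_sex["female"] == pytest.approx(10.25)
        assert set(by_sex.index) == {"male", "female"}

    def test_no_unknowns_is_identity(self, gc_map):
        rec = make_records(sexes=["male", "female"], ages=[12, 17],
                           causes=["X70", "Y10"])
        out = redistribute_missing_demographics(rec, gc_map)
        pd.testing.assert_frame_equal(
            out.sort_values("sex").reset_index(drop=True),
            classify_records(rec, gc_map).sort_values("sex").reset_index(drop=True))

    def test_two_unknowns_against_enumerated_shares(self, gc_map):
        # known mix: 1 male 10-14, 3 female 15-19 -> unknowns split 0.5 / 1.5
        rec = make_records(
            sexes=["male"] + ["female"] * 3 + ["unknown"] * 2,
            ages=[12, 17, 17, 17, None, None],
            causes=["X70"])
        out = redistribute_missing_demographics(rec, gc_map)
        cells = out.groupby(["sex", "age_group"])["weight"].sum()
        assert cells[("male", "10-14")] == pytest.approx(1 + 0.5)
        assert cells[("female", "15-19")] == pytest.approx(3 + 1.5)

    def test_empty_stratum_falls_back_to_year_mix(self, gc_map):
        # the unknown record's cause category (garbage) has no specified records
        rec = make_records(sexes=["male", "male", "unknown"], ages=[16, 16, None],
                           causes=["X70", "X70", "Y10"])
        imp = MissingDemographicsImputer(gc_map=gc_map).fit(rec)
        out = imp.transform(classify_records(rec, gc_map))
        assert imp.fallback_counts_["year_level"] == 1
        assert out[out["cause"] == "Y10"]["sex"].tolist() == ["male"]

    def test_known_age_is_respected_when_only_sex_missing(self, gc_map):
        rec = make_records(sexes=["male", "female", "unknown"], ages=[12, 17, 12],
                           causes=["X70"])
        out = redistribute_missing_demographics(rec, gc_map)
        split = out[(out["age_group"] == "10-14")]
        # unknown-sex 12-year-old can only land on the male 10-14 cell
        assert split["weight"].sum() == pytest.approx(2.0)
        assert set(split["sex"]) == {"male"}


class TestGarbageRedistribution:
    def test_empirical_weight_arithmetic(self, gc_map, weight_table):
        # 10 undetermined-intent deaths, female 10-14 suicide weight 0.35 -> +3.5
        rec = make_records(sexes=["female"] * 12, ages=[12],
                           causes=["X70", "X70"] + ["Y20"] * 10)
        corr = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
            .fit_transform(classify_records(rec, gc_map))
        sui = corr[corr["cause_group"] == "suicide"]
        gained = sui[sui["source"] == "redistributed"]["count"].sum()
        assert gained == pytest.approx(10 * 0.35)
        assert total_weight(corr) == pytest.approx(12.0, abs=1e-9)

    def test_proportional_split_matches_enumeration(self, gc_map, weight_table):
        # unspecified accidents split across road_traffic:other_accident = 8:2
        rec = make_records(
            sexes=["male"] * 15, ages=[17],
            causes=["V43"] * 8 + ["W74"] * 2 + ["X59"] * 5)
        corr = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
            .fit_transform(classify_records(rec, gc_map))
        red = corr[corr["source"] == "redistributed"].set_index("cause_group")["count"]
        assert red["road_traffic"] == pytest.approx(4.0)
        assert red["other_accident"] == pytest.approx(1.0)

    def test_rejects_records_with_unknown_demographics(self, gc_map, weight_table):
        rec = make_records(sexes=["unknown"], ages=[16], causes=["X70"])
        with pytest.raises(ValueError, match="unknown demographics"):
            GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
                .fit_transform(classify_records(rec, gc_map))

    def test_idempotent_without_garbage_or_unknowns(self, gc_map, weight_table):
        rec = make_records(sexes=["male", "female"], ages=[16, 12],
                           causes=["X70", "I21"])
        corr = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
            .fit_transform(classify_records(rec, gc_map))
        assert (corr["source"] == "direct").all()
        assert total_weight(corr) == pytest.approx(2.0, abs=1e-12)

    def test_conservation_and_monotonicity_on_random_inputs(self, gc_map, weight_table):
        """Total weight is conserved to 1e-9 and corrected suicide mass never
        falls below the directly coded mass, over 100 random datasets."""
        rng = np.random.default_rng(2024)
        imputer = MissingDemographicsImputer(gc_map=gc_map)
        redis = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table)
        for _ in range(100):
            rec = classify_records(random_records(rng, n=120), gc_map)
            step2 = imputer.fit(rec).transform(rec)
            assert step2["weight"].sum() == pytest.approx(rec["weight"].sum(), abs=1e-9)
            corr = redis.fit(step2).transform(step2)
            adolescent = step2[step2["age_group"].isin(("10-14", "15-19"))]
            assert corr["count"].sum() == pytest.approx(
                adolescent["weight"].sum(), abs=1e-9)
            sui = corr[corr["cause_group"] == "suicide"]
            direct = sui[sui["source"] == "direct"].groupby(
                ["year", "sex", "age_group"])["count"].sum()
            total = sui.groupby(["year", "sex", "age_group"])["count"].sum()
            assert (total.reindex(direct.index) - direct >= -1e-12).all()


class TestMethodAssignment:
    def test_split_follows_direct_method_mix(self, gc_map, weight_table):
        rec = make_records(
            sexes=["female"] * 15, ages=[12],
            causes=["X70"] * 6 + ["X64"] * 2 + ["X72"] * 2 + ["Y20"] * 5)
        corr = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
            .fit_transform(classify_records(rec, gc_map))
        out = assign_methods_to_redistributed(corr)
        mass = 5 * 0.35  # empirical suicide weight for female 10-14
        red = out[(out["cause_group"] == "suicide")
                  & (out["source"] == "redistributed")].set_index("method")["count"]
        assert red["hanging"] == pytest.approx(mass * 0.6)
        assert red["poisoning"] == pytest.approx(mass * 0.2)
        assert red["firearm"] == pytest.approx(mass * 0.2)

    def test_no_pending_mass_is_identity(self, gc_map, weight_table):
        rec = make_records(sexes=["male"], ages=[16], causes=["X70"])
        corr = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
            .fit_transform(classify_records(rec, gc_map))
        out = assign_methods_to_redistributed(corr)
        pd.testing.assert_frame_equal(out, corr)

    def test_empty_cell_borrows_year_distribution(self, gc_map, weight_table):
        # all direct suicides are male; redistributed female mass follows the
        # year-level method mix (hanging 2 : poisoning 1)
        rec = pd.concat([
            make_records(sexes=["male"] * 3, ages=[16],
                         causes=["X70", "X70", "X64"]),
            make_records(sexes=["female"] * 4, ages=[12], causes=["Y20"]),
        ], ignore_index=True)
        corr = GarbageCodeRedistributor(gc_map=gc_map, weights=weight_table) \
            .fit_transform(classify_records(rec, gc_map))
        out = assign_methods_to_redistributed(corr)
        red = out[(out["sex"] == "female") & (out["cause_group"] == "suicide")]
        by_method = red.set_index("method")["count"]
        mass = 4 * 0.35
        assert by_method["hanging"] == pytest.approx(mass * 2 / 3)
        assert by_method["poisoning"] == pytest.approx(mass * 1 / 3)


def test_weight_table_validation(tmp_path):
    p = tmp_path / "w.csv"
    p.write_text("gc_group,sex,age_group,target_group,weight\n"
                 "g1,male,10-14,suicide,0.4\ng1,male,10-14,homicide,0.4\n")
    with pytest.raises(ValueError, match="sum to 1"):
        load_weight_table(p)
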