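"""Adequacy rule set, per-child classification and cohort summaries."""

import json

import numpy as np
import pandas as pd
import pytest

from ffqpipe import classify, default_rules, load_rules, summarize_adequacy
from ffqpipe.adequacy import AdequacyRule


@pytest.fixture(scope="module")
def rules():
    return default_rules()


def rule(rules, rid):
    return next(r for r in rules if r.rule_id == rid)


class TestRuleSet:
    def test_bundled_cutoffs(self, rules):
        assert rule(rules, "selenium").threshold == 20
        assert rule(rules, "selenium").direction == "at_least"
        assert rule(rules, "niacin").basis == "per_MJ"
        assert rule(rules, "niacin").threshold == 1.6
        assert rule(rules, "iodine").threshold == 85  # midpoint of the 80-90 range
        assert rule(rules, "sodium_infant").threshold == 370
        assert rule(rules, "sodium_1_3y").threshold == 1100
        assert rule(rules, "omega3_infant").threshold == 1.0
        assert rule(rules, "omega3_1_3y").threshold == 0.5
        assert rule(rules, "sfa").strict is True

    def test_round_trip_through_json(self, rules, tmp_path):
        path = tmp_path / "rules.json"
        from ffqpipe.adequacy import AdequacyRule
        from dataclasses import asdict

        path.write_text(json.dumps({"rules": [asdict(r) for r in rules]}))
        assert load_rules(path) == rules

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            AdequacyRule(
                rule_id="bad", label="Bad", nutrient="fat_epct",
                basis="energy_percent", direction="within",
                rule_class="RI", low=45, high=30,
            )

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            AdequacyRule(
                rule_id="bad", label="Bad", nutrient="x", basis="per_fortnight",
                direction="at_least", rule_class="RI", threshold=1,
            )


def frame(**cols):
    return pd.DataFrame({k: [v] for k, v in cols.items()}, index=["c1"])


class TestClassify:
    def test_selenium_below_cutoff_not_met(self):
        nut = frame(selenium_ug=13.12, energy_kcal=805.59)
        res = classify(nut)
        assert res.verdicts.loc["c1", "selenium"] == 0.0

    def test_inclusive_boundary(self):
        nut = frame(iron_mg=10.0, energy_kcal=805.59)
        res = classify(nut)
        assert res.verdicts.loc["c1", "iron"] == 1.0

    def test_sodium_exceeds_both_age_variants(self):
        nut = frame(sodium_mg=1149.42, energy_kcal=805.59)
        infant = classify(nut, age_variant="infant_le_11m")
        toddler = classify(nut, age_variant="child_1_3y")
        assert infant.verdicts.loc["c1", "sodium_infant"] == 0.0
        assert toddler.verdicts.loc["c1", "sodium_1_3y"] == 0.0

    def test_strict_sfa_boundary_is_exclusive(self):
        res = classify(frame(sfa_epct=10.0, energy_kcal=800.0))
        assert res.verdicts.loc["c1", "sfa"] == 0.0
        res = classify(frame(sfa_epct=9.999, energy_kcal=800.0))
        assert res.verdicts.loc["c1", "sfa"] == 1.0

    def test_missing_nutrient_gives_missing_verdict_not_failure(self):
        nut = frame(selenium_ug=np.nan, energy_kcal=800.0)
        res = classify(nut)
        assert np.isnan(res.verdicts.loc["c1", "selenium"])
        srow = res.summary().set_index("rule_id").loc["selenium"]
        assert srow["n_total"] == 0

    def test_absent_rule_column_is_skipped_with_metadata(self):
        res = classify(frame(energy_kcal=800.0, selenium_ug=25.0))
        assert "iron" in res.skipped
        assert "selenium" not in res.skipped

    def test_trans_fat_rule_yields_no_verdict(self):
        res = classify(frame(trans_epct=1.0, energy_kcal=800.0))
        assert np.isnan(res.verdicts.loc["c1", "trans_fat"])

    def test_per_mj_basis(self):
        # 12 mg NE at 956 kcal = 4 MJ -> 3.0 NE/MJ >= 1.6
        res = classify(frame(niacin_eq_mg=12.0, energy_kcal=956.0))
        assert res.verdicts.loc["c1", "niacin"] == 1.0
        res = classify(frame(niacin_eq_mg=4.0, energy_kcal=956.0))
        assert res.verdicts.loc["c1", "niacin"] == 0.0

    def test_rule_engine_matches_handcoded_predicates(self, rules):
        """Verdicts equal independent per-rule predicates on 200 random
        nutrient vectors."""
        rng = np.random.default_rng(123)
        n = 200
        nut = pd.DataFrame(
            {
                "energy_kcal": rng.uniform(150, 2800, n),
                "selenium_ug": rng.uniform(0, 45, n),
                "iron_mg": rng.uniform(0, 22, n),
                "sodium_mg": rng.uniform(100, 3400, n),
                "iodine_ug": rng.uniform(0, 350, n),
                "vitamin_d_ug": rng.uniform(0, 22, n),
                "niacin_eq_mg": rng.uniform(0, 32, n),
                "thiamine_mg": rng.uniform(0, 1.5, n),
                "carbohydrate_epct": rng.uniform(20, 80, n),
                "fat_epct": rng.uniform(10, 60, n),
                "protein_epct": rng.uniform(5, 25, n),
                "omega3_epct": rng.uniform(0, 3, n),
                "omega6_epct": rng.uniform(0, 8, n),
                "sfa_epct": rng.uniform(2, 20, n),
            },
            index=[f"r{i}" for i in range(n)],
        )
        res = classify(nut, age_variant="infant_le_11m")
        v = res.verdicts
        mj = nut["energy_kcal"] / 239.0
        expected = {
            "selenium": nut["selenium_ug"] >= 20,
            "iron": nut["iron_mg"] >= 10,
            "sodium_infant": nut["sodium_mg"] <= 370,
            "iodine": nut["iodine_ug"] >= 85,
            "vitamin_d": nut["vitamin_d_ug"] >= 10,
            "niacin": nut["niacin_eq_mg"] / mj >= 1.6,
            "thiamine": nut["thiamine_mg"] / mj >= 0.1,
            "carbohydrate_epct": (nut["carbohydrate_epct"] >= 45)
            & (nut["carbohydrate_epct"] <= 60),
            "fat_epct": (nut["fat_epct"] >= 30) & (nut["fat_epct"] <= 45),
            "protein_epct": (nut["protein_epct"] >= 7)
            & (nut["protein_epct"] <= 15),
            "omega3_infant": nut["omega3_epct"] >= 1.0,
            "omega6": nut["omega6_epct"] >= 4.0,
            "sfa": nut["sfa_epct"] < 10.0,
        }
        for rid, exp in expected.items():
            np.testing.assert_array_equal(
                v[rid].to_numpy(), exp.astype(float).to_numpy(), err_msg=rid
            )

    def test_age_relaxation_is_monotone(self, small_nutrients):
        """Moving from the infant to the 1-3 y variant never shrinks the
        set meeting omega-3 or staying within the sodium guideline."""
        infant = classify(small_nutrients, age_variant="infant_le_11m")
        toddler = classify(small_nutrients, age_variant="child_1_3y")
        o3_i = infant.verdicts["omega3_infant"]
        o3_t = toddler.verdicts["omega3_1_3y"]
        assert (o3_t >= o3_i).all()
        na_i = infant.verdicts["sodium_infant"]
        na_t = toddler.verdicts["sodium_1_3y"]
        assert (na_t >= na_i).all()


class TestSummarize:
    def test_everyone_meets_gives_proportion_one(self):
        nut = pd.DataFrame(
            {"selenium_ug": [25.0, 30.0], "energy_kcal": [800.0, 900.0]},
            index=["a", "b"],
        )
        s = summarize_adequacy(classify(nut)).set_index("rule_id")
        assert s.loc["selenium", "proportion_met"] == 1.0

    def test_half_below_vitamin_d(self):
        nut = pd.DataFrame(
            {"vitamin_d_ug": [5.0, 8.0, 12.0, 11.0], "energy_kcal": [800.0] * 4},
            index=list("abcd"),
        )
        s = summarize_adequacy(classify(nut)).set_index("rule_id")
        assert s.loc["vitamin_d", "proportion_not_met"] == 0.5

    def test_empty_cohort_gives_empty_summary(self):
        nut = pd.DataFrame(columns=["energy_kcal", "selenium_ug"])
        s = summarize_adequacy(classify(nut))
        assert (s["n_total"] == 0).all()

    def test_ordered_by_share_not_meeting(self, small_nutrients):
        s = summarize_adequacy(classify(small_nutrients))
        shares = s["proportion_not_met"].dropna()
        assert (shares.diff().dropna() <= 1e-12).all()
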