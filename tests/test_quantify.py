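"""FFQ answer -> grams/day quantification and food-group aggregation."""

import numpy as np
import pandas as pd
import pytest

from ffqpipe import (
    DEFAULT_FOOD_GROUPS,
    FoodGroupSchema,
    aggregate_groups,
    quantify_cohort,
    quantify_item,
)
from ffqpipe.instrument import DEFAULT_FREQUENCY_MAPPING

FREQ_LABELS = list(DEFAULT_FREQUENCY_MAPPING)


class TestQuantifyItem:
    def test_unanswered_question_is_exactly_zero(self, instrument, response_factory):
        r = response_factory()
        out = quantify_item(r, "egg", instrument)
        assert out == {"egg": (0.0, "coded_zero")}

    def test_bread_slices_follow_up(self, instrument, response_factory):
        # 1-2 times/week, 2 slices x 30 g: 1.5/7 * 60 = 12.857 g/day
        r = response_factory(
            answers={"bread": "1-2 times/week"},
            slices_answers={"fu_bread_slices": 2.0},
            type_answers={"fu_bread_type": ["white_bread"]},
        )
        out = quantify_item(r, "bread", instrument)
        assert out["white_bread"][0] == pytest.approx(1.5 / 7 * 60)
        assert out["wholegrain_bread"][0] == 0.0

    def test_portion_picture_lookup(self, instrument, response_factory):
        # 3-4 times/week with picture 3 (75 g) = 0.5 * 75 = 37.5 g/day
        r = response_factory(
            answers={"pasta": "3-4 times/week"}, portion_answers={"starch": 3}
        )
        assert quantify_item(r, "pasta", instrument)["pasta"][0] == pytest.approx(37.5)

    def test_dont_know_portion_falls_back_to_scale_median(
        self, instrument, response_factory
    ):
        r = response_factory(
            answers={"pasta": "1 time/day"},
            portion_answers={"starch": "do not know"},
        )
        assert quantify_item(r, "pasta", instrument)["pasta"][0] == pytest.approx(75.0)

    def test_amount_question(self, instrument, response_factory):
        r = response_factory(
            answers={"candy": "1-3 times/month"},
            amount_answers={"candy": "50 g"},
        )
        grams, prov = quantify_item(r, "candy", instrument)["candy"]
        assert grams == pytest.approx(2 / 30.44 * 50)
        assert prov == "amount_question"

    def test_type_split_divides_equally(self, instrument, response_factory):
        r = response_factory(
            answers={"yoghurt": "2 times/day"},
            type_answers={"fu_yoghurt_type": ["plain_yoghurt", "flavored_yoghurt"]},
        )
        out = quantify_item(r, "yoghurt", instrument)
        assert out["plain_yoghurt"][0] == pytest.approx(100.0)
        assert out["flavored_yoghurt"][0] == pytest.approx(100.0)
        assert out["plain_yoghurt"][1] == "follow_up_split"

    def test_unknown_question_raises(self, instrument, response_factory):
        with pytest.raises(KeyError, match="nonexistent"):
            quantify_item(response_factory(), "nonexistent", instrument)

    def test_independent_rate_times_portion_oracle(
        self, instrument, response_factory
    ):
        """grams/day equals an independently coded rate x portion product
        for every frequency category of a fixed-portion question."""
        for label in FREQ_LABELS:
            r = response_factory(answers={"water": label})
            expected = DEFAULT_FREQUENCY_MAPPING[label] * 200.0
            assert quantify_item(r, "water", instrument)["water"][0] == pytest.approx(
                expected
            )

    def test_calendar_simulation_oracle(self, instrument, response_factory):
        """A long simulated calendar of consumption days converges to the
        category-rate x portion value the quantifier reports."""
        rng = np.random.default_rng(42)
        n_days = 200_000
        for label in ("1-2 times/week", "1 time/day"):
            rate = DEFAULT_FREQUENCY_MAPPING[label]
            eaten = rng.random(n_days) < min(rate, 1.0)
            sim = eaten.sum() * 200.0 / n_days
            r = response_factory(answers={"water": label})
            got = quantify_item(r, "water", instrument)["water"][0]
            assert got == pytest.approx(sim, rel=0.02)

    def test_monotone_in_frequency_category(self, instrument, response_factory):
        """Raising the frequency category never decreases grams/day."""
        for qid in ("water", "pasta", "egg", "candy"):
            prev = -1.0
            for label in FREQ_LABELS:
                r = response_factory(
                    answers={qid: label},
                    portion_answers={"starch": 2},
                    amount_answers={"candy": "a few pieces"},
                )
                grams = sum(v for v, _ in quantify_item(r, qid, instrument).values())
                assert grams >= prev
                prev = grams


class TestQuantifyCohort:
    def test_matches_per_item_calls(self, instrument, small_cohort):
        rs = small_cohort.responses[:3]
        table = quantify_cohort(rs, instrument)
        for r in rs:
            for q in instrument.frequency_questions:
                for item, (grams, _) in quantify_item(
                    r, q.question_id, instrument
                ).items():
                    assert table.values.loc[r.child_id, item] == pytest.approx(grams)

    def test_silent_child_gives_all_zero_row(self, instrument, response_factory):
        table = quantify_cohort([response_factory()], instrument)
        assert (table.values.loc["X1"] == 0).all()

    def test_water_three_times_daily_hits_the_cap(
        self, instrument, response_factory
    ):
        r = response_factory(answers={"water": "3 times/day or more"})
        table = quantify_cohort([r], instrument)
        assert table.values.loc["X1", "water"] == pytest.approx(600.0)


class TestAggregateGroups:
    def test_group_is_sum_of_members(self, instrument, small_cohort):
        table = aggregate_groups(
            quantify_cohort(small_cohort.responses, instrument), DEFAULT_FOOD_GROUPS
        )
        for group, members in DEFAULT_FOOD_GROUPS.groups.items():
            np.testing.assert_allclose(
                table.values[group], table.values[members].sum(axis=1), rtol=1e-9
            )

    def test_seafood_additivity(self, instrument, response_factory):
        r = response_factory(
            answers={"fish": "1 time/day"},
            portion_answers={"protein": 1},
            type_answers={"fu_fish_type": ["lean_fish", "fatty_fish"]},
        )
        table = aggregate_groups(quantify_cohort([r], instrument), DEFAULT_FOOD_GROUPS)
        assert table.values.loc["X1", "total_seafood"] == pytest.approx(
            table.values.loc["X1", "lean_fish"]
            + table.values.loc["X1", "fatty_fish"]
        )

    def test_missing_member_names_group_and_member(self, instrument, response_factory):
        table = quantify_cohort([response_factory()], instrument)
        schema = FoodGroupSchema({"total_fish": ["lean_fish", "narwhal"]})
        with pytest.raises(ValueError, match="total_fish.*narwhal"):
            aggregate_groups(table, schema)

    def test_all_zero_members_give_zero_group(self, instrument, response_factory):
        table = aggregate_groups(
            quantify_cohort([response_factory()], instrument), DEFAULT_FOOD_GROUPS
        )
        assert (table.values.loc["X1", list(DEFAULT_FOOD_GROUPS.groups)] == 0).all()
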