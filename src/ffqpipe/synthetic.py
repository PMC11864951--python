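"""Synthetic one-year FFQ cohorts with the statistical structure the
analysis assumes.

The generator emulates the data a Nordic birth cohort would collect at the
one-year visit: a ~20-question semi-quantitative FFQ with portion pictures
and type follow-ups, parent-reported weight and height, family
characteristics, feeding-status marginals that drive the exclusion flow
(149 still breastfed / 10 unknown / 95 on formula / 18 unknown out of 523),
and a handful of planted covariate-diet effects for parameter-recovery
testing. Effects act on the ordinal frequency answer through a
cumulative-log-odds (proportional-odds) shift, so they pass through the
same measurement process the pipeline ingests. Items are otherwise
independent across questions; the truth record lists every planted effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import (
    DEFAULT_FREQUENCY_MAPPING,
    NUTRIENT_REGISTRY,
    FfqInstrument,
    FfqResponse,
    FoodCompositionTable,
    FrequencyCategory,
    FrequencyScale,
    PortionScale,
    PortionSource,
    Question,
    SUPPLEMENT_FREQUENCY_LABELS,
    default_frequency_scale,
)

logger = logging.getLogger("ffqpipe")

FREQ_LABELS = list(DEFAULT_FREQUENCY_MAPPING)  # ascending


# --------------------------------------------------------------------------
# Default instrument
# --------------------------------------------------------------------------


def build_default_instrument() -> FfqInstrument:
    """A 20-question instrument with three portion-picture scales,
    type/slices follow-ups, amount questions and a supplement section."""
    freq = default_frequency_scale("standard")
    supp = FrequencyScale(
        "supplement",
        [
            FrequencyCategory("1-3 times/month", 2.0 / 30.44),
            FrequencyCategory("once a week", 1.0 / 7.0),
            FrequencyCategory("a few times a week", 3.0 / 7.0),
            FrequencyCategory("daily", 1.0),
        ],
    )
    scales = {
        "starch": PortionScale("starch", [(1, 35), (2, 55), (3, 75), (4, 100), (5, 125)]),
        "protein": PortionScale("protein", [(1, 30), (2, 50), (3, 75), (4, 100), (5, 125)]),
        "vegetable": PortionScale("vegetable", [(1, 10), (2, 20), (3, 30), (4, 45), (5, 60)]),
    }

    def fq(qid, items, portion, follow_ups=()):
        return Question(
            question_id=qid, kind="frequency", food_items=list(items),
            frequency_scale="standard", portion=portion,
            follow_ups=list(follow_ups),
        )

    def split(qid, parent, options):
        return Question(
            question_id=qid, kind="type_split", parent=parent, options=list(options)
        )

    grams = lambda g: PortionSource(kind="grams", grams=g)
    scale = lambda s: PortionSource(kind="scale", scale_id=s)

    questions = [
        fq("water", ["water"], grams(200)),
        fq("cows_milk", ["cows_milk"], grams(150)),
        fq("soda", ["soda"], grams(200)),
        fq("juice", ["juice"], grams(150)),
        fq("gruel", ["gruel"], grams(225)),
        fq("porridge", ["powder_based_porridge", "oatmeal"], grams(130),
           ["fu_porridge_type"]),
        fq("yoghurt", ["plain_yoghurt", "flavored_yoghurt"], grams(100),
           ["fu_yoghurt_type"]),
        fq("pasta", ["pasta"], scale("starch")),
        fq("rice", ["rice"], scale("starch")),
        fq("potato", ["boiled_potato"], scale("starch")),
        fq("meat", ["minced_meat", "chicken", "sausage"], scale("protein"),
           ["fu_meat_type"]),
        fq("fish", ["lean_fish", "fatty_fish"], scale("protein"), ["fu_fish_type"]),
        fq("vegetables", ["carrot", "other_vegetables"], scale("vegetable"),
           ["fu_veg_type"]),
        fq("fruit", ["banana", "apple", "other_fruit"], grams(80), ["fu_fruit_type"]),
        fq("bread", ["white_bread", "wholegrain_bread"],
           PortionSource(kind="slices", follow_up="fu_bread_slices",
                         grams_per_unit=30.0),
           ["fu_bread_type", "fu_bread_slices"]),
        fq("egg", ["egg"], grams(25)),
        fq("liver_pate", ["liver_pate"], grams(5)),
        fq("buns_biscuits", ["buns_biscuits"], grams(15)),
        fq("candy", ["candy"],
           PortionSource(kind="amount",
                         options={"a few pieces": 10.0, "50 g": 50.0,
                                  "100 g or more": 100.0})),
        fq("ice_cream", ["ice_cream"],
           PortionSource(kind="amount",
                         options={"less than 1 scoop": 25.0, "1 scoop": 50.0,
                                  "2 scoops": 100.0, "3 scoops or more": 150.0})),
        split("fu_porridge_type", "porridge", ["powder_based_porridge", "oatmeal"]),
        split("fu_yoghurt_type", "yoghurt", ["plain_yoghurt", "flavored_yoghurt"]),
        split("fu_meat_type", "meat", ["minced_meat", "chicken", "sausage"]),
        split("fu_fish_type", "fish", ["lean_fish", "fatty_fish"]),
        split("fu_veg_type", "vegetables", ["carrot", "other_vegetables"]),
        split("fu_fruit_type", "fruit", ["banana", "apple", "other_fruit"]),
        split("fu_bread_type", "bread", ["white_bread", "wholegrain_bread"]),
        Question(question_id="fu_bread_slices", kind="slices", parent="bread"),
    ]
    return FfqInstrument(
        frequency_scales={"standard": freq, "supplement": supp},
        portion_scales=scales,
        questions={q.question_id: q for q in questions},
        supplement_types=["vitamin_d", "iron", "multivitamin", "omega_3"],
        supplement_scale="supplement",
    )


# --------------------------------------------------------------------------
# Default composition table
# --------------------------------------------------------------------------

# per-100 g values; energy is set from the Atwater factors 4/4/9.
_COMPOSITION: dict[str, dict[str, float]] = {
    "water": {},
    "cows_milk": {"protein_g": 3.4, "fat_g": 1.5, "carbohydrate_g": 4.9,
                  "sugars_g": 0.0, "sfa_g": 1.0, "trans_fa_g": 0.06,
                  "fa_4_10_g": 0.18, "fa_12_0_g": 0.06, "fa_14_0_g": 0.17,
                  "fa_18_2_g": 0.05, "fa_18_3_g": 0.01,
                  "calcium_mg": 120, "iodine_ug": 15, "vitamin_d_ug": 1.0,
                  "riboflavin_mg": 0.18, "vitamin_b12_ug": 0.5,
                  "potassium_mg": 150, "phosphorus_mg": 95, "zinc_mg": 0.4,
                  "selenium_ug": 1.5, "magnesium_mg": 11, "sodium_mg": 42,
                  "vitamin_a_ug": 15, "niacin_mg": 0.1},
    "soda": {"carbohydrate_g": 10.6, "sugars_g": 10.6},
    "juice": {"carbohydrate_g": 9.0, "sugars_g": 8.5, "vitamin_c_mg": 30,
              "potassium_mg": 150, "folate_ug": 15},
    "gruel": {"protein_g": 2.5, "fat_g": 1.5, "carbohydrate_g": 8.0,
              "fiber_g": 0.4, "salt_g": 0.1, "iron_mg": 1.2,
              "vitamin_d_ug": 1.0, "thiamine_mg": 0.1, "zinc_mg": 0.5,
              "calcium_mg": 90, "iodine_ug": 10, "folate_ug": 15,
              "magnesium_mg": 15, "potassium_mg": 160, "sodium_mg": 40,
              "sfa_g": 0.4, "fa_18_2_g": 0.3, "fa_18_3_g": 0.05,
              "vitamin_e_mg": 0.8, "niacin_mg": 0.8, "riboflavin_mg": 0.15,
              "vitamin_b6_mg": 0.08, "phosphorus_mg": 80, "selenium_ug": 1.5,
              "vitamin_a_ug": 40, "vitamin_c_mg": 8},
    "powder_based_porridge": {
        "protein_g": 2.8, "fat_g": 2.0, "carbohydrate_g": 12.0, "fiber_g": 1.0,
        "salt_g": 0.13, "iron_mg": 1.7, "vitamin_d_ug": 1.2, "thiamine_mg": 0.12,
        "zinc_mg": 0.6, "iodine_ug": 12, "folate_ug": 20, "calcium_mg": 80,
        "magnesium_mg": 20, "potassium_mg": 180, "sodium_mg": 50,
        "sfa_g": 0.5, "fa_18_2_g": 0.8, "fa_18_3_g": 0.08, "vitamin_e_mg": 1.0,
        "niacin_mg": 1.0, "riboflavin_mg": 0.18, "vitamin_b6_mg": 0.1,
        "phosphorus_mg": 90, "selenium_ug": 2.0, "vitamin_a_ug": 60,
        "vitamin_c_mg": 10},
    "oatmeal": {"protein_g": 1.5, "fat_g": 0.8, "carbohydrate_g": 9.0,
                "fiber_g": 1.2, "salt_g": 0.2, "iron_mg": 0.6,
                "thiamine_mg": 0.06, "magnesium_mg": 30, "zinc_mg": 0.5,
                "selenium_ug": 1.0, "sodium_mg": 70, "fa_18_2_g": 0.3,
                "fa_18_3_g": 0.02, "sfa_g": 0.15, "vitamin_e_mg": 0.5,
                "niacin_mg": 0.3, "phosphorus_mg": 60, "folate_ug": 8,
                "potassium_mg": 70},
    "plain_yoghurt": {"protein_g": 3.7, "fat_g": 3.0, "carbohydrate_g": 5.0,
                      "sfa_g": 1.9, "trans_fa_g": 0.1, "fa_4_10_g": 0.35,
                      "fa_12_0_g": 0.11, "fa_14_0_g": 0.33,
                      "calcium_mg": 130, "iodine_ug": 17, "riboflavin_mg": 0.2,
                      "vitamin_b12_ug": 0.5, "potassium_mg": 160,
                      "phosphorus_mg": 100, "zinc_mg": 0.5, "selenium_ug": 1.6,
                      "magnesium_mg": 12, "sodium_mg": 45, "vitamin_a_ug": 28},
    "flavored_yoghurt": {"protein_g": 3.3, "fat_g": 2.5, "carbohydrate_g": 12.0,
                         "sugars_g": 8.0, "sfa_g": 1.6, "trans_fa_g": 0.08,
                         "fa_4_10_g": 0.3, "fa_12_0_g": 0.09, "fa_14_0_g": 0.28,
                         "calcium_mg": 120, "iodine_ug": 15,
                         "riboflavin_mg": 0.18, "vitamin_b12_ug": 0.4,
                         "potassium_mg": 150, "phosphorus_mg": 95,
                         "zinc_mg": 0.45, "selenium_ug": 1.5,
                         "magnesium_mg": 11, "sodium_mg": 45,
                         "vitamin_a_ug": 25},
    "pasta": {"protein_g": 5.0, "fat_g": 0.9, "carbohydrate_g": 28.0,
              "fiber_g": 1.8, "selenium_ug": 2.0, "magnesium_mg": 18,
              "iron_mg": 0.5, "folate_ug": 7, "zinc_mg": 0.7,
              "fa_18_2_g": 0.4, "fa_18_3_g": 0.02, "sfa_g": 0.2,
              "niacin_mg": 1.0, "thiamine_mg": 0.05, "phosphorus_mg": 55,
              "potassium_mg": 45},
    "rice": {"protein_g": 2.6, "fat_g": 0.3, "carbohydrate_g": 28.0,
             "fiber_g": 0.4, "selenium_ug": 3.0, "magnesium_mg": 12,
             "iron_mg": 0.2, "zinc_mg": 0.5, "niacin_mg": 0.4,
             "phosphorus_mg": 40, "potassium_mg": 35},
    "boiled_potato": {"protein_g": 1.8, "fat_g": 0.1, "carbohydrate_g": 17.0,
                      "fiber_g": 1.5, "potassium_mg": 380, "vitamin_c_mg": 12,
                      "magnesium_mg": 20, "iron_mg": 0.4, "folate_ug": 10,
                      "niacin_mg": 1.0, "vitamin_b6_mg": 0.25,
                      "phosphorus_mg": 45},
    "minced_meat": {"protein_g": 20.0, "fat_g": 15.0, "sfa_g": 6.0,
                    "trans_fa_g": 0.3, "fa_14_0_g": 0.4, "fa_18_2_g": 0.4,
                    "fa_18_3_g": 0.08, "fa_20_4_g": 0.03,
                    "iron_mg": 2.1, "zinc_mg": 4.2, "vitamin_b12_ug": 2.0,
                    "selenium_ug": 7.0, "sodium_mg": 300, "salt_g": 0.75,
                    "niacin_mg": 4.5, "vitamin_b6_mg": 0.3,
                    "phosphorus_mg": 180, "potassium_mg": 300,
                    "vitamin_d_ug": 0.3, "riboflavin_mg": 0.18},
    "chicken": {"protein_g": 22.0, "fat_g": 6.0, "sfa_g": 1.7,
                "fa_18_2_g": 1.0, "fa_18_3_g": 0.07, "fa_20_4_g": 0.05,
                "niacin_mg": 8.0, "vitamin_b6_mg": 0.4, "selenium_ug": 10.0,
                "phosphorus_mg": 200, "zinc_mg": 1.0, "potassium_mg": 280,
                "iron_mg": 0.7, "vitamin_b12_ug": 0.4, "magnesium_mg": 25,
                "sodium_mg": 70},
    "sausage": {"protein_g": 11.0, "fat_g": 20.0, "carbohydrate_g": 4.0,
                "sfa_g": 7.5, "trans_fa_g": 0.15, "fa_14_0_g": 0.3,
                "fa_18_2_g": 1.8, "fa_18_3_g": 0.15,
                "sodium_mg": 700, "salt_g": 1.8, "iron_mg": 1.2,
                "zinc_mg": 1.8, "vitamin_b12_ug": 0.8, "selenium_ug": 5.0,
                "niacin_mg": 2.5, "phosphorus_mg": 120, "potassium_mg": 200},
    "lean_fish": {"protein_g": 18.0, "fat_g": 0.7, "sfa_g": 0.15,
                  "fa_22_6_g": 0.15, "fa_20_5_g": 0.05, "fa_22_5_g": 0.02,
                  "iodine_ug": 130, "selenium_ug": 25, "vitamin_b12_ug": 1.0,
                  "vitamin_d_ug": 1.5, "phosphorus_mg": 200, "zinc_mg": 0.45,
                  "niacin_mg": 2.0, "vitamin_b6_mg": 0.25, "sodium_mg": 90,
                  "potassium_mg": 350, "magnesium_mg": 25},
    "fatty_fish": {"protein_g": 18.0, "fat_g": 12.0, "sfa_g": 2.5,
                   "fa_22_6_g": 1.1, "fa_20_5_g": 0.7, "fa_22_5_g": 0.1,
                   "fa_18_3_g": 0.2, "vitamin_d_ug": 8.0, "selenium_ug": 30,
                   "iodine_ug": 40, "vitamin_b12_ug": 3.0, "niacin_mg": 6.0,
                   "vitamin_e_mg": 2.0, "phosphorus_mg": 240,
                   "potassium_mg": 380, "sodium_mg": 60, "vitamin_a_ug": 15},
    "carrot": {"protein_g": 0.7, "fat_g": 0.2, "carbohydrate_g": 7.0,
               "fiber_g": 2.7, "vitamin_a_ug": 835, "vitamin_c_mg": 6,
               "potassium_mg": 320, "vitamin_k_ug": 13, "folate_ug": 19,
               "magnesium_mg": 12},
    "other_vegetables": {"protein_g": 1.5, "fat_g": 0.3, "carbohydrate_g": 4.0,
                         "fiber_g": 2.0, "folate_ug": 50, "vitamin_c_mg": 25,
                         "vitamin_k_ug": 40, "vitamin_a_ug": 50,
                         "potassium_mg": 250, "magnesium_mg": 15,
                         "calcium_mg": 35, "iron_mg": 0.7,
                         "vitamin_e_mg": 0.5},
    "banana": {"protein_g": 1.1, "fat_g": 0.3, "carbohydrate_g": 20.0,
               "fiber_g": 2.6, "potassium_mg": 360, "vitamin_b6_mg": 0.37,
               "vitamin_c_mg": 9, "magnesium_mg": 27, "folate_ug": 20},
    "apple": {"protein_g": 0.3, "fat_g": 0.2, "carbohydrate_g": 12.0,
              "fiber_g": 2.0, "vitamin_c_mg": 5, "potassium_mg": 110,
              "folate_ug": 3},
    "other_fruit": {"protein_g": 0.8, "fat_g": 0.3, "carbohydrate_g": 11.0,
                    "fiber_g": 2.0, "vitamin_c_mg": 30, "folate_ug": 20,
                    "potassium_mg": 180, "vitamin_a_ug": 30,
                    "magnesium_mg": 12},
    "white_bread": {"protein_g": 8.0, "fat_g": 3.0, "carbohydrate_g": 47.0,
                    "fiber_g": 3.0, "sodium_mg": 430, "salt_g": 1.1,
                    "selenium_ug": 5.0, "thiamine_mg": 0.25, "folate_ug": 30,
                    "iron_mg": 1.1, "niacin_mg": 1.5, "magnesium_mg": 25,
                    "fa_18_2_g": 1.2, "fa_18_3_g": 0.12, "sfa_g": 0.6,
                    "trans_fa_g": 0.02, "vitamin_e_mg": 0.3, "zinc_mg": 0.8,
                    "phosphorus_mg": 95, "potassium_mg": 120,
                    "calcium_mg": 40},
    "wholegrain_bread": {"protein_g": 9.0, "fat_g": 3.5, "carbohydrate_g": 40.0,
                         "fiber_g": 7.0, "iron_mg": 2.3, "zinc_mg": 1.7,
                         "magnesium_mg": 70, "selenium_ug": 6.0,
                         "thiamine_mg": 0.3, "folate_ug": 40,
                         "sodium_mg": 400, "salt_g": 1.0, "fa_18_2_g": 1.4,
                         "fa_18_3_g": 0.15, "sfa_g": 0.7, "niacin_mg": 3.0,
                         "vitamin_e_mg": 0.8, "phosphorus_mg": 190,
                         "potassium_mg": 230, "calcium_mg": 55},
    "egg": {"protein_g": 12.6, "fat_g": 9.5, "carbohydrate_g": 0.7,
            "sfa_g": 3.1, "fa_18_2_g": 1.4, "fa_18_3_g": 0.05,
            "fa_20_4_g": 0.08, "fa_22_6_g": 0.04,
            "vitamin_d_ug": 2.9, "vitamin_b12_ug": 1.1, "selenium_ug": 23,
            "vitamin_a_ug": 160, "riboflavin_mg": 0.46, "folate_ug": 47,
            "iodine_ug": 27, "iron_mg": 1.8, "vitamin_e_mg": 1.0,
            "phosphorus_mg": 180, "zinc_mg": 1.3, "sodium_mg": 130,
            "potassium_mg": 130, "vitamin_k_ug": 0.3},
    "liver_pate": {"protein_g": 11.0, "fat_g": 22.0, "carbohydrate_g": 3.0,
                   "sfa_g": 8.0, "trans_fa_g": 0.2, "fa_18_2_g": 2.0,
                   "fa_18_3_g": 0.2, "fa_20_4_g": 0.1,
                   "vitamin_a_ug": 6600, "iron_mg": 5.5, "vitamin_b12_ug": 6.0,
                   "folate_ug": 120, "sodium_mg": 700, "salt_g": 1.8,
                   "selenium_ug": 20, "zinc_mg": 2.3, "riboflavin_mg": 1.0,
                   "niacin_mg": 5.0, "vitamin_d_ug": 0.6,
                   "phosphorus_mg": 200, "vitamin_k_ug": 5},
    "buns_biscuits": {"protein_g": 6.0, "fat_g": 18.0, "carbohydrate_g": 58.0,
                      "fiber_g": 2.0, "sugars_g": 20.0, "trans_fa_g": 0.6,
                      "sfa_g": 8.0, "fa_14_0_g": 0.5, "fa_18_2_g": 2.5,
                      "fa_18_3_g": 0.2, "sodium_mg": 300, "salt_g": 0.75,
                      "vitamin_e_mg": 1.5, "iron_mg": 1.2, "thiamine_mg": 0.1,
                      "selenium_ug": 3.0, "calcium_mg": 50, "zinc_mg": 0.6,
                      "phosphorus_mg": 95, "potassium_mg": 130,
                      "magnesium_mg": 20, "folate_ug": 15},
    "candy": {"protein_g": 3.0, "fat_g": 20.0, "carbohydrate_g": 65.0,
              "sugars_g": 55.0, "sfa_g": 12.0, "trans_fa_g": 0.3,
              "fa_14_0_g": 0.4, "sodium_mg": 60, "calcium_mg": 90},
    "ice_cream": {"protein_g": 3.5, "fat_g": 9.0, "carbohydrate_g": 22.0,
                  "sugars_g": 18.0, "sfa_g": 6.0, "trans_fa_g": 0.15,
                  "fa_14_0_g": 0.9, "fa_4_10_g": 0.5, "fa_12_0_g": 0.3,
                  "calcium_mg": 110, "vitamin_a_ug": 90, "sodium_mg": 55,
                  "potassium_mg": 150, "phosphorus_mg": 90,
                  "riboflavin_mg": 0.2},
}


def default_composition_table() -> FoodCompositionTable:
    """Composition table for the default instrument's 29 food items; energy
    equals the Atwater-factor sum 4*protein + 4*carbohydrate + 9*fat."""
    rows = {}
    for item, vals in _COMPOSITION.items():
        row = {nid: 0.0 for nid in NUTRIENT_REGISTRY}
        row.update(vals)
        row["energy_kcal"] = (
            4.0 * row["protein_g"] + 4.0 * row["carbohydrate_g"] + 9.0 * row["fat_g"]
        )
        row["niacin_eq_mg"] = row["niacin_mg"] + row["protein_g"] * 11.0 / 60.0
        rows[item] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "food_item"
    return FoodCompositionTable(table[list(NUTRIENT_REGISTRY)])


def generate_composition_fixture(
    n_items: int, seed: int = 0
) -> FoodCompositionTable:
    """The default items padded with random filler rows up to ``n_items``.

    Filler nutrients are drawn from broad plausible ranges; energy is the
    Atwater sum perturbed by at most +-8% so the unit-audit invariant holds
    by construction.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    base = default_composition_table().table
    if n_items <= len(base):
        return FoodCompositionTable(base.iloc[:n_items].copy())
    rng = np.random.default_rng(seed)
    rows = {}
    for k in range(n_items - len(base)):
        p = rng.uniform(0, 15)
        f = rng.uniform(0, 20)
        c = rng.uniform(0, 50)
        row = {nid: 0.0 for nid in NUTRIENT_REGISTRY}
        row.update(
            protein_g=p, fat_g=f, carbohydrate_g=c,
            fiber_g=rng.uniform(0, 5), salt_g=rng.uniform(0, 1.5),
            sfa_g=f * rng.uniform(0.1, 0.5), trans_fa_g=f * rng.uniform(0, 0.02),
            fa_18_2_g=f * rng.uniform(0.02, 0.2), fa_18_3_g=f * rng.uniform(0, 0.05),
            iron_mg=rng.uniform(0, 3), zinc_mg=rng.uniform(0, 3),
            selenium_ug=rng.uniform(0, 20), iodine_ug=rng.uniform(0, 40),
            calcium_mg=rng.uniform(0, 200), sodium_mg=rng.uniform(0, 600),
            potassium_mg=rng.uniform(20, 400), magnesium_mg=rng.uniform(2, 60),
            phosphorus_mg=rng.uniform(10, 250), folate_ug=rng.uniform(0, 80),
            vitamin_c_mg=rng.uniform(0, 40), vitamin_d_ug=rng.uniform(0, 3),
            vitamin_a_ug=rng.uniform(0, 300), vitamin_e_mg=rng.uniform(0, 2),
            vitamin_k_ug=rng.uniform(0, 30), thiamine_mg=rng.uniform(0, 0.3),
            riboflavin_mg=rng.uniform(0, 0.4), niacin_mg=rng.uniform(0, 5),
            vitamin_b6_mg=rng.uniform(0, 0.4), vitamin_b12_ug=rng.uniform(0, 2),
        )
        row["energy_kcal"] = (4 * p + 4 * c + 9 * f) * rng.uniform(0.92, 1.08)
        row["niacin_eq_mg"] = row["niacin_mg"] + p * 11.0 / 60.0
        rows[f"item_{k + 1:03d}"] = row
    extra = pd.DataFrame.from_dict(rows, orient="index")[list(NUTRIENT_REGISTRY)]
    table = pd.concat([base, extra])
    table.index.name = "food_item"
    return FoodCompositionTable(table)


# --------------------------------------------------------------------------
# Cohort configuration
# --------------------------------------------------------------------------

#: baseline probabilities over [no answer] + the 7 frequency categories
DEFAULT_FREQUENCY_PROBS: dict[str, list[float]] = {
    "water":         [0.02, 0.00, 0.01, 0.02, 0.05, 0.15, 0.25, 0.50],
    "cows_milk":     [0.51, 0.16, 0.10, 0.05, 0.03, 0.10, 0.03, 0.02],
    "soda":          [0.890, 0.060, 0.030, 0.010, 0.005, 0.003, 0.001, 0.001],
    "juice":         [0.850, 0.080, 0.040, 0.015, 0.005, 0.005, 0.003, 0.002],
    "gruel":         [0.15, 0.03, 0.05, 0.07, 0.10, 0.25, 0.25, 0.10],
    "porridge":      [0.08, 0.04, 0.08, 0.12, 0.15, 0.32, 0.16, 0.05],
    "yoghurt":       [0.40, 0.15, 0.20, 0.10, 0.05, 0.07, 0.02, 0.01],
    "pasta":         [0.05, 0.08, 0.25, 0.40, 0.12, 0.07, 0.02, 0.01],
    "rice":          [0.15, 0.25, 0.40, 0.14, 0.03, 0.02, 0.007, 0.003],
    "potato":        [0.06, 0.10, 0.25, 0.35, 0.14, 0.08, 0.015, 0.005],
    "meat":          [0.03, 0.03, 0.08, 0.15, 0.20, 0.30, 0.15, 0.06],
    "fish":          [0.08, 0.18, 0.49, 0.21, 0.02, 0.01, 0.007, 0.003],
    "vegetables":    [0.06, 0.08, 0.15, 0.18, 0.15, 0.20, 0.12, 0.06],
    "fruit":         [0.05, 0.03, 0.05, 0.07, 0.08, 0.27, 0.28, 0.17],
    "bread":         [0.10, 0.10, 0.20, 0.20, 0.15, 0.18, 0.05, 0.02],
    "egg":           [0.25, 0.25, 0.30, 0.12, 0.04, 0.03, 0.007, 0.003],
    "liver_pate":    [0.55, 0.14, 0.15, 0.08, 0.04, 0.03, 0.007, 0.003],
    "buns_biscuits": [0.63, 0.20, 0.10, 0.04, 0.02, 0.007, 0.002, 0.001],
    "candy":         [0.950, 0.038, 0.008, 0.002, 0.001, 0.001, 0.0, 0.0],
    "ice_cream":     [0.930, 0.050, 0.015, 0.003, 0.001, 0.001, 0.0, 0.0],
}

_TYPE_CHOICES = {  # fu id -> (subsets, probabilities)
    "fu_porridge_type": ([["powder_based_porridge"], ["oatmeal"],
                          ["powder_based_porridge", "oatmeal"]], [0.55, 0.25, 0.20]),
    "fu_yoghurt_type": ([["plain_yoghurt"], ["flavored_yoghurt"],
                         ["plain_yoghurt", "flavored_yoghurt"]], [0.40, 0.35, 0.25]),
    "fu_meat_type": ([["minced_meat"], ["minced_meat", "chicken"],
                      ["minced_meat", "chicken", "sausage"], ["chicken"],
                      ["sausage"]], [0.20, 0.25, 0.35, 0.12, 0.08]),
    "fu_fish_type": ([["lean_fish"], ["fatty_fish"],
                      ["lean_fish", "fatty_fish"]], [0.45, 0.25, 0.30]),
    "fu_veg_type": ([["carrot"], ["other_vegetables"],
                     ["carrot", "other_vegetables"]], [0.30, 0.30, 0.40]),
    "fu_fruit_type": ([["banana"], ["apple"], ["banana", "apple"],
                       ["banana", "apple", "other_fruit"]],
                      [0.25, 0.20, 0.35, 0.20]),
    "fu_bread_type": ([["white_bread"], ["wholegrain_bread"],
                       ["white_bread", "wholegrain_bread"]], [0.60, 0.25, 0.15]),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A covariate shifting a question's frequency distribution.

    ``beta`` is the cumulative-log-odds shift toward higher categories per
    unit of the covariate (covariate values capped at ``cap`` so a very
    large sibship does not explode the shift).
    """

    covariate: str
    question: str
    beta: float
    cap: float = 2.0

    def exposure(self, value: float) -> float:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return 0.0
        return float(min(value, self.cap))


DEFAULT_PLANTED_EFFECTS = (
    PlantedEffect("maternal_smoking_before_pregnancy", "soda", 3.0, cap=1.0),
    PlantedEffect("maternal_smoking_before_pregnancy", "juice", 3.0, cap=1.0),
    PlantedEffect("n_siblings", "buns_biscuits", 1.5),
    PlantedEffect("n_siblings", "cows_milk", 1.2),
)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the generator.

    Defaults follow the one-year cohort this package models: 523 eligible
    children; 149 still breastfed, 10 with unknown breastfeeding duration,
    95 on formula and 18 with unknown formula status (leaving 251 with diet
    as the sole energy source); weight ~ N(10.43, 1.17) kg for boys and
    N(9.70, 1.13) for girls; height ~ N(0.77, 0.04) / N(0.75, 0.03) m.
    """

    n_children: int = 523
    seed: int = 0
    feeding_marginals: tuple[int, int, int, int] = (149, 10, 95, 18)
    weight_mean: dict[str, float] = field(
        default_factory=lambda: {"boy": 10.43, "girl": 9.70}
    )
    weight_sd: dict[str, float] = field(
        default_factory=lambda: {"boy": 1.17, "girl": 1.13}
    )
    height_mean: dict[str, float] = field(
        default_factory=lambda: {"boy": 0.77, "girl": 0.75}
    )
    height_sd: dict[str, float] = field(
        default_factory=lambda: {"boy": 0.04, "girl": 0.03}
    )
    frequency_probs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FREQUENCY_PROBS.items()}
    )
    planted_effects: tuple[PlantedEffect, ...] = DEFAULT_PLANTED_EFFECTS
    smoking_prevalence: float = 0.08
    anthro_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if sum(self.feeding_marginals) > self.n_children:
            raise ValueError(
                f"feeding marginals {self.feeding_marginals} sum to more than "
                f"n_children={self.n_children}"
            )
        for q, p in self.frequency_probs.items():
            if len(p) != 8 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(
                    f"frequency probabilities for {q!r} must be 8 values "
                    "summing to 1"
                )


@dataclass
class SyntheticCohort:
    instrument: FfqInstrument
    responses: list[FfqResponse]
    anthropometry: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _shifted_probs(base: np.ndarray, shift: float) -> np.ndarray:
    """Proportional-odds shift of an ordinal distribution: the cumulative
    log-odds of being at or below each category drop by ``shift``."""
    if shift == 0.0:
        return base
    cum = np.cumsum(base)[:-1]
    with np.errstate(divide="ignore"):
        logit = np.log(cum) - np.log1p(-cum)
    shifted = 1.0 / (1.0 + np.exp(-(logit - shift)))
    probs = np.diff(np.concatenate([[0.0], shifted, [1.0]]))
    return np.clip(probs, 0.0, 1.0) / np.clip(probs, 0.0, 1.0).sum()


def _sample_supplements(rng: np.random.Generator) -> dict[str, str]:
    out: dict[str, str] = {}
    if rng.random() < 0.54:  # vitamin D is by far the most common
        out["vitamin_d"] = rng.choice(
            SUPPLEMENT_FREQUENCY_LABELS, p=[0.01, 0.02, 0.21, 0.76]
        )
    if rng.random() < 0.05:
        out["iron"] = rng.choice(SUPPLEMENT_FREQUENCY_LABELS, p=[0.1, 0.1, 0.2, 0.6])
    if rng.random() < 0.08:
        out["multivitamin"] = rng.choice(
            SUPPLEMENT_FREQUENCY_LABELS, p=[0.05, 0.1, 0.15, 0.7]
        )
    if rng.random() < 0.04:
        out["omega_3"] = rng.choice(
            SUPPLEMENT_FREQUENCY_LABELS, p=[0.17, 0.2, 0.43, 0.2]
        )
    return out


def generate(config: SyntheticCohortConfig | None = None) -> SyntheticCohort:
    """Generate a reproducible cohort; the seed fully determines the output."""
    cfg = config or SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_children
    instrument = build_default_instrument()
    ids = [f"C{i + 1:04d}" for i in range(n)]

    # --- feeding status driving the exclusion flow
    bf_yes, bf_unk, fo_yes, fo_unk = cfg.feeding_marginals
    breastfed = np.array(
        ["yes"] * bf_yes + ["unknown"] * bf_unk + ["no"] * (n - bf_yes - bf_unk)
    )
    formula = np.array(["no"] * n, dtype=object)
    # formula stages apply to the children passing the breastfeeding stages
    passed = np.arange(bf_yes + bf_unk, n)
    formula[passed[:fo_yes]] = "yes"
    formula[passed[fo_yes : fo_yes + fo_unk]] = "unknown"
    # children dropped at the breastfeeding stages get an arbitrary status
    formula[: bf_yes + bf_unk] = rng.choice(
        ["yes", "no", "unknown"], size=bf_yes + bf_unk, p=[0.3, 0.6, 0.1]
    )
    perm = rng.permutation(n)
    breastfed, formula = breastfed[perm], formula[perm]

    # --- anthropometry
    sex = np.where(rng.random(n) < 0.5, "boy", "girl")
    weight = np.empty(n)
    height = np.empty(n)
    for s in ("boy", "girl"):
        m = sex == s
        weight[m] = rng.normal(cfg.weight_mean[s], cfg.weight_sd[s], m.sum())
        height[m] = rng.normal(cfg.height_mean[s], cfg.height_sd[s], m.sum())
    weight = np.clip(weight, 7.0, 14.0)
    height = np.clip(height, 0.61, 1.05)
    w_missing = rng.random(n) < cfg.anthro_missing_rate
    h_missing = rng.random(n) < cfg.anthro_missing_rate
    anthro = pd.DataFrame(
        {
            "weight": np.where(w_missing, np.nan, np.round(weight, 2)),
            "height": np.where(h_missing, np.nan, np.round(height, 3)),
            "sex": sex,
        },
        index=pd.Index(ids, name="child_id"),
    )

    # --- family characteristics (codings low -> high)
    cov = pd.DataFrame(index=pd.Index(ids, name="child_id"))
    cov["maternal_age"] = np.round(np.clip(rng.normal(30.5, 4.2, n), 18, 45), 1)
    cov["maternal_education"] = rng.choice([0, 1, 2], size=n, p=[0.05, 0.25, 0.70])
    cov["maternal_bmi"] = np.round(np.clip(rng.normal(24.5, 4.0, n), 16, 45), 1)
    cov["n_siblings"] = rng.choice([0, 1, 2, 3], size=n, p=[0.49, 0.32, 0.13, 0.06])
    cov["maternal_income"] = rng.choice(
        np.arange(7), size=n, p=[0.02, 0.05, 0.08, 0.20, 0.30, 0.25, 0.10]
    )
    cov["paternal_income"] = rng.choice(
        np.arange(7), size=n, p=[0.02, 0.04, 0.06, 0.18, 0.28, 0.27, 0.15]
    )
    cov["swedish_nationality"] = (rng.random(n) < 0.92).astype(int)
    cov["allergic_heredity"] = (rng.random(n) < 0.64).astype(int)
    cov["pet_at_home"] = (rng.random(n) < 0.40).astype(int)
    cov["living_area"] = rng.choice([0, 1, 2, 3], size=n, p=[0.50, 0.30, 0.15, 0.05])
    cov["maternal_smoking_before_pregnancy"] = (
        rng.random(n) < cfg.smoking_prevalence
    ).astype(int)
    cov["child_sex"] = (sex == "boy").astype(int)
    # sporadic missingness so pairwise deletion is exercised
    for col, rate in (("maternal_income", 0.05), ("paternal_income", 0.07),
                      ("maternal_bmi", 0.03)):
        miss = rng.random(n) < rate
        cov[col] = cov[col].astype(float)
        cov.loc[miss, col] = np.nan

    # --- FFQ answers
    effects_by_q: dict[str, list[PlantedEffect]] = {}
    for e in cfg.planted_effects:
        effects_by_q.setdefault(e.question, []).append(e)
    ages = rng.integers(357, 401, size=n)
    responses: list[FfqResponse] = []
    for i in range(n):
        answers: dict[str, str] = {}
        portion_answers: dict[str, int | str] = {}
        amount_answers: dict[str, str] = {}
        type_answers: dict[str, list[str]] = {}
        slices_answers: dict[str, float] = {}
        for q in instrument.frequency_questions:
            base = np.asarray(cfg.frequency_probs[q.question_id])
            shift = sum(
                e.beta * e.exposure(cov.iloc[i][e.covariate])
                for e in effects_by_q.get(q.question_id, [])
            )
            probs = _shifted_probs(base, shift)
            cat = int(rng.choice(8, p=probs))
            if cat == 0:
                continue
            answers[q.question_id] = FREQ_LABELS[cat - 1]
            if q.portion.kind == "scale" and q.portion.scale_id not in portion_answers:
                if rng.random() < 0.05:
                    portion_answers[q.portion.scale_id] = "do not know"
                else:
                    portion_answers[q.portion.scale_id] = int(
                        np.clip(round(rng.normal(3.0, 1.0)), 1, 5)
                    )
            elif q.portion.kind == "amount":
                opts = list(q.portion.options)
                p = [0.75, 0.2, 0.05] if len(opts) == 3 else [0.35, 0.45, 0.15, 0.05]
                amount_answers[q.question_id] = str(rng.choice(opts, p=p))
            elif q.portion.kind == "slices":
                slices_answers[q.portion.follow_up] = float(
                    rng.choice([1.0, 2.0], p=[0.6, 0.4])
                )
            for fu in q.follow_ups:
                if fu in _TYPE_CHOICES:
                    subsets, pr = _TYPE_CHOICES[fu]
                    type_answers[fu] = list(subsets[rng.choice(len(subsets), p=pr)])
        responses.append(
            FfqResponse(
                child_id=ids[i],
                age_days=int(ages[i]),
                answers=answers,
                portion_answers=portion_answers,
                amount_answers=amount_answers,
                type_answers=type_answers,
                slices_answers=slices_answers,
                supplement_answers=_sample_supplements(rng),
                breastfed_beyond_10m=str(breastfed[i]),
                formula_beyond_10m=str(formula[i]),
            )
        )

    truth = {
        "seed": cfg.seed,
        "n_children": n,
        "feeding_marginals": list(cfg.feeding_marginals),
        "planted_effects": [
            {
                "covariate": e.covariate,
                "question": e.question,
                "beta": e.beta,
                "cap": e.cap,
                "direction": "positive" if e.beta > 0 else "negative",
            }
            for e in cfg.planted_effects
        ],
    }
    return SyntheticCohort(instrument, responses, anthro, cov, truth)
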