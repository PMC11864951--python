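"""Daily nutrient intakes from grams/day and a per-100 g composition table.

nutrient(child, n) = sum over food items of grams/day x amount(item, n)/100.
Derived columns follow the reporting conventions for this age group:
energy in MJ via 1 MJ = 239 kcal, energy-percentages (E%) from the Atwater
factors 4/4/9 kcal per g for protein/carbohydrate/fat (fatty-acid E% uses
the fat factor), omega-3 = ALA + EPA + DPA + DHA, omega-6 = LA + AA, and
nutrient densities per MJ for niacin equivalents and thiamine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import FoodCompositionTable
from .quantify import IntakeTable

logger = logging.getLogger("ffqpipe")

#: kcal per MJ.
KCAL_PER_MJ = 239.0

OMEGA3_COMPONENTS = ["fa_18_3_g", "fa_20_5_g", "fa_22_5_g", "fa_22_6_g"]
OMEGA6_COMPONENTS = ["fa_18_2_g", "fa_20_4_g"]


@dataclass(frozen=True)
class EnergyConversionFactors:
    """kcal per gram for the energy-yielding macronutrients."""

    protein: float = 4.0
    carbohydrate: float = 4.0
    fat: float = 9.0
    fiber: float = 0.0

    def __post_init__(self) -> None:
        if min(self.protein, self.carbohydrate, self.fat, self.fiber) < 0:
            raise ValueError("energy conversion factors must be >= 0")


def compute_nutrients(
    intakes: IntakeTable, composition: FoodCompositionTable
) -> pd.DataFrame:
    """Matrix-join intakes with the composition table.

    Group columns are excluded from the sum so member items are not counted
    twice. An unmapped item with any nonzero intake is an error; an unmapped
    item that nobody consumed is dropped with a warning.
    """
    item_cols = intakes.item_columns
    values = intakes.values[item_cols]
    mapped = [c for c in item_cols if c in composition.table.index]
    unmapped = [c for c in item_cols if c not in composition.table.index]
    bad = [c for c in unmapped if (values[c] != 0).any()]
    if bad:
        raise ValueError(
            f"food items with nonzero intake but no composition row: {bad}"
        )
    for c in unmapped:
        logger.warning("dropping unconsumed, unmapped item %r", c)
    comp = composition.table.loc[mapped]
    all_missing = [n for n in comp.columns if comp[n].isna().all()]
    for n in all_missing:
        logger.warning("nutrient column %r has no data; emitted as missing", n)
    filled = comp.fillna(0.0)
    out = values[mapped].to_numpy() @ (filled.to_numpy() / 100.0)
    nutrients = pd.DataFrame(out, index=values.index, columns=comp.columns)
    nutrients[all_missing] = np.nan
    nutrients["energy_mj"] = nutrients["energy_kcal"] / KCAL_PER_MJ
    return nutrients


def energy_percent(
    nutrients: pd.DataFrame,
    factors: EnergyConversionFactors = EnergyConversionFactors(),
) -> pd.DataFrame:
    """Append E% columns: grams x kcal/g / energy_kcal x 100.

    For children with zero (or missing) reported energy the E% columns are
    missing, with a warning — a share of nothing is undefined.
    """
    out = nutrients.copy()
    energy = out["energy_kcal"]
    zero = ~(energy > 0)
    if zero.any():
        logger.warning(
            "E%% undefined for %d children with zero reported energy",
            int(zero.sum()),
        )
    denom = energy.where(~zero)
    spec = {
        "protein_epct": ("protein_g", factors.protein),
        "fat_epct": ("fat_g", factors.fat),
        "carbohydrate_epct": ("carbohydrate_g", factors.carbohydrate),
        # fatty-acid shares use the fat factor
        "sfa_epct": ("sfa_g", factors.fat),
        "trans_epct": ("trans_fa_g", factors.fat),
        "omega3_epct": ("omega3_g", factors.fat),
        "omega6_epct": ("omega6_g", factors.fat),
    }
    for col, (src, factor) in spec.items():
        if src in out.columns:
            out[col] = out[src] * factor / denom * 100.0
    return out


def derive_fatty_acid_sums(nutrients: pd.DataFrame) -> pd.DataFrame:
    """Append omega-3 (ALA+EPA+DPA+DHA) and omega-6 (LA+AA) gram sums."""
    out = nutrients.copy()
    missing = [
        c for c in OMEGA3_COMPONENTS + OMEGA6_COMPONENTS if c not in out.columns
    ]
    if missing:
        raise ValueError(f"missing fatty-acid component columns: {missing}")
    out["omega3_g"] = out[OMEGA3_COMPONENTS].sum(axis=1)
    out["omega6_g"] = out[OMEGA6_COMPONENTS].sum(axis=1)
    return out


def derive_densities(nutrients: pd.DataFrame) -> pd.DataFrame:
    """Append per-MJ densities used by the adequacy cutoffs.

    Niacin equivalents are taken from the composition-derived column when
    present; otherwise NE = niacin mg + protein g / 60 x 1000 mg Trp ~
    niacin mg + protein g x 11/60 (tryptophan assumed 1.1% of protein).
    """
    out = nutrients.copy()
    mj = out["energy_mj"].where(out["energy_mj"] > 0)
    if "niacin_eq_mg" not in out.columns or out["niacin_eq_mg"].isna().all():
        if {"niacin_mg", "protein_g"}.issubset(out.columns):
            out["niacin_eq_mg"] = out["niacin_mg"] + out["protein_g"] * 11.0 / 60.0
    if "niacin_eq_mg" in out.columns:
        out["niacin_eq_per_mj"] = out["niacin_eq_mg"] / mj
    if "thiamine_mg" in out.columns:
        out["thiamine_mg_per_mj"] = out["thiamine_mg"] / mj
    return out


def full_nutrient_table(
    intakes: IntakeTable,
    composition: FoodCompositionTable,
    factors: EnergyConversionFactors = EnergyConversionFactors(),
) -> pd.DataFrame:
    """compute_nutrients + fatty-acid sums + E% + per-MJ densities."""
    nut = compute_nutrients(intakes, composition)
    nut = derive_fatty_acid_sums(nut)
    nut = energy_percent(nut, factors)
    nut = derive_densities(nut)
    return nut
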