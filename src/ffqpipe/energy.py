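"""Energy-requirement equations for one-year-old children.

Resting energy expenditure (REE) uses the Henry weight-and-height
equations, evaluated in MJ/day and converted to kcal/day with
1 MJ = 239 kcal:

    boys:  (0.118 * weight + 3.59 * height - 1.55) * 239
    girls: (0.127 * weight + 2.94 * height - 1.20) * 239

with weight in kg and height in metres. The average energy requirement
(AER) is a per-kilogram allowance converted from kJ with 1 kcal = 4.184 kJ:
337 kJ/kg (boys), 333 kJ/kg (girls). The food intake level (FIL) is the
ratio of reported energy intake to REE and gauges reporting plausibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("ffqpipe")

KCAL_PER_MJ = 239.0
KJ_PER_KCAL = 4.184

HENRY_COEFFICIENTS = {  # sex -> (weight, height, intercept), MJ/day
    "boy": (0.118, 3.59, -1.55),
    "girl": (0.127, 2.94, -1.20),
}

AER_KJ_PER_KG = {"boy": 337.0, "girl": 333.0}


@dataclass
class EnergyProfile:
    """Per-child energy intake (EI), REE, AER and FIL, NaN when undefined."""

    child_id: str
    EI: float
    REE: float
    AER: float
    FIL: float


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def ree_henry(weight: float, height: float, sex: str) -> float:
    """Resting energy expenditure in kcal/day; NaN on missing or
    non-positive input."""
    if sex not in HENRY_COEFFICIENTS:
        raise ValueError(f"sex must be 'boy' or 'girl', got {sex!r}")
    if _is_missing(weight) or _is_missing(height) or weight <= 0 or height <= 0:
        logger.warning("REE undefined for weight=%r height=%r", weight, height)
        return float("nan")
    a, b, c = HENRY_COEFFICIENTS[sex]
    return (a * weight + b * height + c) * KCAL_PER_MJ


def aer(weight: float, sex: str) -> float:
    """Average energy requirement in kcal/day; NaN on missing or
    non-positive weight."""
    if sex not in AER_KJ_PER_KG:
        raise ValueError(f"sex must be 'boy' or 'girl', got {sex!r}")
    if _is_missing(weight) or weight <= 0:
        logger.warning("AER undefined for weight=%r", weight)
        return float("nan")
    return AER_KJ_PER_KG[sex] * weight / KJ_PER_KCAL


def fil(EI: float, REE: float) -> float:
    """Food intake level EI/REE; NaN when REE is missing or non-positive."""
    if _is_missing(EI) or _is_missing(REE) or REE <= 0:
        return float("nan")
    return EI / REE


def energy_profiles(
    nutrients: pd.DataFrame, anthropometry: pd.DataFrame
) -> pd.DataFrame:
    """Per-child EI/REE/AER/FIL table, indexed by child_id.

    Children absent from the anthropometry table, or with missing weight or
    height, get missing REE/AER (and hence missing FIL).
    """
    out = pd.DataFrame(index=nutrients.index)
    out["EI"] = nutrients["energy_kcal"]
    ree_v, aer_v = [], []
    for cid in out.index:
        if cid in anthropometry.index:
            row = anthropometry.loc[cid]
            sex = row["sex"]
            if isinstance(sex, str) and sex in HENRY_COEFFICIENTS:
                w = float(row["weight"]) if not pd.isna(row["weight"]) else float("nan")
                h = float(row["height"]) if not pd.isna(row["height"]) else float("nan")
                ree_v.append(ree_henry(w, h, sex) if w > 0 and h > 0 else float("nan"))
                aer_v.append(aer(w, sex) if w > 0 else float("nan"))
                continue
        ree_v.append(float("nan"))
        aer_v.append(float("nan"))
    out["REE"] = ree_v
    out["AER"] = aer_v
    out["FIL"] = np.where(out["REE"] > 0, out["EI"] / out["REE"], np.nan)
    return out
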