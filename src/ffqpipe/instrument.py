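"""Typed model and I/O for the FFQ instrument and its companion tables.

The instrument is a semi-quantitative food frequency questionnaire for
one-year-old children: each top-level question records how often a food is
eaten (categories from roughly "1-3 times/month" up to "3 times/day or
more"), and portion size comes from one of several sources — a five-picture
portion scale, a categorical amount question (candy, ice cream), a
slices-per-occasion follow-up (bread), or a fixed per-item default gram
weight. Type follow-ups (e.g. plain vs flavored yoghurt) split a parent
question across food items.

This module also reads/writes the response table, the per-100 g food
composition table, and the family-characteristics and anthropometry tables,
enforcing the coding and range invariants the downstream statistics assume.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ffqpipe")

# --------------------------------------------------------------------------
# Frequency categories
# --------------------------------------------------------------------------

#: Average month length used to convert "times per month" to a daily rate.
MONTH_DAYS = 30.44

#: Default frequency-label -> occurrences/day mapping (category midpoints).
DEFAULT_FREQUENCY_MAPPING: dict[str, float] = {
    "1-3 times/month": 2.0 / MONTH_DAYS,
    "1-2 times/week": 1.5 / 7.0,
    "3-4 times/week": 3.5 / 7.0,
    "5-6 times/week": 5.5 / 7.0,
    "1 time/day": 1.0,
    "2 times/day": 2.0,
    "3 times/day or more": 3.0,
}

#: Supplement-use frequency labels, low to high.
SUPPLEMENT_FREQUENCY_LABELS = (
    "1-3 times/month",
    "once a week",
    "a few times a week",
    "daily",
)

DONT_KNOW = "do not know"


@dataclass(frozen=True)
class FrequencyCategory:
    """One answer option of a frequency scale."""

    label: str
    per_day: float

    def __post_init__(self) -> None:
        if self.per_day < 0:
            raise ValueError(
                f"frequency category {self.label!r}: occurrences/day must be >= 0"
            )


@dataclass
class FrequencyScale:
    """Ordered set of frequency categories, ascending by daily rate."""

    scale_id: str
    categories: list[FrequencyCategory]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            raise ValueError(f"frequency scale {self.scale_id!r}: duplicate labels")
        rates = [c.per_day for c in self.categories]
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError(
                f"frequency scale {self.scale_id!r}: categories must be ordered "
                "ascending by occurrences/day"
            )

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.categories]

    def per_day(self, label: str) -> float:
        for c in self.categories:
            if c.label == label:
                return c.per_day
        raise KeyError(
            f"unknown frequency label {label!r}; valid labels: {self.labels}"
        )


def default_frequency_scale(scale_id: str = "standard") -> FrequencyScale:
    cats = [FrequencyCategory(k, v) for k, v in DEFAULT_FREQUENCY_MAPPING.items()]
    return FrequencyScale(scale_id, cats)


# --------------------------------------------------------------------------
# Portion sources
# --------------------------------------------------------------------------

DONT_KNOW_POLICIES = ("median_choice", "zero", "impute_group_median")


@dataclass
class PortionScale:
    """Five-picture portion scale; each picture maps to a gram weight."""

    scale_id: str
    choices: list[tuple[int, float]]  # (picture_index 1..5, grams)
    dont_know_policy: str = "median_choice"

    def __post_init__(self) -> None:
        if len(self.choices) < 2:
            raise ValueError(f"portion scale {self.scale_id!r}: needs >= 2 choices")
        idx = [i for i, _ in self.choices]
        grams = [g for _, g in self.choices]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(
                f"portion scale {self.scale_id!r}: picture indices must be "
                "unique and ascending"
            )
        if any(g <= 0 for g in grams):
            raise ValueError(f"portion scale {self.scale_id!r}: grams must be > 0")
        if any(b <= a for a, b in zip(grams, grams[1:])):
            raise ValueError(
                f"portion scale {self.scale_id!r}: grams must be strictly "
                "increasing with picture index"
            )
        if self.dont_know_policy not in DONT_KNOW_POLICIES:
            raise ValueError(
                f"portion scale {self.scale_id!r}: unknown dont_know_policy "
                f"{self.dont_know_policy!r}"
            )

    def grams_for(self, picture_index: int) -> float:
        for i, g in self.choices:
            if i == picture_index:
                return g
        raise KeyError(
            f"portion scale {self.scale_id!r}: no picture {picture_index}"
        )

    def median_grams(self) -> float:
        grams = sorted(g for _, g in self.choices)
        n = len(grams)
        if n % 2:
            return grams[n // 2]
        return 0.5 * (grams[n // 2 - 1] + grams[n // 2])


# Portion-source descriptors attached to questions. Exactly one per
# frequency question.
@dataclass
class PortionSource:
    kind: str  # "scale" | "amount" | "slices" | "grams"
    scale_id: str | None = None          # kind == "scale"
    options: dict[str, float] | None = None  # kind == "amount": label -> grams
    follow_up: str | None = None         # kind == "slices": slices question id
    grams_per_unit: float | None = None  # kind == "slices"
    grams: float | None = None           # kind == "grams"

    def __post_init__(self) -> None:
        ok = {
            "scale": self.scale_id is not None,
            "amount": bool(self.options),
            "slices": self.follow_up is not None and self.grams_per_unit,
            "grams": self.grams is not None and self.grams >= 0,
        }
        if self.kind not in ok:
            raise ValueError(f"unknown portion source kind {self.kind!r}")
        if not ok[self.kind]:
            raise ValueError(f"portion source {self.kind!r}: missing fields")


@dataclass
class Question:
    """A top-level frequency question or a follow-up.

    kinds:
      frequency  — has a frequency scale and a portion source; covers one or
                   more food items (more than one only via a type_split
                   follow-up).
      type_split — follow-up listing which of the parent's food items were
                   eaten; the parent's grams/day are divided across them.
      slices     — follow-up giving units per occasion (e.g. bread slices).
    """

    question_id: str
    kind: str = "frequency"
    food_items: list[str] = field(default_factory=list)
    frequency_scale: str | None = None
    portion: PortionSource | None = None
    follow_ups: list[str] = field(default_factory=list)
    parent: str | None = None       # for follow-ups
    exclusive: bool = False          # type_split: single choice only
    options: list[str] | None = None  # type_split: selectable food items

    def __post_init__(self) -> None:
        if self.kind not in ("frequency", "type_split", "slices"):
            raise ValueError(f"question {self.question_id!r}: bad kind {self.kind!r}")
        if self.kind == "frequency":
            if self.frequency_scale is None or self.portion is None:
                raise ValueError(
                    f"question {self.question_id!r}: frequency questions need a "
                    "frequency scale and a portion source"
                )
            if not self.food_items:
                raise ValueError(
                    f"question {self.question_id!r}: no food items declared"
                )


@dataclass
class FfqInstrument:
    """The full questionnaire: scales, questions and supplement section."""

    frequency_scales: dict[str, FrequencyScale]
    portion_scales: dict[str, PortionScale]
    questions: dict[str, Question]
    supplement_types: list[str] = field(default_factory=list)
    supplement_scale: str | None = None

    def __post_init__(self) -> None:
        for q in self.questions.values():
            for fu in q.follow_ups:
                if fu not in self.questions:
                    raise ValueError(
                        f"question {q.question_id!r}: follow-up {fu!r} does not "
                        "reference an existing question"
                    )
            if q.kind == "frequency":
                if q.frequency_scale not in self.frequency_scales:
                    raise ValueError(
                        f"question {q.question_id!r}: unknown frequency scale "
                        f"{q.frequency_scale!r}"
                    )
                if q.portion.kind == "scale" and (
                    q.portion.scale_id not in self.portion_scales
                ):
                    raise ValueError(
                        f"question {q.question_id!r}: unknown portion scale "
                        f"{q.portion.scale_id!r}"
                    )
                if q.portion.kind == "slices" and (
                    q.portion.follow_up not in self.questions
                ):
                    raise ValueError(
                        f"question {q.question_id!r}: slices follow-up "
                        f"{q.portion.follow_up!r} does not exist"
                    )
            if q.kind in ("type_split", "slices") and q.parent is not None:
                if q.parent not in self.questions:
                    raise ValueError(
                        f"follow-up {q.question_id!r}: parent {q.parent!r} "
                        "does not exist"
                    )
        if self.supplement_scale is not None and (
            self.supplement_scale not in self.frequency_scales
        ):
            raise ValueError(
                f"unknown supplement frequency scale {self.supplement_scale!r}"
            )

    @property
    def frequency_questions(self) -> list[Question]:
        return [q for q in self.questions.values() if q.kind == "frequency"]

    @property
    def food_items(self) -> list[str]:
        items: list[str] = []
        for q in self.frequency_questions:
            for it in q.food_items:
                if it not in items:
                    items.append(it)
        return items

    def unmapped_items(self, composition: "FoodCompositionTable") -> list[str]:
        """Food items with no row in the composition table (warned, not fatal)."""
        missing = [i for i in self.food_items if i not in composition.items]
        for item in missing:
            logger.warning("food item %r has no composition row", item)
        return missing


# --------------------------------------------------------------------------
# Responses
# --------------------------------------------------------------------------

TRISTATE = ("yes", "no", "unknown")

#: Plausible age window (days) for a questionnaire nominally sent at 1 year.
AGE_DAYS_RANGE = (300, 450)


@dataclass
class FfqResponse:
    """One child's questionnaire answers.

    A question missing from ``answers`` means the parent skipped it, which
    the instrument defines as no consumption: downstream intake is exactly
    zero, never missing. Feeding status beyond 10 months is an explicit
    tristate; "unknown" is never silently coerced.
    """

    child_id: str
    age_days: int
    answers: dict[str, str] = field(default_factory=dict)
    portion_answers: dict[str, int | str] = field(default_factory=dict)
    amount_answers: dict[str, str] = field(default_factory=dict)
    type_answers: dict[str, list[str]] = field(default_factory=dict)
    slices_answers: dict[str, float] = field(default_factory=dict)
    supplement_answers: dict[str, str] = field(default_factory=dict)
    breastfed_beyond_10m: str = "unknown"
    formula_beyond_10m: str = "unknown"

    def __post_init__(self) -> None:
        if not (AGE_DAYS_RANGE[0] <= self.age_days <= AGE_DAYS_RANGE[1]):
            raise ValueError(
                f"child {self.child_id!r}: age_days {self.age_days} outside "
                f"plausible range {AGE_DAYS_RANGE}"
            )
        for name in ("breastfed_beyond_10m", "formula_beyond_10m"):
            v = getattr(self, name)
            if v not in TRISTATE:
                raise ValueError(
                    f"child {self.child_id!r}: {name} must be one of {TRISTATE}, "
                    f"got {v!r}"
                )


# --------------------------------------------------------------------------
# Nutrient registry and composition table
# --------------------------------------------------------------------------

#: canonical id -> (display name, unit). Units follow the reporting
#: convention for this age group: energy kcal, macronutrients g, trace
#: elements/vitamins mg or ug as listed.
NUTRIENT_REGISTRY: dict[str, tuple[str, str]] = {
    "energy_kcal": ("Energy", "kcal"),
    "protein_g": ("Protein", "g"),
    "fat_g": ("Fat", "g"),
    "carbohydrate_g": ("Carbohydrates", "g"),
    "fiber_g": ("Fiber", "g"),
    "salt_g": ("Salt", "g"),
    "sugars_g": ("Sugars", "g"),
    "sfa_g": ("Sum saturated fatty acids", "g"),
    "trans_fa_g": ("Sum trans fatty acids", "g"),
    "fa_4_10_g": ("Fatty acid 4:0-10:0", "g"),
    "fa_12_0_g": ("Fatty acid 12:0", "g"),
    "fa_14_0_g": ("Fatty acid 14:0", "g"),
    "fa_18_2_g": ("Fatty acid 18:2", "g"),
    "fa_20_4_g": ("Fatty acid 20:4", "g"),
    "fa_18_3_g": ("Fatty acid 18:3", "g"),
    "fa_20_5_g": ("EPA (Fatty acid 20:5)", "g"),
    "fa_22_5_g": ("DPA (Fatty acid 22:5)", "g"),
    "fa_22_6_g": ("DHA (Fatty acid 22:6)", "g"),
    "vitamin_a_ug": ("Vitamin A", "ug"),
    "vitamin_d_ug": ("Vitamin D", "ug"),
    "vitamin_e_mg": ("Vitamin E", "mg"),
    "vitamin_k_ug": ("Vitamin K", "ug"),
    "thiamine_mg": ("Thiamine", "mg"),
    "riboflavin_mg": ("Riboflavin", "mg"),
    "vitamin_c_mg": ("Vitamin C", "mg"),
    "niacin_mg": ("Niacin", "mg"),
    "niacin_eq_mg": ("Niacin equivalents", "mg"),
    "vitamin_b6_mg": ("Vitamin B6", "mg"),
    "vitamin_b12_ug": ("Vitamin B12", "ug"),
    "folate_ug": ("Folate", "ug"),
    "phosphorus_mg": ("Phosphorus", "mg"),
    "iodine_ug": ("Iodine", "ug"),
    "iron_mg": ("Iron", "mg"),
    "calcium_mg": ("Calcium", "mg"),
    "potassium_mg": ("Potassium", "mg"),
    "magnesium_mg": ("Magnesium", "mg"),
    "sodium_mg": ("Sodium", "mg"),
    "selenium_ug": ("Selenium", "ug"),
    "zinc_mg": ("Zinc", "mg"),
}

_DISPLAY_TO_ID = {name.lower(): nid for nid, (name, _) in NUTRIENT_REGISTRY.items()}

_HEADER_RE = re.compile(r"^(?P<name>.*\S)\s*\((?P<unit>[^)]+)\)\s*$")


def nutrient_header(nutrient_id: str) -> str:
    name, unit = NUTRIENT_REGISTRY[nutrient_id]
    return f"{name} ({unit})"


def parse_nutrient_header(header: str) -> str:
    """Map a unit-annotated column header to a canonical nutrient id.

    Raises on an unknown nutrient name or a unit that contradicts the
    registry (e.g. "Iron (g)" when iron is registered in mg).
    """
    m = _HEADER_RE.match(header)
    if not m:
        raise ValueError(
            f"composition column {header!r} lacks a unit annotation "
            "(expected 'Name (unit)')"
        )
    name = m.group("name").strip().lower()
    unit = m.group("unit").strip().replace("μ", "u")
    nid = _DISPLAY_TO_ID.get(name)
    if nid is None:
        raise ValueError(f"unknown nutrient column {header!r}")
    expected = NUTRIENT_REGISTRY[nid][1]
    if unit.lower() != expected.lower():
        raise ValueError(
            f"nutrient column {header!r}: unit {unit!r} does not match the "
            f"registered unit {expected!r}"
        )
    return nid


@dataclass
class FoodCompositionTable:
    """Nutrient amounts per 100 g edible food, canonical columns."""

    table: pd.DataFrame  # index: food_item, columns: nutrient ids

    def __post_init__(self) -> None:
        if "energy_kcal" not in self.table.columns:
            raise ValueError("composition table: energy column is required")
        neg = self.table[self.table.lt(0).any(axis=1)]
        if not neg.empty:
            raise ValueError(
                "composition table: negative amounts in rows "
                f"{list(neg.index)}"
            )
        if self.table["energy_kcal"].isna().any():
            raise ValueError("composition table: energy missing for some items")

    @property
    def items(self) -> list[str]:
        return list(self.table.index)

    @property
    def nutrients(self) -> list[str]:
        return list(self.table.columns)


# --------------------------------------------------------------------------
# Instrument JSON I/O
# --------------------------------------------------------------------------


def _portion_to_json(p: PortionSource) -> dict:
    d = {"kind": p.kind}
    if p.kind == "scale":
        d["scale_id"] = p.scale_id
    elif p.kind == "amount":
        d["options"] = p.options
    elif p.kind == "slices":
        d["follow_up"] = p.follow_up
        d["grams_per_unit"] = p.grams_per_unit
    elif p.kind == "grams":
        d["grams"] = p.grams
    return d


def _portion_from_json(d: Mapping) -> PortionSource:
    return PortionSource(
        kind=d["kind"],
        scale_id=d.get("scale_id"),
        options=dict(d["options"]) if d.get("options") else None,
        follow_up=d.get("follow_up"),
        grams_per_unit=d.get("grams_per_unit"),
        grams=d.get("grams"),
    )


def instrument_to_dict(inst: FfqInstrument) -> dict:
    return {
        "frequency_scales": {
            sid: [{"label": c.label, "per_day": c.per_day} for c in s.categories]
            for sid, s in inst.frequency_scales.items()
        },
        "portion_scales": {
            sid: {
                "choices": [list(c) for c in s.choices],
                "dont_know_policy": s.dont_know_policy,
            }
            for sid, s in inst.portion_scales.items()
        },
        "questions": [
            {
                "question_id": q.question_id,
                "kind": q.kind,
                "food_items": q.food_items,
                "frequency_scale": q.frequency_scale,
                "portion": _portion_to_json(q.portion) if q.portion else None,
                "follow_ups": q.follow_ups,
                "parent": q.parent,
                "exclusive": q.exclusive,
                "options": q.options,
            }
            for q in inst.questions.values()
        ],
        "supplement_types": inst.supplement_types,
        "supplement_scale": inst.supplement_scale,
    }


def instrument_from_dict(data: Mapping) -> FfqInstrument:
    try:
        freq = {
            sid: FrequencyScale(
                sid, [FrequencyCategory(c["label"], c["per_day"]) for c in cats]
            )
            for sid, cats in data["frequency_scales"].items()
        }
        portions = {
            sid: PortionScale(
                sid,
                [(int(i), float(g)) for i, g in s["choices"]],
                s.get("dont_know_policy", "median_choice"),
            )
            for sid, s in data["portion_scales"].items()
        }
        questions: dict[str, Question] = {}
        for qd in data["questions"]:
            q = Question(
                question_id=qd["question_id"],
                kind=qd.get("kind", "frequency"),
                food_items=list(qd.get("food_items") or []),
                frequency_scale=qd.get("frequency_scale"),
                portion=_portion_from_json(qd["portion"]) if qd.get("portion") else None,
                follow_ups=list(qd.get("follow_ups") or []),
                parent=qd.get("parent"),
                exclusive=bool(qd.get("exclusive", False)),
                options=list(qd["options"]) if qd.get("options") else None,
            )
            questions[q.question_id] = q
        return FfqInstrument(
            frequency_scales=freq,
            portion_scales=portions,
            questions=questions,
            supplement_types=list(data.get("supplement_types") or []),
            supplement_scale=data.get("supplement_scale"),
        )
    except KeyError as exc:
        raise ValueError(f"instrument schema violation: missing field {exc}") from exc


def read_instrument(path: str | Path) -> FfqInstrument:
    """Read an instrument definition from JSON, validating all invariants."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return instrument_from_dict(data)


def write_instrument(inst: FfqInstrument, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(instrument_to_dict(inst), fh, indent=1, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# Response table I/O
# --------------------------------------------------------------------------
#
# CSV layout: child_id, age_days, breastfed_beyond_10m, formula_beyond_10m,
# one column per frequency question id (label or blank), "portion:<scale>"
# columns (picture index or "do not know"), "amount:<qid>", "types:<fu id>"
# (pipe-separated food items), "slices:<fu id>", "supp:<type>".


def _sniff_reader(path: str | Path):
    with open(path, encoding="utf-8", newline="") as fh:
        text = fh.read()
    if not text.strip():
        return None, text
    delim = "\t" if text.splitlines()[0].count("\t") >= text.splitlines()[0].count(",") else ","
    return csv.DictReader(io.StringIO(text), delimiter=delim), text


def responses_to_frame(
    responses: Sequence[FfqResponse], instrument: FfqInstrument
) -> pd.DataFrame:
    """Flatten responses into the canonical CSV layout (stable column order)."""
    cols = ["child_id", "age_days", "breastfed_beyond_10m", "formula_beyond_10m"]
    qcols = [q.question_id for q in instrument.frequency_questions]
    scale_cols = sorted({f"portion:{s}" for s in instrument.portion_scales})
    amount_cols = [
        f"amount:{q.question_id}"
        for q in instrument.frequency_questions
        if q.portion.kind == "amount"
    ]
    type_cols = [
        f"types:{q.question_id}"
        for q in instrument.questions.values()
        if q.kind == "type_split"
    ]
    slice_cols = [
        f"slices:{q.question_id}"
        for q in instrument.questions.values()
        if q.kind == "slices"
    ]
    supp_cols = [f"supp:{t}" for t in instrument.supplement_types]
    rows = []
    for r in responses:
        row: dict[str, object] = {
            "child_id": r.child_id,
            "age_days": r.age_days,
            "breastfed_beyond_10m": r.breastfed_beyond_10m,
            "formula_beyond_10m": r.formula_beyond_10m,
        }
        for q in qcols:
            row[q] = r.answers.get(q, "")
        for c in scale_cols:
            row[c] = r.portion_answers.get(c.split(":", 1)[1], "")
        for c in amount_cols:
            row[c] = r.amount_answers.get(c.split(":", 1)[1], "")
        for c in type_cols:
            row[c] = "|".join(r.type_answers.get(c.split(":", 1)[1], []))
        for c in slice_cols:
            v = r.slices_answers.get(c.split(":", 1)[1])
            row[c] = "" if v is None else v
        for c in supp_cols:
            row[c] = r.supplement_answers.get(c.split(":", 1)[1], "")
        rows.append(row)
    frame = pd.DataFrame(
        rows, columns=cols + qcols + scale_cols + amount_cols + type_cols
        + slice_cols + supp_cols
    )
    return frame


def responses_from_frame(
    frame: pd.DataFrame, instrument: FfqInstrument
) -> list[FfqResponse]:
    qids = {q.question_id for q in instrument.frequency_questions}
    missing = qids - set(frame.columns)
    if missing:
        raise ValueError(
            f"response table lacks columns for questions: {sorted(missing)}"
        )
    seen: set[str] = set()
    out: list[FfqResponse] = []
    for _, row in frame.iterrows():
        cid = str(row["child_id"])
        if cid in seen:
            raise ValueError(f"duplicate child_id {cid!r}")
        seen.add(cid)
        answers: dict[str, str] = {}
        for q in instrument.frequency_questions:
            label = row.get(q.question_id)
            if label is None or (isinstance(label, float) and math.isnan(label)):
                continue
            label = str(label).strip()
            if not label:
                continue
            scale = instrument.frequency_scales[q.frequency_scale]
            if label not in scale.labels:
                raise ValueError(
                    f"child {cid!r}, question {q.question_id!r}: unknown "
                    f"frequency label {label!r}; valid labels: {scale.labels}"
                )
            answers[q.question_id] = label
        portion_answers: dict[str, int | str] = {}
        amount_answers: dict[str, str] = {}
        type_answers: dict[str, list[str]] = {}
        slices_answers: dict[str, float] = {}
        supplement_answers: dict[str, str] = {}
        for col in frame.columns:
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            sval = str(raw).strip()
            if not sval:
                continue
            if col.startswith("portion:"):
                key = col.split(":", 1)[1]
                portion_answers[key] = (
                    sval if sval == DONT_KNOW else int(float(sval))
                )
            elif col.startswith("amount:"):
                amount_answers[col.split(":", 1)[1]] = sval
            elif col.startswith("types:"):
                type_answers[col.split(":", 1)[1]] = [
                    t for t in sval.split("|") if t
                ]
            elif col.startswith("slices:"):
                slices_answers[col.split(":", 1)[1]] = float(sval)
            elif col.startswith("supp:"):
                supplement_answers[col.split(":", 1)[1]] = sval
        out.append(
            FfqResponse(
                child_id=cid,
                age_days=int(row["age_days"]),
                answers=answers,
                portion_answers=portion_answers,
                amount_answers=amount_answers,
                type_answers=type_answers,
                slices_answers=slices_answers,
                supplement_answers=supplement_answers,
                breastfed_beyond_10m=str(row["breastfed_beyond_10m"]).strip(),
                formula_beyond_10m=str(row["formula_beyond_10m"]).strip(),
            )
        )
    return out


def read_responses(
    path: str | Path, instrument: FfqInstrument
) -> list[FfqResponse]:
    """Read per-child FFQ responses. Blank frequency cells are stored as an
    absent answer (no consumption), never as missing data."""
    reader, text = _sniff_reader(path)
    if reader is None:
        logger.warning("response file %s is empty", path)
        return []
    delim = "\t" if text.splitlines()[0].count("\t") >= text.splitlines()[0].count(",") else ","
    frame = pd.read_csv(io.StringIO(text), sep=delim, dtype=str)
    if frame.empty:
        logger.warning("response file %s has a header but no rows", path)
        return []
    return responses_from_frame(frame, instrument)


def write_responses(
    responses: Sequence[FfqResponse], instrument: FfqInstrument, path: str | Path
) -> None:
    responses_to_frame(responses, instrument).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Composition table I/O
# --------------------------------------------------------------------------


def read_composition(path: str | Path) -> FoodCompositionTable:
    """Read a per-100 g food composition table with unit-annotated headers."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    delim = "\t" if first.count("\t") >= first.count(",") else ","
    raw = pd.read_csv(path, sep=delim)
    if raw.columns[0].lower() not in ("food_item", "item", "food item"):
        raise ValueError(
            "composition table: first column must be the food item name"
        )
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "food_item"
    canonical = {col: parse_nutrient_header(col) for col in raw.columns}
    table = raw.rename(columns=canonical).astype(float)
    if "energy_kcal" not in table.columns:
        raise ValueError("composition table: missing energy column")
    neg_rows = table.index[table.lt(0).any(axis=1)]
    if len(neg_rows):
        raise ValueError(
            f"composition table: negative amounts in rows {list(neg_rows)}"
        )
    return FoodCompositionTable(table)


def write_composition(comp: FoodCompositionTable, path: str | Path) -> None:
    out = comp.table.rename(columns={c: nutrient_header(c) for c in comp.table.columns})
    out.to_csv(path, index=True, index_label="food_item")


# --------------------------------------------------------------------------
# Covariate and anthropometry tables
# --------------------------------------------------------------------------

#: covariate -> (kind, allowed/levels). Codings are low -> high.
COVARIATE_SCHEMA: dict[str, tuple[str, tuple]] = {
    "maternal_age": ("continuous", (15.0, 55.0)),
    "maternal_education": ("ordinal", (0, 1, 2)),  # 9 y, 12 y, >12 y
    "maternal_bmi": ("continuous", (12.0, 60.0)),
    "n_siblings": ("count", (0, 15)),
    "maternal_income": ("ordinal", tuple(range(7))),
    "paternal_income": ("ordinal", tuple(range(7))),
    "swedish_nationality": ("binary", (0, 1)),
    "allergic_heredity": ("binary", (0, 1)),
    "pet_at_home": ("binary", (0, 1)),
    "living_area": ("ordinal", (0, 1, 2, 3)),
    "maternal_smoking_before_pregnancy": ("binary", (0, 1)),
    "child_sex": ("binary", (0, 1)),  # girl=0, boy=1
}


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the family-characteristics table, checking codings.

    Missing values stay NaN; statistics downstream use pairwise-complete
    deletion.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    delim = "\t" if first.count("\t") >= first.count(",") else ","
    frame = pd.read_csv(path, sep=delim)
    if "child_id" not in frame.columns:
        raise ValueError("covariate table: child_id column required")
    frame = frame.set_index(frame["child_id"].astype(str)).drop(columns="child_id")
    validate_covariates(frame)
    return frame


def validate_covariates(frame: pd.DataFrame) -> None:
    for col, (kind, spec) in COVARIATE_SCHEMA.items():
        if col not in frame.columns:
            continue
        vals = frame[col].dropna()
        if kind in ("ordinal", "binary", "count") and kind != "count":
            bad = vals[~vals.isin(spec)]
            if not bad.empty:
                raise ValueError(
                    f"covariate {col!r}: values {sorted(set(bad))} outside "
                    f"coding {spec}"
                )
        elif kind == "count":
            if (vals < spec[0]).any() or (vals > spec[1]).any():
                raise ValueError(f"covariate {col!r}: counts outside {spec}")
        else:
            lo, hi = spec
            if (vals < lo).any() or (vals > hi).any():
                raise ValueError(f"covariate {col!r}: values outside [{lo}, {hi}]")


WEIGHT_RANGE = (2.0, 30.0)
HEIGHT_RANGE = (0.4, 1.3)


def read_anthropometry(path: str | Path) -> pd.DataFrame:
    """Read child weight (kg), height (m) and sex. Missing values are kept
    and propagate to missing REE/AER downstream."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    delim = "\t" if first.count("\t") >= first.count(",") else ","
    frame = pd.read_csv(path, sep=delim)
    need = {"child_id", "weight", "height", "sex"}
    if not need.issubset(frame.columns):
        raise ValueError(f"anthropometry table: columns {sorted(need)} required")
    frame = frame.set_index(frame["child_id"].astype(str)).drop(columns="child_id")
    validate_anthropometry(frame)
    return frame


def validate_anthropometry(frame: pd.DataFrame) -> None:
    w = frame["weight"].dropna()
    h = frame["height"].dropna()
    if ((w <= WEIGHT_RANGE[0]) | (w >= WEIGHT_RANGE[1])).any():
        raise ValueError(f"anthropometry: weight outside {WEIGHT_RANGE} kg")
    if ((h <= HEIGHT_RANGE[0]) | (h >= HEIGHT_RANGE[1])).any():
        raise ValueError(f"anthropometry: height outside {HEIGHT_RANGE} m")
    bad_sex = frame["sex"].dropna()[~frame["sex"].dropna().isin(["boy", "girl"])]
    if not bad_sex.empty:
        raise ValueError("anthropometry: sex must be 'boy' or 'girl'")
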