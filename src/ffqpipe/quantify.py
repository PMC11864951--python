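"""Convert categorical FFQ answers into grams/day per food item.

grams/day = occurrences/day (frequency category midpoint) x portion grams.
The portion comes from a five-picture portion scale, a categorical amount
question, a slices-per-occasion follow-up, or a fixed per-item default.
A skipped frequency question means no consumption and is coded as exactly
0 g/day. Type follow-ups divide the parent question's grams/day equally
across the reported types (full amount to one type when the follow-up is
exclusive-choice); with no type reported the amount is split equally over
all the question's food items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import DONT_KNOW, FfqInstrument, FfqResponse, Question

logger = logging.getLogger("ffqpipe")

# provenance codes per cell
ANSWERED = "answered"
CODED_ZERO = "coded_zero"
AMOUNT_QUESTION = "amount_question"
FOLLOW_UP_SPLIT = "follow_up_split"


@dataclass
class IntakeTable:
    """child_id x food_item grams/day matrix with per-cell provenance."""

    values: pd.DataFrame
    provenance: pd.DataFrame
    group_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intake table: negative grams/day")

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.values.columns if c not in self.group_columns]


@dataclass
class FoodGroupSchema:
    """Named food groups as sums of member item columns."""

    groups: dict[str, list[str]]

    def validate(self, columns: Sequence[str]) -> None:
        for group, members in self.groups.items():
            if group in self.groups and any(m in self.groups for m in members):
                raise ValueError(f"food group {group!r}: nested groups not allowed")
            for m in members:
                if m not in columns:
                    raise ValueError(
                        f"food group {group!r}: member {m!r} is not an intake column"
                    )


#: Groups mirroring the headline totals of a one-year dietary report.
DEFAULT_FOOD_GROUPS = FoodGroupSchema(
    {
        "total_seafood": ["lean_fish", "fatty_fish"],
        "total_meat": ["minced_meat", "chicken", "sausage"],
        "total_fruit_and_berries": ["banana", "apple", "other_fruit"],
        "total_bread": ["white_bread", "wholegrain_bread"],
        "total_porridge": ["powder_based_porridge", "oatmeal"],
        "sugary_drinks": ["soda", "juice"],
        "total_vegetables": ["carrot", "other_vegetables"],
    }
)


def _portion_grams(
    response: FfqResponse, question: Question, instrument: FfqInstrument
) -> tuple[float, str]:
    """Resolve the per-occasion portion in grams and its provenance."""
    p = question.portion
    if p is None:
        raise ValueError(
            f"question {question.question_id!r}: answered frequency but no "
            "portion source is defined"
        )
    if p.kind == "scale":
        scale = instrument.portion_scales[p.scale_id]
        ans = response.portion_answers.get(p.scale_id)
        if ans is None or ans == DONT_KNOW:
            if scale.dont_know_policy == "zero":
                return 0.0, ANSWERED
            # median_choice (default) and impute_group_median both fall back
            # to the scale median for a single child.
            return scale.median_grams(), ANSWERED
        return scale.grams_for(int(ans)), ANSWERED
    if p.kind == "amount":
        label = response.amount_answers.get(question.question_id)
        if label is None or label == DONT_KNOW:
            grams = sorted(p.options.values())
            n = len(grams)
            med = grams[n // 2] if n % 2 else 0.5 * (grams[n // 2 - 1] + grams[n // 2])
            return med, AMOUNT_QUESTION
        if label not in p.options:
            raise ValueError(
                f"question {question.question_id!r}: unknown amount option "
                f"{label!r}; valid: {sorted(p.options)}"
            )
        return p.options[label], AMOUNT_QUESTION
    if p.kind == "slices":
        n_units = response.slices_answers.get(p.follow_up, 1.0)
        return float(n_units) * p.grams_per_unit, ANSWERED
    if p.kind == "grams":
        return float(p.grams), ANSWERED
    raise ValueError(f"unknown portion kind {p.kind!r}")


def quantify_item(
    response: FfqResponse, question_id: str, instrument: FfqInstrument
) -> dict[str, tuple[float, str]]:
    """Grams/day for every food item covered by one frequency question.

    Returns ``{food_item: (grams_per_day, provenance)}``. An unanswered
    question yields 0 g/day (``coded_zero``) for all its items.
    """
    if question_id not in instrument.questions:
        raise KeyError(f"unknown question {question_id!r}")
    question = instrument.questions[question_id]
    if question.kind != "frequency":
        raise ValueError(f"question {question_id!r} is not a frequency question")

    label = response.answers.get(question_id)
    if label is None:
        return {item: (0.0, CODED_ZERO) for item in question.food_items}

    scale = instrument.frequency_scales[question.frequency_scale]
    occurrences = scale.per_day(label)
    grams, provenance = _portion_grams(response, question, instrument)
    total = occurrences * grams

    # Distribute over food items via a type_split follow-up when present.
    split_fu = next(
        (
            instrument.questions[fu]
            for fu in question.follow_ups
            if instrument.questions[fu].kind == "type_split"
        ),
        None,
    )
    items = question.food_items
    if split_fu is not None:
        reported = [
            t
            for t in response.type_answers.get(split_fu.question_id, [])
            if t in (split_fu.options or items)
        ]
        if reported:
            if split_fu.exclusive:
                reported = reported[:1]
            share = total / len(reported)
            out = {item: (0.0, CODED_ZERO) for item in items}
            for t in reported:
                out[t] = (share, FOLLOW_UP_SPLIT)
            return out
        # no type reported: spread evenly, uninformative
        share = total / len(items)
        return {item: (share, FOLLOW_UP_SPLIT) for item in items}
    if len(items) == 1:
        return {items[0]: (total, provenance)}
    share = total / len(items)
    return {item: (share, provenance) for item in items}


def quantify_cohort(
    responses: Sequence[FfqResponse], instrument: FfqInstrument
) -> IntakeTable:
    """Quantify every child x question into the child x food-item matrix."""
    items = instrument.food_items
    values = np.zeros((len(responses), len(items)))
    prov = np.full((len(responses), len(items)), CODED_ZERO, dtype=object)
    col = {item: j for j, item in enumerate(items)}
    ids = []
    for i, r in enumerate(responses):
        ids.append(r.child_id)
        for q in instrument.frequency_questions:
            try:
                per_item = quantify_item(r, q.question_id, instrument)
            except (ValueError, KeyError) as exc:
                raise type(exc)(f"child {r.child_id!r}: {exc}") from exc
            for item, (grams, p) in per_item.items():
                j = col[item]
                values[i, j] += grams
                if p != CODED_ZERO:
                    prov[i, j] = p
    vdf = pd.DataFrame(values, index=pd.Index(ids, name="child_id"), columns=items)
    pdf = pd.DataFrame(prov, index=vdf.index, columns=items)
    return IntakeTable(vdf, pdf)


def aggregate_groups(intakes: IntakeTable, schema: FoodGroupSchema) -> IntakeTable:
    """Append one column per food group as the row-wise sum of its members."""
    schema.validate(list(intakes.values.columns))
    values = intakes.values.copy()
    prov = intakes.provenance.copy()
    for group, members in schema.groups.items():
        values[group] = values[members].sum(axis=1)
        prov[group] = "group_sum"
    return IntakeTable(values, prov, group_columns=list(schema.groups))
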