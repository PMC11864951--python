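"""Nutrient-adequacy classification against Nordic Nutrition Recommendation
cutoffs.

Each rule compares one nutrient against a cutoff on one of three bases:
an absolute daily amount, a density per MJ of reported energy, or a share
of energy (E%). ">=" and "<=" cutoffs are inclusive; a strict rule (the
"<10 E%" saturated-fat guideline) is exclusive, following the printed
symbol. Rules may carry an age variant — up to 11 months vs 1-3 years —
which switches, e.g., the sodium guideline from 370 to 1,100 mg and the
omega-3 target from 1 to 0.5 E%. A "keep as low as possible" rule has no
numeric cutoff and yields no verdict, only the descriptive summary.

A missing nutrient value gives a missing verdict and is never counted as a
failure; cohort proportions are over non-missing verdicts only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nutrients import KCAL_PER_MJ

logger = logging.getLogger("ffqpipe")

BASES = ("absolute", "per_MJ", "energy_percent")
DIRECTIONS = ("at_least", "at_most", "within", "as_low_as_possible")
RULE_CLASSES = ("RI", "AI", "upper_guideline")
AGE_VARIANTS = ("infant_le_11m", "child_1_3y")


@dataclass(frozen=True)
class AdequacyRule:
    """One nutrient cutoff."""

    rule_id: str
    label: str
    nutrient: str
    basis: str
    direction: str
    rule_class: str
    threshold: float | None = None
    low: float | None = None
    high: float | None = None
    unit: str = ""
    strict: bool = False
    age_variant: str | None = None

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"rule {self.rule_id!r}: unknown basis {self.basis!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"rule {self.rule_id!r}: unknown direction {self.direction!r}"
            )
        if self.rule_class not in RULE_CLASSES:
            raise ValueError(
                f"rule {self.rule_id!r}: unknown class {self.rule_class!r}"
            )
        if self.age_variant is not None and self.age_variant not in AGE_VARIANTS:
            raise ValueError(
                f"rule {self.rule_id!r}: unknown age variant {self.age_variant!r}"
            )
        if self.direction == "within":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(
                    f"rule {self.rule_id!r}: 'within' needs low < high, got "
                    f"({self.low}, {self.high})"
                )
        elif self.direction in ("at_least", "at_most") and self.threshold is None:
            raise ValueError(f"rule {self.rule_id!r}: threshold required")

    def evaluate(self, value: float) -> float:
        """1.0 met, 0.0 not met, NaN undefined."""
        if value is None or np.isnan(value):
            return float("nan")
        if self.direction == "as_low_as_possible":
            return float("nan")
        if self.direction == "at_least":
            return float(value >= self.threshold)
        if self.direction == "at_most":
            met = value < self.threshold if self.strict else value <= self.threshold
            return float(met)
        return float(self.low <= value <= self.high)


@dataclass
class AdequacyResult:
    """Per-child verdicts plus the cohort summary."""

    verdicts: pd.DataFrame          # child_id x rule_id, 1.0/0.0/NaN
    rules: list[AdequacyRule]
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for rule in self.rules:
            if rule.rule_id not in self.verdicts.columns:
                continue
            col = self.verdicts[rule.rule_id]
            n_total = int(col.notna().sum())
            n_met = int((col == 1.0).sum())
            rows.append(
                {
                    "rule_id": rule.rule_id,
                    "label": rule.label,
                    "rule_class": rule.rule_class,
                    "n_met": n_met,
                    "n_total": n_total,
                    "proportion_met": n_met / n_total if n_total else float("nan"),
                    "proportion_not_met": (
                        (n_total - n_met) / n_total if n_total else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows)


def _rules_from_obj(obj: dict) -> list[AdequacyRule]:
    rules = []
    for rd in obj["rules"]:
        rules.append(
            AdequacyRule(
                rule_id=rd["rule_id"],
                label=rd["label"],
                nutrient=rd["nutrient"],
                basis=rd["basis"],
                direction=rd["direction"],
                rule_class=rd["rule_class"],
                threshold=rd.get("threshold"),
                low=rd.get("low"),
                high=rd.get("high"),
                unit=rd.get("unit", ""),
                strict=bool(rd.get("strict", False)),
                age_variant=rd.get("age_variant"),
            )
        )
    return rules


def load_rules(path: str | Path) -> list[AdequacyRule]:
    """Load an adequacy rule set from JSON."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return _rules_from_obj(obj)


def default_rules() -> list[AdequacyRule]:
    """The bundled one-year rule set."""
    text = (
        resources.files("ffqpipe").joinpath("data/nnr2023_one_year.json").read_text()
    )
    return _rules_from_obj(json.loads(text))


def _rule_values(rule: AdequacyRule, nutrients: pd.DataFrame) -> pd.Series | None:
    if rule.basis == "absolute":
        if rule.nutrient not in nutrients.columns:
            return None
        return nutrients[rule.nutrient]
    if rule.basis == "per_MJ":
        if rule.nutrient not in nutrients.columns or "energy_kcal" not in nutrients:
            return None
        mj = (nutrients["energy_kcal"] / KCAL_PER_MJ).where(
            nutrients["energy_kcal"] > 0
        )
        return nutrients[rule.nutrient] / mj
    # energy_percent: the rule references a precomputed E% column
    if rule.nutrient not in nutrients.columns:
        return None
    return nutrients[rule.nutrient]


def classify(
    nutrients: pd.DataFrame,
    rules: list[AdequacyRule] | None = None,
    age_variant: str = "infant_le_11m",
) -> AdequacyResult:
    """Evaluate every applicable rule per child.

    Rules bound to a different age variant are filtered out; rules whose
    nutrient column is absent are skipped with a warning and recorded in the
    result metadata.
    """
    if age_variant not in AGE_VARIANTS:
        raise ValueError(f"unknown age variant {age_variant!r}")
    if rules is None:
        rules = default_rules()
    applicable = [
        r for r in rules if r.age_variant is None or r.age_variant == age_variant
    ]
    verdicts: dict[str, pd.Series] = {}
    kept: list[AdequacyRule] = []
    skipped: list[str] = []
    for rule in applicable:
        values = _rule_values(rule, nutrients)
        if values is None:
            logger.warning(
                "rule %r skipped: nutrient %r not in the table",
                rule.rule_id,
                rule.nutrient,
            )
            skipped.append(rule.rule_id)
            continue
        verdicts[rule.rule_id] = values.map(rule.evaluate)
        kept.append(rule)
    frame = pd.DataFrame(verdicts, index=nutrients.index)
    return AdequacyResult(frame, kept, skipped)


def summarize_adequacy(result: AdequacyResult) -> pd.DataFrame:
    """Cohort met / not-met shares per rule, ordered with the worst-met
    nutrients first (ready for a diverging-bar export)."""
    summary = result.summary()
    if summary.empty:
        logger.warning("adequacy summary over an empty cohort or rule set")
        return summary
    return summary.sort_values(
        "proportion_not_met", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
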