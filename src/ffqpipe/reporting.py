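"""Cohort summary tables, supplement-use tallies, and the end-to-end
pipeline runner."""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import adequacy as adequacy_mod
from .cohort_filter import apply_exclusions
from .energy import energy_profiles
from .instrument import FfqResponse, read_composition, read_instrument, read_responses
from .nutrients import EnergyConversionFactors, full_nutrient_table
from .quantify import DEFAULT_FOOD_GROUPS, aggregate_groups, quantify_cohort
from .screening import spearman_screen
from .synthetic import (
    SyntheticCohortConfig,
    default_composition_table,
    generate,
)

logger = logging.getLogger("ffqpipe")


def summarize(table: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Descriptive statistics per variable over non-missing values.

    Quantiles use linear interpolation. The interquartile range is emitted
    both as the 25th-75th span (p25, p75) and as its width (iqr_width),
    since dietary reports mix the two conventions. Values at 2 d.p.
    """
    cols = list(variables) if variables is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    for c in cols:
        v = pd.to_numeric(table[c], errors="coerce").dropna()
        n = len(v)
        if n == 0:
            rows.append({"variable": c, "n": 0})
            continue
        p25, med, p75 = (float(np.percentile(v, q)) for q in (25, 50, 75))
        rows.append(
            {
                "variable": c,
                "n": n,
                "mean": round(float(v.mean()), 2),
                "sd": round(float(v.std(ddof=1)) if n > 1 else 0.0, 2),
                "median": round(med, 2),
                "p25": round(p25, 2),
                "p75": round(p75, 2),
                "iqr_width": round(p75 - p25, 2),
                "min": round(float(v.min()), 2),
                "max": round(float(v.max()), 2),
            }
        )
    return pd.DataFrame(rows)


#: supplement frequency labels counted as regular (vs sporadic) use
REGULAR_LABELS = ("daily", "a few times a week")


@dataclass
class SupplementTally:
    """Supplement-use combinations and per-type totals."""

    per_child: pd.DataFrame       # child_id, types, usage {regular,sporadic,none}
    combinations: Counter         # frozenset of types -> count
    type_totals: Counter          # type -> count of users
    frequency_by_type: dict[str, Counter] = field(default_factory=dict)

    @property
    def usage_counts(self) -> Counter:
        return Counter(self.per_child["usage"])


def tally_supplements(
    responses: Sequence[FfqResponse],
    known_types: Sequence[str] | None = None,
) -> SupplementTally:
    """Classify each child's supplement use and tally combinations.

    A child is a regular user if any supplement is taken daily or a few
    times a week, sporadic if supplements are used but only weekly or less,
    and a non-user otherwise. Unknown supplement labels are counted under
    "other" with a warning.
    """
    per_child = []
    combos: Counter = Counter()
    totals: Counter = Counter()
    freq_by_type: dict[str, Counter] = {}
    for r in responses:
        types = []
        regular = False
        for t, label in r.supplement_answers.items():
            if known_types is not None and t not in known_types:
                logger.warning(
                    "child %s: unknown supplement type %r counted as 'other'",
                    r.child_id, t,
                )
                t = "other"
            types.append(t)
            totals[t] += 1
            freq_by_type.setdefault(t, Counter())[label] += 1
            if label in REGULAR_LABELS:
                regular = True
        usage = "regular" if regular else ("sporadic" if types else "none")
        if types:
            combos[frozenset(types)] += 1
        per_child.append(
            {"child_id": r.child_id, "types": "|".join(sorted(types)), "usage": usage}
        )
    return SupplementTally(
        pd.DataFrame(per_child), combos, totals, freq_by_type
    )


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run every stage end to end and write the artifacts.

    config keys: either ``simulate`` (a mapping of SyntheticCohortConfig
    overrides) or ``instrument``/``responses``/``anthropometry``/
    ``covariates`` file paths; optional ``composition`` path,
    ``age_variant``, ``total_tests``, ``alpha``. Deterministic given the
    inputs and seed; the run log records every stage's row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": []}

    def stage(name: str, **info):
        log["stages"].append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    try:
        if "simulate" in config:
            cohort = generate(SyntheticCohortConfig(**config["simulate"]))
            instrument = cohort.instrument
            responses = cohort.responses
            anthro = cohort.anthropometry
            covariates = cohort.covariates
            composition = (
                read_composition(config["composition"])
                if config.get("composition")
                else default_composition_table()
            )
            (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=1))
        else:
            instrument = read_instrument(config["instrument"])
            responses = read_responses(config["responses"], instrument)
            from .instrument import read_anthropometry, read_covariates

            anthro = read_anthropometry(config["anthropometry"])
            covariates = read_covariates(config["covariates"])
            composition = read_composition(config["composition"])
        stage("inputs", n_responses=len(responses))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    report = apply_exclusions(responses)
    included = set(report.included_ids)
    analysed = [r for r in responses if r.child_id in included]
    (outdir / "exclusion_flow.json").write_text(json.dumps(report.to_dict(), indent=1))
    stage("cohort_filter", n_initial=report.n_initial, n_final=report.n_final)

    try:
        intakes = aggregate_groups(
            quantify_cohort(analysed, instrument), DEFAULT_FOOD_GROUPS
        )
        intakes.values.to_csv(outdir / "intakes.csv")
        stage("quantification", n_children=len(intakes.values),
              n_items=len(intakes.values.columns))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'quantification' failed: {exc}") from exc

    try:
        factors = EnergyConversionFactors()
        nutrients = full_nutrient_table(intakes, composition, factors)
        nutrients.to_csv(outdir / "nutrients.csv")
        stage("nutrient_computation", n_children=len(nutrients),
              n_nutrients=len(nutrients.columns))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage 'nutrient_computation' failed: {exc}"
        ) from exc

    energy = energy_profiles(nutrients, anthro)
    energy.to_csv(outdir / "energy.csv")
    stage("energy_requirements", n_children=len(energy))

    age_variant = config.get("age_variant", "infant_le_11m")
    result = adequacy_mod.classify(nutrients, age_variant=age_variant)
    result.verdicts.to_csv(outdir / "adequacy.csv")
    adequacy_mod.summarize_adequacy(result).to_csv(
        outdir / "adequacy_summary.csv", index=False
    )
    stage("adequacy", n_rules=len(result.rules), skipped=result.skipped)

    diet = pd.concat(
        [
            intakes.values,
            nutrients[[c for c in ("trans_fa_g", "sugars_g", "sfa_g")
                       if c in nutrients.columns]],
        ],
        axis=1,
    )
    screen = spearman_screen(
        covariates.loc[covariates.index.isin(included)],
        diet,
        total_tests=config.get("total_tests"),
        alpha=config.get("alpha", 0.05),
    )
    screen.table.to_csv(outdir / "screening.csv", index=False)
    stage("screening", n_cells=len(screen.table), total_tests=screen.total_tests)

    summarize(nutrients).to_csv(outdir / "nutrient_summary.csv", index=False)
    summarize(energy).to_csv(outdir / "energy_summary.csv", index=False)
    tally = tally_supplements(responses, instrument.supplement_types)
    pd.DataFrame(
        [{"combination": "+".join(sorted(k)), "count": v}
         for k, v in sorted(tally.combinations.items(),
                            key=lambda kv: -kv[1])]
    ).to_csv(outdir / "supplement_combinations.csv", index=False)
    stage("reporting", usage=dict(tally.usage_counts))

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return log
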