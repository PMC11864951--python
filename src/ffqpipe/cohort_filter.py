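"""Inclusion/exclusion flow selecting children whose diet is the sole
energy source.

Children still breastfed beyond 10 months, or with unknown breastfeeding
duration, are removed first; then children still on infant formula, or with
unknown formula status. Stage order is fixed so the per-stage counts are
comparable across cohorts; the final included set is order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .instrument import FfqResponse

STAGES = (
    ("breastfed_beyond_10m", "yes", "still_breastfed"),
    ("breastfed_beyond_10m", "unknown", "breastfeeding_info_missing"),
    ("formula_beyond_10m", "yes", "still_formula_fed"),
    ("formula_beyond_10m", "unknown", "formula_info_missing"),
)


@dataclass
class ExclusionReport:
    """Per-stage exclusion counts and the final included ids."""

    n_initial: int
    stages: list[tuple[str, int, int]]  # (stage name, n_excluded, n_remaining)
    included_ids: list[str] = field(default_factory=list)
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        remaining = [n for _, _, n in self.stages]
        if any(b > a for a, b in zip([self.n_initial] + remaining, remaining)):
            raise ValueError("exclusion report: n_remaining must be non-increasing")
        total_excluded = sum(n for _, n, _ in self.stages)
        if self.n_initial - total_excluded != len(self.included_ids):
            raise ValueError("exclusion report: counts do not conserve children")

    @property
    def n_final(self) -> int:
        return len(self.included_ids)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "stages": [
                {"stage": s, "n_excluded": e, "n_remaining": r}
                for s, e, r in self.stages
            ],
            "n_final": self.n_final,
            "included_ids": self.included_ids,
        }


def apply_exclusions(responses: Sequence[FfqResponse]) -> ExclusionReport:
    """Run the four sequential feeding-status exclusions."""
    remaining = list(responses)
    stages: list[tuple[str, int, int]] = []
    excluded_ids: dict[str, list[str]] = {}
    for attr, value, name in STAGES:
        dropped = [r for r in remaining if getattr(r, attr) == value]
        remaining = [r for r in remaining if getattr(r, attr) != value]
        stages.append((name, len(dropped), len(remaining)))
        excluded_ids[name] = [r.child_id for r in dropped]
    return ExclusionReport(
        n_initial=len(responses),
        stages=stages,
        included_ids=[r.child_id for r in remaining],
        excluded_ids=excluded_ids,
    )
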