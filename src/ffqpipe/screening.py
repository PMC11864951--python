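"""Screening of family characteristics against food and nutrient intakes.

The primary screen is a grid of Spearman rank correlations (average ranks
for ties, two-sided p), adjusted with the Benjamini-Hochberg false
discovery rate. The total number of tests m entering the adjustment is an
explicit parameter so the family can be defined over the full set of diet
variables even when only a subset is screened. Missing covariate values
are removed pairwise.

Significant correlations with categorical covariates are followed up with
group-location tests (Mann-Whitney U for binary, Kruskal-Wallis for
multilevel covariates) reporting per-group medians and quartiles, and
categorical-by-categorical contrasts use chi-square, the linear-by-linear
association test (M^2 = (N-1) r^2, 1 df) or Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ffqpipe")


# --------------------------------------------------------------------------
# Benjamini-Hochberg adjustment with explicit family size
# --------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float], total_tests: int) -> np.ndarray:
    """BH-adjusted p-values (q-values) against a family of ``total_tests``.

    Each p-value is multiplied by the family size and divided by its
    ascending rank, then monotonized with a cumulative minimum from the
    largest rank down and capped at 1, so that rejecting q <= alpha is the
    classic step-up decision.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = int(total_tests)
    if m < p.size:
        raise ValueError(
            f"total_tests ({m}) must be >= number of p-values ({p.size})"
        )
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, p.size + 1)
    scaled = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# Spearman screen
# --------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    """Long-format covariate x intake screen, heatmap-ready."""

    table: pd.DataFrame  # covariate, variable, rho, p_raw, q, n_pairs, significant
    total_tests: int
    alpha: float = 0.05


MIN_PAIRS = 3


def spearman_screen(
    covariates: pd.DataFrame,
    intakes: pd.DataFrame,
    total_tests: int | None = None,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Spearman rho and BH-adjusted p for every covariate x intake cell.

    Cells with a constant variable or fewer than three complete pairs get a
    missing rho and do not enter the adjustment. ``total_tests`` defaults to
    the number of cells attempted (the full screened family).
    """
    common = covariates.index.intersection(intakes.index)
    cov = covariates.loc[common]
    diet = intakes.loc[common]
    cells = []
    for c in cov.columns:
        for v in diet.columns:
            x = pd.to_numeric(cov[c], errors="coerce")
            y = pd.to_numeric(diet[v], errors="coerce")
            mask = x.notna() & y.notna()
            n = int(mask.sum())
            rho = p = float("nan")
            if n < MIN_PAIRS:
                logger.warning("cell %s x %s: only %d complete pairs", c, v, n)
            elif x[mask].nunique() < 2 or y[mask].nunique() < 2:
                logger.warning("cell %s x %s: constant variable", c, v)
            else:
                res = stats.spearmanr(x[mask], y[mask])
                rho, p = float(res.statistic), float(res.pvalue)
                if np.isnan(p):
                    rho = p = float("nan")
                else:
                    # a perfect correlation can return p = 0 exactly; keep
                    # it inside the (0, 1] domain of the adjustment
                    p = max(p, np.finfo(float).tiny)
            cells.append(
                {"covariate": c, "variable": v, "rho": rho, "p_raw": p, "n_pairs": n}
            )
    table = pd.DataFrame(cells)
    m = int(total_tests) if total_tests is not None else len(table)
    computed = table["p_raw"].notna()
    if m < int(computed.sum()):
        raise ValueError(
            f"total_tests ({m}) smaller than the number of computed cells "
            f"({int(computed.sum())})"
        )
    q = np.full(len(table), np.nan)
    if computed.any():
        q[computed.to_numpy()] = bh_adjust(table.loc[computed, "p_raw"], m)
    table["q"] = q
    table["significant"] = table["q"] < alpha
    return ScreeningResult(table, total_tests=m, alpha=alpha)


# --------------------------------------------------------------------------
# Follow-up group tests
# --------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    covariate: str
    variable: str
    test: str
    statistic: float
    p: float
    groups: pd.DataFrame = field(default_factory=pd.DataFrame)  # per-group stats


#: largest per-group n at which the exact Mann-Whitney null is used
EXACT_N = 25


def _group_summary(values_by_group: dict) -> pd.DataFrame:
    rows = []
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        rows.append(
            {
                "group": g,
                "n": len(v),
                "median": float(np.median(v)),
                "p25": float(np.percentile(v, 25)),
                "p75": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows)


def group_tests(
    covariate: pd.Series, intake: pd.Series, kind: str
) -> GroupTestResult:
    """One follow-up comparison.

    kind = "binary" -> Mann-Whitney U (exact null when both groups have at
    most 25 observations and the data are untied); "multilevel" ->
    Kruskal-Wallis; "categorical_outcome" -> chi-square plus
    linear-by-linear on an r x k contingency table, Fisher's exact test
    when 2 x 2.
    """
    mask = covariate.notna() & intake.notna()
    x, y = covariate[mask], intake[mask]
    levels = sorted(x.unique())
    groups = {g: y[x == g].to_numpy(float) for g in levels}
    non_empty = {g: v for g, v in groups.items() if len(v)}
    if len(non_empty) < 2:
        logger.warning(
            "comparison %s x %s skipped: fewer than two non-empty groups",
            covariate.name,
            intake.name,
        )
        return GroupTestResult(
            str(covariate.name), str(intake.name), "skipped",
            float("nan"), float("nan"),
        )
    if kind == "binary":
        if len(non_empty) != 2:
            raise ValueError("binary comparison needs exactly two groups")
        a, b = non_empty.values()
        method = "exact" if max(len(a), len(b)) <= EXACT_N else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupTestResult(
            str(covariate.name), str(intake.name), "Mann-Whitney U",
            float(res.statistic), float(res.pvalue), _group_summary(non_empty),
        )
    if kind == "multilevel":
        res = stats.kruskal(*non_empty.values())
        return GroupTestResult(
            str(covariate.name), str(intake.name), "Kruskal-Wallis",
            float(res.statistic), float(res.pvalue), _group_summary(non_empty),
        )
    if kind == "categorical_outcome":
        table = pd.crosstab(x, y)
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table.to_numpy())
            return GroupTestResult(
                str(covariate.name), str(intake.name), "Fisher exact",
                float("nan"), float(p),
            )
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy())
        m2, p_lbl = linear_by_linear(table.to_numpy())
        # report the more targeted trend test alongside the omnibus chi-square
        result = GroupTestResult(
            str(covariate.name), str(intake.name), "Chi-square",
            float(chi2), float(p),
        )
        result.groups = pd.DataFrame(
            [{"test": "Linear-by-Linear", "statistic": m2, "p": p_lbl}]
        )
        return result
    raise ValueError(f"unknown comparison kind {kind!r}")


def linear_by_linear(table: np.ndarray) -> tuple[float, float]:
    """Mantel-Haenszel linear-by-linear association: M^2 = (N-1) r^2 with
    integer row/column scores, chi-square with 1 df."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    r_scores = np.arange(table.shape[0])
    c_scores = np.arange(table.shape[1])
    pr = table.sum(axis=1) / n
    pc = table.sum(axis=0) / n
    mr = (r_scores * pr).sum()
    mc = (c_scores * pc).sum()
    sr = np.sqrt(((r_scores - mr) ** 2 * pr).sum())
    sc = np.sqrt(((c_scores - mc) ** 2 * pc).sum())
    if sr == 0 or sc == 0:
        return float("nan"), float("nan")
    cov = ((np.outer(r_scores - mr, c_scores - mc) * table).sum()) / n
    r = cov / (sr * sc)
    m2 = (n - 1) * r**2
    return float(m2), float(stats.chi2.sf(m2, df=1))
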