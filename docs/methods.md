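# Methods

This note records the modelling assumptions, defaults and numerical choices
behind `ffqpipe`, and what the synthetic-cohort tests do and do not show
about real data.

## The measurement model

A semi-quantitative FFQ records, per question, a frequency category and a
portion representation. The pipeline treats intake as the product of two
independent quantities:

* **occurrences/day** — the frequency category mapped to a daily rate. The
  default mapping uses category midpoints over the stated period, with a
  month taken as 30.44 days: "1–3 times/month" → 2/30.44, "1–2 times/week" →
  1.5/7, "3–4 times/week" → 0.5, "5–6 times/week" → 5.5/7, "1 time/day" → 1,
  "2 times/day" → 2, "3 times/day or more" → 3. The midpoint is the standard
  FFQ convention; the mapping ships as data on the instrument so
  questionnaire-specific calibrations can be dropped in without code
  changes.
* **portion grams** — from a five-picture portion scale (each picture a
  fixed gram weight, strictly increasing), a categorical amount question
  ("a few pieces" = 10 g, one ice-cream scoop = 50 g by default), a
  slices-per-occasion follow-up (30 g per bread slice), or a fixed per-item
  default. The gram weights behind the pictures are instrument data, not
  constants; the bundled values are plausible placeholders for a one-year
  questionnaire, not measurements.

A skipped question is defined as *no consumption* and contributes exactly
0 g/day. This is a property of the instrument (parents are instructed to
skip foods the child does not eat), so unanswered frequency questions never
produce missing data downstream. "Do not know" portion answers fall back to
the scale's median picture — the least-biased single imputation; the policy
is configurable per scale (zero, or group-median for cohort-level
imputation).

Type follow-ups (plain vs flavored yoghurt, the meat types, …) divide the
parent question's grams/day **equally across the reported types**, or assign
everything to the single choice when the follow-up is exclusive. Whether a
real questionnaire splits or replicates the parent frequency across types is
an instrument-design question; equal division is the conservative choice
because it conserves the parent total (group sums then equal the parent
quantity by construction).

No upper truncation is applied to intakes: extreme but possible reports
(e.g. a 2,800 kcal day total) are kept, and no child is excluded on
energy-misreporting grounds.

## Nutrients and derived quantities

Nutrient intake is the linear join with a per-100 g composition table;
group columns are excluded from the sum to avoid double counting. Units are
enforced at parse time against a registry (e.g. iron must arrive in mg).

Derived columns:

* energy MJ = energy kcal / 239 (exact, by definition of the conversion
  used throughout);
* E% = grams × (kcal/g) / energy kcal × 100 with Atwater factors 4 (protein),
  4 (carbohydrate), 9 (fat); fiber contributes 0 kcal by default
  (configurable to 2 kcal/g — immaterial at this scale); all fatty-acid E%
  use the fat factor;
* omega-3 = 18:3 + 20:5 + 22:5 + 22:6 and omega-6 = 18:2 + 20:4 — these are
  the n-3/n-6 species carried by the composition table;
* niacin equivalents are taken from the composition table when present,
  otherwise NE = niacin mg + protein g × 11/60 (tryptophan ≈ 1.1% of
  protein, 60 mg Trp ≈ 1 mg NE).

E% is undefined (missing, with a warning) for a child with zero reported
energy: a share of nothing is not zero. Because cohort-level E% can be
formed either as the median of per-child ratios or as the ratio of medians,
both are available — per-child E% columns are emitted and any summary of
them is the former; the latter can be formed from the absolute summaries.

## Energy requirements

REE uses the Henry weight–height equations for this age, evaluated as a
linear expression in MJ/day and then converted: boys
(0.118·w + 3.59·h − 1.55) × 239, girls (0.127·w + 2.94·h − 1.20) × 239,
with w in kg and h in metres. The grouping matters: the linear expression is
computed first, then scaled — evaluated any other way the equations produce
physically absurd values, and the grouped form reproduces the reference
medians (girl at 10 kg, 0.75 m → 543.73 kcal). AER is 337 (boys) / 333
(girls) kJ per kg body weight, ÷ 4.184 to kcal. FIL = EI/REE. Missing or
non-positive weight/height propagate to missing REE/AER/FIL, never to an
error. Full precision is kept internally; reports round to 2 d.p.

## Adequacy rules

The bundled rule set (`data/nnr2023_one_year.json`) encodes NNR-style
cutoffs for about one year of age on three bases — absolute daily amount,
density per MJ, share of energy — with three rule classes (recommended
intake, adequate intake, upper guideline). Decisions:

* ≥ and ≤ cutoffs are inclusive; the "<10 E%" saturated-fat guideline is
  exclusive, following the printed symbol;
* the iodine adequate intake is given as a range (80–90 μg) and is encoded
  at its midpoint, 85 μg;
* trans fat ("as low as possible") has no numeric cutoff: it yields no
  verdict, only a descriptive summary;
* age variants switch sodium (≤370 mg up to 11 months, ≤1,100 mg at
  1–3 years) and omega-3 (≥1 E% vs ≥0.5 E%); relaxing the variant can only
  enlarge the set of children meeting those rules, which the tests assert;
* comparisons use full-precision intakes, not rounded ones;
* a missing nutrient value gives a missing verdict and is excluded from the
  denominator — absence of data is never a failure.

Only the cutoffs relevant to this age band are bundled; the set is a JSON
file precisely so other age groups can be supplied externally.

## Exclusion flow

The primary analysis set is children whose diet is the sole energy source.
Four sequential stages remove: still breastfed beyond 10 months; unknown
breastfeeding duration; still formula-fed; unknown formula status. Stage
order is fixed (breastfeeding before formula) so per-stage counts are
comparable; the final membership is order-invariant because each child's
fate depends only on their own tristate fields. A child both breastfed and
formula-fed beyond 10 months is counted at the first stage that catches
them.

## Screening statistics

Spearman rank correlation (average ranks for ties, two-sided p) is computed
per covariate × intake cell with pairwise-complete deletion; cells with
fewer than 3 complete pairs or a constant variable are reported missing.
p-values of exactly zero (perfect monotone association at small n under the
asymptotic null) are clamped to the smallest positive float so they stay in
the adjustment's domain.

The BH adjustment takes the **total number of tests m as an explicit
parameter**, defaulting to the number of cells screened. This makes it
possible to define the family over a full set of diet variables while
screening (or visualising) a subset. q-values are monotonized with a
cumulative minimum — the classical algorithm, which a plain
"multiply by m/rank" description omits — and capped at 1, so q ≤ α
reproduces the textbook step-up decision exactly (property-tested against a
brute-force implementation).

Follow-up tests: Mann–Whitney U for binary covariates (exact null when both
groups have ≤ 25 observations, asymptotic otherwise), Kruskal–Wallis for
multilevel ones, with per-group medians and quartiles; chi-square plus the
linear-by-linear association test (M² = (N−1)r² on integer scores, 1 df)
for ordered contingency tables and Fisher's exact test for 2×2.

## Synthetic cohort

The generator emulates the study conditions of a one-year Nordic FFQ
cohort: 523 eligible children; feeding marginals 149/10/95/18 so the
exclusion flow leaves 364 after the breastfeeding stages and 251 in the
primary set; sex-specific anthropometry (boys ~N(10.43, 1.17) kg,
N(0.77, 0.04) m; girls ~N(9.70, 1.13) kg, N(0.75, 0.03) m, clipped to the
plausible 7–14 kg / 0.61–1.05 m window, ~2% missing); family
characteristics with realistic prevalences (8% smoking before pregnancy,
~51% with older siblings, 64% allergic heredity, sporadic missingness in
the income variables).

Per-question frequency distributions are chosen so that headline intakes
land at realistic one-year levels (gruel ≈ 225 g/day and water ≈ 600 g/day
at the median, pasta/potato near 37.5 g/day, median energy ≈ 700–800 kcal);
they are configuration, not estimates.

Planted effects act on the **ordinal frequency answer** via a
cumulative-log-odds (proportional-odds) shift — not directly on grams — so
the signal passes through the same categorical measurement process the
pipeline ingests. Defaults: maternal smoking shifts soda and juice by
β = 3.0; each older sibling (capped at 2) shifts buns/biscuits by β = 1.5
and cow's milk by β = 1.2, which propagates into trans fat, sugars and
saturated-fat intakes through the composition table. These effect sizes are
deliberately stronger than the modest contrasts typically reported in
observational cohorts: with only ~8% exposed smokers and a zero-inflated
outcome, a literature-sized contrast is not reliably detectable at n = 250,
and the generator's purpose is a sharp parameter-recovery test (correct
sign at q < 0.05 in ≥ 90% of replicates), not effect-size realism. The
truth record carries every planted effect with its direction.

What the generator does **not** emulate: inter-item correlation structure
(dietary patterns) — items are independent apart from the planted effects;
seasonal or weekday/weekend variation; differential misreporting; the full
100+-item granularity of a real instrument (29 food items across 20
questions). Passing recovery and type-I tests therefore validates the
statistical machinery under the stated measurement model, not the
robustness of conclusions to correlated real-world diets.

## Problem sizes and numerics

The default composition table sets energy exactly equal to the Atwater sum,
which makes the three macronutrient E% columns sum to 100 identically — a
deliberate property used as a test invariant; the random fixture perturbs
energy by ±8% to exercise the unit-audit tolerance (±15%). Test problem
sizes: oracle suites use 200–500 random vectors; the null-screening check
runs 1,000 replicates of an 8-cell screen at n = 60; planted-effect
recovery runs 100 replicates of a 250-child cohort screened over a
6 × 10 covariate–diet family (m = 60 cells, the full screened family).
Group additivity is enforced to 1e−9 relative; summary statistics round to
2 d.p. only at the reporting boundary.

## Known limitations

* Portion-picture gram weights, amount-question values and the
  frequency-midpoint mapping are placeholders pending instrument-specific
  calibration data; all are editable configuration.
* The bundled composition table is a small synthetic stand-in with
  plausible per-100 g values (including the fortified-porridge vs oatmeal
  iron contrast of 1.7 vs 0.6 mg/100 g); it is not a national food
  database, and absolute cohort nutrient levels depend on it directly.
* Retinol/α-tocopherol equivalents are taken as delivered by the
  composition table, never recomputed.
* Supplement doses are not added to nutrient intakes; supplement use is
  tallied descriptively only (regular = daily or a few times a week,
  sporadic = weekly or less — a configurable convention).
* The screening is deliberately model-free (no regression adjustment);
  q-values control the FDR within the declared family only.
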