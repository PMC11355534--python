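# Methods

This note records the statistical model behind `equiflow`, the choices made
where the method is genuinely under-determined, and what the synthetic
cohort does and does not establish about real data.

## Event model and canonical token order

A treatment episode is an interval `[start, end]` (the end may be absent
for episodes still open at extraction); admission and discharge are
instantaneous anchor milestones, not treatments. A case is flattened into
tokens — `admission`, `start:a`, `end:a`, `discharge` — sorted by
`(timestamp, kind, label)` with kind ranked admission < end < start <
discharge and ties broken lexicographically by activity label.

The tie-break is the one place the variant definition is under-determined
by the data, and it matters: clinical timestamps are minute-coarse, so
"ends at the same minute the next one starts" is common. Ranking
end-tokens before start-tokens prevents such boundary ties from minting
spurious overlap variants; the lexicographic label rule makes extraction
deterministic under any input row order. One subtlety the property suite
enforces: a *zero-duration* episode's end token shares the start rank with
a trailing sub-key, so it sorts immediately after its own start rather
than before it — otherwise the end-before-start rule would produce an
ill-nested signature. Repeated episodes of the same
treatment keep their repeated tokens (the definition is over the literal
order of starts and ends), and a case without a discharge keeps an
open-ended signature — censoring is represented, not hidden.

Events timestamped outside the admission–discharge window (including
exactly at discharge) are flagged by validation but not dropped. Rows that
fail parsing, or with `end < start`, are quarantined with a reason;
equity audits cannot afford silent drops. Timestamps are timezone-naive
(de-identified logs carry shifted dates); durations are reals in hours.

## Disparity metrics

Within one variant, split by a sensitive attribute:

* **step duration** — `end − start` in hours for the k-th occurrence of an
  activity; group mean.
* **SOFA at step start** — the event's SOFA score; if missing, the next
  available SOFA among the case's subsequent events in time order; cases
  with no SOFA anywhere are excluded and the exclusion counted. (The
  next-available rule has no further fallback; inventing one — e.g.
  carrying an *earlier* value forward — would silently change the
  severity control.)
* **inter-step time** — the gap between adjacent signature tokens, in
  hours; the admission → first-start gap is the time to first treatment.
* **outcomes** — mortality as a proportion, length of stay (discharge −
  admission) in hours.

Point estimates are means (not medians): the quantity of interest is the
average burden per group, and means compose additively across gaps.
Uncertainty is a **percentile bootstrap CI of the mean**, default level
0.90 and B = 1000 resamples — the standard accuracy/runtime compromise,
configurable. The percentile method (not BCa) was chosen for transparency:
the reported interval is literally the middle 90% of resampled means. The
interval could alternatively have been read as a tolerance band of the
data distribution; we implement the CI of the mean and note the ambiguity.
Each metric derives its own resampling seed from the run seed and the
metric/group name, so results are bitwise reproducible and independent of
evaluation order.

## Baseline tables and the global test

Baseline-characteristics tables report categorical attributes as counts
with integer percentages (rounded half-away-from-zero, the convention of
printed clinical tables) and numeric attributes as median (IQR = Q3−Q1).
Between-group tests, computed only for exactly two non-missing groups:
Pearson chi-square, with the Yates continuity correction iff the
contingency table is 2×2, and the Mann–Whitney U test for numeric
attributes (medians/IQR presentation implies a rank-based comparison; the
choice is configurable in principle and recorded here rather than claimed
canonical). Missing attribute values form their own reported row and are
excluded from the test denominator.

The global level compares, for each unordered pair of groups, the 2×V
contingency of cases over the min-support-surviving variants with
Pearson's chi-square (no correction for V > 2). The minimum-support filter
(default 50 cases per variant) bounds variant totals but not per-group
expected counts, so columns with any expected count < 5 are pooled into an
"other" column (flagged in the result) before testing. Raw p-values are
always reported; with more than two groups each pair also carries a
Bonferroni-adjusted p. Significance thresholds are presentation, not
method, and are left to the user.

## Synthetic ICU cohort

The generator emulates the structure of an ICU sepsis cohort: a mixture of
variant templates (ventilation only; ventilation enclosing vasopressor;
vasopressor only; vasopressor then ventilation; a dialysis-containing
pathway), per-gap lognormal timing in hours (right-skewed, clinically
plausible: median ≈ 3 h to ventilation, ≈ 1–2 day episode durations),
initial SOFA from a discretised right-skewed distribution peaking near 7
with per-event drift −0.5 and 15% missingness, mortality from a logistic
model (intercept −3.0, +0.18 per initial SOFA point → ≈ 16% cohort
mortality), and a roughly 10:1 English-speaking : non-English-speaking
split. Group disparity is injected as an **additive shift** on named gaps
(default +2 h on admission → start:ventilation for the non-ESP group),
the simplest recoverable effect. All draws come from one seeded stream;
the same seed reproduces the cohort byte-for-byte. Gaps are floored at one
minute so minute-rounding can never collapse two tokens and reorder a
template.

What the generator does **not** emulate: correlation between severity and
pathway choice, treatment re-entries, inter-current events, attribute
confounding (language × ethnicity × age), or informative missingness.
Passing tests therefore establish that the pipeline recovers disparities
it is pointed at under clean conditions — not that it adjusts for the
confounding structure of real hospital data, where SOFA-style controls
and within-variant comparison are aids, not guarantees.

One arithmetic consequence worth naming: length of stay is defined as
discharge − admission, so an injected admission→treatment delay of Δ
lengthens LOS by exactly Δ in expectation. A delay disparity therefore
*mechanically* appears in LOS as well; at n = 400/group a 2 h shift on a
~80 h stay separates the LOS intervals. In real cohorts LOS variance is
far larger relative to plausible delays, which is why delay disparities
need not be visible in outcomes there.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well inside the asserted bands: chi-square calibration with 1 000
replicates of 500 patients per group over a 5-variant mixture (null
rejection ≈ 0.05 ± 0.014 at 2 SE); bootstrap coverage with 500 replicates
of n = 50, B = 2 000 (coverage SE ≈ 0.013); delay recovery at n = 400 per
group on the nested ventilation⊃vasopressor template, where the ±2 h
effect is ≈ 10 standard errors of the gap mean. Degenerate inputs:
a single observation yields the degenerate interval [v, v] with a
warning; constant samples likewise; a group absent from a variant is
omitted from its panel with a note; an empty variant table halts
downstream testing explicitly rather than emitting vacuous results.

## Design choices that were genuinely open

* **Panels per variant, not pooled across variants** — pooling would
  reintroduce the pathway confounding the variant split exists to remove.
* **Missing-attribute patients** form an explicit "missing" group excluded
  from tests by default; disparity audits must report them, not test them
  as a pseudo-category.
* **Cohort filters** (diagnosis, minimum age, any-of comorbidity set) are
  a pure conjunction; stage-wise counts are reported in
  diagnosis → age → comorbidity order to mirror an inclusion-flow diagram,
  but the outcome is order-independent. An empty spec is the identity; the
  shipped sepsis spec uses age ≥ 18 with an any-of {chf, mi, copd}
  comorbidity requirement.
* **Top-k panels** default to the 5 most frequent variants; deeper panels
  are a runtime, not a methodological, cost.
* **Report JSON** is schema-versioned and bit-stable given seed and
  config, excepting the single wall-clock `created_at` field; every number
  in the text rendering traces to a JSON field.

## Known limitations

Exact signature equality is deliberately strict: near-identical variants
(e.g. differing only in a 1-minute overlap) are distinct rows, and the
min-support filter discards rare pathways — which may themselves be
disparity signals; the removed-case count is reported for this reason.
The chi-square is an omnibus allocation test and does not localise which
variant drives a difference beyond standardized residuals. Bootstrap CIs
of small groups (n ≲ 20) are noisy, and the CI-overlap reading of two
group intervals is a conservative visual heuristic, not a formal
two-sample test.
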