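"""Within-variant disparity metrics with bootstrap confidence intervals.

For the cases of a single treatment variant, split by a sensitive
attribute, this module computes:

* **single-step metrics** — the mean duration of one treatment step
  (hours) and the mean SOFA score at its start (a severity control
  variable; when an event carries no SOFA value, the next available value
  within the same case is used);
* **multiple-step metrics** — the mean time between adjacent tokens of the
  signature (hours); the admission → first-start gap is the time to first
  treatment, the headline delay metric;
* **outcome metrics** — mortality proportion and mean length of stay.

Every point estimate is a group mean accompanied by a 90% percentile
bootstrap confidence interval of the mean, deterministic under a fixed
seed.  :func:`build_variant_panel` assembles the full per-variant panel:
every adjacent token gap exactly once, every step's duration and SOFA, and
the outcomes, per group.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataContractError
from .eventlog import Case
from .variants import VariantSignature, case_to_variant, case_tokens

HOUR = 3600.0


@dataclass
class GroupMetric:
    """An aggregated statistic for one patient group.

    ``estimate`` is the group mean; ``(ci_low, ci_high)`` the percentile
    bootstrap interval of the mean at the configured level.  ``n_excluded``
    counts cases that could not contribute (e.g. no SOFA value anywhere in
    the case, missing outcome).
    """

    name: str
    group: str
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    unit: str
    n_excluded: int = 0


@dataclass
class VariantMetricPanel:
    """All disparity metrics of one variant, per group."""

    signature: VariantSignature
    group_sizes: dict[str, int] = field(default_factory=dict)
    gaps: list[dict[str, GroupMetric]] = field(default_factory=list)  # one per adjacent pair
    durations: dict[str, dict[str, GroupMetric]] = field(default_factory=dict)
    sofa: dict[str, dict[str, GroupMetric]] = field(default_factory=dict)
    outcomes: dict[str, dict[str, GroupMetric]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def all_metrics(self) -> list[GroupMetric]:
        out: list[GroupMetric] = []
        for d in self.gaps:
            out.extend(d.values())
        for coll in (self.durations, self.sofa, self.outcomes):
            for d in coll.values():
                out.extend(d.values())
        return out


def bootstrap_ci(
    values,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean.

    Resamples ``values`` with replacement ``B`` times and returns the
    (1−level)/2 and 1−(1−level)/2 quantiles of the resampled means.
    Deterministic given ``seed``.  A single observation yields the
    degenerate interval [v, v] with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DataContractError("bootstrap_ci requires a non-empty sample")
    if not 0 < level < 1:
        raise DataContractError(f"level must be in (0, 1), got {level}")
    if B < 1:
        raise DataContractError(f"B must be >= 1, got {B}")
    if x.size == 1:
        warnings.warn("bootstrap interval of a single observation is degenerate")
        return float(x[0]), float(x[0])
    if np.ptp(x) == 0.0:
        return float(x[0]), float(x[0])
    res = stats.bootstrap(
        (x,), np.mean, n_resamples=B, confidence_level=level,
        method="percentile", rng=np.random.default_rng(seed), vectorized=True,
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def _metric_seed(seed: int | None, *parts: str) -> int | None:
    """A stable per-metric sub-seed so panels are reproducible regardless
    of the order in which metrics are computed."""
    if seed is None:
        return None
    h = zlib.crc32("|".join(parts).encode())
    return (int(seed) * 1_000_003 + h) % (2**31)


def _group_cases(cases: list[Case], split) -> dict[str, list[Case]]:
    if split is None:
        return {"all": list(cases)}
    of = split.group_of()
    out: dict[str, list[Case]] = {g: [] for g in split.test_groups()}
    for c in cases:
        g = of.get(c.case_id)
        if g in out:
            out[g].append(c)
    return out


def _aggregate(
    name: str,
    unit: str,
    per_group_values: dict[str, list[float]],
    per_group_excluded: dict[str, int],
    level: float,
    B: int,
    seed: int | None,
) -> dict[str, GroupMetric]:
    out = {}
    for g, vals in per_group_values.items():
        if not vals:
            continue
        lo, hi = bootstrap_ci(vals, level=level, B=B, seed=_metric_seed(seed, name, g))
        out[g] = GroupMetric(name, g, len(vals), float(np.mean(vals)), lo, hi,
                             unit, per_group_excluded.get(g, 0))
    return out


def _nth_event(case: Case, activity: str, occurrence: int):
    """The event behind the ``occurrence``-th start:activity token."""
    k = -1
    for tok in case_tokens(case):
        if tok.kind == "start" and tok.label == activity:
            k += 1
            if k == occurrence:
                return tok.event
    return None


def _check_same_variant(cases: list[Case]) -> VariantSignature:
    sigs = {case_to_variant(c) for c in cases}
    if len(sigs) != 1:
        raise DataContractError(f"cases span {len(sigs)} variants; expected exactly one")
    return next(iter(sigs))


def step_duration(
    cases: list[Case],
    activity: str,
    occurrence: int = 0,
    split=None,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> dict[str, GroupMetric]:
    """Mean duration (hours) of one treatment step, per group."""
    sig = _check_same_variant(cases)
    if sig.tokens.count(f"start:{activity}") <= occurrence:
        raise DataContractError(
            f"occurrence {occurrence} of {activity!r} not in signature {sig}")
    vals: dict[str, list[float]] = {}
    exc: dict[str, int] = {}
    for g, gc in _group_cases(cases, split).items():
        vals[g], exc[g] = [], 0
        for c in gc:
            e = _nth_event(c, activity, occurrence)
            if e is None or e.end is None:
                exc[g] += 1  # open-ended episode: no duration
                continue
            vals[g].append((e.end - e.start).total_seconds() / HOUR)
    name = f"duration {activity}" + (f" #{occurrence + 1}" if occurrence else "")
    return _aggregate(name, "hours", vals, exc, level, B, seed)


def sofa_at_start(
    cases: list[Case],
    activity: str,
    occurrence: int = 0,
    split=None,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> dict[str, GroupMetric]:
    """Mean SOFA score at the start of one treatment step, per group.

    When the event itself carries no SOFA value, the next available value
    among the case's subsequent events (in time order) is used; cases with
    no SOFA value anywhere are excluded and counted.
    """
    sig = _check_same_variant(cases)
    if sig.tokens.count(f"start:{activity}") <= occurrence:
        raise DataContractError(
            f"occurrence {occurrence} of {activity!r} not in signature {sig}")
    vals: dict[str, list[float]] = {}
    exc: dict[str, int] = {}
    for g, gc in _group_cases(cases, split).items():
        vals[g], exc[g] = [], 0
        for c in gc:
            target = _nth_event(c, activity, occurrence)
            sofa = _sofa_with_fallback(c, target)
            if sofa is None:
                exc[g] += 1
            else:
                vals[g].append(float(sofa))
    name = f"sofa {activity}" + (f" #{occurrence + 1}" if occurrence else "")
    return _aggregate(name, "SOFA points", vals, exc, level, B, seed)


def _sofa_with_fallback(case: Case, event) -> int | None:
    if event is None:
        return None
    if event.sofa_start is not None:
        return event.sofa_start
    later = sorted((e for e in case.events if e.start >= event.start and e is not event),
                   key=lambda e: (e.start, e.activity))
    for e in later:
        if e.sofa_start is not None:
            return e.sofa_start
    return None


def inter_step_time(
    cases: list[Case],
    token_index: int,
    split=None,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> dict[str, GroupMetric]:
    """Mean time (hours) between signature tokens i and i+1, per group.

    ``token_index`` 0 (admission → first start token) is the time to first
    treatment.
    """
    sig = _check_same_variant(cases)
    if not 0 <= token_index < len(sig) - 1:
        raise DataContractError(
            f"token_index {token_index} has no successor in signature of length {len(sig)}")
    vals: dict[str, list[float]] = {}
    for g, gc in _group_cases(cases, split).items():
        vals[g] = []
        for c in gc:
            toks = case_tokens(c)
            gap = (toks[token_index + 1].time - toks[token_index].time).total_seconds() / HOUR
            vals[g].append(gap)
    name = f"gap {sig.tokens[token_index]} → {sig.tokens[token_index + 1]}"
    return _aggregate(name, "hours", vals, {}, level, B, seed)


def outcome_stats(
    cases: list[Case],
    split=None,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> dict[str, dict[str, GroupMetric]]:
    """Mortality proportion and mean length of stay, per group."""
    mort: dict[str, list[float]] = {}
    los: dict[str, list[float]] = {}
    mort_exc: dict[str, int] = {}
    los_exc: dict[str, int] = {}
    for g, gc in _group_cases(cases, split).items():
        mort[g], los[g], mort_exc[g], los_exc[g] = [], [], 0, 0
        for c in gc:
            m = c.patient.outcomes.get("mortality")
            if m is None:
                mort_exc[g] += 1
            else:
                mort[g].append(1.0 if m else 0.0)
            stay = c.patient.outcomes.get("length_of_stay")
            if stay is None:
                los_exc[g] += 1
            else:
                los[g].append(float(stay))
    return {
        "mortality": _aggregate("mortality", "proportion", mort, mort_exc, level, B, seed),
        "length_of_stay": _aggregate("length of stay", "hours", los, los_exc, level, B, seed),
    }


def build_variant_panel(
    cases: list[Case],
    split,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> VariantMetricPanel:
    """Assemble the full metric panel of one variant.

    Enumerates every adjacent token pair once (gaps), every start token of
    the signature (duration and SOFA of that occurrence), and the two
    outcomes, each per group with its bootstrap CI.  Groups with no case
    in this variant are omitted with a note.
    """
    sig = _check_same_variant(cases)
    grouped = _group_cases(cases, split)
    panel = VariantMetricPanel(signature=sig,
                               group_sizes={g: len(gc) for g, gc in grouped.items()})
    for g, gc in grouped.items():
        if not gc:
            panel.notes.append(f"group {g!r} has no case in this variant; omitted")
    for i in range(len(sig) - 1):
        panel.gaps.append(inter_step_time(cases, i, split, level, B, seed))
    occurrence_count: dict[str, int] = {}
    for tok in sig.tokens:
        if tok.startswith("start:"):
            activity = tok[len("start:"):]
            k = occurrence_count.get(activity, 0)
            occurrence_count[activity] = k + 1
            key = activity if k == 0 else f"{activity}#{k + 1}"
            panel.durations[key] = step_duration(cases, activity, k, split, level, B, seed)
            panel.sofa[key] = sofa_at_start(cases, activity, k, split, level, B, seed)
    panel.outcomes = outcome_stats(cases, split, level, B, seed)
    return panel


def cis_disjoint(a: GroupMetric, b: GroupMetric) -> bool:
    """True when two group CIs do not overlap (a crude disparity flag)."""
    return a.ci_low > b.ci_high or b.ci_low > a.ci_high
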