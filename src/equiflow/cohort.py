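"""Cohort homogenisation, sensitive-attribute splits, baseline tables.

A cohort is homogenised by primary diagnosis, minimum age and an "any-of"
comorbidity requirement before disparity analysis, so that variant
differences reflect care delivery rather than case mix.  The cohort is then
partitioned by a sensitive attribute (sex, language, ethnicity,
insurance, ...) and summarised in a baseline-characteristics table:
categorical attributes as counts with integer percentages and a Pearson
chi-square test (Yates continuity correction for 2×2 tables), numeric
attributes as median (IQR) with a Mann–Whitney rank test.  Percentages are
rounded half-away-from-zero, the convention of printed clinical tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataContractError
from .eventlog import EventLog

logger = logging.getLogger(__name__)

MISSING_GROUP = "missing"


@dataclass
class CohortSpec:
    """Inclusion rules: diagnosis, minimum age, any-of comorbidity set.

    All fields default to ``None`` (no filtering), so an empty spec is the
    identity.  The sepsis study configuration is
    ``CohortSpec(required_diagnosis={"sepsis"}, min_age=18,
    required_comorbidities={"chf", "mi", "copd"})``.
    """

    required_diagnosis: set[str] | None = None
    min_age: int | None = None
    required_comorbidities: set[str] | None = None
    diagnosis_attribute: str = "diagnosis"
    age_attribute: str = "age"

    def __post_init__(self) -> None:
        if self.min_age is not None and self.min_age < 0:
            raise ConfigError(f"min_age must be >= 0, got {self.min_age}")


@dataclass
class CohortFlow:
    """Stage-wise inclusion/exclusion counts of cohort filtering."""

    n_input: int = 0
    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, excluded, remaining)

    @property
    def n_final(self) -> int:
        return self.stages[-1][2] if self.stages else self.n_input


@dataclass
class CohortSplit:
    """Disjoint patient groups defined by one sensitive attribute."""

    attribute: str
    groups: dict[str, set[str]] = field(default_factory=dict)
    missing_group: str | None = None  # label of the missing-value group, if any

    def test_groups(self) -> dict[str, set[str]]:
        """Groups entering hypothesis tests (missing-value group excluded)."""
        return {g: ids for g, ids in self.groups.items() if g != self.missing_group}

    def group_of(self) -> dict[str, str]:
        return {cid: g for g, ids in self.groups.items() for cid in ids}


def apply_cohort_spec(log: EventLog, spec: CohortSpec) -> tuple[EventLog, CohortFlow]:
    """Filter the log to the cohort, reporting counts at each stage.

    Filters are applied diagnosis → age → comorbidity; they are a pure
    conjunction, so the final cohort is order-independent even though the
    stage counts mirror an inclusion/exclusion flow diagram.
    """
    flow = CohortFlow(n_input=len(log.patients))
    frame = log.patients_frame()
    if frame.empty:
        return log.restrict([]), flow
    keep = frame

    if spec.required_diagnosis is not None:
        if spec.diagnosis_attribute not in keep.columns:
            raise ConfigError(f"patient table has no attribute {spec.diagnosis_attribute!r}")
        mask = keep[spec.diagnosis_attribute].isin(spec.required_diagnosis)
        flow.stages.append(("diagnosis", int((~mask).sum()), int(mask.sum())))
        keep = keep[mask]
    if spec.min_age is not None:
        if spec.age_attribute not in keep.columns:
            raise ConfigError(f"patient table has no attribute {spec.age_attribute!r}")
        ages = pd.to_numeric(keep[spec.age_attribute], errors="coerce")
        mask = ages >= spec.min_age
        flow.stages.append(("age", int((~mask).sum()), int(mask.sum())))
        keep = keep[mask]
    if spec.required_comorbidities is not None:
        cols = [f"comorbidity_{c}" for c in sorted(spec.required_comorbidities)]
        missing_cols = [c for c in cols if c not in keep.columns]
        present = [c for c in cols if c in keep.columns]
        if not present and missing_cols:
            raise ConfigError(f"patient table has none of the comorbidity flags {missing_cols}")
        mask = keep[present].astype(float).fillna(0).sum(axis=1) > 0 if present else \
            pd.Series(False, index=keep.index)
        flow.stages.append(("comorbidity", int((~mask).sum()), int(mask.sum())))
        keep = keep[mask]

    return log.restrict(keep["case_id"].tolist()), flow


def split_by_attribute(
    log: EventLog,
    attribute: str,
    level_map: dict[str, str] | None = None,
    default_level: str | None = None,
) -> CohortSplit:
    """Partition the cohort by one sensitive attribute.

    ``level_map`` regroups raw values into analysis levels (e.g.
    ``{"ENGLISH": "ESP"}`` with ``default_level="non-ESP"`` for a
    language-proficiency split).  Patients with a missing value form an
    explicit "missing" group that is excluded from tests by default.
    """
    groups: dict[str, set[str]] = {}
    missing: set[str] = set()
    found = False
    for p in log.patients:
        raw = p.attributes.get(attribute)
        if attribute in p.attributes:
            found = True
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            missing.add(p.case_id)
            continue
        raw = str(raw)
        if level_map is not None:
            level = level_map.get(raw, default_level)
            if level is None:
                missing.add(p.case_id)
                continue
        else:
            level = raw
        groups.setdefault(level, set()).add(p.case_id)
    if not found and log.patients:
        raise ConfigError(f"attribute {attribute!r} not present in the patient table")
    if len(groups) == 1:
        logger.warning("attribute %r has a single observed level %r",
                       attribute, next(iter(groups)))
    split = CohortSplit(attribute=attribute,
                        groups=dict(sorted(groups.items())))
    if missing:
        split.groups[MISSING_GROUP] = missing
        split.missing_group = MISSING_GROUP
    return split


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class AttributeBlock:
    """One attribute's rows of a baseline table."""

    attribute: str
    kind: str  # "categorical" | "numeric"
    # categorical: level -> {group: (count, pct)}; numeric: group -> (median, iqr)
    cells: dict[str, Any] = field(default_factory=dict)
    n_missing: dict[str, int] = field(default_factory=dict)
    test_name: str | None = None
    statistic: float | None = None
    p_value: float | None = None


@dataclass
class BaselineTable:
    """Baseline characteristics per group, with between-group tests."""

    attribute: str  # the splitting attribute
    group_sizes: dict[str, int] = field(default_factory=dict)
    blocks: list[AttributeBlock] = field(default_factory=list)


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2×2 table [[a, b], [c, d]].

    Returns (statistic, p).  Thin wrapper over the standard contingency
    test; kept as a named function because 2×2 tables with the Yates
    correction are the workhorse of baseline-characteristics comparisons.
    """
    res = stats.chi2_contingency(np.array([[a, b], [c, d]]), correction=True)
    return float(res.statistic), float(res.pvalue)


def baseline_table(
    split: CohortSplit,
    patients_frame: pd.DataFrame,
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
) -> BaselineTable:
    """Build a baseline-characteristics table for a cohort split.

    Between-group p-values are computed only for exactly two (non-missing)
    groups: Pearson chi-square for categorical attributes (Yates-corrected
    when the contingency table is 2×2) and the Mann–Whitney U rank test for
    numeric attributes.  Missing attribute values are excluded from the
    test denominator and reported separately.  A zero-count group
    suppresses the test and leaves descriptives only.
    """
    categorical = categorical or []
    numeric = numeric or []
    frame = patients_frame.set_index("case_id")
    groups = split.test_groups()
    table = BaselineTable(attribute=split.attribute,
                          group_sizes={g: len(ids) for g, ids in groups.items()})
    do_tests = len(groups) == 2 and all(len(ids) > 0 for ids in groups.values())

    for attr in categorical:
        if attr not in frame.columns:
            raise ConfigError(f"attribute {attr!r} not in patient table")
        block = AttributeBlock(attribute=attr, kind="categorical")
        per_group: dict[str, pd.Series] = {}
        for g, ids in groups.items():
            vals = frame.loc[frame.index.intersection(ids), attr]
            missing = vals.isna() | (vals.astype(str).str.strip() == "")
            block.n_missing[g] = int(missing.sum())
            per_group[g] = vals[~missing].astype(str)
        levels = sorted(set().union(*(set(v.unique()) for v in per_group.values())) or set())
        for level in levels:
            block.cells[level] = {}
            for g, ids in groups.items():
                n = len(ids)
                count = int((per_group[g] == level).sum())
                pct = round_half_away(100.0 * count / n) if n else 0
                block.cells[level][g] = (count, pct)
        if do_tests and len(levels) >= 2:
            counts = np.array([[int((per_group[g] == lv).sum()) for lv in levels]
                               for g in groups])
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] >= 2:
                correction = counts.shape == (2, 2)
                res = stats.chi2_contingency(counts, correction=correction)
                block.test_name = "chi-square (Yates)" if correction else "chi-square"
                block.statistic, block.p_value = float(res.statistic), float(res.pvalue)
        table.blocks.append(block)

    for attr in numeric:
        if attr not in frame.columns:
            raise ConfigError(f"attribute {attr!r} not in patient table")
        block = AttributeBlock(attribute=attr, kind="numeric")
        samples: dict[str, np.ndarray] = {}
        for g, ids in groups.items():
            vals = pd.to_numeric(frame.loc[frame.index.intersection(ids), attr], errors="coerce")
            block.n_missing[g] = int(vals.isna().sum())
            x = vals.dropna().to_numpy()
            samples[g] = x
            if len(x):
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                block.cells[g] = (float(med), float(q3 - q1))
            else:
                block.cells[g] = (math.nan, math.nan)
        if do_tests and all(len(x) > 0 for x in samples.values()):
            xs = list(samples.values())
            res = stats.mannwhitneyu(xs[0], xs[1], alternative="two-sided")
            block.test_name = "Mann-Whitney U"
            block.statistic, block.p_value = float(res.statistic), float(res.pvalue)
        table.blocks.append(block)

    return table
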