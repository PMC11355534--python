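"""Global treatment-allocation comparison via Pearson chi-square tests.

The global level of the disparity analysis asks whether two patient groups
are allocated to the same distribution over treatment variants.  For each
unordered group pair, the per-variant case counts form a 2×V contingency
table tested with Pearson's chi-square under the null of equal variant
distributions.  Variants whose expected count falls below 5 in any cell
are pooled into an "other" column first — the minimum-support filter
bounds the totals, not the per-group expecteds, so the approximation needs
its own guard.  Raw p-values are always reported; with more than two
groups a Bonferroni-adjusted p accompanies each pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .cohort import CohortSplit
from .errors import DataContractError
from .variants import VariantTable

EXPECTED_MIN = 5.0


@dataclass
class GlobalTestResult:
    """Chi-square comparison of two groups' variant distributions."""

    group_pair: tuple[str, str]
    observed: np.ndarray  # 2 x V counts after pooling
    column_labels: list[str]  # variant labels, possibly ending in "other"
    statistic: float
    df: int
    p_value: float
    pooled: bool = False
    n_pooled_columns: int = 0
    residuals: np.ndarray | None = None  # standardized (O-E)/sqrt(E)
    p_adjusted: float | None = None  # Bonferroni, when part of a pairwise family


def variant_contingency(
    table: VariantTable,
    split: CohortSplit,
    pair: tuple[str, str],
) -> tuple[np.ndarray, list[str]]:
    """2×V count matrix of the pair's cases over the surviving variants.

    Zero cells are preserved: a variant absent from one group is exactly
    the kind of allocation difference the test must see.
    """
    g1, g2 = pair
    for g in pair:
        if g not in split.groups:
            raise DataContractError(f"group {g!r} not in split on {split.attribute!r}")
    if len(table) < 2:
        raise DataContractError(
            f"need at least 2 variants for a distribution comparison, have {len(table)}")
    counts = np.array([[row.group_counts.get(g, 0) for row in table.rows] for g in pair])
    labels = [str(row.signature) for row in table.rows]
    return counts, labels


def chi_square_variants(
    contingency: np.ndarray,
    column_labels: list[str] | None = None,
    group_pair: tuple[str, str] = ("group1", "group2"),
    pool_threshold: float = EXPECTED_MIN,
) -> GlobalTestResult:
    """Pearson chi-square on a groups × variants contingency table.

    Tables larger than 2×2 use the plain Σ(O−E)²/E statistic; a 2×2 table
    (possible after pooling) gets the Yates continuity correction.
    Columns with any expected count below ``pool_threshold`` are merged
    into a trailing "other" column before testing.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataContractError(f"contingency table must be at least 2x2, got {obs.shape}")
    row_totals = obs.sum(axis=1)
    if (row_totals == 0).any():
        bad = [i for i, t in enumerate(row_totals) if t == 0]
        names = [group_pair[i] if i < len(group_pair) else str(i) for i in bad]
        raise DataContractError(f"group(s) with zero total cases: {names}")
    labels = list(column_labels) if column_labels is not None else \
        [f"variant {i}" for i in range(obs.shape[1])]

    expected = np.outer(row_totals, obs.sum(axis=0)) / obs.sum()
    pool_mask = (expected < pool_threshold).any(axis=0)
    pooled = False
    n_pooled = 0
    if pool_mask.any() and (~pool_mask).sum() >= 1:
        keep = obs[:, ~pool_mask]
        other = obs[:, pool_mask].sum(axis=1, keepdims=True)
        n_pooled = int(pool_mask.sum())
        if n_pooled > 1 or (~pool_mask).sum() >= 2:
            obs = np.hstack([keep, other]) if other.sum() > 0 else keep
            labels = [l for l, m in zip(labels, pool_mask) if not m]
            if other.sum() > 0:
                labels.append("other")
            pooled = True
    if obs.shape[1] < 2:
        raise DataContractError("fewer than 2 variant columns remain after pooling")

    correction = obs.shape == (2, 2)
    res = stats.chi2_contingency(obs, correction=correction)
    expected = np.asarray(res.expected_freq)
    residuals = (obs - expected) / np.sqrt(np.where(expected > 0, expected, np.nan))
    return GlobalTestResult(
        group_pair=group_pair,
        observed=obs,
        column_labels=labels,
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        pooled=pooled,
        n_pooled_columns=n_pooled if pooled else 0,
        residuals=residuals,
    )


def pairwise_global_tests(
    table: VariantTable,
    split: CohortSplit,
    bonferroni: bool | None = None,
) -> list[GlobalTestResult]:
    """One chi-square test per unordered pair of (non-missing) groups.

    ``bonferroni=None`` applies the adjustment automatically when there is
    more than one pair; a single pair carries only the raw p-value.
    """
    groups = [g for g in split.test_groups() if split.groups[g]]
    if len(groups) < 2:
        raise DataContractError(f"need at least 2 non-empty groups, have {len(groups)}")
    pairs = list(combinations(groups, 2))
    if bonferroni is None:
        bonferroni = len(pairs) > 1
    results = []
    for pair in pairs:
        counts, labels = variant_contingency(table, split, pair)
        res = chi_square_variants(counts, labels, pair)
        if bonferroni:
            res.p_adjusted = min(1.0, res.p_value * len(pairs))
        results.append(res)
    return results
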