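"""Treatment variants: abstracting a case to its ordered start/end token stream.

Two cases belong to the same treatment variant when their treatments started
and ended in exactly the same order.  Each case is flattened into a token
sequence over {"admission", "discharge"} ∪ {"start:"+activity,
"end:"+activity}; exact sequence equality defines the variant.

Clinical timestamps are coarse (minute resolution), so simultaneous tokens
are common.  The canonical tie-break — end-tokens before start-tokens at
equal time, then lexicographic label — keeps variant extraction
deterministic and stops a treatment that ends the same minute another
starts from spawning a spurious "overlap" variant.  This ordering is the
single place where the variant definition is under-determined by the data,
and it is applied uniformly everywhere tokens are sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataContractError
from .eventlog import ADMISSION, DISCHARGE, Case, TreatmentEvent

#: tie-break rank at equal timestamps: admission first, then end-tokens,
#: then start-tokens, discharge last
_KIND_RANK = {ADMISSION: 0, "end": 1, "start": 2, DISCHARGE: 3}


@dataclass(frozen=True)
class TokenOccurrence:
    """One token of one case: its timestamp and the event it came from."""

    time: pd.Timestamp
    kind: str  # admission | end | start | discharge
    label: str  # activity, or "" for milestones
    event: TreatmentEvent | None = None
    #: end token of a zero-duration episode: must not jump before its own start
    zero_length: bool = False

    @property
    def token(self) -> str:
        if self.kind in (ADMISSION, DISCHARGE):
            return self.kind
        return f"{self.kind}:{self.label}"

    def sort_key(self):
        # A zero-duration episode's end shares rank with start tokens and a
        # trailing sub-key, so it sorts immediately after its own start
        # instead of before it (the end-before-start rule is for *other*
        # episodes closing at that timestamp).
        if self.zero_length:
            return (self.time, _KIND_RANK["start"], self.label, 1)
        return (self.time, _KIND_RANK[self.kind], self.label, 0)


@dataclass(frozen=True)
class VariantSignature:
    """The ordered token sequence identifying one treatment variant."""

    tokens: tuple[str, ...]

    def __str__(self) -> str:
        return " → ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def validate(self) -> None:
        """Raise if the sequence is not a well-formed variant signature.

        Requirements: starts with "admission"; "discharge", if present, is
        last; every end-token closes a previously opened start-token of the
        same activity (matching by counting — interleavings are legal).
        Open intervals (start without end) are legal: they represent
        episodes censored at data extraction.
        """
        if not self.tokens or self.tokens[0] != ADMISSION:
            raise DataContractError(f"signature must begin with 'admission': {self}")
        if ADMISSION in self.tokens[1:]:
            raise DataContractError(f"repeated admission token: {self}")
        if DISCHARGE in self.tokens and self.tokens[-1] != DISCHARGE:
            raise DataContractError(f"'discharge' must be the final token: {self}")
        open_counts: dict[str, int] = {}
        for tok in self.tokens[1:]:
            if tok == DISCHARGE:
                continue
            kind, _, label = tok.partition(":")
            if kind == "start":
                open_counts[label] = open_counts.get(label, 0) + 1
            elif kind == "end":
                if open_counts.get(label, 0) <= 0:
                    raise DataContractError(f"'end:{label}' without matching start: {self}")
                open_counts[label] -= 1
            else:
                raise DataContractError(f"unknown token {tok!r}: {self}")


@dataclass
class VariantRow:
    signature: VariantSignature
    count: int
    group_counts: dict[str, int] = field(default_factory=dict)
    case_ids: list[str] = field(default_factory=list)


@dataclass
class VariantTable:
    """Variants with total and per-group case counts, descending by count."""

    rows: list[VariantRow] = field(default_factory=list)
    n_cases: int = 0
    n_removed: int = 0  # cases dropped by support filtering

    def __len__(self) -> int:
        return len(self.rows)

    def signatures(self) -> list[VariantSignature]:
        return [r.signature for r in self.rows]


def case_tokens(case: Case) -> list[TokenOccurrence]:
    """The case's token stream in canonical order.

    Milestones and each event's start/end points are merged and sorted by
    (timestamp, tie-break rank, label); deterministic for any input order
    of the underlying rows.
    """
    toks = [TokenOccurrence(case.admission.time, ADMISSION, "")]
    for e in case.events:
        toks.append(TokenOccurrence(e.start, "start", e.activity, e))
        if e.end is not None:
            toks.append(TokenOccurrence(e.end, "end", e.activity, e,
                                        zero_length=e.end == e.start))
    if case.discharge is not None:
        toks.append(TokenOccurrence(case.discharge.time, DISCHARGE, ""))
    toks.sort(key=TokenOccurrence.sort_key)
    return toks


def case_to_variant(case: Case) -> VariantSignature:
    """Abstract a case to its treatment variant."""
    sig = VariantSignature(tuple(t.token for t in case_tokens(case)))
    sig.validate()
    return sig


def compute_variants(cases: list[Case], split=None) -> VariantTable:
    """Group cases by exact signature equality and tabulate counts.

    ``split`` (a :class:`~equiflow.cohort.CohortSplit`) supplies per-group
    counts; cases outside every group are counted in the totals only.
    Rows are ordered by descending total count, ties broken by token
    sequence so the table is deterministic.
    """
    group_of: dict[str, str] = {}
    group_labels: list[str] = []
    if split is not None:
        group_labels = list(split.groups)
        for label, ids in split.groups.items():
            for cid in ids:
                group_of[cid] = label

    by_sig: dict[VariantSignature, VariantRow] = {}
    for case in cases:
        sig = case_to_variant(case)
        row = by_sig.get(sig)
        if row is None:
            row = by_sig[sig] = VariantRow(sig, 0, {g: 0 for g in group_labels})
        row.count += 1
        row.case_ids.append(case.case_id)
        g = group_of.get(case.case_id)
        if g is not None:
            row.group_counts[g] += 1
    rows = sorted(by_sig.values(), key=lambda r: (-r.count, r.signature.tokens))
    return VariantTable(rows=rows, n_cases=len(cases))


def filter_variants(table: VariantTable, min_support: int = 50) -> VariantTable:
    """Drop variants with fewer than ``min_support`` cases.

    Infrequent variants lack the statistical support for group comparison;
    the default threshold keeps variants of at least 50 patients.  Removed
    case counts are carried on the returned table.  Idempotent, and
    monotone in ``min_support``.
    """
    if min_support < 1:
        raise DataContractError(f"min_support must be >= 1, got {min_support}")
    kept = [r for r in table.rows if r.count >= min_support]
    removed = sum(r.count for r in table.rows if r.count < min_support)
    if not kept:
        import logging

        logging.getLogger(__name__).warning(
            "all %d variants fall below support %d; downstream tests will refuse to run",
            len(table.rows), min_support)
    return VariantTable(rows=kept, n_cases=table.n_cases,
                        n_removed=table.n_removed + removed)


def cases_of_variant(cases: list[Case], signature: VariantSignature) -> list[Case]:
    """The subset of cases whose variant equals ``signature``."""
    return [c for c in cases if case_to_variant(c) == signature]
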