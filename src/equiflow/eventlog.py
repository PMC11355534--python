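"""Interval-event treatment logs: data model, CSV readers/writers, validation.

The central object is the :class:`EventLog`: a collection of treatment
episodes (:class:`TreatmentEvent`, each an interval with start and end
timestamps), stay milestones (:class:`Milestone`: admission / discharge,
instantaneous anchor points rather than treatments), and one
:class:`PatientRecord` per case carrying sensitive attributes, comorbidity
flags and outcomes.  Grouping all events of one patient yields a
:class:`Case` — the full ordered set of treatment steps of a single stay.

Dirty rows are quarantined with a reason instead of aborting: EHR extracts
are messy, and an equity audit must account for every excluded row.
Timestamps are timezone-naive (de-identified hospital data carries shifted
dates with no meaningful timezone); durations are reported in hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataContractError

logger = logging.getLogger(__name__)

#: canonical labels for the stay anchor milestones
ADMISSION = "admission"
DISCHARGE = "discharge"

_CANONICAL_EVENT_COLUMNS = ("case_id", "activity", "start", "end", "sofa_start", "amount", "unit")
_PATIENT_RESERVED = ("case_id", "mortality", "length_of_stay")


@dataclass
class ColumnMapping:
    """Maps the columns of an events CSV onto the canonical schema.

    ``timestamp_format`` is a :func:`time.strftime`-style pattern applied to
    both start and end columns.  Milestone rows are recognised by their
    activity label (``admission_label`` / ``discharge_label``).
    """

    case_id: str = "case_id"
    activity: str = "activity"
    start: str = "start"
    end: str = "end"
    sofa_start: str | None = "sofa_start"
    amount: str | None = "amount"
    unit: str | None = "unit"
    timestamp_format: str = "%Y-%m-%d %H:%M:%S"
    admission_label: str = ADMISSION
    discharge_label: str = DISCHARGE


@dataclass
class TreatmentEvent:
    """One treatment episode of one patient.

    ``end`` may be absent for an episode still open at data extraction.
    ``sofa_start`` is the 24-hour SOFA illness-severity score (integer
    0–24) recorded at the start of the episode, if available.
    """

    case_id: str
    activity: str
    start: pd.Timestamp
    end: pd.Timestamp | None = None
    sofa_start: int | None = None
    amount: float | None = None
    unit: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def duration_hours(self) -> float | None:
        if self.end is None:
            return None
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class Milestone:
    """An instantaneous stay anchor: ICU admission or discharge."""

    case_id: str
    kind: str  # ADMISSION or DISCHARGE
    time: pd.Timestamp


@dataclass
class PatientRecord:
    """Per-patient attributes, comorbidity flags and outcomes."""

    case_id: str
    attributes: dict[str, Any] = field(default_factory=dict)
    comorbidities: set[str] = field(default_factory=set)
    outcomes: dict[str, Any] = field(default_factory=dict)


@dataclass
class Violation:
    kind: str
    case_id: str
    description: str
    fatal: bool = False


@dataclass
class ValidationReport:
    """Outcome of structural validation of an :class:`EventLog`."""

    n_cases: int = 0
    n_events: int = 0
    violations: list[Violation] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(v.fatal for v in self.violations)

    def add(self, kind: str, case_id: str, description: str, fatal: bool = False) -> None:
        self.violations.append(Violation(kind, case_id, description, fatal))


@dataclass
class EventLog:
    """Treatment events + milestones + patient records of one cohort."""

    events: list[TreatmentEvent] = field(default_factory=list)
    milestones: list[Milestone] = field(default_factory=list)
    patients: list[PatientRecord] = field(default_factory=list)
    #: quarantined input rows from ingestion; not part of log identity
    ingest_report: ValidationReport | None = field(default=None, compare=False)

    def case_ids(self) -> list[str]:
        return [p.case_id for p in self.patients]

    def patient_map(self) -> dict[str, PatientRecord]:
        return {p.case_id: p for p in self.patients}

    def patients_frame(self) -> pd.DataFrame:
        """Flatten patient records into a DataFrame (one row per case)."""
        rows = []
        for p in self.patients:
            row: dict[str, Any] = {"case_id": p.case_id}
            row.update(p.attributes)
            for c in sorted(p.comorbidities):
                row[f"comorbidity_{c}"] = 1
            row.update(p.outcomes)
            rows.append(row)
        frame = pd.DataFrame(rows)
        comorb = [c for c in frame.columns if c.startswith("comorbidity_")]
        if comorb:
            frame[comorb] = frame[comorb].fillna(0).astype(int)
        return frame

    def restrict(self, case_ids: Iterable[str]) -> "EventLog":
        """A new log containing only the given cases (order preserved)."""
        keep = set(case_ids)
        return EventLog(
            events=[e for e in self.events if e.case_id in keep],
            milestones=[m for m in self.milestones if m.case_id in keep],
            patients=[p for p in self.patients if p.case_id in keep],
        )


@dataclass
class Case:
    """All events of one patient, with the stay anchors and the record."""

    case_id: str
    patient: PatientRecord
    admission: Milestone
    discharge: Milestone | None = None
    events: list[TreatmentEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_ts(raw: Any, fmt: str) -> pd.Timestamp | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    ts = pd.to_datetime(text, format=fmt, errors="coerce")
    return None if pd.isna(ts) else ts


def _parse_optional_int(raw: Any) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    return int(float(text))


def _parse_optional_float(raw: Any) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    return float(text)


def _clean_str(raw: Any) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    return str(raw).strip()


def read_event_log(
    events_path: str | Path,
    patients_path: str | Path,
    mapping: ColumnMapping | None = None,
) -> EventLog:
    """Read an events CSV and a patient-attribute CSV into an :class:`EventLog`.

    Rows whose mandatory fields (case id, activity, start timestamp) do not
    parse are quarantined into ``log.ingest_report`` rather than raising;
    rows with ``end < start`` are likewise excluded with a "negative
    duration" violation.  Rows whose activity equals the configured
    admission/discharge label become milestones.
    """
    mapping = mapping or ColumnMapping()
    events_path, patients_path = Path(events_path), Path(patients_path)
    for p in (events_path, patients_path):
        if not p.exists():
            raise ConfigError(f"input file does not exist: {p}")

    try:
        raw_events = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataContractError(f"events file is empty: {events_path}")
    for col in (mapping.case_id, mapping.activity, mapping.start, mapping.end):
        if col not in raw_events.columns:
            raise ConfigError(f"events file is missing mandatory column {col!r}")

    report = ValidationReport()
    events: list[TreatmentEvent] = []
    milestones: list[Milestone] = []
    for idx, row in raw_events.iterrows():
        case_id = _clean_str(row[mapping.case_id])
        activity = _clean_str(row[mapping.activity])
        if not case_id or not activity:
            report.add("missing mandatory field", case_id or f"<row {idx}>",
                       "empty case_id or activity", fatal=False)
            continue
        start = _parse_ts(row[mapping.start], mapping.timestamp_format)
        if start is None:
            report.add("unparseable start", case_id, f"row {idx}: {row[mapping.start]!r}")
            continue
        if activity == mapping.admission_label:
            milestones.append(Milestone(case_id, ADMISSION, start))
            continue
        if activity == mapping.discharge_label:
            milestones.append(Milestone(case_id, DISCHARGE, start))
            continue
        end = _parse_ts(row[mapping.end], mapping.timestamp_format)
        if _clean_str(row[mapping.end]) and end is None:
            report.add("unparseable end", case_id, f"row {idx}: {row[mapping.end]!r}")
            continue
        if end is not None and end < start:
            report.add("negative duration", case_id,
                       f"row {idx}: end {end} before start {start}")
            continue
        try:
            sofa = (_parse_optional_int(row[mapping.sofa_start])
                    if mapping.sofa_start and mapping.sofa_start in raw_events.columns else None)
            amount = (_parse_optional_float(row[mapping.amount])
                      if mapping.amount and mapping.amount in raw_events.columns else None)
        except ValueError as exc:
            report.add("unparseable numeric attribute", case_id, f"row {idx}: {exc}")
            continue
        if sofa is not None and not 0 <= sofa <= 24:
            report.add("sofa out of range", case_id, f"row {idx}: sofa_start={sofa}")
            continue
        unit = (_clean_str(row[mapping.unit]) or None
                if mapping.unit and mapping.unit in raw_events.columns else None)
        known = {mapping.case_id, mapping.activity, mapping.start, mapping.end,
                 mapping.sofa_start, mapping.amount, mapping.unit}
        extra = {c: row[c] for c in raw_events.columns if c not in known and _clean_str(row[c])}
        events.append(TreatmentEvent(case_id, activity, start, end, sofa, amount, unit, extra))

    patients = _read_patients(patients_path)
    report.n_events = len(events)
    report.n_cases = len(patients)
    log = EventLog(events=events, milestones=milestones, patients=patients,
                   ingest_report=report)
    return log


def _read_patients(path: Path) -> list[PatientRecord]:
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataContractError(f"patients file is empty: {path}")
    if "case_id" not in raw.columns:
        raise ConfigError("patients file is missing mandatory column 'case_id'")
    patients = []
    for _, row in raw.iterrows():
        case_id = _clean_str(row["case_id"])
        attributes: dict[str, Any] = {}
        comorbidities: set[str] = set()
        outcomes: dict[str, Any] = {}
        for col in raw.columns:
            if col == "case_id":
                continue
            val = _clean_str(row[col])
            if col.startswith("comorbidity_"):
                if val not in ("", "0", "false", "False"):
                    comorbidities.add(col[len("comorbidity_"):])
            elif col == "mortality":
                if val:
                    outcomes["mortality"] = val in ("1", "true", "True")
            elif col == "length_of_stay":
                if val:
                    outcomes["length_of_stay"] = float(val)
            else:
                attributes[col] = val if val else None
        patients.append(PatientRecord(case_id, attributes, comorbidities, outcomes))
    return patients


def write_event_log(
    log: EventLog,
    events_path: str | Path,
    patients_path: str | Path,
    mapping: ColumnMapping | None = None,
) -> None:
    """Write the log to two CSVs such that :func:`read_event_log` round-trips it."""
    mapping = mapping or ColumnMapping()
    fmt = mapping.timestamp_format

    def ts(t: pd.Timestamp | None) -> str:
        return "" if t is None else t.strftime(fmt)

    extra_cols: list[str] = []
    for e in log.events:
        for k in e.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = []
    for m in log.milestones:
        label = mapping.admission_label if m.kind == ADMISSION else mapping.discharge_label
        rows.append({"case_id": m.case_id, "activity": label, "start": ts(m.time),
                     "end": "", "sofa_start": "", "amount": "", "unit": ""})
    for e in log.events:
        row = {"case_id": e.case_id, "activity": e.activity, "start": ts(e.start),
               "end": ts(e.end),
               "sofa_start": "" if e.sofa_start is None else str(e.sofa_start),
               "amount": "" if e.amount is None else repr(float(e.amount)),
               "unit": e.unit or ""}
        for k in extra_cols:
            row[k] = e.extra.get(k, "")
        rows.append(row)
    cols = list(_CANONICAL_EVENT_COLUMNS) + extra_cols
    pd.DataFrame(rows, columns=cols).to_csv(events_path, index=False)

    attr_cols: list[str] = []
    comorb_cols: list[str] = []
    for p in log.patients:
        for k in p.attributes:
            if k not in attr_cols:
                attr_cols.append(k)
        for c in sorted(p.comorbidities):
            col = f"comorbidity_{c}"
            if col not in comorb_cols:
                comorb_cols.append(col)
    prows = []
    for p in log.patients:
        row: dict[str, Any] = {"case_id": p.case_id}
        for k in attr_cols:
            v = p.attributes.get(k)
            row[k] = "" if v is None else str(v)
        for col in comorb_cols:
            row[col] = "1" if col[len("comorbidity_"):] in p.comorbidities else "0"
        mort = p.outcomes.get("mortality")
        row["mortality"] = "" if mort is None else ("1" if mort else "0")
        los = p.outcomes.get("length_of_stay")
        row["length_of_stay"] = "" if los is None else repr(float(los))
        prows.append(row)
    pcols = ["case_id"] + attr_cols + comorb_cols + ["mortality", "length_of_stay"]
    pd.DataFrame(prows, columns=pcols).to_csv(patients_path, index=False)


def write_token_stream(log: EventLog, path: str | Path) -> None:
    """Export the flattened start/end token stream as a three-column CSV.

    One row per token (case id, token label, timestamp), in the canonical
    within-case order — the interchange shape generic process-mining tools
    ingest directly.
    """
    from .variants import case_tokens  # local import to avoid a cycle

    rows = []
    for case in to_cases(log):
        for tok in case_tokens(case):
            rows.append({"case_id": case.case_id, "token": tok.token,
                         "timestamp": tok.time.strftime("%Y-%m-%d %H:%M:%S")})
    pd.DataFrame(rows, columns=["case_id", "token", "timestamp"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation and case assembly


def validate_event_log(log: EventLog) -> ValidationReport:
    """Structural validation; the log is not modified.

    Fatal violations are missing case ids and negative durations
    (``end < start``, including discharge before admission).  Everything
    else — duplicate or missing anchors, events outside the stay window,
    unknown patients, out-of-range SOFA — is reported non-fatally so the
    caller can decide what to exclude.
    """
    report = ValidationReport(n_cases=len(log.patients), n_events=len(log.events))
    known = {p.case_id for p in log.patients}

    anchors: dict[str, dict[str, list[Milestone]]] = {}
    for m in log.milestones:
        anchors.setdefault(m.case_id, {ADMISSION: [], DISCHARGE: []})[m.kind].append(m)
        if m.case_id not in known:
            report.add("unknown patient", m.case_id, f"{m.kind} milestone for case not in patient table")
    for case_id, byk in anchors.items():
        if len(byk[ADMISSION]) == 0:
            report.add("missing admission", case_id, "case has milestones but no admission")
        elif len(byk[ADMISSION]) > 1:
            report.add("duplicate admission", case_id, f"{len(byk[ADMISSION])} admission milestones")
        if len(byk[DISCHARGE]) > 1:
            report.add("duplicate discharge", case_id, f"{len(byk[DISCHARGE])} discharge milestones")
        if byk[ADMISSION] and byk[DISCHARGE]:
            adm, dis = byk[ADMISSION][0], byk[DISCHARGE][0]
            if dis.time < adm.time:
                report.add("negative duration", case_id,
                           f"discharge {dis.time} before admission {adm.time}", fatal=True)

    for e in log.events:
        if not e.case_id:
            report.add("missing case_id", "<unknown>", f"event {e.activity!r} has no case id", fatal=True)
            continue
        if e.case_id not in known:
            report.add("unknown patient", e.case_id, f"event {e.activity!r} for case not in patient table")
        if e.end is not None and e.end < e.start:
            report.add("negative duration", e.case_id,
                       f"event {e.activity!r} end {e.end} before start {e.start}", fatal=True)
        if e.sofa_start is not None and not 0 <= e.sofa_start <= 24:
            report.add("sofa out of range", e.case_id,
                       f"event {e.activity!r} sofa_start={e.sofa_start}")
        byk = anchors.get(e.case_id)
        if byk and byk[ADMISSION]:
            adm = byk[ADMISSION][0].time
            dis = byk[DISCHARGE][0].time if byk[DISCHARGE] else None
            if e.start < adm or (dis is not None and (e.start > dis or (e.end or e.start) > dis)):
                # events exactly at the discharge timestamp are flagged, not dropped
                report.add("event outside stay window", e.case_id,
                           f"event {e.activity!r} [{e.start}, {e.end}] outside "
                           f"[{adm}, {dis if dis is not None else 'open'}]")

    seen: set[str] = set()
    for p in log.patients:
        if p.case_id in seen:
            report.add("duplicate patient", p.case_id, "case_id repeated in patient table")
        seen.add(p.case_id)
    return report


def to_cases(log: EventLog) -> list[Case]:
    """Assemble one :class:`Case` per patient, events in canonical order.

    Events are sorted by (start, activity); patients with no admission
    milestone cannot be anchored to a stay and are excluded with a warning.
    Patients with an admission but no treatment events yield a milestone-only
    case.  The total number of events is conserved across included cases.
    """
    adm: dict[str, Milestone] = {}
    dis: dict[str, Milestone] = {}
    for m in log.milestones:
        target = adm if m.kind == ADMISSION else dis
        target.setdefault(m.case_id, m)
    events_by_case: dict[str, list[TreatmentEvent]] = {}
    for e in log.events:
        events_by_case.setdefault(e.case_id, []).append(e)

    cases = []
    for p in log.patients:
        if p.case_id not in adm:
            logger.warning("case %s has no admission milestone; excluded", p.case_id)
            continue
        evs = sorted(events_by_case.get(p.case_id, []), key=lambda e: (e.start, e.activity))
        cases.append(Case(p.case_id, p, adm[p.case_id], dis.get(p.case_id), evs))
    return cases
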