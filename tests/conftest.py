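import pandas as pd
import pytest

from equiflow.eventlog import (ADMISSION, DISCHARGE, EventLog, Milestone,
                               PatientRecord, TreatmentEvent)
from equiflow.synthetic import generate_cohort, preset_sepsis_demo

T0 = pd.Timestamp("2140-01-01 00:00:00")


def ts(hours: float) -> pd.Timestamp:
    return T0 + pd.Timedelta(hours=hours)


def build_log(cases, default_attrs=None):
    """Build an EventLog from compact case descriptions.

    ``cases`` is a list of dicts with keys: case_id, adm (hours), dis
    (hours or None), events (list of (activity, start_h, end_h|None,
    sofa|None)), attrs (dict), outcomes (dict).
    """
    events, milestones, patients = [], [], []
    for c in cases:
        cid = c["case_id"]
        if c.get("adm") is not None:
            milestones.append(Milestone(cid, ADMISSION, ts(c["adm"])))
        if c.get("dis") is not None:
            milestones.append(Milestone(cid, DISCHARGE, ts(c["dis"])))
        for activity, start_h, end_h, sofa in c.get("events", []):
            events.append(TreatmentEvent(
                cid, activity, ts(start_h),
                None if end_h is None else ts(end_h), sofa))
        attrs = dict(default_attrs or {})
        attrs.update(c.get("attrs", {}))
        patients.append(PatientRecord(cid, attrs, set(c.get("comorbidities", [])),
                                      dict(c.get("outcomes", {}))))
    return EventLog(events=events, milestones=milestones, patients=patients)


@pytest.fixture(scope="session")
def demo_log():
    """A small two-group synthetic sepsis cohort shared across tests."""
    cfg = preset_sepsis_demo(seed=7, n_per_group={"ESP": 300, "non-ESP": 120})
    return generate_cohort(cfg)
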