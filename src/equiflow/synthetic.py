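"""Synthetic ICU sepsis event-log generator with controllable group structure.

Real ICU treatment logs sit behind credentialed access, so every pipeline
stage here is exercised on simulated cohorts instead.  The generator
emulates the structure of an ICU sepsis stay: admission and discharge
milestones; ventilation, vasopressor and renal-replacement-therapy (rrt)
episodes drawn from a mixture of variant templates; per-event SOFA
severity scores with missingness; and mortality / length-of-stay outcomes
tied to severity.

Timing model: each template is a token sequence, and each *gap* between
consecutive tokens is drawn from a lognormal distribution in hours
(clinically plausible right skew), optionally shifted additively for one
patient group.  That per-group additive delay is the injectable disparity
— e.g. +2 h on the admission → start:ventilation gap for non-English
speakers reproduces, qualitatively, a delayed time to first treatment.
All draws flow from a single seeded stream, so one integer reproduces the
cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .eventlog import (ADMISSION, DISCHARGE, EventLog, Milestone,
                       PatientRecord, TreatmentEvent)
from .variants import VariantSignature

#: gaps are floored at one minute so that rounding to minute precision can
#: never collapse two tokens onto the same instant and reorder a template
MIN_GAP_HOURS = 1.0 / 60.0


@dataclass(frozen=True)
class GapModel:
    """Lognormal gap distribution: parameters on the log-hour scale."""

    log_mean: float
    log_sd: float

    def __post_init__(self):
        if self.log_sd <= 0:
            raise ConfigError(f"log_sd must be > 0, got {self.log_sd}")


@dataclass(frozen=True)
class VariantTemplate:
    """A named token sequence defining which treatments occur in what order."""

    name: str
    tokens: tuple[str, ...]

    def __post_init__(self):
        VariantSignature(tuple(self.tokens)).validate()

    @property
    def n_gaps(self) -> int:
        return len(self.tokens) - 1


@dataclass
class SyntheticConfig:
    """Full description of one synthetic cohort.

    ``group_shifts`` maps group → {(template_name, gap_index) → Δ hours},
    an additive delay on that gap for that group only.  The SOFA model is
    an initial score drawn from ``sofa_init_probs`` (a distribution over
    0–24) plus a per-event drift with rounding and clipping; each event's
    score is missing with probability ``sofa_missing_prob``.  Mortality is
    Bernoulli with logit = intercept + coef · initial SOFA; length of stay
    is discharge − admission in hours.
    """

    group_sizes: dict[str, int]
    templates: list[VariantTemplate]
    mixture: dict[str, float]  # template name -> probability
    gap_models: dict[str, list[GapModel]]  # template name -> one model per gap
    attribute: str = "language"
    group_shifts: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    sofa_init_probs: list[float] = field(default_factory=lambda: _default_sofa_probs())
    sofa_drift: float = -0.5  # mean change per subsequent event
    sofa_missing_prob: float = 0.15
    mortality_intercept: float = -3.0
    mortality_sofa_coef: float = 0.18
    start_date: str = "2140-01-01"
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigError("group_sizes must name at least one group")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ConfigError(f"group {g!r} has negative size {n}")
        if set(self.mixture) != {t.name for t in self.templates}:
            raise ConfigError("mixture keys must match template names exactly")
        total = sum(self.mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"mixture probabilities must sum to 1, got {total}")
        for t in self.templates:
            models = self.gap_models.get(t.name)
            if models is None or len(models) != t.n_gaps:
                raise ConfigError(
                    f"template {t.name!r} needs {t.n_gaps} gap models, "
                    f"got {0 if models is None else len(models)}")
        if not 0 <= self.sofa_missing_prob <= 1:
            raise ConfigError(f"sofa_missing_prob must be in [0,1], got {self.sofa_missing_prob}")
        probs = np.asarray(self.sofa_init_probs, dtype=float)
        if probs.size != 25 or (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("sofa_init_probs must be 25 non-negative values summing to 1")


def _default_sofa_probs() -> list[float]:
    # discretised, right-skewed severity distribution peaking around 6-8
    x = np.arange(25, dtype=float)
    w = np.exp(-0.5 * ((x - 7.0) / 3.5) ** 2) * (1 + 0.02 * (24 - x))
    w /= w.sum()
    return [float(v) for v in w]


_ETHNICITIES = ["White", "Black", "Hispanic/Latino", "Asian", "Native American", "Other"]
_ETHNICITY_PROBS = [0.66, 0.11, 0.04, 0.03, 0.002, 0.158]
_INSURANCE = ["Medicare", "Medicaid", "Private", "Other"]
_INSURANCE_PROBS = [0.5, 0.12, 0.3, 0.08]
_COMORBIDITIES = ["chf", "mi", "copd"]


def generate_cohort(config: SyntheticConfig) -> EventLog:
    """Draw a full synthetic cohort from ``config``.

    Per case: group → template (mixture) → gap times (lognormal + group
    shift, floored at one minute) → timestamps accumulated from admission
    and rounded to the minute → SOFA per event with missingness → outcomes.
    The result always passes structural validation with ``fatal=False``,
    and the same seed yields a byte-identical log on disk.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base = pd.Timestamp(config.start_date)
    templates = {t.name: t for t in config.templates}
    names = sorted(config.mixture)
    probs = np.array([config.mixture[n] for n in names])

    events: list[TreatmentEvent] = []
    milestones: list[Milestone] = []
    patients: list[PatientRecord] = []
    case_no = 0
    for group in config.group_sizes:
        shifts = config.group_shifts.get(group, {})
        for _ in range(config.group_sizes[group]):
            case_no += 1
            cid = f"case{case_no:05d}"
            tname = names[int(rng.choice(len(names), p=probs))]
            tpl = templates[tname]

            gaps = []
            for i, gm in enumerate(config.gap_models[tname]):
                gap = float(rng.lognormal(gm.log_mean, gm.log_sd))
                gap += shifts.get((tname, i), 0.0)
                gaps.append(max(gap, MIN_GAP_HOURS))
            admission = (base + pd.Timedelta(days=case_no - 1,
                                             minutes=int(rng.integers(0, 1440)))).floor("min")
            times = [admission]
            for gap in gaps:
                times.append((times[-1] + pd.Timedelta(hours=gap)).floor("min"))
            # re-impose strict ordering lost to minute rounding
            for i in range(1, len(times)):
                if times[i] <= times[i - 1]:
                    times[i] = times[i - 1] + pd.Timedelta(minutes=1)

            sofa0 = int(rng.choice(25, p=np.asarray(config.sofa_init_probs)))
            open_events: dict[str, list[TreatmentEvent]] = {}
            discharge_time = None
            event_idx = 0
            for tok, t in zip(tpl.tokens, times):
                if tok == ADMISSION:
                    milestones.append(Milestone(cid, ADMISSION, t))
                elif tok == DISCHARGE:
                    discharge_time = t
                    milestones.append(Milestone(cid, DISCHARGE, t))
                elif tok.startswith("start:"):
                    activity = tok[len("start:"):]
                    drift = config.sofa_drift * event_idx + rng.normal(0, 1.0)
                    sofa = int(np.clip(round(sofa0 + drift), 0, 24))
                    if rng.random() < config.sofa_missing_prob:
                        sofa = None
                    ev = TreatmentEvent(cid, activity, t, None, sofa)
                    events.append(ev)
                    open_events.setdefault(activity, []).append(ev)
                    event_idx += 1
                else:  # end:activity — close the earliest open episode
                    activity = tok[len("end:"):]
                    ev = open_events[activity].pop(0)
                    ev.end = t

            p_mort = 1.0 / (1.0 + math.exp(-(config.mortality_intercept
                                             + config.mortality_sofa_coef * sofa0)))
            mortality = bool(rng.random() < p_mort)
            outcomes: dict = {"mortality": mortality}
            if discharge_time is not None:
                outcomes["length_of_stay"] = (
                    discharge_time - admission).total_seconds() / 3600.0
            attributes = {
                "language": "ESP" if rng.random() < 0.9 else "non-ESP",
                "sex": "F" if rng.random() < 0.42 else "M",
                "ethnicity": _ETHNICITIES[int(rng.choice(len(_ETHNICITIES),
                                                         p=_ETHNICITY_PROBS))],
                "insurance": _INSURANCE[int(rng.choice(len(_INSURANCE),
                                                       p=_INSURANCE_PROBS))],
                "age": str(int(np.clip(round(rng.normal(68.0, 14.0)), 18, 99))),
                "diagnosis": "sepsis",
            }
            # the splitting attribute is fixed to the case's generator group
            attributes[config.attribute] = group
            comorb = {c for c in _COMORBIDITIES if rng.random() < 0.4}
            if not comorb:
                comorb = {_COMORBIDITIES[int(rng.integers(0, 3))]}
            patients.append(PatientRecord(cid, attributes, comorb,
                                          outcomes))
    return EventLog(events=events, milestones=milestones, patients=patients)


# ---------------------------------------------------------------------------
# shipped templates and the sepsis demo preset

TEMPLATE_VENT = VariantTemplate("vent", (ADMISSION, "start:ventilation",
                                         "end:ventilation", DISCHARGE))
#: ventilation enclosing a vasopressor episode — the canonical nested stay
TEMPLATE_VENT_VASO = VariantTemplate(
    "vent_vaso", (ADMISSION, "start:ventilation", "start:vasopressor",
                  "end:vasopressor", "end:ventilation", DISCHARGE))
TEMPLATE_VASO = VariantTemplate("vaso", (ADMISSION, "start:vasopressor",
                                         "end:vasopressor", DISCHARGE))
TEMPLATE_VASO_VENT = VariantTemplate(
    "vaso_vent", (ADMISSION, "start:vasopressor", "start:ventilation",
                  "end:vasopressor", "end:ventilation", DISCHARGE))
#: dialysis-containing pathway
TEMPLATE_VENT_VASO_RRT = VariantTemplate(
    "vent_vaso_rrt", (ADMISSION, "start:ventilation", "start:vasopressor",
                      "end:vasopressor", "end:ventilation", "start:rrt",
                      "end:rrt", DISCHARGE))

_PRESET_GAPS: dict[str, list[GapModel]] = {
    # gap parameters on the log-hour scale: medians of ~3h to ventilation,
    # ~2d ventilation episodes, ~1d vasopressor episodes, ~1d weaning tails
    "vent": [GapModel(math.log(3.0), 0.6), GapModel(math.log(48.0), 0.5),
             GapModel(math.log(24.0), 0.6)],
    "vent_vaso": [GapModel(math.log(3.0), 0.6), GapModel(math.log(4.0), 0.6),
                  GapModel(math.log(24.0), 0.5), GapModel(math.log(12.0), 0.6),
                  GapModel(math.log(24.0), 0.6)],
    "vaso": [GapModel(math.log(4.0), 0.6), GapModel(math.log(24.0), 0.5),
             GapModel(math.log(36.0), 0.6)],
    "vaso_vent": [GapModel(math.log(4.0), 0.6), GapModel(math.log(3.0), 0.6),
                  GapModel(math.log(20.0), 0.5), GapModel(math.log(24.0), 0.5),
                  GapModel(math.log(24.0), 0.6)],
    "vent_vaso_rrt": [GapModel(math.log(3.0), 0.6), GapModel(math.log(4.0), 0.6),
                      GapModel(math.log(24.0), 0.5), GapModel(math.log(12.0), 0.6),
                      GapModel(math.log(6.0), 0.6), GapModel(math.log(8.0), 0.5),
                      GapModel(math.log(36.0), 0.6)],
}

_PRESET_MIXTURE = {"vent": 0.28, "vent_vaso": 0.26, "vaso": 0.20,
                   "vaso_vent": 0.14, "vent_vaso_rrt": 0.12}


def preset_sepsis_demo(
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    delay_shift_hours: float = 2.0,
) -> SyntheticConfig:
    """The shipped ICU sepsis demo cohort.

    Five variant templates (including the ventilation-enclosing-vasopressor
    stay and a dialysis-containing pathway), a two-group English-proficiency
    split of roughly 10:1 English-speaking (ESP) to non-English-speaking
    (non-ESP) patients, and a configurable additive delay (default +2 h) on
    the admission → start:ventilation gap for the non-ESP group — the
    qualitative disparity pattern of delayed first treatment for patients
    facing a language barrier.  ``delay_shift_hours=0`` gives a null cohort.
    """
    sizes = n_per_group or {"ESP": 2700, "non-ESP": 300}
    shifts: dict[str, dict[tuple[str, int], float]] = {}
    if delay_shift_hours and "non-ESP" in sizes:
        shifted = {}
        for tname in _PRESET_MIXTURE:
            tpl_tokens = {t.name: t.tokens for t in _preset_templates()}[tname]
            for i in range(len(tpl_tokens) - 1):
                if tpl_tokens[i] == ADMISSION and tpl_tokens[i + 1] == "start:ventilation":
                    shifted[(tname, i)] = float(delay_shift_hours)
        shifts["non-ESP"] = shifted
    return SyntheticConfig(
        group_sizes=sizes,
        templates=_preset_templates(),
        mixture=dict(_PRESET_MIXTURE),
        gap_models={k: list(v) for k, v in _PRESET_GAPS.items()},
        attribute="language",
        group_shifts=shifts,
        seed=seed,
    )


def _preset_templates() -> list[VariantTemplate]:
    return [TEMPLATE_VENT, TEMPLATE_VENT_VASO, TEMPLATE_VASO,
            TEMPLATE_VASO_VENT, TEMPLATE_VENT_VASO_RRT]


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    data = asdict(config)
    data["templates"] = [{"name": t.name, "tokens": list(t.tokens)}
                         for t in config.templates]
    data["gap_models"] = {k: [[g.log_mean, g.log_sd] for g in v]
                          for k, v in config.gap_models.items()}
    data["group_shifts"] = {
        g: [{"template": t, "gap": i, "shift_hours": s}
            for (t, i), s in m.items()]
        for g, m in config.group_shifts.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    data = yaml.safe_load(Path(path).read_text())
    try:
        data["templates"] = [VariantTemplate(t["name"], tuple(t["tokens"]))
                             for t in data["templates"]]
        data["gap_models"] = {k: [GapModel(m, s) for m, s in v]
                              for k, v in data["gap_models"].items()}
        data["group_shifts"] = {
            g: {(e["template"], int(e["gap"])): float(e["shift_hours"]) for e in entries}
            for g, entries in data.get("group_shifts", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed synthetic config {path}: {exc}")
    cfg = SyntheticConfig(**data)
    cfg.validate()
    return cfg
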