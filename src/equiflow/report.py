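"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` executes the whole audit — read (or simulate) → validate →
cohort filter → sensitive-attribute split → variant extraction →
minimum-support filter → pairwise global tests → per-variant metric panels
for the top-k variants — and returns an :class:`EquityReport` in which
every rendered number traces to a machine-readable field.  Each stage logs
its exclusions with a reason: an equity audit must account for every
patient it drops.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import globaltest, metrics, synthetic, variants
from .errors import ConfigError, DataContractError
from .eventlog import EventLog, read_event_log, to_cases, validate_event_log

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    events_path: str | None = None
    patients_path: str | None = None
    synthetic_preset: str | None = None  # "sepsis-demo"
    n_per_group: dict[str, int] | None = None
    delay_shift_hours: float = 2.0
    split_attribute: str = "language"
    level_map: dict[str, str] | None = None
    default_level: str | None = None
    cohort_spec: cohort_mod.CohortSpec | None = None
    min_support: int = 50
    top_k: int = 5
    B: int = 1000
    ci_level: float = 0.90
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        spec = data.pop("cohort_spec", None)
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config {path}: {exc}")
        if spec is not None:
            for k in ("required_diagnosis", "required_comorbidities"):
                if spec.get(k) is not None:
                    spec[k] = set(spec[k])
            cfg.cohort_spec = cohort_mod.CohortSpec(**spec)
        return cfg

    def digest(self) -> str:
        data = dataclasses.asdict(self)
        if data.get("cohort_spec"):
            for k in ("required_diagnosis", "required_comorbidities"):
                if data["cohort_spec"].get(k) is not None:
                    data["cohort_spec"][k] = sorted(data["cohort_spec"][k])
        return hashlib.sha256(
            json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class EquityReport:
    """Machine-readable results of one full pipeline run."""

    config_digest: str
    seed: int
    created_at: str
    cohort_flow: cohort_mod.CohortFlow | None = None
    validation: dict[str, Any] = field(default_factory=dict)
    split_attribute: str = ""
    group_sizes: dict[str, int] = field(default_factory=dict)
    variant_summary: list[dict[str, Any]] = field(default_factory=list)
    n_variants: int = 0
    n_cases: int = 0
    n_removed_by_support: int = 0
    global_tests: list[globaltest.GlobalTestResult] = field(default_factory=list)
    panels: list[metrics.VariantMetricPanel] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "config_digest": self.config_digest,
            "seed": self.seed,
            "created_at": self.created_at,
            "cohort_flow": _jsonify(self.cohort_flow),
            "validation": _jsonify(self.validation),
            "split_attribute": self.split_attribute,
            "group_sizes": self.group_sizes,
            "n_cases": self.n_cases,
            "n_variants": self.n_variants,
            "n_removed_by_support": self.n_removed_by_support,
            "variants": _jsonify(self.variant_summary),
            "global_tests": _jsonify(self.global_tests),
            "panels": _jsonify(self.panels),
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _jsonify(obj: Any) -> Any:
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    if isinstance(obj, float):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if isinstance(obj, variants.VariantSignature):
        return list(obj.tokens)
    if dataclasses.is_dataclass(obj):
        return {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    return str(obj)


def _obtain_log(config: PipelineConfig) -> EventLog:
    if config.synthetic_preset is not None:
        if config.synthetic_preset != "sepsis-demo":
            raise ConfigError(f"unknown synthetic preset {config.synthetic_preset!r}")
        scfg = synthetic.preset_sepsis_demo(
            seed=config.seed, n_per_group=config.n_per_group,
            delay_shift_hours=config.delay_shift_hours)
        return synthetic.generate_cohort(scfg)
    if not config.events_path or not config.patients_path:
        raise ConfigError("config must name events_path and patients_path, "
                          "or a synthetic preset")
    return read_event_log(config.events_path, config.patients_path)


def run_pipeline(config: PipelineConfig) -> EquityReport:
    """Execute the full audit; deterministic given config + seed."""
    report = EquityReport(config_digest=config.digest(), seed=config.seed,
                          created_at=datetime.now(timezone.utc).isoformat())

    log = _obtain_log(config)
    vreport = validate_event_log(log)
    report.validation = {
        "n_cases": vreport.n_cases, "n_events": vreport.n_events,
        "n_violations": len(vreport.violations), "fatal": vreport.fatal,
        "violations": [dataclasses.asdict(v) for v in vreport.violations[:100]],
    }
    if vreport.fatal:
        raise DataContractError(
            "validate: event log has fatal structural violations; see report")

    if config.cohort_spec is not None:
        log, flow = cohort_mod.apply_cohort_spec(log, config.cohort_spec)
        report.cohort_flow = flow

    split = cohort_mod.split_by_attribute(
        log, config.split_attribute, config.level_map, config.default_level)
    report.split_attribute = config.split_attribute
    report.group_sizes = {g: len(ids) for g, ids in split.groups.items()}

    cases = to_cases(log)
    case_map = {c.case_id: c for c in cases}
    table = variants.compute_variants(cases, split)
    table = variants.filter_variants(table, config.min_support)
    report.n_cases = table.n_cases
    report.n_variants = len(table)
    report.n_removed_by_support = table.n_removed
    report.variant_summary = [
        {"signature": row.signature, "count": row.count,
         "group_counts": dict(row.group_counts)}
        for row in table.rows
    ]
    if not table.rows:
        report.warnings.append("no variants above minimum support; "
                               "global tests and panels skipped")
        return report

    if len(split.test_groups()) >= 2 and len(table) >= 2:
        report.global_tests = globaltest.pairwise_global_tests(table, split)
    else:
        report.warnings.append("global tests skipped: need >=2 groups and >=2 variants")

    for row in table.rows[: config.top_k]:
        panel_cases = [case_map[cid] for cid in row.case_ids]
        report.panels.append(metrics.build_variant_panel(
            panel_cases, split, level=config.ci_level, B=config.B, seed=config.seed))
    return report


# ---------------------------------------------------------------------------
# rendering


def render_report(report: EquityReport, fmt: str, out: str | Path) -> list[Path]:
    """Render to ``json``, ``text`` or ``figures``; returns written paths."""
    out = Path(out)
    if fmt == "json":
        out.write_text(report.to_json() + "\n")
        return [out]
    if fmt == "text":
        out.write_text(render_text(report))
        return [out]
    if fmt == "figures":
        return render_figures(report, out)
    raise ConfigError(f"unknown report format {fmt!r}")


def _fmt_metric(m: metrics.GroupMetric) -> str:
    return (f"{m.name:<44.44s} {m.group:>10}  n={m.n:<5d} {m.estimate:9.2f} "
            f"[{m.ci_low:8.2f}, {m.ci_high:8.2f}] {m.unit}"
            + (f"  ({m.n_excluded} excluded)" if m.n_excluded else ""))


def render_text(report: EquityReport) -> str:
    """Aligned-text report: variant chains with per-group metrics and CIs."""
    lines: list[str] = []
    lines.append(f"equity report (schema {SCHEMA_VERSION}, config {report.config_digest}, "
                 f"seed {report.seed})")
    if report.cohort_flow is not None:
        lines.append(f"cohort: {report.cohort_flow.n_input} patients in")
        for name, excluded, remaining in report.cohort_flow.stages:
            lines.append(f"  {name}: -{excluded} -> {remaining}")
    lines.append(f"split by {report.split_attribute}: "
                 + ", ".join(f"{g}={n}" for g, n in report.group_sizes.items()))
    lines.append(f"{report.n_variants} variants above support "
                 f"({report.n_removed_by_support} cases in infrequent variants removed)")
    for i, row in enumerate(report.variant_summary, 1):
        sig = " → ".join(row["signature"].tokens
                         if isinstance(row["signature"], variants.VariantSignature)
                         else row["signature"])
        lines.append(f"  #{i} n={row['count']}  {sig}")
    for res in report.global_tests:
        adj = f", Bonferroni p={res.p_adjusted:.4g}" if res.p_adjusted is not None else ""
        pooled = f" ({res.n_pooled_columns} sparse variants pooled)" if res.pooled else ""
        lines.append(f"global test {res.group_pair[0]} vs {res.group_pair[1]}: "
                     f"chi2={res.statistic:.3f}, df={res.df}, p={res.p_value:.4g}{adj}{pooled}")
    for panel in report.panels:
        lines.append("")
        lines.append(f"variant panel: {panel.signature}")
        lines.append("  groups: " + ", ".join(f"{g}={n}" for g, n in panel.group_sizes.items()))
        toks = panel.signature.tokens
        # Interleave gaps with the step metrics, in token-chain order
        occurrence: dict[str, int] = {}
        for i in range(len(toks) - 1):
            for m in panel.gaps[i].values():
                lines.append("    " + _fmt_metric(m))
            nxt = toks[i + 1]
            if nxt.startswith("start:"):
                activity = nxt[len("start:"):]
                k = occurrence.get(activity, 0)
                occurrence[activity] = k + 1
                key = activity if k == 0 else f"{activity}#{k + 1}"
                for m in panel.durations.get(key, {}).values():
                    lines.append("    " + _fmt_metric(m))
                for m in panel.sofa.get(key, {}).values():
                    lines.append("    " + _fmt_metric(m))
        for per_group in panel.outcomes.values():
            for m in per_group.values():
                lines.append("    " + _fmt_metric(m))
        for note in panel.notes:
            lines.append(f"    note: {note}")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


def render_figures(report: EquityReport, out_dir: str | Path) -> list[Path]:
    """One errorbar figure per variant panel, mirroring the metric layout."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, panel in enumerate(report.panels, 1):
        names: list[str] = []
        series: dict[str, list[tuple[int, metrics.GroupMetric]]] = {}
        for m in panel.all_metrics():
            if m.name not in names:
                names.append(m.name)
            series.setdefault(m.group, []).append((names.index(m.name), m))
        fig, ax = plt.subplots(figsize=(8, max(3, 0.45 * len(names))))
        offsets = np.linspace(-0.15, 0.15, max(len(series), 1))
        for off, (group, points) in zip(offsets, sorted(series.items())):
            ys = [p[0] + off for p in points]
            xs = [p[1].estimate for p in points]
            err = [[p[1].estimate - p[1].ci_low for p in points],
                   [p[1].ci_high - p[1].estimate for p in points]]
            ax.errorbar(xs, ys, xerr=err, fmt="o", capsize=3, label=group)
        ax.set_yticks(range(len(names)))
        ax.set_yticklabels(names)
        ax.invert_yaxis()
        ax.set_xlabel("estimate with 90% bootstrap CI")
        ax.set_title(f"variant #{i}: {panel.signature}", fontsize=8)
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"panel_{i:02d}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
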