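"""End-to-end orchestration: waveform -> characteristics -> fits -> report.

`process_subject` turns one subject's PPG record and annotations into
per-arousal response calls and stable-sleep samples; `run_cohort` pools
subjects and builds the cohort report. `RunConfig` gathers every module's
parameters into one serializable object so a run is reproducible from its
manifest alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__, events, features, respmodel, stats, synth
from .records import AnnotationSet, PPGRecord

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "subject_id", "arousal_start_s", "arousal_duration_s", "cause", "stage",
    "kind", "category_id", "response_present", "response_step", "magnitude",
    "delay", "recovery_present", "level_before", "level_after", "ssr",
]
STABLE_COLUMNS = ["subject_id", "start_s", "duration_s", "stage",
                  "mean_frequency", "mean_amplitude"]
DROP_COLUMNS = ["subject_id", "arousal_start_s", "kind", "reason"]


@dataclass
class RunConfig:
    seed: int = 0
    synth: synth.CohortConfig | None = field(default_factory=synth.CohortConfig)
    events: events.EventConfig = field(default_factory=events.EventConfig)
    fit: respmodel.FitConfig = field(default_factory=respmodel.FitConfig)
    report: stats.ReportConfig = field(default_factory=stats.ReportConfig)
    input_dir: str | None = None  # directory of per-subject CSVs (overrides synth)

    def validate(self) -> list[str]:
        """Schema/range checks; an empty list means the config is runnable."""
        problems: list[str] = []
        ev = self.events
        for key in ("proximity_s", "min_event_s", "desat_window_s",
                    "stable_duration_s", "stable_grid_s"):
            if getattr(ev, key) <= 0:
                problems.append(f"events.{key} must be positive")
        if ev.assoc_lookback_s < 0:
            problems.append("events.assoc_lookback_s must be >= 0")
        if ev.min_arousal_s >= ev.max_arousal_s:
            problems.append("events.min_arousal_s must be below events.max_arousal_s")
        fit = self.fit
        # the narrowest includable arousal (3 s) gives a fit window of
        # [-8, 11]; c1 guesses must stay inside [t_min, t_max - 3]
        t_min = -features.TRACE_MARGIN_S
        t_max_min = ev.min_arousal_s + features.TRACE_MARGIN_S
        for g in fit.c1_guesses:
            if not (t_min <= g <= t_max_min - 3.0):
                problems.append(
                    f"fit.c1_guesses value {g} outside the fit window "
                    f"[{t_min}, {t_max_min - 3.0}]"
                )
        for name in ("c2_rel_guesses", "c3_rel_guesses"):
            for g in getattr(fit, name):
                if not (0.0 <= g <= 1.0):
                    problems.append(f"fit.{name} value {g} outside [0, 1]")
        if not (0 < fit.considerable_fraction < 1):
            problems.append("fit.considerable_fraction must be in (0, 1)")
        if self.report.n_iterations < 1:
            problems.append("report.n_iterations must be >= 1")
        if self.synth is not None:
            problems.extend(f"synth.{p}" for p in self.synth.validate())
        if self.synth is None and self.input_dir is None:
            problems.append("either a synth config or an input_dir is required")
        return problems

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "seed": self.seed,
            "input_dir": self.input_dir,
            "synth": enc(self.synth) if self.synth else None,
            "events": enc(self.events),
            "fit": enc(self.fit),
            "report": enc(self.report),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc_type, section, tuple_keys=()):
            if section is None:
                return None
            kwargs = dict(section)
            for k in tuple_keys:
                if k in kwargs and isinstance(kwargs[k], list):
                    kwargs[k] = tuple(kwargs[k])
            return dc_type(**kwargs)

        synth_cfg = None
        if d.get("synth") is not None:
            s = dict(d["synth"])
            if "effects" in s:
                s["effects"] = {
                    c: synth.CauseEffects(**v) if isinstance(v, dict) else v
                    for c, v in s["effects"].items()
                }
            for k in ("baseline_rate_range", "arousal_duration_range"):
                if k in s and isinstance(s[k], list):
                    s[k] = tuple(s[k])
            synth_cfg = synth.CohortConfig(**s)
        return cls(
            seed=d.get("seed", 0),
            input_dir=d.get("input_dir"),
            synth=synth_cfg,
            events=build(events.EventConfig, d.get("events", {})),
            fit=build(respmodel.FitConfig, d.get("fit", {}),
                      ("c1_guesses", "c2_rel_guesses", "c3_rel_guesses")),
            report=build(stats.ReportConfig, d.get("report", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_subject(
    record: PPGRecord,
    ann: AnnotationSet,
    subject_id: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full per-subject analysis.

    Returns (calls, stable_samples, exclusions, drops) tables. ``drops`` lists
    arousals lost after inclusion (segment out of bounds / failed fits).
    """
    record64 = features.decimate(record)
    cases, exclusions = events.filter_and_classify(ann, subject_id, config.events)
    call_rows: list[dict] = []
    drop_rows: list[dict] = []
    for case in cases:
        try:
            freq_series, amp_series = features.arousal_characteristics(record64, case)
        except features.SegmentOutOfBounds as exc:
            drop_rows.append({"subject_id": subject_id, "arousal_start_s": case.start_s,
                              "kind": "both", "reason": str(exc)})
            continue
        for series in (freq_series, amp_series):
            call = respmodel.detect_response(series, config.fit)
            if call is None:
                drop_rows.append({"subject_id": subject_id,
                                  "arousal_start_s": case.start_s,
                                  "kind": series.kind, "reason": "all fit starts failed"})
                continue
            call_rows.append(
                {
                    "subject_id": subject_id,
                    "arousal_start_s": case.start_s,
                    "arousal_duration_s": case.duration_s,
                    "cause": case.cause,
                    "stage": case.stage,
                    "kind": call.kind,
                    "category_id": call.category_id,
                    "response_present": call.response_present,
                    "response_step": call.response_step,
                    "magnitude": call.magnitude,
                    "delay": call.delay,
                    "recovery_present": call.recovery_present,
                    "level_before": call.level_before,
                    "level_after": call.level_after,
                    "ssr": call.ssr,
                }
            )

    provider = lambda start, dur: features.window_means(record64, start, dur)
    stable = events.sample_stable_sleep(
        ann, cases, provider, rng,
        subject_id=subject_id,
        record_start_s=record64.start_time_s + features.WINDOW_S,
        record_end_s=record64.end_time_s - features.WINDOW_S,
        config=config.events,
    )
    stable_rows = [
        {"subject_id": s.subject_id, "start_s": s.start_s, "duration_s": s.duration_s,
         "stage": s.stage, "mean_frequency": s.mean_frequency,
         "mean_amplitude": s.mean_amplitude}
        for s in stable
    ]
    return (
        pd.DataFrame(call_rows, columns=CALL_COLUMNS),
        pd.DataFrame(stable_rows, columns=STABLE_COLUMNS),
        events.exclusions_to_frame(exclusions, subject_id),
        pd.DataFrame(drop_rows, columns=DROP_COLUMNS),
    )


def run_cohort(
    subjects: Iterable[tuple[PPGRecord, AnnotationSet, str]],
    config: RunConfig,
) -> dict:
    """Process a cohort and build the report. Returns all artifact tables."""
    rng = np.random.default_rng(config.seed)
    calls, stable, excl, drops = [], [], [], []
    for record, ann, subject_id in subjects:
        c, s, e, d = process_subject(record, ann, subject_id, config, rng)
        calls.append(c)
        stable.append(s)
        excl.append(e)
        drops.append(d)
    def _concat(frames: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=columns)

    calls_df = _concat(calls, CALL_COLUMNS)
    stable_df = _concat(stable, STABLE_COLUMNS)
    report = stats.build_report(
        calls_df, stable_df,
        dataclasses.replace(config.report, seed=config.seed),
    )
    return {
        "calls": calls_df,
        "stable": stable_df,
        "exclusions": pd.concat(excl, ignore_index=True) if excl else pd.DataFrame(),
        "drops": pd.concat(drops, ignore_index=True) if drops else pd.DataFrame(columns=DROP_COLUMNS),
        "report": report,
    }


def run_synthetic(config: RunConfig) -> dict:
    """Generate the configured synthetic cohort and analyze it."""
    if config.synth is None:
        raise ValueError("config has no synth section")
    cohort = synth.generate_cohort(config.synth)
    artifacts = run_cohort(
        ((rec, ann, truth.subject_id) for rec, ann, truth in cohort), config
    )
    artifacts["truth"] = synth.truth_table([t for _, _, t in cohort])
    return artifacts


def write_artifacts(artifacts: dict, out_dir: str | Path, config: RunConfig) -> None:
    """Write every artifact table plus a run manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("calls", "stable", "exclusions", "drops", "truth"):
        if name in artifacts:
            artifacts[name].to_csv(out / f"{name}.csv", index=False)
    for name, table in artifacts["report"].items():
        table.to_csv(out / f"report_{name}.csv", index=False)
    summary = {
        name: table.to_dict(orient="records")
        for name, table in artifacts["report"].items()
    }
    (out / "report_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
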