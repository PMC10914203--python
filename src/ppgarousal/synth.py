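"""Synthetic polysomnography cohorts with known arousal-response ground truth.

Each subject is an amplitude-modulated pulse train

.. math:: x(t) = A(t)\\, w(\\varphi(t)) + \\varepsilon(t), \\qquad
          \\varphi'(t) = 2\\pi r(t),

where ``w`` is a fixed periodic pulse shape built from the first three
harmonics (so the power-weighted mean frequency of the waveform sits above
the pulse rate, as for real PPG), ``r(t)`` is a slowly varying pulse rate
carrying planted logistic frequency responses, ``A(t)`` carries planted
logistic amplitude dips, and ``eps`` is white Gaussian noise.

Planted responses use the same logistic kernel (growth rate 5) as the
analysis model, so parameter recovery is well-posed; a config switch swaps in
raised-cosine transitions for robustness checks. Frequency-response
magnitudes are specified in *observable* mean-instantaneous-frequency units:
the generator divides the planted pulse-rate step by the pulse shape's
harmonic weighting factor so the planted value is what the estimator should
read. Amplitude responses are specified as drops of the measured (max - min)
amplitude in a.u.

Annotations are laid out to satisfy the event-selection rules: arousals of
3-15 s, associated obstructive events of >= 10 s ending within [start - 5 s,
arousal end], desaturations overlapping the event for "+des" causes, 30-s
stage epochs, >= 10 s clearance between arousal clusters, and long stable
stretches in between. Optional deliberately excludable arousals (flagged in
the truth record) exercise the exclusion rules.

All distributional choices are stand-ins for the clinical cohort the
analysis was designed for; defaults follow the reported group medians where
those exist and are otherwise documented conventions (see docs/methods.md).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .events import CAUSES
from .records import (
    AnnotationSet,
    Arousal,
    Desaturation,
    PPGRecord,
    RespEvent,
    StageEpoch,
)

#: pulse-shape harmonic amplitudes and phases (documented constants; unit
#: energy after normalisation). The 2nd/3rd harmonics give the dicrotic-like
#: spectral spread that pulls the weighted mean frequency above the pulse rate.
PULSE_HARMONIC_AMPLITUDES = (1.0, 0.35, 0.15)
PULSE_HARMONIC_PHASES = (0.0, 0.6, 1.2)

GROWTH_RATE = 5.0  # matches the analysis model's logistic kernel

EXCLUDABLE_KINDS = ("short", "long", "close_pair", "short_event")


def pulse_shape(phase: np.ndarray) -> np.ndarray:
    """Fixed periodic pulse shape w(phase), unit energy over one cycle."""
    amps = np.asarray(PULSE_HARMONIC_AMPLITUDES)
    amps = amps / np.sqrt(np.sum(amps**2))
    out = np.zeros_like(np.asarray(phase, float))
    for k, (ak, pk) in enumerate(zip(amps, PULSE_HARMONIC_PHASES), start=1):
        out += ak * np.sin(k * np.asarray(phase, float) + pk)
    return out


def harmonic_weight_factor() -> float:
    """Power-weighted mean harmonic index of the pulse shape.

    For a pulse train at rate r, the power-weighted mean frequency of the
    waveform is approximately ``factor * r``.
    """
    a2 = np.asarray(PULSE_HARMONIC_AMPLITUDES) ** 2
    k = np.arange(1, len(a2) + 1)
    return float(np.sum(k * a2) / np.sum(a2))


def pulse_shape_range() -> float:
    """max(w) - min(w) over one cycle (the noiseless measured amplitude of a
    unit-carrier pulse train)."""
    w = pulse_shape(np.linspace(0, 2 * np.pi, 4096, endpoint=False))
    return float(w.max() - w.min())


@dataclass(frozen=True)
class CauseEffects:
    """Response-effect distribution for one arousal cause.

    Frequency magnitudes are in observable mean-instantaneous-frequency Hz,
    amplitude drops in measured-amplitude a.u.; delays in seconds from the
    EEG arousal start to the response's logistic midpoint.
    """

    freq_prob: float
    freq_mag_mean: float
    freq_mag_sd: float
    freq_delay_mean: float
    freq_recovery_prob: float
    amp_prob: float
    amp_drop_mean: float
    amp_drop_sd: float
    amp_delay_mean: float
    amp_recovery_prob: float
    delay_sd: float = 0.8


#: defaults follow the reported group medians (magnitudes, delays, response
#: and recovery proportions); spreads are stand-in conventions
DEFAULT_EFFECTS: dict[str, CauseEffects] = {
    "spontaneous": CauseEffects(0.713, 0.15, 0.05, 3.8, 0.683, 0.82, 1.29, 0.40, 3.8, 0.512),
    "apnea+des": CauseEffects(0.831, 0.25, 0.05, 4.7, 0.66, 0.779, 1.50, 0.40, 4.4, 0.485),
    "apnea-des": CauseEffects(0.831, 0.25, 0.05, 4.7, 0.557, 0.805, 1.37, 0.40, 4.4, 0.412),
    "hypopnea+des": CauseEffects(0.78, 0.18, 0.05, 4.7, 0.66, 0.809, 1.50, 0.40, 4.1, 0.485),
    "hypopnea-des": CauseEffects(0.78, 0.18, 0.05, 3.8, 0.66, 0.839, 1.37, 0.40, 3.8, 0.512),
}

#: stand-in cause mix for an OSA-clinic cohort (hypopnea arousals more common
#: than apnea arousals, desaturating events more common than not)
DEFAULT_CAUSE_PROPORTIONS: dict[str, float] = {
    "spontaneous": 0.55,
    "apnea+des": 0.10,
    "apnea-des": 0.05,
    "hypopnea+des": 0.18,
    "hypopnea-des": 0.12,
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters; identical seed => identical cohort."""

    n_subjects: int = 20
    arousals_per_subject: int = 6
    cause_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_PROPORTIONS)
    )
    effects: dict[str, CauseEffects] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    seed: int = 0
    sampling_rate: float = 64.0
    noise_sd: float = 0.05  # a.u., additive white noise on the waveform
    baseline_rate_range: tuple[float, float] = (0.9, 1.4)  # Hz pulse rate
    baseline_amplitude_mean: float = 6.32  # a.u., measured (max-min) amplitude
    baseline_amplitude_sd: float = 0.8
    arousal_spacing_s: float = 90.0
    arousal_duration_range: tuple[float, float] = (8.0, 12.0)
    lead_in_s: float = 60.0
    #: deliberately excludable arousals appended per subject (cycled kinds)
    n_excludable: int = 0
    #: pre-response pulse-rate dip (Hz) planted before respiratory responses
    pre_response_dip_hz: float = 0.0
    transition_shape: str = "logistic"  # or 'raised_cosine'
    recovery_lag_mean: float = 5.0
    recovery_lag_sd: float = 1.0

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.n_subjects < 0:
            problems.append("n_subjects must be >= 0")
        if self.arousals_per_subject < 0:
            problems.append("arousals_per_subject must be >= 0")
        props = self.cause_proportions
        if any(c not in CAUSES for c in props):
            problems.append(f"unknown cause in proportions: {sorted(props)}")
        if props and abs(sum(props.values()) - 1.0) > 1e-6:
            problems.append("cause_proportions must sum to 1")
        if self.transition_shape not in ("logistic", "raised_cosine"):
            problems.append(f"unknown transition_shape {self.transition_shape!r}")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        # event geometry: an associated event may begin ~29 s before its
        # arousal; the previous arousal ends <= 12 s after its own start, and
        # 10 s clearance is required between the two clusters
        min_spacing = (
            self.arousal_duration_range[1] + 29.0 + 10.0 + 2.0
        )
        if self.arousal_spacing_s < min_spacing:
            problems.append(
                "arousal_spacing_s too small to satisfy the 10-s clearance rule "
                f"between arousal clusters (need >= {min_spacing:.0f} s)"
            )
        return problems


@dataclass(frozen=True)
class ArousalTruth:
    """Ground truth for one planted arousal."""

    index: int
    cause: str
    start_s: float
    duration_s: float
    includable: bool = True
    excludable_kind: str = ""
    freq_present: bool = False
    freq_magnitude: float = 0.0  # Hz, observable units
    freq_delay: float = np.nan
    freq_recovery: bool = False
    freq_recovery_lag: float = np.nan
    amp_present: bool = False
    amp_drop_au: float = 0.0
    amp_drop_fraction: float = 0.0
    amp_delay: float = np.nan
    amp_recovery: bool = False
    amp_recovery_lag: float = np.nan

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SubjectTruth:
    subject_id: str
    baseline_pulse_rate: float  # Hz
    baseline_pulse_amplitude: float  # a.u., measured (max-min) units
    arousals: list[ArousalTruth] = field(default_factory=list)


def _step(t: np.ndarray, c: float, shape: str) -> np.ndarray:
    """Unit upward transition centred at c (logistic or raised-cosine)."""
    if shape == "logistic":
        return expit(GROWTH_RATE * (t - c))
    half = 2.0 / GROWTH_RATE  # comparable 10-90% rise time
    x = np.clip((t - c) / (2 * half), -0.5, 0.5)
    return 0.5 * (1.0 + np.sin(np.pi * x))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _draw_arousal_truth(
    rng: np.random.Generator,
    index: int,
    cause: str,
    start: float,
    duration: float,
    eff: CauseEffects,
    config: CohortConfig,
    baseline_amp: float,
) -> ArousalTruth:
    end = start + duration

    def draw_response(prob, mag_mean, mag_sd, delay_mean, rec_prob):
        present = rng.random() < prob
        mag = _truncnorm(rng, mag_mean, mag_sd, 0.25 * mag_mean, 4 * mag_mean) if present else 0.0
        delay = _truncnorm(rng, delay_mean, eff.delay_sd, -1.5, duration + 3.0)
        recovery = bool(present and rng.random() < rec_prob)
        # the recovery step must finish inside the analysis window [-8, end+8]
        lag_hi = (end + 5.0) - (start + delay) - 1.0
        lag = _truncnorm(rng, config.recovery_lag_mean, config.recovery_lag_sd, 2.0, max(2.5, lag_hi))
        return present, mag, delay, recovery, lag

    f_present, f_mag, f_delay, f_rec, f_lag = draw_response(
        eff.freq_prob, eff.freq_mag_mean, eff.freq_mag_sd, eff.freq_delay_mean,
        eff.freq_recovery_prob,
    )
    a_present, a_drop, a_delay, a_rec, a_lag = draw_response(
        eff.amp_prob, eff.amp_drop_mean, eff.amp_drop_sd, eff.amp_delay_mean,
        eff.amp_recovery_prob,
    )
    return ArousalTruth(
        index=index,
        cause=cause,
        start_s=start,
        duration_s=duration,
        freq_present=f_present,
        freq_magnitude=f_mag if f_present else 0.0,
        freq_delay=f_delay if f_present else np.nan,
        freq_recovery=f_rec,
        freq_recovery_lag=f_lag if f_rec else np.nan,
        amp_present=a_present,
        amp_drop_au=a_drop if a_present else 0.0,
        amp_drop_fraction=(a_drop / baseline_amp) if a_present else 0.0,
        amp_delay=a_delay if a_present else np.nan,
        amp_recovery=a_rec,
        amp_recovery_lag=a_lag if a_rec else np.nan,
    )


def _annotations_for_arousal(
    rng: np.random.Generator, truth: ArousalTruth, ann: AnnotationSet
) -> None:
    cause = truth.cause
    scored = "spontaneous" if cause == "spontaneous" else "respiratory"
    ann.arousals.append(Arousal(truth.start_s, truth.duration_s, scored_cause=scored))
    if cause == "spontaneous":
        return
    ev_dur = rng.uniform(15.0, 25.0)
    ev_end = truth.start_s + rng.uniform(-4.0, min(4.0, truth.duration_s))
    ev_type = "obstructive_apnea" if cause.startswith("apnea") else "hypopnea"
    event = RespEvent(ev_end - ev_dur, ev_dur, type=ev_type)
    ann.resp_events.append(event)
    if cause.endswith("+des"):
        ann.desaturations.append(Desaturation(event.end_s - 5.0, 15.0))


def _append_excludable(
    rng: np.random.Generator,
    kind: str,
    index: int,
    start: float,
    ann: AnnotationSet,
) -> list[ArousalTruth]:
    """Plant an arousal (cluster) that must fail the inclusion rules."""
    if kind == "short":
        ann.arousals.append(Arousal(start, 2.0, scored_cause="spontaneous"))
        return [ArousalTruth(index, "spontaneous", start, 2.0, includable=False,
                             excludable_kind=kind)]
    if kind == "long":
        ann.arousals.append(Arousal(start, 16.0, scored_cause="spontaneous"))
        return [ArousalTruth(index, "spontaneous", start, 16.0, includable=False,
                             excludable_kind=kind)]
    if kind == "close_pair":
        ann.arousals.append(Arousal(start, 5.0, scored_cause="spontaneous"))
        ann.arousals.append(Arousal(start + 13.0, 5.0, scored_cause="spontaneous"))
        return [
            ArousalTruth(index, "spontaneous", start, 5.0, includable=False,
                         excludable_kind=kind),
            ArousalTruth(index + 1, "spontaneous", start + 13.0, 5.0, includable=False,
                         excludable_kind=kind),
        ]
    if kind == "short_event":
        # respiratory arousal whose only candidate event lasted < 10 s
        ann.arousals.append(Arousal(start, 8.0, scored_cause="respiratory"))
        ann.resp_events.append(RespEvent(start - 9.0, 9.0, type="obstructive_apnea"))
        return [ArousalTruth(index, "spontaneous", start, 8.0, includable=False,
                             excludable_kind=kind)]
    raise ValueError(f"unknown excludable kind {kind!r}")


def generate_subject(
    config: CohortConfig, subject_index: int
) -> tuple[PPGRecord, AnnotationSet, SubjectTruth]:
    """Generate one synthetic subject (waveform, annotations, ground truth).

    The RNG stream is derived from ``(seed, subject_index)`` so each subject
    is independently reproducible.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid cohort config: " + "; ".join(problems))
    if subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    rng = np.random.default_rng([config.seed, subject_index])
    subject_id = f"synth{subject_index:03d}"

    r0 = rng.uniform(*config.baseline_rate_range)
    amp0 = _truncnorm(
        rng, config.baseline_amplitude_mean, config.baseline_amplitude_sd,
        0.3 * config.baseline_amplitude_mean, 3 * config.baseline_amplitude_mean,
    )
    truth = SubjectTruth(subject_id, baseline_pulse_rate=r0, baseline_pulse_amplitude=amp0)
    ann = AnnotationSet()

    causes = list(config.cause_proportions) or ["spontaneous"]
    probs = np.array([config.cause_proportions.get(c, 0.0) for c in causes])
    probs = probs / probs.sum() if probs.sum() else np.full(len(causes), 1 / len(causes))

    spacing = config.arousal_spacing_s
    t_cursor = config.lead_in_s
    for i in range(config.arousals_per_subject):
        cause = causes[rng.choice(len(causes), p=probs)]
        duration = rng.uniform(*config.arousal_duration_range)
        at = _draw_arousal_truth(
            rng, i, cause, t_cursor, duration, config.effects[cause], config, amp0
        )
        truth.arousals.append(at)
        _annotations_for_arousal(rng, at, ann)
        t_cursor += spacing

    t_cursor += 30.0  # clearance before the excludable tail
    idx = config.arousals_per_subject
    for j in range(config.n_excludable):
        kind = EXCLUDABLE_KINDS[j % len(EXCLUDABLE_KINDS)]
        planted = _append_excludable(rng, kind, idx, t_cursor, ann)
        truth.arousals.extend(planted)
        idx += len(planted)
        t_cursor += 60.0

    total_s = t_cursor + config.lead_in_s
    n_epochs = int(np.ceil(total_s / 30.0))
    ann.stage_epochs = [StageEpoch(30.0 * k, stage="N2") for k in range(n_epochs)]

    record = _synthesize_waveform(rng, truth, n_epochs * 30.0, config)
    record.subject_id = subject_id
    return record, ann, truth


def _synthesize_waveform(
    rng: np.random.Generator, truth: SubjectTruth, total_s: float, config: CohortConfig
) -> PPGRecord:
    fs = config.sampling_rate
    t = np.arange(int(round(total_s * fs))) / fs
    shape = config.transition_shape
    hf = harmonic_weight_factor()

    rate = np.full_like(t, truth.baseline_pulse_rate)
    modulation = np.ones_like(t)
    for at in truth.arousals:
        end = at.end_s
        if at.freq_present and at.freq_magnitude > 0:
            mid = at.start_s + at.freq_delay
            off = mid + at.freq_recovery_lag if at.freq_recovery else end + 12.0
            rate += (at.freq_magnitude / hf) * (_step(t, mid, shape) - _step(t, off, shape))
        if config.pre_response_dip_hz > 0 and at.cause != "spontaneous":
            on = at.start_s - 30.0
            off = end + 12.0
            rate -= (config.pre_response_dip_hz / hf) * (_step(t, on, shape) - _step(t, off, shape))
        if at.amp_present and at.amp_drop_fraction > 0:
            mid = at.start_s + at.amp_delay
            off = mid + at.amp_recovery_lag if at.amp_recovery else end + 12.0
            modulation -= at.amp_drop_fraction * (_step(t, mid, shape) - _step(t, off, shape))
    modulation = np.clip(modulation, 0.05, None)

    phase = 2 * np.pi * np.cumsum(rate) / fs
    carrier = truth.baseline_pulse_amplitude / pulse_shape_range()
    x = carrier * modulation * pulse_shape(phase)
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal(len(t))
    return PPGRecord(samples=x, sampling_rate=fs, subject_id=truth.subject_id)


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[PPGRecord, AnnotationSet, SubjectTruth]]:
    """Generate all subjects of a cohort (deterministic for a fixed seed)."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def truth_table(subjects: list[SubjectTruth]) -> pd.DataFrame:
    """Flatten per-arousal ground truth into one cohort-level table."""
    rows = []
    for st in subjects:
        for at in st.arousals:
            rows.append(
                {
                    "subject_id": st.subject_id,
                    "arousal_index": at.index,
                    "cause": at.cause,
                    "start_s": at.start_s,
                    "duration_s": at.duration_s,
                    "includable": at.includable,
                    "excludable_kind": at.excludable_kind,
                    "baseline_pulse_rate_hz": st.baseline_pulse_rate,
                    "baseline_amplitude_au": st.baseline_pulse_amplitude,
                    "freq_present": at.freq_present,
                    "freq_magnitude_hz": at.freq_magnitude,
                    "freq_delay_s": at.freq_delay,
                    "freq_recovery": at.freq_recovery,
                    "amp_present": at.amp_present,
                    "amp_drop_au": at.amp_drop_au,
                    "amp_drop_fraction": at.amp_drop_fraction,
                    "amp_delay_s": at.amp_delay,
                    "amp_recovery": at.amp_recovery,
                }
            )
    return pd.DataFrame(rows)
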