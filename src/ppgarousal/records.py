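"""Core data containers: PPG waveforms and polysomnography annotation tracks.

Time convention: seconds from recording start; event intervals are half-open
``[start_s, start_s + duration_s)``. Sleep stages are scored in 30-s epochs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

STAGE_EPOCH_S = 30.0
STAGES = ("W", "N1", "N2", "N3", "R")
UNSCORED = "unscored"

#: respiratory event types; only the first two can cause an included arousal
OBSTRUCTIVE_TYPES = ("obstructive_apnea", "hypopnea")
RESP_EVENT_TYPES = OBSTRUCTIVE_TYPES + ("central_apnea", "mixed_apnea")


@dataclass(frozen=True)
class Interval:
    """A scored event on the recording time axis."""

    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def overlaps(self, start_s: float, end_s: float) -> bool:
        """True if this event intersects the half-open window [start_s, end_s)."""
        return self.start_s < end_s and self.end_s > start_s

    def gap_to(self, other: "Interval") -> float:
        """Smallest separation between the two intervals (0 when they overlap)."""
        return max(0.0, max(self.start_s, other.start_s) - min(self.end_s, other.end_s))


@dataclass(frozen=True)
class Arousal(Interval):
    #: 'spontaneous' or 'respiratory' as scored; other labels are excluded downstream
    scored_cause: str = "spontaneous"


@dataclass(frozen=True)
class RespEvent(Interval):
    type: str = "obstructive_apnea"

    def __post_init__(self) -> None:
        if self.type not in RESP_EVENT_TYPES:
            raise ValueError(f"unknown respiratory event type {self.type!r}")


@dataclass(frozen=True)
class Desaturation(Interval):
    """A >=3 percentage-point blood-oxygen desaturation event."""


@dataclass(frozen=True)
class StageEpoch:
    epoch_start_s: float
    stage: str = UNSCORED


@dataclass
class PPGRecord:
    """A uniformly sampled photoplethysmogram.

    ``start_time_s`` anchors the first sample on the recording clock so that
    slices keep their absolute timing.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("PPG samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.samples)) / self.sampling_rate

    def slice(self, start_s: float, end_s: float) -> "PPGRecord":
        """Return the sub-record covering [start_s, end_s) on the recording clock."""
        i0 = int(round((start_s - self.start_time_s) * self.sampling_rate))
        i1 = int(round((end_s - self.start_time_s) * self.sampling_rate))
        if i0 < 0 or i1 > len(self.samples):
            raise ValueError(
                f"slice [{start_s}, {end_s}) s exceeds record bounds "
                f"[{self.start_time_s}, {self.end_time_s}) s"
            )
        return replace(self, samples=self.samples[i0:i1], start_time_s=start_s)


@dataclass
class AnnotationSet:
    """Per-subject scored event tracks on one time axis."""

    arousals: list[Arousal] = field(default_factory=list)
    resp_events: list[RespEvent] = field(default_factory=list)
    desaturations: list[Desaturation] = field(default_factory=list)
    stage_epochs: list[StageEpoch] = field(default_factory=list)

    def stage_at(self, t_s: float) -> str:
        """Sleep stage of the 30-s epoch containing t_s (UNSCORED if none)."""
        for ep in self.stage_epochs:
            if ep.epoch_start_s <= t_s < ep.epoch_start_s + STAGE_EPOCH_S:
                return ep.stage
        return UNSCORED

    def scored_events(self) -> Sequence[Interval]:
        """All scored events (arousals, respiratory events, desaturations)."""
        return [*self.arousals, *self.resp_events, *self.desaturations]
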