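"""Arousal inclusion rules, cause classification and stable-sleep sampling.

An arousal enters the analysis only when it passes, in order:

1. **duration** — 3 s <= duration <= 15 s;
2. **stage** — the 30-s epoch containing the arousal start, or the previous
   epoch, has a scored sleep stage;
3. **proximity** — no other arousal, and no respiratory event other than the
   assumed cause, within 10 s of the arousal's start or end;
4. **cause** — the scored cause is spontaneous or respiratory (limb-movement
   and other arousals are out of scope);
5. **association/uniqueness** — a respiratory arousal must be uniquely
   associated with one obstructive event (obstructive apnea or hypopnea) of
   >= 10 s that ended no earlier than 5 s before the arousal start and no
   later than the arousal end.

Respiratory arousals are further split by event type and by whether a >= 3%
desaturation accompanied the event, giving five causes: spontaneous,
apnea+des, apnea-des, hypopnea+des, hypopnea-des. Only the first failing rule
is logged per excluded arousal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    STAGE_EPOCH_S,
    UNSCORED,
    AnnotationSet,
    Arousal,
    Desaturation,
    OBSTRUCTIVE_TYPES,
    RespEvent,
)

logger = logging.getLogger(__name__)

CAUSES = ("spontaneous", "apnea+des", "apnea-des", "hypopnea+des", "hypopnea-des")
RESPIRATORY_CAUSES = CAUSES[1:]

#: exclusion rules in evaluation (and logging) order
RULES = ("duration", "stage", "proximity", "cause", "association", "uniqueness")


@dataclass(frozen=True)
class EventConfig:
    """Selection-rule parameters (defaults follow the scoring conventions)."""

    min_arousal_s: float = 3.0
    max_arousal_s: float = 15.0
    proximity_s: float = 10.0
    assoc_lookback_s: float = 5.0
    min_event_s: float = 10.0
    #: window after the respiratory event's end within which an overlapping
    #: desaturation counts as accompanying it (circulatory delay allowance)
    desat_window_s: float = 20.0
    stable_duration_s: float = 10.0
    stable_grid_s: float = 1.0


DEFAULT_EVENT_CONFIG = EventConfig()


@dataclass(frozen=True)
class ArousalCase:
    """One included arousal with its classified cause."""

    subject_id: str
    start_s: float
    duration_s: float
    cause: str
    associated_event: RespEvent | None
    stage: str

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ValueError(f"unknown cause {self.cause!r}")
        if (self.cause == "spontaneous") != (self.associated_event is None):
            raise ValueError("spontaneous cases must not carry an associated event")


@dataclass(frozen=True)
class Exclusion:
    arousal_index: int
    start_s: float
    duration_s: float
    rule: str
    details: str


@dataclass(frozen=True)
class StableSleepSample:
    subject_id: str
    start_s: float
    duration_s: float
    stage: str
    mean_frequency: float
    mean_amplitude: float


def _arousal_stage(ann: AnnotationSet, arousal: Arousal) -> str:
    """Stage of the epoch containing the arousal start, else the previous epoch."""
    stage = ann.stage_at(arousal.start_s)
    if stage != UNSCORED:
        return stage
    return ann.stage_at(arousal.start_s - STAGE_EPOCH_S)


def associate_respiratory_event(
    arousal: Arousal,
    resp_events: list[RespEvent],
    config: EventConfig = DEFAULT_EVENT_CONFIG,
) -> tuple[RespEvent | None, int]:
    """Find the unique obstructive event that can explain a respiratory arousal.

    A candidate is an obstructive apnea or hypopnea of >= ``min_event_s``
    whose end falls in ``[arousal start - assoc_lookback_s, arousal end]``.
    Returns ``(event, n_candidates)``; the event is ``None`` unless exactly one
    candidate exists (respiratory arousals must be uniquely associated).
    """
    candidates = [
        e
        for e in resp_events
        if e.type in OBSTRUCTIVE_TYPES
        and e.duration_s >= config.min_event_s
        and arousal.start_s - config.assoc_lookback_s <= e.end_s <= arousal.end_s
    ]
    if len(candidates) == 1:
        return candidates[0], 1
    return None, len(candidates)


def flag_desaturation(
    event: RespEvent,
    desaturations: list[Desaturation],
    config: EventConfig = DEFAULT_EVENT_CONFIG,
) -> bool:
    """True when a desaturation overlaps [event start, event end + desat window)."""
    return any(
        d.overlaps(event.start_s, event.end_s + config.desat_window_s)
        for d in desaturations
    )


def _proximity_conflicts(
    arousal: Arousal,
    ann: AnnotationSet,
    exempt: list[RespEvent],
    config: EventConfig,
) -> str | None:
    """First proximity violation (description) or None.

    Any other scored arousal, or any respiratory event that is not the assumed
    cause, lying within ``proximity_s`` of the arousal's start or end is a
    violation. Overlapping duplicate arousal annotations fall out naturally
    (distance 0). All scored arousals count, including ones excluded by other
    rules.
    """
    for other in ann.arousals:
        if other is arousal:
            continue
        if arousal.gap_to(other) < config.proximity_s:
            return f"arousal at {other.start_s:.1f}s within {config.proximity_s:.0f}s"
    for ev in ann.resp_events:
        if any(ev is x for x in exempt):
            continue
        if arousal.gap_to(ev) < config.proximity_s:
            return f"{ev.type} at {ev.start_s:.1f}s within {config.proximity_s:.0f}s"
    return None


def filter_and_classify(
    ann: AnnotationSet,
    subject_id: str = "",
    config: EventConfig = DEFAULT_EVENT_CONFIG,
) -> tuple[list[ArousalCase], list[Exclusion]]:
    """Apply the inclusion rules to every scored arousal.

    Every input arousal ends up exactly once in the returned cases or in the
    exclusion log, tagged with the first failing rule.
    """
    cases: list[ArousalCase] = []
    exclusions: list[Exclusion] = []

    def exclude(i: int, a: Arousal, rule: str, details: str) -> None:
        exclusions.append(Exclusion(i, a.start_s, a.duration_s, rule, details))

    for i, arousal in enumerate(ann.arousals):
        if not (config.min_arousal_s <= arousal.duration_s <= config.max_arousal_s):
            exclude(i, arousal, "duration", f"{arousal.duration_s:.1f}s")
            continue
        stage = _arousal_stage(ann, arousal)
        if stage == UNSCORED:
            exclude(i, arousal, "stage", "no scored stage in own or previous epoch")
            continue

        # Potential causes of a scored-respiratory arousal (obstructive events
        # ending within the association window, regardless of length) are
        # exempt from the proximity rule: they are "the assumed cause", even
        # when they later fail the 10-s association gate.
        exempt: list[RespEvent] = []
        assoc: RespEvent | None = None
        n_cand = 0
        if arousal.scored_cause == "respiratory":
            assoc, n_cand = associate_respiratory_event(arousal, ann.resp_events, config)
            exempt = [
                e
                for e in ann.resp_events
                if e.type in OBSTRUCTIVE_TYPES
                and arousal.start_s - config.assoc_lookback_s <= e.end_s <= arousal.end_s
            ]

        conflict = _proximity_conflicts(arousal, ann, exempt, config)
        if conflict is not None:
            exclude(i, arousal, "proximity", conflict)
            continue

        if arousal.scored_cause == "spontaneous":
            cases.append(
                ArousalCase(subject_id, arousal.start_s, arousal.duration_s,
                            "spontaneous", None, stage)
            )
        elif arousal.scored_cause == "respiratory":
            if n_cand == 0:
                exclude(i, arousal, "association", "no qualifying obstructive event")
                continue
            if n_cand > 1:
                exclude(i, arousal, "uniqueness", f"{n_cand} qualifying events")
                continue
            assert assoc is not None
            des = flag_desaturation(assoc, ann.desaturations, config)
            base = "apnea" if assoc.type == "obstructive_apnea" else "hypopnea"
            cause = f"{base}+des" if des else f"{base}-des"
            cases.append(
                ArousalCase(subject_id, arousal.start_s, arousal.duration_s,
                            cause, assoc, stage)
            )
        else:
            exclude(i, arousal, "cause", f"scored cause {arousal.scored_cause!r}")
    return cases, exclusions


def exclusions_to_frame(exclusions: list[Exclusion], subject_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "arousal_index": e.arousal_index,
                "start_s": e.start_s,
                "duration_s": e.duration_s,
                "rule": e.rule,
                "details": e.details,
            }
            for e in exclusions
        ],
        columns=["subject_id", "arousal_index", "start_s", "duration_s", "rule", "details"],
    )


def _stable_candidates(
    ann: AnnotationSet, record_start_s: float, record_end_s: float, config: EventConfig
) -> list[tuple[float, str]]:
    """Event-free, transition-free 10-s windows on a 1-s grid, greedily thinned
    to be non-overlapping (the enumeration grid is a convention, not a scored
    quantity)."""
    dur = config.stable_duration_s
    events = ann.scored_events()
    out: list[tuple[float, str]] = []
    last_end = -np.inf
    t = np.ceil(record_start_s / config.stable_grid_s) * config.stable_grid_s
    while t + dur <= record_end_s:
        if t >= last_end:
            stage = ann.stage_at(t)
            same_stage = stage != UNSCORED and all(
                ann.stage_at(x) == stage
                for x in np.arange(t, t + dur, STAGE_EPOCH_S / 2)
            ) and ann.stage_at(t + dur - 1e-9) == stage
            if same_stage and not any(e.overlaps(t, t + dur) for e in events):
                out.append((float(t), stage))
                last_end = t + dur
        t += config.stable_grid_s
    return out


def sample_stable_sleep(
    ann: AnnotationSet,
    included_cases: list[ArousalCase],
    characteristics_provider,
    rng: np.random.Generator,
    subject_id: str = "",
    record_start_s: float = 0.0,
    record_end_s: float | None = None,
    config: EventConfig = DEFAULT_EVENT_CONFIG,
) -> list[StableSleepSample]:
    """Draw stable-sleep reference windows matched to the respiratory arousals.

    Per sleep stage, candidate event-free 10-s windows are randomly permuted
    and up to the subject's number of included *respiratory* arousals in that
    stage are taken (all candidates if fewer exist). Each sample carries the
    mean frequency and amplitude over its window, computed by
    ``characteristics_provider(start_s, duration_s) -> (freq, amp)``.
    """
    if record_end_s is None:
        record_end_s = max(
            (ep.epoch_start_s + STAGE_EPOCH_S for ep in ann.stage_epochs), default=0.0
        )
    wanted: dict[str, int] = {}
    for case in included_cases:
        if case.cause in RESPIRATORY_CAUSES:
            wanted[case.stage] = wanted.get(case.stage, 0) + 1
    if not wanted:
        return []
    candidates = _stable_candidates(ann, record_start_s, record_end_s, config)
    if not candidates:
        logger.info("subject %s: no stable-sleep candidates", subject_id)
        return []
    samples: list[StableSleepSample] = []
    for stage, n_wanted in sorted(wanted.items()):
        pool = [c for c in candidates if c[1] == stage]
        if not pool:
            logger.info("subject %s: no stable candidates in stage %s", subject_id, stage)
            continue
        order = rng.permutation(len(pool))
        for idx in order[: min(n_wanted, len(pool))]:
            start, st = pool[idx]
            freq, amp = characteristics_provider(start, config.stable_duration_s)
            samples.append(
                StableSleepSample(subject_id, start, config.stable_duration_s, st, freq, amp)
            )
    return samples
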