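"""PPG signal characteristics around arousals.

Two characteristics are derived from a 64-Hz PPG segment spanning 10 s before
the arousal start to 10 s after its end:

* **mean instantaneous frequency** — power-weighted mean of the short-time
  spectrum,

  .. math:: \\bar f_{inst}(t) = \\frac{\\sum_{f \\in F} f \\, PSD_f(x[t-1s, t+63/64\\,s])}
            {\\sum_{f \\in F} PSD_f(x[t-1s, t+63/64\\,s])},

  computed from a spectrogram with a 2-s boxcar window (128 samples), a hop of
  one sample, and a zero-padded transform of length 16 x 64 = 1024, giving
  frequency bins F = 0..32 Hz in steps of 1/16 Hz. Because weights are spectral
  power, higher harmonics of the pulse rate pull the metric above the
  fundamental; that bias cancels in before/after comparisons.

* **instantaneous amplitude** — max minus min of the PPG within the same 2-s
  sliding window (tracks peripheral pulse-wave amplitude).

Both traces are smoothed with a centred 2-s moving average and trimmed to a
time axis of the arousal duration plus 16 s, anchored at the EEG arousal start
(t = 0), i.e. covering [-8 s, end + 8 s).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .records import Interval, PPGRecord

logger = logging.getLogger(__name__)

TARGET_HZ = 64
WINDOW_S = 2.0  # analysis window for spectrogram / amplitude / smoothing
PAD_FACTOR = 16  # zero-padded transform length = PAD_FACTOR * sampling rate
SEGMENT_MARGIN_S = 10.0  # raw segment extends this far beyond the arousal
TRACE_MARGIN_S = 8.0  # final characteristic extends this far beyond the arousal


class InsufficientSamplingRate(ValueError):
    pass


class SegmentOutOfBounds(ValueError):
    pass


@dataclass
class CharacteristicSeries:
    """A smoothed characteristic trace on a time axis relative to arousal start."""

    times: np.ndarray  # s relative to EEG arousal start, step 1/64 s
    values: np.ndarray  # Hz (frequency) or a.u. (amplitude)
    kind: str  # 'frequency' | 'amplitude'
    arousal_duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("frequency", "amplitude"):
            raise ValueError(f"kind must be 'frequency' or 'amplitude', got {self.kind!r}")
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


def decimate(record: PPGRecord, target_hz: int = TARGET_HZ) -> PPGRecord:
    """Anti-alias filter and downsample a PPG record to ``target_hz``.

    Integer factors use an IIR decimator; non-integer ratios fall back to
    polyphase resampling. A record already at the target rate is returned
    unchanged.
    """
    fs = record.sampling_rate
    if fs < target_hz:
        raise InsufficientSamplingRate(
            f"insufficient sampling rate: {fs} Hz < {target_hz} Hz"
        )
    if math.isclose(fs, target_hz):
        return record
    # polyphase FIR resampling: flat passband (unlike IIR decimation) and
    # handles non-integer ratios uniformly
    ratio = Fraction(fs / target_hz).limit_denominator(1000)  # fs/target = down/up
    out = signal.resample_poly(record.samples, ratio.denominator, ratio.numerator)
    return PPGRecord(
        samples=out,
        sampling_rate=float(target_hz),
        subject_id=record.subject_id,
        start_time_s=record.start_time_s,
    )


def extract_segment(record: PPGRecord, arousal: Interval) -> PPGRecord:
    """Slice [start - 10 s, end + 10 s) around an arousal.

    Raises :class:`SegmentOutOfBounds` when the window does not fit in the
    record; callers drop (and log) such arousals.
    """
    start = arousal.start_s - SEGMENT_MARGIN_S
    end = arousal.end_s + SEGMENT_MARGIN_S
    if start < record.start_time_s or end > record.end_time_s + 1e-9:
        raise SegmentOutOfBounds(
            f"segment [{start}, {end}) s outside record "
            f"[{record.start_time_s}, {record.end_time_s}) s"
        )
    return record.slice(start, min(end, record.end_time_s))


def _sliding_windows(x: np.ndarray, fs: int) -> np.ndarray:
    n_win = int(round(WINDOW_S * fs))
    if len(x) < n_win:
        raise ValueError(f"segment shorter than the {WINDOW_S}-s analysis window")
    return sliding_window_view(x, n_win)


def mean_instantaneous_frequency(x: np.ndarray, fs: int = TARGET_HZ) -> np.ndarray:
    """Power-weighted mean frequency per 2-s sliding window (hop = 1 sample).

    Returns one value per window position; the value of window ``i`` refers to
    time ``i/fs + 1 s`` after the first sample. Windows are raw (no detrend):
    residual DC power slightly deflates the estimate, identically across the
    trace. All-zero windows yield 0 Hz.
    """
    windows = _sliding_windows(np.asarray(x, float), fs)
    n_fft = PAD_FACTOR * fs
    psd = np.abs(np.fft.rfft(windows, n=n_fft, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)  # 0..fs/2 step 1/16 Hz
    total = psd.sum(axis=1)
    out = np.zeros(len(windows))
    ok = total > 0
    if not ok.all():
        logger.info("mean frequency: %d all-zero windows set to 0 Hz", (~ok).sum())
    out[ok] = psd[ok] @ freqs / total[ok]
    return out


def instantaneous_amplitude(x: np.ndarray, fs: int = TARGET_HZ) -> np.ndarray:
    """Max minus min of the signal per 2-s sliding window (hop = 1 sample)."""
    windows = _sliding_windows(np.asarray(x, float), fs)
    return windows.max(axis=1) - windows.min(axis=1)


def moving_average(values: np.ndarray, fs: int = TARGET_HZ) -> np.ndarray:
    """Centred 2-s moving average, valid region only."""
    n = int(round(WINDOW_S * fs))
    kernel = np.full(n, 1.0 / n)
    return np.convolve(np.asarray(values, float), kernel, mode="valid")


def _characteristic(
    segment: PPGRecord, arousal: Interval, raw_fn, kind: str
) -> CharacteristicSeries:
    fs = int(round(segment.sampling_rate))
    if fs != TARGET_HZ:
        raise ValueError(f"characteristics require a {TARGET_HZ}-Hz segment, got {fs} Hz")
    raw = raw_fn(segment.samples, fs)
    smooth_vals = moving_average(raw, fs)
    # After windowing (1 s lost each end) and smoothing (1 s more), the trace
    # spans [start-8, end+8]; trim to exactly (duration + 16 s) * fs samples.
    n_target = int(round((arousal.duration_s + 2 * TRACE_MARGIN_S) * fs))
    if len(smooth_vals) < n_target:
        raise ValueError("segment too short for the requested characteristic length")
    values = smooth_vals[:n_target]
    # windowing then smoothing each shift the first valid value by half a
    # window: the first smoothed value refers to segment start + 2 s = start - 8 s
    t0 = (segment.start_time_s + WINDOW_S) - arousal.start_s
    times = t0 + np.arange(n_target) / fs
    return CharacteristicSeries(times, values, kind, arousal.duration_s)


def frequency_series(segment: PPGRecord, arousal: Interval) -> CharacteristicSeries:
    """Smoothed mean-instantaneous-frequency trace for one arousal segment."""
    return _characteristic(segment, arousal, mean_instantaneous_frequency, "frequency")


def amplitude_series(segment: PPGRecord, arousal: Interval) -> CharacteristicSeries:
    """Smoothed instantaneous-amplitude trace for one arousal segment."""
    return _characteristic(segment, arousal, instantaneous_amplitude, "amplitude")


def arousal_characteristics(
    record: PPGRecord, arousal: Interval
) -> tuple[CharacteristicSeries, CharacteristicSeries]:
    """Frequency and amplitude traces for one arousal from a 64-Hz record."""
    segment = extract_segment(record, arousal)
    return frequency_series(segment, arousal), amplitude_series(segment, arousal)


def window_means(
    record: PPGRecord, start_s: float, duration_s: float = 10.0
) -> tuple[float, float]:
    """Mean frequency and amplitude of a stable-sleep window.

    Both characteristics are derived exactly as for arousal segments and
    averaged over the window; the record must supply 2 s of context on each
    side (half a window for the sliding analysis plus half for the smoother).
    """
    pad = WINDOW_S
    segment = record.slice(start_s - pad, start_s + duration_s + pad)
    fs = int(round(record.sampling_rate))
    n = int(round(duration_s * fs))
    freq = moving_average(mean_instantaneous_frequency(segment.samples, fs), fs)
    amp = moving_average(instantaneous_amplitude(segment.samples, fs), fs)
    return float(freq[:n].mean()), float(amp[:n].mean())
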