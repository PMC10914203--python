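import numpy as np
import pytest

from ppgarousal import synth
from ppgarousal.features import CharacteristicSeries
from ppgarousal.respmodel import FitWindow, LogisticFit

FS = 64


def make_series(
    fit: LogisticFit,
    kind: str = "frequency",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    duration_s: float | None = None,
) -> CharacteristicSeries:
    """Sample a triple-logistic model on its fit window's 64-Hz grid."""
    w = fit.window
    t = np.arange(w.t_min, w.t_max, 1.0 / FS)
    y = fit(t)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        y = y + noise_sd * rng.standard_normal(len(t))
    dur = duration_s if duration_s is not None else (w.t_max - 8.0)
    return CharacteristicSeries(t, y, kind, dur)


@pytest.fixture(scope="session")
def clean_subject():
    """One noiseless subject with a single planted response per characteristic."""
    effects = {
        c: synth.CauseEffects(
            freq_prob=1.0, freq_mag_mean=0.3, freq_mag_sd=1e-9, freq_delay_mean=4.0,
            freq_recovery_prob=0.0, amp_prob=1.0, amp_drop_mean=1.5, amp_drop_sd=1e-9,
            amp_delay_mean=4.0, amp_recovery_prob=0.0, delay_sd=1e-9,
        )
        for c in synth.DEFAULT_EFFECTS
    }
    config = synth.CohortConfig(
        n_subjects=1, arousals_per_subject=1, noise_sd=0.0, seed=5,
        effects=effects, cause_proportions={"spontaneous": 1.0},
    )
    return synth.generate_subject(config, 0), config
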