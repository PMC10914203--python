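"""Triple-logistic step fitting and response categorisation."""
import dataclasses

import numpy as np
import pytest

from ppgarousal.respmodel import (
    FitConfig,
    FitWindow,
    LogisticFit,
    categorize,
    fit_once,
    initial_guesses,
    multistart_fit,
    step_times,
    window_from_series,
)
from .conftest import make_series

FS = 64


def example_fit(**over):
    params = dict(
        a=1.5, b1=0.3, b2_rel=1.2, b3_rel=0.8, c1=-2.0, c2_rel=0.4, c3_rel=0.6,
        window=FitWindow(-8.0, 18.0, 3.0),
    )
    params.update(over)
    return LogisticFit(**params)


class TestStepTimeReparameterisation:
    def test_steps_are_ordered_with_unit_gaps(self):
        for c1, c2r, c3r in [(-4, 0, 0), (0, 0.5, 0.5), (5, 1, 1)]:
            c1_, c2, c3 = step_times(c1, c2r, c3r, t_max=18.0)
            assert c2 >= c1_ + 1
            assert c3 >= c2 + 1
            assert c3 <= 18.0 - 1 + 1e-9


class TestFitOnce:
    def test_fixed_point_recovers_exact_parameters(self):
        truth = example_fit()
        series = make_series(truth)
        fitted = fit_once(series, truth.window,
                          [truth.a, truth.b1, truth.b2_rel, truth.b3_rel,
                           truth.c1, truth.c2_rel, truth.c3_rel])
        assert fitted.ssr == pytest.approx(0.0, abs=1e-8)
        for name in ("a", "b1", "b2_rel", "b3_rel", "c1", "c2_rel", "c3_rel"):
            assert getattr(fitted, name) == pytest.approx(getattr(truth, name), abs=1e-4)

    def test_constant_series_yields_flat_fit(self):
        truth = example_fit(b1=0.0)
        series = make_series(truth)
        fitted = fit_once(series, truth.window, initial_guesses(series)[0])
        assert fitted.b1 == pytest.approx(0.0, abs=1e-6)
        assert fitted.a == pytest.approx(truth.a, abs=1e-6)

    def test_noisy_steps_recovered(self):
        # planted steps with 5% noise: magnitudes within 15%, times within 0.5 s
        rng = np.random.default_rng(42)
        ok = 0
        n_rep = 20
        for _ in range(n_rep):
            truth = example_fit(
                a=rng.uniform(1, 2), b1=rng.uniform(0.3, 0.6) * rng.choice([-1, 1]),
                c1=rng.uniform(-3, 1), c2_rel=rng.uniform(0.3, 0.5),
                c3_rel=rng.uniform(0.4, 0.6),
            )
            series = make_series(truth, noise_sd=0.05 * truth.a, rng=rng)
            fitted = multistart_fit(series, truth.window)
            mag_ok = np.allclose(
                fitted.step_magnitudes, truth.step_magnitudes, rtol=0.15
            )
            t_fit = step_times(fitted.c1, fitted.c2_rel, fitted.c3_rel, 18.0)
            t_true = step_times(truth.c1, truth.c2_rel, truth.c3_rel, 18.0)
            time_ok = np.max(np.abs(np.subtract(t_fit, t_true))) < 0.5
            ok += mag_ok and time_ok
        assert ok >= 0.9 * n_rep


class TestMultistart:
    def test_finds_late_response_missed_by_single_start(self):
        # a response near the end of the window is found by the grid even when
        # a single central start stalls in a local optimum
        truth = example_fit(c1=8.0, c2_rel=0.6, c3_rel=0.8, b1=0.5)
        series = make_series(truth)
        best = multistart_fit(series, truth.window)
        single = fit_once(series, truth.window, initial_guesses(series)[0])
        assert best.ssr <= single.ssr + 1e-12
        assert best.ssr == pytest.approx(0.0, abs=1e-6)

    def test_returns_argmin_over_grid(self):
        truth = example_fit()
        series = make_series(truth, noise_sd=0.02, rng=np.random.default_rng(1))
        window = truth.window
        best = multistart_fit(series, window)
        for guess in initial_guesses(series):
            fit = fit_once(series, window, guess)
            if fit.success:
                assert best.ssr <= fit.ssr + 1e-9

    def test_deterministic(self):
        truth = example_fit()
        series = make_series(truth, noise_sd=0.05, rng=np.random.default_rng(7))
        f1 = multistart_fit(series)
        f2 = multistart_fit(series)
        assert f1.ssr == f2.ssr
        assert f1.c1 == f2.c1


class TestCategorize:
    def test_all_steps_below_threshold_means_no_response(self):
        fit = example_fit(b1=0.01, b2_rel=1.0, b3_rel=1.0)
        call = categorize(fit, "frequency")
        assert not call.response_present
        assert np.isnan(call.magnitude)

    def test_response_and_recovery_semantics(self):
        # up-down pattern: frequency response at step 1, recovery at step 2
        fit = example_fit(b1=0.4, b2_rel=1.0, b3_rel=0.0)
        call = categorize(fit, "frequency")
        assert call.response_present and call.response_step == 1
        assert call.recovery_present
        assert call.delay == pytest.approx(fit.c1)
        # the same fit read as amplitude: response is the decreasing step 2
        call_a = categorize(fit, "amplitude")
        assert call_a.response_step == 2
        assert not call_a.recovery_present

    def test_category_ids_partition_the_16_classes(self):
        seen = set()
        for b1 in (0.4, -0.4):
            for b2 in (0.0, 1.0):
                for b3 in (0.0, 1.0):
                    for small in (1.0, 0.01):
                        fit = example_fit(b1=b1 * small, b2_rel=b2, b3_rel=b3)
                        seen.add(categorize(fit, "frequency").category_id)
        assert seen <= set(range(1, 17))
        assert len(seen) >= 8

    def test_scale_equivariance(self):
        truth = example_fit()
        series = make_series(truth, noise_sd=0.03, rng=np.random.default_rng(3))
        call1 = categorize(multistart_fit(series), "frequency")
        scaled = dataclasses.replace(series, values=series.values * 7.0)
        call2 = categorize(multistart_fit(scaled), "frequency")
        assert call2.category_id == call1.category_id
        assert call2.response_step == call1.response_step
        assert call2.magnitude == pytest.approx(7.0 * call1.magnitude, rel=1e-3)
        assert call2.delay == pytest.approx(call1.delay, abs=1e-3)

    def test_time_shift_equivariance(self):
        truth = example_fit()
        series = make_series(truth)
        fit1 = multistart_fit(series)
        delta = 1.5
        shifted = dataclasses.replace(series, times=series.times + delta)
        w = window_from_series(shifted)
        fit2 = multistart_fit(shifted, w)
        assert fit2.c1 == pytest.approx(fit1.c1 + delta, abs=0.02)
        assert fit2.c2 == pytest.approx(fit1.c2 + delta, abs=0.05)

    def test_pattern_oracle_agreement(self):
        # planted signed-considerability patterns must be reproduced by the
        # full multistart + categorisation path on noiseless series
        rng = np.random.default_rng(2024)
        n_rep, agree = 200, 0
        for _ in range(n_rep):
            window = FitWindow(-8.0, 16.0, 10.0)
            truth = LogisticFit(
                a=rng.uniform(1, 2.5),
                b1=rng.uniform(0.3, 1.0) * rng.choice([-1, 1]),
                b2_rel=rng.choice([0.0, rng.uniform(0.5, 2.0)]),
                b3_rel=rng.choice([0.0, rng.uniform(0.5, 2.0)]),
                c1=rng.uniform(-4, 2),
                c2_rel=rng.uniform(0.2, 0.6),
                c3_rel=rng.uniform(0.3, 0.7),
                window=window,
            )
            planted = categorize(truth, "frequency")
            series = make_series(truth)
            fitted = multistart_fit(series, window)
            agree += categorize(fitted, "frequency").category_id == planted.category_id
        assert agree >= 0.95 * n_rep
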