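"""Arousal response detection by triple-logistic step fitting.

A sum of three consecutive logistic steps with alternating signs,

.. math::

   f(t) = a + \\frac{b_1}{1+e^{-5(t-c_1)}} - \\frac{b_1 b_{2,rel}}{1+e^{-5(t-c_2)}}
          + \\frac{b_1 b_{3,rel}}{1+e^{-5(t-c_3)}},

is fitted to each smoothed characteristic trace by bounded least squares from
a grid of initial guesses. The step times are reparameterised so that they are
ordered with at least 1-s gaps by construction:

.. math::

   c_2 = c_1 + 1 + c_{2,rel}\\,(t_{max} - c_1 - 3), \\qquad
   c_3 = c_2 + 1 + c_{3,rel}\\,(t_{max} - c_2 - 2),

with :math:`c_{2,rel}, c_{3,rel} \\in [0, 1]` and :math:`t_{max}` the end of
the fit window (time is relative to the EEG arousal start). The logistic
growth rate is fixed at 5, matching the time scale of typical arousal
responses.

Each fitted step is *considerable* when its magnitude exceeds 5% of the mean
fitted value over the window; the signed-considerability pattern of the three
steps (first-step sign x three considerability flags) defines 16 fit classes
from which response presence, magnitude, delay and recovery are read off.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .features import CharacteristicSeries

logger = logging.getLogger(__name__)

GROWTH_RATE = 5.0

#: response direction per characteristic: arousals raise pulse frequency and
#: lower pulse-wave amplitude
RESPONSE_DIRECTION = {"frequency": +1.0, "amplitude": -1.0}


@dataclass(frozen=True)
class FitWindow:
    """Fit range on the arousal-relative time axis."""

    t_min: float
    t_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not self.t_min < 0 < self.t_max:
            raise ValueError("fit window must contain the arousal start (t=0)")


@dataclass(frozen=True)
class FitConfig:
    """Bounds, initial-guess grids and optimizer settings for the step fit."""

    b_rel_max: float = 20.0
    c1_guesses: tuple[float, ...] = (-4.0, -2.0, 0.0, 2.0, 4.0)
    c2_rel_guesses: tuple[float, ...] = (0.25, 0.5, 0.75)
    c3_rel_guesses: tuple[float, ...] = (0.6, 0.8, 0.95)
    considerable_fraction: float = 0.05
    tol: float = 1e-8
    max_nfev: int = 2000
    #: residuals are evaluated on every ``fit_stride``-th trace sample; the
    #: 2-s-smoothed characteristics carry no structure finer than this, so the
    #: subgrid is a pure speed-up. SSR is always reported on the full grid.
    fit_stride: int = 4


DEFAULT_FIT_CONFIG = FitConfig()


def step_times(
    c1: float, c2_rel: float, c3_rel: float, t_max: float
) -> tuple[float, float, float]:
    """Map (c1, c2_rel, c3_rel) to ordered step times (c1, c2, c3)."""
    c2 = c1 + 1.0 + c2_rel * (t_max - c1 - 3.0)
    c3 = c2 + 1.0 + c3_rel * (t_max - c2 - 2.0)
    return c1, c2, c3


def relative_step_times(
    c1: float, c2: float, c3: float, t_max: float
) -> tuple[float, float]:
    """Invert :func:`step_times`: recover (c2_rel, c3_rel) from absolute times."""
    c2_rel = (c2 - c1 - 1.0) / (t_max - c1 - 3.0)
    c3_rel = (c3 - c2 - 1.0) / (t_max - c2 - 2.0)
    return c2_rel, c3_rel


@dataclass
class LogisticFit:
    """A fitted (or analytically specified) triple-logistic model."""

    a: float
    b1: float
    b2_rel: float
    b3_rel: float
    c1: float
    c2_rel: float
    c3_rel: float
    window: FitWindow
    ssr: float = np.nan
    success: bool = True

    @property
    def c2(self) -> float:
        return step_times(self.c1, self.c2_rel, self.c3_rel, self.window.t_max)[1]

    @property
    def c3(self) -> float:
        return step_times(self.c1, self.c2_rel, self.c3_rel, self.window.t_max)[2]

    @property
    def step_magnitudes(self) -> tuple[float, float, float]:
        """Signed step sizes (s1, s2, s3) with the model's alternating signs."""
        return (self.b1, -self.b1 * self.b2_rel, self.b1 * self.b3_rel)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, float)
        _, c2, c3 = step_times(self.c1, self.c2_rel, self.c3_rel, self.window.t_max)
        return (
            self.a
            + self.b1 * expit(GROWTH_RATE * (t - self.c1))
            - self.b1 * self.b2_rel * expit(GROWTH_RATE * (t - c2))
            + self.b1 * self.b3_rel * expit(GROWTH_RATE * (t - c3))
        )

    @classmethod
    def from_absolute(
        cls,
        a: float,
        b1: float,
        b1_b2_rel: float,
        b1_b3_rel: float,
        c1: float,
        c2: float,
        c3: float,
        window: FitWindow,
    ) -> "LogisticFit":
        """Build a fit from absolute step magnitudes and times.

        Convenient for instantiating a model from reported parameter values
        (e.g. the worked examples in the docs) where the step magnitudes are
        given as ``b1 * b_rel`` products and the times as c2, c3.
        """
        c2_rel, c3_rel = relative_step_times(c1, c2, c3, window.t_max)
        return cls(a, b1, b1_b2_rel / b1, b1_b3_rel / b1, c1, c2_rel, c3_rel, window)


@dataclass
class ResponseCall:
    """Outcome of categorizing one fitted characteristic."""

    kind: str  # 'frequency' | 'amplitude'
    category_id: int  # 1..16: signed-considerability pattern of the 3 steps
    response_present: bool
    response_step: int | None = None  # 1..3
    magnitude: float = np.nan  # |level after response step - a|
    delay: float = np.nan  # step time of the response, s from arousal start
    recovery_present: bool = False
    level_before: float = np.nan  # fitted window-start level a
    level_after: float = np.nan  # fitted level after the response step
    ssr: float = np.nan
    considerable: tuple[bool, bool, bool] = field(default=(False, False, False))


def window_from_series(series: CharacteristicSeries) -> FitWindow:
    return FitWindow(
        t_min=float(series.times[0]),
        t_max=float(series.times[-1]),
        y_max=float(np.max(series.values)),
    )


def _model_and_jac(params: np.ndarray, t: np.ndarray, t_max: float):
    a, b1, b2, b3, c1, c2r, c3r = params
    c2 = c1 + 1.0 + c2r * (t_max - c1 - 3.0)
    c3 = c2 + 1.0 + c3r * (t_max - c2 - 2.0)
    L1 = expit(GROWTH_RATE * (t - c1))
    L2 = expit(GROWTH_RATE * (t - c2))
    L3 = expit(GROWTH_RATE * (t - c3))
    f = a + b1 * L1 - b1 * b2 * L2 + b1 * b3 * L3

    dL1 = -GROWTH_RATE * L1 * (1.0 - L1)  # dL/dc
    dL2 = -GROWTH_RATE * L2 * (1.0 - L2)
    dL3 = -GROWTH_RATE * L3 * (1.0 - L3)
    dc2_dc1 = 1.0 - c2r
    dc3_dc2 = 1.0 - c3r
    dc2_dc2r = t_max - c1 - 3.0
    dc3_dc3r = t_max - c2 - 2.0

    jac = np.empty((len(t), 7))
    jac[:, 0] = 1.0
    jac[:, 1] = L1 - b2 * L2 + b3 * L3
    jac[:, 2] = -b1 * L2
    jac[:, 3] = b1 * L3
    jac[:, 4] = (
        b1 * dL1
        - b1 * b2 * dL2 * dc2_dc1
        + b1 * b3 * dL3 * dc3_dc2 * dc2_dc1
    )
    jac[:, 5] = -b1 * b2 * dL2 * dc2_dc2r + b1 * b3 * dL3 * dc3_dc2 * dc2_dc2r
    jac[:, 6] = b1 * b3 * dL3 * dc3_dc3r
    return f, jac


def fit_once(
    series: CharacteristicSeries,
    window: FitWindow,
    guess: Sequence[float],
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> LogisticFit:
    """Bounded least-squares fit of the step model from one initial guess.

    Parameter order: (a, b1, b2_rel, b3_rel, c1, c2_rel, c3_rel). A failed
    optimisation returns a flagged fit with infinite SSR rather than raising.
    """
    stride = max(1, int(config.fit_stride))
    t = series.times[::stride]
    y = series.values[::stride]
    y_max = window.y_max
    lower = np.array([0.0, -y_max, 0.0, 0.0, window.t_min, 0.0, 0.0])
    upper = np.array(
        [y_max, y_max, config.b_rel_max, config.b_rel_max, window.t_max - 3.0, 1.0, 1.0]
    )
    x0 = np.clip(np.asarray(guess, float), lower, upper)

    cache: dict = {}

    def _eval(p: np.ndarray):
        key = p.tobytes()
        if key not in cache:
            cache.clear()  # only the optimizer's current point is ever reused
            cache[key] = _model_and_jac(p, t, window.t_max)
        return cache[key]

    def residuals(p: np.ndarray) -> np.ndarray:
        return _eval(p)[0] - y

    def jacobian(p: np.ndarray) -> np.ndarray:
        return _eval(p)[1]

    try:
        res = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=(lower, upper),
            method="trf",
            ftol=config.tol,
            xtol=config.tol,
            gtol=config.tol,
            max_nfev=config.max_nfev,
        )
    except Exception:  # numerical breakdown for one start is not fatal
        logger.debug("fit_once: optimizer raised", exc_info=True)
        return LogisticFit(*x0, window=window, ssr=np.inf, success=False)
    if not res.success or not np.all(np.isfinite(res.x)):
        return LogisticFit(*res.x, window=window, ssr=np.inf, success=False)
    fit = LogisticFit(*res.x, window=window, success=True)
    fit.ssr = float(np.sum((fit(series.times) - series.values) ** 2))
    return fit


def initial_guesses(
    series: CharacteristicSeries, config: FitConfig = DEFAULT_FIT_CONFIG
) -> list[np.ndarray]:
    """The documented grid of starting points, in tie-break order.

    ``a`` starts at the median value before arousal start, ``b1`` at 0 (no
    directional bias), the relative magnitudes at 1; the step-time guesses span
    the window (``c1`` centred on the arousal start, ``c2_rel`` around halfway,
    ``c3_rel`` at large values to catch very late changes).
    """
    before = series.values[series.times < 0]
    a0 = float(np.median(before)) if len(before) else float(np.median(series.values))
    return [
        np.array([a0, 0.0, 1.0, 1.0, c1, c2r, c3r])
        for c1, c2r, c3r in itertools.product(
            config.c1_guesses, config.c2_rel_guesses, config.c3_rel_guesses
        )
    ]


def multistart_fit(
    series: CharacteristicSeries,
    window: FitWindow | None = None,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> LogisticFit | None:
    """Fit from every grid start and keep the minimum-SSR solution.

    Ties are broken by grid order (first minimal SSR wins). Returns ``None``
    when every start fails; callers discard such arousals from analyses.
    """
    if window is None:
        window = window_from_series(series)
    best: LogisticFit | None = None
    for guess in initial_guesses(series, config):
        fit = fit_once(series, window, guess, config)
        if fit.success and (best is None or fit.ssr < best.ssr):
            best = fit
    if best is None:
        logger.warning("multistart_fit: all %d starts failed", len(initial_guesses(series, config)))
    return best


def categorize(
    fit: LogisticFit,
    kind: str,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> ResponseCall:
    """Classify a fit and extract the response, if any.

    A step is considerable when its magnitude exceeds
    ``considerable_fraction`` (default 5%) of the mean fitted value over the
    window — the threshold is relative, so calls are invariant to rescaling
    the signal. The response is the considerable step in the response
    direction (frequency increase / amplitude decrease) whose post-step level
    is farthest from the window-start level ``a``; its magnitude is
    ``|level_after - a|`` and its delay the step's logistic midpoint. A
    recovery is a considerable step in the opposite direction occurring after
    the response step.
    """
    direction = RESPONSE_DIRECTION[kind]
    w = fit.window
    grid = np.arange(w.t_min, w.t_max, 1.0 / 64.0)
    mean_fitted = float(np.mean(fit(grid)))
    threshold = config.considerable_fraction * abs(mean_fitted)

    steps = np.array(fit.step_magnitudes)
    times = np.array(step_times(fit.c1, fit.c2_rel, fit.c3_rel, w.t_max))
    considerable = np.abs(steps) > threshold
    levels_after = fit.a + np.cumsum(steps)

    # 16 classes: sign of the first step (2) x considerability pattern (8)
    sign_bit = 1 if fit.b1 < 0 else 0
    category_id = 1 + 8 * sign_bit + int(
        4 * considerable[0] + 2 * considerable[1] + considerable[2]
    )

    candidates = [
        k for k in range(3) if considerable[k] and np.sign(steps[k]) == direction
    ]
    if not candidates:
        return ResponseCall(
            kind=kind,
            category_id=category_id,
            response_present=False,
            ssr=fit.ssr,
            level_before=fit.a,
            considerable=tuple(bool(c) for c in considerable),
        )
    k_resp = max(candidates, key=lambda k: abs(levels_after[k] - fit.a))
    recovery = any(
        considerable[j] and np.sign(steps[j]) == -direction for j in range(k_resp + 1, 3)
    )
    return ResponseCall(
        kind=kind,
        category_id=category_id,
        response_present=True,
        response_step=k_resp + 1,
        magnitude=float(abs(levels_after[k_resp] - fit.a)),
        delay=float(times[k_resp]),
        recovery_present=recovery,
        level_before=float(fit.a),
        level_after=float(levels_after[k_resp]),
        ssr=fit.ssr,
        considerable=tuple(bool(c) for c in considerable),
    )


def detect_response(
    series: CharacteristicSeries, config: FitConfig = DEFAULT_FIT_CONFIG
) -> ResponseCall | None:
    """Multistart fit + categorisation for one characteristic trace."""
    fit = multistart_fit(series, config=config)
    if fit is None:
        return None
    return categorize(fit, series.kind, config)


def detect_responses(
    freq_series: CharacteristicSeries,
    amp_series: CharacteristicSeries,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> tuple[ResponseCall | None, ResponseCall | None]:
    """Detect the frequency and amplitude responses of one arousal."""
    return detect_response(freq_series, config), detect_response(amp_series, config)
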