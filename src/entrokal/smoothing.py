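"""Measurement-noise reduction for entropy series.

The entropy value of each window is treated as a noisy scalar measurement
Z_k of a latent "true" complexity X_k that follows a random walk:

    X_k = X_{k-1} + W_{k-1},   W ~ N(0, Q)
    Z_k = X_k + V_k,           V ~ N(0, R)

The scalar Kalman filter for this model is the causal recursion

    prediction:  x^-  = x,          p^- = p + Q
    gain:        K    = p^- / (p^- + R)
    update:      x    = x^- + K (Z_k - x^-),   p = (1 - K) p^-

initialized at the first measurement (x = Z_0, error variance p0).  Two
conventional baselines are provided — a trailing moving average and an
exponentially weighted moving average (EWMA) — and the effect of any
smoother is quantified by the variance reduction rate

    VRR = (V_before - V_after) / V_before * 100%.

Undefined (NaN) entropy windows are skipped by every smoother: the state
is held, the output is NaN there, and those windows are excluded from
both variances in the VRR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .entropy import EntropySeries
from .errors import EmptySeriesError, ParameterError, UndefinedVrrError

__all__ = [
    "KalmanParams",
    "KalmanState",
    "SmoothedSeries",
    "kalman_smooth",
    "steady_state_gain",
    "steady_state_error_variance",
    "moving_average",
    "ewma",
    "vrr",
    "cost_model",
    "smooth_all",
]


@dataclass(frozen=True)
class KalmanParams:
    """Process-noise variance ``q``, measurement-noise variance ``r``,
    initial error variance ``p0``.  The filter state is initialized at the
    first measurement (x0 = Z_0)."""

    q: float = 0.1
    r: float = 0.5
    p0: float = 1.0

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ParameterError(f"Q must be >= 0, got {self.q}")
        if not self.r > 0:
            raise ParameterError(f"R must be > 0, got {self.r}")
        if self.p0 < 0:
            raise ParameterError(f"p0 must be >= 0, got {self.p0}")


@dataclass
class KalmanState:
    """A posteriori estimate, error variance, and last gain of the filter."""

    x_hat: float
    p: float
    k_gain: float = 0.0


@dataclass
class SmoothedSeries:
    """Smoothed entropy series plus the VRR achieved against the raw input."""

    values: np.ndarray
    method: str
    vrr: float = math.nan
    state: KalmanState | None = None


def _as_values(series: EntropySeries | np.ndarray) -> np.ndarray:
    if isinstance(series, EntropySeries):
        return series.values
    return np.asarray(series, dtype=float)


def steady_state_error_variance(q: float, r: float) -> float:
    """Fixed point P* of the a posteriori error-variance recursion."""
    if not r > 0:
        raise ParameterError(f"R must be > 0, got {r}")
    if q < 0:
        raise ParameterError(f"Q must be >= 0, got {q}")
    return (-q + math.sqrt(q * q + 4.0 * q * r)) / 2.0


def steady_state_gain(q: float, r: float) -> float:
    """Limiting Kalman gain K* = (P* + Q) / (P* + Q + R)."""
    p_star = steady_state_error_variance(q, r)
    return (p_star + q) / (p_star + q + r)


def kalman_smooth(
    series: EntropySeries | np.ndarray,
    params: KalmanParams = KalmanParams(),
) -> SmoothedSeries:
    """Single-pass causal Kalman filtering of an entropy series.

    NaN inputs are skipped (state held, output NaN).  The first defined
    value initializes the state without an update step.
    """
    z = _as_values(series)
    defined = np.isfinite(z)
    if not defined.any():
        raise EmptySeriesError("series has no defined values to filter")
    out = np.full(z.size, np.nan)
    state: KalmanState | None = None
    for k in range(z.size):
        if not defined[k]:
            continue
        if state is None:
            state = KalmanState(x_hat=float(z[k]), p=params.p0)
            out[k] = state.x_hat
            continue
        p_pred = state.p + params.q
        gain = p_pred / (p_pred + params.r)
        state.x_hat = state.x_hat + gain * (z[k] - state.x_hat)
        state.p = (1.0 - gain) * p_pred
        state.k_gain = gain
        out[k] = state.x_hat
    result = SmoothedSeries(values=out, method="kalman", state=state)
    result.vrr = _vrr_or_nan(z, out)
    return result


def moving_average(
    series: EntropySeries | np.ndarray,
    w: int = 5,
    centered: bool = False,
) -> SmoothedSeries:
    """Trailing (causal) moving average over the ``w`` most recent defined
    values; during warm-up the available prefix is used.  ``centered``
    switches to a symmetric window of the same width (not used for the
    online monitoring comparisons)."""
    if w < 1:
        raise ParameterError(f"window size must be >= 1, got {w}")
    z = _as_values(series)
    defined = np.isfinite(z)
    out = np.full(z.size, np.nan)
    if centered:
        half = (w - 1) // 2
        for k in np.nonzero(defined)[0]:
            lo, hi = max(0, k - half), min(z.size, k + w - half)
            vals = z[lo:hi]
            out[k] = np.nanmean(vals)
        method = "ma_centered"
    else:
        recent: list[float] = []
        for k in range(z.size):
            if not defined[k]:
                continue
            recent.append(float(z[k]))
            if len(recent) > w:
                recent.pop(0)
            out[k] = sum(recent) / len(recent)
        method = "ma"
    result = SmoothedSeries(values=out, method=method)
    result.vrr = _vrr_or_nan(z, out)
    return result


def ewma(
    series: EntropySeries | np.ndarray,
    alpha: float = 0.5,
) -> SmoothedSeries:
    """Exponentially weighted moving average
    EMA(t) = alpha * x(t) + (1 - alpha) * EMA(t-1), initialized at the
    first defined value.  NaN inputs are skipped with state carry-over."""
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    z = _as_values(series)
    defined = np.isfinite(z)
    out = np.full(z.size, np.nan)
    ema: float | None = None
    for k in range(z.size):
        if not defined[k]:
            continue
        ema = float(z[k]) if ema is None else alpha * float(z[k]) + (1 - alpha) * ema
        out[k] = ema
    result = SmoothedSeries(values=out, method="ewma")
    result.vrr = _vrr_or_nan(z, out)
    return result


def vrr(
    before: EntropySeries | np.ndarray,
    after: SmoothedSeries | np.ndarray,
) -> float:
    """Variance reduction rate (V_before - V_after)/V_before * 100.

    Variances use the n-1 denominator over windows where both series are
    defined.  Raises when the raw variance is zero (VRR undefined).
    """
    b = _as_values(before)
    a = after.values if isinstance(after, SmoothedSeries) else np.asarray(after, float)
    if b.size != a.size:
        raise ParameterError("before/after series lengths differ")
    mask = np.isfinite(b) & np.isfinite(a)
    if mask.sum() < 2:
        raise EmptySeriesError("need at least 2 jointly defined windows for VRR")
    v_before = float(np.var(b[mask], ddof=1))
    v_after = float(np.var(a[mask], ddof=1))
    if v_before == 0:
        raise UndefinedVrrError("raw series has zero variance; VRR undefined")
    return (v_before - v_after) / v_before * 100.0


def _vrr_or_nan(before: np.ndarray, after: np.ndarray) -> float:
    try:
        return vrr(before, after)
    except (UndefinedVrrError, EmptySeriesError):
        return math.nan


def cost_model(method: str, n: int, w: int = 5) -> dict[str, int]:
    """Per-update and total primitive-operation counts of each smoother.

    The unit is one primitive recursion operation: the naive moving
    average touches one sample per element summed (``min(k, w)`` per
    update), the running-sum moving average and the EWMA perform 2
    operations per update, and the Kalman recursion 3 (predict, gain,
    correct).  This abstract count replaces hardware-dependent wall-clock
    comparisons while preserving the observed ordering: total Kalman cost
    3n is below the naive moving average's w*n - w(w-1)/2 for n > w.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if w < 1:
        raise ParameterError(f"w must be >= 1, got {w}")
    if method == "kalman":
        per, total = 3, 3 * n
    elif method == "ewma":
        per, total = 2, 2 * n
    elif method == "ma_naive":
        per = min(n, w)
        total = sum(min(k, w) for k in range(1, n + 1))
    elif method == "ma_running":
        per, total = 2, 2 * n
    else:
        raise ParameterError(f"unknown method {method!r}")
    return {"per_update": per, "total": total}


def smooth_all(
    series: EntropySeries | np.ndarray,
    kalman_params: KalmanParams = KalmanParams(),
    ma_window: int = 5,
    ewma_alpha: float = 0.5,
) -> dict[str, SmoothedSeries]:
    """Apply all three smoothers; returns {"kalman", "ma", "ewma"} results."""
    return {
        "kalman": kalman_smooth(series, kalman_params),
        "ma": moving_average(series, ma_window),
        "ewma": ewma(series, ewma_alpha),
    }
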