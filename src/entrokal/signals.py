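"""Synthetic benchmark signals and the basic signal container.

Three signal families are provided, each with a controllable degree of
irregularity so that downstream entropy smoothing can be validated across
the stochastic/chaotic spectrum:

* power-law ("power") noise with spectrum 1/f^beta — beta=0 white,
  beta=0.5 pink-ish, beta=1 the classic 1/f noise;
* the logistic map x_{i+1} = r x_i (1 - x_i) in its chaotic regimes;
* the x-coordinate of the Rössler system, integrated with fixed-step RK4.

All generators are deterministic given their spec (including seed); there
is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, IntegrationError, ParameterError

__all__ = [
    "SignalRecord",
    "PowerNoiseSpec",
    "LogisticMapSpec",
    "RosslerSpec",
    "generate_power_noise",
    "generate_logistic_map",
    "generate_rossler",
    "rossler_derivative",
    "fit_spectral_slope",
]


@dataclass
class SignalRecord:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    values : ndarray
        The samples, in whatever physical units the source uses
        (dimensionless for the synthetic generators, microvolts for EEG).
    fs : float
        Sampling rate in Hz.
    label : str
        Provenance label, e.g. ``"power(beta=1)"`` or an EEG channel name.
    """

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("SignalRecord expects a 1-d sample vector")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.times, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "SignalRecord":
        df = pd.read_csv(path)
        if not {"t", "value"} <= set(df.columns):
            raise ParameterError(f"{path}: expected columns t,value")
        if len(df) < 2:
            raise EmptySeriesError(f"{path}: need at least 2 samples")
        dt = np.diff(df["t"].to_numpy())
        fs = 1.0 / float(np.median(dt))
        return cls(values=df["value"].to_numpy(), fs=fs, label=label or str(path))


@dataclass(frozen=True)
class PowerNoiseSpec:
    """1/f^beta noise: ``beta`` spectral exponent, ``n`` samples at ``fs`` Hz."""

    beta: float
    n: int = 50_000
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if not self.fs > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")


@dataclass(frozen=True)
class LogisticMapSpec:
    """Logistic-map series: parameter ``r``, ``n`` kept iterates after ``burn_in``."""

    r: float
    n: int = 50_000
    x0: float = 0.5
    burn_in: int = 1_000

    def __post_init__(self) -> None:
        if not 0 < self.r <= 4:
            raise ParameterError(f"r must be in (0, 4], got {self.r}")
        if not 0 < self.x0 < 1:
            raise ParameterError(f"x0 must be in (0, 1), got {self.x0}")
        if self.n < 1 or self.burn_in < 0:
            raise ParameterError("n must be >= 1 and burn_in >= 0")


@dataclass(frozen=True)
class RosslerSpec:
    """Rössler system; the output is the x-coordinate only.

    ``transient`` leading samples are discarded; one sample is kept every
    ``sample_every`` RK4 steps of size ``dt``.
    """

    a: float = 0.38
    b: float = 0.2
    c: float = 5.7
    dt: float = 0.05
    sample_every: int = 1
    n: int = 50_000
    transient: int = 5_000
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.transient < 0 or self.n < 1 or self.sample_every < 1:
            raise ParameterError("transient >= 0, n >= 1, sample_every >= 1 required")


def generate_power_noise(spec: PowerNoiseSpec) -> SignalRecord:
    """Synthesize 1/f^beta noise in the frequency domain.

    Fourier amplitudes are set to f^(-beta/2), phases drawn i.i.d. uniform,
    Hermitian symmetry enforced by the real inverse FFT, and the result is
    standardized to zero mean and unit variance.  The DC component is zero.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(spec.n, d=1.0 / spec.fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spec.beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if spec.n % 2 == 0:
        # Nyquist bin must be real for a real-valued signal.
        spectrum[-1] = amp[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spectrum, n=spec.n)
    x = (x - x.mean()) / x.std()
    return SignalRecord(values=x, fs=spec.fs, label=f"power(beta={spec.beta:g})")


def generate_logistic_map(spec: LogisticMapSpec) -> SignalRecord:
    """Iterate x_{i+1} = r x_i (1 - x_i), discarding ``burn_in`` leading iterates.

    The sampling rate is nominal (one iterate per "sample"); 100 Hz is used
    so that the windowing convention L = 5 fs matches the noise generators.
    """
    x = spec.x0
    r = spec.r
    for _ in range(spec.burn_in):
        x = r * x * (1.0 - x)
    out = np.empty(spec.n)
    for i in range(spec.n):
        x = r * x * (1.0 - x)
        out[i] = x
    return SignalRecord(values=out, fs=100.0, label=f"logistic(r={spec.r:g})")


def rossler_derivative(
    state: Sequence[float], a: float, b: float, c: float
) -> tuple[float, float, float]:
    """Vector field of the Rössler system at ``state`` = (x, y, z)."""
    x, y, z = state
    return (-y - z, x + a * y, b + z * (x - c))


def generate_rossler(spec: RosslerSpec) -> SignalRecord:
    """Integrate the Rössler system with fixed-step classical RK4.

    Output sampling rate is 1/(dt * sample_every) in the system's own time
    units (treated as seconds downstream).
    """
    a, b, c, dt = spec.a, spec.b, spec.c, spec.dt
    x, y, z = map(float, spec.initial_state)
    n_steps = (spec.transient + spec.n) * spec.sample_every
    out = np.empty(spec.n)
    kept = 0
    half = dt / 2.0
    sixth = dt / 6.0
    for step in range(1, n_steps + 1):
        k1x, k1y, k1z = (-y - z, x + a * y, b + z * (x - c))
        x1, y1, z1 = x + half * k1x, y + half * k1y, z + half * k1z
        k2x, k2y, k2z = (-y1 - z1, x1 + a * y1, b + z1 * (x1 - c))
        x2, y2, z2 = x + half * k2x, y + half * k2y, z + half * k2z
        k3x, k3y, k3z = (-y2 - z2, x2 + a * y2, b + z2 * (x2 - c))
        x3, y3, z3 = x + dt * k3x, y + dt * k3y, z + dt * k3z
        k4x, k4y, k4z = (-y3 - z3, x3 + a * y3, b + z3 * (x3 - c))
        x += sixth * (k1x + 2 * k2x + 2 * k3x + k4x)
        y += sixth * (k1y + 2 * k2y + 2 * k3y + k4y)
        z += sixth * (k1z + 2 * k2z + 2 * k3z + k4z)
        if step % spec.sample_every == 0:
            sample_idx = step // spec.sample_every - 1
            if sample_idx >= spec.transient:
                out[kept] = x
                kept += 1
                if kept == spec.n:
                    break
    if kept < spec.n:
        raise IntegrationError("integration ended before producing n samples")
    if not np.all(np.isfinite(out)) or not np.isfinite(x + y + z):
        raise IntegrationError("Rössler trajectory diverged (non-finite state)")
    fs = 1.0 / (dt * spec.sample_every)
    return SignalRecord(values=out, fs=fs, label=f"rossler(c={spec.c:g})")


def fit_spectral_slope(
    record: SignalRecord,
    fmin: float = 1.0,
    fmax: float = 40.0,
    nperseg: int = 4096,
) -> float:
    """Least-squares slope of the log-log Welch periodogram over [fmin, fmax].

    For 1/f^beta noise the expected slope is -beta.
    """
    from scipy.signal import welch

    f, pxx = welch(record.values, fs=record.fs, nperseg=min(nperseg, record.n))
    keep = (f >= fmin) & (f <= fmax) & (pxx > 0)
    if keep.sum() < 2:
        raise ParameterError("fewer than 2 periodogram bins in [fmin, fmax]")
    slope = np.polyfit(np.log(f[keep]), np.log(pxx[keep]), 1)[0]
    return float(slope)
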