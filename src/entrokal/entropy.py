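"""Windowed entropy measurement: sample entropy, approximate entropy, and
the analytic variance of the sample-entropy conditional probability.

Sample entropy (SampEn) of a window u(1..N) with embedding dimension m and
tolerance r is

    SampEn(m, r, N) = -ln(A / B) = -ln CP,

where B counts pairs of m-point templates within Chebyshev distance r of
each other (self-matches excluded, strict inequality d < r), and A counts
the same pairs extended to m+1 points.  Both counts run over the template
start indices i = 1..N-m (the Richman–Moorman convention), so every
m-template that enters B has an (m+1)-point extension and A <= B always
holds.  CP = A/B is the conditional probability that sequences matching
for m points still match at the next point.

Because template pairs that share time indices are statistically
dependent, the variance of the CP estimate is not simply binomial.  The
correction of Lake et al. uses the overlap counts K_A and K_B — the
number of unordered pairs of distinct matching (m+1)- and m-template
pairs whose index ranges share at least one time index:

    var(CP) = CP (1 - CP) / B + [K_A - K_B CP^2] / B^2

The delta method then gives var(SampEn) ~= var(CP) / CP^2.

Approximate entropy (ApEn) follows Pincus: self-matches are included, so
the per-template match frequency is never zero and the log never blows up;
the price is a systematic downward bias relative to SampEn on short
windows.

Tolerance convention: r = c * sigma, with sigma the sample standard
deviation (n-1 denominator) of the window itself, recomputed per window.
A zero-variance window makes r = 0 and the entropy undefined; undefined
windows are flagged as NaN, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, ParameterError, WindowTooShortError
from .signals import SignalRecord

__all__ = [
    "EntropyParams",
    "TemplateMatchCounts",
    "SampEnResult",
    "EntropySeries",
    "template_match_counts",
    "sample_entropy",
    "approximate_entropy",
    "cp_variance",
    "sampen_variance",
    "windowed_entropy_series",
]

#: pair-of-pairs overlap testing is chunked to bound peak memory
_OVERLAP_CHUNK = 8192


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension ``m``, tolerance coefficient ``c`` (r = c*sigma),
    window length ``L`` in samples.  ``L=None`` means "derive as 5*fs" at the
    point of use (five seconds of signal per entropy measurement)."""

    m: int = 2
    c: float = 0.15
    L: int | None = 500

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")
        if not self.c > 0:
            raise ParameterError(f"c must be > 0, got {self.c}")
        if self.L is not None and self.L <= self.m + 1:
            raise ParameterError(f"L must exceed m+1, got L={self.L}, m={self.m}")

    def window_length(self, fs: float) -> int:
        L = self.L if self.L is not None else int(round(5 * fs))
        if L <= self.m + 1:
            raise ParameterError(f"derived window length {L} <= m+1")
        return L


@dataclass(frozen=True)
class TemplateMatchCounts:
    """Raw match statistics of one window.

    b_count / a_count: matching m- / (m+1)-template pairs (i<j);
    k_b / k_a: unordered pairs of distinct matching pairs that overlap
    in time (share at least one sample index).
    """

    b_count: int
    a_count: int
    k_b: int = 0
    k_a: int = 0

    def __post_init__(self) -> None:
        if min(self.b_count, self.a_count, self.k_b, self.k_a) < 0:
            raise ParameterError("counts must be non-negative")
        if self.a_count > self.b_count:
            raise ParameterError("A cannot exceed B under the shared-range convention")

    @property
    def cp(self) -> float:
        """Conditional probability A/B; NaN when B = 0."""
        return self.a_count / self.b_count if self.b_count > 0 else math.nan


@dataclass(frozen=True)
class SampEnResult:
    """Sample entropy of one window, with its ingredients."""

    value: float  # -ln CP, NaN when undefined
    cp: float
    r: float  # tolerance actually used, in signal units
    counts: TemplateMatchCounts | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


def _template_match_matrix(close: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    """Boolean matrix M[i, j] = templates of length m starting at i and j match.

    ``close`` is the pairwise |u_i - u_j| < r matrix of the raw samples.
    """
    M = close[:n_templates, :n_templates].copy()
    for a in range(1, m):
        M &= close[a : a + n_templates, a : a + n_templates]
    return M


def _overlapping_pair_count(match: np.ndarray, template_len: int) -> int:
    """Count unordered pairs of distinct matching template pairs that overlap.

    A matching pair (i, j) covers samples [i, i+len-1] and [j, j+len-1]; two
    pairs overlap when any of the four interval combinations intersect,
    i.e. the start indices differ by less than the template length.
    """
    ii, jj = np.nonzero(np.triu(match, k=1))
    n_pairs = ii.size
    if n_pairs < 2:
        return 0
    total = 0
    order = np.arange(n_pairs)
    for start in range(0, n_pairs, _OVERLAP_CHUNK):
        sl = slice(start, min(start + _OVERLAP_CHUNK, n_pairs))
        i1 = ii[sl][:, None]
        j1 = jj[sl][:, None]
        near = (
            (np.abs(i1 - ii[None, :]) < template_len)
            | (np.abs(i1 - jj[None, :]) < template_len)
            | (np.abs(j1 - ii[None, :]) < template_len)
            | (np.abs(j1 - jj[None, :]) < template_len)
        )
        # keep q > p so each unordered pair-of-pairs is counted once
        total += int((near & (order[None, :] > order[sl][:, None])).sum())
    return total


def template_match_counts(
    window: np.ndarray,
    m: int,
    r: float,
    count_overlaps: bool = True,
) -> TemplateMatchCounts:
    """Chebyshev template matching of one window at absolute tolerance ``r``.

    Self-matches are excluded and matches use the strict inequality d < r.
    Both the m- and (m+1)-template counts run over start indices
    i = 1..N-m.  With ``count_overlaps`` the K_A/K_B statistics needed by
    :func:`cp_variance` are included (quadratic in the number of matching
    pairs; skip it when only SampEn is needed).
    """
    u = np.asarray(window, dtype=float)
    N = u.size
    if N <= m + 1:
        raise WindowTooShortError(f"window of {N} samples too short for m={m}")
    if not r > 0:
        raise ParameterError(f"tolerance r must be > 0, got {r}")
    close = np.abs(u[:, None] - u[None, :]) < r
    n_templates = N - m
    match_m = _template_match_matrix(close, m, n_templates)
    match_m1 = match_m & close[m : m + n_templates, m : m + n_templates]
    iu = np.triu_indices(n_templates, k=1)
    b_count = int(match_m[iu].sum())
    a_count = int(match_m1[iu].sum())
    k_b = k_a = 0
    if count_overlaps:
        k_b = _overlapping_pair_count(match_m, m)
        k_a = _overlapping_pair_count(match_m1, m + 1)
    return TemplateMatchCounts(b_count=b_count, a_count=a_count, k_b=k_b, k_a=k_a)


def _resolve_tolerance(u: np.ndarray, r: float | None, c: float) -> float:
    if r is not None:
        return float(r)
    return float(c * u.std(ddof=1))


def sample_entropy(
    window: np.ndarray,
    m: int = 2,
    r: float | None = None,
    c: float = 0.15,
    count_overlaps: bool = False,
) -> SampEnResult:
    """Sample entropy -ln(A/B) of one window.

    Tolerance is ``r`` if given (absolute, signal units), else c * sigma of
    the window.  Degenerate windows (sigma = 0, B = 0, or A = 0) yield an
    undefined result (NaN value) rather than raising.
    """
    u = np.asarray(window, dtype=float)
    if u.size <= m + 1:
        raise WindowTooShortError(f"window of {u.size} samples too short for m={m}")
    tol = _resolve_tolerance(u, r, c)
    if tol <= 0:  # constant window
        return SampEnResult(value=math.nan, cp=math.nan, r=tol, counts=None)
    counts = template_match_counts(u, m, tol, count_overlaps=count_overlaps)
    if counts.b_count == 0 or counts.a_count == 0:
        return SampEnResult(value=math.nan, cp=counts.cp, r=tol, counts=counts)
    cp = counts.cp
    return SampEnResult(value=-math.log(cp), cp=cp, r=tol, counts=counts)


def approximate_entropy(
    window: np.ndarray,
    m: int = 2,
    r: float | None = None,
    c: float = 0.15,
) -> float:
    """Approximate entropy Phi^m(r) - Phi^{m+1}(r) of one window.

    Self-matches are included, so every per-template frequency is at least
    1/(N-m+1) and the logarithms are always finite.  Returns NaN for a
    zero-variance window (tolerance collapses to 0).
    """
    u = np.asarray(window, dtype=float)
    N = u.size
    if N <= m + 1:
        raise WindowTooShortError(f"window of {N} samples too short for m={m}")
    tol = _resolve_tolerance(u, r, c)
    if tol <= 0:
        return math.nan
    close = np.abs(u[:, None] - u[None, :]) < tol

    def phi(k: int) -> float:
        n_t = N - k + 1
        M = _template_match_matrix(close, k, n_t)
        freq = M.sum(axis=1) / n_t  # includes the self-match on the diagonal
        return float(np.mean(np.log(freq)))

    return phi(m) - phi(m + 1)


def cp_variance(counts: TemplateMatchCounts) -> float:
    """Analytic variance of CP = A/B from the match/overlap counts.

    Binomial term CP(1-CP)/B plus the overlap correction
    [K_A - K_B CP^2]/B^2 for dependence between template pairs that share
    samples.  NaN when B = 0.
    """
    if counts.b_count == 0:
        return math.nan
    cp = counts.cp
    b = counts.b_count
    return cp * (1.0 - cp) / b + (counts.k_a - counts.k_b * cp**2) / b**2


def sampen_variance(counts: TemplateMatchCounts) -> float:
    """Delta-method variance of SampEn = -ln CP: var(CP)/CP^2.

    NaN when CP is 0 or undefined.
    """
    cp = counts.cp
    if not math.isfinite(cp) or cp == 0:
        return math.nan
    return cp_variance(counts) / cp**2


@dataclass
class EntropySeries:
    """Per-window entropy measurements Z_k of one signal.

    ``values`` holds one entropy value per non-overlapping window (NaN for
    undefined windows); ``variances`` the per-window analytic CP variance
    (NaN where unavailable).  ``t_start`` gives each window's start time in
    seconds.
    """

    values: np.ndarray
    window_length: int
    params: EntropyParams
    measure: str = "sampen"
    fs: float = 1.0
    cp: np.ndarray | None = None
    variances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.values.size

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of windows with a finite entropy value."""
        return np.isfinite(self.values)

    @property
    def t_start(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_length / self.fs

    def to_frame(self) -> pd.DataFrame:
        nan = np.full(self.n_windows, np.nan)
        return pd.DataFrame(
            {
                "window_index": np.arange(self.n_windows),
                "t_start": self.t_start,
                "entropy": self.values,
                "cp": self.cp if self.cp is not None else nan,
                "cp_variance": self.variances if self.variances is not None else nan,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def windowed_entropy_series(
    signal: SignalRecord,
    params: EntropyParams = EntropyParams(),
    measure: str = "sampen",
    with_variance: bool = False,
) -> EntropySeries:
    """Entropy over non-overlapping windows of ``signal``.

    floor(N/L) windows are used and the leftover tail is discarded; the
    tolerance r = c*sigma is recomputed from each window's own standard
    deviation.  For ``measure="sampen"`` with ``with_variance`` the
    analytic CP variance is attached per window (this is quadratic in the
    number of matching template pairs and can dominate runtime on highly
    regular signals — leave it off when only the entropy series is needed).
    """
    if measure not in ("sampen", "apen"):
        raise ParameterError(f"measure must be 'sampen' or 'apen', got {measure!r}")
    L = params.window_length(signal.fs)
    n_windows = signal.n // L
    if n_windows < 1:
        raise EmptySeriesError(f"signal of {signal.n} samples shorter than one window ({L})")
    values = np.full(n_windows, np.nan)
    cps = np.full(n_windows, np.nan)
    variances = np.full(n_windows, np.nan)
    for k in range(n_windows):
        win = signal.values[k * L : (k + 1) * L]
        if measure == "apen":
            values[k] = approximate_entropy(win, m=params.m, c=params.c)
            continue
        res = sample_entropy(win, m=params.m, c=params.c, count_overlaps=with_variance)
        values[k] = res.value
        cps[k] = res.cp
        if with_variance and res.counts is not None:
            variances[k] = cp_variance(res.counts)
    return EntropySeries(
        values=values,
        window_length=L,
        params=params,
        measure=measure,
        fs=signal.fs,
        cp=cps if measure == "sampen" else None,
        variances=variances if (measure == "sampen" and with_variance) else None,
    )
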