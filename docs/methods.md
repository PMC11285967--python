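# Methods

## Entropy as a noisy measurement

The package's organizing idea is that a windowed entropy estimate is a
measurement in the instrumental sense: an estimator applied to a finite
sample, carrying estimation variance that behaves like sensor noise.
The latent quantity — the signal's "true" complexity over the window — is
assumed to evolve slowly relative to the window spacing, which motivates
the random-walk-plus-noise state-space model

    X_k = X_{k−1} + W_{k−1},  W ~ N(0, Q)
    Z_k = X_k + V_k,          V ~ N(0, R)

with identity transition and observation maps. This is the standard
local-level model; its optimal causal estimator is the scalar Kalman
filter, whose gain converges geometrically to

    K* = (P* + Q)/(P* + Q + R),  P* = (−Q + √(Q² + 4QR))/2.

At the defaults Q = 0.1, R = 0.5 this gives K* ≈ 0.3583: the steady-state
filter behaves like an EWMA with weight 0.358 on the newest measurement.
For a constant state in i.i.d. noise the output variance is
K*/(2−K*) of the input, i.e. an asymptotic VRR of ≈ 78.2% — the
theoretical ceiling visible in the white-noise studies.

## Sample entropy and its analytic variance

SampEn uses the Richman–Moorman convention throughout: both the m- and
(m+1)-template counts run over start indices 1..N−m, so A ≤ B, CP = A/B
is well defined and SampEn = −ln CP ≥ 0 whenever defined. Matches use
strict Chebyshev distance d < r with self-matches excluded. The
tolerance is recomputed per window as r = c·σ (σ with the n−1
denominator), which makes the measure invariant under amplitude scaling
of the window — each window is an independent measurement with its own
gauge.

The variance of CP is not binomial because template pairs that share
samples are dependent. The implemented correction is

    var(CP) = CP(1−CP)/B + [K_A − K_B·CP²]/B²

where K_A (K_B) counts *unordered pairs of distinct matching
(m+1)- (m-) template pairs whose index ranges share at least one sample*.
This overlap definition is deliberately concrete — it is enforced against
a brute-force set-intersection enumerator in the tests — because prose
definitions of "overlapping pairs" are ambiguous. On 1,000 i.i.d.
Gaussian windows of 500 samples the median analytic estimate sits within
a factor of two of the empirical variance of CP (the test asserts the
full factor-two band; the observed ratio is ≈ 1.5, i.e. mildly
conservative). The delta-method SampEn-scale variance var(CP)/CP² is
exposed separately (`sampen_variance`) since figures in the literature
plot either scale.

Overlap counting is quadratic in the number of matching pairs, which is
large for highly regular signals (Rössler, logistic near periodic
windows). It is therefore optional (`with_variance`), off in the
large simulation studies where only the VRR is needed, and chunked to
bound memory when on.

Approximate entropy includes self-matches (Pincus), so its template
frequencies are bounded below by 1/(N−m+1) and its logarithms are always
finite; the known consequence, a downward bias relative to SampEn on
i.i.d. data, is asserted as a property test rather than treated as an
error.

Undefined windows — zero variance (r = 0), B = 0, or A = 0 — are flagged
NaN. All smoothers skip NaN inputs with state carry-over, and VRR
excludes them from both variances. Imputation is never performed.

## Smoother baselines and the EWMA weight

The moving average is trailing (causal) with window 5, matching online
monitoring; during warm-up the available prefix is averaged. A centered
variant exists behind a flag but is not used in any study.

The EWMA weight default is α = 0.5. This was a genuinely open choice and
the reasoning is frequency-domain: an EWMA with weight α has squared
gain α²/(1 + (1−α)² − 2(1−α)cos ω), monotone in α at every frequency. Any
α below the Kalman steady-state gain K* ≈ 0.358 therefore attenuates
*every* frequency more than the Kalman filter and would mechanically beat
it on VRR regardless of the signal — contradicting the well-replicated
observation that the Kalman filter attains the highest VRR on real EEG.
A reasonable baseline must smooth *less* than the filter under test;
α = 0.5 (the midpoint of the conventional (0,1) range, effective memory
≈ 3 windows) does so at all frequencies. With it, the expected ordering
KF > MA(5) > EWMA on drifting complexity reproduces robustly.

## Synthetic families and study conditions

* **Power noise**: frequency-domain synthesis — amplitudes ∝ f^(−β/2),
  i.i.d. uniform phases, Hermitian symmetry via the real inverse FFT,
  then standardization to zero mean/unit variance. The periodogram slope
  is −β by construction (tested on the synthesis rule directly and on
  Welch estimates of the output).
* **Logistic map**: x_{i+1} = r·x_i(1−x_i), burn-in 1,000 iterates,
  x₀ ~ U(0.1, 0.9) per seed in studies.
* **Rössler**: classical fixed-step RK4, dt = 0.05, transient 5,000
  samples, base state (1,1,1) perturbed by U(−0.5, 0.5) per coordinate
  across study replicates. Step-halving confirms 4th-order convergence;
  dt = 0.05 agrees with a dt = 0.005 reference to < 10⁻³ over 10 time
  units, ample for entropy at tolerance 0.15σ.

Studies use series of 50,000 samples at a nominal 100 Hz with L = 5·fs =
500-sample windows (100 entropy measurements per series) and average VRR
across 20 independent realizations, reporting mean ± sd; single-draw VRRs
scatter by several percentage points, so seed-averaged means are the
meaningful summary. Hyperparameter sweeps (c × m, R at fixed Q, Q at
fixed R) replicate each grid point across ≥ 10 series of stationary white
noise and report standard errors.

The **drift study** stands in for slowly evolving clinical EEG, which
cannot ship with the package: a 4 Hz sine carrier mixed with white noise,
mixing fraction λ_t = 0.35 + 0.25·sin(·) sweeping three slow cycles per
record. Windowed SampEn then drifts over ≈ 0.8 nats between regular and
irregular regimes, putting the drift variance on the same order as the
measurement noise — the regime where the smoothers genuinely differ and
VRRs (≈ 50–70%) fall between the pure-noise ceiling and published sleep
values. What passing this study shows is the *ordering* of smoothers
under drifting complexity; it does not certify absolute VRR values on
real recordings, whose nonstationarity (artifacts, stage transitions,
seizures) is richer than a smooth sinusoidal drift.

## EDF handling

Reading delegates to mne (`read_raw_edf`); samples are returned in
microvolts at the header rate, and segment bounds are half-open seconds
([t_start, t_stop), index = floor(t·fs)) so adjacent segments never share
a sample. Writing is a minimal EDF encoder used only to build synthetic
fixtures: one-second records, symmetric 16-bit digital range, physical
bounds formatted into the 8-character header fields and *those formatted
values* used as the encoding scale, so the worst-case round-trip error is
half a digital step. Annotations (hypnograms, seizure marks) are not
parsed; segments are user-specified.

## Computational cost model

Wall-clock smoother comparisons are hardware-dependent, so the package
exposes an abstract per-update operation count instead: the naive
trailing mean touches one sample per element summed (w per update after
warm-up), the running-sum mean and the EWMA perform 2 primitive
operations per update, the Kalman recursion 3 (predict, gain, correct).
Totals then satisfy kalman(n) = 3n < w·n − w(w−1)/2 = ma_naive(n, 5) for
every n > 5, preserving the qualitative ordering (Kalman cheapest against
a naive moving average) without timing anything.

## Known limitations

* VRR rewards aggressive smoothing as such; it does not measure fidelity
  to the latent state. A filter that over-smooths a fast transient can
  post a high VRR while lagging the event. Q/R remain fixed; adaptive
  noise estimation is out of scope.
* The analytic CP variance assumes the window is internally stationary;
  windows straddling regime boundaries violate this.
* The logistic and Rössler series are deterministic; their "measurement
  noise" is estimation variance only, which is why their VRR spread
  across initial conditions is wide (notably Rössler c = 2.5, where the
  near-periodic attractor leaves very little raw variance to reduce).
* EDF support covers EDF proper; EDF+ annotation semantics are ignored.
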