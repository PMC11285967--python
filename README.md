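# entrokal

Entropy of a physiological signal — sample entropy of EEG, most commonly —
is almost always computed over a sliding window and read as a time series:
complexity during anaesthesia, across sleep stages, around seizures. Each
windowed value is, however, a *statistical estimate* with substantial
estimation variance, so the entropy trace is noisy even when the underlying
dynamics barely change. `entrokal` treats each windowed entropy value
`Z_k` as a noisy physical measurement of a latent complexity state `X_k`
and denoises the trace online with a scalar Kalman filter, for anyone who
needs a stable continuous entropy readout (neuromonitoring, sleep and
epilepsy research, benchmark studies of entropy estimators).

## The model

Sample entropy of a window `u(1..N)` with embedding dimension `m` and
tolerance `r = c·σ` (σ = the window's own standard deviation):

    SampEn(m, r, N) = −ln(A / B) = −ln CP

where `B` counts pairs of `m`-point templates within Chebyshev distance
`r` (self-matches excluded, strict `d < r`) and `A` the same pairs still
matching at length `m+1`. The estimation variance of the conditional
probability `CP = A/B` is computed analytically, including the correction
for overlapping (statistically dependent) template pairs:

    var(CP) = CP(1−CP)/B + [K_A − K_B·CP²]/B²

with `K_A`, `K_B` the numbers of overlapping pairs of matching templates.
Approximate entropy (Pincus convention, self-matches included) is provided
as a second measure.

The latent complexity is modelled as a random walk observed in noise,

    X_k = X_{k−1} + W_{k−1},  W ~ N(0, Q)
    Z_k = X_k + V_k,          V ~ N(0, R)

filtered by the scalar Kalman recursion (defaults Q = 0.1, R = 0.5,
initialized at the first measurement). Trailing moving-average and EWMA
smoothers serve as baselines, and every smoother is scored by the
variance reduction rate

    VRR = (V_before − V_after) / V_before × 100%.

Three synthetic signal families with known character validate the chain:
1/f^β power noise (β = 0, 0.5, 1), the logistic map
`x_{i+1} = r·x_i(1−x_i)` (r = 3.57, 3.77, 3.9), and the Rössler system
(a = 0.38, b = 0.2, c = 2.5, 4, 5.7; RK4 integration). Real recordings are
read from EDF (European Data Format) files by channel label, with the
window length derived as 5× the sampling rate (500 samples at 100 Hz,
1280 at 256 Hz).

## Worked example

```sh
$ entrokal simulate --family power --param 1 --n 50000 --seed 7 --out pink.csv
wrote 50000 samples (power(beta=1)) to pink.csv

$ entrokal entropy --in pink.csv --window 500 --out pink_entropy.csv
100 windows of 500 samples -> pink_entropy.csv

$ entrokal smooth --in pink_entropy.csv --out pink_smoothed.csv
VRR kalman: 72.91%
VRR ma: 74.62%
VRR ewma: 62.00%
```

The entropy CSV holds one row per 5-second window — here SampEn wanders
around 1.9–2.3 nats purely through estimation noise (1/f noise has no
regime changes at this scale):

```
window_index,t_start,entropy,cp,cp_variance
0,0.0,1.8869232468653663,0.15153733528550511,
1,4.9999999999954525,1.9824995964876053,0.1377245508982036,
```

The smoothing summary says the Kalman filter removed 72.91% of the
entropy trace's variance on this single realization; the 5-point moving
average removes a comparable amount on stationary input (it averages
slightly harder), while on *drifting* complexity — the realistic
monitoring case — the Kalman filter gives the highest VRR of the three
(see the drift study in `entrokal.pipeline.run_drift_study`).

The same analysis for an EEG channel in an EDF file:

```sh
entrokal analyze --edf night1.edf --channel "EEG Fpz-Cz" --start 0 --stop 3600 --out-dir out/
```

which writes the per-window table (raw entropy, analytic variance, all
three smoothed traces) and a VRR summary JSON.

Library use mirrors the CLI: `generate_power_noise`,
`windowed_entropy_series`, `kalman_smooth`, `vrr`, `run_simulation_study`
and friends are all importable from `entrokal`.

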