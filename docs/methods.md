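# Methods

## Scope and model

`dyadsync` implements an idiographic (single-dyad) analysis of second-by-second
parent–child physiological synchrony in respiratory sinus arrhythmia (RSA).
Each dyad-task contributes two aligned per-second RSA series, and the
scientific question is directional: does a fluctuation in one partner's RSA at
second *t−1* predict the other partner's RSA at second *t*, over and above
that partner's own stability?

The model per dyad-task is a latent-mean bivariate lag-1 process. With
`y_t = (parent_t, child_t)` in ln ms²,

```
y_t − μ = Φ (y_{t−1} − μ) + e_t,    e_t ~ N(0, Σ)

Φ = [ φ_p   β_c→p ]
    [ β_p→c  φ_c  ]
```

`β_p→c` is parent-driven synchrony (parent's deviation predicting the child's
next-second deviation) and `β_c→p` is child-driven synchrony. A positive
cross-lag is in-phase (same-direction) coupling, a negative one anti-phase.
The means are parameters of the likelihood ("latent mean centring") rather
than sample averages subtracted beforehand; this keeps the cross-lags defined
on within-person deviations from an *estimated* trait level and avoids the
bias that plug-in centring introduces at T ≈ 300.

## RSA estimation

RSA is the natural log of IBI spectral power (ms²) in the respiration band —
0.12–0.40 Hz for adults; for children a configurable age-keyed table, default
0.15–0.66 Hz for ages 6–11 (a package default, not a literature-fixed value;
override `child_bands` when the study dictates otherwise).

Stages, with the constants that matter:

1. **Beats → IBI.** Differences of R-peak times, ms.
2. **Artifact rules.** An interval *needs correction* if outside 300–1500 ms
   or if it jumps more than 25% from the preceding accepted interval (both
   configurable; they stand in for manual editing and are deliberately
   conservative). A run of flagged intervals is measured in *implied beats* —
   a 12 s gap amid 800 ms beats is worth ~14 beats even though it is a single
   interval. Runs worth 1–2 beats are repaired by linear interpolation; runs
   worth ≥ 3 beats become missing segments spanning the affected time range.
3. **4 Hz resampling.** Cubic spline of (time, IBI) onto a half-open uniform
   grid, sample k at k/4 s. Missing segments of duration ≥ 10 s (boundary
   inclusive) are masked; shorter gaps are bridged by the spline and stay
   valid. Samples more than 2 s outside the observed beat span are masked as
   unsupported extrapolation.
4. **Sliding multitaper STFT.** 32-s windows (128 samples) advancing 1 s;
   each window is mean-detrended (no first-differencing), tapered, and the
   eigenspectra averaged; one-sided PSD integrated over the band is the band
   power assigned to the window's central second. Estimates exist for integer
   seconds in [16, duration − 16].
5. **Log transform.** `ln(max(power, floor))`, floor 1e−6 ms².

**Window/validity convention.** Power is computed from the 128 samples in
[t−16, t+16); validity additionally requires the sample at exactly t+16 when
it exists. Under this convention a masked segment [a, b) invalidates output
seconds exactly on [a−16, b+16) — e.g. masking [100, 110) s invalidates
[84, 126) s — which is the "16 s before until 16 s after" propagation rule.

**Tapers.** The default family is DPSS with time-bandwidth NW = 2 over the
32-s window (half-bandwidth 0.0625 Hz, i.e. resolution on the order of the
window's 1/32 Hz Rayleigh limit) and K = 3 tapers. A peak-matched family is
also provided: the leading eigenvectors of the Toeplitz covariance implied by
a locally peaked target spectrum (30 dB decay across the half-bandwidth),
which is the appropriate choice when the band contains a sharp respiratory
peak. Both banks are orthonormal by construction; the acceptance property is
recovery of known band power, not equality with any particular toolbox, and
the bank is pluggable.

## Stationarity screen

Augmented Dickey-Fuller at lag 1 in two deterministic specifications (single
mean; linear trend), run on the longest contiguous valid stretch of each
series (the regression needs contiguity; ≥ 20 observations required). A
series "meets stationarity" when the unit root is rejected at α = 0.05 in at
least one specification — the lenient disjunctive reading, since a single
per-dyad verdict from two models is reported. The screen is advisory: flagged
dyads are retained, and mild violations are instead handled by the sampler's
admissibility safeguard (below).

## Estimation

Blocked Gibbs sampler with conditionally conjugate, effectively uninformative
priors: N(0, 1e6) on each mean and dynamic coefficient, inverse-Wishart
(identity scale, 3 df) on Σ. Blocks: coefficient matrix given means and Σ
(matrix-normal full conditional), means given dynamics (normal), Σ given the
rest (inverse-Wishart), and missing seconds by data augmentation (normal full
conditionals from the two adjacent transitions; a missing initial second uses
a N(μ, Σ) prior term). The first observation is conditioned on (conditional
likelihood), standard for lag-1 models.

Two chains start from dispersed values (means perturbed by ±2 posterior-scale
SDs, covariance scaled by up to e^±0.7). Default ceiling 100,000 iterations;
every 500 iterations (after a minimum) the Gelman–Rubin PSR — computed from
between/within-chain variances on the second half of each chain, floored at
1 — is checked for all nine parameters and sampling stops early once all are
below 1.05. Non-convergence at the ceiling is flagged on the result, never
silent. The first half of the run is discarded as burn-in.

**Admissibility safeguard.** Before summarizing, draws are discarded when any
standardized autoregressive coefficient exceeds 1 in magnitude — cross-lags
scaled by the ratio of the two series' implied stationary SDs under that
draw's dynamics, and any draw with a non-stationary transition matrix
discarded outright. The discarded fraction is reported; on stationary
synthetic data it is far below 1%.

Summaries are posterior medians with equal-tailed 95% credible intervals. A
cross-lag is classified **positive** when its CrI lies entirely above zero,
**negative** entirely below, otherwise **null** (an endpoint exactly at zero
counts as containing it).

## Cohort aggregation

Analyzable Ns count usable dyads per task and in both tasks from the manifest.
Category percentages use each task's own denominator, rounded
half-away-from-zero to one decimal (9/26 → 34.6). Cross-task agreement per
direction×sign category is Cohen's kappa on the binary present/absent
indicator over dyads with both tasks — the only reading consistent with one
kappa per category row — with an approximate p-value from the large-sample
normal test of κ = 0 (Fleiss SE under independence). A kappa undefined by
constant agreement is flagged, not raised.

## Synthetic data: what it emulates, and what it does not

The generator defines ground truth at the RSA level and works backwards:
per-second RSA trajectories are drawn from the stationary VAR(1) (initial
state from the stationary distribution, Gaussian innovations, matching the
fitted likelihood), then encoded into beat times as
`IBI(t) = base + A(t) sin(2π f_resp t)` with `A(t) = sqrt(2 exp(rsa(t)))`, so
the local sinusoid power equals `exp(rsa(t))` and the spectral stage has an
analytic target. Defaults are the study's conditions: two tasks of 300 s,
28 dyads, adult base IBI 800 ms at 0.25 Hz respiration, child 600 ms at
0.30 Hz, μ = 6.5/6.0 ln ms², φ = 0.4, innovation SD 0.5 with correlation 0.2.
Cross-lag magnitudes are not reported in the literature for this design;
±0.3 is the fixture's effect size, chosen once to be comfortably detectable
at T = 300 (posterior SD ≈ 0.055). Corruption adds Poisson ectopic
displacement runs and dropout segments with a truth map.

Not emulated: ECG waveforms (the pipeline starts at beat times, so R-peak
detection is out of scope), respiration signals, non-Gaussian innovations,
slow drifts/nonstationarity, and within-task changes in respiratory rate.
Passing tests therefore demonstrate correctness of the estimation machinery
under the model's own assumptions, not robustness to every failure mode of
real ECG.

## Validation studies and problem sizes

`dyadsync.validation` holds the calibration experiments (also used by
`scripts/acceptance.py`):

- **Cross-lag recovery/calibration** — regimes with both cross-lags at
  −0.3, 0, +0.3; T = 300; 100 replicates per non-null regime and 500 null
  replicates (binomial SE ≈ 1% for the false-non-null rate); coverage pooled
  across the grid (700 trials per direction). Simulation fits use 2 chains,
  1500–3000 iterations with PSR checks every 250 — scaled-down chain settings
  chosen for Monte-Carlo throughput; the production default keeps the
  100,000-iteration ceiling.
- **ADF size** — 2000 random walks of length 300, lag-1 single-mean model.
- **Spectral round trip** — constant-RSA encode/decode, in-band (0.25 Hz)
  and out-of-band (0.05 Hz).

## Numerical choices and degenerate inputs

- Semi-definite covariances are factored by eigendecomposition with negative
  eigenvalues clipped at zero, so a noise-free (zero-covariance) process
  simulates exactly.
- `band_power_to_rsa` floors power at 1e−6 ms² so silence maps to a finite
  log value.
- Fewer than 2 beats, fewer than 4 spline support points, or fewer than 50
  both-valid seconds raise `UnusableRecordError`; constant or too-short
  series raise `DegenerateInputError` in the ADF screen. The CLI logs and
  skips such records; they remain in the manifest with their usability flag.
- PSR of zero-variance chains is reported as 1 with a degeneracy flag.
- Percentages use decimal half-away-from-zero rounding, not banker's
  rounding.

## Known limitations

- **Spectral smoothing vs per-second dynamics.** The 32-s sliding window is a
  low-pass filter: RSA estimated from beat times is a heavily smoothed
  functional of the underlying trajectory. When the generating process has
  white per-second innovations (the synthetic ground truth), the *estimated*
  series has autoregression near 1 and cross-lags attenuated toward zero, so
  second-scale coupling injected at the RSA-process level is not recoverable
  after the spectral stage — an intrinsic property of windowed estimators,
  not an implementation defect. Accordingly, coupling recovery and CrI
  calibration are validated on directly simulated RSA series, while the
  beat-level path is validated by the analytic constant-power round trip and
  end-to-end integration runs. Interpretations of fitted lag-1 dynamics on
  real windowed RSA estimates inherit the same caveat.
- Single-level (per-dyad) models only; no hierarchical pooling across dyads,
  no continuous-time variant, no time-varying coefficients.
- The beat-encoding forward model assigns each emitted interval the
  continuous IBI value at the interval's start, a first-order scheme whose
  discretization error is negligible at the tested modulation depths but
  grows with `f_resp · IBI`.
- The peak-matched taper family follows the peak-matched design principle but
  is not a bit-exact reimplementation of any published toolbox.
- Kappa p-values use the large-sample normal approximation, which is crude at
  n ≈ 25; they are labelled approximate.
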