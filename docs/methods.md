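# Methods

This note documents the models and procedures implemented in `gradpuff`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic validation shows.

## 1. Signal model and scope

A contaminated electrode signal inside an MRI bore is a sum of the
electrophysiological signal, RF-induced voltage, magnetohydrodynamic
voltage and the gradient-switching component. `gradpuff` characterizes the
gradient-switching component only, as obtained in vitro with no injected
signal: the other components are out of scope and the synthetic generator
sets them to zero. What remains is a pseudo-periodic train of short
oscillatory bursts ("puffs"), amplitude-modulated by a slow pseudo-sinusoid
and band-limited by the acquisition chain.

## 2. Synthetic generator (`synthgen`)

Each recording is built as

```
x(t) = sum_k A * w(t - t_k) * [1 + m sin(2*pi*f_am t)]  +  baseline(t)  +  noise(t)
```

followed by a zero-phase low-pass. Components and defaults:

* **Burst template** `w`: exponentially damped cosine
  `exp(-lambda*t) cos(2*pi*f0*t)` on a support of `puff_duration` seconds.
  This is a deliberate stand-in — the true waveform depends on coil
  geometry and sequence programming and no closed form is claimed; the
  template family is pluggable (`register_template`). The decay follows the
  one rule `lambda = 2/puff_duration`, i.e. the envelope falls to
  e⁻² ≈ 13.5 % of its peak at the end of the nominal support. This keeps
  the ground-truth interval coincident with where the burst actually
  carries energy while leaving a detectable edge at the burst end.
* **Timing**: onsets every `puff_period` seconds (0.0625 s default — 80
  bursts per 5 s), with optional Gaussian onset jitter truncated at
  ±`puff_period`/4 so intervals stay disjoint.
* **Amplitude modulation**: multiplicative on the burst train only,
  pointwise in global time (`am_depth` 0.25–0.35, `am_frequency` ~1 Hz in
  the presets) — emulating the slow pseudo-sinusoidal envelope seen on
  measured recordings.
* **Additive low-frequency baseline and 1/f-ish noise** are separate
  optional components (`baseline_amplitude`, `pink_noise_sd`), both 0 in
  the presets: they emulate the no-sequence background when wanted, but a
  robust envelope segmentation baseline is easiest to reason about without
  them, and they are one config field away.
* **Noise floor**: additive white Gaussian, `noise_sd` (0.05 of the unit
  burst amplitude in the presets).
* **Bandwidth emulation**: 4th-order Butterworth low-pass at 350 Hz applied
  forward-backward (zero phase) as the last step.
* **Presets**: six sequence × orientation design points. FSE-like: 62.5 ms
  period, 18–22 ms bursts, carriers 96–288 Hz; CINE-like: 50 ms period,
  8–9 ms bursts, carriers 220–260 Hz. Carriers are multiples of the
  repetition rate, so the line comb of the periodic train has a line exactly
  at the carrier (this makes "PSD peak at the carrier" well-defined).
  Carrier placement is loosely guided by the reported per-orientation
  spectral ranges of measured data but the presets are synthetic design
  points, not fits. CINE bursts are deliberately too short for the
  time-frequency test (see §6) to reproduce that known failure mode.

Ground truth lists every burst's half-open sample interval. The generator is
bit-reproducible given (config, seed).

**What the generator does not emulate**: RF/MHD components, eddy-current
tails, inter-burst waveform changes beyond AM, electrode drift,
non-Gaussian noise, or any physical model of the gradient chain. Passing
tests on this synthetic family therefore validates the *analysis machinery*
(segmentation, features, tests), not claims about real scanner waveforms.

## 3. Preprocessing (`preprocess`)

* **Z-score** `y = (x - mean)/SD`. The SD convention is the sample (n−1)
  SD by default (exposed as `ddof`); the choice is irrelevant at recording
  lengths but is documented because both conventions are in circulation.
* **Automatic segmentation** (a stand-in for manual delineation): centered
  moving-RMS envelope (window 5 ms), threshold `median + k·(1.4826·MAD)` of
  the envelope with k = 3, merge gaps < 5 ms, drop runs < 5 ms, then
  contract each run by half the envelope window per side. The contraction
  removes a deterministic bias: a centered window of width w starts
  responding w/2 before the burst and keeps responding w/2 after it. The
  robust (median/MAD) baseline tolerates the high-amplitude bursts as long
  as the elevated-envelope duty cycle stays below ~50 %; segmentation of
  signals with near-continuous activity needs either a larger `threshold_k`
  or manual annotations. Counts are empirically non-increasing in
  `threshold_k` and `min_duration` on burst-train inputs, though the former
  is not a theorem (a rising threshold can in principle split a run).
* Intervals are 0-based half-open everywhere; automatic segmentations can
  be exported to the annotation text format, hand-corrected and re-imported.

## 4. Features (`features`)

* **Mean puff**: puffs resampled to a common grid (default: median puff
  length) by band-limited (FFT) resampling, `method="linear"` as fallback,
  then averaged pointwise.
* **Normalized MSE** between a puff and the mean curve:
  `sum((yhat-y)^2) / (N * r^2)` with `r` the mean-curve peak-to-peak range.
  This form is dimensionless and invariant to a common rescaling, which is
  the property needed for comparing normalized sequences; the non-invariant
  `1/ybar` prefactor variant is available as `normalization="printed"`. An
  explicit `value_range` override exists for degenerate mean curves.
* **Welch-WOSA PSD**: Hamming window, 50 % overlap, segment length 4096
  samples for global spectra (~1.2 Hz resolution at 5 kHz) and
  `seg_len = len(puff)` (a single modified periodogram, no zero-padding)
  per puff. No detrending by default (inputs are z-scored). These estimator
  settings are package choices; none are dictated by the method itself.
* **Band moments** on the one-sided PSD restricted to an optional band:
  mean frequency (first moment), peak frequency (argmax), spectral SD
  (root second central moment), all in Hz. Reported spectral SDs are
  therefore on the Hz scale; dimensionless alternatives would require a
  different normalization of the PSD and are not emulated.

## 5. KPSS test (`kpss`)

Statistic `eta = T^-2 sum_t S_t^2 / s^2(l)` with OLS residuals (constant,
or constant + trend), Bartlett-kernel long-run variance, default bandwidth
`floor(4 (T/100)^0.25)` (Newey–West style; the bandwidth choice is open in
the original formulation). The default variant is **trend**, because the
0.1460 decision threshold in use for induced-potential recordings is the
trend-variant asymptotic α=0.05 critical value; the level variant is one
argument away. The boundary convention is strict: stationary iff
statistic < critical value. Monte-Carlo critical values simulate Gaussian
white noise under the null with zero-lag long-run variance and return the
empirical quantile; at T=2000 with 50,000 replicates the trend α=0.05 value
reproduces 0.146 within ±0.005 (the finite-sample quantile sits ~0.002
above the asymptotic value). An independent implementation (statsmodels) is
used in the test suite as a cross-check oracle, never as the
implementation.

## 6. Time-frequency surrogate test (`tfstat`)

* **Hermite bank**: first K Hermite functions sampled on
  `linspace(-tmax, tmax, Nh)` (`tmax = max(6, sqrt(2K+1)+3)`), then Löwdin
  (symmetric) orthonormalization so the discrete Gram matrix is the
  identity to machine precision. `Nh` must be odd and exceed `4K` for the
  highest-order window to be resolved.
* **Spectrogram**: for each analysis instant, the K squared short-time
  rFFT magnitudes are averaged. Instants are spaced by half the window
  length (a fraction of the equivalent width; here the equivalent width is
  taken as `Nh` itself) and span the positions where the window is fully
  supported; frame extraction zero-fills defensively.
* **Window size**: `win_frac` is a *fraction of the analyzed record*
  (`Nh = odd(round(win_frac·n))`) — the local horizon is defined relative
  to the global observation scale, which is what makes the notion of
  "stationary relative to this horizon" well-posed. The reference sweep is
  `[0.03, 0.04, 0.05, 0.07, 0.075]`; one printed source lists a 0.005 entry
  in that range, almost certainly a typo for 0.05 — any admissible value is
  accepted, neither is asserted.
* **Surrogates**: rFFT modulus kept exactly; phases i.i.d. uniform on
  [−π, π]; DC and Nyquist bins keep their original phase so the inverse
  transform is real with an unchanged modulus. One master seed drives a
  single generator; surrogates are drawn in fixed-size batches so results
  are reproducible for a given (signal, J, seed).
* **Dissimilarity**: `k(G,H) = kKL(G~,H~) * (1 + kLSD(G,H))` with the
  symmetrized (Jeffreys) KL divergence on unit-sum normalized spectra and
  the summed absolute log-ratio on the raw spectra; discrete sums carry
  unit bin weight, and bins are floored at 1e-12 of each spectrum's maximum
  before logs. θ is the empirical (1/N) variance of the local-global
  dissimilarities over analysis instants — for the signal (θ₁) and for
  each surrogate (θ₀(j)) alike.
* **Threshold**: maximum-likelihood gamma fit to {θ₀} (location fixed at 0,
  method-of-moments initialization); γ is the gamma (1−α) quantile,
  α = 0.05 default. If the fit fails the empirical quantile is used and a
  warning logged. With J = 5000 the gamma and empirical quantiles agree
  within ~10 %; J = 50 already gives the same decisions on clear cases and
  is the fast default outside full studies.
* **INS**: reported as `sqrt(theta1/mean(theta0))` with threshold
  `sqrt(gamma/mean(theta0))` — ≈1 under the null, matching the convention
  in which INS thresholds land around 1.3–1.6. The literal un-rooted ratio
  is available via `ins_convention="ratio"`. One printed formulation of the
  index omits the square root while reporting threshold magnitudes
  consistent with it; the rooted form is the default here for that reason.
* **Short-signal failure**: the test needs `Nh > 4K` and at least two
  analysis instants. Very short bursts (≲10 ms at 5 kHz with K=5) cannot
  satisfy this at any sensible `win_frac` — the CINE regime. The pipeline
  records these as not-computable with the reason instead of failing the
  study; per-puff analyses use a larger default window fraction
  (`tf_puff_win_frac = 0.2`) than global ones (0.05) because a burst is
  its own, much shorter, observation horizon.

Operating characteristics verified in the acceptance suite (n = 2000,
K = 5, win_frac = 0.05, J = 50, 100 seeded runs): white noise is declared
stationary in ≥ 91 runs; noise amplitude-modulated by three sine cycles
over the record is declared non-stationary with INS above threshold in
≥ 95 runs.

## 7. Pipeline (`pipeline`)

Global analyses run on the first `analysis_window` seconds (default 5 s) of
the z-scored trace. Per-item failures are caught and recorded so one short
puff or degenerate segment cannot abort a study. Reports follow a fixed
four-table layout (RMS/MSE, frequency parameters, global stationarity,
local stationarity) with Global / min–max / mean–stdev aggregates; the JSON
report round-trips all floats exactly, and mean–stdev cells equal direct
recomputation from the serialized per-puff records. The master seed is
split per recording (and per puff for surrogate draws) via
`numpy.random.SeedSequence`, making whole studies byte-reproducible.

## 8. Problem sizes used in the validation suite

The test suite exercises the chain at reduced but statistically meaningful
sizes chosen as the package's own validation design: 2 s recordings (32–40
puffs) for pipeline tests, J = 8–50 surrogates for decision tests and
J = 2000 for null-distribution shape checks, 100-run operating
characteristic estimates, and 50,000 × 2,000 Monte-Carlo replicates for the
KPSS critical value (the full-size computation, a few seconds when
vectorized). Full-protocol runs (10 s records, J = 5000) use the same code
paths with larger parameters.

## 9. Known limitations

* The burst template and presets are plausibility-driven stand-ins; none of
  the data-dependent table values from measured recordings can be (or are)
  reproduced.
* The envelope segmenter assumes bursts are sparse in time (duty cycle
  below ~50 %); it is a stand-in for manual delineation, and its boundary
  accuracy is limited to about half the envelope window.
* Spectral-SD units are Hz by definition here; sources reporting
  dimensionless spectral SDs on normalized spectra are not comparable
  without renormalization.
* The KPSS long-run-variance bandwidth rule affects statistics on strongly
  autocorrelated signals; nlags is exposed everywhere for sensitivity
  checks.
* The gamma null model for θ₀ is an approximation; with few surrogates
  (J ≲ 30) its upper quantile is noticeably noisy and decisions near the
  threshold should be re-run with larger J.
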