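# Methods

This note documents the models, parameter choices and numerical decisions behind
`alphadyn`, and what the synthetic-data validation does and does not establish.

## Synthetic EEG generator

Each channel is the sum of an aperiodic process and an alpha oscillation.

**Aperiodic component.** The target one-sided PSD is `S(f) = 10^b · f^(−x)` with
offset `b` (log10 power) and exponent `x ≥ 0`. Synthesis shapes white noise in the
frequency domain: deterministic amplitudes `∝ √S(f)` with uniform random phases,
inverse-transformed. Two consequences matter. First, the synthesized spectrum follows
the model *exactly* in expectation, so spectral estimators can be judged against known
truth. Second, below the 1 Hz fit-range edge the PSD is held constant at `S(1)`
(a plateau). Real EEG is high-pass filtered and does not follow a power law to DC;
without the plateau, the (for `x = 2`, enormous) sub-Hz power leaks through the 2-Hz
mainlobe of the 1-s Hann window into the lowest analysis bins and biases the recovered
exponent upward by ≈ +0.2.

**Alpha oscillation.** A phase-continuous frequency-modulated sinusoid. Its
instantaneous frequency is a piecewise-constant center-frequency (CF) trajectory:
values drawn from the configured process (`iid_gaussian` with mean `mean_cf` and SD
`cf_jitter_sd`, clipped to 8–13 Hz; or a reflected bounded random walk), each held for
`dwell` seconds. Default `dwell = 3 s`: IAPF drift in real EEG is autocorrelated over
seconds, and CF states much shorter than the spectral estimator's temporal resolution
(five averaged 1-s windows ≈ 3 s, see below) are attenuated by *any* windowed
estimator, which would confound a recovery assessment. The trajectory is the ground
truth for the variability analyses.

**Amplitude calibration.** The `amplitude` parameter is defined as the fitted peak
height above the aperiodic component in log10 units. The sinusoid amplitude is
`A = k·√(S_ap(mean_cf)·(10^a − 1))` with `k = √3 · 10^(−0.075)`: √3 is the analytic
value for a Hann equivalent-noise bandwidth of 1.5 Hz, and the 10^(−0.075) factor
corrects the ≈ 0.15-decade overestimate that otherwise arises because a narrow spectral
line is fitted by a Gaussian clipped at the minimum width limit. The constant is held
fixed and verified by a round-trip unit test (tolerance ±0.2).

Defaults: `b = 0`, `x = 1.0`, `mean_cf = 10 Hz`, `amplitude = 1.0` (a 10× peak over
the aperiodic component at 10 Hz — strong but typical eyes-closed posterior alpha;
weaker peaks push per-window CF estimation against its noise floor, see Limitations),
`cf_jitter_sd = 0.4 Hz`. Cohort presets: the *null* design uses identical parameters
for every group × condition; the *hypnosis-contrast* design raises post-induction
`cf_jitter_sd` to 1.0 Hz in the high-susceptibility group (low group 0.4 Hz), all else
equal. Channels are simulated independently — there is no volume-conduction model, no
channel covariance, no artifacts (see Limitations). Subject- and channel-level
reproducibility comes from `numpy` seed sequences spawned deterministically from the
master seed.

## Time-resolved spectral parametrization

Per channel: short-time Fourier transform with 1-s Hann windows and 50% overlap,
power spectra restricted to 1–40 Hz. Each output spectrum is the mean of `n_avg = 5`
consecutive periodograms (stride one hop), matching the local averaging of the
published time-resolved parametrization tooling; `n_avg` is configurable. The grid is
zero-padded ×2 (0.5 Hz spacing) because Gaussian peak fitting on the native 1 Hz grid
is coarse.

**Log-spectrum debiasing.** The log of an averaged periodogram is biased:
`E[log10(χ²_2k/2k)] = log10(e)·(ψ(k) − ln k)` (≈ −0.25 at k = 1, −0.045 at k = 5),
with `k` the effective number of independent periodograms (Welch-corrected for the
0.167 lag-one correlation of 50%-overlapped Hann windows). This bias is subtracted so
the log spectrum estimates `log10 S(f)` without offset bias at any `n_avg`. Reference
implementations do not debias; their offset estimates inherit the bias.

**Window fit.** (1) Robust aperiodic fit: OLS of `log10 S` on `log10 f`, then refit on
the bins at or below the 2.5th percentile of the zero-floored residuals (discards peak
bins). (2) Iterative peak guessing on the flattened spectrum: repeatedly take the
maximum while it clears `max(0.1, 2·SD(flattened))`; width guessed from the
half-height extent (FWHM/2.355) and clipped to Gaussian-SD limits [0.75, 3] Hz (the
printed 1.5–6 Hz limits interpreted on `2w`); the guess is subtracted before the next
iteration; at most three peaks. (3) Joint refit of all guesses by damped Gauss–Newton
with projection onto bounds; each center is additionally constrained to ±1.5
guess-widths of its guess, which prevents a peak from sliding onto neighbouring
structure when the flattened background is locally elevated. (4) Pruning: a peak is
dropped if its center lies within 0.75·(its width) of a fit-range edge, or within
0.75·(the larger peak's width) of a larger peak. (5) Final plain OLS aperiodic fit on
the peak-subtracted spectrum; the model's mean squared error in log10 units and R² are
reported side by side. Windows whose fit fails are marked missing, never interpolated.
The "minimum peak height of 1 dB" is interpreted as 0.1 log10(power) units (1 dB =
0.1 bel), the unit convention of the reference tooling.

The kernels are numba-compiled: cohort-level analyses fit millions of windows, and the
permutation machinery needs the same throughput. scipy-based fits (`curve_fit` on the
same spectra) serve as independent oracles in the test suite, as does the published
reference implementation where installed.

**Alpha selection and exclusions.** Per window, the largest-amplitude peak with center
in 8–13 Hz. Channels whose fraction of alpha-containing windows falls below a
configurable floor (default 0.25) are flagged, and flagged subjects are excluded from
every feature table, mirroring subject-level exclusion when the algorithm cannot model
alpha peaks. Note that with the printed 1-dB/2-SD peak thresholds, single noisy windows
yield spurious in-band maxima at a measured floor of roughly 35–40% even without any
oscillation; the floor is logged, and exclusion is driven by the *relative* contrast to
genuine alpha coverage (≈ 100% at default SNR), not by an assumption that the false
rate is near zero.

## Features

Per channel and recording: the sample SD (n−1) of each parameter time series over
non-missing windows (alpha parameters are complete-case; channels with fewer than two
valid windows are missing), for pre-induction and for Δinduction = post − pre. The
mean and SD of the per-window MSE form a separate control family; mean normalized LZ76
complexity forms a third.

## Decoding and inference

For each held-out subject, 15 subjects per class (configurable) are drawn at random
from the remainder; channels are z-scored on the training draw (zero-variance channels
zeroed); a linear hinge-loss SVM (C = 1, L2-regularized intercept via feature
augmentation) is fitted by dual coordinate descent and the held-out decision value
recorded. Decision values are pooled within a repetition into one midrank AUC; the
observed statistic averages 10 repetitions. The permutation null shuffles subject
labels once per permutation and reruns the whole procedure (default 1 repetition per
permutation, for tractability; configurable); `p = (1 + #{null ≥ obs})/(1 + N)`; the
raw decision compares the observed AUC with the null's 95th percentile (one-tailed
α = 0.05). Bonferroni families: the five spectral-variability features within a
contrast; MSE-control and LZ features are corrected within their own families. The
Haufe activation pattern — training-covariance × weights, averaged over every fold and
repetition — is reported per channel. The dual coordinate-descent solver is verified
against an established SVM implementation to 10⁻³ in the test suite. Known property of
the balanced-LOOCV statistic: under the null its distribution centers very slightly
below 0.5 (the held-out subject is absent from its own training draw); the permutation
null inherits the same shift, so test levels are preserved. Each table's test is exact
(empirically verified: 5.0% conditional rejection rate at α = 0.05 under random
relabelings), but the feature tables within a family are strongly dependent — offset,
exponent and width variability derive from the same window fits, and the Δinduction
contrast shares the pre-induction data — so false positives cluster within a cohort,
and counts of rejections *across* features in repeated studies are overdispersed
relative to a binomial independence assumption.

## Validation scope

Passing tests establish that the pipeline recovers planted aperiodic parameters
(|error| ≲ 0.07 over exponents 0.5–2, offsets −1–1), recovers alpha-CF jitter SDs of
0.5–1.0 Hz to within ±15%, holds its nominal false-positive rates on null cohorts, and
detects a group difference carried only by post-induction CF jitter while leaving
pre-induction and complexity features at chance. They do *not* establish performance
under volume conduction, artifacts, non-stationary aperiodic activity, multiple or
drifting non-alpha peaks, or real inter-subject variability — none of which the
generator emulates.

## Known limitations

- **Per-window CF noise floor.** With 1-s windows, five-periodogram averaging and a
  10× alpha peak, the per-window CF estimate has an irreducible SD of ≈ 0.15–0.22 Hz
  (χ² spectral noise interacting with the line; verified against scipy oracles and
  with oracle-flattened spectra). Recovered CF-variability therefore includes this
  floor in quadrature: planted jitter SDs at or below ≈ 0.2 Hz are overestimated by
  ≈ 25–40%, while 0.5–1.0 Hz jitter recovers within ±15%. Group comparisons are
  unaffected (the floor is common to both groups), but absolute variability at the
  low end should be read as `sqrt(true² + floor²)`.
- The spectral estimator's ≈ 3-s effective resolution attenuates CF dynamics faster
  than the averaging span (measured attenuation ≈ 0.9 at the 3-s default dwell).
- LZ76 on 1-minute epochs at 250 Hz yields ≈ 700–900 components; raw counts depend on
  epoch length, hence the normalized value is the decoded feature by default.
- EDF output is 16-bit quantized over per-channel integer bounds; CSV output is exact.
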