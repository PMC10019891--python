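# Methods

## The task model

The synthetic generator emulates a retro-cue orientation working-memory
experiment. Each of 16 subjects completes 10 acquisition blocks of 18
trials (180 trials). On every trial two grating orientations are drawn
from 9 bases (0–160° in 20° steps); a strict circular separation
constraint (>20°, which on the 20° grid forces ≥40°) keeps the two items
discriminable; each item receives an independent jitter of 1–5° magnitude
with random sign. A retro-cue (1 or 2, uniform) selects the item to
retain. After the delay the cued orientation is reproduced: with
probability 1 − λ the report is the cued orientation plus wrapped Gaussian
noise (SD σ_r), with probability λ it is uniform on [0, 180)
(an attentional lapse).

Behavioral defaults σ_r = 15°, λ = 0.03 were fixed a priori so the
Gaussian-plus-lapse mixture has a pooled linear SD near 17°
(√(0.97·15² + 0.03·90²/3) ≈ 17.3°), the scale typical of this paradigm
with an effective set size of one. Under these defaults roughly 145 of a
subject's 180 trials fall below 20° absolute error and ~33 land between
20° and 3·SD; a heavier-tailed empirical error distribution would shift a
few trials from the larger-error bin into the small bin relative to this
Gaussian mixture.

## The signal model

Voxel time series are laid out on a fixed TR grid per trial (5 baseline
TRs, 1 encoding TR, 1 cue TR, 5 delay TRs, 1 response TR). Delay TRs carry
`snr_cued · W c(θ_cued) + snr_uncued · W c(θ_uncued)`; the encoding TR
carries both items at `snr_encoding`; everything receives additive
Gaussian noise with a random symmetric positive-definite spatial
covariance `I + γ·AAᵀ/m` (A standard normal, γ = `noise_cov_strength`).
Hemodynamic convolution is deliberately not simulated — the analysis
consumes raw delay TRs, and adding an HRF would only relabel which TRs the
event map calls "delay".

Ground-truth tuning weights give each voxel a preferred orientation (the
first k voxels cover the k channel centers, so every channel has a
maximally loading voxel), a broad nonnegative tuning profile (rectified
sinusoid, exponent 2), a random gain in [0.5, 1.5], and a small
nonnegative perturbation. A `one_hot` mode with orthogonal columns exists
for exact forward/backward consistency checks.

Defaults `snr_cued = snr_encoding = 0.85`, `snr_uncued = 0`,
`noise_sd = 1` yield clearly detectable but not saturated delay
information at 40 voxels. Two deliberate simplifications matter when
interpreting simulated statistics:

- **Subjects are homogeneous.** All subjects share the same SNR; only
  noise realizations differ. Group-level t values and effect sizes are
  therefore much larger than in real data, where between-subject
  variability dominates. Tests that need realistic subject heterogeneity
  (e.g. the IEM↔RSA subject correlation) impose an explicit per-subject
  SNR grid instead.
- **`snr_uncued = 0` is a modeling choice, not an empirical fact.** The
  central claim being emulated is cued-specific delay information;
  leakage of uncued information is configurable for alternative
  hypotheses.

### Residual uncued information

Even with `snr_uncued = 0`, uncued-aligned decoding recovers a small
positive R (~0.03 against ~0.18 cued) at simulator SNR. This is not a
decoder artifact: it disappears when the two items are drawn
independently. The item-separation constraint makes the cued and uncued
labels statistically dependent, so a decoder trained on uncued labels
picks up genuinely predictive cued-item signal. At realistic fMRI SNR this
leakage is far below noise level.

### Precision coupling

For the behavior-linked analysis the generator can couple decodability to
recall: each trial receives an attention gain g drawn uniformly from
[1 − s, 1 + s] (default spread s = 0.7); the delay signal is scaled by g
and the recall SD by 1/g. Well-attended trials are then both better
decoded and more precisely recalled, which is the data-generating
assumption the error-linked contrast is designed to detect.

## Delay-pattern extraction

Each run is z-scored per voxel across its TRs (population SD, ddof = 0 by
default; the convention is configurable and only rescales patterns).
Zero-variance voxels are zeroed with a warning. Each trial's 5 delay TRs
are collapsed with the triangular TENT-style weight vector (0, 1, 2, 1, 0),
normalized by the weight sum — a weighted mean emphasizing mid-delay
activity. Normalization does not affect correlations or decoding contrasts
but keeps pattern units interpretable. A `peak_shift` parameter slides the
window across time for the time-varying variant, and the same weighting
applied to the 5 pre-stimulus baseline TRs provides baseline-epoch
patterns for the cross-region comparison.

## Channel basis

Nine half-wave rectified sinusoids over the 180° orientation space,
`f_j(θ) = max(0, cos(πΔ_j/180))^p` with Δ_j the signed circular difference
to center ψ_j ∈ {0, 20, …, 160}. Each channel is 1 at its own center, 0 at
the orthogonal orientation, and nonnegative everywhere. The exponent p
controls tuning width; p = 8 is the conventional default for this basis
family and all basis properties are exercised at p ∈ {2, 6, 8}. Training
labels default to the jittered (actually presented) orientations; base
(binned) labels are available via a switch — jitter is ≤5° against 20°
channel spacing, so the choice is second-order.

## Decoding

Weights are ordinary least squares per voxel, `W = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹`, with a
pseudo-inverse fallback (logged) for rank-deficient designs. Per-channel
noise covariance uses the rank-1 channel prediction residual
εᵢ = B₁ − WᵢC₁ᵢ, the uncentered covariance εᵢεᵢᵀ/(n₁−1) (residuals are
model errors, not re-centered), and analytic shrinkage toward a scaled
identity: λ = min(1, b²/d²) with d² the squared distance of the sample
covariance from its identity target and b² the average squared
fluctuation of per-trial outer products — vanishing as n₁ grows and
guaranteeing invertibility when voxels outnumber trials. Degenerate
residuals (e.g. noiseless training data) fall back to δ·I with
δ = 1e-8, logged. Filters `Vᵢ = Σᵢ⁻¹Wᵢ/(WᵢᵀΣᵢ⁻¹Wᵢ)` have unit own-channel
gain by construction; an `identity` covariance mode reduces them to
`Wᵢ/‖Wᵢ‖²`.

Cross-validation is leave-one-block-out over the 10 acquisition blocks
(or, for the error-linked analysis, a seeded random re-blocking into
blocks of 18). Condition labels are the cued orientations, the uncued
orientations, or a seeded within-subject shuffle of the cued labels.

Reconstructed channel responses are placed at their centers, circularly
linearly interpolated to a 1°/180-point grid (the first point appended at
center + 180° to close the circle), and rotated so the trial's label maps
to 0°. With off-grid (jittered) labels, linear interpolation snaps curve
peaks to the nearest channel center, so per-trial peaks are exact only for
on-grid labels; R is insensitive to this at the tested SNRs. The
information metric is computed from the aligned curve as the real part of
the mean orientation-doubled phasor; dividing by the number of grid points
(i.e. `z` is the *mean* channel response) fixes the scale such that a unit
delta response at the center of a k-point representation gives R = 1/k.
Per-trial R values are averaged to condition level (trial-then-average;
since R is linear in the curve, averaging order only matters for
asymmetric summaries, and both orders are available).

A useful exact symmetry, used in tests: shifting every orientation label
by one channel spacing against the same voxel data permutes the channel
estimates and leaves aligned curves exactly invariant, through the full
shrinkage path. Regenerating data with rotated labels against a *fixed*
random voxel set is not exactly invariant, because a finite voxel
population has non-circulant channel crosstalk.

## RSA

Neural similarity is the pairwise cosine of delay-pattern rows (zero-norm
rows flagged and zeroed). Stimulus similarity is 180° minus the circular
orientation distance (range [90, 180]; only ranks matter downstream, and
the circular metric is the only one consistent with orientation stimuli).
The association is a Spearman correlation over the lower triangles with
average-rank ties, Fisher-z transformed with |ρ| clipped at 1 − 1e-7.
Group tests compare per-subject Fisher-z against zero (a permutation null
is available but zero is the default reference). The cross-region
comparison is second-order: the Spearman correlation between two regions'
neural-similarity lower triangles, computed per epoch (baseline vs delay).

## Group statistics

Paired t-tests are two-tailed with Cohen's d = mean(diff)/SD(diff)
(sample SD). Bootstrap p values resample subjects with replacement
(default 1000 iterations), p = 2·min(frac ≤ 0, frac ≥ 0), floored at
1/n_iter and reported as "<0.001" below the floor. Bonferroni adjusts by
an explicit family size (defaulting to the number of tests supplied —
never inferred silently, since the comparison family is an analysis
choice). The 2×2 cue-by-region interaction is the one-sample t on the
per-subject difference-of-differences, squared to F(1, n−1) — equivalent
to the repeated-measures ANOVA interaction, verified against a full
decomposition. The error-linked contrast draws |larger| trials from the
small-error pool *without replacement* per iteration (5000 iterations,
seeded), averages across iterations, and contrasts against the mean over
all larger-error trials; subjects with fewer than 2 larger-error trials
are excluded with a log entry. The resampled mean is unbiased for the
small-pool mean (verified against exhaustive subset enumeration on a tiny
instance).

## Numerical and design choices

- Signed recall errors live in [−90, 90); the boundary orientation maps
  to −90. The upper categorization bound is inclusive (20° ≤ e ≤ 3·SD);
  the pooled (not per-subject) SD is the default, with per-subject offered
  as an option. "Empirical SD" is the ordinary linear SD of the pooled
  signed errors, not a circular dispersion.
- All public angle interfaces are degrees; the orientation-doubling factor
  2 is applied after conversion to radians inside the information metric.
- Every stochastic operation takes an explicit seed; pipeline outputs are
  pure functions of (config, seed), and the CLI writes config hashes and
  seeds to provenance sidecars.
- Voxel flattening of volumetric input follows native volume index order
  (C order over x, y, z) — stable across runs, irrelevant to statistics.

## Validation scale and limitations

The validation studies run at the emulated design size (16 subjects,
180 trials) with 16–24 simulated voxels per region — the analysis cost is
dominated by per-fold covariance estimation, and these sizes keep the
null-calibration study (200 replicate experiments) and the
signal-recovery study (20 replicate experiments) to a few minutes on one
core while leaving Monte-Carlo error far below the tested effects.

Passing tests demonstrate that the estimators are correct, calibrated
under the null, and able to recover the qualitative result pattern under
the generator's assumptions. They do not demonstrate robustness to
properties the generator omits: hemodynamic dynamics and temporal
autocorrelation, scanner drift and motion, non-Gaussian noise,
between-subject anatomical and SNR variability, or heavy-tailed recall
errors. Real-data effect sizes will be far smaller than simulated ones.
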