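# Methods

This note documents the modelling assumptions, default parameters, and
numerical choices behind `audenc`, and what the synthetic-data tests do
and do not establish about real data.

## Stimulus representation

Audio (16 kHz, ~1 s) is passed through 128 overlapping bandpass filters
with center frequencies log-spaced between 180 and 7040 Hz
(log2(7040/180) ≈ 5.29 octaves, quoted as 5.3). The filterbank is
gammatone-shaped with ERB bandwidths (`scipy.signal.gammatone`); only
the log-spaced grid and the overlapping-bandpass character matter
downstream, because every model space consumes the *time-averaged*
profile. Channel energy is half-wave rectified, squared, and framed at
8 ms; the frame length is immaterial after averaging. Because gammatone
bandwidth grows with center frequency, a pure tone's energy peak can
fall one channel above the nominally nearest center — the tests allow
exactly that.

Octave binning partitions the 128 channels into `n_bins` bins of equal
log2 bandwidth; a channel belongs to the bin containing its center
frequency (half-open bins, closed at the top edge for the last bin).
Every channel lands in exactly one bin; a bin with no channels (possible
only at unusual bin counts) reads 0.

## Feature spaces

All four spaces carry F = 42 parameters, chosen against the 56 training
sounds. Location-bearing spaces are azimuth-major (blocks ascending
−90° → +90°), frequency ascending within a block; this ordering is the
contract between `model_spaces`, the ridge fit, and the 6 × 7 reshape in
`topography`, and is enforced through feature labels at predict time.
The location-only taper [1/6, 1/3, 1, 1, 1/3, 1/6] is used exactly as
printed, without per-row renormalization.

## Synthetic ground truth

The generator's job is recoverability: every downstream stage can be
validated against planted parameters.

* **Sounds** — spectral profiles are mixtures of 1–3 Gaussian bumps in
  log2-frequency (widths 0.3–1.5 octaves, amplitudes 0.5–1), a sparse,
  natural-sound-like shape. Azimuths are balanced exactly across the
  7-point grid within the training and test sets.
* **Voxels** — separable Gaussian tuning in log2(frequency) × azimuth.
  The encoding model itself assumes nothing about tuning shape (it fits
  42 free weights); the Gaussian form is the simplest way to plant a
  unique (CF, azimuth) preference. Default bandwidths: 0.5–1.5 octaves,
  25–45°; default response noise sd 0.05 (roughly 7% of the typical
  signal sd, "moderate noise").
* **Responses** — Y = W_joint · R_true + iid Gaussian noise, the exact
  linear model the encoding fit assumes. Model mismatch (nonlinearity,
  non-Gaussian noise, voxel correlations) is deliberately absent.
* **Time series** — events in random order at interstimulus intervals
  of 2, 3, or 4 TRs (TR = 2.8 s), each contributing beta × HRF; the
  canonical kernel is a double gamma (peak 6 s, undershoot 16 s, ratio
  1/6) sampled at TR over 7 taps (~19.6 s), normalized to unit peak.
* **Binaural audio** — the right channel is the left channel with
  per-band amplitude gain 10^(−ILD/20) and an exact fractional delay
  applied in the frequency domain. Carriers are bandpass noise or
  random-phase multi-tone complexes. Optional per-channel measurement
  noise is scaled by a *shared* reference level; scaling it per channel
  would lateralize the noise floor itself and leak spurious ILD into
  bins without stimulus energy.

All randomness flows through `numpy.random.default_rng(seed)`;
regeneration with the same seed is bit-identical.

## Response estimation

Three stages mirror an event-related deconvolution pipeline, kept
self-contained rather than delegating to an external denoising package:

1. **Noise regressors.** The noise pool is selected by split-half
   cross-validated R² of a *combined* task regressor (all onsets,
   canonical HRF): voxels at or below 0 are task-insensitive. In-sample
   R² is useless here (nonnegative by construction), and a per-sound
   design cannot be cross-validated when each sound appears once.
   Residuals are then taken against the full per-sound design so
   task-locked variance cannot enter the PCA; pool voxels with
   numerically negligible residuals are dropped. Top `n_components`
   (default 5) standardized-residual PCs become nuisance columns.
2. **HRF.** One FIR kernel per voxel over a 7-TR window, shared across
   sounds. The bilinear amplitude × kernel model is scale-ambiguous, so
   kernels are normalized to unit positive peak and amplitude lives in
   the betas. A unit-weight deconvolution is a compromise fit when
   amplitudes vary across sounds; `estimate_responses` therefore runs
   one alternating-least-squares pass (betas under the canonical
   kernel → amplitude-weighted deconvolution → final betas), which makes
   the noise-free round trip exact to machine precision.
3. **Betas.** Per-sound least squares with each sound's onsets convolved
   with that voxel's kernel, nuisance columns and intercept included.
   Rows flagged `target` or `zero` in the event table are excluded
   before estimation. Betas are not standardized per voxel (an option
   exists upstream of the ridge fit via its centering).

## Ridge fit and penalty selection

Per voxel, R_j = (WᵀW + λ_j I)⁻¹ Wᵀ Y_j. W columns and Y voxels are
mean-centered before solving (the standard ridge intercept convention);
means are restored in prediction. One eigendecomposition of WᵀW is
shared across voxels and penalties and agrees with the explicit inverse
to better than 1e-8 relative error (tested on 56 × 42 systems across the
full grid).

The penalty grid is 25 points log-spaced over [1e-3, 1e3] × mean
diag(WᵀW). λ_j is the smallest grid value whose ridge trace has
stabilized: the maximum absolute coefficient change to the next grid
point, relative to the largest current coefficient, falls below 5%. If
no grid point qualifies, the largest penalty is used. The published
ridge-trace procedure this emulates is not specified in formulas
anywhere accessible, so this rule is a documented, monotone stand-in;
no result in this package depends on a particular λ value, and the
permutation test freezes λ at the unpermuted values by construction.

Voxel selection takes the best `cap` voxels (default 5000) by the
one-sample t statistic of their responses against zero, strictly above
the threshold (default t > 2.9), inside an optional anatomical mask.

## Identification and inference

P_i = 1 − (r_i − 1)/(S_test − 1) is the unique affine function of the
rank with P(1) = 1, P(S_test) = 0 and E[P] = 0.5 under random ranking.
Correlation ties resolve to average ranks. Calibration is verified
empirically: with predictions independent of measurements, the grand
mean over 500 draws sits within 0.01 of 0.5.

The permutation null shuffles which training sound carries which
response, constrained so no sound receives a label from its own
azimuth. Permutations are sampled by seeded shuffle-with-repair: start
from a uniform random permutation and resolve conflicts with random
constraint-preserving swaps. Pure rejection sampling was rejected on
cost grounds — for 7 balanced groups of 8 the acceptance probability is
about e⁻⁸, i.e. ~3000 draws per usable permutation — while repair
converges in a handful of swaps; the different-azimuth constraint is
verified to hold in 100% of sampled permutations, and the sampler is
deterministic under a seed. The p-value convention (1 + k)/(1 + n_perm)
never reports zero; its validity (super-uniformity at α = 0.05 under a
true null) is checked over 200 seeded repetitions.

Group-level comparisons apply atanh to accuracies (clipped away from
±1) before one-tailed one-sample (vs the chance equivalent) and paired
t-tests, Bonferroni-corrected. Whether the transform should instead act
on 2(P − 0.5) is not decidable from the available description; atanh of
the accuracy is implemented and documented here.

## Binaural cues

Cue extraction uses a 32 ms Hann / 8 ms hop STFT rather than the
cochlear filterbank because phase is required. ILD is the difference of
time-averaged log power in dB (positive = left louder); dB is chosen
over raw power difference for scale invariance. ITD per bin converts
the power-weighted circular mean interaural phase difference:
ITD = Δφ/(2πf). Phase is unambiguous only while |Δφ| < π, so bins at or
above f = 1/(2·max ITD) are flagged invalid; the default assumed
maximum |ITD| is 700 µs (human head), giving a ~714 Hz validity limit.
STFT bins at the edges of a band-limited carrier are dominated by
window leakage and do not measure the imposed cue; recovery guarantees
hold in band interiors.

Cue informativeness subtracts the per-bin cue at +90° from that at
−90° per sound, normalizes the mean difference by its maximum over
bins, and tests each bin with a one-tailed one-sample t-test
(Bonferroni over tested bins; correction method is otherwise
unspecified upstream, Bonferroni is the conservative choice). Sounds —
not time frames — are the observations. Bins whose mean power falls
more than 40 dB below the loudest bin are excluded: interaural cues are
undefined without stimulus energy, and leakage-level content otherwise
produces spurious flags.

## Topography

Each voxel's 42 joint weights reshape to 6 frequencies × 7 azimuths and
are smoothed with a 3 × 3 Gaussian kernel of SD 0.5 grid units. The
kernel is truncated and renormalized at the edges (no wraparound:
neither frequency nor azimuth is circular), which preserves constants,
so preferences are invariant to positive rescaling and to adding a
constant. Argmax ties resolve to the lowest frequency bin, then the
most central azimuth (left first), with a tie flag recorded.

Gradient directions: the spatial gradient of log2(best frequency) in a
2D slice by central differences, one-sided at edges and next to
unmapped neighbours; voxels with no usable neighbour pair are skipped.
Angles use the convention 0° along the first in-plane axis,
counterclockwise positive — comparisons are internal to the package, so
only consistency matters. The angular histogram (default 20° bins) is
circularly smoothed over 3 bins; peaks are circular local maxima at or
above half the histogram maximum, with plateaus collapsed to their
strongest bin. A single planted gradient yields one peak; a
mirror-symmetric low–high–low pattern yields two peaks ~180° apart.

Azimuth distributions are reported overall and split at CF = 1.5 kHz
(the frequency above which only level cues carry azimuth information);
periphery (±90°) vs each central azimuth is tested with one-tailed
paired t-tests across replicates, Bonferroni-corrected. Contra/ipsi
maps flip the azimuth sign in left-hemisphere structures; 0° voxels are
classed "central" and excluded from contra/ipsi proportions. Group
alignment across real anatomies is out of scope; a voxelwise averaging
utility suffices for co-registered synthetic replicates.

## Validation conditions and problem sizes

The test suite runs the full pipeline at desk scale: 56 + 28 sounds,
60–500 voxels, 200-permutation nulls over 200 repetitions. The
parameter-recovery check plants 500 on-grid voxels and requires ≥ 90%
exact (CF bin, azimuth) recovery; it runs at response noise sd 0.02
(amplitude SNR ≈ 35). That level was chosen as the clean-recovery
regime after characterizing the recovery curve: recovery is limited by
the collinearity of smooth natural-sound profiles within the 6-bin
joint space (adjacent frequency bins correlate strongly across sounds)
rather than by noise alone, and the check validates the fit/reshape/
argmax machinery, not field-realistic sensitivity. Real single-voxel
fMRI betas are far noisier than any level used here, which is precisely
why the empirical literature reports identification accuracies near
0.56–0.60 rather than 1.0.

## What passing tests do not show

The generator draws responses from the same linear model family the
analysis fits, with iid Gaussian noise and exactly balanced designs.
Passing recovery tests therefore demonstrates correctness of the
machinery, not robustness to HRF mismatch beyond scale/latency, serial
correlations, motion artifacts, draining-vein displacement, partial
voluming, or anatomical misalignment — none of which are modelled.
Binaural fixtures impose idealized frequency-independent delays and
piecewise-constant level differences; real reverberant recordings mix
both cues across frequency.
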