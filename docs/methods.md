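# Methods

## Model and procedure

The package implements a speaker-modeling approach to dysarthric speech
classification. Each recording is described not by pooled feature
statistics but by how a reference density model must be deformed to fit it:
a universal background model (UBM) — a diagonal-covariance Gaussian mixture
p(x|λ) = Σᵢ wᵢ pᵢ(x) trained on frames from healthy-control speech — is
MAP-adapted to the recording's frames, and the adapted means and diagonal
covariances are stacked into a fixed-length supervector (2·M·D entries for
M components and D features). Supervectors are then classified with
RBF-kernel SVMs.

Adaptation is a single MAP pass (classical GMM-UBM practice; the pass count
is configurable). With soft counts nᵢ = Σₜ Pr(i|xₜ) and the normalized
first/second moments Eᵢ(x), Eᵢ(x²), every parameter group is interpolated
between its UBM value and the data estimate through
αᵢ = nᵢ/(nᵢ + r). All three groups (weights, means, variances) are adapted
with a single shared relevance factor r = 16; mean-only adaptation is
available as a flag. Components receiving zero posterior mass are skipped
outright — exactly equivalent to αᵢ = 0 but immune to the floating-point
cancellation in the variance update. Adapted variances are floored at the
UBM's variance floor.

## Feature dimensions

* **Articulation (58)** targets the initiation of vocal-fold vibration:
  22 Bark band energies (Traunmüller's critical-band mapping, 22 contiguous
  bands on 0–8 kHz, natural-log energies floored at 1e−10) and 12 MFCCs
  (26-filter mel bank, DCT-II, c₀ excluded) with regression Δ/ΔΔ
  (width 2, edge replication), on three 40 ms frames (20 ms shift) of each
  80 ms unvoiced→voiced onset segment. Offsets (voiced→unvoiced) are not
  extracted; onsets discriminate at least as well and halve the work.
* **Phonation (7)**, per voiced segment: mean absolute first and second
  frame-to-frame F0 differences (Hz), jitter and shimmer (mean absolute
  consecutive period/amplitude difference over the mean, %), the 11-point
  APQ and 5-point PPQ (each value against the mean of its centered
  neighborhood; the neighborhood shrinks to all available cycles when a
  segment has 5–10 of them), and segment log energy (dB). Segments with
  fewer than 5 detected cycles are dropped from phonation only. Glottal
  cycles are marked at positive-going zero crossings of the signal
  lowpassed just above the segment's median F0, gated to [0.6, 1.6] of the
  expected period.
* **Prosody (13)**, per voiced segment with ≥ 6 frames: duration (s), six
  coefficients (ascending powers, time normalized to [0, 1]) of a
  least-squares degree-5 fit to the F0 contour, and the frame-energy
  contour's values at six equally spaced nodes — the coefficients of its
  degree-5 Lagrange interpolant. F0 stays in Hz (no semitone conversion);
  this is a known limitation, as Hz-scale coefficients conflate speaker
  register with contour shape.

## Segmentation

F0 is tracked by Praat-style autocorrelation: 40 ms Hann-windowed frames
every 10 ms, FFT autocorrelation normalized by the window's own
autocorrelation, peak search in [1/fmax, 1/fmin] with parabolic
interpolation. Defaults fmin = 60 Hz, fmax = 400 Hz bracket adult speech;
the voicing threshold is 0.45 on the corrected peak, and frames whose peak
amplitude falls below 3% of the recording's global peak are forced
unvoiced (after DC removal, "silence" is a small constant, and a frame
straddling it and true zero padding is a step function with deceptively
high normalized autocorrelation).

Voiced segments are maximal voiced-frame runs mapped to samples as
[first_frame·hop, last_frame·hop + frame_len); the 40 ms minimum run
duration is measured on that span, so a single voiced frame survives —
anything shorter could not host one analysis frame. Onset borders are
placed at the first frame of a voiced run whose preceding 40 ms of frames
are unvoiced; borders within 40 ms of either signal edge are dropped rather
than zero-padded, since padding would leak silence into the Bark energies.
Indexing is 0-based with half-open intervals throughout.

## EM fitting

UBMs are fit by a hand-written EM loop for diagonal mixtures:
k-means++ centers (seeded, on a ≤ 5000-frame subsample) with
hard-assignment initialization of weights and variances; per-dimension
variance floor at 1e−4 of the data variance; convergence when the relative
change of the mean log-likelihood drops below 1e−5 or after 200 iterations;
components whose soft count collapses are re-seeded at the frames with the
lowest model density. The per-iteration mean log-likelihood trace is stored
on the fitted model and is non-decreasing (up to 1e−8 slack from the
variance floor). M = 1 short-circuits to the closed-form maximum-likelihood
solution.

## Evaluation protocol

Stratified 10-fold cross-validation repeated 10 times, with one master seed
deriving per-repetition fold seeds. Inside each training fold, in order:
z-score normalization (train statistics only; zero-variance columns map to
0), optional PCA keeping the fewest components reaching 90% cumulative
variance, then a grid search over
C ∈ {0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 5, 10, 50, 100, 500, 1000} and
γ ∈ {0.0001, 0.001, 0.01, 0.1, 1, 10, 100, 1000} (the printed grid
endpoints with decade/half-decade interiors) by inner 5-fold accuracy. The
winner is refit on the whole training fold and scored on the held-out fold.
RBF kernels are precomputed per (fold, γ), which keeps the full 104-point
grid under the 10×10 protocol affordable on one CPU. Inner-CV candidate
scoring uses libsvm's native one-vs-one voting (identical to the binary
case when there are two classes); the final per-fold model is one-vs-rest
for ≥ 3 classes, matching the reported tri-class scheme.

Accuracy is reported as mean ± SD **over repetitions** (never over folds);
confusion matrices pool every held-out prediction. Bi-class sensitivity/
specificity use PD as the positive class; tri-class values are
macro-averaged one-vs-rest (accuracy is the primary tri-class metric).
Selected hyperparameters are the mode over all folds × repetitions, ties
broken toward smaller C, then smaller γ — the simpler model. The mixture
size M is an outer sweep; only the best-M row is reported. Whether
hyperparameters are selected inside or outside the reported CV changes the
optimism of the estimate; here selection is fully nested, so reported
accuracies carry no grid-search optimism.

Early fusion concatenates the per-recording supervectors in the fixed
order articulation | phonation | prosody; recordings missing any dimension
are excluded and counted.

## Synthetic cohorts

The generator is source-filter-lite: utterances alternate bandpassed
(2–6 kHz) noise bursts with harmonic voiced nuclei synthesized cycle by
cycle via continuous phase accumulation (cycle boundaries fall on
fractional samples; rounding periods to whole samples would alternate
between two lengths and inject a spurious subharmonic that an
autocorrelation tracker happily locks onto). Injected jitter/shimmer are
i.i.d. per-cycle perturbations of period and amplitude, so the perturbation
measures have known targets.

Class templates (defaults, per utterance: 6 syllables of 60 ms gap +
100 ms burst + 200 ms nucleus):

| parameter | HC | PD-like | ET-like |
|---|---|---|---|
| base F0 (Hz) | 130 | 125 | 140 |
| F0 drift range (Hz) | 30 | 8 | 35 |
| tremor rate / depth | – | – | 5 Hz / 0.08 |
| amplitude modulation | 0.02 | 0.02 | 0.20 |
| onset rise (ms) | 10 | 60 | 10 |
| jitter / shimmer inject (%) | 0.5 / 2 | 1.5 / 5 | 1.0 / 3 |
| voiced level | 1.0 | 0.55 | 1.0 |

The hypokinetic profile encodes monopitch, soft slow onsets and reduced
loudness; the hyperkinetic profile encodes 4–8 Hz F0/amplitude tremor with
wide pitch excursions. Cohorts add lognormal subject-level random effects
(SD 0.10 on log parameters) around the templates. What the generator does
**not** emulate: vocal-tract resonances and coarticulation, phonotactics of
any language, recording-channel variability, severity gradation within a
class, or correlated symptom profiles. Passing tests therefore demonstrate
that the pipeline recovers the class structure its features are designed to
capture when that structure is present — not that clinical PD/ET/HC cohorts
are separable at the same rates.

## Problem sizes and numerical choices

The end-to-end evaluation uses 150 subjects (50 per class, mirroring a
50/50/50 clinical cohort), M = 4 supervectors for the protocol-scale runs,
and the full C/γ grids under 10×10 CV; the M sweep itself is exercised at
smaller scale. Tolerances: weight sums to 1e−10; brute-force density and
statistics agreement to 1e−9; EM monotonicity slack 1e−8. Degenerate
inputs: all-zero recordings pass through with a silence flag; empty onset
lists give 0×58 matrices; recordings with no frames in a dimension raise
with the recording id and are excluded (and counted) from fusion.

## Known limitations

- The F0 tracker has no octave-cost term or Viterbi smoothing; occasional
  halving errors at voicing boundaries inflate |ΔF0| for all classes alike.
- Measured jitter/shimmer sit above the injected values (segment-edge
  cycles, filter transients); comparisons across classes remain valid.
- Phonation log energy is per segment, not per frame; a per-frame variant
  would change the phonation row count contract.
- The generator's class separation is deliberately strong; accuracy on it
  upper-bounds nothing about clinical recordings.
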