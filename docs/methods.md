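# Methods

## Problem and data model

An auditory brainstem response (ABR) is a scalp-recorded potential evoked
by a brief acoustic stimulus, observed here as a 10 ms post-stimulus
voltage trace sampled on a canonical grid of 244 points (dt = 10/244 ms ≈
41 µs). In rodents it shows five characteristic positive waves within the
window; wave 1 reflects auditory-nerve output. Recordings are indexed by
subject, stimulus frequency (kHz) and stimulus level (dB). The family of
recordings for one subject × frequency across descending levels — a
*stack* — is the unit at which a hearing threshold is defined: the
quietest level at which a response is present.

The grid constant matters: the three refinement parameters 0.4098,
0.6557 and 0.2869 ms are exactly 10, 16 and 7 samples of this grid, so
all window arithmetic is integral. Traces sampled differently are
truncated to 10 ms and resampled: piecewise-linear interpolation when
downsampling, a natural cubic spline when upsampling. Both branches
reproduce polynomials of degree ≤ 1 exactly, which the tests pin against
brute-force interpolation oracles.

## Peak detection

Peak finding is a two-step procedure:

1. **CNN initial guess.** A small 1-D CNN (two blocks of convolution →
   batch norm → ReLU → max pool → dropout; then two dense layers)
   regresses the continuous wave-1 peak index from the per-waveform scaled
   trace (z-score across timepoints, then min-max to [0, 1]). Targets are
   divided by 243 during training for loss stability. Squared-error loss,
   Adam (lr 1e-3), batch 64, early stopping on validation loss with
   patience 25 and best-epoch weight restoration. Architecture
   hyperparameters (channels 16→32, kernels 9/5, pool 2, dropout 0.25,
   64 hidden units) are this package's choices and are config-exposed.
2. **Local-extremum refinement.** The trace is smoothed with a normalized
   Gaussian kernel (σ = 1 sample, truncated at 4σ, reflect padding) and
   scanned for local maxima starting 10 samples before the rounded CNN
   index. Among maxima closer than 16 samples the higher survives
   (`scipy.signal.find_peaks(distance=16)` semantics); the first five
   survivors in time order are waves 1–5. Local minima are found the same
   way with a 7-sample separation, and trough *k* is the first minimum
   after peak *k* (and before peak *k*+1 when present). If fewer than five
   maxima exist before 10 ms, later waves are reported absent rather than
   relaxing the separation; a trace with no maximum at all yields a
   "not-found" result, not an exception.

All reported voltages are read from the **unsmoothed** trace at the found
indices, because smoothing attenuates amplitudes. Wave-1 latency is
`peak_index · dt`; wave-1 amplitude is peak-minus-trough voltage.

The network layers themselves (convolution, batch norm, pooling, dropout,
dense, Adam) are implemented in numpy with explicit forward/backward
passes and are verified against finite-difference gradients in the test
suite. At this input size (244 samples, a few thousand training rows) CPU
training takes a few minutes.

## Threshold estimation

A binary classifier scores each waveform as supra-threshold (positive
class) or noise-only. Features are the 244 stack-scaled voltages only —
stimulus level and frequency are deliberately withheld so the model
cannot learn the threshold from the dB label itself. Stack scaling pools
every sample of the stack through one affine map (z-score then min-max),
preserving relative amplitudes across levels.

Three families are provided:

* **CNN** — three conv blocks, two dense layers and a sigmoid head,
  trained with sample-weighted binary cross-entropy on the unaligned
  stack-scaled traces;
* **XGBoost** and **logistic regression** — flat feature views that get
  time-warp-aligned traces (below) before scaling, since they cannot
  model the level-dependent latency shift convolutionally.

The stack threshold is read off the per-level binary calls (score ≥ 0.5
by default; the operating point is configurable because no canonical
value exists). The default **literal** rule returns the quietest level
called positive; the optional **contiguous** rule returns the quietest
level of the positive run that starts at the loudest level, which is
robust to an isolated false positive deep below threshold. All-negative
calls yield the no-response sentinel (`NR` in CSV output). Both rules are
verified against an exhaustive enumeration oracle over all 2⁶ call
vectors and are monotone: flipping any call to positive never raises the
estimate.

## Time warping

Alignment of a stack is landmark-guided piecewise-linear warping: up to
five prominent smoothed peaks per waveform (prominence at least 10% of
the *reference* waveform's span, so noise-only members yield no
landmarks) are matched in time order to the reference's landmarks
(default reference: the loudest level), and a monotone piecewise-linear
map with fixed endpoints re-parameterizes the time axis. Voltages are
re-evaluated by linear interpolation at the warped times, so amplitudes
change only by interpolation error (< 2% of the span in tests). When
landmark matching fails (crossing landmarks), a classic O(n²)
dynamic-time-warping fallback produces the monotone map; flat or
landmark-free waveforms keep the identity warp. A principled functional
registration (e.g. square-root-slope alignment) would be a reasonable
alternative; the contract here is only monotonicity, fixed endpoints and
variance reduction of aligned landmarks, which the simpler construction
satisfies and the tests verify.

## Training and evaluation machinery

* **Splits** are always by subject, per source: 80% of each source's
  subjects to training, 20% to test, then 20% of the training subjects to
  validation (round to nearest, at least one subject per partition;
  sources with fewer than three subjects are rejected).
* **Source balancing**: per-sample loss weights `w = N/(S·n_source)`
  equalize each source's total contribution; per-source weight sums agree
  to 1e-12 by construction.
* **Augmentation** doubles the training matrix with exactly one copy per
  original — noise injection, elastic (cubic-spline control-point jitter,
  ±2 samples), or time shift (±3 samples), drawn uniformly per sample.
  Magnitudes live on the scaled [0, 1] signal and are config-exposed.
  The peak regressor uses noise injection only: warping or shifting a
  copy moves the true peak away from its positional label.
* **Early stopping** halts at the first run of `patience` (default 25)
  consecutive epochs without strict validation-loss improvement and
  restores the best epoch's weights.
* **Metrics**: accuracy/TPR/FPR/TNR at the operating point; AUCROC
  (trapezoidal, equal to tie-aware pairwise concordance) and AUCPR
  (step-integrated average precision) via scikit-learn; RMSE/MAE/mean
  signed error ± SEM for peak metrics; within-k-dB agreement for
  thresholds (a pair with exactly one no-response counts as a miss, two
  no-responses as a hit); two-sample proportion z-tests with optional
  Bonferroni correction. Bootstrap CIs are unpaired percentile intervals
  (2,000 seeded resamples) — the choice of an unpaired bootstrap is this
  package's own.

## Synthetic data generator

The simulator produces stacks with known ground truth so that every stage
is trainable and verifiable at desk scale. Each supra-threshold waveform
is a sum of five biphasic wavelets: a positive Gaussian lobe (σ = 0.15 ms)
at the wave's latency and a negative lobe (0.7× the height, σ = 0.18 ms)
0.3 ms later, plus white Gaussian recording noise (default 0.2 µV RMS).
Defaults emulate a murine protocol: levels 90→10 dB in 5 dB steps, base
latencies 1.5/2.5/3.4/4.4/5.3 ms at 90 dB lengthening by 0.01 ms per dB
of attenuation, peak amplitudes up to 3/1.8/2.2/1.4/1.0 µV growing
sigmoidally (slope 0.1 dB⁻¹) above a per-stack threshold drawn uniformly
from the 5 dB grid in [20, 55] dB. Below threshold the signal is noise
only — a hard gate, which makes the classification target exact.
Per-subject random effects (±10% latency, ±20% amplitude) make
subject-level splits meaningful; subjects can be assigned to "sources"
with different native sampling rates (e.g. 195 or 488 points / 10 ms) to
exercise resampling and per-source weighting. Wave spacing always
exceeds the 16-sample peak-separation constant, so the refinement problem
is well posed.

Two conventions are worth stating explicitly:

* **Latencies are quantized to the canonical grid**, so ground-truth peak
  indices are well defined at the sample level.
* **Truth indices follow the measurement convention of the detector**:
  the argmax/argmin of the σ = 1-smoothed noise-free trace. The raw and
  smoothed discrete extrema can disagree by one sample on near-ties
  (the overlapping trough lobe skews the peak sub-sample position), so an
  index truth defined on the raw trace would be ill-posed. Truth
  *voltages* are read from the unsmoothed clean trace, mirroring how the
  detector reports amplitudes.

What the generator does **not** emulate: cochlear micromechanics,
frequency-dependent tuning beyond a scalar latency offset, non-Gaussian
or structured noise (mains hum, movement artifacts), level-dependent wave
shape changes, or missing levels. Passing recovery tests on this data
therefore demonstrates that the algorithms are implemented correctly and
can learn the latency/amplitude/threshold structure they target — not
that trained-on-synthetic models transfer to real recordings.

## Recovery experiments (desk scale)

`abrkit.experiments` runs the two end-to-end experiments the acceptance
script reports:

* **Peak recovery**: 90 simulated subjects × 3 frequencies × 17 levels;
  subjects split 80/20/20; ~2,000 supra-threshold training waveforms
  doubled by noise augmentation; 150 epochs max (patience 25). Evaluation:
  500 held-out waveforms with wave-1 SNR ≥ 3 (true amplitude at least 3×
  the noise SD), scored end-to-end (scale → CNN → refine).
* **Threshold recovery**: ~70 training stacks (with validation subjects
  held out) from one cohort; evaluation on 60 stacks from an
  independently seeded cohort; CNN classifier, 40 epochs, literal rule.

These sizes keep each experiment within a few minutes on one CPU while
leaving clear margins on the recovery bounds (measured at seed 1:
latency MAE ≈ 0.01 ms against a 0.1 ms bound; amplitude RMSE ≈ 0.32 µV
against 0.4; thresholds 100% within 5 dB).

## Numerical choices and edge cases

* Constant (zero-variance) waveforms scale to all 0.5 with a logged
  warning instead of erroring mid-batch.
* Cubic-spline boundary condition is natural (zero second derivative);
  beyond the last native sample the spline's natural extrapolation is
  used, preserving degree-≤1 exactness.
* Score ties at the operating point count as positive (`score ≥ 0.5`).
* Plateaus in the extremum scan resolve to a single peak via
  `find_peaks`' plateau handling; equal-height neighbors within the
  separation window collapse to one peak.
* The metrics CSV writes 6 decimals; write→read round-trips agree to
  1e-6. `NR` encodes no-response.
* Checkpoints: the peak regressor serializes to a versioned `.npz`
  (arrays + JSON header); the shallow classifiers pickle.

## Known limitations

* Waves 2–5 are detected but not validated against any human truth.
* The approach can fail when latency is far outside the trained range
  (e.g. severe pathology); no mitigation is implemented.
* The threshold operating point (0.5) and tie-handling between positive
  runs are conventions, not fitted quantities; both are configurable.
* The numpy network is CPU-only and single-threaded beyond BLAS; it is
  sized for the 244-sample problem, not a general deep-learning stack.
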