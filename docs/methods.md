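# Methods

## Signal model and preprocessing

A PPG record is a uniformly sampled amplitude series (default 300 Hz) with
subject/period/NRS metadata. Preprocessing applies a second-order Butterworth
low-pass at 8 Hz (equipment noise) and high-pass at 0.5 Hz (baseline wander).
Both are applied forward–backward (`scipy.signal.sosfiltfilt`, odd-reflect
padding), so peak timing is unlagged and the effective magnitude response is
the squared single-pass response. The high-passed signal is half-wave
rectified and squared to emphasize the systolic upstroke.

## Beat detection

Two centred moving means of the squared signal are compared: window W1 =
111 ms (33 samples at 300 Hz, forced odd for symmetry) tracks the systolic
rise, W2 = 667 ms (201 samples) the beat cycle. Candidate blocks are maximal
runs where the short mean exceeds the long mean plus `beta·mean(S)` with
beta = 0.02; `mean(S)` is taken over the whole record so the offset adapts
to overall signal power rather than per sample. Blocks narrower than W1 (in
samples) are discarded as noise. The per-block systolic peak is the argmax
of the *low-passed* signal (so amplitude features reflect pulse morphology,
not the squared transform); valleys are argmins strictly between consecutive
peaks. Argmax/argmin ties break to the earliest index. Edge effects: the
first/last beat of a record can fall in a clipped block and be missed, which
is why detection recall is measured at ~99.7% rather than 100% on clean
records.

## PPI artifact rules

Interval i is flagged when any of the three rules fires:

- T1: `PPIᵢ < m₂₀ − 2σ₂₀` and `PPIᵢ₊₁ > m₂₀ + 2σ₂₀`;
- T2: `PPIᵢ < 0.75·PPIᵢ₋₁` or `PPIᵢ₊₁ < 0.75·PPIᵢ₋₁`;
- T3: `PPIᵢ > 1.75·PPIᵢ₋₁`.

Design choices where the rule set is silent: `m₂₀/σ₂₀` are computed over
the previous up-to-20 *unflagged* intervals and shrink to the available
history early in the series; T1 is skipped with fewer than two history
intervals; boundary intervals skip clauses that need a missing neighbour.
T2's second clause compares the next interval against PPIᵢ₋₁ as stated;
since that subscript is plausibly a misprint for PPIᵢ, the variant is
available via `t2_reference="current"`. Flagged intervals are repaired by
linear interpolation over the interval index (leading/trailing runs take
the nearest clean value); interpolating in index rather than cumulative
time is the simplest reading and is exact for isolated artifacts.

## Features

Seventeen per 5-minute window, stepped by 1 minute (a 14-minute record
yields 10 windows; windows with fewer than 10 beats are dropped):

- geometry: mean peak-minus-preceding-valley amplitude, mean valley→peak and
  peak→valley times (s), and average heart rate from instantaneous
  HR = 60000/PPIᵢ (bpm);
- HRV time domain: AVNN, SDNN (population SD by default), RMSSD (ms), NN20,
  pNN20, NN50, pNN50. pNN denominators use successive-difference pairs (the
  standard HRV convention); the per-interval variant is available;
- HRV frequency domain: the corrected tachogram (interval value at its
  ending beat time) is cubic-interpolated onto a uniform 4 Hz grid,
  mean-detrended, and a single-segment boxcar periodogram is integrated
  (trapezoid) over VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 and total
  0.003–0.4 Hz; plus LF/HF (NaN when HF = 0) and the maximum PSD value in
  0.1–0.25 Hz (respiratory-rate power). 4 Hz resampling is the standard
  choice for short-term HRV; Welch averaging is deliberately not used so the
  estimator matches a bare FFT periodogram. Band powers are kept in raw ms²;
  the later min–max normalization absorbs scale.

## Post-processing

Outliers: per feature, MAD = 1.4826·median|x − median|; any row with a value
at or beyond median ± 2.5·MAD in any feature is removed before splitting.
Zero-MAD features (e.g. NN50 in quiet cohorts) are skipped rather than
removing every off-median row. Min–max normalization is fitted on training
rows only and clipped to [0, 1] elsewhere; a constant training feature maps
to 0. Screening: paired Wilcoxon signed-rank per feature on
(subject, window) matched pre/post pairs for the 2-class protocol, one-way
ANOVA across statuses for 4-class, retaining p < 0.05. No multiple-testing
correction is applied, matching the screening protocol this mirrors.

## Classifiers

The DBN stacks Bernoulli–Bernoulli RBMs (CD-1, momentum 0.9, weight decay
2.9e-4, learning rate 0.08 for weights and both bias sets, batch 104,
pre-training 20 epochs) and fine-tunes the unrolled network — sigmoid units
throughout, one output unit per class, cross-entropy loss — by mini-batch
gradient descent for 800 epochs. Min–max-normalized inputs are treated as
Bernoulli probabilities by the first RBM. The MLP is the identical network
fine-tuned from small uniform (±0.1) random weights; forcing the DBN's
post-pretraining weights into the MLP trainer reproduces its trajectory
exactly, which the tests exploit as an equivalence oracle. The SVM baseline
is `sklearn.svm.SVC` (RBF, γ = 0.05, C = 1) with logistic-squashed margins
(binary) or softmaxed one-vs-rest decision values (multiclass) as scores.
All trainers are deterministic given their seed.

Pre-training epoch count: the reference range is 10–100 with reconstruction
error converging from ~20 epochs; 20 is the default. Fine-tuning defaults
to the top of the 100–800 reference range.

## Ensembles

Bagging trains 50 base classifiers on bootstrap resamples (with
replacement, same size as the training set) and fuses them by majority
vote; vote ties (possible with an even bag) break by the larger summed
class score, then the lower class index, so voting is deterministic and
permutation-invariant. Selective bagging prunes the bag by greedy forward
hill climbing on validation accuracy (best-improvement steps, start from
the best single base model, stop when no addition strictly improves), so
its validation accuracy is never below the best single base model's by
construction. A backward pass is not implemented; forward-only is the
standard ensemble-pruning reading.

## Evaluation

Subjects are the unit of splitting: k near-equal shuffled groups; fold i
tests group i, validates group i+1 (mod k), trains on the rest, so every
subject is tested exactly once and windows never leak across roles. With 78
subjects and k = 6 this gives 52/13/13 subjects → 1040/260/260 windows per
fold. Accuracy is reported per fold and as the mean over folds (pooling is
available); the window is the evaluation unit. ROC curves come from a
threshold sweep (`sklearn.metrics.roc_curve`) with trapezoidal AUC —
verified in tests against a hand-written O(n²) Mann–Whitney pairwise
oracle. AUC uncertainty is estimated by bootstrap resampling of test scores
(default 300 replicates, resamples lacking a class are redrawn) with a
two-tailed one-sample t-test against 0.5; a zero-variance sample takes a
degenerate branch (p = 1 at exactly 0.5, else the floating-point floor).

## Synthetic cohorts

The generator emulates what the pipeline assumes about recovery-room finger
PPG: beats placed by integrating an instantaneous period (mean HR plus
sinusoidal interval modulations at 0.02/0.10/0.25 Hz; intervals floored at
250 ms), an asymmetric pulse per beat (half-cosine rise over `rise_fraction`
of the cycle, exponential fall with time constant a quarter of the fall
span), sinusoidal baseline wander, white Gaussian noise, and ectopic events
that shorten one interval by 40% and lengthen the next to conserve time —
exactly the short/long signature the T2/T3 rules target. Ground-truth PPIs
are defined from the rounded peak indices so
`diff(true_peak_idx)/fs·1000` reproduces them exactly.

Cohorts draw per-subject parameters from class-conditional (mean, SD)
distributions patterned on the reference cohort's reported feature
statistics: heart rate 66.32 ± 10.30 → 69.66 ± 10.28 bpm, pulse amplitude
0.908 ± 0.206 → 0.673 ± 0.489, rise fraction up slightly, and modulation
amplitudes chosen to land SDNN near 40 ms with the LF/HF balance falling
postoperatively. Classes differ only at the parameter level — the pipeline
must recover separability from the raw waveform. Pre/post pairs share a
per-parameter standardized deviate plus 15% within-subject jitter, making
the design paired as in the study. The reported SDs are treated as
between-subject spread, which makes cross-subject classification
deliberately hard (classes overlap heavily); synthetic-cohort accuracies
(~60–80% depending on seed) are therefore not comparable to the reference
clinical accuracies and are only required to beat chance decisively.
Severity grading for 4-class cohorts scales the pre→post shift by
0.5/1.0/1.5 (mild/moderate/severe) — an invented convention, since no
per-severity statistics are reported. The generator does not model the
dicrotic notch, SpO₂, vasomotor drift, or a separate respiration channel
beyond the HF interval modulation; noise is white, not motion-like. Passing
tests therefore demonstrate correctness of the pipeline's mechanics and
recovery of known ground truth, not clinical performance.

## Problem sizes

The default test suite and the reproduction script scale problem sizes to
single-CPU runs: acceptance uses the full 78-subject, 6-fold protocol with
800 fine-tuning epochs; the test suite's end-to-end check uses 20 bags and
the script uses the reference 50. Unit tests use 300–840 s records and
6–16-subject cohorts. These sizes are the package's defaults for desk-scale
verification; all reference hyperparameters (filters, windows, thresholds,
network and ensemble settings) are kept at their stated values throughout.

## Known limitations

- Beat detection assumes a single dominant pulse per cycle; pathological
  morphologies (bigeminy, severe artifacts) are only handled downstream by
  the interval rules.
- The T2 rule as stated flags the interval *preceding* an ectopic as well;
  interpolation restores both, but flag counts overestimate event counts.
- Spectral features on 5-minute windows have coarse (1/300 Hz) native
  resolution; VLF estimates in particular are noisy.
- The generator's class separability is an assumption, not a measurement;
  absolute synthetic accuracies should not be quoted as expected clinical
  performance.
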