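# Methods

This note records the models, conventions and numerical choices behind
`cqtnet`, in the spirit of a model-documentation page: what is assumed,
what is tunable, and what passing the test suite does and does not show.

## Data model

A *chart* is one 40 Hz recording pass of five channels (PPG, blood
pressure, thoracic respiration, abdominal respiration, skin conductance)
with question-onset annotations; three charts form a *series*, the unit
that receives the final decision. Each chart carries exactly three
(comparison, relevant) question pairs; irrelevant questions are stored but
never scored. Onset times in seconds are converted to sample indices by
`floor(onset_s × 40)` — the floor is an arbitrary but reproducible
convention. The on-disk format (CSV trace + JSON sidecar per chart, CSV
manifest per dataset) is this package's own: it is human-inspectable,
diff-able and round-trips bit-exactly at 17 significant digits.

## Synthetic sessions

Real CQT examinations are sensitive and essentially never public, so the
generator in `signal_sim` is a first-class part of the package. It
emulates the *structure* of an examination (series → 3 charts → 3 question
pairs, one irrelevant opener per chart, comparison always preceding its
relevant partner at a fixed 25 s spacing) and the *direction* of the
sympathetic-arousal responses:

| channel | model | arousal response |
|---|---|---|
| skin conductance | tonic level 8 + phasic transients | bi-exponential rise 0.75 s / decay 4 s, gain 0.6/unit |
| PPG | two-harmonic pulse train at 1.2 Hz | envelope drops ∝ arousal (vasoconstriction) |
| blood pressure | baseline 90 | slow rise ∝ arousal (rise 2 s / decay 12 s) |
| respiration ×2 | sinusoids at 0.25 Hz, abdomen lagged 0.3 rad | amplitude suppressed ∝ arousal |

Responses start 1.5 s after question onset. Every channel receives white
noise (`noise_sd`, scaled per channel so 1.0 ≈ response-sized noise) and a
Gaussian random-walk drift (`drift_sd`). Event amplitudes carry lognormal
trial-to-trial jitter (σ = 0.2).

The deception signal is a single dial: under the deceptive condition the
expected relevant-question amplitude is `(1 + effect_size)` times the
comparison amplitude; under the truthful condition the ratio is 0.8. At
`effect_size = 0` relevant and comparison responses are exchangeable, the
no-signal null. A model-free oracle statistic (`scr_contrast`: mean
baseline-corrected skin-conductance elevation, relevant minus comparison
windows) is monotone in the effect size and is used by the tests to verify
the generator independently of the classifier.

All amplitudes, time constants and gains are simulator conventions chosen
to look like textbook phasic physiology — no quantitative claims about
real polygraph subjects are attached to them, and per-segment z-scoring
makes their absolute units irrelevant downstream. What the simulator does
**not** model: motion artifacts, countermeasures, habituation across
charts, demographic variation, or channel-specific sensor noise spectra.
Passing tests therefore demonstrate that the pipeline recovers a
physiologically shaped, event-locked arousal contrast — not field
accuracy on human data.

## Preprocessing

Window length is 22.4 s (896 samples) per question — roughly the longest
conventional human-scoring reaction window plus a short margin — chosen so
that the joined 1792-sample segment drives the convolution stack to
exactly 89 time steps (below). The offset-join is evaluated as
`(second − second[0]) + first[−1]` so the junction sample equals the
preceding sample *exactly* in floating point. Each channel of the joined
segment is z-scored per segment; a zero-variance channel maps to zeros
rather than NaN.

## Network and training

The classifier is implemented from scratch on NumPy/SciPy (forward,
backward, Adam), since the architecture itself is the package's core.
Structural facts, asserted at build time and in tests:

* valid (un-padded) convolutions, stride 1; max-pool size 2 stride 2 with
  floor on odd lengths, giving the time chain 1792 → 861 → 406 → 188 → 89;
* per-branch blocks: conv(filters = kernel = 70, 50, 30, 10) + ReLU +
  pool + dropout(0.50, 0.50, 0.25, 0.25), one independent branch per
  channel (no weight sharing);
* merge = feature-axis concatenation (5 × 10 → 50), the only merge that
  makes an 89 × 50 LSTM output dimensionally consistent;
* LSTM: 50 hidden units, tanh, all time steps returned, forget-gate bias
  1, Glorot input weights, orthogonal recurrent blocks;
* head: flatten (89 × 50 = 4450) → dense 50 ReLU → dense 2 softmax; class
  index 1 is "deceptive" and the scalar probability reported everywhere is
  its softmax mass.

Convolutions run on one of two numerically equivalent paths: a direct
im2col GEMM when the patch width `C_in·K ≤ 512` (transform overhead beats
FFTs there) and an FFT path otherwise (rFFT length `next_fast_len(L)`,
spectral products evaluated as stacked complex GEMMs; with N ≥ L the
circular correlation is wrap-free on the retained lags). Both paths are
verified against `scipy.signal.correlate` and central finite differences
in float64; production arithmetic is float32 with float64 Adam moments.
The first conv layer of each branch skips its input gradient.

Training: Adam (lr 0.0015, β = 0.9/0.999), batch 64, mean softmax
cross-entropy; dropout active only in training. Default schedule is up to
100 epochs with early stopping (patience 10) on a 10 % validation split
carved from the training data, best parameters restored; setting
`validation_fraction = 0` disables early stopping for fixed-budget runs.
All randomness (init, shuffling, dropout, splits) flows from explicit
integer seeds, so identical calls give bit-identical parameters;
`train` never raises on finite data but aborts on a non-finite loss.

## Scoring

Series score = sum of the nine question-set probabilities ∈ [0, 9]. The
Utah cut-offs ±6 on the −18…+18 scale map affinely to thresholds 6 and 3;
the mapping keeps an explicit `score_min` term so other score ranges
reuse it. Decisions use strict inequalities outward — a score exactly on
a threshold is inconclusive, the conservative reading of "above"/"below".
Inconclusive outcomes are tabulated separately, never as correct or
incorrect.

## Evaluation

`kfold_split` deals each label class (seeded shuffle) to consecutive
folds round-robin, the deal position carrying over between classes; this
yields per-class *and* overall fold sizes differing by at most one, which
off-the-shelf stratified splitters do not guarantee jointly. The default
unit is the series (all nine question sets share a fold, so no model is
ever tested on a participant it trained on); `question_set` mode exposes
the plain 9:1 split over all segments. Per-fold recall/precision/F1 treat
deceptive as positive with 0/0 → 0 and a warning; mean ± SD uses the n−1
denominator over the ten folds. Each segment is predicted exactly once
across folds; the pooled probabilities feed the series decision table.

For the no-signal check, the chance reference for F1 is `2pq/(p+q)` where
p is the fold's true-positive rate and q the classifier's own
predicted-positive rate: an uninformative network under heavy dropout
often collapses toward one class, and a fixed 0.5 reference would mistake
that marginal shift for signal.

## Problem sizes in the shipped tests

The cross-validated experiments in the test suite use 24 series
(12 deceptive + 12 truthful, 216 question sets) at effect size 3 with
noise 0.1, and the same at effect size 0, trained for 4 epochs without
early stopping — a budget at which strongly separable data are already
fit nearly perfectly (training cross-entropy falls below 0.02 within
~10 epochs at one batch per epoch, sooner with more batches). The
seeded-determinism and CLI pipeline checks use 6-series datasets. These
sizes are the package's chosen desk-scale experiment; the generator and
harness run unchanged at larger counts (e.g. 42 + 36 series reproduces
the reference arithmetic of 78 series / 702 question sets).

## Known limitations

* Synthetic-only validation; see the generator caveats above.
* Single fixed question schedule per chart; no variable pacing.
* No artifact detection — corrupted charts should be excluded upstream.
* The inference path is CPU-bound NumPy; large-scale retraining would
  want a GPU framework, though the shipped experiments run in minutes.
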