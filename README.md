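# cqtnet

A computerized scoring system (CSS) for comparison-question-test (CQT)
polygraph examinations, built around a deep multichannel time-series
classifier. It takes annotated five-channel polygraph charts —
photoplethysmogram (PPG), blood pressure, thoracic respiration, abdominal
respiration and skin conductance, all sampled at 40 Hz — and produces a
*deception / non-deception / inconclusive* decision per examination
series, replacing the examiner's manual numerical chart scoring.

The package is aimed at researchers in psychophysiology and forensic
signal processing who want a fully reproducible, end-to-end scoring
pipeline: because real polygraph examinations are sensitive and rarely
shared, it ships a synthetic session generator that emulates the CQT data
structure and the sympathetic-arousal responses the test relies on, so
every experiment here runs from scratch on simulated data.

## The method

**CQT premise.** Each chart carries three question *sets*, a (comparison,
relevant) question pair. Deceptive subjects respond more strongly to
relevant questions than to comparison questions; truthful subjects show
the opposite (or equal) pattern.

**Preprocessing.** For each question set, a 22.4 s window (896 samples) is
cut at each question onset, and the two windows are concatenated with an
*offset-join*: the second window is shifted by a constant so its first
sample equals the last sample of the first window, removing the boundary
discontinuity. Each of the five channels is then z-scored, giving a
5 × 1792 segment.

**Classifier.** Each channel feeds its own 1-D CNN of four blocks —
filters (and kernel sizes) 70, 50, 30, 10, ReLU, max-pool 2, dropout
50/50/25/25 % — compressing 1792 samples to 89 time steps of 10 features.
The five branch outputs are concatenated (89 × 50), passed through a
single 50-unit tanh LSTM returning all steps, flattened to 4450 values,
and classified by a 50-unit ReLU layer and a 2-way softmax. Training
minimizes mean softmax cross-entropy with Adam (learning rate 0.0015,
batch 64). The network emits, per question set, the probability p ∈ [0, 1]
that the answer was deceptive.

**Series scoring.** A series is three charts, hence nine question sets;
its score is s = Σᵢ pᵢ ∈ [0, 9]. Decision thresholds come from mapping the
Utah numerical-scoring cut-offs (±6 on the −18…+18 total-score scale)
affinely onto [0, 9]:

    threshold = (cutoff − utah_min) / (utah_max − utah_min) · (score_max − score_min)

giving threshold₁ = 6 (deception) and threshold₂ = 3 (truth): s > 6 ⇒
deception, s < 3 ⇒ non-deception, 3 ≤ s ≤ 6 ⇒ inconclusive.

**Evaluation.** 10-fold cross-validation (9:1), stratified and optionally
grouped so a series never straddles folds, reporting recall, precision
and F1 (mean ± SD over folds) plus a correct/incorrect/inconclusive
decision table per ground-truth group.

## Worked example

```sh
cqtnet simulate --n-deceptive 3 --n-truthful 3 --effect-size 3 \
    --noise-sd 0.1 --seed 9 --out demo/data
cqtnet preprocess --in demo/data --out demo/segments.npz
cqtnet train --data demo/segments.npz --epochs 10 --seed 1 --out demo/model.npz
cqtnet score --model demo/model.npz --data demo/segments.npz \
    --manifest demo/data/manifest.csv --out demo/scores.json
```

The `simulate` step prints `wrote 18 charts / 6 series to demo/data`
(6 series × 3 charts); `preprocess` prints `wrote 54 question-set segments
to demo/segments.npz` (9 question sets per series). Training prints the
epoch count and final cross-entropy — here `trained 10 epochs, final
train loss 0.1650; saved to demo/model.npz`, already low because effect
size 3 with low noise is strongly separable. `demo/scores.json` then
contains, for each series, its summed score and decision, e.g.

```json
{"series_id": "S001", "score": 7.0884213156, "decision": "deception"}
```

(well above threshold 6), together with the per-group decision counts —
for this run all 3 deceptive and all 3 truthful series are decided
correctly with no inconclusives. (Scoring training data, as
here, is only a smoke test; use `cqtnet evaluate --data demo/data --k 10
--seed 9 --out demo/cv` for honest held-out metrics and the
cross-validated decision table.)

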