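# Methods

`egdloc` implements a real-time anatomical-location inference pipeline for
esophagogastroduodenoscopy (EGD) video: a coarse-to-fine per-frame
classification cascade, a fixed-interval frame sampler with a
sliding-window hard-voting smoother, and a frame-level evaluation protocol
designed for second-resolution interval ground truth. Because no public
EGD corpus exists, a synthetic procedure simulator provides every input
the pipeline consumes; the classifier backend is pluggable, with a
confusion-matrix mock standing in for trained CNNs.

## Label taxonomy

Eleven fine classes cover the endoscope's path — esophagus (ES),
gastroesophageal junction (GE), cardia (CR), upper/middle/lower gastric
body (UB/MB/LB), angle (AG), antrum (AT), duodenal bulb (BB), second part
of the duodenum (SD) — plus non-clear (NO) for frames in which no landmark
is identifiable (rapid motion, lens against the mucosa, fluid). Visually
contiguous classes with ambiguous boundaries are merged for the 7-way
primary stage: {ES, GE}, {UB, MB, LB}, {BB, SD}; CR, AG, AT and NO stand
alone. The secondary stage refines a merged part into its members. The
canonical ordering (ES, GE, CR, UB, MB, LB, AG, AT, BB, SD, NO) fixes
serialization and score-vector layout.

## Dataset splitting

The split procedure reflects a corpus with strong class imbalance
(31,403 stills over 11 classes in the reference distribution). Per class
of the task, a fixed quota of records (180 for the primary task; 88 for
the two-class parts; 191 for the gastric bodies) is undersampled into a
balanced test set, and the class's remainder is divided
train:validation = 8:1. The integer rule is
`n_train = round(remainder * 8/9)`, remainder to validation; classes are
processed in canonical order with a seeded uniform shuffle, so the split
is byte-reproducible. The split conserves the manifest exactly (no record
duplicated or dropped).

Distribution-table percentages are **truncated** (not rounded) to one
decimal. Truncation reproduces all printed percentages of the reference
corpus distribution (e.g. 2203/6910 → 31.8, 8815/31403 → 28.0,
3046/8815 → 34.5), which round-half-up does not.

## Classification cascade

A backend is any callable mapping a frame to a normalized score vector
over a label space. The cascade takes the primary backend's argmax; when
it is a merged part, that part's secondary backend picks the fine label,
otherwise the singleton passes through. Combination is by **sequential
argmax**, not by multiplying stage probabilities — the secondary model is
applied to the primary's categorical decision. Argmax ties break to the
lowest canonical index, making inference deterministic.

Backends included:

- **Mock (confusion-matrix) backend** — the acceptance surface. Frames
  carry their true label; the prediction is sampled from the true label's
  row of a row-stochastic confusion matrix (seeded). This reproduces a
  trained CNN's *error structure* without weights or images.
- **Trainable scikit-learn backends** (logistic regression, small MLP on
  downsampled pixels). These are CPU stand-ins for the heavyweight CNN
  architectures (ResNet101/InceptionV3/InceptionResNetV2 with ImageNet
  transfer at 224/299-pixel inputs) that would fill this slot in a
  clinical deployment; no deep-learning framework is assumed. The recorded
  config keeps the CNN training recipe (300 epochs, batch 32, SGD at 1e-5,
  reduce-on-plateau factor 0.1 / patience 10) for provenance; only
  `epochs` and `learning_rate` influence the sklearn stand-ins.
  Secondary backends train only on images of their own part.

## Video sampling and hard-vote smoothing

Classifying every frame of 60 fps video is redundant (adjacent frames are
nearly identical) and unstable (each frame is judged independently). The
sampler takes every 20th frame — 3 inferences per second — and each
sampled prediction is pooled with the previous k−1 into a sliding window
whose modal label (hard vote) is the emitted location; k = 7 by default.

Numerical choices:

- **Tie-break:** the tied label seen most recently wins, favoring the
  newer region while the endoscope transits a boundary.
- **Warm-up:** the first k−1 outputs vote over however many predictions
  exist, so every sampled frame yields an output (a real-time
  requirement); k = 1 is the identity.
- **NO votes:** non-clear participates in voting like any other label;
  exclusion is the evaluator's concern.
- Frame indices are 0-based; sampling starts at frame 0.

For a stationary segment with i.i.d. per-frame accuracy p, the vote over
k frames is correct with probability `sum_{i>ceil(k/2)-1} C(k,i) p^i
(1-p)^(k-i)`; at p = 0.8, k = 7 this is 0.9667, the noise-suppression
bound the tests verify by Monte Carlo. After a clean label change the
vote flips within ceil(k/2) samples (the lag cost of smoothing).

## Frame-level evaluation

Ground truth for video is labeled in whole seconds because anatomical
boundaries are visually ambiguous. Per-frame truth expands the intervals;
every frame within an **ambiguity window** — `round(3 s × fps)` = 180
frames at 60 fps, centered on each transition boundary — accepts either
adjacent label. When two boundaries are closer than the window width
(e.g. a 1.5 s non-clear burst), a frame joins the window of its *nearest*
boundary only (tie → earlier boundary), so an allowed set never exceeds
two labels. Interval lists must tile the video without gaps or overlaps;
violations raise with the offending boundary.

Scoring is frame-by-frame, one-vs-rest per class:

- A frame whose predicted label is NO is **excluded** from scoring — the
  model declared the view uninterpretable — unless the truth itself
  allows NO there, in which case the NO vote counts as correct.
- A prediction is correct iff it is in the frame's allowed set. The voted
  class takes the TP; on an incorrect frame each allowed class takes an
  FN and the voted class an FP; everything else is TN. Per class,
  TP+TN+FP+FN equals the evaluated frame count.
- Metrics: accuracy (TP+TN)/total, precision TP/(TP+FP), recall
  (= sensitivity) TP/(TP+FN), specificity TN/(TN+FP), F1 the harmonic
  mean of precision and recall. Undefined ratios (0/0) are NaN, never 0.
  (A published variant of the accuracy formula omits TN from the
  numerator; the standard form is used here.)
- Summary rows are **macro** averages over classes with at least one
  positive frame (TP+FN ≥ 1), NaN metrics skipped; the reported accuracy
  is micro (correct/evaluated). Balanced test sets make macro and
  weighted averages nearly coincide; macro is the simpler convention.

`window_sweep` re-smooths one raw stream at several window sizes
(default 4/7/10/13) and evaluates each, for choosing k.

## Synthetic stated world

The simulator emulates a complete EGD procedure:

- **Trajectory:** an insertion pass through the ten anatomical classes in
  order, then a withdrawal pass in reverse (exercising label re-entry),
  19 segments total. Segment durations are seeded uniform weights in
  [0.5, 1.5] rescaled to 177 s — matching the reported ~2 min 57 s
  average procedure length — at 60 fps (10,620 frames).
- **Non-clear bursts:** a Poisson process at 2 bursts/min, 1.5 s each,
  overwrites the underlying anatomy with NO — brief uninterpretable
  stretches as occur in practice. Rate and duration are this package's
  choice of a realistic regime (a few short obscured episodes per
  procedure); they are part of the stated world, not tuning knobs.
- **Emission:** predictions are drawn from an 11×11 confusion matrix with
  0.8 diagonal; off-diagonal mass splits equally between the class's
  neighbors along the traversal chain and NO, mimicking the reported
  confusability of visually contiguous regions (the gastric body trio
  especially). The NO row spreads its error uniformly.
- **Rendering:** procedurally textured frames (distinct hue and texture
  frequency per class; NO blurred and low-contrast) exist solely so the
  trainable backends have separable toy inputs.
- **Corpus fixture:** a manifest whose per-class counts equal the
  reference distribution exactly (total 31,403), for split arithmetic.

What a green suite does and does not establish: the simulator validates
the *mechanics* — sampling arithmetic, vote/oracle equivalence, binomial
noise suppression, truth construction, exclusion accounting, and that
smoothing strictly improves accuracy under i.i.d.-ish confusion noise. It
does not reproduce clinical performance numbers: real CNN errors are
temporally correlated (a bubble obscures many consecutive frames), class
difficulty is highly uneven, and real procedures dwell and revisit
irregularly. Published video-level F1 in the 60% range is therefore out
of reach of any desk-scale check and is not asserted anywhere.

## Known limitations

- Hard voting retains the previous location during long obscured
  stretches instead of switching to non-clear; temporally correlated
  noise is not simulated.
- Splitting is image-level, not patient-level.
- No bootstrap confidence intervals; no ROC/AUC on video streams.
- The sklearn backends are functional stand-ins, not competitive models.
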