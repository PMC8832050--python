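# Methods

This note documents the models, algorithms, and design choices behind the
package, in the order data flows through the pipeline.

## Problem setting

Myocardial infarction (MI) alters the 12-lead ECG in ways that localize the
injured wall: ST-segment deviation, pathological Q waves and T-wave changes
appear preferentially in the leads that face the infarct (precordial V3/V4
for anterior, II/III/aVF for inferior, I/aVL/V5/V6 for lateral walls;
posterior infarcts show reciprocal ST depression in V1/V2). The package
classifies individual heartbeats — fixed 651-sample, 12-lead windows at
1 kHz — into eleven categories: healthy (H) plus ten infarct localizations
(A, AL, AS, I, IL, IP, IPL, L, P, PL), or into two categories (HC vs MI)
for plain detection. Alongside the class decision it reports *which leads
the model used*, through squeeze-excitation (SE) attention gates and
Grad-CAM relevance maps.

## Preprocessing

* **Baseline removal.** A running median over 333 samples (333 ms at 1 kHz)
  estimates the baseline per lead and is subtracted. The median window
  passes the slow wander (respiration, electrode drift, ~0.1–0.5 Hz) while
  ignoring the brief QRS excursions. Edges use reflect padding — the
  filter is then length-preserving and exactly nulls constant signals. An
  even window parameter is rounded up to the next odd value.
* **R-peak detection.** A Pan–Tompkins-style front end on lead II:
  band-pass 5–15 Hz (2nd-order Butterworth, zero-phase), differentiate,
  square, 150-ms moving-window integration. Candidates are peaks of the
  integrated energy above an adaptive threshold (25% of the 98th
  percentile — robust to a few extreme beats) with a 200-ms refractory
  period, then refined to the local maximum of the raw baseline-corrected
  lead within ±50 samples. The detection lead, refractory period, band and
  refinement radius are configurable.
* **Segmentation.** Each beat window spans 250 samples before the R-peak
  through 400 after (651 total); the R-peak always sits at row 250. Beats
  whose window would cross a record boundary are dropped and counted, never
  padded — the classifier sees only complete, aligned windows.
* Records at other sampling rates are polyphase-resampled to 1 kHz before
  segmentation, because all window constants are in samples at 1 kHz.

## The network

Input is a 651 × 12 × 1 array (time × leads × value). The architecture is:

1. **Lead-stage squeeze-excitation** over the 12-lead axis. Squeeze:
   global average over time; excitation: dense(12→3) → ReLU → dense(3→12)
   → logistic; reweight: multiply each lead by its gate. The gates are the
   model's per-lead attention and are exposed for inspection.
2. **Three convolutional branches**, one per kernel length (3×1, 5×1, 7×1).
   All convolutions run along time only, stride 1, "same" padding — a
   single kernel is shared across leads, so the branches' parameter counts
   are independent of the number of leads (verified by test). Each branch:
   a stem convolution to F channels, one pre-activation residual unit
   (Block1), a stack of further units (Block2), a channel-wise SE over the
   F feature channels, and global average pooling over time and leads.
   A residual unit is BN → ReLU → conv, twice, plus an identity skip
   (1×1 projection only if channel counts differ).
3. **Fusion and head.** The three pooled branch vectors are concatenated
   and mapped by a single dense layer to class logits; softmax gives
   probabilities.

Width parameters (filters per branch, SE reduction r, Block2 depth) are
architectural free parameters exposed in `EcgNetConfig`; defaults are 32
filters, r = 4, three Block2 units. The lead-stage SE is applied to the raw
input (before any convolution), which makes the "weight of each lead"
reading literal.

The network, its training loop, and backpropagation run on a compact
reverse-mode autodiff engine written on NumPy (`ecgnet.nn`), built for this
package: time-only convolutions (im2col-free GEMM formulation with
cache-resident per-record tap buffers, optionally accelerated by small
numba kernels with a pure-NumPy fallback), batch normalization with the
fused two-reduction backward form, SE blocks, dense layers, and a softmax
cross-entropy head. Keeping the engine in-repo makes every gradient
inspectable — which Grad-CAM exploits directly — and every primitive is
verified against central finite differences in the test suite.

## Training protocol

* Loss: categorical cross-entropy (optionally class-weighted; off by
  default). Optimizer: Adam.
* Splits: 15% of beats held out for testing; the remainder split 7:3 into
  training and validation; all splits stratified per class; five-fold
  cross-validation rotates the test partition. Splitting is at the beat
  level.
* Early stopping: training halts when the monitored loss has not improved
  for 5 consecutive epochs, and the checkpoint with the lowest monitored
  loss is restored. The monitor is **validation** loss — selecting on test
  error would leak the held-out partition — with a config switch to monitor
  training loss instead.
* Two hyperparameter regimes: `TrainConfig.paper_protocol()` (learning rate
  8e-7, batch 64) reflects the published full-database protocol, which at
  hundreds of thousands of beats takes many epochs on GPUs. The desk-scale
  default is learning rate 1e-3 (the reference study below uses 1e-2),
  batch 64 by default.

No class rebalancing is applied by default, matching the published setup
despite its extreme class imbalance; a weighting option exists.

## Evaluation metrics

Per class, one-vs-rest reduction of the K×K confusion matrix gives TP, FP,
TN, FN, and from them ACC = (TP+TN)/n, PRE = TP/(TP+FP), SPE = TN/(TN+FP),
SEN = TP/(TP+FN), F1 = 2·SEN·PRE/(SEN+PRE). A zero denominator yields an
explicit null, never 0 or 100 — a six-beat class otherwise produces
meaningless percentages. Fold averaging is the unweighted arithmetic mean
per class and metric; rounding (two decimals, half-up) happens only at
presentation. The mislocalization rate counts diseased beats assigned a
*different diseased* class, over all diseased beats; diseased beats
predicted healthy are detection errors and excluded from its numerator.

## Attribution

* **SE weights.** The input-stage gates are directly lead-indexed. Branch
  SE gates index feature channels, not leads; the per-scale lead weights
  reported are the input-stage lead gates multiplied by an energy-weighted
  convex combination of the branch's channel gates per lead (weights
  proportional to each channel's time-mean squared activation at that
  lead). Both factors lie in (0,1), so the product does too. The output
  metadata labels this interpretation explicitly — it is a reconstruction,
  since no lead-resolved gate exists after convolution.
* **Grad-CAM.** For a chosen class, the gradient of the *pre-softmax* class
  score (softmax saturation flattens gradients) with respect to each
  branch's last residual feature map is averaged over time and leads to
  give one weight per channel; the rectified weighted channel sum is the
  branch's relevance map. Maps are interpolated linearly along time to the
  input length if needed (the lead axis is never interpolated) and fused
  across branches by the mean (max available). Lead scores are time-means
  of the fused map; rank ties break by canonical lead order
  (I, II, III, aVR, aVL, aVF, V1–V6).

## Synthetic data

The generator provides ground truth for every stage. Each beat is a sum of
Gaussian bumps (P, Q, R, S, T) with template amplitudes 0.15, −0.10, 1.00,
−0.20, 0.30 mV, centred at −180, −28, 0, +28, +300 ms from the R-peak,
scaled per lead by a fixed profile (aVR inverted, precordial amplitudes
growing toward V4–V5). The S and T placement keeps the ST window
(R+40 … R+160 ms) within a few hundredths of a millivolt of baseline in
healthy beats. An infarct class adds, in its signature leads only: a
0.2 mV boxcar ST shift over that window, a 0.15 mV Q-wave deepening, and
for some classes an inverted T wave; posterior involvement adds the
mirror-image ST depression in V1/V2. Compound localizations take unions of
their constituent lead sets. Records carry 0.4 Hz sinusoidal baseline
wander (0.1 mV default), white Gaussian noise (0.05 mV default), and
lognormal RR jitter (σ = 0.03) around a 1.2 Hz beat rate; the seed fully
determines the output. Beats enter datasets through the *real*
preprocessing chain, and the planted R indices are returned exactly.

What the generator does **not** emulate: inter-patient morphology
variability, arrhythmic beats, muscle/powerline noise, electrode artefacts,
or the waveform statistics of any real database. Passing tests on this
data demonstrate that the pipeline's mechanics are correct and that the
model can learn and attribute planted, well-separated lead signatures —
not that the reported clinical-database performance transfers.

## The desk-scale reference study

`ecgnet.evaluation.desk_scale_study` is the package's end-to-end
experiment, sized for a single CPU: four classes (H, A, I, L), 200 beats
per class at the generator defaults, a small ECGNet (4 filters per branch,
one Block2 unit — same topology as the full model), and five-fold
cross-validation with learning rate 1e-2, batch 16, a 10-epoch cap and
patience 5. It then measures how often Grad-CAM places a planted signature
lead in the top 3 for infarct beats.

Attribution in the study is **ensembled over the five fold models**: for
each beat, the relevance maps of the fold models that classify it
correctly are normalized to unit mass, averaged, and ranked. The reason is
a genuine property of the task, worth stating plainly: at (near-)perfect
accuracy a single small model is free to adopt an *exclusion coding* —
recognizing, say, an anterior infarct by the absence of inferior and
lateral signatures rather than by the V3/V4 shift itself — and Grad-CAM,
which is faithful to the model rather than to the generator, then
highlights non-signature leads. Which coding a given model learns depends
on initialization and data shuffling. Averaging attribution over
independently trained models suppresses these idiosyncratic solutions
(as perturbation-averaged saliency methods do) and makes the lead ranking
reflect the consensus evidence; single-model rankings remain available
through `grad_cam` directly. Even so, the ensemble recall varies with the
random seed (roughly 0.7–0.97 across seeds in our runs) precisely because
exclusion codings can dominate a majority of folds; the study reports the
measured value rather than guaranteeing a floor. Typical results are mean
cross-validated accuracy above 0.95 and ensemble top-3 signature recall
around 0.9, with the whole study completing in under ten minutes.

## Numerical and design notes

* All network arithmetic is float32; tests of gradients run the same code
  in float64.
* BN uses ε = 1e-5 and running-stat momentum 0.9; evaluation mode uses the
  running statistics (so early-epoch validation metrics lag the weights —
  visible in the first epochs of the reference study).
* The adaptive detector threshold uses a percentile rather than the global
  maximum so one outlier beat cannot suppress the rest of the record.
* Dataset files are a binary array bundle plus a JSON sidecar carrying the
  class vocabulary, sampling rate, window geometry and generator
  provenance; a version field guards against silent format drift.
* WFDB support covers the header + 16-bit signal layout (the PTB format);
  annotation files are out of scope and labels come from a header comment,
  an external table, or the caller.
* Known limitations: beat-level splitting means beats from one record can
  appear in both training and test partitions (the published evaluation
  bookkeeping is beat-level as well); patient-disjoint splitting is the
  obvious extension. The published headline accuracies require the full
  clinical database and long training, and are not reproduced here — the
  package reproduces the *arithmetic* of the published tables exactly and
  the *behaviour* of the method on synthetic ground truth.
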