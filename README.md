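# ecgnet

Beat-level detection and localization of myocardial infarction (MI) from
12-lead ECG, with lead-level interpretability.

Infarcts announce themselves in the leads that face the injured wall:
ST-segment deviation in V3/V4 points anterior, in II/III/aVF inferior, in
I/aVL/V5/V6 lateral, with reciprocal V1/V2 depression for posterior
involvement. This package classifies fixed 651-sample, 12-lead heartbeat
windows (1 kHz; 250 samples before the R-peak, 400 after) into healthy plus
ten MI localizations — or just healthy-vs-MI — and reports *which leads
drove the decision*.

The core model, **ECGNet**, is a multi-scale residual network with
squeeze-excitation (SE) attention:

* a lead-stage SE over the 12-lead axis: squeeze by global average pooling,
  excitation through a dense(12→12/r)–ReLU–dense–logistic bottleneck, and
  channel-wise multiplicative reweighting — one inspectable gate per lead;
* three parallel branches with time-axis kernels 3×1, 5×1, 7×1 (shared
  across leads, never spanning them), each a stem convolution plus
  pre-activation residual units (BN → ReLU → conv, ×2, identity skip),
  a channel SE, and global average pooling;
* concatenation of branch features and a dense softmax head.

Per class *c*, evaluation uses the one-vs-rest reduction of the confusion
matrix: ACC = (TP+TN)/n, PRE = TP/(TP+FP), SPE = TN/(TN+FP),
SEN = TP/(TP+FN), F1 = 2·SEN·PRE/(SEN+PRE). Attribution comes from the SE
gates and from Grad-CAM: channel weights are spatially averaged gradients
of the pre-softmax class score with respect to each branch's last
convolutional feature map; the rectified weighted channel sum, fused
across branches, gives a time×lead relevance map and a per-lead ranking.

A built-in synthetic 12-lead generator (sum-of-Gaussians P-QRS-T morphology,
baseline wander, noise, and class signatures planted in the
pathophysiologically matching leads) provides exact ground truth for every
stage — R-peak locations, ST shifts, and signature leads. The network and
its training loop run on a compact NumPy autodiff engine included in the
package (`ecgnet.nn`), so there is no deep-learning-framework dependency
and every intermediate gradient is inspectable.

## Worked example

```python
import numpy as np
from ecgnet import (SyntheticConfig, synthesize_dataset, EcgNetConfig,
                    TrainConfig, crossvalidate, grad_cam, build_ecgnet)

# 4-class study: healthy + anterior, inferior, lateral MI; 200 beats/class
ds, truth = synthesize_dataset(["H", "A", "I", "L"], 200, SyntheticConfig(seed=11))

model_cfg = EcgNetConfig(n_classes=4, base_filters=4, block2_repeats=1)
train_cfg = TrainConfig(seed=11, learning_rate=1e-2, batch_size=16, max_epochs=10)
folds, averaged = crossvalidate(ds, model_cfg, train_cfg)
print([round(f.test_report.overall_accuracy, 4) for f in folds])
print(round(averaged.overall_accuracy, 4))

# explain one correctly classified anterior beat
model = build_ecgnet(model_cfg, rng=np.random.default_rng(train_cfg.seed))
model.set_weights(folds[0].best_weights)
i = int(np.flatnonzero(ds.y == ds.taxonomy.encode("A"))[0])
cam = grad_cam(model, ds.X[i], ds.taxonomy.encode("A"))
print(cam.ranking[:4])
```

Output from this exact script:

```
[1.0, 1.0, 0.9875, 0.9938, 1.0]
0.9962
('V4', 'V3', 'aVR', 'V5')
```

Five-fold test accuracies on the synthetic task, their mean (99.62%), and
the Grad-CAM lead ranking for an anterior beat — V3/V4, the leads carrying
the planted anterior signature, rank at the top. (Single-model rankings
can be idiosyncratic; `ecgnet.evaluation.gradcam_signature_recall`
averages attribution over all five fold models — see `docs/methods.md`.)

The same flow is available from the shell:

```bash
ecgnet simulate --classes H,A,I,L --n 200 --seed 11 --out beats
ecgnet train --data beats --task localize --out results/
ecgnet explain --model results/model --data beats --class A --out ranking.json
ecgnet run --task detect --seed 7 --out experiment/   # full orchestrated run
```

## Layout

| Module | Contents |
| --- | --- |
| `ecgnet.io_formats` | WFDB (.hea/.dat, format 16) and text-matrix records, dataset bundles, lead canonicalization, label taxonomies |
| `ecgnet.preprocess` | median-filter baseline removal, Pan–Tompkins-style R-peak detection, 651-sample segmentation |
| `ecgnet.architecture` | ECGNet: SE blocks, pre-activation residual branches, model (de)serialization |
| `ecgnet.training` | stratified splits, Adam + early stopping, five-fold cross-validation |
| `ecgnet.metrics` | confusion matrices, per-class ACC/PRE/SPE/SEN/F1, fold averaging, mislocalization rate |
| `ecgnet.attribution` | SE lead-weight extraction, Grad-CAM maps and lead rankings |
| `ecgnet.synthetic` | ground-truth 12-lead generator with per-class lead signatures |
| `ecgnet.evaluation` | reference experiments (detector scoring, desk-scale study) |
| `ecgnet.pipeline` / `ecgnet.cli` | YAML-configured experiments and the `ecgnet` command |
| `ecgnet.nn` | the NumPy reverse-mode autodiff engine and layers |

See `docs/methods.md` for the full methods description, parameter tables,
and known limitations.
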