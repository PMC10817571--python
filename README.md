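# nervetrace

Synthetic ultrasound nerve phantoms, encoder–decoder segmentation, mask
morphometry and method-agreement statistics — an end-to-end, fully
reproducible desk-scale emulation of how automated median-nerve
segmentation is validated against manual annotation.

## The problem

Sonographic assessment of the median nerve (e.g. in carpal tunnel
syndrome work) relies on tracing the nerve's cross-section on transverse
B-mode images and reporting its cross-sectional area (MNCSA),
circumference, and the longest diameters in the radial–ulnar (D1) and
dorsal–palmar (D2) directions, taken as the sides of the minimum-area
bounding rectangle of the traced outline. Manual tracing is slow and
rater-dependent, so encoder–decoder CNNs — U-Net (deconvolution + skip
connections) and SegNet (max-pooling-index unpooling) — are natural
automations. Validating them requires segmentation metrics

    precision = TP/(TP+FP)        recall = TP/(TP+FN)
    DICE = 2TP/(2TP+FP+FN)        IoU  = TP/(TP+FP+FN)

plus Spearman rank correlation, Student's *t*-test and Bland–Altman
limits of agreement (mean difference ± 1.96 SD of the differences)
between manual and automated morphometry.

Real clinical images are rarely shareable, so `nervetrace` generates
speckled phantoms — a hypoechoic elliptical nerve with a hyperechoic rim
on multiplicative gamma speckle — with *exact* geometric ground truth,
including an elongated/blurred stratum that emulates the known hard
cases. Everything downstream (splitting, flip augmentation, training
with Adam on binary cross-entropy, prediction, morphometry, agreement
analysis) is seeded and reproducible. The networks run on a small NumPy
engine included in the package, verified by finite-difference gradient
tests.

## A worked example

```python
from nervetrace import RunConfig, Seeds, run_study

cfg = RunConfig(
    n_images=120, frame_size=(64, 64), input_size=64,
    covariate_ranges={"a": (10.0, 24.0), "b": (7.0, 14.0),
                      "center_jitter": 4.0},
    hard_ranges={"b": (6.0, 8.0), "aspect": (2.5, 3.2),
                 "blur_sigma": (2.0, 3.0)},
    depth=3, base_channels=8, epochs=20,
    batch_size=12, learning_rate={"unet": 3e-3, "segnet": 1e-2},
    clip_norm=1.0, seeds=Seeds())
report = run_study(cfg)
print(report.summaries["unet"]["table"].round(3))
print(report.per_image.groupby(["architecture", "stratum"]).iou.mean().round(3))
```

which prints (a couple of minutes on one CPU):

```
            mean     sd
precision  0.987  0.017
recall     0.977  0.023
dice       0.982  0.012
iou        0.964  0.022
architecture  stratum
segnet        easy       0.949
              hard       0.897
unet          easy       0.974
              hard       0.927
```

Read: after 20 epochs the U-Net overlaps the true nerve at mean IoU ≈
0.96 on 64×64 phantoms; SegNet, without skip connections, trails it — and
both models lose accuracy on the elongated, blurred-outline stratum, the
same qualitative ordering and failure mode reported for this task on real
images. `report.agreement` holds the Spearman/Bland–Altman table (4
measurements × 2 models) against a simulated manual rater.

The `examples/` scripts walk the capabilities one at a time (phantoms,
training, morphometry, agreement, full study), and the `nervetrace` CLI
exposes the same pipeline for shell use (`nervetrace generate | prepare |
train | predict | measure | run`).

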