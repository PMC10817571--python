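# Methods

`nervetrace` reproduces, on synthetic data, the full workflow of a
manual-versus-CNN study of median-nerve morphology in wrist ultrasound:
phantom generation with exact ground truth, encoder–decoder segmentation,
binary-mask morphometry, and method-agreement statistics. This note
records the models, the defaults and the design choices, and what the
synthetic results do and do not show about real data.

## Phantom model

A phantom frame emulates a cropped transverse B-mode view of the carpal
tunnel region reduced to its essentials: one hypoechoic elliptical nerve
cross-section with a hyperechoic epineurium rim on a mid-grey background.
The echogenicity map (interior < background < rim, defaults 0.18 / 0.45 /
0.75 on a [0, 1] reflectivity scale) is blurred by an isotropic Gaussian of
standard deviation `blur_sigma` (pixels), multiplied by gamma-distributed
speckle with mean 1 and shape `speckle_shape` (variance 1/shape; gamma
multiplicative noise is the standard B-mode proxy), clipped and quantised
to 8 bits. Defaults: 300×300 frames; semi-axes a ∈ [18, 34], b ∈ [10, 20]
px; rim 2–4 px; blur ∈ [0, 1.5] px; speckle shape ∈ [15, 50]; all sampled
uniformly per image from a seeded generator, with per-image child seeds so
any frame is reproducible in isolation.

Ground truth is geometric: the mask marks exactly the pixels whose centers
lie inside the unblurred ellipse. Blur and speckle degrade the image only
— the anatomy is fixed, the imaging is not. A quarter of each dataset (by
default) comes from a "hard" stratum with aspect ratio ≥ 2.5 and blur ≥ 2
px, emulating the elongated, blurred-outline nerves on which segmentation
networks are known to degrade.

An annotation perturber emulates manual tracing variability: the mask
boundary is displaced by a smooth zero-mean radial field (first four
Fourier harmonics of the polar angle, RMS scaled to a `magnitude` in
pixels, default 2), with the result kept a single filled component.

What the phantoms do **not** model: acoustic physics (no point-spread
function or RF simulation), neighbouring anatomy (tendons, ligament,
bone shadowing), probe-pressure deformation, and real intensity
statistics. Passing tests therefore demonstrate that the pipeline is
correct and behaves as expected under controlled difficulty, not that the
trained weights transfer to clinical images.

## Networks

Both architectures share an encoder of `depth` stages (two 3×3
same-padding convolutions + ReLU, then 2×2 max-pooling), channel widths
doubling from `base_channels`. At the defaults (256×256 input, depth 5,
base 16) the bottleneck feature map is 8×8. U-Net decodes with learned
2×2 stride-2 transposed convolutions and skip concatenation; SegNet
decodes by index unpooling (values routed to the argmax positions the
encoder recorded) with no skips, hence strictly fewer parameters at equal
configuration. A 1×1 convolution and logistic head give per-pixel
foreground probabilities; masks are thresholded at 0.5.

The networks run on a small NumPy engine written for this package
(`nervetrace.nn`): explicit forward/backward passes for every layer and
an Adam optimizer. Convolutions are computed as k² shifted matrix
products; correctness is established by finite-difference gradient tests
on every layer and on both full models. One published description of the
encoder reads "2×2 convolution and 3×3 max-pooling"; we treat this as a
typographical swap and use the canonical 3×3 convolutions with 2×2
pooling, which is also what the stated 256 → 8 halving chain requires.
No batch normalisation or dropout is used. Weight initialisation is He
(seeded) for all ReLU convolutions; the 1×1 sigmoid head is
zero-initialised so every untrained network starts from the
uninformative prediction p = 0.5 (initial loss exactly ln 2) rather than
a seed-dependent confidently-wrong state — He variance is calibrated for
ReLU layers, not a logistic output.

## Training

Adam (lr 10⁻³, β = (0.9, 0.999), ε = 10⁻⁷) minimises mean binary
cross-entropy, with probabilities clipped at 10⁻⁷ to avoid log(0). Each
epoch the training set is divided into five mini-batches (batch size
⌈n/5⌉, last batch smaller); training runs a fixed 20 epochs with no early
stopping or schedule. The per-epoch training loss is the pixel-weighted
mean over batches, so it equals the dataset mean regardless of the
shuffle; validation loss is computed without weight updates. All
stochastic elements (initialisation, shuffling, phantom sampling,
augmentation, splits) derive from named seeds, so a study re-run
reproduces its outputs bit-identically on one platform.

Dataset preparation follows the study protocol: random partition at
proportions 3/4 : 1/12 : 1/6 (600 images → 450/50/100; for other n,
train = round(3n/4) then validation = round(n/12), remainder to test),
and the training set doubled by adding exactly one randomly flipped copy
of each image (vertical, horizontal, or both). Frames resize bilinearly,
masks nearest-neighbour (they stay binary); intensity normalisation to
[0, 1] happens at model ingestion.

## Morphometry

Measures are computed from a binary mask after keeping its largest
8-connected component: area as foreground pixel count × (mm/px)²;
circumference as the perimeter of the Moore-neighbour traced boundary
polygon through pixel centers (steps 1 or √2 px); D1/D2 as the sides of
the minimum-area bounding rectangle of the contour, computed by convex
hull (monotone chain) plus rotating calipers — exact, since the optimal
rectangle has a side collinear with a hull edge. The side within ±45° of
the image horizontal is D1 (radial–ulnar), the other D2 (dorsal–palmar);
at exactly 45° the longer side is D1.

Coordinates are pixel centers, so a W×H filled rectangle measures
(W−1)×(H−1) across; an optional half-pixel-pad mode adds 1 px per
dimension for area-consistent sizing (with it, the bound d1·d2 ≥ area
holds). `mm_per_pixel` defaults to 1.0, i.e. pixel units, since no
calibration is assumed. Degenerate inputs signal explicitly: empty masks
raise an empty-measure error, masks under 4 px a degenerate-shape error;
the pipeline converts these to NaN rows rather than aborting.

A note on parameter recovery: for a rotated low-eccentricity ellipse the
bounding-rectangle area is nearly flat in angle, so the minimum-area
rectangle of the *discretised* mask need not align with the ellipse axes.
The recovery tests therefore compare rectangle sides against the
ellipse's support-function extent in the measured direction, which is the
exact prediction at any angle.

## Statistics

Spearman correlation uses midranks for ties and the two-sided
t-approximation (t = rs·√((n−2)/(1−rs²)), n−2 df) for p-values —
appropriate at the n = 100 scale of the emulated study; an exact
permutation oracle backs the tests at small n. Interpretation bands:
|rs| ∈ [0.2, 0.39] weak, [0.4, 0.59] moderate, [0.6, 0.79] strong,
otherwise "other" (bands are taken on |rs|). Student's t defaults to the
unpaired pooled-variance form, with a paired option; zero-variance
degeneracies return (0, 1) for equal means and (±∞, 0) otherwise.
Bland–Altman differences are reference − test, so a positive mean
difference reads "the test method underestimates"; limits of agreement
are mean ± 1.96 sample SD (n−1), and the inclusive coverage fraction is
reported. Segmentation metrics are computed per image and then averaged
(never pooled over pixels); two empty masks count as perfect agreement,
an empty prediction against a non-empty truth as zero precision.

## Problem sizes

The packaged end-to-end runs (tests and the acceptance script) use
scaled-down study conditions chosen once as a realistic desk-scale
configuration for a pure-NumPy CPU engine: 64×64 frames with
proportionally scaled covariates (a ∈ [10, 24], b ∈ [7, 14] px; hard
stratum b ∈ [6, 8], aspect ∈ [2.5, 3.2], blur ∈ [2, 3]), 120 phantoms
(90/10/20 split, 180 after augmentation), depth-3 networks with 8 base
channels (8×8 bottleneck, mirroring the full-scale geometry), 20 epochs.
At this scale each five-batch epoch would provide only five Adam updates
on 64² frames — about 64× less pixel gradient signal per update than the
full-scale protocol — which under-trains the skip-less SegNet decoder.
The scaled runs therefore use batch size 12 (≈15 updates per epoch) with
per-architecture learning rates — 3×10⁻³ for U-Net and 10⁻² for the
slower-starting SegNet — plus global gradient-norm clipping at 1.0 as a
safety net; the five-batch, lr 10⁻³ defaults remain in place for
full-scale configurations.
Architecture contracts (bottleneck size, parameter ordering) are still
verified at the full 256×256 / depth-5 / base-16 configuration, and
dataset mechanics at the full 600-image scale.

## Known limitations

* Phantoms are single-structure and stationary; domain gap to clinical
  frames is large by construction.
* The absolute morphometric agreement values (mean differences in mm) of
  any real study are not recoverable without its calibration; results
  here are in pixel units unless a calibration is supplied.
* The NumPy engine is single-threaded-friendly but slow; full-scale
  (256×256, base 16) training is possible but takes hours, not minutes.
* Bit-identical reproducibility is guaranteed per platform/BLAS, not
  across different BLAS builds.
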