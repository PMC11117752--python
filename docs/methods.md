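# Methods

## Problem setting

Segmentation of the T2-hyperintense lesion (the "whole tumor" on FLAIR:
edema plus non-enhancing infiltration) from a single un-skull-stripped
3D FLAIR volume. Models trained on newly-diagnosed glioma generalize poorly
to treated patients, whose lesions have low-contrast, heterogeneous borders,
contain resection cavities, and coexist with treatment-related signal
changes that mimic the lesion's leading edge. The package implements three
remedies and the machinery to compare them: mixing post-treatment cases
into training, transfer learning (pre-train on the newly-diagnosed domain,
fine-tune on the post-treatment domain), and spatial regularization of the
loss.

## Network

A V-net-style 3D encoder–decoder. Encoder: a 3×3×3 convolution stem, then
`depth` stages of stride-2 convolution (doubling filters) plus one same-
resolution convolution, all ReLU. Decoder: nearest-neighbor ×2 upsampling,
channel-halving convolution, additive skip connection from the encoder
stage at that resolution, and a second convolution; a 1×1×1 sigmoid head
yields the lesion probability. The variational branch squeezes the
bottleneck to 8 channels, maps it linearly to a Gaussian code (mu,
log-variance), samples via the reparameterization trick, and decodes a
reconstruction of the input through the mirrored path; its KL and L2 terms
regularize the shared encoder during training only.

The full-scale configuration ([224, 224, 128] crop, 16 initial filters,
depth 3) gives the 28 × 28 × 16 bottleneck grid with 128 channels. Tests
and experiments run a [48, 48, 32] / 4-filter or [32, 32, 16] / 4-filter,
depth-2 instance; parameter counts scale ≈ 4× when the width doubles.
Internals that the reference description leaves open (block type,
normalization, upsampling flavor) are the package's own choices and are
deliberately simple; exact replication of any particular published network
is a non-goal.

Everything is float64 numpy with a hand-written reverse-mode autodiff tape
(`spatreg._autodiff`): no deep-learning framework is required, runs are
bit-reproducible for a fixed seed, and the gradients of the complete
network-plus-loss graph are checked against central finite differences in
the test suite (relative tolerance 1e-4).

## Losses

`L_tot = λ₁·L_Dice + λ₂·L_CE + λ₃·L_KL + λ₃·L_L2` with λ₁ = 1.0,
λ₂ = λ₃ = 0.1. Notes on each term:

* **Soft Dice** `1 − (2Σyy′ + ε_num)/(Σy² + Σy′² + ε_den)` with squared
  sums in the denominator; training smoothing (0, 1e-5), evaluation
  smoothing 0.001 on both top and bottom. For binary masks the squared-sum
  and set forms coincide. The empty-vs-empty training case degenerates to
  loss 1.0 and is documented rather than special-cased (training sets
  always contain lesion voxels).
* **Weighted cross entropy**: mean over the crop's N voxels; predictions
  clipped to [1e-7, 1−1e-7] before logs (the reference description is
  silent on clipping). Weights come from precomputed maps (below) and are
  validated to lie in [1, 2], which bounds the weighted CE by twice the
  unweighted value.
* **KL** `(1/N)Σ(μ² + e^v − v − 1)` normalized by the image voxel count,
  following the originating architecture's convention; the normalization is
  a single argument if a different one is wanted.
* **L2**: mean squared reconstruction error.
* The "Dice loss alone" comparison arm keeps the KL and L2 terms and sets
  only λ₂ = 0.

## Spatial weight maps

Distance fields are exact anisotropic Euclidean distance transforms
(scipy EDT with the voxel spacing as sampling), voxel-center to
voxel-center. The boundary reference set is the 6-connectivity surface:
mask voxels with a face-adjacent background neighbor (voxels on the array
border count as surface). The same surface definition is reused by the HD95
metric so loss and evaluation agree on what "the boundary" is.

The construction of the weighting terms is not prescribed beyond
`w = 1 + M`, `M ∈ [0, 1]`; the package uses exponential decay for the edge
map (`M_edge = exp(−d/τ)`, τ default 3 mm — the e-folding width of the
emphasized band, a few voxels at 1 mm resolution) and a clipped linear ramp
for the cavity map (`M_cavity = max(0, 1 − d/d_max)`, d_max default 40 mm,
roughly the scale over which recurrence is plausible around a cavity).
Whether cavity weighting should emphasize near- or far-cavity voxels is
genuinely open; the default emphasizes voxels NEAR the cavity (recurrence
concentrates at the resection margin) and `near=False` flips the ramp.
Maps are computed once from ground-truth masks before training, cropped and
flipped together with the image, and never needed at inference.

The heuristic cavity detector (largest 6-connected component below a
within-bounding-box intensity percentile) is intentionally simple and
intrinsically variable: with heavy noise or a very small cavity the largest
low-intensity cluster may not be the cavity. Tests exercise it at a scale
where the cavity dominates.

## Synthetic phantoms

The generator is the package's study population, not a fixture. Each case
is a pure function of its seed: an ellipsoidal "head" of tissue intensity
1.0 with a 2 mm bright skull shell (volumes are not skull-stripped) and
exactly-zero background (so nonzero-intensity normalization is well
defined); a lesion built as a smoothed-noise perturbation of an ellipsoid
(irregular, non-geometric borders); intensities form a full-contrast
plateau over the annotated mask with a linear hyperintense halo decaying
over `boundary_softness` mm OUTSIDE the annotation — the faint leading edge
that makes boundary placement hard; optional spherical resection cavity
(hypointense, 0.35) excluded from the lesion annotation; optional faint
"mimic" blobs far from the lesion, at lesion-like intensity but NOT part of
any annotation, representing treatment-related signal change; Gaussian
noise on the head support.

Two appearance styles define the imaging domains:

| parameter          | newly_diagnosed | post_treatment |
|--------------------|-----------------|----------------|
| boundary_softness  | 0.3 mm          | 0.6 mm         |
| lesion_contrast    | 2.4             | 1.7            |
| lesion_texture     | 0.05            | 0.10           |
| cavity             | no              | yes            |
| n_mimics           | 0               | 3 (contrast 2.2) |

The newly-diagnosed style is a sharp, bright, solid blob; the
post-treatment style is a dimmer, textured ring around a cavity, in a
volume that also contains small BRIGHT non-lesion mimics. This makes the
domain gap *structural*: a model trained only on the newly-diagnosed style
has learned "bright blob = lesion", which on post-treatment cases selects
the mimics and misses the dim ring; post-treatment appearance must be
learned from post-treatment examples. That is the property the data-mixing
and transfer-learning experiments measure. These parameters were fixed as
the package's emulation of the clinical contrast difference; no
quantitative description of post-treatment texture exists to calibrate
against, so they are qualitative stand-ins.

What the phantoms do NOT model: MRI physics (bias fields, k-space
artifacts), real anatomy (ventricles, gray/white matter), partial-volume
effects at acquisition resolution, multi-focal disease, and real
annotation variability. Passing trend tests therefore show that the
*pipeline* reproduces the expected qualitative behavior under a controlled
domain shift, not that the effect sizes transfer to clinical data.

## Training

Batch size 1 volume. Adam (1e-4 full scale following the originating
model's hyperparameters; 1e-3 at the toy scales used in tests, where a
4-filter model on ~10⁴-voxel volumes tolerates and needs a larger step),
polynomial learning-rate decay of power 0.9 over the configured epochs, and
global-norm gradient clipping at 5.0 — the clipping guards the fine-tuning
arms, where switching both imaging domain and loss function mid-training
can otherwise blow up the first updates. Preprocessing: z-score over the
nonzero support (background stays 0), random crop, random axis flips, and
±10% multiplicative / ±0.1 additive intensity jitter on the tissue support
in training; deterministic center crop in evaluation. The identical spatial
transform is applied to image, masks and weight map.

Checkpoint selection takes the epoch with the highest validation Dice
(smoothed, ε = 0.001, at threshold 0.5). Divergence is flagged when the
loss goes non-finite before the step limit (default 10,000) or when the
validation Dice sits below 0.05 after a grace period (default 5 epochs;
the grace period exists because a freshly initialized model legitimately
starts near zero). On divergence the comparison harness discards that seed
for EVERY arm and substitutes the next candidate, so compared arms always
share a seed set. Binarization threshold 0.5 and center pad-or-crop at
inference (mapped back to native geometry) are package conventions.

Split planning reproduces the published experiment plans: the post-domain
pool is the nearest integer to `target × total`, and each domain pool
splits 80/20 with round-half-up on the training side. Two pool sizes (192
and 128 post-treatment cases) carry pre-committed splits (153/39 and
103/25) that the cohort design fixed by hand rather than by rounding; they
ship as default anchors. Exact-ratio targets such as two-thirds should be
passed as fractions, not as their 2-decimal display.

## Evaluation and statistics

Per case: smoothed Dice (ε = 0.001), robust HD95 in mm (max of the two
directed 95th percentiles over 6-connectivity surface-voxel distances,
linear-interpolation percentile; 0 when both masks are empty; when exactly
one mask is empty the physical diagonal of the volume is returned as a
finite sentinel with a flag, so cohort averages stay finite and reports can
exclude such cases), voxel sensitivity/specificity (empty-truth convention:
sensitivity 1 if the prediction is also empty, else 0, flagged), volumes in
ml. Whether HD95 should take the max of directed percentiles or a pooled
percentile is a convention; the max-of-directed form is used and fixed.

Cohort level: metrics are averaged per patient across seeds BEFORE any
test. Arm comparisons use the two-sided Wilcoxon signed-rank test on paired
per-case differences with zeros discarded; for n ≤ 12 the p-value comes
from exact enumeration of all 2ⁿ sign assignments with average ranks (exact
even under ties, where the usual implementations fall back to a normal
approximation), larger n defers to scipy. Fewer than 5 informative pairs
yields an explicit "insufficient pairs" result. Volume agreement is OLS of
predicted on true volume (slope, intercept, R²); 95% CIs are normal
approximation (mean ± 1.96·SE); HD95 outliers are counted above an 8 mm
threshold.

## Problem sizes used by the test suite

Chosen as the package's CPU-scale study conditions: the training smoke runs
24 newly-diagnosed phantoms at [48, 48, 32] (4 initial filters, depth 3)
for 8 epochs × 3 seeds; the trend experiments run at [32, 32, 16]
(4 filters, depth 2, 24 epochs): a 24-case pre-only arm, a 12 + 12 mixed
arm, and a fine-tune arm on 12 post-treatment cases, evaluated on 12
held-out post-style cases across 3 seeds with reseeding. The acceptance
script repeats the pipeline at the same sizes with 2 seeds for the trends.

## Known limitations

* The phantom domain gap is deliberately strong; real pre/post differences
  are subtler, and the observed effect sizes (near-zero Dice for the
  pre-only arm on post-style cases) exaggerate the clinical ones.
* The numpy network is small; conclusions about architecture capacity do
  not transfer.
* Divergence under fine-tuning with spatially weighted losses occurs at a
  nontrivial rate at toy scale; the reseed harness handles it, but single
  runs without the harness can land on a collapsed model.
* The exact signed-rank enumeration is limited to n ≤ 12 pairs; beyond
  that the scipy implementation (normal approximation under ties) takes
  over.
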