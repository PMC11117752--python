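# spatreg

Spatially regularized 3D segmentation of the T2-hyperintense lesion on
single-contrast FLAIR-like volumes, with the training strategies that make
such models usable on *post-treatment* glioma: data mixing across imaging
domains, transfer learning from the newly-diagnosed to the post-treatment
domain, and distance-map-weighted loss functions that concentrate the
penalty at the lesion boundary and around the resection cavity.

## Who this is for

Researchers studying why lesion-segmentation models trained on
newly-diagnosed (treatment-naive) imaging degrade on treated patients, and
what combination of cohort composition, fine-tuning and boundary-aware loss
design recovers that performance. Real post-treatment cohorts are private,
so the toolkit ships a synthetic phantom generator that reproduces the
*structure* of the problem — dim, textured lesions around resection
cavities, bright treatment-related mimics, un-skull-stripped volumes — and
every experiment in the package runs end to end on CPU at phantom scale.

## The model and losses

The segmenter is a V-net-style 3D encoder–decoder with a variational
reconstruction branch that regularizes the shared encoder during training
(single input channel, single output channel; the branch is unused at
inference). Training minimizes

    L_tot = λ₁·L_Dice + λ₂·L_CE + λ₃·L_KL + λ₃·L_L2,   λ₁=1.0, λ₂=λ₃=0.1

where the cross entropy is spatially reweighted per voxel:

    L_CE = −(1/N) Σᵢ w(yᵢ)·[yᵢ·log y′ᵢ + (1−yᵢ)·log(1−y′ᵢ)]

with `w = 1 + M_edge` (edge weighting, `M_edge = exp(−d_boundary/τ)`) or
`w = 1 + M_cavity` (cavity weighting, `M_cavity = max(0, 1 − d_cavity/d_max)`),
both precomputed from anisotropic Euclidean distance maps before training.
The +1 offset keeps `w ∈ [1, 2]`, bounding the weighted loss and avoiding
vanishing gradients away from the emphasized region.

Evaluation uses the smoothed Dice score `(2|P∩T|+ε)/(|P|+|T|+ε)` with
ε = 0.001 (so a correctly predicted empty case scores 1), the robust
95th-percentile Hausdorff distance in mm over 6-connectivity surface voxels
(max of the two directed percentiles), voxel sensitivity/specificity, and
lesion volumes in ml, plus exact Wilcoxon signed-rank comparisons and
volume-agreement regression at cohort level.

The network, its gradients and the optimizer are implemented in numpy (a
small reverse-mode autodiff engine, `spatreg._autodiff`), so everything is
dependency-light, deterministic for a fixed seed, and verified against
finite differences in the test suite.

## A worked example

`examples/04_train_and_evaluate.py` trains a 4-filter model on 12
post-treatment-style phantoms at [32, 32, 16] and evaluates 4 held-out
cases (about two minutes on one core):

```
selected epoch 20 with validation Dice 0.811; diverged=False
  case_id  dice  hd95_mm  sensitivity
case_0000 0.774    1.414        0.727
case_0001 0.797    1.000        0.736
case_0002 0.607    4.619        0.654
case_0003 0.716    2.629        0.763
```

Dice measures bulk overlap; HD95 measures how far the predicted boundary
strays in mm — a few misclassified voxels far from the lesion barely move
Dice but dominate HD95, which is why both are reported. The other examples
cover cohort generation (`01`), distance/weight maps (`02`), the composite
loss (`03`) and cohort-level statistics (`05`).

A thin CLI mirrors the pipeline stages:

```bash
spatreg phantoms --n-pre 4 --n-post 4 --seed 7 --shape 48,48,32 --out cohort/
spatreg weights  --manifest cohort/manifest.csv --kind edge --tau 3
spatreg splits   --post-fraction 0.26 --training-total 192
spatreg train    --manifest cohort/manifest.csv --config run.yaml \
                 --pre-total 4 --post-total 4 --out ckpt.npz
spatreg evaluate --ckpt ckpt.npz --truth-manifest cohort/manifest.csv --out metrics.csv
spatreg compare  --a metricsA.csv --b metricsB.csv --metric hd95_mm
```

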