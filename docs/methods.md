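# Methods

`adslice` implements a 2D-slice pipeline for separating Alzheimer's disease
(AD) patients from cognitively normal (CN) controls on T1-weighted MRI: a
volume is rigidly aligned to a population template in two steps (whole head,
then skull-stripped brain), a fixed range of coronal slices covering the
medial temporal lobe is extracted and min–max normalized, a convolutional
slice classifier augmented with subject metadata scores each slice, and the
subject-level prediction is the average over slices and over the five models
of a stratified cross-validation. Because no clinical images ship with the
package, a synthetic phantom generator provides cohorts with known
ground-truth atrophy, misalignment and noise, against which every stage is
validated.

## Phantom generator

Each phantom is a nest of axis-aligned ellipsoids in a world frame centered
on the grid (RAS axes, world origin at the grid center): a 4 mm thick bright
outer shell (scalp/skull surrogate, intensity 1.0, outer semi-axes
66×80×62 mm), an interior brain ellipsoid (0.6, semi-axes 56×70×52 mm), and
a bilateral pair of medial-temporal ellipsoids (0.8, semi-axes 12×18×10 mm,
centers (±28, −10, −15) mm) elongated along the anterior–posterior axis like
the hippocampal/parahippocampal complex. The intensity ordering
(background < brain < structure < shell) mimics a T1 image so Otsu
thresholding and per-slice min–max normalization behave as they would on
real data. Images are band-limited with a 0.5-voxel Gaussian before
resampling.

The class effect is volumetric: an AD subject's structure volume is scaled
by `(1 − atrophy_effect)`, and every subject receives lognormal volume
jitter (log-SD 0.05 by default), so the AD/CN volume ratio is exactly
`1 − atrophy_effect` in law. Each subject is resampled through a random
rigid transform (up to ±10° and ±10 mm per axis by default) and corrupted by
additive Gaussian noise with SD equal to 5% of the brain-tissue intensity.
Ages are drawn from N(74.6, 7.0²) years clipped to [55, 95] and sex is
Bernoulli(0.467), identically in both classes (a matched design); an
optional `age_class_shift_years` induces age–class confounding for
sensitivity studies. All generation is a pure function of (spec, seed).

What the phantom does *not* emulate: MR physics (bias fields, partial
volume beyond trilinear blur), scanner/site heterogeneity, anatomical
variability beyond a single volume dial, and cortical or ventricular
structures. Passing the end-to-end criteria therefore shows that the
pipeline recovers a known volumetric group difference through registration,
skull stripping, slicing and learning — not that it attains any particular
accuracy on clinical data.

## Template and two-step alignment

The template is the voxelwise mean of CN volumes rigidly aligned to the
first, with a brain mask extracted from the mean, and the anchor coronal
index — where the medial-temporal slice range starts — computed analytically
from the phantom geometry (the structure's posterior-most extent, −28 mm,
e.g. index 99 on a 256-voxel 1 mm grid). Template subjects are generated
without misalignment, standing in for a reference population that was
co-registered when the template was constructed, so the template frame is
canonical and the analytic anchor applies exactly.

Registration is 6-DOF rigid (ITK Euler angles, rotation center at the world
origin) optimizing mean-squared intensity difference (mutual information is
selectable for multi-site data) with a regular-step gradient-descent
optimizer over a shrink-factor pyramid. Two accelerations matter on one
CPU: a closed-form initialization from the two images' intensity centroids
and principal axes (valid for the modest misalignments of head positioning),
and a final guard that keeps the initialization if it scores better than the
optimizer's result on the unsmoothed images. Median recovery error over
random misalignments within ±10°/±10 mm is ≈0.4° and ≈0.04 mm at 2 mm
voxels. Only rigid maps are ever applied (linear-part determinant 1), so
brain morphology is preserved.

Skull stripping is deterministic: Otsu threshold, morphological opening
(≈3 mm radius ball) to detach the thin bright shell, largest connected
component, closing and hole filling. It replaces a learned extractor behind
the same interface; on noise-free phantoms it recovers the brain ellipsoid
with Dice ≈0.98. Step 1 registers the whole head to the template; step 2
registers the stripped brain to the stripped template, which measurably
reduces the mean alignment error relative to step 1 alone.

Slice extraction takes `n_slices` consecutive coronal planes starting at
the anchor and proceeding anteriorly (posterior-to-anterior; the direction
is configurable since either reading of "starting at" is defensible), each
min–max normalized to [0, 1]; a constant slice maps to zeros by convention.

## Slice classifier and training recipe

Each greyscale slice is replicated to three channels and fed to a backbone
that emits a fixed-length feature vector; age/100, sex∈{0,1} and
slice_number/n_slices are appended (1024 + 3 = 1027 entries in the reference
configuration) and a fully connected head with softmax yields the AD
probability. The training loss is the batch-mean binary cross-entropy
J(w) = −(1/N) Σ [yⁿ log f(xᵢⁿ; w) + (1−yⁿ) log(1−f(xᵢⁿ; w))], with
probabilities clamped at 1e−7. Optimization is mini-batch SGD with Nesterov
momentum (0.9), batch size 64, weight decay 5×10⁻⁵, and a base learning
rate of 1e−3 decayed by 0.1 (at most three times) when the validation loss
plateaus (relative tolerance 1e−4, patience 3). Training stops early when
the 5-epoch moving average of subject-level validation accuracy fails to
improve by more than 5×10⁻⁴ over the window (equality stops), and the
returned weights are those of the best-validation-accuracy epoch.
Augmentation (rotation, isotropic scale, translation, contrast, gamma; one
uniform draw per slice per epoch, geometric-then-intensity order, bilinear
resampling, output clipped to [0, 1]) applies to training slices only.

The provided backbone, `tiny_cnn`, is two 3×3-conv → batch-norm → ReLU →
2×2-max-pool stages followed by a fully connected, batch-normalized, ReLU
feature projection, written in numpy with explicit backprop (im2col matrix
products). Batch normalization is affine-free and plays the same
conditioning role it plays in the modern Inception-class backbones this
classifier emulates; its running statistics are recalibrated at the end of
every epoch in one clean pass over an evenly spaced sample of the training
slices, because after an
epoch of augmented mini-batches the exponential running averages lag the
weights and shift inference-mode probabilities by a global bias. An
`inception_v4` backbone name is accepted by configuration but not provided:
without its pretrained weights (out of scope) a 497-layer network offers
nothing at this scale, and any backbone honoring the feature-vector
contract can be slotted in.

Two recipe parameters differ between the package defaults (which follow the
reference recipe above) and the desk-scale run configuration, because the recipe
presupposes a pretrained backbone: the desk configuration trains from
random initialization with base LR 3e−3, and consults the early-stop rule
only after 8 epochs (the rule itself is unchanged; the first epochs of a
randomly initialized network are uninformative and would otherwise trigger
a spurious stop).

## Evaluation protocol and statistics

Per trial: an 80/20 per-class split into development and test sets (floored
development count; 195+195 subjects yield 156+156 and 39+39), stratified
fivefold cross-validation on the development set (per-class validation
counts differ by at most one), one classifier per fold, and subject
prediction by averaging the per-slice probabilities within each fold model
and then the five fold-level averages. The ensemble is evaluated on the
held-out test split (within-dataset) and, unchanged, on the entirety of a
second dataset (between-dataset). Trials repeat with seeds
`master_seed + trial_index` and are aggregated as mean and sample SD
(n−1).

AUC is the Mann–Whitney concordance probability with ties counted ½
(verified exactly against O(n²) pair counting); its variance comes from
DeLong placement values, giving normal-approximation confidence intervals
(truncated to [0, 1]) and the DeLong z-test for AUC differences (paired
covariance via placement vectors, or independent-sample variance sums).
Operating points maximize Youden's J = sensitivity + specificity − 1 over
the observed scores (ties broken toward the lowest threshold) with accuracy
counted at that cut. Group comparisons use the pooled-variance Student's t
(including directly from printed means/SDs/counts), the paired t on
per-trial metrics, and the Pearson chi-square without continuity correction
(the uncorrected form is transparent for the matched-count worked examples;
correction is a one-line change). All p-values are two-sided.

## Numerical and reproducibility choices

Grids are cubic and world-centered; arrays are indexed (x, y, z) in RAS.
Intensities interpolate trilinearly, masks nearest-neighbor. ITK runs
single-threaded so registration results are bit-reproducible. All
randomness flows from explicit seeds (cohorts from the phantom seed, trial
seeds derived from the master seed, per-fold generators seeded by
(trial_seed, fold_index)); identical configuration and master seed
reproduce byte-identical reports. Loss probabilities are clamped at 1e−7;
batch-norm uses ε = 1e−5; gradient correctness is checked against central
finite differences in float64.

## Desk-scale study conditions

The reference configuration used by the reproduction script
(`scripts/acceptance.py`) and the end-to-end tests: 96-voxel 2 mm phantoms,
60 AD + 60 CN subjects, atrophy effect 0.3 (and 0.0 for the null), 15
coronal slices at 2 mm — the same 30 mm anatomical span the full-scale
configuration covers with thirty 1 mm slices — classifier inputs resized to
32 px, tiny backbone with channels (16, 32) and a 256-dim feature vector,
three trials, augmentation ranges scaled to the 32 px resolution (±5°,
scale 0.97–1.03, ±1 px, contrast/gamma 0.9–1.1). The full-scale
configuration (256³ grid at 1 mm, 30 slices, feature dim 1024) remains the
package default for every component; the desk scale exists so the full
pipeline runs in minutes on one CPU. Under these conditions the
within-dataset test AUC is expected ≥ 0.85 with the atrophy effect present
and near 0.5 for the zero-effect null.

## Known limitations

The phantom's rotational symmetry leaves the registration metric flat
within ≈±0.3° at 2 mm voxels, so sub-half-degree alignment cannot be
guaranteed (and does not matter at slice thickness 2 mm). The brain
extractor assumes the T1-like intensity ordering and a detached bright
shell. The numpy backbone is deliberately small; it demonstrates the
training recipe and ensembling contracts, not state-of-the-art capacity.
Between-dataset transfer is exercised on phantom cohorts drawn from the
same generative family, which is a far weaker domain shift than a real
scanner or population change.
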