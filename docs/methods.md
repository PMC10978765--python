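# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of deshkit. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The quantitative model of DESH

DESH (disproportionately enlarged subarachnoid-space hydrocephalus) is a
redistribution of cerebrospinal fluid: the ventricles (V) and the Sylvian
fissures + basal cistern (S) enlarge while the subarachnoid space over the
high convexity (H) is compressed. deshkit expresses this as three
dimensionless volume ratios,

    DESH index = (V + S) / H,   Venthi = V / H,   Sylhi = S / H,

so `DESH = Venthi + Sylhi` holds identically. All volumes are in mL,
computed as voxel counts times voxel volume; the indices are
scale-invariant and undefined when H = 0 (guarded with an explicit error).

The high-convexity region is defined by four landmark rules evaluated in
world millimetres: superior to the top of the bodies of the lateral
ventricles (an axial level), within 30 mm perpendicular distance of the
midsagittal plane, on or posterior to the coronal plane through the front
edge of the genu of the corpus callosum (plane normal along the AC–PC
direction), and anterior to the posterior parts of the callosomarginal
sulci (a coronal level along the same axis). Whether the 30 mm lateral
bound should be a true perpendicular distance to the midsagittal plane or
an in-slice distance is not specified anatomically; deshkit uses the
perpendicular distance, which is identical for axis-aligned grids and
well-defined for oblique ones. The Sylvian fissure + basal cistern
compartment has no algorithmic definition in clinical practice (it is
delineated manually or by commercial software); deshkit extracts it as the
26-connected components of the remaining SAS that contain supplied seed
points, and documents this seed-growth rule as a stand-in for manual
delineation. Everything left over is "other SAS".

## Stage 1: segmentation U-Net

A 4-level 3D U-Net maps a percentile-normalised intensity volume
(quantile window 0.05–0.95, clipped to [0, 1]; linear interpolation
between order statistics, pinned so tests can assert exact values) to
six per-voxel category scores. Each encoder level applies two
(conv 3×3×3 → batch norm → ReLU) blocks and 2×2×2 max pooling; the decoder
mirrors it with stride-2 up-convolutions (kernel 3; implemented as 2×
zero-stuffed upsampling followed by a same-padded convolution, the
standard transposed convolution that exactly doubles each axis) and skip
concatenation; a 1×1×1 convolution emits the scores. Channel widths
double per level from `base_channels` (default 8: 8-16-32-64) — a
desk-scale default chosen so a full training run fits comfortably on one
CPU; widths are configurable. Input grids must be divisible by
2^(depth−1); violations raise at build time.

Training minimises the smoothed soft Dice loss with ε = 1e-4. The loss
averages the per-category Dice over **all six categories including
background**: averaging over foreground only leaves the background channel
without direct gradient, and in early experiments the network then parked
an arbitrary foreground label on the background region (perfect volume
correlation, near-zero overlap). The foreground-only Dice remains the
reported evaluation quantity. Optimisation is Adam at 3e-3 (1e-3 was too
slow to converge within desk-scale iteration budgets), batch of one
volume, with on-the-fly augmentation: one shared random rigid+scale
transform per iteration (rotation ±10° per axis, isotropic scale 0.9–1.1,
translation ±5 mm — conventional mild ranges, configurable; the magnitudes
are not prescribed anywhere authoritative), linear interpolation for
intensities and nearest-neighbour for labels so no new label codes can
appear. "Training repeated over 1,000 times" in the source protocol is
ambiguous between iterations and epochs; deshkit reads it as iterations
and exposes `max_iterations` (desk-scale default 300).

Evaluation reports per-category hard Dice (same ε), precision, recall and
signed volume difference; Dice is averaged per subject then across
subjects. Argmax ties resolve to the lowest category code.

## Stage 2: multimodal classifier

Four independent binary networks (one per determination) each consume the
task-specific mask prescribed by the two-step design: the whole
intracranial CSF mask for DESH, ventricles for VD, high-convexity SAS for
THC, Sylvian/basal for SFD — separate models match that task-to-input
mapping literally, rather than one shared backbone. Masks are min-max
normalised; each conv block is conv 3×3×3 → batch norm → ReLU → channel
self-attention → 2× max pooling. "Self-attention" is realised as a
squeeze-and-excitation channel gate (global average pool → two-layer
bottleneck → sigmoid rescale); the original description names the
operation without a formula, and the block is swappable. After global
average pooling, the age (standardised by training-split mean/SD) and a
sex one-hot pass through a small linear embedding (default 8 dims, ReLU)
and are concatenated to the image features before the fully connected
head; a two-way softmax yields the probability score. The decision
threshold is fixed at 0.5.

Because classification consumes smooth mask shapes rather than voxel
detail, the input grid is average-pooled 2× before the network (default;
configurable) — this is a computational default, and partial-volume values
after pooling carry the same shape information. Training is cross-entropy
with Adam (1e-3), minibatches of 4, and the same augmentation family.
The mean softmax probability score is reported over all subjects (primary)
and over positive calls only, since the convention is ambiguous.

## ROC calibration

Detection thresholds for each index are calibrated on the
internal-validation split only and frozen before external evaluation
(a leakage test asserts that permuting external labels leaves thresholds
bit-identical). AUC is the empirical trapezoidal area, computed in its
rank-statistic form with ties counted one half; candidate thresholds are
the midpoints of consecutive sorted unique scores plus sentinels beyond
the data range; the operating point maximises sensitivity + specificity
(Youden), with ties broken toward the smaller threshold (favouring
sensitivity) and flagged on the result. Confidence intervals for AUC,
threshold, sensitivity and specificity are nonparametric bootstrap
percentile intervals over subjects (seeded; resamples drawn until both
classes are present). DeLong or binomial intervals would also be
defensible; bootstrap was chosen as one method covering all four
quantities. Pearson correlations between predicted and true volumes carry
Fisher-z confidence intervals.

## The synthetic phantom cohort

Real cohorts of this kind are not shareable, so deshkit generates
schematic cranial phantoms: a cranial ellipsoid (semi-axes 70×75×62 mm,
intracranial volume ≈ 1.36 L) of parenchyma into which the six categories
are carved — paired ellipsoidal lateral ventricles plus midline third and
fourth ventricles; two oblique Sylvian slabs and a basal-cistern shell
(kept radially interior so they never touch the outer SAS shell, which
keeps seeded region growth exact); a thin vertex shell restricted by
exactly the landmark rule above (high-convexity SAS); and a residual outer
shell (other SAS). Each compartment has one free geometric parameter
fitted by bisection so the realised voxel volume matches its target within
5%; unreachable targets raise rather than truncate. Landmarks are emitted
from the fitted geometry, so the partition module's rules reproduce the
generator's high-convexity label exactly. Default grid: 64³ voxels at
2.5 mm isotropic (desk scale; the field of view must hold the whole head,
so smaller grids should scale the voxel size up, e.g. 32³ at 5 mm).
Sub-millimetre clinical grids are supported but not default.

Volume targets are sampled from a built-in calibration table of per-group
(DESH vs healthy) means ± SDs per contrast, reflecting published automated
volumetry in Hakim patients and healthy controls (T1-like: ventricles
129.2 ± 35.1 vs 26.9 ± 19.4 mL, Sylvian/basal 90.2 ± 12.0 vs 42.9 ± 10.3,
high-convexity 17.9 ± 3.7 vs 42.5 ± 12.1; analogous T2 columns). The
other-SAS row is derived as total SAS minus the two named compartments.
Only marginal statistics are published, so deshkit couples the
compartments through a single per-subject severity latent (truncated
normal, ±2.4 SD, weight 0.95, plus 5% independent jitter), sign-flipped
for the high-convexity compartment in the DESH group — more severe disease
means larger ventricles/fissures *and* tighter convexity. This coupling
matches the clinical picture of CSF redistribution and guarantees that the
two groups do not overlap in index space, as the published group effect
sizes imply. Targets are floored at max(0.5 mL, 128 voxel volumes): a
compartment smaller than that cannot honour a 5% volume tolerance at the
default grid resolution. Intensities are flat per tissue (CSF-bright
T2-like: 900 vs parenchyma 350; CSF-dark T1-like: 150 vs 600; background
20) plus Gaussian noise (default SD 20). Cohorts draw DESH ages from
N(75, 7) and non-DESH from N(54, 15) years (mirroring the age imbalance of
real cohorts), sex ≈ 43% male. DESH implies THC and SFD by definition; VD
accompanies DESH with probability 0.95; isolated VD/THC/SFD occur in
non-DESH subjects at 2% (never THC and SFD together, which would
constitute DESH). Volume targets are keyed by the DESH flag alone, so the
rare isolated flags are label noise for the secondary tasks.

What the phantoms deliberately lack: cortical folding, partial-volume
mixing, bias fields, k-space artefacts, anatomical left-right asymmetry,
and any pathology other than CSF-space morphometry. Passing tests
therefore demonstrate that the pipeline's mathematics and learning
machinery are correct on geometry with known truth — not that the trained
networks would transfer to clinical MRI, which requires real training
data.

## Numerical and engineering choices

The networks run on a small NumPy engine written for this package:
convolutions evaluate as fused row-wise kernels (numba-compiled, with a
pure-NumPy shifted-GEMM reference path; the two are cross-checked in the
tests), and every layer's backward pass is verified against central finite
differences. Batch normalisation with batch size one normalises over the
spatial grid, and the same per-input instance statistics are used at
inference: the network co-adapts to per-subject statistics during
training, so an exponential moving average over training subjects matches
none of them (a known batch-size-one failure mode that collapsed held-out
segmentation in early experiments). Inference remains deterministic. All randomness flows from one top-level seed through named
substreams (phantom, augmentation, training, bootstrap); identical seeds
give identical cohorts, parameters and reports on the same platform
(floating-point reduction order pins exact bitwise repeats to
single-threaded execution). Checkpoints are single `.npz` files embedding
the configuration.

Desk-scale problem sizes used by the test suite and the acceptance script
— e.g. 20 training phantoms at 64³ with ≤ 300 U-Net iterations, 40
training phantoms at 32³ for the classifier, 60-phantom cohorts for the
ROC pathway — were chosen so the whole suite runs on a single CPU in well
under half an hour while leaving comfortable margins on every check.

## Known limitations

* The phantom geometry is schematic; segmentation difficulty is far below
  clinical MRI, so the U-Net accuracy on phantoms is an upper bound.
* The seed-grown Sylvian/basal extraction requires seeds inside the
  compartment; on predicted (noisy) masks, seeds falling outside the
  predicted SAS are dropped, and missing seeds shift volume to other SAS.
* THC/SFD severity has no quantitative definition; phantom flags are
  assigned by construction (volume regime), which cannot capture expert
  visual judgment.
* Published CIs for AUC/sensitivity/specificity do not state their method;
  bootstrap percentile intervals are one defensible choice, not the only
  one.
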