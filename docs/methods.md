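# Methods

This note documents the models, numerical choices, and study conditions
behind `flairwm`, in the spirit of a model-description appendix.

## Pipeline model and assumptions

The pipeline assumes its input FLAIR volumes are already bias-corrected and
nonlinearly registered to a common template space, so that the template's WM
probability map is voxelwise meaningful for every scan. Those two steps are
external (hooks shell out to user-installed tools; see
`flairwm.preprocess.ExternalPreprocessing`); everything downstream is
computed by the package. The central assumption is that WM abnormalities are
the *brightest* WM compartment on FLAIR, so an intensity clustering of the
extracted WM concentrates lesion evidence in the top intensity cluster, and
per-voxel fuzzy memberships — unlike raw intensities — are comparable across
scanners because fuzzy C-means is equivariant under affine intensity maps.

## Robust fuzzy C-means

The clustering minimizes the spatially penalized objective

    J(u, v) = Σ_j Σ_k u_jk^q (y_j − v_k)² +
              (β/2) Σ_j Σ_k u_jk^q Σ_{l∈N_j} Σ_{m≠k} u_lm^q

subject to Σ_k u_jk = 1, with q = 2 and the 6-face neighborhood N_j. The
cross-class penalty charges a voxel for committing to a cluster its
neighbors avoid, yielding smoother membership maps and some noise
insensitivity.

Numerical scheme. Memberships are updated in a red-black (checkerboard)
sweep: with a 6-face neighborhood the penalty couples only voxels of
opposite parity, so updating one parity class with the other fixed is an
*exact* block-coordinate minimization (closed form
u_jk ∝ D_jk^(−1/(q−1)) with D_jk = (y_j − v_k)² + β Σ_{l∈N_j} Σ_{m≠k}
u_lm^q), followed by the closed-form centroid update. Every sub-step is a
descent step, so the objective is non-increasing at every iteration — a
property the test suite asserts, and one a fully synchronous (Jacobi) update
would not guarantee. At β = 0 both parities reduce to the identical standard
FCM update, which is how the implementation is cross-checked against a
direct-formula FCM oracle.

Defaults: K = 3 clusters, q = 2, β = 0.005, convergence when the largest
centroid change falls below 1e−5, at most 200 iterations, with a final
membership refresh so the returned memberships correspond to the returned
centroids. β = 0.005 puts the penalty term at roughly ten percent of the
data term on the default 32³ phantom, small enough not to distort the
three-level recovery, large enough to exercise the smoothing. Centroids are
initialized at the 25th/50th/75th in-mask intensity percentiles
(deterministic; a seeded random fallback exists), and are returned sorted
ascending with memberships permuted accordingly, which makes "cluster 3"
(the brightest) well-defined regardless of initialization order. The
clustering support is {voxels with extracted-WM intensity > 0}: WM
extraction is multiplicative, so zero means no WM evidence. Degenerate
inputs (empty mask, fewer than K distinct intensities) raise; voxels whose
intensity coincides exactly with a centroid get membership 1 there (split
over ties).

Cluster selection binarizes each membership map and the reference at 0.5
and takes the highest Dice; ties break toward the highest centroid (lesions
are the brightest compartment). Dice of two empty masks is defined as 1
(vacuous agreement), but an all-zero Dice vector raises — it signals
mis-registration or an incompatible reference rather than a valid "no
match". Membership thresholding zeroes values below τ = 0.5 and keeps the
rest as floats (not binarized). The reference ships as a procedure, not a
file: `build_reference` averages the brightest-cluster maps of four
lesion-positive phantoms, mirroring how a fixed reference is made from a
handful of clinical scans.

## The 3D CNN

The classifier consumes the thresholded membership map, never the raw
image. Reference configuration: input layer; five blocks of
Conv3D(3×3×3, same padding, stride 1, ReLU) → MaxPool3D(2³, stride 2) →
BatchNorm; then GlobalAvgPool3D → Dense(512, ReLU) → Dropout(0.3) →
Dense(1, sigmoid). That is 20 layers and 1,795,905 parameters, counting 4
per batch-normalized channel (scale, shift, moving mean, moving variance);
global average pooling makes the count independent of the input grid.
Same padding with floor-division pooling lets five halvings work on
arbitrary dims (193 → 96 → 48 → 24 → 12 → 6). Training uses binary
cross-entropy, Adam, early stopping on validation loss with patience 40,
and a checkpoint rule that saves when validation accuracy strictly
improves, or — accuracy unchanged — when validation loss has decreased
relative to the best checkpoint; the returned weights are the checkpointed
ones. Unspecified training hyperparameters default to learning rate 1e−4,
batch size 4, 200 epochs, all configurable. Inference thresholds the
sigmoid at 0.5 with ties labeled positive (a screening context favors
sensitivity). Ensemble predictions use majority vote with exact ties
positive.

The network runs on a compact NumPy engine written for this package
(im2col + BLAS matmul convolution, reshape-reduce pooling, manual
backpropagation, float32). It is sized for desk-scale volumes; the
reference 193×229×193 configuration builds and counts correctly but is not
meant to be trained at full scale here.

## Synthetic phantoms

The generator emulates what the pipeline sees after preprocessing:
pre-aligned volumes plus a WM probability map. A head is three nested
ellipsoids — CSF core (ventricle-like), WM shell, GM rim — whose hard
labels are Gaussian-blurred into smooth probability maps (the blur
preserves the partition of unity, so the maps sum to ≤ 1). FLAIR-like
contrast uses fixed tissue levels 0.1 / 0.5 / 0.65 (CSF / WM / GM,
arbitrary units): only the ordering CSF < WM < GM < lesion matters
downstream. White matter additionally carries a smooth per-subject
multiplicative texture (sd 8% of the WM level, clipped at ±25%): real WM
is not uniformly bright, and this biological variation is what makes the
brightest cluster spatially diffuse in healthy brains versus
lesion-concentrated in abnormal ones — without it the top cluster is nearly
identical in both classes and the classification problem collapses.
Lesions are 1–3 smooth-edged blobs placed in the WM core (probability
≥ 0.5), radii from 2.5 voxels up to a fifth of the smallest dimension
(loads of roughly 3–10% of the WM core, the multifocal-to-confluent
regime), with mean intensity `lesion_contrast` × the WM level (default
1.6).

Protocol heterogeneity is purely non-biological and applied in order:
smooth multiplicative bias field (peak-to-peak fraction `bias_amplitude`),
affine map gain·x + offset, additive Gaussian noise, and optional
thick-slice emulation (slab-average the slice axis down to `n_slices`, then
nearest-neighbor re-expand — how a 2D acquisition looks after resampling to
template space). Noise is Gaussian rather than Rician; Rician noise, real
anatomy, motion artifacts, and longitudinal structure are out of scope.
Two subjects generated from the same seed under different protocols have
identical lesion masks. The default battery (`default_protocols`) spans
gains 0.7–2.5, offsets −0.1–0.5, noise 0.03–0.08, bias 0.10–0.35, and two
thick-slice protocols; the benign battery (`easy_protocols`) uses low noise
(0.02–0.03), mild bias, and contrast 1.8 — kept moderate deliberately,
because pushing contrast much higher makes the top cluster lesion-only and
spatially idiosyncratic, which degrades Dice matching against a fixed
reference.

What passing tests do and do not show: the phantoms demonstrate that the
implementation is correct and that the clustering mechanism suppresses
affine/bias/noise protocol effects as designed; they do not demonstrate
clinical performance, which depends on real anatomy, real lesion
morphology, and registration quality.

## Evaluation machinery

Metrics are accuracy, sensitivity, specificity, precision, F1 (all in
percent, computed from the confusion counts, NaN — never silently 0 — when
undefined) and AUROC (rank statistic with tie correction, reported in
percent with the unit recorded). MLcps% is the pentagon radar area
½·sin 72° · Σ r_i·r_{i+1(cyclic)} normalized by the all-100 pentagon, in
the fixed axis order (accuracy, sensitivity, specificity, F1, precision);
the area depends on axis order, which is therefore recorded in every
report. It is invariant under cyclic rotation and reversal but not
arbitrary permutation. The permutation test shuffles the pooled train+val
labels, retrains the pipeline, and records test accuracy; the p-value uses
the add-one convention (1 + #{null ≥ observed})/(1 + n) to avoid zero
p-values. Segmentation masks binarize to scan labels via connected
components: positive iff some face-6-connected component has ≥ 5 voxels
(18/26-connectivity configurable).

Split designs. Family A splits each dataset 70/10/20 (largest-remainder
apportionment, remainder priority train → test → val; classes interleaved
so every partition is balanced to within one scan) and, for index i > 0,
removes ~10%·i of the original train+val pool while the test set stays
byte-identical; removals alternate classes, come from the partition where
that class is most over-represented, and always take from the
most-represented protocol, never a protocol's last scan while another has
two or more. Family B draws identical per-protocol counts (default 5/1/1)
with per-protocol class quotas alternating across protocols so totals stay
balanced; infeasible protocols are excluded with a warning. Family C keeps
entire protocols out of training (only strict-3D scans participate; the
held-out pair rotates through the enumerated protocol combinations).
Family D fixes the train+val total (the paper-scale 82 is a parameter)
while varying the protocol count, per-protocol quotas within one of each
other. The orchestrator runs the full shuffle × run grid from one seed,
with every child seed derived deterministically per (shuffle, run, scan).

## Desk-scale study conditions

The validation suite and `scripts/acceptance.py` share one frozen
configuration (`flairwm.desk`): 32³ phantoms, four easy protocols, 48-scan
balanced cohorts split 24/8/16, the small CNN preset (blocks of 8/16
filters, 32 dense units, batch-norm momentum 0.9 so moving statistics
converge within short runs), Adam at 3e−3 for 30 epochs for observed
models, and 8-epoch retrains inside the 50-shuffle permutation null — a
label-shuffled model sits at chance regardless of training length, so the
null is unaffected while fifty retrains stay affordable on one CPU. The
full-scale counterparts (50 shuffles × 10 runs, 1,000 permutations,
193×229×193 inputs) remain available as parameters.

## Known limitations

Registration failures dominate real-world errors and are out of scope
(hooks only). The reference-matching step assumes the lesion-salient
cluster retains a consistent bright-WM background shape; cohorts whose top
cluster is lesion-only match less reliably. The NumPy CNN engine is
single-threaded BLAS-bound and not meant for full-resolution training.
Phantom realism is deliberately minimal (ellipsoidal anatomy, Gaussian
noise).
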