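# Methods

## Scope and data model

`svseg` segments a single-channel 3D MR intensity volume into CSF, GM and WM
given a brain mask and a small set of labelled voxels (or, for experiments, a
label budget drawn from a ground truth).  Volumes are handled in canonical
NIfTI orientation; all spatial arithmetic uses voxel spacing in millimetres,
so anisotropic acquisitions (e.g. 1×1×2 mm) produce physically isotropic
supervoxels.  Labels follow the convention 0 = unknown/background, 1 = CSF,
2 = GM, 3 = WM.

## Noise estimation

The noise standard deviation is estimated as `1.4826 × MAD` of the
finest-scale diagonal (HHH) 3D Haar wavelet coefficients, restricted to
2×2×2 blocks fully inside the mask.  These coefficients are pure noise
wherever the image is locally smooth; the median absolute deviation ignores
the sparse large coefficients that tissue edges contribute.  The estimator is
exact for additive Gaussian noise; for Rician noise at realistic SNR the
deviation from Gaussianity is second-order and inflates the estimate by at
most a few percent, which downstream use tolerates.  The consistency
constant 1.4826 assumes Gaussianity.

The estimate drives the patch-smoothing kernel through a bounded monotone
map: `kernel_sigma = clip(0.5 + g·σ/R, 0.5, 2.0)` voxels, where `R` is the
robust intensity range (1st–99th in-mask percentile span) and the gain
`g = (2.0 − 0.5)/0.09` interpolates linearly from the floor at zero noise to
the cap at a noise level of 9% of the range — the top of the noise range
simulated MRI benchmarks cover.  The kernel radius is `ceil(2·kernel_sigma)`.
Floor, cap and gain are exposed as keyword arguments, and a measured σ can
be overridden.

## Supervoxel stage

Localized k-means in the joint (intensity, space) domain:

* **Distance.** `d = |S(i) − I_c| + γ·d_spa` with `S = G ∗ I` the
  Gaussian-patch smoothed image, `d_spa` in mm and `γ = 0.2`
  (intensity-units per mm).  The smoothing is implemented as one
  whole-volume masked convolution — kernel weights falling outside the mask
  are renormalized over the in-mask support — which equals evaluating the
  smoothed patch at each center in O(N) and never drags boundary tissue
  toward the zero background.  Seed intensities and center updates live in
  smoothed-intensity space so both distance terms stay commensurate.
* **Seeding.** A voxel-center-aligned regular grid with per-axis step
  `L_mm/spacing` where `L_mm = ∛(N·v/q)` (`v` = voxel volume).  The grid is
  continuous (sub-voxel) and symmetric in each axis, which avoids systematic
  tie planes between neighbouring seeds.  Grid points outside the mask move
  to the nearest in-mask voxel if within `L/4` mm (rescuing thin structures
  the grid narrowly misses) and are dropped otherwise.  Each seed then moves
  to the lowest-gradient voxel of its 3×3×3 neighbourhood (ties keep the
  original position) so no seed starts on a tissue edge.
* **Iteration.** Assign (within each seed's `±L` window; equal distances keep
  the lower seed id), then update centers to member means; stop when the
  mean center displacement drops below 0.1 mm (default) or after 10
  iterations.  The algorithm is fully deterministic.
* **Cleanup.** Voxels covered by no window and, with
  `enforce_connectivity=True`, all non-largest 26-connected fragments of
  each supervoxel are re-attached by shell-wise region growing: every
  unassigned voxel that touches an assigned region joins the adjacent
  supervoxel with the closest mean intensity (ties to the lower id).
  Because each voxel attaches to a region it touches, every supervoxel is
  guaranteed to end as a single 26-connected component — a stronger and
  simpler rule than merging only small fragments, whose size threshold would
  otherwise leave multi-component supervoxels behind.  Unreachable mask
  islands become new supervoxels.  Ids are relabelled contiguously.

Defaults: `q = 4000` supervoxels and `γ = 0.2` for full-resolution brain
volumes; the desk-scale experiments in the test suite use 64³ phantoms with
`q = 500`, which keeps the per-supervoxel size (~200 voxels) in the same
regime at a few seconds of runtime.

## Graph-filter stage

* **Graph.** Node feature = mean smoothed intensity of the supervoxel (a
  scalar keeps the RBF weight exactly `exp(−(v_i−v_j)²/2α)`).  Each node
  connects to its `K = 10` nearest neighbours in feature space (ties to the
  lower id), the adjacency is symmetrized by union, given a zero diagonal,
  and divided by its largest-magnitude eigenvalue so that matrix powers are
  non-divergent; the scale change is absorbed by the fitted taps.  The
  bandwidth `α` defaults to the median squared feature distance over the
  selected KNN edges (self-scaling median heuristic), with a variance-based
  fallback when all selected distances vanish.
* **Filter.** `H = Σ_{l=0}^{L} h_l A^l` with `L = 4` taps by default,
  applied by iterated sparse matrix–vector products — no eigendecomposition
  and no assumption of diagonalizability.
* **Tap fitting.** For each class, `s_known` is +1/−1/0; half of the known
  nodes (stratified by sign, seeded) form `s_train`; the taps solve
  `argmin_h ‖D·h(A)·s_train − 1‖` with `D = diag(s_known)`.  Rows with
  `s_known = 0` contribute a constant and are dropped, making the target the
  all-ones vector on the known rows; `numpy.linalg.lstsq` returns the
  minimum-norm least-squares solution, which also covers rank-deficient
  systems (degenerate fixtures with constant features) without an explicit
  ridge term.  An identically zero system raises with advice to enlarge the
  training set.
* **Decision.** Scores `h_c(A)·s_known` per class, argmax with ties to the
  lower class id; nodes with given labels keep them.  With a label volume as
  input, each supervoxel's known label is the majority non-zero label of its
  voxels; in self-labelling experiments, `max(2, round(ratio·n_c))`
  supervoxels per class are drawn uniformly (the classifier requires at
  least two known nodes per class).

## Evaluation

`DSC = 2TP/(2TP+FP+FN)` and `VDR = |FP−FN|/(TP+FN)` per tissue, counted over
the evaluation mask (by default the union of the two foregrounds; pass an
explicit brain mask to restrict further).  DSC at zero overlap is reported
as 0; a class absent from the truth is reported as undefined rather than 0.
DSC is symmetric under swapping prediction and truth, VDR is not (its
denominator is the true class volume).  Supervoxel boundary adherence is
summarized as purity: the fraction of each supervoxel's voxels carrying its
majority ground-truth label.

## Phantom generator

The generator emulates simulated T1 brain volumes: three nested ellipsoidal
shells (outer CSF, GM, WM core) with a sinusoidal angular ripple on the
WM/GM interface, giving both large smooth regions and thin curved
structures; piecewise-constant tissue means (defaults 50/120/200 for
CSF/GM/WM); background exactly zero.  Corruption follows the acquisition
order — a smooth multiplicative bias field first (a single broad Gaussian
blob min–max scaled exactly to `[1−inu/2, 1+inu/2]`; its breadth keeps
voxel-to-voxel increments below 0.01 on a 64³ grid), then Rician noise
`sqrt((v+n₁)² + n₂²)` with `σ = noise_percent × max tissue mean`, i.e. the
noise percentage is read relative to the brightest tissue.  Everything is
deterministic given the spec's seed.

What the phantom does **not** emulate: partial-volume mixing at tissue
interfaces, anatomically realistic cortical geometry, spatially varying or
correlated noise, and multi-coil artefacts.  Passing tests on phantoms
therefore demonstrate the mechanics and noise behaviour of the pipeline, not
clinical-grade accuracy on real scans; on real data, accuracy is limited by
partial-volume effects the piecewise-constant model hides.

## Numerical choices and edge cases

* All ties (seed assignment, KNN selection, argmax over classes, fragment
  merging) break toward the lower index, making every stage deterministic.
* Seeds that lose all members during iteration are removed and ids
  compacted; empty supervoxels are an invariant violation thereafter.
* The spectral normalization uses a dense symmetric eigensolver below 256
  nodes and a Lanczos solver with a fixed deterministic start vector above.
* Graph-score magnitudes obey `‖h(A)s‖₂ ≤ Σ|h_l|·‖s‖₂` after normalization
  (the ℓ∞ analogue does not hold in general, since the row sums of the
  spectrally normalized adjacency may exceed 1).
* `dwtn` blocks are cropped to even dimensions so every Haar coefficient
  covers a real 2×2×2 block; with fewer than 8 fully in-mask blocks the
  estimator falls back to all blocks.

## Known limitations

* A single scalar intensity feature cannot separate tissues whose mean
  intensities collide under a strong bias field; the feature extractor
  accepts the smoothed image, but no bias-field correction is performed.
* Heavy patch smoothing (kernel near its 2-voxel cap) creates a thin
  intermediate-intensity band along very-high-contrast interfaces in the
  smoothed image; cluster centers can settle in that band and cost a few
  boundary voxels of purity.  At such contrasts the raw distance is already
  noise-proof, so the patch distance's advantage materializes at
  tissue-scale contrasts (where noise is competitive), not at extreme ones.
* The label-budget sampler assumes every class is present among the
  supervoxel-level truth; classes thinner than a supervoxel may vanish at
  the node level before sampling.
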