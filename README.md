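# svseg

Semi-supervised brain-tissue segmentation for 3D MR images, in two stages:
noise-robust **supervoxel** generation, followed by supervoxel classification
into cerebrospinal fluid (CSF), grey matter (GM) and white matter (WM) by
**polynomial graph filtering** of a partially labelled graph signal.

It is aimed at neuroimaging researchers who have a skull-stripped T1 volume
(NIfTI), optionally a handful of labelled voxels, and want a full tissue
segmentation without atlases or training data beyond those labels.

## Method

**Stage 1 — supervoxels.** The masked volume is oversegmented into ~q
compact supervoxels by a SLIC-style localized k-means.  Because magnitude MR
images carry Rician noise, the voxel-to-seed similarity compares a
Gaussian-patch-smoothed intensity rather than the raw voxel:

    d_int = | (G * I)(i) − I_c |,        d = d_int + γ · d_spa

where `G` is a Gaussian kernel whose width adapts to the noise level
(estimated by the median absolute deviation of the finest-scale 3D Haar
wavelet coefficients), `I_c` is the seed intensity, `d_spa` the Euclidean
voxel-to-seed distance in millimetres, and `γ = 0.2` the spatial
regularization weight.  Seeds start on a regular grid of spacing
`L = ∛(N/q)`, are nudged off intensity edges, and compete for voxels inside
a `2L × 2L × 2L` window; every supervoxel ends up a single 26-connected
component.

**Stage 2 — graph filtering.**  Each supervoxel becomes a graph node with
feature `v_i` (mean smoothed intensity); nodes are joined to their K nearest
neighbours in feature space with RBF weights
`A(i,j) = exp(−(v_i − v_j)² / 2α)`, symmetrized and normalized by the
largest eigenvalue.  Known labels enter as a graph signal `s_known` (+1 /
−1 / 0) and are propagated by a polynomial graph filter

    H = h(A) = Σ_{l=0}^{L} h_l A^l,        s_predict = h(A) · s_known

whose taps `h` are fitted per class from a training subset of the known
nodes by least squares, `argmin_h ‖ D·h(A)·s_train − 1 ‖` with
`D = diag(s_known)`.  Multi-class segmentation is one-against-all; voxels
inherit their supervoxel's class.

Accuracy is reported per tissue as the Dice similarity coefficient
`DSC = 2TP / (2TP + FP + FN)` and the volume difference ratio
`VDR = |FP − FN| / (TP + FN)`.

A synthetic phantom generator (nested ellipsoidal CSF/GM/WM shells with a
rippled cortical interface, multiplicative bias field, Rician noise)
provides ground-truthed test volumes so the whole pipeline runs offline.

## Worked example

```python
from svseg import PhantomSpec, generate_phantom, segment_volume

ph = generate_phantom(PhantomSpec(shape=(64, 64, 64), noise_percent=0.05,
                                  inu_percent=0.2, rng_seed=1))
res = segment_volume(ph.intensity, truth=ph.truth, label_ratio=0.3,
                     q=500, K=10, L_taps=4, rng_seed=1)
for row in res.evaluate(ph.truth, mask=ph.mask).rows():
    print(row["class"], round(row["DSC"], 4), round(row["VDR"], 4))
```

prints

```
CSF 0.9724 0.0261
GM 0.9449 0.0306
WM 0.9333 0.014
```

i.e. with 30% of supervoxels labelled, ≥ 93% Dice overlap with the ground
truth for every tissue and class-volume errors of 1–3%, on a phantom with 5%
Rician noise and a 20% bias field.

The same pipeline is scriptable from the shell:

```sh
svseg phantom --shape 64,64,64 --noise 0.05 --inu 0.2 --seed 1 \
      --out-img img.nii.gz --out-truth truth.nii.gz
svseg segment --img img.nii.gz --truth truth.nii.gz --label-ratio 0.3 \
      --q 500 --seed 1 --out seg.nii.gz
svseg evaluate --pred seg.nii.gz --truth truth.nii.gz --out metrics.csv
svseg sweep --ratios 0.02,0.05,0.1,0.15,0.2,0.3 --seeds 5 --out sweep.csv
```

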