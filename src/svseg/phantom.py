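"""Synthetic 3D brain-like phantoms with ground truth, Rician noise and bias.

The generator emulates the statistical structure of simulated T1 brain MRI:
approximately piecewise-constant tissue regions (an outer CSF shell, a GM
shell, and a WM core whose boundary carries a sinusoidal "cortical folding"
ripple), corrupted first by a smooth multiplicative intensity-non-uniformity
(INU) field and then by Rician noise.  Noise level is expressed, BrainWeb
style, as a fraction of the brightest tissue mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabelVolume, Volume

DEFAULT_TISSUE_MEANS = {1: 50.0, 2: 120.0, 3: 200.0}  # CSF, GM, WM


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    noise_percent is the Rician noise level as a fraction of the maximum
    tissue mean (0.09 = "9% noise"); inu_percent the peak-to-peak amplitude
    of the multiplicative bias field (0.20 / 0.40 for "20% / 40% INU").
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    tissue_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_percent: float = 0.0
    inu_percent: float = 0.0
    rng_seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape components must be >= 8, got {self.shape}")
        if set(self.tissue_means) != {1, 2, 3}:
            raise ValueError(f"tissue_means must map classes {{1,2,3}}, got {sorted(self.tissue_means)}")
        means = [float(self.tissue_means[c]) for c in (1, 2, 3)]
        if any(m <= 0 for m in means):
            raise ValueError(f"tissue_means must be strictly positive, got {means}")
        if len(set(means)) != 3:
            raise ValueError(f"tissue_means must be pairwise distinct, got {means}")
        if not 0.0 <= self.noise_percent < 1.0:
            raise ValueError(f"noise_percent must lie in [0, 1), got {self.noise_percent}")
        if not 0.0 <= self.inu_percent < 1.0:
            raise ValueError(f"inu_percent must lie in [0, 1), got {self.inu_percent}")


@dataclass
class LabeledPhantom:
    """A phantom intensity volume with its ground-truth tissue labels."""

    intensity: Volume
    truth: LabelVolume

    def __post_init__(self) -> None:
        if self.intensity.shape != self.truth.shape:
            raise ValueError("intensity and truth shapes differ")

    @property
    def mask(self) -> np.ndarray:
        return self.truth.data > 0


def _as_data(x) -> np.ndarray:
    return x.data if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)


def _like(x, data: np.ndarray):
    if isinstance(x, Volume):
        return Volume(data, spacing=x.spacing, mask=x.mask, affine=x.affine)
    return data


def add_rician_noise(clean, sigma: float, rng_seed: int):
    """Corrupt an image with Rician noise of parameter ``sigma``.

    Each voxel v becomes sqrt((v + n1)^2 + n2^2) with n1, n2 independent
    zero-mean Gaussians of standard deviation sigma — the magnitude of a
    complex Gaussian-corrupted signal, as in magnitude MR reconstruction.
    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    data = _as_data(clean)
    if sigma == 0:
        return _like(clean, data.copy())
    rng = np.random.default_rng(rng_seed)
    n1 = rng.normal(0.0, sigma, size=data.shape)
    n2 = rng.normal(0.0, sigma, size=data.shape)
    return _like(clean, np.sqrt((data + n1) ** 2 + n2 ** 2))


def bias_field(shape: tuple[int, int, int], inu_percent: float, rng_seed: int) -> np.ndarray:
    """A smooth multiplicative field scaled exactly to [1 - inu/2, 1 + inu/2].

    The field is one broad Gaussian blob (width 1.2 in coordinates normalized
    to [-1, 1]) with a randomly jittered centre, min-max rescaled.  The broad
    width bounds the voxel-to-voxel increment well below 0.01 on typical
    grids, mimicking slowly-varying coil sensitivity.
    """
    if not 0.0 <= inu_percent < 1.0:
        raise ValueError(f"inu_percent must lie in [0, 1), got {inu_percent}")
    if inu_percent == 0:
        return np.ones(shape, dtype=np.float64)
    rng = np.random.default_rng(rng_seed)
    center = rng.uniform(-0.4, 0.4, size=3)
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    tx, ty, tz = np.meshgrid(*axes, indexing="ij")
    width = 1.2
    f = np.exp(-((tx - center[0]) ** 2 + (ty - center[1]) ** 2 + (tz - center[2]) ** 2)
               / (2.0 * width ** 2))
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:  # degenerate (tiny grid): flat field
        return np.ones(shape, dtype=np.float64)
    g = (f - fmin) / (fmax - fmin)
    return (1.0 - inu_percent / 2.0) + inu_percent * g


def add_bias_field(clean, inu_percent: float, rng_seed: int):
    """Multiply an image by a smooth INU field; ``inu_percent = 0`` is identity."""
    data = _as_data(clean)
    if inu_percent == 0:
        return _like(clean, data.copy())
    return _like(clean, data * bias_field(data.shape, inu_percent, rng_seed))


def generate_phantom(spec: PhantomSpec) -> LabeledPhantom:
    """Generate a labelled phantom: nested ellipsoidal CSF/GM/WM shells.

    The WM/GM interface carries a sinusoidal angular ripple so the phantom
    exhibits both large smooth regions and thin curved structures.  The clean
    image equals the tissue mean at each voxel (background exactly zero);
    the bias field is applied first, Rician noise second, matching the
    physical acquisition order.  Deterministic for a fixed ``rng_seed``.
    """
    if not isinstance(spec, PhantomSpec):
        spec = PhantomSpec(**spec) if isinstance(spec, dict) else PhantomSpec(*spec)
    shape = np.array(spec.shape)
    center = (shape - 1) / 2.0
    semi = 0.46 * shape
    ii, jj, kk = np.indices(spec.shape, dtype=np.float64)
    ux = (ii - center[0]) / semi[0]
    uy = (jj - center[1]) / semi[1]
    uz = (kk - center[2]) / semi[2]
    r = np.sqrt(ux ** 2 + uy ** 2 + uz ** 2)
    theta = np.arctan2(uy, ux)
    phi = np.arccos(np.clip(uz / np.maximum(r, 1e-12), -1.0, 1.0))
    # WM core boundary with angular ripple; GM out to 0.85, CSF out to 1.0
    wm_r = 0.58 + 0.10 * np.sin(4.0 * theta) * np.sin(3.0 * phi)

    truth = np.zeros(spec.shape, dtype=np.uint8)
    truth[r <= 1.0] = 1
    truth[r <= 0.85] = 2
    truth[r <= wm_r] = 3

    clean = np.zeros(spec.shape, dtype=np.float64)
    for c, mean in spec.tissue_means.items():
        clean[truth == c] = float(mean)

    ss = np.random.SeedSequence(spec.rng_seed)
    bias_seed, noise_seed = (int(s) % (2 ** 31) for s in ss.generate_state(2))
    img = add_bias_field(clean, spec.inu_percent, bias_seed)
    sigma = spec.noise_percent * max(spec.tissue_means.values())
    img = add_rician_noise(img, sigma, noise_seed)

    vol = Volume(img, spacing=spec.spacing, mask=truth > 0)
    return LabeledPhantom(intensity=vol, truth=LabelVolume(truth))


def two_slab_phantom(shape: tuple[int, int, int] = (32, 32, 32),
                     low: float = 0.0, high: float = 200.0,
                     axis: int = 2) -> LabeledPhantom:
    """A full-mask volume split into two constant-intensity slabs.

    The simplest boundary-adherence fixture: one flat interface separating
    class 1 (intensity ``low``) from class 2 (intensity ``high``).
    """
    data = np.full(shape, float(low))
    truth = np.ones(shape, dtype=np.uint8)
    half = shape[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = slice(half, None)
    data[tuple(sl)] = float(high)
    truth[tuple(sl)] = 2
    vol = Volume(data, mask=np.ones(shape, dtype=bool))
    return LabeledPhantom(intensity=vol, truth=LabelVolume(truth))
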