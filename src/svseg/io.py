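"""NIfTI-1 input/output for intensity, mask and tissue-label volumes.

All internal math works on canonically-oriented arrays with 0-based voxel
indices; header/orientation handling is confined to this module.  Voxel
spacing is carried in millimetres so that anisotropic acquisitions (e.g.
1 x 1 x 2 mm) enter spatial distances physically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: tissue label convention used throughout: 0 = background/unknown
TISSUE_NAMES = {1: "CSF", 2: "GM", 3: "WM"}
VALID_LABELS = frozenset({0, 1, 2, 3})


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and an optional brain mask."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume.data must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume.data contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (all voxels when no mask is set)."""
        if self.mask is None:
            return int(self.data.size)
        return int(self.mask.sum())

    def get_mask(self) -> np.ndarray:
        """Boolean mask; a full-true array when no mask was provided."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask


@dataclass
class LabelVolume:
    """A 3D integer grid of tissue labels (0=unknown, 1=CSF, 2=GM, 3=WM)."""

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume.data must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("label volume contains non-integer values")
            self.data = rounded.astype(np.int64)
        found = set(np.unique(self.data).tolist())
        bad = found - VALID_LABELS
        if bad:
            raise ValueError(f"invalid label values {sorted(bad)}; allowed {sorted(VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def read_volume(path: str | Path, as_labels: bool = False) -> Volume | LabelVolume:
    """Load a NIfTI-1 file as a :class:`Volume` (or :class:`LabelVolume`).

    The image is reoriented to the closest canonical (RAS) axis order and the
    voxel spacing is read from the header.  With ``as_labels=True`` the voxel
    values are validated against the tissue label set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D image, got {img.ndim}D: {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    if as_labels:
        return LabelVolume(data, affine=np.asarray(img.affine))
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"image contains non-finite voxels: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(path: str | Path, volume: Volume) -> None:
    """Write an intensity volume as 32-bit float NIfTI-1."""
    affine = volume.affine if volume.affine is not None else _default_affine(volume.spacing)
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labels(path: str | Path, labels: LabelVolume,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a label volume as 8-bit unsigned-integer NIfTI-1.

    Validation happens in the :class:`LabelVolume` constructor, i.e. before
    any file is created.
    """
    if not isinstance(labels, LabelVolume):
        labels = LabelVolume(labels)  # validates before any I/O
    affine = labels.affine if labels.affine is not None else _default_affine(spacing)
    img = nib.Nifti1Image(labels.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def write_assignment(path: str | Path, assignment: np.ndarray,
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     affine: np.ndarray | None = None) -> None:
    """Write a supervoxel assignment grid as 32-bit signed-integer NIfTI-1."""
    if affine is None:
        affine = _default_affine(spacing)
    img = nib.Nifti1Image(np.asarray(assignment).astype(np.int32), affine)
    nib.save(img, str(path))
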