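"""Noise-robust SLIC supervoxels for 3D MRI volumes.

Localized k-means over joint intensity/space coordinates, with the intensity
term computed on a Gaussian-patch-smoothed image so that the voxel-to-seed
similarity d = d_int + gamma * d_spa is robust to Rician noise:

    d_int = | (G * I)(i) - I_c |        (G: noise-adaptive Gaussian kernel)
    d_spa = Euclidean voxel-to-seed distance in millimetres

Seeds start on a regular grid of spacing L = (N/q)^(1/3), are perturbed off
edges, and each seed competes for voxels inside a 2L x 2L x 2L window around
it.  Centers are iterated to convergence; stranded fragments and uncovered
voxels are merged into adjacent supervoxels so every supervoxel is one
26-connected component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Volume
from .noise import NoiseEstimate

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_OFFSETS26 = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


@dataclass
class SlicConfig:
    """Supervoxel clustering parameters.

    q: target supervoxel count; gamma: spatial regularization weight in the
    distance d = d_int + gamma * d_spa (intensity units per mm).
    """

    q: int = 4000
    gamma: float = 0.2
    max_iters: int = 10
    convergence_tol: float = 0.1  # mm, mean center displacement
    enforce_connectivity: bool = True

    def __post_init__(self) -> None:
        if self.q < 8:
            raise ValueError(f"q must be >= 8, got {self.q}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.max_iters < 1:
            raise ValueError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.convergence_tol <= 0:
            raise ValueError(f"convergence_tol must be > 0, got {self.convergence_tol}")


@dataclass
class SeedState:
    """Continuous seed positions (voxel coordinates), seed intensities, and grid spacing."""

    positions: np.ndarray    # (n, 3) float voxel coordinates
    intensities: np.ndarray  # (n,)
    L_spacing: float         # grid step, voxels: (N/q)^(1/3)
    step_vox: np.ndarray     # (3,) per-axis step in voxels (spacing-scaled)

    @property
    def n_seeds(self) -> int:
        return len(self.positions)


@dataclass
class SupervoxelMap:
    """Per-voxel supervoxel ids (-1 outside the mask) plus final centers."""

    assignment: np.ndarray
    centers: SeedState
    n_supervoxels: int

    def sizes(self) -> np.ndarray:
        inm = self.assignment >= 0
        return np.bincount(self.assignment[inm], minlength=self.n_supervoxels)


def _grid_geometry(volume: Volume, q: int) -> tuple[float, float, np.ndarray]:
    """Return (L_vox, L_mm, per-axis step in voxels) for target count q."""
    n = volume.n_voxels
    spacing = np.asarray(volume.spacing)
    L_vox = (n / q) ** (1.0 / 3.0)
    L_mm = (n * float(np.prod(spacing)) / q) ** (1.0 / 3.0)
    step_vox = np.maximum(L_mm / spacing, 1.0)
    return L_vox, L_mm, step_vox


def init_seeds(volume: Volume, q: int) -> SeedState:
    """Seeds on a regular grid of spacing L = (N/q)^(1/3) voxels.

    The per-axis step is scaled by voxel spacing so physical steps are
    near-isotropic.  Grid points outside the mask are moved to the nearest
    in-mask voxel when within L/4 mm of it (rescuing thin structures the
    grid narrowly misses), otherwise dropped; duplicate positions are
    collapsed.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    if q > volume.n_voxels:
        raise ValueError(f"q = {q} exceeds in-mask voxel count N = {volume.n_voxels}")
    mask = volume.get_mask()
    L_vox, L_mm, step_vox = _grid_geometry(volume, q)
    # continuous voxel-center-aligned grid: symmetric margins, no tie planes
    axes = []
    for dim, step in zip(volume.shape, step_vox):
        m = max(1, len(np.arange(step / 2.0, dim, step)))
        offset = (dim - step * (m - 1) - 1) / 2.0
        axes.append(offset + step * np.arange(m))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    vox = np.clip(np.floor(grid + 0.5).astype(int), 0,
                  np.asarray(volume.shape) - 1)

    inside = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    positions = [grid[inside]]
    voxels = [vox[inside]]
    outside = vox[~inside]
    if len(outside):
        dist, idx = ndimage.distance_transform_edt(
            ~mask, sampling=volume.spacing, return_indices=True)
        d = dist[outside[:, 0], outside[:, 1], outside[:, 2]]
        movable = d <= L_mm / 4.0
        moved = np.stack([idx[a][outside[movable, 0], outside[movable, 1],
                                outside[movable, 2]] for a in range(3)], axis=1)
        positions.append(moved.astype(np.float64))
        voxels.append(moved)
    positions = np.concatenate(positions, axis=0)
    voxels = np.concatenate(voxels, axis=0)
    _, keep = np.unique(voxels, axis=0, return_index=True)
    keep = np.sort(keep)
    positions, voxels = positions[keep], voxels[keep]
    intens = volume.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    return SeedState(positions=positions, intensities=intens,
                     L_spacing=L_vox, step_vox=step_vox)


def perturb_seeds(seeds: SeedState, volume: Volume) -> SeedState:
    """Move each seed to the lowest-gradient voxel in its 3x3x3 neighborhood.

    Keeps seeds off tissue edges.  Ties keep the original voxel (gradient
    strictly smaller is required to move); out-of-mask neighbors never win.
    Seed intensity is re-read at the new position.
    """
    mask = volume.get_mask()
    grads = np.gradient(volume.data, *volume.spacing)
    gm = np.sqrt(sum(g ** 2 for g in grads))
    gm = np.where(mask, gm, np.inf)
    shape = volume.shape
    vox = np.clip(np.floor(seeds.positions + 0.5).astype(int), 0,
                  np.asarray(shape) - 1)
    new_pos = seeds.positions.copy()
    new_vox = vox.copy()
    for s in range(len(vox)):
        best = gm[tuple(vox[s])]
        for off in _OFFSETS26:
            p = vox[s] + off
            if np.any(p < 0) or np.any(p >= shape):
                continue
            g = gm[tuple(p)]
            if g < best:
                best = g
                new_vox[s] = p
                # translate by the integer offset, preserving sub-voxel phase
                new_pos[s] = seeds.positions[s] + (p - vox[s])
    intens = volume.data[new_vox[:, 0], new_vox[:, 1], new_vox[:, 2]]
    return SeedState(positions=new_pos, intensities=intens,
                     L_spacing=seeds.L_spacing, step_vox=seeds.step_vox)


def patch_smoothed_intensity(volume: Volume, noise: NoiseEstimate | None) -> np.ndarray:
    """Gaussian-patch smoothing of the volume (the G * I of the distance).

    One whole-volume masked convolution: kernel weights falling outside the
    mask are renormalized over the in-mask support, so boundary tissue is
    never dragged toward the zero background.  ``noise=None`` (or a kernel
    radius of 0) bypasses smoothing, reducing d_int to the plain |I_i - I_c|.
    """
    mask = volume.get_mask()
    if noise is None or noise.kernel_radius == 0:
        return np.where(mask, volume.data, 0.0)
    truncate = noise.kernel_radius / noise.kernel_sigma
    num = ndimage.gaussian_filter(np.where(mask, volume.data, 0.0),
                                  noise.kernel_sigma, truncate=truncate)
    den = ndimage.gaussian_filter(mask.astype(np.float64),
                                  noise.kernel_sigma, truncate=truncate)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-12)
    return np.where(mask, out, 0.0)


def _window(center: np.ndarray, hw: np.ndarray, shape: tuple[int, ...]) -> tuple[slice, ...]:
    lo = np.maximum(np.round(center).astype(int) - hw, 0)
    hi = np.minimum(np.round(center).astype(int) + hw + 1, shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _keep_largest_components(assignment: np.ndarray, n: int) -> np.ndarray:
    """Boolean grid of voxels lying in the largest 26-component of their id."""
    keep = np.zeros(assignment.shape, dtype=bool)
    objects = ndimage.find_objects(assignment + 1)
    for c in range(n):
        if c >= len(objects) or objects[c] is None:
            continue
        sl = objects[c]
        local = assignment[sl] == c
        comp, ncomp = ndimage.label(local, structure=_STRUCT26)
        if ncomp <= 1:
            keep[sl] |= local
        else:
            sizes = np.bincount(comp[local])
            largest = int(np.argmax(sizes[1:])) + 1  # ties -> lowest comp id
            keep[sl] |= comp == largest
    return keep


def _grow_unassigned(assignment: np.ndarray, smoothed: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Merge unassigned in-mask voxels into adjacent supervoxels, shell by shell.

    Each pass attaches every unassigned voxel that touches an assigned one to
    the 26-neighbor supervoxel whose mean intensity is closest (ties to the
    lower id).  Because each attached voxel touches its target's current
    region, every supervoxel stays a single connected component.  Fragments
    unreachable from any assigned region (disconnected mask islands) are
    promoted to new supervoxels.
    """
    assignment = assignment.copy()
    inm = assignment[mask]
    n = int(assignment.max()) + 1
    sums = np.bincount(inm[inm >= 0], weights=smoothed[mask][inm >= 0], minlength=n)
    counts = np.bincount(inm[inm >= 0], minlength=n)
    mean_int = list(sums / np.maximum(counts, 1))

    while True:
        un = (assignment < 0) & mask
        if not un.any():
            break
        padded = np.pad(assignment, 1, constant_values=-1)
        best_d = np.full(assignment.shape, np.inf)
        best_lab = np.full(assignment.shape, -1, dtype=np.int64)
        mi = np.asarray(mean_int)
        for dx, dy, dz in _OFFSETS26:
            nb = padded[1 + dx:1 + dx + assignment.shape[0],
                        1 + dy:1 + dy + assignment.shape[1],
                        1 + dz:1 + dz + assignment.shape[2]]
            cand = un & (nb >= 0)
            if not cand.any():
                continue
            d = np.abs(smoothed - mi[np.maximum(nb, 0)])
            better = cand & ((d < best_d) | ((d == best_d) & (nb < best_lab)))
            best_d[better] = d[better]
            best_lab[better] = nb[better]
        attach = best_lab >= 0
        if attach.any():
            assignment[attach] = best_lab[attach]
        else:
            # isolated mask islands: promote each connected fragment to a new id
            comp, ncomp = ndimage.label(un, structure=_STRUCT26)
            for k in range(1, ncomp + 1):
                sel = comp == k
                assignment[sel] = len(mean_int)
                mean_int.append(float(smoothed[sel].mean()))
    return assignment


def _relabel_contiguous(assignment: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, int]:
    ids = np.unique(assignment[mask])
    ids = ids[ids >= 0]
    lut = np.full(int(assignment.max()) + 2, -1, dtype=np.int32)
    lut[ids] = np.arange(len(ids), dtype=np.int32)
    out = np.full(assignment.shape, -1, dtype=np.int32)
    out[mask] = lut[assignment[mask]]
    return out, len(ids)


def run_slic(volume: Volume, config: SlicConfig | None = None,
             noise: NoiseEstimate | None = None) -> SupervoxelMap:
    """Partition the masked volume into ~q compact noise-robust supervoxels.

    Iterates (assign, update): each in-mask voxel takes the seed minimizing
    d = |smoothed(i) - I_c| + gamma * d_spa(mm) over seeds whose 2L-window
    contains it (equal d keeps the lower seed id); each center then moves to
    the mean position / mean smoothed intensity of its members.  Stops when
    the mean center displacement falls below ``convergence_tol`` (mm).
    Uncovered voxels and, when ``enforce_connectivity``, stranded fragments
    are merged into adjacent supervoxels; ids are relabelled contiguously.
    Fully deterministic.
    """
    if config is None:
        config = SlicConfig()
    mask = volume.get_mask()
    if not mask.any():
        raise ValueError("empty mask")
    smoothed = patch_smoothed_intensity(volume, noise)
    svol = Volume(smoothed, spacing=volume.spacing, mask=mask)
    seeds = perturb_seeds(init_seeds(svol, config.q), svol)

    spacing = np.asarray(volume.spacing)
    _, L_mm, _ = _grid_geometry(volume, config.q)
    hw = np.maximum(1, np.ceil(L_mm / spacing).astype(int))  # window half-width, voxels
    shape = volume.shape

    pos = seeds.positions.copy()
    inten = seeds.intensities.copy()
    mask_idx = np.nonzero(mask)
    coords_mm = np.stack(mask_idx, axis=1) * spacing  # (N, 3)

    lab = np.full(shape, -1, dtype=np.int64)
    for _ in range(config.max_iters):
        best = np.full(shape, np.inf)
        lab = np.full(shape, -1, dtype=np.int64)
        for c in range(len(pos)):
            sl = _window(pos[c], hw, shape)
            subs = smoothed[sl]
            axes_mm = [(np.arange(s.start, s.stop) - pos[c][a]) * spacing[a]
                       for a, s in enumerate(sl)]
            d_spa = np.sqrt(axes_mm[0][:, None, None] ** 2
                            + axes_mm[1][None, :, None] ** 2
                            + axes_mm[2][None, None, :] ** 2)
            d = np.abs(subs - inten[c]) + config.gamma * d_spa
            bw, lw = best[sl], lab[sl]
            upd = (d < bw) & mask[sl]
            bw[upd] = d[upd]
            lw[upd] = c

        labs = lab[mask_idx]
        assigned = labs >= 0
        idx = labs[assigned]
        counts = np.bincount(idx, minlength=len(pos))
        alive = counts > 0
        new_pos = np.empty_like(pos)
        for a in range(3):
            new_pos[:, a] = np.bincount(idx, weights=mask_idx[a][assigned],
                                        minlength=len(pos)) / np.maximum(counts, 1)
        new_int = np.bincount(idx, weights=smoothed[mask_idx][assigned],
                              minlength=len(pos)) / np.maximum(counts, 1)
        disp = np.sqrt((((new_pos - pos) * spacing) ** 2).sum(axis=1))
        mean_disp = float(disp[alive].mean()) if alive.any() else 0.0
        # drop seeds that lost all members; remap surviving ids contiguously
        if not alive.all():
            remap = np.full(len(pos), -1, dtype=np.int64)
            remap[alive] = np.arange(int(alive.sum()))
            lab[mask] = np.where(lab[mask] >= 0, remap[np.maximum(lab[mask], 0)], -1)
        pos = new_pos[alive]
        inten = new_int[alive]
        if mean_disp < config.convergence_tol:
            break

    assignment = np.where(mask, lab, -1)
    if config.enforce_connectivity:
        n = int(assignment.max()) + 1
        keep = _keep_largest_components(np.where(mask, assignment, -1), n)
        assignment = np.where(keep, assignment, -1)
    assignment = _grow_unassigned(assignment, smoothed, mask)
    assignment, n_sv = _relabel_contiguous(assignment, mask)

    # final centers from the final partition
    labs = assignment[mask_idx]
    counts = np.bincount(labs, minlength=n_sv)
    fpos = np.stack([np.bincount(labs, weights=mask_idx[a], minlength=n_sv)
                     / np.maximum(counts, 1) for a in range(3)], axis=1)
    fint = np.bincount(labs, weights=smoothed[mask_idx], minlength=n_sv) / np.maximum(counts, 1)
    centers = SeedState(positions=fpos, intensities=fint,
                        L_spacing=seeds.L_spacing, step_vox=seeds.step_vox)
    return SupervoxelMap(assignment=assignment, centers=centers, n_supervoxels=n_sv)
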