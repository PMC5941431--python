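"""Per-tissue segmentation metrics (DSC, VDR) and supervoxel diagnostics.

DSC = 2 TP / (2 TP + FP + FN)  measures overlap with the ground truth;
VDR = |FP - FN| / (TP + FN)    measures the relative volume mismatch.
Counts are taken over the evaluation mask only (the brain; background is not
a tissue class).  DSC is symmetric in FP<->FN, VDR is not (its denominator
is the true class volume), so swapping prediction and truth can change VDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabelVolume, TISSUE_NAMES
from .slic import SupervoxelMap


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (class absent where required)."""


def _as_labels(x) -> np.ndarray:
    return x.data if isinstance(x, LabelVolume) else np.asarray(x)


def confusion_counts(pred, truth, class_id: int,
                     mask: np.ndarray | None = None) -> tuple[int, int, int]:
    """(TP, FP, FN) voxel counts for one class over the evaluation mask.

    With ``mask=None`` the domain is every voxel either volume labels
    (the union of the two foregrounds).
    """
    p = _as_labels(pred)
    t = _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if mask is None:
        mask = (p > 0) | (t > 0)
    elif mask.shape != p.shape:
        raise ValueError(f"mask shape {mask.shape} != label shape {p.shape}")
    p = p[mask]
    t = t[mask]
    tp = int(np.sum((p == class_id) & (t == class_id)))
    fp = int(np.sum((p == class_id) & (t != class_id)))
    fn = int(np.sum((p != class_id) & (t == class_id)))
    return tp, fp, fn


def dice(tp: int, fp: int, fn: int) -> float:
    """DSC = 2 TP / (2 TP + FP + FN); 0 at zero overlap, undefined if all counts are 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp == 0 and fp == 0 and fn == 0:
        raise UndefinedMetricError("class absent from both volumes: DSC undefined")
    return 2.0 * tp / (2.0 * tp + fp + fn)


def vdr(tp: int, fp: int, fn: int) -> float:
    """VDR = |FP - FN| / (TP + FN); undefined when the class is absent from truth."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp + fn == 0:
        raise UndefinedMetricError("class absent from ground truth: VDR undefined")
    return abs(fp - fn) / (tp + fn)


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    dsc: float | None  # None = undefined (class absent from truth)
    vdr: float | None


@dataclass
class TissueMetrics:
    """DSC/VDR per tissue class (1=CSF, 2=GM, 3=WM)."""

    per_class: dict[int, ClassMetrics]

    def __getitem__(self, class_id: int) -> ClassMetrics:
        return self.per_class[class_id]

    def rows(self) -> list[dict]:
        out = []
        for c, m in sorted(self.per_class.items()):
            out.append({"class": TISSUE_NAMES.get(c, str(c)), "TP": m.tp,
                        "FP": m.fp, "FN": m.fn, "DSC": m.dsc, "VDR": m.vdr})
        return out


def evaluate_segmentation(pred, truth, mask: np.ndarray | None = None,
                          classes: tuple[int, ...] = (1, 2, 3)) -> TissueMetrics:
    """Per-tissue DSC and VDR.  Classes absent from the truth are reported as
    undefined (None), not zero."""
    per_class: dict[int, ClassMetrics] = {}
    for c in classes:
        tp, fp, fn = confusion_counts(pred, truth, c, mask=mask)
        if tp + fn == 0:
            per_class[c] = ClassMetrics(tp, fp, fn, dsc=None, vdr=None)
        else:
            per_class[c] = ClassMetrics(tp, fp, fn, dsc=dice(tp, fp, fn),
                                        vdr=vdr(tp, fp, fn))
    return TissueMetrics(per_class)


def supervoxel_purity(svmap: SupervoxelMap, truth) -> np.ndarray:
    """Per-supervoxel fraction of voxels holding the majority truth label.

    Operationalizes boundary adherence: a supervoxel fully inside one tissue
    has purity 1.0; one straddling a boundary has purity < 1.0.
    """
    t = _as_labels(truth)
    if t.shape != svmap.assignment.shape:
        raise ValueError("truth shape does not match supervoxel map")
    inm = svmap.assignment >= 0
    labs = svmap.assignment[inm]
    tl = t[inm].astype(np.int64)
    n_lab = int(tl.max()) + 1
    counts = np.bincount(labs * n_lab + tl,
                         minlength=svmap.n_supervoxels * n_lab)
    counts = counts.reshape(svmap.n_supervoxels, n_lab)
    sizes = counts.sum(axis=1)
    if np.any(sizes == 0):
        raise ValueError("supervoxel with no voxels (invariant violation)")
    return counts.max(axis=1) / sizes
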