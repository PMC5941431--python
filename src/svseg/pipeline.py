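"""End-to-end segmentation pipeline: noise -> supervoxels -> graph -> labels.

Glues the stages together for the two operating modes:

* a partial label volume supplies the known supervoxel labels (each
  supervoxel takes the majority nonzero label among its voxels), or
* self-labelling experiments: known labels are sampled per class from the
  ground truth at a given ratio of supervoxels (stratified, seeded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import (SupervoxelGraph, build_knn_graph, classify_one_vs_all,
                    extract_features, labels_to_volume)
from .io import LabelVolume, Volume
from .metrics import TissueMetrics, evaluate_segmentation
from .noise import NoiseEstimate, estimate_noise
from .slic import SlicConfig, SupervoxelMap, run_slic


def node_majority_labels(svmap: SupervoxelMap, labels) -> np.ndarray:
    """Per-supervoxel majority label among labelled (nonzero) voxels; 0 if none.

    Majority ties break toward the lower class id.
    """
    lv = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    if lv.shape != svmap.assignment.shape:
        raise ValueError("label volume shape does not match supervoxel map")
    inm = svmap.assignment >= 0
    labs = svmap.assignment[inm]
    vals = lv[inm].astype(np.int64)
    n_lab = int(vals.max()) + 1
    counts = np.bincount(labs * n_lab + vals,
                         minlength=svmap.n_supervoxels * n_lab)
    counts = counts.reshape(svmap.n_supervoxels, n_lab)
    if n_lab <= 1:
        return np.zeros(svmap.n_supervoxels, dtype=np.int64)
    fg = counts[:, 1:]
    best = np.argmax(fg, axis=1) + 1
    return np.where(fg.sum(axis=1) > 0, best, 0).astype(np.int64)


def sample_known_labels(node_truth: np.ndarray, ratio: float,
                        rng_seed: int) -> np.ndarray:
    """Sample a per-class fraction of supervoxels as known labels.

    Draws max(2, round(ratio * n_c)) supervoxels uniformly per class c
    (clamped to the class size; the classifier needs >= 2 known nodes per
    class), 0 elsewhere.  Deterministic for a fixed seed.
    """
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must lie in (0, 1], got {ratio}")
    node_truth = np.asarray(node_truth).astype(np.int64).ravel()
    rng = np.random.default_rng(rng_seed)
    known = np.zeros_like(node_truth)
    for c in sorted(int(c) for c in np.unique(node_truth) if c > 0):
        members = np.flatnonzero(node_truth == c)
        k = min(len(members), max(2, int(round(ratio * len(members)))))
        sel = rng.choice(members, size=k, replace=False)
        known[sel] = c
    return known


@dataclass
class SegmentationResult:
    labels: LabelVolume
    svmap: SupervoxelMap
    graph: SupervoxelGraph
    noise: NoiseEstimate
    node_pred: np.ndarray
    node_known: np.ndarray

    def evaluate(self, truth, mask: np.ndarray | None = None) -> TissueMetrics:
        return evaluate_segmentation(self.labels, truth, mask=mask)


def segment_volume(volume: Volume,
                   known_labels: LabelVolume | np.ndarray | None = None,
                   truth: LabelVolume | np.ndarray | None = None,
                   label_ratio: float | None = None,
                   q: int = 4000, gamma: float = 0.2,
                   K: int = 10, L_taps: int = 4,
                   train_fraction: float = 0.5,
                   rng_seed: int = 0,
                   alpha: float | None = None,
                   override_sigma: float | None = None,
                   max_iters: int = 10,
                   convergence_tol: float = 0.1,
                   enforce_connectivity: bool = True) -> SegmentationResult:
    """Segment a masked volume into CSF/GM/WM.

    Either ``known_labels`` (a partial label volume) or both ``truth`` and
    ``label_ratio`` (self-labelling from ground truth) must be provided.
    """
    noise = estimate_noise(volume, override_sigma=override_sigma)
    config = SlicConfig(q=q, gamma=gamma, max_iters=max_iters,
                        convergence_tol=convergence_tol,
                        enforce_connectivity=enforce_connectivity)
    svmap = run_slic(volume, config, noise)
    features = extract_features(volume, svmap, noise)
    graph = build_knn_graph(features, K=K, alpha=alpha)

    if known_labels is not None:
        node_known = node_majority_labels(svmap, known_labels)
    elif truth is not None and label_ratio is not None:
        node_truth = node_majority_labels(svmap, truth)
        node_known = sample_known_labels(node_truth, label_ratio, rng_seed)
    else:
        raise ValueError("provide known_labels, or truth together with label_ratio")

    node_pred = classify_one_vs_all(graph, node_known, L_taps=L_taps,
                                    train_fraction=train_fraction,
                                    rng_seed=rng_seed)
    labels = labels_to_volume(node_pred, svmap)
    return SegmentationResult(labels=labels, svmap=svmap, graph=graph,
                              noise=noise, node_pred=node_pred,
                              node_known=node_known)
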