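"""Semi-supervised supervoxel classification with polynomial graph filters.

A KNN graph is built over per-supervoxel intensity features with RBF edge
weights A(i,j) = exp(-(v_i - v_j)^2 / (2 alpha)); the adjacency is
symmetrized by union and normalized by its largest-magnitude eigenvalue so
matrix powers stay bounded.  Labels (+1/-1 on known nodes, 0 elsewhere) are
propagated by a polynomial graph filter

    H = h(A) = sum_{l=0}^{L} h_l A^l,      s_predict = h(A) s_known,

whose taps h are fitted per class from a training subset of the known nodes
by least squares:  argmin_h || D h(A) s_train - 1 ||  with D = diag(s_known).
Multi-class segmentation uses the one-against-all strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io import LabelVolume, Volume
from .noise import NoiseEstimate
from .slic import SupervoxelMap, patch_smoothed_intensity


class DegenerateSystemError(RuntimeError):
    """Raised when the tap-fitting system is identically zero."""


@dataclass
class SupervoxelGraph:
    """KNN RBF graph over supervoxel features, spectrally normalized."""

    node_features: np.ndarray   # (n,) or (n, f)
    adjacency: sp.csr_matrix    # normalized: largest |eigenvalue| == 1
    alpha: float                # RBF bandwidth (squared intensity units)
    K: int
    spectral_norm: float        # the eigenvalue magnitude A was divided by

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GraphFilter:
    """Polynomial filter tap coefficients h_0 .. h_L."""

    taps: np.ndarray

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=np.float64).ravel()
        if self.taps.size < 1 or not np.all(np.isfinite(self.taps)):
            raise ValueError("taps must be a non-empty finite vector")

    @property
    def order(self) -> int:
        return self.taps.size - 1


@dataclass
class LabelSignal:
    """Known (+1/-1/0) and training-restricted label signals on the graph."""

    s_known: np.ndarray
    s_train: np.ndarray

    def __post_init__(self) -> None:
        self.s_known = np.asarray(self.s_known, dtype=np.float64).ravel()
        self.s_train = np.asarray(self.s_train, dtype=np.float64).ravel()
        if self.s_known.shape != self.s_train.shape:
            raise ValueError("s_known and s_train must have the same length")
        for name, s in (("s_known", self.s_known), ("s_train", self.s_train)):
            if not np.all(np.isin(s, (-1.0, 0.0, 1.0))):
                raise ValueError(f"{name} values must be in {{-1, 0, +1}}")
        if not ((self.s_known == 1).any() and (self.s_known == -1).any()):
            raise ValueError("s_known must contain at least one +1 and one -1")
        if np.any((self.s_train != 0) & (self.s_train != self.s_known)):
            raise ValueError("support of s_train must lie inside s_known")


def extract_features(volume: Volume, svmap: SupervoxelMap,
                     noise: NoiseEstimate | None = None) -> np.ndarray:
    """Per-supervoxel feature: mean (smoothed) intensity over member voxels."""
    if svmap.assignment.shape != volume.shape:
        raise ValueError("supervoxel map shape does not match volume")
    data = patch_smoothed_intensity(volume, noise)
    inm = svmap.assignment >= 0
    labs = svmap.assignment[inm]
    counts = np.bincount(labs, minlength=svmap.n_supervoxels)
    if np.any(counts == 0):
        raise RuntimeError("empty supervoxel encountered (invariant violation)")
    sums = np.bincount(labs, weights=data[inm], minlength=svmap.n_supervoxels)
    return sums / counts


def build_knn_graph(features: np.ndarray, K: int = 10,
                    alpha: float | None = None) -> SupervoxelGraph:
    """KNN RBF graph: per-node edges to the K nearest neighbors in feature space.

    Weights follow A(i,j) = exp(-(v_i - v_j)^2 / (2 alpha)); neighbor ties go
    to the lower node id.  The graph is symmetrized by union (an edge is kept
    if either endpoint selected it), the diagonal is zero, and the matrix is
    divided by its largest-magnitude eigenvalue.  ``alpha=None`` uses the
    median of squared feature distances over the selected KNN edges.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n <= K:
        raise ValueError(f"need n > K nodes, got n={n}, K={K}")
    if alpha is not None and alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")

    nbr = np.empty((n, K), dtype=np.int64)
    d2sel = np.empty((n, K), dtype=np.float64)
    chunk = max(1, int(2e7) // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = ((X[lo:hi, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        d2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        order = np.argsort(d2, axis=1, kind="stable")[:, :K]
        nbr[lo:hi] = order
        d2sel[lo:hi] = np.take_along_axis(d2, order, axis=1)

    if alpha is None:
        alpha = float(np.median(d2sel))
        if alpha <= 0:  # degenerate: all selected neighbors identical
            spread = float(np.var(X))
            alpha = spread if spread > 0 else 1.0

    w = np.exp(-d2sel / (2.0 * alpha))
    rows = np.repeat(np.arange(n), K)
    W = sp.coo_matrix((w.ravel(), (rows, nbr.ravel())), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union symmetrization

    if n <= 256:
        lam = float(np.max(np.abs(np.linalg.eigvalsh(W.toarray()))))
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals = spla.eigsh(W, k=1, which="LM", v0=v0, return_eigenvectors=False)
        lam = float(np.abs(vals[0]))
    if lam <= 0:
        raise ValueError("graph has no edges; cannot normalize")
    A = (W / lam).tocsr()
    return SupervoxelGraph(node_features=np.asarray(features, dtype=np.float64),
                           adjacency=A, alpha=float(alpha), K=K, spectral_norm=lam)


def apply_graph_filter(graph: SupervoxelGraph, filt: GraphFilter,
                       signal: np.ndarray) -> np.ndarray:
    """Evaluate s_out = sum_l h_l A^l s by iterated sparse products."""
    s = np.asarray(signal, dtype=np.float64).ravel()
    A = graph.adjacency
    if s.size != A.shape[0]:
        raise ValueError(f"signal length {s.size} != n_nodes {A.shape[0]}")
    x = s.copy()
    out = filt.taps[0] * x
    for h in filt.taps[1:]:
        x = A @ x
        out = out + h * x
    return out


def _power_columns(A: sp.csr_matrix, s: np.ndarray, L_taps: int) -> np.ndarray:
    cols = [s.copy()]
    x = s.copy()
    for _ in range(L_taps):
        x = A @ x
        cols.append(x.copy())
    return np.stack(cols, axis=1)  # (n, L+1)


def fit_filter_taps(graph: SupervoxelGraph, labels: LabelSignal,
                    L_taps: int = 4) -> GraphFilter:
    """Fit taps by least squares:  argmin_h || D h(A) s_train - 1 ||.

    Rows where s_known = 0 contribute a constant to the objective (D zeroes
    them) and are dropped; the minimum-norm least-squares solution of the
    remaining system B h = 1 is returned.
    """
    if L_taps < 0:
        raise ValueError(f"L_taps must be >= 0, got {L_taps}")
    if not ((labels.s_train == 1).any() and (labels.s_train == -1).any()):
        raise ValueError("training subset must contain both a +1 and a -1 node")
    M = _power_columns(graph.adjacency, labels.s_train, L_taps)
    known = labels.s_known != 0
    B = labels.s_known[known, None] * M[known]
    if not np.any(B):
        raise DegenerateSystemError(
            "tap-fitting system is identically zero; enlarge the training set")
    target = np.ones(int(known.sum()))
    h, *_ = np.linalg.lstsq(B, target, rcond=None)
    return GraphFilter(taps=h)


def classify_one_vs_all(graph: SupervoxelGraph, known_labels: np.ndarray,
                        L_taps: int = 4, train_fraction: float = 0.5,
                        rng_seed: int = 0) -> np.ndarray:
    """Multi-class supervoxel classification, one filter per class.

    For each class c the label signal is +1 on known nodes of class c, -1 on
    other known nodes, 0 elsewhere; a train subset (seeded, stratified by
    sign) fits the taps; scores are h_c(A) s_known; each unknown node takes
    the argmax class (ties to the lower class id).  Known nodes keep their
    given labels.
    """
    known = np.asarray(known_labels).astype(np.int64).ravel()
    n = graph.n_nodes
    if known.size != n:
        raise ValueError(f"known_labels length {known.size} != n_nodes {n}")
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must lie in (0, 1], got {train_fraction}")
    classes = sorted(int(c) for c in np.unique(known) if c > 0)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes among known labels")
    for c in classes:
        if int((known == c).sum()) < 2:
            raise ValueError(f"class {c} has fewer than 2 known nodes")

    rng = np.random.default_rng(rng_seed)
    scores = np.empty((len(classes), n))
    for ci, c in enumerate(classes):
        s_known = np.zeros(n)
        s_known[known == c] = 1.0
        s_known[(known > 0) & (known != c)] = -1.0
        train = np.zeros(n, dtype=bool)
        for sign in (1.0, -1.0):
            members = np.flatnonzero(s_known == sign)
            k = min(len(members), max(1, int(round(train_fraction * len(members)))))
            train[rng.choice(members, size=k, replace=False)] = True
        sig = LabelSignal(s_known=s_known, s_train=np.where(train, s_known, 0.0))
        filt = fit_filter_taps(graph, sig, L_taps=L_taps)
        scores[ci] = apply_graph_filter(graph, filt, s_known)

    pred = np.asarray(classes)[np.argmax(scores, axis=0)]
    pred = np.where(known > 0, known, pred)
    return pred.astype(np.int64)


def labels_to_volume(node_labels: np.ndarray, svmap: SupervoxelMap) -> LabelVolume:
    """Paint per-supervoxel class decisions back onto the voxel grid."""
    node_labels = np.asarray(node_labels).astype(np.int64).ravel()
    if node_labels.size != svmap.n_supervoxels:
        raise ValueError(
            f"node_labels length {node_labels.size} != n_supervoxels {svmap.n_supervoxels}")
    out = np.zeros(svmap.assignment.shape, dtype=np.uint8)
    inm = svmap.assignment >= 0
    out[inm] = node_labels[svmap.assignment[inm]]
    return LabelVolume(out)
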