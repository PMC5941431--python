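import numpy as np
import pytest
import scipy.sparse as sp

from svseg import (GraphFilter, LabelSignal, SupervoxelGraph, Volume,
                   apply_graph_filter, build_knn_graph, classify_one_vs_all,
                   estimate_noise, extract_features, fit_filter_taps,
                   labels_to_volume, run_slic, SlicConfig)


def _graph_from_dense(W):
    """Wrap an explicit symmetric weight matrix (normalizing by |lambda|max)."""
    W = np.asarray(W, dtype=float)
    lam = float(np.max(np.abs(np.linalg.eigvalsh(W))))
    return SupervoxelGraph(node_features=np.zeros(len(W)),
                           adjacency=sp.csr_matrix(W / lam),
                           alpha=1.0, K=1, spectral_norm=lam)


def _random_graph(rng, n, K=3):
    return build_knn_graph(rng.normal(size=n) * 10, K=K)


# ---------------------------------------------------------------- features

def test_feature_of_constant_supervoxel_is_its_intensity(study_phantom, study_svmap):
    vol = Volume(np.full((64, 64, 64), 120.0), mask=study_phantom.mask)
    feats = extract_features(vol, study_svmap)
    assert np.allclose(feats, 120.0)


def test_slab_features_form_two_separated_clusters(slab):
    est = estimate_noise(slab.intensity)
    svmap = run_slic(slab.intensity, SlicConfig(q=64), est)
    feats = extract_features(slab.intensity, svmap, est)
    low = feats[feats < 100]
    high = feats[feats >= 100]
    assert len(low) and len(high)
    assert high.min() - low.max() >= 100.0  # at least half the slab contrast


# ---------------------------------------------------------------- knn graph

def test_three_node_adjacency_hand_computed():
    """features (0, 0, 10), K=1, alpha=50: nodes 0 and 1 pick each other
    (weight exp(0)=1); node 2 ties between 0 and 1 -> lower id 0, with
    weight exp(-100/(2*50)) = 1/e; union symmetrization and division by the
    largest eigenvalue sqrt(1 + e^-2)."""
    g = build_knn_graph(np.array([0.0, 0.0, 10.0]), K=1, alpha=50.0)
    w = np.exp(-1.0)
    W = np.array([[0, 1, w], [1, 0, 0], [w, 0, 0]])
    lam = np.sqrt(1 + w ** 2)
    assert np.allclose(g.adjacency.toarray(), W / lam, atol=1e-12)
    assert g.spectral_norm == pytest.approx(lam)


def test_weight_at_one_bandwidth_is_inv_e():
    # (v_i - v_j)^2 = 2 alpha -> pre-normalization weight e^-1
    g = build_knn_graph(np.array([0.0, 2.0, 100.0]), K=1, alpha=2.0)
    # edge 0-1 has squared distance 4 = 2*alpha
    assert g.adjacency[0, 1] * g.spectral_norm == pytest.approx(np.exp(-1))


def test_spectral_norm_bounds_eigenvalues():
    g = _random_graph(np.random.default_rng(0), 40)
    lam = np.max(np.abs(np.linalg.eigvalsh(g.adjacency.toarray())))
    assert lam <= 1 + 1e-9


def test_neighbor_counts_between_k_and_2k():
    g = _random_graph(np.random.default_rng(1), 50, K=4)
    deg = (g.adjacency.toarray() > 0).sum(axis=1)
    assert deg.min() >= 4 and deg.max() <= 8


def test_too_few_nodes_rejected():
    with pytest.raises(ValueError, match="n > K"):
        build_knn_graph(np.arange(5.0), K=5)


# ---------------------------------------------------------------- filtering

def test_identity_taps_reproduce_signal():
    g = _random_graph(np.random.default_rng(2), 30)
    s = np.random.default_rng(3).normal(size=30)
    out = apply_graph_filter(g, GraphFilter([1, 0, 0, 0, 0]), s)
    assert np.array_equal(out, s)


def test_two_node_shift_hand_computed():
    g = _graph_from_dense([[0, 0.7], [0.7, 0]])  # normalizes to weight 1
    out = apply_graph_filter(g, GraphFilter([0, 1]), np.array([1.0, 0.0]))
    assert np.allclose(out, [0.0, 1.0])
    # un-normalized weight w survives through a manually built graph
    g2 = SupervoxelGraph(node_features=np.zeros(2),
                         adjacency=sp.csr_matrix(np.array([[0, 0.7], [0.7, 0]])),
                         alpha=1.0, K=1, spectral_norm=1.0)
    out2 = apply_graph_filter(g2, GraphFilter([0, 1]), np.array([1.0, 0.0]))
    assert np.allclose(out2, [0.0, 0.7])


def test_filter_linearity():
    g = _random_graph(np.random.default_rng(4), 25)
    rng = np.random.default_rng(5)
    s1, s2 = rng.normal(size=25), rng.normal(size=25)
    filt = GraphFilter(rng.normal(size=5))
    lhs = apply_graph_filter(g, filt, 2.0 * s1 - 3.0 * s2)
    rhs = 2.0 * apply_graph_filter(g, filt, s1) - 3.0 * apply_graph_filter(g, filt, s2)
    assert np.allclose(lhs, rhs, atol=1e-9)


def test_filter_matches_dense_polynomial():
    rng = np.random.default_rng(6)
    for _ in range(5):
        n = int(rng.integers(10, 50))
        g = _random_graph(rng, n)
        taps = rng.normal(size=5)
        s = rng.normal(size=n)
        A = g.adjacency.toarray()
        dense = sum(h * np.linalg.matrix_power(A, l) for l, h in enumerate(taps)) @ s
        assert np.allclose(apply_graph_filter(g, GraphFilter(taps), s), dense,
                           atol=1e-9)


def test_score_l2_bound():
    g = _random_graph(np.random.default_rng(7), 40)
    rng = np.random.default_rng(8)
    s = rng.choice([-1.0, 0.0, 1.0], size=40)
    taps = rng.normal(size=5)
    out = apply_graph_filter(g, GraphFilter(taps), s)
    assert np.linalg.norm(out) <= np.sum(np.abs(taps)) * np.linalg.norm(s) + 1e-9


# ---------------------------------------------------------------- tap fitting

def test_returned_taps_never_worse_than_identity_taps():
    g = _random_graph(np.random.default_rng(9), 30)
    rng = np.random.default_rng(10)
    s_known = rng.choice([-1.0, 1.0], size=30)
    sig = LabelSignal(s_known=s_known, s_train=s_known)
    filt = fit_filter_taps(g, sig, L_taps=4)

    def residual(h):
        pred = apply_graph_filter(g, GraphFilter(h), sig.s_train)
        r = s_known * pred - 1.0
        return np.linalg.norm(r[s_known != 0])

    assert residual(filt.taps) <= residual([1, 0, 0, 0, 0]) + 1e-12


def test_path_graph_taps_hand_computed():
    """Path 0-1-2 with weights 1 and 0.5, s_known=(1,1,-1), s_train=(1,0,-1),
    L=1: the normal equations give h = (1, sqrt(5)) exactly (h0 fits the end
    rows, h1 the middle row, both with zero residual)."""
    W = np.array([[0, 1, 0], [1, 0, 0.5], [0, 0.5, 0]])
    g = _graph_from_dense(W)
    sig = LabelSignal(s_known=np.array([1.0, 1.0, -1.0]),
                      s_train=np.array([1.0, 0.0, -1.0]))
    filt = fit_filter_taps(g, sig, L_taps=1)
    assert np.allclose(filt.taps, [1.0, np.sqrt(5.0)], atol=1e-9)


def test_taps_beat_grid_search_oracle():
    rng = np.random.default_rng(11)
    g = _random_graph(rng, 10)
    s_known = rng.choice([-1.0, 1.0], size=10)
    sig = LabelSignal(s_known=s_known, s_train=s_known)
    filt = fit_filter_taps(g, sig, L_taps=2)

    M = np.stack([sig.s_train,
                  g.adjacency @ sig.s_train,
                  g.adjacency @ (g.adjacency @ sig.s_train)], axis=1)
    B = s_known[:, None] * M

    def residual(h):
        return np.linalg.norm(B @ np.asarray(h) - 1.0)

    grid = np.linspace(-2, 2, 17)
    best = min(residual((a, b, c)) for a in grid for b in grid for c in grid)
    assert residual(filt.taps) <= best + 1e-6


def test_one_sided_training_set_rejected():
    g = _graph_from_dense([[0, 1, 0], [1, 0, 0.5], [0, 0.5, 0]])
    with pytest.raises(ValueError, match="train"):
        fit_filter_taps(g, LabelSignal(s_known=np.array([0.0, 1.0, -1.0]),
                                       s_train=np.array([0.0, 1.0, 0.0])),
                        L_taps=1)


# ---------------------------------------------------------------- one-vs-all

def _two_cluster_graph():
    feats = np.array([0.0] * 5 + [10.0] * 5)
    return build_knn_graph(feats, K=2)


def test_separated_clusters_fully_recovered():
    g = _two_cluster_graph()
    known = np.array([1, 1, 0, 0, 0, 2, 2, 0, 0, 0])
    pred = classify_one_vs_all(g, known, L_taps=2, rng_seed=0)
    assert np.array_equal(pred, [1] * 5 + [2] * 5)


def test_known_nodes_never_relabelled(study_graph):
    rng = np.random.default_rng(12)
    known = np.zeros(study_graph.n_nodes, dtype=int)
    idx = rng.choice(study_graph.n_nodes, size=60, replace=False)
    known[idx] = rng.integers(1, 4, size=60)
    for c in (1, 2, 3):  # ensure >= 2 known per class
        if (known == c).sum() < 2:
            known[rng.choice(np.flatnonzero(known == 0), size=2, replace=False)] = c
    pred = classify_one_vs_all(study_graph, known, rng_seed=1)
    assert np.array_equal(pred[known > 0], known[known > 0])


def test_binary_case_equals_score_thresholding():
    g = _two_cluster_graph()
    known = np.array([1, 1, 0, 0, 0, 2, 2, 0, 0, 0])
    pred = classify_one_vs_all(g, known, L_taps=2, train_fraction=0.5, rng_seed=3)
    # independently recompute the two one-vs-all scores with the same rng stream
    rng = np.random.default_rng(3)
    scores = []
    for c in (1, 2):
        s_known = np.where(known == c, 1.0, np.where(known > 0, -1.0, 0.0))
        train = np.zeros(10, dtype=bool)
        for sign in (1.0, -1.0):
            members = np.flatnonzero(s_known == sign)
            k = min(len(members), max(1, int(round(0.5 * len(members)))))
            train[rng.choice(members, size=k, replace=False)] = True
        filt = fit_filter_taps(g, LabelSignal(s_known, np.where(train, s_known, 0.0)),
                               L_taps=2)
        scores.append(apply_graph_filter(g, filt, s_known))
    manual = np.where(scores[0] >= scores[1], 1, 2)
    manual = np.where(known > 0, known, manual)
    assert np.array_equal(pred, manual)


def test_classification_deterministic(study_graph):
    rng = np.random.default_rng(13)
    known = np.zeros(study_graph.n_nodes, dtype=int)
    known[rng.choice(study_graph.n_nodes, 30, replace=False)] = \
        rng.integers(1, 4, size=30)
    for c in (1, 2, 3):
        if (known == c).sum() < 2:
            known[np.flatnonzero(known == 0)[:2]] = c
    a = classify_one_vs_all(study_graph, known, rng_seed=5)
    b = classify_one_vs_all(study_graph, known, rng_seed=5)
    assert np.array_equal(a, b)


def test_class_with_one_known_node_rejected():
    g = _two_cluster_graph()
    with pytest.raises(ValueError, match="fewer than 2"):
        classify_one_vs_all(g, np.array([1, 1, 0, 0, 0, 2, 0, 0, 0, 0]))


# ---------------------------------------------------------------- painting

def test_constant_node_labels_paint_whole_mask(study_svmap):
    lv = labels_to_volume(np.full(study_svmap.n_supervoxels, 2), study_svmap)
    inm = study_svmap.assignment >= 0
    assert np.all(lv.data[inm] == 2)
    assert np.all(lv.data[~inm] == 0)


def test_label_painting_counts_match_supervoxel_sizes(study_svmap):
    rng = np.random.default_rng(14)
    node_labels = rng.integers(1, 4, size=study_svmap.n_supervoxels)
    lv = labels_to_volume(node_labels, study_svmap)
    sizes = study_svmap.sizes()
    for c in (1, 2, 3):
        assert (lv.data == c).sum() == sizes[node_labels == c].sum()


def test_label_length_mismatch_rejected(study_svmap):
    with pytest.raises(ValueError, match="n_supervoxels"):
        labels_to_volume(np.ones(3), study_svmap)
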