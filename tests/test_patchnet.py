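"""Patch CNN, radius graphs, graph-attention prediction, propagation,
follicle docking, and evaluation statistics."""

import numpy as np
import pytest
from shapely.geometry import Point

from marginmap import patchnet, synthfix
from marginmap._autodiff import Tensor
from marginmap._nn import GATConv, GATNet, cross_entropy
from marginmap.patchnet import (
    ModelConfig,
    bootstrap_ci,
    build_patch_graph,
    embed_patches,
    evaluate_auc,
    follicle_adjust,
    gnn_predict,
    propagate_predictions,
    train_gnn,
    train_patch_cnn,
)


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutodiff:
    def test_gat_layer_gradients_match_numerics(self):
        rng = np.random.default_rng(0)
        h = rng.standard_normal((5, 3))
        edges = np.array([[0, 1, 1, 2, 3, 4, 0, 1, 2, 3, 4],
                          [1, 0, 2, 1, 4, 3, 0, 1, 2, 3, 4]])
        net = GATNet(3, 2, rng, dims=(4, 4))
        labels = np.array([0, 1, 0, 1, 1])
        loss = cross_entropy(net(Tensor(h), edges), labels)
        loss.backward()
        for p in net.parameters()[:4]:
            ng = _num_grad(lambda: float(
                cross_entropy(net(Tensor(h), edges), labels).data), p.data)
            assert np.abs(ng - p.grad).max() <= 1e-6 * max(np.abs(ng).max(), 1.0)

    def test_conv_gradients_match_numerics(self):
        from marginmap._nn import Conv2d

        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 3, 7, 7))
        conv = Conv2d(3, 2, rng)
        loss = (conv(Tensor(x)) ** 2.0).mean()
        loss.backward()
        ng = _num_grad(lambda: float((conv(Tensor(x)) ** 2.0).mean().data),
                       conv.W.data)
        assert np.abs(ng - conv.W.grad).max() <= 1e-6 * np.abs(ng).max()


class TestGraph:
    def test_collinear_chain_edges(self):
        g = build_patch_graph([(0, 0), (256, 0), (512, 0)], np.zeros((3, 2)), 256.0)
        pairs = {tuple(sorted(e)) for e in g.edge_index.T}
        assert pairs == {(0, 1), (1, 2)}

    def test_single_node_no_edges(self):
        g = build_patch_graph([(5, 5)], np.zeros((1, 2)), 100.0)
        assert g.edge_index.shape[1] == 0

    def test_matches_brute_force_distance_filter(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 1000, (200, 2))
        g = build_patch_graph(coords, np.zeros((200, 1)), 120.0)
        got = {tuple(sorted(e)) for e in g.edge_index.T}
        want = set()
        for i in range(200):
            for j in range(i + 1, 200):
                if np.linalg.norm(coords[i] - coords[j]) <= 120.0:
                    want.add((i, j))
        assert got == want

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            build_patch_graph([(0, 0)], np.zeros((1, 1)), 0.0)


@pytest.fixture(scope="module")
def texture_patches():
    """Small labelled patch set from one rendered tumor slide."""
    from marginmap._demo import _patches_and_labels, render_cohort

    slides = render_cohort(5, n_slides=2, patch_size=64)
    ps0, p0, y0 = _patches_and_labels(slides[0], 64)
    ps1, p1, y1 = _patches_and_labels(slides[1], 64)
    return (ps0, p0, y0), (ps1, p1, y1)


class TestCNN:
    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="2 classes"):
            train_patch_cnn(rng.random((8, 32, 32, 3)), np.zeros(8, dtype=int),
                            ModelConfig(epochs_cnn=1))

    def test_zero_epochs_returns_finite_initialization(self):
        rng = np.random.default_rng(0)
        cnn = train_patch_cnn(rng.random((8, 32, 32, 3)),
                              np.array([0, 1] * 4), ModelConfig(epochs_cnn=0))
        emb = embed_patches(cnn, rng.random((8, 32, 32, 3)))
        assert np.isfinite(emb).all() and cnn.loss_curve == []

    def test_same_seed_identical_weights(self, texture_patches):
        (_, p, y), _ = texture_patches
        cfg = ModelConfig(epochs_cnn=2, seed=9)
        a = train_patch_cnn(p, y, cfg)
        b = train_patch_cnn(p, y, cfg)
        for wa, wb in zip(a.net.state_dict(), b.net.state_dict()):
            assert np.array_equal(wa, wb)

    def test_duplicated_patch_identical_embeddings(self, texture_patches):
        (_, p, y), _ = texture_patches
        cnn = train_patch_cnn(p, y, ModelConfig(epochs_cnn=1))
        dup = np.stack([p[0], p[0], p[1]])
        emb = embed_patches(cnn, dup)
        assert np.array_equal(emb[0], emb[1]) and not np.array_equal(emb[0], emb[2])

    def test_patch_size_mismatch_rejected(self, texture_patches):
        (_, p, y), _ = texture_patches
        cnn = train_patch_cnn(p, y, ModelConfig(epochs_cnn=1))
        with pytest.raises(ValueError, match="backbone"):
            embed_patches(cnn, np.zeros((2, 48, 48, 3)))

    def test_embeddings_linearly_separate_texture_classes(self, texture_patches):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        (_, p0, y0), (_, p1, y1) = texture_patches
        cnn = train_patch_cnn(p0, y0, ModelConfig.desk(seed=0))
        emb1 = embed_patches(cnn, p1)
        emb0 = embed_patches(cnn, p0)
        probe = LogisticRegression(max_iter=2000).fit(emb0, y0)
        auc = roc_auc_score(y1 == 0, probe.predict_proba(emb1)[:, 0])
        assert auc >= 0.85


class TestGNN:
    @pytest.fixture(scope="class")
    def tiny_graphs(self):
        gs = synthfix.make_patch_dataset(3, 64, feature_dim=4, seed=0)
        pgs = [build_patch_graph(g.coords, g.features, g.radius) for g in gs]
        return pgs, [g.labels for g in gs]

    def test_untrained_probabilities_normalized(self, tiny_graphs):
        pgs, ys = tiny_graphs
        gnn = train_gnn(pgs, ys, ModelConfig(epochs_gnn=0), task="tumor_map")
        probs = gnn_predict(gnn, pgs[0])
        assert probs.shape == (64, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_node_permutation_equivariance(self, tiny_graphs):
        pgs, ys = tiny_graphs
        gnn = train_gnn(pgs, ys, ModelConfig(epochs_gnn=3), task="tumor_map")
        g = pgs[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        gp = build_patch_graph(g.coords[perm], g.features[perm], g.radius)
        assert np.allclose(gnn_predict(gnn, gp)[inv], gnn_predict(gnn, g), atol=1e-10)

    def test_translation_invariance(self, tiny_graphs):
        pgs, ys = tiny_graphs
        gnn = train_gnn(pgs, ys, ModelConfig(epochs_gnn=3), task="tumor_map")
        g = pgs[0]
        gt = build_patch_graph(g.coords + 1e6, g.features, g.radius)
        assert np.allclose(gnn_predict(gnn, gt), gnn_predict(gnn, g), atol=1e-10)

    def test_label_task_mismatch_rejected(self, tiny_graphs):
        pgs, _ = tiny_graphs
        bad = [np.full(g.n_nodes, 7) for g in pgs]
        with pytest.raises(ValueError, match="class set"):
            train_gnn(pgs, bad, ModelConfig(epochs_gnn=1), task="tumor_map")


class TestPropagation:
    @pytest.fixture(scope="class")
    def graph(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        probs = np.array([0.0, 1.0, 0.2, 0.8])
        return build_patch_graph(coords, np.zeros((4, 1)), 150.0), probs

    def test_query_at_node_returns_node_probability(self, graph):
        g, probs = graph
        vals, found = propagate_predictions(g, probs, [(100.0, 0.0)])
        assert found[0] and vals[0, 0] == pytest.approx(1.0)

    def test_midpoint_averages_symmetric_neighbors(self):
        # only nodes at (0,0) p=0 and (100,0) p=1 lie within radius, at
        # equal distance from the query
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        g2 = build_patch_graph(coords, np.zeros((2, 1)), 60.0)
        vals, _ = propagate_predictions(g2, np.array([0.0, 1.0]), [(50.0, 0.0)])
        assert vals[0, 0] == pytest.approx(0.5)

    def test_matches_brute_force_idw(self, graph):
        g, probs = graph
        rng = np.random.default_rng(3)
        queries = rng.uniform(0, 100, (20, 2))
        vals, found = propagate_predictions(g, probs, queries)
        for q, v, f in zip(queries, vals, found):
            d = np.linalg.norm(g.coords - q, axis=1)
            sel = d <= g.radius
            if not sel.any():
                assert not f
                continue
            w = 1.0 / d[sel]
            assert v[0] == pytest.approx((w * probs[sel]).sum() / w.sum(), abs=1e-9)

    def test_query_without_neighbors_flagged_missing(self):
        g = build_patch_graph([[0.0, 0.0], [1000.0, 1000.0]], np.zeros((2, 1)), 10.0)
        vals, found = propagate_predictions(g, [0.3, 0.7], [(500.0, 500.0)])
        assert not found[0] and np.isnan(vals[0, 0])


class TestFollicleAdjust:
    def test_no_follicles_leaves_probabilities(self):
        p = np.array([0.3, 0.9])
        out = follicle_adjust(p, [(0, 0), (10, 10)], [])
        assert np.array_equal(out, p)

    def test_total_overlap_docks_to_zero(self):
        big = Point(0, 0).buffer(2000)
        out = follicle_adjust([0.9], [(0, 0)], [big])
        assert out[0] == pytest.approx(0.0, abs=1e-3)

    def test_hand_arithmetic(self):
        # overlaps (0, 0, 0.5), weights (0.6, 0.3, 0.1), p = 0.9
        # -> penalty 0.05, adjusted 0.855.  A ring covering only half of
        # the outer circle's area: annulus from r=362.04 (half the outer
        # circle's area lies beyond it) to beyond 512.
        inner = 512.0 / np.sqrt(2)
        ring = Point(0, 0).buffer(600).difference(Point(0, 0).buffer(inner))
        out = follicle_adjust([0.9], [(0, 0)], [ring])
        assert out[0] == pytest.approx(0.855, abs=0.002)

    def test_weight_validation(self):
        with pytest.raises(ValueError, match="sum"):
            follicle_adjust([0.5], [(0, 0)], [Point(0, 0).buffer(10)],
                            weights=(0.5, 0.3, 0.1))
        with pytest.raises(ValueError, match="decrease"):
            follicle_adjust([0.5], [(0, 0)], [Point(0, 0).buffer(10)],
                            weights=(0.1, 0.3, 0.6))

    def test_never_increases_probability(self):
        rng = np.random.default_rng(4)
        probs = rng.random(10)
        coords = rng.uniform(-500, 500, (10, 2))
        folls = [Point(*rng.uniform(-500, 500, 2)).buffer(rng.uniform(50, 300))
                 for _ in range(3)]
        out = follicle_adjust(probs, coords, folls)
        assert (out <= probs + 1e-12).all()


class TestStatistics:
    def test_perfect_separation_auc_one(self):
        assert evaluate_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_auc_half(self):
        assert evaluate_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_case_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        conc = 0.0
        npairs = 0
        for i in np.nonzero(labels == 1)[0]:
            for j in np.nonzero(labels == 0)[0]:
                npairs += 1
                conc += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
        assert evaluate_auc(scores, labels) == pytest.approx(conc / npairs)

    def test_macro_is_mean_of_per_slide_aucs(self):
        scores = np.array([0.1, 0.9, 0.4, 0.6, 0.2, 0.7, 0.3, 0.8])
        labels = np.array([0, 1, 1, 0, 0, 1, 0, 1])
        slides = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        per = [evaluate_auc(scores[slides == s], labels[slides == s])
               for s in ("a", "b")]
        got = evaluate_auc(scores, labels, slides, macro=True)
        assert got == pytest.approx(np.mean(per))

    def test_single_class_pooled_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            evaluate_auc([0.1, 0.2], [1, 1])

    def test_macro_skips_single_class_slide_with_warning(self):
        scores = [0.1, 0.9, 0.5, 0.6]
        labels = [0, 1, 1, 1]
        slides = ["a", "a", "b", "b"]
        with pytest.warns(UserWarning, match="skipped"):
            got = evaluate_auc(scores, labels, slides, macro=True)
        assert got == 1.0

    def test_bootstrap_constant_statistic(self):
        lo, hi = bootstrap_ci(lambda r: 3.14, np.arange(10),
                              np.repeat([0, 1], 5), n_boot=50, seed=0)
        assert lo == hi == pytest.approx(3.14)

    def test_two_cluster_mean_within_enumerable_resamples(self):
        vals = np.array([1.0, 1.0, 5.0, 5.0])
        clusters = np.array([0, 0, 1, 1])
        possible = {1.0, 3.0, 5.0}  # (a,a), (a,b)/(b,a), (b,b)
        lo, hi = bootstrap_ci(lambda r: float(np.mean(r)), vals, clusters,
                              n_boot=200, seed=1)
        assert lo in possible and hi in possible

    def test_bootstrap_seeded_reproducible(self):
        rng = np.random.default_rng(5)
        vals = rng.random(30)
        clusters = np.repeat(np.arange(6), 5)
        a = bootstrap_ci(lambda r: float(np.mean(r)), vals, clusters, 200, seed=7)
        b = bootstrap_ci(lambda r: float(np.mean(r)), vals, clusters, 200, seed=7)
        assert a == b

    def test_bootstrap_requires_two_clusters(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.arange(4), np.zeros(4), 10)


def test_model_config_validates_rates():
    with pytest.raises(ValueError):
        ModelConfig(dropedge=1.5)
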