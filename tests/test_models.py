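"""Architectures, metric-learning losses, gradients, training behavior."""

from __future__ import annotations

import numpy as np
import pytest

from scretrieve import models as M
from scretrieve.ontology import OntologyDAG, OntoTerm


# ---------------------------------------------------------------------------
# Losses against independent direct-formula evaluation
# ---------------------------------------------------------------------------

def _contrastive_reference(D, Y, m):
    # independent piecewise evaluation, scalar at a time
    if Y == 1:
        return 0.5 * D * D
    gap = m - D
    return 0.5 * gap * gap if gap > 0 else 0.0


def _triplet_reference(d_ap, d_an, alpha):
    v = d_ap - d_an + alpha
    return v if v > 0 else 0.0


class TestLossOracles:
    def test_contrastive_matches_reference_on_random_inputs(self, rng):
        D = rng.uniform(0, 3, size=1000)
        Y = rng.integers(0, 2, size=1000)
        got = M.contrastive_loss(D, Y, m=1.0)
        expected = [_contrastive_reference(d, y, 1.0) for d, y in zip(D, Y)]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_contrastive_worked_examples(self):
        assert M.contrastive_loss(0.0, 1) == 0.0
        assert M.contrastive_loss(0.0, 0, m=1.0) == pytest.approx(0.5)
        assert M.contrastive_loss(1.5, 0, m=1.0) == 0.0

    def test_contrastive_rejects_bad_inputs(self):
        with pytest.raises(M.ModelError):
            M.contrastive_loss(-0.1, 1)
        with pytest.raises(M.ModelError):
            M.contrastive_loss(0.5, 1, m=0.0)

    def test_triplet_matches_reference_on_random_inputs(self, rng):
        d_ap = rng.uniform(0, 4, size=1000)
        d_an = rng.uniform(0, 4, size=1000)
        got = M.triplet_loss(d_ap, d_an, alpha=0.2)
        expected = [_triplet_reference(a, b, 0.2) for a, b in zip(d_ap, d_an)]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_triplet_worked_examples(self):
        assert M.triplet_loss(0.0, 4.0, alpha=0.2) == 0.0
        assert M.triplet_loss(1.0, 1.0, alpha=0.2) == pytest.approx(0.2)
        assert M.triplet_loss(2.0, 0.5, alpha=0.2) == pytest.approx(1.7)

    def test_gradients_match_numerical_differentiation(self, rng):
        eps = 1e-6
        for _ in range(200):
            D = float(rng.uniform(0.05, 3))
            Y = int(rng.integers(0, 2))
            if abs(D - 1.0) < 1e-3:  # stay away from the hinge kink
                continue
            num = (M.contrastive_loss(D + eps, Y) - M.contrastive_loss(D - eps, Y)) / (2 * eps)
            assert M.contrastive_loss_grad(D, Y) == pytest.approx(num, abs=1e-4)
        for _ in range(200):
            d_ap = float(rng.uniform(0, 3))
            d_an = float(rng.uniform(0, 3))
            if abs(d_ap - d_an + 0.2) < 1e-3:
                continue
            g_ap, g_an = M.triplet_loss_grad(d_ap, d_an, 0.2)
            num_ap = (M.triplet_loss(d_ap + eps, d_an) - M.triplet_loss(d_ap - eps, d_an)) / (2 * eps)
            num_an = (M.triplet_loss(d_ap, d_an + eps) - M.triplet_loss(d_ap, d_an - eps)) / (2 * eps)
            assert g_ap == pytest.approx(num_ap, abs=1e-4)
            assert g_an == pytest.approx(num_an, abs=1e-4)


class TestBackpropGradients:
    """Analytic network gradients vs central differences on a tiny model."""

    def _numeric_grad(self, lossfn, W, eps=1e-6):
        g = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + eps
            lp = lossfn()
            W[idx] = orig - eps
            lm = lossfn()
            W[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
            it.iternext()
        return g

    def test_classifier_step_gradient(self, rng):
        model = M.build_dense(5, [4, 3], classes=["a", "b"], seed=0)
        X = rng.normal(size=(6, 5))
        y = np.array([0, 1, 0, 1, 1, 0])

        def loss():
            return M._ce_loss(model, X, y)

        hs, zs = model._forward(X)
        logits = hs[-1] @ model.head_W + model.head_b
        probs = M._softmax(logits)
        d = probs.copy()
        d[np.arange(6), y] -= 1
        d /= 6
        gW, gb = M._backward(model, hs, zs, d @ model.head_W.T)
        for i in range(2):
            np.testing.assert_allclose(
                gW[i], self._numeric_grad(loss, model.weights[i]), atol=1e-5
            )

    def test_siamese_pair_gradient(self, rng):
        model = M.build_dense(4, [3, 2], seed=1)
        X = rng.normal(size=(4, 4))
        pairs = [(0, 1, 1), (2, 3, 0)]

        def loss():
            return M._pair_loss(model, X, pairs, 1.0)

        i, j, Y = (np.asarray(v) for v in zip(*pairs))
        hs1, zs1 = model._forward(X[i])
        hs2, zs2 = model._forward(X[j])
        diff = hs1[-1] - hs2[-1]
        D = np.linalg.norm(diff, axis=1)
        dD = M.contrastive_loss_grad(D, Y, 1.0) / len(pairs)
        dE1 = (dD / np.where(D > 0, D, 1))[:, None] * diff
        gW1, _ = M._backward(model, hs1, zs1, dE1)
        gW2, _ = M._backward(model, hs2, zs2, -dE1)
        for k in range(2):
            np.testing.assert_allclose(
                gW1[k] + gW2[k], self._numeric_grad(loss, model.weights[k]), atol=1e-5
            )


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

class TestBuilders:
    def test_dense_shapes_and_embedding_dim(self):
        model = M.build_dense(10, [4])
        assert model.weights[0].shape == (10, 4)
        assert model.embedding_dim == 4
        model = M.build_dense(1136, [1136, 100])
        assert [w.shape for w in model.weights] == [(1136, 1136), (1136, 100)]

    def test_same_seed_same_initial_weights(self):
        a = M.build_dense(20, [8, 4], seed=5)
        b = M.build_dense(20, [8, 4], seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_empty_hidden_sizes_rejected(self):
        with pytest.raises(M.ModelError):
            M.build_dense(10, [])

    def test_masked_prior_membership_encoding(self):
        groups = {"G1": {"g1", "g2"}, "G2": {"g2", "g3"}}
        model = M.build_masked_prior(groups, ["g1", "g2", "g3"], [4], dense_side_units=0)
        np.testing.assert_array_equal(
            model.masks[0], np.array([[1, 0], [1, 1], [0, 1]], dtype=float)
        )
        assert model.spec.hidden_sizes == [2, 4]

    def test_masked_weights_stay_zero_through_training(self, rng):
        groups = {"G1": {"g0", "g1"}, "G2": {"g2", "g3"}}
        genes = [f"g{i}" for i in range(6)]
        model = M.build_masked_prior(groups, genes, [4], dense_side_units=1,
                                     classes=["a", "b"], seed=0)
        X = rng.normal(size=(40, 6))
        labels = ["a", "b"] * 20
        M.train(model, X, labels, M.TrainingConfig(epochs=5, seed=0))
        forbidden = model.masks[0] == 0
        assert np.all(model.weights[0][forbidden] == 0.0)
        assert np.any(model.weights[0][~forbidden] != 0.0)

    def test_group_without_genes_dropped_with_warning(self):
        groups = {"ok": {"g1"}, "empty": {"zz"}}
        with pytest.warns(UserWarning, match="empty"):
            model = M.build_masked_prior(groups, ["g1", "g2"], [4], dense_side_units=0)
        assert model.masks[0].shape == (2, 1)
        with pytest.raises(M.ModelError):
            M.build_masked_prior({"none": {"zz"}}, ["g1"], [4])

    def test_gmt_parsing(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tg1\tg2\nS2\t-\tg3\n")
        groups = M.read_gmt(p)
        assert groups == {"S1": {"g1", "g2"}, "S2": {"g3"}}
        with pytest.raises(M.ModelError):
            M.read_gmt("onlyname\tdesc")

    def test_go_hierarchy_chain_layers(self):
        dag = OntologyDAG(
            [OntoTerm("GO:A", "a"), OntoTerm("GO:B", "b"), OntoTerm("GO:R", "root")],
            [("GO:A", "GO:B"), ("GO:B", "GO:R")],
        )
        model = M.build_go_hierarchy(dag, {"g1": ["GO:A"], "g2": ["GO:A"]}, 4,
                                     genes=["g1", "g2", "g3"])
        # layer 1 holds A (+catch-all), layer 2 holds B (+catch-all), dense head
        assert model.layer_terms[0][0] == "GO:A"
        assert model.layer_terms[1][0] == "GO:B"
        assert model.spec.hidden_sizes[-1] == 4
        # annotated genes wire to A, unannotated g3 to the catch-all
        np.testing.assert_array_equal(model.masks[0][:, 0], [1, 1, 0])
        np.testing.assert_array_equal(model.masks[0][:, 1], [0, 0, 1])
        # A connects only to its parent B, not across
        assert model.masks[1][0, 0] == 1.0


# ---------------------------------------------------------------------------
# Pair / triplet sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_pairs_balanced(self):
        labels = ["a", "a", "b", "b"]
        pairs = M.make_pairs(labels, 8, seed=0)
        assert sum(y for _, _, y in pairs) == 4
        for i, j, y in pairs:
            assert (labels[i] == labels[j]) == bool(y)

    def test_triplets_satisfy_class_constraints(self):
        labels = ["a"] * 3 + ["b"] * 3 + ["c"]
        with pytest.warns(UserWarning, match="single member"):
            trips = M.make_triplets(labels, 50, seed=1)
        for a, p, n in trips:
            assert labels[a] == labels[p] and a != p
            assert labels[n] != labels[a]

    def test_sampling_deterministic_per_seed(self):
        labels = ["a", "a", "b", "b", "c", "c"]
        assert M.make_pairs(labels, 10, seed=3) == M.make_pairs(labels, 10, seed=3)
        assert M.make_triplets(labels, 10, seed=3) == M.make_triplets(labels, 10, seed=3)

    def test_single_class_rejected(self):
        with pytest.raises(M.ModelError):
            M.make_pairs(["a", "a"], 4)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _separable_toy(rng, n_per=30, n_classes=4, dim=12):
    centers = np.eye(n_classes, dim) * 6.0
    X = np.vstack([centers[c] + rng.normal(scale=0.3, size=(n_per, dim))
                   for c in range(n_classes)])
    y = [f"t{c}" for c in range(n_classes) for _ in range(n_per)]
    return X, y


class TestTraining:
    def test_classifier_fits_separable_classes(self, rng):
        X, y = _separable_toy(rng)
        model = M.build_dense(X.shape[1], [8, 4], classes=sorted(set(y)), seed=0)
        model, hist = M.train(model, X, y, M.TrainingConfig(epochs=50, seed=0))
        acc = np.mean(np.array(model.predict(X)) == np.array(y))
        assert acc == 1.0
        assert hist.best_epoch >= 0

    def test_best_epoch_weights_reproduce_best_val_loss(self, rng):
        X, y = _separable_toy(rng)
        model = M.build_dense(X.shape[1], [8, 4], classes=sorted(set(y)), seed=0)
        cfg = M.TrainingConfig(epochs=20, seed=0)
        model, hist = M.train(model, X, y, cfg)
        # recompute the validation CE with the restored best weights
        n = X.shape[0]
        perm = np.random.default_rng(cfg.seed).permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        val_idx = perm[:n_val]
        pos = {c: i for i, c in enumerate(model.classes)}
        yv = np.array([pos[y[i]] for i in val_idx])
        assert M._ce_loss(model, X[val_idx], yv) == pytest.approx(
            hist.val_loss[hist.best_epoch], abs=1e-9
        )

    def test_history_reproducible_under_seed(self, rng):
        X, y = _separable_toy(rng, n_per=15)
        runs = []
        for _ in range(2):
            model = M.build_dense(X.shape[1], [6, 3], classes=sorted(set(y)), seed=2)
            _, hist = M.train(model, X, y, M.TrainingConfig(epochs=8, seed=2))
            runs.append(hist)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_loss == runs[1].val_loss

    def test_contrastive_training_contracts_same_class_pairs(self, rng):
        X, y = _separable_toy(rng, n_per=20, n_classes=2)
        ya = np.array(y)
        def mean_same_dist(model):
            a = model.embed(X)[ya == ya[0]]
            return float(np.linalg.norm(a[:10] - a[10:20], axis=1).mean())
        model = M.build_dense(X.shape[1], [6, 3], seed=3)
        before = mean_same_dist(model)
        model, _ = M.train(model, X, y, M.TrainingConfig(
            mode="siamese", epochs=20, learning_rate=0.02, seed=3))
        assert mean_same_dist(model) < before

    def test_triplet_training_widens_margin_on_heldout_triplets(self, rng):
        X, y = _separable_toy(rng, n_per=24, n_classes=3)
        heldout = M.make_triplets(y, 100, seed=99)
        def gap(model):
            a, p, n = (np.asarray(v) for v in zip(*heldout))
            ea, ep, en = model.embed(X[a]), model.embed(X[p]), model.embed(X[n])
            return float(np.mean(np.sum((ea - en) ** 2, 1) - np.sum((ea - ep) ** 2, 1)))
        model = M.build_dense(X.shape[1], [6, 3], seed=4)
        before = gap(model)
        model, hist = M.train(model, X, y, M.TrainingConfig(
            mode="triplet", epochs=20, learning_rate=0.02,
            selection="frac-active", seed=4))
        assert gap(model) > before
        assert len(hist.frac_active) == len(hist.val_loss)
        assert all(0.0 <= f <= 1.0 for f in hist.frac_active)

    def test_fraction_active_triplets_counts(self, rng):
        model = M.build_dense(4, [3, 2], seed=0)
        A = rng.normal(size=(10, 4))
        frac = M.fraction_active_triplets(model, A, A, A, alpha=0.2)
        assert frac == 1.0  # d_ap == d_an, margin makes every loss positive
        with pytest.raises(M.ModelError):
            M.fraction_active_triplets(model, A[:0], A[:0], A[:0])

    def test_divergence_raises_with_epoch(self, rng):
        # linear twin networks with an absurd learning rate blow up
        # multiplicatively (gradient scales with the embedding itself)
        X, y = _separable_toy(rng, n_per=40, n_classes=2)
        model = M.build_dense(X.shape[1], [6, 3], activation="linear", seed=0)
        with pytest.raises(M.TrainingDivergedError, match="epoch"):
            M.train(model, X, y, M.TrainingConfig(
                mode="siamese", epochs=50, learning_rate=1e6, seed=0))


class TestPretraining:
    def test_zero_epochs_leaves_weights_unchanged(self, rng):
        model = M.build_dense(6, [4, 3], seed=1)
        before = model.copy_weights()
        M.pretrain_unsupervised(model, rng.normal(size=(20, 6)), epochs=0, seed=0)
        for a, b in zip(before, model.copy_weights()):
            np.testing.assert_array_equal(a, b)

    def test_reconstruction_loss_non_increasing(self, rng):
        model = M.build_dense(6, [4, 3], seed=1)
        X = rng.normal(size=(50, 6))
        M.pretrain_unsupervised(model, X, epochs=30, seed=0, learning_rate=0.01)
        for losses in model.pretrain_losses_:
            diffs = np.diff(losses)
            assert np.all(diffs <= 1e-3)
            assert losses[-1] < losses[0]

    def test_pretraining_deterministic(self, rng):
        X = rng.normal(size=(30, 5))
        outs = []
        for _ in range(2):
            model = M.build_dense(5, [4, 2], seed=7)
            M.pretrain_unsupervised(model, X, epochs=5, seed=7)
            outs.append(model.copy_weights())
        for a, b in zip(*outs):
            np.testing.assert_array_equal(a, b)


class TestEmbedAndPersistence:
    def test_identical_cells_identical_embeddings(self, rng):
        model = M.build_dense(5, [4, 3], seed=0)
        x = rng.normal(size=(1, 5))
        X = np.vstack([x, x])
        emb = M.embed(model, X)
        np.testing.assert_array_equal(emb[0], emb[1])
        assert emb.shape == (2, 3)
        assert np.all(np.abs(emb) < 1.0)  # tanh bounds

    def test_dimension_mismatch_rejected(self, rng):
        model = M.build_dense(5, [3, 2], seed=0)
        with pytest.raises(M.ModelError):
            M.embed(model, rng.normal(size=(2, 7)))

    def test_save_load_round_trip(self, tmp_path, rng):
        groups = {"G1": {"g0", "g1"}}
        model = M.build_masked_prior(groups, [f"g{i}" for i in range(4)], [3],
                                     dense_side_units=1, classes=["a", "b"], seed=0)
        X = rng.normal(size=(3, 4))
        path = tmp_path / "model.h5"
        M.save_model(model, path)
        back = M.load_model(path)
        np.testing.assert_array_equal(model.embed(X), back.embed(X))
        np.testing.assert_array_equal(model.logits(X), back.logits(X))
        assert back.classes == ["a", "b"]
        assert back.genes == model.genes
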