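import numpy as np
import pytest
import scipy.sparse as sp

from ppigcn.dataset import MaskedDataset
from ppigcn.gcn import (
    GCNConfig,
    GCNConfigError,
    GCNInterfaceClassifier,
    GCNParams,
    _loss_and_grads,
    gcn_forward,
    glorot_init,
    masked_loss,
    normalize_adjacency,
    predict,
    train,
)
from ppigcn.synthetic import PlantedDatasetSpec, make_planted_dataset


@pytest.fixture(scope="module")
def small_planted():
    """Small strong-signal dataset reused by the training tests."""
    spec = PlantedDatasetSpec(n_proteins=8, residues_per_protein=25,
                              interface_fraction=0.3, signal_strength=2.5,
                              seed=11)
    dataset, truth = make_planted_dataset(spec)
    return dataset


def random_adjacency(n, rng, density=0.3):
    W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
    return sp.csr_matrix(W + W.T)


class TestNormalizeAdjacency:
    def test_two_node_hand_computation(self):
        A = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(normalize_adjacency(A).toarray(),
                                   [[0.5, 0.5], [0.5, 0.5]])

    def test_edgeless_graph_is_identity(self):
        np.testing.assert_allclose(
            normalize_adjacency(sp.csr_matrix((4, 4))).toarray(), np.eye(4))

    def test_modes_coincide_on_binary(self):
        rng = np.random.default_rng(0)
        A = (random_adjacency(10, rng).toarray() > 0).astype(float)
        np.testing.assert_allclose(
            normalize_adjacency(A, "weighted").toarray(),
            normalize_adjacency(A, "unweighted").toarray())

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(1)
        for n in (5, 20, 50):
            A = random_adjacency(n, rng)
            Ad = A.toarray() + np.eye(n)
            for mode in ("weighted", "unweighted"):
                if mode == "weighted":
                    deg = Ad.sum(axis=1)
                else:
                    deg = (Ad > 0).sum(axis=1)
                D = np.diag(1.0 / np.sqrt(deg))
                np.testing.assert_allclose(
                    normalize_adjacency(A, mode).toarray(), D @ Ad @ D,
                    atol=1e-12)

    def test_spectral_radius_at_most_one(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            A_hat = normalize_adjacency(random_adjacency(12, rng)).toarray()
            eigs = np.linalg.eigvalsh(A_hat)
            assert np.abs(eigs).max() <= 1.0 + 1e-10

    def test_block_structure_preserved(self):
        A = sp.block_diag([np.array([[0, 1], [1, 0.0]]),
                           np.array([[0, 0.5], [0.5, 0.0]])], format="csr")
        A_hat = normalize_adjacency(A).toarray()
        assert np.all(A_hat[:2, 2:] == 0)

    def test_asymmetric_rejected(self):
        with pytest.raises(GCNConfigError):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestForward:
    def test_single_layer_hand_computation(self):
        # one isolated node: A_hat = [[1]]; a single ReLU layer
        params = GCNParams(weights=[np.eye(2), np.eye(2)])
        probs = gcn_forward(sp.identity(1, format="csr"),
                            np.array([[2.0, -1.0]]), params)
        # hidden = ReLU([2,-1]) = [2,0]; logits = [2,0]
        expected = np.exp([2.0, 0.0]) / np.exp([2.0, 0.0]).sum()
        np.testing.assert_allclose(probs[0], expected)

    def test_rows_are_probability_vectors(self):
        rng = np.random.default_rng(3)
        A = random_adjacency(15, rng)
        X = rng.normal(size=(15, 6))
        params = GCNParams(weights=glorot_init((6, 35, 32, 2), rng))
        probs = gcn_forward(normalize_adjacency(A), X, params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_sparse_equals_dense_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            n, d = 20, 7
            A = random_adjacency(n, rng)
            X = rng.normal(size=(n, d))
            params = GCNParams(weights=glorot_init((d, 35, 32, 2), rng))
            Ad = A.toarray() + np.eye(n)
            D = np.diag(1.0 / np.sqrt(Ad.sum(axis=1)))
            Ah = D @ Ad @ D
            Z = np.maximum(Ah @ X @ params.weights[0], 0)
            Z = np.maximum(Ah @ Z @ params.weights[1], 0)
            logits = Ah @ Z @ params.weights[2]
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            dense = e / e.sum(axis=1, keepdims=True)
            probs = gcn_forward(normalize_adjacency(A), X, params)
            np.testing.assert_allclose(probs, dense, atol=1e-8)

    def test_dropout_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        A = random_adjacency(10, rng)
        X = rng.normal(size=(10, 4))
        params = GCNParams(weights=glorot_init((4, 5, 4, 2), rng))
        p1 = gcn_forward(normalize_adjacency(A), X, params,
                         dropout_active=True, seed=42)
        p2 = gcn_forward(normalize_adjacency(A), X, params,
                         dropout_active=True, seed=42)
        np.testing.assert_array_equal(p1, p2)


class TestMaskedLoss:
    def test_perfect_predictions_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert masked_loss(probs, np.array([0, 1]),
                           np.ones(2, bool)) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_ln2(self):
        probs = np.full((4, 2), 0.5)
        assert masked_loss(probs, np.array([0, 1, 0, 1]),
                           np.ones(4, bool)) == pytest.approx(np.log(2))

    def test_independent_of_unmasked_labels(self):
        rng = np.random.default_rng(6)
        probs = rng.dirichlet((1, 1), size=6)
        labels = np.array([0, 1, 0, 1, 0, 1])
        mask = np.array([1, 1, 1, 0, 0, 0], bool)
        flipped = labels.copy()
        flipped[~mask] = 1 - flipped[~mask]
        assert masked_loss(probs, labels, mask) == masked_loss(probs, flipped, mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(GCNConfigError):
            masked_loss(np.full((2, 2), 0.5), np.array([0, 1]), np.zeros(2, bool))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        n, d = 6, 4
        A_hat = normalize_adjacency(random_adjacency(n, rng))
        X = rng.normal(size=(n, d))
        y = rng.integers(0, 2, size=n)
        mask = np.array([1, 1, 1, 0, 1, 0], bool)
        params = GCNParams(weights=glorot_init((d, 5, 4, 2), rng))
        _, grads, _ = _loss_and_grads(A_hat, X, params, y, mask)
        eps = 1e-6
        for h in range(3):
            it = np.nditer(params.weights[h], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                params.weights[h][idx] += eps
                lp, _, _ = _loss_and_grads(A_hat, X, params, y, mask)
                params.weights[h][idx] -= 2 * eps
                lm, _, _ = _loss_and_grads(A_hat, X, params, y, mask)
                params.weights[h][idx] += eps
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(grads[h][idx]), 1e-8)
                assert abs(fd - grads[h][idx]) / denom < 1e-5


class TestTraining:
    def test_loss_decreases(self, small_planted):
        config = GCNConfig(max_epochs=500, patience=500, seed=0)
        params, hist = train(small_planted, config)
        # reported train losses carry dropout noise, so compare a trailing
        # average against the starting loss
        assert np.mean(hist.train_loss[-20:]) < hist.train_loss[0]
        assert min(hist.val_loss) < hist.val_loss[0]

    def test_same_seed_identical_history(self, small_planted):
        config = GCNConfig(max_epochs=40, patience=40, seed=3)
        _, h1 = train(small_planted, config)
        _, h2 = train(small_planted, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.best_epoch == h2.best_epoch

    def test_early_stopping_with_tiny_patience(self, small_planted):
        # a signal-free run plateaus almost immediately
        ds = small_planted
        rng = np.random.default_rng(0)
        null = MaskedDataset(
            composite=ds.composite, features=ds.features,
            labels=rng.permutation(ds.labels), train_mask=ds.train_mask,
            val_mask=ds.val_mask, test_mask=ds.test_mask)
        config = GCNConfig(max_epochs=1500, patience=1, seed=0)
        _, hist = train(null, config)
        assert hist.n_epochs < 1500
        assert "plateau" in hist.stop_reason

    def test_best_epoch_params_restored(self, small_planted):
        config = GCNConfig(max_epochs=60, patience=60, seed=1)
        params, hist = train(small_planted, config)
        assert hist.best_epoch == int(np.argmin(hist.val_loss))

    def test_single_class_training_nodes_rejected(self, small_planted):
        ds = small_planted
        bad = MaskedDataset(
            composite=ds.composite, features=ds.features,
            labels=np.zeros_like(ds.labels), train_mask=ds.train_mask,
            val_mask=ds.val_mask, test_mask=ds.test_mask)
        with pytest.raises(GCNConfigError):
            train(bad, GCNConfig(max_epochs=5))


class TestPredict:
    def test_probabilities_in_unit_interval(self, small_planted):
        params, _ = train(small_planted, GCNConfig(max_epochs=30, seed=0))
        A_hat = normalize_adjacency(small_planted.composite.weights)
        scores = predict(params, A_hat, small_planted.features)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_equals_forward_positive_column(self, small_planted):
        params, _ = train(small_planted, GCNConfig(max_epochs=30, seed=0))
        A_hat = normalize_adjacency(small_planted.composite.weights)
        scores = predict(params, A_hat, small_planted.features)
        probs = gcn_forward(A_hat, small_planted.features, params)
        np.testing.assert_array_equal(scores, probs[:, 1])

    def test_transductive_isolation(self, small_planted):
        """Per-protein predictions are unchanged by batching with others."""
        params, _ = train(small_planted, GCNConfig(max_epochs=30, seed=0))
        ds = small_planted
        A_hat = normalize_adjacency(ds.composite.weights)
        batched = predict(params, A_hat, ds.features)
        for pid, (start, stop) in ds.offsets.items():
            block_A = ds.composite.weights[start:stop, start:stop]
            solo = predict(params, normalize_adjacency(block_A),
                           ds.features[start:stop])
            np.testing.assert_allclose(solo, batched[start:stop], atol=1e-10)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        est = GCNInterfaceClassifier(learning_rate=0.01, max_epochs=10)
        params = est.get_params()
        assert params["learning_rate"] == 0.01
        est2 = GCNInterfaceClassifier(**params)
        assert est2.get_params() == params

    def test_fitted_attributes_and_persistence(self, small_planted, tmp_path):
        ds = small_planted
        est = GCNInterfaceClassifier(max_epochs=30, seed=0)
        est.fit(ds.features, ds.labels, adjacency=ds.composite.weights,
                train_mask=ds.train_mask, val_mask=ds.val_mask)
        assert est.n_features_in_ == 33
        np.testing.assert_array_equal(est.classes_, [0, 1])
        proba = est.predict_proba()
        assert proba.shape == (ds.n, 2)
        hard = est.predict()
        assert set(np.unique(hard)) <= {0, 1}

        path = est.save(tmp_path / "model.json")
        loaded = GCNInterfaceClassifier.from_file(path)
        np.testing.assert_allclose(
            loaded.predict_proba(ds.features, ds.composite.weights), proba)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(GCNConfigError):
            GCNInterfaceClassifier().predict_proba()
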