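"""Competitive layer: net input, competition, Kohonen rule, conscience, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromafuse import clnn
from aromafuse.synthetic import toy_clnn_fixture
from conftest import make_blobs


class TestNetInput:
    def test_zero_at_matching_weight_and_maximal(self):
        fx = toy_clnn_fixture()
        n = clnn.net_input(fx.w[1], fx.w, 0.0)
        assert n[1] == pytest.approx(0.0)
        assert np.argmax(n) == 1
        assert np.all(n <= 0.0)

    def test_all_negative_when_far(self):
        n = clnn.net_input(np.array([100.0, 100.0]), toy_clnn_fixture().w, 0.0)
        assert np.all(n < 0)

    def test_bias_additivity(self):
        fx = toy_clnn_fixture()
        p = np.array([0.3, -0.4])
        base = clnn.net_input(p, fx.w, 0.0)
        delta = np.array([0.0, 0.7, 0.0])
        shifted = clnn.net_input(p, fx.w, delta)
        assert np.allclose(shifted - base, delta)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clnn.net_input(np.ones(3), toy_clnn_fixture().w)


class TestCompete:
    def test_toy_p2_selects_second_neuron(self):
        fx = toy_clnn_fixture()
        res = clnn.compete(clnn.net_input(fx.p[1], fx.w, 0.0))
        assert res.winner == 1
        assert np.array_equal(res.output, [0.0, 1.0, 0.0])
        assert res.output.sum() == 1.0

    def test_tie_goes_to_lowest_index(self):
        res = clnn.compete(np.array([-1.0, -0.5, -0.5]))
        assert res.winner == 1

    def test_exact_weight_match_wins(self):
        fx = toy_clnn_fixture()
        res = clnn.compete(clnn.net_input(fx.w[2], fx.w, 0.0))
        assert res.winner == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clnn.compete(np.array([]))


class TestKohonenUpdate:
    def test_printed_worked_example(self):
        fx = toy_clnn_fixture()
        w2 = clnn.kohonen_update(fx.w[1], fx.p[1], 0.5)
        assert np.allclose(w2, [0.451, 0.844], atol=1e-3)

    def test_alpha_zero_is_identity(self):
        w = np.array([1.0, 2.0])
        assert np.array_equal(clnn.kohonen_update(w, np.array([5.0, 5.0]), 0.0), w)

    def test_alpha_one_jumps_to_input(self):
        p = np.array([5.0, -3.0])
        assert np.array_equal(clnn.kohonen_update(np.zeros(2), p, 1.0), p)

    @given(
        alpha=st.floats(min_value=0.0, max_value=1.0),
        w=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
        p=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
    )
    @settings(max_examples=100, deadline=None)
    def test_contraction_identity(self, alpha, w, p):
        w, p = np.array(w), np.array(p)
        w_new = clnn.kohonen_update(w, p, alpha)
        assert np.linalg.norm(w_new - p) == pytest.approx(
            (1 - alpha) * np.linalg.norm(w - p), abs=1e-9
        )

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            clnn.kohonen_update(np.zeros(2), np.ones(2), 1.5)


class TestBiasUpdate:
    def test_zero_rate_changes_nothing(self):
        c = np.array([0.2, 0.3, 0.5])
        b = np.array([1.0, 2.0, 3.0])
        c2, b2 = clnn.bias_update(c, b, winner=0, bias_lr=0.0)
        assert np.array_equal(c2, c) and np.array_equal(b2, b)

    def test_uniform_wins_converge_to_uniform_frequencies(self):
        c = np.array([0.7, 0.2, 0.1])
        b = np.zeros(3)
        for step in range(3000):
            c, b = clnn.bias_update(c, b, winner=step % 3, bias_lr=0.01)
        assert np.allclose(c, 1.0 / 3.0, atol=0.01)
        assert c.sum() == pytest.approx(1.0, abs=1e-8)

    def test_losing_neuron_bias_strictly_increases(self):
        c = np.full(3, 1.0 / 3.0)
        b = np.zeros(3)
        history = []
        for step in range(50):
            c, b = clnn.bias_update(c, b, winner=step % 2, bias_lr=0.05)
            history.append(b[2])  # neuron 2 never wins
        assert np.all(np.diff(history) > 0)


class TestZeroBiasNearestNeighbour:
    def test_competition_equals_brute_force_argmin(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            W = rng.normal(size=(6, 4))
            p = rng.normal(size=4)
            res = clnn.compete(clnn.net_input(p, W, 0.0))
            brute = int(np.argmin([np.linalg.norm(p - w) for w in W]))
            assert res.winner == brute


class TestTrain:
    def test_toy_fixture_weights_find_clusters(self):
        fx = toy_clnn_fixture()
        # zero biases as in the worked illustration; the learning-rate decay
        # damps the limit-cycle jitter of the constant-alpha rule so the
        # weights settle onto the cluster centroids
        model = clnn.train(
            fx.p, n_neurons=3, alpha=0.5, bias_lr=0.0, epochs=150,
            repeats=1, seed=0, init_weights=fx.w, alpha_decay=0.9,
        )
        # visual clusters of the seven inputs
        centroids = [fx.p[:2].mean(axis=0), fx.p[2:5].mean(axis=0),
                     fx.p[5:].mean(axis=0)]
        for c in centroids:
            d = np.linalg.norm(model.weights - c, axis=1).min()
            assert d < 0.15

    def test_single_neuron_converges_to_centroid(self):
        rng = np.random.default_rng(21)
        X = rng.normal([2.0, -1.0], 0.3, (100, 2))
        model = clnn.train(X, n_neurons=1, alpha=0.05, bias_lr=0.0,
                           epochs=80, repeats=1, seed=0)
        assert np.linalg.norm(model.weights[0] - X.mean(axis=0)) < 0.15

    def test_zero_epochs_keeps_initialization(self):
        X = np.random.default_rng(22).normal(size=(20, 2))
        init = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = clnn.train(X, n_neurons=2, epochs=0, repeats=1, seed=0,
                           init_weights=init)
        assert np.array_equal(model.weights, init)

    def test_deterministic_under_seed(self):
        X, _ = make_blobs([[0, 0], [5, 5]], 20, 0.5, seed=23)
        a = clnn.train(X, n_neurons=2, epochs=20, seed=9)
        b = clnn.train(X, n_neurons=2, epochs=20, seed=9)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.biases, b.biases)

    def test_more_neurons_than_rows_rejected(self):
        with pytest.raises(ValueError):
            clnn.train(np.zeros((3, 2)), n_neurons=4)

    def test_centroid_recovery_over_seeds(self):
        centroids = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], float)
        sd, n_per = 0.3, 50
        dists = []
        for seed in range(10):
            X, _ = make_blobs(centroids, n_per, sd, seed=seed)
            model = clnn.train(X, n_neurons=4, alpha=0.1, bias_lr=0.001,
                               epochs=60, repeats=3, seed=seed)
            for c in centroids:
                dists.append(np.linalg.norm(model.weights - c, axis=1).min())
        # constant-alpha updates jitter, so accuracy is judged on average
        assert np.mean(dists) <= 3 * sd * np.sqrt(2) / np.sqrt(n_per)

    def test_conscience_revives_dead_neurons(self):
        # all weights start coincident; without conscience only one would win
        centroids = np.array([[0, 0], [5, 0], [0, 5], [5, 5], [10, 5]], float)
        for seed in range(3):
            X, _ = make_blobs(centroids, 30, 0.3, seed=seed)
            model = clnn.train(X, n_neurons=4, alpha=0.1, bias_lr=0.001,
                               epochs=60, repeats=1, seed=seed, init="midpoint")
            wins = np.bincount(model.assign(X), minlength=4)
            assert np.all(wins > 0)


class TestAssignAndMap:
    def test_six_clean_clusters_detected(self):
        centroids = np.eye(6) * 10
        X, y = make_blobs(centroids, 20, 0.5, seed=24)
        model = clnn.train(X, n_neurons=6, epochs=60, seed=0)
        mapping = clnn.assign_and_map(model, X, y)
        assert mapping.n_clusters_detected == 6
        assert mapping.n_classes_detected == 6
        preds = clnn.classify(model, X)
        assert (preds == y).mean() > 0.99

    def test_coincident_classes_collapse(self):
        # classes 4, 5, 6 share one centroid: at most 4 groups are detectable
        centroids = np.array(
            [[0, 0], [10, 0], [0, 10], [7, 7], [7, 7], [7, 7]], float
        )
        X, y = make_blobs(centroids, 20, 0.6, seed=25)
        model = clnn.train(X, n_neurons=6, epochs=80, seed=1)
        mapping = clnn.assign_and_map(model, X, y)
        assert mapping.n_clusters_detected == 4
        assert mapping.n_classes_detected <= 4

    def test_single_class_maps_to_one(self):
        X = np.random.default_rng(26).normal(size=(40, 2))
        y = np.ones(40, dtype=int)
        model = clnn.train(X, n_neurons=3, epochs=40, seed=2)
        mapping = clnn.assign_and_map(model, X, y)
        assert mapping.n_classes_detected == 1
        assert set(mapping.neuron_to_class.values()) == {1}

    def test_model_json_round_trip(self, tmp_path):
        X, y = make_blobs([[0, 0], [6, 6]], 15, 0.4, seed=27)
        model = clnn.train(X, n_neurons=2, epochs=30, seed=3)
        clnn.assign_and_map(model, X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = clnn.CLNNModel.from_json(path)
        assert np.allclose(back.weights, model.weights)
        assert back.neuron_to_class == model.neuron_to_class


class TestEvaluateSplit:
    def test_split_sizes_on_full_dataset(self, fused_matrix):
        fm, y = fused_matrix
        report = clnn.evaluate_split(fm.data.to_numpy(), y, seed=1, epochs=40)
        assert report.n_train == 120
        assert report.n_test == 360

    def test_separable_limit_perfect(self):
        centroids = np.eye(4) * 20
        X, y = make_blobs(centroids, 16, 0.1, seed=28)
        report = clnn.evaluate_split(X, y, train_frac=0.25, seed=0, epochs=60)
        assert report.accuracy_pct == 100.0
        assert report.n_classes_detected == 4

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 3))
            y = np.repeat(np.arange(1, 7), 20)
            accs.append(
                clnn.evaluate_split(X, rng.permutation(y), seed=seed,
                                    epochs=30).accuracy_pct
            )
        assert abs(np.median(accs) - 100.0 / 6.0) <= 8.0

    def test_class_absent_from_split_rejected(self):
        X = np.random.default_rng(29).normal(size=(21, 2))
        y = np.array([1] * 20 + [2])
        with pytest.raises(ValueError, match="absent"):
            clnn.stratified_split(y, 0.25, seed=0)
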