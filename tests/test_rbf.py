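"""RBF network: activation convention, least squares, greedy training, scan."""

import math

import numpy as np
import pytest
from carpfrost import (
    RBFNetwork,
    TrainingConfig,
    hidden_activations,
    load_model,
    predict,
    save_model,
    scan_hyperparameters,
    solve_output_weights,
    split_dataset,
    train_incremental,
)
from carpfrost.errors import (
    ConfigError,
    DimensionError,
    InsufficientDataError,
    ModelParseError,
)
from carpfrost.preprocess import fit_minmax
from carpfrost.rbf import BANDWIDTH_CONSTANT


def _net(centers, spread, W=None, b=None):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n, k = centers.shape[0], 1
    W = np.ones((k, n)) if W is None else np.asarray(W, dtype=float)
    b = np.zeros(k) if b is None else np.asarray(b, dtype=float)
    return RBFNetwork(centers=centers, spread=spread, output_weights=W,
                      output_biases=b)


def brute_force_predict(net, X):
    """Independent re-evaluation of the activation and read-out formulas."""
    X = np.atleast_2d(X)
    out = np.zeros((len(X), net.n_outputs))
    c = net.bandwidth_constant / net.spread
    for i, x in enumerate(X):
        for k in range(net.n_outputs):
            acc = net.output_biases[k]
            for j in range(net.n_hidden):
                d2 = sum((net.centers[j, q] - x[q]) ** 2 for q in range(len(x)))
                acc += net.output_weights[k, j] * math.exp(-(c ** 2) * d2)
            out[i, k] = acc
    return out


class TestHiddenActivations:
    def test_unit_activation_at_center(self):
        net = _net([[0.3, -0.2]], spread=0.7)
        assert hidden_activations(net, [0.3, -0.2])[0] == 1.0

    def test_half_activation_at_distance_equal_spread(self):
        """The 0.8326 convention: response 0.5 one spread from the centre."""
        for spread in (0.05, 0.5, 1.0, 2.5):
            net = _net([[0.0, 0.0]], spread=spread)
            act = hidden_activations(net, [spread, 0.0])[0]
            assert act == pytest.approx(0.5, abs=1e-4)
            assert act == pytest.approx(math.exp(-BANDWIDTH_CONSTANT ** 2))

    def test_activations_approach_one_for_huge_spread(self):
        net = _net([[0.0, 0.0]], spread=1e6)
        assert hidden_activations(net, [1.0, 1.0])[0] == pytest.approx(1.0, abs=1e-9)

    def test_arity_mismatch_rejected(self):
        net = _net([[0.0, 0.0]], spread=1.0)
        with pytest.raises(DimensionError):
            hidden_activations(net, [0.0, 0.0, 0.0])


class TestPredict:
    def test_zero_hidden_neurons_outputs_bias(self):
        net = RBFNetwork(centers=np.zeros((0, 2)), spread=1.0,
                         output_weights=np.zeros((2, 0)),
                         output_biases=np.array([0.4, -1.2]))
        out = predict(net, [[0.0, 0.0], [5.0, -3.0]])
        np.testing.assert_allclose(out, [[0.4, -1.2], [0.4, -1.2]])

    def test_single_center_unit_weight(self):
        net = _net([[0.1, 0.2]], spread=1.0)
        assert predict(net, [[0.1, 0.2]])[0, 0] == pytest.approx(1.0)

    def test_matches_brute_force_formula(self, rng):
        """Trained net equals an independent double-sum evaluation to 1e-10."""
        X = rng.uniform(-1, 1, size=(30, 2))
        Y = np.column_stack([np.sin(X[:, 0]), X[:, 1] ** 2, X.sum(axis=1)])
        cfg = TrainingConfig(spread=0.8, max_neurons=12, seed=0)
        net, _ = train_incremental(X, Y, cfg)
        probe = rng.uniform(-1.5, 1.5, size=(20, 2))
        np.testing.assert_allclose(predict(net, probe),
                                   brute_force_predict(net, probe), atol=1e-10)

    def test_original_scale_round_trips_normalization(self, rng):
        X = rng.uniform(0, 10, size=(12, 2))
        Y = rng.uniform(-5, 5, size=(12, 3))
        xn, yn = fit_minmax(X, ("a", "b")), fit_minmax(Y, ("u", "v", "w"))
        cfg = TrainingConfig(spread=1.0, max_neurons=8, seed=0)
        net, _ = train_incremental(xn.transform(X), yn.transform(Y), cfg)
        net.x_norm, net.y_norm = xn, yn
        manual = yn.inverse(predict(net, xn.transform(X)))
        np.testing.assert_allclose(predict(net, X, scale="original"), manual,
                                   atol=1e-12)


class TestSolveOutputWeights:
    def test_interpolation_regime_drives_mse_to_zero(self, rng):
        """Centers = all distinct inputs: the Gaussian kernel interpolates."""
        X = rng.uniform(-1, 1, size=(8, 2))
        Y = rng.uniform(-1, 1, size=(8, 3))
        _, _, mse = solve_output_weights(X, 0.8, X, Y)
        assert mse <= 1e-8

    def test_constant_target_fits_with_bias(self, rng):
        X = rng.uniform(-1, 1, size=(10, 2))
        Y = np.full((10, 1), 3.7)
        W, b, mse = solve_output_weights(X[:3], 1.0, X, Y)
        assert mse == pytest.approx(0.0, abs=1e-18)
        assert predict(RBFNetwork(X[:3], 1.0, W, b), X) == pytest.approx(3.7)

    def test_duplicate_center_leaves_residual_unchanged(self, rng):
        X = rng.uniform(-1, 1, size=(12, 2))
        Y = rng.uniform(-1, 1, size=(12, 2))
        _, _, mse1 = solve_output_weights(X[:4], 0.9, X, Y)
        dup = np.vstack([X[:4], X[[0]]])
        _, _, mse2 = solve_output_weights(dup, 0.9, X, Y)
        assert mse2 == pytest.approx(mse1, abs=1e-12)

    def test_empty_training_rejected(self):
        with pytest.raises(InsufficientDataError):
            solve_output_weights(np.zeros((0, 2)), 1.0, np.zeros((0, 2)),
                                 np.zeros((0, 1)))


class TestTrainIncremental:
    def test_single_point_single_neuron_exact(self):
        X, Y = np.array([[0.5, 0.5]]), np.array([[2.0, -1.0]])
        cfg = TrainingConfig(spread=1.0, max_neurons=1, seed=0)
        net, trace = train_incremental(X, Y, cfg)
        assert trace[-1][1] <= 1e-20
        np.testing.assert_allclose(predict(net, X), Y, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mse_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(20, 2))
        Y = rng.uniform(-1, 1, size=(20, 5))
        cfg = TrainingConfig(spread=1.0, max_neurons=15, seed=seed)
        _, trace = train_incremental(X, Y, cfg)
        mses = [m for _, m in trace]
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))

    def test_full_budget_reaches_interpolation(self, rng):
        X = rng.uniform(-1, 1, size=(5, 2))
        Y = rng.uniform(-1, 1, size=(5, 2))
        cfg = TrainingConfig(spread=0.8, max_neurons=5, seed=0)
        net, trace = train_incremental(X, Y, cfg)
        assert trace[-1][1] <= 1e-8

    def test_budget_beyond_distinct_points_rejected(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        Y = np.zeros((2, 1))
        with pytest.raises(ConfigError):
            train_incremental(X, Y, TrainingConfig(spread=1.0, max_neurons=3, seed=0))

    def test_mse_goal_stops_early(self, rng):
        X = rng.uniform(-1, 1, size=(15, 2))
        Y = rng.uniform(-1, 1, size=(15, 2))
        cfg = TrainingConfig(spread=1.0, max_neurons=15, mse_goal=0.05, seed=0)
        net, trace = train_incremental(X, Y, cfg)
        assert trace[-1][1] <= 0.05
        assert net.n_hidden < 15 or trace[-2][1] > 0.05


class TestSplitDataset:
    def test_rounded_sizes(self):
        tr, asx, te = split_dataset(20, (0.70, 0.15, 0.15), seed=0)
        assert (len(tr), len(asx), len(te)) == (14, 3, 3)

    def test_disjoint_and_exhaustive(self):
        tr, asx, te = split_dataset(33, (0.70, 0.15, 0.15), seed=5)
        union = np.concatenate([tr, asx, te])
        assert sorted(union) == list(range(33))
        assert len(set(union)) == 33

    def test_deterministic_given_seed(self):
        a = split_dataset(33, (0.70, 0.15, 0.15), seed=9)
        b = split_dataset(33, (0.70, 0.15, 0.15), seed=9)
        c = split_dataset(33, (0.70, 0.15, 0.15), seed=10)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            split_dataset(2, (0.70, 0.15, 0.15), seed=0)


class TestScanHyperparameters:
    def test_default_grid_has_15_by_8_rows(self, rng):
        X = rng.uniform(-1, 1, size=(33, 2))
        Y = rng.uniform(-1, 1, size=(33, 5))
        res = scan_hyperparameters(X, Y, config=TrainingConfig(seed=0))
        assert len(res.table) == 15 * 8
        assert res.table["feasible"].all()

    def test_single_point_grid_selected(self, rng):
        X = rng.uniform(-1, 1, size=(10, 2))
        Y = rng.uniform(-1, 1, size=(10, 2))
        res = scan_hyperparameters(X, Y, neuron_counts=[4], spreads=[0.9],
                                   config=TrainingConfig(seed=0))
        assert (res.selected_neurons, res.selected_spread) == (4, 0.9)

    def test_selection_is_argmin_of_training_mse(self, rng):
        X = rng.uniform(-1, 1, size=(16, 2))
        Y = np.column_stack([np.sin(2 * X[:, 0]), X[:, 1]])
        res = scan_hyperparameters(X, Y, neuron_counts=[0, 2, 4, 8],
                                   spreads=[0.3, 0.8, 1.5],
                                   config=TrainingConfig(seed=1))
        t = res.table
        best = t.loc[t["mse_train"].idxmin()]
        sel = t[(t["neurons"] == res.selected_neurons)
                & (t["spread"] == res.selected_spread)].iloc[0]
        assert sel["mse_train"] <= best["mse_train"] + 1e-15

    def test_infeasible_counts_marked_not_fatal(self, rng):
        X = rng.uniform(-1, 1, size=(6, 2))
        Y = rng.uniform(-1, 1, size=(6, 2))
        res = scan_hyperparameters(X, Y, neuron_counts=[0, 4, 10], spreads=[1.0],
                                   config=TrainingConfig(seed=0))
        infeasible = res.table[res.table["neurons"] == 10]
        assert not infeasible["feasible"].any()
        assert res.selected_neurons <= 4

    def test_train_mse_non_increasing_in_neurons_at_fixed_spread(self, rng):
        X = rng.uniform(-1, 1, size=(25, 2))
        Y = rng.uniform(-1, 1, size=(25, 3))
        res = scan_hyperparameters(X, Y, neuron_counts=[0, 2, 4, 6, 8, 10],
                                   spreads=[0.7], config=TrainingConfig(seed=0))
        mses = res.table.sort_values("neurons")["mse_train"].tolist()
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))


class TestModelPersistence:
    def test_save_load_predict_identical(self, rng, tmp_path):
        X = rng.uniform(0, 10, size=(12, 2))
        Y = rng.uniform(-5, 5, size=(12, 5))
        xn = fit_minmax(X, ("a", "b"))
        yn = fit_minmax(Y, tuple("uvwxy"))
        net, _ = train_incremental(xn.transform(X), yn.transform(Y),
                                   TrainingConfig(spread=0.9, max_neurons=8, seed=0),
                                   ("a", "b"), tuple("uvwxy"))
        net.x_norm, net.y_norm = xn, yn
        p = tmp_path / "model.yaml"
        save_model(net, p)
        back = load_model(p)
        probe = rng.uniform(0, 10, size=(7, 2))
        np.testing.assert_allclose(predict(back, probe, scale="original"),
                                   predict(net, probe, scale="original"),
                                   rtol=0, atol=1e-15)

    def test_missing_spread_is_parse_error(self, tmp_path):
        p = tmp_path / "broken.yaml"
        p.write_text("version: '1'\ncenters: []\n")
        with pytest.raises(ModelParseError, match="spread"):
            load_model(p)

    def test_version_tag_preserved(self, tmp_path):
        net = _net([[0.0, 0.0]], spread=1.0)
        p = tmp_path / "m.yaml"
        save_model(net, p)
        assert load_model(p).metadata["format_version"] == "1"
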