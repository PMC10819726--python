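import numpy as np
import pytest

from pigcall.audio import ValidationError
from pigcall.gabp import (
    GAConfig,
    LabeledDataset,
    NetworkParams,
    TrainConfig,
    bp_train,
    forward,
    ga_optimize,
    mse,
    one_hot,
    predict,
    stratified_split,
    train_variant,
)


def make_net(n_in, n_hidden=10, n_out=3, fill=0.0):
    return NetworkParams(
        W1=np.full((n_in, n_hidden), fill),
        b1=np.full(n_hidden, fill),
        W2=np.full((n_hidden, n_out), fill),
        b2=np.full(n_out, fill),
    )


class TestNetworkParams:
    @pytest.mark.parametrize("n_in,expected", [(15, 193), (16, 203), (33, 373)])
    def test_parameter_count_formula(self, n_in, expected):
        assert make_net(n_in).n_params == expected

    def test_flat_round_trip(self, rng):
        genes = rng.uniform(-1, 1, 203)
        net = NetworkParams.from_flat(genes, (16, 10, 3))
        assert np.array_equal(net.flatten(), genes)

    def test_wrong_chromosome_length_rejected(self):
        with pytest.raises(ValidationError):
            NetworkParams.from_flat(np.zeros(100), (16, 10, 3))


class TestForward:
    def test_zero_network_outputs_half(self):
        out = forward(make_net(5), np.zeros(5))
        assert np.allclose(out, 0.5)

    def test_outputs_strictly_in_unit_interval(self, rng):
        net = NetworkParams(
            W1=rng.uniform(-5, 5, (4, 10)),
            b1=rng.uniform(-5, 5, 10),
            W2=rng.uniform(-5, 5, (10, 3)),
            b2=rng.uniform(-5, 5, 3),
        )
        out = forward(net, rng.uniform(0, 1, (20, 4)))
        assert np.all((out > 0) & (out < 1))

    def test_single_path_closed_form(self):
        net = NetworkParams(W1=np.array([[1.0]]), b1=np.zeros(1), W2=np.array([[1.0]]), b2=np.zeros(1))
        out = forward(net, np.array([0.0]))
        # sigmoid(sigmoid(0)) = sigmoid(0.5)
        assert out[0] == pytest.approx(1 / (1 + np.exp(-0.5)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            forward(make_net(5), np.zeros(4))


class TestMSE:
    def test_outputs_equal_to_targets_give_zero_error(self):
        net = make_net(2, n_out=1, fill=0.0)  # all outputs are exactly 0.5
        data = LabeledDataset(X=np.zeros((3, 2)), y=np.full((3, 1), 0.5))
        assert mse(net, data) == pytest.approx(0.0)

    def test_half_outputs_vs_one_hot_by_direct_loop(self):
        net = make_net(2)
        y = one_hot(np.array(["grunt", "squeal", "cough", "grunt"]))
        data = LabeledDataset(X=np.zeros((4, 2)), y=y)
        out = forward(net, data.X)
        brute = np.mean([(out[i, j] - y[i, j]) ** 2 for i in range(4) for j in range(3)])
        assert mse(net, data) == pytest.approx(brute)

    def test_invariant_to_sample_order(self, rng):
        net = NetworkParams(
            W1=rng.standard_normal((3, 10)),
            b1=rng.standard_normal(10),
            W2=rng.standard_normal((10, 3)),
            b2=rng.standard_normal(3),
        )
        X = rng.uniform(0, 1, (10, 3))
        y = one_hot(np.array(["grunt", "squeal"] * 5))
        perm = rng.permutation(10)
        assert mse(net, LabeledDataset(X, y)) == pytest.approx(
            mse(net, LabeledDataset(X[perm], y[perm]))
        )


class TestBPTrain:
    def test_learns_xor(self, rng):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([[0.0], [1], [1], [0]])
        data = LabeledDataset(X, y)
        net = NetworkParams(
            W1=rng.uniform(-1, 1, (2, 10)),
            b1=rng.uniform(-1, 1, 10),
            W2=rng.uniform(-1, 1, (10, 1)),
            b2=rng.uniform(-1, 1, 1),
        )
        trained, history = bp_train(net, data, TrainConfig(max_epochs=1000, learning_rate=0.5))
        assert history[-1] < 0.05

    def test_zero_learning_rate_is_noop(self, rng):
        data = LabeledDataset(rng.uniform(0, 1, (6, 4)), one_hot(np.array(["grunt"] * 6)))
        net = NetworkParams(
            W1=rng.standard_normal((4, 10)),
            b1=rng.standard_normal(10),
            W2=rng.standard_normal((10, 3)),
            b2=rng.standard_normal(3),
        )
        trained, _ = bp_train(net, data, TrainConfig(max_epochs=5, learning_rate=0.0))
        assert np.array_equal(trained.W1, net.W1)
        assert np.array_equal(trained.b2, net.b2)

    def test_same_seed_identical_history(self, rng):
        data = LabeledDataset(
            rng.uniform(0, 1, (12, 4)), one_hot(np.array(["grunt", "squeal", "cough"] * 4))
        )
        net = NetworkParams(
            W1=rng.uniform(-1, 1, (4, 10)),
            b1=rng.uniform(-1, 1, 10),
            W2=rng.uniform(-1, 1, (10, 3)),
            b2=rng.uniform(-1, 1, 3),
        )
        cfg = TrainConfig(max_epochs=50, seed=11)
        _, h1 = bp_train(net, data, cfg)
        _, h2 = bp_train(net, data, cfg)
        assert np.array_equal(h1, h2)

    def test_final_error_not_above_initial(self, rng):
        data = LabeledDataset(
            rng.uniform(0, 1, (12, 4)), one_hot(np.array(["grunt", "squeal", "cough"] * 4))
        )
        net = NetworkParams(
            W1=rng.uniform(-1, 1, (4, 10)),
            b1=rng.uniform(-1, 1, 10),
            W2=rng.uniform(-1, 1, (10, 3)),
            b2=rng.uniform(-1, 1, 3),
        )
        trained, history = bp_train(net, data, TrainConfig(max_epochs=100))
        assert mse(trained, data) <= history[0] + 1e-12


class TestGAOptimize:
    @pytest.fixture
    def toy_data(self, rng):
        X = rng.uniform(0, 1, (9, 3))
        return LabeledDataset(X, one_hot(np.array(["grunt", "squeal", "cough"] * 3)))

    def test_best_fitness_monotone_nondecreasing(self, toy_data):
        _, history = ga_optimize(
            (3, 10, 3), toy_data, GAConfig(seed=3, generations=30), return_history=True
        )
        assert np.all(np.diff(history) >= -1e-12)

    def test_returned_beats_initial_population(self, toy_data):
        cfg = GAConfig(seed=5, generations=20)
        best, history = ga_optimize((3, 10, 3), toy_data, cfg, return_history=True)
        best_fit = 1.0 / (1.0 + mse(best, toy_data))
        assert best_fit >= history[0] - 1e-12

    def test_measurable_improvement_on_fixed_seed(self, rng):
        X = rng.uniform(0, 1, (1, 3))
        data = LabeledDataset(X, one_hot(np.array(["squeal"])))
        best, history = ga_optimize(
            (3, 10, 3), data, GAConfig(seed=9), return_history=True
        )
        initial_best_mse = 1.0 / history[0] - 1.0
        final_mse = mse(best, data)
        assert final_mse <= 0.9 * initial_best_mse

    def test_no_variation_reduces_to_selection(self, toy_data):
        cfg = GAConfig(seed=4, generations=15, crossover_prob=0.0, mutation_prob=0.0)
        best, history = ga_optimize((3, 10, 3), toy_data, cfg, return_history=True)
        assert history[-1] == pytest.approx(history[0])
        assert 1.0 / (1.0 + mse(best, toy_data)) == pytest.approx(history[0])

    def test_odd_population_rejected(self):
        with pytest.raises(ValidationError):
            GAConfig(population=51)


class TestStratifiedSplit:
    def test_published_class_counts_split(self):
        labels = np.array(["grunt"] * 291 + ["squeal"] * 357 + ["cough"] * 291)
        train, val = stratified_split(labels, seed=0)
        val_labels = labels[val]
        assert (val_labels == "grunt").sum() == 87
        assert (val_labels == "squeal").sum() == 107
        assert (val_labels == "cough").sum() == 87

    def test_partition_disjoint_and_exhaustive(self):
        labels = np.array(["grunt"] * 20 + ["squeal"] * 30 + ["cough"] * 10)
        train, val = stratified_split(labels, seed=1)
        assert len(set(train) & set(val)) == 0
        assert sorted(np.concatenate([train, val])) == list(range(60))

    def test_same_seed_same_split(self):
        labels = np.array(["grunt", "squeal", "cough"] * 10)
        assert np.array_equal(stratified_split(labels, seed=7)[1], stratified_split(labels, seed=7)[1])

    def test_tiny_class_rejected(self):
        labels = np.array(["grunt", "squeal", "squeal", "cough", "cough"])
        with pytest.raises(ValidationError):
            stratified_split(labels)


@pytest.fixture(scope="module")
def bundles(small_feature_table):
    cfgs = dict(
        ga_cfg=GAConfig(seed=0, generations=10, population=10),
        train_cfg=TrainConfig(seed=0, max_epochs=50),
        seed=0,
    )
    return {
        v: train_variant(small_feature_table, v, **cfgs)
        for v in ("raw33", "pca15", "pca15_plus_score")
    }


class TestTrainVariant:
    def test_input_dimensions_by_variant(self, bundles):
        assert bundles["raw33"].net.topology[0] == 33
        k = bundles["pca15"].pca_model.k
        assert bundles["pca15"].net.topology[0] == k
        assert bundles["pca15_plus_score"].net.topology[0] == k + 1

    def test_confusion_rows_match_validation_counts(self, bundles):
        cm = bundles["raw33"].validation_cm
        labels = bundles["raw33"].predictions["true_label"]
        assert cm.counts.sum(axis=1).tolist() == [
            (labels == c).sum() for c in ("grunt", "squeal", "cough")
        ]

    def test_identical_seed_identical_confusion(self, small_feature_table):
        kw = dict(
            ga_cfg=GAConfig(seed=2, generations=5, population=10),
            train_cfg=TrainConfig(seed=2, max_epochs=20),
            seed=2,
        )
        b1 = train_variant(small_feature_table, "pca15", **kw)
        b2 = train_variant(small_feature_table, "pca15", **kw)
        assert np.array_equal(b1.validation_cm.counts, b2.validation_cm.counts)

    def test_predict_applies_stored_transforms(self, bundles, small_feature_table):
        preds = predict(bundles["pca15_plus_score"], small_feature_table)
        assert set(preds) <= {"grunt", "squeal", "cough"}
        assert len(preds) == len(small_feature_table)

    def test_predict_rejects_wrong_dimension(self, bundles):
        with pytest.raises(ValidationError):
            predict(bundles["raw33"], np.zeros((2, 10)))

    def test_bundle_json_round_trip(self, bundles, tmp_path, small_feature_table):
        from pigcall.gabp import ModelBundle

        bundles["pca15_plus_score"].save(tmp_path / "m.json")
        back = ModelBundle.load(tmp_path / "m.json")
        p1 = predict(bundles["pca15_plus_score"], small_feature_table)
        p2 = predict(back, small_feature_table)
        assert np.array_equal(p1, p2)
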