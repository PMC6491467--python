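"""Network construction, training behavior, and inference contracts."""

import numpy as np
import pytest

from psfdecode import networks as nw
from psfdecode.config import ConfigurationError

SMALL_CLS = nw.NetworkSpec(
    input_size=20, hidden_layers=(16, 16, 8, 8), n_classes=2, dropout_rate=0.5
)
SMALL_REG = nw.NetworkSpec(
    input_size=20, hidden_layers=(16, 16, 8, 8), weight_decay=0.01
)


def separable_data(n, seed, input_size=20):
    """Two classes split by a random hyperplane with a wide margin."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=input_size)
    X = rng.normal(size=(n, input_size))
    margin = X @ w
    y = (margin > 0).astype(int)
    X += 0.5 * np.outer(np.sign(margin), w / np.linalg.norm(w))
    return X, y


class TestSpecValidation:
    def test_dropout_and_weight_decay_exclusive(self):
        with pytest.raises(ConfigurationError):
            nw.NetworkSpec(n_classes=2, dropout_rate=0.5, weight_decay=0.01)

    def test_four_hidden_layers_required(self):
        with pytest.raises(ConfigurationError):
            nw.NetworkSpec(hidden_layers=(64, 64))

    def test_classifier_needs_two_classes(self):
        with pytest.raises(ConfigurationError):
            nw.NetworkSpec(n_classes=1)


class TestBuildNetwork:
    def test_softmax_head_normalized_for_any_input(self):
        net = nw.build_network(SMALL_CLS, seed=0)
        X = np.random.default_rng(1).normal(size=(10, 20)) * 100.0
        P = net.predict_proba(X)
        assert P.shape == (10, 2)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    def test_regressor_outputs_scalar(self):
        net = nw.build_network(SMALL_REG, seed=0)
        out = net.predict_scalar(np.zeros((5, 20)))
        assert out.shape == (5,)

    def test_same_seed_identical_parameters(self):
        a = nw.build_network(SMALL_CLS, seed=11)
        b = nw.build_network(SMALL_CLS, seed=11)
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)

    def test_different_seed_different_parameters(self):
        a = nw.build_network(SMALL_CLS, seed=11)
        b = nw.build_network(SMALL_CLS, seed=12)
        assert not np.array_equal(a.weights[0], b.weights[0])

    def test_input_dimension_mismatch_rejected(self):
        net = nw.build_network(SMALL_CLS, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((3, 21)))


class TestClassifierTraining:
    def test_linearly_separable_data_learned(self):
        Xall, yall = separable_data(800, seed=2)
        X, y = Xall[:600], yall[:600]
        Xv, yv = Xall[600:], yall[600:]
        spec = nw.NetworkSpec(
            input_size=20, hidden_layers=(64, 64, 32, 16), n_classes=2,
            dropout_rate=0.5,
        )
        net = nw.build_network(spec, seed=4)
        net, log = nw.train_color_network(
            net, (X, y), (Xv, yv),
            nw.TrainingConfig(initial_learning_rate=1e-3, batch_size=32,
                              max_epochs=10, seed=4),
        )
        train_acc = np.mean(net.predict_proba(X).argmax(axis=1) == y)
        assert train_acc >= 0.99
        assert log.stopped_epoch <= 10

    def test_single_class_rejected(self):
        X = np.zeros((10, 20))
        y = np.zeros(10, dtype=int)
        net = nw.build_network(SMALL_CLS, seed=0)
        with pytest.raises(ConfigurationError):
            nw.train_color_network(net, (X, y), (X, y))

    def test_training_deterministic_under_seed(self):
        X, y = separable_data(300, seed=5)
        results = []
        for _ in range(2):
            net = nw.build_network(SMALL_CLS, seed=6)
            net, log = nw.train_color_network(
                net, (X, y), (X, y),
                nw.TrainingConfig(initial_learning_rate=1e-3, batch_size=32,
                                  max_epochs=3, seed=6),
            )
            results.append((tuple(log.train_loss), tuple(log.val_metric)))
        assert results[0] == results[1]


class TestRegressorTraining:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 20))
        y = np.full(400, 150.0)
        net = nw.build_network(SMALL_REG, seed=8)
        net, _ = nw.train_axial_network(
            net, (X, y), (X[:50], y[:50]),
            nw.TrainingConfig(initial_learning_rate=1e-2, batch_size=32,
                              max_epochs=20, plateau_patience=20, seed=8),
        )
        preds = net.predict_scalar(rng.normal(size=(50, 20)))
        assert abs(preds.mean() - 150.0) < 10.0
        assert preds.std() < 40.0

    def test_mixed_fluorophore_set_rejected(self):
        X = np.zeros((10, 20))
        y = np.zeros(10)
        net = nw.build_network(SMALL_REG, seed=0)
        with pytest.raises(ConfigurationError):
            nw.train_axial_network(net, (X, y), (X, y),
                                   color_labels=[0] * 5 + [1] * 5)

    def test_learning_rate_schedule_steps_down(self):
        cfg = nw.TrainingConfig(initial_learning_rate=1e-3, decay_factor=0.2,
                                decay_interval=1000)
        assert cfg.learning_rate(0) == 1e-3
        assert cfg.learning_rate(999) == 1e-3
        assert cfg.learning_rate(1000) == pytest.approx(2e-4)
        assert cfg.learning_rate(2500) == pytest.approx(4e-5)


class TestInference:
    def test_zero_threshold_accepts_everything(self):
        net = nw.build_network(SMALL_CLS, seed=0)
        X = np.random.default_rng(2).normal(size=(30, 20))
        calls = nw.infer_color(net, X, delta_threshold=0.0)
        assert all(c.accepted for c in calls)

    def test_rejection_rate_nondecreasing_in_threshold(self):
        net = nw.build_network(SMALL_CLS, seed=1)
        X = np.random.default_rng(3).normal(size=(100, 20))
        rates = []
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0 + 1e-9):
            calls = nw.infer_color(net, X, delta_threshold=thr)
            rates.append(np.mean([not c.accepted for c in calls]))
        assert np.all(np.diff(rates) >= 0)
        assert rates[-1] == pytest.approx(
            np.mean([abs(c.delta) < 1.0 for c in nw.infer_color(net, X, 0.0)])
        )

    def test_posterior_and_delta_invariants(self):
        net = nw.build_network(SMALL_CLS, seed=2)
        X = np.random.default_rng(4).normal(size=(50, 20))
        for call in nw.infer_color(net, X, 0.3):
            assert abs(call.posterior.sum() - 1.0) < 1e-6
            assert -1.0 <= call.delta <= 1.0
            assert call.accepted == (abs(call.delta) >= 0.3)
            assert call.map_class == int(np.argmax(call.posterior))

    def test_binary_delta_is_signed_posterior_difference(self):
        net = nw.build_network(SMALL_CLS, seed=3)
        X = np.random.default_rng(5).normal(size=(20, 20))
        P = net.predict_proba(X)
        calls = nw.infer_color(net, X, 0.0)
        np.testing.assert_allclose(
            [c.delta for c in calls], P[:, 0] - P[:, 1], atol=1e-12
        )

    def test_inference_deterministic(self):
        net = nw.build_network(SMALL_REG, seed=4)
        X = np.random.default_rng(6).normal(size=(10, 20))
        np.testing.assert_array_equal(nw.infer_axial(net, X), nw.infer_axial(net, X))

    def test_save_load_preserves_outputs(self, tmp_path):
        net = nw.build_network(SMALL_CLS, seed=5)
        X = np.random.default_rng(7).normal(size=(5, 20))
        before = net.predict_proba(X)
        net.save(tmp_path / "clf")
        loaded = nw.Network.load(tmp_path / "clf")
        np.testing.assert_array_equal(loaded.predict_proba(X), before)


class TestLateralNetworks:
    def test_transposed_training_gives_equivalent_precision(self, optics, grid,
                                                            fine_stacks):
        """An x-regressor on patches and a y-regressor on transposed patches
        see statistically identical problems."""
        from psfdecode import psf_sim as ps

        ds = ps.generate_benchmark_dataset(
            [optics[600]], grid, 1200, photon_distribution=(4500, 5500),
            z_distribution=(-200.0, 200.0), rng_seed=91, stacks=[fine_stacks[600]],
        )
        patches = [img for img, _ in ds]
        x_labels = np.array([t.x_nm for _, t in ds])
        y_labels = np.array([t.y_nm for _, t in ds])
        Xx = nw.patches_to_inputs(patches)
        Xy = nw.patches_to_inputs([p.T for p in patches])
        spec = nw.NetworkSpec(hidden_layers=(128, 64, 32, 16), weight_decay=0.01)
        cfg = nw.TrainingConfig(initial_learning_rate=1e-3, batch_size=32,
                                max_epochs=15, plateau_patience=5, seed=9)
        rmses = []
        for X, labels in ((Xx, x_labels), (Xy, y_labels)):
            net = nw.build_network(spec, seed=9)
            net, _ = nw.train_lateral_network(
                net, (X[:1000], labels[:1000]), (X[1000:], labels[1000:]), cfg
            )
            err = net.predict_scalar(X[1000:]) - labels[1000:]
            rmses.append(np.sqrt(np.mean(err**2)))
        assert abs(rmses[0] - rmses[1]) / max(rmses) < 0.3
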