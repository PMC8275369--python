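"""CNN classifier: layer arithmetic, gradients, training contract, I/O."""

import numpy as np
import pytest

import encore
from encore import _net
from encore.model import (EnhancerClassifier, build_model, class_weights,
                          load_model, predict, save_model)


def toy_estimator(**kw):
    """Small float64 network for exact numeric checks."""
    defaults = dict(n_filters=4, dense_units=8, dropout=0.0, random_state=1,
                    max_epochs=0, dtype="float64")
    defaults.update(kw)
    est = EnhancerClassifier(**defaults)
    est.fit(np.random.default_rng(0).random((2, 5, 400)), [0, 1])
    return est


class TestConvArithmetic:
    def test_first_conv_matches_nested_loop_correlation(self):
        """Direct correlation oracle on a 5 x 20 toy input, one filter."""
        rng = np.random.default_rng(0)
        conv = _net.Conv2D(1, 1, 5, 10, pad_h="valid", pad_w="valid",
                           dtype=np.float64, rng=rng)
        x = rng.random((1, 1, 5, 20))
        out = conv.forward(x)
        assert out.shape == (1, 1, 1, 11)
        W = conv.W.reshape(5, 10)
        for j in range(11):
            expected = (x[0, 0, :, j:j + 10] * W).sum() + conv.b[0]
            assert np.isclose(out[0, 0, 0, j], expected)

    def test_delta_input_reproduces_kernel_response(self):
        rng = np.random.default_rng(1)
        conv = _net.Conv2D(1, 1, 1, 4, pad_h="valid", pad_w="valid",
                           dtype=np.float64, rng=rng)
        x = np.zeros((1, 1, 1, 20))
        x[0, 0, 0, 10] = 1.0
        out = conv.forward(x)[0, 0, 0] - conv.b[0]
        w = conv.W.reshape(4)
        # position j reads x[j..j+3]; the delta at 10 responds at j = 10-q
        for j in range(17):
            expected = w[10 - j] if 7 <= j <= 10 else 0.0
            assert np.isclose(out[j], expected)

    def test_valid_2d_collapse_height(self):
        # 5-row input with a full-height kernel leaves height 5 - 5 + 1 = 1
        est = toy_estimator()
        logits, acts = est.net_.forward(
            np.random.default_rng(0).random((1, 1, 5, 400)), capture=("conv2",))
        assert acts["conv2"].shape[2] == 1

    def test_maxpool_output_dims(self):
        pool = _net.MaxPoolW(4)
        out = pool.forward(np.random.default_rng(0).random((2, 3, 5, 400)))
        assert out.shape == (2, 3, 5, 100)
        with pytest.raises(ValueError, match="divisible"):
            pool.forward(np.zeros((1, 1, 1, 21)))


class TestGradients:
    def test_all_parameter_gradients_match_finite_differences(self):
        est = toy_estimator()
        net = est.net_
        rng = np.random.default_rng(3)
        X = rng.random((3, 1, 5, 400))
        net.forward(X)
        net.backward(np.ones(3))
        for layer in net.layers:
            for pname, gname in layer.params():
                P = getattr(layer, pname)
                G = getattr(layer, gname)
                for _ in range(2):
                    idx = tuple(int(rng.integers(0, s)) for s in P.shape)
                    eps = 1e-6
                    old = P[idx]
                    P[idx] = old + eps
                    lp, _ = net.forward(X)
                    P[idx] = old - eps
                    lm, _ = net.forward(X)
                    P[idx] = old
                    fd = (lp.sum() - lm.sum()) / (2 * eps)
                    assert np.isclose(fd, G[idx], rtol=1e-4, atol=1e-7), \
                        f"{layer.name}.{pname}{idx}"

    def test_activation_gradients_match_finite_differences(self):
        """d(logit)/d(activation) at a mid conv layer — the Grad-CAM path."""
        est = toy_estimator()
        net = est.net_
        rng = np.random.default_rng(4)
        X = rng.random((2, 1, 5, 400))
        _, acts = net.forward(X, capture=("conv5",))
        grads = net.backward(np.ones(2), capture=("conv5",))
        A, G = acts["conv5"], grads["conv5"]
        for _ in range(4):
            idx = tuple(int(rng.integers(0, s)) for s in A.shape)
            eps = 1e-6
            Ap = A.copy(); Ap[idx] += eps
            Am = A.copy(); Am[idx] -= eps
            fd = (net.forward_from("conv5", Ap).sum()
                  - net.forward_from("conv5", Am).sum()) / (2 * eps)
            assert np.isclose(fd, G[idx], rtol=1e-4, atol=1e-7)


class TestBuildAndPredict:
    def test_output_is_probability(self, trained_model, small_sim):
        X = small_sim["dataset"].X[:5]
        p = trained_model.predict_proba(X)[:, 1]
        assert np.all((p > 0) & (p < 1))

    def test_zero_parameters_give_exactly_half(self):
        est = toy_estimator()
        zero = [np.zeros_like(a) for a in est.net_.param_state()]
        est.net_.set_param_state(zero)
        p = est.predict_proba(np.random.default_rng(0).random((3, 5, 400)))
        assert np.all(p[:, 1] == 0.5)

    def test_prediction_deterministic(self, trained_model, small_sim):
        X = small_sim["dataset"].X[:8]
        a = trained_model.predict_proba(X)
        b = trained_model.predict_proba(X)
        assert np.array_equal(a, b)

    def test_trained_model_separates_planted_enhancers(self, trained_model,
                                                       small_sim):
        ds = small_sim["dataset"]
        p = trained_model.predict_proba(ds.X)[:, 1]
        assert p[ds.y == 1].mean() > 0.5 > p[ds.y == 0].mean()

    def test_dimension_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError):
            trained_model.predict_proba(np.zeros((2, 5, 100)))

    def test_parameter_count_reported(self, trained_model):
        assert trained_model.n_parameters_ == \
            trained_model.net_.n_parameters()
        assert trained_model.n_parameters_ > 10_000

    def test_functional_wrappers(self, trained_model, small_sim):
        est = build_model(max_epochs=0)
        assert isinstance(est, EnhancerClassifier)
        matrix = small_sim["dataset"].X[0]
        p = predict(trained_model, matrix)
        assert 0 < p < 1


class TestTrainingContract:
    def _data(self, n=220, seed=0):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 11 == 0).astype(np.int8)
        X = rng.random((n, 5, 400), dtype=np.float32)
        X[y == 1, 2, 180:220] += 4.0
        return X, y

    def test_max_epochs_zero_returns_initial_state(self):
        X, y = self._data(40)
        est = EnhancerClassifier(max_epochs=0, random_state=0)
        est.fit(X, y)
        assert est.history_ == {"train_loss": [], "val_loss": []}
        assert est.predict_proba(X).shape == (40, 2)

    def test_single_class_rejected(self):
        X, _ = self._data(20)
        est = EnhancerClassifier(max_epochs=1)
        with pytest.raises(ValueError, match="both classes"):
            est.fit(X, np.ones(20))

    def test_validation_split_is_stratified_80_20(self):
        X, y = self._data(220)
        est = EnhancerClassifier(max_epochs=1, random_state=0, n_filters=8,
                                 dense_units=8)
        est.fit(X, y)
        assert len(est.val_indices_) == 44
        assert len(est.train_indices_) == 176
        # stratification preserves the 1:10 imbalance in both partitions
        assert y[est.val_indices_].sum() == 4
        assert set(est.val_indices_) & set(est.train_indices_) == set()

    def test_separable_data_reduces_validation_loss(self):
        X, y = self._data(220)
        est = EnhancerClassifier(max_epochs=6, random_state=0, batch_size=16,
                                 n_filters=8, dense_units=16)
        est.fit(X, y)
        h = est.history_["val_loss"]
        assert h[-1] < h[0]

    def test_identical_seeds_identical_history(self):
        X, y = self._data(110)
        kw = dict(max_epochs=3, random_state=7, batch_size=16, n_filters=8,
                  dense_units=8)
        a = EnhancerClassifier(**kw).fit(X, y)
        b = EnhancerClassifier(**kw).fit(X, y)
        assert a.history_ == b.history_

    def test_early_stopping_restores_best_weights(self):
        X, y = self._data(110)
        est = EnhancerClassifier(max_epochs=8, patience=2, random_state=1,
                                 batch_size=16, n_filters=8, dense_units=8)
        est.fit(X, y)
        n_epochs = len(est.history_["val_loss"])
        assert n_epochs <= 8
        assert est.best_epoch_ == int(np.argmin(est.history_["val_loss"]))

    def test_class_weight_formula(self):
        y = np.array([1] * 10 + [0] * 100)
        cw = class_weights(y)
        assert np.isclose(cw[1], 110 / 20)
        assert np.isclose(cw[0], 110 / 200)
        # equal total mass per class compensates the imbalance
        assert np.isclose(cw[1] * 10, cw[0] * 100)

    def test_weighted_loss_balances_class_mass(self):
        logits = np.full(6, 0.3)
        y_pos, y_neg = np.ones(6), np.zeros(6)
        # per-example losses differ, but with weights from a 1:10 dataset the
        # total weight mass assigned to each class over the dataset is equal
        w = class_weights(np.array([1] * 6 + [0] * 60))
        loss_pos, _ = _net.bce_with_logits(logits, y_pos,
                                           np.full(6, w[1]))
        loss_neg, _ = _net.bce_with_logits(logits, y_neg,
                                           np.full(6, w[0]))
        assert loss_pos > 0 and loss_neg > 0
        assert np.isclose(w[1] * 6, w[0] * 60)


class TestPersistence:
    def test_round_trip_predictions_bitwise_equal(self, trained_model,
                                                  small_sim, tmp_path):
        p = tmp_path / "model.npz"
        save_model(trained_model, p)
        back = load_model(p)
        X = small_sim["dataset"].X[:10]
        assert np.array_equal(trained_model.predict_proba(X),
                              back.predict_proba(X))

    def test_metadata_survives(self, trained_model, tmp_path):
        trained_model.panel_order_ = ("H3K4me3", "H3K9ac", "accessibility",
                                      "H3K27ac", "H3K4me1")
        p = tmp_path / "model.npz"
        trained_model.save(p)
        back = load_model(p)
        assert back.random_state == trained_model.random_state
        assert back.panel_order_ == trained_model.panel_order_
        assert back.history_ == trained_model.history_

    def test_truncated_file_rejected(self, trained_model, tmp_path):
        p = tmp_path / "model.npz"
        trained_model.save(p)
        data = p.read_bytes()
        p.write_bytes(data[:len(data) // 2])
        with pytest.raises(ValueError, match="not a valid model archive"):
            load_model(p)
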