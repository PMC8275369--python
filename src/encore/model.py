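"""CNN binary enhancer classifier as a scikit-learn estimator.

The network consumes a 5 x 400 matrix of binned epigenetic signal (five
assays x 10 bp bins over a 4 kb window) and emits the probability that the
window contains an enhancer.  Architecture (defaults):

* conv1: 2D, kernel 5x10, same padding — spans all five assay rows so the
  filters blend accessibility and histone signal; output 5 x 400.
* width max-pool (1x4).
* conv2: 2D, kernel 5x10, valid in height — collapses the assay axis to a
  1D feature map over the genomic axis.
* conv3..conv7: 1D, kernel 1x4, same padding along the genome.
* squeeze-and-excitation channel gates between consecutive conv layers.
* width max-pool (1x4), then dense(64) -> dropout -> dense(1) -> sigmoid.

Training: Adam (lr 5e-5), binary cross-entropy on the logit, inverse class
frequency weights for the 1:10 positive:negative imbalance, seeded
stratified 80-20 train/validation split, early stopping on validation loss
with best-weight restoration.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _net
from .signal_io import N_ASSAYS, N_BINS, WindowMatrix

__all__ = ["EnhancerClassifier", "build_model", "train", "predict",
           "save_model", "load_model", "class_weights"]


def class_weights(y) -> dict:
    """Inverse-frequency weights w_c = N / (2 * N_c).

    Total weight mass per class is then equal (N/2 each), which is what
    compensates the 1:10 positive:negative imbalance in the loss.
    """
    y = np.asarray(y)
    n = len(y)
    out = {}
    for c in (0, 1):
        nc = int((y == c).sum())
        if nc == 0:
            raise ValueError(f"class {c} absent; cannot compute class weights")
        out[c] = n / (2.0 * nc)
    return out


class EnhancerClassifier(ClassifierMixin, BaseEstimator):
    """Binary CNN classifier over 5 x 400 epigenetic signal matrices.

    Parameters
    ----------
    n_filters : filters per convolutional layer.
    kernel_2d : (height, width) of the cross-assay 2D kernels (conv1/conv2).
    kernel_1d : width of the 1D kernels (conv3..7).
    n_conv : total convolutional layers (2 are the 2D stage).
    pool1, pool2 : width max-pool factors after conv1 and after the last conv.
    se_reduction : bottleneck reduction of the squeeze-and-excitation gates.
    dense_units : size of the first dense layer.
    dropout : dropout rate after the first dense layer.
    learning_rate, max_epochs, patience, validation_fraction, batch_size :
        training configuration; early stopping monitors validation loss and
        restores the best weights.
    class_weight : 'balanced' (w_c = N/(2 N_c)), None, or a {0: w0, 1: w1}
        mapping.
    random_state : seed controlling weight init, the 80-20 split, epoch
        shuffling and dropout; fixed seed + single-threaded BLAS gives
        bit-identical training histories.
    dtype : 'float32' (default) or 'float64' (used by gradient-check tests).
    """

    def __init__(self, n_filters=32, kernel_2d=(5, 10), kernel_1d=4,
                 n_conv=7, pool1=4, pool2=4, se_reduction=4, dense_units=64,
                 dropout=0.3, learning_rate=5e-5, max_epochs=100, patience=10,
                 validation_fraction=0.2, batch_size=64,
                 class_weight="balanced", random_state=None, dtype="float32",
                 input_shape=(N_ASSAYS, N_BINS), verbose=0):
        self.n_filters = n_filters
        self.kernel_2d = kernel_2d
        self.kernel_1d = kernel_1d
        self.n_conv = n_conv
        self.pool1 = pool1
        self.pool2 = pool2
        self.se_reduction = se_reduction
        self.dense_units = dense_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.random_state = random_state
        self.dtype = dtype
        self.input_shape = input_shape
        self.verbose = verbose

    # ------------------------------------------------------------------ #
    # architecture
    # ------------------------------------------------------------------ #

    def _build(self, rng) -> "_net.Network":
        if self.n_conv < 3:
            raise ValueError("need at least 3 conv layers (2D stage + 1D stage)")
        h, w = self.input_shape
        kh, kw = self.kernel_2d
        if kh != h:
            raise ValueError(
                f"2D kernel height {kh} must span all {h} assay rows")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        dt = np.dtype(self.dtype).type
        F = self.n_filters
        layers = [
            # fused conv1 + width max-pool; the following ReLU commutes with
            # max-pooling, so this equals conv -> relu -> pool
            _net.InputConvPool(F, kh, kw, self.pool1, dtype=dt, rng=rng,
                               name="conv1_pre"),
            _net.ReLU(name="conv1"),
            _net.SEBlock(F, self.se_reduction, dtype=dt, rng=rng, name="se1"),
            _net.Conv2D(F, F, kh, kw, pad_h="valid", pad_w="same",
                        dtype=dt, rng=rng, name="conv2_pre"),
            _net.ReLU(name="conv2"),
            _net.SEBlock(F, self.se_reduction, dtype=dt, rng=rng, name="se2"),
        ]
        for i in range(3, self.n_conv + 1):
            layers += [
                _net.Conv2D(F, F, 1, self.kernel_1d, pad_h="same", pad_w="same",
                            dtype=dt, rng=rng, name=f"conv{i}_pre"),
                _net.ReLU(name=f"conv{i}"),
            ]
            if i < self.n_conv:  # SE gates sit between consecutive convs
                layers.append(_net.SEBlock(F, self.se_reduction, dtype=dt,
                                           rng=rng, name=f"se{i}"))
        layers.append(_net.MaxPoolW(self.pool2, name="pool2"))
        w_after = (w // self.pool1) // self.pool2
        layers += [
            _net.Flatten(name="flatten"),
            _net.Dense(F * w_after, self.dense_units, dtype=dt, rng=rng,
                       name="dense1"),
            _net.ReLU(name="dense1_act"),
            _net.Dropout(self.dropout, name="dropout"),
            _net.Dense(self.dense_units, 1, dtype=dt, rng=rng, name="logit"),
        ]
        return _net.Network(layers)

    @property
    def conv_layer_names_(self):
        check_is_fitted(self, "net_")
        return [f"conv{i}" for i in range(1, self.n_conv + 1)]

    # ------------------------------------------------------------------ #
    # data plumbing
    # ------------------------------------------------------------------ #

    def _as_input(self, X) -> np.ndarray:
        X = np.asarray(X)
        h, w = self.input_shape
        if X.ndim == 2 and X.shape == (h, w):
            X = X[None]
        elif X.ndim == 2 and X.shape[1] == h * w:
            X = X.reshape(-1, h, w)
        if X.ndim != 3 or X.shape[1:] != (h, w):
            raise ValueError(
                f"expected input of shape (n, {h}, {w}) or (n, {h * w}), "
                f"got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X[:, None, :, :].astype(self.dtype, copy=False)  # NCHW

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        X4 = self._as_input(X)
        y = np.asarray(y).astype(np.int8).ravel()
        if len(y) != len(X4):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.max_epochs and (len(self.classes_) < 2):
            raise ValueError("training requires both classes present")
        if not set(self.classes_) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.n_features_in_ = int(np.prod(self.input_shape))

        seed = self.random_state if self.random_state is not None else 0
        rng = np.random.default_rng(seed)
        self.net_ = self._build(rng)
        self.n_parameters_ = self.net_.n_parameters()
        self.history_ = {"train_loss": [], "val_loss": []}

        if self.max_epochs == 0:
            return self

        if self.class_weight == "balanced":
            cw = class_weights(y)
        elif self.class_weight is None:
            cw = {0: 1.0, 1: 1.0}
        else:
            cw = {0: float(self.class_weight[0]), 1: float(self.class_weight[1])}
        self.class_weight_ = cw

        idx = np.arange(len(y))
        tr, va = train_test_split(
            idx, test_size=self.validation_fraction, stratify=y,
            random_state=seed, shuffle=True)
        self.train_indices_, self.val_indices_ = tr, va
        Xtr, ytr = X4[tr], y[tr]
        Xva, yva = X4[va], y[va]
        wtr = np.where(ytr == 1, cw[1], cw[0]).astype(np.float64)

        opt = _net.Adam(self.net_, lr=self.learning_rate)
        best_loss, best_state, best_epoch = np.inf, None, -1
        n = len(ytr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                sel = order[lo:lo + self.batch_size]
                logits, _ = self.net_.forward(Xtr[sel], training=True, rng=rng)
                loss, dlog = _net.bce_with_logits(logits, ytr[sel], wtr[sel])
                self.net_.backward(dlog)
                opt.step()
                losses.append(loss)
            val_logits = self._forward_eval(Xva)
            val_loss, _ = _net.bce_with_logits(val_logits, yva)
            self.history_["train_loss"].append(float(np.mean(losses)))
            self.history_["val_loss"].append(float(val_loss))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.max_epochs} "
                      f"train_loss={np.mean(losses):.5f} val_loss={val_loss:.5f}")
            if val_loss < best_loss - 1e-12:
                best_loss, best_epoch = val_loss, epoch
                best_state = self.net_.param_state()
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            self.net_.set_param_state(best_state)
        self.best_epoch_ = best_epoch
        return self

    def _forward_eval(self, X4, batch_size=256):
        out = np.empty(len(X4), dtype=np.float64)
        for lo in range(0, len(X4), batch_size):
            logits, _ = self.net_.forward(X4[lo:lo + batch_size], training=False)
            out[lo:lo + len(logits)] = logits
        return out

    # ------------------------------------------------------------------ #
    # inference
    # ------------------------------------------------------------------ #

    def decision_function(self, X) -> np.ndarray:
        """Pre-sigmoid logits, shape (n,)."""
        check_is_fitted(self, "net_")
        return self._forward_eval(self._as_input(X))

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    # ------------------------------------------------------------------ #
    # persistence
    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        """Single-file .npz archive: parameters + config + history."""
        check_is_fitted(self, "net_")
        arrays, meta = {}, []
        i = 0
        for layer in self.net_.layers:
            for pname, _ in layer.params():
                key = f"p{i:03d}"
                arrays[key] = getattr(layer, pname)
                meta.append([layer.name, pname, key])
                i += 1
        header = {
            "format_version": 1,
            "params": self.get_params(),
            "history": getattr(self, "history_", {}),
            "classes": [int(c) for c in getattr(self, "classes_", [0, 1])],
            "seed": self.random_state,
            "panel_order": list(getattr(self, "panel_order_",
                                        ())) or None,
            "param_meta": meta,
        }
        arrays["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "EnhancerClassifier":
        import zipfile
        try:
            with np.load(path, allow_pickle=False) as npz:
                header = json.loads(bytes(npz["header"]).decode())
                arrays = {k: npz[k] for k in npz.files if k != "header"}
        except (OSError, ValueError, KeyError, json.JSONDecodeError,
                zipfile.BadZipFile) as exc:
            raise ValueError(f"not a valid model archive: {path}: {exc}") from exc
        params = header["params"]
        for key in ("kernel_2d", "input_shape"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        est = cls(**params)
        rng = np.random.default_rng(est.random_state or 0)
        est.net_ = est._build(rng)
        by_name = {l.name: l for l in est.net_.layers}
        for lname, pname, key in header["param_meta"]:
            getattr(by_name[lname], pname)[...] = arrays[key]
        est.history_ = header.get("history", {})
        est.classes_ = np.asarray(header.get("classes", [0, 1]))
        est.n_parameters_ = est.net_.n_parameters()
        est.n_features_in_ = int(np.prod(est.input_shape))
        if header.get("panel_order"):
            est.panel_order_ = tuple(header["panel_order"])
        return est


# ---------------------------------------------------------------------- #
# thin functional wrappers
# ---------------------------------------------------------------------- #

def build_model(**config) -> EnhancerClassifier:
    """Construct an (unfitted) classifier from architecture config."""
    return EnhancerClassifier(**config)


def train(model: EnhancerClassifier, dataset, **fit_overrides):
    """Fit the classifier on a LabeledDataset; returns (model, history)."""
    if fit_overrides:
        model.set_params(**fit_overrides)
    model.panel_order_ = tuple(dataset.panel.assays)
    model.fit(dataset.X, dataset.y)
    return model, model.history_


def predict(model: EnhancerClassifier, matrix) -> float:
    """Probability that a single window matrix contains an enhancer."""
    data = matrix.data if isinstance(matrix, WindowMatrix) else np.asarray(matrix)
    return float(model.predict_proba(data[None] if data.ndim == 2 else data)[0, 1])


def save_model(model: EnhancerClassifier, path) -> None:
    model.save(path)


def load_model(path) -> EnhancerClassifier:
    return EnhancerClassifier.load(path)
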