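"""Gradient-weighted class activation mapping for the enhancer classifier.

For a convolutional layer with activation maps :math:`A^k` and the positive
class score :math:`y` (by default the pre-sigmoid logit), each filter gets a
scalar importance

    a_k = (1/Z) * sum_{i,j} dy / dA^k_{i,j}

(the global-average-pooled gradient, Z = number of spatial positions), and
the map is the rectified weighted sum

    L = ReLU( sum_k a_k * A^k )

linearly interpolated back to the 400-bin input resolution.  The map from
the last 1D convolutional layer is the *position-wise* score (importance of
each 10 bp bin); the map from the first convolutional layer, which still
spans all five assay rows, is the *feature-wise* score (assay x bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.utils.validation import check_is_fitted

from .model import EnhancerClassifier
from .signal_io import N_ASSAYS, N_BINS, WindowMatrix

__all__ = ["GradCamWeights", "GradCamMap", "channel_importance",
           "gradcam_map", "positionwise_scores", "featurewise_scores",
           "mean_featurewise"]


@dataclass
class GradCamWeights:
    """Per-filter importance scores a_k for the positive class."""

    values: np.ndarray        # (k,)
    n_positions: int          # Z, spatial positions averaged over
    layer: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite channel importances")


@dataclass
class GradCamMap:
    """Non-negative importance map at input resolution."""

    values: np.ndarray        # (5, 400) feature-wise or (400,) position-wise
    kind: str                 # 'feature-wise' | 'position-wise'
    layer: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("Grad-CAM maps are non-negative by construction")


def _as_batch(model: EnhancerClassifier, X) -> tuple[np.ndarray, bool]:
    if isinstance(X, WindowMatrix):
        X = X.data
    X = np.asarray(X)
    single = X.ndim == 2
    return model._as_input(X), single


def _check_conv_layer(model: EnhancerClassifier, layer: str) -> None:
    check_is_fitted(model, "net_")
    if layer not in model.conv_layer_names_:
        raise ValueError(
            f"{layer!r} is not a convolutional layer; choose from "
            f"{model.conv_layer_names_}")


def _acts_and_grads(model, X4, layer, post_sigmoid=False):
    """Activation maps and d(score)/d(activation) at `layer`, batched.

    Per-sample gradients are valid from one batched backward pass because no
    layer mixes samples.
    """
    logits, acts = model.net_.forward(X4, training=False, capture=(layer,))
    if post_sigmoid:
        p = 1.0 / (1.0 + np.exp(-logits))
        dlog = (p * (1.0 - p)).astype(X4.dtype)
    else:
        dlog = np.ones_like(logits, dtype=X4.dtype)
    grads = model.net_.backward(dlog, capture=(layer,))
    return acts[layer], grads[layer]


def channel_importance(model: EnhancerClassifier, matrix, layer: str,
                       post_sigmoid: bool = False) -> GradCamWeights:
    """Global-average-pooled gradient of the positive-class score per filter."""
    _check_conv_layer(model, layer)
    X4, single = _as_batch(model, matrix)
    A, G = _acts_and_grads(model, X4, layer, post_sigmoid)
    a = G.astype(np.float64).mean(axis=(2, 3))       # (n, k)
    z = int(A.shape[2] * A.shape[3])
    if single:
        return GradCamWeights(values=a[0], n_positions=z, layer=layer)
    return [GradCamWeights(values=row, n_positions=z, layer=layer) for row in a]


def _interp_width(maps: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Linearly interpolate (n, h, w) maps to width `n_bins`, aligning the
    centers of the (pooled) columns with the input bins they cover."""
    n, h, w = maps.shape
    if w == n_bins:
        return maps
    scale = n_bins / w
    src = (np.arange(w) + 0.5) * scale - 0.5
    tgt = np.arange(n_bins)
    flat = maps.reshape(n * h, w)
    out = np.empty((n * h, n_bins), dtype=np.float64)
    for i in range(n * h):
        out[i] = np.interp(tgt, src, flat[i])
    return out.reshape(n, h, n_bins)


def _raw_maps(model, X4, layer, post_sigmoid=False):
    """ReLU(sum_k a_k A_k) per sample at native layer resolution: (n, h, w)."""
    A, G = _acts_and_grads(model, X4, layer, post_sigmoid)
    a = G.astype(np.float64).mean(axis=(2, 3))               # (n, k)
    m = np.einsum("nk,nkhw->nhw", a, A.astype(np.float64))
    return np.maximum(m, 0.0)


def gradcam_map(model: EnhancerClassifier, matrix, layer: str,
                post_sigmoid: bool = False) -> GradCamMap:
    """Grad-CAM map for one window at the given conv layer, interpolated to
    input resolution (400 bins wide)."""
    _check_conv_layer(model, layer)
    X4, single = _as_batch(model, matrix)
    maps = _interp_width(_raw_maps(model, X4, layer, post_sigmoid))
    kind = "feature-wise" if maps.shape[1] == N_ASSAYS else "position-wise"
    vals = maps if maps.shape[1] > 1 else maps[:, 0, :]
    if single:
        return GradCamMap(values=vals[0], kind=kind, layer=layer)
    return [GradCamMap(values=v, kind=kind, layer=layer) for v in vals]


def positionwise_scores(model: EnhancerClassifier, X,
                        layer: str | None = None,
                        post_sigmoid: bool = False,
                        batch_size: int = 128) -> np.ndarray:
    """Length-400 importance per 10 bp bin, from the last 1D conv layer.

    Accepts a single window (WindowMatrix or (5, 400) array) or a batch
    (n, 5, 400); returns (400,) or (n, 400) accordingly.
    """
    layer = layer or model.conv_layer_names_[-1]
    _check_conv_layer(model, layer)
    X4, single = _as_batch(model, X)
    out = np.empty((len(X4), N_BINS), dtype=np.float64)
    for lo in range(0, len(X4), batch_size):
        maps = _raw_maps(model, X4[lo:lo + batch_size], layer, post_sigmoid)
        if maps.shape[1] != 1:
            raise ValueError(
                f"layer {layer!r} is not 1D over the genomic axis "
                f"(height {maps.shape[1]}); use featurewise_scores")
        out[lo:lo + len(maps)] = _interp_width(maps)[:, 0, :]
    return out[0] if single else out


def featurewise_scores(model: EnhancerClassifier, X,
                       layer: str = "conv1",
                       post_sigmoid: bool = False,
                       batch_size: int = 128) -> np.ndarray:
    """5 x 400 importance map (assay x bin) from an early conv layer."""
    _check_conv_layer(model, layer)
    X4, single = _as_batch(model, X)
    out = np.empty((len(X4), N_ASSAYS, N_BINS), dtype=np.float64)
    for lo in range(0, len(X4), batch_size):
        maps = _raw_maps(model, X4[lo:lo + batch_size], layer, post_sigmoid)
        if maps.shape[1] != N_ASSAYS:
            raise ValueError(
                f"layer {layer!r} does not retain the {N_ASSAYS} assay rows "
                f"(height {maps.shape[1]}); use positionwise_scores")
        out[lo:lo + len(maps)] = _interp_width(maps)
    return out[0] if single else out


def save_featurewise_maps(path, windows, maps) -> None:
    """Archive feature-wise maps keyed by window coordinate.

    `windows` are GenomicIntervals and `maps` the matching (n, 5, 400)
    scores; stored as an .npz with keys 'chrom:start-end'.
    """
    maps = np.asarray(maps)
    if len(windows) != len(maps):
        raise ValueError("windows/maps length mismatch")
    arrays = {f"{w.chrom}:{w.start}-{w.end}": maps[i].astype(np.float32)
              for i, w in enumerate(windows)}
    np.savez_compressed(path, **arrays)


def mean_featurewise(model: EnhancerClassifier, X, layer: str = "conv1",
                     batch_size: int = 128) -> np.ndarray:
    """Per-assay mean feature-wise map across many windows: (5, 400).

    Aggregates the feature-wise Grad-CAM maps of (typically positive)
    windows row-wise, the way per-assay importance profiles are summarised.
    """
    maps = featurewise_scores(model, X, layer=layer, batch_size=batch_size)
    if maps.ndim == 2:
        return maps
    return maps.mean(axis=0)
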