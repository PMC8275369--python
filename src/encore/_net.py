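"""Minimal feed-forward CNN engine on numpy.

Implements exactly the layer set the enhancer classifier needs — 2D/1D
convolution (stride 1, GEMM via im2col), width-wise max-pooling,
squeeze-and-excitation channel gates, dense layers, inverted dropout — with
hand-written backward passes.  Gradients are exact (verified against central
finite differences in the test suite), which is what the Grad-CAM stage
relies on: it needs d(logit)/d(activation) at arbitrary convolutional layers,
not just parameter gradients.

Arrays are NCHW: (batch, channels, height=assays, width=genomic bins).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "InputConvPool",
    "ReLU",
    "Sigmoid",
    "MaxPoolW",
    "SEBlock",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "bce_with_logits",
]


def _same_pad(k: int) -> tuple[int, int]:
    # TF-style 'same' padding for stride 1: total k-1, extra goes to the right
    return (k - 1) // 2, k // 2


class Layer:
    """Base layer: stateless API, caches live on the instance."""

    name: str = ""

    def params(self):
        """List of (param_array_attr, grad_attr) names."""
        return []

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 cross-correlation, per-axis 'same' or 'valid' padding.

    1D convolutions over the genomic axis are the special case kh == 1.
    Weights are stored as (in_ch*kh*kw, out_ch) so forward/backward are
    single GEMMs on im2col matrices.
    """

    def __init__(self, in_ch, out_ch, kh, kw, pad_h="same", pad_w="same",
                 dtype=np.float32, rng=None, name="", input_layer=False):
        if kh <= 0 or kw <= 0:
            raise ValueError("kernel dims must be positive")
        self.in_ch, self.out_ch, self.kh, self.kw = in_ch, out_ch, kh, kw
        self.pad_h = _same_pad(kh) if pad_h == "same" else (0, 0)
        self.pad_w = _same_pad(kw) if pad_w == "same" else (0, 0)
        self.name = name
        # the stack's first layer never needs d(loss)/d(input)
        self.input_layer = input_layer
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_ch * kh * kw))
        self.W = rng.normal(0.0, scale, (in_ch * kh * kw, out_ch)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)

    def params(self):
        return [("W", "dW"), ("b", "db")]

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} channels, got {c}")
        (pt, pb), (pl, pr) = self.pad_h, self.pad_w
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if pt + pb + pl + pr else x
        ho = xp.shape[2] - self.kh + 1
        wo = xp.shape[3] - self.kw + 1
        if ho <= 0 or wo <= 0:
            raise ValueError(f"{self.name}: input {h}x{w} too small for kernel "
                             f"{self.kh}x{self.kw}")
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        # (n, c, ho, wo, kh, kw) -> (n*ho*wo, c*kh*kw)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * ho * wo, c * self.kh * self.kw)
        out = cols @ self.W + self.b
        self._cache = (x.shape, xp.shape, cols)
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dout):
        (xshape, xpshape, cols) = self._cache
        n, k, ho, wo = dout.shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, k)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        if self.input_layer:
            return None
        c, kh, kw = self.in_ch, self.kh, self.kw
        (pt, _), (pl, _) = self.pad_h, self.pad_w
        h, w = xshape[2], xshape[3]
        if ho == 1:
            # height-1 output (the post-collapse 1D stage and the collapse
            # layer itself): grad wrt input is a width-only full correlation
            # with the flipped kernel — a single GEMM
            wp = xpshape[3]
            dpadw = np.pad(dout, ((0, 0), (0, 0), (0, 0), (kw - 1, kw - 1)))
            colsd = sliding_window_view(dpadw, kw, axis=3)
            colsd = np.ascontiguousarray(
                colsd.transpose(0, 2, 3, 1, 4)).reshape(n * wp, k * kw)
            wf = self.W.reshape(c, kh, kw, k)[:, :, ::-1, :]
            wf = np.ascontiguousarray(wf.transpose(3, 2, 0, 1)).reshape(
                k * kw, c * kh)
            dxp = (colsd @ wf).reshape(n, wp, c, kh).transpose(0, 2, 3, 1)
            return np.ascontiguousarray(dxp[:, :, pt:pt + h, pl:pl + w])
        # general case: scatter each kernel offset's contribution (col2im)
        dcols = (dflat @ self.W.T).reshape(n, ho, wo, c, kh, kw)
        dcols = np.ascontiguousarray(dcols.transpose(0, 3, 4, 5, 1, 2))
        dxp = np.zeros((n, c) + xpshape[2:], dtype=dout.dtype)
        for p in range(kh):
            for q in range(kw):
                dxp[:, :, p:p + ho, q:q + wo] += dcols[:, :, p, q]
        return np.ascontiguousarray(dxp[:, :, pt:pt + h, pl:pl + w])


class InputConvPool(Layer):
    """Fused first layer: full-height 2D convolution + width max-pool.

    Specialisation of Conv2D for the network input: single input channel,
    kernel height equal to the matrix height (the five assay rows), 'same'
    padding on both axes, followed by width max-pooling.  Because the kernel
    spans the full height, each output row r is one GEMM of a shared
    width-im2col against a row-shifted (zero-padded) copy of the kernel —
    about 5x less data movement than the generic im2col.  Max-pooling before
    the (elementwise, monotone) ReLU that follows is exact.

    Weights use the same canonical (kh*kw, out_ch) layout as Conv2D.
    """

    def __init__(self, out_ch, kh, kw, pool, dtype=np.float32, rng=None,
                 name=""):
        self.out_ch, self.kh, self.kw, self.pool = out_ch, kh, kw, pool
        self.pad_w = _same_pad(kw)
        self.pt = (kh - 1) // 2
        self.name = name
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (kh * kw))
        self.W = rng.normal(0.0, scale, (kh * kw, out_ch)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)

    def params(self):
        return [("W", "dW"), ("b", "db")]

    def _row_kernels(self):
        """(kh, kh*kw, out_ch) stack: row r sees input rows shifted by r."""
        kh, kw = self.kh, self.kw
        w3 = self.W.reshape(kh, kw, self.out_ch)
        wr = np.zeros((kh, kh * kw, self.out_ch), dtype=self.W.dtype)
        for r in range(kh):
            for p in range(kh):
                h = r + p - self.pt
                if 0 <= h < kh:
                    wr[r, h * kw:(h + 1) * kw] = w3[p]
        return wr

    def forward(self, x, training=False, rng=None):
        n, c, hh, wd = x.shape
        if c != 1 or hh != self.kh:
            raise ValueError(
                f"{self.name}: expects (n, 1, {self.kh}, w) input, got {x.shape}")
        if wd % self.pool:
            raise ValueError(f"{self.name}: width {wd} not divisible by pool")
        pl, pr = self.pad_w
        xp = np.pad(x[:, 0], ((0, 0), (0, 0), (pl, pr)))
        cols = sliding_window_view(xp, self.kw, axis=2)       # (n, kh, wd, kw)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3))
        cols = cols.reshape(n * wd, self.kh * self.kw)
        wr = self._row_kernels()
        wq = wd // self.pool
        out = np.empty((n, self.out_ch, self.kh, wq), dtype=x.dtype)
        args = []
        for r in range(self.kh):
            res = (cols @ wr[r] + self.b).reshape(n, wq, self.pool,
                                                  self.out_ch)
            arg = res.argmax(axis=2)                          # (n, wq, k)
            pooled = np.take_along_axis(res, arg[:, :, None, :], axis=2)
            out[:, :, r, :] = pooled[:, :, 0, :].transpose(0, 2, 1)
            args.append(arg)
        self._cache = (cols, args, n, wd)
        return out

    def backward(self, dout):
        cols, args, n, wd = self._cache
        kh, kw, k = self.kh, self.kw, self.out_ch
        wq = wd // self.pool
        self.db = dout.sum(axis=(0, 2, 3))
        dW = np.zeros_like(self.W)
        for r in range(kh):
            dp = np.ascontiguousarray(dout[:, :, r, :].transpose(0, 2, 1))
            dres = np.zeros((n, wq, self.pool, k), dtype=dout.dtype)
            np.put_along_axis(dres, args[r][:, :, None, :],
                              dp[:, :, None, :], axis=2)
            dwr = cols.T @ dres.reshape(n * wd, k)            # (kh*kw, k)
            for p in range(kh):
                h = r + p - self.pt
                if 0 <= h < kh:
                    dW[p * kw:(p + 1) * kw] += dwr[h * kw:(h + 1) * kw]
        self.dW = dW
        return None  # input layer


class ReLU(Layer):
    def __init__(self, name=""):
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def __init__(self, name=""):
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._y = _sigmoid(x)
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MaxPoolW(Layer):
    """Max-pooling along the width (genomic) axis with window w.

    Output width is input_width // w; the input width must be divisible,
    matching the (i/w)x(j/h) pooled-dimension contract.
    """

    def __init__(self, w, name=""):
        if w < 1:
            raise ValueError("pool width must be >= 1")
        self.w = w
        self.name = name

    def forward(self, x, training=False, rng=None):
        n, c, h, wd = x.shape
        if wd % self.w:
            raise ValueError(f"{self.name}: width {wd} not divisible by pool {self.w}")
        xr = x.reshape(n, c, h, wd // self.w, self.w)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, wd = self._shape
        dxr = np.zeros((n, c, h, wd // self.w, self.w), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h, wd)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Global-average-pools each channel, passes the channel descriptor through
    a two-layer bottleneck (reduction r) and rescales the input by the
    resulting sigmoid gate: out = x * g(x).  Acts as a learned gate on how
    much of each feature map is passed to the next convolution.
    """

    def __init__(self, channels, reduction=4, dtype=np.float32, rng=None, name=""):
        self.channels = channels
        hidden = max(1, channels // reduction)
        rng = rng or np.random.default_rng()
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / hidden)
        self.W1 = rng.normal(0.0, s1, (channels, hidden)).astype(dtype)
        self.b1 = np.zeros(hidden, dtype=dtype)
        self.W2 = rng.normal(0.0, s2, (hidden, channels)).astype(dtype)
        self.b2 = np.zeros(channels, dtype=dtype)
        self.name = name

    def params(self):
        return [("W1", "dW1"), ("b1", "db1"), ("W2", "dW2"), ("b2", "db2")]

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        s = x.mean(axis=(2, 3))                      # (n, c)
        z = s @ self.W1 + self.b1
        zr = np.maximum(z, 0.0)
        g = _sigmoid(zr @ self.W2 + self.b2)         # (n, c)
        self._cache = (x, s, z, zr, g)
        return x * g[:, :, None, None]

    def backward(self, dout):
        x, s, z, zr, g = self._cache
        n, c, h, w = x.shape
        dx = dout * g[:, :, None, None]
        dg = (dout * x).sum(axis=(2, 3))
        dpre2 = dg * g * (1.0 - g)
        self.dW2 = zr.T @ dpre2
        self.db2 = dpre2.sum(axis=0)
        dzr = dpre2 @ self.W2.T
        dz = dzr * (z > 0)
        self.dW1 = s.T @ dz
        self.db1 = dz.sum(axis=0)
        ds = dz @ self.W1.T
        dx += (ds / (h * w))[:, :, None, None]
        return dx


class Flatten(Layer):
    def __init__(self, name=""):
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, dtype=np.float32, rng=None, name=""):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.name = name

    def params(self):
        return [("W", "dW"), ("b", "db")]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate, name=""):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Network:
    """Ordered layer stack ending in a single pre-sigmoid logit."""

    def __init__(self, layers):
        self.layers = list(layers)
        self._by_name = {l.name: i for i, l in enumerate(self.layers) if l.name}

    def layer_index(self, name):
        if name not in self._by_name:
            raise KeyError(f"no layer named {name!r}; have {sorted(self._by_name)}")
        return self._by_name[name]

    def forward(self, x, training=False, rng=None, capture=()):
        """Run the stack; returns (logits, {name: activation})."""
        acts = {}
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
            if layer.name in capture:
                acts[layer.name] = out
        return out.reshape(out.shape[0]), acts

    def backward(self, dlogits, capture=()):
        """Backprop from d(loss)/d(logit); returns {name: grad wrt activation}.

        Parameter gradients are left on the layers for the optimizer.
        """
        grads = {}
        d = np.asarray(dlogits).reshape(-1, 1)
        for layer in reversed(self.layers):
            if layer.name in capture:
                grads[layer.name] = d
            d = layer.backward(d)
            if d is None:  # reached an input layer; nothing upstream needs grads
                break
        return grads

    def forward_from(self, name, activation):
        """Re-run the tail of the network with an injected activation.

        The stack is evaluated starting right after layer `name`, taking
        `activation` as that layer's output.  Used by finite-difference
        oracles that perturb intermediate feature maps.
        """
        i = self.layer_index(name)
        out = activation
        for layer in self.layers[i + 1:]:
            out = layer.forward(out, training=False)
        return out.reshape(out.shape[0])

    def param_state(self):
        """Flat copy of all parameters (for checkpoint/restore)."""
        state = []
        for layer in self.layers:
            for pname, _ in layer.params():
                state.append(getattr(layer, pname).copy())
        return state

    def set_param_state(self, state):
        it = iter(state)
        for layer in self.layers:
            for pname, _ in layer.params():
                arr = next(it)
                getattr(layer, pname)[...] = arr

    def n_parameters(self):
        return int(sum(getattr(l, p).size for l in self.layers for p, _ in l.params()))


class Adam:
    """Adam with bias correction, applied in registration order."""

    def __init__(self, network, lr=5e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = []
        for layer in network.layers:
            for pname, gname in layer.params():
                p = getattr(layer, pname)
                self.slots.append((layer, pname, gname,
                                   np.zeros_like(p), np.zeros_like(p)))

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        for layer, pname, gname, m, v in self.slots:
            g = getattr(layer, gname)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            getattr(layer, pname)[...] -= lr_t * m / (np.sqrt(v) + self.eps)


def bce_with_logits(logits, y, sample_weight=None):
    """Numerically stable binary cross-entropy on pre-sigmoid logits.

    Returns (mean loss, d loss / d logits).  With sample weights the mean is
    a weighted arithmetic mean with the weights as given (not renormalized),
    matching the usual class_weight semantics.
    """
    z = logits.astype(np.float64)
    y = y.astype(np.float64)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = _sigmoid(z)
    grad = p - y
    n = z.shape[0]
    if sample_weight is not None:
        w = sample_weight.astype(np.float64)
        return float((w * per).mean()), (w * grad / n).astype(logits.dtype)
    return float(per.mean()), (grad / n).astype(logits.dtype)
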