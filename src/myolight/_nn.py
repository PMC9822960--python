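"""Compact CPU neural-network backend (NumPy, NHWC layout).

Implements exactly the layer set the decoders need — 2-D convolution,
batch normalization, dropout, max-pooling, dense layers, layer
normalization, multi-head self-attention and learned patch/position
embeddings — with hand-derived backward passes, Adam, and a seeded
mini-batch training loop with early stopping on the training loss.
Every backward pass is verified against finite differences in the test
suite.  All randomness (init, shuffling, dropout) comes from a single
`numpy.random.Generator`, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ContractError


class Layer:
    """Base layer: ``forward(x, train)`` then ``backward(gy)`` -> gx."""

    def params(self):
        """Yield (name, param, grad) triples; grads are same-shape arrays."""
        p = getattr(self, "p", {})
        g = getattr(self, "g", {})
        for k in p:
            yield k, p, g

    def forward(self, x, train):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in, d_out, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / d_in)
        self.p = {
            "W": (rng.standard_normal((d_in, d_out)) * scale).astype(dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}

    def forward(self, x, train):
        self._shape = x.shape
        self._x2 = x.reshape(-1, x.shape[-1])
        y = self._x2 @ self.p["W"] + self.p["b"]
        return y.reshape(*x.shape[:-1], -1)

    def backward(self, gy):
        gy2 = gy.reshape(-1, gy.shape[-1])
        self.g["W"] += self._x2.T @ gy2
        self.g["b"] += gy2.sum(axis=0)
        gx = gy2 @ self.p["W"].T
        return gx.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class GELU(Layer):
    """Gaussian error linear unit (tanh approximation)."""

    _C = 0.7978845608028654  # sqrt(2/pi)

    def forward(self, x, train):
        self._x = x
        inner = self._C * (x + 0.044715 * x**3)
        self._t = np.tanh(inner)
        return 0.5 * x * (1.0 + self._t)

    def backward(self, gy):
        x, t = self._x, self._t
        dinner = self._C * (1.0 + 3 * 0.044715 * x**2)
        dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
        return gy * dy


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate, rng):
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, NHWC."""

    def __init__(self, c_in, c_out, ksize, rng, dtype=np.float32):
        self.k = int(ksize)
        fan_in = self.k * self.k * c_in
        self.c_in, self.c_out = c_in, c_out
        self.p = {
            "W": (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
                  ).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}

    def forward(self, x, train):
        n, h, w, c = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # [N,H,W,C,k,k]
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        self._cols2 = cols.reshape(n * h * w, k * k * c)
        self._xshape = x.shape
        y = self._cols2 @ self.p["W"] + self.p["b"]
        return y.reshape(n, h, w, self.c_out)

    def backward(self, gy):
        n, h, w, c = self._xshape
        k = self.k
        pad = k // 2
        gy2 = gy.reshape(-1, self.c_out)
        self.g["W"] += self._cols2.T @ gy2
        self.g["b"] += gy2.sum(axis=0)
        gcols = (gy2 @ self.p["W"].T).reshape(n, h, w, k, k, c)
        gxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + h, j : j + w, :] += gcols[:, :, :, i, j, :]
        return gxp[:, pad : pad + h, pad : pad + w, :]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    full pool cell are dropped (floor semantics)."""

    def __init__(self, pool_h=2, pool_w=2):
        self.ph, self.pw = int(pool_h), int(pool_w)

    def forward(self, x, train):
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        if ho < 1 or wo < 1:
            raise ContractError(
                f"input {h}x{w} too small for {ph}x{pw} pooling"
            )
        self._xshape = x.shape
        xc = x[:, : ho * ph, : wo * pw, :]
        xr = xc.reshape(n, ho, ph, wo, pw, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, ho, wo, c, ph * pw)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, gy):
        n, h, w, c = self._xshape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        flat = np.zeros((n, ho, wo, c, ph * pw), dtype=gy.dtype)
        np.put_along_axis(flat, self._arg[..., None], gy[..., None], axis=-1)
        gx = np.zeros((n, h, w, c), dtype=gy.dtype)
        gcrop = flat.reshape(n, ho, wo, c, ph, pw).transpose(0, 1, 4, 2, 5, 3)
        gx[:, : ho * ph, : wo * pw, :] = gcrop.reshape(n, ho * ph, wo * pw, c)
        return gx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (works for NHWC and NC)."""

    def __init__(self, channels, dtype=np.float32, momentum=0.9, eps=1e-5):
        self.p = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}
        self.run_mean = np.zeros(channels, dtype=dtype)
        self.run_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def start_calibration(self):
        c = self.run_mean.shape[0]
        self._cal_n = 0.0
        self._cal_s1 = np.zeros(c)
        self._cal_s2 = np.zeros(c)

    def calibrate(self, x):
        """Accumulate exact activation statistics (used after training with
        dropout disabled, where the train-time running averages are biased
        by the dropout-inflated variance)."""
        axes = tuple(range(x.ndim - 1))
        m = x.size // x.shape[-1]
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        self._cal_n += m
        self._cal_s1 += m * mu
        self._cal_s2 += m * (var + mu**2)
        xhat = (x - mu) / np.sqrt(var + self.eps)
        return self.p["gamma"] * xhat + self.p["beta"]

    def end_calibration(self):
        if self._cal_n > 0:
            mean = self._cal_s1 / self._cal_n
            self.run_mean = mean.astype(self.run_mean.dtype)
            self.run_var = (self._cal_s2 / self._cal_n - mean**2).astype(
                self.run_var.dtype)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu).astype(self.run_mean.dtype)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(self.run_var.dtype)
            self._m = x.size // x.shape[-1]
            self._inv = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._inv
            self._train = True
            return self.p["gamma"] * self._xhat + self.p["beta"]
        self._train = False
        xhat = (x - self.run_mean) / np.sqrt(self.run_var + self.eps)
        self._xhat_eval = xhat
        return self.p["gamma"] * xhat + self.p["beta"]

    def backward(self, gy):
        axes = tuple(range(gy.ndim - 1))
        if not self._train:
            self.g["gamma"] += (gy * self._xhat_eval).sum(axis=axes)
            self.g["beta"] += gy.sum(axis=axes)
            return gy * self.p["gamma"] / np.sqrt(self.run_var + self.eps)
        xhat, inv, m = self._xhat, self._inv, self._m
        self.g["gamma"] += (gy * xhat).sum(axis=axes)
        self.g["beta"] += gy.sum(axis=axes)
        gxhat = gy * self.p["gamma"]
        gx = (inv / m) * (
            m * gxhat
            - gxhat.sum(axis=axes)
            - xhat * (gxhat * xhat).sum(axis=axes)
        )
        return gx.astype(gy.dtype)


class LayerNorm(Layer):
    """Normalization over the last axis with learned affine parameters."""

    def __init__(self, dim, dtype=np.float32, eps=1e-5):
        self.p = {
            "gamma": np.ones(dim, dtype=dtype),
            "beta": np.zeros(dim, dtype=dtype),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}
        self.eps = eps
        self.dim = dim

    def forward(self, x, train):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.p["gamma"] * self._xhat + self.p["beta"]

    def backward(self, gy):
        xhat, inv, d = self._xhat, self._inv, self.dim
        axes = tuple(range(gy.ndim - 1))
        self.g["gamma"] += (gy * xhat).sum(axis=axes)
        self.g["beta"] += gy.sum(axis=axes)
        gxhat = gy * self.p["gamma"]
        gx = (inv / d) * (
            d * gxhat
            - gxhat.sum(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
        )
        return gx.astype(gy.dtype)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention over token sequences [N, T, D]."""

    def __init__(self, dim, n_heads, rng, dtype=np.float32):
        if dim % n_heads:
            raise ContractError("embed dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.dh = dim // n_heads
        self.qkv = Dense(dim, 3 * dim, rng, dtype)
        self.proj = Dense(dim, dim, rng, dtype)

    def params(self):
        yield from self.qkv.params()
        yield from self.proj.params()

    def _split(self, z):
        n, t, _ = z.shape
        return z.reshape(n, t, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x, train):
        n, t, d = x.shape
        qkv = self.qkv.forward(x, train)
        q, k, v = (self._split(z) for z in np.split(qkv, 3, axis=-1))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = attn @ v  # [N, h, T, dh]
        self._cache = (q, k, v, attn)
        merged = ctx.transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj.forward(merged, train)

    def backward(self, gy):
        q, k, v, attn = self._cache
        n, h, t, dh = q.shape
        gmerged = self.proj.backward(gy)
        gctx = gmerged.reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        gattn = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn.transpose(0, 1, 3, 2) @ gctx
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores /= np.sqrt(dh)
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        merge = lambda z: z.transpose(0, 2, 1, 3).reshape(n, t, h * dh)
        gqkv = np.concatenate([merge(gq), merge(gk), merge(gv)], axis=-1)
        return self.qkv.backward(gqkv)


class MLP(Layer):
    def __init__(self, dim, hidden, rng, dtype=np.float32):
        self.fc1 = Dense(dim, hidden, rng, dtype)
        self.act = GELU()
        self.fc2 = Dense(hidden, dim, rng, dtype)

    def params(self):
        yield from self.fc1.params()
        yield from self.fc2.params()

    def forward(self, x, train):
        return self.fc2.forward(
            self.act.forward(self.fc1.forward(x, train), train), train
        )

    def backward(self, gy):
        return self.fc1.backward(self.act.backward(self.fc2.backward(gy)))


class TransformerBlock(Layer):
    """Pre-norm encoder block: x + MHA(LN(x)); then x + MLP(LN(x))."""

    def __init__(self, dim, n_heads, mlp_dim, rng, dtype=np.float32):
        self.n_heads = n_heads
        self.ln1 = LayerNorm(dim, dtype)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, dtype)
        self.ln2 = LayerNorm(dim, dtype)
        self.mlp = MLP(dim, mlp_dim, rng, dtype)

    def params(self):
        for sub in (self.ln1, self.attn, self.ln2, self.mlp):
            yield from sub.params()

    def forward(self, x, train):
        h = x + self.attn.forward(self.ln1.forward(x, train), train)
        return h + self.mlp.forward(self.ln2.forward(h, train), train)

    def backward(self, gy):
        gh = gy + self.ln2.backward(self.mlp.backward(gy))
        return gh + self.ln1.backward(self.attn.backward(gh))


class PatchEmbed(Layer):
    """p x p patch extraction + linear projection + learned position embedding.

    Input [N, H, W, C] is cropped to multiples of the patch size, flattened
    patch-wise, projected to the embed dimension, and offset by a learned
    per-token position embedding.
    """

    def __init__(self, in_shape, patch, embed_dim, rng, dtype=np.float32):
        h, w, c = in_shape
        self.th, self.tw = h // patch, w // patch
        if self.th < 1 or self.tw < 1:
            raise ContractError(
                f"input {h}x{w} too small for {patch}x{patch} patches"
            )
        self.patch = patch
        self.n_tokens = self.th * self.tw
        self.proj = Dense(patch * patch * c, embed_dim, rng, dtype)
        self.p = {"pos": (0.02 * rng.standard_normal(
            (1, self.n_tokens, embed_dim))).astype(dtype)}
        self.g = {"pos": np.zeros_like(self.p["pos"])}

    def params(self):
        yield from self.proj.params()
        yield from Layer.params(self)

    def forward(self, x, train):
        n, h, w, c = x.shape
        p = self.patch
        self._xshape = x.shape
        xc = x[:, : self.th * p, : self.tw * p, :]
        xr = xc.reshape(n, self.th, p, self.tw, p, c).transpose(0, 1, 3, 2, 4, 5)
        tokens = xr.reshape(n, self.n_tokens, p * p * c)
        return self.proj.forward(tokens, train) + self.p["pos"]

    def backward(self, gy):
        n, h, w, c = self._xshape
        p = self.patch
        self.g["pos"] += gy.sum(axis=0, keepdims=True)
        gtok = self.proj.backward(gy)
        gr = gtok.reshape(n, self.th, self.tw, p, p, c).transpose(0, 1, 3, 2, 4, 5)
        gx = np.zeros((n, h, w, c), dtype=gy.dtype)
        gx[:, : self.th * p, : self.tw * p, :] = gr.reshape(
            n, self.th * p, self.tw * p, c
        )
        return gx


class MeanPoolTokens(Layer):
    """Mean over the token axis: [N, T, D] -> [N, D]."""

    def forward(self, x, train):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy):
        return np.repeat(gy[:, None, :], self._t, axis=1) / self._t


# ---------------------------------------------------------------------------
# losses, optimizer, training loop


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_ce(logits, y):
    """Mean sparse cross-entropy; returns (loss, grad wrt logits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-300))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


def mse(pred, y):
    """Mean squared error over a single-output head; returns (loss, grad)."""
    d = pred[:, 0] - y
    loss = float(np.mean(d * d))
    grad = np.zeros_like(pred)
    grad[:, 0] = 2.0 * d / d.shape[0]
    return loss, grad


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, layers):
        self.t += 1
        b1, b2 = self.b1, self.b2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for layer in layers:
            for key, p, g in layer.params():
                m, v = self.slots.setdefault(
                    (id(p), key),
                    (np.zeros_like(p[key]), np.zeros_like(p[key])),
                )
                grad = g[key]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                p[key] -= lr_t * m / (np.sqrt(v) + self.eps)
                g[key][...] = 0.0


class Network:
    """A feed-forward stack trained with Adam and mini-batches.

    ``loss`` is ``"ce"`` (sparse softmax cross-entropy, integer targets) or
    ``"mse"`` (single linear output, float targets).
    """

    def __init__(self, layers, loss: str, rng: np.random.Generator,
                 dtype=np.float32):
        self.layers = list(layers)
        self.loss_name = loss
        self.rng = rng
        self.dtype = dtype

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def fit(self, x, y, epochs=50, batch_size=64, lr=1e-3, patience=10,
            min_delta=1e-4):
        """Mini-batch training; stops early when the epoch training loss has
        not improved by ``min_delta`` for ``patience`` epochs.  The
        final-epoch weights are kept (no best-of-run rollback)."""
        x = np.asarray(x, dtype=self.dtype)
        loss_fn = softmax_ce if self.loss_name == "ce" else mse
        y = np.asarray(y, dtype=np.int64 if self.loss_name == "ce" else self.dtype)
        opt = Adam(lr=lr)
        n = x.shape[0]
        history: list[float] = []
        best = np.inf
        stall = 0
        for _ in range(epochs):
            order = self.rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                out = self.forward(x[idx], train=True)
                loss, gy = loss_fn(out, y[idx])
                self.backward(gy)
                opt.step(self.layers)
                total += loss * idx.size
            epoch_loss = total / n
            history.append(epoch_loss)
            if epoch_loss < best - min_delta:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        self._recalibrate_batchnorm(x, batch_size)
        return history

    def _recalibrate_batchnorm(self, x, batch_size, max_batches=16):
        """Replace BN running statistics with exact post-training activation
        statistics, computed with dropout off (inference conditions)."""
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        if not bns:
            return
        for bn in bns:
            bn.start_calibration()
        n = x.shape[0]
        starts = range(0, n, batch_size)
        if len(starts) > max_batches:
            starts = [int(s) for s in
                      np.linspace(0, n - batch_size, max_batches)]
        for s in starts:
            h = x[s : s + batch_size]
            for layer in self.layers:
                if isinstance(layer, BatchNorm):
                    h = layer.calibrate(h)
                else:
                    h = layer.forward(h, train=False)
        for bn in bns:
            bn.end_calibration()

    def predict(self, x, batch_size=512):
        x = np.asarray(x, dtype=self.dtype)
        if x.shape[0] == 0:
            probe = self.forward(x[:0], train=False)
            return probe
        outs = [
            self.forward(x[s : s + batch_size], train=False)
            for s in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)
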