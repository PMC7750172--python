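"""Minimal CNN training core (numpy + BLAS).

Implements exactly the layers the artefact-correction U-Net needs —
3x3 same-padding convolution, 2x2 transposed convolution, batch
normalization, ReLU, 2x2 max pooling, inverted dropout — each with a
hand-written backward pass, plus the Adam optimizer.  Convolutions are
lowered to matrix multiplication with an im2col gather so that all heavy
arithmetic runs in single-precision BLAS.

Internally tensors are laid out channels-last, (N, H, W, C): patch
gathering then copies contiguous channel runs and GEMM results land in
their final memory order, which is what makes a pure-numpy training loop
viable.  The public ``UNet.forward`` accepts (H, W), (N, H, W) or
(N, 1, H, W) arrays.  Every layer caches what its backward pass needs
during forward; ``params()`` exposes Param objects consumed by Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ConvTranspose2x2", "BatchNorm2d", "ReLU",
           "MaxPool2x2", "Dropout", "Adam", "UNet"]

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix for stride-1 same conv."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, h, w, k, k, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3]))
    return view.reshape(n * h * w, k * k * c)


class Conv2d:
    """3x3 (or 1x1) stride-1 convolution with same padding and bias.

    Weights are stored (k, k, c_in, c_out) to match the im2col column
    ordering.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.k, self.pad = k, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def forward(self, x, training=False):
        n, h, w, _ = x.shape
        if self.k == 1:
            self._cols = x.reshape(-1, self.c_in)
        else:
            self._cols = _im2col(x, self.k, self.pad)
        out = self._cols @ self.W.value.reshape(-1, self.c_out) + self.b.value
        return out.reshape(n, h, w, self.c_out)

    def backward(self, g):
        n, h, w, _ = g.shape
        gm = g.reshape(-1, self.c_out)
        self.W.grad += (self._cols.T @ gm).reshape(self.W.value.shape)
        self.b.grad += gm.sum(axis=0)
        self._cols = None
        if self.k == 1:
            gx = gm @ self.W.value.reshape(self.c_in, self.c_out).T
            return gx.reshape(n, h, w, self.c_in)
        # input gradient of a same-padded correlation = correlation of g
        # with the kernel rotated 180 deg and its channel axes swapped
        w_rot = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)
        gcols = _im2col(g, self.k, self.pad)
        gx = gcols @ w_rot.reshape(-1, self.c_in)
        return gx.reshape(n, h, w, self.c_in)

    def params(self):
        return [self.W, self.b]


class ConvTranspose2x2:
    """2x2 stride-2 transposed convolution (non-overlapping upsampling).

    Weights are (c_in, 2, 2, c_out): each input pixel paints one 2x2
    output block.
    """

    def __init__(self, c_in: int, c_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, 2, 2, c_out)))
        self.b = Param(np.zeros(c_out))

    def forward(self, x, training=False):
        self._x = x
        n, h, w, ci = x.shape
        out = x.reshape(-1, ci) @ self.W.value.reshape(ci, -1)  # (NHW, 4co)
        out = out.reshape(n, h, w, 2, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(out).reshape(n, 2 * h, 2 * w, self.c_out) + \
            self.b.value

    def backward(self, g):
        n, H, W_, co = g.shape
        h, w = H // 2, W_ // 2
        gg = g.reshape(n, h, 2, w, 2, co).transpose(0, 1, 3, 2, 4, 5)
        gg = np.ascontiguousarray(gg).reshape(-1, 4 * co)
        xm = self._x.reshape(-1, self.c_in)
        self.W.grad += (xm.T @ gg).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=(0, 1, 2))
        gx = gg @ self.W.value.reshape(self.c_in, -1).T
        self._x = None
        return gx.reshape(n, h, w, self.c_in)

    def params(self):
        return [self.W, self.b]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv = xhat, inv
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        m = g.shape[0] * g.shape[1] * g.shape[2]
        self.gamma.grad += (g * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += g.sum(axis=(0, 1, 2))
        gxhat = g * self.gamma.value
        gsum = gxhat.sum(axis=(0, 1, 2))
        gdot = (gxhat * xhat).sum(axis=(0, 1, 2))
        self._xhat = None
        return (inv / m) * (m * gxhat - gsum - xhat * gdot)

    def params(self):
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x, training=False):
        out = np.maximum(x, 0.0)
        self._mask = out > 0
        return out

    def backward(self, g):
        out = g * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool2x2:
    def forward(self, x, training=False):
        n, h, w, c = x.shape
        v = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = v.max(axis=(2, 4))
        # first-max tie break so exactly one input per window gets gradient
        flat = v.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
        is_max = flat == out[:, :, :, None, :]
        first = np.cumsum(is_max, axis=3) == 1
        self._mask = (is_max & first)
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h2, w2, c = g.shape
        gx = self._mask * g[:, :, :, None, :]
        self._mask = None
        gx = gx.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(gx).reshape(self._shape)

    def params(self):
        return []


class Dropout:
    """Inverted dropout; mask RNG supplied per forward pass by the model."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        rng = rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(F32)
        self._mask /= F32(keep)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class Adam:
    def __init__(self, params, lr=5e-4, beta1=0.8, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class _DoubleConv:
    """conv-BN-ReLU x2 followed by dropout — one U-Net scale block."""

    def __init__(self, c_in, c_out, dropout_rate, use_bn, rng):
        self.layers = []
        for ci, co in ((c_in, c_out), (c_out, c_out)):
            self.layers.append(Conv2d(ci, co, 3, rng))
            if use_bn:
                self.layers.append(BatchNorm2d(co))
            self.layers.append(ReLU())
        self.drop = Dropout(dropout_rate)

    def forward(self, x, training, rng):
        for lay in self.layers:
            x = lay.forward(x, training)
        return self.drop.forward(x, training, rng)

    def backward(self, g):
        g = self.drop.backward(g)
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def params(self):
        out = []
        for lay in self.layers:
            out += lay.params()
        return out


class UNet:
    """Encoder-decoder with skip concatenations and a linear 1x1 output.

    ``depth`` down/up levels with ``base_filters`` channels at the top,
    doubling per level; dropout and batch normalization in every scale
    block; the last layer is a single-filter 1x1 convolution with no
    activation, since the output is a real-valued image rather than a
    segmentation map.
    """

    def __init__(self, depth=4, base_filters=64, dropout_rate=0.5,
                 use_batchnorm=True, seed=0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc, self.pools = [], []
        c_prev = 1
        for d in range(depth):
            c = base_filters * 2 ** d
            self.enc.append(_DoubleConv(c_prev, c, dropout_rate, use_batchnorm, rng))
            self.pools.append(MaxPool2x2())
            c_prev = c
        c_bot = base_filters * 2 ** depth
        self.bottleneck = _DoubleConv(c_prev, c_bot, dropout_rate, use_batchnorm, rng)
        self.ups, self.dec = [], []
        c_prev = c_bot
        for d in reversed(range(depth)):
            c = base_filters * 2 ** d
            self.ups.append(ConvTranspose2x2(c_prev, c, rng))
            self.dec.append(_DoubleConv(2 * c, c, dropout_rate, use_batchnorm, rng))
            c_prev = c
        self.head = Conv2d(c_prev, 1, 1, rng)
        self.dropout_rate = dropout_rate

    # -- graph --------------------------------------------------------------
    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        elif x.ndim == 4 and x.shape[1] == 1:  # channels-first single channel
            x = x[:, 0]
        h = x[..., None]  # (N, H, W, 1)
        if h.shape[1] % (2 ** self.depth) or h.shape[2] % (2 ** self.depth):
            raise ValueError(
                f"input size {h.shape[1:3]} not divisible by 2^{self.depth}")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h, training, rng)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training, rng)
        self._splits = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            self._splits.append(skip.shape[-1])
            h = np.concatenate([skip, h], axis=-1)
            h = dec.forward(h, training, rng)
        out = self.head.forward(h, training)
        return out.transpose(0, 3, 1, 2)  # (N, 1, H, W) for the caller

    def backward(self, g):
        g = np.asarray(g, dtype=F32).transpose(0, 2, 3, 1)
        g = self.head.backward(g)
        skip_grads = []
        for up, dec, cs in zip(reversed(self.ups), reversed(self.dec),
                               reversed(self._splits)):
            g = dec.backward(g)
            skip_grads.append(g[..., :cs])
            g = up.backward(np.ascontiguousarray(g[..., cs:]))
        g = self.bottleneck.backward(g)
        for enc, pool, gs in zip(reversed(self.enc), reversed(self.pools),
                                 reversed(skip_grads)):
            g = pool.backward(g)
            g = enc.backward(g + gs)
        return g

    # -- bookkeeping --------------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.ups, self.dec):
            out += up.params()
            out += dec.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_weights(self):
        return [p.value.copy() for p in self.params()] + \
            [(bn.run_mean.copy(), bn.run_var.copy()) for bn in self._bns()]

    def set_weights(self, weights):
        ps = self.params()
        for p, w in zip(ps, weights[:len(ps)]):
            p.value[...] = w
        for bn, (rm, rv) in zip(self._bns(), weights[len(ps):]):
            bn.run_mean[...] = rm
            bn.run_var[...] = rv

    def _bns(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out += [l for l in blk.layers if isinstance(l, BatchNorm2d)]
        return out
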