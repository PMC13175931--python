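"""Minimal CNN building blocks in numpy.

Just enough machinery to run a two-stage fine-tuning schedule at desk scale:
convolution / pooling / dense layers with explicit backprop, inverted
dropout, softmax cross-entropy, and Adam.  Layers carry a ``trainable`` flag
so a backbone can be frozen wholesale and selectively unfrozen from the
output end — the contract the training harness relies on.

Data layout is NCHW throughout.  This is not a general autodiff framework;
graphs are straight-line ``Sequential`` stacks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base layer: forward/backward with cached activations."""

    trainable: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patches for stride-1 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2D(Layer):
    """3x3 stride-1 'same' convolution (cross-correlation), He init."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, scale, (c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        pad = self.k // 2
        cols = _im2col(x, self.k, pad)
        y = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape = self._cache
        n, c, h, w = xshape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, h * w, self.c_out)
        self.W.grad[...] = np.einsum("npo,npk->ok", dyf, cols)
        self.b.grad[...] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.value
        return _col2im(dcols, xshape, self.k, self.k // 2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean; the pooled feature output."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class AvgPoolGrid(Layer):
    """Average-pool each channel onto a coarse ``g x g`` grid and flatten.

    A pooled feature output that, unlike a global average, keeps coarse
    spatial layout — important when classes differ mainly in lesion
    geometry.  Input H and W must be divisible by ``g``.
    """

    def __init__(self, grid: int = 4):
        self.grid = grid

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        g = self.grid
        if h % g or w % g:
            raise ValueError(f"spatial dims {h}x{w} not divisible by grid {g}")
        self._shape = x.shape
        return x.reshape(n, c, g, h // g, g, w // g).mean(axis=(3, 5)).reshape(n, -1)

    def backward(self, dy):
        n, c, h, w = self._shape
        g = self.grid
        d = dy.reshape(n, c, g, g)[:, :, :, None, :, None]
        d = np.broadcast_to(d, (n, c, g, h // g, g, w // g))
        return (d / ((h // g) * (w // g))).reshape(n, c, h, w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad[...] = self._x.T @ dy
        self.b.grad[...] = dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self, trainable_only: bool = False) -> list[Param]:
        out = []
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            out.extend(layer.params())
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy ``-sum y log p`` over the batch."""
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def softmax_xent_grad(probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits."""
    return (probs - onehot) / probs.shape[0]


class Adam:
    """Adam over an explicit parameter list; frozen layers are simply
    excluded from the list handed to the optimizer."""

    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TinyCNNBackbone:
    """Three conv blocks ending in a coarse average-pooled feature grid.

    Satisfies the harness backbone contract: an ordered ``layers``
    enumeration, ``freeze_all`` / ``unfreeze_last``, a ``feature_dim``, and
    forward/backward over the stack.  Inputs in [0, 1] are centred to
    [-1, 1] internally (the backbone's own normalization, as pretrained
    backbones do).  Input is (N, 3, H, W) with H, W divisible by
    ``4 * pool_grid``.
    """

    def __init__(
        self,
        seed: int = 0,
        channels: tuple[int, int, int] = (8, 16, 32),
        pool_grid: int = 4,
    ):
        rng = np.random.default_rng([seed, 0xBB])
        c1, c2, c3 = channels
        self.net = Sequential(
            [
                Conv2D(3, c1, rng=rng),
                ReLU(),
                MaxPool2(),
                Conv2D(c1, c2, rng=rng),
                ReLU(),
                MaxPool2(),
                Conv2D(c2, c3, rng=rng),
                ReLU(),
                AvgPoolGrid(pool_grid),
            ]
        )
        self.feature_dim = c3 * pool_grid * pool_grid

    @property
    def layers(self) -> list[Layer]:
        return self.net.layers

    def freeze_all(self) -> None:
        for layer in self.layers:
            layer.trainable = False

    def unfreeze_last(self, n: int) -> None:
        """Make the last ``n`` layers (in enumeration order from the output
        end) trainable again; ``n`` beyond the stack depth unfreezes all."""
        for layer in self.layers[max(0, len(self.layers) - n) :]:
            layer.trainable = True

    def forward(self, x, train=False):
        return self.net.forward((x - 0.5) * 2.0, train=train)

    def backward(self, dy):
        return self.net.backward(dy)

    def params(self, trainable_only: bool = False):
        return self.net.params(trainable_only=trainable_only)
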