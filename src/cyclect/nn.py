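"""A small NumPy convolutional-network engine with manual backpropagation.

Provides exactly the layer set the translation networks need — 2-D
convolution (zero padding, stride 1/2), transposed convolution, reflection
padding, instance normalization, (leaky) ReLU, residual blocks — plus an
Adam optimizer.  Layers are stateless in their activations: ``forward``
returns ``(output, cache)`` and ``backward(cache, grad_out)`` returns the
input gradient while accumulating parameter gradients, so the same network
can be applied several times inside one computational graph (as both cycle
directions of the trainer require).

Everything is float64 and single-threaded NumPy: runs are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Array = np.ndarray


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: Array):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# functional conv primitives (shared by Conv2d and ConvTranspose2d)
# ---------------------------------------------------------------------------

def _im2col(x: Array, k: int, stride: int, pad: int):
    """(N,C,H,W) -> column view (N, Ho, Wo, C, k, k) of zero-padded input."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))      # (N,C,Ho*,Wo*,k,k)
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d_forward(x: Array, w: Array, b: Array, stride: int, pad: int):
    """x (N,C,H,W), w (F,C,k,k), b (F,) -> y (N,F,Ho,Wo) plus backward cache."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    cols = _im2col(x, k, stride, pad)                       # (N,Ho,Wo,C,k,k)
    ho, wo = cols.shape[1], cols.shape[2]
    cols2 = cols.reshape(n * ho * wo, c * k * k)
    y = cols2 @ w.reshape(f, -1).T + b
    y = y.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    return y, (cols2, x.shape, (k, stride, pad))


def conv2d_backward(dy: Array, w: Array, cache):
    """Returns (dx, dw, db) for conv2d_forward."""
    cols2, x_shape, (k, stride, pad) = cache
    n, c, h, wd = x_shape
    f = w.shape[0]
    dy2 = dy.transpose(0, 2, 3, 1).reshape(-1, f)           # (N*Ho*Wo, F)
    dw = (dy2.T @ cols2).reshape(w.shape)
    db = dy2.sum(axis=0)
    dcols2 = dy2 @ w.reshape(f, -1)                         # (N*Ho*Wo, C*k*k)
    ho, wo = dy.shape[2], dy.shape[3]
    dcols = dcols2.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    hp, wp = h + 2 * pad, wd + 2 * pad
    dxp = np.zeros((n, c, hp, wp))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, :, :, i, j]
    dx = dxp[:, :, pad:hp - pad, pad:wp - pad] if pad else dxp
    return dx, dw, db


class Layer:
    """Base class: parameterless layers only override forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: Array):
        raise NotImplementedError

    def backward(self, cache, dy: Array) -> Array:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 name: str = "conv"):
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(f"{name}.w", np.zeros((cout, cin, k, k)))
        self.b = Param(f"{name}.b", np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        return conv2d_forward(x, self.w.value, self.b.value, self.stride, self.pad)

    def backward(self, cache, dy):
        dx, dw, db = conv2d_backward(dy, self.w.value, cache)
        self.w.grad += dw
        self.b.grad += db
        return dx


class ConvTranspose2d(Layer):
    """Fractional-stride ("stride 1/2") convolution that exactly doubles the
    spatial size: kernel 3, stride 2, pad 1, output padding 1.

    Implemented as zero-insertion upsampling followed by a stride-1
    convolution with the spatially flipped, channel-swapped kernel, which is
    algebraically identical to the usual transposed convolution.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, output_pad: int = 1, name: str = "convT"):
        self.k, self.stride, self.pad, self.opad = k, stride, pad, output_pad
        self.w = Param(f"{name}.w", np.zeros((cin, cout, k, k)))
        self.b = Param(f"{name}.b", np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def _weight_as_conv(self):
        # (cin,cout,k,k) -> (cout,cin,k,k) with flipped taps
        return self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)

    def forward(self, x):
        n, c, h, wd = x.shape
        s, k, p, op = self.stride, self.k, self.pad, self.opad
        hz, wz = (h - 1) * s + 1 + op, (wd - 1) * s + 1 + op
        z = np.zeros((n, c, hz, wz))
        z[:, :, ::s, ::s] = x
        y, conv_cache = conv2d_forward(z, self._weight_as_conv(), self.b.value,
                                       stride=1, pad=k - 1 - p)
        return y, (conv_cache, x.shape)

    def backward(self, cache, dy):
        conv_cache, x_shape = cache
        dz, dwc, db = conv2d_backward(dy, self._weight_as_conv(), conv_cache)
        self.w.grad += dwc.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        self.b.grad += db
        return dz[:, :, ::self.stride, ::self.stride]


class ReflectionPad2d(Layer):
    def __init__(self, pad: int):
        self.pad = pad

    @staticmethod
    def _index(n: int, p: int) -> Array:
        idx = np.abs(np.arange(-p, n + p))
        return np.where(idx >= n, 2 * (n - 1) - idx, idx)

    def forward(self, x):
        p = self.pad
        ri = self._index(x.shape[2], p)
        ci = self._index(x.shape[3], p)
        return x[:, :, ri][:, :, :, ci], (x.shape, ri, ci)

    def backward(self, cache, dy):
        (n, c, h, w), ri, ci = cache
        # fold columns then rows back onto their source indices
        tmp = np.zeros((n, c, h + 2 * self.pad, w))
        for j, cj in enumerate(ci):
            tmp[:, :, :, cj] += dy[:, :, :, j]
        dx = np.zeros((n, c, h, w))
        for i, rk in enumerate(ri):
            dx[:, :, rk, :] += tmp[:, :, i, :]
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes (no affine
    parameters, matching the reference image-translation networks)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat, (xhat, inv)

    def backward(self, cache, dy):
        xhat, inv = cache
        m1 = dy.mean(axis=(2, 3), keepdims=True)
        m2 = (dy * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dy - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.slope * dy)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dy = l.backward(c, dy)
        return dy


class Residual(Layer):
    """y = x + body(x) with an additive skip connection."""

    def __init__(self, body: Sequential):
        self.body = body

    def params(self):
        return self.body.params()

    def forward(self, x):
        y, cache = self.body.forward(x)
        return x + y, cache

    def backward(self, cache, dy):
        return dy + self.body.backward(cache, dy)


class Network:
    """A Sequential with named-parameter weight state and seeding helpers."""

    def __init__(self, net: Sequential):
        self.net = net
        self.params = net.params()
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    def forward(self, x: Array):
        return self.net.forward(x)

    def backward(self, cache, dy: Array) -> Array:
        return self.net.backward(cache, dy)

    def __call__(self, x: Array) -> Array:
        return self.net.forward(x)[0]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def get_weights(self) -> dict[str, Array]:
        return {p.name: p.value.copy() for p in self.params}

    def set_weights(self, state: dict[str, Array]) -> None:
        for p in self.params:
            if p.name not in state:
                raise KeyError(f"missing weight {p.name}")
            if state[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = state[p.name]

    def init_weights(self, seed: int, std: float = 0.02) -> None:
        """CycleGAN-convention init: kernels ~ N(0, std), biases 0. Seeded."""
        rng = np.random.default_rng(seed)
        for p in self.params:
            if p.value.ndim > 1:
                p.value[...] = rng.normal(0.0, std, size=p.value.shape)
            else:
                p.value[...] = 0.0


class Adam:
    """Adam with a mutable learning rate (for the linear-decay schedule)."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, st: dict) -> None:
        self.t = st["t"]
        for m, ms in zip(self.m, st["m"]):
            m[...] = ms
        for v, vs in zip(self.v, st["v"]):
            v[...] = vs
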