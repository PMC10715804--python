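"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the layers the spectrogram encoder, projector and
classification head need — 2-D convolution (via im2col), ELU, 2x2 max
pooling, global average pooling and dense layers — with hand-written
backward passes and an Adam optimizer.  Every layer is a pure function of
(input, parameters); there is no dropout or batch normalisation, so forward
passes are deterministic and training/inference behave identically.

Parameters are plain ``float`` numpy arrays held in each layer's ``params``
dict; ``collect_params`` flattens a network into an ordered list of arrays
so that copying, checkpointing and exponential-moving-average updates can
operate on whole networks.

The backward passes are verified against central-difference numeric
gradients in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ELU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "collect_params",
    "collect_grads",
    "set_network_params",
    "clone_params",
    "l2_normalize",
    "l2_normalize_backward",
]


class Layer:
    """Base class: ``forward`` caches what ``backward`` needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


try:  # jitted patch gather/scatter; numpy fallback keeps behavior identical
    from numba import njit as _njit

    @_njit(fastmath=True)
    def _gather_patches(x, k, p, cols):  # pragma: no cover - compiled
        """Patch matrix with implicit zero padding: x (B,H,W,C) -> cols
        (B*H*W, k*k*C)."""
        b_n, h, w, c = x.shape
        for b in range(b_n):
            for y in range(h):
                for xx in range(w):
                    r = (b * h + y) * w + xx
                    for i in range(k):
                        yy = y + i - p
                        for j in range(k):
                            ww = xx + j - p
                            base = (i * k + j) * c
                            if 0 <= yy < h and 0 <= ww < w:
                                for ch in range(c):
                                    cols[r, base + ch] = x[b, yy, ww, ch]
                            else:
                                for ch in range(c):
                                    cols[r, base + ch] = 0.0

    @_njit(fastmath=True)
    def _scatter_patches(gx, k, p, gcols):  # pragma: no cover - compiled
        """Transpose of _gather_patches: accumulate cols back into gx."""
        b_n, h, w, c = gx.shape
        for b in range(b_n):
            for y in range(h):
                for xx in range(w):
                    r = (b * h + y) * w + xx
                    for i in range(k):
                        yy = y + i - p
                        for j in range(k):
                            ww = xx + j - p
                            base = (i * k + j) * c
                            if 0 <= yy < h and 0 <= ww < w:
                                for ch in range(c):
                                    gx[b, yy, ww, ch] += gcols[r, base + ch]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


class Conv2d(Layer):
    """kxk convolution, stride 1, 'same' zero padding, channel-last layout.

    Operates on (B, H, W, C) tensors: patches are gathered into a
    contiguous (B*H*W, k*k*C) matrix with near-sequential copies (the
    channel axis is innermost) and the channel mixing is one GEMM.  The
    weight is stored as (k, k, in_ch, out_ch).
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2
        # set on the network's first layer: its input gradient is never used
        self.skip_input_grad = False
        fan_in = in_ch * kernel * kernel
        # He-normal init for ELU-family activations
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, in_ch, out_ch))
        self.params = {"W": w.astype(dtype), "b": np.zeros(out_ch, dtype=dtype)}
        self.zero_grad()

    def _gather(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        k, p = self.kernel, self.pad
        cols = np.empty((b * h * w, k * k * c), dtype=x.dtype)
        if _HAVE_NUMBA:
            _gather_patches(np.ascontiguousarray(x), k, p, cols)
            return cols
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cv = cols.reshape(b, h, w, k * k, c)
        for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            cv[:, :, :, t, :] = xp[:, i : i + h, j : j + w, :]
        return cols

    def _scatter(self, gcols: np.ndarray, xshape: tuple) -> np.ndarray:
        b, h, w, c = xshape
        p, k = self.pad, self.kernel
        gx = np.zeros(xshape, dtype=gcols.dtype)
        if _HAVE_NUMBA:
            _scatter_patches(gx, k, p, np.ascontiguousarray(gcols))
            return gx
        gxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=gcols.dtype)
        gc = gcols.reshape(b, h, w, k * k, c)
        for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            gxp[:, i : i + h, j : j + w, :] += gc[:, :, :, t, :]
        return gxp[:, p : p + h, p : p + w, :]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        cols = self._gather(x)
        self._cache = (cols, x.shape)
        wmat = self.params["W"].reshape(-1, self.out_ch)
        out = cols @ wmat + self.params["b"]
        return out.reshape(b, h, w, self.out_ch)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        g = np.ascontiguousarray(gout, dtype=cols.dtype).reshape(-1, self.out_ch)
        self.grads["b"] += g.sum(axis=0)
        self.grads["W"] += (cols.T @ g).reshape(self.params["W"].shape)
        if self.skip_input_grad:
            return np.empty(0, dtype=cols.dtype)  # discarded by the caller
        gcols = g @ self.params["W"].reshape(-1, self.out_ch).T
        return self._scatter(gcols, xshape)


class ELU(Layer):
    """Exponential linear unit, x if x > 0 else alpha*(exp(x) - 1).

    Written branch-free: max(x, 0) + alpha*min(exp(min(x, 0)) - 1, 0), so
    only cheap vectorized primitives touch the full tensor.
    """

    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        neg = np.exp(np.minimum(x, 0.0))
        neg -= 1.0
        out = np.maximum(x, 0.0) + self.alpha * np.minimum(neg, 0.0)
        self._cache = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        out = self._cache
        if self.alpha == 1.0:
            # min(out, 0) + 1 equals 1 on the positive branch, exp(x) on the other
            return gout * (np.minimum(out, 0.0) + 1.0)
        return gout * np.where(out > 0, 1.0, out + self.alpha)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, channel-last; a trailing odd row/column
    is dropped.  Ties route the gradient to the first window position in
    row-major order."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[1], x.shape[2]
        oh, ow = h // 2, w // 2
        if oh < 1 or ow < 1:
            raise ValueError(f"cannot 2x2-pool a {h}x{w} feature map")
        quads = [
            x[:, di : oh * 2 : 2, dj : ow * 2 : 2, :]
            for di in (0, 1)
            for dj in (0, 1)
        ]
        m = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        self._cache = (quads, m, x.shape)
        return m

    def backward(self, gout: np.ndarray) -> np.ndarray:
        quads, m, xshape = self._cache
        h, w = xshape[1], xshape[2]
        oh, ow = h // 2, w // 2
        gx = np.zeros(xshape, dtype=gout.dtype)
        taken = np.zeros(m.shape, dtype=bool)
        for q, (di, dj) in zip(quads, ((0, 0), (0, 1), (1, 0), (1, 1))):
            hit = (q == m) & ~taken
            gx[:, di : oh * 2 : 2, dj : ow * 2 : 2, :] = gout * hit
            taken |= hit
        return gx


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._cache
        return np.broadcast_to(gout[:, None, None, :], (b, h, w, c)) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._cache)


class Linear(Layer):
    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32
    ) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.params = {"W": w.astype(dtype), "b": np.zeros(out_dim, dtype=dtype)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += x.T @ gout
        self.grads["b"] += gout.sum(axis=0)
        return gout @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


# -- parameter plumbing -------------------------------------------------


def _walk(net: Layer):
    if isinstance(net, Sequential):
        for layer in net.layers:
            yield from _walk(layer)
    elif net.params:
        yield net


def collect_params(net: Layer) -> list[np.ndarray]:
    """Ordered list of parameter arrays (live references)."""
    out: list[np.ndarray] = []
    for layer in _walk(net):
        for k in sorted(layer.params):
            out.append(layer.params[k])
    return out


def collect_grads(net: Layer) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for layer in _walk(net):
        for k in sorted(layer.params):
            out.append(layer.grads[k])
    return out


def set_network_params(net: Layer, values: list[np.ndarray]) -> None:
    current = collect_params(net)
    if len(current) != len(values):
        raise ValueError("parameter structure mismatch")
    for dst, src in zip(current, values):
        if dst.shape != src.shape:
            raise ValueError(f"parameter shape mismatch: {dst.shape} vs {src.shape}")
        dst[...] = src


def clone_params(values: list[np.ndarray]) -> list[np.ndarray]:
    return [v.copy() for v in values]


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient structure mismatch")
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# -- unit-sphere projection ---------------------------------------------


def l2_normalize(u: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    """Project vectors onto the unit hypersphere; errors on (near-)zero input."""
    norm = np.linalg.norm(u, axis=axis, keepdims=True)
    if np.any(norm < eps):
        raise ValueError("cannot L2-normalize a zero vector (degenerate projection)")
    return u / norm


def l2_normalize_backward(u: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Backward of row-wise L2 normalization: g -> dL/du given dL/dz, z = u/|u|."""
    norm = np.linalg.norm(u, axis=-1, keepdims=True)
    z = u / norm
    return (g - z * np.sum(g * z, axis=-1, keepdims=True)) / norm
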