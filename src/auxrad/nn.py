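"""Numpy building blocks for the encoder / classifier networks.

Every layer carries its parameters and hand-coded gradients; ``backward``
consumes the gradient w.r.t. the layer output and returns the gradient
w.r.t. its input while accumulating parameter gradients in ``grads``.
Gradients are verified against central finite differences in the test
suite, which is what lets the rest of the package trust them.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Layer:
    """Base class: parameterless identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def spatial(self) -> bool:
        """True if the layer's output has (N, C, H, W) feature maps."""
        return False


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": (rng.standard_normal((n_in, n_out)) * scale).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    @property
    def spatial(self):
        return self._mask is not None and self._mask.ndim == 4


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Owns a seeded RNG stream."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Conv2d(Layer):
    """Same-padded 2-D convolution on NCHW arrays via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.params = {
            "W": (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self._cols = None
        self._xshape = None
        self._out_hw = None

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k)
        Wm = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ Wm.T + self.params["b"]
        self._cols, self._xshape, self._out_hw = cols, x.shape, (Ho, Wo)
        return out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        N, C, H, W = self._xshape
        Ho, Wo = self._out_hw
        k, s, p = self.k, self.stride, self.pad
        c_out = self.params["W"].shape[0]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        self.grads["W"] = (dmat.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"].reshape(c_out, -1)
        dwin = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dwin[..., i, j]
        return dxp[:, :, p:p + H, p:p + W]

    @property
    def spatial(self):
        return True


class MaxPool2d(Layer):
    """Non-overlapping max pooling; window must divide the spatial dims."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size
        self._cache = None

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        s = self.size
        if H % s or W % s:
            raise ValueError(f"pool size {s} must divide spatial dims {(H, W)}")
        xr = x.reshape(N, C, H // s, s, W // s, s)
        out = xr.max(axis=(3, 5))
        # ties share the gradient equally (valid subgradient, FD-consistent)
        mask = (xr == out[:, :, :, None, :, None])
        cnt = mask.sum(axis=(3, 5), keepdims=True)
        self._cache = (mask, cnt, x.shape)
        return out

    def backward(self, dout):
        mask, cnt, xshape = self._cache
        d = dout[:, :, :, None, :, None] * mask / cnt
        N, C, H, W = xshape
        return d.reshape(N, C, H // self.size, self.size,
                         W // self.size, self.size).reshape(xshape)


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._xshape = None

    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._xshape
        return np.broadcast_to(dout[:, :, None, None] / (H * W),
                               self._xshape).astype(dout.dtype)


class ConcatConv(Layer):
    """Inception-style mixed block: parallel same-padded convolutions whose
    channel outputs are concatenated.  Branch kernel sizes are configurable;
    a 1x1 branch stands in for the pooling projection."""

    def __init__(self, c_in: int, branch_channels: list[int],
                 branch_kernels: list[int], rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        assert len(branch_channels) == len(branch_kernels)
        self.branches = [Conv2d(c_in, c, rng, k=k, dtype=dtype)
                         for c, k in zip(branch_channels, branch_kernels)]
        self._splits = np.cumsum(branch_channels)[:-1]
        for i, br in enumerate(self.branches):
            for n, v in br.params.items():
                self.params[f"br{i}_{n}"] = v

    def forward(self, x, train=False):
        return np.concatenate([br.forward(x, train) for br in self.branches],
                              axis=1)

    def backward(self, dout):
        parts = np.split(dout, self._splits, axis=1)
        dx = None
        for i, (br, d) in enumerate(zip(self.branches, parts)):
            g = br.backward(np.ascontiguousarray(d))
            for n, v in br.grads.items():
                self.grads[f"br{i}_{n}"] = v
            dx = g if dx is None else dx + g
        return dx

    @property
    def spatial(self):
        return True


class Sequential:
    """Ordered layer stack with optional activation/gradient capture for
    class-activation mapping."""

    def __init__(self, layers: list[Layer], names: list[str] | None = None):
        self.layers = layers
        self.names = names or [f"layer{i}" for i in range(len(layers))]
        self._acts: list[np.ndarray] | None = None
        self.captured_grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, capture=False):
        acts = [] if capture else None
        for layer in self.layers:
            x = layer.forward(x, train)
            if capture:
                acts.append(x)
        self._acts = acts
        return x

    def backward(self, dout, capture_at: set[str] | None = None):
        self.captured_grads = {}
        for name, layer in zip(reversed(self.names), reversed(self.layers)):
            if capture_at and name in capture_at:
                # entering iteration i, dout is the gradient w.r.t. the
                # output of layer i -- exactly what CAM needs
                self.captured_grads[name] = dout
            dout = layer.backward(dout)
        return dout

    def activation(self, name: str) -> np.ndarray:
        if self._acts is None:
            raise RuntimeError("forward(capture=True) has not been run")
        return self._acts[self.names.index(name)]

    def parameters(self):
        for name, layer in zip(self.names, self.layers):
            for pname in layer.params:
                yield f"{name}.{pname}", layer, pname


class Adam:
    """Adaptive-moment optimizer over a list of (key, layer, pname) refs."""

    def __init__(self, modules: list[Sequential | Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.refs = []
        for mod in modules:
            if isinstance(mod, Sequential):
                self.refs.extend(mod.parameters())
            else:
                for pname in mod.params:
                    self.refs.append((pname, mod, pname))
        self.m = [np.zeros_like(layer.params[p]) for _, layer, p in self.refs]
        self.v = [np.zeros_like(layer.params[p]) for _, layer, p in self.refs]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (_, layer, p) in enumerate(self.refs):
            g = layer.grads.get(p)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            layer.params[p] -= (self.lr * (self.m[i] / b1t)
                                / (np.sqrt(self.v[i] / b2t) + self.eps))

    def zero_grads(self):
        for _, layer, p in self.refs:
            layer.grads.pop(p, None)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)
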