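"""Minimal numpy neural-network engine (NHWC layout).

Implements exactly the layer set the classification architectures need:
2D convolution with stride and dilation ('same' padding), batch
normalization, ReLU, dense, dropout, average / global-average pooling,
broadcast upsampling, reshape and channel concatenation — each with a
hand-derived backward pass — plus a DAG container and an Adam optimizer.
Softmax cross-entropy is provided as a fused loss.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: owns parameters, gradients, and a trainable flag."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def forward(self, *xs: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _same_pad(size: int, k: int, stride: int, dilation: int) -> tuple[int, int]:
    eff = (k - 1) * dilation + 1
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + eff - size, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1, dilation: int = 1, bias: bool = True) -> None:
        super().__init__()
        self.k, self.stride, self.dilation = k, stride, dilation
        scale = np.sqrt(2.0 / (k * k * in_ch))  # He init
        self.params["W"] = rng.standard_normal((k, k, in_ch, out_ch)) * scale
        if bias:
            self.params["b"] = np.zeros(out_ch)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s, d = self.k, self.stride, self.dilation
        n, h, w, c = x.shape
        pt, pb = _same_pad(h, k, s, d)
        pl, pr = _same_pad(w, k, s, d)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        oh = -(-h // s)
        ow = -(-w // s)
        cols = np.empty((n, oh, ow, k, k, c))
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[
                    :, i * d : i * d + (oh - 1) * s + 1 : s,
                    j * d : j * d + (ow - 1) * s + 1 : s, :,
                ]
        y = np.tensordot(cols, self.params["W"], axes=([3, 4, 5], [0, 1, 2]))
        if "b" in self.params:
            y = y + self.params["b"]
        self._cache = (cols, x.shape, (pt, pb, pl, pr), (oh, ow))
        return y

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        cols, xshape, (pt, pb, pl, pr), (oh, ow) = self._cache
        k, s, d = self.k, self.stride, self.dilation
        self.grads["W"] = np.tensordot(cols, grad, axes=([0, 1, 2], [0, 1, 2]))
        if "b" in self.params:
            self.grads["b"] = grad.sum(axis=(0, 1, 2))
        dcols = np.tensordot(grad, self.params["W"], axes=([3], [3]))
        n, h, w, c = xshape
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i * d : i * d + (oh - 1) * s + 1 : s,
                    j * d : j * d + (ow - 1) * s + 1 : s, :] += dcols[:, :, :, i, j, :]
        return (dxp[:, pt : pt + h, pl : pl + w, :],)


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channels)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(ch)
        self.params["beta"] = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training and self.trainable:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        self._cache = (xhat, invstd, axes, x.shape)
        return xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        xhat, invstd, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        dxhat = grad * self.params["gamma"]
        dx = (invstd / m) * (
            m * dxhat - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return (dx,)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        return (grad * self._mask,)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.params["W"] = rng.standard_normal((in_dim, out_dim)) * scale
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return (grad @ self.params["W"].T,)


class Dropout(Layer):
    """Inverted dropout with its own seeded random stream."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        return (grad if self._mask is None else grad * self._mask,)


class AvgPool2D(Layer):
    """Non-overlapping average pooling (spatial size must divide evenly)."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.f = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.f
        self._shape = x.shape
        return x.reshape(n, h // f, f, w // f, f, c).mean(axis=(2, 4))

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        n, h, w, c = self._shape
        f = self.f
        g = np.repeat(np.repeat(grad, f, axis=1), f, axis=2) / (f * f)
        return (g,)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        n, h, w, c = self._shape
        return (np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w),)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]) -> None:
        super().__init__()
        self.target = target

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        return (grad.reshape(self._shape),)


class BroadcastUpsample(Layer):
    """Replicate a (N, 1, 1, C) map to (N, H, W, C).

    Bilinear upsampling from a single spatial cell is constant, so
    replication is exactly the bilinear result for this geometry.
    """

    def __init__(self, target_hw: tuple[int, int]) -> None:
        super().__init__()
        self.hw = target_hw

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1:3] != (1, 1):
            raise ValueError("BroadcastUpsample expects a 1x1 spatial input")
        h, w = self.hw
        return np.broadcast_to(x, (x.shape[0], h, w, x.shape[3])).copy()

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        return (grad.sum(axis=(1, 2), keepdims=True),)


class Concat(Layer):
    def forward(self, *xs: np.ndarray, training: bool = False) -> np.ndarray:
        self._sizes = [x.shape[-1] for x in xs]
        return np.concatenate(xs, axis=-1)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        splits = np.cumsum(self._sizes)[:-1]
        return tuple(np.split(grad, splits, axis=-1))


class Identity(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        return (grad,)


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "layer", "inputs")

    def __init__(self, name: str, layer: Layer, inputs: tuple[str, ...]) -> None:
        self.name, self.layer, self.inputs = name, layer, inputs


class Graph:
    """A DAG of named layers, evaluated in insertion order."""

    def __init__(self, input_names: tuple[str, ...], output_name: str) -> None:
        self.input_names = input_names
        self.output_name = output_name
        self.nodes: list[_Node] = []
        self.shapes: dict[str, tuple[int, ...]] = {}

    def add(self, name: str, layer: Layer, *inputs: str) -> str:
        known = set(self.input_names) | {n.name for n in self.nodes}
        for inp in inputs:
            if inp not in known:
                raise ValueError(f"unknown input tensor {inp!r} for node {name!r}")
        self.nodes.append(_Node(name, layer, inputs))
        return name

    def forward(self, feed: dict[str, np.ndarray], training: bool = False) -> np.ndarray:
        vals = dict(feed)
        for node in self.nodes:
            xs = [vals[i] for i in node.inputs]
            vals[node.name] = node.layer.forward(*xs, training=training)
        self.shapes = {k: tuple(v.shape) for k, v in vals.items()}
        return vals[self.output_name]

    def backward(self, dout: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {self.output_name: dout}
        for node in reversed(self.nodes):
            g = grads.pop(node.name, None)
            if g is None:
                continue
            gs = node.layer.backward(g)
            for inp, gi in zip(node.inputs, gs):
                grads[inp] = grads[inp] + gi if inp in grads else gi
        return grads

    def param_layers(self) -> list[tuple[str, Layer]]:
        return [(n.name, n.layer) for n in self.nodes if n.layer.params]

    def n_params(self) -> int:
        return sum(layer.n_params() for _, layer in self.param_layers())


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n)
    return loss, (p - onehot) / n


class Adam:
    def __init__(self, graph: Graph, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.graph = graph
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[str, str], np.ndarray] = {}
        self.v: dict[tuple[str, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for name, layer in self.graph.param_layers():
            if not layer.trainable:
                continue
            for pname, p in layer.params.items():
                g = layer.grads.get(pname)
                if g is None:
                    continue
                key = (name, pname)
                m = self.m.get(key, np.zeros_like(p))
                v = self.v.get(key, np.zeros_like(p))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.m[key], self.v[key] = m, v
                mh = m / (1 - self.b1**self.t)
                vh = v / (1 - self.b2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)
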