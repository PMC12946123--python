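"""Minimal NumPy neural-network layers for the encoder backbones.

The package trains small encoders on desk-scale synthetic benchmarks, so
the layer zoo is deliberately tiny: 3x3 same-padding convolution (im2col
via sliding windows), ReLU, 2x2 max/average pooling, flatten and dense
layers, plus SGD with momentum and step learning-rate decay.  Every backward pass
is hand-derived and finite-difference checked in the test suite.

Arrays are ``float64`` throughout; convolutional layers use NCHW layout.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Conv2d",
    "AvgPool2d",
    "MaxPool2d",
    "Flatten",
    "Sequential",
    "SGD",
    "Encoder",
    "build_backbone",
    "l2_normalize",
    "l2_normalize_backward",
]


class Layer:
    """Base layer: ``params``/``grads`` dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv2d(Layer):
    """3x3 convolution, stride 1, same (zero) padding, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols = None

    def forward(self, x):
        p, k = self.pad, self.kernel
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # contiguous im2col matrix (N*H*W, C*k*k) feeds a BLAS matmul
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5))
        self._cols = cols.reshape(n * h * w, c * k * k)
        self._xshape = (n, c, h, w)
        w_mat = self.params["W"].reshape(self.params["W"].shape[0], -1).T
        out = self._cols @ w_mat + self.params["b"]
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        p, k = self.pad, self.kernel
        n, c, h, w = self._xshape
        o = grad.shape[1]
        g_mat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(n * h * w, o)
        self.grads["W"] += (g_mat.T @ self._cols).reshape(o, c, k, k)
        self.grads["b"] += g_mat.sum(axis=0)
        d_cols = (g_mat @ self.params["W"].reshape(o, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += d_cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class AvgPool2d(Layer):
    """2x2 average pooling, stride 2; spatial dims must be even."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2d needs even spatial dimensions")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return out


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; preserves rectified texture energy
    better than averaging."""

    def __init__(self):
        super().__init__()
        self._argmask = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d needs even spatial dimensions")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._argmask = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, (n, c, h, w) = self._argmask
        out_flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(out_flat, idx[..., None], grad[..., None], axis=-1)
        blocks = out_flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        """Yield ``(layer, name)`` pairs for every trainable array."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def zero_grad(self):
        for layer, name in self.parameters():
            layer.grads[name][...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (layer, name), arr in zip(self.parameters(), state, strict=True):
            if layer.params[name].shape != arr.shape:
                raise ValueError("state shape mismatch")
            layer.params[name][...] = arr


class SGD:
    """SGD with heavy-ball momentum and step learning-rate decay."""

    def __init__(self, net: Sequential, lr: float = 0.1, momentum: float = 0.9,
                 lr_step: int = 40, lr_gamma: float = 0.1, grad_clip: float | None = 5.0):
        self.net = net
        self.lr0 = lr
        self.lr = lr
        self.momentum = momentum
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.grad_clip = grad_clip
        self._velocity_map: dict[tuple[int, str], np.ndarray] = {}

    def _clip(self):
        # global-norm clipping keeps plain (normalisation-free) nets stable
        if self.grad_clip is None:
            return
        total = np.sqrt(sum(float((layer.grads[name] ** 2).sum())
                            for layer, name in self.net.parameters()))
        if total > self.grad_clip:
            scale = self.grad_clip / total
            for layer, name in self.net.parameters():
                layer.grads[name] *= scale

    def step(self):
        self._clip()
        for layer, name in self.net.parameters():
            key = (id(layer), name)
            v = self._velocity_map.get(key)
            if v is None:
                v = np.zeros_like(layer.params[name])
                self._velocity_map[key] = v
            v *= self.momentum
            v -= self.lr * layer.grads[name]
            layer.params[name] += v

    def set_epoch(self, epoch: int):
        self.lr = self.lr0 * (self.lr_gamma ** (epoch // self.lr_step))


def l2_normalize(x: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    norm = np.linalg.norm(x, axis=axis, keepdims=True)
    return x / np.maximum(norm, eps)


def l2_normalize_backward(x: np.ndarray, grad: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Gradient of a row-wise L2 normalisation ``z = x / ||x||``.

    ``dL/dx = (grad - z * (grad . z)) / ||x||`` per row.
    """
    norm = np.maximum(np.linalg.norm(x, axis=-1, keepdims=True), eps)
    z = x / norm
    return (grad - z * np.sum(grad * z, axis=-1, keepdims=True)) / norm


class Encoder:
    """Feature extractor plus linear classification head.

    ``features`` maps images to a d-dimensional representation h; the
    head ``omega`` maps h to logits over the extended label space.  The
    contrastive embedding is the L2-normalised h.
    """

    def __init__(self, backbone: Sequential, head: Dense, input_layout: str):
        self.backbone = backbone
        self.head = head
        self.input_layout = input_layout  # "nchw" or "flat"

    def prepare(self, images: np.ndarray) -> np.ndarray:
        """NHWC image batch -> centred backbone input layout."""
        x = np.asarray(images, dtype=np.float64) - 0.5
        if x.ndim == 3:
            x = x[None]
        if self.input_layout == "nchw":
            return np.transpose(x, (0, 3, 1, 2))
        return x.reshape(x.shape[0], -1)

    def features(self, images: np.ndarray) -> np.ndarray:
        return self.backbone.forward(self.prepare(images))

    def logits(self, h: np.ndarray) -> np.ndarray:
        return self.head.forward(h)

    def all_params(self):
        yield from self.backbone.parameters()
        for name in self.head.params:
            yield self.head, name

    def state(self):
        return [layer.params[name].copy() for layer, name in self.all_params()]

    def clone(self) -> "Encoder":
        return copy.deepcopy(self)


def build_backbone(
    name: str,
    input_size: int,
    embed_dim: int,
    rng: np.random.Generator,
) -> tuple[Sequential, str]:
    """Construct a named backbone; returns (net, input layout).

    ``small_cnn``: two 3x3 conv + ReLU + 2x2 pool blocks then a dense
    embedding — the default encoder.  ``mlp``: one hidden dense layer —
    the fast test path.
    """
    if name == "small_cnn":
        if input_size % 4 != 0:
            raise ValueError("small_cnn needs input_size divisible by 4")
        feat = 32 * (input_size // 4) ** 2
        net = Sequential([
            Conv2d(3, 16, rng),
            ReLU(),
            MaxPool2d(),
            Conv2d(16, 32, rng),
            ReLU(),
            MaxPool2d(),
            Flatten(),
            Dense(feat, embed_dim, rng),
        ])
        return net, "nchw"
    if name == "mlp":
        n_in = input_size * input_size * 3
        net = Sequential([
            Dense(n_in, 128, rng),
            ReLU(),
            Dense(128, embed_dim, rng),
        ])
        return net, "flat"
    raise ValueError(f"unknown backbone {name!r}")
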