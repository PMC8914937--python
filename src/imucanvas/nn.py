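"""A small NumPy implementation of the layers the baseline CNN needs.

Convolutions are computed as matrix products on im2col patch matrices
(float32 throughout), max-pooling keeps argmax indices for the backward
pass, and Adam is the only optimizer.  Everything is seeded through a
``numpy.random.Generator``, so identical seeds give identical weights,
shuffles, and fitted models.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: parameters and gradients live in parallel dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid (no padding), stride-1 2-D convolution, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        # He initialization for ReLU nonlinearities
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, _ = x.shape
        ho, wo = h - k + 1, w - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (n, ho, wo, c_in, k, k) -> (n*ho*wo, k*k*c_in) matching W's layout
        cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, k * k * self.c_in
        )
        self._cols, self._xshape = cols, x.shape
        wm = self.params["W"].reshape(-1, self.c_out)
        out = cols @ wm + self.params["b"]
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._xshape is not None
        k = self.k
        n, h, w, c_in = self._xshape
        ho, wo = h - k + 1, w - k + 1
        dm = dout.reshape(-1, self.c_out)
        self.grads["W"] = (self._cols.T @ dm).reshape(self.params["W"].shape)
        self.grads["b"] = dm.sum(axis=0)
        dcols = (dm @ self.params["W"].reshape(-1, self.c_out).T).reshape(
            n, ho, wo, k, k, c_in
        )
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + ho, j:j + wo, :] += dcols[:, :, :, i, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are cropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, :ho * 2, :wo * 2, :].reshape(n, ho, 2, wo, 2, c)
        patches = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, 4)
        self._argmax = patches.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(
            patches, self._argmax[..., None], axis=-1
        ).squeeze(-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        ho, wo = h // 2, w // 2
        dpatches = np.zeros((n, ho, wo, c, 4), dtype=np.float32)
        np.put_along_axis(dpatches, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._xshape, dtype=np.float32)
        dx[:, :ho * 2, :wo * 2, :] = (
            dpatches.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, ho * 2, wo * 2, c)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)
        ).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def param_count(self) -> int:
        return sum(layer.params[n].size for layer, n in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[n].copy() for layer, n in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights, strict=True):
            layer.params[name] = w.copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
    dlogits = probs.astype(np.float32)
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment gradient descent over a :class:`Sequential` model."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n]) for l, n in model.parameters()]
        self.v = [np.zeros_like(l.params[n]) for l, n in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
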