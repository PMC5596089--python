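"""Minimal NumPy neural-network layers with reverse-mode gradients.

Just enough machinery for the crop classifier: 3x3 same-padded
convolutions, 2x2 max pooling, dense layers, ReLU, dropout and an Adam
optimizer.  Shapes are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "MaxPool2x2", "ReLU", "Flatten", "Dense", "Dropout",
    "Adam", "softmax", "cross_entropy_grad",
]


class Layer:
    """Base layer: parameters in ``params``, matching ``grads`` after
    :meth:`backward`."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def describe(self) -> str:
        return type(self).__name__


class Conv2D(Layer):
    """3x3 (or k x k) convolution with same padding, stride 1, via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (out_channels, in_channels, kernel, kernel))
        self.params["b"] = np.zeros(out_channels)
        self._cache = None

    def describe(self) -> str:
        return (f"Conv2D({self.in_channels}->{self.out_channels}, "
                f"{self.kernel}x{self.kernel}, same)")

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
        idx = 0
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di:di + h, dj:dj + w]
                cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, h * w)
                idx += 1
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        cols = self._im2col(x)
        k = self.kernel
        wmat = self.params["W"].transpose(0, 2, 3, 1).reshape(self.out_channels, -1)
        out = np.einsum("fp,npq->nfq", wmat, cols) + self.params["b"][None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(n, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols = self._cache
        k, p = self.kernel, self.kernel // 2
        dflat = dout.reshape(n, self.out_channels, h * w)
        dwmat = np.einsum("nfq,npq->fp", dflat, cols)
        self.grads["W"] = (
            dwmat.reshape(self.out_channels, k, k, c).transpose(0, 3, 1, 2)
        )
        self.grads["b"] = dflat.sum(axis=(0, 2))
        wmat = self.params["W"].transpose(0, 2, 3, 1).reshape(self.out_channels, -1)
        dcols = np.einsum("fp,nfq->npq", wmat, dflat)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        idx = 0
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += (
                    dcols[:, idx * c:(idx + 1) * c, :].reshape(n, c, h, w)
                )
                idx += 1
        return dxp[:, :, p:p + h, p:p + w]


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"input {h}x{w} too small for a 2x2 pool")
        xc = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xc.max(axis=(3, 5))
        mask = xc == out[:, :, :, None, :, None]
        # ties share the gradient equally
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._cache = (x.shape, mask)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), mask = self._cache
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, c, h, w))
        dx[:, :, :h2 * 2, :w2 * 2] = (
            mask * dout[:, :, :, None, :, None]
        ).reshape(n, c, h2 * 2, w2 * 2)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def describe(self) -> str:
        return f"Dense({self.n_in}->{self.n_out})"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._rng = rng
        self._mask = None

    def describe(self) -> str:
        return f"Dropout(p={self.p})"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with the usual defaults (lr 1e-3, betas .9/.999)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
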