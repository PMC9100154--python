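"""A compact numpy neural-network engine for the CPU-scale training grid.

Implements exactly what the grid needs and nothing more: 3x3 same-padding
convolutions (im2col), ReLU, 2x2 max pooling, global average pooling, a
dense softmax head, categorical cross-entropy, and the two optimizers of
the study design (plain SGD and AdaGrad), either at a fixed learning rate
or driven by a step-indexed schedule.  Everything is single-threaded
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "BatchNorm", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense",
    "SmallCNN", "SGD", "AdaGrad",
    "softmax", "cross_entropy",
]


class Layer:
    """Base layer: parameter-free unless it overrides ``params``."""

    trainable = True

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, same padding, NHWC layout."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * cin
        self.k = k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(k * k * cin, cout))
        self.b = np.zeros(cout)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="constant")
        cols = np.empty((n, h, w, self.k * self.k, c), dtype=x.dtype)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                cols[:, :, :, idx, :] = xp[:, di:di + h, dj:dj + w, :]
                idx += 1
        return cols.reshape(n * h * w, self.k * self.k * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        n, h, w, _ = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.w + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, cin = self._xshape
        gflat = grad.reshape(-1, grad.shape[-1])
        self.dw = self._cols.T @ gflat
        self.db = gflat.sum(axis=0)
        dcols = (gflat @ self.w.T).reshape(n, h, w, self.k * self.k, cin)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, cin))
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, idx, :]
                idx += 1
        return dxp[:, p:p + h, p:p + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W), as used by every
    published backbone family; moving statistics are tracked for inference
    and never count as trainable parameters."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.moving_mean = np.zeros(c)
        self.moving_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean = (self.momentum * self.moving_mean
                                + (1 - self.momentum) * mean)
            self.moving_var = (self.momentum * self.moving_var
                               + (1 - self.momentum) * var)
        else:
            mean, var = self.moving_mean, self.moving_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.dgamma = (grad * self._xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        m = self._m
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._x = x
        self._out = out
        return out

    def backward(self, grad):
        n, h, w, c = self._x.shape
        up = np.repeat(np.repeat(self._out, 2, axis=1), 2, axis=2)
        mask = self._x == up
        counts = mask.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        gup = np.repeat(np.repeat(grad / counts, 2, axis=1), 2, axis=2)
        return gup * mask


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               (n, h, w, c)).copy()


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout))
        self.b = np.zeros(cout)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class SmallCNN:
    """conv-BN-ReLU-pool stacked classifier with a GAP + dense softmax head.

    The convolution/pooling stack is the "backbone"; the dense softmax layer
    is the always-trainable head.  The quarter-freeze fine-tuning policy
    marks the first ``floor(0.25 * L)`` backbone layers (L counting every
    backbone layer, parameterised or not, as frameworks enumerate them)
    non-trainable.
    """

    def __init__(self, conv_widths: tuple[int, ...], n_classes: int = 4,
                 seed: int = 0, freeze_first_quarter: bool = False):
        rng = np.random.default_rng(seed)
        self.backbone: list[Layer] = []
        cin = 3
        for width in conv_widths:
            self.backbone += [Conv2D(cin, width, rng=rng), BatchNorm(width),
                              ReLU(), MaxPool2()]
            cin = width
        self.backbone.append(GlobalAvgPool())
        self.head = Dense(cin, n_classes, rng=rng)
        self.freeze_first_quarter = freeze_first_quarter
        if freeze_first_quarter:
            boundary = int(0.25 * len(self.backbone))
            for layer in self.backbone[:boundary]:
                layer.trainable = False

    @property
    def layers(self) -> list[Layer]:
        return [*self.backbone, self.head]

    def set_training(self, training: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.training = training

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.set_training(False)
        try:
            return softmax(self.forward(x))
        finally:
            self.set_training(True)

    def count_trainable(self) -> int:
        return sum(p.size for layer in self.layers if layer.trainable
                   for p in layer.params)

    def trainable_params_and_grads(self):
        for layer in self.layers:
            if layer.trainable:
                yield from zip(layer.params, layer.grads)


class _Optimizer:
    """Shared stepping logic; ``lr`` may be a float or a callable of the step."""

    def __init__(self, lr):
        self._lr = lr
        self.t = 0

    def current_rate(self) -> float:
        return float(self._lr(self.t)) if callable(self._lr) else float(self._lr)

    def step(self, model: SmallCNN) -> None:
        rate = self.current_rate()
        for param, grad in model.trainable_params_and_grads():
            self._update(param, grad, rate)
        self.t += 1

    def _update(self, param, grad, rate):  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    """Plain mini-batch gradient descent (no momentum)."""

    def _update(self, param, grad, rate):
        param -= rate * grad


class AdaGrad(_Optimizer):
    """Per-parameter accumulated-squared-gradient scaling, zero initial state."""

    def __init__(self, lr, eps: float = 1e-7):
        super().__init__(lr)
        self.eps = eps
        self._acc: dict[int, np.ndarray] = {}

    def _update(self, param, grad, rate):
        acc = self._acc.setdefault(id(param), np.zeros_like(param))
        acc += grad * grad
        param -= rate * grad / (np.sqrt(acc) + self.eps)
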