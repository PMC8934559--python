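"""Minimal NumPy implementation of the small feedforward CNNs used by
the pipeline: stride-1 same-padding convolutions, batch normalization,
ReLU, non-overlapping max pooling, dropout, dense layers and a softmax
cross-entropy head, trained with SGD + momentum, L2 penalty,
learning-rate decay and early stopping on validation accuracy.

Data layout is (N, H, W, C) float32; convolutions are computed by
shift-and-accumulate GEMMs, which is the fastest pure-NumPy formulation
at these image sizes.
"""

from __future__ import annotations

import numpy as np


class Layer:
    trainable: bool = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def decayed(self) -> list[bool]:
        """Whether each parameter receives L2 weight decay."""
        return []

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv2D(Layer):
    trainable = True

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        self.xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w, self.c_out)).copy()
        for dy in range(k):
            for dx in range(k):
                out += self.xp[:, dy : dy + h, dx : dx + w, :] @ self.W[dy, dx]
        self.out_shape = out.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self.out_shape
        k, p = self.k, self.k // 2
        g2 = grad.reshape(-1, self.c_out)
        self.db = g2.sum(axis=0)
        dxp = np.zeros_like(self.xp)
        for dy in range(k):
            for dx in range(k):
                xs = self.xp[:, dy : dy + h, dx : dx + w, :].reshape(-1, self.c_in)
                self.dW[dy, dx] = xs.T @ g2
                dxp[:, dy : dy + h, dx : dx + w, :] += grad @ self.W[dy, dx].T
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def decayed(self):
        return [True, False]


class BatchNorm(Layer):
    trainable = True

    def __init__(self, c: int, momentum: float = 0.6, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def _axes(self, x: np.ndarray):
        return tuple(range(x.ndim - 1))  # all but the channel axis

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = np.maximum((x * x).mean(axis=axes) - mean * mean, 0.0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_sd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self.xhat = (x - mean) * self.inv_sd
        return self.gamma * self.xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = self._axes(grad)
        self.dgamma = (grad * self.xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        gxhat = grad * self.gamma
        dx = (
            gxhat
            - gxhat.mean(axis=axes)
            - self.xhat * (gxhat * self.xhat).mean(axis=axes)
        ) * self.inv_sd
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def decayed(self):
        return [False, False]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self.mask


class MaxPool(Layer):
    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.p
        if h % p or w % p:
            raise ValueError(f"spatial size {h}x{w} not divisible by pool size {p}")
        win = x.reshape(n, h // p, p, w // p, p, c).transpose(0, 1, 3, 5, 2, 4)
        win = np.ascontiguousarray(win.reshape(n, h // p, w // p, c, p * p))
        self.argmax = win.argmax(axis=-1)  # single winner per window
        out = np.take_along_axis(win, self.argmax[..., None], axis=-1)[..., 0]
        self.x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        p = self.p
        g = np.zeros((*grad.shape, p * p), dtype=grad.dtype)
        np.put_along_axis(g, self.argmax[..., None], grad[..., None], axis=-1)
        g = g.reshape(n, h // p, w // p, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(g.reshape(n, h, w, c))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.spatial = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self.spatial
        g = np.broadcast_to(grad[:, None, None, :], (grad.shape[0], h, w, grad.shape[1]))
        return (g / (h * w)).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self.x_shape)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self.mask = None
            return x
        self.mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(
            np.float32
        )
        return x * self.mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.mask is None:
            return grad
        return grad * self.mask


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self.x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def decayed(self):
        return [True, False]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """Sequence of layers ending in logits; softmax applied at the head.

    ``stage_names`` optionally labels layer outputs so activations can be
    captured for representational analyses.
    """

    def __init__(self, layers: list[Layer], stage_names: dict[int, str] | None = None):
        self.layers = layers
        self.stage_names = stage_names or {}

    def forward(self, x: np.ndarray, train: bool = False,
                capture: bool = False):
        acts: dict[str, np.ndarray] = {}
        if capture:
            acts["input"] = x.reshape(x.shape[0], -1).copy()
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train)
            if capture and i in self.stage_names:
                acts[self.stage_names[i]] = x.reshape(x.shape[0], -1).copy()
        probs = softmax(x)
        if capture:
            acts["output"] = probs.copy()
            return probs, acts
        return probs

    def backward(self, probs: np.ndarray, y: np.ndarray) -> None:
        n = probs.shape[0]
        grad = ((probs - np.eye(probs.shape[1], dtype=np.float32)[y]) / n).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def n_params(self) -> int:
        return int(sum(layer.n_params() for layer in self.layers))

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()] + [
            b.copy()
            for layer in self.layers
            if isinstance(layer, BatchNorm)
            for b in (layer.running_mean, layer.running_var)
        ]

    def set_params(self, snapshot: list[np.ndarray]) -> None:
        it = iter(snapshot)
        for layer in self.layers:
            for p in layer.params():
                p[...] = next(it)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


class SGDMomentum:
    def __init__(self, net: Network, lr: float, momentum: float, l2: float, lr_decay: float):
        self.net = net
        self.lr0, self.momentum, self.l2, self.lr_decay = lr, momentum, l2, lr_decay
        self.velocity = [np.zeros_like(p) for layer in net.layers for p in layer.params()]
        self.epoch = 0

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.lr_decay * self.epoch)

    def step(self) -> None:
        i = 0
        for layer in self.net.layers:
            for p, g, decay in zip(layer.params(), layer.grads(), layer.decayed()):
                g_eff = g + (self.l2 * p if decay else 0.0)
                self.velocity[i] = self.momentum * self.velocity[i] - self.lr * g_eff
                p += self.velocity[i].astype(p.dtype)
                i += 1
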