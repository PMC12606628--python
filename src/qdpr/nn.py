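"""Compact NumPy neural-network stack used by the surrogate and score models.

The networks here are deliberately small (one or two 1-D convolutions over
the residue axis plus a dense head, or a single dense hidden layer), so a
hand-rolled forward/backward pass with Adam is fast, dependency-free, and
bit-reproducible under a seed. Layers cache activations during ``forward``
and consume them in ``backward``; parameters and their gradient buffers live
on the layer objects.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1D", "LeakyReLU", "Flatten", "Network", "Adam", "train_network"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Conv1D(Layer):
    """1-D convolution over the residue axis with 'same' zero padding.

    Input (n, L, c_in) -> output (n, L, c_out); odd kernel width required so
    the residue axis stays aligned.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd")
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        fan_in = kernel * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _patches(self, x):
        n, length, _ = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (n, L, c_in, k) -> (n, L, k * c_in)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            n, length, self.kernel * self.c_in
        )

    def forward(self, x):
        self._shape = x.shape
        self._p = self._patches(x)
        return self._p @ self.w + self.b

    def backward(self, grad):
        n, length, _ = self._shape
        self.grads[0][...] = np.einsum("nlf,nlo->fo", self._p, grad)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        gp = grad @ self.w.T  # (n, L, k * c_in)
        gp = gp.reshape(n, length, self.kernel, self.c_in)
        pad = self.kernel // 2
        gx = np.zeros((n, length + 2 * pad, self.c_in))
        for j in range(self.kernel):
            gx[:, j : j + length] += gp[:, :, j]
        return gx[:, pad : pad + length]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_network(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    *,
    max_epochs: int,
    batch_size: int,
    learning_rate: float,
    patience: int | None,
    rng: np.random.Generator,
    weight_decay: float = 0.0,
) -> dict:
    """Minibatch MSE training with optional patience-based early stopping.

    With a validation set, training stops once validation MSE has not
    improved for ``patience`` epochs and the best-epoch weights are restored.
    Without one, the network trains for exactly ``max_epochs`` epochs.
    Returns a history dict (per-epoch train/validation MSE, best epoch).
    """
    n = x.shape[0]
    batch_size = min(batch_size, n)
    opt = Adam(net.params, lr=learning_rate)
    history = {"train_mse": [], "val_mse": [], "best_epoch": None}
    best_val, best_weights, best_epoch, stale = np.inf, None, None, 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = net.forward(x[idx])
            err = pred - y[idx]
            sq_sum += float((err**2).sum())
            net.backward(2.0 * err / err.size)
            opt.step(net.grads)
            if weight_decay:
                for p in net.params:
                    p -= learning_rate * weight_decay * p
        history["train_mse"].append(sq_sum / (n * y.shape[1]))
        if x_val is not None and len(x_val):
            val_mse = float(((net.forward(x_val) - y_val) ** 2).mean())
            history["val_mse"].append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val, best_epoch, stale = val_mse, epoch, 0
                best_weights = net.get_weights()
            else:
                stale += 1
                if patience is not None and stale >= patience:
                    break
    if best_weights is not None:
        net.set_weights(best_weights)
        history["best_epoch"] = best_epoch
        history["best_val_mse"] = best_val
    return history
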