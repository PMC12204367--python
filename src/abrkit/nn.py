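"""Minimal 1-D convolutional network machinery (numpy, CPU).

Implements exactly the pieces the two ABR models need — 1-D convolution
with 'same' padding, batch normalization, ReLU, max pooling, dropout,
dense layers, Adam, and sample-weighted squared-error / binary
cross-entropy losses — with explicit forward/backward passes.  Inputs are
``(N, C, L)`` float32 arrays; training is mini-batch SGD with early
stopping on validation loss and best-epoch weight restoration.

Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger("abrkit")

_EPS = 1e-5


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Cross-correlation with 'same' zero padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init
        W = rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        W, b = self.params
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._cols = sliding_window_view(xp, self.kernel, axis=2)  # (N,C,L,k)
        y = np.einsum("nclk,ock->nol", self._cols, W, optimize=True)
        return y + b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W, _ = self.params
        k, p = self.kernel, self.kernel // 2
        n, c_in, L = self._cols.shape[0], self._cols.shape[1], self._cols.shape[2]
        self.grads[0][...] = np.einsum("nclk,nol->ock", self._cols, dy, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dcols = np.einsum("nol,ock->nclk", dy, W, optimize=True)
        dxp = np.zeros((n, c_in, L + 2 * p), dtype=dy.dtype)
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j]
        return dxp[:, :, p:p + L]


class BatchNorm1d(Layer):
    """Per-channel normalization over the batch and time axes."""

    def __init__(self, channels: int, momentum: float = 0.1) -> None:
        super().__init__()
        self.momentum = momentum
        gamma = np.ones(channels, dtype=np.float32)
        beta = np.zeros(channels, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
        return gamma[None, :, None] * self._xhat + beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        self.grads[0][...] = (dy * self._xhat).sum(axis=(0, 2))
        self.grads[1][...] = dy.sum(axis=(0, 2))
        m = dy.shape[0] * dy.shape[2]
        mean_dy = dy.sum(axis=(0, 2)) / m
        mean_dy_xhat = (dy * self._xhat).sum(axis=(0, 2)) / m
        return (gamma * self._inv_std)[None, :, None] * (
            dy - mean_dy[None, :, None] - self._xhat * mean_dy_xhat[None, :, None]
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing odd sample is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, L = x.shape
        L2 = L // self.size
        self._in_len = L
        xr = x[:, :, :L2 * self.size].reshape(n, c, L2, self.size)
        self._argmax = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, L2 = dy.shape
        dxr = np.zeros((n, c, L2, self.size), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=dy.dtype)
        dx[:, :, :L2 * self.size] = dxr.reshape(n, c, L2 * self.size)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        W, b = self.params
        return x @ W + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ W.T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        out = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[:len(params)]):
            p[...] = s
        i = len(params)
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[i]
                layer.running_var[...] = state[i + 1]
                i += 2


# ---------------------------------------------------------------------------
# Optimizer and losses
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def weighted_mse(pred: np.ndarray, y: np.ndarray,
                 w: np.ndarray) -> tuple[float, np.ndarray]:
    """Sample-weighted squared-error loss and its gradient wrt ``pred``."""
    pred, y = pred.ravel(), y.ravel()
    diff = pred - y
    loss = float(np.mean(w * diff * diff))
    grad = (2.0 * w * diff / len(y)).reshape(-1, 1).astype(np.float32)
    return loss, grad


def weighted_bce_logits(logits: np.ndarray, y: np.ndarray,
                        w: np.ndarray) -> tuple[float, np.ndarray]:
    """Sample-weighted binary cross-entropy on logits, numerically stable."""
    z, y = logits.ravel(), y.ravel()
    loss = float(np.mean(w * (np.logaddexp(0.0, z) - y * z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = (w * (sig - y) / len(y)).reshape(-1, 1).astype(np.float32)
    return loss, grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based
    stopped_epoch: int = 0       # 1-based, last epoch run


def fit(model: Sequential, loss_fn, X: np.ndarray, y: np.ndarray,
        w: np.ndarray, X_val: np.ndarray, y_val: np.ndarray,
        w_val: np.ndarray, *, lr: float = 1e-3, batch_size: int = 64,
        max_epochs: int = 200, patience: int = 25,
        rng: np.random.Generator | None = None) -> FitHistory:
    """Mini-batch Adam with early stopping on validation loss.

    Training halts once the validation loss has failed to improve for
    ``patience`` consecutive epochs; the best-epoch weights (including
    batch-norm running statistics) are restored before returning.
    """
    from .train_eval import EarlyStopper  # local import avoids a cycle at import time

    rng = rng or np.random.default_rng(0)
    X = np.ascontiguousarray(X, dtype=np.float32)
    X_val = np.ascontiguousarray(X_val, dtype=np.float32)
    opt = Adam(model.parameters(), lr=lr)
    stopper = EarlyStopper(patience=patience)
    history = FitHistory()
    best_state = model.state()
    n = len(X)

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            out = model.forward(X[idx], train=True)
            loss, grad = loss_fn(out, y[idx], w[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.backward(grad)
            opt.step(model.gradients())
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / n)

        val_out = model.forward(X_val, train=False)
        val_loss, _ = loss_fn(val_out, y_val, w_val)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.val_loss.append(val_loss)

        if stopper.update(val_loss):
            best_state = model.state()
        if stopper.should_stop:
            break

    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = len(history.val_loss)
    model.load_state(best_state)
    logger.info(
        "training stopped after %d epochs (best epoch %d, val loss %.5g)",
        history.stopped_epoch, history.best_epoch,
        history.val_loss[history.best_epoch - 1],
    )
    return history
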