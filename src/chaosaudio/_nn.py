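"""Minimal seeded neural-network engine (numpy, CPU).

Implements exactly the pieces the chaos CNN needs: 2-D convolution
(im2col + BLAS matmul), batch normalization, ReLU, max pooling,
dense layers, softmax cross-entropy and Adam, with a patience-based
early-stopping training loop.  Everything runs in float32; all
randomness (init, shuffling, validation split) flows from an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

#: Compute dtype for the whole engine.  float32 for speed; tests flip it
#: to float64 for finite-difference gradient checks.
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad: np.ndarray | None = None


class Layer:
    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """5x5 (or kxk) convolution with 'same' zero padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.W = Param(rng.normal(0.0, scale, size=(c_in * k * k, c_out)))
        self.b = Param(np.zeros(c_out))
        self.params = [self.W, self.b]
        self.k = k
        self.c_in, self.c_out = c_in, c_out

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, C * k * k
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        self._shape = x.shape
        cols = self._cols(x)
        self._cols_cache = cols if train else None
        out = cols @ self.W.value + self.b.value
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        k, p = self.k, self.k // 2
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.W.grad = self._cols_cache.T @ dy_flat
        self.b.grad = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.W.value.T).reshape(B, H, W, C, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j]
        self._cols_cache = None
        return dxp[:, :, p : p + H, p : p + W]


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c, dtype=DTYPE)
        self.run_var = np.ones(c, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu
            self.run_var = m * self.run_var + (1 - m) * var
        else:
            mu, var = self.run_mean, self.run_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._xhat, self._ivar = xhat, ivar
        g = self.gamma.value[None, :, None, None]
        return (g * xhat + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (ivar[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)
        self._xhat = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(DTYPE)


class MaxPool(Layer):
    """Square max pooling with stride = size; trailing rows/cols dropped."""

    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.s
        B, C, H, W = x.shape
        self._in_shape = x.shape
        H2, W2 = H // s, W // s
        xr = x[:, :, : H2 * s, : W2 * s].reshape(B, C, H2, s, W2, s)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, s * s)
        self._idx = np.argmax(xr, axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.s
        B, C, H, W = self._in_shape
        H2, W2 = H // s, W // s
        dxr = np.zeros((B, C, H2, W2, s * s), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(B, C, H2, W2, s, s).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W), dtype=DTYPE)
        dx[:, :, : H2 * s, : W2 * s] = dxr.reshape(B, C, H2 * s, W2 * s)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.params = [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad = self._x.T @ dy
        self.b.grad = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.value.T


class ReLU1D(ReLU):
    pass


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.params: list[Param] = [p for lay in layers for p in lay.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy over integer labels; grad w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.maximum(probs[np.arange(n), y], 1e-12))))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.value -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def predict_proba(net: Sequential, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    out = []
    for lo in range(0, X.shape[0], batch_size):
        out.append(softmax(net.forward(X[lo : lo + batch_size], train=False)))
    return np.concatenate(out, axis=0)


def fit(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 64,
    lr: float = 1e-3,
    patience: int = 15,
    max_epochs: int = 60,
) -> list[dict]:
    """Train with Adam + CCE; early-stop on validation accuracy.

    Training halts once validation accuracy has failed to improve for
    ``patience`` consecutive epochs (or at ``max_epochs``); the weights
    from the best epoch are restored.  Returns the per-epoch history.
    """
    opt = Adam(net.params, lr=lr)
    best_acc, best_state, since_best = -1.0, net.state(), 0
    history: list[dict] = []
    n = X.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlogits = cce_loss_and_grad(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = float(
            (predict_proba(net, X_val).argmax(axis=1) == y_val).mean()
        ) if len(y_val) else float("nan")
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
        )
        if len(y_val) and val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, net.state(), 0
        else:
            since_best += 1
            if len(y_val) and since_best >= patience:
                break
    if len(y_val):
        net.load_state(best_state)
    return history
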