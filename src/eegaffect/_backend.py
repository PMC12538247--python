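"""NumPy layer implementations: gated recurrent cells, dropout, dense, Adam.

All arithmetic is float32.  A gated recurrent (LSTM) cell follows the
standard formulation with input, forget and output gates and a cell state:

    z_t = x_t Wx + h_{t-1} Wh + b          (gates packed as [i, f, g, o])
    i, f, o = sigmoid(.), g = tanh(.)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)

giving 4*h*(d + h + 1) trainable parameters for input width d and h units.
A bidirectional wrapper runs an independent backward-time cell and
concatenates per-step outputs, doubling the count.  Backpropagation through
time accumulates gate deltas over the full sequence and reduces the weight
gradients with two matrix products.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

F32 = np.float32


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((rows, cols))
    q, r = np.linalg.qr(a if rows >= cols else a.T)
    q = q if rows >= cols else q.T
    return (q * np.sign(np.diag(r))[: min(rows, cols)]).astype(F32)


def _glorot(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (rows + cols))
    return rng.uniform(-limit, limit, size=(rows, cols)).astype(F32)


class Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class LSTM(Layer):
    """Unidirectional gated recurrent layer over (batch, time, features) input.

    ``return_sequences`` returns all per-step hidden states (batch, T, h);
    otherwise only the final state (batch, h).  ``go_backwards`` processes
    the sequence in reverse time order and re-reverses sequence output, so a
    bidirectional pair aligns step-for-step.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True, go_backwards: bool = False,
                 name: str = "lstm"):
        self.input_dim, self.units = int(input_dim), int(units)
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.name = name
        h, d = self.units, self.input_dim
        self.Wx = _glorot(rng, d, 4 * h)
        # per-gate orthogonal blocks keep the recurrence well conditioned
        self.Wh = np.concatenate([_orthogonal(rng, h, h) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * h, F32)
        self.b[h : 2 * h] = 1.0  # forget-gate bias at 1: remember by default
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return {f"{self.name}.Wx": self.Wx, f"{self.name}.Wh": self.Wh,
                f"{self.name}.b": self.b}

    def gradients(self):
        return {f"{self.name}.Wx": self.dWx, f"{self.name}.Wh": self.dWh,
                f"{self.name}.b": self.db}

    def forward(self, x, train, rng):
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ValidationError(
                f"{self.name}: expected (batch, time, {self.input_dim}) input, "
                f"got shape {x.shape}"
            )
        if self.go_backwards:
            x = x[:, ::-1]
        B, T, _ = x.shape
        h = self.units
        pre = (x.reshape(B * T, -1).astype(F32, copy=False) @ self.Wx).reshape(B, T, 4 * h)
        H = np.empty((B, T, h), F32)
        C = np.empty((B, T, h), F32)
        gates = np.empty((B, T, 4 * h), F32)
        ht = np.zeros((B, h), F32)
        ct = np.zeros((B, h), F32)
        for t in range(T):
            z = pre[:, t] + ht @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            ct = f * ct + i * g
            ht = o * np.tanh(ct)
            gates[:, t, :h] = i
            gates[:, t, h : 2 * h] = f
            gates[:, t, 2 * h : 3 * h] = g
            gates[:, t, 3 * h :] = o
            C[:, t] = ct
            H[:, t] = ht
        if train:
            self._cache = (x, gates, C, H)
        if self.return_sequences:
            return H[:, ::-1] if self.go_backwards else H
        return H[:, -1]

    def backward(self, dy):
        x, gates, C, H = self._cache
        B, T, _ = x.shape
        h = self.units
        if self.return_sequences:
            dH = dy[:, ::-1] if self.go_backwards else dy
            dH = dH.astype(F32, copy=True)
        else:
            dH = np.zeros((B, T, h), F32)
            dH[:, -1] = dy
        tanh_c = np.tanh(C)
        dZ = np.empty((B, T, 4 * h), F32)
        dc_next = np.zeros((B, h), F32)
        dh_next = np.zeros((B, h), F32)
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + dh_next
            i = gates[:, t, :h]
            f = gates[:, t, h : 2 * h]
            g = gates[:, t, 2 * h : 3 * h]
            o = gates[:, t, 3 * h :]
            tc = tanh_c[:, t]
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, h), F32)
            dz = dZ[:, t]
            dz[:, :h] = dc * g * i * (1.0 - i)
            dz[:, h : 2 * h] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * h : 3 * h] = dc * i * (1.0 - g * g)
            dz[:, 3 * h :] = dh * tc * o * (1.0 - o)
            dc_next = dc * f
            dh_next = dz @ self.Wh.T
        h_prev = np.concatenate([np.zeros((B, 1, h), F32), H[:, :-1]], axis=1)
        dZ_flat = dZ.reshape(B * T, 4 * h)
        self.dWx[...] = x.reshape(B * T, -1).T @ dZ_flat
        self.dWh[...] = h_prev.reshape(B * T, h).T @ dZ_flat
        self.db[...] = dZ_flat.sum(axis=0)
        dx = (dZ_flat @ self.Wx.T).reshape(B, T, self.input_dim)
        return dx[:, ::-1] if self.go_backwards else dx


class Bidirectional(Layer):
    """Forward and independent backward cells with concatenated outputs."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True, name: str = "bilstm"):
        self.units = int(units)
        self.return_sequences = return_sequences
        self.name = name
        self.fwd = LSTM(input_dim, units, rng, return_sequences=return_sequences,
                        go_backwards=False, name=f"{name}.fwd")
        self.bwd = LSTM(input_dim, units, rng, return_sequences=return_sequences,
                        go_backwards=True, name=f"{name}.bwd")

    def parameters(self):
        return {**self.fwd.parameters(), **self.bwd.parameters()}

    def gradients(self):
        return {**self.fwd.gradients(), **self.bwd.gradients()}

    def forward(self, x, train, rng):
        yf = self.fwd.forward(x, train, rng)
        yb = self.bwd.forward(x, train, rng)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        h = self.units
        dxf = self.fwd.backward(dy[..., :h])
        dxb = self.bwd.backward(dy[..., h:])
        return dxf + dxb


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        if not (0.0 <= rate < 1.0):
            raise ValidationError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = float(rate)
        self.name = name
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    """Fully connected layer on (batch, features) input; logits output.

    The softmax lives in the loss (fused softmax/cross-entropy) and in
    ``predict_proba``; numerically this is the standard arrangement.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.input_dim, self.units = int(input_dim), int(units)
        self.name = name
        self.W = _glorot(rng, self.input_dim, self.units)
        self.b = np.zeros(self.units, F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def parameters(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def gradients(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x, train, rng):
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValidationError(
                f"{self.name}: expected (batch, {self.input_dim}) input, got {x.shape}"
            )
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(F32)


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                for g in grads.values()))
            if total > self.clip_norm:
                scale = F32(self.clip_norm / (total + 1e-12))
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
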