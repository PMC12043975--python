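"""Minimal NumPy neural-network layer: LSTM, affine maps, AdamW.

Only what the forecaster and annotator need, with hand-derived gradients.
Conventions follow the common deep-learning defaults: gate order (input,
forget, cell, output), dual bias vectors per recurrent layer (so an LSTM
with input size I and hidden size H holds 4*H*(I+H+2) trainable scalars),
and uniform(-1/sqrt(fan), 1/sqrt(fan)) initialization.

Sequences are laid out time-major, ``(T, B, features)``.  Batches of
variable-length prefixes are left-padded and accompanied by a ``(T, B)``
mask; masked steps leave the recurrent state untouched and contribute no
gradient.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


class Linear:
    """Affine map y = x W^T + b with weight ``(out, in)``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        self.n_in, self.n_out = n_in, n_out
        k = 1.0 / np.sqrt(n_in)
        if rng is None:
            self.weight = np.zeros((n_out, n_in))
            self.bias = np.zeros(n_out)
        else:
            self.weight = rng.uniform(-k, k, size=(n_out, n_in))
            self.bias = rng.uniform(-k, k, size=n_out)

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weight.T + self.bias

    def backward(self, x: np.ndarray, dy: np.ndarray):
        """Returns (dx, dweight, dbias) for a batch of rows."""
        return dy @ self.weight, dy.T @ x, dy.sum(axis=0)

    def parameters(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.weight": self.weight, f"{prefix}.bias": self.bias}

    def load(self, prefix: str, tensors: dict[str, np.ndarray]) -> None:
        self.weight = tensors[f"{prefix}.weight"].copy()
        self.bias = tensors[f"{prefix}.bias"].copy()


class LSTM:
    """Single-layer LSTM with dual biases and masked batched BPTT."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator | None = None):
        self.n_in, self.n_hidden = n_in, n_hidden
        shape_ih = (4 * n_hidden, n_in)
        shape_hh = (4 * n_hidden, n_hidden)
        if rng is None:
            self.w_ih = np.zeros(shape_ih)
            self.w_hh = np.zeros(shape_hh)
            self.b_ih = np.zeros(4 * n_hidden)
            self.b_hh = np.zeros(4 * n_hidden)
        else:
            k = 1.0 / np.sqrt(n_hidden)
            self.w_ih = rng.uniform(-k, k, size=shape_ih)
            self.w_hh = rng.uniform(-k, k, size=shape_hh)
            self.b_ih = rng.uniform(-k, k, size=4 * n_hidden)
            self.b_hh = rng.uniform(-k, k, size=4 * n_hidden)

    @property
    def n_params(self) -> int:
        return self.w_ih.size + self.w_hh.size + self.b_ih.size + self.b_hh.size

    def _gates(self, x: np.ndarray, h: np.ndarray):
        pre = x @ self.w_ih.T + h @ self.w_hh.T + (self.b_ih + self.b_hh)
        H = self.n_hidden
        i = sigmoid(pre[:, :H])
        f = sigmoid(pre[:, H : 2 * H])
        g = np.tanh(pre[:, 2 * H : 3 * H])
        o = sigmoid(pre[:, 3 * H :])
        return i, f, g, o

    def step(self, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One recurrence step without caching (generation-time use)."""
        i, f, g, o = self._gates(x, h)
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        return h_new, c_new

    def forward(
        self,
        xs: np.ndarray,
        mask: np.ndarray | None = None,
        h0: np.ndarray | None = None,
        c0: np.ndarray | None = None,
    ):
        """Run the recurrence over ``xs`` of shape (T, B, n_in).

        Returns ``(hs, (h, c), cache)``: ``hs`` is (T, B, H) — the carried
        state after each step — ``(h, c)`` the final hidden/cell state, and
        ``cache`` feeds :meth:`backward`.
        """
        T, B, _ = xs.shape
        H = self.n_hidden
        h = np.zeros((B, H)) if h0 is None else h0.copy()
        c = np.zeros((B, H)) if c0 is None else c0.copy()
        hs = np.empty((T, B, H))
        cache = []
        for t in range(T):
            x = xs[t]
            i, f, g, o = self._gates(x, h)
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if mask is not None:
                m = mask[t][:, None]
                h_next = m * h_new + (1.0 - m) * h
                c_next = m * c_new + (1.0 - m) * c
            else:
                m = None
                h_next, c_next = h_new, c_new
            cache.append((x, h, c, i, f, g, o, c_new, tc, m))
            h, c = h_next, c_next
            hs[t] = h
        return hs, (h, c), cache

    def backward(
        self,
        cache,
        dh_last: np.ndarray | None = None,
        dhs: np.ndarray | None = None,
    ):
        """Backpropagate through time.

        ``dh_last`` is the gradient w.r.t. the final carried state; ``dhs``
        (T, B, H) adds gradients w.r.t. each step's carried state.  Returns a
        dict of parameter gradients.
        """
        H = self.n_hidden
        B = cache[0][0].shape[0]
        dw_ih = np.zeros_like(self.w_ih)
        dw_hh = np.zeros_like(self.w_hh)
        db = np.zeros(4 * H)
        dh_carry = np.zeros((B, H)) if dh_last is None else dh_last.copy()
        dc_carry = np.zeros((B, H))
        for t in range(len(cache) - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tc, m = cache[t]
            dh_total = dh_carry if dhs is None else dh_carry + dhs[t]
            if m is not None:
                dh_new = dh_total * m
                dh_pass = dh_total * (1.0 - m)
                dc_new_in = dc_carry * m
                dc_pass = dc_carry * (1.0 - m)
            else:
                dh_new, dh_pass = dh_total, 0.0
                dc_new_in, dc_pass = dc_carry, 0.0
            do = dh_new * tc
            dc_new = dc_new_in + dh_new * o * (1.0 - tc * tc)
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dc_prev = dc_new * f + dc_pass
            dpre = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dw_ih += dpre.T @ x
            dw_hh += dpre.T @ h_prev
            db += dpre.sum(axis=0)
            dh_carry = dh_pass + dpre @ self.w_hh
            dc_carry = dc_prev
        # dual biases receive identical gradients
        return {"w_ih": dw_ih, "w_hh": dw_hh, "b_ih": db, "b_hh": db.copy()}

    def parameters(self, prefix: str) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.w_ih": self.w_ih,
            f"{prefix}.w_hh": self.w_hh,
            f"{prefix}.b_ih": self.b_ih,
            f"{prefix}.b_hh": self.b_hh,
        }

    def load(self, prefix: str, tensors: dict[str, np.ndarray]) -> None:
        self.w_ih = tensors[f"{prefix}.w_ih"].copy()
        self.w_hh = tensors[f"{prefix}.w_hh"].copy()
        self.b_ih = tensors[f"{prefix}.b_ih"].copy()
        self.b_hh = tensors[f"{prefix}.b_hh"].copy()


class AdamW:
    """AdamW with decoupled, per-component weight decay.

    ``params`` maps names to arrays updated in place; ``weight_decay`` maps a
    name prefix (the component, e.g. ``"encoder"``) to its decay rate.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        weight_decay: dict[str, float] | None = None,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay or {}
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def _decay_for(self, name: str) -> float:
        component = name.split(".", 1)[0]
        return self.weight_decay.get(component, 0.0)

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            wd = self._decay_for(name)
            if wd:
                p -= self.lr * wd * p
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
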