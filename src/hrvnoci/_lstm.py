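"""Minimal single-layer LSTM binary sequence classifier in numpy.

Forward pass, backpropagation through time and Adam are written out by hand;
the model is deliberately tiny (scalar input, one LSTM layer, sigmoid output
on the final hidden state) and fully deterministic given its seed.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class TinyLSTM:
    """Single-layer LSTM, scalar input per step, binary sigmoid head.

    Parameters are packed as W_x (1 x 4H), W_h (H x 4H), b (4H) with gate
    order [input, forget, cell, output], plus a linear readout (w_out, b_out)
    on the final hidden state.
    """

    def __init__(self, hidden_size: int = 16, seed: int = 0,
                 forget_bias: float = 1.0):
        self.hidden = hidden_size
        self.forget_bias = forget_bias
        rng = np.random.default_rng(seed)
        h = hidden_size
        scale = 1.0 / np.sqrt(h)
        self.params = {
            "Wx": rng.normal(0.0, scale, size=(1, 4 * h)),
            "Wh": rng.normal(0.0, scale, size=(h, 4 * h)),
            "b": np.zeros(4 * h),
            "w_out": rng.normal(0.0, scale, size=h),
            "b_out": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, keep_cache: bool):
        """X: (B, T) scalar sequences. Returns probabilities (B,) [+ cache]."""
        B, T = X.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = [] if keep_cache else None
        for t in range(T):
            x_t = X[:, t : t + 1]                       # (B, 1)
            z = x_t @ Wx + h @ Wh + b                   # (B, 4H)
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H] + self.forget_bias)
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if keep_cache:
                cache.append((x_t, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        logit = h @ self.params["w_out"] + self.params["b_out"][0]
        prob = _sigmoid(logit)
        if keep_cache:
            return prob, (cache, h)
        return prob

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float), keep_cache=False)

    # -- training ----------------------------------------------------------

    def _backward(self, X: np.ndarray, y: np.ndarray, prob: np.ndarray,
                  cache_pack) -> dict[str, np.ndarray]:
        cache, h_T = cache_pack
        B, T = X.shape
        H = self.hidden
        Wh = self.params["Wh"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        dlogit = (prob - y) / B                          # dBCE/dlogit, (B,)
        grads["w_out"] = h_T.T @ dlogit
        grads["b_out"][0] = dlogit.sum()
        dh = np.outer(dlogit, self.params["w_out"])      # (B, H)
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )                                            # (B, 4H)
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ Wh.T
            dc = dc * f
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k]
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g**2
            m_hat = self._adam_m[k] / (1 - beta1**t)
            v_hat = self._adam_v[k] / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and parameter gradients (for training
        and for finite-difference verification)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        prob, cache_pack = self._forward(X, keep_cache=True)
        p = np.clip(prob, 1e-12, 1.0 - 1e-12)
        loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return loss, self._backward(X, y, prob, cache_pack)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 50,
            lr: float = 0.02) -> list[float]:
        """Full-batch Adam training; returns the per-epoch loss trace."""
        losses = []
        for _ in range(epochs):
            loss, grads = self.loss_and_grads(X, y)
            self._adam_step(grads, lr)
            losses.append(loss)
        return losses
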