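"""Single-layer LSTM with backpropagation through time."""

from __future__ import annotations

import numpy as np

from dstan.nn.layers import Module, Parameter


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Module):
    """Standard LSTM; consumes (t, N, d), returns the hidden states (t, N, h).

    Gate order in the stacked weight matrices is input, forget, cell, output.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.input_size = input_size
        self.hidden_size = hidden_size
        sx = np.sqrt(1.0 / input_size)
        sh = np.sqrt(1.0 / hidden_size)
        self.w_x = Parameter((rng.standard_normal((4 * hidden_size, input_size)) * sx
                              ).astype(dtype))
        self.w_h = Parameter((rng.standard_normal((4 * hidden_size, hidden_size)) * sh
                              ).astype(dtype))
        self.bias = Parameter(np.zeros(4 * hidden_size, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        t, n, _ = x.shape
        hs_dim = self.hidden_size
        h = np.zeros((n, hs_dim), dtype=x.dtype)
        c = np.zeros((n, hs_dim), dtype=x.dtype)
        steps = []
        hs = np.empty((t, n, hs_dim), dtype=x.dtype)
        for k in range(t):
            z = x[k] @ self.w_x.data.T + h @ self.w_h.data.T + self.bias.data
            i = _sigmoid(z[:, :hs_dim])
            f = _sigmoid(z[:, hs_dim : 2 * hs_dim])
            g = np.tanh(z[:, 2 * hs_dim : 3 * hs_dim])
            o = _sigmoid(z[:, 3 * hs_dim :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[k] = h
            steps.append((x[k], h_prev, c_prev, i, f, g, o, tc))
        self._cache = steps
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        steps = self._cache
        t = len(steps)
        n = dhs.shape[1]
        hs_dim = self.hidden_size
        dx = np.empty((t, n, self.input_size), dtype=dhs.dtype)
        dh_next = np.zeros((n, hs_dim), dtype=dhs.dtype)
        dc_next = np.zeros((n, hs_dim), dtype=dhs.dtype)
        for k in range(t - 1, -1, -1):
            x_k, h_prev, c_prev, i, f, g, o, tc = steps[k]
            dh = dhs[k] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            self.w_x.grad += dz.T @ x_k
            self.w_h.grad += dz.T @ h_prev
            self.bias.grad += dz.sum(axis=0)
            dx[k] = dz @ self.w_x.data
            dh_next = dz @ self.w_h.data
        return dx
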