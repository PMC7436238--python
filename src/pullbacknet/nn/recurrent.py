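"""Stacked LSTM and GRU layers with backpropagation through time.

Sequences are batch-first ``(N, T, input)``.  State is a list with one entry
per layer: an ``(h, c)`` pair for the LSTM, a bare ``h`` for the GRU, each of
shape ``(N, hidden)``.  ``None`` means the all-zero state, so a whole video
can be processed either in one call or chunk-by-chunk with the carried state.

Gate conventions match the common (i, f, g, o) and (r, z, n) packings:

    LSTM:  i, f, o = sigmoid;  g = tanh;  c' = f*c + i*g;  h' = o*tanh(c')
    GRU:   r, z = sigmoid;  n = tanh(W_in x + b_in + r*(W_hn h + b_hn));
           h' = (1 - z)*n + z*h
"""

from __future__ import annotations

import numpy as np

from .layers import Module, Param


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp may overflow for strongly negative inputs; the result still
    # saturates to exactly 0, so the warning is suppressed, not the math
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _uniform(rng: np.random.Generator, shape, bound: float, dtype) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class _LSTMLayer(Module):
    def __init__(self, nin: int, nh: int, *, rng: np.random.Generator, dtype):
        b = 1.0 / np.sqrt(nh)
        self.nh = nh
        self.W_ih = Param("W_ih", _uniform(rng, (4 * nh, nin), b, dtype))
        self.W_hh = Param("W_hh", _uniform(rng, (4 * nh, nh), b, dtype))
        self.b = Param("b", _uniform(rng, (4 * nh,), b, dtype))
        self._cache = None

    def forward(self, x: np.ndarray, state):
        N, T, _ = x.shape
        nh = self.nh
        if state is None:
            h = np.zeros((N, nh), dtype=x.dtype)
            c = np.zeros((N, nh), dtype=x.dtype)
        else:
            h, c = state
        gates, cs, tanh_cs, h_prevs, c_prevs = [], [], [], [], []
        ys = np.empty((N, T, nh), dtype=x.dtype)
        for t in range(T):
            z = x[:, t] @ self.W_ih.value.T + h @ self.W_hh.value.T + self.b.value
            i = _sigmoid(z[:, :nh])
            f = _sigmoid(z[:, nh:2 * nh])
            g = np.tanh(z[:, 2 * nh:3 * nh])
            o = _sigmoid(z[:, 3 * nh:])
            h_prevs.append(h)
            c_prevs.append(c)
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            ys[:, t] = h
            gates.append((i, f, g, o))
            cs.append(c)
            tanh_cs.append(tc)
        self._cache = (x, gates, cs, tanh_cs, h_prevs, c_prevs)
        return ys, (h, c)

    def backward(self, dy: np.ndarray, dstate=None) -> np.ndarray:
        x, gates, cs, tanh_cs, h_prevs, c_prevs = self._cache
        N, T, _ = x.shape
        nh = self.nh
        if dstate is None:
            dh_next = np.zeros((N, nh), dtype=x.dtype)
            dc_next = np.zeros((N, nh), dtype=x.dtype)
        else:
            dh_next, dc_next = dstate
        dx = np.empty_like(x)
        for t in range(T - 1, -1, -1):
            i, f, g, o = gates[t]
            tc = tanh_cs[t]
            dh = dy[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.concatenate(
                [
                    dc * g * i * (1.0 - i),
                    dc * c_prevs[t] * f * (1.0 - f),
                    dc * i * (1.0 - g * g),
                    dh * tc * o * (1.0 - o),
                ],
                axis=1,
            )
            self.W_ih.grad += dz.T @ x[:, t]
            self.W_hh.grad += dz.T @ h_prevs[t]
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.W_ih.value
            dh_next = dz @ self.W_hh.value
            dc_next = dc * f
        self._cache = None
        return dx


class _GRULayer(Module):
    def __init__(self, nin: int, nh: int, *, rng: np.random.Generator, dtype):
        b = 1.0 / np.sqrt(nh)
        self.nh = nh
        self.W_ih = Param("W_ih", _uniform(rng, (3 * nh, nin), b, dtype))
        self.W_hh = Param("W_hh", _uniform(rng, (3 * nh, nh), b, dtype))
        self.b_ih = Param("b_ih", _uniform(rng, (3 * nh,), b, dtype))
        self.b_hh = Param("b_hh", _uniform(rng, (3 * nh,), b, dtype))
        self._cache = None

    def forward(self, x: np.ndarray, state):
        N, T, _ = x.shape
        nh = self.nh
        h = np.zeros((N, nh), dtype=x.dtype) if state is None else state
        steps = []
        ys = np.empty((N, T, nh), dtype=x.dtype)
        for t in range(T):
            gi = x[:, t] @ self.W_ih.value.T + self.b_ih.value
            gh = h @ self.W_hh.value.T + self.b_hh.value
            r = _sigmoid(gi[:, :nh] + gh[:, :nh])
            z = _sigmoid(gi[:, nh:2 * nh] + gh[:, nh:2 * nh])
            hn = gh[:, 2 * nh:]
            n = np.tanh(gi[:, 2 * nh:] + r * hn)
            h_prev = h
            h = (1.0 - z) * n + z * h
            ys[:, t] = h
            steps.append((r, z, n, hn, h_prev))
        self._cache = (x, steps)
        return ys, h

    def backward(self, dy: np.ndarray, dstate=None) -> np.ndarray:
        x, steps = self._cache
        N, T, _ = x.shape
        nh = self.nh
        dh_next = np.zeros((N, nh), dtype=x.dtype) if dstate is None else dstate
        dx = np.empty_like(x)
        for t in range(T - 1, -1, -1):
            r, z, n, hn, h_prev = steps[t]
            dh = dy[:, t] + dh_next
            dn_pre = dh * (1.0 - z) * (1.0 - n * n)
            dz_pre = dh * (h_prev - n) * z * (1.0 - z)
            dr_pre = dn_pre * hn * r * (1.0 - r)
            d_gi = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            d_gh = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
            self.W_ih.grad += d_gi.T @ x[:, t]
            self.b_ih.grad += d_gi.sum(axis=0)
            self.W_hh.grad += d_gh.T @ h_prev
            self.b_hh.grad += d_gh.sum(axis=0)
            dx[:, t] = d_gi @ self.W_ih.value
            dh_next = dh * z + d_gh @ self.W_hh.value
        self._cache = None
        return dx


class _StackedRNN(Module):
    layer_cls: type

    def __init__(self, input_size: int, hidden_size: int, num_layers: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.layers = [
            self.layer_cls(input_size if i == 0 else hidden_size, hidden_size,
                           rng=rng, dtype=dtype)
            for i in range(num_layers)
        ]

    def forward(self, x: np.ndarray, state=None):
        """Run the stack; ``state`` is a per-layer list (None = zeros)."""
        if state is None:
            state = [None] * self.num_layers
        if len(state) != self.num_layers:
            raise ValueError(f"state must have {self.num_layers} per-layer entries")
        new_state = []
        y = x
        for layer, s in zip(self.layers, state):
            y, s_out = layer.forward(y, s)
            new_state.append(s_out)
        return y, new_state

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class LSTM(_StackedRNN):
    layer_cls = _LSTMLayer


class GRU(_StackedRNN):
    layer_cls = _GRULayer
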