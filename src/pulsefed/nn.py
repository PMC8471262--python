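"""Minimal float32 neural-network layers with hand-written backpropagation.

This backend exists so the waveform-translation GAN can train on a plain
CPU stack: stacked LSTM layers for the sequence generators, 1-D
convolution / max-pooling / dense layers for the discriminators, and an
Adam optimizer.  Every layer exposes ``forward(x) -> (y, cache)`` and
``backward(dy, cache) -> (dx, grads)`` where ``grads`` maps parameter
names to arrays shaped like the parameters.  Parameters live in per-layer
``params`` dicts so whole networks can be exported/imported as flat
name -> array mappings (the weight sets exchanged in federated training).

The recurrent layers use a time-major layout ``(T, B, D)`` internally:
the per-timestep recurrence is the hot loop on CPU, so its body is written
with preallocated buffers and ``out=`` ufunc calls only.  Everything is
float32 and deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically safe for float32: exp overflow saturates to 0/1 anyway
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def uniform_init(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape).astype(F32)


class LSTM:
    """Single LSTM layer, time-major input (T, B, D) -> hidden states (T, B, H).

    Gate packing order along the 4H axis is [input, forget, output, cell]
    so the three sigmoid gates occupy one contiguous block.  The forget
    gate bias is initialised to 1 (standard remedy for early gradient
    vanishing through the cell state).
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        D, H = input_dim, hidden_dim
        k = 1.0 / np.sqrt(H)
        self.D, self.H = D, H
        b = uniform_init(rng, 4 * H, k)
        b[H : 2 * H] += 1.0  # forget gate
        self.params = {
            "Wx": uniform_init(rng, (D, 4 * H), k),
            "Wh": uniform_init(rng, (H, 4 * H), k),
            "b": b,
        }

    def forward(self, x: np.ndarray):
        from . import _lstm_kernels

        T, B, D = x.shape
        H = self.H
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        # input contribution for all timesteps in one GEMM; the kernel then
        # overwrites the buffer in place with post-activation gate values
        gates = (x.reshape(T * B, D) @ Wx).reshape(T, B, 4 * H)
        gates += b
        cells = np.empty((T, B, H), dtype=F32)
        tanhc = np.empty((T, B, H), dtype=F32)
        hs = np.empty((T, B, H), dtype=F32)
        rec = np.empty((B, 4 * H), dtype=F32)
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        for t in range(T):
            a = gates[t]
            np.dot(h, Wh, out=rec)
            a += rec
            _lstm_kernels.step_forward(a, c, cells[t], tanhc[t], hs[t])
            h = hs[t]
            c = cells[t]
        cache = (x, gates, cells, tanhc, hs)
        return hs, cache

    def backward(self, dy: np.ndarray, cache, need_param_grads: bool = True):
        from . import _lstm_kernels

        x, gates, cells, tanhc, hs = cache
        T, B, D = x.shape
        H = self.H
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        WhT = np.ascontiguousarray(Wh.T)
        dA = np.empty((T, B, 4 * H), dtype=F32)
        dy = np.ascontiguousarray(dy, dtype=F32)
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        zeros = np.zeros((B, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            c_prev = cells[t - 1] if t > 0 else zeros
            _lstm_kernels.step_backward(gates[t], tanhc[t], c_prev, dy[t],
                                        dh_next, dc_next, dA[t])
            np.dot(dA[t], WhT, out=dh_next)
        dA_flat = dA.reshape(T * B, 4 * H)
        dx = (dA_flat @ Wx.T).reshape(T, B, D)
        grads = {}
        if need_param_grads:
            h_prev = np.empty((T, B, H), dtype=F32)
            h_prev[0] = 0.0
            h_prev[1:] = hs[:-1]
            grads = {
                "Wx": x.reshape(T * B, D).T @ dA_flat,
                "Wh": h_prev.reshape(T * B, H).T @ dA_flat,
                "b": dA_flat.sum(axis=0),
            }
        return dx, grads


class TimeDense:
    """Per-timestep affine map (T, B, D) -> (T, B, F)."""

    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(input_dim)
        self.D, self.F = input_dim, output_dim
        self.params = {
            "W": uniform_init(rng, (input_dim, output_dim), k),
            "b": np.zeros(output_dim, dtype=F32),
        }

    def forward(self, x: np.ndarray):
        T, B, D = x.shape
        y = x.reshape(T * B, D) @ self.params["W"] + self.params["b"]
        return y.reshape(T, B, self.F), x

    def backward(self, dy: np.ndarray, cache, need_param_grads: bool = True):
        x = cache
        T, B, D = x.shape
        dy_flat = dy.reshape(T * B, self.F)
        grads = {}
        if need_param_grads:
            grads = {"W": x.reshape(T * B, D).T @ dy_flat, "b": dy_flat.sum(axis=0)}
        dx = (dy_flat @ self.params["W"].T).reshape(T, B, D)
        return dx, grads


class Dense:
    """Plain affine map (B, D) -> (B, F)."""

    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(input_dim)
        self.D, self.F = input_dim, output_dim
        self.params = {
            "W": uniform_init(rng, (input_dim, output_dim), k),
            "b": np.zeros(output_dim, dtype=F32),
        }

    def forward(self, x: np.ndarray):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dy: np.ndarray, cache, need_param_grads: bool = True):
        x = cache
        grads = {}
        if need_param_grads:
            grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T, grads


class Conv1d:
    """1-D convolution, stride 1, zero 'same' padding: (B, C, L) -> (B, F, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        assert kernel % 2 == 1
        k = 1.0 / np.sqrt(in_channels * kernel)
        self.C, self.F, self.K = in_channels, out_channels, kernel
        self.params = {
            "W": uniform_init(rng, (out_channels, in_channels, kernel), k),
            "b": np.zeros(out_channels, dtype=F32),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        p = self.K // 2
        xp = np.zeros((B, C, L + 2 * p), dtype=F32)
        xp[:, :, p : p + L] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, self.K, axis=2)
        # (B, C, L, K) -> (B*L, C*K)
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, C * self.K)

    def forward(self, x: np.ndarray):
        B, C, L = x.shape
        cols = self._im2col(x)
        Wf = self.params["W"].reshape(self.F, C * self.K)
        y = cols @ Wf.T + self.params["b"]
        y = np.ascontiguousarray(y.reshape(B, L, self.F).transpose(0, 2, 1))
        return y, (cols, x.shape)

    def backward(self, dy: np.ndarray, cache, need_param_grads: bool = True):
        cols, (B, C, L) = cache
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, self.F)
        Wf = self.params["W"].reshape(self.F, C * self.K)
        grads = {}
        if need_param_grads:
            grads = {
                "W": (dy_flat.T @ cols).reshape(self.F, C, self.K),
                "b": dy_flat.sum(axis=0),
            }
        dcols = (dy_flat @ Wf).reshape(B, L, C, self.K)
        p = self.K // 2
        dxp = np.zeros((B, C, L + 2 * p), dtype=F32)
        for k in range(self.K):
            dxp[:, :, k : k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, p : p + L], grads


class MaxPool1d:
    """Non-overlapping max pooling, width 2; odd trailing sample dropped."""

    def forward(self, x: np.ndarray):
        B, C, L = x.shape
        Lp = L // 2
        x0 = x[:, :, 0 : 2 * Lp : 2]
        x1 = x[:, :, 1 : 2 * Lp : 2]
        left = x0 >= x1
        y = np.where(left, x0, x1)
        return y, (left, (B, C, L))

    def backward(self, dy: np.ndarray, cache, need_param_grads: bool = True):
        left, (B, C, L) = cache
        Lp = L // 2
        dx = np.zeros((B, C, L), dtype=F32)
        dx[:, :, 0 : 2 * Lp : 2] = np.where(left, dy, 0.0)
        dx[:, :, 1 : 2 * Lp : 2] = np.where(left, 0.0, dy)
        return dx, {}


class ReLU:
    def forward(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy: np.ndarray, mask, need_param_grads: bool = True):
        return dy * mask, {}


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, lr: float = 2e-3, beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for name, g in grads.items():
            g = g.astype(F32, copy=False)
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[name] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f wrt array x (test utility)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        old = x[ix]
        x[ix] = old + eps
        fp = f()
        x[ix] = old - eps
        fm = f()
        x[ix] = old
        g[ix] = (fp - fm) / (2 * eps)
    return g
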