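"""A small, deterministic numpy 1-D CNN for raw-clip classification.

conv('same', stride 1) -> ReLU -> maxpool blocks, then dense ReLU layers
with inverted dropout, and a softmax output trained with class-weighted
cross-entropy and Adam. Everything is seeded: training is bit-reproducible
on a single thread. Sized for the clip-scale problems in this package
(hundreds to a few thousand examples of ~312 x 6), not for large-scale
deep learning.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_windows(x: np.ndarray, kernel: int) -> np.ndarray:
    """(B, L, Cin) -> (B, L, Cin, K) sliding windows with 'same' padding."""
    pad_l = (kernel - 1) // 2
    pad_r = kernel - 1 - pad_l
    xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    return sliding_window_view(xp, kernel, axis=1)


class NumpyCNN:
    """conv/pool feature extractor + dense head, numpy only.

    Parameters mirror the architecture description: ``conv`` is a list of
    (kernel, filters, pool) triples, ``dense`` a list of widths; the output
    is a softmax over ``n_classes``.
    """

    def __init__(self, input_samples: int, input_channels: int,
                 conv=((32, 16, 4), (16, 32, 6)), dense=(32, 32),
                 n_classes: int = 2, dropout: float = 0.5, seed: int = 0):
        self.input_samples = int(input_samples)
        self.input_channels = int(input_channels)
        self.conv_spec = [tuple(int(v) for v in c) for c in conv]
        self.dense_spec = [int(d) for d in dense]
        self.n_classes = int(n_classes)
        self.dropout = float(dropout)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        L, C = self.input_samples, self.input_channels
        for i, (k, f, p) in enumerate(self.conv_spec):
            self.params[f"Wc{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / (k * C)), size=(k, C, f))
            self.params[f"bc{i}"] = np.zeros(f)
            L, C = L // p, f
            if L < 1:
                raise ValueError("pooled length collapsed below 1 sample")
        dim = L * C
        self.flat_dim = dim
        for i, d in enumerate(self.dense_spec):
            self.params[f"Wd{i}"] = rng.normal(0.0, np.sqrt(2.0 / dim), size=(dim, d))
            self.params[f"bd{i}"] = np.zeros(d)
            dim = d
        self.params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / dim),
                                       size=(dim, self.n_classes))
        self.params["bo"] = np.zeros(self.n_classes)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # ---------------------------------------------------------------- forward

    def _forward(self, x: np.ndarray, train: bool,
                 rng: np.random.Generator | None):
        cache = {"x": x, "conv": [], "dense": []}
        h = x
        for i, (k, f, p) in enumerate(self.conv_spec):
            win = _conv_windows(h, k)                       # (B, L, Cin, K)
            z = np.tensordot(win, self.params[f"Wc{i}"],
                             axes=([2, 3], [1, 0])) + self.params[f"bc{i}"]
            a = np.maximum(z, 0.0)
            B, L, F = a.shape
            Lp = L // p
            t = a[:, :Lp * p].reshape(B, Lp, p, F)
            arg = t.argmax(axis=2)
            h = np.take_along_axis(t, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache["conv"].append((win, z, a.shape, arg))
        B = h.shape[0]
        h = h.reshape(B, -1)
        for i in range(len(self.dense_spec)):
            z = h @ self.params[f"Wd{i}"] + self.params[f"bd{i}"]
            a = np.maximum(z, 0.0)
            if train and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
            else:
                mask = None
            cache["dense"].append((h, z, mask))
            h = a * mask if mask is not None else a
        logits = h @ self.params["Wo"] + self.params["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache["head"] = h
        return probs, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = [self._forward(x[i:i + batch_size], train=False, rng=None)[0]
               for i in range(0, x.shape[0], batch_size)]
        return np.vstack(out)

    # --------------------------------------------------------------- backward

    def _backward(self, probs, y, w, cache):
        grads = {}
        B = y.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (w / w.sum())[:, None]
        h = cache["head"]
        grads["Wo"] = h.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wo"].T
        for i in reversed(range(len(self.dense_spec))):
            hin, z, mask = cache["dense"][i]
            if mask is not None:
                dh = dh * mask
            dz = dh * (z > 0)
            grads[f"Wd{i}"] = hin.T @ dz
            grads[f"bd{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"Wd{i}"].T
        # back through flatten into the conv stack
        for i in reversed(range(len(self.conv_spec))):
            k, f, p = self.conv_spec[i]
            win, z, a_shape, arg = cache["conv"][i]
            B_, L, F = a_shape
            Lp = L // p
            dh = dh.reshape(B_, Lp, F)
            dt = np.zeros((B_, Lp, p, F))
            np.put_along_axis(dt, arg[:, :, None, :], dh[:, :, None, :], axis=2)
            da = np.zeros(a_shape)
            da[:, :Lp * p] = dt.reshape(B_, Lp * p, F)
            dz = da * (z > 0)
            grads[f"Wc{i}"] = np.tensordot(win, dz, axes=([0, 1], [0, 1])
                                           ).transpose(1, 0, 2)   # (K, Cin, F)
            grads[f"bc{i}"] = dz.sum(axis=(0, 1))
            W = self.params[f"Wc{i}"]
            Cin = W.shape[1]
            pad_l = (k - 1) // 2
            Lin = win.shape[1]
            dxp = np.zeros((B_, Lin + k - 1, Cin))
            for kk in range(k):
                dxp[:, kk:kk + Lin] += dz @ W[kk].T
            dh = dxp[:, pad_l:pad_l + Lin]
        return grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            mh = m / (1 - beta1 ** t)
            vh = v / (1 - beta2 ** t)
            self.params[key] -= lr * mh / (np.sqrt(vh) + eps)

    # -------------------------------------------------------------------- fit

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int = 30,
            batch_size: int = 64, learning_rate: float = 1e-3,
            class_weight: dict | None = None, seed: int | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.shape[1:] != (self.input_samples, self.input_channels):
            raise ValueError(f"expected input shape (*, {self.input_samples}, "
                             f"{self.input_channels}), got {x.shape}")
        w = np.ones(y.shape[0])
        if class_weight:
            for c, cw in class_weight.items():
                w[y == c] = cw
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                probs, cache = self._forward(x[idx], train=True, rng=rng)
                grads = self._backward(probs, y[idx], w[idx], cache)
                self._adam_step(grads, learning_rate)
        return self

    # ---------------------------------------------------------- serialization

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=float)
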