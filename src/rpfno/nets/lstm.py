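"""LSTM network for decoding recurrence-plot frames back to raw signals.

Each frame in a sequence is flattened to its M^2 entries and consumed as one
LSTM step; a two-layer fully connected head maps every step's hidden state
to that frame's 3-axis sample, so a stack of ``T_hat`` frames decodes to
``T_hat`` samples per axis.
"""

from __future__ import annotations

import numpy as np

from .core import sigmoid, relu, uniform_fan_in, mse_loss


class LSTMDecoderNet:
    """Single-layer LSTM + two fully connected layers, manual BPTT."""

    kind = "lstm_decoder"

    def __init__(self, input_dim: int, hidden: int = 128, head_hidden: int = 64,
                 out_dim: int = 3, seed: int = 0):
        self.input_dim = input_dim
        self.hidden = hidden
        self.head_hidden = head_hidden
        self.out_dim = out_dim
        self.seed = seed
        self.scale = 1.0
        rng = np.random.default_rng(seed)
        h = hidden
        p: dict = {}
        p["Wx"] = uniform_fan_in(rng, input_dim, (input_dim, 4 * h))
        p["Wh"] = uniform_fan_in(rng, h, (h, 4 * h))
        p["b"] = np.zeros(4 * h, dtype=np.float32)
        p["b"][h : 2 * h] = 1.0  # forget-gate bias
        p["U1"] = uniform_fan_in(rng, h, (h, head_hidden))
        p["c1"] = np.zeros(head_hidden, dtype=np.float32)
        p["U2"] = uniform_fan_in(rng, head_hidden, (head_hidden, out_dim))
        p["c2"] = np.zeros(out_dim, dtype=np.float32)
        self.params = p

    @property
    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _forward(self, x: np.ndarray, want_cache: bool):
        # x: (B, S, input_dim)
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ValueError(
                f"expected input of shape (B, S, {self.input_dim}), got {x.shape}"
            )
        p = self.params
        x = np.ascontiguousarray(x, dtype=p["Wx"].dtype)
        B, S, _ = x.shape
        H = self.hidden
        dt = x.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        cache = {"x": x, "steps": []} if want_cache else None
        ys = np.empty((B, S, self.out_dim), dtype=dt)
        xw = x @ p["Wx"]  # precompute input contributions: (B, S, 4H)
        for t in range(S):
            z = xw[:, t] + h @ p["Wh"] + p["b"]
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            a1 = relu(h @ p["U1"] + p["c1"])
            ys[:, t] = a1 @ p["U2"] + p["c2"]
            if want_cache:
                cache["steps"].append(
                    dict(i=i, f=f, g=g, o=o, c=c, c_prev=c_prev, tc=tc,
                         h=h, h_prev=h_prev, a1=a1)
                )
        return ys, cache

    def forward(self, x: np.ndarray) -> np.ndarray:
        ys, _ = self._forward(x, want_cache=False)
        return ys

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        ys, cache = self._forward(x, want_cache=True)
        loss, gy = mse_loss(ys, np.asarray(y, dtype=ys.dtype))
        p = self.params
        H = self.hidden
        B, S, _ = cache["x"].shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dt = cache["x"].dtype
        gh_next = np.zeros((B, H), dtype=dt)
        gc_next = np.zeros((B, H), dtype=dt)
        gxw = np.empty((B, S, 4 * H), dtype=dt)
        for t in reversed(range(S)):
            st = cache["steps"][t]
            # head
            ga2 = gy[:, t]
            grads["U2"] += st["a1"].T @ ga2
            grads["c2"] += ga2.sum(axis=0)
            ga1 = (ga2 @ p["U2"].T) * (st["a1"] > 0)
            grads["U1"] += st["h"].T @ ga1
            grads["c1"] += ga1.sum(axis=0)
            gh = ga1 @ p["U1"].T + gh_next
            # cell
            go = gh * st["tc"]
            gc = gh * st["o"] * (1.0 - st["tc"] ** 2) + gc_next
            gi = gc * st["g"]
            gf = gc * st["c_prev"]
            gg = gc * st["i"]
            gc_next = gc * st["f"]
            gz = np.concatenate(
                [
                    gi * st["i"] * (1 - st["i"]),
                    gf * st["f"] * (1 - st["f"]),
                    gg * (1 - st["g"] ** 2),
                    go * st["o"] * (1 - st["o"]),
                ],
                axis=1,
            )
            gxw[:, t] = gz
            grads["Wh"] += st["h_prev"].T @ gz
            grads["b"] += gz.sum(axis=0)
            gh_next = gz @ p["Wh"].T
        grads["Wx"] += np.einsum("bsd,bsk->dk", cache["x"], gxw)
        return loss, grads
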