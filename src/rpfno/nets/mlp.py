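"""Two-layer fully connected classifier over flattened frame stacks."""

from __future__ import annotations

import numpy as np
from scipy.special import log_softmax

from .core import relu, uniform_fan_in


class TwoLayerClassifier:
    """``flatten -> dense -> ReLU -> dense -> logits`` with cross-entropy."""

    kind = "classifier"

    def __init__(self, input_dim: int, hidden: int, n_classes: int, seed: int = 0):
        self.input_dim = input_dim
        self.hidden = hidden
        self.n_classes = n_classes
        self.seed = seed
        self.scale = 1.0
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": uniform_fan_in(rng, input_dim, (input_dim, hidden)),
            "b1": np.zeros(hidden, dtype=np.float32),
            "W2": uniform_fan_in(rng, hidden, (hidden, n_classes)),
            "b2": np.zeros(n_classes, dtype=np.float32),
        }

    @property
    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-class logits for a batch of flattened stacks (B, input_dim)."""
        x = np.ascontiguousarray(x, dtype=self.params["W1"].dtype)
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValueError(
                f"expected input of shape (B, {self.input_dim}), got {x.shape}"
            )
        p = self.params
        a = relu(x @ p["W1"] + p["b1"])
        return a @ p["W2"] + p["b2"]

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy against integer class labels ``y``."""
        x = np.ascontiguousarray(x, dtype=self.params["W1"].dtype)
        y = np.asarray(y, dtype=int)
        p = self.params
        a = relu(x @ p["W1"] + p["b1"])
        logits = a @ p["W2"] + p["b2"]
        logp = log_softmax(logits, axis=1)
        n = x.shape[0]
        loss = float(-logp[np.arange(n), y].mean())
        gz = np.exp(logp).astype(x.dtype)
        gz[np.arange(n), y] -= 1.0
        gz /= n
        grads = {
            "W2": a.T @ gz,
            "b2": gz.sum(axis=0),
        }
        ga = (gz @ p["W2"].T) * (a > 0)
        grads["W1"] = x.T @ ga
        grads["b1"] = ga.sum(axis=0)
        return loss, grads
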