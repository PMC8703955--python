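"""Optimizer, activations and initialisation helpers for the numpy models."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function (tanh form, dtype-preserving)."""
    out = np.tanh(0.5 * z)
    out += 1.0
    out *= 0.5
    return out


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad


def uniform_fan_in(rng: np.random.Generator, fan_in: int, shape, dtype=np.float32):
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialisation."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Adam:
    """Adam optimizer over a dict of named parameter arrays.

    The learning rate is passed per step so schedules stay outside the
    optimizer.  State is kept per parameter name; parameters are updated in
    place.
    """

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
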