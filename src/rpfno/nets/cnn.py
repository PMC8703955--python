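"""Convolutional baseline matched to the operator's lift/project structure.

Four convolution layers (kernel 5, stride 1, zero padding so the spatial
size never changes) followed by three fully connected layers that map the
flattened feature grid to the ``T_hat`` predicted frames.  ReLU follows
every layer except the last fully connected one.

Unlike the spectral model, the fully connected head ties the parameters to
one grid size: the baseline cannot evaluate at a different resolution, which
is exactly the contrast the mesh-invariance experiment demonstrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import relu, uniform_fan_in, mse_loss

KERNEL = 5


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 2-D convolution. x (B,C,M,M), w (D,C,K,K).

    Evaluated as K^2 shifted channel-mixing matmuls, which keeps the work
    in BLAS; returns the output and the padded input for the backward pass.
    """
    bsz, c, m, _ = x.shape
    d, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    y = np.zeros((bsz, d, m * m), dtype=x.dtype)
    for u in range(k):
        for v in range(k):
            xs = xp[:, :, u : u + m, v : v + m].reshape(bsz, c, m * m)
            y += w[:, :, u, v] @ xs
    y = y.reshape(bsz, d, m, m)
    y += b[None, :, None, None]
    return y, xp


def conv2d_backward(gy: np.ndarray, xp: np.ndarray, w: np.ndarray):
    """Gradients of the same-padded convolution (shift decomposition)."""
    bsz, d, m, _ = gy.shape
    c = w.shape[1]
    k = w.shape[-1]
    pad = k // 2
    gyr = gy.reshape(bsz, d, m * m)
    gb = gyr.sum(axis=(0, 2))
    gw = np.empty_like(w)
    gxp = np.zeros_like(xp)
    for u in range(k):
        for v in range(k):
            xs = xp[:, :, u : u + m, v : v + m].reshape(bsz, c, m * m)
            gw[:, :, u, v] = np.matmul(gyr, xs.transpose(0, 2, 1)).sum(axis=0)
            gxp[:, :, u : u + m, v : v + m] += (w[:, :, u, v].T @ gyr).reshape(
                bsz, c, m, m
            )
    gx = gxp[:, :, pad : pad + m, pad : pad + m] if pad else gxp
    return gx, gw, gb


@dataclass(frozen=True)
class CNNConfig:
    """Baseline hyperparameters; ``grid_size`` is baked into the head."""

    channels: int = 32
    hidden: tuple = (256, 256)
    input_steps: int = 30
    horizon: int = 20
    grid_size: int = 29

    def __post_init__(self) -> None:
        if self.channels < 1 or self.grid_size < KERNEL:
            raise ValueError("channels must be >= 1 and grid_size >= kernel size")


class CNNForecaster:
    """Four conv layers + three fully connected layers, manual gradients."""

    kind = "cnn"

    def __init__(self, config: CNNConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.scale = 1.0
        rng = np.random.default_rng(seed)
        c = config
        p: dict = {}
        chans = [c.input_steps, c.channels, c.channels, c.channels, c.channels]
        for i in range(4):
            fan_in = chans[i] * KERNEL * KERNEL
            p[f"conv{i}_W"] = uniform_fan_in(
                rng, fan_in, (chans[i + 1], chans[i], KERNEL, KERNEL)
            )
            p[f"conv{i}_b"] = np.zeros(chans[i + 1], dtype=np.float32)
        m2 = c.grid_size * c.grid_size
        dims = [c.channels * m2, *c.hidden, c.horizon * m2]
        for i in range(3):
            p[f"fc{i}_W"] = uniform_fan_in(rng, dims[i], (dims[i], dims[i + 1]))
            p[f"fc{i}_b"] = np.zeros(dims[i + 1], dtype=np.float32)
        self.params = p

    @property
    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _forward(self, x: np.ndarray, want_cache: bool):
        c = self.config
        if x.ndim != 4 or x.shape[1] != c.input_steps:
            raise ValueError(
                f"expected input of shape (B, {c.input_steps}, M, M), got {x.shape}"
            )
        if x.shape[-1] != c.grid_size or x.shape[-2] != c.grid_size:
            raise ValueError(
                f"the convolutional baseline is tied to its training grid "
                f"{c.grid_size}x{c.grid_size} and cannot run on "
                f"{x.shape[-2]}x{x.shape[-1]} frames"
            )
        p = self.params
        x = np.ascontiguousarray(x, dtype=p["conv0_W"].dtype)
        cache = {"x": x} if want_cache else None
        h = x
        for i in range(4):
            z, xpad = conv2d_forward(h, p[f"conv{i}_W"], p[f"conv{i}_b"])
            h = relu(z)
            if want_cache:
                cache[f"pad{i}"] = xpad
                cache[f"relu{i}"] = h
        B = x.shape[0]
        flat = h.reshape(B, -1)
        if want_cache:
            cache["flat"] = flat
        a = flat
        for i in range(3):
            z = a @ p[f"fc{i}_W"] + p[f"fc{i}_b"]
            a = relu(z) if i < 2 else z
            if want_cache:
                cache[f"fc{i}_out"] = a
        out = a.reshape(B, c.horizon, c.grid_size, c.grid_size)
        return out, cache

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, _ = self._forward(x, want_cache=False)
        return out

    def predict(self, frames: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(frames, dtype=np.float32) / self.scale, False)
        return out * self.scale

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        c = self.config
        out, cache = self._forward(x, want_cache=True)
        loss, gout = mse_loss(out, np.asarray(y, dtype=out.dtype))
        p = self.params
        grads: dict = {}
        B = out.shape[0]
        ga = gout.reshape(B, -1)
        fc_inputs = [cache["flat"], cache["fc0_out"], cache["fc1_out"]]
        for i in reversed(range(3)):
            if i < 2:  # ReLU preceded this gradient
                ga = ga * (fc_inputs[i + 1] > 0)
            grads[f"fc{i}_W"] = fc_inputs[i].T @ ga
            grads[f"fc{i}_b"] = ga.sum(axis=0)
            ga = ga @ p[f"fc{i}_W"].T
        gh = ga.reshape(B, c.channels, c.grid_size, c.grid_size)
        for i in reversed(range(4)):
            gh = gh * (cache[f"relu{i}"] > 0)
            gh, gw, gb = conv2d_backward(gh, cache[f"pad{i}"], p[f"conv{i}_W"])
            grads[f"conv{i}_W"] = gw
            grads[f"conv{i}_b"] = gb
        return loss, grads
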