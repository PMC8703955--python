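"""Fourier neural operator forecasting stacks of recurrence-plot frames.

The model maps ``T`` input frames (treated as channels over the M x M grid)
to ``T_hat`` predicted frames:

1. a pointwise linear *lift* takes the ``T`` channel values at each grid
   point to a ``width``-dimensional representation ``v_0``;
2. ``N`` Fourier layers update the state as
   ``v_{n+1} = sigmoid(F_n(v_n) + W_n v_n + b_n)`` where the spectral branch
   ``F_n(v) = IFFT(R_n . FFT(v))`` mixes channels on a truncated set of 2-D
   frequency modes with learned complex weights ``R_n`` and zeroes all other
   modes;
3. a pointwise linear *projection* maps the final state to ``T_hat`` output
   channels.

Because the spectral weights live on frequency indices rather than grid
points, the parameter count is independent of the grid size M and the same
trained weights evaluate on any admissible resolution (mesh invariance).

Mode truncation convention: with ``modes = k`` the retained set is axis-0
frequencies ``{0, +-1, ..., +-(k-1)}`` crossed with nonnegative axis-1
frequencies ``{0..k-1}`` of the real-input half spectrum; the negative
axis-0 rows reuse the conjugated weight tensor, which keeps the full
spectrum multiplier Hermitian-symmetric so the layer is an exactly
real-linear operator.

Since only ``(2k-1) x k`` modes survive the truncation, the transform is
evaluated as a pair of small dense DFT matrix products restricted to the
retained frequencies rather than a full FFT (the grids are tiny and of
prime size, where generic FFTs are at their slowest); this is exact, not an
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import sigmoid, uniform_fan_in, mse_loss


def max_modes(grid_size: int) -> int:
    """Largest admissible ``modes`` for an M x M grid: (M + 1) // 2."""
    return (grid_size + 1) // 2


def _check_modes(k: int, grid_size: int) -> None:
    bound = max_modes(grid_size)
    if k > bound:
        raise ValueError(
            f"modes={k} is inadmissible for a {grid_size}x{grid_size} grid; "
            f"the bound is modes <= (M + 1) // 2 = {bound}"
        )


@dataclass(frozen=True)
class FNOConfig:
    """Architecture hyperparameters.

    num_layers
        Number of Fourier layers N (default 4).
    width
        Channels of the lifted representation (default 32).
    modes
        Retained frequencies k per grid axis (default 8; keeps the 17, 23
        and 29 grids of the mesh-invariance experiment admissible).
    input_steps / horizon
        Input frames T (30) and predicted frames T_hat (20).
    """

    num_layers: int = 4
    width: int = 32
    modes: int = 8
    input_steps: int = 30
    horizon: int = 20

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.width < 1 or self.modes < 1:
            raise ValueError("width and modes must be >= 1")


class _SpectralBasis:
    """Cached truncated-DFT matrices for one (grid size, modes, dtype).

    Rows are ordered ``[0, 1, .., k-1, -(k-1), .., -1]`` (axis-0
    frequencies); columns are the nonnegative axis-1 frequencies
    ``0..k-1``.  ``analysis`` maps a real grid to the retained complex
    modes; ``synthesis`` is its Hermitian-aware inverse, with columns
    ``1..k-1`` carrying multiplicity 2 for their conjugate mirrors.
    """

    _cache: dict = {}

    def __init__(self, m: int, k: int, cdtype):
        self.m, self.k = m, k
        rows = np.concatenate([np.arange(k), np.arange(-(k - 1), 0)])
        self.n_rows = rows.size
        grid = np.arange(m)
        # analysis (forward DFT) factors
        self.e1 = np.exp(-2j * np.pi * np.outer(rows, grid) / m).astype(cdtype)
        self.e2t = np.exp(-2j * np.pi * np.outer(grid, np.arange(k)) / m).astype(cdtype)
        # synthesis (inverse DFT) factors: conjugate transposes
        self.a = self.e1.conj().T.copy()
        self.bt = self.e2t.conj().T.copy()
        colmult = np.full(k, 2.0, dtype=np.float32)
        colmult[0] = 1.0
        self.colmult = colmult.astype(cdtype)
        self.inv_m2 = 1.0 / (m * m)

    @classmethod
    def get(cls, m: int, k: int, cdtype) -> "_SpectralBasis":
        key = (m, k, np.dtype(cdtype).name)
        if key not in cls._cache:
            cls._cache[key] = cls(m, k, cdtype)
        return cls._cache[key]

    def analyze(self, v: np.ndarray) -> np.ndarray:
        """(.., M, M) real -> (.., 2k-1, k) retained modes."""
        return (self.e1 @ v.astype(self.e1.dtype)) @ self.e2t

    def synthesize(self, modes: np.ndarray) -> np.ndarray:
        """Retained modes -> real grid, applying Hermitian multiplicity."""
        return ((self.a @ (modes * self.colmult)) @ self.bt).real * self.inv_m2


def _full_weights(r_weights: np.ndarray, k: int) -> np.ndarray:
    """(C, D, k, k) -> per-mode (2k-1, k, C, D), conjugated on negative rows."""
    rt = r_weights.transpose(2, 3, 0, 1)  # (k, k, C, D)
    if k == 1:
        return rt
    return np.concatenate([rt, rt[k - 1 : 0 : -1].conj()], axis=0)


def spectral_conv_forward(v: np.ndarray, r_weights: np.ndarray, k: int):
    """Spectral branch: truncated DFT, channel mixing per mode, inverse.

    Parameters
    ----------
    v : (B, C, M, M) real state
    r_weights : (C, D, k, k) complex mode weights
    k : retained frequencies per axis

    Returns the real (B, D, M, M) output and the cached retained modes of
    ``v`` for the backward pass.
    """
    m = v.shape[-1]
    _check_modes(k, m)
    cdtype = np.complex64 if v.dtype == np.float32 else np.complex128
    basis = _SpectralBasis.get(m, k, cdtype)
    vb = basis.analyze(v)  # (B, C, 2k-1, k)
    vt = vb.transpose(2, 3, 0, 1)  # (2k-1, k, B, C)
    ot = vt @ _full_weights(r_weights.astype(cdtype), k)
    ob = ot.transpose(2, 3, 0, 1)  # (B, D, 2k-1, k)
    y = basis.synthesize(ob).astype(v.dtype)
    return y, vb


def spectral_conv_backward(gy: np.ndarray, vb: np.ndarray, r_weights: np.ndarray, k: int):
    """Adjoint of :func:`spectral_conv_forward`.

    Returns the gradient with respect to the input state and the complex
    gradient with respect to the mode weights (real part = d/dRe,
    imaginary part = d/dIm).
    """
    m = gy.shape[-1]
    cdtype = vb.dtype
    basis = _SpectralBasis.get(m, k, cdtype)
    # complex gradient w.r.t. the mixed modes
    gob = basis.analyze(gy) * (basis.colmult * basis.inv_m2)
    gt = gob.transpose(2, 3, 0, 1)  # (2k-1, k, B, D)
    r_full = _full_weights(r_weights.astype(cdtype), k)
    # back through the per-mode channel mixing
    gvt = gt @ r_full.conj().transpose(0, 1, 3, 2)
    gvb = gvt.transpose(2, 3, 0, 1)  # (B, C, 2k-1, k)
    gv = basis.synthesize(gvb / basis.colmult / basis.inv_m2).astype(gy.dtype)
    # weight gradient per mode, folded back onto the (k, k) tensor
    vt = vb.transpose(2, 3, 0, 1)
    g_full = vt.conj().transpose(0, 1, 3, 2) @ gt  # (2k-1, k, C, D)
    g_r = g_full[:k].transpose(2, 3, 0, 1).copy()
    if k > 1:
        g_r[:, :, 1:k, :] += g_full[k:][::-1].conj().transpose(2, 3, 0, 1)
    return gv, g_r


class FNOForecaster:
    """The trainable operator, with manual forward/backward passes."""

    kind = "fno"

    def __init__(self, config: FNOConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.scale = 1.0  # frame normalizer, set by the training pipeline
        rng = np.random.default_rng(seed)
        c = config
        p: dict = {}
        p["lift_W"] = uniform_fan_in(rng, c.input_steps, (c.input_steps, c.width))
        p["lift_b"] = np.zeros(c.width, dtype=np.float32)
        r_scale = 1.0 / (c.width * c.width)
        for layer in range(c.num_layers):
            p[f"R{layer}_re"] = (
                r_scale * rng.random((c.width, c.width, c.modes, c.modes))
            ).astype(np.float32)
            p[f"R{layer}_im"] = (
                r_scale * rng.random((c.width, c.width, c.modes, c.modes))
            ).astype(np.float32)
            p[f"W{layer}"] = uniform_fan_in(rng, c.width, (c.width, c.width))
            p[f"b{layer}"] = np.zeros(c.width, dtype=np.float32)
        p["proj_W"] = uniform_fan_in(rng, c.width, (c.width, c.horizon))
        p["proj_b"] = np.zeros(c.horizon, dtype=np.float32)
        self.params = p

    @property
    def param_count(self) -> int:
        """Total parameter count; independent of the grid size M."""
        return int(sum(v.size for v in self.params.values()))

    def _r(self, layer: int) -> np.ndarray:
        return self.params[f"R{layer}_re"] + 1j * self.params[f"R{layer}_im"]

    def _forward(self, x: np.ndarray, want_cache: bool):
        c = self.config
        if x.ndim != 4 or x.shape[1] != c.input_steps:
            raise ValueError(
                f"expected input of shape (B, {c.input_steps}, M, M), got {x.shape}"
            )
        if x.shape[-2] != x.shape[-1]:
            raise ValueError("frames must be square")
        m = x.shape[-1]
        _check_modes(c.modes, m)
        p = self.params
        x = np.ascontiguousarray(x, dtype=p["lift_W"].dtype)
        b = x.shape[0]
        xr = x.reshape(b, c.input_steps, m * m)
        v = p["lift_W"].T @ xr + p["lift_b"][:, None]  # (B, width, M^2)
        cache = {"xr": xr, "v0": v} if want_cache else None
        for layer in range(c.num_layers):
            vg = v.reshape(b, c.width, m, m)
            s_branch, vb = spectral_conv_forward(vg, self._r(layer), c.modes)
            z = s_branch.reshape(b, c.width, m * m)
            z += p[f"W{layer}"].T @ v
            z += p[f"b{layer}"][:, None]
            v = sigmoid(z)
            if want_cache:
                cache[f"vb{layer}"] = vb
                cache[f"out{layer}"] = v
        out = p["proj_W"].T @ v + p["proj_b"][:, None]
        return out.reshape(b, c.horizon, m, m), cache

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Predict ``(B, T_hat, M, M)`` frame stacks (normalized units)."""
        out, _ = self._forward(x, want_cache=False)
        return out

    def predict(self, frames: np.ndarray) -> np.ndarray:
        """Predict on raw-distance frames, applying the stored normalizer."""
        out, _ = self._forward(np.asarray(frames, dtype=np.float32) / self.scale, False)
        return out * self.scale

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        c = self.config
        out, cache = self._forward(x, want_cache=True)
        loss, gout = mse_loss(out, np.asarray(y, dtype=out.dtype))
        p = self.params
        b, m = out.shape[0], out.shape[-1]
        gout = gout.reshape(b, c.horizon, m * m)
        grads: dict = {}
        v_last = cache[f"out{c.num_layers - 1}"]
        grads["proj_W"] = np.matmul(v_last, gout.transpose(0, 2, 1)).sum(axis=0)
        grads["proj_b"] = gout.sum(axis=(0, 2))
        gv = p["proj_W"] @ gout
        for layer in reversed(range(c.num_layers)):
            v_out = cache[f"out{layer}"]
            v_in = cache[f"out{layer - 1}"] if layer > 0 else cache["v0"]
            gz = gv * v_out * (1.0 - v_out)
            grads[f"W{layer}"] = np.matmul(v_in, gz.transpose(0, 2, 1)).sum(axis=0)
            grads[f"b{layer}"] = gz.sum(axis=(0, 2))
            gv_w = p[f"W{layer}"] @ gz
            gv_s, g_r = spectral_conv_backward(
                gz.reshape(b, c.width, m, m), cache[f"vb{layer}"], self._r(layer), c.modes
            )
            grads[f"R{layer}_re"] = np.ascontiguousarray(g_r.real)
            grads[f"R{layer}_im"] = np.ascontiguousarray(g_r.imag)
            gv = gv_w + gv_s.reshape(b, c.width, m * m)
        grads["lift_W"] = np.matmul(cache["xr"], gv.transpose(0, 2, 1)).sum(axis=0)
        grads["lift_b"] = gv.sum(axis=(0, 2))
        return loss, grads

    def evaluate_at_resolution(self, frames: np.ndarray) -> np.ndarray:
        """Run the fixed weights on frames of a different grid size.

        The transform is taken at the new size and the same retained modes
        are mixed with the same weights; no retraining.  Raises when
        ``modes`` is inadmissible at the new size.
        """
        return self.forward(np.asarray(frames, dtype=np.float32))
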