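"""Recurrence-plot encoding of sensor windows and sequence-sample assembly.

The encoding turns a fixed-rate 3-axis stream into a sequence of small
distance images.  For each end index ``t`` a window of the most recent
``Tw`` samples per axis is taken, the three windows are concatenated into a
single vector ``X_t`` of length ``3*Tw`` (15 under the defaults), one linear
midpoint is inserted between every consecutive pair of entries (length
``M = 6*Tw - 1 = 29``), and the distance-only recurrence plot

    Y_t[i, j] = |X_t[i] - X_t[j]|

is formed.  No threshold and no step function are applied: thresholded
binary recurrence plots discard amplitude information that the forecaster
and decoder need, so only the distance component is kept.  The classical
thresholded variant is provided for reference/testing as
:func:`thresholded_recurrence_plot`.

Cross recurrence plots compare a gyroscope window against an accelerometer
window of the same length, ``C[i, j] = |x_i - y_j|``; they are generally not
symmetric and have no zero diagonal.

A supervised sample stacks ``T`` consecutive frames as input (1 s of motion
at 30 Hz with stride 1) and the following ``T_hat`` frames as the forecast
target (~0.6 s), together with the raw 3-axis samples aligned to the target
frames' end indices so the decoder can be trained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import h5py
import numpy as np

from .streams import SensorStream


@dataclass(frozen=True)
class EncodingConfig:
    """Windowing and sample-assembly parameters.

    window_size
        Samples per axis entering one window (``Tw``, default 5).
    stride
        Step between consecutive window end indices (default 1).
    interpolate
        Insert one linear midpoint between consecutive entries of the
        concatenated vector (default on; gives the 29-entry vector).
    input_steps
        Frames per model input (``T``, default 30).
    horizon
        Frames per forecast target (``T_hat``, default 20).
    """

    window_size: int = 5
    stride: int = 1
    interpolate: bool = True
    input_steps: int = 30
    horizon: int = 20

    def __post_init__(self) -> None:
        for name in ("window_size", "stride", "input_steps", "horizon"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def grid_size(self) -> int:
        """Side length M of one recurrence-plot frame."""
        base = 3 * self.window_size
        return 2 * base - 1 if self.interpolate else base


def window_axes(stream: SensorStream, cfg: EncodingConfig):
    """Concatenated end-anchored windows, one per admissible end index.

    Returns ``(vectors, end_indices)`` where ``vectors`` has shape
    ``(n_windows, 3*Tw)`` and row ``r`` is
    ``[x-window; y-window; z-window]`` ending at sample ``end_indices[r]``.
    End indices run from ``Tw - 1`` to ``N - 1`` in steps of the stride, so
    ``n_windows = floor((N - Tw) / stride) + 1``.
    """
    tw, s = cfg.window_size, cfg.stride
    n = stream.n_samples
    if n < tw:
        raise ValueError(f"stream has {n} samples; need at least window_size={tw}")
    per_axis = np.lib.stride_tricks.sliding_window_view(stream.axes, tw, axis=1)
    # per_axis: (3, N - Tw + 1, Tw); subsample by stride and concatenate axes
    per_axis = per_axis[:, ::s, :]
    vectors = np.concatenate([per_axis[0], per_axis[1], per_axis[2]], axis=1)
    end_indices = np.arange(tw - 1, n, s)
    return vectors, end_indices


def interpolate_window(values: np.ndarray) -> np.ndarray:
    """Insert the arithmetic midpoint between consecutive entries.

    Operates on the whole concatenated vector as one sequence (crossing axis
    boundaries), mapping length ``L`` to ``2L - 1`` with the original values
    preserved at even positions.  Works on a single vector or a batch
    ``(n, L)``.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[None, :]
    n, L = values.shape
    if L < 2:
        raise ValueError("need at least 2 entries to interpolate")
    out = np.empty((n, 2 * L - 1), dtype=values.dtype)
    out[:, 0::2] = values
    out[:, 1::2] = 0.5 * (values[:, :-1] + values[:, 1:])
    return out[0] if squeeze else out


def recurrence_plot(x: np.ndarray) -> np.ndarray:
    """Distance-only recurrence plot ``Y[i, j] = |x_i - x_j|``.

    Each entry of the (concatenated, interpolated) window is a scalar state,
    so the L2 norm of the difference reduces to the absolute difference.
    Accepts a single vector ``(M,)`` or a batch ``(n, M)`` and returns
    ``(M, M)`` or ``(n, M, M)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.abs(x[:, None] - x[None, :])
    return np.abs(x[:, :, None] - x[:, None, :])


def cross_recurrence_plot(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cross recurrence plot ``C[i, j] = |x_i - y_j|`` between two sensors.

    ``x`` and ``y`` must have the same (post-interpolation) length; the
    result is generally not symmetric and its diagonal is not zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"window length mismatch: {x.shape} vs {y.shape}")
    if x.ndim == 1:
        return np.abs(x[:, None] - y[None, :])
    return np.abs(x[:, :, None] - y[:, None, :])


def subgrid_positions(coarse_window_size: int, window_size: int = 5) -> np.ndarray:
    """Positions of a coarser window's grid entries within the fine grid.

    A window of ``coarse_window_size < window_size`` samples per axis uses
    the last ``coarse_window_size`` samples of each axis, so after
    concatenation and midpoint interpolation each entry of the coarse
    vector corresponds to a position on the fine vector's index grid (the
    original samples land on even fine positions; coarse midpoints fall
    between them).  The returned vector ``q`` (length
    ``6 * coarse_window_size - 1``) maps coarse grid index ``p`` to fine
    grid coordinate ``q[p]`` and lets a fine recurrence plot be compared
    with a coarse one of the same underlying samples via
    ``fine[np.ix_(q, q)]`` (all positions are integers for the window
    sizes used here; midpoints across axis seams make the correspondence
    approximate in value, not in position).
    """
    if not 1 <= coarse_window_size <= window_size:
        raise ValueError("coarse_window_size must lie in [1, window_size]")
    base = [
        2.0 * (axis * window_size + (window_size - coarse_window_size) + j)
        for axis in range(3)
        for j in range(coarse_window_size)
    ]
    return interpolate_window(np.asarray(base))


def thresholded_recurrence_plot(x: np.ndarray, epsilon: float) -> np.ndarray:
    """Classical binary recurrence plot ``Theta(eps - |x_i - x_j|)``.

    Reference implementation of the thresholded variant; not used in the
    forecasting pipeline (the distance-only form above is).
    """
    return (recurrence_plot(x) <= epsilon).astype(float)


def frames_from_stream(
    stream: SensorStream,
    cfg: EncodingConfig,
    accel_stream: SensorStream | None = None,
):
    """All recurrence-plot (or cross-recurrence) frames of a stream.

    Returns ``(frames, end_indices)`` with ``frames`` of shape
    ``(n_frames, M, M)``.  If ``accel_stream`` is given it must share the
    stream's length and rate; frames are then cross recurrence plots pairing
    the gyroscope window with the accelerometer window ending at the same
    sample index.
    """
    vectors, end_indices = window_axes(stream, cfg)
    if cfg.interpolate:
        vectors = interpolate_window(vectors)
    if accel_stream is None:
        frames = recurrence_plot(vectors)
    else:
        if accel_stream.n_samples != stream.n_samples:
            raise ValueError("gyro and accelerometer streams must have equal length")
        accel_vectors, _ = window_axes(accel_stream, cfg)
        if cfg.interpolate:
            accel_vectors = interpolate_window(accel_vectors)
        frames = cross_recurrence_plot(vectors, accel_vectors)
    return frames.astype(np.float32), end_indices


@dataclass
class RPSequenceDataset:
    """Supervised forecasting samples assembled from consecutive frames.

    inputs
        ``(n, T, M, M)`` input frame stacks.
    targets
        ``(n, T_hat, M, M)`` target frame stacks.
    signals
        ``(n, 3, T_hat)`` raw samples aligned to the target frames' end
        indices (decoder targets).
    target_end_indices
        ``(n, T_hat)`` sample indices of the target frames' ends.
    """

    inputs: np.ndarray
    targets: np.ndarray
    signals: np.ndarray
    target_end_indices: np.ndarray
    config: EncodingConfig
    subject_id: str = ""
    motion: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    @property
    def grid_size(self) -> int:
        return self.inputs.shape[-1]

    def subset(self, index) -> "RPSequenceDataset":
        return RPSequenceDataset(
            inputs=self.inputs[index],
            targets=self.targets[index],
            signals=self.signals[index],
            target_end_indices=self.target_end_indices[index],
            config=self.config,
            subject_id=self.subject_id,
            motion=self.motion,
            meta=dict(self.meta),
        )

    def save(self, path) -> None:
        """Persist as an HDF5 container with the config as a JSON attribute."""
        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=self.inputs, compression="gzip")
            f.create_dataset("targets", data=self.targets, compression="gzip")
            f.create_dataset("signals", data=self.signals, compression="gzip")
            f.create_dataset("target_end_indices", data=self.target_end_indices)
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["subject_id"] = self.subject_id
            f.attrs["motion"] = self.motion

    @classmethod
    def load(cls, path) -> "RPSequenceDataset":
        with h5py.File(path, "r") as f:
            cfg = EncodingConfig(**json.loads(f.attrs["config"]))
            return cls(
                inputs=f["inputs"][...],
                targets=f["targets"][...],
                signals=f["signals"][...],
                target_end_indices=f["target_end_indices"][...],
                config=cfg,
                subject_id=str(f.attrs.get("subject_id", "")),
                motion=str(f.attrs.get("motion", "")),
            )


def assemble_samples(
    frames: np.ndarray,
    end_indices: np.ndarray,
    stream: SensorStream,
    cfg: EncodingConfig,
    subject_id: str = "",
    motion: str = "",
) -> RPSequenceDataset:
    """Slide over consecutive frames to build supervised samples.

    Sample ``i`` takes frames ``[i, i+T)`` as input and frames
    ``[i+T, i+T+T_hat)`` as target, with the raw 3-axis samples at the
    target frames' end indices as the decoder target; the count is
    ``n_frames - T - T_hat + 1``.
    """
    t_in, t_out = cfg.input_steps, cfg.horizon
    n_frames = frames.shape[0]
    total = t_in + t_out
    n = n_frames - total + 1
    if n < 1:
        raise ValueError(
            f"need at least T + T_hat = {total} frames, got {n_frames}"
        )
    idx = np.arange(n)
    input_idx = idx[:, None] + np.arange(t_in)[None, :]
    target_idx = idx[:, None] + t_in + np.arange(t_out)[None, :]
    inputs = frames[input_idx]
    targets = frames[target_idx]
    target_ends = end_indices[target_idx]
    signals = stream.axes[:, target_ends].transpose(1, 0, 2).astype(np.float32)
    return RPSequenceDataset(
        inputs=inputs,
        targets=targets,
        signals=signals,
        target_end_indices=target_ends,
        config=cfg,
        subject_id=subject_id or str(stream.meta.get("subject_id", "")),
        motion=motion or str(stream.meta.get("motion", "")),
    )


def encode_stream(
    stream: SensorStream,
    cfg: EncodingConfig | None = None,
    accel_stream: SensorStream | None = None,
) -> RPSequenceDataset:
    """Stream -> frames -> supervised dataset, in one call."""
    cfg = cfg or EncodingConfig()
    frames, end_indices = frames_from_stream(stream, cfg, accel_stream)
    return assemble_samples(frames, end_indices, stream, cfg)
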