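"""Fixed-rate 3-axis sensor streams: container, CSV I/O, trimming, resampling.

A :class:`SensorStream` holds one recording from a single wearable sensor
(gyroscope angular velocity in rad/s, or accelerometer specific force in
m/s^2) as three equally long sample tracks on a nominally uniform time grid.
The forecasting pipeline assumes a fixed rate (30 Hz by default), so
irregular or differently rated recordings are brought onto a uniform grid
with :func:`resample` before windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default pipeline rate in Hz. 30 Hz is the acquisition rate the method was
#: designed around (selected between 10 and 100 Hz).
DEFAULT_RATE_HZ = 30.0

SENSOR_KINDS = ("gyroscope", "accelerometer")

CSV_COLUMNS = ("t_s", "x", "y", "z")


@dataclass
class SensorStream:
    """A timestamped, fixed-rate, 3-axis sensor sequence.

    Parameters
    ----------
    timestamps : ndarray, shape (N,)
        Sample times in seconds, strictly increasing.
    axes : ndarray, shape (3, N)
        Per-axis samples (x, y, z rows).
    rate_hz : float
        Nominal sampling rate in Hz.
    sensor_kind : str
        ``"gyroscope"`` or ``"accelerometer"``.
    """

    timestamps: np.ndarray
    axes: np.ndarray
    rate_hz: float
    sensor_kind: str = "gyroscope"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[0] != 3:
            raise ValueError(f"axes must have shape (3, N), got {self.axes.shape}")
        if self.timestamps.shape[0] != self.axes.shape[1]:
            raise ValueError(
                f"timestamps ({self.timestamps.shape[0]}) and axes "
                f"({self.axes.shape[1]}) disagree in length"
            )
        if self.n_samples < 1:
            raise ValueError("stream must contain at least one sample")
        if self.n_samples > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(
                f"unknown sensor_kind {self.sensor_kind!r}; expected one of {SENSOR_KINDS}"
            )
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration_s(self) -> float:
        """Sample-period-inclusive duration: N / rate for a uniform stream."""
        if self.n_samples == 1:
            return 1.0 / self.rate_hz
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.rate_hz


def write_stream(stream: SensorStream, path) -> None:
    """Write a stream as CSV with header ``t_s,x,y,z``."""
    frame = pd.DataFrame(
        {
            "t_s": stream.timestamps,
            "x": stream.axes[0],
            "y": stream.axes[1],
            "z": stream.axes[2],
        }
    )
    frame.to_csv(path, index=False)


def read_stream(path, sensor_kind: str = "gyroscope") -> SensorStream:
    """Read a ``t_s,x,y,z`` CSV into a :class:`SensorStream`.

    The rate is inferred from the median timestamp spacing. Missing columns,
    empty files and non-monotone timestamps are rejected with the offending
    file (and first bad row, where known) named in the message.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected header t_s,x,y,z")
    if len(frame) == 0:
        raise ValueError(f"{path}: no data rows")
    t = frame["t_s"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            # +2 converts 0-based diff index to a 1-based CSV data line
            raise ValueError(
                f"{path}: timestamps not strictly increasing at data row {bad[0] + 2}"
            )
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = DEFAULT_RATE_HZ
    axes = frame[["x", "y", "z"]].to_numpy(dtype=float).T
    return SensorStream(timestamps=t, axes=axes, rate_hz=rate, sensor_kind=sensor_kind)


def trim_guard(stream: SensorStream, head_s: float = 3.0, tail_s: float = 3.0) -> SensorStream:
    """Drop guard intervals at both ends of a recording.

    Emulates the acquisition protocol in which the subject starts the motion
    a few seconds after pressing start and stops a few seconds before
    pressing stop: ``round(head_s * rate)`` leading and ``round(tail_s * rate)``
    trailing samples are removed.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim durations must be nonnegative")
    n_head = int(round(head_s * stream.rate_hz))
    n_tail = int(round(tail_s * stream.rate_hz))
    if n_head + n_tail >= stream.n_samples:
        raise ValueError(
            f"trim of {n_head}+{n_tail} samples exceeds stream length {stream.n_samples}"
        )
    stop = stream.n_samples - n_tail
    return replace(
        stream,
        timestamps=stream.timestamps[n_head:stop].copy(),
        axes=stream.axes[:, n_head:stop].copy(),
    )


def resample(stream: SensorStream, target_hz: float) -> SensorStream:
    """Linearly interpolate each axis onto a uniform grid at ``target_hz``.

    The grid is half-open: it starts at the first timestamp and carries
    ``floor(duration * target_hz)`` points spaced ``1/target_hz`` apart, where
    the duration counts one trailing sample period (so a 60 s recording at
    30 Hz keeps exactly 1800 samples when resampled to its own rate, and the
    operation is the identity on an already uniform stream).
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if stream.n_samples < 2:
        raise ValueError("cannot resample a single-sample stream")
    n_out = int(np.floor(stream.duration_s * target_hz + 1e-9))
    t0 = stream.timestamps[0]
    grid = t0 + np.arange(n_out) / target_hz
    # stay within the recorded range; the half-open count guarantees this
    grid = np.minimum(grid, stream.timestamps[-1])
    axes = np.vstack([np.interp(grid, stream.timestamps, ax) for ax in stream.axes])
    return replace(stream, timestamps=grid, axes=axes, rate_hz=float(target_hz))
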