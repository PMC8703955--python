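"""Decoding recurrence-plot frame sequences back to raw 3-axis signals.

A distance-only recurrence plot is invariant to a global sign flip and a
constant offset of its window (``x -> -x + c`` leaves every ``|x_i - x_j|``
unchanged), so frames alone cannot pin the signal down; a trained decoder
resolves the ambiguity from what its training distribution disambiguates.
The decoder is an LSTM over the frame sequence (each M x M frame flattened
to M^2 entries per step) with a two-layer fully connected head emitting the
3-axis sample at each frame's end index.  It is trained on (true frames ->
true signals) pairs and applied at inference to FNO-predicted frames; the
forecaster and decoder are trained separately, both with Adam on MSE.

Because of the sign/offset ambiguity, recovery quality on held-out data is
scored by per-axis correlation (shape agreement) rather than absolute
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import RPSequenceDataset
from .nets import LSTMDecoderNet
from .training import TrainingConfig, split_dataset, train_model


@dataclass
class ReconstructedSegment:
    """Decoded 3-axis samples aligned to absolute sample indices."""

    samples: np.ndarray  # (3, L)
    indices: np.ndarray  # (L,) strictly increasing sample indices
    gaps: list = field(default_factory=list)  # uncovered indices after stitching

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if self.samples.shape != (3, self.indices.shape[0]):
            raise ValueError("samples must be (3, L) aligned with L indices")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("alignment indices must be strictly increasing")


def decode_sequence(frames: np.ndarray, model: LSTMDecoderNet,
                    indices: np.ndarray | None = None) -> ReconstructedSegment:
    """Decode one stack of frames to one 3-axis sample per frame.

    ``frames`` is ``(S, M, M)`` in raw distance units; the decoder's stored
    normalizer is applied.  ``indices`` gives each frame's end sample index
    (defaults to ``0..S-1``).
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3 or frames.shape[-1] != frames.shape[-2]:
        raise ValueError(f"expected (S, M, M) frames, got {frames.shape}")
    m2 = frames.shape[-1] * frames.shape[-2]
    if m2 != model.input_dim:
        raise ValueError(
            f"decoder was trained on {model.input_dim}-entry frames; "
            f"got {frames.shape[-2]}x{frames.shape[-1]} = {m2}"
        )
    flat = frames.reshape(1, frames.shape[0], m2) / model.scale
    ys = model.forward(flat)[0]  # (S, 3)
    if indices is None:
        indices = np.arange(frames.shape[0])
    return ReconstructedSegment(samples=ys.T, indices=np.asarray(indices, dtype=int))


def decode_batch(frames: np.ndarray, model: LSTMDecoderNet,
                 batch_size: int = 64) -> np.ndarray:
    """Decode ``(n, S, M, M)`` stacks to ``(n, S, 3)`` samples."""
    frames = np.asarray(frames, dtype=np.float32)
    n, s = frames.shape[:2]
    flat = frames.reshape(n, s, -1) / model.scale
    out = np.empty((n, s, 3), dtype=np.float32)
    for lo in range(0, n, batch_size):
        out[lo : lo + batch_size] = model.forward(flat[lo : lo + batch_size])
    return out


def stitch_predictions(segments: list) -> ReconstructedSegment:
    """Merge overlapping decoded segments, keeping the earliest value.

    Segments must be ordered by start index.  Where several segments cover
    the same sample index the value from the earliest-issued segment wins;
    indices in the union range covered by no segment are kept as NaN and
    reported in ``gaps`` rather than silently filled.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    starts = [int(s.indices[0]) for s in segments]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("segments must be ordered by start index")
    lo = min(int(s.indices[0]) for s in segments)
    hi = max(int(s.indices[-1]) for s in segments)
    length = hi - lo + 1
    out = np.full((3, length), np.nan)
    for seg in segments:
        pos = seg.indices - lo
        unfilled = np.isnan(out[0, pos])
        out[:, pos[unfilled]] = seg.samples[:, unfilled]
    gap_idx = np.nonzero(np.isnan(out[0]))[0] + lo
    return ReconstructedSegment(
        samples=out, indices=np.arange(lo, hi + 1), gaps=gap_idx.tolist()
    )


def train_signal_decoder(
    dataset: RPSequenceDataset,
    cfg: TrainingConfig | None = None,
    hidden: int = 128,
    head_hidden: int = 64,
    drop_overlap: bool = True,
):
    """Train a decoder on (true target frames -> true signals) pairs.

    Returns ``(model, curves, test_subset)``.  Frames are normalized by the
    training split's maximum distance (stored as ``model.scale``); signals
    stay in raw units.
    """
    cfg = cfg or TrainingConfig()
    train, val, test = split_dataset(dataset, cfg, drop_overlap=drop_overlap)
    m = dataset.grid_size
    model = LSTMDecoderNet(
        input_dim=m * m, hidden=hidden, head_hidden=head_hidden, seed=cfg.seed
    )
    scale = float(train.targets.max(initial=0.0)) or 1.0
    model.scale = scale

    def to_xy(subset):
        n = subset.n_samples
        x = subset.targets.reshape(n, subset.targets.shape[1], -1) / scale
        y = subset.signals.transpose(0, 2, 1)  # (n, T_hat, 3)
        return x, y

    curves = train_model(model, to_xy(train), to_xy(val), cfg)
    return model, curves, test
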