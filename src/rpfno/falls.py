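"""Energy-based early warning for falls from forecasted frame stacks.

A small two-layer classifier is trained to recognize the normal activities
(walking vs. running) from FNO-*predicted* recurrence-plot stacks.  At
deployment the classifier never sees a fall class; instead, the energy
statistic of its logits,

    E(x) = -log sum_i exp(logit_i(x)),

separates in-distribution inputs (low energy) from out-of-distribution
ones (high energy) more sharply than softmax confidence.  A threshold tau
is calibrated as an upper quantile (default 0.95) of the energies on
normal training data — one-class calibration, falls are never used to set
tau — and a window is flagged as a potential fall when its energy exceeds
tau.

Because the energies are computed on *forecasted* frames, an alert can be
raised before the anomalous motion is fully observed: the detector slides
along the stream, forecasting ~0.6 s ahead at every step, and an alert
fires as soon as the forecast stack scores above tau.  When the energy of
subsequently *observed* frames also exceeds tau the event is confirmed as
a fall; the alert lead is the gap between the first alert and the
confirmed onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .encoding import EncodingConfig, frames_from_stream
from .nets import TwoLayerClassifier
from .streams import SensorStream
from .training import TrainingConfig, train_model


def energy_score(logits: np.ndarray) -> np.ndarray | float:
    """Energy statistic ``-log sum exp(logits)``, overflow-safe.

    Accepts a single logit vector or a batch ``(n, C)``; higher energy
    means more out-of-distribution.  Adding a constant c to every logit
    subtracts c from the energy.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise ValueError("empty logit vector")
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    return -logsumexp(logits, axis=-1)


def calibrate_threshold(training_energies, quantile: float = 0.95) -> float:
    """Empirical quantile of normal-data energies (linear interpolation)."""
    energies = np.asarray(training_energies, dtype=float)
    if energies.size == 0:
        raise ValueError("no energies to calibrate on")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(energies, quantile, method="linear"))


def predicted_stacks(fno, dataset, batch_size: int = 64) -> np.ndarray:
    """FNO forecasts for every sample of a dataset, flattened per stack.

    Returns ``(n, T_hat * M * M)`` in the forecaster's normalized units —
    the representation the activity classifier consumes.
    """
    s = fno.scale
    n = dataset.n_samples
    out = None
    for lo in range(0, n, batch_size):
        pred = fno.forward(dataset.inputs[lo : lo + batch_size] / s)
        flat = pred.reshape(pred.shape[0], -1)
        if out is None:
            out = np.empty((n, flat.shape[1]), dtype=np.float32)
        out[lo : lo + flat.shape[0]] = flat
    return out


def train_activity_classifier(
    stacks: np.ndarray,
    labels: np.ndarray,
    cfg: TrainingConfig | None = None,
    hidden: int = 64,
    class_names: tuple = ("walking", "running"),
):
    """Cross-entropy training of the two-layer activity classifier.

    ``stacks`` are flattened predicted frame stacks, ``labels`` integer
    class ids.  At least two classes must be present.  Returns the
    classifier and its learning curves (training cross-entropy only).
    """
    cfg = cfg or TrainingConfig()
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two activity classes to train the classifier")
    model = TwoLayerClassifier(
        input_dim=stacks.shape[1], hidden=hidden, n_classes=len(class_names), seed=cfg.seed
    )
    model.class_names = class_names
    empty = (np.empty((0,) + stacks.shape[1:], dtype=stacks.dtype), np.empty((0,), dtype=int))
    curves = train_model(model, (stacks, labels), empty, cfg)
    return model, curves


def classifier_accuracy(model: TwoLayerClassifier, stacks: np.ndarray,
                        labels: np.ndarray) -> float:
    pred = model.forward(stacks).argmax(axis=1)
    return float(np.mean(pred == np.asarray(labels, dtype=int)))


@dataclass
class EnergyVerdict:
    """Decision for one detector step (anchored at an observed sample)."""

    frame_index: int  # index of the last observed sample at decision time
    energy: float  # energy of the forecast stack
    threshold: float
    decision: str  # "normal" or "potential_fall"
    observed_energy: float = float("nan")

    def __post_init__(self) -> None:
        expected = "potential_fall" if self.energy > self.threshold else "normal"
        if self.decision != expected:
            raise ValueError("decision must equal (energy > threshold)")


@dataclass
class DetectionResult:
    """Full detector trace over one stream."""

    verdicts: list
    threshold: float
    alert_sample: int | None = None  # first forecast-energy exceedance
    confirmed_sample: int | None = None  # first observed-energy exceedance
    meta: dict = field(default_factory=dict)

    @property
    def alert_lead(self) -> int | None:
        """Samples between the early alert and the confirmed fall onset."""
        if self.alert_sample is None or self.confirmed_sample is None:
            return None
        return self.confirmed_sample - self.alert_sample

    @property
    def n_alerts(self) -> int:
        return sum(1 for v in self.verdicts if v.decision == "potential_fall")


def detect(
    stream: SensorStream,
    fno,
    classifier: TwoLayerClassifier,
    threshold: float,
    encoding: EncodingConfig | None = None,
    hop: int = 1,
) -> DetectionResult:
    """Slide the forecaster+classifier over a stream and score energies.

    At each anchor (every ``hop`` frames, once ``T`` input frames are
    available) the forecaster predicts the next ``T_hat`` frames, the
    classifier scores their energy, and energies above the threshold raise
    a potential-fall alert anchored at the current observed sample.  The
    energy of the most recent ``T_hat`` *observed* frames is tracked the
    same way; its first exceedance confirms the event, so the alert lead is
    ``confirmed_sample - alert_sample``.
    """
    encoding = encoding or EncodingConfig()
    t_in, t_out = encoding.input_steps, encoding.horizon
    frames, end_indices = frames_from_stream(stream, encoding)
    n_frames = frames.shape[0]
    if n_frames < t_in:
        raise ValueError("stream too short for one forecast window")
    anchors = np.arange(t_in, n_frames + 1, hop)
    s = fno.scale
    norm = frames / s
    # batch all forecast windows
    inputs = np.stack([norm[a - t_in : a] for a in anchors])
    forecast_flat = None
    for lo in range(0, inputs.shape[0], 64):
        pred = fno.forward(inputs[lo : lo + 64])
        flat = pred.reshape(pred.shape[0], -1)
        if forecast_flat is None:
            forecast_flat = np.empty((inputs.shape[0], flat.shape[1]), dtype=np.float32)
        forecast_flat[lo : lo + flat.shape[0]] = flat
    forecast_energy = energy_score(classifier.forward(forecast_flat))
    # observed stacks: last T_hat observed frames at each anchor
    obs_ok = anchors >= t_out
    observed_energy = np.full(anchors.shape, np.nan)
    obs_stack = np.stack(
        [norm[a - t_out : a].reshape(-1) for a in anchors[obs_ok]]
    )
    if obs_stack.size:
        observed_energy[obs_ok] = energy_score(classifier.forward(obs_stack))

    verdicts = []
    alert_sample = confirmed_sample = None
    for pos, anchor in enumerate(anchors):
        sample_idx = int(end_indices[anchor - 1])
        e = float(forecast_energy[pos])
        decision = "potential_fall" if e > threshold else "normal"
        verdicts.append(
            EnergyVerdict(
                frame_index=sample_idx,
                energy=e,
                threshold=threshold,
                decision=decision,
                observed_energy=float(observed_energy[pos]),
            )
        )
        if decision == "potential_fall" and alert_sample is None:
            alert_sample = sample_idx
        if (
            alert_sample is not None
            and confirmed_sample is None
            and np.isfinite(observed_energy[pos])
            and observed_energy[pos] > threshold
        ):
            confirmed_sample = sample_idx
    return DetectionResult(
        verdicts=verdicts,
        threshold=threshold,
        alert_sample=alert_sample,
        confirmed_sample=confirmed_sample,
        meta={"hop": hop, "n_anchors": len(anchors)},
    )
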