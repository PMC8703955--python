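"""Training protocol and evaluation battery for the forecasting models.

The protocol: Adam, mean-squared-error loss on normalized frame stacks,
batch size 32, 200 epochs with the learning rate starting at 1e-3 and
halved every 50 epochs, and a chronological 6:2:2 train/validation/test
split per subject.  Splits are chronological (not shuffled) because
consecutive sliding-window samples share frames; shuffling would leak
near-duplicates of training windows into the held-out sets.  For the same
reason the first ``T + T_hat - 1`` samples of the validation and test
partitions — whose frame spans still overlap the preceding partition — can
be dropped via ``drop_overlap``.

Frames are min-max normalized by the training split's global maximum
distance before entering any model; the normalizer is stored on the model
(``model.scale``) and travels with its checkpoint.

Evaluation follows the personalized-model design: one forecaster per
subject, and an S x S matrix whose entry (i, j) is the MSE of subject i's
model on subject j's test set.  Low diagonals with high off-diagonals
indicate that each model captured its own subject's gait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import RPSequenceDataset
from .nets import Adam, FNOConfig, FNOForecaster, CNNConfig, CNNForecaster


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule parameters."""

    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    lr_halving_period: int = 50
    split_ratio: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio must sum to 1")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


def split_counts(n: int, ratio=(0.6, 0.2, 0.2)) -> tuple:
    """Floor-allocated chronological split counts, remainder to train.

    Validation and test get ``floor(r * n)`` samples each; training takes
    everything else, so 3600 -> (2160, 720, 720) and 10 -> (6, 2, 2).
    """
    n_val = int(np.floor(ratio[1] * n))
    n_test = int(np.floor(ratio[2] * n))
    return n - n_val - n_test, n_val, n_test


def split_dataset(dataset: RPSequenceDataset, cfg: TrainingConfig | None = None,
                  drop_overlap: bool = False):
    """Contiguous chronological train/validation/test split.

    With ``drop_overlap`` the leading samples of validation and test whose
    input+target frame span still overlaps the previous partition are
    dropped (a sample spans ``T + T_hat`` consecutive frames, so the first
    ``T + T_hat - 1`` samples after each boundary leak and are removed).
    """
    cfg = cfg or TrainingConfig()
    n = dataset.n_samples
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    n_train, n_val, n_test = split_counts(n, cfg.split_ratio)
    span = dataset.config.input_steps + dataset.config.horizon
    guard = span - 1 if drop_overlap else 0
    train = dataset.subset(slice(0, n_train))
    val = dataset.subset(slice(n_train + guard, n_train + n_val))
    test = dataset.subset(slice(n_train + n_val + guard, n))
    if drop_overlap and (val.n_samples < 1 or test.n_samples < 1):
        raise ValueError("partitions too small after dropping boundary-overlap samples")
    return train, val, test


def lr_schedule(epoch: int, cfg: TrainingConfig) -> float:
    """Learning rate at ``epoch``: halved every ``lr_halving_period`` epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.learning_rate * 0.5 ** (epoch // cfg.lr_halving_period)


@dataclass
class LearningCurves:
    """Per-epoch mean training and validation losses."""

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)


def _batched_loss(model, x: np.ndarray, y: np.ndarray, batch_size: int = 64) -> float:
    total, n = 0.0, x.shape[0]
    for lo in range(0, n, batch_size):
        xb = x[lo : lo + batch_size]
        pred = model.forward(xb)
        total += float(np.sum((pred - y[lo : lo + batch_size]) ** 2))
    return total / (n * np.prod(y.shape[1:]))


def train_model(model, train_xy, validation_xy, cfg: TrainingConfig) -> LearningCurves:
    """Minimize MSE (or the model's own loss) with Adam over minibatches.

    ``train_xy`` and ``validation_xy`` are ``(inputs, targets)`` array
    pairs already on the scale the model expects.  Returns the per-epoch
    learning curves; training is deterministic given ``cfg.seed``.  Raises
    ``RuntimeError`` if the loss becomes non-finite.
    """
    x, y = train_xy
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    curves = LearningCurves()
    optimizer = Adam(model.params)
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, batch {n_batches}: "
                    f"loss={loss}"
                )
            optimizer.step(grads, lr)
            epoch_loss += loss
            n_batches += 1
        curves.train.append(epoch_loss / max(n_batches, 1))
        vx, vy = validation_xy
        curves.validation.append(
            _batched_loss(model, vx, vy) if vx.shape[0] else float("nan")
        )
    return curves


def _normalizer(train: RPSequenceDataset) -> float:
    scale = float(max(train.inputs.max(initial=0.0), train.targets.max(initial=0.0)))
    return scale if scale > 0 else 1.0


def make_forecaster(kind: str, dataset_cfg, model_cfg=None, seed: int = 0):
    """Construct an untrained forecaster matching a dataset's geometry."""
    if kind == "fno":
        cfg = model_cfg or FNOConfig(
            input_steps=dataset_cfg.input_steps, horizon=dataset_cfg.horizon
        )
        return FNOForecaster(cfg, seed=seed)
    if kind == "cnn":
        cfg = model_cfg or CNNConfig(
            input_steps=dataset_cfg.input_steps,
            horizon=dataset_cfg.horizon,
            grid_size=dataset_cfg.grid_size,
        )
        return CNNForecaster(cfg, seed=seed)
    raise ValueError(f"unknown forecaster kind {kind!r}; expected 'fno' or 'cnn'")


def train_forecaster(
    dataset: RPSequenceDataset,
    kind: str = "fno",
    cfg: TrainingConfig | None = None,
    model_cfg=None,
    drop_overlap: bool = True,
):
    """Split, normalize and train one per-subject forecaster.

    Returns ``(model, curves, test_subset)``; the normalizer (the training
    split's maximum distance) is stored on ``model.scale`` and the test
    subset is kept raw for later cross-subject evaluation.
    """
    cfg = cfg or TrainingConfig()
    train, val, test = split_dataset(dataset, cfg, drop_overlap=drop_overlap)
    model = make_forecaster(kind, dataset.config, model_cfg, seed=cfg.seed)
    model.scale = _normalizer(train)
    s = model.scale
    curves = train_model(
        model,
        (train.inputs / s, train.targets / s),
        (val.inputs / s, val.targets / s),
        cfg,
    )
    return model, curves, test


def evaluate_mse(model, dataset: RPSequenceDataset, batch_size: int = 64,
                 relative: bool = False) -> float:
    """Mean squared error of a forecaster on a dataset.

    By default the MSE is in the model's normalized frame units (training
    loss scale).  With ``relative=True`` predictions are compared in raw
    distance units and divided by the test set's own mean squared target,
    giving a dimensionless relative error that is comparable across
    subjects of different movement amplitude — the scale cross-subject
    matrices are reported on.
    """
    s = model.scale
    mse = _batched_loss(model, dataset.inputs / s, dataset.targets / s, batch_size)
    if not relative:
        return mse
    raw_mse = mse * s * s
    denom = float(np.mean(dataset.targets.astype(np.float64) ** 2))
    return raw_mse / denom


@dataclass
class EvalReport:
    """Cross-subject evaluation: MSE matrix plus per-subject curves."""

    mse_matrix: np.ndarray  # (S, S): row = model's subject, column = test subject
    subject_ids: list
    model_kind: str
    learning_curves: dict = field(default_factory=dict)  # subject -> LearningCurves

    def to_json(self) -> str:
        payload = {
            "model_kind": self.model_kind,
            "subject_ids": self.subject_ids,
            "mse_matrix": np.asarray(self.mse_matrix).tolist(),
            "learning_curves": {
                sid: {"train": c.train, "validation": c.validation}
                for sid, c in self.learning_curves.items()
            },
        }
        return json.dumps(payload, indent=2)


def cross_subject_mse_matrix(models: list, testsets: list, curves: dict | None = None,
                             model_kind: str = "") -> EvalReport:
    """Evaluate every subject's model on every subject's test set.

    Entries are relative MSEs (raw-unit squared error over the test set's
    mean squared target) so that rows are comparable across subjects with
    different movement amplitudes; a personalized model shows a low
    diagonal against its own row's off-diagonal entries.
    """
    if len(models) != len(testsets):
        raise ValueError("need one test set per model")
    s = len(models)
    matrix = np.zeros((s, s))
    for i, model in enumerate(models):
        for j, testset in enumerate(testsets):
            matrix[i, j] = evaluate_mse(model, testset, relative=True)
    subject_ids = [t.subject_id or f"s{j + 1}" for j, t in enumerate(testsets)]
    kind = model_kind or getattr(models[0], "kind", "")
    return EvalReport(matrix, subject_ids, kind, curves or {})


def compare_models(report_fno: EvalReport, report_cnn: EvalReport) -> dict:
    """Diagonal MSE ratios CNN/FNO and the per-subject ordering flag."""
    a = np.asarray(report_fno.mse_matrix)
    b = np.asarray(report_cnn.mse_matrix)
    if a.shape != b.shape:
        raise ValueError("reports have mismatched shapes")
    d_fno, d_cnn = np.diag(a), np.diag(b)
    ratios = d_cnn / d_fno
    return {
        "subject_ids": report_fno.subject_ids,
        "fno_diagonal": d_fno.tolist(),
        "cnn_diagonal": d_cnn.tolist(),
        "cnn_over_fno_ratio": ratios.tolist(),
        "fno_never_worse": bool(np.all(d_fno <= d_cnn)),
    }


def overfit_ratio(curves: LearningCurves) -> float:
    """Final validation loss over its running minimum (1.0 = no blow-up)."""
    val = np.asarray(curves.validation, dtype=float)
    if val.size == 0 or not np.isfinite(val).all():
        return float("nan")
    return float(val[-1] / val.min())
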