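"""Shared fixtures.

Heavy fixtures (trained models) are session-scoped and sized for a desk-
scale run: 35 s streams at 30 Hz per subject (~600 training samples after
the 6:2:2 split), FNO width 16, 12 epochs.  Everything is generated
programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import rpfno as rp
from rpfno.nets import FNOConfig, CNNConfig

DESK_DURATION_S = 35.0
DESK_RATE_HZ = 30.0
DESK_EPOCHS = 20
DESK_FNO = FNOConfig(width=16)
DESK_CNN = CNNConfig(channels=6, hidden=(96, 96))


@pytest.fixture(scope="session")
def cohort_profiles():
    return rp.make_cohort(6, "walking", seed=7)


@pytest.fixture(scope="session")
def cohort_datasets(cohort_profiles):
    datasets = []
    for profile in cohort_profiles:
        stream = rp.generate_motion_stream(profile, DESK_DURATION_S, DESK_RATE_HZ)
        datasets.append(rp.encode_stream(stream))
    return datasets


@pytest.fixture(scope="session")
def trained_cohort(cohort_datasets):
    """One personalized FNO per synthetic subject."""
    models, tests, curves = [], [], {}
    for i, ds in enumerate(cohort_datasets):
        cfg = rp.TrainingConfig(epochs=DESK_EPOCHS, seed=11 + i)
        model, curve, test = rp.train_forecaster(ds, "fno", cfg, DESK_FNO)
        models.append(model)
        tests.append(test)
        curves[ds.subject_id or f"s{i + 1}"] = curve
    return SimpleNamespace(models=models, tests=tests, curves=curves)


@pytest.fixture(scope="session")
def cohort_report(trained_cohort):
    return rp.cross_subject_mse_matrix(
        trained_cohort.models, trained_cohort.tests, trained_cohort.curves
    )


@pytest.fixture(scope="session")
def cnn_cohort(cohort_datasets):
    """Matched-budget CNN baselines (same data, epochs and seeds)."""
    models, tests, curves = [], [], {}
    for i, ds in enumerate(cohort_datasets):
        cfg = rp.TrainingConfig(epochs=DESK_EPOCHS, seed=11 + i)
        model, curve, test = rp.train_forecaster(ds, "cnn", cfg, DESK_CNN)
        models.append(model)
        tests.append(test)
        curves[ds.subject_id or f"s{i + 1}"] = curve
    return SimpleNamespace(models=models, tests=tests, curves=curves)


@pytest.fixture(scope="session")
def decoder_setup(cohort_datasets):
    """Signal decoder trained on subject 1's walking frames."""
    cfg = rp.TrainingConfig(epochs=15, seed=3)
    model, curves, test = rp.train_signal_decoder(
        cohort_datasets[0], cfg, hidden=96, head_hidden=64
    )
    return SimpleNamespace(model=model, curves=curves, test=test)


@pytest.fixture(scope="session")
def fall_setup(cohort_profiles, cohort_datasets):
    """Forecaster on walking+running, activity classifier, calibrated tau."""
    cfg = rp.TrainingConfig(epochs=DESK_EPOCHS, seed=21)
    walk = cohort_datasets[0]
    run_profile = rp.make_subject_profile(
        cohort_profiles[0].subject_id, "running", seed=71
    )
    run = rp.encode_stream(
        rp.generate_motion_stream(run_profile, DESK_DURATION_S, DESK_RATE_HZ)
    )
    wtr, wval, wtest = rp.split_dataset(walk, cfg, drop_overlap=True)
    rtr, _rval, rtest = rp.split_dataset(run, cfg, drop_overlap=True)
    fno = rp.FNOForecaster(DESK_FNO, seed=21)
    inputs = np.concatenate([wtr.inputs, rtr.inputs])
    targets = np.concatenate([wtr.targets, rtr.targets])
    fno.scale = float(max(inputs.max(), targets.max()))
    rp.train_model(
        fno,
        (inputs / fno.scale, targets / fno.scale),
        (wval.inputs / fno.scale, wval.targets / fno.scale),
        cfg,
    )
    train_stacks = np.concatenate(
        [rp.predicted_stacks(fno, wtr), rp.predicted_stacks(fno, rtr)]
    )
    train_labels = np.concatenate(
        [np.zeros(wtr.n_samples, int), np.ones(rtr.n_samples, int)]
    )
    classifier, _ = rp.train_activity_classifier(
        train_stacks, train_labels, rp.TrainingConfig(epochs=10, seed=5)
    )
    tau = rp.calibrate_threshold(
        rp.energy_score(classifier.forward(train_stacks)), quantile=0.95
    )
    held_stacks = np.concatenate(
        [rp.predicted_stacks(fno, wtest), rp.predicted_stacks(fno, rtest)]
    )
    held_labels = np.concatenate(
        [np.zeros(wtest.n_samples, int), np.ones(rtest.n_samples, int)]
    )
    return SimpleNamespace(
        fno=fno,
        classifier=classifier,
        tau=tau,
        train_stacks=train_stacks,
        held_stacks=held_stacks,
        held_labels=held_labels,
        profile=cohort_profiles[0],
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, quick dataset for unit-level pipeline tests (17 x 17 grid)."""
    profile = rp.make_subject_profile("tiny", "walking", seed=3)
    stream = rp.generate_motion_stream(profile, 16.0, 30.0)
    cfg = rp.EncodingConfig(window_size=3, input_steps=10, horizon=5)
    return rp.encode_stream(stream, cfg)
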