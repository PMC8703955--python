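"""Training protocol: splits, schedule, determinism, evaluation."""

import numpy as np
import pytest

import rpfno as rp
from rpfno.nets import FNOConfig, FNOForecaster
from rpfno.training import split_counts, LearningCurves


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(3600, (2160, 720, 720)), (10, (6, 2, 2)), (1747, (1049, 349, 349))],
    )
    def test_floor_allocation_counts(self, n, expected):
        assert split_counts(n) == expected
        assert sum(split_counts(n)) == n

    def test_chronological_disjoint_exhaustive(self, tiny_dataset):
        train, val, test = rp.split_dataset(tiny_dataset)
        n = tiny_dataset.n_samples
        assert train.n_samples + val.n_samples + test.n_samples == n
        # chronological: first target indices are ordered without overlap
        assert train.target_end_indices[-1, 0] < val.target_end_indices[0, 0]
        assert val.target_end_indices[-1, 0] < test.target_end_indices[0, 0]

    def test_drop_overlap_removes_leaky_samples(self, tiny_dataset):
        cfg = rp.TrainingConfig()
        plain = rp.split_dataset(tiny_dataset, cfg)
        guarded = rp.split_dataset(tiny_dataset, cfg, drop_overlap=True)
        span = tiny_dataset.config.input_steps + tiny_dataset.config.horizon
        assert plain[1].n_samples - guarded[1].n_samples == span - 1
        assert plain[2].n_samples - guarded[2].n_samples == span - 1
        # no frame shared between train and guarded validation
        last_train_frame = plain[0].target_end_indices[-1, -1]
        first_val_frame_start = guarded[1].target_end_indices[0, 0] - (
            span - 1 + tiny_dataset.config.window_size - 1
        )
        assert first_val_frame_start > last_train_frame - span

    def test_too_few_samples_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="at least 10"):
            rp.split_dataset(tiny_dataset.subset(slice(0, 5)))


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected", [(0, 1e-3), (49, 1e-3), (50, 5e-4), (100, 2.5e-4), (199, 1.25e-4)]
    )
    def test_halving_every_50_epochs(self, epoch, expected):
        assert rp.lr_schedule(epoch, rp.TrainingConfig()) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            rp.lr_schedule(-1, rp.TrainingConfig())


class TestTrainModel:
    def test_zero_epochs_returns_empty_curves_and_untouched_model(self, tiny_dataset):
        cfg = rp.TrainingConfig(epochs=0, seed=0)
        model_cfg = FNOConfig(width=4, modes=3, input_steps=10, horizon=5)
        model, curves, _ = rp.train_forecaster(tiny_dataset, "fno", cfg, model_cfg)
        reference = FNOForecaster(model_cfg, seed=0)
        assert curves.train == [] and curves.validation == []
        for key in model.params:
            assert np.array_equal(model.params[key], reference.params[key])

    def test_validation_improves_on_synthetic_subject(self, tiny_dataset):
        cfg = rp.TrainingConfig(epochs=5, seed=1)
        model_cfg = FNOConfig(width=8, modes=4, input_steps=10, horizon=5)
        _, curves, _ = rp.train_forecaster(tiny_dataset, "fno", cfg, model_cfg)
        assert curves.validation[-1] < curves.validation[0]

    def test_training_deterministic_given_seed(self, tiny_dataset):
        cfg = rp.TrainingConfig(epochs=2, seed=4)
        model_cfg = FNOConfig(width=4, modes=3, input_steps=10, horizon=5)
        m1, c1, _ = rp.train_forecaster(tiny_dataset, "fno", cfg, model_cfg)
        m2, c2, _ = rp.train_forecaster(tiny_dataset, "fno", cfg, model_cfg)
        assert c1.train == c2.train
        for key in m1.params:
            assert np.array_equal(m1.params[key], m2.params[key])

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostics(self, tiny_dataset):
        cfg = rp.TrainingConfig(epochs=1, seed=0)
        model = FNOForecaster(FNOConfig(width=4, modes=3, input_steps=10, horizon=5))
        # sigmoid layers bound the hidden states, so corrupt the final
        # linear projection to force a non-finite loss
        model.params["proj_W"][:] = np.float32(1e30)
        train, val, _ = rp.split_dataset(tiny_dataset, cfg)
        with pytest.raises(RuntimeError, match="diverged"):
            rp.train_model(model, (train.inputs, train.targets),
                           (val.inputs, val.targets), cfg)


class TestEvaluation:
    def test_mse_invariant_to_sample_order(self, tiny_dataset):
        cfg = rp.TrainingConfig(epochs=1, seed=2)
        model, _, test = rp.train_forecaster(
            tiny_dataset, "fno", cfg, FNOConfig(width=4, modes=3, input_steps=10, horizon=5)
        )
        direct = rp.evaluate_mse(model, test)
        rng = np.random.default_rng(0)
        shuffled = test.subset(rng.permutation(test.n_samples))
        assert rp.evaluate_mse(model, shuffled) == pytest.approx(direct, rel=1e-6)

    def test_matrix_bookkeeping(self, trained_cohort, cohort_report):
        matrix = np.asarray(cohort_report.mse_matrix)
        assert matrix.shape == (6, 6)
        assert np.all(matrix >= 0)
        # diagonal entry i is model i evaluated on its own test set
        own = rp.evaluate_mse(
            trained_cohort.models[2], trained_cohort.tests[2], relative=True
        )
        assert matrix[2, 2] == pytest.approx(own, rel=1e-6)

    def test_compare_models_identity_and_scale_invariance(self, cohort_report):
        identical = rp.compare_models(cohort_report, cohort_report)
        assert np.allclose(identical["cnn_over_fno_ratio"], 1.0)
        assert identical["fno_never_worse"]
        scaled = rp.EvalReport(
            np.asarray(cohort_report.mse_matrix) * 3.7,
            cohort_report.subject_ids,
            "cnn",
        )
        ratios = rp.compare_models(cohort_report, scaled)["cnn_over_fno_ratio"]
        assert np.allclose(ratios, 3.7)

    def test_overfit_ratio(self):
        curves = LearningCurves(train=[1, 0.5], validation=[1.0, 0.4, 0.5])
        assert rp.overfit_ratio(curves) == pytest.approx(1.25)
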