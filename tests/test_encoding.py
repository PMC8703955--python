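"""Recurrence-plot encoding: windows, interpolation, RP/CRP, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rpfno as rp
from rpfno.encoding import EncodingConfig, thresholded_recurrence_plot
from rpfno.streams import SensorStream


def _stream(n, seed=0, rate=30.0):
    rng = np.random.default_rng(seed)
    return SensorStream(np.arange(n) / rate, rng.standard_normal((3, n)), rate)


class TestWindowing:
    def test_concatenated_window_length_is_15(self):
        vectors, _ = rp.window_axes(_stream(50), EncodingConfig())
        assert vectors.shape[1] == 15

    def test_window_size_one_is_current_sample(self):
        stream = _stream(10)
        vectors, ends = rp.window_axes(stream, EncodingConfig(window_size=1))
        assert np.allclose(vectors, stream.axes.T)
        assert np.array_equal(ends, np.arange(10))

    @pytest.mark.parametrize("n,tw,stride", [(10, 5, 1), (20, 5, 3), (7, 7, 1), (30, 4, 5)])
    def test_window_count_formula_vs_enumeration(self, n, tw, stride):
        stream = _stream(n)
        vectors, ends = rp.window_axes(stream, EncodingConfig(window_size=tw, stride=stride))
        expected_ends = list(range(tw - 1, n, stride))
        assert vectors.shape[0] == (n - tw) // stride + 1 == len(expected_ends)
        assert list(ends) == expected_ends
        # brute-force window content
        for row, t in zip(vectors, ends):
            manual = np.concatenate(
                [stream.axes[ax, t - tw + 1 : t + 1] for ax in range(3)]
            )
            assert np.allclose(row, manual)

    def test_stream_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window_size"):
            rp.window_axes(_stream(3), EncodingConfig(window_size=5))


class TestInterpolation:
    def test_midpoints(self):
        assert np.allclose(rp.interpolate_window(np.array([0.0, 2.0])), [0, 1, 2])
        assert np.allclose(
            rp.interpolate_window(np.array([1.0, 4.0, 9.0])), [1, 2.5, 4, 6.5, 9]
        )

    def test_length_15_gives_29(self):
        out = rp.interpolate_window(np.arange(15.0))
        assert out.shape == (29,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            rp.interpolate_window(np.array([1.0]))

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_even_positions_recover_original(self, values):
        x = np.asarray(values)
        out = rp.interpolate_window(x)
        assert out.shape == (2 * x.size - 1,)
        assert np.allclose(out[0::2], x)
        assert np.allclose(out[1::2], 0.5 * (x[:-1] + x[1:]))


class TestRecurrencePlot:
    def test_constant_vector_gives_zero_grid(self):
        grid = rp.recurrence_plot(np.full(7, 3.5))
        assert grid.shape == (7, 7)
        assert np.all(grid == 0)

    def test_small_example(self):
        grid = rp.recurrence_plot(np.array([0.0, 1.0, 3.0]))
        assert np.allclose(grid, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_29_vector_gives_29x29(self):
        grid = rp.recurrence_plot(np.arange(29.0))
        assert grid.shape == (29, 29)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=29))
    @settings(deadline=None, max_examples=60)
    def test_matches_bruteforce_and_invariants(self, values):
        x = np.asarray(values)
        grid = rp.recurrence_plot(x)
        brute = np.array([[abs(a - b) for b in x] for a in x])
        assert np.allclose(grid, brute)
        assert np.allclose(grid, grid.T)
        assert np.allclose(np.diag(grid), 0)
        assert np.all(grid >= 0)

    def test_triangle_type_bound(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(29)
        y = rp.recurrence_plot(x)
        # |Y[i,k] - Y[k,j]| <= Y[i,j] for every i, j, k (reverse triangle)
        diff = np.abs(y[:, None, :] - y.T[None, :, :])  # (i, j, k)
        assert np.all(diff.max(axis=2) <= y + 1e-12)

    def test_sign_flip_and_offset_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(15)
        base = rp.recurrence_plot(x)
        assert np.allclose(rp.recurrence_plot(-x + 4.2), base)

    def test_thresholded_reference_variant(self):
        x = np.array([0.0, 1.0, 3.0])
        binary = thresholded_recurrence_plot(x, epsilon=1.5)
        assert np.array_equal(binary, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])


class TestCrossRecurrencePlot:
    def test_degenerate_crp_equals_rp(self):
        x = np.random.default_rng(2).standard_normal(12)
        assert np.allclose(rp.cross_recurrence_plot(x, x), rp.recurrence_plot(x))

    def test_small_example_and_asymmetry(self):
        grid = rp.cross_recurrence_plot(np.array([0.0, 1.0]), np.array([2.0, 0.0]))
        assert np.allclose(grid, [[2, 0], [1, 1]])
        assert not np.allclose(grid, grid.T)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rp.cross_recurrence_plot(np.zeros(4), np.zeros(5))

    def test_gyro_accel_fusion_gives_29_grid(self):
        profile = rp.make_subject_profile("s1", "walking", seed=7)
        gyro = rp.generate_motion_stream(profile, 5.0, 30.0)
        accel = rp.companion_accelerometer_stream(profile, 5.0, 30.0)
        dataset = rp.encode_stream(gyro, accel_stream=accel)
        assert dataset.grid_size == 29
        crp = dataset.inputs[0, 0]
        assert not np.allclose(crp, crp.T)  # CRPs are not symmetric in general


class TestAssembly:
    def test_counts_from_60s_stream(self):
        profile = rp.make_subject_profile("s1", "walking", seed=7)
        stream = rp.generate_motion_stream(profile, 60.0, 30.0)
        dataset = rp.encode_stream(stream)
        # 1800 samples -> 1796 frames -> 1796 - 50 + 1 samples
        assert dataset.n_samples == 1747
        assert dataset.inputs.shape == (1747, 30, 29, 29)
        assert dataset.targets.shape == (1747, 20, 29, 29)
        assert dataset.signals.shape == (1747, 3, 20)

    def test_exactly_t_plus_horizon_frames_give_one_sample(self):
        cfg = EncodingConfig(input_steps=4, horizon=2)
        stream = _stream(5 + 4 + 2 - 1)  # Tw-1 + needed frames
        dataset = rp.encode_stream(stream, cfg)
        assert dataset.n_samples == 1

    def test_too_few_frames_rejected(self):
        cfg = EncodingConfig(input_steps=4, horizon=2)
        with pytest.raises(ValueError, match="frames"):
            rp.encode_stream(_stream(8), cfg)

    def test_input_spans_one_second_at_30hz(self):
        cfg = EncodingConfig()
        assert cfg.input_steps / 30.0 == 1.0  # 30 frames at stride 1 = 1 s
        assert cfg.horizon / 30.0 == pytest.approx(0.6667, abs=1e-3)

    def test_target_signals_aligned_to_frame_ends(self):
        stream = _stream(80, seed=5)
        cfg = EncodingConfig(input_steps=6, horizon=3)
        dataset = rp.encode_stream(stream, cfg)
        for i in (0, 10, dataset.n_samples - 1):
            ends = dataset.target_end_indices[i]
            assert np.allclose(dataset.signals[i], stream.axes[:, ends])

    def test_frames_are_consecutive(self, tiny_dataset):
        # sample i's target frames are sample (i+1)'s shifted by one
        assert np.allclose(tiny_dataset.inputs[1, :-1], tiny_dataset.inputs[0, 1:])


def test_hdf5_round_trip(tmp_path, tiny_dataset):
    path = tmp_path / "data.h5"
    tiny_dataset.save(path)
    back = rp.RPSequenceDataset.load(path)
    assert back.config == tiny_dataset.config
    assert np.array_equal(back.inputs, tiny_dataset.inputs)
    assert np.array_equal(back.signals, tiny_dataset.signals)
    assert back.subject_id == tiny_dataset.subject_id
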