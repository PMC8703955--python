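"""Fourier neural operator and CNN baseline: spectral oracles, shapes, training."""

import numpy as np
import pytest

import rpfno as rp
from rpfno.nets import FNOConfig, FNOForecaster, CNNConfig, CNNForecaster
from rpfno.nets.fno import spectral_conv_forward, max_modes

rng = np.random.default_rng(0)


def _identity_weights(channels, k):
    r = np.zeros((channels, channels, k, k), dtype=complex)
    for c in range(channels):
        r[c, c] = 1.0
    return r


class TestSpectralModule:
    def test_zero_input_gives_zero_output(self):
        r = rng.standard_normal((3, 3, 2, 2)) + 1j * rng.standard_normal((3, 3, 2, 2))
        out, _ = spectral_conv_forward(np.zeros((2, 3, 9, 9)), r, 2)
        assert np.allclose(out, 0)

    @pytest.mark.parametrize("m", [5, 7, 29])
    def test_full_modes_identity(self, m):
        k = max_modes(m)
        v = rng.standard_normal((2, 2, m, m))
        out, _ = spectral_conv_forward(v, _identity_weights(2, k), k)
        assert np.allclose(out, v, atol=1e-10)

    def test_linearity(self):
        r = rng.standard_normal((2, 2, 3, 3)) + 1j * rng.standard_normal((2, 2, 3, 3))
        v1 = rng.standard_normal((1, 2, 11, 11))
        v2 = rng.standard_normal((1, 2, 11, 11))
        combined, _ = spectral_conv_forward(2.0 * v1 - 3.0 * v2, r, 3)
        o1, _ = spectral_conv_forward(v1, r, 3)
        o2, _ = spectral_conv_forward(v2, r, 3)
        assert np.allclose(combined, 2.0 * o1 - 3.0 * o2, atol=1e-10)

    def test_dc_mode_algebra(self):
        # k=1 keeps only the mean: constant input c maps to c . Re(R[., ., 0, 0])
        r = rng.standard_normal((3, 2, 1, 1)) + 1j * rng.standard_normal((3, 2, 1, 1))
        c = rng.standard_normal(3)
        v = np.ones((1, 3, 5, 5)) * c[None, :, None, None]
        out, _ = spectral_conv_forward(v, r, 1)
        expected = c @ r[:, :, 0, 0].real
        assert np.allclose(out, expected[None, :, None, None], atol=1e-12)

    def test_matches_fft_reference(self):
        # independent oracle: full rfft2 with explicit mode masking
        import scipy.fft as sfft

        m, k = 13, 4
        v = rng.standard_normal((2, 3, m, m))
        r = rng.standard_normal((3, 3, k, k)) + 1j * rng.standard_normal((3, 3, k, k))
        vh = sfft.rfft2(v, axes=(-2, -1))
        out_hat = np.zeros((2, 3, m, vh.shape[-1]), dtype=complex)
        out_hat[:, :, :k, :k] = np.einsum("bcxy,cdxy->bdxy", vh[:, :, :k, :k], r)
        out_hat[:, :, m - k + 1 :, :k] = np.einsum(
            "bcxy,cdxy->bdxy",
            vh[:, :, m - k + 1 :, :k],
            np.conj(r[:, :, k - 1 : 0 : -1, :]),
        )
        reference = sfft.irfft2(out_hat, s=(m, m), axes=(-2, -1))
        ours, _ = spectral_conv_forward(v, r, k)
        assert np.allclose(ours, reference, atol=1e-10)

    def test_cyclic_shift_commutes_at_full_modes(self):
        m = 9
        k = max_modes(m)
        r = rng.standard_normal((2, 2, k, k)) + 1j * rng.standard_normal((2, 2, k, k))
        # make the full-spectrum multiplier Hermitian-consistent per mode by
        # using the operator itself: shift equivariance holds for any weights
        v = rng.standard_normal((1, 2, m, m))
        out, _ = spectral_conv_forward(v, r, k)
        shifted_out, _ = spectral_conv_forward(np.roll(v, (2, 3), axis=(-2, -1)), r, k)
        assert np.allclose(np.roll(out, (2, 3), axis=(-2, -1)), shifted_out, atol=1e-9)

    def test_inadmissible_modes_rejected_with_bound(self):
        v = np.zeros((1, 2, 9, 9))
        r = _identity_weights(2, 6)
        with pytest.raises(ValueError, match=r"\(M \+ 1\) // 2 = 5"):
            spectral_conv_forward(v, r, 6)


class TestFNOForecaster:
    def test_shape_contract_30_to_20(self):
        model = FNOForecaster(FNOConfig(width=4, modes=3), seed=0)
        out = model.forward(rng.standard_normal((2, 30, 29, 29)).astype(np.float32))
        assert out.shape == (2, 20, 29, 29)

    def test_zero_projection_gives_zero_prediction(self):
        model = FNOForecaster(FNOConfig(width=4, modes=2), seed=0)
        model.params["proj_W"][:] = 0.0
        model.params["proj_b"][:] = 0.0
        out = model.forward(rng.standard_normal((1, 30, 17, 17)).astype(np.float32))
        assert np.allclose(out, 0)

    def test_zero_weight_layer_outputs_half(self):
        # sigma(0) = 0.5: with all weights and biases zero every layer state is 0.5
        model = FNOForecaster(FNOConfig(num_layers=2, width=3, modes=2,
                                        input_steps=4, horizon=2), seed=0)
        for key in model.params:
            model.params[key][:] = 0.0
        _, cache = model._forward(rng.standard_normal((1, 4, 9, 9)), want_cache=True)
        assert np.allclose(cache["out0"], 0.5)
        assert np.allclose(cache["out1"], 0.5)

    def test_layer_states_lie_in_unit_interval(self):
        model = FNOForecaster(FNOConfig(num_layers=3, width=4, modes=2,
                                        input_steps=5, horizon=2), seed=1)
        _, cache = model._forward(
            5.0 * rng.standard_normal((2, 5, 9, 9)), want_cache=True
        )
        for layer in range(3):
            state = cache[f"out{layer}"]
            assert np.all(state > 0) and np.all(state < 1)

    def test_param_count_independent_of_grid_size(self):
        model = FNOForecaster(FNOConfig(width=4, modes=3, input_steps=6, horizon=2), seed=0)
        n_params = model.param_count
        for m in (17, 23, 29):
            out = model.evaluate_at_resolution(
                rng.standard_normal((1, 6, m, m)).astype(np.float32)
            )
            assert out.shape == (1, 2, m, m)
            assert model.param_count == n_params

    def test_shape_mismatch_rejected(self):
        model = FNOForecaster(FNOConfig(width=4, modes=2), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model.forward(np.zeros((1, 10, 29, 29)))
        with pytest.raises(ValueError, match="square"):
            model.forward(np.zeros((1, 30, 29, 23)))

    def test_single_sample_overfit(self):
        cfg = FNOConfig(num_layers=2, width=24, modes=4, input_steps=6, horizon=4)
        model = FNOForecaster(cfg, seed=2)
        x = rng.random((1, 6, 11, 11)).astype(np.float32)
        y = rng.random((1, 4, 11, 11)).astype(np.float32)
        curves = rp.train_model(
            model, (x, y), (x[:0], y[:0]),
            rp.TrainingConfig(batch_size=1, epochs=500, learning_rate=2e-2,
                              lr_halving_period=10**6, seed=0),
        )
        assert curves.train[-1] < 1e-3


class TestCNNBaseline:
    def test_shape_contract_and_same_padding(self):
        for m in (9, 17):
            cfg = CNNConfig(channels=3, hidden=(8, 8), input_steps=5, horizon=2,
                            grid_size=m)
            model = CNNForecaster(cfg, seed=0)
            out = model.forward(rng.standard_normal((2, 5, m, m)).astype(np.float32))
            assert out.shape == (2, 2, m, m)

    def test_locked_to_training_grid(self):
        model = CNNForecaster(CNNConfig(channels=3, hidden=(8, 8)), seed=0)
        with pytest.raises(ValueError, match="cannot run"):
            model.forward(np.zeros((1, 30, 23, 23)))

    def test_parameter_budget_reported(self):
        model = CNNForecaster(CNNConfig(channels=6, hidden=(96, 96)), seed=0)
        assert model.param_count == sum(v.size for v in model.params.values())
        assert model.param_count > 0

    def test_single_sample_overfit(self):
        cfg = CNNConfig(channels=4, hidden=(16, 16), input_steps=6, horizon=4,
                        grid_size=11)
        model = CNNForecaster(cfg, seed=2)
        x = rng.random((1, 6, 11, 11)).astype(np.float32)
        y = rng.random((1, 4, 11, 11)).astype(np.float32)
        curves = rp.train_model(
            model, (x, y), (x[:0], y[:0]),
            rp.TrainingConfig(batch_size=1, epochs=300, learning_rate=3e-3,
                              lr_halving_period=150, seed=0),
        )
        assert curves.train[-1] < 1e-2
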