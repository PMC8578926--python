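"""Resampling, derivative, normalization, splitting and noise tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elastnet import (
    PressureWave,
    WaveformMatrix,
    add_awgn,
    bp_summary,
    fit_channel_scalers,
    make_channels,
    minmax_apply,
    minmax_fit,
    resample_to_200,
    split_60_20_20,
    time_derivative,
)
from elastnet.preprocessing import minmax_inverse


class TestResample:
    def test_identity_on_200_uniform_samples(self):
        s = np.random.default_rng(0).normal(100, 10, 200)
        out = resample_to_200(PressureWave(s, 0.8))
        assert np.allclose(out, s)

    def test_constant_wave_any_length(self):
        out = resample_to_200(PressureWave(np.full(37, 100.0), 0.9))
        assert out.shape == (200,)
        assert np.allclose(out, 100.0)

    def test_sine_cycle_against_analytic_values(self):
        T = 0.8
        t50 = np.arange(50) * T / 50
        wave = PressureWave(100 + 20 * np.sin(2 * np.pi * t50 / T), T)
        out = resample_to_200(wave)
        t200 = np.arange(200) * T / 200
        expected = 100 + 20 * np.sin(2 * np.pi * t200 / T)
        assert np.max(np.abs(out - expected)) < 0.2  # linear-interp error bound

    def test_first_sample_preserved(self):
        s = np.random.default_rng(1).normal(100, 10, 63)
        out = resample_to_200(PressureWave(s, 0.7))
        assert out[0] == s[0]

    def test_preserves_bp_summary_on_simulator_output(self, reference_simulation):
        w = reference_simulation.pressure["left_brachial"]
        out = bp_summary(PressureWave(resample_to_200(w), w.period))
        orig = bp_summary(w)
        assert out.SBP == pytest.approx(orig.SBP, abs=0.5)
        assert out.DBP == pytest.approx(orig.DBP, abs=0.5)


class TestTimeDerivative:
    def test_constant_wave_gives_zeros(self):
        assert np.all(time_derivative(np.full(200, 95.0), 0.8) == 0.0)

    def test_exact_on_linear_interior(self):
        a = 3.7
        f = a * np.arange(200.0)
        tau = 0.8 / 200
        d = time_derivative(f, 0.8)
        assert np.allclose(d[1:199], a / tau)

    def test_second_order_accurate_on_sinusoid(self):
        T = 1.0
        t = np.arange(200) * T / 200
        f = np.sin(2 * np.pi * t / T)
        d = time_derivative(f, T)
        exact = (2 * np.pi / T) * np.cos(2 * np.pi * t / T)
        assert np.max(np.abs(d - exact)) <= 1e-2 * (2 * np.pi / T)

    def test_periodic_wraparound_at_endpoints(self):
        T = 1.0
        t = np.arange(200) * T / 200
        f = np.sin(2 * np.pi * t / T)
        d = time_derivative(f, T)
        tau = T / 200
        assert d[0] == pytest.approx((f[1] - f[199]) / (2 * tau))
        assert d[199] == pytest.approx((f[0] - f[198]) / (2 * tau))

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        f, g = rng.normal(size=(2, 200))
        lhs = time_derivative(a * f + b * g, 0.8)
        rhs = a * time_derivative(f, 0.8) + b * time_derivative(g, 0.8)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_rowwise_periods(self):
        x = np.vstack([np.sin(np.linspace(0, 2 * np.pi, 200, endpoint=False))] * 2)
        d = time_derivative(x, np.array([0.5, 1.0]))
        assert np.allclose(d[0], 2.0 * d[1])

    def test_rejects_nonpositive_period(self):
        with pytest.raises(ValueError):
            time_derivative(np.ones(200), 0.0)


class TestMinMax:
    def test_fit_records_column_extremes(self):
        x = np.array([[0.0, 5.0], [1.0, 7.0], [0.5, 6.0]])
        st_ = minmax_fit(x)
        assert np.allclose(st_.data_min, [0.0, 5.0])
        assert np.allclose(st_.data_max, [1.0, 7.0])

    def test_training_rows_map_into_unit_interval(self):
        x = np.random.default_rng(2).normal(size=(50, 200))
        st_ = minmax_fit(x)
        z = minmax_apply(x, st_)
        assert z.min() >= 0.0 and z.max() <= 1.0
        assert np.any(z == 0.0) and np.any(z == 1.0)

    def test_out_of_range_values_not_clipped(self):
        st_ = minmax_fit(np.array([[0.0], [1.0]]))
        assert minmax_apply(np.array([[2.0]]), st_)[0, 0] == pytest.approx(2.0)

    def test_constant_columns_map_to_zero(self):
        x = np.ones((5, 3))
        x[:, 1] = np.arange(5)
        st_ = minmax_fit(x)
        z = minmax_apply(x, st_)
        assert np.all(z[:, 0] == 0.0) and np.all(z[:, 2] == 0.0)

    def test_round_trip_identity_on_nonconstant_columns(self):
        x = np.random.default_rng(3).normal(size=(20, 8))
        st_ = minmax_fit(x)
        back = minmax_inverse(minmax_apply(x, st_), st_)
        assert np.max(np.abs(back - x)) < 1e-12

    def test_refit_is_deterministic(self):
        x = np.random.default_rng(4).normal(size=(10, 5))
        a, b = minmax_fit(x), minmax_fit(x)
        assert np.array_equal(a.data_min, b.data_min)
        assert np.array_equal(a.data_max, b.data_max)

    def test_column_mismatch_rejected(self):
        st_ = minmax_fit(np.random.default_rng(5).normal(size=(4, 6)))
        with pytest.raises(ValueError):
            minmax_apply(np.zeros((2, 7)), st_)


class TestSplit:
    def test_paper_cohort_sizes(self):
        s = split_60_20_20(3748, seed=0)
        assert (s.train.size, s.validation.size, s.test.size) == (2248, 750, 750)

    def test_small_n_exact_percentages(self):
        s = split_60_20_20(10, seed=0)
        assert (s.train.size, s.validation.size, s.test.size) == (6, 2, 2)

    def test_same_seed_identical_partition(self):
        a, b = split_60_20_20(101, seed=9), split_60_20_20(101, seed=9)
        for part in ("train", "validation", "test"):
            assert np.array_equal(getattr(a, part), getattr(b, part))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(5, 5000), st.integers(0, 2**31 - 1))
    def test_partition_covers_everything_once(self, n, seed):
        s = split_60_20_20(n, seed=seed)
        union = np.concatenate([s.train, s.validation, s.test])
        assert np.array_equal(np.sort(union), np.arange(n))
        assert abs(s.validation.size - 0.2 * n) <= 0.5
        assert abs(s.test.size - 0.2 * n) <= 0.5


class TestChannels:
    def test_one_channel_shape(self, toy_dataset):
        wm = toy_dataset["wm"]
        sc = fit_channel_scalers(wm, toy_dataset["split"].train, "one_channel")
        X = make_channels(wm, "one_channel", sc)
        assert X.shape == (wm.n, 1, 200)

    def test_two_channel_shape(self, toy_dataset):
        assert toy_dataset["X"].shape == (500, 2, 200)

    def test_empty_input(self, toy_dataset):
        wm = WaveformMatrix(values=np.empty((0, 200)), periods=np.empty(0))
        X = make_channels(wm, "two_channel", toy_dataset["scalers"])
        assert X.shape == (0, 2, 200)

    def test_derivative_channel_computed_before_normalization(self, toy_dataset):
        # channel 1 must invert (through its own scaler) to the raw derivative
        wm, sc = toy_dataset["wm"], toy_dataset["scalers"]
        X = toy_dataset["X"]
        deriv_raw = time_derivative(wm.values, wm.periods)
        back = minmax_inverse(X[:, 1, :], sc["derivative"])
        assert np.max(np.abs(back - deriv_raw)) < 1e-9


class TestAWGN:
    def test_very_high_snr_returns_input(self):
        x = np.random.default_rng(6).normal(100, 15, 200)
        assert np.array_equal(add_awgn(x, 250.0, seed=0), x)

    def test_unit_power_signal_noise_variance(self):
        # snr 30 dB on unit-power signal -> sigma^2 = 1e-3
        x = np.ones(200)
        noisy = np.concatenate([add_awgn(x, 30.0, seed=s) - x for s in range(500)])
        assert np.var(noisy) == pytest.approx(1e-3, rel=0.05)

    def test_empirical_snr_within_point_two_db(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100.0, 20.0, size=(1000, 200))
        noisy = add_awgn(x, 40.0, seed=8)
        p_sig = np.mean(x**2)
        p_noise = np.mean((noisy - x) ** 2)
        snr_emp = 10 * np.log10(p_sig / p_noise)
        assert abs(snr_emp - 40.0) < 0.2

    def test_reproducible_given_seed(self):
        x = np.random.default_rng(9).normal(100, 15, 200)
        assert np.array_equal(add_awgn(x, 40, seed=1), add_awgn(x, 40, seed=1))

    def test_corruption_grows_as_snr_drops(self):
        x = np.random.default_rng(10).normal(100, 15, (50, 200))
        rmse = [
            np.sqrt(np.mean((add_awgn(x, snr, seed=2) - x) ** 2))
            for snr in (70, 60, 50, 40, 30)
        ]
        assert np.all(np.diff(rmse) > 0)

    def test_zero_power_input_rejected(self):
        with pytest.raises(ValueError):
            add_awgn(np.zeros(200), 40.0, seed=0)
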