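import math

import numpy as np
import pytest
from scipy.signal import correlate

import snapshotpa as sp
from snapshotpa.encoder_sim import lateral_mix, scramble_coda


class TestTransducerPulse:
    def test_unit_norm(self, params):
        assert np.linalg.norm(sp.transducer_pulse(params)) == pytest.approx(1.0)

    def test_spectral_peak_at_center_frequency(self, params):
        pulse = sp.transducer_pulse(params)
        n = 1 << 16
        f = np.fft.rfftfreq(n, 1.0 / params.fs)
        power = np.abs(np.fft.rfft(pulse, n)) ** 2
        assert abs(f[power.argmax()] - params.f_c) <= params.fs / n

    def test_minus6db_fractional_width(self, params):
        pulse = sp.transducer_pulse(params)
        n = 1 << 16
        f = np.fft.rfftfreq(n, 1.0 / params.fs)
        power = np.abs(np.fft.rfft(pulse, n)) ** 2
        above = f[power >= power.max() * 10 ** -0.6]
        measured = (above.max() - above.min()) / f[power.argmax()]
        assert measured == pytest.approx(params.frac_bw_6db, rel=0.02)


class TestCriticalAngle:
    def test_water_silica_value(self, params):
        assert math.degrees(sp.critical_angle(params)) == pytest.approx(14.73, abs=0.005)

    def test_half_speed_ratio_gives_30_degrees(self):
        p = sp.AcousticParams(v_water=2950.0, v_pipe=5900.0)
        assert math.degrees(sp.critical_angle(p)) == pytest.approx(30.0)

    def test_approaches_90_degrees_at_matched_speeds(self):
        p = sp.AcousticParams(v_water=5899.999, v_pipe=5900.0)
        assert math.degrees(sp.critical_angle(p)) > 89.0

    def test_no_critical_angle_without_speed_contrast(self):
        from types import SimpleNamespace
        with pytest.raises(ValueError):
            sp.critical_angle(SimpleNamespace(v_water=1500.0, v_pipe=1500.0))


class TestTimeOfFlight:
    def test_on_axis_15mm(self, params):
        tof = sp.time_of_flight((0, 0, 15), params)
        assert tof * 1e6 == pytest.approx(15e-3 / 1500 * 1e6 + 0.30 / 5900 * 1e6)
        assert tof * 1e6 == pytest.approx(60.85, abs=0.01)

    def test_entrance_center_is_pipe_transit_only(self, params):
        assert sp.time_of_flight((0, 0, 0), params) * 1e6 == pytest.approx(50.85, abs=0.01)

    def test_monotone_in_water_distance(self, params):
        assert (sp.time_of_flight((0, 0, 20), params)
                > sp.time_of_flight((0, 0, 10), params))

    def test_behind_entrance_plane_rejected(self, params):
        with pytest.raises(ValueError):
            sp.time_of_flight((0, 0, -1), params)


class TestApertureWeight:
    def test_critical_angle_cap_value(self, params):
        # at 50 mm the 15 mm entrance disk subtends atan(15/50) > theta_c
        w = sp.aperture_weight((0, 0, 50), params)
        assert w == pytest.approx((1 - math.cos(math.radians(14.73))) / 2, rel=1e-3)
        assert w == pytest.approx(0.01643, abs=2e-5)

    def test_monotone_in_effective_angle(self, params):
        # far enough that the disk subtends less than theta_c: weight shrinks
        w_near = sp.aperture_weight((0, 0, 50), params)
        w_far = sp.aperture_weight((0, 0, 200), params)
        w_farther = sp.aperture_weight((0, 0, 400), params)
        assert w_near > w_far > w_farther

    def test_weight_vanishes_at_large_distance(self, params):
        assert sp.aperture_weight((0, 0, 1e6), params) < 1e-9

    def test_zero_distance_rejected(self, params):
        with pytest.raises(ValueError):
            sp.aperture_weight((0, 0, 0), params)


class TestScrambleCoda:
    def test_deterministic(self, params):
        enc = sp.EncoderConfig(seed=11, coda_len=2000)
        a = scramble_coda(5, enc, params)
        b = scramble_coda(5, enc, params)
        assert np.array_equal(a, b)

    def test_distinct_voxels_nearly_orthogonal(self, params):
        enc = sp.EncoderConfig(seed=11, coda_len=2000)
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            i, j = rng.choice(5000, size=2, replace=False)
            ci = scramble_coda(int(i), enc, params)
            cj = scramble_coda(int(j), enc, params)
            worst = max(worst, abs(np.corrcoef(ci, cj)[0, 1]))
        assert worst < 0.1

    def test_single_sample_coda_is_unit_impulse(self, params):
        enc = sp.EncoderConfig(seed=0, coda_len=1)
        assert np.array_equal(scramble_coda(0, enc, params), [1.0])


class TestBuildDictionary:
    def test_degenerate_config_is_delay_and_scale(self, params, tiny_grid):
        enc = sp.EncoderConfig(seed=0, coda_len=1, lateral_fwhm_mm=0.0,
                               calib_snr_db=None)
        K = sp.build_dictionary(tiny_grid, params, enc)
        pulse = sp.transducer_pulse(params)
        for i in [0, tiny_grid.n_voxels // 2, tiny_grid.n_voxels - 1]:
            coord = tiny_grid.voxel_center(i)
            tof = sp.time_of_flight(coord, params)
            w = sp.aperture_weight(coord, params)
            expected_lag = round(tof * params.fs)
            xc = correlate(K.columns[:, i], pulse, mode="full")
            lag = int(np.argmax(xc)) - (pulse.size - 1)
            assert lag == expected_lag
            assert K.columns[:, i].max() == pytest.approx(w * pulse.max())

    def test_equal_depth_voxels_share_arrival_but_not_coda(self, params, tiny_grid):
        enc = sp.EncoderConfig(seed=0, lateral_fwhm_mm=0.0, calib_snr_db=None)
        K = sp.build_dictionary(tiny_grid, params, enc)
        # mirror-symmetric lateral positions have equal water distance
        i = tiny_grid.linear_index((0, 1, 2))
        j = tiny_grid.linear_index((2, 1, 2))
        ki, kj = K.columns[:, i], K.columns[:, j]
        assert np.flatnonzero(ki)[0] == np.flatnonzero(kj)[0]
        assert not np.allclose(ki, kj)

    def test_reproducible_from_seed(self, params, tiny_grid):
        enc = sp.EncoderConfig(seed=42)
        K1 = sp.build_dictionary(tiny_grid, params, enc)
        K2 = sp.build_dictionary(tiny_grid, params, enc)
        assert np.array_equal(K1.columns, K2.columns)

    def test_shot_averaging_halves_noise_variance(self, params):
        grid = sp.centered_grid((1, 1, 0.3), (1, 1, 0.3))
        var = {}
        for n_avg in (1, 2):
            devs = []
            for seed in range(100):
                noiseless = sp.build_dictionary(
                    grid, params, sp.EncoderConfig(seed=seed, calib_snr_db=None))
                enc = sp.EncoderConfig(seed=seed, calib_snr_db=20.0, n_avg=n_avg)
                K = sp.build_dictionary(grid, params, enc)
                devs.append(np.var(K.columns - noiseless.columns))
            var[n_avg] = np.mean(devs)
        assert var[1] / var[2] == pytest.approx(2.0, rel=0.15)

    def test_record_too_short_names_the_voxel(self, tiny_grid):
        short = sp.AcousticParams(n_samples=1000)  # 50 us < pipe transit
        with pytest.raises(ValueError, match="voxel"):
            sp.build_dictionary(tiny_grid, short,
                                sp.EncoderConfig(seed=0, calib_snr_db=None))

    def test_normalized_columns_are_unit_with_norms_cached(self, tiny_dict):
        Kn = tiny_dict.normalized()
        assert np.allclose(np.linalg.norm(Kn.columns, axis=0), 1.0)
        assert np.allclose(Kn.column_norms,
                           np.linalg.norm(tiny_dict.columns, axis=0))

    def test_column_incoherence_beyond_lateral_fwhm(self, params):
        grid = sp.centered_grid((3, 3, 1.2), (0.5, 0.5, 0.3))  # 7 x 7 x 5
        K = sp.build_dictionary(grid, params, sp.EncoderConfig(seed=5))
        A = K.normalized().columns
        G = np.abs(A.T @ A)
        centers = grid.voxel_centers()
        lat = centers[:, :2]
        d = np.linalg.norm(lat[:, None, :] - lat[None, :, :], axis=2)
        far = d > K.encoder.lateral_fwhm_mm
        assert G[far].max() < 0.5


class TestLateralMix:
    def test_zero_fwhm_is_identity(self, params, tiny_grid):
        K = np.arange(float(4096 * tiny_grid.n_voxels)).reshape(4096, -1)
        assert lateral_mix(K, tiny_grid, 0.0) is K

    def test_kernel_weights_sum_to_one(self, params):
        grid = sp.centered_grid((2, 2, 0.3), (0.5, 0.5, 0.3))
        ones = np.ones((8, grid.n_voxels))
        mixed = lateral_mix(ones, grid, 2.5)
        assert np.allclose(mixed, 1.0)

    def test_mixing_raises_neighbor_correlation(self, params):
        grid = sp.centered_grid((2, 2, 0.3), (0.5, 0.5, 0.3))  # 5 x 5 x 1
        enc = sp.EncoderConfig(seed=2, lateral_fwhm_mm=0.0, calib_snr_db=None)
        K0 = sp.build_dictionary(grid, params, enc).columns
        K1 = lateral_mix(K0, grid, 2.5)
        i = grid.linear_index((2, 2, 0))
        j = grid.linear_index((3, 2, 0))  # 0.5 mm neighbor
        before = np.corrcoef(K0[:, i], K0[:, j])[0, 1]
        after = np.corrcoef(K1[:, i], K1[:, j])[0, 1]
        assert after > before


class TestAddNoise:
    def test_infinite_snr_is_identity(self, rng):
        y = sp.MeasuredSignal(np.sin(np.arange(256)), fs=1e6)
        out = sp.add_noise(y, None, rng)
        assert np.array_equal(out.samples, y.samples)

    def test_realized_snr_matches_request(self):
        y = sp.MeasuredSignal(np.sin(0.1 * np.arange(4096)), fs=1e6)
        sig_power = np.mean(y.samples**2)
        ratios = []
        for seed in range(100):
            out = sp.add_noise(y, 20.0, np.random.default_rng(seed))
            noise_power = np.mean((out.samples - y.samples) ** 2)
            ratios.append(sig_power / noise_power)
        realized_db = 10 * np.log10(np.mean(ratios))
        assert abs(realized_db - 20.0) < 0.5

    def test_seeded_noise_reproducible(self):
        y = sp.MeasuredSignal(np.ones(64), fs=1e6)
        a = sp.add_noise(y, 10.0, np.random.default_rng(7))
        b = sp.add_noise(y, 10.0, np.random.default_rng(7))
        assert np.array_equal(a.samples, b.samples)

    def test_zero_power_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            sp.add_noise(sp.MeasuredSignal(np.zeros(16), fs=1e6), 20.0, rng)


class TestPulseEnergyCorrect:
    def test_reference_energy_is_identity(self):
        y = sp.MeasuredSignal(np.arange(8.0), fs=1e6)
        out = sp.pulse_energy_correct(y, 1.0, 1.0)
        assert np.array_equal(out.samples, y.samples)

    def test_double_energy_halves_amplitude(self):
        y = sp.MeasuredSignal(np.arange(8.0), fs=1e6)
        out = sp.pulse_energy_correct(y, 2.0, 1.0)
        assert np.allclose(out.samples, y.samples / 2)
        assert out.pulse_energy == 1.0

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            sp.pulse_energy_correct(sp.MeasuredSignal(np.ones(4), fs=1e6), 0.0)
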