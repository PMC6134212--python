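import math

import numpy as np
import pytest

from plsbeam.simulate import (NoiseSpec, SourceSpec, add_noise,
                              calibrate_sigma_ladder, noise_ladder,
                              project_dipole, sinc_waveform, snr_db)


class TestSincWaveform:
    def test_peak_is_exactly_one_at_shifted_origin(self):
        for tau in (0.0, 0.5, -1.25):
            w = sinc_waveform(101, 100.0, tau=tau, time_scale=1.0)
            t = (np.arange(101) - 50) / 100.0
            i = np.argmin(np.abs(t + tau))
            if np.isclose(t[i] + tau, 0.0):
                assert w[i] == 1.0

    def test_half_unit_offset_gives_two_over_pi(self):
        # choose sampling so that t + tau hits exactly 0.5 in scaled units
        w = sinc_waveform(4, 1.0, tau=0.5, time_scale=1.0)
        # t = [-2,-1,0,1]; t+tau = [-1.5,-0.5,0.5,1.5]
        assert w[2] == pytest.approx(2.0 / math.pi, abs=1e-12)

    def test_integer_offsets_are_zeros(self):
        w = sinc_waveform(7, 1.0, tau=0.0, time_scale=1.0)
        # t = -3..3; all nonzero integers are sine zeros
        for i, t in enumerate(range(-3, 4)):
            if t != 0:
                assert abs(w[i]) < 1e-15

    def test_default_main_lobe_spans_100ms(self):
        w = sinc_waveform()
        t_ms = (np.arange(600) - 300)
        lobe = np.abs(t_ms) < 50          # scaled |t| < 1
        assert np.all(w[lobe] > 0)
        assert w[np.abs(t_ms) == 50].max() < 1e-12


class TestProjectDipole:
    def test_zero_amplitude_gives_zero_data(self, small_context):
        ctx = small_context
        loc = ctx.grid.points[5]
        spec = SourceSpec(location=loc, orientation=np.array([0.0, 1.0, 0.0]),
                          amplitude=0.0)
        A, _, _ = project_dipole(spec, ctx.lead)
        assert np.all(A == 0)

    def test_projection_is_linear_in_sources(self, small_context):
        ctx = small_context
        loc = ctx.grid.points[5]
        s1 = SourceSpec(location=loc, orientation=np.array([0.0, 1.0, 0.0]),
                        amplitude=40.0)
        s2 = SourceSpec(location=loc, orientation=np.array([0.0, 0.0, 1.0]),
                        amplitude=70.0)
        A1, _, _ = project_dipole(s1, ctx.lead)
        A2, _, _ = project_dipole(s2, ctx.lead)
        both = SourceSpec(location=loc,
                          orientation=np.array([0.0, 40.0 / np.hypot(40, 70),
                                                70.0 / np.hypot(40, 70)]),
                          amplitude=float(np.hypot(40, 70)))
        A12, _, _ = project_dipole(both, ctx.lead)
        assert np.allclose(A12, A1 + A2, rtol=1e-10)

    def test_matches_elementwise_brute_force_loop(self, small_context, rng):
        ctx = small_context
        idx = 7
        spec = SourceSpec(location=ctx.grid.points[idx],
                          orientation=np.array([0.0, 0.0, 1.0]), amplitude=55.0,
                          waveform=rng.normal(size=20))
        A, snapped, _ = project_dipole(spec, ctx.lead)
        assert snapped == idx
        moment = spec.amplitude * spec.orientation
        for m in range(0, ctx.lead.n_channels, 17):
            for t in range(0, 20, 7):
                direct = (ctx.lead.gains[idx, m] @ moment) * spec.waveform[t]
                assert A[m, t] == pytest.approx(direct, rel=1e-12, abs=1e-15)

    def test_far_off_grid_location_rejected(self, small_context):
        ctx = small_context
        away = ctx.grid.points[0] + np.array([500.0, 0.0, 0.0])
        spec = SourceSpec(location=away, orientation=np.array([0.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="grid"):
            project_dipole(spec, ctx.lead)


class TestAddNoise:
    def test_observed_is_exactly_clean_plus_stored_noise(self, rng):
        clean = rng.normal(size=(8, 30))
        ds = add_noise(clean, NoiseSpec(sigma=2.0, seed=42))
        assert np.array_equal(ds.observed, ds.clean + ds.noise)
        assert np.allclose(ds.observed - ds.clean, ds.noise, atol=1e-12)

    def test_doubling_sigma_costs_six_db(self, rng):
        clean = rng.normal(size=(8, 30))
        d1 = add_noise(clean, NoiseSpec(sigma=1.5, seed=7))
        d2 = add_noise(clean, NoiseSpec(sigma=3.0, seed=7))
        assert d1.snr_db - d2.snr_db == pytest.approx(20 * math.log10(2), abs=1e-6)

    def test_equal_power_means_zero_db(self, rng):
        A = rng.normal(size=(5, 9))
        assert snr_db(A, A.copy()) == 0.0

    def test_reported_snr_matches_direct_recomputation(self, rng):
        clean = rng.normal(size=(8, 30)) * 5
        ds = add_noise(clean, NoiseSpec(sigma=0.7, seed=3))
        direct = 10 * math.log10(np.sum(ds.clean**2) / np.sum(ds.noise**2))
        assert ds.snr_db == pytest.approx(direct, abs=1e-12)

    def test_fixed_seed_is_bit_reproducible(self, rng):
        clean = rng.normal(size=(8, 30))
        d1 = add_noise(clean, NoiseSpec(sigma=1.0, seed=11))
        d2 = add_noise(clean, NoiseSpec(sigma=1.0, seed=11))
        assert np.array_equal(d1.noise, d2.noise)


class TestNoiseLadder:
    def test_mean_snr_strictly_decreasing(self, rng):
        clean = rng.normal(size=(20, 200)) * 3
        _, mean_snr = noise_ladder(clean, n_levels=12, n_reps=5, base_seed=0)
        assert np.all(np.diff(mean_snr) < 0)

    def test_snr_monotone_for_every_individual_seed(self, rng):
        clean = rng.normal(size=(20, 200)) * 3
        datasets, _ = noise_ladder(clean, n_levels=6, n_reps=4, base_seed=1)
        per_rep = np.array([[datasets[lvl][rep].snr_db for lvl in range(6)]
                            for rep in range(4)])
        assert np.all(np.diff(per_rep, axis=1) < 0)

    def test_calibration_hits_requested_endpoints_in_expectation(self, rng):
        clean = rng.normal(size=(30, 300)) * 2
        sigmas = calibrate_sigma_ladder(clean, 12)
        assert np.all(np.diff(sigmas) > 0)
        expected_top = 10 * math.log10(np.sum(clean**2) / (sigmas[0]**2 * clean.size))
        assert expected_top == pytest.approx(6.990, abs=1e-9)

    def test_noise_variance_within_three_standard_errors(self, rng):
        clean = rng.normal(size=(15, 100))
        datasets, _ = noise_ladder(clean, n_levels=3, n_reps=10, base_seed=5)
        sigmas = calibrate_sigma_ladder(clean, 3)
        for lvl in range(3):
            pooled = np.concatenate([d.noise.ravel() for d in datasets[lvl]])
            var = pooled.var()
            se = sigmas[lvl]**2 * math.sqrt(2.0 / pooled.size)
            assert abs(var - sigmas[lvl]**2) < 3 * se

    def test_datasets_bit_identical_across_runs(self, rng):
        clean = rng.normal(size=(10, 50))
        d1, _ = noise_ladder(clean, n_levels=3, n_reps=2, base_seed=9)
        d2, _ = noise_ladder(clean, n_levels=3, n_reps=2, base_seed=9)
        for l in range(3):
            for r in range(2):
                assert np.array_equal(d1[l][r].noise, d2[l][r].noise)

    def test_invalid_parameters_rejected(self, rng):
        clean = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            noise_ladder(clean, n_levels=1)
        with pytest.raises(ValueError):
            noise_ladder(clean, n_reps=0)
        with pytest.raises(ValueError):
            calibrate_sigma_ladder(np.zeros((3, 3)))
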