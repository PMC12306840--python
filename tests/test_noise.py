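"""g-factor noise synthesis: solver correctness against closed forms and a
grid-scan oracle, Monte-Carlo noise statistics, and seeded determinism."""

import numpy as np
import pytest

import cinedenoise.noise as nz
from cinedenoise.noise import (
    DEFAULT_SNR_LEVELS,
    GFactorMap,
    InfeasibleTargetError,
    add_gfactor_noise,
    foreground_mask,
    degraded_snr_map,
    make_training_sample,
    measure_median_snr,
    solve_noise_sd,
    synth_gfactor_map,
)


def uniform_gmap(shape=(16, 16)):
    return GFactorMap(np.ones(shape))


class TestGFactorMap:
    def test_values_below_one_rejected(self):
        with pytest.raises(ValueError):
            GFactorMap(np.full((4, 4), 0.9))

    def test_unit_gmax_gives_flat_map(self):
        g = synth_gfactor_map((32, 32), gmax=1.0, seed=5)
        assert np.allclose(g.values, 1.0)

    def test_range_and_determinism_over_seeds(self):
        for seed in range(100):
            g = synth_gfactor_map((24, 20), gmax=2.5, seed=seed)
            assert g.values.min() >= 1.0 - 1e-12
            assert g.values.max() <= 2.5 + 1e-12
        a = synth_gfactor_map((24, 20), seed=42).values
        b = synth_gfactor_map((24, 20), seed=42).values
        assert np.array_equal(a, b)


class TestSolver:
    def test_uniform_closed_form(self):
        snr = np.full((8, 8), 2.0)
        nn = solve_noise_sd(snr, uniform_gmap((8, 8)), 1.0,
                            foreground=np.ones((8, 8), bool))
        assert abs(nn - np.sqrt(3.0)) < 1e-5

    def test_target_equal_to_median_gives_zero(self):
        snr = np.full((8, 8), 2.0)
        nn = solve_noise_sd(snr, uniform_gmap((8, 8)), 2.0,
                            foreground=np.ones((8, 8), bool))
        assert nn == 0.0

    def test_infeasible_target(self):
        snr = np.full((8, 8), 2.0)
        with pytest.raises(InfeasibleTargetError):
            solve_noise_sd(snr, uniform_gmap((8, 8)), 3.0,
                           foreground=np.ones((8, 8), bool))

    def test_nonuniform_g_matches_grid_scan_oracle(self, rng):
        snr = rng.uniform(5.0, 80.0, (32, 32))
        gmap = synth_gfactor_map((32, 32), gmax=2.2, seed=9)
        fg = np.ones((32, 32), bool)
        target = 1.3
        nn = solve_noise_sd(snr, gmap, target, foreground=fg)
        # dense scan over nn: the objective crosses the target exactly once
        grid = np.linspace(0.5 * nn, 2.0 * nn, 20001)
        med = np.array([
            np.median(snr / np.sqrt(1 + (g * gmap.values) ** 2))
            for g in grid
        ])
        best = grid[np.argmin(np.abs(med - target))]
        assert abs(nn - best) / best < 1e-4

    def test_monotone_decreasing_in_target(self, desk_phantom, desk_gmap):
        _, series, _ = desk_phantom
        mag = series.magnitude()
        fg = foreground_mask(mag)
        sds = [solve_noise_sd(mag, desk_gmap, lv, foreground=fg)
               for lv in DEFAULT_SNR_LEVELS]
        assert all(a > b for a, b in zip(sds, sds[1:]))


class TestDegrade:
    def test_zero_noise_is_identity(self, rng):
        x = rng.normal(size=(1, 1, 2, 16, 16)) + 0j
        out = add_gfactor_noise(x, 0.0, uniform_gmap())
        assert np.array_equal(out.values, x)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            add_gfactor_noise(np.zeros((1, 1, 1, 4, 4), complex), -0.1,
                              uniform_gmap((4, 4)))

    def test_seed_determinism(self):
        x = np.ones((1, 1, 2, 8, 8), complex)
        g = synth_gfactor_map((8, 8), seed=1)
        a = add_gfactor_noise(x, 1.5, g, seed=9).values
        b = add_gfactor_noise(x, 1.5, g, seed=9).values
        assert np.array_equal(a, b)
        c = add_gfactor_noise(x, 1.5, g, seed=10).values
        assert not np.array_equal(a, c)

    def test_empirical_sd_matches_nn_times_g(self):
        nn = 2.0
        g = synth_gfactor_map((12, 12), gmax=2.0, seed=4)
        zeros = np.zeros((1, 1, 1, 12, 12), complex)
        draws = np.stack([
            add_gfactor_noise(zeros, nn, g, seed=s).values[0, 0, 0].real
            for s in range(10000)
        ])
        emp = draws.std(axis=0)
        assert np.abs(emp / (nn * g.values) - 1.0).max() < 0.03

    def test_unit_g_reduces_to_plain_gaussian(self):
        x = np.zeros((1, 1, 1, 64, 64), complex)
        out = add_gfactor_noise(x, 3.0, uniform_gmap((64, 64)), seed=2).values
        assert abs(out.real.std() - 3.0) / 3.0 < 0.05
        assert abs(out.imag.std() - 3.0) / 3.0 < 0.05


class TestMeasurement:
    def test_constant_magnitude_full_foreground(self):
        img = np.full((1, 1, 2, 8, 8), 5.0) * np.exp(0.3j)
        assert measure_median_snr(img, np.ones((8, 8), bool)) == pytest.approx(5.0)

    def test_two_value_image_midpoint_median(self):
        img = np.concatenate([np.full((1, 1, 1, 4, 8), 2.0),
                              np.full((1, 1, 1, 4, 8), 4.0)], axis=-2)
        assert measure_median_snr(img + 0j, np.ones((8, 8), bool)) == 3.0

    def test_matches_percentile_oracle_on_phantom(self, desk_phantom):
        _, series, _ = desk_phantom
        fg = foreground_mask(series.magnitude())
        med = measure_median_snr(series, fg)
        oracle = np.percentile(series.magnitude()[fg], 50.0)
        assert abs(med - oracle) < 1e-9

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError):
            foreground_mask(np.zeros((8, 8)))


class TestTrainingSample:
    def test_channel_layout_and_target_identity(self, desk_phantom, desk_gmap):
        _, series, _ = desk_phantom
        inp, tgt, meta = make_training_sample(series, desk_gmap, 1.0, seed=3)
        assert inp.shape[1] == 3 and tgt.shape[1] == 2
        for f in range(inp.shape[2]):
            assert np.array_equal(inp[0, 2, f], desk_gmap.values)
        assert np.array_equal(tgt[0, 0], series.values[0, 0].real)
        assert np.array_equal(tgt[0, 1], series.values[0, 0].imag)
        assert meta["nn"] > 0 and meta["target_level"] == 1.0

    def test_lower_snr_means_larger_input_error(self, desk_phantom, desk_gmap):
        _, series, _ = desk_phantom
        hi, tgt, _ = make_training_sample(series, desk_gmap, 8.0, seed=1)
        lo, _, _ = make_training_sample(series, desk_gmap, 0.05, seed=1)
        mse_hi = np.mean((hi[:, :2] - tgt) ** 2)
        mse_lo = np.mean((lo[:, :2] - tgt) ** 2)
        assert mse_lo > mse_hi

    def test_gmap_shape_mismatch_raises(self, desk_phantom):
        _, series, _ = desk_phantom
        with pytest.raises(ValueError):
            make_training_sample(series, uniform_gmap((8, 8)), 1.0)


class TestRoundtrip:
    def test_degrade_then_measure_recovers_levels(self, desk_phantom,
                                                  desk_gmap):
        _, series, _ = desk_phantom
        mag = series.magnitude()
        fg = foreground_mask(mag)
        for level in (0.1, 1.0, 4.0):
            nn = solve_noise_sd(mag, desk_gmap, level, foreground=fg)
            measured = measure_median_snr(
                degraded_snr_map(series, nn, desk_gmap), fg
            )
            assert abs(measured - level) / level < 0.02
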