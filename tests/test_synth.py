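"""Synthetic spiking-experiment generator: backgrounds, troughs, cubes,
absorbance series, determinism and range invariants."""

from dataclasses import replace

import numpy as np
import pytest

from phycospec import (
    MATRIX_SPECS,
    MatrixSpec,
    SpikePlan,
    Spectrum,
    TROUGH_PROFILES,
    WavelengthAxis,
    apply_pigment_troughs,
    continuum_removed,
    default_axis,
    index_map,
    make_background,
    rabd,
    roi_mean,
    simulate_absorbance_series,
    simulate_spiking_cubes,
)


class TestBackground:
    def test_flat_knots_give_constant_spectrum(self, axis):
        spec = replace(
            MATRIX_SPECS["organic"],
            background_knots=((400.0, 0.6), (700.0, 0.6), (1000.0, 0.6)),
        )
        bg = make_background(spec, axis)
        np.testing.assert_allclose(bg.values, 0.6, atol=1e-12)

    def test_two_knots_interpolate_linearly(self, axis):
        spec = replace(
            MATRIX_SPECS["organic"], background_knots=((400.0, 0.4), (1000.0, 0.8))
        )
        bg = make_background(spec, axis)
        assert bg.at(700.0) == pytest.approx(0.6, rel=1e-9)

    @pytest.mark.parametrize("matrix", sorted(MATRIX_SPECS))
    def test_default_backgrounds_sit_on_their_hull(self, matrix, axis):
        """Unspiked matrix baselines are concave, so continuum removal
        leaves them at exactly 1 — no spurious absorption troughs."""
        bg = make_background(MATRIX_SPECS[matrix], axis)
        cr = continuum_removed(bg)
        assert np.max(np.abs(cr.values - 1.0)) < 1e-9

    def test_rejects_knots_not_covering_axis(self, axis):
        spec = replace(
            MATRIX_SPECS["organic"], background_knots=((500.0, 0.5), (900.0, 0.6))
        )
        with pytest.raises(ValueError, match="do not cover"):
            make_background(spec, axis)


class TestTroughs:
    def test_zero_masses_return_background(self, axis, organic_noiseless):
        bg = make_background(organic_noiseless, axis)
        out = apply_pigment_troughs(bg, 0, 0, 0, organic_noiseless)
        np.testing.assert_allclose(out.values, bg.values)

    def test_pc_trough_minimum_lands_at_620(self, axis, organic_noiseless):
        flat = Spectrum(axis, np.full(axis.band_count, 0.6))
        out = apply_pigment_troughs(flat, pc_mass=150, spec=organic_noiseless)
        assert axis.centres[np.argmin(out.values)] == pytest.approx(620.0, abs=1.0)

    def test_sensitivity_and_mass_are_interchangeable(self, axis, organic_noiseless):
        bg = make_background(organic_noiseless, axis)
        double_sens = replace(
            organic_noiseless, sensitivity_pc=2 * organic_noiseless.sensitivity_pc
        )
        a = apply_pigment_troughs(bg, pc_mass=50, spec=double_sens)
        b = apply_pigment_troughs(bg, pc_mass=100, spec=organic_noiseless)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_rejects_negative_mass(self, axis, organic_noiseless):
        bg = make_background(organic_noiseless, axis)
        with pytest.raises(ValueError, match="non-negative"):
            apply_pigment_troughs(bg, pc_mass=-1, spec=organic_noiseless)

    def test_trough_additivity_on_flat_background(self, axis, organic_noiseless):
        """Continuum-removed absorbance of a two-pigment spectrum is the sum
        of the single-pigment trough absorbances on a flat background."""
        spec = replace(
            organic_noiseless,
            background_knots=((400.0, 0.8), (1000.0, 0.8)),
        )
        bg = make_background(spec, axis)
        both = apply_pigment_troughs(bg, pc_mass=100, chla_mass=15, spec=spec)
        only_pc = apply_pigment_troughs(bg, pc_mass=100, spec=spec)
        only_chla = apply_pigment_troughs(bg, chla_mass=15, spec=spec)
        absorb = lambda s: -np.log10(continuum_removed(s).values)
        np.testing.assert_allclose(
            absorb(both), absorb(only_pc) + absorb(only_chla), atol=1e-6
        )


class TestCubes:
    def test_one_cube_per_cumulative_step(self, organic_noiseless):
        plan = SpikePlan("PC", (0.0, 50.0, 100.0, 150.0))
        cubes, truth = simulate_spiking_cubes(organic_noiseless, plan, shape=(4, 4))
        assert len(cubes) == 4
        assert truth.masses_ug == (0.0, 50.0, 100.0, 150.0)

    def test_noiseless_cube_is_homogeneous(self, organic_noiseless):
        cubes, _ = simulate_spiking_cubes(
            organic_noiseless, SpikePlan("PC", (100.0,)), shape=(5, 6)
        )
        values = cubes[0].values
        assert np.all(values == values[0, 0])

    def test_roi_mean_rabd620_strictly_increases_with_pc(self, organic_noiseless):
        plan = SpikePlan("PC", (0.0, 50.0, 100.0, 150.0))
        cubes, _ = simulate_spiking_cubes(organic_noiseless, plan, shape=(4, 4))
        means = [roi_mean(index_map(c, TROUGH_PROFILES["RABD620"])) for c in cubes]
        assert np.all(np.diff(means) > 0)

    def test_same_seed_is_bit_identical_and_seeds_differ(self):
        spec = MATRIX_SPECS["organic"]
        plan = SpikePlan("PC", (0.0, 50.0))
        a, _ = simulate_spiking_cubes(spec, plan, shape=(4, 4), seed=123)
        b, _ = simulate_spiking_cubes(spec, plan, shape=(4, 4), seed=123)
        c, _ = simulate_spiking_cubes(spec, plan, shape=(4, 4), seed=124)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.values, cb.values)
        assert not np.array_equal(a[0].values, c[0].values)

    def test_reflectance_stays_in_unit_interval(self):
        spec = replace(MATRIX_SPECS["organic"], noise_sd=0.3)
        cubes, _ = simulate_spiking_cubes(
            spec, SpikePlan("PC", (150.0,)), shape=(8, 8), seed=5
        )
        assert cubes[0].values.min() > 0
        assert cubes[0].values.max() <= 1.0

    def test_visible_fraction_scales_the_response(self, axis, organic_noiseless):
        bg = make_background(organic_noiseless, axis)
        half = replace(organic_noiseless, visible_fraction=0.5)
        a = apply_pigment_troughs(bg, pc_mass=100, spec=half)
        b = apply_pigment_troughs(bg, pc_mass=50, spec=organic_noiseless)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_rejects_tiny_cube(self, organic_noiseless):
        with pytest.raises(ValueError, match="4x4"):
            simulate_spiking_cubes(organic_noiseless, SpikePlan("PC", (0.0,)), shape=(2, 2))


class TestAbsorbanceSeries:
    def test_zero_concentration_gives_zero_absorbance(self):
        assert simulate_absorbance_series([0.0])[0] == 0.0

    def test_beer_lambert_worked_value(self):
        # alpha = 88.15 l/g/cm, L = 1 cm, c = 10 ug/ml = 0.01 g/l
        a = simulate_absorbance_series([10.0], alpha=88.15, path_cm=1.0)
        assert a[0] == pytest.approx(0.8815, rel=1e-12)

    def test_noiseless_series_is_a_perfect_line(self):
        from phycospec import fit_calibration

        c = np.linspace(0, 100, 7)
        a = simulate_absorbance_series(c, alpha=88.15)
        model = fit_calibration(c, a)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_absorbance_series([-1.0])


def test_spike_plan_rejects_decreasing_masses():
    with pytest.raises(ValueError, match="non-decreasing"):
        SpikePlan("PC", (50.0, 20.0))


def test_matrix_spec_invariants():
    with pytest.raises(ValueError, match=r"\(0, 1\]"):
        MatrixSpec("bad", background_knots=((400.0, 0.0), (1000.0, 0.5)))
    with pytest.raises(ValueError, match="noise_sd"):
        replace(MATRIX_SPECS["organic"], noise_sd=-0.1)
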