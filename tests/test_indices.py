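"""RABD/RABA trough indices, ROI statistics and series normalization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycospec import (
    HyperspectralCube,
    Spectrum,
    SpikeSeries,
    TROUGH_PROFILES,
    TroughDefinition,
    WavelengthAxis,
    index_map,
    index_ratio,
    normalize_series,
    raba,
    rabd,
    roi_mean,
)


def _spectrum(wavelengths, values):
    return Spectrum(WavelengthAxis(np.asarray(wavelengths, float)),
                    np.asarray(values, float))


class TestRabd:
    def test_flat_spectrum_gives_exactly_one(self):
        s = _spectrum([600, 610, 620, 630, 640], [0.7] * 5)
        t = TroughDefinition("t", 600, 620, 640)
        assert rabd(s, t) == 1.0

    def test_symmetric_trough_hand_value(self):
        # X_left=2, X_right=2, R_left=0.8, R_right=0.78, R_min=0.5
        s = _spectrum([600, 610, 620, 630, 640], [0.8, 0.7, 0.5, 0.7, 0.78])
        t = TroughDefinition("t", 600, 620, 640)
        assert rabd(s, t) == pytest.approx(((2 * 0.8 + 2 * 0.78) / 4) / 0.5, rel=1e-12)
        assert rabd(s, t) == pytest.approx(1.58, rel=1e-12)

    def test_asymmetric_trough_hand_value(self):
        # X_left=1, X_right=3: continuum = (3*1.0 + 1*0.6)/4 = 0.9
        s = _spectrum([600, 610, 620, 630, 640], [1.0, 0.45, 0.5, 0.55, 0.6])
        t = TroughDefinition("t", 600, 610, 640)
        assert rabd(s, t) == pytest.approx(2.0, rel=1e-12)

    def test_deeper_minimum_strictly_increases_index(self):
        t = TroughDefinition("t", 600, 620, 640)
        values = []
        for r_min in (0.6, 0.5, 0.4, 0.3):
            s = _spectrum([600, 610, 620, 630, 640], [0.8, 0.7, r_min, 0.7, 0.8])
            values.append(rabd(s, t))
        assert np.all(np.diff(values) > 0)

    def test_float_min_finds_deepest_band(self):
        s = _spectrum([600, 610, 620, 630, 640], [0.8, 0.4, 0.5, 0.7, 0.8])
        fixed = TroughDefinition("t", 600, 620, 640)
        floating = TroughDefinition("t", 600, 620, 640, float_min=True)
        assert rabd(s, floating) > rabd(s, fixed)

    def test_rejects_zero_minimum_and_off_axis_bands(self):
        s = _spectrum([600, 610, 620, 630, 640], [0.8, 0.7, 0.0, 0.7, 0.8])
        with pytest.raises(ValueError, match="non-positive"):
            rabd(s, TroughDefinition("t", 600, 620, 640))
        with pytest.raises(ValueError, match="outside the axis"):
            rabd(s, TroughDefinition("t", 500, 620, 640))


class TestRaba:
    def test_spectrum_on_chord_gives_zero(self):
        s = _spectrum([600, 610, 620, 630, 640], np.linspace(0.8, 0.78, 5))
        assert raba(s, TroughDefinition("t", 600, 620, 640)) == pytest.approx(0.0, abs=1e-12)

    def test_term_by_term_hand_value(self, five_band_trough):
        t = TroughDefinition("t", 600, 620, 640)
        expected = 0.045 / 0.795 + 0.29 / 0.79 + 0.065 / 0.785
        assert raba(five_band_trough, t) == pytest.approx(expected, rel=1e-12)
        assert raba(five_band_trough, t) == pytest.approx(0.5065, abs=5e-4)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_scale_invariance(self, k):
        s = _spectrum([600, 610, 620, 630, 640], np.array([0.8, 0.75, 0.5, 0.72, 0.78]))
        scaled = Spectrum(s.axis, s.values * k)
        t = TroughDefinition("t", 600, 620, 640)
        assert raba(scaled, t) == pytest.approx(raba(s, t), rel=1e-9)


class TestMapsAndRoi:
    def _homogeneous_cube(self, values):
        axis = WavelengthAxis(np.array([600.0, 610, 620, 630, 640]))
        cube = np.broadcast_to(np.asarray(values, float), (5, 4, 5)).copy()
        return HyperspectralCube(axis, cube)

    def test_homogeneous_cube_gives_constant_map(self):
        cube = self._homogeneous_cube([0.8, 0.7, 0.5, 0.7, 0.78])
        t = TroughDefinition("t", 600, 620, 640)
        imap = index_map(cube, t)
        single = rabd(cube.pixel(0, 0), t)
        np.testing.assert_allclose(imap.values, single)
        assert roi_mean(imap) == pytest.approx(single, rel=1e-12)

    def test_masking_halves_finite_count(self):
        cube = self._homogeneous_cube([0.8, 0.7, 0.5, 0.7, 0.78])
        t = TroughDefinition("t", 600, 620, 640)
        mask = np.zeros((5, 4), dtype=bool)
        mask[:, :2] = True
        imap = index_map(cube, t, mask=mask)
        assert imap.finite_count == index_map(cube, t).finite_count // 2

    def test_roi_mean_matches_brute_force(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(1.0, 2.0, (6, 7))
        t = TroughDefinition("t", 600, 620, 640)
        from phycospec.indices import PigmentIndexMap
        imap = PigmentIndexMap(t, values)
        assert roi_mean(imap) == pytest.approx(values.sum() / values.size, rel=1e-12)
        with pytest.raises(ValueError, match="no finite"):
            roi_mean(imap, mask=np.zeros((6, 7), bool))

    def test_pixel_first_differs_from_mean_spectrum_on_heterogeneous_cube(self):
        """ROI-mean of per-pixel RABD equals RABD of the mean spectrum only
        for homogeneous cubes; the pipeline uses the pixel-first order."""
        axis = WavelengthAxis(np.array([600.0, 610, 620, 630, 640]))
        a = np.array([0.8, 0.7, 0.2, 0.7, 0.8])
        b = np.array([0.8, 0.7, 0.7, 0.7, 0.8])
        cube = HyperspectralCube(axis, np.stack([a, b])[None, :, :].repeat(4, axis=0))
        t = TroughDefinition("t", 600, 620, 640)
        pixel_first = roi_mean(index_map(cube, t))
        spectrum_first = rabd(cube.mean_spectrum(), t)
        assert pixel_first != pytest.approx(spectrum_first, rel=1e-6)
        assert pixel_first > spectrum_first  # Jensen: 1/R_min is convex


class TestSeries:
    def test_normalization_divides_by_unspiked_baseline(self):
        series = SpikeSeries("organic", "PC", [0.0, 50, 100], [1.05, 1.10, 1.21])
        norm = normalize_series(series)
        np.testing.assert_allclose(
            norm.index_normalized, [1.0, 1.10 / 1.05, 1.21 / 1.05], rtol=1e-12
        )
        assert norm.index_normalized[0] == 1.0

    def test_normalization_is_idempotent_and_needs_baseline(self):
        series = SpikeSeries("organic", "PC", [0.0, 50], [1.2, 1.2])
        norm = normalize_series(normalize_series(series))
        np.testing.assert_allclose(norm.index_normalized, [1.0, 1.0])
        with pytest.raises(ValueError, match="mass 0"):
            normalize_series(SpikeSeries("organic", "PC", [50.0, 100], [1.1, 1.2]))

    def test_index_ratio_of_identical_maps_is_one(self):
        from phycospec.indices import PigmentIndexMap
        t = TROUGH_PROFILES["RABD620"]
        values = np.full((4, 4), 1.3)
        m = PigmentIndexMap(t, values)
        assert index_ratio(m, m) == pytest.approx(1.0, rel=1e-12)
        scaled = PigmentIndexMap(t, values * 0.61)
        assert index_ratio(scaled, m) == pytest.approx(0.61, rel=1e-12)


def test_conservative_windows_share_no_band(axis):
    """The PC window (600-640) and chlorin window (650-700) are disjoint so
    RABD620 is a pure phycocyanin signal."""
    pc = TROUGH_PROFILES["RABD620"]
    chlorins = TROUGH_PROFILES["RABD675"]
    pc_bands = set(axis.window(pc.lambda_left, pc.lambda_right).tolist())
    chl_bands = set(axis.window(chlorins.lambda_left, chlorins.lambda_right).tolist())
    assert pc_bands and chl_bands
    assert pc_bands.isdisjoint(chl_bands)
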