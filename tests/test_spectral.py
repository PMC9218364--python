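"""Primary SPDs, receptor normalisation, troland conversions and bleaching."""

import numpy as np
import pytest

from melsum import spectral as sp


class TestPrimarySpd:
    def test_half_maximum_at_fwhm(self, grid):
        spd = sp.make_primary_spd(456.0, 10.0, grid)
        assert spd.values.max() == pytest.approx(1.0)
        assert grid[np.argmax(spd.values)] == 456.0
        idx_lo = np.searchsorted(grid, 451.0)
        idx_hi = np.searchsorted(grid, 461.0)
        assert spd.values[idx_lo] == pytest.approx(0.5, abs=1e-9)
        assert spd.values[idx_hi] == pytest.approx(0.5, abs=1e-9)

    def test_gaussian_integral_matches_closed_form(self, grid):
        fwhm = 10.0
        sigma = fwhm / 2.3548200450309493
        spd = sp.make_primary_spd(540.0, fwhm, grid)
        area = np.trapezoid(spd.values, grid)
        assert area == pytest.approx(sigma * np.sqrt(2 * np.pi), rel=1e-6)

    def test_peak_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError):
            sp.make_primary_spd(900.0, 10.0, grid)

    def test_default_basis_peaks(self, primaries):
        for spd, peak in zip(primaries.spds, sp.PRIMARY_PEAKS_NM):
            assert abs(spd.wavelengths[np.argmax(spd.values)] - peak) <= 0.5


class TestReceptorSet:
    def test_equal_energy_normalisation_is_canonical(self, receptors):
        ee = sp.equal_energy_spd(receptors=receptors, photopic_td=1.0)
        exc = sp.excitation_vector(ee, receptors)
        np.testing.assert_allclose(
            exc.as_array(), [2 / 3, 1 / 3, 1.0, 1.0, 1.0], rtol=1e-12
        )
        assert exc.photopic_td == pytest.approx(1.0)

    def test_sensitivities_nonnegative_unit_peak(self, receptors):
        assert receptors.sensitivities.min() >= 0
        np.testing.assert_allclose(receptors.sensitivities.max(axis=1), 1.0)

    def test_melanopsin_template_peaks_near_480(self, grid, receptors):
        i_row = receptors.sensitivities[sp.CLASSES.index("i")]
        assert abs(grid[np.argmax(i_row)] - 480.0) <= 1.0

    def test_normalisation_holds_for_shifted_templates(self, grid):
        shifted = sp.build_receptor_set(grid, lambda_max={"r": 495.0, "i": 484.0})
        ee = sp.equal_energy_spd(receptors=shifted, photopic_td=1.0)
        exc = sp.excitation_vector(ee, shifted)
        np.testing.assert_allclose(
            exc.as_array(), [2 / 3, 1 / 3, 1.0, 1.0, 1.0], rtol=1e-12
        )

    def test_lambda_max_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError):
            sp.build_receptor_set(grid, lambda_max={"i": 200.0})


class TestExcitation:
    def test_linearity(self, grid, receptors, rng):
        v1 = rng.random(grid.size)
        v2 = rng.random(grid.size)
        s1 = sp.SpectralFunction(grid, v1)
        s2 = sp.SpectralFunction(grid, v2)
        combo = sp.SpectralFunction(grid, 0.3 * v1 + 1.7 * v2)
        lhs = sp.excitation_vector(combo, receptors).as_array()
        rhs = (
            0.3 * sp.excitation_vector(s1, receptors).as_array()
            + 1.7 * sp.excitation_vector(s2, receptors).as_array()
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_doubling_spd_doubles_excitations(self, grid, receptors, rng):
        s = sp.SpectralFunction(grid, rng.random(grid.size))
        e1 = sp.excitation_vector(s, receptors).as_array()
        e2 = sp.excitation_vector(s.scaled(2.0), receptors).as_array()
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-12)

    def test_grid_mismatch_rejected(self, receptors):
        other = sp.SpectralFunction(np.arange(400.0, 701.0), np.ones(301))
        with pytest.raises(ValueError):
            sp.excitation_vector(other, receptors)

    def test_background_melanopsin_excitation_at_200td(self):
        exc = sp.excitations_at_td(
            {"l": 0.755, "m": 0.244, "s": 0.107, "r": 0.345, "i": 0.265}, 200.0
        )
        assert exc.i == pytest.approx(53.0, abs=0.1)


class TestScotopicConversion:
    @pytest.mark.parametrize(
        "photopic, scotopic",
        [(200.0, 498.0), (3000.0, 7470.0), (0.0, 0.0)],
    )
    def test_anchor_scaling(self, photopic, scotopic):
        assert sp.scotopic_from_photopic(photopic) == pytest.approx(scotopic)

    def test_round_trip_through_anchor_is_identity(self):
        sc = sp.scotopic_from_photopic(123.4)
        back = sc * 200.0 / 498.0
        assert back == pytest.approx(123.4)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sp.scotopic_from_photopic(-1.0)
        with pytest.raises(ValueError):
            sp.scotopic_from_photopic(100.0, anchor=(0.0, 498.0))


class TestBleach:
    def test_fixed_points(self):
        model = sp.BleachModel(half_bleach_td=1000.0)
        assert sp.steady_state_bleach(0.0, model) == 0.0
        assert sp.steady_state_bleach(1000.0, model) == pytest.approx(0.5)

    def test_photopic_levels_match_reported_percentages(self):
        # 2000 Td: ~6 % bleached; >=94 % available; 8000 Td: >=78 % available
        p2000 = sp.steady_state_bleach(2000.0)
        p8000 = sp.steady_state_bleach(8000.0)
        assert 100 * p2000 == pytest.approx(6.0, abs=0.1)
        assert 100 * (1 - p2000) >= 94.0
        assert 100 * (1 - p8000) >= 78.0

    def test_monotone_and_bounded(self):
        I = np.linspace(0, 1e6, 200)
        p = sp.steady_state_bleach(I)
        assert np.all(np.diff(p) > 0)
        assert p[0] == 0.0 and p[-1] < 1.0

    def test_negative_illuminance_rejected(self):
        with pytest.raises(ValueError):
            sp.steady_state_bleach(-5.0)
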