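"""Canopy model: leaf angle distribution, soil mixing, four-stream RT."""

import numpy as np
import pytest

from prosailgpr.canopy import (
    SAIL13_CENTRES,
    CanopyParams,
    SoilSpectrum,
    ViewGeometry,
    lidf_from_ala,
    mix_soil,
    sail_reflectance,
)
from prosailgpr.leaf import LeafParams, Spectrum, leaf_rt

from ._oracles import sail_analytic_direct, sail_numerical


def flat_soil(wl, value):
    return SoilSpectrum(Spectrum(wl, np.full_like(wl, float(value))))


class TestLIDF:
    @pytest.mark.parametrize("ala", [15.0, 40.0, 45.0, 57.3, 70.0, 80.0])
    def test_normalized_and_mean_within_2deg(self, ala):
        f = lidf_from_ala(ala)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(f >= 0)
        assert (f * SAIL13_CENTRES).sum() == pytest.approx(ala, abs=2.0)

    def test_erectophile_has_more_steep_mass(self):
        steep = SAIL13_CENTRES >= 60
        assert lidf_from_ala(80)[steep].sum() > lidf_from_ala(40)[steep].sum()

    def test_uniform_classes_supported(self):
        f = lidf_from_ala(45, n_classes=9)
        assert f.size == 9 and f.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("ala", [0.0, 90.0, -5.0])
    def test_out_of_range_rejected(self, ala):
        with pytest.raises(ValueError):
            lidf_from_ala(ala)


class TestMixSoil:
    def setup_method(self):
        self.wl = np.arange(400.0, 2501.0)
        self.dry = Spectrum(self.wl, np.full_like(self.wl, 0.3))
        self.wet = Spectrum(self.wl, np.full_like(self.wl, 0.1))

    def test_endmember_identity(self):
        assert np.allclose(mix_soil(self.dry, self.wet, 1.0).spectrum.values, 0.3)
        assert np.allclose(mix_soil(self.dry, self.wet, 0.0).spectrum.values, 0.1)

    def test_midpoint(self):
        assert np.allclose(mix_soil(self.dry, self.wet, 0.5).spectrum.values, 0.2)

    def test_out_of_range_scaling_rejected(self):
        with pytest.raises(ValueError):
            mix_soil(self.dry, self.wet, 1.2)

    def test_grid_mismatch_rejected(self):
        short = Spectrum(self.wl[:-1], np.full(self.wl.size - 1, 0.1))
        with pytest.raises(ValueError):
            mix_soil(self.dry, short, 0.5)


class TestSailReflectance:
    def test_bare_soil_limit(self, table, rng):
        """At LAI = 0 the canopy is absent: output equals the soil."""
        wl = table.wavelengths
        for _ in range(20):
            leaf = LeafParams(rng.uniform(1.2, 2.5), rng.uniform(10, 55),
                              rng.uniform(0, 0.05), rng.uniform(0, 0.03))
            R, T = leaf_rt(leaf, table)
            soil = flat_soil(wl, rng.uniform(0.05, 0.6))
            geom = ViewGeometry(rng.uniform(10, 60), rng.uniform(0, 20),
                                rng.uniform(0, 180))
            out = sail_reflectance(R, T, CanopyParams(LAI=0.0), soil, geom)
            assert np.max(np.abs(out.values - soil.spectrum.values)) < 1e-6

    def test_physical_range_over_parameter_space(self, table, rng):
        wl = table.wavelengths
        for _ in range(200):
            leaf = LeafParams(rng.uniform(1.2, 2.5), rng.uniform(10, 55),
                              rng.uniform(0, 0.05), rng.uniform(0, 0.03))
            R, T = leaf_rt(leaf, table)
            cp = CanopyParams(rng.uniform(0.2, 9), rng.uniform(40, 80), 0.01, 0.1)
            soil = flat_soil(wl, rng.uniform(0.02, 0.6))
            geom = ViewGeometry(30, 0, rng.uniform(0, 180))
            out = sail_reflectance(R, T, cp, soil, geom).values
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_nir_buildup_over_black_soil(self, table):
        wl = table.wavelengths
        R, T = leaf_rt(LeafParams(1.85, 32.5, 0.025, 0.015), table)
        soil = flat_soil(wl, 0.0)
        geom = ViewGeometry(30, 0, 0)
        vals = [
            sail_reflectance(R, T, CanopyParams(LAI=l, ALA=60), soil, geom).values[400]
            for l in [0.2, 0.5, 1, 2, 4, 6, 9]
        ]
        assert np.all(np.diff(vals) >= 0)
        # saturating: reflectance gained per unit LAI shrinks
        lai = np.array([0.2, 0.5, 1, 2, 4, 6, 9])
        slopes = np.diff(vals) / np.diff(lai)
        assert slopes[-1] < slopes[0]

    def test_hotspot_enhancement(self, table):
        """Retro-reflection: view == sun direction is at least as bright
        as a 20-degree azimuth offset, everything else equal."""
        wl = table.wavelengths
        R, T = leaf_rt(LeafParams(1.85, 32.5, 0.025, 0.015), table)
        soil = flat_soil(wl, 0.2)
        cp = CanopyParams(LAI=3.0, ALA=60.0, hotspot=0.05, skyl=0.0)
        hot = sail_reflectance(R, T, cp, soil, ViewGeometry(30, 30, 0)).values
        off = sail_reflectance(R, T, cp, soil, ViewGeometry(30, 30, 20)).values
        assert np.all(hot >= off - 1e-12)

    def test_matches_multilayer_numerical_oracle(self, table):
        """Spec configuration: the analytic four-stream solution against a
        finite-difference discretization of the same turbid medium."""
        geom = ViewGeometry(30, 0, 0)
        lidf = lidf_from_ala(60.0)
        cases = [
            (0.45, 0.45, 2.0, 0.2),
            (0.08, 0.05, 2.0, 0.3),
            (0.545, 0.455, 5.0, 0.0),
            (0.3, 0.25, 0.5, 0.15),
            (0.52, 0.46, 9.0, 0.4),
        ]
        for rho, tau, lai, rsoil in cases:
            ana = sail_analytic_direct(rho, tau, lai, lidf, geom, rsoil)
            num = sail_numerical(rho, tau, lai, lidf, geom, rsoil)
            assert ana == pytest.approx(num, abs=1e-3)

    def test_oracle_agreement_off_nadir(self, table):
        geom = ViewGeometry(45, 20, 90)
        lidf = lidf_from_ala(50.0)
        ana = sail_analytic_direct(0.4, 0.42, 3.0, lidf, geom, 0.25)
        num = sail_numerical(0.4, 0.42, 3.0, lidf, geom, 0.25)
        assert ana == pytest.approx(num, abs=1e-3)

    def test_grid_mismatch_rejected(self, table):
        wl = table.wavelengths
        R, T = leaf_rt(LeafParams(1.5, 30, 0.02, 0.01), table)
        soil = SoilSpectrum(Spectrum(wl[:-1], np.full(wl.size - 1, 0.2)))
        with pytest.raises(ValueError):
            sail_reflectance(R, T, CanopyParams(LAI=1.0), soil)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            CanopyParams(LAI=-0.5)


def test_view_geometry_folds_azimuth():
    assert ViewGeometry(30, 0, 270.0).relative_azimuth == 90.0
    assert ViewGeometry(30, 0, -30.0).relative_azimuth == 30.0
    with pytest.raises(ValueError):
        ViewGeometry(95, 0, 0)
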