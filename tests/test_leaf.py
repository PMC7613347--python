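"""Leaf radiative-transfer model: plate-stack optics and invariants."""

import numpy as np
import pytest
from scipy.special import exp1

from prosailgpr.leaf import (
    AbsorptionTable,
    LeafParams,
    Spectrum,
    elementary_transmissivity,
    exp_integral_e1,
    layer_absorption,
    leaf_rt,
    tav,
)
from prosailgpr.leaf import _stokes_stack

from ._oracles import stack_plates_adding, transmissivity_quadrature

MIDPOINT = LeafParams(N=1.85, Cab=32.5, Cw=0.025, Cm=0.015)


def tiny_table(n_wl=5, k_cab=0.02):
    wl = np.linspace(400, 2500, n_wl)
    return AbsorptionTable(
        wl,
        np.full(n_wl, 1.45),
        np.full(n_wl, k_cab),
        np.full(n_wl, 0.5),
        np.full(n_wl, 3.0),
    )


class TestLayerAbsorption:
    def test_zero_absorbers_give_zero(self):
        t = tiny_table()
        k = layer_absorption(LeafParams(1.5, 0, 0, 0), t)
        assert np.all(k == 0)

    def test_linear_combination_by_hand(self):
        t = tiny_table(k_cab=0.02)
        t = AbsorptionTable(t.wavelengths, t.refractive_index, t.k_cab,
                            np.zeros(5), np.zeros(5))
        k = layer_absorption(LeafParams(N=2, Cab=10, Cw=0, Cm=0), t)
        assert np.allclose(k, 0.1)

    def test_matches_elementwise_loop(self, table):
        k = layer_absorption(MIDPOINT, table)
        expected = np.array(
            [
                (MIDPOINT.Cab * table.k_cab[i] + MIDPOINT.Cw * table.k_cw[i]
                 + MIDPOINT.Cm * table.k_cm[i]) / MIDPOINT.N
                for i in range(table.wavelengths.size)
            ]
        )
        assert np.allclose(k, expected, atol=0, rtol=1e-14)
        assert np.all(k >= 0)

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError, match="length"):
            AbsorptionTable(np.arange(5), np.full(5, 1.4), np.zeros(5),
                            np.zeros(4), np.zeros(5))


class TestElementaryTransmissivity:
    def test_no_absorption(self):
        assert elementary_transmissivity(0.0) == 1.0

    def test_opaque_limit(self):
        assert elementary_transmissivity(50.0) < 1e-6

    @pytest.mark.parametrize("k", [0.05, 0.5, 2.0, 8.0])
    def test_matches_quadrature(self, k):
        assert elementary_transmissivity(k) == pytest.approx(
            transmissivity_quadrature(k), abs=1e-9
        )

    def test_strictly_decreasing(self):
        ks = np.linspace(0, 10, 200)
        th = elementary_transmissivity(ks)
        assert np.all(np.diff(th) < 0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            elementary_transmissivity(-0.1)


def test_exponential_integral_matches_reference():
    x = np.concatenate([np.geomspace(1e-6, 1.0, 40), np.geomspace(1.001, 300, 40)])
    ours = exp_integral_e1(x)
    ref = exp1(x)
    assert np.allclose(ours, ref, rtol=1e-12, atol=1e-300)


def test_tav_normal_incidence_is_fresnel():
    nr = np.array([1.5])
    assert tav(0.0, nr)[0] == pytest.approx(4 * 1.5 / 2.5**2, abs=1e-12)


class TestLeafRT:
    def test_opaque_leaf_transmits_nothing(self, table):
        _, T = leaf_rt(LeafParams(1.5, 1e5, 10.0, 10.0), table)
        absorbing = (table.k_cab > 0.01) | (table.k_cw > 1) | (table.k_cm > 5)
        assert np.all(T.values[absorbing] < 1e-6)

    def test_chlorophyll_darkens_red(self, table):
        i670 = 270
        r = [leaf_rt(LeafParams(1.5, c, 0.02, 0.01), table)[0].values[i670]
             for c in np.linspace(10, 55, 10)]
        t = [leaf_rt(LeafParams(1.5, c, 0.02, 0.01), table)[1].values[i670]
             for c in np.linspace(10, 55, 10)]
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all(np.diff(t) <= 1e-12)

    def test_water_darkens_1940(self, table):
        i1940 = 1540
        r = [leaf_rt(LeafParams(1.5, 30, cw, 0.01), table)[0].values[i1940]
             for cw in np.linspace(0, 0.05, 10)]
        assert np.all(np.diff(r) <= 1e-12)

    def test_energy_conservation_random_leaves(self, table, rng):
        for _ in range(200):
            leaf = LeafParams(rng.uniform(1.2, 2.5), rng.uniform(10, 55),
                              rng.uniform(0, 0.05), rng.uniform(0, 0.03))
            R, T = leaf_rt(leaf, table)
            assert R.values.min() >= 0 and T.values.min() >= 0
            assert np.max(R.values + T.values) <= 1.0 + 1e-12

    def test_structure_raises_nir_reflectance(self, table):
        i800 = 400
        r = [leaf_rt(LeafParams(n, 30, 0.02, 0.01), table)[0].values[i800]
             for n in np.linspace(1.2, 2.5, 10)]
        assert np.all(np.diff(r) >= -1e-12)

    def test_invalid_structure_rejected(self):
        with pytest.raises(ValueError):
            LeafParams(0.9, 30, 0.02, 0.01)
        with pytest.raises(ValueError):
            LeafParams(1.5, -1, 0.02, 0.01)


class TestPlateStackOracle:
    """The real-N Stokes extension against discrete adding composition."""

    @pytest.mark.parametrize("n_layers", [1, 2, 3, 4])
    def test_stokes_matches_adding(self, n_layers, rng):
        r = rng.uniform(0.01, 0.3, 25)
        t = rng.uniform(0.1, 0.65, 25)
        Rs, Ts = _stokes_stack(r, t, float(n_layers))
        Ra, Ta = r.copy(), t.copy()
        for _ in range(n_layers - 1):
            dn = 1 - Ra * r
            Ra, Ta = Ra + Ta * Ta * r / dn, Ta * t / dn
        assert np.allclose(Rs, Ra, atol=1e-6)
        assert np.allclose(Ts, Ta, atol=1e-6)

    @pytest.mark.parametrize("n_int", [2, 3])
    def test_leaf_rt_matches_full_adding_composition(self, table, n_int):
        """Integer-N leaves: analytic result equals numerically composing
        the top plate over N-1 internal plates, at sampled wavelengths."""
        from prosailgpr.leaf import elementary_transmissivity as theta_fn
        from prosailgpr.leaf import layer_absorption as k_fn
        from prosailgpr.leaf import tav as tav_fn

        idx = np.array([100, 400, 900, 1540, 2000])
        for cab, cw, cm in [(15, 0.005, 0.002), (32.5, 0.025, 0.015),
                            (55, 0.05, 0.03), (10, 0.0, 0.0), (40, 0.01, 0.02)]:
            leaf = LeafParams(float(n_int), cab, cw, cm)
            k = k_fn(leaf, table)[idx]
            theta = theta_fn(k)
            nr = table.refractive_index[idx]
            talf = tav_fn(40.0, nr)
            t12 = tav_fn(90.0, nr)
            t21 = t12 / nr**2
            r21 = 1 - t21
            denom = 1 - r21**2 * theta**2
            Ta = talf * theta * t21 / denom
            Ra = (1 - talf) + r21 * theta * Ta
            t = t12 * theta * t21 / denom
            r = (1 - t12) + r21 * theta * t
            R_add, T_add = stack_plates_adding(Ra, Ta, r, t, n_int - 1)
            R, T = leaf_rt(leaf, table)
            assert np.allclose(R.values[idx], R_add, atol=1e-6)
            assert np.allclose(T.values[idx], T_add, atol=1e-6)


def test_spectrum_validates_monotone_grid():
    with pytest.raises(ValueError):
        Spectrum(np.array([400.0, 400.0, 500.0]), np.zeros(3))


def test_default_grid_shape(table):
    assert table.wavelengths.size == 2101
    assert table.wavelengths[0] == 400 and table.wavelengths[-1] == 2500
    assert np.all(table.refractive_index > 1)
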