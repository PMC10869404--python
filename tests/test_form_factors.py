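"""Closed-form scattering models against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import j1

from starbrush import (
    ChainParams,
    CoreGeometry,
    StarParams,
    chain_intensity,
    core_amplitude,
    core_self_correlation,
    debye_chain,
    nu_from_rg,
    rg_from_nu,
    star_intensity,
)


class TestChainIntensity:
    def test_forward_value_is_I0(self, chain_params):
        assert chain_intensity(np.array([0.0]), chain_params)[0] == pytest.approx(
            chain_params.I0
        )

    def test_nu_0212_reduces_to_pure_guinier(self):
        p = ChainParams(I0=3.0, Rg=2.5, nu=0.212 + 0.0)
        q = np.linspace(0.0, 0.8, 40)
        expected = 3.0 * np.exp(-((q * 2.5) ** 2) / 3.0)
        np.testing.assert_allclose(
            chain_intensity(q, p, warn_window=False), expected, rtol=1e-14
        )

    def test_hand_value_at_qrg_one(self):
        # I0=1, qRg=1, nu=0.6: exp(-1/3 + 0.0479*0.388)
        p = ChainParams(I0=1.0, Rg=1.0, nu=0.6)
        expected = math.exp(-1.0 / 3.0 + 0.0479 * (0.6 - 0.212))
        assert chain_intensity(np.array([1.0]), p)[0] == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.7300, abs=1e-4)

    def test_warns_beyond_validity_window(self, chain_params):
        with pytest.warns(UserWarning, match="qRg > 2"):
            chain_intensity(np.array([5.0]), chain_params)


class TestRgNuRelation:
    def test_single_residue_prefactor(self):
        nu, b, gamma = 0.5, 0.55, 1.615
        expected = (
            math.sqrt(
                gamma * (gamma + 1)
                / (2 * (gamma + 2 * nu) * (gamma + 2 * nu + 1))
            )
            * b
        )
        assert rg_from_nu(1, nu) == pytest.approx(expected, rel=1e-12)

    def test_hand_value_ideal_chain(self):
        assert rg_from_nu(104, 0.5) == pytest.approx(2.651, abs=1e-3)

    def test_strictly_increasing_in_nu(self):
        nus = np.linspace(0.4, 0.8, 81)
        rgs = [rg_from_nu(104, nu) for nu in nus]
        assert np.all(np.diff(rgs) > 0)

    @pytest.mark.parametrize("nu", [1 / 3, 0.5, 0.65, 0.9, 1.0])
    def test_inverse_roundtrip(self, nu):
        rg = rg_from_nu(146, nu)
        assert nu_from_rg(rg, 146) == pytest.approx(nu, abs=1e-6)

    def test_out_of_range_rg_names_bracket(self):
        with pytest.raises(ValueError, match="attainable range"):
            nu_from_rg(0.01, 146)
        with pytest.raises(ValueError, match="attainable range"):
            nu_from_rg(1e4, 146)


class TestCoreAmplitude:
    def test_normalized_at_zero_for_both_shapes(self):
        q0 = np.array([1e-12])
        sphere = CoreGeometry("sphere", R=1.3)
        cyl = CoreGeometry("cylinder", R=0.9, L=1.2)
        assert core_amplitude(q0, sphere)[0] == pytest.approx(1.0, abs=1e-9)
        assert core_amplitude(q0, cyl)[0] == pytest.approx(1.0, abs=1e-9)
        assert core_self_correlation(q0, cyl)[0] == pytest.approx(1.0, abs=1e-9)

    def test_sphere_first_zero_matches_tan_root(self):
        # independent oracle: first positive root of tan x = x
        root = brentq(lambda x: math.tan(x) - x, math.pi + 0.01, 1.5 * math.pi)
        R = 2.0
        geom = CoreGeometry("sphere", R=R)
        f = lambda q: core_amplitude(np.array([q]), geom)[0]
        zero = brentq(f, 3.0 / R, 5.5 / R)
        assert zero * R == pytest.approx(root, abs=1e-3)
        assert root == pytest.approx(4.4934, abs=1e-4)

    def test_cylinder_thin_limit_approaches_disk(self):
        # oracle: orientation-averaged thin-disk amplitude by quadrature
        R = 1.5
        q = np.linspace(0.1, 3.0, 30)
        alpha = np.linspace(1e-6, math.pi / 2, 4001)
        disk = []
        for qi in q:
            x = qi * R * np.sin(alpha)
            amp = 2.0 * j1(x) / x
            disk.append(np.trapezoid(amp * np.sin(alpha), alpha))
        thin = core_amplitude(q, CoreGeometry("cylinder", R=R, L=1e-6))
        np.testing.assert_allclose(thin, disk, rtol=1e-3)

    def test_volume_and_equivalent_radius(self):
        sphere = CoreGeometry("sphere", R=1.0)
        assert sphere.volume == pytest.approx(4 * math.pi / 3)
        cyl = CoreGeometry("cylinder", R=0.89, L=1.19)
        assert cyl.volume == pytest.approx(math.pi * 0.89**2 * 1.19)
        assert cyl.equivalent_radius == pytest.approx(
            (3 * cyl.volume / (4 * math.pi)) ** (1 / 3)
        )


class TestDebyeChain:
    def test_normalized_and_hand_value(self):
        assert debye_chain(np.array([0.0]), 3.0)[0] == pytest.approx(1.0)
        # x = (q Rg)^2 = 1 -> 2/e
        val = debye_chain(np.array([1.0]), 1.0)[0]
        assert val == pytest.approx(2.0 * math.exp(-1.0), rel=1e-12)

    def test_large_x_asymptote(self):
        q = np.array([50.0])
        x = (q * 1.0) ** 2
        assert debye_chain(q, 1.0)[0] == pytest.approx(2.0 / x[0], rel=1e-3)

    def test_matches_discrete_gaussian_chain_sum(self):
        # brute-force oracle: (1/N^2) sum_ij exp(-q^2 |i-j| b^2 / 6)
        N, b = 200, 0.38
        rg2 = N * b**2 / 6.0
        rg = math.sqrt(rg2)
        q = np.linspace(0.05, 3.0 / rg, 25)
        ij = np.abs(np.subtract.outer(np.arange(N), np.arange(N)))
        brute = np.array(
            [np.exp(-(qi**2) * ij * b**2 / 6.0).mean() for qi in q]
        )
        np.testing.assert_allclose(debye_chain(q, rg), brute, rtol=0.01)


class TestStarIntensity:
    def test_forward_limit_identity(self, sphere_star_params):
        p = sphere_star_params
        val = star_intensity(np.array([1e-12]), p)[0]
        assert val == pytest.approx(p.Z**2 * (p.beta_c + p.beta_t) ** 2, rel=1e-10)

    def test_single_chain_has_no_tail_tail_term(self):
        # Z=1 with beta_c=0 must reduce to exactly one Debye tail
        p = StarParams(
            Z=1.0,
            core=CoreGeometry("sphere", R=1.0),
            Rg_tail=3.0,
            beta_c=0.0,
            beta_t=2.0,
            scale=1.0,
        )
        q = np.linspace(0.01, 2.0, 50)
        np.testing.assert_allclose(
            star_intensity(q, p), 4.0 * debye_chain(q, 3.0), rtol=1e-12
        )

    def test_tailless_star_is_pure_core(self):
        p = StarParams(
            Z=4.0,
            core=CoreGeometry("sphere", R=2.0),
            Rg_tail=3.0,
            beta_c=1.5,
            beta_t=0.0,
            scale=1.0,
        )
        q = np.linspace(0.05, 4.0, 200)
        expected = 16.0 * 1.5**2 * core_self_correlation(q, p.core)
        np.testing.assert_allclose(star_intensity(q, p), expected, rtol=1e-12)
        # first minimum (touching zero) of the sphere term at qR ~ 4.4934
        from scipy.optimize import minimize_scalar

        f = lambda qq: star_intensity(np.array([qq]), p)[0]
        res = minimize_scalar(f, bounds=(1.7, 2.6), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x * 2.0 == pytest.approx(4.4934, abs=1e-3)

    def test_invalid_aggregation_number_rejected(self):
        with pytest.raises(ValueError, match="Z"):
            StarParams(
                Z=0.5,
                core=CoreGeometry("sphere", R=1.0),
                Rg_tail=3.0,
                beta_c=1.0,
                beta_t=1.0,
            )

    @settings(max_examples=50, deadline=None)
    @given(
        Z=st.floats(1.0, 20.0),
        R=st.floats(0.3, 3.0),
        rg=st.floats(0.5, 10.0),
        bc=st.floats(0.1, 50.0),
        bt=st.floats(0.1, 150.0),
        d=st.floats(1.0, 2.0),
    )
    def test_nonnegative_for_physical_parameters(self, Z, R, rg, bc, bt, d):
        p = StarParams(
            Z=Z,
            core=CoreGeometry("sphere", R=R),
            Rg_tail=rg,
            beta_c=bc,
            beta_t=bt,
            d=d,
            scale=1.0,
        )
        q = np.geomspace(1e-3, 5.0, 200)
        assert np.all(star_intensity(q, p) >= 0.0)
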