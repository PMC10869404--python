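"""Scaling-theory overlays and derived structural quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starbrush import (
    BrushTheoryParams,
    CoreGeometry,
    UnsupportedGeometryError,
    brush_regime_ratio,
    core_residues,
    grafting_distance,
    nu_from_brush_height,
    polyelectrolyte_nu,
    salt_brush_height,
)
from starbrush.scaling import fit_grafting_density_trend, grafting_distance_for


class TestSaltBrushHeight:
    def test_exact_minus_third_power_law_at_fixed_grafting(self):
        p = BrushTheoryParams()
        h1 = salt_brush_height(50.0, p, sigma_g=0.44)
        h8 = salt_brush_height(400.0, p, sigma_g=0.44)
        assert h8 / h1 == pytest.approx(0.5, abs=1e-12)

    def test_loglog_slope_is_minus_third(self):
        p = BrushTheoryParams()
        slope = (
            math.log(salt_brush_height(500.0, p, sigma_g=0.44))
            - math.log(salt_brush_height(200.0, p, sigma_g=0.44))
        ) / (math.log(500.0) - math.log(200.0))
        assert slope == pytest.approx(-1.0 / 3.0, abs=1e-10)

    def test_linear_grafting_density_adds_analytic_correction(self):
        # with sigma_g = a + b Cs, d ln h/d ln Cs = -1/3 + (1/3) b Cs/(a + b Cs)
        p = BrushTheoryParams(sigma_g0=0.3, sigma_g_slope=5e-4)
        cs = 250.0
        eps = 1e-4
        num = (
            math.log(salt_brush_height(cs * (1 + eps), p))
            - math.log(salt_brush_height(cs * (1 - eps), p))
        ) / (math.log((1 + eps) / (1 - eps)))
        analytic = -1.0 / 3.0 + (1.0 / 3.0) * (5e-4 * cs) / (0.3 + 5e-4 * cs)
        assert num == pytest.approx(analytic, abs=1e-6)

    def test_magnitude_is_nanometric(self):
        h = salt_brush_height(170.0, BrushTheoryParams())
        assert 3.0 < h < 30.0

    def test_nonpositive_salinity_rejected(self):
        with pytest.raises(ValueError):
            salt_brush_height(0.0)


class TestBrushHeightToNu:
    def test_exact_inverse_of_power_law(self):
        p = BrushTheoryParams()
        h = 0.38 * 146**0.6
        assert nu_from_brush_height(h, p) == pytest.approx(0.6, abs=1e-12)

    def test_rod_limit(self):
        p = BrushTheoryParams()
        assert nu_from_brush_height(0.38 * 146, p) == pytest.approx(1.0, abs=1e-12)

    def test_sub_segment_height_rejected(self):
        with pytest.raises(ValueError):
            nu_from_brush_height(0.3, BrushTheoryParams())

    def test_composition_with_salt_law_declines_linearly_in_log_cs(self):
        p = BrushTheoryParams()
        cs = np.geomspace(100.0, 600.0, 20)
        h = np.array([salt_brush_height(c, p, sigma_g=0.44) for c in cs])
        nu = nu_from_brush_height(h, p)
        # nu = const - (1/3) log(Cs)/log(N): exactly linear in log Cs
        coeffs = np.polyfit(np.log(cs), nu, 1)
        assert coeffs[0] == pytest.approx(-1.0 / (3.0 * math.log(146)), rel=1e-9)
        residual = nu - np.polyval(coeffs, np.log(cs))
        assert np.max(np.abs(residual)) < 1e-12


class TestPolyelectrolyteNu:
    def test_monotone_decrease_with_screening(self):
        p = BrushTheoryParams()
        cs = np.geomspace(20.0, 520.0, 30)
        nu = polyelectrolyte_nu(cs, p)
        assert np.all(np.diff(nu) < 0)
        assert polyelectrolyte_nu(20.0, p) > polyelectrolyte_nu(520.0, p)

    def test_high_salt_plateau_is_neutral_chain_limit(self):
        p = BrushTheoryParams()
        plateau = (
            p.c_poly
            * math.log(math.sqrt(p.N) * (1 + p.z_neutral) ** 0.2)
            / math.log(p.N)
        )
        assert polyelectrolyte_nu(1e7, p) == pytest.approx(plateau, abs=1e-3)

    def test_prefactor_scales_linearly(self):
        base = BrushTheoryParams(c_poly=1.0)
        scaled = BrushTheoryParams(c_poly=1.24)
        assert polyelectrolyte_nu(100.0, scaled) == pytest.approx(
            1.24 * polyelectrolyte_nu(100.0, base), rel=1e-12
        )

    def test_low_salt_values_in_extended_chain_range(self):
        nu = polyelectrolyte_nu(20.0, BrushTheoryParams(N=104))
        assert 0.6 < nu < 0.85


class TestCoreResidues:
    def test_hand_values(self):
        assert core_residues(2.0, 10.0, 0.1) == pytest.approx(2.0)
        assert core_residues(1.5, 5.0, 0.11) == pytest.approx(2.727, abs=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(
        V=st.floats(0.1, 50.0),
        Z=st.floats(1.0, 20.0),
        phi=st.floats(0.05, 0.3),
    )
    def test_inverse_homogeneity_in_Z(self, V, Z, phi):
        assert core_residues(V, 2 * Z, phi) == pytest.approx(
            core_residues(V, Z, phi) / 2.0, rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            core_residues(1.0, 0.0, 0.1)
        with pytest.raises(ValueError):
            core_residues(1.0, 2.0, -0.1)


class TestGraftingDistance:
    def test_algebraic_identities(self):
        assert grafting_distance(1.0, 4 * math.pi) == pytest.approx(1.0, rel=1e-12)
        assert grafting_distance(1.0, 1.0) == pytest.approx(
            math.sqrt(4 * math.pi), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(R=st.floats(0.2, 5.0), Z=st.floats(1.0, 30.0))
    def test_inverse_sqrt_homogeneity_in_Z(self, R, Z):
        assert grafting_distance(R, 4 * Z) == pytest.approx(
            grafting_distance(R, Z) / 2.0, rel=1e-12
        )

    def test_cylinder_geometry_unsupported(self):
        with pytest.raises(UnsupportedGeometryError):
            grafting_distance_for(CoreGeometry("cylinder", R=1.0, L=2.0), 2.0)


class TestBrushRegime:
    def test_ratio_and_flag(self):
        ratio, brush = brush_regime_ratio(10.0, 1.0)
        assert ratio == 10.0 and brush

    def test_boundary_not_flagged(self):
        ratio, brush = brush_regime_ratio(1.0, 1.0)
        assert ratio == 1.0 and not brush

    def test_threshold_configurable(self):
        _, brush = brush_regime_ratio(2.0, 1.0, threshold=3.0)
        assert not brush


class TestGraftingTrend:
    def test_linear_trend_recovered(self):
        cs = np.array([20.0, 170.0, 320.0, 520.0])
        sigma_true = 0.3 + 4e-4 * cs
        rho = 1.0 / np.sqrt(sigma_true)
        intercept, slope = fit_grafting_density_trend(cs, rho)
        assert intercept == pytest.approx(0.3, rel=1e-9)
        assert slope == pytest.approx(4e-4, rel=1e-9)
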