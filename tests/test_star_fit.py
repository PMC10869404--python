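"""Star-brush form-factor fitting and derived brush quantities."""

import math

import numpy as np
import pytest

from starbrush import (
    CoreGeometry,
    StarFitConfig,
    StarParams,
    SyntheticSpec,
    compare_core_models,
    derive_nu_from_height,
    fit_star,
    generate_curve,
    rg_from_nu,
)


def star_curve(params, noise=0.0, seed=0):
    spec = SyntheticSpec(
        model="star", true_params=params, noise_frac=noise, noise_floor_frac=0.0
    )
    return generate_curve(spec, seed=seed)


def sphere_truth(Z=5.0, R=1.0, Rg_tail=4.0, beta_c=1.0, beta_t=1.0):
    return StarParams(
        Z=Z,
        core=CoreGeometry("sphere", R=R),
        Rg_tail=Rg_tail,
        beta_c=beta_c,
        beta_t=beta_t,
        scale=1.0,
    )


class TestFitStar:
    def test_noiseless_sphere_recovery(self):
        truth = sphere_truth()
        curve = star_curve(truth)
        cfg = StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0,
                            fix_background=True)
        res = fit_star(curve, cfg)
        assert res.Z == pytest.approx(5.0, rel=0.02)
        assert res.params.core.R == pytest.approx(1.0, rel=0.02)
        assert res.params.Rg_tail == pytest.approx(4.0, rel=0.02)

    def test_single_chain_truth_drives_Z_to_lower_bound(self):
        truth = sphere_truth(Z=1.0)
        curve = star_curve(truth, noise=0.005, seed=1)
        cfg = StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0,
                            fix_background=True)
        res = fit_star(curve, cfg)
        assert res.Z == pytest.approx(1.0, abs=0.05)

    def test_forward_limit_identity_preserved_through_fit(self):
        truth = sphere_truth()
        curve = star_curve(truth, noise=0.01, seed=3)
        cfg = StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0)
        res = fit_star(curve, cfg)
        p = res.params
        from starbrush import star_intensity

        val = star_intensity(np.array([1e-12]), p)[0]
        assert val == pytest.approx(p.forward_intensity, rel=1e-10)

    def test_doubled_scattering_lengths_rescale_only_the_scale(self):
        truth = sphere_truth()
        curve = star_curve(truth, noise=0.01, seed=7)
        res_1 = fit_star(
            curve, StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0)
        )
        res_2 = fit_star(
            curve, StarFitConfig(shape="sphere", beta_c=2.0, beta_t=2.0)
        )
        assert res_2.Z == pytest.approx(res_1.Z, rel=0.02)
        assert res_2.params.scale == pytest.approx(res_1.params.scale / 4, rel=0.05)

    def test_recovery_grid_median_error_under_five_percent(self):
        rel_errors = []
        seed = 0
        for Z in (2.0, 5.0, 10.0):
            for rg in (2.0, 4.0, 6.0):
                truth = sphere_truth(Z=Z, Rg_tail=rg)
                curve = star_curve(truth, noise=0.01, seed=seed)
                seed += 1
                res = fit_star(
                    curve,
                    StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0,
                                  fix_background=True),
                )
                rel_errors.append(abs(res.Z - Z) / Z)
                rel_errors.append(abs(res.params.Rg_tail - rg) / rg)
        assert np.median(rel_errors) < 0.05

    def test_error_propagation_formulas(self):
        truth = sphere_truth()
        curve = star_curve(truth, noise=0.01, seed=11)
        res = fit_star(
            curve, StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0)
        )
        dR = res.param_errors["R"]
        assert res.dV_over_V == pytest.approx(
            math.sqrt(3.0) * dR / res.params.core.R, rel=1e-12
        )
        dRg = res.param_errors["Rg_tail"]
        assert res.d_nu == pytest.approx(
            math.log(1.0 + dRg / res.params.Rg_tail) / math.log(146), rel=1e-12
        )

    def test_fixed_core_requires_dimensions(self, simple_curve):
        with pytest.raises(ValueError, match="R"):
            fit_star(simple_curve, StarFitConfig(shape="sphere", fix_core=True))


class TestDeriveNu:
    def test_roundtrip_through_height(self):
        h = 2.0 * rg_from_nu(146, 0.7)
        nu, _ = derive_nu_from_height(h, N=146)
        assert nu == pytest.approx(0.7, abs=1e-9)

    def test_hand_value_of_exponent_error(self):
        # dRg/Rg = 0.1, N = 146 -> dnu = ln(1.1)/ln(146) ~ 0.0191
        assert math.log(1.1) / math.log(146) == pytest.approx(0.0191, abs=2e-4)

    def test_unattainable_height_raises(self):
        with pytest.raises(ValueError, match="attainable"):
            derive_nu_from_height(0.05, N=146)


class TestCompareCoreModels:
    def _configs(self):
        return [
            StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0,
                          fix_background=True),
            StarFitConfig(shape="cylinder", beta_c=1.0, beta_t=1.0,
                          fix_background=True),
        ]

    def test_sphere_data_ranks_sphere_first(self):
        truth = sphere_truth(Z=4.0, R=1.5, Rg_tail=3.0)
        curve = star_curve(truth, noise=0.005, seed=21)
        ranked = compare_core_models(curve, self._configs())
        assert ranked[0][0] == "sphere"

    def test_elongated_cylinder_data_ranks_cylinder_first(self):
        truth = StarParams(
            Z=4.0,
            core=CoreGeometry("cylinder", R=0.6, L=6.0),
            Rg_tail=3.0,
            beta_c=1.0,
            beta_t=1.0,
            scale=1.0,
        )
        curve = star_curve(truth, noise=0.005, seed=22)
        ranked = compare_core_models(curve, self._configs())
        assert ranked[0][0] == "cylinder"

    def test_tie_broken_toward_fewer_free_parameters(self):
        # noiseless sphere data: the free fit and the core-fixed fit both
        # reach chi2 ~ 0; the model with fewer free parameters must rank first
        truth = sphere_truth(Z=3.0, R=1.2, Rg_tail=3.5)
        curve = star_curve(truth)
        free_cfg = StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0,
                                 fix_background=True)
        fixed_cfg = StarFitConfig(shape="sphere", beta_c=1.0, beta_t=1.0,
                                  fix_core=True, R=1.2, fix_background=True)
        ranked = compare_core_models(curve, [free_cfg, fixed_cfg])
        assert ranked[0][1].n_free < ranked[1][1].n_free

    def test_single_candidate_rejected(self, simple_curve):
        with pytest.raises(ValueError):
            compare_core_models(simple_curve, self._configs()[:1])
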