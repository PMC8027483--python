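"""Solver validation: closed-form oracles, conservation laws,
refinement stability, and model-variant behavior."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mtpb.observables import lumen_electroneutrality_residual
from mtpb.physical_model import (
    CONSTANTS,
    BufferSpec,
    ChargedCylinderSpec,
    PermittivityModel,
    debye_length,
    thermal_voltage,
)
from mtpb.pb_solver import (
    SolverOptions,
    compare_model_variants,
    lpb_exterior_potential,
    lpb_interior_potential,
    solve_nlpb,
    solve_nlpb_exterior,
    solve_nlpb_interior,
)
from mtpb.validation_fixtures import (
    grahame_surface_potential,
    mp_lpb_potential,
    reference_nlpb_bvp,
)


class TestAnalyticLpb:
    def test_interior_matches_arbitrary_precision_bessel(self, mt, buffer_160):
        r = np.linspace(0.0, mt.inner.R - buffer_160.d_stern, 40)
        got = lpb_interior_potential(mt.inner, buffer_160, 78.5, r)
        exp = mp_lpb_potential(mt.inner, buffer_160, 78.5, r)
        assert np.max(np.abs(got - exp)) / np.max(np.abs(exp)) < 1e-10

    def test_exterior_matches_arbitrary_precision_bessel(self, mt, buffer_160):
        a = mt.outer.R + buffer_160.d_stern
        r = np.geomspace(a, a + 20 * debye_length(buffer_160, 78.5), 40)
        got = lpb_exterior_potential(mt.outer, buffer_160, 78.5, r)
        exp = mp_lpb_potential(mt.outer, buffer_160, 78.5, r)
        assert np.max(np.abs(got - exp)) / np.max(np.abs(exp)) < 1e-10

    def test_exterior_decays_to_zero(self, mt, buffer_160):
        lam = debye_length(buffer_160, 78.5)
        far = lpb_exterior_potential(mt.outer, buffer_160, 78.5,
                                     mt.outer.R + 30 * lam)
        near = lpb_exterior_potential(mt.outer, buffer_160, 78.5,
                                      mt.outer.R + buffer_160.d_stern)
        assert abs(far) < 1e-10 * abs(near)

    def test_planar_limit_recovers_debye_huckel_surface_potential(self):
        # K0/K1 -> 1 for R >> lambda_D, d = 0
        buf = BufferSpec.kcl(150.0, d_stern=0.0)
        lam = debye_length(buf, 78.5)
        cyl = ChargedCylinderSpec(R=5000 * lam, sigma=-1e-4, side="exterior")
        V0 = lpb_exterior_potential(cyl, buf, 78.5, cyl.R)
        planar = cyl.sigma * lam / (CONSTANTS.eps0 * 78.5)
        assert V0 == pytest.approx(planar, rel=1e-3)

    def test_zero_charge_is_zero_everywhere(self, mt, buffer_160):
        cyl = replace(mt.inner, sigma=0.0)
        assert lpb_interior_potential(cyl, buffer_160, 78.5, 0.5 * cyl.R) == 0.0

    def test_domain_validation(self, mt, buffer_160):
        with pytest.raises(ValueError):
            lpb_interior_potential(mt.inner, buffer_160, 78.5, mt.inner.R)
        with pytest.raises(ValueError):
            lpb_exterior_potential(mt.outer, buffer_160, 78.5, mt.outer.R)


class TestNlpbOracles:
    def test_zero_charge_gives_flat_solution(self, mt, buffer_160, perm_full,
                                             fast_opts):
        cyl = replace(mt.outer, sigma=0.0)
        p = solve_nlpb_exterior(cyl, buffer_160, perm_full, fast_opts)
        assert np.all(p.V == 0.0)
        assert np.allclose(p.c_cation, buffer_160.c_s)

    def test_linear_regime_matches_analytic_lpb(self, mt, buffer_160,
                                                perm_const):
        # |V| << V_t: nonlinear and linear solutions agree to < 0.5%
        for cyl_base, solve in ((mt.outer, solve_nlpb_exterior),
                                (mt.inner, solve_nlpb_interior)):
            cyl = replace(cyl_base, sigma=cyl_base.sigma * 1e-3)
            p = solve(cyl, buffer_160, perm_const)
            if cyl.side == "exterior":
                Va = lpb_exterior_potential(cyl, buffer_160, 78.5, p.r)
            else:
                Va = lpb_interior_potential(cyl, buffer_160, 78.5, p.r)
            dev = np.max(np.abs(p.V - Va)) / np.max(np.abs(Va))
            assert dev < 5e-3

    def test_planar_limit_grahame_relation(self):
        # R = 1000 lambda_D, d = 0, constant eps: surface potential
        # satisfies the Grahame charge-potential relation to < 0.5%
        buf = BufferSpec.kcl(100.0, d_stern=0.0)
        lam = debye_length(buf, 78.5)
        cyl = ChargedCylinderSpec(R=1000 * lam, sigma=-0.083, side="exterior")
        p = solve_nlpb_exterior(cyl, buf, PermittivityModel(mode="constant"))
        V0 = grahame_surface_potential(-0.083, buf.c_s, 78.5)
        assert p.V_ohp == pytest.approx(V0, rel=5e-3)

    @pytest.mark.parametrize("c_mM", [0.01, 160.0])
    def test_matches_independent_collocation_solver(self, mt, perm_const, c_mM):
        # cross-check against scipy.solve_bvp (different discretization)
        buf = BufferSpec.kcl(c_mM)
        p = solve_nlpb_exterior(mt.outer, buf, perm_const)
        r_ref, V_ref = reference_nlpb_bvp(mt.outer, buf, 78.5)
        V_interp = np.interp(r_ref, p.r, p.V)
        dev = np.max(np.abs(V_interp - V_ref)) / np.max(np.abs(V_ref))
        assert dev < 1e-3

    def test_nlpb_to_lpb_first_order_in_sigma(self, mt, buffer_160, perm_const):
        # the NLPB-LPB deviation is O(sigma^3) absolute, O(sigma^2)
        # relative: quartering expected when sigma is halved
        devs = []
        for scale in (0.2, 0.1):
            cyl = replace(mt.outer, sigma=mt.outer.sigma * scale)
            p = solve_nlpb_exterior(cyl, buffer_160, perm_const)
            Va = lpb_exterior_potential(cyl, buffer_160, 78.5, p.r)
            devs.append(np.max(np.abs(p.V - Va)) / np.max(np.abs(Va)))
        ratio = devs[1] / devs[0]
        assert 0.15 < ratio < 0.35


class TestConservationLaws:
    @pytest.mark.parametrize("c_mM", [0.01, 160.0, 500.0])
    def test_exterior_screening_completeness(self, mt, perm_full, c_mM):
        # Gauss: line-integrated ion charge cancels the surface charge
        buf = BufferSpec.kcl(c_mM)
        p = solve_nlpb_exterior(mt.outer, buf, perm_full)
        rho = CONSTANTS.e * CONSTANTS.N_A * (p.c_cation - p.c_anion)
        q_ions = 2 * math.pi * np.trapezoid(rho * p.r, p.r)
        q_surf = 2 * math.pi * mt.outer.R * mt.outer.sigma
        assert abs(q_ions + q_surf) / abs(q_surf) < 1e-3

    @pytest.mark.parametrize("c_mM", [0.01, 160.0])
    def test_lumen_electroneutrality(self, mt, perm_full, c_mM):
        p = solve_nlpb_interior(mt.inner, BufferSpec.kcl(c_mM), perm_full)
        assert lumen_electroneutrality_residual(p) < 1e-3

    def test_boltzmann_identity_by_construction(self, solved_160):
        for p in solved_160:
            assert np.allclose(p.c_cation * p.c_anion,
                               p.buffer.c_s ** 2, rtol=1e-12)

    def test_far_field_is_screened(self, solved_160, solved_10uM):
        Vt = thermal_voltage()
        for p in (*solved_160, *solved_10uM):
            if p.side == "exterior":
                assert abs(p.V[-1]) < 1e-3 * Vt

    def test_potential_magnitude_decays_from_surface(self, solved_160):
        lumen, outer, ct = solved_160
        assert np.all(np.diff(np.abs(outer.V)) <= 1e-15)
        assert np.all(np.diff(np.abs(lumen.V)) >= -1e-15)  # grows toward wall


class TestRefinement:
    def test_grid_doubling_stability(self, mt, buffer_160, perm_full):
        base = SolverOptions(n_grid=1000)
        p1 = solve_nlpb_exterior(mt.outer, buffer_160, perm_full, base)
        p2 = solve_nlpb_exterior(mt.outer, buffer_160, perm_full,
                                 replace(base, n_grid=2000))
        assert abs(p2.V_ohp / p1.V_ohp - 1) < 1e-4

    def test_truncation_doubling_stability(self, mt, buffer_10uM, perm_full):
        base = SolverOptions(n_grid=1000)
        p1 = solve_nlpb_exterior(mt.outer, buffer_10uM, perm_full, base)
        p2 = solve_nlpb_exterior(mt.outer, buffer_10uM, perm_full,
                                 replace(base, r_max_factor=80.0))
        assert abs(p2.V_ohp / p1.V_ohp - 1) < 1e-4

    def test_observed_convergence_order_is_second(self, mt, buffer_160,
                                                  perm_const):
        vals = [solve_nlpb_exterior(mt.outer, buffer_160, perm_const,
                                    SolverOptions(n_grid=n)).V_ohp
                for n in (500, 1000, 2000)]
        order = math.log2(abs(vals[1] - vals[0]) / abs(vals[2] - vals[1]))
        assert 1.7 < order < 2.3


class TestPermittivityCoupling:
    def test_permittivity_profile_shape(self, solved_160, perm_full):
        # strongly reduced at the OHP, recovering the bulk-solution value
        # (eps_w corrected for the bulk ion fraction) within a few lambda_D
        _, outer, _ = solved_160
        assert outer.eps[0] < 0.9 * 78.5
        lam = debye_length(outer.buffer, 78.5)
        far = outer.r > outer.r_ohp + 5 * lam
        eps_bulk = float(perm_full.evaluate(0.0, outer.buffer.c_s))
        assert np.all(outer.eps[far] > 0.999 * eps_bulk)
        assert np.all((outer.eps > 1.8) & (outer.eps <= 78.5 + 1e-9))

    def test_full_mode_below_booth_only(self, mt, buffer_160, fast_opts):
        pf = solve_nlpb_exterior(mt.outer, buffer_160,
                                 PermittivityModel(mode="full"), fast_opts)
        pb = solve_nlpb_exterior(mt.outer, buffer_160,
                                 PermittivityModel(mode="booth_only"), fast_opts)
        # crowding by low-permittivity cations can only reduce eps further
        assert pf.eps[0] < pb.eps[0]


class TestModelVariants:
    def test_constant_permittivity_is_minor_at_physiological_strength(
            self, mt, buffer_160, perm_full, fast_opts):
        cmp = compare_model_variants(mt.outer, buffer_160, perm_full, fast_opts)
        vmax = np.max(np.abs(cmp.alpha.V))
        assert cmp.max_dev_alpha_beta < 0.1 * vmax

    def test_linearization_breaks_down_at_low_concentration(
            self, mt, perm_full, fast_opts):
        c160 = compare_model_variants(mt.outer, BufferSpec.kcl(160.0),
                                      perm_full, fast_opts)
        c10 = compare_model_variants(mt.outer, BufferSpec.kcl(10.0),
                                     perm_full, fast_opts)
        rel160 = c160.max_dev_alpha_gamma / np.max(np.abs(c160.alpha.V))
        rel10 = c10.max_dev_alpha_gamma / np.max(np.abs(c10.alpha.V))
        assert rel10 > 2 * rel160

    def test_all_variants_coincide_at_zero_charge(self, mt, buffer_160,
                                                  perm_full, fast_opts):
        cyl = replace(mt.outer, sigma=0.0)
        cmp = compare_model_variants(cyl, buffer_160, perm_full, fast_opts)
        assert cmp.max_dev_alpha_beta == 0.0
        assert cmp.max_dev_alpha_gamma == 0.0


class TestDeterminism:
    def test_repeat_solve_is_bit_identical(self, mt, buffer_160, perm_full,
                                           fast_opts):
        p1 = solve_nlpb_exterior(mt.ct, buffer_160, perm_full, fast_opts)
        p2 = solve_nlpb_exterior(mt.ct, buffer_160, perm_full, fast_opts)
        assert np.array_equal(p1.V, p2.V)
        assert np.array_equal(p1.eps, p2.eps)

    def test_side_dispatch_and_validation(self, mt, buffer_160):
        with pytest.raises(ValueError):
            solve_nlpb_exterior(mt.inner, buffer_160)
        with pytest.raises(ValueError):
            solve_nlpb_interior(mt.outer, buffer_160)
        with pytest.raises(ValueError):
            # Stern layer thicker than the cylinder
            solve_nlpb(ChargedCylinderSpec(R=0.2e-9, sigma=-0.1,
                                           side="interior"), buffer_160)
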