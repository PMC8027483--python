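"""Bound layers, charge bookkeeping, and conductivity observables."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mtpb import observables as obs
from mtpb.physical_model import (
    CONSTANTS,
    BufferSpec,
    buffer_conductivity,
    thermal_voltage,
)
from mtpb.pb_solver import solve_nlpb_exterior, solve_nlpb_interior
from mtpb.pipeline import solve_structure


class TestBoltzmannConcentrations:
    def test_reference_points(self, buffer_160):
        Vt = thermal_voltage()
        cp, cm = obs.concentrations_from_potential(0.0, buffer_160)
        assert cp == cm == buffer_160.c_s
        cp, _ = obs.concentrations_from_potential(-Vt, buffer_160)
        assert cp == pytest.approx(math.e * buffer_160.c_s, rel=1e-12)

    def test_product_identity(self, buffer_160):
        V = np.linspace(-0.3, 0.05, 50)
        cp, cm = obs.concentrations_from_potential(V, buffer_160)
        assert np.allclose(cp * cm, buffer_160.c_s ** 2, rtol=1e-12)


class TestBoundLayer:
    def test_outer_extent_brackets_at_160mM(self, solved_160):
        _, outer, _ = solved_160
        s = obs.bound_layer(outer)
        # sub-nm bound layer at BRB80 strength
        assert 0.3e-9 < s.extent < 1.5e-9
        assert s.net_bound_charge > 0
        assert s.bound_anion_charge <= 0 < s.bound_cation_charge

    def test_whole_lumen_bound_at_low_concentration(self, solved_10uM):
        lumen, _, _ = solved_10uM
        s = obs.bound_layer(lumen)
        assert s.extent == pytest.approx(lumen.cylinder.R)  # capped at radius
        # full neutralization of the inner wall: +5 e per dimer
        mt_charge = s.net_bound_charge * 8e-9 / 13 / CONSTANTS.e
        assert mt_charge == pytest.approx(5.0, rel=2e-3)

    def test_lumen_unbound_at_high_concentration(self, mt, perm_full):
        # |V(OHP)| < V_t at 500 mM: zero ions bound to the lumen
        p = solve_nlpb_interior(mt.inner, BufferSpec.kcl(500.0), perm_full)
        s = obs.bound_layer(p)
        assert s.extent == 0.0
        assert s.net_bound_charge == 0.0

    def test_infinite_threshold_empties_the_layer(self, solved_160):
        _, outer, _ = solved_160
        s = obs.bound_layer(outer, threshold=-10.0)
        assert s.extent == 0.0 and s.net_bound_charge == 0.0

    def test_threshold_sign_validation(self, solved_160):
        with pytest.raises(ValueError):
            obs.bound_layer(solved_160[1], threshold=+0.025)

    def test_extent_and_charge_monotone_in_concentration(self, mt, perm_full,
                                                         fast_opts):
        extents, charges = [], []
        for c_mM in (0.1, 1.0, 10.0, 100.0):
            p = solve_nlpb_exterior(mt.outer, BufferSpec.kcl(c_mM), perm_full,
                                    fast_opts)
            s = obs.bound_layer(p)
            extents.append(s.extent)
            charges.append(s.net_bound_charge)
        assert all(a > b for a, b in zip(extents, extents[1:]))
        assert all(a > b for a, b in zip(charges, charges[1:]))


class TestChargeBookkeeping:
    def test_net_complex_charge_at_160mM(self, solved_160, mt):
        lumen, outer, ct = solved_160
        q = obs.net_complex_charge_per_dimer(
            obs.bound_layer(lumen), obs.bound_layer(outer),
            obs.bound_layer(ct), mt)
        # bound ions can only partially offset the -52 e protein charge
        assert -52.0 < q < 0.0

    def test_no_bound_ions_returns_protein_charge(self, mt, solved_160):
        lumen, outer, ct = solved_160
        empty = [obs.bound_layer(p, threshold=-10.0) for p in (lumen, outer, ct)]
        q = obs.net_complex_charge_per_dimer(*empty, mt)
        assert q == pytest.approx(mt.protein_charge_per_dimer_e(), rel=1e-12)

    def test_per_dimer_conversion_conserves_totals(self, solved_160, mt):
        _, outer, _ = solved_160
        s = obs.bound_layer(outer)
        ring = s.net_bound_charge * mt.dimer_repeat  # one 8-nm ring
        assert s.per_dimer_e(mt) * 13 * CONSTANTS.e == pytest.approx(ring, rel=1e-12)

    def test_electroneutrality_zero_for_uncharged_wall(self, buffer_160,
                                                       perm_full, fast_opts,
                                                       mt):
        cyl = replace(mt.inner, sigma=0.0)
        p = solve_nlpb_interior(cyl, buffer_160, perm_full, fast_opts)
        assert obs.lumen_electroneutrality_residual(p) == 0.0


class TestConductivity:
    def test_uncharged_system_has_buffer_conductivity(self, mt, buffer_160,
                                                      perm_full, fast_opts):
        cyl = replace(mt.outer, sigma=0.0)
        p = solve_nlpb_exterior(cyl, buffer_160, perm_full, fast_opts)
        sig = obs.local_conductivity(p, buffer_160)
        assert np.allclose(sig, buffer_conductivity(buffer_160), rtol=1e-12)

    def test_local_conductivity_recovers_buffer_far_away(self, solved_160):
        _, outer, _ = solved_160
        sig = obs.local_conductivity(outer, outer.buffer)
        assert sig[-1] == pytest.approx(buffer_conductivity(outer.buffer),
                                        rel=1e-3)

    def test_surface_conductivity_dominated_by_cations_at_low_c(
            self, solved_10uM):
        _, outer, _ = solved_10uM
        buf = outer.buffer
        sig = obs.local_conductivity(outer, buf)
        ratio_sig = sig[0] / buffer_conductivity(buf)
        ratio_cat = outer.c_cation[0] / buf.c_s * (
            buf.lambda_cation / (buf.lambda_cation + buf.lambda_anion))
        assert ratio_sig == pytest.approx(ratio_cat, rel=1e-3)
        # five orders of magnitude between surface and bulk concentration
        assert outer.c_cation[0] / buf.c_s > 1e5

    def test_mean_conductivity_structure(self, solved_160, mt, smt):
        lumen, outer, ct = solved_160
        buf = lumen.buffer
        res_mt = obs.mean_axial_conductivity(lumen, outer, ct, mt, buf)
        res_smt = obs.mean_axial_conductivity(lumen, outer, None, smt, buf)
        assert res_mt.sigma_mean > res_smt.sigma_mean > 0
        assert res_mt.A_norm == res_smt.A_norm >= math.pi * mt.outer.R ** 2
        assert res_mt.G_ct_each > 0 and res_smt.G_ct_each == 0.0

    def test_empty_bound_region_gives_zero(self, solved_160, mt):
        lumen, outer, ct = solved_160
        res = obs.mean_axial_conductivity(lumen, outer, ct, mt, lumen.buffer,
                                          threshold=-10.0)
        assert res.sigma_mean == 0.0

    def test_mismatched_buffers_rejected(self, mt, perm_full, fast_opts):
        l1, o1, c1 = solve_structure(BufferSpec.kcl(160.0), perm_full, fast_opts)
        l2, _, _ = solve_structure(BufferSpec.kcl(10.0), perm_full, fast_opts)
        with pytest.raises(ValueError, match="different buffer"):
            obs.mean_axial_conductivity(l2, o1, c1, mt, o1.buffer)


class TestCtOverlap:
    def test_wells_overlap_at_physiological_strength(self, solved_160, mt):
        _, _, ct = solved_160
        result = obs.ct_overlap(ct, spacing=mt.ct_spacing)
        assert result.overlap
        assert result.margin > 0

    def test_no_overlap_without_a_well(self, mt, buffer_160, perm_full,
                                       fast_opts):
        cyl = replace(mt.ct, sigma=-1e-6)  # essentially uncharged tail
        p = solve_nlpb_exterior(cyl, buffer_160, perm_full, fast_opts)
        assert not obs.ct_overlap(p, spacing=mt.ct_spacing).overlap

    def test_margin_monotone_in_concentration(self, mt, perm_full, fast_opts):
        margins = []
        for c_mM in (1.0, 10.0, 100.0, 500.0):
            p = solve_nlpb_exterior(mt.ct, BufferSpec.kcl(c_mM), perm_full,
                                    fast_opts)
            margins.append(obs.ct_overlap(p, spacing=mt.ct_spacing).margin)
        assert all(a > b for a, b in zip(margins, margins[1:]))
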