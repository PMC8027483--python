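"""Derived electrical observables of microtubule-counterion complexes.

Given converged radial profiles, this module computes the quantities a
bioelectricity experiment reports: the extent of the thermally bound
counterion layer, the ionic charge bound to each surface, the net
charge of the protein-ion complex per tubulin heterodimer, local and
mean axial conductivities, and whether the potential wells of adjacent
C-termini overlap.

Conventions:

* An ion is *bound* where the local potential is below a binding
  threshold, by default the negative thermal voltage -k_B T / e
  (-25.68 mV at 298 K).
* Bound-layer extents are measured from the outer Helmholtz plane,
  where the ion-bearing domain begins.  The lumen extent is capped at
  the lumen radius when the entire interior is bound.
* Charge integrals are 2 pi Int N_A e (c+ - c-) r dr over the bound
  region; both species contribute, with signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physical_model import (
    CONSTANTS,
    BufferSpec,
    MicrotubuleSpec,
    PhysicalConstants,
    buffer_conductivity,
    thermal_voltage,
)
from .pb_solver import RadialProfile

__all__ = [
    "BoundLayerSummary",
    "ConductivityResult",
    "CtOverlap",
    "concentrations_from_potential",
    "bound_layer",
    "net_complex_charge_per_dimer",
    "lumen_electroneutrality_residual",
    "local_conductivity",
    "mean_axial_conductivity",
    "ct_overlap",
]

#: Default edge of a resolvable potential well, V (see ``ct_overlap``).
WELL_EDGE_V = 1.0e-3


def concentrations_from_potential(V: np.ndarray | float, buffer: BufferSpec,
                                  constants: PhysicalConstants = CONSTANTS
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann ion concentrations at potential V (mol/m^3).

    c+ = c_s exp(-eV/kT), c- = c_s exp(+eV/kT); their product is c_s^2
    for any V.
    """
    Vt = thermal_voltage(constants)
    x = np.clip(np.asarray(V, dtype=float) / Vt, -80.0, 80.0)
    return buffer.c_s * np.exp(-x), buffer.c_s * np.exp(x)


@dataclass
class BoundLayerSummary:
    """Extent and integrated charge of the thermally bound ion layer.

    ``extent`` is measured from the OHP (capped at the lumen radius for
    interior problems); ``r_edge`` is the same location as a radius
    from the cylinder axis.  Charges are per unit cylinder length, C/m;
    net = cation + anion contributions (anion contribution is
    negative).
    """

    threshold: float            # binding potential, V (negative)
    extent: float               # m
    r_edge: float               # m, thermal-voltage radius from the axis
    bound_cation_charge: float  # C/m, > 0
    bound_anion_charge: float   # C/m, < 0
    net_bound_charge: float     # C/m
    side: str

    def per_dimer_e(self, mt: MicrotubuleSpec,
                    constants: PhysicalConstants = CONSTANTS) -> float:
        """Net bound charge per tubulin dimer, in units of e, for an
        SMT surface (one 8-nm ring hosts 13 dimers)."""
        return self.net_bound_charge * mt.dimer_repeat / mt.protofilaments / constants.e


def _crossing_radius(r: np.ndarray, V: np.ndarray, threshold: float,
                     rising: bool) -> float | None:
    """First radius where V crosses ``threshold``.

    ``rising=True`` scans for V rising above the (negative) threshold
    with increasing r (exterior); ``rising=False`` scans for V falling
    below it (interior, approaching the wall)."""
    above = V > threshold
    if rising:
        if above[0]:
            return None  # never bound
        if not above.any():
            return math.inf  # bound beyond the grid (should not happen)
        i = int(np.argmax(above))
    else:
        if above[-1]:  # wall node unbound -> nothing bound anywhere
            return None
        if not above.any():
            return -math.inf  # entire domain bound
        i = int(len(V) - np.argmax(above[::-1]))  # first bound node index
    r0, r1 = r[i - 1], r[i]
    V0, V1 = V[i - 1], V[i]
    return float(r0 + (threshold - V0) / (V1 - V0) * (r1 - r0))


def _charge_integral(r: np.ndarray, rho: np.ndarray, lo: float, hi: float) -> float:
    """2 pi Int rho r dr over [lo, hi] by trapezoid with interpolated
    end points."""
    if hi <= lo:
        return 0.0
    inside = (r > lo) & (r < hi)
    rr = np.concatenate([[lo], r[inside], [hi]])
    ff = np.interp(rr, r, rho * r)
    return 2.0 * math.pi * float(np.trapezoid(ff, rr))


def bound_layer(profile: RadialProfile, threshold: float | None = None
                ) -> BoundLayerSummary:
    """Locate the thermally bound layer and integrate its ionic charge.

    The bound region is where V < threshold (default -k_B T / e).  For
    exterior problems it is the annulus [OHP, r_cross]; for the lumen
    it is [r_cross, wall OHP], possibly the whole interior.  Charges
    are 2 pi Int N_A e c(r) r dr over that region, per species.
    """
    if not profile.converged:
        raise ValueError("profile is not converged")
    c = profile.constants
    if threshold is None:
        threshold = -thermal_voltage(c)
    if threshold >= 0:
        raise ValueError("binding threshold must be negative for anionic surfaces")
    r, V = profile.r, profile.V
    R = profile.cylinder.R

    if profile.side == "exterior":
        rc = _crossing_radius(r, V, threshold, rising=True)
        if rc is None:
            return BoundLayerSummary(threshold, 0.0, profile.r_ohp, 0.0, 0.0, 0.0,
                                     profile.side)
        lo, hi = profile.r_ohp, rc
        extent = rc - profile.r_ohp
        r_edge = rc
    else:
        rc = _crossing_radius(r, V, threshold, rising=False)
        if rc is None:
            return BoundLayerSummary(threshold, 0.0, profile.r_ohp, 0.0, 0.0, 0.0,
                                     profile.side)
        if rc == -math.inf:  # whole lumen bound; extent capped at the radius
            lo, hi = 0.0, profile.r_ohp
            extent = R
            r_edge = 0.0
        else:
            lo, hi = rc, profile.r_ohp
            extent = R - rc
            r_edge = rc

    e_NA = c.e * c.N_A
    q_cat = _charge_integral(r, e_NA * profile.c_cation, lo, hi)
    q_an = _charge_integral(r, -e_NA * profile.c_anion, lo, hi)
    return BoundLayerSummary(threshold, extent, r_edge, q_cat, q_an,
                             q_cat + q_an, profile.side)


def net_complex_charge_per_dimer(lumen: BoundLayerSummary,
                                 outer: BoundLayerSummary,
                                 ct: BoundLayerSummary,
                                 mt: MicrotubuleSpec,
                                 constants: PhysicalConstants = CONSTANTS) -> float:
    """Net charge of the protein-ion complex per heterodimer (units e).

    Sums the modeled protein charge (-52 e with CT for the default
    geometry) and the thermally bound ionic charge of every surface:
    lumen and outer wall per-length charges convert through one 8-nm,
    13-dimer ring; each of the two CT per dimer contributes its
    per-length bound charge over the 4 nm CT length.
    """
    q = mt.protein_charge_per_dimer_e(constants)
    q += lumen.per_dimer_e(mt, constants)
    q += outer.per_dimer_e(mt, constants)
    if mt.include_ct:
        q += mt.ct_per_dimer * ct.net_bound_charge * mt.ct_length / constants.e
    return q


def lumen_electroneutrality_residual(profile: RadialProfile) -> float:
    """Relative deviation from lumen electroneutrality.

    The flux boundary condition implies that the total ion charge per
    length inside the lumen cancels the inner wall charge; this
    recomputes both sides by quadrature: |Q_ions + 2 pi R_i sigma_i| /
    |2 pi R_i sigma_i|.  Returns 0 for an uncharged wall.
    """
    if profile.side != "interior":
        raise ValueError("electroneutrality residual is defined for the lumen")
    cyl = profile.cylinder
    if cyl.sigma == 0.0:
        return 0.0
    c = profile.constants
    rho = c.e * c.N_A * (profile.c_cation - profile.c_anion)
    q_ions = _charge_integral(profile.r, rho, 0.0, profile.r_ohp)
    q_wall = 2.0 * math.pi * cyl.R * cyl.sigma
    return abs(q_ions + q_wall) / abs(q_wall)


def local_conductivity(profile: RadialProfile, buffer: BufferSpec) -> np.ndarray:
    """Local ionic conductivity sigma(r) = lambda+ c+(r) + lambda- c-(r),
    S/m, assuming bulk molar conductivities along equipotentials."""
    return (buffer.lambda_cation * profile.c_cation
            + buffer.lambda_anion * profile.c_anion)


@dataclass
class ConductivityResult:
    """Mean axial conductivity of a microtubule-ion complex.

    Conductances are per unit length over the bound regions (units
    S*m); the mean conductivity divides their sum by the normalization
    cross-section A_norm = pi r_edge,outer^2 (the MT plus its outer
    bound layer).
    """

    G_outer: float          # S*m
    G_lumen: float          # S*m
    G_ct_each: float        # S*m
    n_ct_parallel: int
    include_ct: bool
    A_norm: float           # m^2
    sigma_mean: float       # S/m
    sigma_buffer: float     # S/m

    @property
    def ratio(self) -> float:
        return self.sigma_mean / self.sigma_buffer


def _bound_conductance(profile: RadialProfile, buffer: BufferSpec,
                       summary: BoundLayerSummary,
                       cation_only: bool = False) -> float:
    """2 pi Int sigma_local r dr over the bound region, S*m."""
    if summary.extent == 0.0:
        return 0.0
    sig = (buffer.lambda_cation * profile.c_cation if cation_only
           else np.asarray(local_conductivity(profile, buffer)))
    if profile.side == "exterior":
        lo, hi = profile.r_ohp, summary.r_edge
    else:
        lo = 0.0 if summary.extent >= profile.cylinder.R else summary.r_edge
        hi = profile.r_ohp
    return _charge_integral(profile.r, sig, lo, hi)


def mean_axial_conductivity(lumen: RadialProfile, outer: RadialProfile,
                            ct: RadialProfile | None, mt: MicrotubuleSpec,
                            buffer: BufferSpec,
                            threshold: float | None = None,
                            cation_only: bool = False) -> ConductivityResult:
    """Mean axial conductivity of the complex at one buffer state.

    Integrates the local ionic conductivity over the thermally bound
    regions of the lumen, the outer wall, and (when CT are included)
    13 C-termini treated as independent parallel cylinders, then
    normalizes by the cross-section of the MT plus its outer bound
    layer.  Protein electronic conduction is taken as negligible.  Both
    ion species conduct by default; ``cation_only`` restricts the
    integrand to K+ for sensitivity checks.
    """
    for p, side in ((lumen, "interior"), (outer, "exterior")):
        if p.side != side:
            raise ValueError(f"expected a {side} profile")
    buffers = {lumen.buffer.c_s, outer.buffer.c_s}
    if ct is not None:
        buffers.add(ct.buffer.c_s)
    if len(buffers) != 1:
        raise ValueError("profiles were solved at different buffer concentrations")

    s_lumen = bound_layer(lumen, threshold)
    s_outer = bound_layer(outer, threshold)
    G_lumen = _bound_conductance(lumen, buffer, s_lumen, cation_only)
    G_outer = _bound_conductance(outer, buffer, s_outer, cation_only)
    if mt.include_ct:
        if ct is None:
            raise ValueError("CT profile required when include_ct is set")
        s_ct = bound_layer(ct, threshold)
        G_ct = _bound_conductance(ct, buffer, s_ct, cation_only)
    else:
        G_ct = 0.0

    r_norm = max(s_outer.r_edge, mt.outer.R)
    A_norm = math.pi * r_norm ** 2
    G_total = G_lumen + G_outer + (mt.protofilaments * G_ct if mt.include_ct else 0.0)
    return ConductivityResult(
        G_outer=G_outer, G_lumen=G_lumen, G_ct_each=G_ct,
        n_ct_parallel=mt.protofilaments, include_ct=mt.include_ct,
        A_norm=A_norm, sigma_mean=G_total / A_norm,
        sigma_buffer=buffer_conductivity(buffer))


@dataclass
class CtOverlap:
    """Whether the potential wells of adjacent C-termini overlap."""

    overlap: bool
    margin: float       # m; well-edge radius minus half the CT spacing
    r_well_edge: float  # m, radius where |V| decays to the well edge
    half_spacing: float


def ct_overlap(profile: RadialProfile, spacing: float = 4.0e-9,
               well_edge: float = WELL_EDGE_V) -> CtOverlap:
    """Check whether a C-terminus's potential well reaches the midpoint
    to its nearest neighbour along the protofilament.

    The well edge is the radius where |V| decays to ``well_edge``
    (default 1 mV, the point below which the well is electrically
    negligible); wells overlap when this radius reaches half the
    centre-to-centre CT spacing.  The margin (well-edge radius minus
    half-spacing) is monotone non-increasing in the buffer
    concentration because screening only sharpens the well.
    """
    if profile.side != "exterior":
        raise ValueError("CT overlap requires an exterior profile")
    r, V = profile.r, profile.V
    if abs(V[0]) <= well_edge:  # degenerate: no resolvable well at all
        r_edge = profile.r_ohp
    else:
        rc = _crossing_radius(r, V, -abs(well_edge), rising=True)
        r_edge = float(r[-1]) if rc is None or rc == math.inf else rc
    half = spacing / 2.0
    return CtOverlap(overlap=r_edge >= half, margin=r_edge - half,
                     r_well_edge=r_edge, half_spacing=half)
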