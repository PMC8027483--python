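"""Physical constants, scenario types, and closed-form electrolyte quantities.

This module holds everything that can be written down without solving a
boundary-value problem: CODATA constants, the buffer and geometry
descriptions, the Debye length and thermal voltage, surface charge
densities of the microtubule surfaces, and the variable-permittivity
model (dielectric saturation in strong fields — the Booth effect — and
the reduction of permittivity by crowded hydrated cations).

Units are SI throughout (m, V, C, mol/m^3, S/m) with two deliberate
exceptions, flagged at the point of use: the Booth saturation formula is
parameterized with the electric field in mV/Angstrom, and convenience
constructors accept mM and nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "PhysicalConstants",
    "BufferSpec",
    "PermittivityModel",
    "ChargedCylinderSpec",
    "MicrotubuleSpec",
    "CONSTANTS",
    "MV_PER_ANGSTROM_PER_V_PER_M",
    "thermal_voltage",
    "debye_length",
    "surface_charge_density",
    "booth_langevin",
    "booth_permittivity",
    "ion_volume_fraction",
    "concentration_permittivity",
    "buffer_conductivity",
]

#: 1 V/m expressed in mV/Angstrom (1 mV/A = 1e7 V/m).
MV_PER_ANGSTROM_PER_V_PER_M = 1.0e-7

#: Limiting molar conductivity of K+ at 298 K, S*m^2/mol (= 73.52 S*cm^2/mol).
LAMBDA_K = 7.352e-3
#: Limiting molar conductivity of Cl- at 298 K, S*m^2/mol (= 76.34 S*cm^2/mol).
LAMBDA_CL = 7.634e-3

#: Maximum packing concentration of hydrated K+, mol/m^3 (15.9 M).
C_MAX_K = 15.9e3

#: Radius of a hydrated potassium ion, m; used as the Stern-layer
#: thickness (distance of closest approach) for KCl buffers.
D_STERN_K = 0.33e-9


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants plus the scenario temperature.

    All values CODATA-2018 exact; T defaults to 298 K and is fixed per
    scenario.
    """

    e: float = 1.602176634e-19  # elementary charge, C
    k_B: float = 1.380649e-23   # Boltzmann constant, J/K
    N_A: float = 6.02214076e23  # Avogadro constant, 1/mol
    eps0: float = 8.8541878128e-12  # vacuum permittivity, F/m
    T: float = 298.0            # absolute temperature, K

    def __post_init__(self) -> None:
        for name in ("e", "k_B", "N_A", "eps0", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class BufferSpec:
    """Bulk state of a monovalent symmetric (KCl-like) electrolyte.

    Parameters
    ----------
    c_s : float
        Bulk salt concentration, mol/m^3 (1 mol/m^3 == 1 mM).
    lambda_cation, lambda_anion : float
        Limiting molar conductivities, S*m^2/mol.
    d_stern : float
        Distance of closest approach of hydrated ions to a charged
        surface (Stern-layer thickness), m. Default is the hydrated
        K+ radius, 0.33 nm.
    c_max : float
        Maximum packing concentration of the cation, mol/m^3
        (default 15.9 M), used by the concentration-dependent
        permittivity model.
    """

    c_s: float
    lambda_cation: float = LAMBDA_K
    lambda_anion: float = LAMBDA_CL
    d_stern: float = D_STERN_K
    c_max: float = C_MAX_K
    z: int = 1  # |valence| of both species; only 1:1 salts are supported

    def __post_init__(self) -> None:
        if self.c_s <= 0:
            raise ValueError("c_s must be positive")
        if self.z != 1:
            raise ValueError("only monovalent symmetric electrolytes are supported")
        if self.d_stern < 0:
            raise ValueError("d_stern must be non-negative")
        if self.c_max <= 0:
            raise ValueError("c_max must be positive")

    @classmethod
    def kcl(cls, c_mM: float, **kwargs) -> "BufferSpec":
        """KCl buffer from a concentration in mM."""
        return cls(c_s=float(c_mM), **kwargs)

    def with_concentration(self, c_s: float) -> "BufferSpec":
        return replace(self, c_s=c_s)


PermittivityMode = Literal["constant", "booth_only", "concentration_only", "full"]

_PERM_MODES = ("constant", "booth_only", "concentration_only", "full")


@dataclass(frozen=True)
class PermittivityModel:
    """Local relative permittivity of the electrolyte.

    ``mode`` selects which corrections to apply on top of the bulk
    value ``eps_w``:

    - ``constant``: eps_w everywhere.
    - ``booth_only``: dielectric saturation in strong fields only.
    - ``concentration_only``: reduction by crowded hydrated cations only.
    - ``full``: saturation first, then the concentration correction is
      applied to the saturated value.

    ``eps_K`` is the effective relative permittivity attributed to a
    hydrated potassium ion; it enters the concentration correction
    through alpha = eps_K / (2 eps_base). Default 5, a representative
    dielectrically saturated hydration-shell value.
    """

    eps_w: float = 78.5
    eps_K: float = 5.0
    mode: PermittivityMode = "full"

    def __post_init__(self) -> None:
        if self.eps_w <= 1.8:
            raise ValueError("eps_w must exceed the optical limit 1.8")
        if self.eps_K <= 0:
            raise ValueError("eps_K must be positive")
        if self.mode not in _PERM_MODES:
            raise ValueError(f"mode must be one of {_PERM_MODES}")

    def evaluate(self, E: np.ndarray | float, c_cation: np.ndarray | float,
                 c_max: float = C_MAX_K) -> np.ndarray:
        """Local relative permittivity for field E (V/m) and cation
        concentration c_cation (mol/m^3)."""
        E = np.asarray(E, dtype=float)
        c_cation = np.asarray(c_cation, dtype=float)
        if self.mode == "constant":
            return np.broadcast_to(self.eps_w, np.broadcast_shapes(E.shape, c_cation.shape)).copy()
        if self.mode in ("booth_only", "full"):
            base = booth_permittivity(E * MV_PER_ANGSTROM_PER_V_PER_M, self.eps_w)
        else:
            base = np.broadcast_to(self.eps_w, E.shape).astype(float)
        if self.mode in ("concentration_only", "full"):
            rho = ion_volume_fraction(c_cation, c_max)
            return concentration_permittivity(base, rho, self.eps_K)
        return np.asarray(base)


@dataclass(frozen=True)
class ChargedCylinderSpec:
    """An infinitely long cylinder with uniform surface charge.

    ``side`` states which side of the surface the electrolyte occupies:
    ``exterior`` for the outer microtubule wall and C-termini,
    ``interior`` for the lumen.
    """

    R: float            # cylinder radius, m
    sigma: float        # surface charge density, C/m^2 (signed)
    side: Literal["interior", "exterior"] = "exterior"

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.side not in ("interior", "exterior"):
            raise ValueError("side must be 'interior' or 'exterior'")


@dataclass(frozen=True)
class MicrotubuleSpec:
    """Geometry and charge bookkeeping for one microtubule.

    The microtubule is split into cylindrical sub-problems: the lumen
    wall (inner surface, charge from the -5 e per dimer that faces the
    interior), the outer wall of the subtilisin-digested microtubule
    (SMT, -25 e per dimer), and the C-terminal tails (CT, -11 e each),
    each modeled as an isolated infinite cylinder.
    """

    inner: ChargedCylinderSpec = field(
        default_factory=lambda: ChargedCylinderSpec(R=8.4e-9, sigma=-0.0247, side="interior"))
    outer: ChargedCylinderSpec = field(
        default_factory=lambda: ChargedCylinderSpec(R=12.5e-9, sigma=-0.0829, side="exterior"))
    ct: ChargedCylinderSpec = field(
        default_factory=lambda: ChargedCylinderSpec(R=0.5e-9, sigma=-0.1402, side="exterior"))
    ct_length: float = 4.0e-9       # modeled CT cylinder length, m
    ct_spacing: float = 4.0e-9      # CT centre-to-centre spacing along a protofilament, m
    ct_per_dimer: int = 2           # one CT per monomer
    protofilaments: int = 13
    dimer_repeat: float = 8.0e-9    # axial repeat of one dimer ring, m
    include_ct: bool = True

    def __post_init__(self) -> None:
        if not self.inner.R < self.outer.R:
            raise ValueError("inner radius must be smaller than outer radius")
        if any(c.sigma > 0 for c in (self.inner, self.outer, self.ct)):
            raise ValueError("tubulin surfaces are negatively charged")
        if self.protofilaments != 13:
            raise ValueError("the standard microtubule has 13 protofilaments")

    @classmethod
    def default(cls, include_ct: bool = True,
                constants: PhysicalConstants = CONSTANTS) -> "MicrotubuleSpec":
        """The standard 13-protofilament microtubule with surface charge
        densities recomputed from the per-dimer charges (-5 e inner,
        -25 e outer, -11 e per CT)."""
        mt = cls(include_ct=include_ct)
        return replace(
            mt,
            inner=replace(mt.inner, sigma=surface_charge_density(-5.0, mt, "inner", constants)),
            outer=replace(mt.outer, sigma=surface_charge_density(-25.0, mt, "outer", constants)),
            ct=replace(mt.ct, sigma=surface_charge_density(-11.0, mt, "ct", constants)),
        )

    def protein_charge_per_dimer_e(self, constants: PhysicalConstants = CONSTANTS) -> float:
        """Modeled protein charge per heterodimer in units of e
        (back-computed from the surface charge densities; -52 e for
        the default geometry when CT are included)."""
        q = 0.0
        for cyl in (self.inner, self.outer):
            area_per_dimer = 2.0 * math.pi * cyl.R * self.dimer_repeat / self.protofilaments
            q += cyl.sigma * area_per_dimer
        if self.include_ct:
            ct_area = 2.0 * math.pi * self.ct.R * self.ct_length
            q += self.ct_per_dimer * self.ct.sigma * ct_area
        return q / constants.e


def thermal_voltage(constants: PhysicalConstants = CONSTANTS) -> float:
    """k_B T / e, the thermal voltage (V); ~25.7 mV at 298 K.

    Ions sitting at potentials below the *negative* of this value are
    counted as bound to a negatively charged surface.
    """
    if constants.T <= 0:
        raise ValueError("temperature must be positive")
    return constants.k_B * constants.T / constants.e


def debye_length(buffer: BufferSpec, eps_r: float,
                 constants: PhysicalConstants = CONSTANTS) -> float:
    """Debye screening length of a 1:1 electrolyte (m).

    lambda_D = sqrt(eps0 eps_r k_B T / (2 N_A c_s e^2)).
    """
    if buffer.c_s <= 0:
        raise ValueError("concentration must be positive")
    if eps_r <= 0:
        raise ValueError("permittivity must be positive")
    return math.sqrt(
        constants.eps0 * eps_r * constants.k_B * constants.T
        / (2.0 * constants.N_A * buffer.c_s * constants.e ** 2)
    )


def surface_charge_density(charge_per_dimer_e: float, geometry: MicrotubuleSpec,
                           surface: str,
                           constants: PhysicalConstants = CONSTANTS) -> float:
    """Surface charge density (C/m^2) of one microtubule surface.

    For the inner and outer walls the per-dimer charge is spread over
    the cylindrical patch one dimer occupies: 13 dimers per 8-nm ring,
    so the patch area is 2 pi R * repeat / 13.  For a C-terminus the
    charge sits on the lateral area of its 4 nm x 1 nm cylinder.
    """
    if surface in ("inner", "outer"):
        cyl = geometry.inner if surface == "inner" else geometry.outer
        if cyl.R <= 0 or geometry.dimer_repeat <= 0:
            raise ValueError("radii and repeat distances must be positive")
        area = 2.0 * math.pi * cyl.R * geometry.dimer_repeat / geometry.protofilaments
    elif surface == "ct":
        if geometry.ct.R <= 0 or geometry.ct_length <= 0:
            raise ValueError("radii and lengths must be positive")
        area = 2.0 * math.pi * geometry.ct.R * geometry.ct_length
    else:
        raise ValueError(f"unknown surface {surface!r}; expected inner|outer|ct")
    return charge_per_dimer_e * constants.e / area


def booth_langevin(x: np.ndarray | float) -> np.ndarray | float:
    """The saturation factor L(x) = 3 [coth(x) - 1/x] / x.

    This is the classical Langevin function scaled by 3/x, the form in
    which it enters Booth's dielectric-saturation formula.  L(0) = 1 by
    the series limit and L decreases to 0 as x -> infinity.  Evaluated
    by Taylor series for |x| < 1e-4 to avoid catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)  # dummy to keep coth finite
    with np.errstate(over="ignore"):
        bulk = 3.0 * (1.0 / np.tanh(xs) - 1.0 / xs) / xs
    series = 1.0 - x * x / 15.0 + 2.0 * x ** 4 / 315.0
    out = np.where(small, series, bulk)
    return out if out.ndim else float(out)


def booth_permittivity(E_mV_per_A: np.ndarray | float,
                       eps_l: float) -> np.ndarray | float:
    """Field-dependent (saturated) relative permittivity.

    eps_BE = 1.8 + (eps_l - 1.8) L(0.08 E), with E the field magnitude
    in mV/Angstrom and eps_l the local zero-field permittivity.  The
    value decreases monotonically from eps_l at E = 0 to the optical
    limit 1.8 at infinite field.  Parameterization is for 298 K.
    """
    E = np.asarray(E_mV_per_A, dtype=float)
    if np.any(E < 0):
        raise ValueError("field magnitude must be non-negative")
    if eps_l < 1.8:
        raise ValueError("eps_l must be >= 1.8")
    out = 1.8 + (eps_l - 1.8) * booth_langevin(0.08 * E)
    return out if np.ndim(out) else float(out)


def ion_volume_fraction(c_K: np.ndarray | float,
                        c_max: float = C_MAX_K) -> np.ndarray | float:
    """Volume fraction occupied by hydrated cations:
    rho = c / (c + c_max), in [0, 1)."""
    c = np.asarray(c_K, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c / (c + c_max)
    return out if out.ndim else float(out)


def concentration_permittivity(eps_base: np.ndarray | float,
                               rho: np.ndarray | float,
                               eps_K: float) -> np.ndarray | float:
    """Permittivity reduced by the volume fraction rho of hydrated
    cations of permittivity eps_K:

    eps = eps_base (1 - rho + 3 alpha rho) / (1 + rho/2),
    alpha = eps_K / (2 eps_base).

    ``eps_base`` is the bulk water value, or the field-saturated value
    when both corrections are composed.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("rho must lie in [0, 1)")
    eps_base = np.asarray(eps_base, dtype=float)
    alpha = eps_K / (2.0 * eps_base)
    out = eps_base * (1.0 - rho + 3.0 * alpha * rho) / (1.0 + rho / 2.0)
    return out if out.ndim else float(out)


def buffer_conductivity(buffer: BufferSpec) -> float:
    """Bulk conductivity of the buffer (S/m): (lambda+ + lambda-) c_s."""
    if buffer.c_s < 0:
        raise ValueError("concentration must be non-negative")
    return (buffer.lambda_cation + buffer.lambda_anion) * buffer.c_s
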