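"""Oracle cases and canonical scenarios for validating the solvers.

Every expectation here is computed by code *independent* of the solver
modules — closed forms (Grahame/Gouy-Chapman planar theory, the
Debye-Huckel Bessel solutions evaluated in arbitrary precision with
mpmath), or an independent adaptive-collocation solve of the same
boundary-value problem via scipy.integrate.solve_bvp — so agreement is
evidence of correctness rather than tautology.

There is no randomness anywhere: "synthetic data" for this analysis
means parameterized physical scenarios, which is exactly the structure
the deterministic mean-field model assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .physical_model import (
    CONSTANTS,
    BufferSpec,
    ChargedCylinderSpec,
    MicrotubuleSpec,
    PermittivityModel,
    PhysicalConstants,
    debye_length,
    thermal_voltage,
)
from .pb_solver import SolverOptions, solve_nlpb

__all__ = [
    "OracleCase",
    "make_gouy_chapman_case",
    "make_linear_regime_case",
    "make_refinement_suite",
    "canonical_scenarios",
    "grahame_surface_potential",
    "gouy_chapman_profile",
    "mp_lpb_potential",
    "reference_nlpb_bvp",
    "run_oracle_suite",
]


@dataclass
class OracleCase:
    """A self-contained validation scenario with an independent
    expectation and an explicit tolerance."""

    name: str
    kind: str  # lpb_bessel | gouy_chapman_planar | grahame_surface | linear_regime | refinement
    cylinder: ChargedCylinderSpec
    buffer: BufferSpec
    perm: PermittivityModel
    opts: SolverOptions
    rel_tol: float
    expected: dict = field(default_factory=dict)
    check: Callable[["OracleCase"], float] | None = None
    description: str = ""

    def max_rel_error(self) -> float:
        """Run the solver on this case and return the worst relative
        deviation from the independent expectation."""
        if self.check is None:
            raise ValueError("case has no check callable")
        return self.check(self)


# ---------------------------------------------------------------------------
# Closed-form planar theory (independent of pb_solver)
# ---------------------------------------------------------------------------

def grahame_surface_potential(sigma: float, c_s: float, eps_r: float,
                              constants: PhysicalConstants = CONSTANTS) -> float:
    """Planar double-layer surface potential from the charge density.

    Inverts sigma = sqrt(8 c_s N_A eps eps0 kT) sinh(eV0 / 2kT).
    """
    kT = constants.k_B * constants.T
    pref = math.sqrt(8.0 * c_s * constants.N_A * eps_r * constants.eps0 * kT)
    return 2.0 * kT / constants.e * math.asinh(sigma / pref)


def gouy_chapman_profile(V0: float, x: np.ndarray, lam: float,
                         constants: PhysicalConstants = CONSTANTS) -> np.ndarray:
    """Planar nonlinear profile: tanh(eV/4kT) = tanh(eV0/4kT) e^(-x/lam)."""
    Vt = thermal_voltage(constants)
    g0 = math.tanh(V0 / (4.0 * Vt))
    return 4.0 * Vt * np.arctanh(g0 * np.exp(-np.asarray(x) / lam))


def mp_lpb_potential(cyl: ChargedCylinderSpec, buffer: BufferSpec, eps_r: float,
                     r: np.ndarray, constants: PhysicalConstants = CONSTANTS,
                     dps: int = 50) -> np.ndarray:
    """Debye-Huckel Bessel solution evaluated in arbitrary precision.

    Independent re-derivation of the linear-regime closed forms using
    mpmath's besseli/besselk at ``dps`` decimal digits, for use as a
    precision oracle against the double-precision implementations.
    """
    import mpmath as mp

    with mp.workdps(dps):
        lam = mp.sqrt(mp.mpf(constants.eps0) * eps_r * constants.k_B * constants.T
                      / (2 * mp.mpf(constants.N_A) * buffer.c_s * mp.mpf(constants.e) ** 2))
        d = mp.mpf(buffer.d_stern)
        R = mp.mpf(cyl.R)
        sig = mp.mpf(cyl.sigma)
        out = []
        if cyl.side == "interior":
            b = R - d
            amp = sig * lam / (mp.mpf(constants.eps0) * eps_r) * R / b
            for ri in np.asarray(r, dtype=float):
                out.append(amp * mp.besseli(0, ri / lam) / mp.besseli(1, b / lam))
        else:
            a = R + d
            amp = sig * lam / (mp.mpf(constants.eps0) * eps_r) * R / a
            for ri in np.asarray(r, dtype=float):
                out.append(amp * mp.besselk(0, ri / lam) / mp.besselk(1, a / lam))
        return np.array([float(v) for v in out])


def reference_nlpb_bvp(cyl: ChargedCylinderSpec, buffer: BufferSpec,
                       eps_r: float, r_max_factor: float = 40.0,
                       constants: PhysicalConstants = CONSTANTS,
                       tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Independent constant-permittivity NLPB solve via adaptive
    collocation (scipy.integrate.solve_bvp).

    Returns (r, V).  Uses a different discretization (4th-order
    collocation with residual-driven mesh adaptation, Dirichlet far
    field) from the production finite-volume Newton solver, so it
    serves as a genuinely independent numeric oracle.
    """
    from scipy.integrate import solve_bvp

    from .pb_solver import lpb_exterior_potential, lpb_interior_potential

    Vt = thermal_voltage(constants)
    lam = debye_length(buffer, eps_r, constants)
    K = 2.0 * constants.e * constants.N_A * buffer.c_s / (constants.eps0 * eps_r)

    def rhs(r, y):
        return np.vstack([y[1],
                          K * np.sinh(np.clip(y[0] / Vt, -60, 60)) - y[1] / r])

    if cyl.side == "exterior":
        a = cyl.R + buffer.d_stern
        r_grid = np.geomspace(a, a + r_max_factor * lam, 3000)
        slope = -cyl.sigma * cyl.R / (eps_r * constants.eps0 * a)

        def bc(ya, yb):
            return np.array([ya[1] - slope, yb[0]])

        y0 = np.zeros((2, r_grid.size))
        y0[0] = np.clip(np.asarray(
            lpb_exterior_potential(cyl, buffer, eps_r, r_grid, constants)),
            -8 * Vt, 8 * Vt)
    else:
        b = cyl.R - buffer.d_stern
        # avoid the r=0 singularity: start at a tiny radius with zero slope
        r_grid = np.linspace(b * 1e-6, b, 3000)
        slope = cyl.sigma * cyl.R / (eps_r * constants.eps0 * b)

        def bc(ya, yb):
            return np.array([ya[1], yb[1] - slope])

        y0 = np.zeros((2, r_grid.size))
        y0[0] = np.clip(np.asarray(
            lpb_interior_potential(cyl, buffer, eps_r, r_grid, constants)),
            -8 * Vt, 8 * Vt)

    sol = solve_bvp(rhs, bc, r_grid, y0, tol=tol, max_nodes=400_000)
    if sol.status != 0:
        raise RuntimeError(f"reference solve_bvp failed: {sol.message}")
    return sol.x, sol.y[0]


# ---------------------------------------------------------------------------
# Oracle case factories
# ---------------------------------------------------------------------------

def make_gouy_chapman_case(c_s_mM: float = 100.0, sigma: float = -0.083,
                           radius_factor: float = 1000.0) -> OracleCase:
    """Planar-limit case: a cylinder of radius >= 1000 Debye lengths
    with no Stern layer must reproduce the Grahame surface potential
    and the planar Gouy-Chapman profile."""
    buffer = BufferSpec.kcl(c_s_mM, d_stern=0.0)
    eps_r = 78.5
    lam = debye_length(buffer, eps_r)
    cyl = ChargedCylinderSpec(R=radius_factor * lam, sigma=sigma, side="exterior")
    perm = PermittivityModel(eps_w=eps_r, mode="constant")
    opts = SolverOptions()
    V0 = grahame_surface_potential(sigma, buffer.c_s, eps_r)

    def check(case: OracleCase) -> float:
        prof = solve_nlpb(case.cylinder, case.buffer, case.perm, case.opts)
        err_surface = abs(prof.V_ohp / case.expected["V0"] - 1.0)
        x = prof.r - case.cylinder.R
        keep = x <= 10 * lam
        V_exp = gouy_chapman_profile(case.expected["V0"], x[keep], lam)
        err_prof = float(np.max(np.abs(prof.V[keep] - V_exp))
                         / np.max(np.abs(V_exp)))
        return max(err_surface, err_prof)

    return OracleCase(
        name=f"gouy_chapman_{c_s_mM:g}mM", kind="gouy_chapman_planar",
        cylinder=cyl, buffer=buffer, perm=perm, opts=opts,
        rel_tol=5e-3, expected={"V0": V0}, check=check,
        description="planar-limit NLPB vs Grahame/Gouy-Chapman closed form")


def make_linear_regime_case(geometry: str = "exterior",
                            sigma_scale: float = 1e-3) -> OracleCase:
    """Low-charge case: the NLPB solution must match the analytic
    Debye-Huckel Bessel profile (recomputed in arbitrary precision)
    once |V| << V_t."""
    mt = MicrotubuleSpec.default()
    buffer = BufferSpec.kcl(160.0)
    base = mt.outer if geometry == "exterior" else mt.inner
    cyl = replace(base, sigma=base.sigma * sigma_scale)
    perm = PermittivityModel(mode="constant")
    opts = SolverOptions()

    def check(case: OracleCase) -> float:
        prof = solve_nlpb(case.cylinder, case.buffer, case.perm, case.opts)
        sub = slice(None, None, max(1, prof.r.size // 64))  # mpmath is slow
        V_exp = mp_lpb_potential(case.cylinder, case.buffer, case.perm.eps_w,
                                 prof.r[sub])
        return float(np.max(np.abs(prof.V[sub] - V_exp)) / np.max(np.abs(V_exp)))

    return OracleCase(
        name=f"linear_regime_{geometry}", kind="linear_regime",
        cylinder=cyl, buffer=buffer, perm=perm, opts=opts,
        rel_tol=5e-3, check=check,
        description="NLPB at tiny sigma vs arbitrary-precision Bessel solution")


def make_refinement_suite() -> list[OracleCase]:
    """Grid- and domain-refinement cases: the potential at the OHP must
    be stable under doubling of n_grid and of the truncation radius."""
    mt = MicrotubuleSpec.default()
    cases = []
    for c_mM, tag, cyl in ((0.01, "outer_10uM", mt.outer),
                           (160.0, "outer_160mM", mt.outer),
                           (160.0, "ct_160mM", mt.ct),
                           (160.0, "lumen_160mM", mt.inner)):
        buffer = BufferSpec.kcl(c_mM)
        perm = PermittivityModel()
        opts = SolverOptions()

        def check(case: OracleCase) -> float:
            coarse = solve_nlpb(case.cylinder, case.buffer, case.perm, case.opts)
            fine = solve_nlpb(case.cylinder, case.buffer, case.perm,
                              replace(case.opts, n_grid=2 * case.opts.n_grid))
            err = abs(fine.V_ohp / coarse.V_ohp - 1.0)
            if case.cylinder.side == "exterior":
                wide = solve_nlpb(case.cylinder, case.buffer, case.perm,
                                  replace(case.opts,
                                          r_max_factor=2 * case.opts.r_max_factor))
                err = max(err, abs(wide.V_ohp / coarse.V_ohp - 1.0))
            return err

        cases.append(OracleCase(
            name=f"refinement_{tag}", kind="refinement",
            cylinder=cyl, buffer=buffer, perm=perm, opts=opts,
            rel_tol=1e-4, check=check,
            description="OHP potential stability under grid/domain doubling"))
    return cases


def canonical_scenarios() -> list[dict]:
    """The canonical study set: all three surfaces at every named
    concentration, with the standard geometry, 0.33 nm Stern distance
    and 298 K.  Each entry is a flat config mapping that round-trips
    through the config reader."""
    from .pipeline import CANONICAL_CONCENTRATIONS_MM

    scenarios = []
    for c_mM in CANONICAL_CONCENTRATIONS_MM:
        cfg = {
            "kcl_mM": float(c_mM),
            "temperature_K": 298.0,
            "stern_nm": 0.33,
            "eps_w": 78.5,
            "eps_K": 5.0,
            "permittivity_mode": "full",
            "c_max_M": 15.9,
            "lambda_K_Sm2permol": 7.352e-3,
            "lambda_Cl_Sm2permol": 7.634e-3,
        }
        scenarios.append({
            "config": cfg,
            "tags": ["lumen", "smt-outer", "ct"],
            "label": "BRB80 ionic strength" if c_mM == 160.0 else
                     f"KCl {c_mM:g} mM",
        })
    return scenarios


def write_fixture_configs(out_dir: str | Path) -> list[Path]:
    """Emit the canonical scenario configs as flat key-value files."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sc in canonical_scenarios():
        c_mM = sc["config"]["kcl_mM"]
        path = out_dir / f"kcl_{c_mM:g}mM.yaml".replace(".yaml", ".yaml")
        path.write_text(yaml.safe_dump(sc["config"], sort_keys=True))
        paths.append(path)
    return paths


def run_oracle_suite(verbose: bool = False) -> int:
    """Run every oracle case; returns the number of failures."""
    cases = [
        make_gouy_chapman_case(),
        make_gouy_chapman_case(c_s_mM=10.0, sigma=-0.025),
        make_linear_regime_case("exterior"),
        make_linear_regime_case("interior"),
        *make_refinement_suite(),
    ]
    failures = 0
    for case in cases:
        err = case.max_rel_error()
        ok = err < case.rel_tol
        failures += not ok
        if verbose:
            print(f"{'PASS' if ok else 'FAIL'} {case.name}: "
                  f"rel err {err:.2e} (tol {case.rel_tol:.0e})")
    return failures
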