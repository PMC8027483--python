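"""Scenario orchestration: single solves, concentration sweeps,
conductivity-crossover search, and the command-line interface.

The canonical study sweeps a KCl buffer from 10 uM to 500 mM around the
standard 13-protofilament microtubule (lumen wall, outer SMT wall, and
C-termini solved as independent cylindrical problems) and derives, per
concentration, the bound-layer extents, bound and net charge per
heterodimer, and the mean axial conductivity of the complex with and
without C-termini.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import observables as obs
from .physical_model import (
    CONSTANTS,
    BufferSpec,
    ChargedCylinderSpec,
    MicrotubuleSpec,
    PermittivityModel,
    PhysicalConstants,
    buffer_conductivity,
    thermal_voltage,
)
from .pb_solver import (
    RadialProfile,
    SolverError,
    SolverOptions,
    solve_nlpb,
    solve_nlpb_exterior,
    solve_nlpb_interior,
)

log = logging.getLogger("mtpb")

__all__ = [
    "ScenarioResult",
    "SweepTable",
    "CANONICAL_CONCENTRATIONS_MM",
    "run_scenario",
    "solve_structure",
    "run_sweep",
    "find_crossover",
    "headline_report",
    "load_config",
    "build_scenario",
    "cli",
]

#: Concentrations (mM) named in the canonical study: the low/physiological
#: regime endpoints, the BRB80 ionic strength (160 mM), and the high-end
#: pair around half-molar.
CANONICAL_CONCENTRATIONS_MM = (0.01, 0.1, 1.0, 10.0, 100.0, 160.0, 500.0, 501.0)

_GEOMETRY_TAGS = ("lumen", "smt-outer", "ct")


@dataclass
class ScenarioResult:
    """One end-to-end solve: profile plus derived observables."""

    tag: str
    profile: RadialProfile
    bound: obs.BoundLayerSummary
    electroneutrality: float | None  # lumen only
    overlap: obs.CtOverlap | None    # ct only

    def summary_dict(self) -> dict:
        p = self.profile
        d = {
            "tag": self.tag,
            "c_s_M": p.buffer.c_s / 1e3,
            "V_ohp_V": p.V_ohp,
            "extent_m": self.bound.extent,
            "net_bound_charge_C_per_m": self.bound.net_bound_charge,
            "outer_sweeps": p.outer_sweeps,
            "newton_iterations": p.newton_iterations,
            "converged": p.converged,
        }
        if self.electroneutrality is not None:
            d["electroneutrality_residual"] = self.electroneutrality
        if self.overlap is not None:
            d["ct_overlap"] = self.overlap.overlap
            d["ct_overlap_margin_m"] = self.overlap.margin
        return d


def _cylinder_for(tag: str, mt: MicrotubuleSpec) -> ChargedCylinderSpec:
    if tag == "lumen":
        return mt.inner
    if tag == "smt-outer":
        return mt.outer
    if tag == "ct":
        return mt.ct
    raise ValueError(f"unknown geometry tag {tag!r}; expected one of {_GEOMETRY_TAGS}")


def run_scenario(tag: str, buffer: BufferSpec,
                 perm: PermittivityModel = PermittivityModel(),
                 opts: SolverOptions = SolverOptions(),
                 mt: MicrotubuleSpec | None = None,
                 constants: PhysicalConstants = CONSTANTS,
                 out_dir: str | Path | None = None) -> ScenarioResult:
    """Solve one surface at one buffer state and derive its observables.

    With ``out_dir`` set, writes ``<tag>_profile.csv`` (radial columns in
    SI with units in the headers) and ``<tag>_summary.json``.
    """
    mt = mt or MicrotubuleSpec.default(constants=constants)
    cyl = _cylinder_for(tag, mt)
    profile = solve_nlpb(cyl, buffer, perm, opts, constants)
    bound = obs.bound_layer(profile)
    en = obs.lumen_electroneutrality_residual(profile) if tag == "lumen" else None
    ov = obs.ct_overlap(profile, spacing=mt.ct_spacing) if tag == "ct" else None
    result = ScenarioResult(tag, profile, bound, en, ov)
    log.info("scenario %s c=%.4g mM: V_ohp=%.4g mV, %d sweeps, %d Newton iters",
             tag, buffer.c_s, profile.V_ohp * 1e3, profile.outer_sweeps,
             profile.newton_iterations)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = tag.replace("-", "_")
        profile.to_frame().to_csv(out_dir / f"{stem}_profile.csv", index=False)
        meta = result.summary_dict()
        meta["options"] = asdict(opts)
        meta["permittivity"] = asdict(perm)
        (out_dir / f"{stem}_summary.json").write_text(json.dumps(meta, indent=2))
    return result


def solve_structure(buffer: BufferSpec,
                    perm: PermittivityModel = PermittivityModel(),
                    opts: SolverOptions = SolverOptions(),
                    mt: MicrotubuleSpec | None = None,
                    constants: PhysicalConstants = CONSTANTS
                    ) -> tuple[RadialProfile, RadialProfile, RadialProfile]:
    """Solve all three sub-problems (lumen, outer wall, CT) at one buffer."""
    mt = mt or MicrotubuleSpec.default(constants=constants)
    lumen = solve_nlpb_interior(mt.inner, buffer, perm, opts, constants)
    outer = solve_nlpb_exterior(mt.outer, buffer, perm, opts, constants)
    ct = solve_nlpb_exterior(mt.ct, buffer, perm, opts, constants)
    return lumen, outer, ct


def _row_for(buffer: BufferSpec, perm: PermittivityModel, opts: SolverOptions,
             mt: MicrotubuleSpec, smt: MicrotubuleSpec,
             constants: PhysicalConstants) -> dict:
    lumen, outer, ct = solve_structure(buffer, perm, opts, mt, constants)
    s_lumen = obs.bound_layer(lumen)
    s_outer = obs.bound_layer(outer)
    s_ct = obs.bound_layer(ct)
    res_mt = obs.mean_axial_conductivity(lumen, outer, ct, mt, buffer)
    res_smt = obs.mean_axial_conductivity(lumen, outer, None, smt, buffer)
    q_net = obs.net_complex_charge_per_dimer(s_lumen, s_outer, s_ct, mt, constants)
    q_bound = q_net - mt.protein_charge_per_dimer_e(constants)
    return {
        "c_s_M": buffer.c_s / 1e3,
        "sigma_buffer_S_per_m": buffer_conductivity(buffer),
        "sigma_smt_S_per_m": res_smt.sigma_mean,
        "sigma_mt_S_per_m": res_mt.sigma_mean,
        "t_bound_outer_m": s_outer.extent,
        "t_bound_lumen_m": s_lumen.extent,
        "t_bound_ct_m": s_ct.extent,
        "q_bound_per_dimer_e": q_bound,
        "q_net_per_dimer_e": q_net,
        "ct_overlap": obs.ct_overlap(ct, spacing=mt.ct_spacing).overlap,
        "electroneutrality_residual": obs.lumen_electroneutrality_residual(lumen),
        "converged": lumen.converged and outer.converged and ct.converged,
    }


@dataclass
class SweepTable:
    """Per-concentration summaries over a log-spaced sweep, with a
    provenance block (option values and a config hash)."""

    table: pd.DataFrame
    provenance: dict

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        path.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=2))


def run_sweep(c_min_mM: float = 0.01, c_max_mM: float = 500.0,
              n_points: int = 25,
              include_canonical: bool = True,
              perm: PermittivityModel = PermittivityModel(),
              opts: SolverOptions = SolverOptions(),
              mt: MicrotubuleSpec | None = None,
              constants: PhysicalConstants = CONSTANTS) -> SweepTable:
    """Concentration sweep over a log-spaced grid.

    Solves lumen, outer wall, and CT at every concentration and collects
    the per-scenario summary rows.  The canonical named concentrations
    are inserted exactly when they fall inside the range.
    """
    if not 0 < c_min_mM < c_max_mM:
        raise ValueError("need 0 < c_min < c_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = set(np.geomspace(c_min_mM, c_max_mM, n_points).tolist())
    if include_canonical:
        grid.update(c for c in CANONICAL_CONCENTRATIONS_MM if c_min_mM <= c <= c_max_mM)
    mt = mt or MicrotubuleSpec.default(constants=constants)
    smt = replace(mt, include_ct=False)
    rows = []
    for c_mM in sorted(grid):
        buffer = BufferSpec.kcl(c_mM)
        try:
            rows.append(_row_for(buffer, perm, opts, mt, smt, constants))
        except SolverError as err:
            raise SolverError(f"sweep row at {c_mM} mM failed: {err}") from err
    table = pd.DataFrame(rows)
    prov = {
        "options": asdict(opts),
        "permittivity": asdict(perm),
        "temperature_K": constants.T,
        "config_hash": hashlib.sha256(
            json.dumps([asdict(opts), asdict(perm)], sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return SweepTable(table=table, provenance=prov)


def find_crossover(structure: str = "mt",
                   bracket_mM: tuple[float, float] = (0.01, 500.0),
                   rel_tol: float = 1e-3,
                   perm: PermittivityModel = PermittivityModel(),
                   opts: SolverOptions = SolverOptions(),
                   mt: MicrotubuleSpec | None = None,
                   constants: PhysicalConstants = CONSTANTS) -> float:
    """Buffer concentration (mM) where the complex's mean conductivity
    equals the buffer conductivity.

    Bisection on log10(c) of the sign of sigma_mean - sigma_buffer, to a
    relative tolerance ``rel_tol`` on the concentration.  Raises if the
    bracket does not straddle a sign change.
    """
    if structure not in ("mt", "smt"):
        raise ValueError("structure must be 'mt' or 'smt'")
    mt_full = mt or MicrotubuleSpec.default(constants=constants)
    model = mt_full if structure == "mt" else replace(mt_full, include_ct=False)

    def excess(c_mM: float) -> float:
        buffer = BufferSpec.kcl(c_mM)
        lumen, outer, ct = solve_structure(buffer, perm, opts, mt_full, constants)
        res = obs.mean_axial_conductivity(
            lumen, outer, ct if model.include_ct else None, model, buffer)
        return res.sigma_mean - res.sigma_buffer

    lo, hi = math.log10(bracket_mM[0]), math.log10(bracket_mM[1])
    f_lo, f_hi = excess(10 ** lo), excess(10 ** hi)
    if f_lo * f_hi > 0:
        raise ValueError("no conductivity crossover inside the bracket")
    while (10 ** hi - 10 ** lo) / 10 ** hi > rel_tol:
        mid = 0.5 * (lo + hi)
        f_mid = excess(10 ** mid)
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 10 ** (0.5 * (lo + hi))


def headline_report(out_dir: str | Path | None = None,
                    perm: PermittivityModel = PermittivityModel(),
                    opts: SolverOptions = SolverOptions(),
                    constants: PhysicalConstants = CONSTANTS) -> dict:
    """Recompute the headline quantities of the canonical study.

    Runs the canonical concentration list, the two conductivity
    crossovers, and the 10 uM MT/SMT conductivity pair; returns (and
    optionally writes) a JSON-serializable report.  Deterministic:
    regenerating the report reproduces it bit for bit.
    """
    mt = MicrotubuleSpec.default(constants=constants)
    sweep = run_sweep(c_max_mM=501.0, perm=perm, opts=opts, constants=constants,
                      n_points=2, include_canonical=True)
    t = sweep.table
    row_at = lambda c_mM: t.loc[(t["c_s_M"] * 1e3 - c_mM).abs().idxmin()]
    r10u, r501 = row_at(0.01), row_at(501.0)
    report = {
        "surface_charge_C_per_m2": {
            "inner": mt.inner.sigma, "outer": mt.outer.sigma, "ct": mt.ct.sigma},
        "protein_charge_per_dimer_e": mt.protein_charge_per_dimer_e(constants),
        "bound_extent_outer_nm": {
            f"{row.c_s_M * 1e3:g}_mM": row.t_bound_outer_m * 1e9
            for row in t.itertuples()},
        "q_net_per_dimer_e": {
            f"{row.c_s_M * 1e3:g}_mM": row.q_net_per_dimer_e
            for row in t.itertuples()},
        "sigma_mt_10uM_mS_per_m": r10u.sigma_mt_S_per_m * 1e3,
        "sigma_smt_10uM_mS_per_m": r10u.sigma_smt_S_per_m * 1e3,
        "ct_removal_decrease_percent": 100.0 * (1 - r10u.sigma_smt_S_per_m
                                                / r10u.sigma_mt_S_per_m),
        "q_net_501mM_e": r501.q_net_per_dimer_e,
        "crossover_mt_mM": find_crossover("mt", perm=perm, opts=opts,
                                          constants=constants),
        "crossover_smt_mM": find_crossover("smt", perm=perm, opts=opts,
                                           constants=constants),
        "all_converged": bool(t["converged"].all()),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "headline_report.json").write_text(json.dumps(report, indent=2))
        sweep.to_csv(out_dir / "canonical_sweep.csv")
    return report


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "temperature_K", "eps_w", "eps_K", "permittivity_mode", "stern_nm",
    "lambda_K_Sm2permol", "lambda_Cl_Sm2permol", "c_max_M",
    "lumen_radius_nm", "outer_radius_nm", "ct_radius_nm", "ct_length_nm",
    "ct_spacing_nm", "charge_inner_e", "charge_outer_e", "charge_ct_e",
    "kcl_mM", "n_grid", "r_max_factor",
}


def load_config(path: str | Path) -> dict:
    """Read a flat key-value config file (YAML syntax, flat mapping)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def build_scenario(config: dict | None = None, **overrides
                   ) -> tuple[MicrotubuleSpec, BufferSpec, PermittivityModel,
                              SolverOptions, PhysicalConstants]:
    """Assemble scenario objects from a flat config dict.

    All defaults reproduce the standard microtubule scenario at 160 mM
    KCl and 298 K; explicit keyword overrides beat config-file values.
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    constants = PhysicalConstants(T=float(cfg.get("temperature_K", 298.0)))
    geo = MicrotubuleSpec(
        inner=ChargedCylinderSpec(
            R=float(cfg.get("lumen_radius_nm", 8.4)) * 1e-9, sigma=-1.0, side="interior"),
        outer=ChargedCylinderSpec(
            R=float(cfg.get("outer_radius_nm", 12.5)) * 1e-9, sigma=-1.0, side="exterior"),
        ct=ChargedCylinderSpec(
            R=float(cfg.get("ct_radius_nm", 0.5)) * 1e-9, sigma=-1.0, side="exterior"),
        ct_length=float(cfg.get("ct_length_nm", 4.0)) * 1e-9,
        ct_spacing=float(cfg.get("ct_spacing_nm", 4.0)) * 1e-9,
    )
    from .physical_model import surface_charge_density

    mt = replace(
        geo,
        inner=replace(geo.inner, sigma=surface_charge_density(
            float(cfg.get("charge_inner_e", -5.0)), geo, "inner", constants)),
        outer=replace(geo.outer, sigma=surface_charge_density(
            float(cfg.get("charge_outer_e", -25.0)), geo, "outer", constants)),
        ct=replace(geo.ct, sigma=surface_charge_density(
            float(cfg.get("charge_ct_e", -11.0)), geo, "ct", constants)),
    )
    buffer = BufferSpec(
        c_s=float(cfg.get("kcl_mM", 160.0)),
        lambda_cation=float(cfg.get("lambda_K_Sm2permol", 7.352e-3)),
        lambda_anion=float(cfg.get("lambda_Cl_Sm2permol", 7.634e-3)),
        d_stern=float(cfg.get("stern_nm", 0.33)) * 1e-9,
        c_max=float(cfg.get("c_max_M", 15.9)) * 1e3,
    )
    perm = PermittivityModel(
        eps_w=float(cfg.get("eps_w", 78.5)),
        eps_K=float(cfg.get("eps_K", 5.0)),
        mode=str(cfg.get("permittivity_mode", "full")),
    )
    opts = SolverOptions(
        n_grid=int(cfg.get("n_grid", 2000)),
        r_max_factor=float(cfg.get("r_max_factor", 40.0)),
    )
    return mt, buffer, perm, opts, constants


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

try:
    import click
except ImportError:  # pragma: no cover - click is a hard dependency
    click = None

if click is not None:

    @click.group()
    @click.option("--config", type=click.Path(exists=True), default=None,
                  help="Flat key-value config file; flags override it.")
    @click.option("-v", "--verbose", is_flag=True)
    @click.pass_context
    def cli(ctx, config, verbose):
        """Ionic double layers and conductivity of microtubules."""
        logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                            format="%(levelname)s %(message)s")
        ctx.obj = load_config(config) if config else {}

    @cli.command()
    @click.option("--geometry", type=click.Choice(_GEOMETRY_TAGS), required=True)
    @click.option("--kcl-mm", "kcl_mM", type=float, default=None,
                  help="Buffer concentration in mM.")
    @click.option("--perm-mode", type=click.Choice(
        ["constant", "booth_only", "concentration_only", "full"]), default=None)
    @click.option("--out", type=click.Path(), default="mtpb_out")
    @click.pass_context
    def profile(ctx, geometry, kcl_mM, perm_mode, out):
        """Solve one radial profile and write CSV + JSON summary."""
        over = {}
        if kcl_mM is not None:
            over["kcl_mM"] = kcl_mM
        if perm_mode is not None:
            over["permittivity_mode"] = perm_mode
        mt, buffer, perm, opts, constants = build_scenario(ctx.obj, **over)
        run_scenario(geometry, buffer, perm, opts, mt, constants, out_dir=out)
        click.echo(f"wrote {geometry} profile to {out}/")

    @cli.command()
    @click.option("--cmin-mm", "cmin", type=float, default=0.01)
    @click.option("--cmax-mm", "cmax", type=float, default=500.0)
    @click.option("--points", type=int, default=25)
    @click.option("--out", type=click.Path(), default="mtpb_out")
    @click.pass_context
    def sweep(ctx, cmin, cmax, points, out):
        """Concentration sweep; writes the sweep table CSV."""
        mt, _, perm, opts, constants = build_scenario(ctx.obj)
        table = run_sweep(cmin, cmax, points, perm=perm, opts=opts, mt=mt,
                          constants=constants)
        table.to_csv(Path(out) / "sweep.csv")
        click.echo(f"wrote {len(table.table)} rows to {out}/sweep.csv")

    @cli.command()
    @click.option("--structure", type=click.Choice(["mt", "smt"]), default="mt")
    @click.pass_context
    def crossover(ctx, structure):
        """Concentration where complex and buffer conductivities match."""
        mt, _, perm, opts, constants = build_scenario(ctx.obj)
        c = find_crossover(structure, perm=perm, opts=opts, mt=mt,
                           constants=constants)
        click.echo(f"{structure} crossover: {c:.3g} mM")

    @cli.command()
    @click.option("--out", type=click.Path(), default="mtpb_out")
    @click.pass_context
    def report(ctx, out):
        """Recompute the canonical headline quantities."""
        _, _, perm, opts, constants = build_scenario(ctx.obj)
        rep = headline_report(out_dir=out, perm=perm, opts=opts,
                              constants=constants)
        click.echo(json.dumps(rep, indent=2))

    @cli.command()
    def validate():
        """Run the closed-form oracle suite against the solver."""
        from .validation_fixtures import run_oracle_suite

        failures = run_oracle_suite(verbose=True)
        if failures:
            raise SystemExit(f"{failures} oracle case(s) failed")
        click.echo("all oracle cases passed")
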