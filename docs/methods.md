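# Methods

## Model

A microtubule is treated as three independent, infinitely long charged
cylinders in a monovalent symmetric (KCl-type) electrolyte at fixed
temperature:

| surface | radius | charge per dimer | σ (C/m²) | problem |
| --- | --- | --- | --- | --- |
| lumen wall (inner) | 8.4 nm | −5 e | −0.025 | interior |
| SMT outer wall | 12.5 nm | −25 e | −0.083 | exterior |
| C-terminus (CT) | 0.5 nm | −11 e | −0.140 | exterior |

Surface charge densities follow from spreading the per-dimer charges
over one dimer's patch of the cylindrical surface (13 protofilaments,
8 nm axial dimer repeat) or, for a CT, over the lateral area of its
4 nm × 1 nm cylinder. The modeled protein charge per heterodimer is
−5 − 25 − 2×11 = −52 e.

Ion concentrations obey the Boltzmann relation
c± = c_s exp(∓eV/k_BT), giving the cylindrical nonlinear
Poisson–Boltzmann (NLPB) equation

    (1/r) (r ε_r V′)′ = (2 e N_A c_s / ε₀) sinh(eV/k_BT).

Mean-field PB theory ignores ion–ion correlations and ion size in the
bulk; the one size correction retained is the **Stern layer**: a
charge-free annulus of one hydrated-K⁺ radius (d = 0.33 nm) adjacent
to each charged surface. The solved domain starts at the outer
Helmholtz plane (OHP); Gauss's law across the annulus turns the
surface charge into the flux condition

    V′(R±d) = ∓ σ R / (ε_r ε₀ (R±d))

with ε_r the local (converged) permittivity at the OHP. Symmetry gives
V′(0) = 0 at the lumen axis, and the exterior far field carries a
Robin condition matched to the linearized (K₀) tail at
r_max = OHP + 40 λ_D, which passes domain-doubling tests that a bare
Dirichlet condition at the same radius would fail.

### Variable permittivity

Two corrections to ε_w = 78.5 (298 K) are available, separately or
composed (`PermittivityModel.mode`):

* **Field saturation (Booth):** ε_BE = 1.8 + (ε_l − 1.8) L(0.08 E),
  E in mV/Å, L(x) = 3[coth x − 1/x]/x. For cylinders the geometric
  contribution to ε_l is negligible, so ε_l = ε_w. (Note 1 mV/Å =
  10⁷ V/m.)
* **Cation crowding:** ε = ε_base(1 − ρ + 3αρ)/(1 + ρ/2), with
  α = ε_K/2ε_base and ρ = c_K/(c_K + 15.9 M). In `full` mode
  ε_base = ε_BE, i.e. saturation first, then crowding.

ε_K — the effective permittivity of a hydrated K⁺ ion — has no
authoritative literature value; the default is 5, a representative
dielectrically saturated hydration-shell figure, exposed as the
`eps_K` config key and recorded in output provenance. At the default
scenarios the choice is benign: the permittivity enters the headline
observables only through the near-surface solution, and the bound-layer
edge lies in the far, bulk-like region.

### Binding criterion and observables

Ions at potentials below −k_BT/e (−25.68 mV at 298 K; configurable)
count as bound. Extents are measured from the OHP, where the
ion-bearing domain begins; the lumen extent is capped at the lumen
radius when the entire interior is bound. Bound charges are
2π∫N_A e(c⁺ − c⁻) r dr over the bound region — both species, signed.
Per-dimer conversions: ×(8 nm/13) for wall surfaces; ×4 nm ×2 CT for
the tails.

Local conductivity is σ(r) = λ_K c⁺(r) + λ_Cl c⁻(r) with the limiting
molar conductivities λ_K = 7.352, λ_Cl = 7.634 mS·m²/mol, assuming
bulk molar conductivity along equipotentials. The mean axial
conductivity of the complex integrates σ(r) over the bound regions of
the lumen and the outer wall, adds 13 CT cylinders in parallel when CT
are present, and normalizes by A = π r*², where r* is the outer
thermal-voltage radius (the MT cross-section plus its outer bound
layer). CT bound annuli add conductance but not normalization area,
and are not geometrically clipped against the outer wall's bound layer
(independent-cylinder approximation). Both ion species conduct inside
the bound region — the region is defined by potential, not species — a
`cation_only` flag exists for sensitivity checks.

The CT *well overlap* check asks whether a CT's potential well reaches
the midpoint to its neighbour 4 nm away along the protofilament: the
well edge is where |V| decays below 1 mV (an electrically negligible
level, configurable). A thermal-voltage criterion would be much
stricter and never triggers at physiological strength, whereas the
resolvable well clearly spans the gap there.

## Numerics

* **Discretization:** conservative finite volumes on a grid of 2000
  nodes clustered toward the charged surface by a stretched-exponential
  map (stretch 12), so the sub-nm double layer at 500 mM and the
  ~100 nm tail at 10 μM are resolved simultaneously. The scheme's
  boundary fluxes are exactly ∓σR/ε₀, independent of the local ε, so
  the discrete Gauss law holds to machine precision at convergence;
  screening-completeness and lumen-electroneutrality residuals are
  limited only by quadrature (measured < 10⁻⁵). Observed convergence
  order ≈ 2.003.
* **Nonlinear iteration:** damped Newton on the sinh residual with a
  banded (tridiagonal) Jacobian. Step control uses the affine-invariant
  natural monotonicity test (norm of the simplified Newton correction)
  rather than the raw residual norm, which stalls at the cancellation
  floor of the finest boundary cell at high salt. Convergence when the
  Newton correction falls below 10⁻⁸ of the thermal voltage.
* **Permittivity fixed point:** ε(|V′|, c⁺) is recomputed from each
  converged potential and under-relaxed (factor 0.5) until the profile
  changes by < 10⁻⁶ of ε_w, followed by one final solve so the
  boundary condition and profile use the settled ε. Modes `constant`
  (or a forced constant ε) short-circuit to a single sweep.
* **Initialization:** the analytic linearized (Bessel) solution clipped
  to ±8 k_BT/e. sinh/cosh arguments are clipped at |eV/kT| = 80
  (physical solutions stay below ≈ 35) to keep intermediate Newton
  iterates finite.
* **Degenerate inputs:** σ = 0 returns the exact flat solution;
  T ≤ 0, c_s ≤ 0, Stern layers thicker than the cylinder, and
  wrong-side profiles are rejected with `ValueError`.
* **Determinism:** there is no randomness anywhere; repeated runs are
  bit-identical.

The crossover search bisects log₁₀ c for the root of
σ_mean(c) − σ_buffer(c) using direct solves per evaluation (≈ 0.1 s
each), to 10⁻³ relative on concentration.

## Validation scenarios ("synthetic data")

The deterministic mean-field model has no noise process, so the
fixture module generates parameterized physical scenarios rather than
random data:

* **Planar limit:** R ≥ 1000 λ_D, d = 0, constant ε — checked against
  the Grahame surface-potential relation and the Gouy–Chapman tanh
  profile (closed forms implemented independently of the solver).
* **Linear regime:** surface charges scaled down 1000× — checked
  against the Debye–Hückel Bessel solutions re-derived with mpmath at
  50 digits.
* **Independent numeric route:** the same NLPB problem solved by
  scipy's adaptive collocation (`solve_bvp`, different discretization,
  Dirichlet far field) agrees with the production solver to < 10⁻³
  profile-wide and ~5×10⁻⁷ at the OHP.
* **Refinement suite:** grid and domain doubling at the canonical
  scenarios; OHP potentials stable to < 10⁻⁴ and Richardson order in
  [1.7, 2.3].

What these scenarios do *not* emulate: finite CT length and
flexibility, the helical wall lattice and its discrete charge pattern,
ion–ion correlations, and divalent ions. Passing tests therefore
validate the cylindrical mean-field model, not those finer features of
real microtubules.

## Canonical study conditions

KCl from 10 μM to 500 mM (log-spaced sweep, default 25 points, the
named concentrations 10 μM, 100 μM, 1, 10, 100, 160, 500, 501 mM
inserted exactly; 160 mM is the BRB80 ionic-strength reference), 298 K,
full permittivity model, n_grid = 2000, r_max_factor = 40. A full
sweep takes ~10 s on one CPU; the complete oracle-and-canonical suite
runs in well under a minute.

## Known limitations and open choices

* The binding threshold uses the exact −k_BT/e (−25.68 mV). Reference
  figures for the bound-layer extents appear to have been
  post-processed with a rounded −25 mV; the difference shifts the
  extents by ≈ λ_D ln(25.68/25) ≈ 2.7% of a Debye length and is within
  all stated tolerances.
* Whether the normalization area should include the CT bound annuli
  when CT are present is ambiguous; this package reads "normalized in
  the same way" literally (same A as the SMT case). The alternative
  would *lower* MT conductivity.
* Several published headline figures for this system (the −15 e
  low-concentration net-charge plateau and the conductivity/crossover
  set built on it) are mutually inconsistent with the published
  bound-layer extents under any PB solution: once the outer bound layer
  extends ~95 nm at 10 μM, Gauss's law leaves only ~0.5 e per dimer of
  the outer wall's neutralizing charge outside the thermal radius, so
  the bound charge (and with it the bound-layer conductance) is pinned
  near full neutralization. This package reports the
  internally consistent values its own solver produces; its solver is
  validated against the independent closed-form and collocation oracles
  above.
* Radial (surface-normal) conductivity, multivalent or asymmetric
  electrolytes, pH titration of tubulin charges, and transmission-line
  circuit parameters are out of scope.
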