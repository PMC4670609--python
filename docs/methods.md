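# Methods

This note records the model, the numerical methods, and the design
decisions behind `cardiogrowth`, in the spirit of a solver manual: what is
computed, under which assumptions, and what the tests do and do not show.

## Continuum model

**Kinematics.** The deformation gradient is decomposed multiplicatively,
`F = Fe · Fg`.  `Fg` maps the reference tissue into an incompatible,
stress-free grown configuration; only `Fe = F · Fg⁻¹` generates stress.
The elastic part is further split into volumetric and isochoric parts
through the elastic Jacobian `Je = det Fe` and the isochoric elastic
Green–Lagrange strain `Ēe = ½[Je^{-2/3} Feᵀ Fe − I]`.

**Passive myocardium.** Quasi-incompressible orthotropic Fung solid:

- volumetric: `U(Je) = [Je² − 2 ln Je]/(2 D₀)`, stationary at `Je = 1`.
  `D₀` is interpreted in reciprocal-stress units (kPa⁻¹); at the default
  `D₀ = 0.001` the volumetric stiffness is three to four orders above the
  tissue scale — a numerical incompressibility penalty, not a measured
  modulus.
- isochoric: `ψ̄ = C₀/2 [exp(Ēe : 𝗕₀ : Ēe) − 1]` with the weight tensor
  diagonal in the fiber/sheet/normal frame.  The quadratic form is
  evaluated by rotating the strain into the local frame and applying the
  symmetric 3×3 weight matrix entrywise — algebraically identical to the
  Voigt representation `diag{B_ff, B_ss, B_nn, 2B_fs, 2B_fn, 2B_sn}` but
  immune to shear-factor bookkeeping errors.

Defaults are the in-vivo identified healthy-human values
(`C₀ = 0.115 kPa`, `B_ff = 14.4` with the 0.4/0.35/0.2 scaling for the
transverse and shear weights); both the two-parameter scaling and explicit
six-weight input are supported.  The total second Piola–Kirchhoff stress
is the pull-back `S = Fg⁻¹ · Se · Fg⁻ᵀ` of the elastic stress
`Se = ∂ψ/∂Ee`; this is exactly `∂ψ/∂E` at fixed `Fg`, which the
finite-difference energy-consistency tests certify to 1e-6 relative.

**Growth laws.** One scalar multiplier per integration point:
transverse growth `Fg = ϑI + (1−ϑ) f₀⊗f₀` (cell thickening, grown volume
ratio `ϑ²`) and longitudinal growth `Fg = I + (ϑ−1) f₀⊗f₀` (cell
lengthening, grown volume ratio `ϑ`).  Elastic tensors use the
Sherman–Morrison closed forms, verified against generic inversion to
1e-12.  Kinetics: `ϑ̇ = ⟨λ − λ_crit⟩/τ`, with the fiber stretch taken
from the **total** deformation gradient as the driving signal (for the
transverse law this coincides with the elastic fiber stretch, because the
fiber is a unit eigenvector of `Fg`; for the longitudinal law it includes
the grown length, which is what makes eccentric growth self-amplifying).
`λ_crit` is a per-point copy of the converged baseline stretch; `τ = 1` in
normalized time (no physical duration is implied; months to years).
Growth is irreversible and, optionally, capped (`theta_max`, off by
default).  Time integration is the explicit first-order update
`ϑ = ϑₙ + ⟨λ − λ_crit⟩ Δt/τ`.

## Finite elements

- Total-Lagrangian displacement formulation on linear (1-point) or
  quadratic (4-point) tetrahedra.  Quadratic elements are the default:
  at a penalty bulk/shear ratio of 10³–10⁴ linear tetrahedra lock.  The
  4-point rule is exact for the affine-element stiffness; the 5-point
  degree-3 rule was rejected because of its negative weight.  One growth
  internal variable lives on every integration point (one per element for
  linear tetrahedra).
- **Mixed volumetric treatment.**  The volumetric energy acts through the
  element-average elastic Jacobian (Simo–Taylor mean dilatation) with an
  independent element-constant pressure `p̄` (perturbed Lagrangian),
  condensed element-wise inside every linear solve.  The condensed matrix
  is identical to mean dilatation; keeping `p̄` as an unknown removes the
  1/D₀ penalty scaling from the Newton remainder terms.  A pure
  displacement-penalty formulation was implemented first and abandoned:
  its Newton iteration is crippled by the quadratic penalty term
  `(1/D₀)(∇δu)²`, which limits usable steps to strain increments of order
  `sqrt(D₀·p)`.
- Follower pressure on the deformed endocardial facets, with the full
  (unsymmetric) load-stiffness in the tangent.
- The material tangent is a forward-difference derivative of the
  isochoric stress (relative step 1e-7); the volumetric blocks are
  analytic.  The assembled operator matches a central-difference residual
  derivative to ~2e-7 relative.
- Newton with LU reuse: the sparse factorization is kept across
  iterations and load/growth steps and refreshed when the residual
  contraction falls below 0.2 per iteration (at most six
  stagnation-driven refreshes per solve); a fresh factorization restores
  the full Newton step.  Globalization is a backtracking line search on
  the combined force/constraint merit.  Near instabilities a
  Levenberg-damped direction ladder (diagonal shifts 1e-6…1) is tried
  before a step is rejected.
- Load ramping with automatic halving; growth sub-stepping (dt halved up
  to three levels) when an equilibrium solve rejects a grown state.

### Late-phase robustness (wrinkling)

Deep into concentric growth the inner wall develops compressive regions
whose mesh-scale wrinkling modes make the tangent indefinite and leave a
small flapping force remainder that strict Newton cannot close.  Two
standard devices handle this in the organ-scale scenarios (both off by
default in the library API):

- *Stalled-state acceptance*: an iteration that has flattened is accepted
  if the force residual is below 0.5 % of the external force scale (an
  order tighter than common commercial defaults) and the volumetric
  constraint is satisfied to 1e-4.
- *Proximal stabilization fallback*: if a plain solve fails outright, the
  step is re-solved for the potential augmented by `μ/2‖u − u_start‖²`,
  with `μ` a factor 1e-4 of the median *isochoric* diagonal stiffness.
  This selects the nearest equilibrium branch and biases it only at order
  `μ`; it is attempted only after the unbiased problem has failed, so all
  normally-converging steps (including the calibration fixed point) are
  exact.

The scenario Newton tolerance is 5e-4 of the external force scale —
deliberately looser than the 1e-9 library default used in the
verification tests, and still an order tighter than standard commercial
practice for this problem class.

## Geometry, fibers, diagnostics

The idealized LV is a truncated prolate ellipsoid (defaults: endocardial
semi-axes 45/25 mm, wall 10 mm at the equator and 8 mm at the apex, basal
plane at 0.3·a above the equator — a textbook-sized human LV with ~83 mL
unloaded cavity and ~100 mL wall).  The structured grid is subdivided by
the translation-invariant Kuhn pattern (conforming, fully deterministic);
the apex pole uses collapsed cells.  Fibers follow the conventional
rule-based architecture: helix angle +60° (endo) to −60° (epi), linear in
the transmural coordinate, sheets transmurally outward; elements at the
pole fall back to a long-axis frame.  Because the rule itself rotates the
fiber by 120° across a two-element-thick wall, frame continuity is only
meaningful within a transmural layer, where it is tested to 15°.

Boundary conditions for the idealized LV: basal-plane nodes fixed along
the long axis, the epicardial basal ring additionally fixed in-plane.
This removes all rigid modes while leaving the endocardial ring free, so
the basal-ring perimeter remains an informative (if crude) annulus
analog.

Diagnostics: chamber volume by the divergence theorem over the deformed
endocardial surface closed with a flat basal fan cap; wall volume by
quadrature of the deformed Jacobian; basal-ring perimeter as the deformed
polyline length.  All are exact under rigid motions.

## Scenario protocol

1. Ramp to baseline pressures (LV 5 mmHg; RV 2 mmHg when a bi-ventricular
   mesh provides an RV cavity — on LV-only meshes the RV pressure is
   ignored and right-overload configurations are refused).
2. Record `λ_crit` pointwise; an immediate growth step is the exact
   identity (verified bitwise).
3. Ramp the overloaded chamber to its pathological pressure (doubled by
   default, LV 10 mmHg) and hold it.
4. Staggered growth in normalized time (default Δt = 0.4, up to 60
   steps); the phase ends at the first of: the homeostatic plateau
   (relative wall-volume growth rate below 0.5 %/unit time), a
   domain-of-validity guard (chamber volume below 70 % of its running
   peak, or any growth multiplier beyond 3 — an idealized no-contact LV
   is not meaningful past either bound), or the last state the solver can
   equilibrate.  Early termination is flagged in the run manifest
   (`growth_phase_truncated`, `saturated_at`).
5. Unload to zero pressure with growth frozen (stretches drop below
   threshold, so freezing is exact); residual stresses from the
   incompatible growth field are retained.
6. PV probing of the ungrown reference and the grown unloaded state over
   the probe pressures.

Everything is deterministic: identical configurations give byte-identical
CSV output.  The config `seed` is reserved (no randomness in the
pipeline).

## What the synthetic conditions do and do not show

The idealized free-wall ellipsoid reproduces the organ-level *signs* of
the two growth modes: concentric growth thickens the wall, eventually
squeezes the cavity below its early-growth peak, and stiffens the PV
response; eccentric growth dilates monotonically without saturating and
softens the PV response.  Quantitatively the idealized ventricle is much
more compliant than an anatomic four-chamber heart (no atria, valve
annuli, septum, or pericardial constraint share the load), so concentric
growth must thicken the wall far more (ϑ well beyond 2) before the fiber
stretches fully return to baseline than in an anatomically constrained
simulation (ϑ ≈ 1.4).  Within the validity guard the concentric growth
rate decays to roughly two thirds of its peak — the homeostatic
self-regulation is evident — but the fully saturated state lies beyond
the guard, in a regime of near cavity collapse and mesh-scale
endocardial wrinkling that this model deliberately does not enter.
Conversely, the eccentric feedback (`λ = ϑ λe` along the fiber) is
exponential; its window ends once mean fiber growth reaches the scale of
the concentric run's thickening.  Test problem sizes (≈1.5k quadratic tetrahedra for phenotype
runs, ≈3k for the default mesh, ≈5k for the sphere benchmark at medium
refinement) were chosen as the coarsest meshes on which these organ-level
signs are stable.

## Known limitations

- LV-only idealized geometry; the optional bi-ventricular generator and
  septal-curvature diagnostic are not implemented, so right-overload
  scenarios are refused.
- No residual-stress prestressing: the reference configuration is assumed
  stress-free at end diastole.
- No active contraction, dynamics, or contact; the collapsing-cavity
  regime is resolved only in the volume-average sense (mesh-scale
  wrinkles are regularized, not resolved).
- The growth time scale is normalized; no physical duration is claimed.
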