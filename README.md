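# cardiogrowth

Finite-growth simulation of cardiac hypertrophy on idealized ventricular
geometries: a quasi-static nonlinear finite-element model of how chronic
pressure and volume overload remodel the left ventricle.

## The science

Cardiomyocytes respond to sustained overload by depositing sarcomeres —
in parallel (the cell thickens; **concentric** hypertrophy, the wall
thickens at roughly constant chamber size) or in series (the cell
lengthens; **eccentric** hypertrophy, the chamber dilates).  The package
models this with the multiplicative decomposition of the deformation
gradient,

    F = Fe · Fg ,

where only the elastic part `Fe` generates stress.  The growth tensor is a
rank-one update of the identity controlled by one scalar growth multiplier
per integration point:

    transverse   (parallel deposition):   Fg = ϑ I + (1 − ϑ) f₀ ⊗ f₀
    longitudinal (serial deposition):     Fg = I + (ϑ − 1) f₀ ⊗ f₀

with `f₀` the local fiber direction; the inverse of either tensor, and
hence `Fe`, is available in Sherman–Morrison closed form.  Growth is
driven by the total fiber stretch `λ = |F·f₀|` through irreversible,
stretch-activated kinetics with a pointwise homeostatic threshold,

    ϑ̇ = ⟨λ − λ_crit⟩ / τ ,

where `λ_crit` is recorded per integration point at the physiological
baseline state (LV 5 mmHg end-diastolic pressure) and `⟨·⟩` is the
Macaulay bracket.  The passive myocardium is a quasi-incompressible
orthotropic Fung solid,

    ψ = [Je² − 2 ln Je]/(2 D₀) + C₀/2 [exp(Ē:𝗕₀:Ē) − 1] ,

with the healthy-human parameter set C₀ = 0.115 kPa, B_ff = 14.4,
B_ss = B_nn = 0.4 B_ff, B_fs = B_fn = 0.35 B_ff, B_sn = 0.2 B_ff,
D₀ = 0.001 kPa⁻¹.  Cavity pressures act as follower loads on the deformed
endocardium; equilibrium and growth are advanced in a staggered loop with
an explicit update of the growth multiplier.

The geometry is a parameterized truncated-ellipsoid left ventricle with
rule-based helical fibers (+60°/−60° endo/epi); meshes are generated
internally (deterministic structured tetrahedra, linear or quadratic) or
read from Gmsh MSH v4.1.

## Worked example

```python
from cardiogrowth import ScenarioConfig, run_pathology
from cardiogrowth.scenarios import phenotype_metrics
from cardiogrowth.geometry import LVGeometryParams

cfg = ScenarioConfig(
    geometry=LVGeometryParams(target_edge=10.0),  # ~1.5k quadratic tets
    growth_mode="transverse",                     # concentric hypertrophy
    n_steps=60,
    output_dir="out/concentric",
)
result = run_pathology(cfg)       # baseline → calibrate → overload → grow → unload → PV
result.save()
for key, value in phenotype_metrics(result).items():
    print(f"{key}: {value:.4f}")
```

This trains the homeostatic thresholds at 5 mmHg, doubles the LV pressure
to 10 mmHg, and lets the wall grow transversely; the phase ends at the
model's validity guard (cavity below 70 % of its peak volume).  Output at
this resolution:

```
wall_volume_increase_pct: 232.0507
chamber_volume_change_pct: -24.7538
chamber_drop_from_peak_pct: 33.1626
final_wall_rate_pct_per_unit_time: 8.9482
peak_wall_rate_pct_per_unit_time: 13.6060
pv_volume_shift_at_baseline_pct: -28.8710
theta_max_final: 2.3982
```

— the wall thickens strongly while the growth rate decays from its peak
(the homeostatic self-regulation; on this unconstrained idealized geometry
full saturation lies beyond the validity guard, see `docs/methods.md`),
the chamber volume falls a third below its early-growth peak, and the
pressure–volume probe shows the stiffened (less compliant) chamber: the
concentric phenotype.  Running the same scenario with
`growth_mode="longitudinal"` and `n_steps=10` produces the opposite,
eccentric picture — a strictly increasing chamber volume (+76 %) with no
rate decay, relatively less wall growth, and a 74 % more compliant
chamber.

The same protocol is available from the shell:

```bash
cardiogrowth run -c scenario.yaml
cardiogrowth generate-mesh -c scenario.yaml -o lv.msh --vtu lv.vtu
cardiogrowth probe-pv -c scenario.yaml
cardiogrowth report out/concentric
```

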