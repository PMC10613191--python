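# osteoadapt

A 2D quasi-static finite-element simulator of load-driven bone remodeling in
an orthotropic second-gradient (strain-gradient) elastic continuum. The
material symmetry orientation and selected stiffnesses of a rectangular
trabecular-bone specimen evolve under diffusing, energy-sourced
mechanobiological stimulus fields, reproducing the trajectorial outcome:
the material symmetry axes align with the principal-strain (isostatic)
directions almost everywhere.

## Model summary

* **Constitutive law** (`osteoadapt.constitutive`): quadratic orthotropic
  first-gradient energy in the strain invariants J1, J2, J4–J7 built from
  the unit symmetry directions A1(ψ), A2(ψ), plus a second-gradient energy
  penalizing fiber stretch gradients and bending. Closed-form stress,
  hyperstress, orientation torque and torque curvature, all guarded by
  finite-difference tests.
* **FEM** (`osteoadapt.fem`): globally C1 tensor-product B-splines
  (degree ≥ 2) on the structured rectangle — conforming for the
  second-gradient weak form — with coefficient-elimination Dirichlet/symmetry
  conditions, edge tractions, double-force terms, and frictionless penalty
  contact against rigid circular pins.
* **Stimulus fields** (`osteoadapt.stimulus`): one reaction–diffusion
  equation per evolving modulus (μ, β1, β2), sourced pointwise by that
  modulus's energy-density share, no-flux boundary, backward Euler.
* **Evolution** (`osteoadapt.evolution`): gradient-flow reorientation of ψ
  (with an unconditionally stable exponential integrator; explicit Euler
  available) and stimulus-feedback drift of the moduli around their
  homeostatic setpoints, advanced by a staggered quasi-static loop.
* **Scenarios** (`osteoadapt.scenarios`): cantilever bending (clamped edge +
  ramped shear traction) and three-point flexure (half domain, symmetry
  condition, two support pins at a 137.5 mm span, displacement-driven
  loading pin). All printed reference parameters ship as exact defaults.
* **Diagnostics** (`osteoadapt.postprocess`): folded (mod π/2) angle
  difference between material axes and principal strain directions,
  aligned-area fractions, line-field streamlines, VTK/CSV export.

## CLI

```bash
osteoadapt validate cantilever        # admissibility check, prints the
                                      # quadratic-form diagonal (GPa)
osteoadapt run cantilever --mesh 30 10 --scaled 1000 --out out/cantilever
osteoadapt run three_point --out out/flexure
osteoadapt export out/cantilever      # snapshots -> CSV
```

`run` also accepts a YAML configuration file (see `ScenarioConfig`); it
writes per-snapshot VTK files, a summary CSV and a JSON manifest.
`--scaled F` divides the evolution viscosities c_γ and c_p by F for
desk-scale demonstration runs (recorded in the manifest).

## Notes

* 2D fields are per unit thickness; edge line densities [N/m] are converted
  to in-plane tractions using the configurable `geometry.thickness`
  (default 25 mm, the specimen depth).
* The deliverable is deterministic: identical configurations produce
  byte-identical outputs.
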