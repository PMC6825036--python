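# lvmodes

Reduced-order simulation of left-ventricular (LV) dynamics using a small
set of global, exactly volume-preserving deformation modes in prolate
spheroidal coordinates.

Most 3D models of ventricular mechanics discretize the myocardium into
thousands of finite elements. For many questions — parameter estimation
from sparse imaging data, remodeling studies, multi-cycle simulations,
aggregate outputs like the pressure–volume (PV) loop — far fewer degrees
of freedom carry the signal. `lvmodes` describes the deformation of the
whole LV wall with N_q kinematic variables **q** (typically 8–46), each
the amplitude of a smooth Fourier deformation mode: radial
expansion/contraction, elongation/shortening, and torsion, with higher
circumferential and longitudinal harmonics for regional asymmetry. The
package is aimed at researchers in cardiac biomechanics and physiological
modelling who want cycle simulations in minutes on a laptop, with full 3D
kinematics and fiber-level stresses.

## Model summary

- **Geometry.** The unstressed wall Ω₀ lies between spline surfaces
  μ_in0(ν₀, φ₀) and μ_out0(ν₀, φ₀) in prolate spheroidal coordinates,
  bounded by a basal curve ν_up0(φ₀); ν = π is the apex.
- **Kinematics.** Displacement fields for (μ_in, ν, φ) are Fourier sums
  `[1 − cos((i+1)(ν₀ − π))]·{cos(mφ₀), sin(mφ₀)}`. The interior radial
  coordinate follows from exact incompressibility: det **F** = 1 holds as
  an algebraic identity (machine precision), because the transmural
  integral of the volume element reduces to a monotone cubic in cosh μ.
- **Dynamics.** Virtual work contracted with each mode variation gives
  `α q̇ + κ − η P_lv = 0` plus blood-volume conservation
  `η·q̇ = q_mv − q_aov`, with Guccione-type passive elasticity, viscous
  stress, active fiber tension A(t)·g(λ_ff)·(k_a + k_av λ̇_ff), smooth
  valve resistances and a windkessel afterload. η is the exact gradient
  of the chamber volume, so pressure work is energy-consistent by
  construction. Time stepping is classical RK4 with a scalar Newton
  solve for P_lv per stage.
- **Verification.** A method-of-manufactured-solutions harness forces the
  system with b = −div σ(q_f) and matching tractions so the exact answer
  is known, plus grid-convergence studies of the recovery errors.
- **Mode fitting.** Gauss–Newton fitting of **q** to point-sampled 3D
  displacement fields (e.g. from tagged-MRI registration), with rigid
  motion removal and nested mode schedules; a synthetic-field generator
  stands in for registration data.

## Worked example

Simulate a normal cardiac cycle with 8 modes (a coarse, fast grid; the
package default is a 5×21×20 quadrature grid at 400 steps/cycle):

```bash
cat > normal_cycle.json <<'CFG'
{
 "modes": {"n_q": 8},
 "grid": {"n_mu": 3, "n_nu": 11, "n_phi": 12},
 "solver": {"n_cycles": 2, "n_pre": 1, "steps_per_cycle": 250}
}
CFG
lvmodes simulate --config normal_cycle.json --out run/
```

which prints

```
stroke work 0.900 J/cycle, stroke volume 70.9 mL -> run/
```

Stroke work is the PV-loop area ∮P_lv dV_lv of the last cycle (counter-
clockwise, high-pressure ejection / low-pressure filling) and the stroke
volume the ejected volume per beat; both land in the normal human range
under the default material and circulation parameters. `run/` contains
`timeseries.csv` (t, q₁…q₈, P_lv, V_lv, valve flows, arterial pressure),
`pvloop.csv`, and `manifest.json` recording the config hash and the mode
ordering of **q** (the ordering is part of every result, since the
kinematic variables are only meaningful relative to it).

The same machinery is scriptable from Python:

```python
from lvmodes.geometry import make_fixture_geometry
from lvmodes.modes import standard_basis
from lvmodes.dynamics import LVModel

model = LVModel(make_fixture_geometry("axisymmetric"), standard_basis(8),
                n_mu=3, n_nu=11, n_phi=12)
res = model.simulate_cycle(n_cycles=2, steps_per_cycle=250, n_pre=1)
print(res.stroke_work(), res.stroke_volume())
```

Other entry points: `lvmodes equilibrium` (static inflation states),
`lvmodes verify manufactured` (recovery/convergence study),
`lvmodes synth-field` and `lvmodes fit` (displacement-field fitting).

## Layout

| module | contents |
| --- | --- |
| `lvmodes.geometry` | prolate coordinates, spline surfaces, quadrature |
| `lvmodes.modes` | mode dictionary and basis functions |
| `lvmodes.kinematics` | incompressibility solve, F/C/E, sensitivities |
| `lvmodes.fibers` | helix-angle fiber/sheet/normal frames |
| `lvmodes.constitutive` | passive, viscous and active stresses |
| `lvmodes.cavity` | chamber closure, volume and its gradient |
| `lvmodes.dynamics` | virtual-work ODEs, circulation, cycle integration |
| `lvmodes.verification` | manufactured solutions, error metrics |
| `lvmodes.modefit` | displacement-field fitting, synthetic fields |
| `lvmodes.config` / `io` / `cli` | configuration, results, command line |

See `docs/methods.md` for the full model description, parameter defaults
with units, numerical choices, and known limitations.
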