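# Methods

## The model

`lvmodes` simulates left-ventricular (LV) dynamics with a small number of
global kinematic degrees of freedom instead of a finite-element mesh. The
unstressed myocardium Ω₀ is described in prolate spheroidal coordinates
(μ, ν, φ) with focal length *a*: bicubic-spline surfaces μ_in0(ν₀, φ₀) and
μ_out0(ν₀, φ₀) bound the wall, a periodic spline ν_up0(φ₀) bounds the
base, and ν = π is the apex.

Deformation is parameterized by three displacement fields built from
separable Fourier terms

    f(ν₀, φ₀) = [1 − cos((i+1)(ν₀ − π))] · {cos(mφ₀) | sin(mφ₀)},

one field each for the endocardial radius μ_in, the longitudinal angle ν
and the circumferential angle φ. Each term's amplitude is one kinematic
variable q_i. The angular displacements are independent of μ₀, so exact
incompressibility can be integrated transmurally in closed form: with the
volume potential W(μ, ν) = cosh³μ/3 − coshμ·cos²ν and the angular area
ratio R = (sinν/sinν₀)(ν,ν₀ φ,φ₀ − ν,φ₀ φ,ν₀), the deformed radial
coordinate of every material point satisfies

    W(μ, ν) = W(μ_in, ν) + [W(μ₀, ν₀) − W(μ_in0, ν₀)] / R,

a strictly monotone cubic in cosh μ (cosh μ ≥ 1 ≥ |cos ν|), solved by a
guarded Newton iteration polished to round-off. The integration constant
is fixed by requiring the endocardial surface to map onto itself, which
makes det F = 1 an algebraic identity of the assembled deformation
gradient — the acceptance checks measure deviations at the 1e-12 level,
i.e. pure round-off.

Stresses: transversely isotropic exponential (Guccione-type) passive
elasticity in a local fiber/sheet/normal frame with a linear transmural
helix angle (+60°/−60° endo/epi by default); a viscous PK2 stress
2 k_v C⁻¹ (∂E/∂q_j) C⁻¹ q̇_j; and an active fiber stress
A(t) g(λ_ff) (k_a + k_av dλ_ff/dt) e_f⊗e_f with a sinᵈ activation pulse
and a Gaussian length–tension curve.

Contracting the virtual-work equation with each mode variation yields
N_q ODEs α q̇ + κ − η P_lv = 0 plus conservation of blood volume
η·q̇ = q_mv − q_aov. The chamber is closed at the base by a ruled cap from
the deformed endocardial rim to the rim centroid on the long axis; the
pressure vector η is computed as the exact gradient of the discrete cavity
volume (complex step through the divergence-theorem quadrature), which
enforces the energy identity η ≡ ∇_q V_lv by construction. The
surface-integral form of η is kept as an independent consistency route and
agrees to quadrature accuracy. Valves are smooth logistic-gated
resistances; the afterload is a two-element windkessel returning to a
constant venous pressure; preload is a constant pulmonary venous pressure.
Time integration is classical RK4 with per-stage coefficient evaluation;
at each stage the scalar pressure is eliminated by a safeguarded Newton
iteration on the monotone flow-balance residual.

## Derivatives

All mode sensitivities (∂E/∂q, ∂x/∂q, ∂λ_ff/∂q, ∂V_lv/∂q) are obtained by
complex-step differentiation through the full pipeline, including the
implicit incompressibility solve — exact to round-off, no subtractive
cancellation. The coordinate partials inside F (∂μ/∂μ₀, ∂μ/∂ν₀, ∂μ/∂φ₀)
are analytic implicit derivatives of the cubic. Central finite differences
serve only as independent test oracles; near the apex the FD oracles use
steps ≥ 1e-4 because the cubic solve has an evaluation-noise floor around
1e-10 that pollutes smaller steps.

## Quadrature

Composite Simpson's rule in all three directions: odd node counts
transmurally (N_μ) and longitudinally (N_ν); circumferentially the panels
wrap the periodic seam (even N_φ, the endpoint weights merging at the
wrapped node). Default dynamics grid 5×21×20. Nodes stop 1e-4 short of the
apex ν₀ = π, where the coordinate system is singular; the omitted strip's
volume is far below quadrature error, and the offset keeps the
1/sin²ν₀-type cancellations in the analytic partials well conditioned.

The verification harness defaults to 9×41×N_φ so that the swept
circumferential resolution is the accuracy-limiting direction; the
acceptance script's 37-mode recovery additionally polishes the solution on
a 13×61×20 grid (warm-started from the 9×41×20 solve), since the fuller
dictionary pushes the transmural/longitudinal quadrature floor above the
recovery tolerance otherwise. Uniform
periodic weights in φ (trapezoid) would be spectrally accurate and leave
the sweep nothing to show below N_φ ≈ 10; Simpson is deliberately used for
its algebraic (≈4th-order) circumferential convergence. Both error metrics
fall steeply (fitted log–log slopes ≈ −2) until they meet the
transmural/longitudinal floor near N_φ ≈ 20–28, beyond which they plateau.

## Manufactured-solution verification

A target state q_f — four entries +0.1 and one −0.1, spread over the
μ/ν/φ blocks so every coordinate deforms asymmetrically while strains stay
moderate (max exponent of the strain energy ≈ 40 on the fixture
geometries) — defines a body force b_f = −div σ_e(q_f) and boundary
tractions t_f = σ_e n on all wall surfaces. The divergence is evaluated
numerically: the stress field is sampled on reference-coordinate stencils,
rotated to Cartesian components at the deformed positions, and chain-ruled
through the reference-to-deformed Jacobian (second-order central
differences; step 1e-4 of the wall thickness transmurally). Global force
balance ∮t_f ds + ∫b_f dv = 0 is checked as a divergence-theorem oracle.
The forced system is solved by damped Newton (finite-difference Jacobian,
least-squares step with a trust cap against aliased near-singular
Jacobians) with the load applied in steps manufactured at scaled targets —
the exponential material is too nonlinear for a cold single-step solve.

## Mode fitting

The fit minimizes the volume-averaged squared displacement error between
model and target displacement fields by damped Gauss–Newton with exact
complex-step Jacobians, warm-started across a nested mode schedule with an
additional cold restart from q = 0 per dictionary size (the warm start
alone can be trapped in a local basin of the non-convex objective).
Weighted-Procrustes rigid-motion removal is applied to targets first; note
that after rigid removal a self-generated field is generally no longer
exactly representable, because the modes cannot produce rigid motion —
exact-recovery statements therefore apply to fits without rigid removal.

## Synthetic data

`modefit.synth_displacement_field` emulates the displacement fields that a
tagged-MRI registration would supply: the model's own smooth displacement
at quadrature nodes plus seeded isotropic Gaussian noise (std in mm). It
reproduces the smoothness and global structure of real myocardial motion
but none of the registration's spatially correlated error, through-plane
undersampling, or segmentation bias — passing fits demonstrate the
optimizer and the representational capacity of the dictionary, not
registration robustness. Fixture geometries are truncated confocal
ellipsoidal shells (human scale: unloaded cavity ≈ 106 mL, wall ≈ 123 mL,
focal length 4.4 cm), optionally with a first-harmonic septal thickening
and a tilted basal curve.

## Parameters

Material and circulation defaults are package defaults in the
physiological range (the source tables for the original simulations are
not public): k_e = 0.9 kPa, b_ff = 18.5, b_xx = 3.6, b_fx = 1.6,
k_v = 0.05 kPa s, k_a = 65 kPa, k_av = 1 kPa s, L_s0/L_smax/L_sw =
1.95/2.2/0.42 µm, activation sin² pulse of 0.30 s starting 0.45 s into an
0.8 s cycle (filling precedes systole); P_pv = 10 mmHg, P_sv = 4 mmHg,
R_mv = 0.01, R_aov = 0.006, R_per = 1.05 mmHg s/mL, C_art = 1.8 mL/mmHg,
initial arterial pressure 85 mmHg. Under these defaults a converged cycle
delivers ≈ 0.9–1.0 J of stroke work at ≈ 70–75 mL stroke volume with peak
pressures ≈ 115 mmHg — the normal-function regime. The viscosity k_v sets
the stiffness of the explicit ODE system: 0.05 kPa s keeps RK4 stable from
≈ 120 steps per cycle; the default is 400 steps per cycle.

## Numerical choices and degenerate inputs

- Cubic root: Newton from max(cosh μ_in, cube-root bound), convex and
  monotone on the admissible branch; no admissible root (the wall would
  collapse through the axis) raises a dedicated error, as do angular
  fold-overs (∂ν/∂ν₀ ≤ 0 or R ≤ 0).
- The pressure Newton at each stage brackets the unique root of the
  monotone residual and bisects when a step leaves the bracket.
- Static equilibria use damped Newton with FD Jacobians; the inflation
  curve V(P) is solved with warm starts along the pressure sweep.
- Valve law: strictly monotone through conduction and closure; the
  exponentially small reverse leak (~1e-3 mL/s) decays back toward zero
  deep in reverse bias rather than growing — physically negligible.
- Torsion leaves the cavity volume exactly invariant when the basal rim
  is a planar circle (axisymmetric fixture); with a tilted rim the ruled
  cap is redefined as the rim rotates, changing the volume at the 1e-5
  relative level.

## Test problem sizes

The suite runs reduced sizes chosen as the package's own test policy:
8–46 modes, 3×11×12 quadrature for cycle tests, 150–400 steps per cycle,
and a 15-mode dictionary for the manufactured-solution study (the
structure of the solve is dictionary-size independent; the full 37-mode
study runs in `scripts/acceptance.py`).

## Known limitations

- Angular displacements independent of μ₀: transmural shear is restricted
  to torsion, by construction of the incompressible solve.
- One activation function A(t) for the whole wall; no activation spread,
  no Frank–Starling dependence of force on end-diastolic strain.
- The prolate apex is a coordinate singularity; modes vanish there and
  quadrature avoids it, so apex-local deformation detail is limited.
- Stress/strain fields converge much more slowly in mode count than
  displacements; the model is not intended for high-resolution local
  stress mapping.
- The closing cap is a modeling surface, not anatomy; only its closure
  and energy-consistency properties are physical.
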