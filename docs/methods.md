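# Methods

`valvefsi` is a desk-scale simulator for the fluid–structure interaction
of heart valves: a weakly-compressible SPH blood solver coupled to an
explicit-dynamics finite-element tissue solver through node-to-surface
penalty contact, with prescribed cardiac-wall motion, piston pressure
boundaries, and clinical post-processing. This note records the models,
the numerical choices that were genuinely open, and what the synthetic
scenes do and do not demonstrate.

## Fluid model

Blood is treated as a Newtonian fluid (ρ₀ = 1056 kg/m³,
μ = 0.0035 Pa·s) discretized as SPH particles with the cubic (M4)
B-spline kernel of support 2h. Density evolves by the continuity
equation in pair-sum form, momentum by the symmetric pressure-gradient
term plus a Morris-type physical viscous term,

    dρ_a/dt = Σ_b m_b v_ab · ∇_a W_ab
    dv_a/dt = − Σ_b m_b (P_a + P_b)/(ρ_a ρ_b) ∇_a W_ab
            + Σ_b m_b (μ_a + μ_b) v_ab /(ρ_a ρ_b r_ab²) (r_ab · ∇_a W_ab),

and pressure closes through an artificial EOS. Defaults:

* **EOS** — linear, P = c₀²(ρ − ρ₀); Tait (γ = 7) selectable. c₀ is
  chosen per scene at ≳10× the largest expected flow speed so density
  fluctuations stay near 1% (standard weak-compressibility practice).
* **Smoothing length** — h = 1.3 Δx with Δx the lattice spacing.
* **Time integration** — symplectic (semi-implicit Euler): velocities
  are kicked with current-state forces, the continuity rate is then
  re-evaluated with the *kicked* velocities before the drift. Evaluating
  both rates from the same state couples the acoustic subsystem through
  an explicit Euler map, which is unconditionally unstable — this
  ordering matters. Δt = 0.25 h/(c₀ + |v|ₘₐₓ), guarded at run time.
* **Stabilization** — the physical viscous term is always on; Monaghan
  artificial viscosity (α per scene, 0.1–0.15 in the settling and valve
  scenes) and a Shepard density re-initialization are config-gated and
  off by default, so the plain-equation mode remains testable.
* **Coincident pairs** — zero contribution with a logged warning.

**Walls.** Rigid boundaries in the fluid-only scenes are frozen "dummy"
particles that take part in every kernel sum. Two standard refinements
are applied: (i) wall-particle pressure is interpolated from the
neighbouring fluid with a hydrostatic correction
(P_w = Σ_f [P_f + ρ_f g·(r_w − r_f)] W / Σ_f W) and the wall density
follows from inverting the EOS — integrating wall densities by
continuity instead makes converging walls (the contracting ventricle)
spuriously stiff, which we measured as a 17% over-ejection before the
change; (ii) an optional no-slip treatment assigns walls the
antisymmetric velocity extension 2v_wall − ⟨v_fluid⟩ in the viscous term
only (used by the channel benchmark; it reduced the Poiseuille profile
error from ~9% to ~1.5% at 24 particles across the channel).

## Tissue model

Leaflets carry the modified anisotropic Holzapfel–Gasser–Ogden energy

    W = c₁{exp[c₂(Ī₁−3)]−1} + k₁/(2k₂) Σ_{i=1,2} [exp{k₂(κĪ₁+(1−3κ)Ī₄ᵢ−1)²}−1]
      + (1/D)(J−1)²

with two symmetric fiber families at ±θ about the circumferential axis
(the single tabulated θ per tissue is read as the half-angle of the
symmetric pair — the standard convention) and a tension-only fiber
switch: a family contributes only while κĪ₁+(1−3κ)Ī₄ᵢ−1 > 0. Chordae
carry the three-term Ogden energy under incompressible uniaxial
kinematics; their axial force is A₀·dW/dλ, which for an incompressible
truss is identical whether one quotes Cauchy or nominal stress, so the
ambiguity has no observable consequence. Chordae are slack below λ = 1
(config-gated off for debugging). Six fitted human-tissue parameter
sets (three leaflet, three chordae) ship with the package.

**Discretization.** Leaflets are constant-strain membrane triangles
with a thickness parameter: the through-thickness stretch of each
element is solved per evaluation so the normal Cauchy stress vanishes
(vectorized Newton, warm-started between steps; the volumetric penalty
with D = 10⁻⁵ kPa⁻¹ keeps J ≈ 1 and makes 1/√det C₂ an excellent
initial guess). Bending stiffness is absent — a real limitation
relative to shell or two-layer solid discretizations: leaflets here are
floppier in the unloaded state and cannot support a bending boundary
layer at the attachment line. Fork-shaped chordal insertions are plain
branching truss connectivity sharing the origin node. Mass is row-sum
lumped; tissue density defaults to 1100 kg/m³.

Explicit central differences advance the structure, substepping 16–24×
inside each fluid step. Two regularizations keep the extremely stiff
leaflet fibers (k₂ ≈ 10³) tractable at desk scale, both of them
standard explicit-dynamics practice and both config-gated:

* **Tension-field (wrinkling) correction** — membranes cannot support
  in-plane compression; negative principal values of the 2nd
  Piola–Kirchhoff stress are scaled down to a 10% residual (zero
  residual lets elements collapse to degeneracy).
* **Mass scaling** (×8 on the valve leaflets) — raises the stable
  increment; leaflet inertia is negligible against the fluid loading,
  so the kinematics of opening/closing are essentially unaffected, but
  quantitative leaflet eigenfrequencies are not meaningful at this
  setting.

A Kelvin–Voigt in-plane viscosity exists in the element but defaults to
0: its explicit damping-stability limit on sub-millimetre free-edge
elements is far below physiological tissue viscosity, so it is not a
usable default.

## Coupling

Node-to-surface penalty contact: every *free* fluid particle within the
contact thickness (0.8 Δx) of a leaflet face gets a normal force
k·depth along the face normal (two-sided, since fluid wets both sides
of a leaflet), with the exact opposite force distributed to the face
nodes barycentrically — Newton's third law holds to machine precision
by construction. Per particle, only the deepest contact of each smooth
surface patch is kept (push directions within ~30° are duplicates seen
across coplanar edges; genuinely folded surfaces keep one contact per
fold); without this filter a flat surface overcounts by ~15–20%.
Tie-breaks at shared edges go to the lowest element index.

Stiffness is auto-scaled, k = m_p/(β Δt²). β = 4 is the rigid-wall
setting; the valve scenes use β = 40 plus normal damping (ζ = 0.5),
which softens the water-hammer kick on light membranes while keeping
the static penetration under pressure at ~0.04 Δx. During the
structural substeps the penetration of the *fixed* contact pairing is
re-evaluated against the moving surface ("live spring"), and the fluid
receives the substep-averaged reaction — holding the force constant
over the substeps destabilizes the leaflets. Tangential coupling is
frictionless by default; a velocity-proportional tangential damping is
config-gated and lets fluid adjacent to a sliding plate track it within
~20% (the no-slip emulation is approximate by construction).

## Boundary conditions

* **Keyframe wall motion** — cubic-spline interpolation of per-node
  displacement keyframes; cardiac tracks use periodic end conditions
  (C¹ across the cycle boundary). End conditions for non-periodic
  tracks are natural splines.
* **Chordal origins** — displaced between their mid-diastole and
  mid-systole anchor positions along a cosine ramp (C¹ at the anchors);
  a linear ramp is selectable.
* **Pistons** — a pressure boundary is a rigid plug of frozen particles
  whose plate velocity is servo-controlled against the imposed waveform:
  u = gain·(P_imposed − P_fluid)/(ρ₀c₀), low-pass filtered and slew-
  limited, with the fluid pressure measured ~1.5h inside the column at
  a probe anchored to the actual plug position. The fixed point of the
  servo is exactly the massless pressure-balancing plate. A direct
  contact-mechanism plate was tried first and rejected: at desk-scale
  resolutions it leaks and hammers. Waveforms are given in mmHg
  (1 mmHg = 133.322 Pa) as constants, callables, or time–value tables;
  scene protocols ramp them over ~20 ms to avoid water-hammer
  transients. A parametric two-phase aortic waveform
  (80–120 mmHg) is provided and is config-replaceable.

## Scenes (the synthetic data)

All geometry is generated from parameters; rebuilding a scene from the
same spec is bit-identical. Default resolutions are chosen once for
single-CPU desk-scale runs (~10³–10⁴ particles; the reference full
model in the literature uses ~5×10⁵ at 0.8 mm — cluster scale):

* `hydrostatic_tank` — 12 mm cube, Δx = 1.2 mm, settled 0.18 s with
  bulk damping; density pre-initialized on the hydrostatic profile.
* `poiseuille_channel` — planar, 24 particles across 1 mm, periodic
  streamwise, body-force driven to u_max = 5 mm/s, run ~5 viscous
  e-foldings.
* `elastic_gate` — 8 mm column retained by a membrane gate
  (Δx = 0.5 mm); the gate mesh is set back so its *wetted* plane (one
  contact thickness in front of the mesh) coincides with the lattice
  wall convention, and the analytic load uses the realized
  (lattice-quantized) column dimensions — both offsets are first-order
  in Δx and were visible in the load before being accounted for.
* `tube_valve` — 10 mm-radius tube, Δx = 1.8 mm, tri-leaflet membrane
  valve of conical patches tapering from the annulus to a small
  free-edge ring (closed reference configuration, watertight up to the
  contact thickness; 1° inter-leaflet seams, far narrower than the
  contact layer), circumferential/meridional fiber frames, pistons at
  both ends. Extensions are ~1–1.35 diameters (parameter; long
  extensions are a particle-budget luxury at desk scale).
* `idealized_lv` — truncated half-ellipsoid (c = 2a) sized to
  EDV = 112 ml, ESV = 47 ml over a 0.8 s cycle on a 10-phase volume
  waveform, Δx = 3 mm, rigid base lid with an outlet orifice
  (r = 11.5 mm) and tube extension open at its far end. The wall is
  three layers of frozen particles riding the outward normal of the
  *nominal* scaled surface at (0.5+k)Δx, so the hydraulic boundary
  tracks the nominal ellipsoid; volume follows the waveform through the
  transverse axes (V ∝ a²). A closed reporting mesh carries the same
  keyframe track for the divergence-theorem volume oracle.

## What the validations show — and what they do not

* Hydrostatic pressure, Poiseuille profile and the rigid-gate load land
  within 5% of their closed forms at the default resolutions; momentum
  and mass conservation of the pair interactions are exact to machine
  precision per step.
* Stresses of both tissue laws equal numerical differentiation of their
  strain energies to 1e-5 on random admissible deformations (draws near
  the tension-only switching surface are excluded — the energy is C¹
  there only in the limit).
* The tube valve opens under forward pressure (projected free-edge
  orifice area grows ~3.5×), closes under reversed pressure, and leaks
  a positive regurgitant volume during closure — sign-level physiology,
  not quantitative leaflet kinematics: at Δx = 1.8 mm with membrane
  elements and mass scaling, opening angles and RVOT/RVCT magnitudes
  are not resolution-converged.
* On the ventricle, the cycle-integrated outlet flux agrees with the
  change of fluid volume in the chamber to <2% (conservation of the
  crossing bookkeeping). The ejected volume tracks the *nominal*
  wall-track volume change only to ~10–15% at Δx = 3 mm: the hydraulic
  wall position is uncertain by a fraction of a spacing over ~10⁻² m²
  of moving wall, which integrates to several ml of stroke volume.
  This is the resolution-limited quantity of the package; it shrinks
  roughly linearly with Δx.
* Nothing here exercises patient-specific anatomy, leaflet–leaflet
  frictional coaptation, calcification, or active myocardial
  contraction; the synthetic scenes emulate geometry and boundary
  conditions, not imaging-derived motion.

## Degenerate inputs and tie-breaks

Zero-area contact faces are excluded with a warning; coincident SPH
pairs contribute zero with a warning; element inversion (non-positive
in-plane metric or Jacobian) aborts the step; flat kinematic traces
raise instead of returning fabricated opening times; the flux probe
counts a particle exactly on the plane once, on leaving the negative
half-space; contacts on shared edges go to the lowest element index.
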