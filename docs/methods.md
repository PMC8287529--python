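# Methods

## Scope and model idea

`atsasim` is a desk-scale, quasi-static musculoskeletal model of a
single replaced glenohumeral (GH) joint: an anatomic total shoulder
arthroplasty (ATSA) with a 48 mm humeral head articulating against a
polyethylene glenoid insert with an 8 mm diametral mismatch. The
question it is built to explore is how rotator-cuff deficiencies
redistribute muscle forces and change the GH contact force during arm
abduction.

Three mechanisms are coupled:

1. **Elastic-foundation contact** between the implant surfaces
   (normal-only, penalty formulation on mesh vertices);
2. **Muscle recruitment** by a polynomial (quadratic by default)
   criterion that resolves the redundancy of the muscle set against the
   three joint moment equations;
3. **Force-dependent kinematics (FDK)**: the three GH translations are
   not prescribed but found, at every driven abduction angle, as the
   point where the net residual force on the humerus falls below a
   tolerance (20 N by default).

The scapula is fixed in the ground frame; the single moving segment is
a lumped arm hanging from the GH center. Inertial terms are neglected
throughout — the 90 s sweep for 90° of elevation is near-static, and
the FDK formulation itself is a search for quasi-static equilibrium.

## Coordinates and units

Right-shoulder frame, origin at the GH joint center: +x anterior (AP),
+y superior (SI), +z lateral (ML). All internal quantities are SI
(m, kg, N, N·m, s); degrees and millimeters appear only at user
interfaces (config file, CLI, trace CSVs for angles) and are converted
once at the boundary. Abduction rotates the humerus about the AP axis
in the frontal plane: the humeral long axis points along −SI at 0° and
along +ML at 90°. The driven angle is interpreted as glenohumeral
elevation; a configurable scapulohumeral-rhythm fraction (default 1.0)
scales the driver angle if a user wants to emulate scapular motion,
which is otherwise out of scope.

## Contact model

Both articular surfaces are spherical caps sampled from a subdivided
icosahedron (near-uniform vertex tributary areas, which is what the
vertex quadrature wants). Faces crossing the cap rim have their outside
vertices clamped onto the rim circle, so the polyhedral cap area matches
the analytic cap area to second order in edge length (0.04% at the
default resolution). The insert cap spans a 60° half-angle, the head
120°, which keeps the contact patch inside both meshes at all sweep
angles. Meshes carry their generating sphere, so penetration depths
against a generated primitive are evaluated exactly; nearest-point
projection onto the master mesh is the fallback for imported geometry.

Per insert vertex *i* with tributary area `A_i` and penetration depth
`d_i` into the head, the foundation law gives a linear
force–penetration-volume relation

    V_i = d_i A_i,    F_i = P_V V_i,

with `P_V` the contact pressure module in N/m³. Forces act along the
slave (insert) inward normal; resultants and moments are exact sums.
The slave is the insert because the deformable body carries the
foundation in elastic-foundation theory. There is no friction and no
tangential stiffness.

The default `P_V = 2.74e11 N/m³` is shipped as a constant. The
foundation-theory expression for a nonlinear polyethylene layer,

    P_V = (1−v)/((1+v)(1−2v)) · (1/h) · (2 p_o/ε_o) · [1 + n (p_i/p_o)^(n−1)],

with `ε_o = 0.0597`, `p_o = 18.4 MPa`, `n = 3`, Poisson ratio `v`
(default 0.46) and layer thickness `h` (default 6 mm), is implemented
and exposed (`contact.pressure_module`) for sensitivity studies, but
the default pipeline never evaluates it: the printed constant cannot be
reproduced without knowing the `v`, `h` and reference pressure `p_i`
actually used, and shipping the constant keeps sweep results
independent of how that expression is read.

## Muscle model and recruitment

Muscles are ideal bounded force actuators routed along straight
polylines between named anchor points (no wrapping surfaces, no
force–length or force–velocity properties). Maximum isometric strength
is PCSA × 27 N/cm². The force on the humerus acts at the first
humerus-bound path point toward its fixed neighbour; the moment-arm
matrix is the cross product of attachment offsets (about the translated
head center) with unit lines of action.

Recruitment solves

    min Σ (f_i/N_i)^p   s.t.  R f = −M_ext,   0 ≤ f_i ≤ bound_i,

with `p = 2` by default (`criterion_order` in the config is the knob
the sensitivity sweep turns). Only the three moment equations enter;
the three force equations belong to the FDK loop. The solver works in
activation space for conditioning: a HiGHS linear program certifies
feasibility and provides the start, SLSQP minimizes the criterion, and
an exact projection onto the equality constraint polishes the result
(residual ≤ 1e-6 relative). Infeasibility — for example when too few
muscles remain to close the moment balance — is a reported status, not
an exception, so sweeps can record failed steps.

Deficiency (a torn muscle) is a zero force bound with the muscle kept
in the model: traces report an explicit 0 N and output schemas are
identical across scenarios. The five deficiency scenarios are
Q1 = {infraspinatus}, Q2 = {supraspinatus}, Q3 = Q1 ∪ Q2,
Q4 = {subscapularis}, Q5 = the whole cuff (supraspinatus,
infraspinatus, subscapularis, teres minor).

## FDK solver

At each driven angle the solver finds the translation `u` zeroing (to
tolerance) the residual

    R(u) = Σ f_i(u) û_i(u) + m g + F_contact(u) + F_spring(u),

with recruitment re-solved inside every residual evaluation. The root
search is damped Newton: forward finite differences (step 1e-5 m) for
the 3×3 Jacobian, step length capped at 2 mm, Armijo-style backtracking
on the residual norm, and a Nelder–Mead polish after three stagnant
iterations — the contact resultant is only piecewise-smooth in `u`
(mesh quadrature), so undamped Newton can chatter. The capsule spring
(stiffness 1.74e4 N/m, acting at the GH center) regularizes the
tangential directions that contact alone leaves soft.

Two tolerances are involved deliberately. Convergence is *reported*
against the physical residual tolerance (20 N default), but the
iteration *aims* for 5% of it. The AP/SI stiffness felt by the residual
can be as low as the spring constant, so a state with a 20 N residual
is only localized to about a millimeter; driving the residual to ~1 N
pins the converged translation to ~1e-4 m and makes it independent of
the iteration path (the warm-start invariance property in the test
suite). Sweeps warm-start each step from the previous converged
translation; the first step starts at zero.

## Abduction driver

The driven angle is a finite Fourier expansion
`Pos(t) = Σ A_j cos(ω_j t + B_j)` in degrees over a 90 s motion. The
original coefficient values are not public, so the shipped default is
the two-term cosine ramp `45 − 45·cos(πt/90)` — expressible exactly in
the stated functional form, smooth at both ends, 0° at t = 0 and 90° at
t = 90 s — declared as a stand-in, and overridable in the config (any
user profile is validated against the endpoint and monotonicity
invariants at load time). The default grid has 91 steps (≈1°
increments, matching per-degree reporting); the step count is a
sensitivity parameter.

## Synthetic model fixtures

No anatomical database is bundled; the default muscle attachment table
is a literature-style fixture for a right shoulder, chosen once, with
these properties (all asserted by tests):

* six required muscles (two deltoid parts, four cuff muscles) plus two
  antagonists (pectoralis major, latissimus dorsi);
* deltoid the largest PCSA overall (22 cm² across both parts),
  subscapularis the largest cuff muscle (16 cm²), teres minor the
  smallest (3 cm²);
* deltoideus scapularis and supraspinatus abduct; pectoralis major and
  latissimus dorsi adduct; subscapularis rotates internally while
  infraspinatus and teres minor rotate externally.

The antagonists matter structurally: with the whole cuff lost (Q5),
two deltoid lines alone cannot close a three-axis moment balance, so an
adductor/internal-rotator pair is required for the scenario to be
solvable at all. The subscapularis ground anchor sits at its effective
anterior line of action rather than the fossa centroid, because
straight-line paths cannot wrap the anterior capsule; this preserves
its internal-rotation role and moderates its compressive component.

The arm segment (4.0 kg, COM 0.30 m down the humeral axis) is an
explicit, configurable stand-in — the source skeletal model is
proprietary and its segment properties are not claimed to be
reproduced.

What the fixture does *not* emulate: muscle wrapping and broad
attachment footprints, force–length/velocity properties, scapular
motion, and patient-specific geometry. Passing the qualitative trend
tests therefore shows that the *mechanisms* (redundancy resolution,
foundation contact, force-dependent translations) interact correctly,
not that any specific patient's force magnitudes are predicted.

## Numerical choices and degenerate inputs

* Mesh resolution default: ~5000 insert triangles (icosphere
  subdivision 5). The contact patch radius at sweep loads is 2–4 mm
  against ~1 mm vertex spacing; refinement tests confirm monotone
  quadrature convergence (subdivisions 4/5/6).
* Penetration of a generated master sphere is exact (signed distance);
  role-swap (Newton's third law) agreement is 5% at default resolution,
  limited by the two meshes' different quadratures.
* Recruitment at 0° with zero external moment returns all-zero forces;
  tangent surfaces yield an all-zero contact result, not an error.
* Sweeps abort (with a diagnostic) when more than half the steps fail;
  isolated failed steps are recorded as NaN rows and excluded from
  summaries.
* Percent changes at query angles interpolate linearly on converged
  rows; 78° is the default query angle, and peak-based changes are
  reported alongside because both conventions appear in practice.

## Problem sizes

Default runs use 91 driver steps per scenario, six scenarios, ~2700
insert vertices in the contact quadrature, and eight muscles in
recruitment; the full six-scenario sweep takes on the order of two
minutes on one CPU. Verification oracles (analytic overlap volume,
two-muscle closed form, brute-force recruitment enumeration) run on
deliberately tiny instances.

## Known limitations

* Force magnitudes are fixture-specific; only directional trends across
  scenarios are asserted.
* No partial-thickness tears (deficiency is all-or-nothing), no
  repairs, no other tear combinations.
* Normal-only contact; no wear, creep, or pressure-distribution
  validation.
* Straight-line muscle paths understate moment arms at extreme angles.
* The GH translation is restrained by a single linear spring; real
  capsuloligamentous restraint is nonlinear and direction-dependent.
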