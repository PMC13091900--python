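# Methods

`pedsim` is a desk-scale forward-dynamics simulator of the human foot:
an anatomically structured rigid-bone skeleton with discrete soft
tissues, driven through three loading protocols (cadaveric axial
compression, quiet standing, muscle-driven walking stance).  This note
records the model, its assumptions, the parameters that matter, and the
limits of what the synthetic-data pipeline can show.

## Model overview

**Units.** Internal units are (mm, g, ms), chosen so forces come out in
newtons and stresses in MPa: every constitutive constant of the
parameter table (`pedsim.materials.MaterialSet`) is used exactly as
printed.  Gravity is 9.81 m/s² = 9.81·10⁻³ mm/ms².  SI inputs are
converted at the I/O boundary.

**Skeleton.** 23 rigid bones (tibia, fibula, talus, calcaneus,
navicular, cuboid, three cuneiforms, five metatarsals, two hallucal
phalanges, one fused phalangeal segment per lesser ray, three
sesamoids), each a solid ellipsoid placed by a template at foot length
255 mm, uniformly scalable, with an adjustable arch-height ratio
(navicular height / foot length, default 0.25) and exact sagittal
mirroring.  Cortical bone is 3–6 orders stiffer than the surrounding
tissue, so bone deformability contributes nothing at joint level; the
bone elastic constants (E = 7300 MPa, ν = 0.30) are kept in the
material registry for element-stress reporting.  Encapsulated
soft-tissue mass is lumped onto the bones through a density multiplier
(default 3×, total ≈ 1.35 kg including the shank), and bones lighter
than 5 g are clamped to 5 g purely as an inertia regularization for
explicit integration — a change of well under 1 % of total weight.

**Constitutive laws.**

* Plantar soft tissue: one-term Ogden, nominal uniaxial stress
  σ(λ) = −(2C/α)(λ^(α−1) − λ^(−α/2−1)) with C = 0.0102 MPa, α = 8.04.
  The leading minus is implemented literally, so compression (λ < 1)
  yields positive stress — the natural sign for a contact-like plantar
  column; a `tension_positive` flag flips it.
* Viscoelasticity: two-term Prony series (g₁ = 0.18, g₂ = 0.12,
  τ₁ = 0.57 s, τ₂ = 6.03 s, converted to ms), applied through the
  standard quasi-linear recursive-convolution update, which is exact
  for elastic stress varying linearly within a step.  At the uniaxial
  column level the full/deviatoric distinction collapses; the registry
  keeps a `prony_on_full_stress` switch to record the choice.
* Skin: Ogden with C = 0.122 MPa, α = 18 (in the registry; the
  reduced-order model does not carry a separate skin layer).
* Ligaments: linear springs in engineering strain with stiffness
  EA/slack (E = 260 MPa), tension-only.  Toe-region nonlinearity is
  deliberately omitted — the data behind the model give only E and
  areas.
* Plantar aponeurosis: E = 412.02 MPa, derived from a cadaveric
  force–strain datum (tension 1.5 × body weight at 5 % strain, 70 kg,
  50 mm² cross-section; E = (1.5·70·9.81/50)/0.05).
* Floor: rigid plane, Coulomb μ_s = μ_d = 0.6.

**Slack lengths.** Default ligaments: 1.1 × the build-pose length
(under-estimating slack leaves every ligament permanently taut and
over-stiffens the foot).  The lateral hindfoot group (ATFL, CFL,
lateral talocalcaneal, lateral calcaneocuboid, bifurcate, PTFL) was
stretched in the slightly inverted reference posture, and the plantar
group was not shortened; both use exactly the build-pose length, as
does the aponeurosis.

**Plantar aponeurosis.** Ten tension-only slips from the calcaneal
origin to the toes, 5 mm² each.  Slip 1 routes through the medial
sesamoid (two pinned segments); the others wrap analytic cylinders on
the metatarsal heads using the tangent–arc–tangent geodesic of the
developed cylinder surface.  Each slip's winding side is fixed at
build time: a tendon held against the plantar surface cannot flip to
the dorsal side, and the fixed winding also keeps the path length
continuous in the bone poses.  With a fixed side the wrap releases to
the straight segment when its arc angle leaves (0, π).  The infinite
cylinder is an approximation; far outside the physiological
metatarsophalangeal range the frictionless chord can clear the surface
where a real tendon would stay contained by the plantar plate.

**Ligament chains and spheres.** Anatomically each ligament is an
alternating series of tension-only springs and 1-mm spheres that slide
frictionlessly on the host bone surfaces, with broad-attachment
hindfoot ligaments as bundles of ten chains.  Because the springs are
linear, a bundle of ten strands of area A/10 on a common path is
force-identical to one chain of area A, so bundles enter only through
area bookkeeping.  The quasi-static sphere projection
(`tissues.resolve_sphere_contacts`) pushes penetrating spheres to
exactly one radius of clearance along the analytic surface normal and
reports the purely normal contact forces.  Inside the time loop the
chains are evaluated as straight attachment-to-attachment springs:
every chain in this skeleton spans a single joint, where the
path-wrap correction is a second-order effect at walking postures.

**Joints.** Each articulation carries three elements:

1. a frictionless sphere-pair penalty contact, touching at the joint
   centre in the build pose (compression only, equal-and-opposite
   wrenches, velocity damping at 0.6 of critical);
2. a zero-rest-length "elastic ball joint" spring between coincident
   joint-centre anchors on the two bones (default 800 N/mm).  This is
   the congruence term: real tarsal joints resist translation through
   interlocking concave–convex surfaces, which a single sphere pair
   cannot represent — without it the skeleton shears apart under
   hundreds of newtons.  Rotation remains the compliant DOF;
3. a torsional capsule spring (5 N·m/rad) for the relative-spin mode
   that no tension element crosses; the wedged midfoot and
   tarsometatarsal articulations, which are nearly rigid in rotation,
   use 30 N·m/rad.  For comparison, arch moments at full load are
   ~30 N·m, so the hindfoot torsion term is a ~2 % correction there.

Penalty and ball-joint stiffnesses are numerical parameters: they are
auto-capped per pair so no contact mode exceeds a 55 rad/ms frequency
(light toe bones would otherwise dictate the global step), and statics
are insensitive to them (doubling the penalty changes the standing GRF
by < 0.5 %, which is tested).

**Plantar contact.** One Ogden/Prony column under each plantar bony
prominence: five across the heel pad, the five metatarsal heads, the
medial sesamoid, the hallux and lesser toe pads, plus a lateral-arch
contact at the cuboid and fifth metatarsal base (the lateral column of
a normal foot does touch down — without it the model rolls medially
under axial load).  Column reference thickness is the build-pose
clearance of its anchor above the floor (≈ 10 mm at the heel); areas
total ≈ 8 500 mm².  The column supplies the normal force (so the
contact stiffness is the physical pad stiffness, not a penalty);
Coulomb friction acts at the column foot through the classic
stick–slip anchor-spring regularization with a tangential dashpot so
fast-sliding points saturate the cone immediately.  The reported GRF
is exactly the sum of column normal and friction forces, and the
pressure-map binning conserves that sum to machine precision (audited
every output frame).

## Integration

Semi-implicit (symplectic) Euler: velocities from current forces, then
positions from new velocities; orientations integrate body-frame
angular velocity through the quaternion exponential map with the
gyroscopic term retained.  The stable step is a per-body assembled
(Gershgorin-style) bound: every spring/penalty element contributes
k·(1/m + r²/I_min) to both endpoint bodies, and
dt = safety · 2/√(max body sum), capped at 1 ms.  For this skeleton
the bound is set by the rotational receptance of the small bones and
sits near 8–20 µs; the 1 ms cap acts as the output/control interval.
With no damping the integrator holds the energy of a test spring
network to < 1 % secular drift over 10⁴ steps (the bounded symplectic
oscillation is larger and is not drift).

Tissue dashpots default to 0.4 of critical per element — in a real
foot the tissues, not the numerics, are the dominant energy sink.
Static solutions use dynamic relaxation: mass-proportional damping
plus kinetic-energy resets, with viscous time accelerated (×200)
during settling so the Prony columns reach their relaxed modulus
instead of creeping for seconds; convergence is a peak residual
acceleration below tolerance (default 1.5·10⁻³ mm/ms² ≈ 0.15 % g,
normalized by physical mass so it keeps meaning under mass scaling).
Stiff-material variants (e.g. the rigid-ligament E×1000 comparison)
use static mass scaling — inertial mass only; gravity loads keep the
physical weight — which leaves equilibria untouched while keeping the
explicit step practical.

## Protocols

**Axial loading.** The proximal tibia and fibula are potted in a
rubber block (70×50×20 mm, E = 4.0 MPa) fixed to a 3.3 kg shaft that
may only translate along and rotate about the vertical axis.  The
block is modelled as four isotropic corner tethers per bone with the
block's axial stiffness EA/t = 700 N/mm shared among them (a 6-DOF
bushing reduced to tethers; shear is then over-stiff by ~3×, a
secondary effect on displacement trends).  After a heel-first
placement (temporary 8 N lift at each metatarsal head), the load ramps
0 → 588 N (60 kg) in quasi-static increments with a static settle at
each level; translations and y–x–z Euler rotations of calcaneus,
talus, cuboid, navicular and first metatarsal are reported relative to
the zero-load (shaft-weight-only) state.  The default acceptance run
uses four levels (0/196/392/588 N), enough for the monotone
arch-flattening check; the navicular drops ≈ 4→9 mm over the ramp and
bone rotations stay in the single-digit degrees, the range seen in
cadaveric feet.

**Quiet standing.** Two-stage static solution for a 72 kg subject:
353 N axial (half body weight, rounded half-up as conventionally
quoted) without tendon traction, then 530 N down on the tibia with
177 N of Achilles traction up at the calcaneal tuberosity (the triceps
surae carries ≈ 50 % of the ground reaction in balanced standing; 177
= round(0.5·353), 530 = 353+177, asserted at construction).  The
tibia is guided vertically — the stabilizing role of the rest of the
body.  Because the half-body-weight target already includes the foot's
own weight, the applied tibial force is net of the model weight, and
the converged vertical GRF equals the target exactly (audited).
Outputs: plantar pressure map (force-conserving binning, optional
block-average downsampling to sensor resolution) and centre of
pressure.

**Walking stance.** The tibia and fibula are driven as one rigid
cluster by the three tibial landmarks (medial/lateral malleolus,
tibial tuberosity): markers are low-pass filtered (zero-phase 4th-order
Butterworth, 20 Hz cutoff), registered to the model landmarks by
closed-form 3-point Procrustes each frame, and applied as prescribed
displacements.  Muscle forces (TS, TA, EDL, EHL) follow sampled
stance-% profiles with linear interpolation along straight-segment
lines of action recomputed every step.  The initial condition comes
from the anchored backward procedure: settle statically at 20 % stance
(tibia near vertical, foot flat), integrate the driven model backward
in time to heel contact, reverse the velocity, reset friction anchors
and viscous history, and run forward.  The procedure is not exactly
reversible — contact, Coulomb friction and tension-only elements
dissipate — which is also true of the physical system; the anchor
state, not heel contact, is the accurately known posture.

**Refinement.** Driving the model with kinematics alone leaves GRF
errors; the tracking loop fits each GRF-error component with an
8th-order least-squares polynomial on normalized stance time, scales
it by a per-component gain (mm per N, auto-estimated by a one-shot
secant probe at half the inverse plant gain for stability margin),
subtracts it from the prescribed displacement (excess downward GRF
lifts the tibia; diagonal component coupling only) and reruns.  On a
scalar linear plant the loop contracts geometrically at |1−gG| per
iteration (tested to 5 %), and the best-seen iterate is returned so
the reported error never exceeds the initial one.

## Synthetic gait generator

The generator stands in for motion capture and force plate.  Measured
quantities are shaped directly: vertical GRF as two Gaussian bumps
(peaks 1.1 BW at ~25 %/75 %, valley ≈ 0.75 BW, smooth tapers to zero
at contact and toe-off), anteroposterior GRF as a single
braking→propulsion period, antisymmetric about mid-stance so the net
impulse vanishes, and a small mediolateral bump.  The shank trajectory
follows two consistency rules rather than free-hand curves:

1. through mid-stance the ankle dips ≈ 5 mm below its unloaded height —
   the plantar-pad compression under body weight; with a
   position-driven shank this dip *is* what loads the foot;
2. the ankle is the stationary pivot of the shank during foot-flat,
   and after heel-off (default 64 % stance) it follows the forefoot
   rocker: a smooth rotation (default 25° at toe-off) about the
   metatarsal-head pivot, so the prescribed path neither drags nor
   crowds the planted forefoot.

Marker trajectories are the rigid-cluster images of the model's tibial
landmarks under this motion, with optional seeded noise.  All
randomness flows from one seeded generator; records are deterministic
per seed.

What the generator does *not* emulate: the inertia of the 72 kg body
above the shank (horizontal GRF magnitudes are therefore set by local
friction mechanics, not whole-body deceleration), soft-tissue marker
artifact, bilateral coordination, and measured double-bump GRF
magnitudes in the simulated output (the generator's GRF is the
*measured-side* input; reproducing it in simulation is the refinement
loop's job).  Passing stance tests therefore demonstrates internal
mechanical consistency (windlass sequence, COP progression, friction
cone, tension-only behaviour, conservation audits) — not agreement
with any subject's recordings.

## Numerical choices and degenerate inputs

* Contact/capsule penalties frequency-capped at 55 rad/ms per pair;
  statics penalty-insensitive (tested).
* Tension-only springs: dashpot force is clipped so a slack or
  shortening chain can never push (no adhesion, no compression —
  audited over whole protocol runs).
* Fully bottomed-out columns clamp the stretch at 10⁻³ to avoid the
  Ogden singularity at λ → 0.
* Euler decomposition flags |about_x| > 89° as gimbal proximity; the
  protocols stay far from it.
* Zero-length spring directions regularized at 10⁻⁹ mm.
* Degenerate pressure maps (no loaded cell) return an all-zero map
  with an undefined-COP flag rather than NaN arithmetic.

## Problem sizes

Default acceptance-scale runs: stance 0.6 s at the stability-bound
step (~8.5 µs, ≈ 70 000 steps) plus a ~25 000-step anchor settle and a
backward pass; axial loading four levels × ≤ 8 000 settle steps;
standing two settles of ≤ 30 000 steps.  These sizes are the package
defaults and complete in minutes on one core.

## Known limitations

* Ellipsoid bones and single-point joints: no articular surface
  geometry, so joint kinematics are governed by the tether/ligament
  layout, not surface congruence shapes.
* The continuum stress fields of a meshed model are reduced to
  element-level quantities (spring tensions, column stresses).
* Ligament linearity (no toe region); no ligament viscoelasticity.
* Muscle paths are straight segments without wrapping surfaces;
  moment arms are whatever the geometry gives.
* The horizontal GRF of the stance simulation reflects foot–shank
  mechanics only (no body inertia above the shank).
* The infinite wrap cylinder can release unphysically far outside the
  physiological MP range (see above).
* The vertically-guided tibia of the standing protocol takes
  horizontal reactions that in a person are closed through the body
  above; horizontal GRF components in that protocol reflect the guide,
  not balance control.
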