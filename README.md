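# pedsim

Explicit forward dynamics of an anatomically structured human foot, at
desk scale.

Whole-body gait models usually collapse the foot into one or two rigid
links, which makes it impossible to ask how tarsal morphology, ligament
architecture or the plantar aponeurosis shape the forces the foot
exchanges with the ground.  `pedsim` is a reduced-order simulator for
exactly those questions: a 23-bone rigid skeleton with discrete soft
tissues, driven by tibial kinematics and muscle forces through the
stance phase of walking, plus the two static protocols classically used
to validate such models (cadaveric axial loading and quiet standing).
It is aimed at foot-biomechanics researchers who want a transparent,
scriptable sandbox — every force element is inspectable, every run is
deterministic and audited for force conservation.

## The model in brief

* **Skeleton** — 23 rigid bones (tibia, fibula, talus, calcaneus,
  navicular, cuboid, 3 cuneiforms, 5 metatarsals, 2 hallucal phalanges,
  fused lesser-ray phalanges, 3 sesamoids) built from a parametric
  template: scalable foot length, adjustable arch height, exact
  left/right mirroring.
* **Soft tissue** — plantar pads as uniaxial columns with a one-term
  Ogden law, σ(λ) = −(2C/α)(λ^(α−1) − λ^(−α/2−1)) (C = 0.0102 MPa,
  α = 8.04), under a two-term Prony relaxation
  g(t) = 1 − Σ gᵢ(1 − e^(−t/τᵢ)) (g₁ = 0.18, g₂ = 0.12, τ₁ = 0.57 s,
  τ₂ = 6.03 s) integrated by recursive convolution.
* **Ligaments** — tension-only chains, stiffness EA/L₀ (E = 260 MPa),
  slack 1.1× the reference-posture length except for the lateral
  hindfoot and plantar groups (1.0×).
* **Plantar aponeurosis** — ten tension-only slips (E = 412.02 MPa,
  from a cadaveric force–strain datum: 1.5 body weights at 5 % strain
  over 50 mm²), wrapping analytic cylinders on the metatarsal heads;
  the first slip routes through the sesamoids.
* **Contact** — rigid floor with Coulomb friction (μ = 0.6,
  stick–slip anchor regularization), frictionless sphere-proxy
  cartilage contact at every joint.
* **Dynamics** — symplectic-Euler explicit integration with an
  assembled per-body stability bound; dynamic relaxation for statics.
* **Kinematics** — y–x–z Euler joint angles (R = R_y R_x R_z;
  plantarflexion/inversion/internal-rotation positive) for the
  talocrural, talonavicular and calcaneocuboid joints and the
  navicular–first-metatarsal arch angle; force-conserving plantar
  pressure maps and centre of pressure.
* **Refinement** — a GRF-tracking loop that fits simulated-minus-
  measured GRF errors with 8th-order polynomials and converts them
  into tibial displacement corrections.

Sign conventions: x anterior, y medial, z superior; the floor is
z = 0.  See `docs/methods.md` for the full account.

## Worked example

Quiet standing for a 72 kg subject — build the default foot, apply the
two-stage load (353 N axial, then 530 N tibial + 177 N Achilles
traction), and read off the ground reaction:

```python
from pedsim.foot_model import build_foot
from pedsim.protocols import StandingConfig, run_quiet_standing

model = build_foot()
result = run_quiet_standing(model, StandingConfig(body_mass=72.0))
print(f"stage-1 GRF {result.stage1_grf[2]:.1f} N")
print(f"final GRF   {result.grf[2]:.1f} N")
print(f"COP         ({result.cop[0]:.1f}, {result.cop[1]:.1f}) mm")
print(f"pressure-map force {result.pressure.total_force:.1f} N")
```

```
stage-1 GRF 353.0 N
final GRF   353.0 N
COP         (94.9, -5.0) mm
pressure-map force 353.0 N
```

The vertical ground reaction matches the half-body-weight target at
both stages to within the settle tolerance, and the pressure map
integrates to exactly the summed contact force (the conservation audit
runs every frame).  The centre of pressure lands 95 mm anterior of the
heel — about 37 % of foot length, the mid-tarsal region where standing
COP is normally measured — and close to the midline.

The same protocols are available from the shell:

```bash
pedsim build --scale 255 --seed 0         # build + validate the skeleton
pedsim stand --body-mass 72 --out stand.h5
pedsim axial --levels 4 --out axial.h5    # 0 -> 588 N ramp
pedsim synth --seed 0 --out-prefix gait   # synthetic markers/GRF/muscles
pedsim walk --out stance.h5 --joint-csv angles.csv
```

`pedsim walk` runs the full muscle-driven stance: anchor settle at
20 % stance, backward integration to heel contact, velocity reversal,
then the forward run driven by the registered tibial landmark
trajectories — reporting GRF, centre-of-pressure progression,
aponeurosis tension and y–x–z joint angles over stance.

## Layout

```
src/pedsim/
  foot_model.py   parametric 23-bone skeleton + validation
  materials.py    Ogden / Prony / linear-elastic registry
  tissues.py      ligament chains, aponeurosis wrapping, muscles, columns
  contact.py      floor friction, cartilage sphere contact
  dynamics.py     explicit integrator, stability bound, dynamic relaxation
  protocols.py    axial loading, quiet standing, walking stance
  refinement.py   GRF-tracking displacement correction
  kinematics.py   Euler angles, pressure maps, COP, filtering, MAE stats
  gait_io.py      TRC/CSV I/O + synthetic stance generator
  runio.py        HDF5 run outputs, CSV logs
  cli.py          the `pedsim` command
```
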