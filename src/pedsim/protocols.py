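"""Loading protocols: cadaveric axial loading, quiet standing, walking stance.

Three scenario drivers reproduce the model's validation experiments on
the synthetic skeleton:

* **axial loading** — the proximal tibia and fibula are potted in a
  rubber block fixed to a vertical shaft (3.3 kg) that can only
  translate along and rotate about the vertical axis; after a
  heel-first initial placement the axial load ramps from zero to
  588 N (60 kg) with a static settle at each level, and the rigid-body
  displacements of calcaneus, talus, cuboid, navicular and first
  metatarsal are reported as translations and y-x-z Euler rotations
  relative to the zero-load state.

* **quiet standing** — a two-stage static solution: first 353 N of
  axial load (half the 72 kg subject's weight per foot) without tendon
  traction, then 530 N down on the tibia together with 177 N of
  upward Achilles traction at the calcaneal tuberosity (the triceps
  surae carries ~50% of the ground reaction in balanced standing).
  Outputs the plantar pressure map and centre of pressure.

* **walking stance** — the tibia and fibula are driven by the
  low-pass-filtered, landmark-registered marker trajectories; muscle
  forces follow their stance-% profiles; the initial condition comes
  from a backward integration from the 20%-stance anchor (where the
  tibia is nearly vertical and the foot flat) with the heel-contact
  velocity reversed.

Applied tibial loads in the static protocols are corrected for the
model's own weight so that the target ground reaction is met exactly:
the half-body-weight target includes the weight of the foot itself.

Every protocol result carries a per-sample force audit
(sum of contact forces, sum of applied loads, residual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    BoundaryCondition,
    MechanicalSystem,
    SimulationState,
    assemble_foot_system,
    settle_static,
    stable_dt,
    step,
)
from .foot_model import FootModel
from .gait_io import GaitRecord, MARKER_NAMES
from .kinematics import (
    EulerYXZ,
    center_of_pressure,
    euler_yxz,
    lowpass_markers,
    pressure_map,
)
from .materials import MaterialSet
from .units import GRAVITY

__all__ = [
    "AxialLoadingConfig",
    "StandingConfig",
    "StanceConfig",
    "AxialLoadingResult",
    "StandingResult",
    "StanceResult",
    "run_axial_loading",
    "run_quiet_standing",
    "initialize_stance",
    "run_stance",
    "register_shank_poses",
]

#: joints reported by the kinematics post-processing:
#: (name, proximal bone, distal bone)
REPORTED_JOINTS = (
    ("TC", "tibia", "talus"),
    ("TN", "talus", "navicular"),
    ("CC", "calcaneus", "cuboid"),
    ("N-1MT", "navicular", "metatarsal_1"),
)

AXIAL_REPORTED_BONES = ("calcaneus", "talus", "cuboid", "navicular",
                        "metatarsal_1")


class ProtocolError(RuntimeError):
    pass


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class AxialLoadingConfig:
    """Cadaveric axial-loading replication parameters."""

    shaft_mass: float = 3.3e3          # g (3.3 kg)
    max_load: float = 588.0            # N (60 kg equivalent)
    n_levels: int = 7                  # load levels including zero
    rubber_block: tuple = (70.0, 50.0, 20.0)   # mm
    rubber_E: float = 4.0              # MPa
    rubber_nu: float = 0.475
    rubber_density: float = 1.2e-3     # g/mm^3
    forefoot_lift_force: float = 8.0   # N per metatarsal head, placement stage
    ramp_ms: float = 40.0              # quasi-static load ramp per level
    settle_tolerance: float = 1.5e-3   # mm/ms^2
    settle_max_steps: int = 30000

    def __post_init__(self):
        if self.max_load < 0:
            raise ProtocolError("max_load must be non-negative")
        if self.n_levels < 2:
            raise ProtocolError("need at least two load levels")

    @property
    def load_levels(self) -> np.ndarray:
        """Non-decreasing ramp from zero to max_load."""
        return np.linspace(0.0, self.max_load, self.n_levels)


@dataclass
class StandingConfig:
    """Quiet-standing load assembly for a given body mass.

    The per-foot ground-reaction target is half body weight; the
    Achilles traction is ``achilles_fraction`` of that target and the
    total tibial load is their sum (internal consistency asserted at
    construction, values rounded to the newton as conventionally
    quoted).
    """

    body_mass: float = 72.0            # kg
    achilles_fraction: float = 0.5
    grf_target: float | None = None    # N; default from body mass
    achilles_load: float | None = None
    tibia_load: float | None = None
    settle_tolerance: float = 1.5e-3
    settle_max_steps: int = 30000

    def __post_init__(self):
        # round half away from zero, the convention behind the quoted
        # 353 / 177 / 530 N values (Python's round() is banker's)
        r = _round_half_up
        if self.grf_target is None:
            self.grf_target = r(self.body_mass * 9.81 / 2.0)   # 353 N @72 kg
        if self.achilles_load is None:
            self.achilles_load = r(self.achilles_fraction * self.grf_target)
        if self.tibia_load is None:
            self.tibia_load = self.grf_target + self.achilles_load
        if abs(self.achilles_load
               - r(self.achilles_fraction * self.grf_target)) > 1.0:
            raise ProtocolError(
                f"achilles_load {self.achilles_load} inconsistent with "
                f"{self.achilles_fraction} x {self.grf_target}"
            )
        if abs(self.tibia_load - (self.grf_target + self.achilles_load)) > 1.0:
            raise ProtocolError(
                f"tibia_load {self.tibia_load} != grf_target + achilles_load"
            )


@dataclass
class StanceConfig:
    """Walking-stance simulation parameters."""

    anchor_pct: float = 20.0
    lowpass_cutoff: float = 20.0       # Hz
    output_stride_ms: float = 5.0
    dt_safety: float = 0.5
    anchor_settle_tolerance: float = 2e-3
    anchor_settle_max_steps: int = 25000


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _fix_body(system: MechanicalSystem, name: str,
              trans_mask=(0, 0, 0), rot_mask=(0, 0, 0)):
    i = system.index[name]
    system.trans_mask[i] = np.asarray(trans_mask, float)
    system.rot_mask[i] = np.asarray(rot_mask, float)


def _audit_triple(audit: dict, applied_z: float) -> tuple[float, float, float]:
    grf_z = float(audit["grf"][2]) if "grf" in audit else 0.0
    return grf_z, applied_z, grf_z - applied_z


def _grf_from_audit(audit):
    fn = audit["column_fn"]
    ft = audit["column_ft"]
    return np.array([ft[:, 0].sum(), ft[:, 1].sum(), fn.sum()])


def _pressure_from_audit(audit, cell_size=10.0):
    pos = audit["column_pos"]
    fn = audit["column_fn"]
    origin = np.array([pos[:, 0].min() - 2 * cell_size,
                       pos[:, 1].min() - 2 * cell_size])
    span = pos[:, :2].max(axis=0) - origin + 2 * cell_size
    shape = (int(np.ceil(span[0] / cell_size)) + 1,
             int(np.ceil(span[1] / cell_size)) + 1)
    return pressure_map(pos[:, :2], fn, origin, cell_size, shape)


def _bone_rotation(state, system, name):
    from scipy.spatial.transform import Rotation

    q = state.quat[system.index[name]]
    return Rotation.from_quat(q[[1, 2, 3, 0]]).as_matrix()


# ---------------------------------------------------------------------------
# Axial loading
# ---------------------------------------------------------------------------

@dataclass
class AxialLoadingResult:
    loads: np.ndarray
    #: bone -> (n_levels, 3) translations, mm, relative to zero load
    translations: dict[str, np.ndarray]
    #: bone -> (n_levels, 3) y-x-z Euler rotations, deg, relative to zero load
    rotations: dict[str, np.ndarray]
    audits: list[tuple[float, float, float]]
    settled: list[bool]


def run_axial_loading(model: FootModel,
                      config: AxialLoadingConfig | None = None,
                      materials: MaterialSet | None = None,
                      mass_scale: float = 1.0,
                      ) -> AxialLoadingResult:
    """Ramped axial compression through a vertically guided shaft.

    ``mass_scale`` scales inertial mass only (static equilibria are
    unaffected); use it to keep the explicit step practical when
    running artificially stiffened tissue variants.
    """
    cfg = config or AxialLoadingConfig()
    mats = materials or MaterialSet()
    system = assemble_foot_system(model, mats, include_muscles=False)
    if mass_scale != 1.0:
        system.apply_mass_scaling(mass_scale)

    # shaft body above the tibia, vertical translation + rotation only
    tib = model.bones["tibia"]
    fib = model.bones["fibula"]
    top_t = tib.landmark_global("shaft_top")
    top_f = fib.landmark_global("shaft_top")
    shaft_pos = 0.5 * (top_t + top_f) + np.array([0.0, 0.0, 30.0])
    lx, ly, lz = cfg.rubber_block
    m_s = cfg.shaft_mass
    inertia = np.diag([m_s / 12 * (ly**2 + lz**2) + 1e4,
                       m_s / 12 * (lx**2 + lz**2) + 1e4,
                       m_s / 12 * (lx**2 + ly**2) + 1e4])
    system = _with_extra_body(system, "shaft", m_s, inertia)
    _fix_body(system, "shaft", trans_mask=(0, 0, 1), rot_mask=(0, 0, 1))

    # rubber block as four isotropic corner tethers per potted bone
    area = lx * ly
    k_axial = cfg.rubber_E * area / lz
    k_corner = k_axial / 8.0   # 4 corners x 2 bones share the axial stiffness
    i_shaft = system.index["shaft"]
    rows = []
    sp = system.springs
    existing = list(zip(sp.ia, sp.ib, sp.la, sp.lb, sp.k, sp.rest,
                        sp.tension_only, sp.damping, sp.names))
    for bone, top in (("tibia", top_t), ("fibula", top_f)):
        ib = system.index[bone]
        for cx in (-lx / 4, lx / 4):
            for cy in (-ly / 4, ly / 4):
                corner = top + np.array([cx, cy, 0.0])
                la = corner - shaft_pos
                lb = model.bones[bone].to_local(corner)
                c = 2.0 * 0.7 * np.sqrt(k_corner * min(m_s, system.mass[ib]))
                rows.append((i_shaft, ib, la, lb, k_corner, 0.0, False, c,
                             f"rubber:{bone}"))
    system.set_springs(existing + rows)

    poses = dict(system.build_pose)
    poses["shaft"] = (shaft_pos, np.eye(3))
    state = system.initial_state(poses)

    # heel-first placement: forefoot lift while only the shaft weight acts
    met_heads = [(system.index[f"metatarsal_{i}"],
                  model.bones[f"metatarsal_{i}"].landmarks["head_plantar"])
                 for i in range(1, 6)]
    lift = cfg.forefoot_lift_force

    def lift_force(t):
        return np.array([0.0, 0.0, lift])

    for i, local in met_heads:
        system.ext_point_forces.append((i, local, lift_force))
    settle_static(system, state, tolerance=5 * cfg.settle_tolerance,
                  max_steps=cfg.settle_max_steps // 2)
    system.ext_point_forces = [
        e for e in system.ext_point_forces if e[2] is not lift_force]

    results_t: dict[str, list] = {b: [] for b in AXIAL_REPORTED_BONES}
    results_r: dict[str, list] = {b: [] for b in AXIAL_REPORTED_BONES}
    audits = []
    settled = []
    ref_pos = {}
    ref_rot = {}
    loads = cfg.load_levels
    prev_load = 0.0
    for level, load in enumerate(loads):
        # quasi-static ramp from the previous level, then settle
        _ramp_shaft_load(system, state, i_shaft, prev_load, load,
                         ramp_ms=cfg.ramp_ms)
        prev_load = load
        system.ext_forces[i_shaft] = (
            lambda t, f=load: np.array([0.0, 0.0, -f]))
        res = settle_static(system, state, tolerance=cfg.settle_tolerance,
                            max_steps=cfg.settle_max_steps)
        settled.append(res.converged)
        audit: dict = {}
        from .dynamics import compute_forces

        compute_forces(system, state.copy(), 0.01, audit=audit)
        applied = load + (system.gravity_mass.sum()) * GRAVITY
        audits.append(_audit_triple(audit, applied))
        for bone in AXIAL_REPORTED_BONES:
            i = system.index[bone]
            R = _bone_rotation(state, system, bone)
            if level == 0:
                ref_pos[bone] = state.pos[i].copy()
                ref_rot[bone] = R
            results_t[bone].append(state.pos[i] - ref_pos[bone])
            rel = ref_rot[bone].T @ R
            e = euler_yxz(rel)
            results_r[bone].append(e.as_array())
    return AxialLoadingResult(
        loads=loads,
        translations={b: np.array(v) for b, v in results_t.items()},
        rotations={b: np.array(v) for b, v in results_r.items()},
        audits=audits, settled=settled,
    )


def _ramp_shaft_load(system, state, i_shaft, f_from, f_to, ramp_ms=40.0):
    """Overdamped quasi-static ramp of the shaft load between levels."""
    from .dynamics import stable_dt as _sdt

    dt = _sdt(system, safety=0.4)
    n = max(1, int(ramp_ms / dt))
    t0 = state.time
    alpha_save = system.damping_alpha
    prony_save = system.prony_time_scale
    system.damping_alpha = max(alpha_save, 0.25)
    system.prony_time_scale = 200.0
    try:
        def ramped(t):
            u = np.clip((t - t0) / ramp_ms, 0.0, 1.0)
            return np.array([0.0, 0.0, -(f_from + (f_to - f_from) * u)])

        system.ext_forces[i_shaft] = ramped
        for _ in range(n):
            step(system, state, dt)
    finally:
        system.damping_alpha = alpha_save
        system.prony_time_scale = prony_save


def _with_extra_body(system: MechanicalSystem, name, mass, inertia
                     ) -> MechanicalSystem:
    """Rebuild the system with one additional rigid body appended."""
    new = MechanicalSystem(system.body_names + [name],
                           np.concatenate([system.mass, [mass]]),
                           np.concatenate([system.inertia, inertia[None]],
                                          axis=0))
    for attr in ("springs", "columns", "cartilage", "rot_springs",
                 "pa_slips", "muscles",
                 "muscle_force_fn", "friction", "materials", "gravity_on",
                 "damping_alpha", "prony_time_scale", "build_pose"):
        setattr(new, attr, getattr(system, attr))
    n_old = system.n_bodies()
    new.gravity_mass[:n_old] = system.gravity_mass
    new.trans_mask[:n_old] = system.trans_mask
    new.rot_mask[:n_old] = system.rot_mask
    new.ext_forces = dict(system.ext_forces)
    new.ext_torques = dict(system.ext_torques)
    new.ext_point_forces = list(system.ext_point_forces)
    new.bcs = dict(system.bcs)
    return new


# ---------------------------------------------------------------------------
# Quiet standing
# ---------------------------------------------------------------------------

@dataclass
class StandingResult:
    state: SimulationState
    pressure: "object"                 # PressureMap
    cop: np.ndarray
    grf: np.ndarray                    # (3,)
    stage1_grf: np.ndarray
    audit: tuple[float, float, float]
    settled: tuple[bool, bool]


def run_quiet_standing(model: FootModel,
                       config: StandingConfig | None = None,
                       materials: MaterialSet | None = None
                       ) -> StandingResult:
    """Two-stage static standing solution (axial load, then Achilles)."""
    cfg = config or StandingConfig()
    mats = materials or MaterialSet()
    system = assemble_foot_system(model, mats, include_muscles=False)
    # balanced standing: the shank is held vertical by the rest of the
    # body; the tibia may only translate vertically
    _fix_body(system, "tibia", trans_mask=(0, 0, 1), rot_mask=(0, 0, 0))
    state = system.initial_state(dict(system.build_pose))
    i_tib = system.index["tibia"]
    weight = float(system.gravity_mass.sum()) * GRAVITY  # model weight, N

    from .dynamics import compute_forces

    # stage 1: axial force only, no tendon traction; the applied tibial
    # force is the GRF target net of the model weight it already carries
    f1 = cfg.grf_target - weight
    system.ext_forces[i_tib] = lambda t: np.array([0.0, 0.0, -f1])
    res1 = settle_static(system, state, tolerance=cfg.settle_tolerance,
                         max_steps=cfg.settle_max_steps)
    audit1: dict = {}
    compute_forces(system, state.copy(), 0.01, audit=audit1)
    stage1_grf = _grf_from_audit(audit1)

    # stage 2: tibial load raised to the full value, Achilles traction up
    f2 = cfg.tibia_load - weight
    system.ext_forces[i_tib] = lambda t: np.array([0.0, 0.0, -f2])
    i_cal = system.index["calcaneus"]
    ach_local = model.attachments["mus:TS:insertion"].local
    ach = float(cfg.achilles_load)

    def achilles(t):
        return np.array([0.0, 0.0, ach])

    system.ext_point_forces.append((i_cal, ach_local, achilles))
    res2 = settle_static(system, state, tolerance=cfg.settle_tolerance,
                         max_steps=cfg.settle_max_steps)
    audit2: dict = {}
    compute_forces(system, state.copy(), 0.01, audit=audit2)
    grf = _grf_from_audit(audit2)
    pmap = _pressure_from_audit(audit2)
    cop = center_of_pressure(audit2["column_pos"][:, :2], audit2["column_fn"])
    return StandingResult(
        state=state, pressure=pmap, cop=cop, grf=grf, stage1_grf=stage1_grf,
        audit=(float(grf[2]), float(cfg.grf_target),
               float(grf[2] - cfg.grf_target)),
        settled=(res1.converged, res2.converged),
    )


# ---------------------------------------------------------------------------
# Walking stance
# ---------------------------------------------------------------------------

def register_shank_poses(model: FootModel, gait: GaitRecord,
                         cutoff: float | None = 20.0):
    """Rigid shank poses from the three tibial markers (3-point Procrustes).

    Returns ``(times, positions, rotations)`` where the pose maps the
    build configuration of the shank to the measured marker cluster at
    each frame, minimizing the landmark--marker RMS error.
    """
    ref = np.stack([
        model.bones["tibia"].landmark_global("medial_malleolus"),
        model.bones["fibula"].landmark_global("lateral_malleolus"),
        model.bones["tibia"].landmark_global("tibial_tuberosity"),
    ])
    meas = gait.marker_array(MARKER_NAMES)   # (n, 3, 3)
    if cutoff is not None and gait.sample_rate > 2 * cutoff:
        flat = meas.reshape(meas.shape[0], -1)
        meas = lowpass_markers(flat, gait.sample_rate, cutoff=cutoff).reshape(
            meas.shape)
    ref_c = ref.mean(axis=0)
    A = ref - ref_c
    n = meas.shape[0]
    positions = np.zeros((n, 3))
    rotations = np.zeros((n, 3, 3))
    for k in range(n):
        B = meas[k] - meas[k].mean(axis=0)
        H = A.T @ B
        U, S, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        positions[k] = meas[k].mean(axis=0) - R @ ref_c
        rotations[k] = R
    return gait.time.copy(), positions, rotations


def _shank_bcs(model, system, times, positions, rotations):
    """Prescribe tibia and fibula from the registered shank transform."""
    for bone in ("tibia", "fibula"):
        i = system.index[bone]
        c0, R0 = system.build_pose[bone]
        pos = positions + np.einsum("kij,j->ki", rotations, c0)
        rot = rotations @ R0
        system.bcs[i] = BoundaryCondition(
            body=bone, times=times, positions=pos, rotations=rot)
        system.trans_mask[i] = 0.0
        system.rot_mask[i] = 0.0


def _apply_shank_transform(state, system, which, positions, rotations, k):
    """Rigidly move all bodies by the frame-k shank transform."""
    from scipy.spatial.transform import Rotation

    R = rotations[k]
    for name, i in system.index.items():
        c0, R0 = system.build_pose[name]
        state.pos[i] = positions[k] + R @ c0
        q = Rotation.from_matrix(R @ R0).as_quat()
        state.quat[i] = q[[3, 0, 1, 2]]
    state.vel[:] = 0.0
    state.omega[:] = 0.0


@dataclass
class StanceResult:
    time: np.ndarray                   # (k,) ms
    grf: np.ndarray                    # (k, 3) N
    cop: np.ndarray                    # (k, 2) mm (nan when unloaded)
    pa_tension: np.ndarray             # (k, n_slips) N
    pa_total: np.ndarray               # (k,) N
    joint_angles: dict[str, np.ndarray]   # joint -> (k, 3) deg (y, x, z)
    bone_positions: dict[str, np.ndarray]
    cone_margin: np.ndarray            # (k,) max(|Ft| - mu_s Fn), N
    min_tissue_tension: np.ndarray     # (k,) min spring/slip tension, N
    column_fn: np.ndarray              # (k, m)
    column_pos: np.ndarray             # (k, m, 3)
    audits: np.ndarray                 # (k, 3) grf_z, applied scale, residual

    @property
    def stance_fraction(self):
        t0, t1 = self.time[0], self.time[-1]
        return (self.time - t0) / (t1 - t0)


def initialize_stance(model: FootModel, gait: GaitRecord,
                      config: StanceConfig | None = None,
                      materials: MaterialSet | None = None,
                      system: MechanicalSystem | None = None):
    """Initial condition at heel contact via anchored backward integration.

    Settles the foot statically at the anchor (default 20% stance,
    tibia near vertical, foot flat), integrates the kinematically
    driven model backward in time to heel contact, and returns the
    heel-contact state with its velocity reversed, ready for the
    forward run.  Returns ``(state, system, registration)``.
    """
    cfg = config or StanceConfig()
    mats = materials or MaterialSet()
    if system is None:
        system = assemble_foot_system(model, mats)
    times, positions, rotations = register_shank_poses(
        model, gait, cutoff=cfg.lowpass_cutoff)
    t0, t1 = gait.stance_window
    t_anchor = t0 + (t1 - t0) * cfg.anchor_pct / 100.0
    k_anchor = int(np.argmin(np.abs(times - t_anchor)))

    # --- anchor settle: hold the shank at the anchor pose ---
    state = system.initial_state(dict(system.build_pose))
    _apply_shank_transform(state, system, None, positions, rotations, k_anchor)
    _reset_contact_state(state, system)
    for bone in ("tibia", "fibula"):
        _fix_body(system, bone)
        i = system.index[bone]
        system.bcs.pop(i, None)
    pct_anchor = cfg.anchor_pct
    system.muscle_force_fn = _muscle_fn_const(gait, pct_anchor)
    res = settle_static(system, state, tolerance=cfg.anchor_settle_tolerance,
                        max_steps=cfg.anchor_settle_max_steps)
    if not res.converged and res.residual > 20 * cfg.anchor_settle_tolerance:
        raise ProtocolError(
            f"anchor settle failed (residual {res.residual:.2e})")

    # --- backward integration: reversed shank trajectory to heel contact ---
    rev_times = times[k_anchor] - times[:k_anchor + 1][::-1] + times[0]
    rev_pos = positions[:k_anchor + 1][::-1]
    rev_rot = rotations[:k_anchor + 1][::-1]
    _shank_bcs(model, system, rev_times, rev_pos, rev_rot)
    system.muscle_force_fn = _muscle_fn_reversed(gait, times, k_anchor)
    state.time = rev_times[0]
    dt = stable_dt(system, safety=cfg.dt_safety)
    n_steps = int(np.ceil((rev_times[-1] - rev_times[0]) / dt))
    for _ in range(n_steps):
        step(system, state, dt)

    # --- reverse velocities for the forward initial condition ---
    state.vel = -state.vel
    state.omega = -state.omega
    state.time = times[0]
    _reset_contact_state(state, system)
    return state, system, (times, positions, rotations)


def _reset_contact_state(state, system):
    """Re-seat friction anchors and viscous history at the current pose."""
    state.prony_r[:] = 0.0
    state.prony_sigma[:] = 0.0
    if system.columns is not None:
        R = state.rotations()
        co = system.columns
        world = (state.pos[co.body]
                 + np.einsum("mij,mj->mi", R[co.body], co.local))
        state.stick_anchors = world[:, :2].copy()


def _muscle_fn_const(gait: GaitRecord, pct: float):
    def fn(t, name):
        frac = np.clip(pct / 100.0, 0.0, 1.0)
        prof = gait.muscles[name]
        return float(np.interp(frac, gait.stance_fraction, prof))
    return fn


def _muscle_fn_reversed(gait: GaitRecord, times, k_anchor):
    t_anchor = times[k_anchor]
    t_start = times[0]

    def fn(t, name):
        # backward clock: simulation time t maps to anchor-time - t
        t_orig = t_anchor - (t - t_start)
        frac = np.clip((t_orig - times[0]) / (times[-1] - times[0]), 0.0, 1.0)
        return float(np.interp(frac, gait.stance_fraction,
                               gait.muscles[name]))
    return fn


def _muscle_fn_forward(gait: GaitRecord):
    def fn(t, name):
        frac = np.clip((t - gait.time[0]) / (gait.time[-1] - gait.time[0]),
                       0.0, 1.0)
        return float(np.interp(frac, gait.stance_fraction,
                               gait.muscles[name]))
    return fn


def run_stance(model: FootModel, gait: GaitRecord,
               init: tuple | None = None,
               config: StanceConfig | None = None,
               materials: MaterialSet | None = None) -> StanceResult:
    """Muscle-driven stance simulation with kinematic shank driving."""
    cfg = config or StanceConfig()
    mats = materials or MaterialSet()
    if init is None:
        init = initialize_stance(model, gait, cfg, mats)
    state, system, (times, positions, rotations) = init
    _shank_bcs(model, system, times, positions, rotations)
    system.muscle_force_fn = _muscle_fn_forward(gait)
    # light ambient damping: unmodelled fat/retinacula dissipation
    system.damping_alpha = 0.01

    dt = stable_dt(system, safety=cfg.dt_safety)
    t_end = times[-1]
    stride = max(1, int(round(cfg.output_stride_ms / dt)))
    mu_s = system.friction.mu_static

    rec = {k: [] for k in ("time", "grf", "cop", "pa", "cone", "min_t",
                           "col_fn", "col_pos", "audit")}
    poses_rec: dict[str, list] = {b: [] for b, *_ in _recorded_bones()}
    rots_rec: dict[str, list] = {b: [] for b, *_ in _recorded_bones()}

    k = 0
    while state.time < t_end - 1e-9:
        audit: dict = {}
        step(system, state, min(dt, t_end - state.time), audit=audit)
        if k % stride == 0 or state.time >= t_end - 1e-9:
            grf = _grf_from_audit(audit)
            fn = audit["column_fn"]
            ft = np.linalg.norm(audit["column_ft"], axis=1)
            cone = float((ft - mu_s * fn).max()) if len(fn) else 0.0
            tensions = audit.get("spring_tension")
            min_t = float(np.nanmin(tensions)) if tensions is not None else 0.0
            min_t = min(min_t, float(audit.get("pa_tension", [0.0]).min()))
            loaded = fn.sum() > 1.0
            cop = (center_of_pressure(audit["column_pos"][:, :2], fn)
                   if loaded else np.array([np.nan, np.nan]))
            rec["time"].append(state.time)
            rec["grf"].append(grf)
            rec["cop"].append(cop)
            rec["pa"].append(audit.get("pa_tension",
                                       np.zeros(len(system.pa_slips))))
            rec["cone"].append(cone)
            rec["min_t"].append(min_t)
            rec["col_fn"].append(fn.copy())
            rec["col_pos"].append(audit["column_pos"].copy())
            rec["audit"].append([grf[2], fn.sum(), grf[2] - fn.sum()])
            for b, *_ in _recorded_bones():
                i = system.index[b]
                poses_rec[b].append(state.pos[i].copy())
                rots_rec[b].append(_bone_rotation(state, system, b))
        k += 1

    time_arr = np.array(rec["time"])
    pa = np.array(rec["pa"])
    angles = {}
    for joint, prox, dist in REPORTED_JOINTS:
        Rp0 = dict(system.build_pose)[prox][1]
        Rd0 = dict(system.build_pose)[dist][1]
        rel0 = Rp0.T @ Rd0
        seq = []
        for Rp, Rd in zip(rots_rec[prox], rots_rec[dist]):
            rel = Rp.T @ Rd
            seq.append(euler_yxz(rel0.T @ rel).as_array())
        angles[joint] = np.array(seq)
    return StanceResult(
        time=time_arr,
        grf=np.array(rec["grf"]),
        cop=np.array(rec["cop"]),
        pa_tension=pa,
        pa_total=pa.sum(axis=1),
        joint_angles=angles,
        bone_positions={b: np.array(v) for b, v in poses_rec.items()},
        cone_margin=np.array(rec["cone"]),
        min_tissue_tension=np.array(rec["min_t"]),
        column_fn=np.array(rec["col_fn"]),
        column_pos=np.array(rec["col_pos"]),
        audits=np.array(rec["audit"]),
    )


def _recorded_bones():
    seen = set()
    out = []
    for joint, prox, dist in REPORTED_JOINTS:
        for b in (prox, dist):
            if b not in seen:
                seen.add(b)
                out.append((b,))
    out.append(("calcaneus",)) if "calcaneus" not in seen else None
    return out
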