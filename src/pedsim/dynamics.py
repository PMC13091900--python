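"""Explicit forward dynamics of the rigid-bone foot system.

The solver advances all rigid bodies with a semi-implicit (symplectic)
Euler scheme: velocities are updated from the current forces, then
positions from the new velocities; orientations integrate body-frame
angular velocity through an incremental quaternion rotation with the
gyroscopic term retained.  The scheme is conditionally stable; the
step defaults to ``min(1 ms, stable_dt())`` where the stability bound
comes from the stiffest spring/penalty element against its lighter
endpoint mass.

Force elements (all vectorized over numpy arrays):

* point-to-point springs — ligament chains and capsule tethers
  (tension-only or bidirectional, with a small axial dashpot that is
  clipped so tension-only elements can never push),
* plantar soft-tissue columns — uniaxial Ogden/Prony elements in
  series with floor contact, carrying the Coulomb friction state,
* cartilage sphere-proxy penalty contacts (frictionless),
* plantar aponeurosis slips with metatarsal-head cylinder wrapping,
* muscle polylines with prescribed time-varying force magnitudes,
* gravity, constant external wrenches, and prescribed-trajectory
  boundary conditions (kinematic driving) with per-axis DOF masks.

Static solutions use dynamic relaxation: mass-proportional damping
plus kinetic-energy resets until the peak residual acceleration drops
below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .contact import FrictionParams, coulomb_tangential
from .materials import MaterialSet, ogden_uniaxial_stress, ogden_uniaxial_tangent
from .units import GRAVITY

__all__ = [
    "SimulationState",
    "BoundaryCondition",
    "MechanicalSystem",
    "IntegrationError",
    "assemble_foot_system",
    "step",
    "stable_dt",
    "settle_static",
]


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Generalized state of all rigid bodies plus element internal state.

    Orientations are unit quaternions (w, x, y, z); angular velocities
    are body-frame (rad/ms).  ``prony_r``/``prony_sigma`` are the
    recursive-convolution variables of the soft-tissue columns;
    ``stick_anchors`` the tangential friction anchors.
    """

    pos: np.ndarray               # (n, 3) mm
    quat: np.ndarray              # (n, 4) wxyz
    vel: np.ndarray               # (n, 3) mm/ms
    omega: np.ndarray             # (n, 3) rad/ms, body frame
    time: float = 0.0
    prony_r: np.ndarray | None = None       # (2, m_cols)
    prony_sigma: np.ndarray | None = None   # (m_cols,)
    stick_anchors: np.ndarray | None = None  # (m_cols, 2)

    def copy(self) -> "SimulationState":
        return SimulationState(
            pos=self.pos.copy(), quat=self.quat.copy(), vel=self.vel.copy(),
            omega=self.omega.copy(), time=self.time,
            prony_r=None if self.prony_r is None else self.prony_r.copy(),
            prony_sigma=(None if self.prony_sigma is None
                         else self.prony_sigma.copy()),
            stick_anchors=(None if self.stick_anchors is None
                           else self.stick_anchors.copy()),
        )

    def rotations(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices (local -> global)."""
        return Rotation.from_quat(self.quat[:, [1, 2, 3, 0]]).as_matrix()


@dataclass
class BoundaryCondition:
    """Kinematic driving of one body.

    Either a sampled trajectory (uniform time grid, positions and
    rotations; velocities by finite difference/slerp) or a constant
    pose.  ``trans_mask``/``rot_mask`` free individual axes instead
    (1 = free); a fully prescribed body has zero masks and a
    trajectory.
    """

    body: str
    times: np.ndarray | None = None          # (k,) ms, uniform
    positions: np.ndarray | None = None      # (k, 3)
    rotations: np.ndarray | None = None      # (k, 3, 3)
    trans_mask: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot_mask: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.times is not None:
            t = np.asarray(self.times, float)
            if t.size > 1:
                dt = np.diff(t)
                if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                    raise ValueError(
                        f"BC for {self.body}: trajectory grid must be uniform")
            self.times = t
            if self.rotations is not None:
                self._slerp = Slerp(t, Rotation.from_matrix(self.rotations))
            else:
                self._slerp = None

    def pose_at(self, t: float):
        t = float(np.clip(t, self.times[0], self.times[-1]))
        pos = np.array([np.interp(t, self.times, self.positions[:, j])
                        for j in range(3)])
        if self._slerp is not None:
            R = self._slerp(t).as_matrix()
        else:
            R = np.eye(3)
        return pos, R

    def velocity_at(self, t: float, h: float = 1.0):
        t0 = float(np.clip(t - h / 2, self.times[0], self.times[-1]))
        t1 = float(np.clip(t + h / 2, self.times[0], self.times[-1]))
        if t1 <= t0:
            return np.zeros(3), np.zeros(3)
        p0, R0 = self.pose_at(t0)
        p1, R1 = self.pose_at(t1)
        v = (p1 - p0) / (t1 - t0)
        dR = R1 @ R0.T
        w = Rotation.from_matrix(dR).as_rotvec() / (t1 - t0)  # world frame
        return v, w


# ---------------------------------------------------------------------------
# System
# ---------------------------------------------------------------------------

@dataclass
class _Springs:
    ia: np.ndarray
    ib: np.ndarray
    la: np.ndarray            # (m, 3) local anchors
    lb: np.ndarray
    k: np.ndarray             # N/mm
    rest: np.ndarray          # mm (slack for tension-only)
    tension_only: np.ndarray  # bool
    damping: np.ndarray       # N per mm/ms (axial)
    names: list


@dataclass
class _Columns:
    body: np.ndarray          # (m,)
    local: np.ndarray         # (m, 3)
    ref_thickness: np.ndarray
    area: np.ndarray
    names: list


@dataclass
class _RotSprings:
    ia: np.ndarray
    ib: np.ndarray
    rel0: np.ndarray          # (m, 3, 3) reference relative rotation Ra^T Rb
    k: np.ndarray             # N*mm/rad
    damping: np.ndarray       # N*mm per rad/ms
    names: list


@dataclass
class _Cartilage:
    ia: np.ndarray
    ib: np.ndarray
    ca: np.ndarray            # (m, 3) sphere centres, local
    cb: np.ndarray
    ra: np.ndarray
    rb: np.ndarray
    penalty: np.ndarray
    damping: np.ndarray
    names: list


class MechanicalSystem:
    """Rigid bodies plus force elements; the integrator's working set."""

    def apply_mass_scaling(self, factor: float):
        """Scale inertial mass (not weight) by ``factor``.

        Static solutions are unchanged — only the explicit stability
        bound improves; dynamic trajectories are *not* physical under
        scaling.  Standard device for quasi-static explicit analyses
        with artificially stiff elements.
        """
        self.mass = self.mass * factor
        self.inertia = self.inertia * factor
        self.inv_inertia = np.linalg.inv(self.inertia)

    def __init__(self, body_names, masses, inertias):
        self.body_names = list(body_names)
        self.index = {n: i for i, n in enumerate(self.body_names)}
        self.mass = np.asarray(masses, float)
        #: mass used for gravity loads; static mass scaling changes the
        #: inertial mass only (equilibrium is unaffected by inertia)
        self.gravity_mass = self.mass.copy()
        self.inertia = np.asarray(inertias, float)       # (n, 3, 3) local
        self.inv_inertia = np.linalg.inv(self.inertia)
        n = len(self.body_names)
        self.springs: _Springs | None = None
        self.columns: _Columns | None = None
        self.cartilage: _Cartilage | None = None
        self.rot_springs: _RotSprings | None = None
        self.pa_slips = []            # list[AponeurosisSlip]
        self.muscles = {}             # name -> MusclePath
        self.muscle_force_fn: Callable[[float, str], float] | None = None
        self.friction = FrictionParams()
        self.materials = MaterialSet()
        self.gravity_on = True
        self.ext_forces: dict[int, Callable[[float], np.ndarray]] = {}
        self.ext_torques: dict[int, Callable[[float], np.ndarray]] = {}
        #: (body index, local point, force_fn(t)->(3,)) applied at a
        #: material point (moment arm included)
        self.ext_point_forces: list[tuple] = []
        self.bcs: dict[int, BoundaryCondition] = {}
        self.trans_mask = np.ones((n, 3))
        self.rot_mask = np.ones((n, 3))
        self.damping_alpha = 0.0      # 1/ms, mass-proportional
        #: multiplies dt in the Prony update; settle_static accelerates
        #: viscous time so statics converge to the relaxed modulus
        self.prony_time_scale = 1.0
        #: set by assemble_foot_system: map body name -> build pose
        self.build_pose: dict[str, tuple] = {}

    # -- construction helpers -----------------------------------------
    def n_bodies(self) -> int:
        return len(self.body_names)

    def set_springs(self, rows):
        if not rows:
            return
        self.springs = _Springs(
            ia=np.array([r[0] for r in rows], int),
            ib=np.array([r[1] for r in rows], int),
            la=np.array([r[2] for r in rows], float),
            lb=np.array([r[3] for r in rows], float),
            k=np.array([r[4] for r in rows], float),
            rest=np.array([r[5] for r in rows], float),
            tension_only=np.array([r[6] for r in rows], bool),
            damping=np.array([r[7] for r in rows], float),
            names=[r[8] for r in rows],
        )

    def set_columns(self, rows):
        if not rows:
            return
        self.columns = _Columns(
            body=np.array([r[0] for r in rows], int),
            local=np.array([r[1] for r in rows], float),
            ref_thickness=np.array([r[2] for r in rows], float),
            area=np.array([r[3] for r in rows], float),
            names=[r[4] for r in rows],
        )

    def set_cartilage(self, rows):
        if not rows:
            return
        self.cartilage = _Cartilage(
            ia=np.array([r[0] for r in rows], int),
            ib=np.array([r[1] for r in rows], int),
            ca=np.array([r[2] for r in rows], float),
            cb=np.array([r[3] for r in rows], float),
            ra=np.array([r[4] for r in rows], float),
            rb=np.array([r[5] for r in rows], float),
            penalty=np.array([r[6] for r in rows], float),
            damping=np.array([r[7] for r in rows], float),
            names=[r[8] for r in rows],
        )

    def set_rot_springs(self, rows):
        if not rows:
            return
        self.rot_springs = _RotSprings(
            ia=np.array([r[0] for r in rows], int),
            ib=np.array([r[1] for r in rows], int),
            rel0=np.array([r[2] for r in rows], float),
            k=np.array([r[3] for r in rows], float),
            damping=np.array([r[4] for r in rows], float),
            names=[r[5] for r in rows],
        )

    def initial_state(self, poses: dict[str, tuple]) -> SimulationState:
        n = self.n_bodies()
        pos = np.zeros((n, 3))
        quat = np.zeros((n, 4))
        quat[:, 0] = 1.0
        for name, (p, R) in poses.items():
            i = self.index[name]
            pos[i] = p
            q = Rotation.from_matrix(R).as_quat()  # xyzw
            quat[i] = q[[3, 0, 1, 2]]
        m_cols = 0 if self.columns is None else len(self.columns.body)
        anchors = np.zeros((m_cols, 2))
        if m_cols:
            R = Rotation.from_quat(quat[:, [1, 2, 3, 0]]).as_matrix()
            world = (pos[self.columns.body]
                     + np.einsum("nij,nj->ni", R[self.columns.body],
                                 self.columns.local))
            anchors = world[:, :2].copy()
        return SimulationState(
            pos=pos, quat=quat, vel=np.zeros((n, 3)), omega=np.zeros((n, 3)),
            time=0.0,
            prony_r=np.zeros((2, m_cols)), prony_sigma=np.zeros(m_cols),
            stick_anchors=anchors,
        )


# ---------------------------------------------------------------------------
# Force evaluation
# ---------------------------------------------------------------------------

def _cross(a, b):
    """Row-wise cross product without numpy's axis bookkeeping overhead."""
    return np.stack([
        a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
        a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
        a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
    ], axis=-1)


def _quat_to_mats(quat):
    return Rotation.from_quat(quat[:, [1, 2, 3, 0]]).as_matrix()


def compute_forces(system: MechanicalSystem, state: SimulationState,
                   dt: float, audit: dict | None = None):
    """Accumulate world-frame forces and torques on every body.

    Mutates the element internal state held in ``state`` (Prony
    variables, friction anchors) as a side effect of the step.
    Returns ``(F, T)`` of shape (n, 3).
    """
    n = system.n_bodies()
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    R = _quat_to_mats(state.quat)
    omega_world = np.einsum("nij,nj->ni", R, state.omega)

    def apply(i, force, point):
        F[i] += force
        T[i] += _cross(point - state.pos[i], force)

    # springs --------------------------------------------------------
    sp = system.springs
    if sp is not None:
        pa = state.pos[sp.ia] + np.einsum("mij,mj->mi", R[sp.ia], sp.la)
        pb = state.pos[sp.ib] + np.einsum("mij,mj->mi", R[sp.ib], sp.lb)
        d = pb - pa
        L = np.linalg.norm(d, axis=1)
        L = np.maximum(L, 1e-9)
        u = d / L[:, None]
        va = state.vel[sp.ia] + _cross(omega_world[sp.ia], pa - state.pos[sp.ia])
        vb = state.vel[sp.ib] + _cross(omega_world[sp.ib], pb - state.pos[sp.ib])
        ldot = np.einsum("mi,mi->m", vb - va, u)
        elong = L - sp.rest
        fmag = sp.k * elong + sp.damping * ldot
        # tension-only elements can never push; bidirectional keep sign
        fmag = np.where(sp.tension_only,
                        np.where(elong > 0.0, np.maximum(fmag, 0.0), 0.0),
                        fmag)
        fvec = fmag[:, None] * u   # force on A towards B
        np.add.at(F, sp.ia, fvec)
        np.add.at(F, sp.ib, -fvec)
        np.add.at(T, sp.ia, _cross(pa - state.pos[sp.ia], fvec))
        np.add.at(T, sp.ib, _cross(pb - state.pos[sp.ib], -fvec))
        if audit is not None:
            audit["spring_tension"] = np.where(sp.tension_only, fmag, np.nan)
            audit["spring_length"] = L

    # plantar columns + floor friction -------------------------------
    co = system.columns
    if co is not None:
        pw = state.pos[co.body] + np.einsum("mij,mj->mi", R[co.body], co.local)
        vw = (state.vel[co.body]
              + _cross(omega_world[co.body], pw - state.pos[co.body]))
        h = pw[:, 2]
        lam = np.clip(h / co.ref_thickness, 1e-3, 1.0)
        # Ogden elastic stress (compression-positive), Prony update
        sigma_e = ogden_uniaxial_stress(lam, system.materials.soft_tissue_ogden)
        pr = system.materials.soft_tissue_prony
        taus = np.array([pr.tau1, pr.tau2])
        hh = dt * system.prony_time_scale / taus
        decay = np.exp(-hh)
        slope = -np.expm1(-hh) / hh
        d_sigma = sigma_e - state.prony_sigma
        state.prony_r = (decay[:, None] * state.prony_r
                         + slope[:, None] * d_sigma[None, :])
        state.prony_sigma = sigma_e
        sigma = (pr.g_inf * sigma_e
                 + pr.g1 * state.prony_r[0] + pr.g2 * state.prony_r[1])
        fn = np.maximum(sigma, 0.0) * co.area
        # small vertical contact damping scaled to the column stiffness
        ktan = np.abs(ogden_uniaxial_tangent(lam, system.materials
                                             .soft_tissue_ogden))
        kz = ktan * co.area / co.ref_thickness
        cz = 0.4 * np.sqrt(kz * system.mass[co.body])
        fn = np.where(fn > 0.0, np.maximum(fn - cz * vw[:, 2], 0.0), 0.0)
        ft, anchors, modes = coulomb_tangential(
            pw[:, :2], vw[:, :2], state.stick_anchors, fn, system.friction)
        state.stick_anchors = anchors
        fvec = np.concatenate([ft, fn[:, None]], axis=1)
        np.add.at(F, co.body, fvec)
        np.add.at(T, co.body, _cross(pw - state.pos[co.body], fvec))
        if audit is not None:
            audit["column_fn"] = fn
            audit["column_ft"] = ft
            audit["column_pos"] = pw
            audit["column_modes"] = modes
            audit["grf"] = fvec.sum(axis=0)

    # cartilage ------------------------------------------------------
    ca = system.cartilage
    if ca is not None:
        A = state.pos[ca.ia] + np.einsum("mij,mj->mi", R[ca.ia], ca.ca)
        B = state.pos[ca.ib] + np.einsum("mij,mj->mi", R[ca.ib], ca.cb)
        d = A - B
        dist = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
        nvec = d / dist[:, None]
        overlap = (ca.ra + ca.rb) - dist
        active = overlap > 0.0
        vA = state.vel[ca.ia] + _cross(omega_world[ca.ia], A - state.pos[ca.ia])
        vB = state.vel[ca.ib] + _cross(omega_world[ca.ib], B - state.pos[ca.ib])
        vn = np.einsum("mi,mi->m", vA - vB, nvec)
        fmag = np.where(active,
                        np.maximum(ca.penalty * overlap - ca.damping * vn, 0.0),
                        0.0)
        cp = B + nvec * (ca.rb - overlap / 2.0)[:, None]
        fvec = fmag[:, None] * nvec
        np.add.at(F, ca.ia, fvec)
        np.add.at(F, ca.ib, -fvec)
        np.add.at(T, ca.ia, _cross(cp - state.pos[ca.ia], fvec))
        np.add.at(T, ca.ib, _cross(cp - state.pos[ca.ib], -fvec))
        if audit is not None:
            audit["cartilage_force"] = fmag

    # torsional capsule springs ---------------------------------------
    rs = system.rot_springs
    if rs is not None:
        Ra = R[rs.ia]
        Rb = R[rs.ib]
        R_err = np.einsum("mji,mjk->mik",
                          np.einsum("mij,mjk->mik", Ra, rs.rel0), Rb)
        phi = Rotation.from_matrix(R_err).as_rotvec()       # ~b-frame
        tau_world = -np.einsum("mij,mj->mi", Rb, rs.k[:, None] * phi)
        w_rel = omega_world[rs.ib] - omega_world[rs.ia]
        tau_world -= rs.damping[:, None] * w_rel
        np.add.at(T, rs.ib, tau_world)
        np.add.at(T, rs.ia, -tau_world)

    # plantar aponeurosis slips (vectorized cylinder wrap) -----------
    if system.pa_slips:
        pa_t = _pa_forces(system, state, R, F, T)
        if audit is not None:
            audit["pa_tension"] = pa_t

    # muscles ----------------------------------------------------------
    if system.muscles and system.muscle_force_fn is not None:
        for name, path in system.muscles.items():
            fmag = system.muscle_force_fn(state.time, name)
            if fmag <= 0.0:
                continue
            pts = []
            for bone, local in path.points:
                i = system.index[bone]
                pts.append((i, state.pos[i] + R[i] @ np.asarray(local)))
            for j, (i, p) in enumerate(pts):
                f = np.zeros(3)
                if j + 1 < len(pts):
                    d = pts[j + 1][1] - p
                    f += fmag * d / np.linalg.norm(d)
                if j > 0:
                    d = pts[j - 1][1] - p
                    f += fmag * d / np.linalg.norm(d)
                apply(i, f, p)

    # gravity / external ----------------------------------------------
    if system.gravity_on:
        F[:, 2] -= system.gravity_mass * GRAVITY
    for i, fn_ext in system.ext_forces.items():
        F[i] += fn_ext(state.time)
    for i, tq in system.ext_torques.items():
        T[i] += tq(state.time)
    for i, local, fn_ext in system.ext_point_forces:
        f = fn_ext(state.time)
        p = state.pos[i] + R[i] @ np.asarray(local)
        F[i] += f
        T[i] += np.cross(p - state.pos[i], f)
    return F, T


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def step(system: MechanicalSystem, state: SimulationState, dt: float,
         audit: dict | None = None) -> SimulationState:
    """Advance the system one explicit step of length ``dt`` (ms).

    Prescribed bodies follow their trajectories exactly at sample
    times; free DOFs advance under the net force/torque; the state is
    mutated in place and returned.  NaN or runaway coordinates raise
    :class:`IntegrationError` naming the first offending body.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    F, T = compute_forces(system, state, dt, audit=audit)
    R = _quat_to_mats(state.quat)
    inv_m = 1.0 / system.mass
    acc = F * inv_m[:, None]
    damp = 1.0 / (1.0 + system.damping_alpha * dt)
    state.vel = (state.vel + dt * acc) * damp * system.trans_mask
    # rotational: body-frame Euler equations with gyroscopic term
    tau_body = np.einsum("nji,nj->ni", R, T)  # R^T T
    Iw = np.einsum("nij,nj->ni", system.inertia, state.omega)
    gyro = np.cross(state.omega, Iw)
    dom = np.einsum("nij,nj->ni", system.inv_inertia, tau_body - gyro)
    state.omega = (state.omega + dt * dom) * damp
    # world-frame rotational DOF masks (only for partially constrained bodies)
    masked = np.where(~np.all(system.rot_mask == 1.0, axis=1))[0]
    for i in masked:
        w_world = R[i] @ state.omega[i]
        state.omega[i] = R[i].T @ (w_world * system.rot_mask[i])
    state.pos = state.pos + dt * state.vel
    # quaternion increment from body-frame omega
    ang = state.omega * dt
    state.quat = _quat_multiply(state.quat, _small_rotation_quat(ang))
    state.quat /= np.linalg.norm(state.quat, axis=1, keepdims=True)
    state.time += dt
    # prescribed bodies override
    for i, bc in system.bcs.items():
        if bc.times is not None:
            p, Rm = bc.pose_at(state.time)
            v, w = bc.velocity_at(state.time, h=max(dt, 1.0))
            state.pos[i] = p
            q = Rotation.from_matrix(Rm).as_quat()
            state.quat[i] = q[[3, 0, 1, 2]]
            state.vel[i] = v
            state.omega[i] = Rm.T @ w
    bad = ~np.isfinite(state.pos).all(axis=1) | (
        np.abs(state.pos).max(axis=1) > 1e7)
    if bad.any():
        name = system.body_names[int(np.argmax(bad))]
        raise IntegrationError(
            f"integration diverged at t={state.time:.3f} ms (body {name})")
    return state


def _pa_arrays(system):
    """Cache the aponeurosis slip data as flat arrays."""
    wrap = [sl for sl in system.pa_slips if not sl.via_sesamoid]
    ses = [sl for sl in system.pa_slips if sl.via_sesamoid]
    arr = {
        "w_io": np.array([system.index[sl.origin_bone] for sl in wrap], int),
        "w_ii": np.array([system.index[sl.insertion_bone] for sl in wrap], int),
        "w_iw": np.array([system.index[sl.wrap_bone] for sl in wrap], int),
        "w_ol": np.array([sl.origin_local for sl in wrap]),
        "w_il": np.array([sl.insertion_local for sl in wrap]),
        "w_cl": np.array([sl.wrap_center_local for sl in wrap]),
        "w_al": np.array([sl.wrap_axis_local for sl in wrap]),
        "w_r": np.array([sl.wrap_radius for sl in wrap]),
        "w_side": np.array([sl.wrap_side for sl in wrap]),
        "w_k": np.array([sl.stiffness for sl in wrap]),
        "w_slack": np.array([sl.slack_length for sl in wrap]),
        "w_pos": [si for si, sl in enumerate(system.pa_slips)
                  if not sl.via_sesamoid],
        "ses": ses,
        "ses_pos": [si for si, sl in enumerate(system.pa_slips)
                    if sl.via_sesamoid],
    }
    return arr


def _pa_forces(system, state, R, F, T):
    """Vectorized aponeurosis slip forces; returns per-slip tensions."""
    if not hasattr(system, "_pa_cache"):
        system._pa_cache = _pa_arrays(system)
    c = system._pa_cache
    tensions = np.zeros(len(system.pa_slips))

    if len(c["w_r"]):
        io, ii, iw = c["w_io"], c["w_ii"], c["w_iw"]
        o = state.pos[io] + np.einsum("mij,mj->mi", R[io], c["w_ol"])
        q = state.pos[ii] + np.einsum("mij,mj->mi", R[ii], c["w_il"])
        cen = state.pos[iw] + np.einsum("mij,mj->mi", R[iw], c["w_cl"])
        ax = np.einsum("mij,mj->mi", R[iw], c["w_al"])
        r = c["w_r"]
        L, dir_o, dir_q, wrapped = _cylinder_wrap_vec(o, q, cen, ax, r,
                                                       side=c["w_side"])
        elong = L - c["w_slack"]
        tens = np.where(elong > 0.0, c["w_k"] * elong, 0.0)
        for pos_idx, m in zip(c["w_pos"], range(len(r))):
            tensions[pos_idx] = tens[m]
        act = tens > 0.0
        if act.any():
            fo = tens[:, None] * dir_o
            fi = tens[:, None] * dir_q
            fo[~act] = 0.0
            fi[~act] = 0.0
            np.add.at(F, io, fo)
            np.add.at(F, ii, fi)
            np.add.at(T, io, _cross(o - state.pos[io], fo))
            np.add.at(T, ii, _cross(q - state.pos[ii], fi))
            fw = -(fo + fi)
            fw[~wrapped] = 0.0
            np.add.at(F, iw, fw)
            np.add.at(T, iw, _cross(cen - state.pos[iw], fw))

    for slip, pos_idx in zip(c["ses"], c["ses_pos"]):
        io = system.index[slip.origin_bone]
        ii = system.index[slip.insertion_bone]
        iv = system.index[slip.via_bone]
        o = state.pos[io] + R[io] @ slip.origin_local
        q = state.pos[ii] + R[ii] @ slip.insertion_local
        v = state.pos[iv] + R[iv] @ slip.via_local
        d1 = v - o
        d2 = q - v
        l1 = np.linalg.norm(d1)
        l2 = np.linalg.norm(d2)
        elong = l1 + l2 - slip.slack_length
        if elong <= 0.0:
            continue
        tension = slip.stiffness * elong
        tensions[pos_idx] = tension
        u1, u2 = d1 / l1, d2 / l2
        for i, f, p in ((io, tension * u1, o), (ii, -tension * u2, q),
                        (iv, tension * (u2 - u1), v)):
            F[i] += f
            T[i] += _cross(p - state.pos[i], f)
    return tensions


def _cylinder_wrap_vec(p, q, center, axis, radius, side=None):
    """Vectorized tangent-arc-tangent wrap (see tissues.cylinder_wrap_length)."""
    m = p.shape[0]
    tmp = np.tile(np.array([1.0, 0.0, 0.0]), (m, 1))
    swap = np.abs((tmp * axis).sum(axis=1)) > 0.9
    tmp[swap] = np.array([0.0, 0.0, 1.0])
    e1 = _cross(tmp, axis)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = _cross(axis, e1)
    relp = p - center
    relq = q - center
    P2 = np.stack([(relp * e1).sum(axis=1), (relp * e2).sum(axis=1)], axis=1)
    Q2 = np.stack([(relq * e1).sum(axis=1), (relq * e2).sum(axis=1)], axis=1)
    pz = (relp * axis).sum(axis=1)
    qz = (relq * axis).sum(axis=1)
    rp = np.linalg.norm(P2, axis=1)
    rq = np.linalg.norm(Q2, axis=1)
    d2 = Q2 - P2
    denom = (d2 * d2).sum(axis=1)
    t = -np.where(denom > 0, (P2 * d2).sum(axis=1) / np.maximum(denom, 1e-12),
                  0.0)
    closest = P2 + t[:, None] * d2
    hits = ((t > 0) & (t < 1)
            & (np.linalg.norm(closest, axis=1) < radius))
    beta_p = np.arccos(np.clip(radius / rp, -1.0, 1.0))
    beta_q = np.arccos(np.clip(radius / rq, -1.0, 1.0))
    tp = np.sqrt(np.maximum(rp * rp - radius * radius, 0.0))
    tq = np.sqrt(np.maximum(rq * rq - radius * radius, 0.0))
    th_p = np.arctan2(P2[:, 1], P2[:, 0])
    th_q = np.arctan2(Q2[:, 1], Q2[:, 0])
    twopi = 2.0 * np.pi
    best_tot = None
    for sgn in (1.0, -1.0):
        ang_tp = th_p + sgn * beta_p
        ang_tq = th_q - sgn * beta_q
        arc = (sgn * (ang_tq - ang_tp)) % twopi
        tot = tp + radius * arc + tq
        if best_tot is None:
            best_tot, best = tot, (ang_tp, ang_tq, arc, np.full(m, sgn))
        else:
            better = tot < best_tot
            best_tot = np.where(better, tot, best_tot)
            best = tuple(np.where(better, new, old)
                         for new, old in zip((ang_tp, ang_tq, arc,
                                              np.full(m, sgn)), best))
    ang_tp, ang_tq, arc, sgn = best
    if side is None:
        side = np.zeros(m)
    else:
        side = np.asarray(side, float)
    sided = side != 0
    if sided.any():
        s_ang_tp = th_p + side * beta_p
        s_ang_tq = th_q - side * beta_q
        s_arc = (side * (s_ang_tq - s_ang_tp)) % twopi
        s_tot = tp + radius * s_arc + tq
        ang_tp = np.where(sided, s_ang_tp, ang_tp)
        ang_tq = np.where(sided, s_ang_tq, ang_tq)
        arc = np.where(sided, s_arc, arc)
        best_tot = np.where(sided, s_tot, best_tot)
    clears = np.where(sided, arc >= np.pi, ~hits)
    dz = qz - pz
    L_wrap = np.hypot(best_tot, dz)
    z_tp = pz + dz * tp / best_tot
    z_tq = pz + dz * (tp + radius * arc) / best_tot
    Tp3 = (center + radius[:, None] * (np.cos(ang_tp)[:, None] * e1
                                       + np.sin(ang_tp)[:, None] * e2)
           + z_tp[:, None] * axis)
    Tq3 = (center + radius[:, None] * (np.cos(ang_tq)[:, None] * e1
                                       + np.sin(ang_tq)[:, None] * e2)
           + z_tq[:, None] * axis)
    dir_p_w = Tp3 - p
    dir_p_w /= np.linalg.norm(dir_p_w, axis=1, keepdims=True)
    dir_q_w = Tq3 - q
    dir_q_w /= np.linalg.norm(dir_q_w, axis=1, keepdims=True)
    straight = q - p
    L_str = np.linalg.norm(straight, axis=1)
    u = straight / np.maximum(L_str, 1e-12)[:, None]
    L = np.where(clears, L_str, L_wrap)
    dir_p = np.where(clears[:, None], u, dir_p_w)
    dir_q = np.where(clears[:, None], -u, dir_q_w)
    return L, dir_p, dir_q, ~clears


def _quat_multiply(q1, q2):
    w1, x1, y1, z1 = q1[:, 0], q1[:, 1], q1[:, 2], q1[:, 3]
    w2, x2, y2, z2 = q2[:, 0], q2[:, 1], q2[:, 2], q2[:, 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=1)


def _small_rotation_quat(ang):
    """Quaternion of a rotation vector (exact exponential map)."""
    theta = np.linalg.norm(ang, axis=1)
    half = theta / 2.0
    w = np.cos(half)
    s = np.where(theta > 1e-12, np.sin(half) / np.maximum(theta, 1e-300), 0.5)
    return np.concatenate([w[:, None], ang * s[:, None]], axis=1)


def stable_dt(system: MechanicalSystem, safety: float = 0.5,
              cap: float = 1.0) -> float:
    """Explicit stability bound: ``safety * min(2/omega)`` over elements.

    ``omega`` is sqrt(k/m) with the lighter endpoint mass of each
    spring/penalty element; soft-tissue columns use the Ogden tangent
    stiffness at 50% compression (their practical operating point
    under body weight).  The result is capped (default 1 ms).
    """
    i_min = np.array([np.linalg.eigvalsh(I).min() for I in system.inertia])
    # per-body assembled stiffness (Gershgorin-style nodal sum): every
    # element contributes its receptance-weighted stiffness to both
    # endpoint bodies; the bound is the stiffest assembled body
    w2sum = np.zeros(system.n_bodies())

    def add(k, i, local):
        r2 = (np.asarray(local, float) ** 2).sum(axis=-1)
        np.add.at(w2sum, i, k * (1.0 / system.mass[i] + r2 / i_min[i]))

    sp = system.springs
    if sp is not None:
        add(sp.k, sp.ia, sp.la)
        add(sp.k, sp.ib, sp.lb)
    ca = system.cartilage
    if ca is not None:
        add(ca.penalty, ca.ia, ca.ca)
        add(ca.penalty, ca.ib, ca.cb)
    co = system.columns
    if co is not None:
        ktan = np.abs(ogden_uniaxial_tangent(
            0.5, system.materials.soft_tissue_ogden))
        kz = ktan * co.area / co.ref_thickness
        add(np.maximum(kz, system.friction.tangential_penalty), co.body,
            co.local)
    rs = system.rot_springs
    if rs is not None:
        np.add.at(w2sum, rs.ia, rs.k / i_min[rs.ia])
        np.add.at(w2sum, rs.ib, rs.k / i_min[rs.ib])
    for slip in system.pa_slips:
        for bone, local in ((slip.origin_bone, slip.origin_local),
                            (slip.insertion_bone, slip.insertion_local)):
            i = system.index[bone]
            add(np.asarray(slip.stiffness), np.asarray([i]),
                np.asarray(local)[None, :])
    w = float(np.sqrt(w2sum.max())) if w2sum.max() > 0 else 0.0
    if w <= 0.0:
        return cap
    return float(min(safety * 2.0 / w, cap))


@dataclass
class SettleResult:
    state: SimulationState
    converged: bool
    residual: float        # peak residual acceleration, mm/ms^2
    steps: int


def settle_static(system: MechanicalSystem, state: SimulationState,
                  tolerance: float = 2e-4, max_steps: int = 40000,
                  dt: float | None = None, kinetic_damping: bool = True
                  ) -> SettleResult:
    """Dynamic relaxation to a static equilibrium under constant loads.

    Integrates with mass-proportional damping, zeroing all velocities
    whenever the kinetic energy peaks (classic kinetic damping), until
    the peak residual acceleration of the free bodies falls below
    ``tolerance`` (mm/ms²).  Returns the state either way, flagged.
    """
    dt = dt if dt is not None else stable_dt(system, safety=0.4)
    alpha_save = system.damping_alpha
    system.damping_alpha = max(alpha_save, 0.05 / dt * 0.02)
    prony_save = system.prony_time_scale
    system.prony_time_scale = max(prony_save, 200.0)
    ke_prev = 0.0
    residual = np.inf
    free = system.trans_mask.sum(axis=1) > 0
    k = 0
    try:
        for k in range(1, max_steps + 1):
            audit: dict = {}
            step(system, state, dt, audit=audit)
            if k % 25 == 0 or k == 1:
                F, T = compute_forces(system, state.copy(), dt)
                # residual normalized by the physical mass so the
                # tolerance keeps its meaning under static mass scaling
                acc = np.linalg.norm(
                    (F * system.trans_mask) / system.gravity_mass[:, None],
                    axis=1)
                residual = float(acc[free].max()) if free.any() else 0.0
                if residual < tolerance:
                    state.vel[:] = 0.0
                    state.omega[:] = 0.0
                    return SettleResult(state, True, residual, k)
            if kinetic_damping:
                ke = float((system.mass * (state.vel ** 2).sum(axis=1)).sum())
                if ke < ke_prev:
                    state.vel[:] = 0.0
                    state.omega[:] = 0.0
                    ke = 0.0
                ke_prev = ke
    finally:
        system.damping_alpha = alpha_save
        system.prony_time_scale = prony_save
    return SettleResult(state, False, residual, k)


# ---------------------------------------------------------------------------
# Assembly from a FootModel
# ---------------------------------------------------------------------------

def assemble_foot_system(
    model,
    materials: MaterialSet | None = None,
    friction: FrictionParams | None = None,
    cartilage_penalty: float = 800.0,
    include_muscles: bool = True,
    spring_damping_ratio: float = 0.4,
    contact_frequency_cap: float = 55.0,
) -> MechanicalSystem:
    """Build the full mechanical system from a foot model.

    Ligament chains enter as straight tension-only springs between
    their attachments (chains here span single joints, so the sphere
    path-wrap correction is a second-order effect at walking
    postures); cartilage pairs as frictionless sphere penalties plus a
    weak capsule tether; plantar columns, aponeurosis slips and muscle
    paths as their dedicated elements.  Spring dashpots are set to the
    given fraction of critical damping — tissue, not numerics, is the
    dominant energy sink in the real foot.
    """
    from .tissues import (build_aponeurosis, build_columns, build_ligaments,
                          build_muscles)

    mats = materials or MaterialSet()
    names = list(model.bones)
    masses = [model.bones[n].mass for n in names]
    inertias = [model.bones[n].inertia for n in names]
    system = MechanicalSystem(names, masses, inertias)
    system.materials = mats
    if friction is not None:
        system.friction = friction

    idx = system.index
    spring_rows = []
    for ch in build_ligaments(model, mats):
        ia, ib = idx[ch.bone_a], idx[ch.bone_b]
        m_red = min(masses[ia], masses[ib])
        c = spring_damping_ratio * 2.0 * np.sqrt(ch.stiffness * m_red)
        spring_rows.append((ia, ib, ch.origin_local, ch.insertion_local,
                            ch.stiffness, ch.slack_length, True, c, ch.name))
    i_min_arr = np.array([np.linalg.eigvalsh(I).min() for I in inertias])
    cart_rows = []
    rot_rows = []
    for cp in model.cartilage_pairs:
        ia, ib = idx[cp.bone_a], idx[cp.bone_b]
        m_red = min(masses[ia], masses[ib])
        # cap the contact frequency so light bones do not dictate the
        # stable step; softer penalties only thicken the (already
        # fictitious) contact boundary layer, never the converged statics
        recept = (1.0 / masses[ia] + 1.0 / masses[ib]
                  + (np.asarray(cp.center_a_local) ** 2).sum() / i_min_arr[ia]
                  + (np.asarray(cp.center_b_local) ** 2).sum() / i_min_arr[ib])
        penalty = min(cartilage_penalty, contact_frequency_cap ** 2 / recept)
        cdamp = 0.6 * np.sqrt(penalty * m_red)
        cart_rows.append((ia, ib, cp.center_a_local, cp.center_b_local,
                          cp.radius_a, cp.radius_b, penalty,
                          cdamp, cp.name))
        # elastic ball joint: zero-rest-length spring between coincident
        # joint-centre anchors — congruence resistance to joint shear and
        # distraction while leaving rotation free (frequency-capped like
        # the contact penalties)
        k_caps = min(cp.capsule_stiffness, contact_frequency_cap ** 2 / recept)
        c = spring_damping_ratio * 2.0 * np.sqrt(k_caps * m_red)
        spring_rows.append((ia, ib, cp.joint_a_local, cp.joint_b_local,
                            k_caps, 0.0, False, c,
                            f"capsule:{cp.name}"))
        # torsional capsule: resists relative spin of the pair
        Ra0 = model.bones[cp.bone_a].orientation
        Rb0 = model.bones[cp.bone_b].orientation
        i_red = min(i_min_arr[ia], i_min_arr[ib])
        c_rot = spring_damping_ratio * 2.0 * np.sqrt(cp.capsule_torsion * i_red)
        rot_rows.append((ia, ib, Ra0.T @ Rb0, cp.capsule_torsion, c_rot,
                         f"torsion:{cp.name}"))
    system.set_springs(spring_rows)
    system.set_cartilage(cart_rows)
    system.set_rot_springs(rot_rows)

    col_rows = []
    for col in build_columns(model, mats):
        col_rows.append((idx[col.bone], col.anchor_local,
                         col.reference_thickness, col.area, col.name))
    system.set_columns(col_rows)

    system.pa_slips = build_aponeurosis(model, mats)
    if include_muscles:
        system.muscles = build_muscles(model)

    system.build_pose = {n: (model.bones[n].centroid.copy(),
                             model.bones[n].orientation.copy())
                         for n in names}
    return system
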