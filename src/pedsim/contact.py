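"""Penalty contact: frictional rigid floor and frictionless cartilage.

The floor is the rigid plane z = 0.  Normal contact is a linear
penalty (force proportional to penetration, plus a small contact
damping term), and Coulomb friction uses the classic stick--slip
regularization: a tangential anchor spring pulls each contact point
back towards the location where it first stuck; when the spring force
reaches the friction cone ``mu_s * Fn`` the anchor slides so the force
sits exactly on the cone (kinetic friction ``mu_d * Fn`` opposing the
slip direction).  With ``mu_s = mu_d`` the transition is
hysteresis-free at the cone boundary.

Articular (bone--bone) contact is frictionless: each cartilage pair is
a pair of penalty spheres touching at the joint centre in the build
pose, transmitting force only along the centre line, in compression
only, as equal and opposite wrenches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FrictionParams",
    "ContactPoint",
    "floor_contact_force",
    "cartilage_contact_force",
    "coulomb_tangential",
]


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class FrictionParams:
    """Floor contact law parameters.

    Penalties in N/mm; ``regularization_velocity`` (mm/ms) sets the
    slip speed below which kinetic friction ramps linearly through
    zero instead of switching sign discontinuously.
    """

    mu_static: float = 0.6
    mu_dynamic: float = 0.6
    normal_penalty: float = 150.0
    tangential_penalty: float = 80.0
    normal_damping: float = 0.0       # N per mm/ms, applied while in contact
    #: tangential dashpot, N per mm/ms: a point sliding fast saturates
    #: the cone immediately instead of waiting for its anchor spring
    tangential_damping: float = 40.0
    regularization_velocity: float = 1e-3

    def __post_init__(self) -> None:
        if self.mu_static < 0 or self.mu_dynamic < 0:
            raise ContactError("friction coefficients must be non-negative")
        if self.normal_penalty <= 0 or self.tangential_penalty <= 0:
            raise ContactError("penalty stiffnesses must be positive")


@dataclass
class ContactPoint:
    """State of one floor contact point."""

    position: np.ndarray          # (3,) mm, current
    penetration: float = 0.0      # mm, >= 0 when active
    normal: np.ndarray = None     # unit
    stick_anchor: np.ndarray = None  # (2,) mm, tangential anchor
    mode: str = "separated"       # separated | stick | slip

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        if self.normal is None:
            self.normal = np.array([0.0, 0.0, 1.0])
        if self.stick_anchor is None:
            self.stick_anchor = self.position[:2].copy()


def floor_contact_force(
    point: ContactPoint,
    velocity,
    params: FrictionParams,
    normal_force: float | None = None,
) -> tuple[np.ndarray, ContactPoint]:
    """Contact force at one floor point and the updated contact state.

    ``velocity`` is the material point velocity (mm/ms).  If
    ``normal_force`` is given (e.g. from a soft-tissue column in series
    with the contact) it replaces the penalty normal force and the
    penetration is interpreted as already resolved by that element.
    Returns ``(force, new_point)``; the force is zero when separated.
    """
    v = np.asarray(velocity, float)
    pos = point.position
    pen = -pos[2] if normal_force is None else point.penetration
    if normal_force is None:
        if pen <= 0.0:
            return np.zeros(3), replace_contact(point, pen=0.0, mode="separated",
                                                anchor=pos[:2].copy())
        fn = params.normal_penalty * pen - params.normal_damping * v[2]
        fn = max(fn, 0.0)
    else:
        fn = max(float(normal_force), 0.0)
        if fn == 0.0:
            return np.zeros(3), replace_contact(point, pen=0.0, mode="separated",
                                                anchor=pos[:2].copy())
    ft, anchor, mode = coulomb_tangential(
        pos[:2][None, :], v[:2][None, :], point.stick_anchor[None, :],
        np.array([fn]), params)
    force = np.array([ft[0, 0], ft[0, 1], fn])
    return force, replace_contact(point, pen=max(pen, 0.0), mode=mode[0],
                                  anchor=anchor[0])


def replace_contact(point: ContactPoint, pen, mode, anchor) -> ContactPoint:
    return ContactPoint(position=point.position.copy(), penetration=float(pen),
                        normal=point.normal.copy(), stick_anchor=np.asarray(anchor),
                        mode=mode)


def coulomb_tangential(pos_xy, vel_xy, anchors, fn, params: FrictionParams):
    """Vectorized stick--slip tangential force for n contact points.

    Parameters are (n, 2) arrays plus (n,) normal forces.  Returns
    ``(ft, new_anchors, modes)``: the tangential force never exceeds
    ``mu_s * fn``; sliding anchors are relocated onto the cone so the
    anchor spring reproduces kinetic friction exactly.
    """
    pos_xy = np.atleast_2d(pos_xy)
    vel_xy = np.atleast_2d(vel_xy)
    anchors = np.atleast_2d(anchors).copy()
    fn = np.atleast_1d(fn).astype(float)
    kt = params.tangential_penalty
    trial = -kt * (pos_xy - anchors) - params.tangential_damping * vel_xy
    trial_mag = np.linalg.norm(trial, axis=1)
    limit_s = params.mu_static * fn
    limit_d = params.mu_dynamic * fn
    modes = np.where(fn > 0.0, "stick", "separated").astype(object)
    ft = trial.copy()
    slipping = (trial_mag > limit_s) & (fn > 0.0)
    if slipping.any():
        idx = np.where(slipping)[0]
        vt = vel_xy[idx]
        vmag = np.linalg.norm(vt, axis=1)
        # direction opposing slip; fall back to the trial direction at
        # negligible slip speed (regularized transition)
        dirs = np.zeros_like(vt)
        fast = vmag > params.regularization_velocity
        dirs[fast] = -vt[fast] / vmag[fast, None]
        slow = ~fast
        tm = trial_mag[idx]
        dirs[slow] = trial[idx][slow] / tm[slow, None]
        ft[idx] = dirs * limit_d[idx, None]
        # relocate anchors so the spring sits exactly on the cone
        anchors[idx] = pos_xy[idx] + ft[idx] / kt
        modes[idx] = "slip"
    separated = fn <= 0.0
    if separated.any():
        ft[separated] = 0.0
        anchors[separated] = pos_xy[separated]
    return ft, anchors, modes


def cartilage_contact_force(
    center_a,
    center_b,
    radius_a: float,
    radius_b: float,
    penalty: float,
    rel_velocity=None,
    damping: float = 0.0,
    max_penetration: float | None = None,
    pair_name: str = "",
):
    """Frictionless sphere-proxy contact force between two bones.

    Returns ``(force_on_a, contact_point)``; the force on B is the
    exact negative applied at the same point, so the pair wrench sums
    to zero.  Force acts along the centre line only (no tangential
    component) and only in compression.  ``max_penetration`` guards
    against a badly initialized pair.
    """
    ca = np.asarray(center_a, float)
    cb = np.asarray(center_b, float)
    d = ca - cb
    dist = float(np.linalg.norm(d))
    overlap = (radius_a + radius_b) - dist
    if overlap <= 0.0 or dist == 0.0:
        return np.zeros(3), 0.5 * (ca + cb)
    if max_penetration is not None and overlap > max_penetration:
        raise ContactError(
            f"cartilage pair {pair_name or '?'}: penetration "
            f"{overlap:.2f} mm exceeds cap {max_penetration:.2f} mm"
        )
    n = d / dist  # from B towards A
    fmag = penalty * overlap
    if rel_velocity is not None and damping > 0.0:
        fmag -= damping * float(np.dot(np.asarray(rel_velocity, float), n))
        fmag = max(fmag, 0.0)
    contact_point = cb + n * (radius_b - overlap / 2.0)
    return fmag * n, contact_point
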