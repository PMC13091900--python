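"""Soft-tissue elements: ligaments, plantar aponeurosis, muscles, columns.

Ligaments are tension-only spring chains.  Anatomically each chain is
an alternating series of springs and small spheres (1 mm diameter)
that may slide frictionlessly over the host bone surfaces, letting the
path wrap around bony contours; hindfoot ligaments with broad
attachments are bundles of ten such chains.  A chain of total
cross-section A along one path carries exactly the same tension as ten
parallel strands of area A/10 on that path, so the bundle count enters
force computation only through the area bookkeeping.

Slack lengths follow the model's reference-posture rule: 1.1 times the
build-pose length by default, but exactly the build-pose length for
the lateral hindfoot group (stretched in the slightly inverted
reference posture) and for the plantar group and plantar aponeurosis
(not shortened in that posture).

The plantar aponeurosis is ten tension-only slips from the calcaneus
to the toes; slips to rays whose metatarsal head they cross wrap a
head cylinder (tangent--arc--tangent geodesic), and the first slip
routes through the medial sesamoid instead.

Plantar soft tissue is discretized as uniaxial columns under the
plantar bony prominences: Ogden hyperelastic in compression with
two-term Prony relaxation, contact-like (zero force in tension).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import (
    MaterialSet,
    OgdenParams,
    PronyParams,
    PronyState,
    ogden_uniaxial_stress,
    viscoelastic_stress_update,
)

__all__ = [
    "LigamentChain",
    "AponeurosisSlip",
    "MusclePath",
    "SoftTissueColumn",
    "assign_slack_length",
    "chain_tension",
    "resolve_sphere_contacts",
    "slip_path_length",
    "cylinder_wrap_length",
    "muscle_force_at",
    "column_force",
    "build_ligaments",
    "build_aponeurosis",
    "build_muscles",
    "build_columns",
]

logger = logging.getLogger(__name__)

LIGAMENT_CATEGORIES = ("default", "lateral_hindfoot", "plantar")

#: slack-length multiplier per ligament category
SLACK_FACTORS = {"default": 1.1, "lateral_hindfoot": 1.0, "plantar": 1.0}


class TissueError(ValueError):
    pass


def assign_slack_length(reference_length: float, category: str) -> float:
    """Slack length from the build-pose (reference) length.

    Default ligaments: 1.1 x reference (underestimating slack leaves
    ligaments permanently taut and over-stiffens every joint); lateral
    hindfoot and plantar groups: 1.0 x reference.
    """
    if reference_length <= 0:
        raise TissueError("reference_length must be positive")
    try:
        return SLACK_FACTORS[category] * reference_length
    except KeyError:
        raise TissueError(
            f"unknown ligament category {category!r}; "
            f"expected one of {LIGAMENT_CATEGORIES}"
        ) from None


@dataclass
class LigamentChain:
    """Tension-only spring--sphere chain between two bones.

    ``nodes`` are the build-pose path points (origin, sphere centres,
    insertion) in mm; ``area`` is the *total* cross-section of the
    bundle.  Stiffness is linear in engineering strain: EA/slack.
    """

    name: str
    category: str
    bone_a: str
    bone_b: str
    origin_local: np.ndarray
    insertion_local: np.ndarray
    nodes: np.ndarray            # (k, 3) build pose, k >= 2
    E: float
    area: float
    slack_length: float
    bundle_count: int = 1
    sphere_radius: float = 0.5
    host_bones: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.slack_length <= 0:
            raise TissueError(f"{self.name}: slack_length must be positive")
        if self.area <= 0:
            raise TissueError(f"{self.name}: area must be positive")

    @property
    def stiffness(self) -> float:
        """N/mm of path elongation beyond slack."""
        return self.E * self.area / self.slack_length


def chain_tension(path_length: float, chain: LigamentChain) -> float:
    """Tension (N) of a chain at the given path length; never negative."""
    if path_length <= 0:
        raise TissueError("path_length must be positive")
    stretch = path_length - chain.slack_length
    if stretch <= 0.0:
        return 0.0
    return chain.stiffness * stretch


def resolve_sphere_contacts(chain: LigamentChain, bones: dict, poses=None,
                            tol: float = 1e-6):
    """Project chain spheres out of their host bone surfaces.

    ``bones`` maps bone name to a :class:`~pedsim.foot_model.Bone`;
    ``poses`` optionally maps bone name to ``(position, rotation)``
    overriding the build pose.  Returns ``(positions, forces)`` where
    interior nodes penetrating a host surface are pushed to exactly
    ``sphere_radius`` clearance along the outward surface normal, and
    ``forces`` are the (frictionless, purely normal) contact forces
    implied by the chain tension at the corrected geometry.

    A sphere whose centre lies deeper inside a host bone than the
    local surface curvature can resolve is a model error.
    """
    nodes = np.array(chain.nodes, dtype=float)
    normals = np.zeros_like(nodes)
    active = np.zeros(len(nodes), dtype=bool)
    for i in range(1, len(nodes) - 1):  # endpoints are bone-anchored
        for bname in chain.host_bones:
            bone = bones[bname]
            pos, rot = _bone_pose(bone, poses)
            local = rot.T @ (nodes[i] - pos)
            d = float(bone.signed_distance_local(local)[0])
            if d < chain.sphere_radius - tol:
                if d < -0.8 * min(_min_semi(bone), 1e9):
                    raise TissueError(
                        f"{chain.name}: sphere {i} initialized deep inside "
                        f"{bname}"
                    )
                n_local = _surface_normal(bone, local)
                n = rot @ n_local
                nodes[i] = nodes[i] + n * (chain.sphere_radius - d)
                normals[i] = n
                active[i] = True
    # contact force on each sphere from the (taut) chain geometry
    seg = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    path_length = float(seg_len.sum())
    T = chain_tension(path_length, chain)
    forces = np.zeros_like(nodes)
    if T > 0:
        u = seg / seg_len[:, None]
        for i in range(1, len(nodes) - 1):
            if active[i]:
                f_net = T * (u[i] - u[i - 1])  # net pull on the node
                n = normals[i]
                forces[i] = -np.dot(f_net, n) * n  # reaction, normal only
    return nodes, forces


def _bone_pose(bone, poses):
    if poses is not None and bone.name in poses:
        return poses[bone.name]
    return bone.centroid, bone.orientation


def _min_semi(bone) -> float:
    return min(float(np.min(semi)) for _, _, semi in bone.parts)


def _surface_normal(bone, local_point) -> np.ndarray:
    """Outward surface normal of the nearest analytic part."""
    best = None
    p = np.asarray(local_point, float)
    for offset, Rp, semi in bone.parts:
        q = Rp.T @ (p - offset)
        level = np.linalg.norm(q / semi)
        if best is None or level < best[0]:
            grad = Rp @ (q / (semi * semi))
            best = (level, grad)
    n = best[1]
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# Plantar aponeurosis
# ---------------------------------------------------------------------------

@dataclass
class AponeurosisSlip:
    """One of ten plantar aponeurosis slips.

    Path: calcaneal origin -> (sesamoid via-point for slip 1, or head
    cylinder wrap) -> phalangeal insertion.  Slack equals the build
    pose length.
    """

    index: int
    origin_bone: str
    origin_local: np.ndarray
    insertion_bone: str
    insertion_local: np.ndarray
    E: float
    area: float
    slack_length: float
    wrap_bone: str | None = None
    wrap_center_local: np.ndarray | None = None
    wrap_axis_local: np.ndarray | None = None
    wrap_radius: float = 0.0
    #: fixed winding side (+1/-1 in the cylinder cross-section frame);
    #: 0 selects the shorter side each call.  A slip keeps the side it
    #: has in the build pose: a tendon held against the plantar surface
    #: of the head cannot flip to the dorsal side.
    wrap_side: float = 0.0
    via_sesamoid: bool = False
    via_bone: str | None = None
    via_local: np.ndarray | None = None

    @property
    def stiffness(self) -> float:
        return self.E * self.area / self.slack_length


def cylinder_wrap_length(p, q, center, axis, radius, side: float = 0.0):
    """Tangent--arc--tangent path from p to q around a cylinder.

    Returns ``(length, dir_p, dir_q, wrapped)`` where ``dir_p`` is the
    unit direction of the path leaving ``p`` (towards its tangent
    point, or towards ``q`` if the path is straight).  The obstacle is
    an infinite frictionless cylinder; the geodesic length is computed
    in the developed (unrolled) plane.  ``side`` fixes the winding
    (+1/-1); with the default 0 the shorter side is chosen each call.
    For a fixed side the wrap stays engaged while its arc angle lies in
    (0, pi) and releases to the straight segment otherwise, which keeps
    the length continuous across engagement.  Endpoints inside the
    cylinder are a model error.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    center = np.asarray(center, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    if radius <= 0:
        raise TissueError("wrap cylinder radius must be positive")
    # cylinder frame: e1, e2 span the cross-section plane
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(tmp, a)) > 0.9:
        tmp = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(tmp, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)

    def to2d(x):
        rel = x - center
        return np.array([np.dot(rel, e1), np.dot(rel, e2)]), np.dot(rel, a)

    P2, pz = to2d(p)
    Q2, qz = to2d(q)
    rp, rq = np.linalg.norm(P2), np.linalg.norm(Q2)
    if rp <= radius or rq <= radius:
        raise TissueError("wrap endpoint inside the cylinder")
    beta_p = np.arccos(np.clip(radius / rp, -1.0, 1.0))
    beta_q = np.arccos(np.clip(radius / rq, -1.0, 1.0))
    tp = np.sqrt(max(rp * rp - radius * radius, 0.0))
    tq = np.sqrt(max(rq * rq - radius * radius, 0.0))
    th_p = np.arctan2(P2[1], P2[0])
    th_q = np.arctan2(Q2[1], Q2[0])

    def sided(s):
        ang_tp = th_p + s * beta_p
        ang_tq = th_q - s * beta_q
        arc = (s * (ang_tq - ang_tp)) % (2.0 * np.pi)
        return tp + radius * arc + tq, s, ang_tp, ang_tq, arc

    if side:
        total2d, s, ang_tp, ang_tq, arc = sided(float(np.sign(side)))
        engaged = arc < np.pi
    else:
        # free side: engaged only when the 2D segment hits the circle
        d2 = Q2 - P2
        t = -np.dot(P2, d2) / np.dot(d2, d2)
        engaged = 0.0 < t < 1.0 and np.linalg.norm(P2 + t * d2) < radius
        if engaged:
            total2d, s, ang_tp, ang_tq, arc = min(
                (sided(+1.0), sided(-1.0)), key=lambda b: b[0])
    if not engaged:
        straight = q - p
        L = float(np.linalg.norm(straight))
        u = straight / L
        return L, u, -u, False
    dz = qz - pz
    L = float(np.hypot(total2d, dz))
    # tangent points with axial coordinate from the developed path
    Tp2 = radius * np.array([np.cos(ang_tp), np.sin(ang_tp)])
    Tq2 = radius * np.array([np.cos(ang_tq), np.sin(ang_tq)])
    z_tp = pz + dz * (tp / total2d)
    z_tq = pz + dz * ((tp + radius * arc) / total2d)
    Tp3 = center + Tp2[0] * e1 + Tp2[1] * e2 + z_tp * a
    Tq3 = center + Tq2[0] * e1 + Tq2[1] * e2 + z_tq * a
    dir_p = Tp3 - p
    dir_p /= np.linalg.norm(dir_p)
    dir_q = Tq3 - q
    dir_q /= np.linalg.norm(dir_q)
    return L, dir_p, dir_q, True


def slip_path_length(slip: AponeurosisSlip, poses: dict):
    """Current path length of a slip and unit force directions at its ends.

    ``poses`` maps bone name to ``(position, rotation)``.  For a
    sesamoid-routed slip the path is two straight segments pinned to
    the sesamoid; otherwise the head-cylinder wrap geometry applies.
    Returns ``(length, dir_origin, dir_insertion, wrapped)`` with
    directions pointing from each endpoint into the path.
    """
    po, Ro = poses[slip.origin_bone]
    pi, Ri = poses[slip.insertion_bone]
    o = po + Ro @ slip.origin_local
    ins = pi + Ri @ slip.insertion_local
    if slip.via_sesamoid:
        pv, Rv = poses[slip.via_bone]
        v = pv + Rv @ slip.via_local
        d1 = v - o
        d2 = ins - v
        l1, l2 = np.linalg.norm(d1), np.linalg.norm(d2)
        return (float(l1 + l2), d1 / l1, -d2 / l2, False)
    if slip.wrap_bone is None:
        d = ins - o
        L = float(np.linalg.norm(d))
        return L, d / L, -d / L, False
    pw, Rw = poses[slip.wrap_bone]
    cen = pw + Rw @ slip.wrap_center_local
    ax = Rw @ slip.wrap_axis_local
    L, dir_o, dir_i, wrapped = cylinder_wrap_length(
        o, ins, cen, ax, slip.wrap_radius, side=slip.wrap_side)
    return L, dir_o, dir_i, wrapped


# ---------------------------------------------------------------------------
# Muscles
# ---------------------------------------------------------------------------

@dataclass
class MusclePath:
    """Line-of-action of one extrinsic muscle.

    ``points`` is an ordered list of ``(bone, local_point)`` anchors
    (origin, via points, insertion); the line of action is recomputed
    from current bone poses every step.  ``profile`` is a sampled
    (stance-%, N) force table, linearly interpolated.
    """

    name: str
    points: list[tuple[str, np.ndarray]]
    profile_pct: np.ndarray
    profile_force: np.ndarray

    def __post_init__(self) -> None:
        pct = np.asarray(self.profile_pct, float)
        f = np.asarray(self.profile_force, float)
        if np.any(np.diff(pct) <= 0):
            raise TissueError(f"{self.name}: stance-% samples must increase")
        if pct.min() < 0 or pct.max() > 100:
            raise TissueError(f"{self.name}: stance-% samples outside [0, 100]")
        if np.any(f < 0):
            raise TissueError(f"{self.name}: negative force sample")
        self.profile_pct = pct
        self.profile_force = f


def muscle_force_at(t_pct: float, path: MusclePath) -> float:
    """Piecewise-linear interpolation of the force profile at stance-%."""
    if t_pct < 0.0 or t_pct > 100.0:
        logger.warning("%s: stance %% %.2f outside [0, 100]; clamped",
                       path.name, t_pct)
        t_pct = float(np.clip(t_pct, 0.0, 100.0))
    return float(np.interp(t_pct, path.profile_pct, path.profile_force))


# ---------------------------------------------------------------------------
# Plantar soft-tissue columns
# ---------------------------------------------------------------------------

@dataclass
class SoftTissueColumn:
    """Uniaxial viscoelastic column between a plantar anchor and the floor.

    ``reference_thickness`` is the build-pose clearance of the anchor
    above the floor; the column stretch is current clearance divided by
    reference.  Compression (stretch < 1) produces force via the Ogden
    law scaled by the Prony relaxation; tension produces none.
    """

    name: str
    bone: str
    anchor_local: np.ndarray
    reference_thickness: float
    area: float
    ogden: OgdenParams
    prony: PronyParams
    state: PronyState = field(default_factory=lambda: PronyState.zeros())

    def __post_init__(self) -> None:
        if self.reference_thickness <= 0:
            raise TissueError(f"{self.name}: reference thickness must be > 0")
        if self.area <= 0:
            raise TissueError(f"{self.name}: area must be > 0")


def column_force(column: SoftTissueColumn, current_thickness: float,
                 dt: float) -> float:
    """Compressive column force (N, >= 0) and internal-state update.

    The Prony state advances every step regardless of contact, so a
    column that lifts off and re-contacts sees the correct stress
    history.
    """
    if current_thickness <= 0:
        # fully bottomed out: clamp the stretch to a small positive value
        current_thickness = 1e-3 * column.reference_thickness
    lam = min(current_thickness / column.reference_thickness, 1.0)
    sigma, column.state = viscoelastic_stress_update(
        lam, column.state, column.ogden, column.prony, dt)
    return max(sigma, 0.0) * column.area


# ---------------------------------------------------------------------------
# Inventory builders (from a FootModel + MaterialSet)
# ---------------------------------------------------------------------------

def build_ligaments(model, materials: MaterialSet | None = None,
                    sphere_spacing: float = 6.0) -> list[LigamentChain]:
    """Instantiate the ligament inventory of a foot model."""
    mats = materials or MaterialSet()
    chains = []
    for spec in model.ligament_specs:
        o = model.attachment_global(f"lig:{spec['name']}:origin")
        i = model.attachment_global(f"lig:{spec['name']}:insertion")
        ref_len = float(np.linalg.norm(i - o))
        n_spheres = max(1, int(ref_len / sphere_spacing) - 1)
        ts = np.linspace(0.0, 1.0, n_spheres + 2)
        nodes = o[None, :] + ts[:, None] * (i - o)[None, :]
        oa = model.attachments[f"lig:{spec['name']}:origin"]
        ia = model.attachments[f"lig:{spec['name']}:insertion"]
        chains.append(LigamentChain(
            name=spec["name"], category=spec["category"],
            bone_a=spec["bone_a"], bone_b=spec["bone_b"],
            origin_local=oa.local, insertion_local=ia.local,
            nodes=nodes, E=mats.ligament.E, area=spec["area"],
            slack_length=assign_slack_length(ref_len, spec["category"]),
            bundle_count=spec["bundle_count"],
            host_bones=(spec["bone_a"], spec["bone_b"]),
        ))
    return chains


def build_aponeurosis(model, materials: MaterialSet | None = None
                      ) -> list[AponeurosisSlip]:
    """Instantiate the ten plantar aponeurosis slips."""
    mats = materials or MaterialSet()
    pa = model.pa_spec
    origin_att = model.attachments["pa:origin"]
    origin_g = model.attachment_global("pa:origin")
    area_per_slip = pa["total_area"] / len(pa["slips"])
    slips = []
    poses0 = {name: (b.centroid, b.orientation)
              for name, b in model.bones.items()}
    for spec in pa["slips"]:
        idx = spec["index"]
        ins_att = model.attachments[f"pa:slip{idx}:insertion"]
        kwargs = dict(
            index=idx, origin_bone=origin_att.bone,
            origin_local=origin_att.local,
            insertion_bone=ins_att.bone, insertion_local=ins_att.local,
            E=mats.plantar_aponeurosis.E, area=area_per_slip,
            slack_length=1.0,  # placeholder; set from build geometry below
        )
        if spec["via_sesamoid"]:
            ses = model.bones["sesamoid_medial"]
            kwargs.update(via_sesamoid=True, via_bone="sesamoid_medial",
                          via_local=np.array([0.0, 0.0, -ses.parts[0][2][2]]))
        else:
            met = f"metatarsal_{spec['ray']}"
            cyl = model.wrap_cylinders[met]
            kwargs.update(wrap_bone=met, wrap_center_local=cyl.center_local,
                          wrap_axis_local=cyl.axis_local,
                          wrap_radius=cyl.radius)
        slip = AponeurosisSlip(**kwargs)
        if slip.wrap_bone is not None:
            slip = replace(slip, wrap_side=_build_pose_side(slip, poses0))
        ref_len, _, _, _ = slip_path_length(slip, poses0)
        slips.append(replace(slip, slack_length=ref_len))
    return slips


def _build_pose_side(slip: AponeurosisSlip, poses) -> float:
    """Winding side of a slip in the build pose (shorter-side choice)."""
    po, Ro = poses[slip.origin_bone]
    pi, Ri = poses[slip.insertion_bone]
    o = po + Ro @ slip.origin_local
    q = pi + Ri @ slip.insertion_local
    pw, Rw = poses[slip.wrap_bone]
    cen = pw + Rw @ slip.wrap_center_local
    ax = Rw @ slip.wrap_axis_local
    best = None
    for s in (+1.0, -1.0):
        L, *_ = cylinder_wrap_length(o, q, cen, ax, slip.wrap_radius, side=s)
        if best is None or L < best[0]:
            best = (L, s)
    return best[1]


def build_muscles(model, profiles: dict | None = None) -> dict[str, MusclePath]:
    """Instantiate the four extrinsic muscle paths (TS, TA, EDL, EHL)."""
    from .gait_io import SYNTHETIC_MUSCLE_PROFILE

    prof = profiles or SYNTHETIC_MUSCLE_PROFILE
    muscles = {}
    for name, spec in model.muscle_specs.items():
        pts = []
        for key in spec["points"]:
            att = model.attachments[key]
            pts.append((att.bone, att.local))
        muscles[name] = MusclePath(
            name=name, points=pts, profile_pct=prof["pct"],
            profile_force=prof[name],
        )
    return muscles


def build_columns(model, materials: MaterialSet | None = None
                  ) -> list[SoftTissueColumn]:
    """Instantiate the plantar column bed from build-pose clearances."""
    mats = materials or MaterialSet()
    cols = []
    for spec in model.column_specs:
        att = model.attachments[f"col:{spec['name']}"]
        anchor_g = model.bones[att.bone].to_global(att.local)
        thickness = float(anchor_g[2])
        cols.append(SoftTissueColumn(
            name=spec["name"], bone=att.bone, anchor_local=att.local,
            reference_thickness=thickness, area=spec["area"],
            ogden=mats.soft_tissue_ogden, prony=mats.soft_tissue_prony,
        ))
    return cols
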