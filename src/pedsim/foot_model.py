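"""Parametric synthetic foot skeleton.

The skeleton is a template of 23 rigid bones (tibia, fibula, talus,
calcaneus, navicular, cuboid, three cuneiforms, five metatarsals, the
two hallucal phalanges, one fused phalangeal segment per lesser ray,
and three sesamoids) standing in for a subject-specific CT geometry.
Bone shapes are solid ellipsoids placed by the template; metatarsal
heads additionally carry analytic cylinder records used by the plantar
aponeurosis wrapping.  The build is deterministic, uniformly scalable
by foot length, adjustable in arch height, and mirrorable about the
sagittal plane.

Global frame: x anterior, y medial (right foot), z superior; the floor
is the plane z = 0 and the template is plantigrade, with the plantar
bony prominences of the calcaneus and metatarsal heads levelled at a
common clearance above the floor (the reference thickness of the
plantar soft-tissue columns).

Bones are rigid: cortical bone is three to six orders of magnitude
stiffer than the surrounding soft tissue, so bone deformation
contributes negligibly to joint-level kinematics at this scale.  Bone
elastic constants are nevertheless kept in :class:`~pedsim.materials.
MaterialSet` for element-stress reporting.  Rigid-body masses lump the
encapsulated soft tissue onto their host bone via a density multiplier,
and very small bones (sesamoids, toe segments) are clamped to a minimum
mass purely as an inertia regularization for explicit integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
import yaml

__all__ = [
    "BuildParams",
    "Bone",
    "Attachment",
    "CartilagePair",
    "WrapCylinder",
    "FootModel",
    "BONE_ENUMERATION",
    "build_foot",
    "validate_model",
    "ValidationReport",
]

#: template foot length, mm (scale=255 reproduces the template verbatim)
TEMPLATE_FOOT_LENGTH = 255.0
#: template arch-height ratio (navicular height / foot length)
TEMPLATE_ARCH_RATIO = 0.25
#: common plantar bone clearance above the floor in the template, mm
PLANTAR_CLEARANCE = 10.0

BONE_ENUMERATION = (
    "tibia", "fibula", "talus", "calcaneus", "navicular", "cuboid",
    "cuneiform_medial", "cuneiform_intermediate", "cuneiform_lateral",
    "metatarsal_1", "metatarsal_2", "metatarsal_3", "metatarsal_4",
    "metatarsal_5", "hallux_proximal_phalanx", "hallux_distal_phalanx",
    "phalanges_ray2", "phalanges_ray3", "phalanges_ray4", "phalanges_ray5",
    "sesamoid_medial", "sesamoid_lateral", "os_peroneum",
)

LESSER_RAY_SEGMENTS = ("phalanges_ray2", "phalanges_ray3",
                       "phalanges_ray4", "phalanges_ray5")

#: bones whose height above the sole scales with the arch-height ratio
ARCH_BONES = ("navicular", "cuboid", "cuneiform_medial",
              "cuneiform_intermediate", "cuneiform_lateral")


class BuildError(ValueError):
    """Invalid build parameter; the message names the offending field."""


@dataclass(frozen=True)
class BuildParams:
    """Parameters of the synthetic skeleton build.

    ``scale`` is the foot length in mm; ``arch_height_ratio`` the
    navicular height as a fraction of foot length (template 0.25);
    ``side`` mirrors the skeleton; ``merge_lesser_rays`` fuses the four
    lesser-toe segments into one rigid body (22-bone variant).
    ``tissue_mass_factor`` lumps encapsulated soft-tissue mass onto the
    bones; ``min_bone_mass`` (g) regularizes the inertia of the
    smallest bones.
    """

    scale: float = 255.0
    arch_height_ratio: float = 0.25
    side: str = "right"
    seed: int = 0
    merge_lesser_rays: bool = False
    tissue_mass_factor: float = 3.0
    min_bone_mass: float = 5.0
    mesh_subdivisions: int = 2

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise BuildError(f"scale must be > 0, got {self.scale}")
        if not (0.0 < self.arch_height_ratio < 1.0):
            raise BuildError(
                f"arch_height_ratio must be in (0, 1), got {self.arch_height_ratio}"
            )
        if self.side not in ("right", "left"):
            raise BuildError(f"side must be 'right' or 'left', got {self.side!r}")
        if self.tissue_mass_factor <= 0:
            raise BuildError("tissue_mass_factor must be > 0")
        if self.min_bone_mass < 0:
            raise BuildError("min_bone_mass must be >= 0")


@dataclass
class Bone:
    """One rigid bone: mass properties, local-frame mesh and landmarks.

    The mesh and landmarks live in the bone-local frame (origin at the
    centroid, axes aligned with the global x-anterior / y-medial /
    z-superior frame at build time via ``orientation``).
    """

    name: str
    mass: float                    # g
    centroid: np.ndarray           # (3,) mm, global, build pose
    inertia: np.ndarray            # (3, 3) g mm^2 about centroid, local frame
    orientation: np.ndarray        # (3, 3) local -> global at build
    surface: trimesh.Trimesh       # local frame
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    #: analytic ellipsoid parts (offset, rotation, semi-axes) in the local
    #: frame; one entry for simple bones, several for fused segments.
    parts: list[tuple] = field(default_factory=list)

    def signed_distance_local(self, points_local) -> np.ndarray:
        """Approximate signed distance to the bone surface (negative inside).

        Uses the radial ellipsoid metric of each analytic part: exact on
        the surface and monotone with depth, sufficient for penetration
        and attachment audits on this primitive-based skeleton.
        """
        pts = np.atleast_2d(np.asarray(points_local, float))
        best = np.full(pts.shape[0], np.inf)
        for offset, R, semi in self.parts:
            q = (pts - offset) @ R  # into part frame
            u = q / semi
            nu = np.linalg.norm(u, axis=1)
            r = np.linalg.norm(q, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(nu > 1e-12, (nu - 1.0) * r / np.maximum(nu, 1e-12),
                             -semi.min())
            best = np.minimum(best, d)
        return best

    def signed_distance_global(self, points_global) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_global, float))
        return self.signed_distance_local((pts - self.centroid) @ self.orientation)

    def to_global(self, local_point) -> np.ndarray:
        return self.centroid + self.orientation @ np.asarray(local_point, float)

    def to_local(self, global_point) -> np.ndarray:
        return self.orientation.T @ (np.asarray(global_point, float) - self.centroid)

    def landmark_global(self, name: str) -> np.ndarray:
        return self.to_global(self.landmarks[name])

    @property
    def vertices_global(self) -> np.ndarray:
        return self.centroid + self.surface.vertices @ self.orientation.T


@dataclass(frozen=True)
class Attachment:
    """A named tissue attachment point on a bone (local coordinates)."""

    bone: str
    local: np.ndarray


@dataclass(frozen=True)
class CartilagePair:
    """Frictionless sphere-proxy articular contact between two bones.

    Each bone carries a proxy sphere; at build pose the spheres just
    touch at the joint centre, so the pair transmits force only under
    joint compression.  In addition the pair carries an elastic
    ball-joint tether (``capsule_stiffness``) representing articular
    congruence plus the joint capsule, and a weak torsional spring
    (``capsule_torsion``) for the spin mode that no tension element
    crosses.
    """

    name: str
    bone_a: str
    bone_b: str
    center_a_local: np.ndarray
    center_b_local: np.ndarray
    radius_a: float
    radius_b: float
    #: joint-centre anchor of the capsule tether, local on each bone
    #: (coincident at build pose)
    joint_a_local: np.ndarray | None = None
    joint_b_local: np.ndarray | None = None
    #: translational joint stiffness, N/mm: the congruent articular
    #: surfaces plus capsule behave as a tight elastic ball joint;
    #: rotation remains the compliant degree of freedom
    capsule_stiffness: float = 800.0
    #: torsional capsule stiffness, N*mm/rad — resists relative bone spin
    #: (a mode no tension element crosses); small against arch moments
    capsule_torsion: float = 5000.0


@dataclass(frozen=True)
class WrapCylinder:
    """Analytic cylinder on a metatarsal head for aponeurosis wrapping."""

    bone: str
    center_local: np.ndarray
    axis_local: np.ndarray    # unit
    radius: float


# ---------------------------------------------------------------------------
# Template tables (mm; foot length 255, arch ratio 0.25, right foot)
# ---------------------------------------------------------------------------

# name -> (center, semi_axes, long_axis_direction or None)
_ELLIPSOIDS: dict[str, tuple] = {
    "tibia": ((60.0, 6.0, 222.0), (15.0, 15.0, 165.0), None),
    "fibula": ((52.0, -28.0, 212.0), (8.0, 8.0, 160.0), None),
    "talus": ((76.0, -1.0, 50.0), (24.0, 13.0, 11.0), None),
    "calcaneus": ((42.0, -6.0, 26.0), (38.0, 16.0, 16.0), None),
    "navicular": ((110.0, 4.0, 42.0), (9.0, 13.0, 10.0), None),
    "cuboid": ((106.0, -24.0, 24.0), (15.0, 10.0, 11.0), None),
    "cuneiform_medial": ((132.0, 11.0, 37.0), (10.0, 7.5, 10.0), None),
    "cuneiform_intermediate": ((134.0, -3.0, 39.0), (8.0, 5.0, 9.0), None),
    "cuneiform_lateral": ((135.0, -13.0, 32.0), (9.0, 5.0, 9.0), None),
}

# long bones: name -> (base, head, radius_y, radius_z)
_LONG_BONES: dict[str, tuple] = {
    "metatarsal_1": ((148.0, 13.0, 33.0), (193.0, 17.0, 13.0), 7.5, 7.5),
    "metatarsal_2": ((152.0, 0.0, 35.0), (198.0, 3.0, 11.5), 5.5, 5.5),
    "metatarsal_3": ((151.0, -11.0, 32.0), (194.0, -10.0, 11.5), 5.0, 5.0),
    "metatarsal_4": ((148.0, -21.0, 28.0), (188.0, -20.0, 11.8), 4.8, 4.8),
    "metatarsal_5": ((142.0, -31.0, 24.0), (180.0, -30.0, 12.0), 4.8, 4.8),
    "hallux_proximal_phalanx": ((208.0, 17.0, 14.0), (232.0, 19.0, 12.0), 7.0, 6.0),
    "hallux_distal_phalanx": ((237.0, 19.0, 11.5), (252.0, 20.0, 10.5), 6.0, 5.0),
    "phalanges_ray2": ((206.0, 3.0, 12.0), (232.0, 4.0, 10.0), 5.0, 4.5),
    "phalanges_ray3": ((201.0, -10.0, 11.5), (225.0, -10.0, 10.0), 5.0, 4.5),
    "phalanges_ray4": ((194.0, -20.0, 11.0), (216.0, -20.0, 9.5), 4.5, 4.0),
    "phalanges_ray5": ((186.0, -30.0, 10.5), (206.0, -30.0, 9.5), 4.5, 4.0),
}

# spheres: name -> (center, radius)
_SPHERES: dict[str, tuple] = {
    "sesamoid_medial": ((188.0, 10.0, 7.5), 2.5),
    "sesamoid_lateral": ((188.0, 24.0, 7.5), 2.5),
    "os_peroneum": ((116.0, -36.0, 16.0), 3.0),
}

_MET_HEADS = {f"metatarsal_{i}": _LONG_BONES[f"metatarsal_{i}"][1] for i in range(1, 6)}

# landmarks: bone -> {name: global template point}
_LANDMARKS: dict[str, dict[str, tuple]] = {
    "tibia": {
        "medial_malleolus": (55.0, 29.0, 55.0),
        "tibial_tuberosity": (85.0, 11.0, 375.0),
        "ankle_center": (60.0, -1.0, 45.0),
        "shaft_top": (60.0, 6.0, 380.0),
    },
    "fibula": {
        "lateral_malleolus": (52.0, -31.0, 50.0),
        "shaft_top": (52.0, -28.0, 365.0),
    },
    "talus": {"dome": (70.0, -1.0, 61.0)},
    "calcaneus": {
        "tuberosity": (8.0, -6.0, 30.0),
        "heel_plantar": (30.0, -6.0, 10.0),
    },
    "navicular": {"tuberosity": (110.0, 16.0, 38.0)},
    "metatarsal_1": {"head_plantar": (193.0, 16.0, 10.0)},
    "metatarsal_2": {"head_plantar": (198.0, 2.0, 10.0)},
    "metatarsal_3": {"head_plantar": (194.0, -9.0, 10.0)},
    "metatarsal_4": {"head_plantar": (188.0, -18.0, 10.0)},
    "metatarsal_5": {"head_plantar": (180.0, -27.0, 10.0)},
    "hallux_distal_phalanx": {"tip": (253.0, 20.0, 10.0)},
}


def _ligament_table() -> list[dict]:
    """Ligament inventory: name, bones, anchor region, category, bundles, area.

    Anchors are template-global points near the joint; the builder
    projects each end onto its bone surface toward the anchor.  Areas
    (mm², totals across a bundle) are representative defaults and
    user-overridable through the tissue inventory.
    """
    L = []

    def lig(name, bone_a, bone_b, anchor, category="default", bundles=1,
            area=15.0, anchor_b=None):
        L.append(dict(name=name, bone_a=bone_a, bone_b=bone_b, anchor=anchor,
                      anchor_b=anchor_b or anchor, category=category,
                      bundle_count=bundles, area=area))

    # lateral hindfoot group (CT posture slightly inverted -> slack = reference)
    lig("ATFL", "fibula", "talus", (68.0, -22.0, 50.0), "lateral_hindfoot", 10, 25.0)
    lig("CFL", "fibula", "calcaneus", (50.0, -24.0, 35.0), "lateral_hindfoot", 10, 20.0)
    lig("PTFL", "fibula", "talus", (48.0, -16.0, 48.0), "lateral_hindfoot", 10, 30.0)
    lig("lateral_talocalcaneal", "talus", "calcaneus", (66.0, -16.0, 40.0),
        "lateral_hindfoot", 10, 12.0)
    lig("lateral_calcaneocuboid", "calcaneus", "cuboid", (92.0, -20.0, 28.0),
        "lateral_hindfoot", 1, 10.0)
    lig("bifurcate_calcaneonavicular", "calcaneus", "navicular",
        (92.0, -4.0, 40.0), "lateral_hindfoot", 1, 10.0)
    lig("bifurcate_calcaneocuboid", "calcaneus", "cuboid", (90.0, -12.0, 32.0),
        "lateral_hindfoot", 1, 10.0)

    # medial / deltoid complex and interosseous (default 1.1x slack rule)
    lig("deltoid_tibiotalar_anterior", "tibia", "talus", (68.0, 16.0, 50.0),
        "default", 10, 30.0)
    lig("deltoid_tibiocalcaneal", "tibia", "calcaneus", (54.0, 14.0, 38.0),
        "default", 10, 30.0)
    lig("deltoid_tibiotalar_posterior", "tibia", "talus", (54.0, 10.0, 48.0),
        "default", 10, 30.0)
    lig("deltoid_tibionavicular", "tibia", "navicular", (80.0, 16.0, 48.0),
        "default", 1, 15.0)
    lig("interosseous_talocalcaneal", "talus", "calcaneus", (66.0, -2.0, 40.0),
        "default", 10, 50.0)
    lig("anterior_tibiofibular", "tibia", "fibula", (58.0, -14.0, 62.0),
        "default", 1, 20.0)
    lig("posterior_tibiofibular", "tibia", "fibula", (48.0, -14.0, 58.0),
        "default", 1, 20.0)
    lig("talonavicular_dorsal", "talus", "navicular", (98.0, 2.0, 52.0),
        "default", 10, 15.0)
    lig("calcaneocuboid_dorsal", "calcaneus", "cuboid", (92.0, -16.0, 36.0),
        "default", 10, 12.0)

    # plantar group (slack = reference length)
    lig("spring_calcaneonavicular", "calcaneus", "navicular", (95.0, 6.0, 30.0),
        "plantar", 1, 50.0)
    lig("short_plantar_calcaneocuboid", "calcaneus", "cuboid", (90.0, -16.0, 16.0),
        "plantar", 1, 60.0)
    lig("long_plantar", "calcaneus", "cuboid", (80.0, -14.0, 12.0),
        "plantar", 1, 80.0, anchor_b=(108.0, -22.0, 13.0))
    lig("plantar_cubonavicular", "cuboid", "navicular", (108.0, -8.0, 28.0),
        "plantar", 1, 12.0)
    lig("plantar_cuneonavicular_medial", "navicular", "cuneiform_medial",
        (121.0, 8.0, 30.0), "plantar", 1, 12.0)
    lig("plantar_cuneonavicular_intermediate", "navicular",
        "cuneiform_intermediate", (122.0, 0.0, 32.0), "plantar", 1, 10.0)
    lig("plantar_cuneonavicular_lateral", "navicular", "cuneiform_lateral",
        (122.0, -6.0, 28.0), "plantar", 1, 10.0)
    lig("plantar_cuneocuboid", "cuboid", "cuneiform_lateral",
        (122.0, -16.0, 24.0), "plantar", 1, 10.0)
    lig("plantar_intercuneiform_mi", "cuneiform_medial", "cuneiform_intermediate",
        (133.0, 4.0, 32.0), "plantar", 1, 8.0)
    lig("plantar_intercuneiform_il", "cuneiform_intermediate", "cuneiform_lateral",
        (134.0, -7.0, 30.0), "plantar", 1, 8.0)
    for i, cun in ((1, "cuneiform_medial"), (2, "cuneiform_intermediate"),
                   (3, "cuneiform_lateral"), (4, "cuboid"), (5, "cuboid")):
        base = _LONG_BONES[f"metatarsal_{i}"][0]
        anchor = (base[0] - 4.0, base[1], base[2] - 6.0)
        lig(f"plantar_tarsometatarsal_{i}", cun, f"metatarsal_{i}", anchor,
            "plantar", 1, 30.0)
        anchor_d = (base[0] - 4.0, base[1], base[2] + 6.0)
        lig(f"dorsal_tarsometatarsal_{i}", cun, f"metatarsal_{i}", anchor_d,
            "default", 1, 20.0)
    for i in range(1, 5):  # deep transverse metatarsal
        ha = _MET_HEADS[f"metatarsal_{i}"]
        hb = _MET_HEADS[f"metatarsal_{i + 1}"]
        anchor = ((ha[0] + hb[0]) / 2, (ha[1] + hb[1]) / 2,
                  (ha[2] + hb[2]) / 2 - 5.0)
        lig(f"plantar_metatarsal_{i}{i + 1}", f"metatarsal_{i}",
            f"metatarsal_{i + 1}", anchor, "plantar", 1, 10.0)
    # sesamoid suspension
    lig("sesamoid_medial_met1", "metatarsal_1", "sesamoid_medial",
        (189.0, 12.0, 12.0), "plantar", 1, 10.0)
    lig("sesamoid_lateral_met1", "metatarsal_1", "sesamoid_lateral",
        (189.0, 20.0, 12.0), "plantar", 1, 10.0)
    lig("sesamoid_medial_phalanx", "sesamoid_medial", "hallux_proximal_phalanx",
        (200.0, 14.0, 10.0), "plantar", 1, 10.0)
    lig("sesamoid_lateral_phalanx", "sesamoid_lateral", "hallux_proximal_phalanx",
        (200.0, 20.0, 10.0), "plantar", 1, 10.0)
    lig("os_peroneum_cuboid", "cuboid", "os_peroneum", (112.0, -32.0, 18.0),
        "plantar", 1, 8.0)
    return L


#: torsional capsule overrides, N*mm/rad: the wedged, interlocking
#: midfoot articulations are far more congruent in rotation than the
#: mobile hindfoot joints
MIDFOOT_TORSION = 30000.0
_TORSION_OVERRIDES = {
    "naviculocuneiform_medial": MIDFOOT_TORSION,
    "naviculocuneiform_intermediate": MIDFOOT_TORSION,
    "naviculocuneiform_lateral": MIDFOOT_TORSION,
    "cuboideonavicular": MIDFOOT_TORSION,
    "intercuneiform_mi": MIDFOOT_TORSION,
    "intercuneiform_il": MIDFOOT_TORSION,
    "cuneocuboid": MIDFOOT_TORSION,
    "tarsometatarsal_1": MIDFOOT_TORSION,
    "tarsometatarsal_2": MIDFOOT_TORSION,
    "tarsometatarsal_3": MIDFOOT_TORSION,
    "tarsometatarsal_4": MIDFOOT_TORSION,
    "tarsometatarsal_5": MIDFOOT_TORSION,
    "intermetatarsal_12": MIDFOOT_TORSION,
    "tibiofibular_syndesmosis": MIDFOOT_TORSION,
}


def _cartilage_table() -> list[tuple[str, str, str, float]]:
    """(name, bone_a, bone_b, proxy sphere radius)."""
    pairs = [
        ("tibiofibular_syndesmosis", "tibia", "fibula", 6.0),
        ("talocrural", "tibia", "talus", 10.0),
        ("talofibular", "fibula", "talus", 6.0),
        ("talocalcaneal", "talus", "calcaneus", 10.0),
        ("talonavicular", "talus", "navicular", 8.0),
        ("calcaneocuboid", "calcaneus", "cuboid", 8.0),
        ("naviculocuneiform_medial", "navicular", "cuneiform_medial", 6.0),
        ("naviculocuneiform_intermediate", "navicular", "cuneiform_intermediate", 5.0),
        ("naviculocuneiform_lateral", "navicular", "cuneiform_lateral", 5.0),
        ("cuboideonavicular", "cuboid", "navicular", 5.0),
        ("intercuneiform_mi", "cuneiform_medial", "cuneiform_intermediate", 5.0),
        ("intercuneiform_il", "cuneiform_intermediate", "cuneiform_lateral", 5.0),
        ("cuneocuboid", "cuneiform_lateral", "cuboid", 5.0),
        ("tarsometatarsal_1", "cuneiform_medial", "metatarsal_1", 6.0),
        ("tarsometatarsal_2", "cuneiform_intermediate", "metatarsal_2", 5.0),
        ("tarsometatarsal_3", "cuneiform_lateral", "metatarsal_3", 5.0),
        ("tarsometatarsal_4", "cuboid", "metatarsal_4", 5.0),
        ("tarsometatarsal_5", "cuboid", "metatarsal_5", 5.0),
        ("intermetatarsal_12", "metatarsal_1", "metatarsal_2", 4.0),
        ("mtp_1", "metatarsal_1", "hallux_proximal_phalanx", 6.0),
        ("hallux_ip", "hallux_proximal_phalanx", "hallux_distal_phalanx", 4.0),
        ("mtp_2", "metatarsal_2", "phalanges_ray2", 4.5),
        ("mtp_3", "metatarsal_3", "phalanges_ray3", 4.5),
        ("mtp_4", "metatarsal_4", "phalanges_ray4", 4.0),
        ("mtp_5", "metatarsal_5", "phalanges_ray5", 4.0),
        ("sesamoid_medial_met1", "metatarsal_1", "sesamoid_medial", 2.5),
        ("sesamoid_lateral_met1", "metatarsal_1", "sesamoid_lateral", 2.5),
    ]
    return pairs


#: plantar soft-tissue column anchors: (name, bone, global template point, area mm^2)
def _column_table() -> list[tuple[str, str, tuple, float]]:
    cols = [
        ("column_heel_center", "calcaneus", (28.0, -6.0, 10.0), 900.0),
        ("column_heel_medial", "calcaneus", (50.0, 7.0, 13.0), 900.0),
        ("column_heel_lateral", "calcaneus", (50.0, -19.0, 13.0), 900.0),
        ("column_heel_postmedial", "calcaneus", (36.0, 6.0, 12.0), 450.0),
        ("column_heel_postlateral", "calcaneus", (36.0, -18.0, 12.0), 450.0),
        ("column_cuboid", "cuboid", (106.0, -30.0, 15.0), 350.0),
        ("column_met5_base", "metatarsal_5", (146.0, -31.0, 20.0), 300.0),
        ("column_hallux", "hallux_distal_phalanx", (243.0, 19.0, 6.5), 500.0),
    ]
    for i in range(1, 6):
        h = _MET_HEADS[f"metatarsal_{i}"]
        area = 800.0 if i <= 2 else 600.0
        cols.append((f"column_met{i}", f"metatarsal_{i}",
                     (h[0], h[1], 10.0), area))
    for ray, seg in ((2, "phalanges_ray2"), (3, "phalanges_ray3"),
                     (4, "phalanges_ray4"), (5, "phalanges_ray5")):
        c = _LONG_BONES[seg]
        mid = tuple((np.array(c[0]) + np.array(c[1])) / 2.0)
        cols.append((f"column_toe{ray}", seg, (mid[0], mid[1], 7.0), 250.0))
    cols.append(("column_sesamoid", "sesamoid_medial", (188.0, 10.0, 5.0), 300.0))
    return cols


def _muscle_table() -> dict[str, dict]:
    """Muscle line-of-action templates: origin/via on the shank, insertion on foot."""
    return {
        "TS": dict(origin=("tibia", (45.0, 2.0, 340.0)), via=[],
                   insertion=("calcaneus", (8.0, -6.0, 34.0))),
        "TA": dict(origin=("tibia", (72.0, 10.0, 300.0)),
                   via=[("tibia", (72.0, 8.0, 80.0))],
                   insertion=("cuneiform_medial", (128.0, 16.0, 34.0))),
        "EDL": dict(origin=("fibula", (58.0, -24.0, 300.0)),
                    via=[("tibia", (70.0, -6.0, 75.0))],
                    insertion=("phalanges_ray3", (205.0, -8.0, 15.0))),
        "EHL": dict(origin=("fibula", (58.0, -22.0, 320.0)),
                    via=[("tibia", (72.0, 6.0, 78.0))],
                    insertion=("hallux_proximal_phalanx", (215.0, 18.0, 20.0))),
    }


def _pa_table() -> dict:
    """Plantar aponeurosis: origin region and per-slip insertion rays.

    Slip 1 routes through the medial sesamoid to the hallux; slips 2-9
    wrap the head cylinders of rays 2-5 (two slips per ray); slip 10 is
    the most medial band to the hallux wrapping the first head cylinder.
    Total cross-section 50 mm² split evenly.
    """
    rays = {1: "hallux_proximal_phalanx", 2: "phalanges_ray2",
            3: "phalanges_ray3", 4: "phalanges_ray4", 5: "phalanges_ray5"}
    slips = []
    assignment = [(1, 1, True), (2, 2, False), (3, 2, False), (4, 3, False),
                  (5, 3, False), (6, 4, False), (7, 4, False), (8, 5, False),
                  (9, 5, False), (10, 1, False)]
    for index, ray, via_ses in assignment:
        slips.append(dict(index=index, ray=ray, insertion_bone=rays[ray],
                          via_sesamoid=via_ses))
    return dict(origin=("calcaneus", (24.0, -6.0, 11.0)), slips=slips,
                total_area=50.0)


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def _ellipsoid_mesh(semi_axes, subdivisions: int) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.vertices = mesh.vertices * np.asarray(semi_axes, float)
    return mesh

def _ellipsoid_inertia(mass: float, semi_axes) -> np.ndarray:
    a, b, c = semi_axes
    return np.diag([mass / 5.0 * (b * b + c * c),
                    mass / 5.0 * (a * a + c * c),
                    mass / 5.0 * (a * a + b * b)])


def _rotation_to_x(direction: np.ndarray) -> np.ndarray:
    """Rotation taking local +x to ``direction`` (minimal twist)."""
    d = direction / np.linalg.norm(direction)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, d)
    s = np.linalg.norm(v)
    cth = float(np.dot(x, d))
    if s < 1e-12:
        return np.eye(3) if cth > 0 else np.diag([-1.0, 1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - cth) / (s * s))


def _project_to_ellipsoid(local_point: np.ndarray, semi_axes) -> np.ndarray:
    """Radial projection onto the ellipsoid surface (exact on-surface)."""
    p = np.asarray(local_point, float)
    semi = np.asarray(semi_axes, float)
    r = np.linalg.norm(p / semi)
    if r < 1e-9:
        return np.array([0.0, 0.0, semi[2]])
    return p / r


class _TemplateBuilder:
    """Assembles the template at unit scale, then applies scale/side."""

    def __init__(self, params: BuildParams):
        self.p = params
        self.s = params.scale / TEMPLATE_FOOT_LENGTH
        self.arch_f = params.arch_height_ratio / TEMPLATE_ARCH_RATIO
        self.bones: dict[str, Bone] = {}
        self.semi_axes: dict[str, np.ndarray] = {}
        self.attachments: dict[str, Attachment] = {}
        self.cartilage_pairs: list[CartilagePair] = []
        self.wrap_cylinders: dict[str, WrapCylinder] = {}
        self.column_specs: list[dict] = []
        self.ligament_specs: list[dict] = []
        self.muscle_specs: dict[str, dict] = {}
        self.pa_spec: dict = {}

    # -- template-space coordinate transforms -------------------------
    def _arch_z(self, bone: str, z: float) -> float:
        """Scale height above the sole for arch bones (template space)."""
        if bone in ARCH_BONES:
            return z * self.arch_f
        return z

    def _point(self, bone: str, template_xyz) -> np.ndarray:
        x, y, z = template_xyz
        z = self._arch_z(bone, z)
        p = np.array([x, y, z]) * self.s
        if self.p.side == "left":
            p[1] = -p[1]
        return p

    # -- bones ---------------------------------------------------------
    def _add_bone(self, name, center_t, semi_axes_t, direction=None):
        center = self._point(name, center_t)
        semi = np.asarray(semi_axes_t, float) * self.s
        mesh = _ellipsoid_mesh(semi, self.p.mesh_subdivisions)
        density = 1.5e-3 * self.p.tissue_mass_factor
        volume = 4.0 / 3.0 * np.pi * semi.prod()
        mass = max(volume * density, self.p.min_bone_mass)
        inertia = _ellipsoid_inertia(mass, semi)
        if direction is None:
            R = np.eye(3)
        else:
            d = np.asarray(direction, float)
            if self.p.side == "left":
                d = d * np.array([1.0, -1.0, 1.0])
            R = _rotation_to_x(d / np.linalg.norm(d))
        self.bones[name] = Bone(name=name, mass=mass, centroid=center,
                                inertia=inertia, orientation=R, surface=mesh,
                                landmarks={},
                                parts=[(np.zeros(3), np.eye(3), semi)])
        self.semi_axes[name] = semi

    def build_bones(self):
        for name, (c, semi, _) in _ELLIPSOIDS.items():
            self._add_bone(name, c, semi)
        for name, (base, head, ry, rz) in _LONG_BONES.items():
            b = self._point(name, base)
            h = self._point(name, head)
            d = h - b
            length = np.linalg.norm(d)
            center = (b + h) / 2.0
            semi = np.array([length / 2.0 + 1.0 * self.s,
                             ry * self.s, rz * self.s])
            mesh = _ellipsoid_mesh(semi, self.p.mesh_subdivisions)
            density = 1.5e-3 * self.p.tissue_mass_factor
            mass = max(4.0 / 3.0 * np.pi * semi.prod() * density,
                       self.p.min_bone_mass)
            R = _rotation_to_x(d)
            self.bones[name] = Bone(
                name=name, mass=mass, centroid=center,
                inertia=_ellipsoid_inertia(mass, semi), orientation=R,
                surface=mesh, landmarks={},
                parts=[(np.zeros(3), np.eye(3), semi)],
            )
            self.semi_axes[name] = semi
        for name, (c, r) in _SPHERES.items():
            self._add_bone(name, c, (r, r, r))

    def add_landmarks(self):
        for bone_name, lm in _LANDMARKS.items():
            bone = self.bones[bone_name]
            for lname, pt in lm.items():
                bone.landmarks[lname] = bone.to_local(self._point(bone_name, pt))
        # plantar-most point of every bone (analytic ellipsoid support
        # point in the -z direction), useful for audits
        down = np.array([0.0, 0.0, -1.0])
        for name, bone in self.bones.items():
            best = None
            for offset, Rp, semi in bone.parts:
                d_part = Rp.T @ (bone.orientation.T @ down)
                sd = semi * semi * d_part
                x_part = sd / np.linalg.norm(semi * d_part)
                local = offset + Rp @ x_part
                z = bone.to_global(local)[2]
                if best is None or z < best[0]:
                    best = (z, local)
            bone.landmarks.setdefault("plantar_low", best[1])

    # -- attachments ---------------------------------------------------
    def _surface_attachment(self, name: str, bone_name: str, toward_global):
        """Attachment on the bone surface, radially toward a target point."""
        bone = self.bones[bone_name]
        local = bone.orientation.T @ (np.asarray(toward_global) - bone.centroid)
        on_surf = _project_to_ellipsoid(local, self.semi_axes[bone_name])
        self.attachments[name] = Attachment(bone=bone_name, local=on_surf)

    def build_tissue_anchors(self):
        for spec in _ligament_table():
            anchor = self._point(spec["bone_a"], spec["anchor"])
            anchor_b = self._point(spec["bone_b"], spec["anchor_b"])
            self._surface_attachment(f"lig:{spec['name']}:origin",
                                     spec["bone_a"], anchor)
            self._surface_attachment(f"lig:{spec['name']}:insertion",
                                     spec["bone_b"], anchor_b)
            self.ligament_specs.append(spec)
        for cname, bone, pt, area in _column_table():
            bone_obj = self.bones[bone]
            target = self._point(bone, pt)
            # anchor on the plantar surface straight below the target
            local = bone_obj.to_local(target)
            on_surf = _project_to_ellipsoid(local, self.semi_axes[bone])
            self.attachments[f"col:{cname}"] = Attachment(bone=bone, local=on_surf)
            self.column_specs.append(dict(name=cname, bone=bone, area=area))
        for mname, spec in _muscle_table().items():
            pts = [("origin", spec["origin"])] + [
                (f"via{i}", v) for i, v in enumerate(spec["via"])
            ] + [("insertion", spec["insertion"])]
            stored = []
            for tag, (bone, pt) in pts:
                key = f"mus:{mname}:{tag}"
                self._surface_attachment(key, bone, self._point(bone, pt))
                stored.append(key)
            self.muscle_specs[mname] = dict(points=stored)
        # plantar aponeurosis
        pa = _pa_table()
        o_bone, o_pt = pa["origin"]
        self._surface_attachment("pa:origin", o_bone, self._point(o_bone, o_pt))
        for slip in pa["slips"]:
            ins_bone = slip["insertion_bone"]
            base, head, *_ = _LONG_BONES[ins_bone]
            frac = 0.25  # plantar base of the phalanx
            tgt = (np.array(base) * (1 - frac) + np.array(head) * frac)
            tgt[2] -= 6.0
            self._surface_attachment(f"pa:slip{slip['index']}:insertion",
                                     ins_bone, self._point(ins_bone, tuple(tgt)))
        self.pa_spec = pa

    def build_cartilage(self):
        for cname, a, b, radius in _cartilage_table():
            ba, bb = self.bones[a], self.bones[b]
            u = bb.centroid - ba.centroid
            dist = np.linalg.norm(u)
            u = u / dist
            # surface points along the centroid line
            sa = ba.centroid + u * self._support_dist(a, u, ba)
            sb = bb.centroid - u * self._support_dist(b, -u, bb)
            joint = (sa + sb) / 2.0
            r = radius * self.s
            ca = ba.to_local(joint - u * r)
            cb = bb.to_local(joint + u * r)
            self.cartilage_pairs.append(CartilagePair(
                name=cname, bone_a=a, bone_b=b, center_a_local=ca,
                center_b_local=cb, radius_a=r, radius_b=r,
                joint_a_local=ba.to_local(joint),
                joint_b_local=bb.to_local(joint),
                capsule_torsion=_TORSION_OVERRIDES.get(cname, 5000.0),
            ))

    def _support_dist(self, name, u_global, bone) -> float:
        """Distance from the centroid to the surface along unit vector u."""
        u_local = bone.orientation.T @ u_global
        semi = self.semi_axes[name]
        return 1.0 / np.linalg.norm(u_local / semi)

    def build_wrap_cylinders(self):
        for i in range(1, 6):
            name = f"metatarsal_{i}"
            bone = self.bones[name]
            head = self._point(name, _MET_HEADS[name])
            ry = _LONG_BONES[name][2] * self.s
            axis = bone.orientation.T @ np.array([0.0, 1.0, 0.0])
            self.wrap_cylinders[name] = WrapCylinder(
                bone=name, center_local=bone.to_local(head),
                axis_local=axis / np.linalg.norm(axis), radius=ry + 1.5 * self.s,
            )

    def merge_lesser(self):
        """Fuse the four lesser-ray segments into one rigid body."""
        segs = [self.bones.pop(n) for n in LESSER_RAY_SEGMENTS]
        mass = sum(b.mass for b in segs)
        centroid = sum(b.mass * b.centroid for b in segs) / mass
        meshes = []
        inertia = np.zeros((3, 3))
        for b in segs:
            verts = b.vertices_global - centroid
            meshes.append(trimesh.Trimesh(
                vertices=verts, faces=b.surface.faces, process=False))
            d = b.centroid - centroid
            R = b.orientation
            I_g = R @ b.inertia @ R.T
            inertia += I_g + b.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
        merged = trimesh.util.concatenate(meshes)
        fused = Bone(name="phalanges_fused", mass=mass, centroid=centroid,
                     inertia=inertia, orientation=np.eye(3), surface=merged,
                     landmarks={},
                     parts=[(b.centroid - centroid, b.orientation,
                             self.semi_axes[b.name]) for b in segs])
        for b in segs:
            for lname, lp in b.landmarks.items():
                fused.landmarks[f"{b.name}:{lname}"] = fused.to_local(
                    b.to_global(lp))
        self.bones["phalanges_fused"] = fused
        self.semi_axes["phalanges_fused"] = None
        remap = {n: "phalanges_fused" for n in LESSER_RAY_SEGMENTS}
        new_att = {}
        for key, att in self.attachments.items():
            if att.bone in remap:
                gp = None
                for b in segs:
                    if b.name == att.bone:
                        gp = b.to_global(att.local)
                new_att[key] = Attachment(bone="phalanges_fused",
                                          local=fused.to_local(gp))
            else:
                new_att[key] = att
        self.attachments = new_att
        self.cartilage_pairs = [
            CartilagePair(
                name=cp.name, bone_a=remap.get(cp.bone_a, cp.bone_a),
                bone_b=remap.get(cp.bone_b, cp.bone_b),
                center_a_local=(cp.center_a_local if cp.bone_a not in remap else
                                fused.to_local(next(b for b in segs
                                                    if b.name == cp.bone_a)
                                               .to_global(cp.center_a_local))),
                center_b_local=(cp.center_b_local if cp.bone_b not in remap else
                                fused.to_local(next(b for b in segs
                                                    if b.name == cp.bone_b)
                                               .to_global(cp.center_b_local))),
                joint_a_local=(cp.joint_a_local if cp.bone_a not in remap else
                               fused.to_local(next(b for b in segs
                                                   if b.name == cp.bone_a)
                                              .to_global(cp.joint_a_local))),
                joint_b_local=(cp.joint_b_local if cp.bone_b not in remap else
                               fused.to_local(next(b for b in segs
                                                   if b.name == cp.bone_b)
                                              .to_global(cp.joint_b_local))),
                radius_a=cp.radius_a, radius_b=cp.radius_b,
                capsule_stiffness=cp.capsule_stiffness,
            )
            for cp in self.cartilage_pairs
            if not (cp.bone_a in remap and cp.bone_b in remap)
        ]
        for spec in self.ligament_specs:
            spec["bone_a"] = remap.get(spec["bone_a"], spec["bone_a"])
            spec["bone_b"] = remap.get(spec["bone_b"], spec["bone_b"])
        for spec in self.column_specs:
            spec["bone"] = remap.get(spec["bone"], spec["bone"])


@dataclass
class FootModel:
    """The assembled synthetic skeleton plus its tissue anchor inventory."""

    bones: dict[str, Bone]
    attachments: dict[str, Attachment]
    cartilage_pairs: list[CartilagePair]
    wrap_cylinders: dict[str, WrapCylinder]
    ligament_specs: list[dict]
    column_specs: list[dict]
    muscle_specs: dict[str, dict]
    pa_spec: dict
    build_params: BuildParams

    @property
    def bone_names(self) -> tuple[str, ...]:
        return tuple(self.bones)

    @property
    def expected_bone_names(self) -> tuple[str, ...]:
        if self.build_params.merge_lesser_rays:
            return tuple(n for n in BONE_ENUMERATION
                         if n not in LESSER_RAY_SEGMENTS) + ("phalanges_fused",)
        return BONE_ENUMERATION

    def attachment_global(self, name: str) -> np.ndarray:
        att = self.attachments[name]
        return self.bones[att.bone].to_global(att.local)

    def landmark_global(self, spec: str) -> np.ndarray:
        bone, lname = spec.split(":")
        return self.bones[bone].landmark_global(lname)

    @property
    def ankle_center(self) -> np.ndarray:
        return self.bones["tibia"].landmark_global("ankle_center")

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bones.values()))

    def all_landmarks_global(self) -> dict[str, np.ndarray]:
        out = {}
        for bname, bone in self.bones.items():
            for lname in bone.landmarks:
                out[f"{bname}:{lname}"] = bone.landmark_global(lname)
        return out

    def export_obj(self, directory):
        """One OBJ object per bone, named, in global build coordinates."""
        import os

        os.makedirs(directory, exist_ok=True)
        for name, bone in self.bones.items():
            mesh = trimesh.Trimesh(vertices=bone.vertices_global,
                                   faces=bone.surface.faces, process=False)
            mesh.export(os.path.join(directory, f"{name}.obj"))

    def params_yaml(self) -> str:
        from dataclasses import asdict

        return yaml.safe_dump(asdict(self.build_params), sort_keys=False)


def build_foot(params: BuildParams | None = None) -> FootModel:
    """Build the synthetic foot skeleton.

    Deterministic for fixed parameters (the seed is recorded for
    downstream consumers; the template itself contains no randomness).
    """
    p = params or BuildParams()
    tb = _TemplateBuilder(p)
    tb.build_bones()
    tb.add_landmarks()
    tb.build_tissue_anchors()
    tb.build_cartilage()
    tb.build_wrap_cylinders()
    if p.merge_lesser_rays:
        tb.merge_lesser()
    return FootModel(
        bones=tb.bones, attachments=tb.attachments,
        cartilage_pairs=tb.cartilage_pairs, wrap_cylinders=tb.wrap_cylinders,
        ligament_specs=tb.ligament_specs, column_specs=tb.column_specs,
        muscle_specs=tb.muscle_specs, pa_spec=tb.pa_spec, build_params=p,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    kind: str
    subject: str
    detail: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.subject}: {self.detail}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind, subject, detail):
        self.violations.append(Violation(kind, subject, detail))

    def __str__(self) -> str:
        if self.ok:
            return "model valid: no violations"
        return "\n".join(str(v) for v in self.violations)


def validate_model(
    model: FootModel,
    penetration_tol: float = 0.5,
    attachment_tol: float = 1.0,
    coplanar_tol: float = 4.0,
) -> ValidationReport:
    """Check every structural invariant of the skeleton; report violations.

    Checks: exact bone enumeration; positive masses; symmetric
    positive-definite inertias; watertight outward meshes; attachments
    within ``attachment_tol`` mm of their host surface; no bone-bone
    mesh penetration beyond ``penetration_tol`` mm; plantigrade
    coplanarity of the calcaneal and metatarsal-head plantar points
    within ``coplanar_tol`` mm.
    """
    rep = ValidationReport()
    expected = set(model.expected_bone_names)
    got = set(model.bones)
    if got != expected:
        missing = expected - got
        extra = got - expected
        rep.add("enumeration", "bones",
                f"missing={sorted(missing)} extra={sorted(extra)}")
    for name, bone in model.bones.items():
        if not bone.mass > 0:
            rep.add("mass", name, f"mass {bone.mass} not positive")
        sym_err = np.abs(bone.inertia - bone.inertia.T).max()
        if sym_err > 1e-9 * max(1.0, np.abs(bone.inertia).max()):
            rep.add("inertia", name, f"asymmetric (max err {sym_err:.3g})")
        else:
            eig = np.linalg.eigvalsh(bone.inertia)
            if eig.min() <= 0:
                rep.add("inertia", name, f"not positive definite (min eig {eig.min():.3g})")
        if not bone.surface.is_watertight:
            rep.add("mesh", name, "surface not watertight")
        elif bone.surface.volume < 0:
            rep.add("mesh", name, "surface inward-oriented")
        R = bone.orientation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            rep.add("orientation", name, "axes not orthonormal")

    # attachment proximity (analytic ellipsoid distance; positive = outside)
    for aname, att in model.attachments.items():
        if att.bone not in model.bones:
            rep.add("attachment", aname, f"host bone {att.bone!r} missing")
            continue
        bone = model.bones[att.bone]
        d = float(bone.signed_distance_local(att.local)[0])
        if d > attachment_tol:
            rep.add("attachment", aname,
                    f"{d:.2f} mm off the {att.bone} surface")

    # pairwise penetration (bounding-sphere prefilter, vertex sampling)
    names = list(model.bones)
    centers = {n: model.bones[n].centroid for n in names}
    radii = {n: np.linalg.norm(
        model.bones[n].surface.vertices, axis=1).max() for n in names}
    verts_global = {n: model.bones[n].vertices_global for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.linalg.norm(centers[a] - centers[b]) > radii[a] + radii[b]:
                continue
            depth = max(
                -float(model.bones[b].signed_distance_global(
                    verts_global[a]).min()),
                -float(model.bones[a].signed_distance_global(
                    verts_global[b]).min()),
                0.0,
            )
            if depth > penetration_tol:
                rep.add("penetration", f"{a}/{b}",
                        f"max penetration {depth:.2f} mm")

    # plantigrade coplanarity
    lows = []
    for n in ("calcaneus", "metatarsal_1", "metatarsal_2", "metatarsal_3",
              "metatarsal_4", "metatarsal_5"):
        if n in model.bones:
            lows.append(model.bones[n].vertices_global[:, 2].min())
        elif "phalanges_fused" in model.bones and n.startswith("phal"):
            pass
    if lows:
        spread = max(lows) - min(lows)
        if spread > coplanar_tol:
            rep.add("plantigrade", "calcaneus/metatarsal heads",
                    f"plantar-most points spread {spread:.2f} mm")
    return rep


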