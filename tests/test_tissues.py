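"""Ligament chains, aponeurosis wrapping, muscles, soft-tissue columns."""

import numpy as np
import pytest

from pedsim.foot_model import build_foot
from pedsim.materials import MaterialSet, OgdenParams, PronyParams, \
    ogden_uniaxial_stress
from pedsim.tissues import (
    AponeurosisSlip,
    LigamentChain,
    MusclePath,
    SoftTissueColumn,
    TissueError,
    assign_slack_length,
    build_aponeurosis,
    build_columns,
    build_ligaments,
    build_muscles,
    chain_tension,
    column_force,
    cylinder_wrap_length,
    muscle_force_at,
    resolve_sphere_contacts,
    slip_path_length,
)


class TestSlackLength:
    @pytest.mark.parametrize("category,expected", [
        ("default", 22.0),            # 1.1 x reference
        ("lateral_hindfoot", 20.0),   # reference length (stretched in CT pose)
        ("plantar", 20.0),            # reference length (not shortened)
    ])
    def test_category_rules(self, category, expected):
        assert assign_slack_length(20.0, category) == pytest.approx(expected)

    def test_unknown_category(self):
        with pytest.raises(TissueError, match="unknown"):
            assign_slack_length(20.0, "dorsal")

    def test_nonpositive_reference(self):
        with pytest.raises(TissueError):
            assign_slack_length(0.0, "default")


def _chain(slack=20.0, E=260.0, area=10.0, bundles=1):
    nodes = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    return LigamentChain(
        name="test", category="default", bone_a="a", bone_b="b",
        origin_local=nodes[0], insertion_local=nodes[-1], nodes=nodes,
        E=E, area=area, slack_length=slack, bundle_count=bundles,
    )


class TestChainTension:
    def test_slack_chain_carries_nothing(self):
        assert chain_tension(19.0, _chain()) == 0.0
        assert chain_tension(20.0, _chain()) == 0.0

    def test_linear_beyond_slack(self):
        # EA/L0 * dL = 260*10/20 * 2 = 260 N
        assert chain_tension(22.0, _chain()) == pytest.approx(260.0)

    def test_never_negative(self, rng):
        ch = _chain()
        for L in rng.uniform(0.1, 40.0, 200):
            assert chain_tension(float(L), ch) >= 0.0

    def test_bundle_equivalence(self):
        """Ten strands of area A/10 on one path == one chain of area A."""
        single = _chain(area=10.0, bundles=1)
        strand = _chain(area=1.0, bundles=1)
        for L in (21.0, 25.0, 30.0):
            assert 10.0 * chain_tension(L, strand) == pytest.approx(
                chain_tension(L, single), rel=1e-12)


class TestSphereContacts:
    def _setup(self, sphere_z):
        model = build_foot()
        bone = model.bones["calcaneus"]
        top = bone.centroid + np.array([0.0, 0.0, 17.0])
        nodes = np.array([
            bone.centroid + [-45.0, 0, 25.0],
            [bone.centroid[0], bone.centroid[1], sphere_z],
            bone.centroid + [45.0, 0, 25.0],
        ])
        chain = LigamentChain(
            name="over_calc", category="default", bone_a="calcaneus",
            bone_b="talus", origin_local=nodes[0], insertion_local=nodes[-1],
            nodes=nodes, E=260.0, area=10.0, slack_length=60.0,
            host_bones=("calcaneus",),
        )
        return model, chain

    def test_clear_sphere_untouched(self):
        model, chain = self._setup(sphere_z=26.0 + 16.0 + 5.0)
        nodes, forces = resolve_sphere_contacts(chain, model.bones)
        assert np.allclose(nodes, chain.nodes)
        assert np.allclose(forces, 0.0)

    def test_penetrating_sphere_pushed_to_clearance(self):
        model, chain = self._setup(sphere_z=26.0 + 16.0 - 0.2)
        nodes, forces = resolve_sphere_contacts(chain, model.bones)
        bone = model.bones["calcaneus"]
        d = float(bone.signed_distance_global(nodes[1][None])[0])
        assert d == pytest.approx(chain.sphere_radius, abs=1e-3)

    def test_contact_force_normal_only(self):
        model, chain = self._setup(sphere_z=26.0 + 16.0 - 0.2)
        nodes, forces = resolve_sphere_contacts(chain, model.bones)
        f = forces[1]
        if np.linalg.norm(f) > 0:
            from pedsim.tissues import _surface_normal
            bone = model.bones["calcaneus"]
            n = bone.orientation @ _surface_normal(
                bone, bone.to_local(nodes[1]))
            tangential = f - np.dot(f, n) * n
            assert np.linalg.norm(tangential) < 1e-9 * max(
                np.linalg.norm(f), 1.0)

    def test_taut_path_at_least_straight_distance(self):
        model, chain = self._setup(sphere_z=26.0 + 16.0 - 0.2)
        nodes, _ = resolve_sphere_contacts(chain, model.bones)
        path = np.linalg.norm(np.diff(nodes, axis=0), axis=1).sum()
        straight = np.linalg.norm(nodes[-1] - nodes[0])
        assert path >= straight - 1e-9


class TestCylinderWrap:
    CEN = np.array([0.0, 0.0, 0.0])
    AX = np.array([0.0, 1.0, 0.0])

    def test_clear_segment_is_euclidean(self):
        p = np.array([-20.0, 0.0, 30.0])
        q = np.array([20.0, 0.0, 30.0])
        L, dp, dq, wrapped = cylinder_wrap_length(p, q, self.CEN, self.AX, 5.0)
        assert not wrapped
        assert L == pytest.approx(40.0)
        assert np.allclose(dp, [1, 0, 0]) and np.allclose(dq, [-1, 0, 0])

    def test_diametric_wrap_against_polyline_oracle(self):
        r = 5.0
        p = np.array([-20.0, 0.0, -0.5])
        q = np.array([20.0, 0.0, 0.5])
        L, dp, dq, wrapped = cylinder_wrap_length(p, q, self.CEN, self.AX, r)
        assert wrapped and L > 40.0
        oracle = _shortest_path_around_cylinder(p, q, self.CEN, self.AX, r)
        assert L == pytest.approx(oracle, rel=1e-3)

    def test_dorsiflexion_sweep_monotone(self):
        """Insertion rotating dorsally about a fixed-side cylinder wrap
        lengthens the path monotonically through 0-40 degrees."""
        r = 8.0
        origin = np.array([-150.0, 0.0, -10.0])
        base = np.array([30.0, 2.0, -12.0])
        lengths = []
        for ang in np.deg2rad(np.linspace(0.0, 40.0, 41)):
            c, s = np.cos(ang), np.sin(ang)
            # rotate the insertion dorsally (up and forward) about the axis
            ins = np.array([base[0] * c - base[2] * s, base[1],
                            base[0] * s + base[2] * c])
            L, *_ = cylinder_wrap_length(origin, ins, self.CEN, self.AX, r,
                                         side=-1.0)
            lengths.append(L)
        assert np.all(np.diff(lengths) > -1e-9)
        assert lengths[-1] > lengths[0] + 1.0

    def test_endpoint_inside_cylinder_rejected(self):
        with pytest.raises(TissueError, match="inside"):
            cylinder_wrap_length([0.0, 0.0, 2.0], [30.0, 0.0, 0.0],
                                 self.CEN, self.AX, 5.0)


def _shortest_path_around_cylinder(p, q, center, axis, radius, n=160,
                                   iters=30000):
    """Dense-polyline numeric oracle: project-and-shorten iteration.

    Relaxed from an initial bulge on each side of the cylinder (a chord
    near the axis is radially degenerate); returns the shorter result.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    axis = np.asarray(axis, float)
    chord = q - p
    side_dir = np.cross(chord, axis)
    side_dir /= np.linalg.norm(side_dir)
    best = np.inf
    for s in (+1.0, -1.0):
        t = np.linspace(0.0, 1.0, n)[:, None]
        bulge = np.sin(np.pi * t) * (radius + 1.0) * s
        pts = p + t * chord + bulge * side_dir
        for _ in range(iters):
            pts[1:-1] = 0.5 * (pts[:-2] + pts[2:])
            rel = pts - center
            axial = rel @ axis
            radial = rel - np.outer(axial, axis)
            rho = np.linalg.norm(radial, axis=1)
            inside = rho < radius
            if inside.any():
                scale = radius / rho[inside]
                pts[inside] = (center + np.outer(axial[inside], axis)
                               + radial[inside] * scale[:, None])
            pts[0], pts[-1] = p, q
        best = min(best, float(np.linalg.norm(np.diff(pts, axis=0),
                                              axis=1).sum()))
    return best


class TestMuscleForce:
    def _path(self):
        return MusclePath(
            name="TA", points=[("tibia", np.zeros(3)),
                               ("cuneiform_medial", np.zeros(3))],
            profile_pct=np.array([0.0, 10.0, 20.0, 100.0]),
            profile_force=np.array([0.0, 100.0, 200.0, 0.0]),
        )

    def test_sample_points_exact(self):
        path = self._path()
        assert muscle_force_at(10.0, path) == 100.0
        assert muscle_force_at(20.0, path) == 200.0

    def test_linear_between_samples(self):
        assert muscle_force_at(15.0, self._path()) == pytest.approx(150.0)

    def test_out_of_range_clamped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pedsim.tissues"):
            v = muscle_force_at(120.0, self._path())
        assert v == 0.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_all_zero_profile(self):
        path = MusclePath(name="TS", points=[("a", np.zeros(3)),
                                             ("b", np.zeros(3))],
                          profile_pct=np.array([0.0, 100.0]),
                          profile_force=np.zeros(2))
        for t in (0.0, 33.0, 100.0):
            assert muscle_force_at(t, path) == 0.0

    def test_invalid_profiles(self):
        with pytest.raises(TissueError):
            MusclePath(name="x", points=[], profile_pct=np.array([0.0, 0.0]),
                       profile_force=np.zeros(2))
        with pytest.raises(TissueError):
            MusclePath(name="x", points=[], profile_pct=np.array([0.0, 50.0]),
                       profile_force=np.array([1.0, -1.0]))


class TestColumnForce:
    def _column(self):
        return SoftTissueColumn(
            name="c", bone="calcaneus", anchor_local=np.zeros(3),
            reference_thickness=10.0, area=100.0,
            ogden=OgdenParams(C=0.0102, alpha=8.04),
            prony=PronyParams(),
        )

    def test_reference_thickness_unloaded(self):
        assert column_force(self._column(), 10.0, dt=1.0) == 0.0

    def test_fast_compression_matches_elastic_oracle(self):
        col = self._column()
        f = column_force(col, 9.0, dt=1e-3)   # t << tau1: no relaxation yet
        elastic = ogden_uniaxial_stress(0.9, col.ogden) * col.area
        assert f == pytest.approx(elastic, rel=1e-3)

    def test_no_adhesion_in_tension(self):
        col = self._column()
        assert column_force(col, 11.0, dt=1.0) == 0.0

    def test_held_compression_relaxes_to_equilibrium(self):
        col = self._column()
        f = 0.0
        for _ in range(3000):
            f = column_force(col, 9.0, dt=1000.0)
        elastic = ogden_uniaxial_stress(0.9, col.ogden) * col.area
        assert f == pytest.approx(0.70 * elastic, rel=1e-3)


class TestInventoryBuilders:
    def test_ligament_inventory_complete(self, default_model):
        chains = build_ligaments(default_model)
        names = {c.name for c in chains}
        for expected in ("ATFL", "CFL", "PTFL", "long_plantar",
                         "spring_calcaneonavicular",
                         "interosseous_talocalcaneal"):
            assert expected in names
        for c in chains:
            assert c.slack_length > 0 and c.area > 0
        # lateral hindfoot and plantar groups engage at the build pose
        for c in chains:
            ref = np.linalg.norm(c.nodes[-1] - c.nodes[0])
            factor = {"default": 1.1, "lateral_hindfoot": 1.0,
                      "plantar": 1.0}[c.category]
            assert c.slack_length == pytest.approx(factor * ref, rel=1e-9)

    def test_aponeurosis_ten_slips_slack_at_build(self, default_model):
        slips = build_aponeurosis(default_model)
        assert len(slips) == 10
        assert sum(s.via_sesamoid for s in slips) == 1
        assert sum(s.area for s in slips) == pytest.approx(50.0)
        poses = {n: (b.centroid, b.orientation)
                 for n, b in default_model.bones.items()}
        for s in slips:
            L, *_ = slip_path_length(s, poses)
            assert L == pytest.approx(s.slack_length, rel=1e-12)
            assert s.E == pytest.approx(412.02)

    def test_muscles_four_paths(self, default_model):
        muscles = build_muscles(default_model)
        assert set(muscles) == {"TS", "TA", "EDL", "EHL"}

    def test_columns_positive_geometry(self, default_model):
        cols = build_columns(default_model)
        assert len(cols) >= 10
        for c in cols:
            assert c.reference_thickness > 0
            assert c.area > 0


class TestSlipPathLength:
    def test_sesamoid_slip_two_segments(self, default_model):
        slips = build_aponeurosis(default_model)
        ses = next(s for s in slips if s.via_sesamoid)
        poses = {n: (b.centroid, b.orientation)
                 for n, b in default_model.bones.items()}
        L, d_o, d_i, wrapped = slip_path_length(ses, poses)
        assert not wrapped
        o = poses[ses.origin_bone][0] + poses[ses.origin_bone][1] @ ses.origin_local
        v = poses[ses.via_bone][0] + poses[ses.via_bone][1] @ ses.via_local
        i = (poses[ses.insertion_bone][0]
             + poses[ses.insertion_bone][1] @ ses.insertion_local)
        manual = np.linalg.norm(v - o) + np.linalg.norm(i - v)
        assert L == pytest.approx(manual, rel=1e-12)

    def test_wrap_engages_under_toe_dorsiflexion(self, default_model):
        """Rotating a toe dorsally about its met head lengthens its slip."""
        slips = build_aponeurosis(default_model)
        slip = next(s for s in slips if s.wrap_bone == "metatarsal_2")
        poses = {n: (b.centroid.copy(), b.orientation.copy())
                 for n, b in default_model.bones.items()}
        L0, *_ = slip_path_length(slip, poses)
        met = default_model.bones["metatarsal_2"]
        pivot = met.to_global(slip.wrap_center_local)
        lengths = [L0]
        from scipy.spatial.transform import Rotation

        toe = default_model.bones[slip.insertion_bone]
        for ang in np.deg2rad(np.linspace(3, 36, 12)):
            R = Rotation.from_rotvec(-ang * np.array([0, 1.0, 0])).as_matrix()
            new_c = pivot + R @ (toe.centroid - pivot)
            poses[slip.insertion_bone] = (new_c, R @ toe.orientation)
            L, *_ = slip_path_length(slip, poses)
            lengths.append(L)
        assert np.all(np.diff(lengths) > -1e-6)
        assert lengths[-1] > lengths[0] + 1.0
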