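"""Explicit integrator: closed-form oracles, stability bound, statics."""

import numpy as np
import pytest

from pedsim.dynamics import (
    BoundaryCondition,
    IntegrationError,
    MechanicalSystem,
    assemble_foot_system,
    settle_static,
    stable_dt,
    step,
)
from pedsim.foot_model import build_foot
from pedsim.units import GRAVITY


def _point_mass(mass=10.0, name="m"):
    sys_ = MechanicalSystem([name], [mass], [np.eye(3) * mass])
    return sys_


def _spring_pair(k=10.0, mass=100.0, rest=10.0, damping=0.0,
                 tension_only=False):
    sys_ = MechanicalSystem(["fix", "m"], [1e9, mass],
                            [np.eye(3) * 1e9, np.eye(3) * mass])
    sys_.gravity_on = False
    sys_.trans_mask[0] = 0.0
    sys_.rot_mask[:] = 0.0
    sys_.set_springs([(0, 1, np.zeros(3), np.zeros(3), k, rest,
                       tension_only, damping, "s")])
    return sys_


class TestIntegratorOracles:
    def test_projectile_matches_half_g_t_squared(self):
        sys_ = _point_mass()
        st = sys_.initial_state({"m": (np.zeros(3), np.eye(3))})
        dt = 0.1
        for _ in range(1000):
            step(sys_, st, dt)
        t = st.time
        exact = -0.5 * GRAVITY * t * t
        # symplectic Euler has a first-order bias of g*t*dt/2
        assert st.pos[0, 2] == pytest.approx(exact, abs=GRAVITY * t * dt)

    def test_oscillator_period_within_one_percent(self):
        k, m = 10.0, 100.0
        sys_ = _spring_pair(k=k, mass=m)
        st = sys_.initial_state({"fix": (np.zeros(3), np.eye(3)),
                                 "m": (np.array([0.0, 0, -12.0]), np.eye(3))})
        period = 2 * np.pi * np.sqrt(m / k)
        dt = period / 1000
        zs = []
        for _ in range(3500):
            step(sys_, st, dt)
            zs.append(st.pos[1, 2])
        x = np.asarray(zs) + 10.0
        up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
        measured = (up[-1] - up[0]) / (len(up) - 1) * dt
        assert measured == pytest.approx(period, rel=0.01)

    def test_fully_prescribed_body_stays_put(self):
        sys_ = _point_mass()
        pose = np.array([1.0, 2.0, 3.0])
        sys_.bcs[0] = BoundaryCondition(
            body="m", times=np.array([0.0, 100.0]),
            positions=np.tile(pose, (2, 1)),
            rotations=np.tile(np.eye(3), (2, 1, 1)))
        sys_.trans_mask[0] = 0.0
        sys_.rot_mask[0] = 0.0
        st = sys_.initial_state({"m": (pose, np.eye(3))})
        for _ in range(100):
            step(sys_, st, 0.5)
        assert np.allclose(st.pos[0], pose)
        assert np.allclose(st.vel[0], 0.0)

    def test_divergence_detected_with_body_name(self):
        sys_ = _spring_pair(k=1e4, mass=0.1)   # far beyond stability
        st = sys_.initial_state({"fix": (np.zeros(3), np.eye(3)),
                                 "m": (np.array([0.0, 0, -20.0]), np.eye(3))})
        with pytest.raises(IntegrationError, match="m"):
            for _ in range(10000):
                step(sys_, st, 1.0)


class TestStableDt:
    def test_single_spring_closed_form(self):
        k, m = 10.0, 100.0
        sys_ = _spring_pair(k=k, mass=m)
        # omega = sqrt(k/m) (fixed endpoint has effectively infinite mass)
        expected = 0.5 * 2.0 * np.sqrt(m / k)
        assert stable_dt(sys_, safety=0.5, cap=1e9) == pytest.approx(
            expected, rel=1e-6)

    def test_stiffer_spring_smaller_dt(self):
        soft = stable_dt(_spring_pair(k=10.0), cap=1e9)
        stiff = stable_dt(_spring_pair(k=40.0), cap=1e9)
        assert stiff == pytest.approx(soft / 2.0, rel=1e-6)

    def test_empty_system_returns_cap(self):
        sys_ = _point_mass()
        assert stable_dt(sys_, cap=1.0) == 1.0

    def test_never_exceeds_one_ms_cap(self):
        sys_ = _spring_pair(k=1e-6, mass=1e9)
        assert stable_dt(sys_) <= 1.0


class TestSettleStatic:
    def test_spring_elongation_mg_over_k(self):
        k, m = 50.0, 100.0
        sys_ = _spring_pair(k=k, mass=m, damping=10.0)
        sys_.gravity_on = True
        st = sys_.initial_state({"fix": (np.zeros(3), np.eye(3)),
                                 "m": (np.array([0.0, 0, -10.0]), np.eye(3))})
        res = settle_static(sys_, st, tolerance=1e-6)
        assert res.converged
        elong = -st.pos[1, 2] - 10.0
        assert elong == pytest.approx(m * GRAVITY / k, rel=1e-3)

    def test_unloaded_system_converges_immediately(self):
        sys_ = _spring_pair(k=50.0, mass=100.0)
        sys_.gravity_on = False
        st = sys_.initial_state({"fix": (np.zeros(3), np.eye(3)),
                                 "m": (np.array([0.0, 0, -10.0]), np.eye(3))})
        res = settle_static(sys_, st, tolerance=1e-6)
        assert res.converged
        assert res.steps <= 25
        assert np.allclose(st.pos[1], [0, 0, -10.0], atol=1e-9)


class TestConservation:
    def test_energy_drift_undamped_spring_network(self, rng):
        """< 1% energy drift over 1e4 steps at dt = 0.1 x stability bound."""
        n = 5
        masses = rng.uniform(50, 150, n)
        names = [f"b{i}" for i in range(n)]
        sys_ = MechanicalSystem(names, masses,
                                [np.eye(3) * m for m in masses])
        sys_.gravity_on = False
        sys_.rot_mask[:] = 0.0
        rows = []
        pos0 = rng.uniform(-50, 50, (n, 3))
        for i in range(n):
            for j in range(i + 1, n):
                rest = np.linalg.norm(pos0[i] - pos0[j])
                rows.append((i, j, np.zeros(3), np.zeros(3),
                             rng.uniform(5, 20), rest, False, 0.0, f"{i}{j}"))
        sys_.set_springs(rows)
        st = sys_.initial_state(
            {nm: (pos0[i] * 1.05, np.eye(3)) for i, nm in enumerate(names)})
        dt = stable_dt(sys_, safety=0.1, cap=1e9)

        def energy():
            ke = 0.5 * (sys_.mass * (st.vel ** 2).sum(axis=1)).sum()
            sp = sys_.springs
            pa = st.pos[sp.ia] + sp.la
            pb = st.pos[sp.ib] + sp.lb
            L = np.linalg.norm(pb - pa, axis=1)
            pe = 0.5 * (sp.k * (L - sp.rest) ** 2).sum()
            return ke + pe

        # symplectic Euler conserves a shadow energy: the true energy
        # oscillates within a bounded band; drift is the change in the
        # windowed mean, which must stay below 1%
        first = []
        last = []
        for i in range(10000):
            step(sys_, st, dt)
            e = energy()
            if i < 1000:
                first.append(e)
            if i >= 9000:
                last.append(e)
        drift = abs(np.mean(last) - np.mean(first))
        assert drift < 0.01 * np.mean(first)

    def test_momentum_balance_under_external_force(self):
        sys_ = _point_mass(mass=25.0)
        sys_.gravity_on = False
        f_ext = np.array([3.0, -2.0, 1.0])
        sys_.ext_forces[0] = lambda t: f_ext
        st = sys_.initial_state({"m": (np.zeros(3), np.eye(3))})
        dt = 0.25
        n = 400
        for _ in range(n):
            step(sys_, st, dt)
        impulse = f_ext * dt * n
        momentum = sys_.mass[0] * st.vel[0]
        assert np.allclose(momentum, impulse, rtol=1e-9)


class TestFootAssembly:
    def test_assembled_system_mass_conserved(self, default_model):
        sys_ = assemble_foot_system(default_model)
        assert sys_.mass.sum() == pytest.approx(default_model.total_mass,
                                                rel=1e-12)

    def test_static_settle_under_gravity_small_displacements(self,
                                                             default_model):
        sys_ = assemble_foot_system(default_model)
        for b in ("tibia", "fibula"):
            i = sys_.index[b]
            sys_.trans_mask[i] = 0.0
            sys_.rot_mask[i] = 0.0
        st = sys_.initial_state(dict(sys_.build_pose))
        res = settle_static(sys_, st, tolerance=2e-3, max_steps=12000)
        # under its own weight the skeleton barely moves from build pose
        for name, (p0, _) in sys_.build_pose.items():
            d = np.linalg.norm(st.pos[sys_.index[name]] - p0)
            assert d < 3.0, f"{name} moved {d:.2f} mm under gravity alone"

    def test_stiffness_doubling_dt_halving_static_grf(self, default_model):
        """Static GRF is penalty-insensitive (doubled contact stiffness)."""
        from pedsim.dynamics import compute_forces

        grfs = []
        for penalty in (800.0, 1600.0):
            sys_ = assemble_foot_system(default_model,
                                        cartilage_penalty=penalty)
            for b in ("tibia", "fibula"):
                i = sys_.index[b]
                sys_.trans_mask[i] = 0.0
                sys_.rot_mask[i] = 0.0
            st = sys_.initial_state(dict(sys_.build_pose))
            settle_static(sys_, st, tolerance=1.5e-3, max_steps=12000)
            audit = {}
            compute_forces(sys_, st.copy(), 0.01, audit=audit)
            grfs.append(audit["grf"][2])
        assert grfs[1] == pytest.approx(grfs[0], rel=0.005)
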