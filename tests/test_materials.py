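"""Constitutive-law unit tests: Ogden, Prony, viscoelastic update, PA modulus."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedsim.materials import (
    MaterialError,
    MaterialSet,
    OgdenParams,
    PronyParams,
    PronyState,
    ogden_uniaxial_stress,
    ogden_uniaxial_tangent,
    pa_elastic_modulus,
    prony_relaxation,
    viscoelastic_stress_update,
)

SOFT = OgdenParams(C=0.0102, alpha=8.04)
SKIN = OgdenParams(C=0.122, alpha=18.0)


def _ogden_oracle(lam, C, alpha):
    # independent one-line evaluation of the nominal stress law
    return -(2 * C / alpha) * (lam ** (alpha - 1) - lam ** (-alpha / 2 - 1))


class TestOgden:
    def test_identity_stretch_gives_zero(self):
        assert ogden_uniaxial_stress(1.0, SOFT) == 0.0
        assert ogden_uniaxial_stress(1.0, SKIN) == 0.0

    @pytest.mark.parametrize(
        "lam,params,expected",
        [
            (1.1, SOFT, _ogden_oracle(1.1, 0.0102, 8.04)),   # ~ -3.391e-3
            (0.9, SKIN, _ogden_oracle(0.9, 0.122, 18.0)),    # ~ +3.662e-2
        ],
    )
    def test_matches_arithmetic_oracle(self, lam, params, expected):
        assert ogden_uniaxial_stress(lam, params) == pytest.approx(expected,
                                                                   rel=1e-12)

    def test_soft_tissue_tension_value(self):
        # frozen from the arithmetic oracle
        assert ogden_uniaxial_stress(1.1, SOFT) == pytest.approx(-3.391e-3,
                                                                 rel=1e-3)
        assert ogden_uniaxial_stress(0.9, SKIN) == pytest.approx(3.662e-2,
                                                                 rel=1e-3)

    def test_compression_positive_convention(self):
        assert ogden_uniaxial_stress(0.8, SOFT) > 0
        assert ogden_uniaxial_stress(1.2, SOFT) < 0
        assert ogden_uniaxial_stress(0.8, SOFT, tension_positive=True) < 0

    def test_monotone_decreasing_in_stretch(self):
        lams = np.linspace(0.3, 2.5, 400)
        for params in (SOFT, SKIN):
            sig = ogden_uniaxial_stress(lams, params)
            assert np.all(np.diff(sig) < 0)

    def test_tangent_matches_central_difference(self):
        h = 1e-6
        for lam in (0.7, 1.0, 1.4):
            num = (ogden_uniaxial_stress(lam + h, SOFT)
                   - ogden_uniaxial_stress(lam - h, SOFT)) / (2 * h)
            assert ogden_uniaxial_tangent(lam, SOFT) == pytest.approx(num,
                                                                      rel=1e-6)

    def test_small_strain_slope_is_minus_3C(self):
        assert ogden_uniaxial_tangent(1.0, SOFT) == pytest.approx(
            -3.0 * SOFT.C, rel=1e-12)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(MaterialError):
            ogden_uniaxial_stress(0.0, SOFT)
        with pytest.raises(MaterialError):
            ogden_uniaxial_stress(-1.0, SOFT)


class TestProny:
    P = PronyParams()  # g1=0.18, g2=0.12, tau 570/6030 ms

    def test_no_relaxation_at_zero_time(self):
        assert prony_relaxation(0.0, self.P) == 1.0

    def test_longtime_limit(self):
        assert prony_relaxation(1e9, self.P) == pytest.approx(0.70, abs=1e-9)

    def test_single_term_closed_form(self):
        p = PronyParams(g1=0.18, g2=0.0, tau1=570.0, tau2=6030.0)
        expected = 1 - 0.18 * (1 - np.exp(-1.0))
        assert prony_relaxation(570.0, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        t = np.linspace(0, 60000, 500)
        g = prony_relaxation(t, self.P)
        assert np.all(np.diff(g) <= 0)
        assert np.all(g <= 1.0) and np.all(g > self.P.g_inf)

    def test_negative_time_rejected(self):
        with pytest.raises(MaterialError):
            prony_relaxation(-1.0, self.P)

    def test_invalid_weights_rejected(self):
        with pytest.raises(MaterialError):
            PronyParams(g1=0.6, g2=0.5)
        with pytest.raises(MaterialError):
            PronyParams(g1=-0.1)


class TestViscoelasticUpdate:
    P = PronyParams()

    def test_identity_stretch_stays_zero(self):
        state = PronyState.zeros()
        for _ in range(50):
            sigma, state = viscoelastic_stress_update(1.0, state, SOFT,
                                                      self.P, dt=10.0)
            assert sigma == 0.0

    def test_step_hold_relaxes_to_equilibrium_fraction(self):
        state = PronyState.zeros()
        elastic = ogden_uniaxial_stress(1.05, SOFT)
        dt = 10.0
        n = int(100 * self.P.tau2 / dt)
        sigma = None
        for _ in range(n):
            sigma, state = viscoelastic_stress_update(1.05, state, SOFT,
                                                      self.P, dt=dt)
        assert sigma == pytest.approx(0.70 * elastic, rel=1e-3)

    def test_zero_weights_reproduce_elastic_law(self):
        p0 = PronyParams(g1=0.0, g2=0.0)
        state = PronyState.zeros()
        for lam in (0.9, 1.1, 0.8, 1.3):
            sigma, state = viscoelastic_stress_update(lam, state, SOFT, p0,
                                                      dt=1.0)
            assert sigma == pytest.approx(ogden_uniaxial_stress(lam, SOFT),
                                          rel=1e-12)

    def test_halved_step_converges_second_order(self):
        # linear ramp of stretch: Richardson comparison between dt and dt/2
        def run(dt, t_end=200.0):
            state = PronyState.zeros()
            n = int(t_end / dt)
            sigma = 0.0
            for i in range(1, n + 1):
                lam = 1.0 - 0.1 * (i * dt / t_end)
                sigma, state = viscoelastic_stress_update(lam, state, SOFT,
                                                          self.P, dt=dt)
            return sigma

    # the recursive update is exact for piecewise-linear elastic stress,
    # so halving the step changes the result only through the nonlinearity
    # of the Ogden law inside each step
        coarse, fine = run(4.0), run(2.0)
        exact = run(0.25)
        assert abs(fine - exact) < abs(coarse - exact) + 1e-15


class TestPAModulus:
    def test_reference_datum(self):
        # 1.5 BW at 5% strain, 70 kg, 50 mm^2 -> 412.02 MPa
        assert pa_elastic_modulus(1.5, 70.0, 0.05, 50.0) == pytest.approx(
            412.02, abs=5e-3)

    def test_strain_proportionality(self):
        e1 = pa_elastic_modulus(1.5, 70.0, 0.05, 50.0)
        e2 = pa_elastic_modulus(1.5, 70.0, 0.10, 50.0)
        assert e1 == pytest.approx(2.0 * e2, rel=1e-12)

    def test_alternate_datum(self):
        # arithmetic oracle: 1.0*50*9.81/50/0.05
        assert pa_elastic_modulus(1.0, 50.0, 0.05, 50.0) == pytest.approx(
            196.2, rel=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(bw_multiple=0), dict(strain=0), dict(area=-1), dict(body_mass=0),
    ])
    def test_invalid_arguments(self, bad):
        kw = dict(bw_multiple=1.5, body_mass=70.0, strain=0.05, area=50.0)
        kw.update(bad)
        with pytest.raises(MaterialError):
            pa_elastic_modulus(**kw)


class TestMaterialSet:
    def test_defaults_match_reference_table(self):
        ms = MaterialSet()
        assert ms.bone.E == 7300.0 and ms.bone.nu == 0.30
        assert ms.soft_tissue_ogden.C == 0.0102
        assert ms.soft_tissue_ogden.alpha == 8.04
        assert ms.skin.C == 0.122 and ms.skin.alpha == 18.0
        assert ms.cartilage.E == 10.0
        assert ms.ligament.E == 260.0
        assert ms.plantar_aponeurosis.E == 412.02
        assert ms.floor_friction_mu == 0.6
        assert ms.soft_tissue_prony.tau1 == 570.0   # 0.57 s in ms
        assert ms.soft_tissue_prony.tau2 == 6030.0

    def test_packaged_defaults_identical(self):
        assert MaterialSet.default() == MaterialSet()

    def test_yaml_roundtrip_bit_exact(self):
        ms = MaterialSet()
        text = ms.to_yaml()
        back = MaterialSet.from_yaml(io.StringIO(text))
        assert back == ms

    def test_override(self):
        ms = MaterialSet.from_dict(
            {**MaterialSet().to_dict(), "floor_friction_mu": 0.3})
        assert ms.floor_friction_mu == 0.3


@settings(deadline=None, max_examples=50, derandomize=True)
@given(lam=st.floats(0.3, 3.0), c=st.floats(0.001, 1.0),
       alpha=st.floats(0.5, 20.0))
def test_ogden_property_matches_formula(lam, c, alpha):
    p = OgdenParams(C=c, alpha=alpha)
    assert ogden_uniaxial_stress(lam, p) == pytest.approx(
        _ogden_oracle(lam, c, alpha), rel=1e-12, abs=1e-15)
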