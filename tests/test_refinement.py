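"""GRF-tracking refinement: polynomial fitting and the correction loop."""

import numpy as np
import pytest

from pedsim.refinement import (
    RefinementConfig,
    RefinementError,
    displacement_correction,
    estimate_gain,
    eval_polynomial,
    fit_polynomial,
    grf_error,
    refine,
)


class TestGrfError:
    def test_identical_series(self):
        err, mae, sd = grf_error(np.ones((50, 3)), np.ones((50, 3)))
        assert np.allclose(err, 0.0)
        assert np.allclose(mae, 0.0) and np.allclose(sd, 0.0)

    def test_constant_offset(self):
        sim = np.zeros(40) + 10.0
        err, mae, sd = grf_error(sim, np.zeros(40))
        assert np.allclose(err, 10.0)
        assert mae[0] == pytest.approx(10.0) and sd[0] == pytest.approx(0.0)

    def test_sinusoid_mae_is_two_over_pi(self):
        t = np.linspace(0.0, 1.0, 20001)
        sim = np.sin(2 * np.pi * 5 * t)
        _, mae, _ = grf_error(sim, np.zeros_like(sim))
        assert mae[0] == pytest.approx(2.0 / np.pi, rel=1e-3)

    def test_shape_mismatch(self):
        with pytest.raises(RefinementError):
            grf_error(np.zeros(10), np.zeros(11))


class TestFitPolynomial:
    def test_constant_series(self):
        coef = fit_polynomial(np.full(30, 4.2), order=8)
        assert coef[0] == pytest.approx(4.2, abs=1e-9)
        assert np.allclose(coef[1:], 0.0, atol=1e-7)

    def test_degree8_synthesis_recovery(self, rng):
        true = rng.uniform(-2, 2, 9)
        t = np.linspace(0.0, 1.0, 200)
        y = eval_polynomial(true, t)
        coef = fit_polynomial(y, order=8)
        assert np.allclose(coef, true, rtol=1e-6, atol=1e-9)

    def test_residual_orthogonal_to_basis(self, rng):
        y = rng.normal(size=100)
        t = np.linspace(0.0, 1.0, 100)
        coef = fit_polynomial(y, order=8, t=t)
        resid = y - eval_polynomial(coef, t)
        V = np.vander(t, 9, increasing=True)
        assert np.abs(V.T @ resid).max() < 1e-8

    def test_nested_model_residuals(self, rng):
        y = rng.normal(size=60)
        t = np.linspace(0, 1, 60)
        r8 = y - eval_polynomial(fit_polynomial(y, 8), t)
        r0 = y - eval_polynomial(fit_polynomial(y, 0), t)
        assert (r8 ** 2).sum() <= (r0 ** 2).sum() + 1e-12

    def test_affine_time_invariance(self, rng):
        y = rng.normal(size=80)
        t1 = np.linspace(0.0, 1.0, 80)
        t2 = 123.0 + 7.0 * t1          # same samples, shifted/scaled clock
        c1 = fit_polynomial(y, order=6, t=t1)
        c2 = fit_polynomial(y, order=6, t=t2)
        assert np.allclose(c1, c2, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(RefinementError):
            fit_polynomial(np.zeros(5), order=8)


class TestDisplacementCorrection:
    def test_zero_coefficients(self):
        t = np.linspace(0, 1, 20)
        corr = displacement_correction(np.zeros(9), [1.0], t)
        assert np.allclose(corr, 0.0)

    def test_constant_error_gain_product(self):
        t = np.linspace(0, 1, 20)
        coef = np.zeros(9)
        coef[0] = 2.0                   # constant error +2
        corr = displacement_correction(coef, [0.5], t)
        assert np.allclose(corr, -1.0)  # excess GRF lifts the tibia

    def test_gain_sign_flip(self, rng):
        t = np.linspace(0, 1, 30)
        coef = rng.normal(size=9)
        a = displacement_correction(coef, [0.7], t)
        b = displacement_correction(coef, [-0.7], t)
        assert np.allclose(a, -b)


class _LinearPlant:
    """GRF = G * displacement (memoryless scalar plant)."""

    def __init__(self, gain):
        self.gain = gain
        self.calls = 0

    def __call__(self, disp):
        self.calls += 1
        return self.gain * np.asarray(disp)


class TestRefineLoop:
    def test_unit_plant_unit_gain_single_iteration(self, rng):
        plant = _LinearPlant(1.0)
        target = rng.normal(size=100)
        disp0 = np.zeros(100)
        cfg = RefinementConfig(gains=[1.0], max_iterations=1)
        best, hist = refine(plant, disp0, target, cfg)
        # after one iteration the error is down to the order-8 fit residual
        final = np.abs(plant(best) - target).mean()
        coef = fit_polynomial(-target, order=8)
        fit_resid = np.abs(-target - eval_polynomial(
            coef, np.linspace(0, 1, 100))).mean()
        assert final == pytest.approx(fit_resid, rel=1e-9)

    @pytest.mark.parametrize("G,g", [(2.0, 0.25), (1.0, 0.5), (0.5, 1.5)])
    def test_geometric_contraction_matches_one_minus_gG(self, G, g):
        plant = _LinearPlant(G)
        t = np.linspace(0.0, 1.0, 120)
        # a degree-8-representable target so the fit residual is zero and
        # the loop contraction is purely |1 - g G|
        target = eval_polynomial(np.array([0.5, -1.0, 2.0, 0, 0, 0.3,
                                           0, 0, -0.2]), t)
        cfg = RefinementConfig(gains=[g], max_iterations=6, threshold=0.0)
        _, hist = refine(plant, np.zeros_like(t), target, cfg)
        mae = np.array([m[0] for m in hist.mae])
        expected = abs(1.0 - g * G)
        ratios = mae[1:] / mae[:-1]
        for r in ratios[:4]:
            assert r == pytest.approx(expected, rel=0.05)

    def test_auto_gain_halves_error_within_five_iterations(self, rng):
        plant = _LinearPlant(3.0)
        t = np.linspace(0, 1, 150)
        target = 30.0 * np.sin(np.pi * t) + 10.0
        cfg = RefinementConfig(max_iterations=5)      # secant auto-gain
        best, hist = refine(plant, np.zeros_like(t), target, cfg)
        mae = np.array([m[0] for m in hist.mae])
        assert mae[-1] <= 0.5 * mae[0]
        assert hist.gains[0] == pytest.approx(0.5 / 3.0, rel=1e-6)

    def test_zero_initial_error_terminates_immediately(self):
        plant = _LinearPlant(1.0)
        target = plant(np.linspace(0, 5, 50))
        cfg = RefinementConfig(gains=[1.0], threshold=1e-12)
        best, hist = refine(plant, np.linspace(0, 5, 50), target, cfg)
        assert hist.converged
        assert len(hist.mae) == 1          # no correction iterations run

    def test_best_seen_monotone_safeguard(self):
        # destabilizing gain (|1-gG| > 1): returned iterate never worse
        plant = _LinearPlant(1.0)
        t = np.linspace(0, 1, 80)
        target = 5.0 * t
        cfg = RefinementConfig(gains=[2.5], max_iterations=4)
        best, hist = refine(plant, np.zeros_like(t), target, cfg)
        final = np.abs(plant(best) - target).mean()
        assert final <= np.abs(-target).mean() + 1e-12

    def test_plant_failure_returns_partial_history(self):
        calls = {"n": 0}

        def flaky(disp):
            calls["n"] += 1
            if calls["n"] >= 3:
                raise RuntimeError("solver blew up")
            return np.asarray(disp) * 1.0

        cfg = RefinementConfig(gains=[1.0], max_iterations=5)
        best, hist = refine(flaky, np.zeros(40), np.ones(40), cfg)
        assert hist.failed
        assert "blew up" in hist.failure_message
        assert len(hist.mae) >= 1
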