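"""Ground-reaction-force tracking by polynomial displacement correction.

Driving a foot model with measured tibial kinematics alone does not
reproduce the measured ground reaction forces: measurement and
modelling errors of a fraction of a millimetre in the vertical tibial
trajectory change the contact force substantially.  The refinement
loop implemented here closes that gap:

1. run the simulation and compute the per-component GRF error
   (simulated minus measured) over normalized stance time,
2. approximate each error component with an 8th-order least-squares
   polynomial,
3. scale the polynomial by a per-component gain (mm per unit force
   error) and *subtract* it from the prescribed tibial displacement
   (excess downward GRF lifts the tibia),
4. rerun, and iterate until the error RMS stops improving or a
   threshold is met.

Coupling is diagonal: vertical GRF error corrects vertical
displacement, anteroposterior corrects anteroposterior, mediolateral
corrects mediolateral.  Gains may be supplied or auto-estimated with a
one-shot secant probe of the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RefinementConfig",
    "RefinementHistory",
    "grf_error",
    "fit_polynomial",
    "eval_polynomial",
    "displacement_correction",
    "estimate_gain",
    "refine",
]


class RefinementError(ValueError):
    pass


@dataclass
class RefinementConfig:
    """Tuning of the GRF-tracking loop.

    ``gains`` are mm of displacement correction per N of GRF error,
    one per component (None -> secant auto-estimate).  ``threshold`` is
    the stop criterion on the worst per-component mean absolute error,
    in the force units of the plant output.
    """

    poly_order: int = 8
    gains: Sequence[float] | None = None
    max_iterations: int = 8
    threshold: float = 0.0
    probe_step: float = 1.0       # mm displacement used by the secant probe
    gain_safety: float = 0.5      # fraction of the inverse plant gain

    def __post_init__(self) -> None:
        if self.poly_order < 0:
            raise RefinementError("poly_order must be >= 0")
        if self.threshold < 0:
            raise RefinementError("threshold must be positive or zero")
        if self.gains is not None and not np.all(np.isfinite(self.gains)):
            raise RefinementError("gains must be finite")


def grf_error(simulated, measured):
    """Per-component GRF error (simulated - measured) plus MAE +/- SD.

    Both series must already live on a common time grid, shape (n,) or
    (n, c).  Returns ``(error, mae, sd)`` where ``mae``/``sd`` are per
    component.
    """
    sim = np.asarray(simulated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if sim.shape != meas.shape:
        raise RefinementError(
            f"GRF series shapes differ after resampling: {sim.shape} vs {meas.shape}"
        )
    err = sim - meas
    flat = err.reshape(err.shape[0], -1)
    mae = np.abs(flat).mean(axis=0)
    sd = np.abs(flat).std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(
        flat.shape[1]
    )
    return err, mae, sd


def fit_polynomial(error_series, order: int = 8, t=None) -> np.ndarray:
    """Least-squares polynomial fit on stance time normalized to [0, 1].

    Returns coefficients in *increasing* power order, shape
    ``(order+1,)`` or ``(order+1, c)`` for multi-component input.
    Solved via numpy's QR-based least squares on the monomial basis of
    the normalized time variable (well conditioned up to order ~10).
    """
    y = np.asarray(error_series, dtype=float)
    n = y.shape[0]
    if n < order + 1:
        raise RefinementError(
            f"need at least {order + 1} samples for an order-{order} fit, got {n}"
        )
    if t is None:
        t = np.linspace(0.0, 1.0, n)
    else:
        t = np.asarray(t, dtype=float)
        span = t.max() - t.min()
        t = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    V = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    return coef


def eval_polynomial(coefficients, t) -> np.ndarray:
    """Evaluate an increasing-power coefficient vector on normalized time."""
    coef = np.asarray(coefficients, dtype=float)
    t = np.asarray(t, dtype=float)
    V = np.vander(t, coef.shape[0], increasing=True)
    return V @ coef


def displacement_correction(coefficients, gains, t) -> np.ndarray:
    """Convert fitted GRF-error polynomials into displacement offsets (mm).

    ``correction(t) = -gain * poly(t)`` per component: an excess
    (positive) vertical GRF error lifts the tibia.  ``t`` is normalized
    stance time.
    """
    poly = eval_polynomial(coefficients, t)
    gains = np.asarray(gains, dtype=float)
    if poly.ndim == 1:
        if gains.size != 1:
            raise RefinementError("one gain required for single-component input")
        return -float(gains.ravel()[0]) * poly
    if gains.size != poly.shape[1]:
        raise RefinementError(
            f"{poly.shape[1]} gains required, got {gains.size}"
        )
    return -poly * gains[None, :]


def estimate_gain(
    plant: Callable[[np.ndarray], np.ndarray],
    displacement: np.ndarray,
    probe_step: float = 1.0,
    safety: float = 0.5,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Secant estimate of per-component loop gains.

    Perturbs each displacement component by ``probe_step`` mm
    (uniformly over the whole stance window), measures the mean GRF
    response of the matching component, and returns
    ``safety * probe_step / response``.  Components with negligible
    response get gain 0.
    """
    disp = np.asarray(displacement, dtype=float)
    if baseline is None:
        baseline = np.asarray(plant(disp), dtype=float)
    ncomp = 1 if disp.ndim == 1 else disp.shape[1]
    gains = np.zeros(ncomp)
    for c in range(ncomp):
        probe = disp.copy()
        if disp.ndim == 1:
            probe += probe_step
        else:
            probe[:, c] += probe_step
        resp = np.asarray(plant(probe), dtype=float) - baseline
        flat = resp if resp.ndim == 1 else resp[:, c]
        mean_resp = flat.mean()
        if abs(mean_resp) > 1e-12:
            gains[c] = safety * probe_step / mean_resp
    return gains


@dataclass
class RefinementHistory:
    """Per-iteration record of the tracking loop."""

    mae: list = field(default_factory=list)        # (iterations+1, c) MAE incl. iter 0
    sd: list = field(default_factory=list)
    gains: np.ndarray | None = None
    best_iteration: int = 0
    converged: bool = False
    failed: bool = False
    failure_message: str | None = None


def refine(
    plant: Callable[[np.ndarray], np.ndarray],
    displacement: np.ndarray,
    measured_grf: np.ndarray,
    config: RefinementConfig | None = None,
) -> tuple[np.ndarray, RefinementHistory]:
    """Iteratively correct a prescribed displacement to track measured GRF.

    ``plant`` maps a displacement series (n,) or (n, c) to a GRF series
    of the same shape and must be deterministic.  Returns the best-seen
    displacement (the iterate with the lowest worst-component MAE —
    never worse than the input) together with the iteration history.
    """
    cfg = config or RefinementConfig()
    disp = np.asarray(displacement, dtype=float).copy()
    meas = np.asarray(measured_grf, dtype=float)
    hist = RefinementHistory()

    try:
        sim = np.asarray(plant(disp), dtype=float)
    except Exception as exc:  # noqa: BLE001 - plant is user code
        hist.failed = True
        hist.failure_message = f"plant failed on initial run: {exc}"
        return disp, hist
    err, mae, sd = grf_error(sim, meas)
    hist.mae.append(mae)
    hist.sd.append(sd)

    if cfg.gains is not None:
        gains = np.asarray(cfg.gains, dtype=float)
    else:
        gains = estimate_gain(
            plant, disp, probe_step=cfg.probe_step, safety=cfg.gain_safety,
            baseline=sim,
        )
    hist.gains = gains

    best_disp = disp.copy()
    best_score = mae.max()
    if best_score <= cfg.threshold:
        hist.converged = True
        return best_disp, hist

    n = disp.shape[0]
    t = np.linspace(0.0, 1.0, n)
    for it in range(1, cfg.max_iterations + 1):
        coef = fit_polynomial(err, order=cfg.poly_order, t=t)
        disp = disp + displacement_correction(coef, gains, t)
        try:
            sim = np.asarray(plant(disp), dtype=float)
        except Exception as exc:  # noqa: BLE001
            hist.failed = True
            hist.failure_message = f"plant failed at iteration {it}: {exc}"
            break
        err, mae, sd = grf_error(sim, meas)
        hist.mae.append(mae)
        hist.sd.append(sd)
        if mae.max() < best_score:
            best_score = mae.max()
            best_disp = disp.copy()
            hist.best_iteration = it
        if best_score <= cfg.threshold:
            hist.converged = True
            break
    return best_disp, hist
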