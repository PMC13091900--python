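"""Constitutive laws for the foot model.

The tissue inventory uses four material models:

* a one-term Ogden hyperelastic law for the encapsulated plantar soft
  tissue and for skin, written as a uniaxial nominal stress--stretch
  relation,
* a two-term Prony relaxation series layered on the Ogden response of
  the soft tissue (quasi-linear viscoelasticity),
* isotropic linear elasticity for bone, cartilage and ligament spring
  elements, and
* a rigid frictional floor characterised by a single Coulomb
  coefficient.

The uniaxial nominal stress of the one-term Ogden solid is

    sigma(lambda) = -(2C/alpha) * (lambda**(alpha-1) - lambda**(-alpha/2-1))

with ``lambda`` the principal stretch.  Note the leading minus sign:
under this convention compression (``lambda < 1``) produces *positive*
nominal stress, which is the natural sign for a contact-like plantar
tissue column.  Pass ``tension_positive=True`` to flip the convention.

All stresses are MPa, times are ms, densities g/mm³ (see
:mod:`pedsim.units`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from .units import GRAVITY_SI, S_TO_MS

__all__ = [
    "OgdenParams",
    "PronyParams",
    "LinearElasticParams",
    "MaterialSet",
    "PronyState",
    "ogden_uniaxial_stress",
    "ogden_uniaxial_tangent",
    "prony_relaxation",
    "viscoelastic_stress_update",
    "pa_elastic_modulus",
]


class MaterialError(ValueError):
    """Invalid material parameter or evaluation outside the law's domain."""


@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden hyperelastic coefficients.

    Parameters
    ----------
    C : float
        Shear-like modulus, MPa.  Must be positive.
    alpha : float
        Dimensionless strain-hardening exponent.  Must be non-zero.
    nu : float
        Poisson ratio, in [0, 0.5).
    density : float
        Mass density, g/mm³.
    """

    C: float
    alpha: float
    nu: float = 0.475
    density: float = 0.937e-3

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise MaterialError(f"Ogden C must be > 0, got {self.C}")
        if self.alpha == 0:
            raise MaterialError("Ogden alpha must be non-zero")
        if not (0 <= self.nu < 0.5):
            raise MaterialError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")


@dataclass(frozen=True)
class PronyParams:
    """Two-term Prony relaxation series.

    ``g1``/``g2`` are the dimensionless relaxation weights and
    ``tau1``/``tau2`` the associated time constants in **ms**.  The
    long-time modulus fraction is ``1 - g1 - g2`` which must stay
    positive.
    """

    g1: float = 0.18
    g2: float = 0.12
    tau1: float = 0.57 * S_TO_MS
    tau2: float = 6.03 * S_TO_MS

    def __post_init__(self) -> None:
        if self.g1 < 0 or self.g2 < 0:
            raise MaterialError("Prony weights must be non-negative")
        if self.g1 + self.g2 >= 1:
            raise MaterialError("Prony weights must satisfy g1 + g2 < 1")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise MaterialError("Prony time constants must be positive")

    @property
    def g_inf(self) -> float:
        """Equilibrium (long-time) modulus fraction."""
        return 1.0 - self.g1 - self.g2


@dataclass(frozen=True)
class LinearElasticParams:
    """Isotropic linear elasticity (bone, cartilage, ligament springs)."""

    E: float
    nu: float
    density: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise MaterialError(f"Young's modulus must be > 0, got {self.E}")
        if not (0 <= self.nu < 0.5):
            raise MaterialError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")


def ogden_uniaxial_stress(stretch, params: OgdenParams, tension_positive: bool = False):
    """Uniaxial nominal stress of the one-term Ogden solid, MPa.

    Evaluates ``-(2C/alpha) * (lam**(alpha-1) - lam**(-alpha/2-1))``.
    With the default sign convention compression (``stretch < 1``)
    yields positive stress.  Accepts scalars or arrays.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise MaterialError("stretch must be positive")
    a = params.alpha
    sigma = -(2.0 * params.C / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    if tension_positive:
        sigma = -sigma
    if np.isscalar(stretch):
        return float(sigma)
    return sigma


def ogden_uniaxial_tangent(stretch, params: OgdenParams):
    """d(sigma)/d(lambda) of :func:`ogden_uniaxial_stress` (compression-positive)."""
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise MaterialError("stretch must be positive")
    a = params.alpha
    d = -(2.0 * params.C / a) * (
        (a - 1.0) * lam ** (a - 2.0) + (a / 2.0 + 1.0) * lam ** (-a / 2.0 - 2.0)
    )
    if np.isscalar(stretch):
        return float(d)
    return d


def prony_relaxation(t, params: PronyParams):
    """Dimensionless relaxation function g(t), monotone from 1 to ``1-g1-g2``.

    ``g(t) = 1 - g1 (1 - exp(-t/tau1)) - g2 (1 - exp(-t/tau2))`` with
    ``t`` in ms.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise MaterialError("time must be non-negative")
    g = (
        1.0
        - params.g1 * (1.0 - np.exp(-tt / params.tau1))
        - params.g2 * (1.0 - np.exp(-tt / params.tau2))
    )
    if np.isscalar(t):
        return float(g)
    return g


@dataclass
class PronyState:
    """Internal variables of the recursive viscoelastic update.

    ``r`` holds one fading-memory variable per Prony term (the
    exponentially weighted history of the elastic stress rate);
    ``sigma_e_prev`` is the elastic stress at the end of the previous
    step.  Arrays broadcast, so one state object can serve a whole
    vector of tissue columns.
    """

    r: np.ndarray
    sigma_e_prev: np.ndarray

    @classmethod
    def zeros(cls, n_terms: int = 2, shape=()) -> "PronyState":
        return cls(
            r=np.zeros((n_terms,) + tuple(np.atleast_1d(shape))
                       if shape != () else (n_terms,)),
            sigma_e_prev=np.zeros(shape) if shape != () else np.float64(0.0),
        )


def viscoelastic_stress_update(
    stretch,
    state: PronyState,
    ogden: OgdenParams,
    prony: PronyParams,
    dt: float,
    tension_positive: bool = False,
):
    """Advance the quasi-linear viscoelastic stress one step.

    The hereditary integral ``sigma(t) = ∫ g(t-s) dsigma_e/ds ds`` is
    integrated with the standard recursive-convolution update, exact
    for an elastic stress that varies linearly within the step:

        r_i  <-  exp(-h_i) r_i + (1 - exp(-h_i))/h_i * (sigma_e_new - sigma_e_old)
        sigma = (1 - g1 - g2) sigma_e + g1 r_1 + g2 r_2

    with ``h_i = dt / tau_i``.  For a step stretch held indefinitely the
    stress relaxes to ``(1 - g1 - g2)`` times the elastic value; with
    ``g1 = g2 = 0`` the pure Ogden law is recovered exactly.

    Returns ``(stress, new_state)``; ``state`` is not mutated.
    """
    if dt <= 0:
        raise MaterialError("dt must be positive")
    sigma_e = np.asarray(
        ogden_uniaxial_stress(stretch, ogden, tension_positive=tension_positive)
    )
    d_sigma = sigma_e - state.sigma_e_prev
    gs = np.array([prony.g1, prony.g2])
    taus = np.array([prony.tau1, prony.tau2])
    h = dt / taus
    decay = np.exp(-h)
    # (1 - e^-h)/h -> 1 as h -> 0; safe since h > 0
    slope = np.where(h > 1e-12, -np.expm1(-h) / h, 1.0 - h / 2.0)
    shape_extra = (1,) * sigma_e.ndim
    r_new = (
        decay.reshape((2,) + shape_extra) * state.r
        + slope.reshape((2,) + shape_extra) * d_sigma
    )
    sigma = prony.g_inf * sigma_e + (gs.reshape((2,) + shape_extra) * r_new).sum(axis=0)
    new_state = PronyState(r=r_new, sigma_e_prev=sigma_e)
    if np.isscalar(stretch):
        return float(sigma), new_state
    return sigma, new_state


def pa_elastic_modulus(
    bw_multiple: float,
    body_mass: float,
    strain: float,
    area: float,
    gravity: float = GRAVITY_SI,
) -> float:
    """Elastic modulus of the plantar aponeurosis from a force-strain datum.

    A cadaveric force--strain relationship gives the aponeurosis tension
    as a multiple of body weight at a known strain; dividing the implied
    tensile stress by that strain yields a linearised Young's modulus:

        E = (bw_multiple * body_mass * g / area) / strain   [MPa]

    with ``body_mass`` in kg, ``area`` in mm² and ``g`` in m/s².  The
    default datum (1.5 BW at 5% strain, 70 kg, 50 mm²) gives 412.02 MPa.
    """
    if bw_multiple <= 0 or body_mass <= 0:
        raise MaterialError("bw_multiple and body_mass must be positive")
    if strain <= 0:
        raise MaterialError("strain must be positive")
    if area <= 0:
        raise MaterialError("area must be positive")
    stress = bw_multiple * body_mass * gravity / area  # N / mm^2 = MPa
    return stress / strain


@dataclass
class MaterialSet:
    """Registry of every constitutive component of the foot model.

    Defaults are the model's standard parameter table; any entry may be
    overridden at construction or via YAML.  Densities are g/mm³,
    moduli MPa, Prony time constants ms.
    """

    bone: LinearElasticParams = field(
        default_factory=lambda: LinearElasticParams(E=7300.0, nu=0.30, density=1.5e-3)
    )
    soft_tissue_ogden: OgdenParams = field(
        default_factory=lambda: OgdenParams(C=0.0102, alpha=8.04, nu=0.475,
                                            density=0.937e-3)
    )
    soft_tissue_prony: PronyParams = field(default_factory=PronyParams)
    skin: OgdenParams = field(
        default_factory=lambda: OgdenParams(C=0.122, alpha=18.0, nu=0.475,
                                            density=0.937e-3)
    )
    cartilage: LinearElasticParams = field(
        default_factory=lambda: LinearElasticParams(E=10.0, nu=0.40, density=2.0e-3)
    )
    ligament: LinearElasticParams = field(
        default_factory=lambda: LinearElasticParams(E=260.0, nu=0.40, density=1.0e-3)
    )
    plantar_aponeurosis: LinearElasticParams = field(
        default_factory=lambda: LinearElasticParams(E=412.02, nu=0.40, density=1.0e-3)
    )
    skin_thickness: float = 1.0  # mm
    floor_friction_mu: float = 0.6
    #: apply Prony scaling to the full stress (True) or deviatoric part only.
    #: At the uniaxial column level the two coincide; kept as a switch.
    prony_on_full_stress: bool = True

    def __post_init__(self) -> None:
        if self.floor_friction_mu < 0:
            raise MaterialError("friction coefficient must be non-negative")
        if self.skin_thickness <= 0:
            raise MaterialError("skin thickness must be positive")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialSet":
        kw = dict(d)
        for name, typ in (
            ("bone", LinearElasticParams),
            ("soft_tissue_ogden", OgdenParams),
            ("soft_tissue_prony", PronyParams),
            ("skin", OgdenParams),
            ("cartilage", LinearElasticParams),
            ("ligament", LinearElasticParams),
            ("plantar_aponeurosis", LinearElasticParams),
        ):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = typ(**kw[name])
        return cls(**kw)

    def to_yaml(self, stream=None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, stream) -> "MaterialSet":
        if isinstance(stream, str) and "\n" not in stream:
            with open(stream) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(stream)
        return cls.from_dict(d)

    @classmethod
    def default(cls) -> "MaterialSet":
        """Defaults as shipped in the package data YAML."""
        text = resources.files("pedsim").joinpath("_data/materials.yaml").read_text()
        return cls.from_yaml(io.StringIO(text))
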