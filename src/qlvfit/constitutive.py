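"""Finite-strain kinematics and instantaneous Ogden hyperelastic stress.

The two homogeneous test modes handled here are simple shear (brain tissue
between parallel plates) and incompressible uniaxial tension (artery
segments).  The deviatoric response is modelled by an N-term Ogden
strain-energy density in principal stretches,

    W(l1, l2, l3) = sum_i (2 mu_i / alpha_i**2) * (l1**a_i + l2**a_i + l3**a_i - 3),

the convention in which ``sum_i mu_i`` is the small-strain shear modulus.
Both test modes are treated as fully incompressible (l1*l2*l3 = 1), so the
hydrostatic pressure is eliminated by the traction-free boundary of each
test and the bulk modulus never enters the stress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "OgdenParameters",
    "PrincipalStretches",
    "DeformationMode",
    "InvalidParameterError",
    "OGDEN_CONVENTION",
    "strain_energy",
    "shear_kinematics",
    "uniaxial_kinematics",
    "instantaneous_shear_stress",
    "instantaneous_uniaxial_stress",
    "small_strain_shear_modulus",
]

#: Human-readable convention string recorded in every exported artifact.
OGDEN_CONVENTION = (
    "W = sum_i 2*mu_i/alpha_i^2 * (l1^alpha_i + l2^alpha_i + l3^alpha_i - 3); "
    "sum_i mu_i = small-strain shear modulus"
)

_MIN_ABS_ALPHA = 0.1  # energy form is singular at alpha = 0


class InvalidParameterError(ValueError):
    """Raised when constitutive parameters violate their invariants."""


class DeformationMode(str, Enum):
    """Homogeneous test mode.

    ``SIMPLE_SHEAR`` curves are parameterised by engineering shear strain
    gamma = plate displacement / sample thickness; ``UNIAXIAL_TENSION``
    curves by axial stretch lambda = current length / reference length.
    """

    SIMPLE_SHEAR = "simple_shear"
    UNIAXIAL_TENSION = "uniaxial_tension"

    @property
    def reference_strain(self) -> float:
        """Strain value of the undeformed state (0 for gamma, 1 for lambda)."""
        return 0.0 if self is DeformationMode.SIMPLE_SHEAR else 1.0


@dataclass(frozen=True)
class OgdenParameters:
    """Ordered (mu_i [kPa], alpha_i [-]) pairs of an N-term Ogden model.

    Invariants: at least one term, every ``mu_i > 0``, every
    ``|alpha_i| >= 0.1`` and ``sum(mu_i) > 0``.
    """

    terms: Tuple[Tuple[float, float], ...]

    def __init__(self, terms: Iterable[Sequence[float]]):
        terms = tuple((float(m), float(a)) for m, a in terms)
        if len(terms) == 0:
            raise InvalidParameterError("Ogden model needs at least one (mu, alpha) term")
        for mu, alpha in terms:
            if not (mu > 0.0) or not math.isfinite(mu):
                raise InvalidParameterError(f"mu must be positive and finite, got {mu}")
            if abs(alpha) < _MIN_ABS_ALPHA or not math.isfinite(alpha):
                raise InvalidParameterError(
                    f"|alpha| must be >= {_MIN_ABS_ALPHA} (got {alpha}); "
                    "the energy density is singular at alpha = 0"
                )
        object.__setattr__(self, "terms", terms)

    @classmethod
    def one_term(cls, mu: float, alpha: float) -> "OgdenParameters":
        return cls([(mu, alpha)])

    @property
    def mus(self) -> np.ndarray:
        return np.array([m for m, _ in self.terms])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for _, a in self.terms])

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class PrincipalStretches:
    """Principal stretches (l1, l2, l3), incompressible: l1*l2*l3 = 1."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        lams = (self.lambda1, self.lambda2, self.lambda3)
        if any(not (l > 0.0) for l in lams):
            raise InvalidParameterError(f"principal stretches must be positive: {lams}")
        j = self.lambda1 * self.lambda2 * self.lambda3
        if abs(j - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"incompressibility violated: l1*l2*l3 = {j!r} differs from 1 by more than 1e-12"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


def strain_energy(stretches: PrincipalStretches, ogden: OgdenParameters) -> float:
    """Ogden strain-energy density [kPa] at the given incompressible stretches.

    Zero if and only if the stretches are all 1 (for positive-mu terms the
    summand is non-negative by the power-mean inequality under l1*l2*l3=1).
    """
    lams = stretches.as_array()
    w = 0.0
    for mu, alpha in ogden.terms:
        w += (2.0 * mu / alpha**2) * (np.sum(lams**alpha) - 3.0)
    return float(w)


def shear_kinematics(gamma: float) -> PrincipalStretches:
    """Principal stretches of simple shear at engineering shear strain gamma.

    The in-plane stretches are (l, 1/l) with l - 1/l = gamma, i.e.
    l = gamma/2 + sqrt(1 + gamma^2/4); the out-of-plane stretch is 1.
    """
    if gamma < 0.0:
        raise ValueError(f"shear strain must be non-negative, got {gamma}")
    lam = gamma / 2.0 + math.sqrt(1.0 + gamma**2 / 4.0)
    return PrincipalStretches(lam, 1.0 / lam, 1.0)


def uniaxial_kinematics(lam: float) -> PrincipalStretches:
    """Incompressible uniaxial stretches (l, l^-1/2, l^-1/2) at axial stretch l."""
    if lam < 1.0:
        raise ValueError(f"axial stretch must be >= 1 in tension, got {lam}")
    # renormalise the lateral stretch so the product is exactly 1 in floats
    lat = 1.0 / math.sqrt(lam)
    return PrincipalStretches(lam, lat, 1.0 / (lam * lat))


def _shear_lambda(gamma: np.ndarray) -> np.ndarray:
    return gamma / 2.0 + np.sqrt(1.0 + gamma**2 / 4.0)


def instantaneous_shear_stress(gamma, ogden: OgdenParameters):
    """Instantaneous Cauchy shear stress sigma_12 [kPa] in simple shear.

    sigma_12(gamma) = sum_i (2 mu_i / alpha_i) (l^a_i - l^-a_i) / (l + 1/l)
    with l from :func:`shear_kinematics`.  Equals dW/dgamma along the shear
    path, and reduces to mu*gamma exactly for alpha = 2 (neo-Hookean).
    Accepts scalars or arrays.
    """
    gamma_arr = np.asarray(gamma, dtype=float)
    if np.any(gamma_arr < 0.0):
        raise ValueError("shear strain must be non-negative")
    lam = _shear_lambda(gamma_arr)
    sigma = np.zeros_like(lam)
    for mu, alpha in ogden.terms:
        sigma += (2.0 * mu / alpha) * (lam**alpha - lam ** (-alpha))
    sigma /= lam + 1.0 / lam
    return sigma if np.ndim(gamma) else float(sigma)


def instantaneous_uniaxial_stress(lam, ogden: OgdenParameters, measure: str = "cauchy"):
    """Instantaneous axial stress [kPa] in incompressible uniaxial tension.

    Cauchy (true) stress sigma_11 = sum_i (2 mu_i / alpha_i)(l^a_i - l^-a_i/2);
    nominal (engineering) stress P_11 = sigma_11 / l.  Both vanish at l = 1.
    """
    if measure not in ("cauchy", "nominal"):
        raise ValueError(f"measure must be 'cauchy' or 'nominal', got {measure!r}")
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 1.0):
        raise ValueError("axial stretch must be >= 1 (compression is out of scope)")
    sigma = np.zeros_like(lam_arr)
    for mu, alpha in ogden.terms:
        sigma += (2.0 * mu / alpha) * (lam_arr**alpha - lam_arr ** (-alpha / 2.0))
    if measure == "nominal":
        sigma = sigma / lam_arr
    return sigma if np.ndim(lam) else float(sigma)


def instantaneous_stress(strain, ogden: OgdenParameters, mode: DeformationMode,
                         measure: str = "cauchy"):
    """Dispatch instantaneous stress by deformation mode."""
    if mode is DeformationMode.SIMPLE_SHEAR:
        return instantaneous_shear_stress(strain, ogden)
    return instantaneous_uniaxial_stress(strain, ogden, measure=measure)


def small_strain_shear_modulus(ogden: OgdenParameters) -> float:
    """Small-strain shear modulus [kPa], equal to sum_i mu_i.

    This is the quantity tabulated as the "shear modulus" of an Ogden
    material; it equals the limit of sigma_12/gamma as gamma -> 0.
    """
    return float(np.sum(ogden.mus))
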