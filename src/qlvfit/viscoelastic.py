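"""Prony-series relaxation and the quasi-linear viscoelastic (QLV) forward model.

The time-dependent stress of a constant-rate ramp test is modelled as a
hereditary convolution of the instantaneous Ogden stress with a reduced
relaxation function

    g_R(t) = 1 - sum_i g_i * (1 - exp(-t / tau_i)),
    sigma(t) = int_0^t g_R(t - s) * d sigma_e / ds ds,

where sigma_e is the instantaneous elastic stress of the active test mode
(a scalar convolution on the measured stress component, the standard
identification idealisation for homogeneous tests).  Two independent
evaluators are provided: a fast recursive internal-variable integrator
(exact for stress histories piecewise linear in time) and a brute-force
trapezoidal quadrature used as a cross-check oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .constitutive import (
    DeformationMode,
    InvalidParameterError,
    OgdenParameters,
    instantaneous_stress,
)

__all__ = [
    "PronySeries",
    "LoadingHistory",
    "StressStrainCurve",
    "reduced_relaxation",
    "ramp_history",
    "qlv_stress_recursive",
    "qlv_stress_quadrature",
    "rate_response_curve",
]


@dataclass(frozen=True)
class PronySeries:
    """Ordered (g_i [-], tau_i [s]) relaxation terms.

    ``g_i`` is the fraction of modulus relaxing with time constant ``tau_i``;
    the long-term modulus fraction is ``1 - sum(g_i)`` and must stay positive.
    Material tables often report decay constants beta_i = 1/tau_i instead;
    use :meth:`from_decay_constants`.
    """

    terms: Tuple[Tuple[float, float], ...]

    def __init__(self, terms: Iterable[Sequence[float]] = ()):
        terms = tuple((float(g), float(tau)) for g, tau in terms)
        for g, tau in terms:
            if g < 0.0 or not math.isfinite(g):
                raise InvalidParameterError(f"relaxation fraction g must be >= 0, got {g}")
            if not (tau > 0.0) or not math.isfinite(tau):
                raise InvalidParameterError(f"relaxation time tau must be positive, got {tau}")
        if sum(g for g, _ in terms) >= 1.0:
            raise InvalidParameterError(
                "sum of relaxation fractions must be < 1 (long-term modulus must stay positive)"
            )
        object.__setattr__(self, "terms", terms)

    @classmethod
    def from_decay_constants(cls, terms: Iterable[Sequence[float]]) -> "PronySeries":
        """Build from (g_i, beta_i) pairs with beta_i = 1/tau_i in 1/s."""
        return cls([(g, 1.0 / float(beta)) for g, beta in terms])

    @classmethod
    def empty(cls) -> "PronySeries":
        return cls(())

    @property
    def gs(self) -> np.ndarray:
        return np.array([g for g, _ in self.terms])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.terms])

    @property
    def decay_constants(self) -> np.ndarray:
        """beta_i = 1/tau_i in 1/s, the tabulated form."""
        return 1.0 / self.taus

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def long_term_fraction(self) -> float:
        return 1.0 - float(np.sum(self.gs)) if self.terms else 1.0


def reduced_relaxation(t, prony: PronySeries):
    """Reduced relaxation function g_R(t); g_R(0) = 1, non-increasing,
    asymptote 1 - sum(g_i).  Accepts scalars or arrays, t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("relaxation time argument must be non-negative")
    g = np.ones_like(t_arr)
    for gi, tau in prony.terms:
        g -= gi * (1.0 - np.exp(-t_arr / tau))
    return g if np.ndim(t) else float(g)


@dataclass(frozen=True)
class LoadingHistory:
    """A strain history on a strictly increasing time grid starting at 0.

    ``strain`` holds gamma for shear and lambda for uniaxial tension;
    ``nominal_rate`` is the declared constant strain rate of the ramp.
    """

    mode: DeformationMode
    time: np.ndarray
    strain: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        strain = np.asarray(self.strain, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "strain", strain)
        if time.ndim != 1 or time.size < 2 or strain.shape != time.shape:
            raise ValueError("time and strain must be equal-length 1-D arrays with >= 2 points")
        if time[0] != 0.0 or np.any(np.diff(time) <= 0.0):
            raise ValueError("time grid must start at 0 and be strictly increasing")
        ref = self.mode.reference_strain
        if abs(strain[0] - ref) > 1e-12:
            raise ValueError(
                f"strain must start at the reference value {ref} for mode {self.mode.value}"
            )

    @property
    def n_steps(self) -> int:
        return self.time.size - 1


def ramp_history(rate: float, max_strain: float, n_steps: int,
                 mode: DeformationMode) -> LoadingHistory:
    """Constant-rate ramp on a uniform time grid.

    The strain excursion (gamma_max for shear, lambda_max - 1 for tension)
    is traversed in ``excursion / rate`` seconds over ``n_steps`` uniform
    steps.
    """
    if rate <= 0.0:
        raise ValueError(f"strain rate must be positive, got {rate}")
    if n_steps < 2:
        raise ValueError(f"need at least 2 steps, got {n_steps}")
    ref = mode.reference_strain
    excursion = max_strain - ref
    if excursion <= 0.0:
        raise ValueError(
            f"max_strain must exceed the reference value {ref} for mode {mode.value}"
        )
    duration = excursion / rate
    time = np.linspace(0.0, duration, n_steps + 1)
    strain = ref + rate * time
    strain[-1] = max_strain  # guard rounding at the endpoint
    return LoadingHistory(mode=mode, time=time, strain=strain, nominal_rate=rate)


@dataclass
class StressStrainCurve:
    """One stress-strain curve (a single test or a replicate-mean summary).

    ``strain`` is gamma (shear) or lambda (uniaxial); ``stress`` is in kPa.
    Summary curves additionally carry pointwise ``sem`` (standard error of
    the mean, kPa) and the replicate count ``n``.
    """

    mode: DeformationMode
    rate: float
    strain: np.ndarray
    stress: np.ndarray
    replicate_id: Optional[str] = None
    curve_id: Optional[str] = None
    sem: Optional[np.ndarray] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-D arrays")
        if self.rate <= 0.0:
            raise ValueError(f"nominal strain rate must be positive, got {self.rate}")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.strain.shape:
                raise ValueError("sem grid must match the strain grid")
            if np.any(self.sem < 0.0):
                raise ValueError("SEM values must be non-negative")
            if self.n is not None and self.n < 1:
                raise ValueError("replicate count n must be >= 1")

    @property
    def peak_stress(self) -> float:
        return float(np.max(np.abs(self.stress)))


def _elastic_stress_history(history: LoadingHistory, ogden: OgdenParameters,
                            measure: str) -> np.ndarray:
    return np.asarray(
        instantaneous_stress(history.strain, ogden, history.mode, measure=measure),
        dtype=float,
    )


def qlv_stress_recursive(history: LoadingHistory, ogden: OgdenParameters,
                         prony: PronySeries, measure: str = "cauchy") -> StressStrainCurve:
    """QLV stress via the recursive internal-variable integrator.

    For each Prony term the relaxed part of the overstress,
    q_i(t) = g_i * int_0^t exp(-(t-s)/tau_i) dse/ds ds, evolves per uniform
    step dt as

        q_i[n+1] = exp(-dt/tau_i) q_i[n]
                   + g_i (tau_i/dt)(1 - exp(-dt/tau_i)) (se[n+1] - se[n]),

    which is exact for se piecewise linear in time, and

        sigma[n] = (1 - sum_i g_i) se[n] + sum_i q_i[n],

    where se is the instantaneous Ogden stress.  With an empty Prony series
    the output equals the instantaneous curve exactly.
    """
    time = history.time
    dts = np.diff(time)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
        raise ValueError("recursive integrator requires a uniform time grid")
    dt = float(dts[0])
    se = _elastic_stress_history(history, ogden, measure)
    sigma = prony.long_term_fraction * se
    dse = np.diff(se)
    for g, tau in prony.terms:
        a = math.exp(-dt / tau)
        c = g * (tau / dt) * (1.0 - a)
        # q[n] = a*q[n-1] + c*dse[n-1]: a first-order IIR filter on the
        # elastic stress increments, q[0] = 0
        q = lfilter([c], [1.0, -a], dse)
        sigma[1:] += q
    return StressStrainCurve(mode=history.mode, rate=history.nominal_rate,
                             strain=history.strain.copy(), stress=sigma)


def qlv_stress_quadrature(history: LoadingHistory, ogden: OgdenParameters,
                          prony: PronySeries, refinement: int = 4,
                          measure: str = "cauchy") -> StressStrainCurve:
    """QLV stress via direct trapezoidal quadrature of the hereditary integral.

    Integrating the convolution by parts (se(0) = 0) gives the equivalent
    form

        sigma(t) = se(t) + int_0^t dg_R/dt(t - s) * se(s) ds,

    with the kernel derivative dg_R/dt(u) = -sum_i (g_i/tau_i) exp(-u/tau_i)
    known analytically, so no numerical differentiation of se is needed and
    the elastic limit is exact.  Evaluated by the trapezoidal rule on the
    history grid refined ``refinement`` times.  Slow (O(N^2)); intended as
    an independent oracle for :func:`qlv_stress_recursive`, not for
    production use.
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    time = history.time
    fine_t = np.linspace(time[0], time[-1], history.n_steps * refinement + 1)
    fine_strain = np.interp(fine_t, time, history.strain)
    fine_hist = LoadingHistory(mode=history.mode, time=fine_t, strain=fine_strain,
                               nominal_rate=history.nominal_rate)
    se = _elastic_stress_history(fine_hist, ogden, measure)
    sigma_fine = se.copy()
    for n in range(1, fine_t.size):
        u = fine_t[n] - fine_t[: n + 1]
        dgr = np.zeros_like(u)
        for g, tau in prony.terms:
            dgr -= (g / tau) * np.exp(-u / tau)
        sigma_fine[n] += np.trapezoid(dgr * se[: n + 1], fine_t[: n + 1])
    sigma = np.interp(time, fine_t, sigma_fine)
    sigma[0] = 0.0
    return StressStrainCurve(mode=history.mode, rate=history.nominal_rate,
                             strain=history.strain.copy(), stress=sigma)


def rate_response_curve(material, mode: DeformationMode, rate: float,
                        max_strain: float, n_steps: int = 1000,
                        measure: str = "cauchy",
                        check_convergence: bool = False,
                        convergence_rtol: float = 2.5e-3) -> StressStrainCurve:
    """Model stress-strain curve of ``material`` for one constant-rate ramp.

    ``material`` is a :class:`~qlvfit.materials.MaterialModel` (or anything
    with ``ogden`` and optional ``prony`` attributes).  Returns the
    recursive QLV curve indexed by strain.  With ``check_convergence`` the
    ramp is re-integrated at half the step size and a step-size sensitivity
    above ``convergence_rtol`` (relative to peak stress) raises.
    """
    ogden = material.ogden
    if ogden is None:
        raise InvalidParameterError(f"material {getattr(material, 'name', '?')!r} has no Ogden terms")
    prony = material.prony if getattr(material, "prony", None) is not None else PronySeries.empty()
    history = ramp_history(rate, max_strain, n_steps, mode)
    curve = qlv_stress_recursive(history, ogden, prony, measure=measure)
    if check_convergence:
        fine_hist = ramp_history(rate, max_strain, 2 * n_steps, mode)
        fine = qlv_stress_recursive(fine_hist, ogden, prony, measure=measure)
        dev = np.max(np.abs(curve.stress - fine.stress[::2])) / max(curve.peak_stress, 1e-30)
        if dev > convergence_rtol:
            raise RuntimeError(
                f"ramp discretisation not converged: halving the step changes the "
                f"stress by {dev:.2%} of peak (> {convergence_rtol:.2%}); "
                f"increase n_steps from {n_steps}"
            )
    return curve
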