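"""Synthetic replicate stress-strain data with the study's design structure.

Emulates the statistical shape of the characterisation experiments — three
strain rates per tissue, n independent replicate curves per rate, reported
as mean +/- SEM — by running the QLV forward model for a chosen material
and drawing noisy replicates around the true curve.  The generating truth
is stored on the replicate set so recovery tests can compare against it.

The noise law is multiplicative-plus-floor Gaussian,
``stress ~ truth + N(0, a*|truth| + b)``; replicate-to-replicate geometry
variation, preconditioning history and failure points are deliberately not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constitutive import DeformationMode
from .materials import ExperimentDesign, MaterialModel
from .viscoelastic import StressStrainCurve, rate_response_curve

__all__ = ["NoiseModel", "ReplicateSet", "generate_replicates", "summarize_replicates"]

#: Forward-model steps used to compute the true curve before it is sampled
#: onto the design's strain grid.
_TRUTH_STEPS = 1000


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise: sd = a*|true stress| + b.

    ``multiplicative`` (a) is a unitless fraction; ``additive`` (b) is a
    stress floor in kPa.  ``additive=None`` resolves per curve to 1% of the
    curve's peak true stress, which keeps the floor meaningful across
    tissues whose stresses differ by orders of magnitude.
    """

    multiplicative: float = 0.05
    additive: Optional[float] = None  # kPa; None -> 0.01 * peak true stress
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative < 0.0:
            raise ValueError("multiplicative noise fraction must be >= 0")
        if self.additive is not None and self.additive < 0.0:
            raise ValueError("additive noise floor must be >= 0")

    def sd(self, truth: np.ndarray) -> np.ndarray:
        floor = self.additive if self.additive is not None else 0.01 * np.max(np.abs(truth))
        return self.multiplicative * np.abs(truth) + floor


@dataclass
class ReplicateSet:
    """Replicate curves per rate, plus the generating truth when synthetic."""

    mode: DeformationMode
    rates: Tuple[float, ...]
    curves: Dict[float, List[StressStrainCurve]]
    design: ExperimentDesign
    material: Optional[MaterialModel] = None  # generating truth, if synthetic
    truth: Optional[Dict[float, StressStrainCurve]] = None
    noise: Optional[NoiseModel] = None

    def __post_init__(self) -> None:
        for rate in self.rates:
            reps = self.curves.get(rate, [])
            if len(reps) != self.design.n_replicates:
                raise ValueError(
                    f"rate {rate}: {len(reps)} replicates but the design declares "
                    f"{self.design.n_replicates}"
                )
            grids = {tuple(np.round(c.strain, 12)) for c in reps}
            if len(grids) > 1:
                raise ValueError(f"rate {rate}: replicates must share one strain grid")

    def resample(self, rng: np.random.Generator) -> "ReplicateSet":
        """Within-rate bootstrap resample (with replacement) of replicates."""
        new_curves: Dict[float, List[StressStrainCurve]] = {}
        for rate in self.rates:
            reps = self.curves[rate]
            idx = rng.integers(0, len(reps), size=len(reps))
            new_curves[rate] = [reps[i] for i in idx]
        return replace(self, curves=new_curves)


def generate_replicates(material: MaterialModel, design: ExperimentDesign,
                        noise: Optional[NoiseModel] = None,
                        stress_measure: str = "cauchy") -> ReplicateSet:
    """Draw a full synthetic replicate set for one material and design.

    For each rate the true QLV curve is computed on a fine ramp and sampled
    onto the design's shared strain grid; ``design.n_replicates`` noisy
    replicates are then drawn independently.  Deterministic given
    ``noise.seed``.
    """
    if material.ogden is None:
        raise ValueError(f"material {material.name!r} has no Ogden terms to simulate")
    noise = noise if noise is not None else NoiseModel(multiplicative=0.0, additive=0.0)
    rng = np.random.default_rng(noise.seed)
    ref = design.mode.reference_strain
    grid = np.linspace(ref, design.max_strain, design.n_points)
    curves: Dict[float, List[StressStrainCurve]] = {}
    truth: Dict[float, StressStrainCurve] = {}
    for rate in design.rates:
        fine = rate_response_curve(material, design.mode, rate, design.max_strain,
                                   n_steps=_TRUTH_STEPS, measure=stress_measure)
        true_stress = np.interp(grid, fine.strain, fine.stress)
        truth[rate] = StressStrainCurve(
            mode=design.mode, rate=rate, strain=grid.copy(), stress=true_stress,
            curve_id=f"{material.name}:{design.mode.value}@{rate:g}/s:truth",
        )
        sd = noise.sd(true_stress)
        reps = []
        for k in range(design.n_replicates):
            noisy = true_stress + rng.normal(0.0, 1.0, size=grid.size) * sd
            reps.append(StressStrainCurve(
                mode=design.mode, rate=rate, strain=grid.copy(), stress=noisy,
                replicate_id=f"rep{k+1:02d}",
                curve_id=f"{material.name}:{design.mode.value}@{rate:g}/s",
            ))
        curves[rate] = reps
    return ReplicateSet(mode=design.mode, rates=tuple(design.rates), curves=curves,
                        design=design, material=material, truth=truth, noise=noise)


def summarize_replicates(reps: ReplicateSet) -> List[StressStrainCurve]:
    """Pointwise mean and SEM curve per rate, in ascending rate order.

    SEM = sd/sqrt(n) with the unbiased (n-1) sample standard deviation; with
    a single replicate the SEM is marked absent rather than reported as a
    silent zero.
    """
    out = []
    for rate in sorted(reps.rates):
        curves = reps.curves[rate]
        if not curves:
            raise ValueError(f"rate {rate} has no replicates to summarise")
        stack = np.vstack([c.stress for c in curves])
        n = stack.shape[0]
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
        out.append(StressStrainCurve(
            mode=reps.mode, rate=rate, strain=curves[0].strain.copy(), stress=mean,
            sem=sem, n=n, curve_id=(curves[0].curve_id or f"{reps.mode.value}@{rate:g}/s"),
        ))
    return out
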