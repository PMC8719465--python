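"""Material models and reference presets for minipig head tissues.

The preset table collects calibrated constitutive parameters for Göttingen
minipig head tissues: Ogden + one-term Prony models for the three brain
regions (from simple-shear tests at 0.01, 150 and 300 1/s) and for the
middle cerebral artery (uniaxial tension at the same rates), a purely
hyperelastic dura, and a compressible linear-elastic skull carried as
metadata only.  Brain, vasculature and dura are treated as incompressible
with a bulk modulus of 2.19 GPa; the bulk modulus never enters the
homogeneous test stresses and is stored as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .constitutive import DeformationMode, InvalidParameterError, OgdenParameters, OGDEN_CONVENTION
from .viscoelastic import PronySeries

__all__ = ["MaterialModel", "ExperimentDesign", "material_presets", "design_presets"]


@dataclass(frozen=True)
class MaterialModel:
    """One named tissue: density, bulk modulus, Ogden backbone, optional
    Prony relaxation, and optional linear-elastic metadata for non-fitted
    components (e.g. bone)."""

    name: str
    density: float  # kg/m^3
    bulk_modulus: Optional[float] = None  # GPa, metadata only
    ogden: Optional[OgdenParameters] = None
    prony: Optional[PronySeries] = None
    elastic_modulus: Optional[float] = None  # GPa, linear-elastic metadata
    poissons_ratio: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.density > 0.0):
            raise InvalidParameterError(f"density must be positive, got {self.density}")
        if self.bulk_modulus is not None and not (self.bulk_modulus > 0.0):
            raise InvalidParameterError(f"bulk modulus must be positive, got {self.bulk_modulus}")
        if self.poissons_ratio is not None and not (-1.0 < self.poissons_ratio < 0.5):
            raise InvalidParameterError(
                f"Poisson's ratio must lie in (-1, 0.5), got {self.poissons_ratio}"
            )

    @property
    def is_hyperelastic(self) -> bool:
        return self.ogden is not None


@dataclass(frozen=True)
class ExperimentDesign:
    """A replicate test design: mode, strain rates, replicates per rate and
    the common maximum strain of the ramps."""

    name: str
    mode: DeformationMode
    rates: Tuple[float, ...]  # 1/s
    n_replicates: int
    max_strain: float  # gamma_max (shear) or lambda_max (uniaxial)
    n_points: int = 101  # shared strain grid per rate

    def __post_init__(self) -> None:
        if any(r <= 0.0 for r in self.rates) or not self.rates:
            raise InvalidParameterError("design needs at least one positive strain rate")
        if self.n_replicates < 1 or self.n_points < 2:
            raise InvalidParameterError("need n_replicates >= 1 and n_points >= 2")
        if self.max_strain <= self.mode.reference_strain:
            raise InvalidParameterError("max_strain must exceed the reference strain")


#: The three strain rates of the characterisation protocol, in 1/s.
STANDARD_RATES: Tuple[float, float, float] = (0.01, 150.0, 300.0)


def material_presets() -> Dict[str, MaterialModel]:
    """The six reference tissue models (parameters in kPa, 1/s, kg/m^3).

    Cerebrum/cerebellum/brainstem and vasculature carry one-term Ogden +
    one-term Prony models; dura is one-term Ogden only; skull is a
    compressible linear-elastic metadata entry (E = 2.00 GPa, nu = 0.22).
    """

    def visco(name: str, mu: float, alpha: float, g: float, beta: float) -> MaterialModel:
        return MaterialModel(
            name=name, density=1040.0, bulk_modulus=2.19,
            ogden=OgdenParameters.one_term(mu, alpha),
            prony=PronySeries.from_decay_constants([(g, beta)]),
            provenance=f"simultaneous 3-rate QLV calibration; {OGDEN_CONVENTION}",
        )

    presets = {
        "cerebrum": visco("cerebrum", 1.81, 10.1, 0.99, 0.276),
        "cerebellum": visco("cerebellum", 1.46, 8.0, 0.92, 0.562),
        "brainstem": visco("brainstem", 2.25, 11.2, 0.99, 0.455),
        "vasculature": visco("vasculature", 700.40, 12.6, 0.90, 0.077),
        "dura": MaterialModel(
            name="dura", density=1040.0, bulk_modulus=2.19,
            ogden=OgdenParameters.one_term(450.00, 16.5),
            provenance="hyperelastic fit to low-rate uniaxial tension; " + OGDEN_CONVENTION,
        ),
        "skull": MaterialModel(
            name="skull", density=1200.0,
            elastic_modulus=2.00, poissons_ratio=0.22,
            provenance="compressible linear-elastic metadata (not fitted here)",
        ),
    }
    return presets


def design_presets() -> Dict[str, ExperimentDesign]:
    """Named replicate designs of the characterisation experiments.

    brain-shear: simple shear, 3 rates, n = 6 replicates per rate,
    gamma_max = 8/7 (8-mm plate displacement on a 7-mm sample).
    vessel-tension: uniaxial tension, 3 rates, n = 12, lambda_max = 1.3.
    """
    return {
        "brain-shear": ExperimentDesign(
            name="brain-shear", mode=DeformationMode.SIMPLE_SHEAR,
            rates=STANDARD_RATES, n_replicates=6, max_strain=8.0 / 7.0,
        ),
        "vessel-tension": ExperimentDesign(
            name="vessel-tension", mode=DeformationMode.UNIAXIAL_TENSION,
            rates=STANDARD_RATES, n_replicates=12, max_strain=1.3,
        ),
    }
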