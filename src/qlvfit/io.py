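"""File formats: curve files, material cards, parameter-table reports.

Two delimited-text curve dialects are defined (comma-separated, UTF-8,
'.' decimal, mandatory header):

* ``long`` — one row per observation:
  ``curve_id,replicate_id,mode,rate_s^-1,strain,stress_kPa``
* ``summary`` — one row per mean-curve point:
  ``curve_id,mode,rate_s^-1,strain,stress_mean_kPa,stress_sem_kPa,n``

The ``strain`` column holds gamma for simple shear and lambda for uniaxial
tension.  Writers are deterministic byte-for-byte (fixed row order, numbers
at 9 significant digits).

Material cards use a documented generic finite-element dialect (keyword
lines; SI units, Pa and s) and are not claimed byte-compatible with any
commercial solver.  Curve files stay in kPa; the kPa->Pa (and GPa->Pa)
conversions happen only in the card writer and are logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import FitResult
from .constitutive import DeformationMode, OgdenParameters, OGDEN_CONVENTION
from .materials import ExperimentDesign, MaterialModel
from .synthetic import ReplicateSet
from .viscoelastic import PronySeries, StressStrainCurve

__all__ = [
    "CurveParseError",
    "LONG_COLUMNS",
    "SUMMARY_COLUMNS",
    "read_curves",
    "write_curves",
    "export_material_card",
    "parse_material_card",
    "report_parameter_table",
]

log = logging.getLogger("qlvfit")

LONG_COLUMNS = ["curve_id", "replicate_id", "mode", "rate_s^-1", "strain", "stress_kPa"]
SUMMARY_COLUMNS = ["curve_id", "mode", "rate_s^-1", "strain",
                   "stress_mean_kPa", "stress_sem_kPa", "n"]

_FMT = "%.9g"  # numeric formatting contract for curve files


class CurveParseError(ValueError):
    """Malformed curve file; message lists offending lines."""


def _fmt(x: float) -> str:
    return _FMT % x


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CurveParseError(f"{path}: missing required column(s) {missing}")


def _validate_rows(df: pd.DataFrame, path) -> List[str]:
    problems = []
    # +2: header line and 1-based numbering
    for i, rate in zip(df.index, df["rate_s^-1"]):
        if not np.isfinite(rate) or rate <= 0:
            problems.append(f"line {i + 2}: non-positive strain rate {rate!r}")
    for i, mode in zip(df.index, df["mode"]):
        if mode not in (m.value for m in DeformationMode):
            problems.append(f"line {i + 2}: unknown mode {mode!r}")
    return problems


def read_curves(path, dialect: str = "long"
                ) -> Union[ReplicateSet, List[StressStrainCurve]]:
    """Read a curve file.

    ``long`` files return a :class:`ReplicateSet` (design inferred from the
    data); ``summary`` files return a list of mean/SEM curves.  Malformed
    content raises :class:`CurveParseError` naming the offending lines.
    """
    path = Path(path)
    if dialect not in ("long", "summary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    required = LONG_COLUMNS if dialect == "long" else SUMMARY_COLUMNS
    _check_header(df, required, path)
    if df.empty:
        raise CurveParseError(f"{path}: no data rows")
    problems = _validate_rows(df, path)
    if problems:
        raise CurveParseError(f"{path}: " + "; ".join(problems))

    if dialect == "summary":
        curves = []
        for (cid, mode, rate), sub in df.groupby(["curve_id", "mode", "rate_s^-1"], sort=True):
            sub = sub.sort_values("strain")
            strain = sub["strain"].to_numpy(dtype=float)
            if np.any(np.diff(strain) <= 0):
                problems.append(f"curve {cid!r}: non-monotone strain grid")
                continue
            sem = sub["stress_sem_kPa"].to_numpy(dtype=float)
            n = None if sub["n"].isna().all() else int(sub["n"].iloc[0])
            curves.append(StressStrainCurve(
                mode=DeformationMode(mode), rate=float(rate), strain=strain,
                stress=sub["stress_mean_kPa"].to_numpy(dtype=float),
                sem=None if np.isnan(sem).all() else sem, n=n, curve_id=str(cid),
            ))
        if problems:
            raise CurveParseError(f"{path}: " + "; ".join(problems))
        return curves

    replicates: Dict[float, List[StressStrainCurve]] = {}
    modes = set()
    for (cid, rid, mode, rate), sub in df.groupby(
            ["curve_id", "replicate_id", "mode", "rate_s^-1"], sort=True):
        sub = sub.sort_values("strain")
        strain = sub["strain"].to_numpy(dtype=float)
        if np.any(np.diff(strain) <= 0):
            problems.append(f"replicate {rid!r} of curve {cid!r}: non-monotone strain")
            continue
        modes.add(mode)
        replicates.setdefault(float(rate), []).append(StressStrainCurve(
            mode=DeformationMode(mode), rate=float(rate), strain=strain,
            stress=sub["stress_kPa"].to_numpy(dtype=float),
            replicate_id=str(rid), curve_id=str(cid),
        ))
    if problems:
        raise CurveParseError(f"{path}: " + "; ".join(problems))
    if len(modes) != 1:
        raise CurveParseError(f"{path}: file mixes deformation modes {sorted(modes)}")
    mode = DeformationMode(modes.pop())
    n_reps = {r: len(v) for r, v in replicates.items()}
    if len(set(n_reps.values())) != 1:
        raise CurveParseError(f"{path}: unbalanced replicate counts per rate: {n_reps}")
    any_curve = next(iter(replicates.values()))[0]
    design = ExperimentDesign(
        name=f"inferred:{path.name}", mode=mode, rates=tuple(sorted(replicates)),
        n_replicates=next(iter(n_reps.values())),
        max_strain=float(max(c.strain.max() for v in replicates.values() for c in v)),
        n_points=any_curve.strain.size,
    )
    return ReplicateSet(mode=mode, rates=design.rates, curves=replicates, design=design)


def write_curves(curves: Union[ReplicateSet, Sequence[StressStrainCurve]],
                 path, dialect: str = "long") -> None:
    """Write curves deterministically (rows ordered by curve id, replicate
    id, then ascending strain; numbers at 9 significant digits)."""
    path = Path(path)
    rows: List[dict] = []
    if dialect == "long":
        if isinstance(curves, ReplicateSet):
            flat = [c for rate in sorted(curves.rates) for c in curves.curves[rate]]
        else:
            flat = list(curves)
        for c in flat:
            cid = c.curve_id or f"{c.mode.value}@{c.rate:g}/s"
            rid = c.replicate_id or "rep01"
            for s, sig in zip(c.strain, c.stress):
                rows.append({"curve_id": cid, "replicate_id": rid, "mode": c.mode.value,
                             "rate_s^-1": _fmt(c.rate), "strain": _fmt(s),
                             "stress_kPa": _fmt(sig)})
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
        df = df.sort_values(["curve_id", "replicate_id", "strain"],
                            key=lambda s: s.astype(float) if s.name == "strain" else s,
                            kind="stable")
    elif dialect == "summary":
        if isinstance(curves, ReplicateSet):
            raise ValueError("summarise the ReplicateSet before writing the summary dialect")
        for c in sorted(curves, key=lambda c: (c.curve_id or "", c.rate)):
            cid = c.curve_id or f"{c.mode.value}@{c.rate:g}/s"
            sem = c.sem if c.sem is not None else [float("nan")] * c.strain.size
            for s, sig, se in zip(c.strain, c.stress, sem):
                rows.append({"curve_id": cid, "mode": c.mode.value,
                             "rate_s^-1": _fmt(c.rate), "strain": _fmt(s),
                             "stress_mean_kPa": _fmt(sig),
                             "stress_sem_kPa": "" if np.isnan(se) else _fmt(se),
                             "n": "" if c.n is None else str(c.n)})
        df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# material cards
# ---------------------------------------------------------------------------

def export_material_card(material: MaterialModel, dialect: str = "generic_fe") -> str:
    """Render one material as a generic FE material card (SI units).

    Hyperelastic lines carry ``(mu_i [Pa], alpha_i, 0)`` with 0 as the
    incompressibility placeholder; Prony lines carry ``(g_i, 0, tau_i [s])``.
    Materials without Ogden terms but with linear-elastic metadata (bone)
    export an ``*ELASTIC`` card instead.
    """
    if dialect != "generic_fe":
        raise ValueError(f"unknown card dialect {dialect!r}")
    lines = [
        "** qlvfit material card (generic FE dialect, SI units: kg, m, s, Pa)",
        f"** ogden convention: {OGDEN_CONVENTION}",
    ]
    if material.bulk_modulus is not None:
        lines.append(f"** bulk_modulus_GPa: {material.bulk_modulus:.6g} (metadata; "
                     "deviatoric response fit fully incompressibly)")
    if material.provenance:
        lines.append(f"** provenance: {material.provenance}")
    lines.append(f"*MATERIAL, NAME={material.name}")
    lines.append("*DENSITY")
    lines.append(f"{material.density:.6g}")
    if material.ogden is not None:
        log.info("card %s: converting mu from kPa to Pa", material.name)
        lines.append(f"*HYPERELASTIC, OGDEN, N={material.ogden.n_terms}")
        for mu, alpha in material.ogden.terms:
            lines.append(f"{mu * 1e3:.6g}, {alpha:.6g}, 0")
        if material.prony is not None and material.prony.n_terms:
            lines.append("*VISCOELASTIC, PRONY")
            for g, tau in material.prony.terms:
                lines.append(f"{g:.6g}, 0, {tau:.6g}")
    elif material.elastic_modulus is not None:
        log.info("card %s: converting E from GPa to Pa", material.name)
        lines.append("*ELASTIC")
        lines.append(f"{material.elastic_modulus * 1e9:.6g}, {material.poissons_ratio:.6g}")
    else:
        raise ValueError(f"material {material.name!r} has neither Ogden terms nor "
                         "linear-elastic metadata; nothing to export")
    return "\n".join(lines) + "\n"


def parse_material_card(text: str) -> MaterialModel:
    """Parse a generic-FE material card back into a :class:`MaterialModel`.

    Inverse of :func:`export_material_card` at 6 significant digits.
    """
    name = None
    density = None
    bulk = None
    provenance = ""
    ogden_terms: List[Tuple[float, float]] = []
    prony_terms: List[Tuple[float, float]] = []
    elastic: Optional[Tuple[float, float]] = None
    section = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("**"):
            body = line.lstrip("*").strip()
            if body.startswith("bulk_modulus_GPa:"):
                bulk = float(body.split(":", 1)[1].split()[0])
            elif body.startswith("provenance:"):
                provenance = body.split(":", 1)[1].strip()
            continue
        if line.startswith("*"):
            key = line.upper()
            if key.startswith("*MATERIAL"):
                for part in line.split(",")[1:]:
                    k, _, v = part.partition("=")
                    if k.strip().upper() == "NAME":
                        name = v.strip()
                section = None
            elif key.startswith("*DENSITY"):
                section = "density"
            elif key.startswith("*HYPERELASTIC"):
                section = "ogden"
            elif key.startswith("*VISCOELASTIC"):
                section = "prony"
            elif key.startswith("*ELASTIC"):
                section = "elastic"
            else:
                raise ValueError(f"unknown card keyword line: {line!r}")
            continue
        values = [float(v) for v in line.split(",")]
        if section == "density":
            density = values[0]
        elif section == "ogden":
            ogden_terms.append((values[0] / 1e3, values[1]))  # Pa -> kPa
        elif section == "prony":
            prony_terms.append((values[0], values[2]))
        elif section == "elastic":
            elastic = (values[0] / 1e9, values[1])  # Pa -> GPa
        else:
            raise ValueError(f"data line outside any section: {line!r}")
    if name is None or density is None:
        raise ValueError("card lacks *MATERIAL NAME or *DENSITY")
    return MaterialModel(
        name=name, density=density, bulk_modulus=bulk,
        ogden=OgdenParameters(ogden_terms) if ogden_terms else None,
        prony=PronySeries(prony_terms) if prony_terms else None,
        elastic_modulus=elastic[0] if elastic else None,
        poissons_ratio=elastic[1] if elastic else None,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# parameter-table report
# ---------------------------------------------------------------------------

def report_parameter_table(items: Sequence[Union[MaterialModel, Tuple[str, FitResult]]]
                           ) -> pd.DataFrame:
    """One row per material (or named fit result) in the layout of the
    reference property table: density, elastic constants, hyperelastic
    constants (mu_i, alpha_i) and viscous constants (g_i and decay constant
    1/tau_i).  Fit results additionally report per-curve and pooled R^2."""
    records = []
    max_ogden = 1
    max_prony = 1
    parsed: List[Tuple[str, Optional[MaterialModel], Optional[FitResult]]] = []
    for item in items:
        if isinstance(item, MaterialModel):
            parsed.append((item.name, item, None))
            if item.ogden is not None:
                max_ogden = max(max_ogden, item.ogden.n_terms)
            if item.prony is not None:
                max_prony = max(max_prony, item.prony.n_terms)
        else:
            name, fit = item
            parsed.append((name, None, fit))
            max_ogden = max(max_ogden, fit.ogden.n_terms)
            max_prony = max(max_prony, fit.prony.n_terms)

    def row(name, density, emod, nu, bulk, ogden, prony, fit=None):
        rec = {"name": name, "density_kg_m3": density, "elastic_modulus_GPa": emod,
               "poissons_ratio": nu, "bulk_modulus_GPa": bulk}
        for i in range(max_ogden):
            mu = alpha = np.nan
            if ogden is not None and i < ogden.n_terms:
                mu, alpha = ogden.terms[i]
            rec[f"mu_{i+1}_kPa"] = mu
            rec[f"alpha_{i+1}"] = alpha
        for i in range(max_prony):
            g = beta = np.nan
            if prony is not None and i < prony.n_terms:
                g, tau = prony.terms[i]
                beta = 1.0 / tau
            rec[f"g_{i+1}"] = g
            rec[f"decay_constant_{i+1}_s^-1"] = beta
        rec["r2_pooled"] = fit.pooled_r2 if fit is not None else np.nan
        rec["r2_per_curve"] = (
            ";".join(f"{k}={v:.4f}" for k, v in sorted(fit.per_curve_r2.items()))
            if fit is not None else ""
        )
        return rec

    for name, mat, fit in parsed:
        if mat is not None:
            records.append(row(name, mat.density, mat.elastic_modulus, mat.poissons_ratio,
                               mat.bulk_modulus, mat.ogden, mat.prony))
        else:
            records.append(row(name, np.nan, np.nan, np.nan, np.nan,
                               fit.ogden, fit.prony, fit))
    columns = (["name", "density_kg_m3", "elastic_modulus_GPa", "poissons_ratio",
                "bulk_modulus_GPa"]
               + [c for i in range(max_ogden) for c in (f"mu_{i+1}_kPa", f"alpha_{i+1}")]
               + [c for i in range(max_prony) for c in (f"g_{i+1}", f"decay_constant_{i+1}_s^-1")]
               + ["r2_pooled", "r2_per_curve"])
    return pd.DataFrame.from_records(records, columns=columns)
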