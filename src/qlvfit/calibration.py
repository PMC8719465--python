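"""Simultaneous multi-rate calibration of Ogden + Prony parameters.

The estimator fits one Ogden hyperelastic backbone and one Prony relaxation
series to stress-strain curves measured at several constant strain rates
*simultaneously*: a single parameter vector must reproduce every curve
through the QLV forward model.  The fit is bounded nonlinear least squares
on per-curve peak-normalised residuals, restarted from several random
initial points because the loss surface is multi-modal in alpha and the
relaxation times.

The public surface is the scikit-learn style :class:`OgdenQLVRegressor`
(``fit(X, y)`` on a table of (mode, rate, strain) rows with stress targets)
plus thin functional wrappers (:func:`fit_multirate`, :func:`residual_vector`,
:func:`bootstrap_uncertainty`) that operate on curve objects.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constitutive import DeformationMode, OgdenParameters
from .viscoelastic import PronySeries, StressStrainCurve, qlv_stress_recursive, ramp_history

__all__ = [
    "FitConfig",
    "FitResult",
    "FitFailureError",
    "OgdenQLVRegressor",
    "fit_multirate",
    "residual_vector",
    "r_squared",
    "bootstrap_uncertainty",
]


class FitFailureError(RuntimeError):
    """No multi-start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[list] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the simultaneous multi-rate fit.

    Bounds are in natural units (mu in kPa, beta in 1/s); mu and beta are
    optimised on a log10 scale.  ``alpha_signs`` fixes the sign of each
    Ogden exponent (all positive by default, matching brain/vessel fits; a
    two-term fit with a negative exponent passes e.g. ``(1, -1)``).
    """

    n_ogden_terms: int = 1
    n_prony_terms: int = 1
    mu_bounds: Tuple[float, float] = (1e-4, 1e6)  # kPa
    alpha_bounds: Tuple[float, float] = (0.1, 50.0)  # magnitude
    alpha_signs: Optional[Tuple[int, ...]] = None
    g_max: float = 0.999
    beta_bounds: Tuple[float, float] = (1e-4, 1e4)  # 1/s
    fixed_alpha: Optional[float] = None
    weighting: str = "peak"  # 'peak' | 'inverse_sem' | 'none'
    n_starts: int = 16
    seed: int = 0
    stress_measure: str = "cauchy"
    n_steps: int = 1000  # forward-model steps per simulated ramp
    ramp_max_strain: Optional[float] = None  # None: ramp to each curve's max strain
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_ogden_terms < 1 or self.n_prony_terms < 0:
            raise ValueError("need >= 1 Ogden term and >= 0 Prony terms")
        for lo, hi in (self.mu_bounds, self.alpha_bounds, self.beta_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < lower < upper")
        if self.n_starts < 1:
            raise ValueError("multi-start count must be >= 1")
        if min(self.ftol, self.xtol, self.gtol) <= 0:
            raise ValueError("optimizer tolerances must be positive")
        if self.weighting not in ("peak", "inverse_sem", "none"):
            raise ValueError(f"unknown weighting rule {self.weighting!r}")
        if self.alpha_signs is not None and len(self.alpha_signs) != self.n_ogden_terms:
            raise ValueError("alpha_signs length must match n_ogden_terms")

    @property
    def signs(self) -> Tuple[int, ...]:
        return self.alpha_signs or tuple([1] * self.n_ogden_terms)


@dataclass
class FitResult:
    """Calibrated parameters with fit diagnostics and provenance."""

    ogden: OgdenParameters
    prony: PronySeries
    per_curve_r2: Dict[str, float]
    pooled_r2: float
    wrss: float  # final weighted residual sum of squares
    converged: bool
    n_starts_tried: int
    best_start_index: int
    seed: int
    start_costs: List[float]  # loss trace across starts (inf = failed start)
    config: FitConfig
    warnings: List[str] = field(default_factory=list)


def _curve_label(curve: StressStrainCurve) -> str:
    base = curve.curve_id or f"{curve.mode.value}@{curve.rate:g}/s"
    return base


def r_squared(model_stress, data_stress) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of a model curve
    against a data curve on a shared strain grid.

    ``SS_tot`` is taken about the data mean; a constant data curve has no
    variance to explain and raises.
    """
    model = np.asarray(getattr(model_stress, "stress", model_stress), dtype=float)
    data = np.asarray(getattr(data_stress, "stress", data_stress), dtype=float)
    if model.shape != data.shape:
        raise ValueError("model and data curves must share one strain grid")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: data curve is constant (SS_tot = 0)")
    ss_res = float(np.sum((model - data) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# parameter packing:  theta = [mu_1.., |alpha|_1.., g_1.., beta_1..]  (natural)
# optimiser space:    x     = [log10 mu.., |alpha|.., g.., log10 beta..]
# ---------------------------------------------------------------------------

def _unpack_natural(theta: np.ndarray, config: FitConfig) -> Tuple[OgdenParameters, PronySeries]:
    no, np_ = config.n_ogden_terms, config.n_prony_terms
    if config.fixed_alpha is None:
        mus, alphas = theta[:no], theta[no:2 * no]
        rest = theta[2 * no:]
        alphas = np.asarray(alphas) * np.asarray(config.signs)
    else:
        mus = theta[:no]
        alphas = np.full(no, config.fixed_alpha, dtype=float)
        rest = theta[no:]
    ogden = OgdenParameters(list(zip(mus, alphas)))
    if np_:
        gs, betas = rest[:np_], rest[np_:2 * np_]
        prony = PronySeries.from_decay_constants(list(zip(gs, betas)))
    else:
        prony = PronySeries.empty()
    return ogden, prony


def _x_to_theta(x: np.ndarray, config: FitConfig) -> np.ndarray:
    no, np_ = config.n_ogden_terms, config.n_prony_terms
    parts = [10.0 ** x[:no]]
    i = no
    if config.fixed_alpha is None:
        parts.append(x[i:i + no])
        i += no
    if np_:
        parts.append(x[i:i + np_])
        parts.append(10.0 ** x[i + np_:i + 2 * np_])
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def _optimiser_bounds(config: FitConfig) -> Tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    no, np_ = config.n_ogden_terms, config.n_prony_terms
    lo += [math.log10(config.mu_bounds[0])] * no
    hi += [math.log10(config.mu_bounds[1])] * no
    if config.fixed_alpha is None:
        lo += [config.alpha_bounds[0]] * no
        hi += [config.alpha_bounds[1]] * no
    lo += [0.0] * np_
    hi += [config.g_max] * np_
    lo += [math.log10(config.beta_bounds[0])] * np_
    hi += [math.log10(config.beta_bounds[1])] * np_
    return np.array(lo), np.array(hi)


def _curve_weights(datasets: Sequence[StressStrainCurve], config: FitConfig) -> List[np.ndarray]:
    weights = []
    for c in datasets:
        if config.weighting == "peak":
            peak = c.peak_stress
            w = np.full_like(c.stress, 1.0 / peak if peak > 0 else 1.0)
        elif config.weighting == "inverse_sem":
            if c.sem is None:
                raise ValueError(f"curve {_curve_label(c)} has no SEM for inverse-SEM weighting")
            floor = 1e-6 * max(c.peak_stress, 1.0)
            w = 1.0 / np.maximum(c.sem, floor)
        else:
            w = np.ones_like(c.stress)
        weights.append(w)
    return weights


def _model_on_curve(curve: StressStrainCurve, ogden: OgdenParameters, prony: PronySeries,
                    config: FitConfig) -> np.ndarray:
    """Simulate the constant-rate ramp of one data curve and interpolate the
    model stress onto the curve's strain grid."""
    max_strain = config.ramp_max_strain or float(np.max(curve.strain))
    if np.max(curve.strain) > max_strain * (1 + 1e-12):
        raise ValueError(
            f"curve {_curve_label(curve)} has strain beyond the simulated ramp "
            f"(max {max_strain}); refusing to extrapolate"
        )
    history = ramp_history(curve.rate, max_strain, config.n_steps, curve.mode)
    model = qlv_stress_recursive(history, ogden, prony, measure=config.stress_measure)
    return np.interp(curve.strain, model.strain, model.stress)


def residual_vector(theta: np.ndarray, datasets: Sequence[StressStrainCurve],
                    config: FitConfig) -> np.ndarray:
    """Weighted residuals (model minus data mean curve) for packed natural
    parameters ``theta = [mu.., |alpha|.., g.., beta..]``.

    One residual per data point, weighted per curve (default: by the inverse
    peak absolute stress, so curves that differ by orders of magnitude
    across rates contribute comparably).
    """
    theta = np.asarray(theta, dtype=float)
    ogden, prony = _unpack_natural(theta, config)
    weights = _curve_weights(datasets, config)
    res = [w * (_model_on_curve(c, ogden, prony, config) - c.stress)
           for c, w in zip(datasets, weights)]
    # soft constraint: total relaxing fraction must stay below g_max
    excess = float(np.sum(prony.gs)) - config.g_max if prony.n_terms else 0.0
    if excess > 0.0:
        res.append(np.array([1e3 * excess]))
    return np.concatenate(res)


def _sample_starts(config: FitConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded initial points: log-uniform in mu and beta, uniform in alpha
    magnitude and g."""
    no, np_ = config.n_ogden_terms, config.n_prony_terms
    cols = [rng.uniform(math.log10(config.mu_bounds[0]), math.log10(config.mu_bounds[1]),
                        size=(config.n_starts, no))]
    if config.fixed_alpha is None:
        cols.append(rng.uniform(config.alpha_bounds[0], config.alpha_bounds[1],
                                size=(config.n_starts, no)))
    if np_:
        cols.append(rng.uniform(0.0, config.g_max, size=(config.n_starts, np_)))
        cols.append(rng.uniform(math.log10(config.beta_bounds[0]),
                                math.log10(config.beta_bounds[1]),
                                size=(config.n_starts, np_)))
    return np.hstack(cols)


def _canonical_order(ogden: OgdenParameters, prony: PronySeries
                     ) -> Tuple[OgdenParameters, PronySeries]:
    """Sort Ogden terms by descending mu and Prony terms by ascending tau so
    equivalent permutations report identically."""
    ot = sorted(ogden.terms, key=lambda t: (-t[0], t[1]))
    pt = sorted(prony.terms, key=lambda t: (t[1], t[0]))
    return OgdenParameters(ot), PronySeries(pt)


def fit_multirate(datasets: Sequence[StressStrainCurve],
                  config: Optional[FitConfig] = None) -> FitResult:
    """Simultaneously fit Ogden + Prony parameters to curves at several rates.

    Runs bounded least squares (scipy ``least_squares``, trust-region
    reflective) from ``config.n_starts`` seeded random initial points and
    returns the best converged start (ties broken by lowest start index).
    Deterministic given (datasets, config, seed).
    """
    config = config or FitConfig()
    if len(datasets) == 0:
        raise ValueError("need at least one stress-strain curve to fit")
    warn_list: List[str] = []
    rates = {(c.mode, c.rate) for c in datasets}
    if config.n_prony_terms > 0 and len({r for _, r in rates}) < 2:
        msg = ("Prony relaxation terms are poorly identifiable from a single "
               "strain rate; provide curves at >= 2 distinct rates")
        warn_list.append(msg)
        _warnings.warn(msg, stacklevel=2)

    lo, hi = _optimiser_bounds(config)
    rng = np.random.default_rng(config.seed)
    starts = _sample_starts(config, rng)

    def objective(x: np.ndarray) -> np.ndarray:
        return residual_vector(_x_to_theta(x, config), datasets, config)

    results = []
    costs: List[float] = []
    for x0 in starts:
        try:
            sol = least_squares(objective, x0, bounds=(lo, hi), method="trf",
                                x_scale="jac", ftol=config.ftol, xtol=config.xtol,
                                gtol=config.gtol, max_nfev=config.max_nfev)
            ok = sol.status > 0 and np.all(np.isfinite(sol.x))
        except (ValueError, FloatingPointError):  # pathological start
            sol, ok = None, False
        results.append((sol, ok))
        costs.append(float(sol.cost) if ok else math.inf)

    best_idx = int(np.argmin(costs))  # argmin takes the first of equal losses
    if not math.isfinite(costs[best_idx]):
        raise FitFailureError(
            f"none of {config.n_starts} starts converged",
            diagnostics=[getattr(s, "message", "exception") for s, _ in results],
        )
    best = results[best_idx][0]
    ogden, prony = _canonical_order(*_unpack_natural(_x_to_theta(best.x, config), config))

    per_curve: Dict[str, float] = {}
    ss_res_tot = ss_tot_tot = 0.0
    for c in datasets:
        model = _model_on_curve(c, ogden, prony, config)
        per_curve[_curve_label(c)] = r_squared(model, c.stress)
        ss_res_tot += float(np.sum((model - c.stress) ** 2))
        ss_tot_tot += float(np.sum((c.stress - c.stress.mean()) ** 2))
    pooled = 1.0 - ss_res_tot / ss_tot_tot if ss_tot_tot > 0 else float("nan")

    return FitResult(
        ogden=ogden, prony=prony, per_curve_r2=per_curve, pooled_r2=pooled,
        wrss=2.0 * float(best.cost), converged=True,
        n_starts_tried=config.n_starts, best_start_index=best_idx,
        seed=config.seed, start_costs=costs, config=config, warnings=warn_list,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

_X_COLUMNS = ("mode", "rate", "strain")


class OgdenQLVRegressor(BaseEstimator, RegressorMixin):
    """Ogden + Prony QLV stress model as a scikit-learn regressor.

    ``X`` is a table of observations with columns ``mode`` (``simple_shear``
    or ``uniaxial_tension``), ``rate`` (nominal strain rate, 1/s) and
    ``strain`` (gamma or lambda); ``y`` is stress in kPa.  ``fit`` groups the
    rows into one curve per (mode, rate) and calibrates all parameters
    simultaneously; ``predict`` returns model stress at the requested rows.

    Parameters mirror :class:`FitConfig`; fitted attributes are ``ogden_``,
    ``prony_`` and the full :class:`FitResult` in ``result_``.
    """

    def __init__(self, n_ogden_terms: int = 1, n_prony_terms: int = 1,
                 mu_bounds: Tuple[float, float] = (1e-4, 1e6),
                 alpha_bounds: Tuple[float, float] = (0.1, 50.0),
                 alpha_signs: Optional[Tuple[int, ...]] = None,
                 g_max: float = 0.999,
                 beta_bounds: Tuple[float, float] = (1e-4, 1e4),
                 fixed_alpha: Optional[float] = None, weighting: str = "peak",
                 n_starts: int = 16, random_state: int = 0,
                 stress_measure: str = "cauchy", n_steps: int = 1000,
                 ramp_max_strain: Optional[float] = None,
                 ftol: float = 1e-12, xtol: float = 1e-12, gtol: float = 1e-12,
                 max_nfev: Optional[int] = None):
        self.n_ogden_terms = n_ogden_terms
        self.n_prony_terms = n_prony_terms
        self.mu_bounds = mu_bounds
        self.alpha_bounds = alpha_bounds
        self.alpha_signs = alpha_signs
        self.g_max = g_max
        self.beta_bounds = beta_bounds
        self.fixed_alpha = fixed_alpha
        self.weighting = weighting
        self.n_starts = n_starts
        self.random_state = random_state
        self.stress_measure = stress_measure
        self.n_steps = n_steps
        self.ramp_max_strain = ramp_max_strain
        self.ftol = ftol
        self.xtol = xtol
        self.gtol = gtol
        self.max_nfev = max_nfev

    def _config(self) -> FitConfig:
        return FitConfig(
            n_ogden_terms=self.n_ogden_terms, n_prony_terms=self.n_prony_terms,
            mu_bounds=self.mu_bounds, alpha_bounds=self.alpha_bounds,
            alpha_signs=self.alpha_signs, g_max=self.g_max,
            beta_bounds=self.beta_bounds, fixed_alpha=self.fixed_alpha,
            weighting=self.weighting, n_starts=self.n_starts,
            seed=self.random_state, stress_measure=self.stress_measure,
            n_steps=self.n_steps, ramp_max_strain=self.ramp_max_strain,
            ftol=self.ftol, xtol=self.xtol, gtol=self.gtol,
            max_nfev=self.max_nfev,
        )

    @staticmethod
    def _validate_X(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=list(_X_COLUMNS))
        missing = [c for c in _X_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing required columns {missing}")
        return X

    @staticmethod
    def _group_curves(X: pd.DataFrame, y: np.ndarray) -> List[StressStrainCurve]:
        curves = []
        for (mode, rate), sub in X.groupby(["mode", "rate"], sort=True):
            strain = sub["strain"].to_numpy(dtype=float)
            order = np.argsort(strain, kind="stable")
            pos = sub.index.to_numpy()[order]
            curves.append(StressStrainCurve(
                mode=DeformationMode(mode), rate=float(rate),
                strain=strain[order], stress=y[pos],
            ))
        return curves

    def fit(self, X, y) -> "OgdenQLVRegressor":
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (len(X),):
            raise ValueError("y must be a 1-D stress vector matching X row-for-row")
        curves = self._group_curves(X.reset_index(drop=True), y)
        result = fit_multirate(curves, self._config())
        self.ogden_ = result.ogden
        self.prony_ = result.prony
        self.result_ = result
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "ogden_"):
            raise AttributeError("estimator is not fitted; call fit first")
        X = self._validate_X(X).reset_index(drop=True)
        config = self._config()
        out = np.empty(len(X), dtype=float)
        for (mode, rate), sub in X.groupby(["mode", "rate"], sort=True):
            strain = sub["strain"].to_numpy(dtype=float)
            order = np.argsort(strain, kind="stable")
            curve = StressStrainCurve(
                mode=DeformationMode(mode), rate=float(rate),
                strain=strain[order], stress=np.zeros(len(sub)),
            )
            model = _model_on_curve(curve, self.ogden_, self.prony_, config)
            out[sub.index.to_numpy()[order]] = model
        return out


def curves_to_frame(datasets: Sequence[StressStrainCurve]) -> Tuple[pd.DataFrame, np.ndarray]:
    """Flatten curves into the (X, y) table form consumed by the regressor."""
    rows, ys = [], []
    for c in datasets:
        for s, sig in zip(c.strain, c.stress):
            rows.append((c.mode.value, c.rate, s))
            ys.append(sig)
    return pd.DataFrame(rows, columns=list(_X_COLUMNS)), np.array(ys)


def bootstrap_uncertainty(replicates, config: Optional[FitConfig] = None,
                          n_boot: int = 50, seed: int = 0,
                          percentiles: Tuple[float, float] = (2.5, 97.5)
                          ) -> Dict[str, Tuple[float, float]]:
    """Percentile confidence intervals for every fitted parameter by
    resampling replicates with replacement within each rate and refitting.

    ``replicates`` is a :class:`~qlvfit.synthetic.ReplicateSet`.  Returns a
    dict keyed ``mu_1``, ``alpha_1``, ``g_1``, ``beta_1``, ... mapping to
    (lower, upper) interval endpoints.  Deterministic given ``seed``.
    """
    from .synthetic import summarize_replicates  # deferred: avoids module cycle

    config = config or FitConfig()
    if n_boot < 2:
        raise ValueError("need n_boot >= 2 bootstrap resamples")
    for rate, reps in replicates.curves.items():
        if len(reps) < 2:
            raise ValueError(f"need >= 2 replicates per rate (rate {rate} has {len(reps)})")
    rng = np.random.default_rng(seed)
    samples: List[np.ndarray] = []
    for _ in range(n_boot):
        resampled = replicates.resample(rng)
        summaries = summarize_replicates(resampled)
        res = fit_multirate(summaries, config)
        theta = np.concatenate([
            res.ogden.mus, res.ogden.alphas,
            res.prony.gs, res.prony.decay_constants,
        ])
        samples.append(theta)
    arr = np.vstack(samples)
    names = ([f"mu_{i+1}" for i in range(config.n_ogden_terms)]
             + [f"alpha_{i+1}" for i in range(config.n_ogden_terms)]
             + [f"g_{i+1}" for i in range(config.n_prony_terms)]
             + [f"beta_{i+1}" for i in range(config.n_prony_terms)])
    lo, hi = np.percentile(arr, percentiles, axis=0)
    return {name: (float(l), float(h)) for name, l, h in zip(names, lo, hi)}
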