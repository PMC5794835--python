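"""Toxicity-parameter estimation with a (µ, λ) evolution strategy.

Chemotherapy toxicity constants are the model quantities for which no
direct biological measurements exist; they are estimated by fitting
simulated median leukocyte curves to observed day/median tables.  Cell
kinetics and G-CSF PK/PD are held fixed — risk groups may differ only in
their toxicity parameters.

The objective is the sum of squared differences of log-transformed WBC
(model interpolated at the exact observation days vs. observed medians);
the log scale keeps nadir values from being drowned out by recovery
peaks.  The search is a classic (µ, λ) evolution strategy with
log-normal self-adaptive per-coordinate step sizes and intermediate
recombination; comma selection, with the best-ever candidate tracked
separately.  Fully reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import ModelParameters
from .simulate import GcsfSchedule, Regimen, simulate

__all__ = [
    "ObservedSeries", "FitSpec", "FitResult",
    "residual", "fit_toxicity", "fit_risk_groups", "apply_free_params",
]

#: large finite penalty for a failed simulation
PENALTY = 1e12

#: toxicity fields that may be freed in a fit
FREE_FIELDS = (
    "s_S", "s_CG", "s_PGB", "s_MGB", "k_tox", "f_first",
    "ly_intensity", "ly_decay", "dose_exponent",
)


@dataclass
class ObservedSeries:
    """One observed median WBC time course under a known treatment."""

    days: np.ndarray
    values: np.ndarray
    regimen: Regimen
    schedule: Optional[GcsfSchedule] = None
    risk_group: Optional[str] = None
    iqr_low: Optional[np.ndarray] = None     # shown in plots, never fitted
    iqr_high: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.values.shape:
            raise ValueError("days and values must be 1-d arrays of equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("observation days must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("observed WBC values must be positive")


@dataclass
class FitSpec:
    """Free parameters, bounds and evolution-strategy settings.

    Free parameters are addressed as ``"<drug>.<field>"`` with fields
    restricted to toxicity constants.  ``mu``/``lam`` are the parent and
    offspring counts; ``init_step`` is the initial mutation step relative
    to the bound width.
    """

    free_params: List[str]
    bounds: Dict[str, Tuple[float, float]]
    mu: int = 5
    lam: int = 35
    max_generations: int = 200
    init_step: float = 0.25
    tol: float = 1e-12
    patience: int = 40
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.free_params:
            raise ValueError("at least one free parameter is required")
        for name in self.free_params:
            drug, _, fld = name.partition(".")
            if fld not in FREE_FIELDS:
                raise ValueError(
                    f"{name!r}: only toxicity parameters may be freed "
                    f"(fields {FREE_FIELDS})"
                )
            if name not in self.bounds:
                raise ValueError(f"missing bounds for {name!r}")
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
        if self.mu < 1 or self.lam < self.mu:
            raise ValueError("need 1 <= mu <= lam")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class FitResult:
    values: Dict[str, float]
    params: ModelParameters
    residual: float
    trace: List[float]            # best-ever residual per generation
    n_evaluations: int
    seed: int
    converged: bool


def apply_free_params(
    base: ModelParameters, names: Sequence[str], values: Sequence[float]
) -> ModelParameters:
    """Copy of ``base`` with the named toxicity parameters replaced."""
    params = base.copy()
    for name, value in zip(names, values):
        drug, _, fld = name.partition(".")
        if drug not in params.drugs:
            raise ValueError(f"unknown drug {drug!r}")
        setattr(params.drugs[drug], fld, float(value))
    params.validate()
    return params


def residual(
    values: Sequence[float],
    names: Sequence[str],
    observed: Sequence[ObservedSeries],
    base: ModelParameters,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Sum of squared log-WBC differences over all series and days.

    Deterministic; a failed simulation maps to a large finite penalty so
    the search can continue.
    """
    try:
        params = apply_free_params(base, names, values)
    except ValueError:
        return PENALTY
    total = 0.0
    for series in observed:
        horizon = max(float(series.days[-1]) + 1.0, series.regimen.duration)
        try:
            result = simulate(
                params, series.regimen, series.schedule,
                horizon=horizon, rtol=rtol, atol=atol,
            )
        except RuntimeError:
            return PENALTY
        model = np.interp(series.days, result.t, result.wbc)
        if np.any(model <= 0):
            return PENALTY
        r = np.log(model) - np.log(series.values)
        total += float(r @ r)
    return total


def fit_toxicity(
    observed: Sequence[ObservedSeries],
    spec: FitSpec,
    base: ModelParameters,
) -> FitResult:
    """(µ, λ) evolution strategy over the free toxicity parameters."""
    if not observed:
        raise ValueError("at least one observed series is required")
    names = list(spec.free_params)
    n = len(names)
    lo = np.array([spec.bounds[k][0] for k in names])
    hi = np.array([spec.bounds[k][1] for k in names])
    width = hi - lo
    rng = np.random.default_rng(spec.seed)

    tau_g = 1.0 / math.sqrt(2.0 * n)
    tau_c = 1.0 / math.sqrt(2.0 * math.sqrt(n))

    def evaluate(x: np.ndarray) -> float:
        return residual(x, names, observed, base, rtol=spec.rtol, atol=spec.atol)

    # initial parents: uniform in bounds, plus the midpoint
    xs = lo + width * rng.random((spec.mu, n))
    xs[0] = lo + 0.5 * width
    sigmas = np.full((spec.mu, n), spec.init_step) * width
    fits = np.array([evaluate(x) for x in xs])
    n_eval = spec.mu

    order = np.argsort(fits)
    best_x = xs[order[0]].copy()
    best_f = float(fits[order[0]])
    trace = [best_f]
    stall = 0
    converged = False

    for _ in range(spec.max_generations):
        off_x = np.empty((spec.lam, n))
        off_s = np.empty((spec.lam, n))
        for k in range(spec.lam):
            if spec.mu > 1:
                i, j = rng.choice(spec.mu, size=2, replace=False)
                x = 0.5 * (xs[i] + xs[j])
                s = np.sqrt(sigmas[i] * sigmas[j])
            else:
                x, s = xs[0].copy(), sigmas[0].copy()
            s = s * np.exp(
                tau_g * rng.standard_normal() + tau_c * rng.standard_normal(n)
            )
            s = np.minimum(s, width)           # step never exceeds the box
            x = x + s * rng.standard_normal(n)
            # reflect into bounds
            x = np.where(x < lo, 2 * lo - x, x)
            x = np.where(x > hi, 2 * hi - x, x)
            x = np.clip(x, lo, hi)
            off_x[k], off_s[k] = x, s
        off_f = np.array([evaluate(x) for x in off_x])
        n_eval += spec.lam

        # comma selection: parents chosen from the offspring only
        sel = np.argsort(off_f, kind="stable")[: spec.mu]
        xs, sigmas, fits = off_x[sel], off_s[sel], off_f[sel]

        if off_f[sel[0]] < best_f - spec.tol * max(1.0, abs(best_f)):
            stall = 0
        else:
            stall += 1
        if off_f[sel[0]] < best_f:
            best_f = float(off_f[sel[0]])
            best_x = off_x[sel[0]].copy()
        trace.append(best_f)
        if stall >= spec.patience:
            converged = True
            break

    return FitResult(
        values={k: float(v) for k, v in zip(names, best_x)},
        params=apply_free_params(base, names, best_x),
        residual=best_f,
        trace=trace,
        n_evaluations=n_eval,
        seed=spec.seed,
        converged=converged,
    )


def fit_risk_groups(
    observed_by_group: Dict[str, Sequence[ObservedSeries]],
    spec: FitSpec,
    base: ModelParameters,
) -> Dict[str, Optional[FitResult]]:
    """Independent toxicity fits per risk group with shared settings.

    Non-toxicity parameters are shared via ``base``; each group gets its
    own :func:`fit_toxicity` run with the same seed.  Groups without data
    are flagged with ``None``.
    """
    results: Dict[str, Optional[FitResult]] = {}
    for group in ("low", "medium", "high"):
        series = observed_by_group.get(group)
        results[group] = fit_toxicity(series, spec, base) if series else None
    return results
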