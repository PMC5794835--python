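"""Reference parameter sets, toy regimens and synthetic observed cohorts.

Everything needed to exercise the simulator, optimizer and calibration
without external data: the bundled reference human parameterization, toy
versions of the clinically motivated regimens (CHOP-14/12, BEACOPP
escalated, sequential ETC, a single-drug regimen for calibration
studies), and a generator of noisy "observed" median leukocyte time
courses from known ground-truth parameters.

The noise model is multiplicative log-normal on counts (counts are
positive and right-skewed); per observation day the median across a
configurable number of pseudo-patients is reported, mimicking the
median curves of clinical trial populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibrate import ObservedSeries
from .params import ModelParameters, load_parameters, reference_params_path, save_parameters
from .simulate import GcsfSchedule, Regimen, save_regimen, save_schedule, simulate

__all__ = [
    "make_reference_params",
    "make_toy_regimen",
    "SyntheticCohortSpec",
    "generate_observed",
    "write_fixtures",
    "TOY_REGIMENS",
]

TOY_REGIMENS = ("chop14_like", "chop12_like", "beacopp_like", "etc_like", "single_drug")


def make_reference_params(risk: Optional[str] = None) -> ModelParameters:
    """The bundled reference human parameterization.

    ``risk`` in {"low", "medium", "high"} applies the risk-group toxicity
    multiplier to every stage-kill intensity and lymphotoxic amplitude
    (risk tertiles differ in chemotherapy sensitivity only; cell kinetics
    and G-CSF PK/PD are shared).
    """
    params = load_parameters(reference_params_path())
    if risk is not None:
        if risk not in params.risk_multipliers:
            raise ValueError(f"unknown risk group {risk!r}")
        m = params.risk_multipliers[risk]
        for drug in params.drugs.values():
            drug.s_S *= m
            drug.s_CG *= m
            drug.s_PGB *= m
            drug.s_MGB *= m
            drug.ly_intensity *= m
    return params


def make_toy_regimen(name: str) -> Regimen:
    """Structurally faithful toy version of a named regimen family."""
    if name == "chop14_like" or name == "chop12_like":
        length = 14.0 if name == "chop14_like" else 12.0
        return Regimen(
            name=name,
            cycle_length=length,
            n_cycles=6,
            administrations=[
                (1, "cyclophosphamide", 750.0),
                (1, "doxorubicin", 50.0),
                (1, "vincristine", 1.4),
            ],
            prednisone_days=[(1, 5)],
        )
    if name == "beacopp_like":
        # escalated-BEACOPP-shaped: etoposide d1-3, the procarbazine
        # course collapsed to one day-1 administration of the course dose
        return Regimen(
            name=name,
            cycle_length=21.0,
            n_cycles=8,
            administrations=[
                (1, "cyclophosphamide", 1250.0),
                (1, "doxorubicin", 35.0),
                (1, "etoposide", 200.0),
                (2, "etoposide", 200.0),
                (3, "etoposide", 200.0),
                (1, "procarbazine", 700.0),
                (8, "vincristine", 1.4),
            ],
            prednisone_days=[(1, 14)],
        )
    if name == "etc_like":
        # sequential dose-dense blocks: epirubicin, paclitaxel, cyclophosphamide
        return Regimen(
            name=name,
            cycle_length=14.0,
            n_cycles=9,
            blocks=[
                (1, 3, [(1, "epirubicin", 150.0)]),
                (4, 6, [(1, "paclitaxel", 225.0)]),
                (7, 9, [(1, "cyclophosphamide", 2500.0)]),
            ],
        )
    if name == "single_drug":
        return Regimen(
            name=name,
            cycle_length=14.0,
            n_cycles=2,
            administrations=[(1, "cyclophosphamide", 750.0)],
        )
    raise ValueError(f"unknown toy regimen {name!r}")


@dataclass
class SyntheticCohortSpec:
    """Specification of one synthetic observed median time course."""

    params: ModelParameters
    regimen: Regimen
    schedule: Optional[GcsfSchedule]
    observation_days: Sequence[float]
    sigma: float = 0.1          # log-normal multiplicative noise scale
    n_patients: int = 25        # pseudo-patients for the median
    seed: int = 0
    risk_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.n_patients < 1:
            raise ValueError("need at least one pseudo-patient")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def generate_observed(spec: SyntheticCohortSpec) -> ObservedSeries:
    """Noisy observed median WBC series from a known generating truth.

    The generating parameters are simulated once, sampled at the
    observation days, then each pseudo-patient's value is drawn with
    multiplicative log-normal noise and the per-day median returned.
    Deterministic per seed; ``sigma = 0`` reproduces the model exactly.
    """
    days = np.asarray(sorted(spec.observation_days), dtype=float)
    if days.size == 0:
        raise ValueError("need at least one observation day")
    horizon = max(float(days[-1]) + 1.0, spec.regimen.duration)
    result = simulate(spec.params, spec.regimen, spec.schedule, horizon=horizon)
    truth = np.interp(days, result.t, result.wbc)
    if spec.sigma == 0:
        values = truth.copy()
    else:
        rng = np.random.default_rng(spec.seed)
        draws = truth[None, :] * np.exp(
            spec.sigma * rng.standard_normal((spec.n_patients, days.size))
        )
        values = np.median(draws, axis=0)
    return ObservedSeries(
        days=days,
        values=values,
        regimen=spec.regimen,
        schedule=spec.schedule,
        risk_group=spec.risk_group,
    )


def write_fixtures(directory, seed: int = 0) -> dict:
    """Write reference params, toy regimens and one synthetic cohort.

    Returns a mapping of fixture names to file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}

    params = make_reference_params()
    p = directory / "reference_params.yaml"
    save_parameters(params, p)
    written["params"] = p

    for name in TOY_REGIMENS:
        path = directory / f"regimen_{name}.yaml"
        save_regimen(make_toy_regimen(name), path)
        written[f"regimen_{name}"] = path

    schedule = GcsfSchedule.consecutive("filgrastim", 4, 10, 300.0)
    sp = directory / "schedule_filgrastim_d4_13.yaml"
    save_schedule(schedule, sp)
    written["schedule"] = sp

    spec = SyntheticCohortSpec(
        params=params,
        regimen=make_toy_regimen("chop14_like"),
        schedule=schedule,
        observation_days=np.arange(0, 85, 3),
        sigma=0.1,
        seed=seed,
    )
    series = generate_observed(spec)
    cp = directory / "synthetic_cohort.csv"
    pd.DataFrame({"day": series.days, "median_wbc": series.values}).to_csv(
        cp, index=False
    )
    written["cohort"] = cp
    return written
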