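"""Exhaustive G-CSF schedule-space evaluation and selection.

For filgrastim, schedules are parameterized by the starting cycle day
and the number of consecutive daily injections; every feasible cell of
that (start × n) grid is simulated and summarized by a leukotoxicity
objective, alongside the no-G-CSF baseline.  For pegfilgrastim (one
injection per cycle) the search runs over injection day and dose,
reporting the smallest dose whose outcome stays within a stated margin
of the full-dose optimum.  Sequential regimens declared in cycle blocks
are optimized by a greedy forward pass over blocks.

All evaluations are pure per-cell computations: results are independent
of evaluation order and a grid cell equals the corresponding direct
``simulate`` + outcome call exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .outcomes import compute_outcomes
from .params import ModelParameters
from .simulate import GcsfSchedule, Regimen, simulate

__all__ = [
    "ScheduleGrid", "OptimalSchedule", "evaluate_grid", "optimal_schedule",
    "PegOptimizationResult", "optimize_peg",
    "StepwiseResult", "stepwise_cycle_optimization",
]

OBJECTIVES = ("wbcaoc", "dol", "mlc")


def _objective_value(result, objective: str, threshold: float, window) -> float:
    m = compute_outcomes(result, threshold=threshold, window=window)
    return getattr(m, objective)


@dataclass
class ScheduleGrid:
    """Outcome values over (start day × number of injections).

    Infeasible cells (injections running past the cycle end) are NaN.
    ``baseline`` is the outcome without any G-CSF support.
    """

    start_days: np.ndarray
    n_injections: np.ndarray
    values: np.ndarray          # shape (len(start_days), len(n_injections))
    objective: str
    baseline: float
    derivative: str
    dose: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"start_day": int(s), "n_injections": int(n),
             "outcome": self.values[i, j]}
            for i, s in enumerate(self.start_days)
            for j, n in enumerate(self.n_injections)
            if np.isfinite(self.values[i, j])
        ]
        df = pd.DataFrame(rows)
        base = pd.DataFrame(
            [{"start_day": 0, "n_injections": 0, "outcome": self.baseline}]
        )
        return pd.concat([base, df], ignore_index=True)


@dataclass
class OptimalSchedule:
    start: int
    n_injections: int
    value: float
    tie_set: List[Tuple[int, int]] = field(default_factory=list)


def evaluate_grid(
    params: ModelParameters,
    regimen: Regimen,
    derivative: str = "filgrastim",
    start_days: Sequence[int] = (),
    n_injections: Sequence[int] = (),
    dose: float = 300.0,
    objective: str = "wbcaoc",
    threshold: float = 4.0,
    window: Optional[Tuple[float, float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    progress: Optional[Callable[[int, int], None]] = None,
) -> ScheduleGrid:
    """One full simulation + outcome per feasible (start, n) cell.

    A cell is feasible when the consecutive daily injections fit within
    the cycle (``start + n − 1 <= cycle_length``); infeasible cells are
    NaN.  Includes the no-G-CSF baseline outcome.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    starts = np.asarray(list(start_days), dtype=int)
    ns = np.asarray(list(n_injections), dtype=int)
    if starts.size == 0 or ns.size == 0:
        raise ValueError("empty schedule grid")
    feasible = (starts[:, None] + ns[None, :] - 1) <= regimen.cycle_length
    if not feasible.any():
        raise ValueError("no feasible cell in the schedule grid")

    base_result = simulate(params, regimen, None, rtol=rtol, atol=atol)
    baseline = _objective_value(base_result, objective, threshold, window)

    values = np.full((starts.size, ns.size), np.nan)
    total = int(feasible.sum())
    done = 0
    for i, s in enumerate(starts):
        for j, n in enumerate(ns):
            if not feasible[i, j]:
                continue
            sched = GcsfSchedule.consecutive(derivative, int(s), int(n), dose)
            result = simulate(params, regimen, sched, rtol=rtol, atol=atol)
            values[i, j] = _objective_value(result, objective, threshold, window)
            done += 1
            if progress is not None:
                progress(done, total)
    return ScheduleGrid(
        start_days=starts, n_injections=ns, values=values,
        objective=objective, baseline=baseline, derivative=derivative, dose=dose,
    )


def optimal_schedule(grid: ScheduleGrid, tie_tol: float = 0.01) -> OptimalSchedule:
    """Best grid cell with least-drug-use tie breaking.

    Minimizes the objective (maximizes for ``mlc``).  Among cells within
    ``tie_tol`` (relative to the optimum) of the optimal value, the cell
    with the fewest injections wins, then the latest start.
    """
    v = grid.values
    if not np.isfinite(v).any():
        raise ValueError("all grid cells are infeasible")
    maximize = grid.objective == "mlc"
    opt = np.nanmax(v) if maximize else np.nanmin(v)
    tol = abs(tie_tol * opt)
    if maximize:
        tied = np.argwhere(v >= opt - tol)
    else:
        tied = np.argwhere(v <= opt + tol)
    # fewest injections first, then latest start
    order = sorted(
        (int(grid.n_injections[j]), -int(grid.start_days[i]), i, j)
        for i, j in tied
    )
    _, _, i, j = order[0]
    return OptimalSchedule(
        start=int(grid.start_days[i]),
        n_injections=int(grid.n_injections[j]),
        value=float(v[i, j]),
        tie_set=[(int(grid.start_days[a]), int(grid.n_injections[b])) for a, b in tied],
    )


@dataclass
class PegOptimizationResult:
    table: pd.DataFrame                   # columns day, dose, outcome
    best_day: int                         # optimal day at the full (max) dose
    best_value: float                     # outcome there
    recommended_dose: float               # smallest dose within the margin
    recommended_day: int
    recommended_value: float
    margin_rel: float
    margin_abs: float


def optimize_peg(
    params: ModelParameters,
    regimen: Regimen,
    days: Sequence[int],
    doses: Sequence[float] = (6000.0,),
    objective: str = "wbcaoc",
    threshold: float = 4.0,
    window: Optional[Tuple[float, float]] = None,
    margin_rel: float = 0.05,
    margin_abs: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PegOptimizationResult:
    """Full factorial (day × dose) pegfilgrastim evaluation.

    The recommended dose is the smallest for which the best outcome over
    days stays within ``max(margin_rel·|best|, margin_abs)`` of the
    full-dose optimum.
    """
    days = [int(d) for d in days]
    doses = sorted(float(d) for d in doses)
    if not days or not doses:
        raise ValueError("empty day or dose range")
    rows = []
    for dose in doses:
        for day in days:
            sched = GcsfSchedule(derivative="pegfilgrastim", days=(day,), dose=dose)
            result = simulate(params, regimen, sched, rtol=rtol, atol=atol)
            rows.append(
                {"day": day, "dose": dose,
                 "outcome": _objective_value(result, objective, threshold, window)}
            )
    table = pd.DataFrame(rows)
    maximize = objective == "mlc"
    sign = -1.0 if maximize else 1.0

    full = table[table["dose"] == doses[-1]]
    best_row = full.loc[(sign * full["outcome"]).idxmin()]
    best_day, best_value = int(best_row["day"]), float(best_row["outcome"])
    margin = max(margin_rel * abs(best_value), margin_abs)

    rec_dose, rec_day, rec_value = doses[-1], best_day, best_value
    for dose in doses:
        sub = table[table["dose"] == dose]
        row = sub.loc[(sign * sub["outcome"]).idxmin()]
        value = float(row["outcome"])
        ok = value >= best_value - margin if maximize else value <= best_value + margin
        if ok:
            rec_dose, rec_day, rec_value = dose, int(row["day"]), value
            break
    return PegOptimizationResult(
        table=table, best_day=best_day, best_value=best_value,
        recommended_dose=rec_dose, recommended_day=rec_day,
        recommended_value=rec_value, margin_rel=margin_rel, margin_abs=margin_abs,
    )


@dataclass
class StepwiseResult:
    per_block: List[dict]     # block bounds, start, n, value at freeze time
    schedule: GcsfSchedule    # concatenated per-block schedule
    overall_value: float      # objective of the full concatenated schedule


def stepwise_cycle_optimization(
    params: ModelParameters,
    regimen: Regimen,
    derivative: str = "filgrastim",
    start_days: Sequence[int] = (),
    n_injections: Sequence[int] = (),
    dose: float = 300.0,
    objective: str = "wbcaoc",
    threshold: float = 4.0,
    window: Optional[Tuple[float, float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StepwiseResult:
    """Greedy forward optimization over the regimen's cycle blocks.

    Block 1's (start, n) is optimized with later blocks unsupported
    (conservative default), then frozen; the pass proceeds block by
    block.  Returns per-block optima and the overall outcome of the
    concatenated schedule.
    """
    if not regimen.blocks:
        raise ValueError("stepwise optimization needs a regimen with cycle blocks")
    starts = [int(s) for s in start_days]
    ns = [int(n) for n in n_injections]
    if not starts or not ns:
        raise ValueError("empty per-block schedule ranges")
    feasible = [
        (s, n) for s in starts for n in ns if s + n - 1 <= regimen.cycle_length
    ]
    if not feasible:
        raise ValueError("no feasible per-block schedule")

    frozen: List[Tuple[int, int, Sequence[float], float]] = []
    per_block: List[dict] = []
    for first, last, _ in regimen.blocks:
        best = None
        for s, n in feasible:
            blocks = frozen + [(first, last, tuple(range(s, s + n)), dose)]
            sched = GcsfSchedule(derivative=derivative, dose=dose, blocks=blocks)
            result = simulate(params, regimen, sched, rtol=rtol, atol=atol)
            value = _objective_value(result, objective, threshold, window)
            key = -value if objective == "mlc" else value
            if best is None or key < best[0] - 1e-12 or (
                abs(key - best[0]) <= 1e-12 and (n, -s) < (best[2], -best[1])
            ):
                best = (key, s, n, value)
        _, s, n, value = best
        frozen = frozen + [(first, last, tuple(range(s, s + n)), dose)]
        per_block.append(
            {"cycles": (first, last), "start": s, "n_injections": n, "value": value}
        )

    final = GcsfSchedule(derivative=derivative, dose=dose, blocks=frozen)
    result = simulate(params, regimen, final, rtol=rtol, atol=atol)
    overall = _objective_value(result, objective, threshold, window)
    return StepwiseResult(per_block=per_block, schedule=final, overall_value=overall)
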