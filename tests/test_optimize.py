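"""Schedule-grid evaluation, selection rules, peg dosing, stepwise blocks."""

import numpy as np
import pytest

from granulosim import (
    GcsfSchedule,
    Regimen,
    evaluate_grid,
    make_reference_params,
    make_toy_regimen,
    optimal_schedule,
    optimize_peg,
    simulate,
    stepwise_cycle_optimization,
    wbcaoc,
)
from granulosim.optimize import ScheduleGrid


@pytest.fixture(scope="module")
def high_params():
    return make_reference_params("high")


def _zero_tox_params():
    p = make_reference_params()
    for drug in p.drugs.values():
        drug.s_S = drug.s_CG = drug.s_PGB = drug.s_MGB = 0.0
        drug.ly_intensity = 0.0
    return p


class TestEvaluateGrid:
    def test_single_cell_equals_direct_call(self, high_params, single_drug):
        grid = evaluate_grid(high_params, single_drug, "filgrastim",
                             [4], [6], dose=300.0)
        sched = GcsfSchedule.consecutive("filgrastim", 4, 6, 300.0)
        direct = wbcaoc(simulate(high_params, single_drug, sched))
        assert grid.values[0, 0] == direct

    def test_zero_toxicity_all_cells_zero(self, single_drug):
        p = _zero_tox_params()
        grid = evaluate_grid(p, single_drug, "filgrastim", [2, 6], [2, 4])
        assert grid.baseline == 0.0
        assert np.nanmax(grid.values) == 0.0

    def test_infeasible_cells_marked_absent(self, high_params, single_drug):
        grid = evaluate_grid(high_params, single_drug, "filgrastim",
                             [4, 12], [2, 6], dose=300.0)
        assert np.isnan(grid.values[1, 1])        # 12 + 6 - 1 > 14
        assert np.isfinite(grid.values[0, 0])

    def test_grid_minimum_not_worse_than_baseline(self, high_params, single_drug):
        grid = evaluate_grid(high_params, single_drug, "filgrastim",
                             [4, 6, 8], [4, 6], dose=300.0)
        assert np.nanmin(grid.values) <= grid.baseline + 1e-9

    def test_empty_grid_rejected(self, high_params, single_drug):
        with pytest.raises(ValueError):
            evaluate_grid(high_params, single_drug, "filgrastim", [], [4])
        with pytest.raises(ValueError):
            evaluate_grid(high_params, single_drug, "filgrastim", [14], [10])


class TestOptimalSchedule:
    def _grid(self, values, starts=(2, 4, 6), ns=(4, 6, 8), objective="wbcaoc"):
        return ScheduleGrid(
            start_days=np.array(starts), n_injections=np.array(ns),
            values=np.asarray(values, float), objective=objective,
            baseline=50.0, derivative="filgrastim", dose=300.0,
        )

    def test_unique_minimum(self):
        v = np.full((3, 3), 10.0)
        v[1, 2] = 1.0
        best = optimal_schedule(self._grid(v))
        assert (best.start, best.n_injections, best.value) == (4, 8, 1.0)

    def test_tie_prefers_fewer_injections(self):
        v = np.full((3, 3), 10.0)
        v[0, 1] = v[0, 2] = 1.0        # n = 6 vs n = 8 exactly tied
        best = optimal_schedule(self._grid(v))
        assert best.n_injections == 6

    def test_tie_prefers_latest_start(self):
        v = np.full((3, 3), 10.0)
        v[0, 0] = v[2, 0] = 1.0        # same n, starts 2 and 6
        best = optimal_schedule(self._grid(v))
        assert best.start == 6

    def test_zero_tolerance_is_pure_argmin(self):
        v = np.full((3, 3), 10.0)
        v[1, 1] = 1.0
        v[0, 0] = 1.004                # within 1 % but not equal
        best = optimal_schedule(self._grid(v), tie_tol=0.0)
        assert (best.start, best.n_injections) == (4, 6)
        relaxed = optimal_schedule(self._grid(v), tie_tol=0.01)
        assert (relaxed.start, relaxed.n_injections) == (2, 4)

    def test_mlc_is_maximized(self):
        v = np.full((3, 3), 2.0)
        v[2, 1] = 3.5
        best = optimal_schedule(self._grid(v, objective="mlc"))
        assert (best.start, best.n_injections, best.value) == (6, 6, 3.5)

    def test_all_infeasible_rejected(self):
        v = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            optimal_schedule(self._grid(v))


class TestOptimizePeg:
    def test_single_dose_reduces_to_day_search(self, high_params, single_drug):
        res = optimize_peg(high_params, single_drug, days=[2, 4, 6],
                           doses=[6000.0])
        assert res.recommended_dose == 6000.0
        by_day = res.table.set_index("day")["outcome"]
        assert by_day[res.best_day] == by_day.min()

    def test_outcome_nonincreasing_in_dose(self, high_params, single_drug):
        res = optimize_peg(high_params, single_drug, days=[4],
                           doses=[250.0, 500.0, 1500.0, 6000.0])
        out = res.table.sort_values("dose")["outcome"].to_numpy()
        assert np.all(np.diff(out) <= 1e-9)

    def test_dose_reduction_recommended_when_safe(self, high_params, single_drug):
        """A reduced dose matching the full-dose outcome is reported."""
        res = optimize_peg(high_params, single_drug, days=[4],
                           doses=[250.0, 3000.0, 6000.0])
        assert res.recommended_dose < 6000.0
        assert res.recommended_value <= res.best_value + max(
            res.margin_rel * abs(res.best_value), res.margin_abs)

    def test_zero_toxicity_flat(self, single_drug):
        p = _zero_tox_params()
        res = optimize_peg(p, single_drug, days=[2, 6], doses=[1000.0, 6000.0])
        assert (res.table["outcome"] == 0.0).all()
        assert res.recommended_dose == 1000.0    # smallest dose suffices

    def test_empty_ranges_rejected(self, high_params, single_drug):
        with pytest.raises(ValueError):
            optimize_peg(high_params, single_drug, days=[], doses=[6000.0])


class TestStepwise:
    def test_single_block_reduces_to_grid_search(self, high_params):
        reg = Regimen(name="blk", cycle_length=14.0, n_cycles=2,
                      blocks=[(1, 2, [(1, "cyclophosphamide", 750.0)])])
        flat = Regimen(name="flat", cycle_length=14.0, n_cycles=2,
                       administrations=[(1, "cyclophosphamide", 750.0)])
        starts, ns = [4, 7], [4, 6]
        step = stepwise_cycle_optimization(high_params, reg, "filgrastim",
                                           starts, ns)
        grid = evaluate_grid(high_params, flat, "filgrastim", starts, ns)
        best = optimal_schedule(grid, tie_tol=0.0)
        blk = step.per_block[0]
        assert (blk["start"], blk["n_injections"]) == (best.start,
                                                       best.n_injections)
        assert step.overall_value == pytest.approx(best.value)

    def test_identical_blocks_get_identical_schedules(self, high_params):
        reg = Regimen(
            name="twin", cycle_length=21.0, n_cycles=4,
            blocks=[(1, 2, [(1, "cyclophosphamide", 750.0)]),
                    (3, 4, [(1, "cyclophosphamide", 750.0)])],
        )
        step = stepwise_cycle_optimization(high_params, reg, "filgrastim",
                                           [5, 8], [5], dose=300.0)
        a, b = step.per_block
        assert (a["start"], a["n_injections"]) == (b["start"], b["n_injections"])

    def test_stepwise_not_worse_than_block1_uniform(self, high_params):
        etc = make_toy_regimen("etc_like")
        step = stepwise_cycle_optimization(high_params, etc, "filgrastim",
                                           [5, 7], [6], dose=300.0)
        s1, n1 = step.per_block[0]["start"], step.per_block[0]["n_injections"]
        uniform = GcsfSchedule.consecutive("filgrastim", s1, n1, 300.0)
        uniform_value = wbcaoc(simulate(high_params, etc, uniform))
        assert step.overall_value <= uniform_value + 1e-9

    def test_requires_blocks(self, high_params, single_drug):
        with pytest.raises(ValueError):
            stepwise_cycle_optimization(high_params, single_drug,
                                        "filgrastim", [4], [4])


def test_early_start_never_optimal_on_reference_chop(ref_params, chop14):
    """On the reference CHOP-like regimen, d1-2 starts stay clearly worse
    than the optimum (regression property, not a universal claim)."""
    grid = evaluate_grid(ref_params, chop14, "filgrastim",
                         [1, 2, 4, 6, 8], [6, 10], dose=300.0)
    best = optimal_schedule(grid)
    assert best.start not in (1, 2)
    opt = best.value
    for i, s in enumerate(grid.start_days):
        if s in (1, 2):
            assert np.nanmin(grid.values[i]) > opt + 0.01 * abs(opt)
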