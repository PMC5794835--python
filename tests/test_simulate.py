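"""Timeline construction and event-driven integration."""

import numpy as np
import pytest

from granulosim import (
    GcsfSchedule,
    Regimen,
    build_timeline,
    simulate,
    wbcaoc,
)
from granulosim.simulate import (
    BLOCK_BASE,
    load_regimen,
    load_schedule,
    save_regimen,
    save_schedule,
)


class TestBuildTimeline:
    def test_event_count_and_first_event(self, ref_params):
        reg = Regimen(name="r", cycle_length=14.0, n_cycles=6,
                      administrations=[(1, "cyclophosphamide", 750.0)])
        sched = GcsfSchedule.consecutive("filgrastim", 6, 7, 300.0)
        events = build_timeline(reg, sched)
        gcsf = [e for e in events if e.kind == "gcsf"]
        assert len(gcsf) == 6 * 7
        assert gcsf[0].t == 5.0              # day 6 -> t = 5.0
        assert len([e for e in events if e.kind == "chemo"]) == 6

    def test_is_first_only_in_cycle_one(self, chop14):
        events = build_timeline(chop14, None)
        firsts = [e for e in events if e.is_first]
        assert {e.name for e in firsts} == {"cyclophosphamide", "doxorubicin",
                                            "vincristine"}
        assert all(e.cycle == 1 for e in firsts)

    def test_empty_schedule_chemo_only(self, chop14):
        events = build_timeline(chop14, None)
        assert all(e.kind == "chemo" for e in events)

    def test_same_day_chemo_precedes_gcsf(self, chop14):
        sched = GcsfSchedule.consecutive("filgrastim", 1, 5, 300.0)
        events = build_timeline(chop14, sched)
        day1 = [e for e in events if e.t == 0.0]
        kinds = [e.kind for e in day1]
        assert kinds == sorted(kinds, key=lambda k: 0 if k == "chemo" else 1)

    def test_day_outside_cycle_rejected(self, chop14):
        sched = GcsfSchedule.consecutive("filgrastim", 10, 10, 300.0)
        with pytest.raises(ValueError):
            build_timeline(chop14, sched)


class TestTreatmentTypes:
    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            Regimen(name="bad", cycle_length=14.0, n_cycles=2,
                    administrations=[(15, "cyclophosphamide", 750.0)])
        with pytest.raises(ValueError):
            Regimen(name="bad", cycle_length=0.0, n_cycles=2)

    def test_peg_single_injection_per_cycle(self):
        with pytest.raises(ValueError):
            GcsfSchedule(derivative="pegfilgrastim", days=(2, 4), dose=6000.0)

    def test_per_kg_dose_resolution(self, ref_params):
        s = GcsfSchedule(derivative="filgrastim", days=(4,), dose_per_kg=5.0)
        assert s.resolve_dose(None, ref_params) == pytest.approx(375.0)

    def test_yaml_round_trips(self, tmp_path, chop14):
        rp = tmp_path / "reg.yaml"
        save_regimen(chop14, rp)
        assert load_regimen(rp).to_dict() == chop14.to_dict()
        etc = __import__("granulosim").make_toy_regimen("etc_like")
        save_regimen(etc, rp)
        assert load_regimen(rp).to_dict() == etc.to_dict()
        sp = tmp_path / "sched.yaml"
        s = GcsfSchedule.consecutive("filgrastim", 4, 10, 300.0)
        save_schedule(s, sp)
        assert load_schedule(sp).to_dict() == s.to_dict()


class TestSimulate:
    def test_untreated_is_flat(self, ref_params):
        result = simulate(ref_params, None, None, horizon=100.0)
        assert np.allclose(result.wbc, 7.0, rtol=1e-6)

    def test_gcsf_support_raises_nadir(self, chop14_no_gcsf_result,
                                       chop14_fil_result):
        assert chop14_fil_result.wbc.min() >= chop14_no_gcsf_result.wbc.min()

    def test_determinism(self, ref_params, chop14, fil_d4_13):
        a = simulate(ref_params, chop14, fil_d4_13)
        b = simulate(ref_params, chop14, fil_d4_13)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.y, b.y)
        assert [(e.t, e.kind, e.name, e.dose) for e in a.events] == [
            (e.t, e.kind, e.name, e.dose) for e in b.events
        ]

    def test_event_exactness(self, chop14_fil_result):
        """A bolus changes exactly one state component, by exactly the bolus."""
        result = chop14_fil_result
        for event, (before, after) in zip(result.events, result.event_states):
            delta = after - before
            nz = np.nonzero(delta)[0]
            assert nz.size == 1
            if event.kind == "gcsf":
                assert nz[0] == BLOCK_BASE[event.name]  # SC1 of that derivative
                assert delta[nz[0]] == pytest.approx(event.dose)
            else:
                assert nz[0] == result.chain_offsets[event.chain_index]

    def test_grid_covers_horizon(self, chop14_fil_result, chop14):
        t = chop14_fil_result.t
        assert t[0] == 0.0
        assert t[-1] == pytest.approx(chop14.duration + 28.0)
        assert np.all(np.diff(t) > 0)
        assert np.max(np.diff(t)) <= 0.25 + 1e-12

    def test_tolerance_convergence(self, ref_params, chop14, fil_d4_13,
                                   chop14_fil_result):
        """Halving rtol/atol moves WBCAOC by < 0.1 %."""
        tight = simulate(ref_params, chop14, fil_d4_13, rtol=5e-9, atol=5e-11)
        a0 = wbcaoc(chop14_fil_result)
        a1 = wbcaoc(tight)
        assert abs(a1 - a0) <= 1e-3 * max(a0, 1e-9)

    def test_horizon_must_cover_regimen(self, ref_params, chop14):
        with pytest.raises(ValueError):
            simulate(ref_params, chop14, None, horizon=10.0)

    def test_unknown_drug_rejected(self, ref_params):
        reg = Regimen(name="x", cycle_length=14.0, n_cycles=1,
                      administrations=[(1, "thiotepa", 100.0)])
        with pytest.raises(ValueError):
            simulate(ref_params, reg)

    def test_grid_step_bounded(self, ref_params):
        with pytest.raises(ValueError):
            simulate(ref_params, None, None, horizon=10.0, grid_step=0.5)

    def test_blocked_regimen_and_schedule(self, ref_params):
        """Sequential (block) regimens integrate with per-block schedules."""
        etc = __import__("granulosim").make_toy_regimen("etc_like")
        sched = GcsfSchedule(
            derivative="filgrastim", dose=300.0,
            blocks=[(1, 3, tuple(range(6, 11)), 300.0),
                    (4, 9, tuple(range(7, 15)), 300.0)],
        )
        result = simulate(ref_params, etc, sched)
        gcsf = [e for e in result.events if e.kind == "gcsf"]
        assert len(gcsf) == 3 * 5 + 6 * 8
        drugs_c1 = {e.name for e in result.events if e.kind == "chemo" and e.cycle == 1}
        drugs_c9 = {e.name for e in result.events if e.kind == "chemo" and e.cycle == 9}
        assert drugs_c1 == {"epirubicin"} and drugs_c9 == {"cyclophosphamide"}
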