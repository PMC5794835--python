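"""Toxicity transit chains, additivity, lymphocytes, prednisone."""

import math

import numpy as np
import pytest
import scipy.integrate as si

from granulosim import (
    PrednisoneWindow,
    Regimen,
    ToxChainCollection,
    apply_dose,
    chain_rhs,
    effective_gra_halflife,
    psi_total,
    simulate,
)
from granulosim.chemo_toxicity import erlang_response, lymphocyte_rhs
from granulosim.params import DrugToxicityParams


def _toy_drug(**kw):
    base = dict(name="toy", s_S=0.1, s_CG=0.3, s_PGB=0.8, s_MGB=0.05,
                n_transit=3, k_tox=1.0, f_first=1.2, ref_dose=100.0)
    base.update(kw)
    return DrugToxicityParams(**base)


def _integrate_chain(n, k, t_end, impulse=1.0):
    z0 = np.zeros(n)
    z0[0] = impulse
    sol = si.solve_ivp(lambda t, z: chain_rhs(z, k), (0, t_end), z0,
                       dense_output=True, rtol=1e-11, atol=1e-13)
    return sol


class TestChainRhs:
    def test_single_stage_exponential(self):
        sol = _integrate_chain(1, 2.0, 2.0)
        assert sol.sol(0.5)[0] == pytest.approx(math.exp(-1.0), rel=1e-8)

    def test_erlang_mode_is_delayed_maximum(self):
        """For n = 3, k = 1/d the terminal stage peaks at (n−1)/k = 2 d."""
        sol = _integrate_chain(3, 1.0, 10.0)
        ts = np.linspace(0, 10, 2001)
        zn = sol.sol(ts)[-1]
        assert ts[np.argmax(zn)] == pytest.approx(2.0, abs=0.01)
        assert zn[0] == 0.0
        # single maximum: rises then decays
        i = np.argmax(zn)
        assert np.all(np.diff(zn[: i + 1]) >= -1e-12)
        assert np.all(np.diff(zn[i:]) <= 1e-12)

    @pytest.mark.parametrize("n,k", [(1, 0.5), (3, 1.0), (5, 2.0)])
    def test_terminal_stage_integrates_to_inverse_rate(self, n, k):
        """Quadrature of z_n over (0, ∞) equals 1/k for any chain length."""
        z0 = np.zeros(n + 1)
        z0[0] = 1.0

        def rhs(t, z):
            dz = np.empty_like(z)
            dz[:-1] = chain_rhs(z[:-1], k)
            dz[-1] = z[n - 1]          # running quadrature of the terminal stage
            return dz

        sol = si.solve_ivp(rhs, (0, 120.0 / k), z0, rtol=1e-11, atol=1e-13)
        assert sol.y[-1, -1] == pytest.approx(1.0 / k, rel=1e-8)

    def test_matches_closed_form(self):
        sol = _integrate_chain(4, 0.7, 12.0)
        ts = np.array([0.5, 2.0, 6.0, 11.0])
        assert np.allclose(sol.sol(ts)[-1], erlang_response(ts, 4, 0.7), rtol=1e-7)


class TestApplyDose:
    def test_reference_dose_unit_impulse(self):
        coll = apply_dose(ToxChainCollection(), _toy_drug(), 100.0, 0.0, False)
        assert coll.chains[0].z[0] == pytest.approx(1.0)

    def test_first_application_excess(self):
        coll = apply_dose(ToxChainCollection(), _toy_drug(), 100.0, 0.0, True)
        assert coll.chains[0].z[0] == pytest.approx(1.2)

    def test_dose_scaling_power_law(self):
        drug = _toy_drug(dose_exponent=0.8)
        coll = apply_dose(ToxChainCollection(), drug, 200.0, 0.0, False)
        assert coll.chains[0].z[0] == pytest.approx(2.0 ** 0.8)

    def test_simultaneous_drugs_independent_chains(self):
        coll = ToxChainCollection()
        coll.apply_dose(_toy_drug(), 100.0, 3.0)
        coll.apply_dose(_toy_drug(name="other", s_PGB=0.4), 100.0, 3.0)
        assert len(coll) == 2
        assert coll.chains[0].z[0] == coll.chains[1].z[0] == 1.0

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            apply_dose(ToxChainCollection(), _toy_drug(), -5.0, 0.0)


class TestPsiTotal:
    def test_empty_collection_zero(self):
        assert psi_total(ToxChainCollection(), "PGB") == 0.0

    def test_product_of_intensity_and_terminal_stage(self):
        coll = ToxChainCollection()
        coll.apply_dose(_toy_drug(s_PGB=0.8), 100.0, 0.0)
        coll.chains[0].z[-1] = 0.5
        assert psi_total(coll, "PGB") == pytest.approx(0.4)

    def test_additivity_of_identical_chains(self):
        one = ToxChainCollection()
        one.apply_dose(_toy_drug(), 100.0, 0.0)
        one.chains[0].z[:] = [0.2, 0.3, 0.4]
        two = one.copy()
        two.apply_dose(_toy_drug(), 100.0, 0.0)
        two.chains[1].z[:] = [0.2, 0.3, 0.4]
        for stage in ("S", "CG", "PGB", "MGB"):
            assert psi_total(two, stage) == pytest.approx(2 * psi_total(one, stage))

    def test_dose_monotonicity(self):
        """Higher dose never lowers Ψ at any time (closed-form chains)."""
        drug = _toy_drug()
        ts = np.linspace(0, 15, 300)
        lo = drug.s_PGB * 1.0 * erlang_response(ts, 3, 1.0)
        hi = drug.s_PGB * 2.0 * erlang_response(ts, 3, 1.0)
        assert np.all(hi >= lo)

    def test_prune_drops_spent_chains(self):
        coll = ToxChainCollection()
        coll.apply_dose(_toy_drug(), 100.0, 0.0)
        coll.chains[0].z[:] = 1e-12
        assert len(coll.prune()) == 0


class TestLymphocytes:
    def test_equilibrium(self, ref_params):
        assert lymphocyte_rhs(ref_params.cell.LY_ss, 0.0, 0.0, ref_params) == 0.0

    def test_recovery_direction(self, ref_params):
        assert lymphocyte_rhs(ref_params.cell.LY_ss / 2, 0.0, 0.0, ref_params) > 0

    def test_single_pulse_recovers(self, ref_params, single_drug):
        """After one course, LY returns to within 2 % of its baseline."""
        reg = Regimen(name="one", cycle_length=14.0, n_cycles=1,
                      administrations=single_drug.administrations)
        result = simulate(ref_params, reg, None, horizon=200.0)
        ly = result.ly
        assert ly.min() < ref_params.cell.LY_ss
        assert ly[-1] == pytest.approx(ref_params.cell.LY_ss, rel=0.02)


class TestPrednisone:
    def test_outside_windows(self):
        w = [PrednisoneWindow(0.0, 5.0, 1.5)]
        assert effective_gra_halflife(7.0, w, 7.0) == 7.0

    def test_inside_window(self):
        w = [PrednisoneWindow(0.0, 5.0, 1.5)]
        assert effective_gra_halflife(2.0, w, 7.0) == pytest.approx(10.5)

    def test_empty_list(self):
        assert effective_gra_halflife(3.0, [], 7.0) == 7.0

    def test_overlap_max_multiplier_wins(self):
        w = [PrednisoneWindow(0.0, 5.0, 1.3), PrednisoneWindow(3.0, 8.0, 1.7)]
        assert effective_gra_halflife(4.0, w, 10.0) == pytest.approx(17.0)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            PrednisoneWindow(5.0, 3.0, 1.5)
        with pytest.raises(ValueError):
            PrednisoneWindow(0.0, 3.0, 1.0)


def test_reversibility_full_recovery(ref_params, chop14):
    """After the last administration every compartment returns to baseline."""
    result = simulate(ref_params, chop14, None, horizon=chop14.duration + 150.0)
    final = result.y[-1, :6]
    baseline = result.y[0, :6]
    assert np.allclose(final, baseline, rtol=0.02)


def test_first_cycle_excess_deepens_first_nadir(ref_params):
    """With marrow-only toxicity and full inter-cycle recovery, the
    first-application excess makes cycle 1 the deepest nadir."""
    params = ref_params.copy()
    params.drugs["cyclophosphamide"].ly_intensity = 0.0
    reg = Regimen(name="stationary", cycle_length=28.0, n_cycles=3,
                  administrations=[(1, "cyclophosphamide", 750.0)])
    result = simulate(params, reg)
    nadirs = []
    for c in range(3):
        mask = (result.t >= c * 28.0) & (result.t < (c + 1) * 28.0)
        nadirs.append(result.wbc[mask].min())
    assert params.drugs["cyclophosphamide"].f_first > 1.0
    assert nadirs[0] <= nadirs[1] + 1e-9
    assert nadirs[0] <= nadirs[2] + 1e-9
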