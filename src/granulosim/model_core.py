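"""Cell-kinetic core: granulopoietic compartment chain with G-CSF feedback.

Compartments
------------
``S``    pluripotent stem cells (dimensionless, 1 at steady state)
``CG``   committed granulopoietic progenitors (dimensionless)
``PGB``  proliferating granulopoietic precursors (dimensionless)
``MGB``  maturing (postmitotic) precursors (dimensionless)
``GRA``  circulating granulocytes [10^3 cells/µL]
``LY``   circulating lymphocytes [10^3 cells/µL]

Each marrow compartment obeys a balance of amplified influx, efflux with
transition time ``T`` and chemotherapy loss ``Ψ``:

    dC/dt = C_in·A − C/T − Ψ·C

Normalizing every marrow compartment to 1 at the untreated steady state
absorbs the baseline amplifications into fixed flux-normalization gains;
G-CSF acts through relative regulation factors on the PGB amplification,
the PGB and MGB transition times and the postmitotic survival fraction.
Stem-cell output splits by a self-renewal probability ``p(S)`` that
declines linearly in ``S`` with ``p(1) = 1/2``, so the stem-cell pool is
self-stabilizing:

    dS/dt = (2·p(S) − 1)·S/T_S − Ψ_S·S
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParameters, RegulationCurve

__all__ = [
    "CELL_NAMES",
    "SystemState",
    "steady_state",
    "regulation_factor",
    "cell_rhs",
    "flux_gains",
]

CELL_NAMES = ("S", "CG", "PGB", "MGB", "GRA", "LY")

LN2 = math.log(2.0)


@dataclass
class SystemState:
    """Instantaneous values of all compartments of the coupled system.

    ``cells`` is ordered as :data:`CELL_NAMES`.  The G-CSF block and the
    toxicity chains are optional so the cell-kinetic core can be used
    standalone; the simulator always populates them.
    """

    cells: np.ndarray
    gcsf: Optional[object] = None          # gcsf_pk.GcsfState
    chains: Optional[object] = None        # chemo_toxicity.ToxChainCollection

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (6,):
            raise ValueError("cell state must have 6 compartments")
        if np.any(self.cells < 0):
            raise ValueError("cell compartments must be non-negative")

    @property
    def wbc(self) -> float:
        return float(self.cells[4] + self.cells[5])

    def copy(self) -> "SystemState":
        import copy as _copy

        return SystemState(
            self.cells.copy(),
            _copy.deepcopy(self.gcsf),
            _copy.deepcopy(self.chains),
        )


def regulation_factor(curve: RegulationCurve, signal: float) -> float:
    """Dimensionless feedback factor for a regulated property.

    Equals 1 exactly at the curve's baseline signal, is monotone in the
    signal and bounded by ``[fmin, fmax]``.
    """
    if np.any(np.asarray(signal) < 0):
        raise ValueError("regulating signal must be non-negative")
    return curve.factor(signal)


def flux_gains(params: ModelParameters) -> np.ndarray:
    """Fixed flux-normalization gains making the unit steady state exact.

    Returns ``[g_CG, g_PGB, g_MGB, g_GRA]`` such that with all regulation
    factors at 1 and all compartments at their steady-state values every
    derivative vanishes.
    """
    c = params.cell
    g_cg = c.T_S / c.T_CG
    g_pgb = c.T_CG / c.T_PGB
    g_mgb = c.T_PGB / (c.mgb_survival * c.T_MGB)
    g_gra = c.gra_decay * c.GRA_ss * c.T_MGB
    return np.array([g_cg, g_pgb, g_mgb, g_gra])


def self_renewal_probability(s: float, params: ModelParameters) -> float:
    c = params.cell
    p = 0.5 - c.self_renewal_slope * (s - 1.0)
    return min(max(p, c.p_min), c.p_max)


def cell_rhs(
    state,
    t: float,
    params: ModelParameters,
    psi=None,
    gcsf_conc: Optional[float] = None,
    ly_psi: float = 0.0,
    gra_halflife_factor: float = 1.0,
) -> np.ndarray:
    """Time derivatives of the six cell compartments.

    Parameters
    ----------
    state
        :class:`SystemState` or a length-6 array ordered as
        :data:`CELL_NAMES`.
    psi
        Stage-specific chemotherapy kill rates ``[Ψ_S, Ψ_CG, Ψ_PGB,
        Ψ_MGB]`` in 1/d (default: no chemotherapy).
    gcsf_conc
        Effective G-CSF serum concentration driving the regulation
        curves; defaults to the endogenous baseline (all factors 1).
    ly_psi
        Lymphotoxic kill rate [1/d].
    gra_halflife_factor
        Multiplier on the granulocyte half-life (prednisone effect).
    """
    cells = state.cells if isinstance(state, SystemState) else np.asarray(state, float)
    if cells.shape != (6,):
        raise ValueError("cell state must have 6 compartments")
    if psi is None:
        psi = np.zeros(4)
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (4,):
        raise ValueError("psi must give kill rates for the 4 marrow stages")
    if np.any(psi < 0) or ly_psi < 0:
        raise ValueError("toxicity rates must be non-negative")
    if gcsf_conc is None:
        gcsf_conc = params.gcsf_base_conc

    c = params.cell
    reg = params.regulation
    f_a = reg["A_PGB"].factor_scalar(gcsf_conc)
    f_tp = reg["T_PGB"].factor_scalar(gcsf_conc)
    f_tm = reg["T_MGB"].factor_scalar(gcsf_conc)
    f_q = reg["MGB_survival"].factor_scalar(gcsf_conc)

    g_cg, g_pgb, g_mgb, g_gra = flux_gains(params)
    s, cg, pgb, mgb, gra, ly = cells

    p = self_renewal_probability(s, params)
    ds = (2.0 * p - 1.0) * s / c.T_S - psi[0] * s

    # commitment flux equals 1/T_S at steady state; gain g_cg scales it to 1/T_CG
    commit_flux = 2.0 * (1.0 - p) * s / c.T_S
    dcg = g_cg * commit_flux - cg / c.T_CG - psi[1] * cg

    t_pgb = c.T_PGB * f_tp
    dpgb = f_a * g_pgb * cg / c.T_CG - pgb / t_pgb - psi[2] * pgb

    q_eff = min(1.0, c.mgb_survival * f_q)
    t_mgb = c.T_MGB * f_tm
    dmgb = q_eff * g_mgb * pgb / t_pgb - mgb / t_mgb - psi[3] * mgb

    gra_loss = c.gra_decay / gra_halflife_factor
    dgra = g_gra * mgb / t_mgb - gra_loss * gra

    dly = (c.LY_ss - ly) / c.T_LY_rec - ly_psi * ly

    return np.array([ds, dcg, dpgb, dmgb, dgra, dly])


def steady_state(params: ModelParameters, tol: float = 1e-9) -> SystemState:
    """Untreated steady state of the coupled system.

    By construction of the flux normalization the steady state is the
    unit marrow state with blood counts at their configured values and
    the G-CSF subsystem at its endogenous equilibrium; this is verified
    against the right-hand side and a :class:`RuntimeError` is raised if
    the residual exceeds ``tol`` (signalling inconsistent parameters).
    """
    from .gcsf_pk import endogenous_steady_state  # local import, avoids cycle

    cells = np.array([1.0, 1.0, 1.0, 1.0, params.cell.GRA_ss, params.cell.LY_ss])
    gcsf = endogenous_steady_state(params)
    state = SystemState(cells, gcsf=gcsf)

    deriv = cell_rhs(state, 0.0, params)
    rel = np.max(np.abs(deriv) / np.maximum(np.abs(cells), 1e-12))
    if rel > tol:
        raise RuntimeError(
            f"steady-state residual {rel:.2e} exceeds tolerance {tol:.1e}; "
            "parameter set is internally inconsistent"
        )
    return state
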