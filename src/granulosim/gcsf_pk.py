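"""G-CSF pharmacokinetics: depot, absorption, distribution, elimination.

Three derivative blocks are tracked — endogenous G-CSF, filgrastim and
pegfilgrastim — each with the same compartment layout:

========  =====================================================
index     meaning
========  =====================================================
``SC1``   subcutaneous subcompartment 1 amount [µg]
``SC2``   subcutaneous subcompartment 2 amount [µg]
``CEN``   central (serum) concentration [µg/L]
``PER``   peripheral (reversibly bound) amount [µg]
``CUM1``  cumulative bioavailability loss [µg]
          (endogenous block: cumulative production [µg])
``CUM2``  cumulative renal elimination [µg]
``CUM3``  cumulative granulocyte-mediated elimination [µg]
========  =====================================================

Injections are subcutaneous boluses into ``SC1``.  A Michaelis-Menten
loss drains ``SC1`` (dose-dependent bioavailability); absorbed drug
reaches the central compartment, exchanges reversibly with the
peripheral compartment (first order both ways), and is eliminated by a
first-order renal route plus a granulocyte-mediated Michaelis-Menten
route scaling linearly with the circulating granulocyte count.
Endogenous production is demand-regulated: it falls with GRA through the
``endog_production`` regulation curve.  Endogenous G-CSF and filgrastim
share one PK parameter set.

The cumulative route integrals make the mass balance auditable:
``injected = SC1 + SC2 + CEN·V_d + PER + CUM1 + CUM2 + CUM3`` per
injected derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .params import DERIVATIVES, GcsfPkParams, ModelParameters

__all__ = [
    "SC1", "SC2", "CEN", "PER", "CUM_BIO", "CUM_REN", "CUM_SPEC", "BLOCK_SIZE",
    "GcsfState", "inject", "pk_rhs", "pk_block_rhs",
    "bioavailable_fraction", "effective_concentration",
    "endogenous_equilibrium_conc", "endogenous_steady_state",
]

SC1, SC2, CEN, PER, CUM_BIO, CUM_REN, CUM_SPEC = range(7)
BLOCK_SIZE = 7

BLOCK_NAMES = ("endogenous",) + DERIVATIVES


@dataclass
class GcsfState:
    """PK state: one 7-component block per derivative plus endogenous."""

    blocks: Dict[str, np.ndarray] = field(
        default_factory=lambda: {n: np.zeros(BLOCK_SIZE) for n in BLOCK_NAMES}
    )

    def __post_init__(self) -> None:
        for name in BLOCK_NAMES:
            if name not in self.blocks:
                self.blocks[name] = np.zeros(BLOCK_SIZE)
            self.blocks[name] = np.asarray(self.blocks[name], dtype=float)
            if self.blocks[name].shape != (BLOCK_SIZE,):
                raise ValueError(f"block {name!r} must have {BLOCK_SIZE} components")
            if np.any(self.blocks[name] < 0):
                raise ValueError("PK state components must be non-negative")

    def copy(self) -> "GcsfState":
        return GcsfState({k: v.copy() for k, v in self.blocks.items()})

    def in_system(self, derivative: str, params: ModelParameters) -> float:
        """Drug amount currently in the body [µg] for one derivative."""
        b = self.blocks[derivative]
        v_d = (params.endog_pk if derivative == "endogenous" else params.gcsf[derivative]).V_d
        return float(b[SC1] + b[SC2] + b[CEN] * v_d + b[PER])

    def eliminated(self, derivative: str) -> float:
        b = self.blocks[derivative]
        return float(b[CUM_BIO] + b[CUM_REN] + b[CUM_SPEC])


def inject(state: GcsfState, derivative: str, dose: float) -> GcsfState:
    """Subcutaneous bolus: add ``dose`` µg to SC1 of one derivative.

    Returns a new state; every other component is unchanged.
    """
    if derivative not in DERIVATIVES:
        raise ValueError(f"unknown G-CSF derivative {derivative!r}")
    if dose <= 0:
        raise ValueError("injection dose must be positive")
    out = state.copy()
    out.blocks[derivative][SC1] += dose
    return out


def pk_block_rhs(
    y: np.ndarray,
    dy: np.ndarray,
    gra: float,
    p: GcsfPkParams,
    production: float = 0.0,
) -> None:
    """In-place derivatives of one 7-component PK block.

    ``production`` is the endogenous production rate [µg/L/d] (zero for
    injected derivatives).  For the endogenous block the CUM1 slot
    integrates cumulative production instead of bioavailability loss.
    """
    sc1 = y[SC1] if y[SC1] > 0.0 else 0.0
    sc2 = y[SC2] if y[SC2] > 0.0 else 0.0
    cen = y[CEN] if y[CEN] > 0.0 else 0.0
    per = y[PER] if y[PER] > 0.0 else 0.0

    bio_loss = p.V_bio * sc1 / (p.K_bio + sc1) if p.V_bio > 0 and sc1 > 0 else 0.0
    spec = p.V_spec * gra * cen / (p.K_spec + cen) if cen > 0 else 0.0

    dy[SC1] = -p.k_sc12 * sc1 - bio_loss
    dy[SC2] = p.k_sc12 * sc1 - p.k_sc2c * sc2
    dy[CEN] = (
        p.k_sc2c * sc2 / p.V_d
        + production
        - p.k_ren * cen
        - spec
        - p.k_cp * cen
        + p.k_pc * per / p.V_d
    )
    dy[PER] = p.k_cp * cen * p.V_d - p.k_pc * per
    dy[CUM_BIO] = production * p.V_d if production > 0.0 else bio_loss
    dy[CUM_REN] = p.k_ren * cen * p.V_d
    dy[CUM_SPEC] = spec * p.V_d


def pk_rhs(state: GcsfState, gra: float, params: ModelParameters) -> GcsfState:
    """Derivatives of the full PK state at granulocyte count ``gra``."""
    if gra < 0:
        raise ValueError("granulocyte count must be non-negative")
    out = GcsfState({n: np.zeros(BLOCK_SIZE) for n in BLOCK_NAMES})
    prod = params.endog_production_base * params.regulation[
        "endog_production"
    ].factor_scalar(gra)
    for name in BLOCK_NAMES:
        p = params.endog_pk if name == "endogenous" else params.gcsf[name]
        pk_block_rhs(
            state.blocks[name],
            out.blocks[name],
            gra,
            p,
            production=prod if name == "endogenous" else 0.0,
        )
    return out


def effective_concentration(state: GcsfState, params: ModelParameters) -> float:
    """Effective G-CSF signal [µg/L] driving every regulation curve.

    Endogenous, filgrastim and pegfilgrastim central concentrations are
    summed with per-derivative potency weights.
    """
    c = state.blocks["endogenous"][CEN]
    for name in DERIVATIVES:
        c += params.gcsf[name].potency * state.blocks[name][CEN]
    return float(c)


def bioavailable_fraction(dose: float, p: GcsfPkParams) -> float:
    """Fraction of a subcutaneous dose reaching the central compartment.

    Computed by integrating the depot subsystem to exhaustion: the
    Michaelis-Menten loss competes with the first-order depot transition,
    so the fraction is dose-dependent and non-decreasing in dose.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if p.V_bio == 0:
        return 1.0

    def rhs(t, y):
        sc1 = max(y[0], 0.0)
        loss = p.V_bio * sc1 / (p.K_bio + sc1)
        return [-p.k_sc12 * sc1 - loss, p.k_sc12 * sc1]

    # SC1 decays at least at rate k_sc12; 60 folding times exhaust it
    t_end = 60.0 / p.k_sc12
    sol = solve_ivp(rhs, (0.0, t_end), [dose, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12 * dose)
    return float(sol.y[1, -1] / dose)


def endogenous_equilibrium_conc(params: ModelParameters, gra: float) -> float:
    """Equilibrium endogenous serum concentration [µg/L] at fixed GRA.

    Solves production(GRA) = elimination(C, GRA); the left side is
    constant in C and the right side strictly increasing, so the positive
    root is unique.  At ``gra = GRA_ss`` it equals the configured
    baseline concentration by construction.
    """
    p = params.endog_pk
    prod = params.endog_production_base * params.regulation[
        "endog_production"
    ].factor_scalar(gra)

    def f(c):
        return prod - (p.k_ren + p.V_spec * gra / (p.K_spec + c)) * c

    hi = max(1.0, prod / max(p.k_ren, 1e-12)) * 2.0 + 1.0
    return brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14)


def endogenous_steady_state(params: ModelParameters) -> GcsfState:
    """PK state at the untreated steady state (no injections)."""
    state = GcsfState()
    b = state.blocks["endogenous"]
    b[CEN] = params.gcsf_base_conc
    b[PER] = params.endog_peripheral_ss
    return state
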