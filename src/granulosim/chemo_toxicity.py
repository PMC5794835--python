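"""Chemotherapy toxicity: transit chains, additivity, lymphocytes, prednisone.

Each bolus administration of a cytotoxic drug starts a transit chain of
``n`` concatenated first-order stages with rate ``k_tox``:

    dz_1/dt = −k·z_1,   dz_i/dt = k·(z_{i−1} − z_i)   (i ≥ 2)

so the terminal stage ``z_n`` follows an Erlang-shaped response peaking
``(n−1)/k`` days after administration — the delayed maximum of cell
damage.  The impulse injected into ``z_1`` carries the dose scaling
``(dose/ref_dose)**exponent`` and, for the first application of a drug,
the first-application excess ``f_first``.  The stage-specific kill rate
is

    Ψ_total^X(t) = Σ_chains s_drug^X · z_n(t)      [1/d]

with the sum running over all active chains (simultaneous drugs are
additive).  One chain per administration drives all four marrow stages
through the stage intensities ``s_X``.

Lymphocyte depletion is phenomenological: each administration adds an
exponential kill-rate pulse with two parameters (intensity, decay rate),
applied directly without a transit chain.  Prednisone prolongs the
granulocyte half-life within its administration window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .params import DrugToxicityParams, ModelParameters

__all__ = [
    "ToxChain",
    "ToxChainCollection",
    "PrednisoneWindow",
    "apply_dose",
    "chain_rhs",
    "psi_total",
    "erlang_response",
    "lymphocyte_psi",
    "lymphocyte_rhs",
    "effective_gra_halflife",
    "dose_scale",
]

#: terminal-stage values below this are considered spent (bounded state growth)
CHAIN_PRUNE_EPS = 1e-9


def dose_scale(drug: DrugToxicityParams, dose: float, is_first: bool) -> float:
    """Impulse magnitude: dose power-law scaling × first-application excess."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    scale = (dose / drug.ref_dose) ** drug.dose_exponent
    if is_first:
        scale *= drug.f_first
    return scale


@dataclass
class ToxChain:
    """One active transit chain started by a single administration."""

    drug: str
    t0: float                      # activation time [d]
    scale: float                   # applied impulse (dose × first factors)
    k: float                       # transit rate [1/d]
    z: np.ndarray                  # stage values z_1..z_n
    s: np.ndarray                  # stage kill intensities [s_S, s_CG, s_PGB, s_MGB]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.z < 0):
            raise ValueError("chain stages must be non-negative")

    @property
    def terminal(self) -> float:
        return float(self.z[-1])


def chain_rhs(z: np.ndarray, k_tox: float) -> np.ndarray:
    """Derivatives of the transit-chain stages ``z_1..z_n``."""
    z = np.asarray(z, dtype=float)
    dz = np.empty_like(z)
    dz[0] = -k_tox * z[0]
    if z.size > 1:
        dz[1:] = k_tox * (z[:-1] - z[1:])
    return dz


def erlang_response(t, n: int, k: float):
    """Terminal stage ``z_n(t)`` after a unit impulse into ``z_1`` at t=0.

    Closed form ``(k t)^{n−1} e^{−k t} / (n−1)!``; peaks at ``(n−1)/k``
    and integrates to ``1/k``.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (k * np.maximum(t, 0.0)) ** (n - 1)
                   * np.exp(-k * np.maximum(t, 0.0)) / math.factorial(n - 1), 0.0)
    return out if out.ndim else float(out)


class ToxChainCollection:
    """Collection of active transit chains with pruning of spent chains."""

    def __init__(self, chains: Iterable[ToxChain] = ()) -> None:
        self.chains: List[ToxChain] = list(chains)

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)

    def apply_dose(
        self,
        drug: DrugToxicityParams,
        dose: float,
        t: float,
        is_first: bool = False,
    ) -> "ToxChainCollection":
        """Append a fresh chain for one administration; existing chains untouched."""
        scale = dose_scale(drug, dose, is_first)
        z = np.zeros(drug.n_transit)
        z[0] = scale
        self.chains.append(
            ToxChain(drug.name, t, scale, drug.k_tox, z, drug.stage_intensities())
        )
        return self

    def psi_total(self, stage) -> float:
        """Overall kill rate Ψ_total^X [1/d] for a marrow stage (index or name)."""
        from .params import MARROW_STAGES

        idx = MARROW_STAGES.index(stage) if isinstance(stage, str) else int(stage)
        return float(sum(c.s[idx] * c.terminal for c in self.chains))

    def psi_vector(self) -> np.ndarray:
        psi = np.zeros(4)
        for c in self.chains:
            psi += c.s * c.terminal
        return psi

    def prune(self, eps: float = CHAIN_PRUNE_EPS) -> "ToxChainCollection":
        """Drop chains whose terminal stage (and total content) has decayed."""
        self.chains = [
            c for c in self.chains if c.terminal >= eps or float(np.max(c.z)) >= eps
        ]
        return self

    def copy(self) -> "ToxChainCollection":
        return ToxChainCollection(
            ToxChain(c.drug, c.t0, c.scale, c.k, c.z.copy(), c.s.copy())
            for c in self.chains
        )


def apply_dose(
    collection: ToxChainCollection,
    drug: DrugToxicityParams,
    dose: float,
    t: float,
    is_first: bool = False,
) -> ToxChainCollection:
    """Functional wrapper around :meth:`ToxChainCollection.apply_dose`."""
    out = collection.copy()
    return out.apply_dose(drug, dose, t, is_first)


def psi_total(collection: ToxChainCollection, stage) -> float:
    return collection.psi_total(stage)


# ----------------------------------------------------------------------
# lymphocytes
# ----------------------------------------------------------------------

def lymphocyte_psi(t, pulses: Sequence) -> float:
    """Lymphotoxic kill rate Ψ^LY(t) [1/d].

    ``pulses`` holds ``(t_dose, amplitude, decay)`` triples, one per
    administration; each contributes ``amplitude·exp(−decay·(t−t_dose))``
    for ``t ≥ t_dose``.
    """
    total = 0.0
    for t0, amp, decay in pulses:
        if t >= t0:
            total += amp * math.exp(-decay * (t - t0))
    return total


def lymphocyte_rhs(ly: float, t: float, psi_ly: float, params: ModelParameters) -> float:
    """dLY/dt: first-order recovery toward LY_ss minus the toxicity pulse."""
    if ly < 0:
        raise ValueError("lymphocyte count must be non-negative")
    c = params.cell
    return (c.LY_ss - ly) / c.T_LY_rec - psi_ly * ly


# ----------------------------------------------------------------------
# prednisone
# ----------------------------------------------------------------------

@dataclass
class PrednisoneWindow:
    """Interval of prednisone administration prolonging the GRA half-life."""

    start: float   # [d]
    end: float     # [d]
    multiplier: float  # granulocyte half-life factor (> 1)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end must be >= start")
        if self.multiplier <= 1.0:
            raise ValueError("half-life multiplier must exceed 1")


def effective_gra_halflife(
    t: float, windows: Sequence[PrednisoneWindow], base_hours: float
) -> float:
    """Granulocyte half-life [h] at time ``t``.

    Inside any window the base half-life is multiplied; where windows
    overlap the largest multiplier wins.
    """
    mult = 1.0
    for w in windows:
        if w.start <= t <= w.end and w.multiplier > mult:
            mult = w.multiplier
    return base_hours * mult


def halflife_multiplier(t: float, windows: Sequence[PrednisoneWindow]) -> float:
    mult = 1.0
    for w in windows:
        if w.start <= t <= w.end and w.multiplier > mult:
            mult = w.multiplier
    return mult
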