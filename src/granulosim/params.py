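"""Parameter containers for the granulopoiesis model.

All quantities that a simulation depends on live in a single
:class:`ModelParameters` object: cell-kinetic constants, G-CSF-mediated
regulation curves, pharmacokinetic constants per G-CSF derivative, and
drug-specific chemotherapy toxicity constants.  Parameter sets are
serialized as YAML; the bundled reference parameterization is in
``granulosim/data/reference_params.yaml``.

Unit conventions
----------------
* times in days (granulocyte half-life stated in hours for readability),
* blood counts in 10^3 cells/µL,
* bone-marrow compartments dimensionless (1 at the untreated steady state),
* G-CSF amounts in µg, serum concentrations in µg/L,
* cytotoxic doses in mg/m² relative to a per-drug reference dose.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, Optional

import numpy as np
import yaml

__all__ = [
    "RegulationCurve",
    "CellKineticParams",
    "GcsfPkParams",
    "DrugToxicityParams",
    "ModelParameters",
    "load_parameters",
    "save_parameters",
    "reference_params_path",
]

DERIVATIVES = ("filgrastim", "pegfilgrastim")
#: bone-marrow stages that receive stage-specific chemotherapy toxicity
MARROW_STAGES = ("S", "CG", "PGB", "MGB")


@dataclass
class RegulationCurve:
    """Sigmoidal (Hill-type) feedback curve, normalized to 1 at baseline.

    The curve maps a regulating signal ``x`` (effective G-CSF serum
    concentration for the bone-marrow properties, circulating granulocyte
    count for endogenous G-CSF production) to a dimensionless factor that
    multiplies the regulated property.  The factor is bounded by
    ``[fmin, fmax]``, is monotone in ``x`` (non-decreasing for stimulated
    properties, non-increasing for suppressed ones) and equals exactly 1
    at the baseline signal ``x_ref``.

    The normalization constant ``A`` that pins the curve to 1 at ``x_ref``
    is ``(1 - fmin)/(fmax - 1)`` for stimulated properties (and its
    reciprocal analogue for suppressed ones).  Once the asymptotes, the
    steepness and the exact-1 anchoring are fixed, the half-effect signal
    is no longer free; it is exposed as the derived :attr:`half_effect`.
    """

    fmin: float
    fmax: float
    hill: float = 1.0
    increasing: bool = True
    x_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.hill <= 0:
            raise ValueError("steepness exponent must be positive")
        if self.x_ref <= 0:
            raise ValueError("baseline signal x_ref must be positive")
        if not (self.fmin <= 1.0 <= self.fmax):
            raise ValueError("regulation factor bounds must satisfy fmin <= 1 <= fmax")
        degenerate = self.fmin == self.fmax
        if not degenerate and (self.fmin >= 1.0 or self.fmax <= 1.0):
            raise ValueError(
                "non-constant regulation curves need fmin < 1 < fmax "
                "(otherwise the exact-1 normalization has no solution)"
            )

    @property
    def is_constant(self) -> bool:
        return self.fmin == self.fmax

    @property
    def norm_constant(self) -> float:
        """Normalization constant A making factor(x_ref) == 1."""
        if self.is_constant:
            return 1.0
        if self.increasing:
            return (1.0 - self.fmin) / (self.fmax - 1.0)
        return (self.fmax - 1.0) / (1.0 - self.fmin)

    @property
    def half_effect(self) -> float:
        """Signal at which the curve sits halfway between its asymptotes."""
        if self.is_constant:
            return self.x_ref
        return self.x_ref * self.norm_constant ** (-1.0 / self.hill)

    def factor(self, x):
        """Evaluate the curve at signal ``x`` (scalar or array, >= 0)."""
        scalar = np.isscalar(x)
        xa = np.asarray(x, dtype=float)
        if np.any(xa < 0):
            raise ValueError("regulating signal must be non-negative")
        if self.is_constant:
            out = np.full_like(xa, 1.0)
            return float(out) if scalar else out
        u = self.norm_constant * (xa / self.x_ref) ** self.hill
        s = u / (1.0 + u)
        if self.increasing:
            out = self.fmin + (self.fmax - self.fmin) * s
        else:
            out = self.fmax - (self.fmax - self.fmin) * s
        return float(out) if scalar else out

    # scalar fast path used inside the ODE right-hand side
    def factor_scalar(self, x: float) -> float:
        if self.is_constant:
            return 1.0
        u = self.norm_constant * (x / self.x_ref) ** self.hill
        s = u / (1.0 + u)
        if self.increasing:
            return self.fmin + (self.fmax - self.fmin) * s
        return self.fmax - (self.fmax - self.fmin) * s


#: names of the regulated properties and their required direction
REGULATED_PROPERTIES = {
    "A_PGB": True,          # amplification in PGB rises with G-CSF
    "T_PGB": True,          # transition time in PGB lengthens with G-CSF
    "T_MGB": False,         # maturation time in MGB shortens with G-CSF
    "MGB_survival": True,   # postmitotic apoptosis is reduced by G-CSF
    "endog_production": False,  # endogenous G-CSF production falls with GRA
}


@dataclass
class CellKineticParams:
    """Cell-kinetic constants of the granulopoietic lineage.

    Transition times ``T_*`` are mean residence times in days; marrow
    compartments are normalized so that all equal 1 at the untreated
    steady state, which absorbs the baseline amplifications into flux
    normalization constants (see :mod:`granulosim.model_core`).
    """

    T_S: float = 5.0            # stem-cell turnover time [d]
    T_CG: float = 6.0           # committed progenitors (CFU-GM...) [d]
    T_PGB: float = 4.0          # proliferating precursors [d]
    T_MGB: float = 6.5          # postmitotic maturation [d]
    T_GRA_hours: float = 7.0    # circulating granulocyte half-life [h]
    mgb_survival: float = 0.8   # fraction surviving postmitotic apoptosis
    self_renewal_slope: float = 0.4  # d p(S)/dS at S = 1 (negative slope magnitude)
    p_min: float = 0.05
    p_max: float = 0.95
    GRA_ss: float = 4.4         # steady-state granulocytes [10^3/µL]
    LY_ss: float = 2.6          # steady-state lymphocytes [10^3/µL]
    T_LY_rec: float = 25.0      # lymphocyte recovery time constant [d]

    def validate(self) -> None:
        for name in ("T_S", "T_CG", "T_PGB", "T_MGB", "T_LY_rec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"transition time {name} must be positive")
        if self.T_GRA_hours <= 0:
            raise ValueError("granulocyte half-life must be positive")
        if not (0.0 < self.mgb_survival <= 1.0):
            raise ValueError("postmitotic survival fraction must be in (0, 1]")
        if not (0.0 < self.p_min < 0.5 < self.p_max < 1.0):
            raise ValueError("self-renewal probability clip must bracket 0.5")
        if self.self_renewal_slope <= 0:
            raise ValueError("self-renewal regulation slope must be positive")
        if self.GRA_ss <= 0 or self.LY_ss <= 0:
            raise ValueError("steady-state blood counts must be positive")
        if self.GRA_ss + self.LY_ss <= 4.0:
            raise ValueError(
                "untreated WBC (GRA_ss + LY_ss) must exceed the 4.0 leukopenia threshold"
            )

    @property
    def wbc_ss(self) -> float:
        return self.GRA_ss + self.LY_ss

    @property
    def gra_decay(self) -> float:
        """First-order granulocyte loss rate [1/d] at the baseline half-life."""
        return math.log(2.0) * 24.0 / self.T_GRA_hours


@dataclass
class GcsfPkParams:
    """Pharmacokinetic constants for one G-CSF derivative.

    The subcutaneous depot is split into two serial subcompartments to
    delay absorption; a Michaelis-Menten loss from the first
    subcompartment makes bioavailability dose-dependent.  Central
    elimination is first-order renal plus granulocyte-mediated
    Michaelis-Menten, the latter scaling linearly with the circulating
    granulocyte count.  Endogenous G-CSF shares the filgrastim constants.
    """

    k_sc12: float       # depot subcompartment 1 -> 2 transition [1/d]
    k_sc2c: float       # subcompartment 2 -> central absorption [1/d]
    V_bio: float        # MM bioavailability-loss capacity [µg/d]
    K_bio: float        # MM bioavailability-loss constant [µg]
    V_d: float          # central distribution volume [L]
    k_cp: float         # central -> peripheral binding [1/d]
    k_pc: float         # peripheral -> central release [1/d]
    k_ren: float        # unspecific renal elimination [1/d]
    V_spec: float       # granulocyte-mediated elimination capacity [µg/L/d per 10^3 cells/µL]
    K_spec: float       # granulocyte-mediated MM constant [µg/L]
    potency: float = 1.0  # weight in the effective PD signal

    def validate(self) -> None:
        for name in ("k_sc12", "k_sc2c", "V_bio", "K_bio", "k_cp", "k_pc",
                     "k_ren", "V_spec", "K_spec"):
            if getattr(self, name) < 0:
                raise ValueError(f"PK constant {name} must be non-negative")
        if self.V_d <= 0:
            raise ValueError("distribution volume must be positive")
        if self.potency < 0:
            raise ValueError("potency weight must be non-negative")


@dataclass
class DrugToxicityParams:
    """Chemotherapy toxicity constants for one cytotoxic drug.

    A bolus administration feeds a transit chain of ``n_transit``
    concatenated first-order stages with rate ``k_tox``; the final chain
    value drives the stage-specific cell-kill rates ``s_X`` (given in 1/d
    at the reference dose, at the chain's unit-impulse scale).  Lymphocyte
    depletion is phenomenological: a two-parameter exponential pulse
    (``ly_intensity``, ``ly_decay``) applied directly at administration.
    """

    name: str
    s_S: float
    s_CG: float
    s_PGB: float
    s_MGB: float
    n_transit: int = 3
    k_tox: float = 0.4          # [1/d]
    f_first: float = 1.15       # first-application toxicity excess
    ref_dose: float = 1.0       # reference dose [mg/m²]
    dose_exponent: float = 1.0  # (dose/ref_dose)**exponent scaling
    ly_intensity: float = 0.0   # lymphotoxic pulse amplitude [1/d]
    ly_decay: float = 0.2       # lymphotoxic pulse decay [1/d]

    def validate(self) -> None:
        for name in ("s_S", "s_CG", "s_PGB", "s_MGB", "ly_intensity", "ly_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"toxicity constant {name} must be non-negative")
        if self.n_transit < 1:
            raise ValueError("transit chain length must be >= 1")
        if self.k_tox <= 0:
            raise ValueError("transit rate must be positive")
        if self.f_first < 1.0:
            raise ValueError("first-application multiplier must be >= 1")
        if self.ref_dose <= 0:
            raise ValueError("reference dose must be positive")

    def stage_intensities(self) -> np.ndarray:
        return np.array([self.s_S, self.s_CG, self.s_PGB, self.s_MGB])


@dataclass
class ModelParameters:
    """Complete parameterization of the coupled model.

    ``gcsf_base_conc`` is the endogenous G-CSF serum concentration at the
    untreated steady state; every G-CSF regulation curve is anchored to 1
    there, and the baseline endogenous production rate is derived from it
    so that the steady state closes exactly.
    """

    cell: CellKineticParams
    regulation: Dict[str, RegulationCurve]
    gcsf: Dict[str, GcsfPkParams]
    drugs: Dict[str, DrugToxicityParams]
    gcsf_base_conc: float = 0.025       # endogenous serum G-CSF [µg/L]
    body_weight_kg: float = 75.0        # for per-kg dose conversion
    prednisone_halflife_multiplier: float = 1.6
    risk_multipliers: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # anchor every regulation curve at the correct baseline signal
        for name, curve in self.regulation.items():
            curve.x_ref = (
                self.cell.GRA_ss if name == "endog_production" else self.gcsf_base_conc
            )
        self.validate()

    def validate(self) -> None:
        self.cell.validate()
        if self.gcsf_base_conc <= 0:
            raise ValueError("baseline G-CSF concentration must be positive")
        if self.prednisone_halflife_multiplier <= 1.0:
            raise ValueError("prednisone half-life multiplier must exceed 1")
        missing = set(REGULATED_PROPERTIES) - set(self.regulation)
        if missing:
            raise ValueError(f"missing regulation curves: {sorted(missing)}")
        for name, increasing in REGULATED_PROPERTIES.items():
            curve = self.regulation[name]
            if not curve.is_constant and curve.increasing != increasing:
                raise ValueError(
                    f"regulation curve {name!r} must be "
                    f"{'non-decreasing' if increasing else 'non-increasing'}"
                )
        for name in DERIVATIVES:
            if name not in self.gcsf:
                raise ValueError(f"missing PK parameter block for {name}")
            self.gcsf[name].validate()
        fil, peg = self.gcsf["filgrastim"], self.gcsf["pegfilgrastim"]
        if peg.k_ren > fil.k_ren:
            raise ValueError(
                "pegfilgrastim renal elimination must not exceed filgrastim's"
            )
        for drug in self.drugs.values():
            drug.validate()

    # ------------------------------------------------------------------
    # derived steady-state quantities
    # ------------------------------------------------------------------
    @property
    def endog_pk(self) -> GcsfPkParams:
        """Endogenous G-CSF shares the filgrastim parameter set."""
        return self.gcsf["filgrastim"]

    @property
    def endog_production_base(self) -> float:
        """Baseline endogenous production [µg/L/d] closing the steady state."""
        p = self.endog_pk
        c = self.gcsf_base_conc
        return (p.k_ren + p.V_spec * self.cell.GRA_ss / (p.K_spec + c)) * c

    @property
    def endog_peripheral_ss(self) -> float:
        """Steady-state peripheral (bound) endogenous G-CSF amount [µg]."""
        p = self.endog_pk
        if p.k_pc == 0:
            return 0.0
        return p.k_cp * self.gcsf_base_conc * p.V_d / p.k_pc

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "cell": asdict(self.cell),
            "regulation": {k: asdict(v) for k, v in self.regulation.items()},
            "gcsf": {k: asdict(v) for k, v in self.gcsf.items()},
            "drugs": {k: asdict(v) for k, v in self.drugs.items()},
            "gcsf_base_conc": self.gcsf_base_conc,
            "body_weight_kg": self.body_weight_kg,
            "prednisone_halflife_multiplier": self.prednisone_halflife_multiplier,
            "risk_multipliers": dict(self.risk_multipliers),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        reg = {}
        for name, spec in d["regulation"].items():
            spec = dict(spec)
            spec.pop("x_ref", None)  # re-anchored in __post_init__
            reg[name] = RegulationCurve(**spec)
        drugs = {}
        for name, spec in d["drugs"].items():
            spec = dict(spec)
            spec.setdefault("name", name)
            drugs[name] = DrugToxicityParams(**spec)
        return cls(
            cell=CellKineticParams(**d["cell"]),
            regulation=reg,
            gcsf={k: GcsfPkParams(**v) for k, v in d["gcsf"].items()},
            drugs=drugs,
            gcsf_base_conc=d.get("gcsf_base_conc", 0.025),
            body_weight_kg=d.get("body_weight_kg", 75.0),
            prednisone_halflife_multiplier=d.get("prednisone_halflife_multiplier", 1.6),
            risk_multipliers=d.get("risk_multipliers", {}) or {},
        )


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_parameters(path) -> ModelParameters:
    with open(path) as fh:
        return ModelParameters.from_dict(yaml.safe_load(fh))


def reference_params_path():
    """Path to the bundled reference (median, normal-risk) parameter file."""
    return resources.files("granulosim").joinpath("data/reference_params.yaml")
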