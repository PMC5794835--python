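"""Treatment timelines and event-driven integration of the coupled system.

The state vector stacks the six cell compartments, three G-CSF PK blocks
(endogenous, filgrastim, pegfilgrastim; 7 components each) and one
toxicity transit chain per chemotherapy administration.  Chains are
pre-allocated from the timeline and activated by a bolus on their first
stage at the administration instant; G-CSF injections are boluses on the
subcutaneous depot.  Integration restarts at every event and at
prednisone window edges, using the VODE multistep solver in Adams
(non-stiff, variable step/order) mode — the closest scipy analogue of
the Adams-Bashford family — with rtol 1e-8 / atol 1e-10 by default.

Day convention: "day 1" is the first day of cycle 1; cycle ``c`` day
``d`` maps to absolute time ``(c-1)*cycle_length + d - 1`` and events
occur at the start of their day.  Same-day chemotherapy precedes G-CSF
in the event ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import ode

from . import gcsf_pk
from .chemo_toxicity import PrednisoneWindow, dose_scale
from .gcsf_pk import BLOCK_SIZE, CEN, SC1
from .model_core import CELL_NAMES, flux_gains, steady_state
from .params import DERIVATIVES, ModelParameters

__all__ = [
    "Regimen", "GcsfSchedule", "Event", "SimulationResult",
    "build_timeline", "simulate",
    "load_regimen", "save_regimen", "load_schedule", "save_schedule",
]

# fixed part of the state vector
N_CELLS = 6
BLOCK_BASE = {"endogenous": 6, "filgrastim": 6 + BLOCK_SIZE, "pegfilgrastim": 6 + 2 * BLOCK_SIZE}
N_FIXED = 6 + 3 * BLOCK_SIZE

_GRID_DECIMALS = 9


# ----------------------------------------------------------------------
# treatment descriptions
# ----------------------------------------------------------------------

@dataclass
class Regimen:
    """A chemotherapy regimen: repeated cycles of drug administrations.

    ``administrations`` holds (cycle-relative day, drug name, dose
    [mg/m²]) triples applied in every cycle; sequential regimens instead
    declare ``blocks`` of cycles with block-specific administrations
    (e.g. epirubicin cycles 1-3, paclitaxel 4-6, cyclophosphamide 7-9).
    ``prednisone_days`` are (first day, last day) windows per cycle.
    """

    name: str
    cycle_length: float
    n_cycles: int
    administrations: List[Tuple[float, str, float]] = field(default_factory=list)
    blocks: Optional[List[Tuple[int, int, List[Tuple[float, str, float]]]]] = None
    prednisone_days: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle length must be positive")
        if self.n_cycles < 1:
            raise ValueError("number of cycles must be >= 1")
        for c in range(1, self.n_cycles + 1):
            for day, drug, dose in self.administrations_for_cycle(c):
                if not (1 <= day <= self.cycle_length):
                    raise ValueError(
                        f"administration day {day} outside cycle of length {self.cycle_length}"
                    )
                if dose <= 0:
                    raise ValueError(f"dose for {drug} must be positive")
        for start, end in self.prednisone_days:
            if not (1 <= start <= end <= self.cycle_length):
                raise ValueError("prednisone window outside cycle")

    def administrations_for_cycle(self, cycle: int) -> List[Tuple[float, str, float]]:
        if self.blocks:
            for first, last, admins in self.blocks:
                if first <= cycle <= last:
                    return admins
            return []
        return self.administrations

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_length

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "cycle_length": self.cycle_length,
            "n_cycles": self.n_cycles,
            "administrations": [list(a) for a in self.administrations],
            "prednisone_days": [list(w) for w in self.prednisone_days],
        }
        if self.blocks:
            d["blocks"] = [
                {"cycles": [first, last], "administrations": [list(a) for a in admins]}
                for first, last, admins in self.blocks
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Regimen":
        blocks = None
        if d.get("blocks"):
            blocks = [
                (b["cycles"][0], b["cycles"][1],
                 [tuple(a) for a in b["administrations"]])
                for b in d["blocks"]
            ]
        return cls(
            name=d["name"],
            cycle_length=d["cycle_length"],
            n_cycles=d["n_cycles"],
            administrations=[tuple(a) for a in d.get("administrations", [])],
            blocks=blocks,
            prednisone_days=[tuple(w) for w in d.get("prednisone_days", [])],
        )


@dataclass
class GcsfSchedule:
    """G-CSF support schedule: injection days per cycle and dose.

    ``days`` are cycle-relative injection days applied in every cycle;
    ``blocks`` optionally override days/dose for cycle ranges.  Doses are
    absolute µg; ``dose_per_kg`` (µg/kg) is resolved against the model's
    body weight at simulation time.  Pegfilgrastim allows at most one
    injection per cycle.
    """

    derivative: str
    days: Sequence[float] = ()
    dose: Optional[float] = None
    dose_per_kg: Optional[float] = None
    blocks: Optional[List[Tuple[int, int, Sequence[float], float]]] = None

    def __post_init__(self) -> None:
        if self.derivative not in DERIVATIVES:
            raise ValueError(f"unknown G-CSF derivative {self.derivative!r}")
        if self.dose is None and self.dose_per_kg is None and (self.days or self.blocks):
            raise ValueError("a dose (absolute or per kg) is required")
        if self.dose is not None and self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.derivative == "pegfilgrastim":
            if len(self.days) > 1:
                raise ValueError("pegfilgrastim allows at most one injection per cycle")
            for blk in self.blocks or []:
                if len(blk[2]) > 1:
                    raise ValueError("pegfilgrastim allows at most one injection per cycle")

    @classmethod
    def consecutive(cls, derivative: str, start: int, n: int, dose: float) -> "GcsfSchedule":
        """Daily injections on days ``start .. start+n-1`` of every cycle."""
        return cls(derivative=derivative, days=tuple(range(start, start + n)), dose=dose)

    def days_for_cycle(self, cycle: int) -> Tuple[Sequence[float], Optional[float]]:
        if self.blocks:
            for first, last, days, dose in self.blocks:
                if first <= cycle <= last:
                    return days, dose
            return (), None
        return self.days, self.dose

    def resolve_dose(self, dose: Optional[float], params: ModelParameters) -> float:
        if dose is not None:
            return dose
        if self.dose_per_kg is not None:
            return self.dose_per_kg * params.body_weight_kg
        raise ValueError("no dose specified")

    def to_dict(self) -> dict:
        d = {"derivative": self.derivative, "days": list(self.days)}
        if self.dose is not None:
            d["dose"] = self.dose
        if self.dose_per_kg is not None:
            d["dose_per_kg"] = self.dose_per_kg
        if self.blocks:
            d["blocks"] = [
                {"cycles": [f, l], "days": list(days), "dose": dose}
                for f, l, days, dose in self.blocks
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GcsfSchedule":
        blocks = None
        if d.get("blocks"):
            blocks = [
                (b["cycles"][0], b["cycles"][1], tuple(b["days"]), b["dose"])
                for b in d["blocks"]
            ]
        return cls(
            derivative=d["derivative"],
            days=tuple(d.get("days", ())),
            dose=d.get("dose"),
            dose_per_kg=d.get("dose_per_kg"),
            blocks=blocks,
        )


@dataclass
class Event:
    """One timeline event: a chemotherapy administration or G-CSF injection."""

    t: float
    kind: str            # "chemo" | "gcsf"
    name: str            # drug or derivative name
    dose: float
    cycle: int
    day: float
    is_first: bool = False
    chain_index: Optional[int] = None  # assigned by the simulator for chemo


def build_timeline(
    regimen: Regimen, schedule: Optional[GcsfSchedule] = None
) -> List[Event]:
    """Absolute-time-sorted chemo and G-CSF events.

    Cycle ``c`` day ``d`` maps to ``t = (c-1)*cycle_length + d - 1``;
    same-time chemo sorts before G-CSF; the first administration of each
    drug is flagged ``is_first``.
    """
    events: List[Event] = []
    seen_drugs: set = set()
    for c in range(1, regimen.n_cycles + 1):
        base = (c - 1) * regimen.cycle_length
        for day, drug, dose in sorted(regimen.administrations_for_cycle(c)):
            first = drug not in seen_drugs
            seen_drugs.add(drug)
            events.append(Event(base + day - 1.0, "chemo", drug, dose, c, day, first))
        if schedule is not None:
            days, dose = schedule.days_for_cycle(c)
            for day in days:
                if not (1 <= day <= regimen.cycle_length):
                    raise ValueError(
                        f"G-CSF day {day} outside cycle of length {regimen.cycle_length}"
                    )
                events.append(
                    Event(base + day - 1.0, "gcsf", schedule.derivative,
                          dose if dose is not None else float("nan"), c, day)
                )
    events.sort(key=lambda e: (e.t, 0 if e.kind == "chemo" else 1, e.name))
    return events


def prednisone_windows(
    regimen: Regimen, multiplier: float
) -> List[PrednisoneWindow]:
    """Absolute prednisone windows; a day-``d1..d2`` course covers
    ``[(c-1)L + d1 - 1, (c-1)L + d2]`` (end of the last day)."""
    windows = []
    for c in range(1, regimen.n_cycles + 1):
        base = (c - 1) * regimen.cycle_length
        for d1, d2 in regimen.prednisone_days:
            windows.append(PrednisoneWindow(base + d1 - 1.0, base + d2, multiplier))
    return windows


# ----------------------------------------------------------------------
# result container
# ----------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Dense trajectories of the coupled system on the reporting grid."""

    t: np.ndarray
    y: np.ndarray                       # (n_grid, state_dim) full state matrix
    events: List[Event]
    therapy_end: float
    chain_offsets: np.ndarray
    chain_lengths: np.ndarray
    event_states: List[Tuple[np.ndarray, np.ndarray]]  # (before, after) per event
    potencies: Tuple[float, float]

    @property
    def gra(self) -> np.ndarray:
        return self.y[:, 4]

    @property
    def ly(self) -> np.ndarray:
        return self.y[:, 5]

    @property
    def wbc(self) -> np.ndarray:
        return self.y[:, 4] + self.y[:, 5]

    @property
    def gcsf_serum(self) -> np.ndarray:
        """Effective (potency-weighted total) G-CSF serum concentration."""
        pot_f, pot_p = self.potencies
        return (
            self.y[:, BLOCK_BASE["endogenous"] + CEN]
            + pot_f * self.y[:, BLOCK_BASE["filgrastim"] + CEN]
            + pot_p * self.y[:, BLOCK_BASE["pegfilgrastim"] + CEN]
        )

    def compartment(self, name: str) -> np.ndarray:
        return self.y[:, CELL_NAMES.index(name)]

    def to_frame(self, full: bool = False) -> pd.DataFrame:
        cols = {
            "time_days": self.t,
            "wbc": self.wbc,
            "gra": self.gra,
            "ly": self.ly,
            "gcsf_serum": self.gcsf_serum,
        }
        if full:
            for i, name in enumerate(("S", "CG", "PGB", "MGB")):
                cols[name] = self.y[:, i]
            for block, base in BLOCK_BASE.items():
                cols[f"gcsf_{block}_serum"] = self.y[:, base + CEN]
        return pd.DataFrame(cols)

    def write_csv(self, path, full: bool = False) -> None:
        self.to_frame(full=full).to_csv(path, index=False)


# ----------------------------------------------------------------------
# the simulator
# ----------------------------------------------------------------------

def _make_rhs(params: ModelParameters, chains, ly_pulses, windows):
    """Build the flat right-hand side for one timeline.

    ``chains`` is (offsets, lengths, rates, s_mat); ``ly_pulses`` is
    (times, amplitudes, decays) arrays; ``windows`` the absolute
    prednisone windows.
    """
    c = params.cell
    g_cg, g_pgb, g_mgb, g_gra = flux_gains(params)
    reg = params.regulation
    f_a = reg["A_PGB"].factor_scalar
    f_tp = reg["T_PGB"].factor_scalar
    f_tm = reg["T_MGB"].factor_scalar
    f_q = reg["MGB_survival"].factor_scalar
    f_prod = reg["endog_production"].factor_scalar
    prod_base = params.endog_production_base
    pk_sets = [params.endog_pk, params.gcsf["filgrastim"], params.gcsf["pegfilgrastim"]]
    bases = [BLOCK_BASE["endogenous"], BLOCK_BASE["filgrastim"], BLOCK_BASE["pegfilgrastim"]]
    pot = [1.0, params.gcsf["filgrastim"].potency, params.gcsf["pegfilgrastim"].potency]
    offs, lens, rates, s_mat = chains
    last_idx = offs + lens - 1
    ly_t, ly_amp, ly_dec = ly_pulses
    T_S, T_CG, T_PGB, T_MGB = c.T_S, c.T_CG, c.T_PGB, c.T_MGB
    q_base = c.mgb_survival
    slope, p_min, p_max = c.self_renewal_slope, c.p_min, c.p_max
    gra_decay, LY_ss, T_LY = c.gra_decay, c.LY_ss, c.T_LY_rec
    n_chains = len(offs)

    def rhs(t, y):
        dy = np.zeros_like(y)

        # --- toxicity kill rates from terminal chain stages
        if n_chains:
            z_last = np.maximum(y[last_idx], 0.0)
            psi = s_mat.T @ z_last
        else:
            psi = np.zeros(4)

        gra = y[4] if y[4] > 0.0 else 0.0

        # --- G-CSF PK blocks
        prod = prod_base * f_prod(gra)
        for i in range(3):
            b = bases[i]
            gcsf_pk.pk_block_rhs(
                y[b:b + BLOCK_SIZE], dy[b:b + BLOCK_SIZE], gra, pk_sets[i],
                production=prod if i == 0 else 0.0,
            )

        ceff = (
            max(y[bases[0] + CEN], 0.0)
            + pot[1] * max(y[bases[1] + CEN], 0.0)
            + pot[2] * max(y[bases[2] + CEN], 0.0)
        )

        # --- regulation factors
        ra = f_a(ceff)
        t_pgb = T_PGB * f_tp(ceff)
        t_mgb = T_MGB * f_tm(ceff)
        q_eff = q_base * f_q(ceff)
        if q_eff > 1.0:
            q_eff = 1.0

        # --- prednisone
        mult = 1.0
        for w in windows:
            if w.start <= t <= w.end and w.multiplier > mult:
                mult = w.multiplier

        # --- cells
        s_ = y[0] if y[0] > 0.0 else 0.0
        cg = y[1] if y[1] > 0.0 else 0.0
        pgb = y[2] if y[2] > 0.0 else 0.0
        mgb = y[3] if y[3] > 0.0 else 0.0
        ly = y[5] if y[5] > 0.0 else 0.0

        p_self = 0.5 - slope * (s_ - 1.0)
        if p_self < p_min:
            p_self = p_min
        elif p_self > p_max:
            p_self = p_max

        dy[0] = (2.0 * p_self - 1.0) * s_ / T_S - psi[0] * s_
        dy[1] = g_cg * 2.0 * (1.0 - p_self) * s_ / T_S - cg / T_CG - psi[1] * cg
        dy[2] = ra * g_pgb * cg / T_CG - pgb / t_pgb - psi[2] * pgb
        dy[3] = q_eff * g_mgb * pgb / t_pgb - mgb / t_mgb - psi[3] * mgb
        dy[4] = g_gra * mgb / t_mgb - (gra_decay / mult) * gra

        # --- lymphocytes (closed-form pulse sum)
        if ly_t.size:
            mask = t >= ly_t
            if mask.any():
                psi_ly = float(
                    np.sum(ly_amp[mask] * np.exp(-ly_dec[mask] * (t - ly_t[mask])))
                )
            else:
                psi_ly = 0.0
        else:
            psi_ly = 0.0
        dy[5] = (LY_ss - ly) / T_LY - psi_ly * ly

        # --- transit chains
        for i in range(n_chains):
            o = offs[i]
            n = lens[i]
            k = rates[i]
            dy[o] = -k * y[o]
            if n > 1:
                dy[o + 1:o + n] = k * (y[o:o + n - 1] - y[o + 1:o + n])

        return dy

    return rhs


def simulate(
    params: ModelParameters,
    regimen: Optional[Regimen] = None,
    schedule: Optional[GcsfSchedule] = None,
    horizon: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_step: float = 0.1,
) -> SimulationResult:
    """Integrate the coupled model from its untreated steady state.

    Returns dense output on a fixed reporting grid (default 0.1 d).  The
    integration restarts at every event so bolus discontinuities are
    exact; the result is deterministic for fixed inputs and tolerances.
    """
    if grid_step <= 0 or grid_step > 0.25:
        raise ValueError("reporting grid step must be in (0, 0.25] days")
    therapy_end = regimen.duration if regimen is not None else 0.0
    if horizon is None:
        horizon = therapy_end + 28.0
    if regimen is not None and horizon < therapy_end:
        raise ValueError("horizon must cover the regimen duration")

    events = build_timeline(regimen, schedule) if regimen is not None else []
    if schedule is not None and regimen is None:
        raise ValueError("a G-CSF schedule requires a regimen timeline")
    for e in events:
        if e.kind == "chemo" and e.name not in params.drugs:
            raise ValueError(f"unknown drug {e.name!r} in regimen")
        if e.kind == "gcsf":
            e.dose = schedule.resolve_dose(
                None if math.isnan(e.dose) else e.dose, params
            )

    windows = (
        prednisone_windows(regimen, params.prednisone_halflife_multiplier)
        if regimen is not None
        else []
    )

    # --- allocate chains and lymphocyte pulses from the timeline
    chemo_events = [e for e in events if e.kind == "chemo"]
    offs, lens, rates = [], [], []
    s_rows = []
    impulses = []
    ly_t, ly_amp, ly_dec = [], [], []
    pos = N_FIXED
    for idx, e in enumerate(chemo_events):
        drug = params.drugs[e.name]
        e.chain_index = idx
        offs.append(pos)
        lens.append(drug.n_transit)
        rates.append(drug.k_tox)
        s_rows.append(drug.stage_intensities())
        scale = dose_scale(drug, e.dose, e.is_first)
        impulses.append(scale)
        if drug.ly_intensity > 0:
            ly_t.append(e.t)
            ly_amp.append(drug.ly_intensity * scale)
            ly_dec.append(drug.ly_decay)
        pos += drug.n_transit
    dim = pos
    chains = (
        np.array(offs, dtype=int),
        np.array(lens, dtype=int),
        np.array(rates, dtype=float),
        np.array(s_rows, dtype=float).reshape(len(offs), 4),
    )
    ly_pulses = (np.array(ly_t), np.array(ly_amp), np.array(ly_dec))

    rhs = _make_rhs(params, chains, ly_pulses, windows)

    # --- initial state: untreated steady state
    ss = steady_state(params)
    y = np.zeros(dim)
    y[:N_CELLS] = ss.cells
    for name, base in BLOCK_BASE.items():
        y[base:base + BLOCK_SIZE] = ss.gcsf.blocks[name]

    # --- reporting grid and breakpoints
    n_grid = int(round(horizon / grid_step))
    grid = np.round(np.arange(n_grid + 1) * grid_step, _GRID_DECIMALS)
    if grid[-1] < horizon - 1e-9:
        grid = np.append(grid, horizon)
    grid[-1] = min(grid[-1], horizon)

    break_ts = {0.0, float(horizon)}
    for e in events:
        if e.t <= horizon:
            break_ts.add(round(e.t, _GRID_DECIMALS))
    for w in windows:
        if w.start <= horizon:
            break_ts.add(round(w.start, _GRID_DECIMALS))
        if w.end <= horizon:
            break_ts.add(round(w.end, _GRID_DECIMALS))
    breakpoints = sorted(break_ts)

    events_at: Dict[float, List[Event]] = {}
    for e in events:
        if e.t <= horizon:
            events_at.setdefault(round(e.t, _GRID_DECIMALS), []).append(e)

    out = np.empty((grid.size, dim))
    filled = np.zeros(grid.size, dtype=bool)
    event_states: List[Tuple[np.ndarray, np.ndarray]] = []

    def store(tb: float, yv: np.ndarray) -> None:
        i = np.searchsorted(grid, tb - 1e-9)
        if i < grid.size and abs(grid[i] - tb) < 1e-8:
            out[i] = yv
            filled[i] = True

    for seg in range(len(breakpoints)):
        tb = breakpoints[seg]
        # apply events at this breakpoint (chemo first: list is pre-sorted)
        for e in events_at.get(tb, []):
            before = y.copy()
            if e.kind == "chemo":
                drug = params.drugs[e.name]
                y[chains[0][e.chain_index]] += dose_scale(drug, e.dose, e.is_first)
            else:
                base = BLOCK_BASE[e.name]
                y[base + SC1] += e.dose
            event_states.append((before, y.copy()))
        store(tb, y)
        if seg == len(breakpoints) - 1:
            break
        t_next = breakpoints[seg + 1]

        r = ode(rhs)
        r.set_integrator(
            "vode", method="adams", with_jacobian=False,
            rtol=rtol, atol=atol, nsteps=200000,
        )
        r.set_initial_value(y, tb)
        i0 = np.searchsorted(grid, tb + 1e-9)
        i1 = np.searchsorted(grid, t_next - 1e-9)
        for i in range(i0, i1):
            r.integrate(grid[i])
            if not r.successful():
                raise RuntimeError(
                    f"ODE integration failed at t={grid[i]:.3f} "
                    f"(segment [{tb}, {t_next}])"
                )
            out[i] = r.y
            filled[i] = True
        r.integrate(t_next)
        if not r.successful():
            raise RuntimeError(
                f"ODE integration failed reaching t={t_next} (from {tb})"
            )
        y = r.y.copy()

    store(breakpoints[-1], y)
    if not filled.all():
        # grid points beyond the last breakpoint cannot occur (horizon is a
        # breakpoint); any hole is a logic error
        missing = grid[~filled]
        raise RuntimeError(f"reporting grid not fully covered: {missing[:5]}")

    pot = (params.gcsf["filgrastim"].potency, params.gcsf["pegfilgrastim"].potency)
    return SimulationResult(
        t=grid, y=out, events=events, therapy_end=therapy_end,
        chain_offsets=chains[0], chain_lengths=chains[1],
        event_states=event_states, potencies=pot,
    )


# ----------------------------------------------------------------------
# YAML IO for treatment descriptions
# ----------------------------------------------------------------------

def save_regimen(regimen: Regimen, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(regimen.to_dict(), fh, sort_keys=False)


def load_regimen(path) -> Regimen:
    with open(path) as fh:
        return Regimen.from_dict(yaml.safe_load(fh))


def save_schedule(schedule: GcsfSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule.to_dict(), fh, sort_keys=False)


def load_schedule(path) -> GcsfSchedule:
    with open(path) as fh:
        return GcsfSchedule.from_dict(yaml.safe_load(fh))
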