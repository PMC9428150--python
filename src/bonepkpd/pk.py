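"""Linear compartmental pharmacokinetics of alendronate.

Alendronate is cleared from plasma by renal excretion and by deposition onto
the bone mineral, with a fast exchange with non-calcified tissues.  Five
compartmental topologies of increasing complexity are implemented, all linear
and time-invariant between dose events:

``1c``           gut -> CC, with two exits from CC (urine and a non-urine sink
                 labelled BC for uniformity of constant names).
``2c``           gut -> CC <-> BC, urine exit from CC.
``3c-series``    gut -> CC <-> BC <-> IC, urine exit from CC.
``3c-parallel``  gut -> CC <-> {NCT, BC}, urine exit from CC.
``4c``           3c-parallel plus BC <-> IC.

Amounts are in mg, time in days.  Serum concentration is the central
compartment amount divided by the distribution volume ``V_c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

#: molar mass of alendronic acid, g/mol (= mg/mmol); configurable per params
MOLAR_MASS_ALENDRONATE = 249.1

# state-vector layout, shared by every topology (unused entries stay zero)
COMPARTMENTS = ("gut", "cc", "nct", "bc", "ic", "urine")
GUT, CC, NCT, BC, IC, URINE = range(6)
N_COMP = 6


class Topology(str, Enum):
    """Compartmental layout of the PK model."""

    ONE_C = "1c"
    TWO_C = "2c"
    THREE_C_SERIES = "3c-series"
    THREE_C_PARALLEL = "3c-parallel"
    FOUR_C = "4c"


#: rate constants each topology requires (beyond k_CC, k_el_urine, V_c, F)
REQUIRED_CONSTANTS = {
    Topology.ONE_C: ("k_BC",),
    Topology.TWO_C: ("k_BC", "k_el_BC"),
    Topology.THREE_C_SERIES: ("k_BC", "k_el_BC", "k_IC", "k_el_IC"),
    Topology.THREE_C_PARALLEL: ("k_BC", "k_el_BC", "k_NCT", "k_el_NCT"),
    Topology.FOUR_C: ("k_BC", "k_el_BC", "k_NCT", "k_el_NCT", "k_IC", "k_el_IC"),
}


@dataclass
class PKParams:
    """Rate constants (1/day), distribution volume (L) and bioavailability.

    Constants not used by a topology may be left ``None``; supplying them is
    not an error (they are ignored), but a missing required constant raises
    at matrix-build time.
    """

    k_CC: float
    k_el_urine: float
    V_c: float
    F: float
    k_NCT: float | None = None
    k_el_NCT: float | None = None
    k_BC: float | None = None
    k_el_BC: float | None = None
    k_IC: float | None = None
    k_el_IC: float | None = None
    molar_mass: float = MOLAR_MASS_ALENDRONATE

    def __post_init__(self) -> None:
        for name in ("k_CC", "k_el_urine", "k_NCT", "k_el_NCT", "k_BC",
                     "k_el_BC", "k_IC", "k_el_IC"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.V_c <= 0:
            raise ValueError(f"V_c must be > 0, got {self.V_c}")
        if not 0 < self.F <= 1:
            raise ValueError(f"F must be in (0, 1], got {self.F}")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")

    def require(self, topology: Topology) -> None:
        missing = [k for k in REQUIRED_CONSTANTS[topology]
                   if getattr(self, k) is None]
        if missing:
            raise ValueError(
                f"topology {topology.value} requires constants {missing}")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: oral bolus (duration 0) or IV infusion."""

    time: float          # day
    route: str           # "oral" | "iv"
    amount: float        # mg
    duration: float = 0.0  # day; 0 for bolus

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.amount <= 0:
            raise ValueError("event amount must be > 0")
        if self.route not in ("oral", "iv"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "oral" and self.duration != 0:
            raise ValueError("oral events must have duration 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class DoseSchedule:
    """Sorted list of dose events.

    Simultaneous same-route events are merged by summing amounts; ties are
    broken by input order, which makes schedule expansion deterministic.
    """

    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: dict[tuple[float, str, float], float] = {}
        order: list[tuple[float, str, float]] = []
        for ev in self.events:
            key = (ev.time, ev.route, ev.duration)
            if key not in merged:
                merged[key] = 0.0
                order.append(key)
            merged[key] += ev.amount
        events = [DoseEvent(t, r, merged[(t, r, d)], d) for (t, r, d) in order]
        self.events = sorted(events, key=lambda e: e.time)

    @property
    def last_time(self) -> float:
        if not self.events:
            return 0.0
        return max(e.time + e.duration for e in self.events)

    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)


#: named regimens from the clinical studies the model is fitted to
REGIMENS = ("weekly70", "daily10", "single70", "iv_khan", "none")


def build_schedule(regimen: str | Sequence[dict], horizon: float) -> DoseSchedule:
    """Expand a named regimen (or custom event list) over ``horizon`` days.

    ``weekly70``: 70 mg oral every 7 days starting day 0.
    ``daily10``: 10 mg oral every day starting day 0.
    ``single70``: one 70 mg oral dose at day 0.
    ``iv_khan``: 4 IV infusions of 7.5 mg over 12 h, one per day on 4
    consecutive days (30 mg total), the long-term urinary-excretion protocol.
    ``none``: empty schedule (untreated run).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if isinstance(regimen, str):
        if regimen == "weekly70":
            events = [DoseEvent(t, "oral", 70.0)
                      for t in np.arange(0.0, horizon, 7.0)]
        elif regimen == "daily10":
            events = [DoseEvent(t, "oral", 10.0)
                      for t in np.arange(0.0, horizon, 1.0)]
        elif regimen == "single70":
            events = [DoseEvent(0.0, "oral", 70.0)]
        elif regimen == "iv_khan":
            events = [DoseEvent(float(d), "iv", 7.5, 0.5) for d in range(4)]
        elif regimen == "none":
            events = []
        else:
            raise ValueError(f"unknown regimen {regimen!r}")
    else:
        events = [DoseEvent(e["t"], e.get("route", "oral"),
                            e["amount_mg"], e.get("duration_d", 0.0))
                  for e in regimen]
    return DoseSchedule(events)


def system_matrix(params: PKParams, topology: Topology) -> np.ndarray:
    """First-order exchange matrix A with d(state)/dt = A @ state (+ inputs).

    The oral route enters through the gut: the gut empties at k_CC and only
    the bioavailable fraction F reaches the central compartment, the
    remainder being (implicit) fecal loss.
    """
    params.require(topology)
    A = np.zeros((N_COMP, N_COMP))
    A[GUT, GUT] = -params.k_CC
    A[CC, GUT] = params.F * params.k_CC
    A[URINE, CC] = params.k_el_urine
    A[CC, CC] -= params.k_el_urine

    # CC -> BC in every topology (for 1c, BC is an absorbing non-urine sink)
    A[BC, CC] = params.k_BC
    A[CC, CC] -= params.k_BC
    if topology is not Topology.ONE_C:
        A[CC, BC] = params.k_el_BC
        A[BC, BC] -= params.k_el_BC

    if topology in (Topology.THREE_C_PARALLEL, Topology.FOUR_C):
        A[NCT, CC] = params.k_NCT
        A[CC, CC] -= params.k_NCT
        A[CC, NCT] = params.k_el_NCT
        A[NCT, NCT] -= params.k_el_NCT

    if topology in (Topology.THREE_C_SERIES, Topology.FOUR_C):
        A[IC, BC] = params.k_IC
        A[BC, BC] -= params.k_IC
        A[BC, IC] = params.k_el_IC
        A[IC, IC] -= params.k_el_IC
    return A


def pk_rhs(state: np.ndarray, t: float, params: PKParams,
           topology: Topology, infusion_rate: float = 0.0) -> np.ndarray:
    """Time derivative of the amounts vector.

    For IV input, the absorption term F*k_CC*Ale_Gut is replaced by the
    infusion rate (mg/day) entering the central compartment directly.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_COMP,):
        raise ValueError(f"state must have shape ({N_COMP},)")
    if np.any(state < 0):
        raise ValueError("negative state entries")
    A = system_matrix(params, topology)
    dy = A @ state
    dy[CC] += infusion_rate
    return dy


@dataclass
class PKTimeSeries:
    """Sampled trajectory of the compartmental amounts.

    ``amounts`` has one row per time point, columns in ``COMPARTMENTS``
    order.  Serum concentration is derived, never stored.
    """

    t: np.ndarray
    amounts: np.ndarray
    params: PKParams
    topology: Topology

    @property
    def serum_mg_per_L(self) -> np.ndarray:
        return self.amounts[:, CC] / self.params.V_c

    @property
    def serum_ng_per_mL(self) -> np.ndarray:
        return self.serum_mg_per_L * 1e3  # 1 mg/L = 1000 ng/mL

    @property
    def serum_mM(self) -> np.ndarray:
        # (mg/L) / (mg/mmol) = mmol/L = mM
        return self.serum_mg_per_L / self.params.molar_mass

    @property
    def cumulative_urine_mg(self) -> np.ndarray:
        return self.amounts[:, URINE]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.amounts,
                          columns=[f"{c}_mg" for c in COMPARTMENTS])
        df.insert(0, "time_d", self.t)
        df["serum_ng_ml"] = self.serum_ng_per_mL
        return df


def _event_boundaries(schedule: DoseSchedule, horizon: float) -> np.ndarray:
    """Times at which the input function changes (bolus jumps, infusion
    starts/stops), clipped to the horizon."""
    times = {0.0, horizon}
    for ev in schedule.events:
        if ev.time < horizon:
            times.add(ev.time)
        end = ev.time + ev.duration
        if 0 < end < horizon:
            times.add(end)
    return np.array(sorted(times))


def _infusion_rate(schedule: DoseSchedule, t0: float, t1: float) -> float:
    """Total IV input rate (mg/day) on the open interval (t0, t1).

    Infusions are piecewise constant; interval boundaries coincide with
    infusion starts/stops, so the rate is constant on each segment.
    """
    tm = 0.5 * (t0 + t1)
    rate = 0.0
    for ev in schedule.events:
        if ev.route == "iv" and ev.duration > 0 and ev.time <= tm < ev.time + ev.duration:
            rate += ev.amount / ev.duration
    return rate


def simulate_pk(params: PKParams, schedule: DoseSchedule, topology: Topology,
                horizon: float, t_eval: Iterable[float] | None = None,
                rtol: float = 1e-8, atol: float = 1e-10,
                method: str = "LSODA") -> PKTimeSeries:
    """Integrate the PK model with event-aware restarts at each dose time.

    Oral boluses are instantaneous jumps of the gut amount; infusions enter
    the central compartment at a constant rate over their duration.  With
    ``method="expm"`` the linear system is propagated exactly with matrix
    exponentials segment by segment (useful inside fitting loops); any other
    value is passed to :func:`scipy.integrate.solve_ivp`.
    """
    if horizon < schedule.last_time:
        raise ValueError("horizon must cover the last dose event")
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 501)
    t_eval = np.asarray(list(t_eval), dtype=float)
    if np.any(np.diff(t_eval) < 0) or t_eval[0] < 0 or t_eval[-1] > horizon:
        raise ValueError("t_eval must be sorted within [0, horizon]")

    A = system_matrix(params, topology)
    boundaries = _event_boundaries(schedule, horizon)
    bolus_at: dict[float, float] = {}
    iv_bolus_at: dict[float, float] = {}  # IV boluses (duration 0) enter CC
    for ev in schedule.events:
        if ev.route == "oral":
            bolus_at[ev.time] = bolus_at.get(ev.time, 0.0) + ev.amount
        elif ev.duration == 0:
            iv_bolus_at[ev.time] = iv_bolus_at.get(ev.time, 0.0) + ev.amount

    out = np.zeros((len(t_eval), N_COMP))
    state = np.zeros(N_COMP)

    for i in range(len(boundaries) - 1):
        t0, t1 = boundaries[i], boundaries[i + 1]
        if t0 in bolus_at:
            state[GUT] += bolus_at[t0]
        if t0 in iv_bolus_at:
            state[CC] += iv_bolus_at[t0]
        rate = _infusion_rate(schedule, t0, t1)
        sel = (t_eval >= t0) & (t_eval < t1) if i < len(boundaries) - 2 \
            else (t_eval >= t0) & (t_eval <= t1)
        # samples exactly at t0 see the post-dose state
        if method == "expm":
            _propagate_expm(A, state, t0, t1, rate, t_eval[sel], out, sel)
        else:
            _propagate_ivp(A, state, t0, t1, rate, t_eval[sel], out, sel,
                           method, rtol, atol)

    neg = out.min()
    if neg < -max(atol * 1e3, 1e-7):
        raise RuntimeError(f"negative amounts ({neg:.2e} mg) signal a "
                           "solver step-size problem; tighten tolerances")
    np.clip(out, 0.0, None, out=out)
    return PKTimeSeries(t=t_eval, amounts=out, params=params, topology=topology)


def _propagate_ivp(A, state, t0, t1, rate, times, out, sel, method, rtol, atol):
    b = np.zeros(N_COMP)
    b[CC] = rate

    def rhs(t, y):
        return A @ y + b

    if t1 - t0 <= 0:
        out[sel] = state
        return
    sol = solve_ivp(rhs, (t0, t1), state, method=method, rtol=rtol, atol=atol,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"PK solver failed on [{t0}, {t1}]: {sol.message}")
    if len(times):
        out[sel] = sol.sol(times).T
    state[:] = sol.y[:, -1]


def _propagate_expm(A, state, t0, t1, rate, times, out, sel):
    """Exact propagation of dx/dt = A x + b via the augmented exponential."""
    from scipy.linalg import expm

    M = np.zeros((N_COMP + 1, N_COMP + 1))
    M[:N_COMP, :N_COMP] = A
    M[CC, N_COMP] = rate
    aug = np.append(state, 1.0)
    if len(times):
        res = np.empty((len(times), N_COMP))
        for j, tt in enumerate(times):
            res[j] = (expm(M * (tt - t0)) @ aug)[:N_COMP]
        out[sel] = res
    state[:] = (expm(M * (t1 - t0)) @ aug)[:N_COMP]


def observables(ts: PKTimeSeries) -> dict[str, np.ndarray]:
    """Serum concentration (ng/mL) and cumulative urinary excretion (mg)."""
    if ts.params.V_c <= 0:
        raise ValueError("V_c must be > 0")
    return {"serum_ng_ml": ts.serum_ng_per_mL,
            "cumulative_urine_mg": ts.cumulative_urine_mg}


def mg_per_L_to_mM(conc: float | np.ndarray,
                   molar_mass: float = MOLAR_MASS_ALENDRONATE):
    return np.asarray(conc) / molar_mass


__all__ = [
    "MOLAR_MASS_ALENDRONATE", "COMPARTMENTS", "Topology", "PKParams",
    "DoseEvent", "DoseSchedule", "REGIMENS", "build_schedule",
    "system_matrix", "pk_rhs", "PKTimeSeries", "simulate_pk", "observables",
    "mg_per_L_to_mM",
]
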