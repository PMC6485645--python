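"""Stochastic three-type logistic branching process of PDAC progression.

A virtual patient starts from a single type-0 cell in the primary site.
Type-0 cells divide at rate ``r0 * (1 - (w + x)/LAI)`` and die at rate
``d0``; each division produces a disseminating type-1 daughter with
probability ``u``.  Type-1 cells divide/die at ``r1 * (1 - (w+x)/LAI)`` /
``d1`` and seed new metastatic colonies at rate ``q`` per cell per month.
Colony ``i`` grows logistically toward its own carrying capacity ``MAI_i``
(drawn i.i.d. at seeding time) at rates ``r2 * (1 - y_i/MAI_i)`` / ``d2``.
Death rates default to 1% of the corresponding division rate.  When the
total number of tumor cells reaches ``M_diag`` the tumor is diagnosed;
when it reaches ``M_death`` the virtual patient dies.

Small compartments are simulated stochastically, large ones
deterministically (see :mod:`pdacsim._kernel` for the hybrid scheme).
Founder lineages that go extinct before establishing are restarted with a
fresh seed, reflecting that every modeled patient develops a tumor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .growth import volume_from_cells
from .synthetic import LogNormalDist, lognormal_from_quartiles

__all__ = [
    "MetastasisCapacitySampler",
    "default_mai_sampler",
    "default_lai_sampler",
    "PatientParameters",
    "TumorState",
    "Trajectory",
    "total_cells",
    "advance",
    "run_to_event",
]

_DT_TOL = 1e-9


@dataclass(frozen=True)
class MetastasisCapacitySampler:
    """Distribution of per-colony carrying capacities (MAI, cells).

    Either log-normal (``values is None``) or empirical (bootstrap of the
    given capacity values, e.g. a column of a per-patient parameter table).
    """

    mu: float = 0.0
    sigma: float = 0.0
    values: Optional[np.ndarray] = None

    @classmethod
    def lognormal(cls, dist: LogNormalDist) -> "MetastasisCapacitySampler":
        return cls(mu=dist.mu, sigma=dist.sigma)

    @classmethod
    def from_quartiles(cls, q1: float, median: float, q3: float) -> "MetastasisCapacitySampler":
        return cls.lognormal(lognormal_from_quartiles(median, q1, q3))

    @classmethod
    def empirical(cls, values: Sequence[float]) -> "MetastasisCapacitySampler":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0 or np.any(arr <= 0):
            raise ValueError("empirical MAI values must be positive and non-empty")
        return cls(values=arr)

    def kernel_args(self):
        if self.values is not None:
            return 1, 0.0, 0.0, self.values
        return 0, self.mu, self.sigma, np.empty(0)


def default_mai_sampler() -> MetastasisCapacitySampler:
    """Synthetic stand-in MAI distribution: quartiles 5e8/2e9/8e9 cells."""
    return MetastasisCapacitySampler.from_quartiles(5e8, 2e9, 8e9)


def default_lai_sampler() -> LogNormalDist:
    """Synthetic stand-in LAI distribution (cells): quartiles 6e9/1.2e10/2.4e10.

    This spread reproduces the reported clinical LAI strata frequencies
    (<5e9, 5-10e9, 10-20e9, >=2e10).
    """
    return lognormal_from_quartiles(1.2e10, 6e9, 2.4e10)


@dataclass(frozen=True)
class PatientParameters:
    """All stochastic-process rates and thresholds for one virtual case.

    Units: rates 1/month, cell thresholds in cells.  ``u`` is the
    probability of a disseminating daughter per type-0 division; ``q`` the
    seeding rate per type-1 cell per month.  Defaults are the published
    simulation settings (u = 6.31e-5, q = 6.31e-7, r0 = r1 = 0.28,
    r2 = 1.16, death rate = division rate / 100, M_diag = 10^9.47,
    M_death = 10^10.6).
    """

    u: float = 6.31e-5
    q: float = 6.31e-7
    r0: float = 0.28
    r1: float = 0.28
    r2: float = 1.16
    d0: Optional[float] = None
    d1: Optional[float] = None
    d2: Optional[float] = None
    lai: float = 1.2e10
    mai_sampler: MetastasisCapacitySampler = field(default_factory=default_mai_sampler)
    m_diag: float = 10**9.47
    m_death: float = 10**10.6
    met_detect_threshold: float = 1e8
    hybrid_threshold: float = 1e4
    max_dt: float = 1.0 / 30.0
    horizon_months: float = 600.0
    restart_below: float = 100.0
    restart_on_extinction: bool = True
    deterministic_only: bool = False
    stromal_fraction: float = 0.8
    cells_per_cm3: float = 1e9
    max_colonies: int = 20000

    def __post_init__(self) -> None:
        if not 0 <= self.u <= 1:
            raise ValueError("u must be a probability")
        if self.q < 0:
            raise ValueError("q must be non-negative")
        for nm in ("r0", "r1", "r2"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        for nm, r in (("d0", self.r0), ("d1", self.r1), ("d2", self.r2)):
            if getattr(self, nm) is None:
                object.__setattr__(self, nm, r / 100.0)
            elif getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if not 0 < self.m_diag < self.m_death:
            raise ValueError("thresholds must satisfy 0 < M_diag < M_death")
        if self.lai <= 0:
            raise ValueError("LAI must be positive")
        if self.max_dt <= 0 or self.max_dt > 1.0 / 30.0 + _DT_TOL:
            raise ValueError("max_dt must lie in (0, 1/30] month")


@dataclass
class TumorState:
    """Instantaneous cell counts of one virtual case.

    ``y``/``mai``/``tbirth`` are aligned per-colony arrays; extinct
    colonies are retained with ``y = 0`` (the colony list only grows).
    """

    t: float = 0.0
    w: float = 1.0
    x: float = 0.0
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    mai: np.ndarray = field(default_factory=lambda: np.empty(0))
    tbirth: np.ndarray = field(default_factory=lambda: np.empty(0))
    diagnosed: bool = False
    alive: bool = True
    first_type1_time: float = float("nan")

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.mai = np.asarray(self.mai, dtype=float)
        self.tbirth = np.asarray(self.tbirth, dtype=float)
        if self.w < 0 or self.x < 0 or np.any(self.y < 0):
            raise ValueError("cell counts must be non-negative")

    @property
    def n_mets_total(self) -> int:
        return int(self.y.size)

    def n_mets_detectable(self, threshold: float) -> int:
        return int(np.count_nonzero(self.y >= threshold))

    @property
    def largest_met(self) -> float:
        return float(self.y.max()) if self.y.size else 0.0

    def copy(self) -> "TumorState":
        return TumorState(
            t=self.t,
            w=self.w,
            x=self.x,
            y=self.y.copy(),
            mai=self.mai.copy(),
            tbirth=self.tbirth.copy(),
            diagnosed=self.diagnosed,
            alive=self.alive,
            first_type1_time=self.first_type1_time,
        )

    def primary_volume_cm3(self, params: "PatientParameters") -> float:
        return volume_from_cells(
            self.w + self.x, params.cells_per_cm3, params.stromal_fraction
        )


def total_cells(state: TumorState) -> float:
    """Total tumor burden: w + x + sum of all colony sizes."""
    return float(state.w + state.x + state.y.sum())


@dataclass
class Trajectory:
    """Sampled time course of one simulated case with its event log."""

    times: np.ndarray
    w: np.ndarray
    x: np.ndarray
    total: np.ndarray
    n_mets_total: np.ndarray
    n_mets_detectable: np.ndarray
    largest_met: np.ndarray
    events: List[Tuple[float, str, float]]
    final_state: TumorState
    diagnosis_time: Optional[float] = None
    death_time: Optional[float] = None
    censored: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_months": self.times,
                "w": self.w,
                "x": self.x,
                "n_mets_total": self.n_mets_total,
                "n_mets_detectable": self.n_mets_detectable,
                "largest_met_cells": self.largest_met,
                "total_cells": self.total,
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["t_months", "event", "value"])


# --------------------------------------------------------------------------
# stepping drivers


class _Buffers:
    """Preallocated colony arrays shared across kernel calls of one run."""

    def __init__(self, state: TumorState, cap: int):
        cap = max(cap, state.y.size + 16)
        self.y = np.zeros(cap)
        self.mai = np.ones(cap)
        self.tb = np.zeros(cap)
        n = state.y.size
        self.y[:n] = state.y
        self.mai[:n] = state.mai
        self.tb[:n] = state.tbirth
        self.n_col = n
        self.state_vec = np.array(
            [state.w, state.x, 0.0, state.first_type1_time if not math.isnan(state.first_type1_time) else -1.0]
        )

    def to_state(self, t: float, template: TumorState) -> TumorState:
        fx = self.state_vec[3]
        return TumorState(
            t=t,
            w=self.state_vec[0],
            x=self.state_vec[1],
            y=self.y[: self.n_col].copy(),
            mai=self.mai[: self.n_col].copy(),
            tbirth=self.tb[: self.n_col].copy(),
            diagnosed=template.diagnosed,
            alive=template.alive,
            first_type1_time=float("nan") if fx < 0 else fx,
        )


def _span(buf: _Buffers, params: PatientParameters, t0, t1, rates0, rates1, stop_total):
    mode, mu, sig, emp = params.mai_sampler.kernel_args()
    status, t, t_cross, n_col = _kernel.advance_span(
        t0,
        t1,
        buf.state_vec,
        buf.y,
        buf.mai,
        buf.tb,
        buf.n_col,
        params.u,
        params.q,
        params.d0,
        params.d1,
        params.d2,
        params.lai,
        0.0 if params.deterministic_only else params.hybrid_threshold,
        params.deterministic_only,
        rates0[0],
        rates1[0],
        rates0[1],
        rates1[1],
        rates0[2],
        rates1[2],
        mode,
        mu,
        sig,
        emp,
        params.max_dt,
        stop_total,
    )
    buf.n_col = n_col
    if status == _kernel.COLONY_OVERFLOW:
        raise RuntimeError("colony buffer overflow; raise PatientParameters.max_colonies")
    return status, t, t_cross


def advance(
    state: TumorState,
    params: PatientParameters,
    dt: float,
    modifier: Optional[Callable[[float], Tuple[float, float, float]]] = None,
    seed: Optional[int] = None,
) -> TumorState:
    """Advance the state by one step of at most the configured maximum.

    ``modifier`` maps time (months) to the current effective division rates
    (r0', r1', r2'); negative on-treatment rates are accepted.  Steps longer
    than ``params.max_dt`` are refused (stability contract).  The kernel's
    global RNG drives the stochastic updates; pass ``seed`` to make a
    single call reproducible, or seed once per run via
    :func:`pdacsim._kernel.seed_kernel`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.max_dt + _DT_TOL:
        raise ValueError(
            f"dt={dt} exceeds the configured maximum step {params.max_dt}"
        )
    if seed is not None:
        _kernel.seed_kernel(seed)
    baseline = (params.r0, params.r1, params.r2)
    r0s = modifier(state.t) if modifier else baseline
    r1s = modifier(state.t + dt) if modifier else baseline
    buf = _Buffers(state, params.max_colonies)
    _span(buf, params, state.t, state.t + dt, r0s, r1s, np.inf)
    return buf.to_state(state.t + dt, state)


def _record(traj_lists, t, buf: _Buffers, det_thresh):
    y = buf.y[: buf.n_col]
    traj_lists["times"].append(t)
    traj_lists["w"].append(buf.state_vec[0])
    traj_lists["x"].append(buf.state_vec[1])
    traj_lists["total"].append(buf.state_vec[0] + buf.state_vec[1] + y.sum())
    traj_lists["n_mets_total"].append(buf.n_col)
    traj_lists["n_mets_detectable"].append(int(np.count_nonzero(y >= det_thresh)))
    traj_lists["largest_met"].append(float(y.max()) if buf.n_col else 0.0)


def run_to_event(
    params: PatientParameters,
    stop: str = "diagnosis",
    seed: int = 0,
    schedule=None,
    initial_state: Optional[TumorState] = None,
    record_dt: float = 0.5,
) -> Trajectory:
    """Simulate until the total burden crosses a threshold.

    ``stop`` is ``"diagnosis"`` (total >= M_diag) or ``"death"``
    (total >= M_death).  Without ``initial_state`` the run starts from a
    single type-0 founder cell at t = 0; founder lineages that go extinct
    are restarted with a fresh seed (conditioning on tumor establishment),
    unless disabled.  ``schedule`` is a compiled treatment
    :class:`~pdacsim.treatment.RateSchedule` on the same clock as the run.
    If no crossing occurs within the horizon the trajectory is returned
    flagged ``censored``.
    """
    if stop not in ("diagnosis", "death"):
        raise ValueError("stop must be 'diagnosis' or 'death'")
    threshold = params.m_diag if stop == "diagnosis" else params.m_death
    seedseq = np.random.SeedSequence(seed)
    attempts = 0
    while True:
        attempts += 1
        kernel_seed = int(seedseq.generate_state(attempts, dtype=np.uint32)[-1])
        _kernel.seed_kernel(kernel_seed)
        traj = _run_once(params, threshold, stop, schedule, initial_state, record_dt)
        if traj is not None:
            return traj
        if attempts > 1000:
            raise RuntimeError("founder lineage failed to establish in 1000 attempts")


def _run_once(params, threshold, stop, schedule, initial_state, record_dt):
    from .treatment import RateSchedule

    if initial_state is None:
        state0 = TumorState(t=0.0, w=1.0, x=0.0)
    else:
        state0 = initial_state.copy()
    t0 = state0.t
    if schedule is None:
        schedule = RateSchedule.constant((params.r0, params.r1, params.r2), params.horizon_months + t0)
    buf = _Buffers(state0, params.max_colonies)
    lists = {k: [] for k in ("times", "w", "x", "total", "n_mets_total", "n_mets_detectable", "largest_met")}
    events: List[Tuple[float, str, float]] = []
    _record(lists, t0, buf, params.met_detect_threshold)

    horizon = t0 + params.horizon_months
    event_queue = sorted((e for e in schedule.events if e[0] >= t0), key=lambda e: e[0])
    eq_i = 0
    grid_next = t0 + record_dt
    t = t0
    n_col_seen = buf.n_col
    crossed_at = None
    extinct = False
    if lists["total"][0] >= threshold:
        crossed_at = t0  # degenerate threshold: already crossed at entry

    while crossed_at is None and t < horizon - 1e-9:
        stops = [horizon, grid_next]
        if eq_i < len(event_queue):
            stops.append(event_queue[eq_i][0])
        stops.append(schedule.next_breakpoint(t))
        t_next = min(s for s in stops if s > t + 1e-12)
        status, t_reached, t_cross = _span(
            buf,
            params,
            t,
            t_next,
            schedule.rates_at(t),
            schedule.rates_at(t_next),
            threshold,
        )
        t = t_reached
        if buf.n_col > n_col_seen:
            for i in range(n_col_seen, buf.n_col):
                events.append((buf.tb[i], "seeding", buf.mai[i]))
            n_col_seen = buf.n_col
        fx = buf.state_vec[3]
        if fx >= 0 and not any(e[1] == "first_type1" for e in events):
            events.append((fx, "first_type1", 0.0))
        if status == _kernel.CROSSED:
            crossed_at = t_cross
            _record(lists, t, buf, params.met_detect_threshold)
            break
        if status == _kernel.EXTINCT:
            extinct = True
            break
        # reached t_next
        while grid_next <= t + 1e-9:
            _record(lists, t, buf, params.met_detect_threshold)
            grid_next += record_dt
        while eq_i < len(event_queue) and event_queue[eq_i][0] <= t + 1e-9:
            et, kind, value = event_queue[eq_i]
            if kind == "surgery":
                buf.state_vec[0] *= value
                buf.state_vec[1] *= value
            elif kind == "rtx_fraction":
                buf.state_vec[0] *= value
                buf.state_vec[1] *= value
            events.append((et, kind, value))
            eq_i += 1

    if extinct and initial_state is None and params.restart_on_extinction:
        return None  # restart the founder with a fresh seed

    final = buf.to_state(t, state0)
    if extinct:
        events.append((t, "extinct", 0.0))
    traj = Trajectory(
        times=np.array(lists["times"]),
        w=np.array(lists["w"]),
        x=np.array(lists["x"]),
        total=np.array(lists["total"]),
        n_mets_total=np.array(lists["n_mets_total"], dtype=int),
        n_mets_detectable=np.array(lists["n_mets_detectable"], dtype=int),
        largest_met=np.array(lists["largest_met"]),
        events=sorted(events, key=lambda e: e[0]),
        final_state=final,
    )
    if crossed_at is not None:
        if stop == "diagnosis":
            traj.diagnosis_time = float(crossed_at)
            final.diagnosed = True
            events.append((crossed_at, "diagnosis", 0.0))
        else:
            traj.death_time = float(crossed_at)
            final.alive = False
            events.append((crossed_at, "death", 0.0))
        traj.events = sorted(events, key=lambda e: e[0])
    else:
        traj.censored = True
    return traj
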