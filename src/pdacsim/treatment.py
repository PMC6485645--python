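"""Treatment operators: chemotherapy, linear-quadratic radiotherapy, surgery.

Chemotherapy substitutes the growth rates of tumor cells with per-patient
on-treatment draws for the duration of each drug interval; drugs modify
growth rates reversibly, with six reversibility scenarios controlling how
rates return to baseline after discontinuation (instantaneous full reversal;
linear recovery over 2 weeks / 1 month / 2 months; instantaneous recovery to
95% / 90% of the original rate).

Radiotherapy follows the linear-quadratic model: each fraction of dose D
multiplies the primary compartments by the surviving fraction
``exp(-(omega*D + xi*D^2))`` with ``xi = omega/10``; the default course is
conventional long-course 3D-CRT, 30 fractions of 1.8 Gy (54 Gy total), five
fractions per week.  Radiotherapy is local: metastases are unaffected.  The
absolute ``omega`` is a free clinical parameter (default 0.3/Gy).

Surgery instantaneously reduces the primary compartments to a remnant
fraction ``epsilon``, sampled log-uniformly from [1e-5, 1e-1]; metastases
are untouched.
"""

from __future__ import annotations

import bisect
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .growth import TreatmentContext
from .simulator import PatientParameters, TumorState

__all__ = [
    "Drug",
    "Modality",
    "RegimenInterval",
    "Regimen",
    "RTxCourse",
    "ChemoEffect",
    "REVERSIBILITY_SCENARIOS",
    "apply_surgery",
    "sample_surgical_remnant",
    "rtx_surviving_fraction",
    "effective_rates",
    "RateSchedule",
    "compile_schedule",
    "standard_regimen",
]

#: Drug identity reuses the treatment-context enum (excluding "none").
Drug = TreatmentContext

WEEK_MONTHS = 7.0 / 30.4375  # mean-month convention

#: Reversibility scenarios: id -> (recovery_time months, recovery_level).
#: 1 = instantaneous full reversal; 2-4 = linear recovery to the original
#: rate over 2 weeks / 1 month / 2 months; 5-6 = instantaneous recovery to
#: 95% / 90% of the original rate.
REVERSIBILITY_SCENARIOS: Dict[int, Tuple[float, float]] = {
    1: (0.0, 1.0),
    2: (2 * WEEK_MONTHS, 1.0),
    3: (1.0, 1.0),
    4: (2.0, 1.0),
    5: (0.0, 0.95),
    6: (0.0, 0.90),
}


class Modality(str, enum.Enum):
    NONE = "none"  # observation / rest
    CTX = "CTx"
    RTX = "RTx"
    SURGERY = "surgery"


@dataclass(frozen=True)
class RegimenInterval:
    start: float  # months relative to diagnosis
    duration: float
    modality: Modality
    drug: Optional[Drug] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        if self.drug is not None:
            drug = Drug(self.drug)
            if drug is TreatmentContext.NONE:
                raise ValueError("CTx interval requires an actual drug")
            object.__setattr__(self, "drug", drug)
        if self.start < 0 or self.duration < 0:
            raise ValueError("interval start and duration must be non-negative")
        if self.modality is Modality.SURGERY and self.duration != 0:
            raise ValueError("surgery is instantaneous (zero duration)")
        if self.modality is Modality.CTX and self.drug is None:
            raise ValueError("CTx interval requires a drug")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered treatment intervals on the post-diagnosis clock.

    ``scenario`` selects the growth-rate reversibility behavior after each
    chemotherapy discontinuation.
    """

    intervals: Tuple[RegimenInterval, ...]
    scenario: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if self.scenario not in REVERSIBILITY_SCENARIOS:
            raise ValueError(f"unknown reversibility scenario {self.scenario}")
        ivs = self.intervals
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.start:
                raise ValueError("intervals must be chronological")
        spans = [iv for iv in ivs if iv.duration > 0]
        for a, b in zip(spans, spans[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("treatment intervals must not overlap")

    @property
    def ctx_intervals(self) -> List[RegimenInterval]:
        return [iv for iv in self.intervals if iv.modality is Modality.CTX]

    @property
    def drugs(self) -> List[Drug]:
        seen = []
        for iv in self.ctx_intervals:
            if iv.drug not in seen:
                seen.append(iv.drug)
        return seen


@dataclass(frozen=True)
class RTxCourse:
    """Fractionated radiotherapy course (linear-quadratic cell kill).

    ``alpha`` (omega) is in 1/Gy; beta (xi) is enforced as alpha/10.
    """

    n_fractions: int = 30
    dose_per_fraction: float = 1.8
    alpha: float = 0.3
    fractions_per_week: int = 5

    def __post_init__(self) -> None:
        if self.dose_per_fraction <= 0 and self.n_fractions > 0:
            raise ValueError("dose per fraction must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_fractions < 0 or self.fractions_per_week <= 0:
            raise ValueError("invalid fraction schedule")

    @property
    def beta(self) -> float:
        return self.alpha / 10.0

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.dose_per_fraction

    @property
    def duration_months(self) -> float:
        return self.n_fractions / self.fractions_per_week * WEEK_MONTHS


def rtx_surviving_fraction(course: RTxCourse, k_fractions: int) -> float:
    """Surviving fraction after ``k`` fractions: [exp(-(wD + xD^2))]^k."""
    if not 0 <= k_fractions <= course.n_fractions:
        raise ValueError("k_fractions must lie in [0, n_fractions]")
    d = course.dose_per_fraction
    sf1 = math.exp(-(course.alpha * d + course.beta * d * d))
    return sf1**k_fractions


@dataclass(frozen=True)
class ChemoEffect:
    """One patient's drawn on-treatment growth rates for one drug.

    ``primary_rate`` replaces r0 and r1, ``metastasis_rate`` replaces r2
    during treatment.  ``recovery_time``/``recovery_level`` implement the
    reversibility scenario after discontinuation.
    """

    drug: Drug
    primary_rate: float
    metastasis_rate: float
    recovery_time: float = 0.0
    recovery_level: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", Drug(self.drug))
        if not 0 < self.recovery_level <= 1:
            raise ValueError("recovery_level must lie in (0, 1]")
        if self.recovery_time < 0:
            raise ValueError("recovery_time must be non-negative")

    @classmethod
    def with_scenario(
        cls, drug: Drug, primary_rate: float, metastasis_rate: float, scenario: int
    ) -> "ChemoEffect":
        rt, lvl = REVERSIBILITY_SCENARIOS[scenario]
        return cls(drug, primary_rate, metastasis_rate, recovery_time=rt, recovery_level=lvl)


def apply_surgery(state: TumorState, epsilon: float) -> TumorState:
    """Resection: the primary compartments shrink to epsilon of their size.

    All metastases are unchanged.  The caller enforces that surgery is only
    offered to diagnosed, non-metastatic cases.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    new = state.copy()
    new.w *= epsilon
    new.x *= epsilon
    return new


def sample_surgical_remnant(
    rng: np.random.Generator, low: float = 1e-5, high: float = 1e-1
) -> float:
    """Draw the surgical remnant fraction, log-uniform on [1e-5, 1e-1]."""
    if not 0 < low < high <= 1:
        raise ValueError("require 0 < low < high <= 1")
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


# --------------------------------------------------------------------------
# compiled rate schedules


Rates = Tuple[float, float, float]


@dataclass
class RateSchedule:
    """Piecewise-linear effective division rates plus instantaneous events.

    ``segments`` are (t_start, t_end, rates_at_start, rates_at_end) with
    linear interpolation inside; ``events`` are (time, kind, value) with
    kind in {"surgery", "rtx_fraction"} and value the multiplicative factor
    applied to the primary compartments.
    """

    segments: List[Tuple[float, float, Rates, Rates]]
    events: List[Tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s[0])
        self.events = sorted(self.events, key=lambda e: e[0])
        self._starts = [s[0] for s in self.segments]

    @classmethod
    def constant(cls, rates: Rates, horizon: float) -> "RateSchedule":
        return cls(segments=[(0.0, horizon, tuple(rates), tuple(rates))])

    def rates_at(self, t: float) -> Rates:
        if not self.segments:
            raise ValueError("empty schedule")
        i = bisect.bisect_right(self._starts, t) - 1
        if i < 0:
            return self.segments[0][2]
        ta, tb, ra, rb = self.segments[i]
        if t >= tb:
            return rb
        f = (t - ta) / (tb - ta) if tb > ta else 0.0
        return tuple(a + (b - a) * f for a, b in zip(ra, rb))

    def next_breakpoint(self, t: float) -> float:
        for ta, tb, _, _ in self.segments:
            if ta > t + 1e-12:
                return ta
            if tb > t + 1e-12:
                return tb
        return math.inf

    def shifted(self, offset: float) -> "RateSchedule":
        return RateSchedule(
            segments=[(ta + offset, tb + offset, ra, rb) for ta, tb, ra, rb in self.segments],
            events=[(t + offset, k, v) for t, k, v in self.events],
        )


def _as_effect_map(
    chemo: Union[ChemoEffect, Mapping[Drug, ChemoEffect], None], regimen: Regimen
) -> Dict[Drug, ChemoEffect]:
    if chemo is None:
        if regimen.ctx_intervals:
            raise ValueError("regimen contains CTx intervals but no chemo effects given")
        return {}
    if isinstance(chemo, ChemoEffect):
        return {d: replace(chemo, drug=d) for d in regimen.drugs} or {chemo.drug: chemo}
    out = {}
    for d in regimen.drugs:
        if d not in chemo:
            raise ValueError(f"no chemo effect provided for drug {d.value}")
        out[d] = chemo[d]
    return out


def compile_schedule(
    params: PatientParameters,
    regimen: Regimen,
    chemo: Union[ChemoEffect, Mapping[Drug, ChemoEffect], None] = None,
    rtx_course: Optional[RTxCourse] = None,
    surgical_remnant: Optional[float] = None,
    horizon: Optional[float] = None,
    t_offset: float = 0.0,
) -> RateSchedule:
    """Compile a regimen into a piecewise-linear rate schedule plus events.

    The schedule clock starts at diagnosis (shift with ``t_offset`` to
    align with an ongoing simulation clock).  On-treatment rates come from
    the per-patient ``chemo`` draws; after each discontinuation the rates
    ramp linearly from the on-treatment values back to
    ``recovery_level * baseline`` over ``recovery_time`` months.
    """
    horizon = params.horizon_months if horizon is None else horizon
    baseline: Rates = (params.r0, params.r1, params.r2)
    effects = _as_effect_map(chemo, regimen)

    segments: List[Tuple[float, float, Rates, Rates]] = []
    events: List[Tuple[float, str, float]] = []
    cur_t = 0.0
    cur_rates: Rates = baseline

    def add_const(t_end: float, rates: Rates) -> None:
        nonlocal cur_t
        if t_end > cur_t + 1e-12:
            segments.append((cur_t, t_end, rates, rates))
            cur_t = t_end

    def add_ramp(t_end: float, r_from: Rates, r_to: Rates) -> Rates:
        nonlocal cur_t
        if t_end > cur_t + 1e-12:
            segments.append((cur_t, t_end, r_from, r_to))
            cur_t = t_end
        return r_to

    pending_ramp: Optional[Tuple[float, Rates, Rates]] = None  # (t_done, from, to)
    resting_rates: Rates = baseline

    def settle_until(t: float) -> Rates:
        """Emit off-treatment segments (ramp then plateau) up to time t."""
        nonlocal pending_ramp, resting_rates
        if pending_ramp is not None:
            t_done, r_from, r_to = pending_ramp
            if t <= t_done:
                # truncated ramp: interpolate the reached level
                f = (t - cur_t) / (t_done - cur_t) if t_done > cur_t else 1.0
                r_mid = tuple(a + (b - a) * f for a, b in zip(r_from, r_to))
                add_ramp(t, r_from, r_mid)
                pending_ramp = None
                return r_mid
            add_ramp(t_done, r_from, r_to)
            pending_ramp = None
            resting_rates = r_to
        add_const(t, resting_rates)
        return resting_rates

    for iv in regimen.intervals:
        if iv.modality is Modality.CTX:
            eff = effects[iv.drug]
            settle_until(iv.start)
            on: Rates = (eff.primary_rate, eff.primary_rate, eff.metastasis_rate)
            add_const(iv.end, on)
            target: Rates = tuple(eff.recovery_level * r for r in baseline)
            if eff.recovery_time > 1e-12:
                pending_ramp = (iv.end + eff.recovery_time, on, target)
            else:
                resting_rates = target
        elif iv.modality is Modality.SURGERY:
            if surgical_remnant is None:
                raise ValueError("regimen contains surgery but no remnant fraction given")
            events.append((iv.start, "surgery", float(surgical_remnant)))
        elif iv.modality is Modality.RTX:
            course = rtx_course or RTxCourse()
            if course.n_fractions > 0:
                sf1 = rtx_surviving_fraction(course, 1)
                span = iv.duration if iv.duration > 0 else course.duration_months
                spacing = span / course.n_fractions
                for j in range(course.n_fractions):
                    events.append((iv.start + (j + 1) * spacing, "rtx_fraction", sf1))
        # Modality.NONE: explicit observation; no segment change

    settle_until(horizon)
    sched = RateSchedule(segments=segments, events=events)
    return sched.shifted(t_offset) if t_offset else sched


def effective_rates(
    params: PatientParameters,
    regimen: Regimen,
    chemo: Union[ChemoEffect, Mapping[Drug, ChemoEffect], None],
    t: float,
) -> Rates:
    """Effective division rates (r0', r1', r2') at time t after diagnosis."""
    sched = compile_schedule(params, regimen, chemo, horizon=max(t + 1.0, 1.0))
    return sched.rates_at(t)


# --------------------------------------------------------------------------
# the standard trial regimens


def standard_regimen(
    number: int,
    drug: Drug = Drug.FFX,
    second_drug: Drug = Drug.GEM,
    scenario: int = 1,
    rtx_course: Optional[RTxCourse] = None,
) -> Regimen:
    """The nine standard in silico trial regimens.

    1: induction CTx months 0-3, long-course RTx, adjuvant CTx 4.5-7.5
    2: CTx 0-6                       (LAPC comparator of 1)
    3: neoadjuvant CTx 0-4, surgery at 4, adjuvant CTx 4-10
    4: surgery at 0, adjuvant CTx 0-6
    5: observation only
    6: CTx 0-2 and 4-6 (two-month drug holiday in months 2-4)
    7: CTx 0-4
    8: CTx 0-6
    9: first-line drug 0-4, second-line drug 4-6
    """
    course = rtx_course or RTxCourse()
    c = Modality.CTX
    if number == 1:
        ivs = [
            RegimenInterval(0.0, 3.0, c, drug),
            RegimenInterval(3.0, course.duration_months, Modality.RTX),
            RegimenInterval(4.5, 3.0, c, drug),
        ]
    elif number == 2:
        ivs = [RegimenInterval(0.0, 6.0, c, drug)]
    elif number == 3:
        ivs = [
            RegimenInterval(0.0, 4.0, c, drug),
            RegimenInterval(4.0, 0.0, Modality.SURGERY),
            RegimenInterval(4.0, 6.0, c, drug),
        ]
    elif number == 4:
        ivs = [
            RegimenInterval(0.0, 0.0, Modality.SURGERY),
            RegimenInterval(0.0, 6.0, c, drug),
        ]
    elif number == 5:
        ivs = []
    elif number == 6:
        ivs = [
            RegimenInterval(0.0, 2.0, c, drug),
            RegimenInterval(4.0, 2.0, c, drug),
        ]
    elif number == 7:
        ivs = [RegimenInterval(0.0, 4.0, c, drug)]
    elif number == 8:
        ivs = [RegimenInterval(0.0, 6.0, c, drug)]
    elif number == 9:
        ivs = [
            RegimenInterval(0.0, 4.0, c, drug),
            RegimenInterval(4.0, 2.0, c, second_drug),
        ]
    else:
        raise ValueError("regimen number must be 1-9")
    return Regimen(intervals=tuple(ivs), scenario=scenario, label=f"regimen {number}")
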