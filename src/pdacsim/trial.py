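"""In silico clinical trials: virtual patients, triage, regimens, endpoints.

A trial draws virtual cases from a population model (per-patient LAI,
diagnosis threshold, metastasis capacities and on-treatment growth rates),
simulates each from a single founder cell to diagnosis, triages it by the
guideline rule (any detectable metastasis -> systemic therapy only;
otherwise surgery/chemoradiation candidates split into resectable vs
locally advanced by primary size), filters by the design's eligibility,
randomizes eligible cases across arms, applies each arm's regimen and runs
to death.  Overall survival is months from diagnosis to reaching the fatal
burden M_death.  Endpoints include Kaplan-Meier estimates, pairwise
log-rank tests (lifelines) and progression-phenotype summaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .growth import LesionClass, TreatmentContext, volume_from_cells
from .simulator import (
    MetastasisCapacitySampler,
    PatientParameters,
    TumorState,
    Trajectory,
    default_lai_sampler,
    default_mai_sampler,
    run_to_event,
)
from .synthetic import DEFAULT_RATE_DISTRIBUTIONS, LogNormalDist, NormalDist
from .stats import polyserial_correlation
from .treatment import (
    ChemoEffect,
    Drug,
    Modality,
    Regimen,
    RTxCourse,
    compile_schedule,
    sample_surgical_remnant,
)

__all__ = [
    "TriageCategory",
    "triage_at_diagnosis",
    "PopulationModel",
    "TrialDesign",
    "TrialResult",
    "run_trial",
    "summarize_phenotype",
    "MET_COUNT_BIN_EDGES",
    "COMPLICATION_VOLUME_CM3",
    "LAI_STRATA_CUTS_CELLS",
]

#: Primary-tumor volume above which local complications are assumed (proxy).
COMPLICATION_VOLUME_CM3 = 65.0

#: Metastasis-count bin edges: <=10, 10-50, >=50.
MET_COUNT_BIN_EDGES = (10, 50)

#: LAI strata cuts in cells: <5e9, 5-10e9, 10-20e9, >=2e10.
LAI_STRATA_CUTS_CELLS = (5e9, 10e9, 20e9)


class TriageCategory(str, enum.Enum):
    NON_METASTATIC_RESECTABLE = "non_metastatic_resectable"
    LAPC = "LAPC"
    METASTATIC = "metastatic"


def triage_at_diagnosis(
    state: TumorState,
    params: PatientParameters,
    resectable_volume_threshold_cm3: float = 20.0,
) -> TriageCategory:
    """Guideline triage at the diagnosis crossing.

    Metastatic iff any colony has reached the detection threshold
    (inclusive); otherwise non-metastatic cases split into resectable vs
    locally advanced (LAPC) by the primary-tumor volume.
    """
    if state.n_mets_detectable(params.met_detect_threshold) > 0:
        return TriageCategory.METASTATIC
    if state.primary_volume_cm3(params) > resectable_volume_threshold_cm3:
        return TriageCategory.LAPC
    return TriageCategory.NON_METASTATIC_RESECTABLE


@dataclass(frozen=True)
class PopulationModel:
    """Distributions from which virtual cases are drawn.

    Defaults are the published simulation settings where printed (diagnosis
    threshold 10^N(9.47, 0.29) cells, fatal burden 10^10.6) and synthetic
    stand-ins for the undeposited empirical distributions (LAI/MAI
    log-normals matched to the reported clinical strata; on-treatment
    growth-rate normals reflecting the reported treatment-effect ordering).
    """

    base: PatientParameters = field(default_factory=PatientParameters)
    lai_dist: LogNormalDist = field(default_factory=default_lai_sampler)
    mai_sampler: MetastasisCapacitySampler = field(default_factory=default_mai_sampler)
    m_diag_log10: NormalDist = NormalDist(9.47, 0.29)
    chemo_rates: Mapping[Drug, Tuple[NormalDist, NormalDist]] = field(
        default_factory=lambda: {
            d: (
                DEFAULT_RATE_DISTRIBUTIONS[(d, LesionClass.PRIMARY)],
                DEFAULT_RATE_DISTRIBUTIONS[(d, LesionClass.METASTASIS)],
            )
            for d in (Drug.GEM, Drug.FFX, Drug.GEM_NAB)
        }
    )
    fixed_m_diag: Optional[float] = None  # overrides the lognormal draw

    def draw_patient(self, rng: np.random.Generator) -> PatientParameters:
        lai = float(self.lai_dist.sample(rng))
        if self.fixed_m_diag is not None:
            m_diag = self.fixed_m_diag
        else:
            m_diag = 10.0 ** float(self.m_diag_log10.sample(rng))
        m_diag = min(m_diag, 0.99 * self.base.m_death)
        return replace(self.base, lai=lai, m_diag=m_diag, mai_sampler=self.mai_sampler)

    def draw_chemo(self, rng: np.random.Generator, drug: Drug, scenario: int) -> ChemoEffect:
        prim, met = self.chemo_rates[drug]
        return ChemoEffect.with_scenario(
            drug, float(prim.sample(rng)), float(met.sample(rng)), scenario
        )


@dataclass(frozen=True)
class TrialDesign:
    """One in silico trial: eligibility, arms, and size.

    ``eligibility`` is one of resectable, LAPC, metastatic, any.  Arms with
    surgery require resectable eligibility; arms with radiotherapy require
    non-metastatic eligibility (resectable or LAPC).
    """

    arms: Tuple[Tuple[str, Regimen], ...]
    n_per_arm: int = 50
    eligibility: str = "any"
    resectable_volume_threshold_cm3: float = 20.0
    rtx_course: RTxCourse = field(default_factory=RTxCourse)
    record_dt: float = 2.0
    max_screen_factor: int = 200

    def __post_init__(self) -> None:
        if len(self.arms) < 1:
            raise ValueError("trial needs at least one arm")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.eligibility not in ("resectable", "LAPC", "metastatic", "any"):
            raise ValueError(f"unknown eligibility {self.eligibility!r}")
        for label, reg in self.arms:
            mods = {iv.modality for iv in reg.intervals}
            if Modality.SURGERY in mods and self.eligibility != "resectable":
                raise ValueError(f"arm {label!r} contains surgery; eligibility must be resectable")
            if Modality.RTX in mods and self.eligibility not in ("resectable", "LAPC"):
                raise ValueError(f"arm {label!r} contains RTx; eligibility must be non-metastatic")

    def accepts(self, category: TriageCategory) -> bool:
        return {
            "any": True,
            "resectable": category is TriageCategory.NON_METASTATIC_RESECTABLE,
            "LAPC": category is TriageCategory.LAPC,
            "metastatic": category is TriageCategory.METASTATIC,
        }[self.eligibility]


@dataclass
class TrialResult:
    """Per-case records and survival endpoints of one simulated trial."""

    records: pd.DataFrame
    km: Dict[str, pd.DataFrame]
    pairwise_logrank: pd.DataFrame
    n_screened: int
    n_censored_prediagnosis: int

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby("arm")
        return pd.DataFrame(
            {
                "n": g.size(),
                "median_os_months": g["os_months"].median(),
                "mean_det_mets_final": g["n_mets_detectable_final"].mean(),
                "complication_rate": g["complication"].mean(),
            }
        )


def _km_table(durations, events) -> pd.DataFrame:
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time_months", "survival"]
    sf["at_risk"] = [kmf.event_table.at[t, "at_risk"] for t in kmf.event_table.index]
    return sf


def _pairwise_logrank(records: pd.DataFrame) -> pd.DataFrame:
    from lifelines.statistics import logrank_test

    arms = list(records["arm"].unique())
    rows = []
    for i, a in enumerate(arms):
        for b in arms[i + 1 :]:
            ra = records[records["arm"] == a]
            rb = records[records["arm"] == b]
            res = logrank_test(
                ra["os_months"], rb["os_months"],
                event_observed_A=ra["event"], event_observed_B=rb["event"],
            )
            rows.append(
                {
                    "arm_a": a,
                    "arm_b": b,
                    "statistic": float(res.test_statistic),
                    "p_value": float(res.p_value),
                }
            )
    return pd.DataFrame(rows)


def simulate_case(
    params: PatientParameters,
    regimen: Optional[Regimen],
    population: PopulationModel,
    rng: np.random.Generator,
    case_seed: int,
    rtx_course: Optional[RTxCourse] = None,
    record_dt: float = 2.0,
) -> Tuple[Trajectory, Trajectory, TriageCategory, Dict[str, float]]:
    """Simulate one case from founder cell through treatment to death.

    Returns (pre-diagnosis trajectory, post-diagnosis trajectory, triage
    category, per-case draws).  Raises if the case never reaches diagnosis
    within the horizon (callers screen for this).
    """
    dx = run_to_event(params, "diagnosis", seed=case_seed, record_dt=record_dt)
    if dx.censored:
        raise ValueError("case never reached diagnosis within the horizon")
    state = dx.final_state
    category = triage_at_diagnosis(state, params)
    draws: Dict[str, float] = {}
    schedule = None
    if regimen is not None and (regimen.intervals or regimen.ctx_intervals):
        effects = {}
        for drug in regimen.drugs:
            eff = population.draw_chemo(rng, drug, regimen.scenario)
            effects[drug] = eff
            draws[f"rate_primary_{drug.value}"] = eff.primary_rate
            draws[f"rate_met_{drug.value}"] = eff.metastasis_rate
        eps = None
        if any(iv.modality is Modality.SURGERY for iv in regimen.intervals):
            eps = sample_surgical_remnant(rng)
            draws["epsilon"] = eps
        schedule = compile_schedule(
            params,
            regimen,
            effects or None,
            rtx_course=rtx_course,
            surgical_remnant=eps,
            horizon=params.horizon_months,
            t_offset=state.t,
        )
    post = run_to_event(
        params,
        "death",
        seed=case_seed + 1,
        schedule=schedule,
        initial_state=state,
        record_dt=record_dt,
    )
    return dx, post, category, draws


def run_trial(
    design: TrialDesign,
    population: Optional[PopulationModel] = None,
    seed: int = 0,
) -> TrialResult:
    """Run one in silico trial; fully reproducible given the seed.

    Cases are simulated from a founder cell, triaged at diagnosis,
    eligibility-filtered, randomized to an arm still recruiting, treated
    per its regimen and run to death.  Aborts with a diagnostic if
    screening exhausts the budget before every arm is filled.
    """
    population = population or PopulationModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    arm_labels = [label for label, _ in design.arms]
    arm_reg = dict(design.arms)
    counts = {label: 0 for label in arm_labels}
    rows = []
    n_screened = 0
    n_censored = 0
    max_screen = design.max_screen_factor * design.n_per_arm * len(arm_labels)
    case_id = 0

    while min(counts.values()) < design.n_per_arm:
        if n_screened >= max_screen:
            empty = [a for a, c in counts.items() if c == 0]
            raise RuntimeError(
                "trial aborted: screening budget exhausted with arms "
                f"unfilled (counts={counts}); no eligible cases for {empty or 'some arms'}"
            )
        n_screened += 1
        case_id += 1
        params = population.draw_patient(rng)
        case_seed = int(rng.integers(0, 2**31 - 1))
        dx_traj = run_to_event(params, "diagnosis", seed=case_seed, record_dt=design.record_dt)
        if dx_traj.censored:
            n_censored += 1
            continue
        state = dx_traj.final_state
        category = triage_at_diagnosis(
            state, params, design.resectable_volume_threshold_cm3
        )
        if not design.accepts(category):
            continue
        open_arms = [a for a in arm_labels if counts[a] < design.n_per_arm]
        arm = open_arms[rng.integers(len(open_arms))]
        regimen = arm_reg[arm]
        effects = {}
        for drug in regimen.drugs:
            effects[drug] = population.draw_chemo(rng, drug, regimen.scenario)
        eps = None
        if any(iv.modality is Modality.SURGERY for iv in regimen.intervals):
            eps = sample_surgical_remnant(rng)
        schedule = (
            compile_schedule(
                params,
                regimen,
                effects or None,
                rtx_course=design.rtx_course,
                surgical_remnant=eps,
                horizon=params.horizon_months,
                t_offset=state.t,
            )
            if regimen.intervals
            else None
        )
        post = run_to_event(
            params,
            "death",
            seed=case_seed + 1,
            schedule=schedule,
            initial_state=state,
            record_dt=design.record_dt,
        )
        counts[arm] += 1
        final = post.final_state
        if post.death_time is not None:
            os_months = post.death_time - state.t
            event = True
        else:
            os_months = params.horizon_months
            event = False
        vol = final.primary_volume_cm3(params)
        rows.append(
            {
                "case_id": case_id,
                "arm": arm,
                "os_months": float(os_months),
                "event": event,
                "triage": category.value,
                "lai_cells": params.lai,
                "m_diag": params.m_diag,
                "primary_cells_final": final.w + final.x,
                "primary_volume_cm3_final": vol,
                "complication": bool(vol > COMPLICATION_VOLUME_CM3),
                "n_mets_detectable_dx": state.n_mets_detectable(params.met_detect_threshold),
                "n_mets_detectable_final": final.n_mets_detectable(params.met_detect_threshold),
                "n_mets_total_final": final.n_mets_total,
                "largest_met_cells_final": final.largest_met,
            }
        )

    records = pd.DataFrame(rows)
    km = {
        arm: _km_table(g["os_months"], g["event"]) for arm, g in records.groupby("arm")
    }
    logrank = _pairwise_logrank(records) if len(arm_labels) > 1 else pd.DataFrame()
    return TrialResult(
        records=records,
        km=km,
        pairwise_logrank=logrank,
        n_screened=n_screened,
        n_censored_prediagnosis=n_censored,
    )


def _met_count_bin(n: float) -> str:
    lo, hi = MET_COUNT_BIN_EDGES
    if n <= lo:
        return f"<={lo}"
    if n < hi:
        return f"{lo}-{hi}"
    return f">={hi}"


def _lai_stratum(lai: float) -> str:
    cuts = LAI_STRATA_CUTS_CELLS
    if lai < cuts[0]:
        return f"<{cuts[0]:.0e}"
    for lo, hi in zip(cuts, cuts[1:]):
        if lai < hi:
            return f"{lo:.0e}-{hi:.0e}"
    return f">={cuts[-1]:.0e}"


def summarize_phenotype(records: pd.DataFrame) -> Dict[str, object]:
    """Progression-phenotype summary of per-case trial records.

    Returns histograms of log10 primary burden, metastasis-count bins
    (<=10, 10-50, >=50) at diagnosis and at the final scan, LAI-stratified
    met counts, the complication-proxy frequency, the Spearman correlation
    of LAI with the final metastasis count, and the per-bin polyserial
    correlations between LAI and bin membership.
    """
    from scipy.stats import spearmanr

    if len(records) < 1:
        raise ValueError("need at least one record")
    rec = records.copy()
    rec["log10_primary_final"] = np.log10(np.maximum(rec["primary_cells_final"], 1.0))
    rec["met_bin_final"] = rec["n_mets_detectable_final"].map(_met_count_bin)
    rec["met_bin_dx"] = rec["n_mets_detectable_dx"].map(_met_count_bin)
    rec["lai_stratum"] = rec["lai_cells"].map(_lai_stratum)

    out: Dict[str, object] = {}
    out["log10_primary_hist"] = np.histogram(
        rec["log10_primary_final"], bins=np.arange(0.0, 12.5, 0.5)
    )
    out["met_bins_final"] = rec["met_bin_final"].value_counts().sort_index()
    out["met_bins_dx"] = rec["met_bin_dx"].value_counts().sort_index()
    out["lai_strata"] = (
        rec.groupby("lai_stratum")
        .agg(
            n=("case_id", "size"),
            mean_mets_final=("n_mets_detectable_final", "mean"),
            mean_largest_met=("largest_met_cells_final", "mean"),
            complication_rate=("complication", "mean"),
        )
    )
    out["complication_rate"] = float(rec["complication"].mean())
    if rec["n_mets_detectable_final"].nunique() > 1 and len(rec) > 2:
        rho, p = spearmanr(rec["lai_cells"], rec["n_mets_detectable_final"])
        out["spearman_lai_mets"] = float(rho)
        out["spearman_p"] = float(p)
    else:
        out["spearman_lai_mets"] = float("nan")
        out["spearman_p"] = float("nan")
    poly_rows = []
    for col, when in (("met_bin_dx", "diagnosis"), ("met_bin_final", "final_scan")):
        for b in sorted(rec[col].unique()):
            member = (rec[col] == b).astype(int).to_numpy()
            if 0 < member.sum() < len(member):
                coef = polyserial_correlation(rec["lai_cells"].to_numpy(), member)
            else:
                coef = float("nan")
            poly_rows.append({"when": when, "bin": b, "polyserial_vs_lai": coef})
    out["polyserial"] = pd.DataFrame(poly_rows)
    return out
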