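"""Synthetic clinical cohorts of longitudinal tumor-volume series.

Real PDAC restaging data (sequential CT volumetry under a consistent
treatment context) are not publicly deposited, so every other module is
exercised against synthetic cohorts generated here.  A cohort mirrors the
clinical layout: groups are the product of treatment context
{none, GEM, FFX, GEM+nab} and lesion class {primary, metastasis}; each
lesion carries >= 3 scans; per-lesion true parameters are drawn from
configurable distributions (log-normal capacities specified by their
quartiles, normal growth rates per context) and observed volumes are the
generating logistic curve times i.i.d. multiplicative log-normal noise.

Default distribution settings echo the headline magnitudes of the clinical
analysis this package models (untreated primary growth rate ~0.28/month,
metastasis ~1.16/month, FOLFIRINOX shrinking the primary while partially
controlling metastases, carrying capacities spanning 5e9-2e10 cells) -- they
are synthetic stand-ins, not the unpublished per-patient estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .growth import (
    CELLS_PER_CM3,
    PRIMARY_STROMAL_FRACTION,
    GrowthCurveParams,
    LesionClass,
    ModelKind,
    TreatmentContext,
    VolumeSeries,
    evaluate_growth,
)

__all__ = [
    "NormalDist",
    "LogNormalDist",
    "lognormal_from_quartiles",
    "CohortConfig",
    "generate_cohort",
    "default_cohort_config",
    "recovery_cohort_config",
    "model_selection_cohort_config",
    "DEFAULT_RATE_DISTRIBUTIONS",
    "DEFAULT_CAPACITY_QUARTILES_CM3",
]

#: z-score of the third quartile of a standard normal.
Z_75 = 0.6744897501960817


@dataclass(frozen=True)
class NormalDist:
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size=None):
        return rng.normal(self.mean, self.sd, size=size)


@dataclass(frozen=True)
class LogNormalDist:
    """Log-normal distribution parameterized by (mu, sigma) of log."""

    mu: float
    sigma: float

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def sample(self, rng: np.random.Generator, size=None):
        return np.exp(rng.normal(self.mu, self.sigma, size=size))

    def quantile(self, p):
        from scipy.stats import norm

        return np.exp(self.mu + self.sigma * norm.ppf(p))


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> LogNormalDist:
    """Log-normal whose median and quartiles match the given summary.

    mu = ln(median); sigma = ln(q3/q1) / (2 * z_0.75).  This inverts the
    median/(q1, q3) layout used in per-cohort parameter summary tables into
    a sampler.  Requires 0 < q1 < median < q3.
    """
    if not 0 < q1 < median < q3:
        raise ValueError("quartiles must satisfy 0 < q1 < median < q3")
    return LogNormalDist(mu=float(np.log(median)), sigma=float(np.log(q3 / q1) / (2 * Z_75)))


# Growth-rate distributions (1/month) per (context, lesion class).  Synthetic
# stand-ins chosen once: FFX shrinks the primary and slows metastases; GEM
# leaves the primary near its untreated rate; GEM+nab sits in between.
DEFAULT_RATE_DISTRIBUTIONS: Dict[Tuple[TreatmentContext, LesionClass], NormalDist] = {
    (TreatmentContext.NONE, LesionClass.PRIMARY): NormalDist(0.28, 0.08),
    (TreatmentContext.NONE, LesionClass.METASTASIS): NormalDist(1.16, 0.35),
    (TreatmentContext.GEM, LesionClass.PRIMARY): NormalDist(0.25, 0.10),
    (TreatmentContext.GEM, LesionClass.METASTASIS): NormalDist(0.80, 0.30),
    (TreatmentContext.FFX, LesionClass.PRIMARY): NormalDist(-0.10, 0.08),
    (TreatmentContext.FFX, LesionClass.METASTASIS): NormalDist(0.25, 0.15),
    (TreatmentContext.GEM_NAB, LesionClass.PRIMARY): NormalDist(0.18, 0.10),
    (TreatmentContext.GEM_NAB, LesionClass.METASTASIS): NormalDist(0.60, 0.25),
}

# Carrying-capacity quartiles in cm^3 of imaged lesion volume.  For the
# primary these correspond (at 1e9 cells/cm^3 and 80% stroma) to LAI
# quartiles of 6e9 / 1.2e10 / 2.4e10 cancer cells, which reproduce the
# reported clinical LAI strata frequencies; metastases are stroma-free.
DEFAULT_CAPACITY_QUARTILES_CM3: Dict[LesionClass, Tuple[float, float, float]] = {
    LesionClass.PRIMARY: (30.0, 60.0, 120.0),
    LesionClass.METASTASIS: (0.5, 2.0, 8.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort of volume series.

    ``group_sizes`` maps (context, lesion class) to the number of lesions;
    one lesion per virtual patient.  ``scan_times`` (months) applies to all
    lesions and must contain >= 3 scans starting at 0.  ``noise_sd`` is the
    log-scale sd of multiplicative measurement noise.
    """

    group_sizes: Dict[Tuple[TreatmentContext, LesionClass], int]
    scan_times: Tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    noise_sd: float = 0.1
    rate_distributions: Dict[Tuple[TreatmentContext, LesionClass], NormalDist] = field(
        default_factory=lambda: dict(DEFAULT_RATE_DISTRIBUTIONS)
    )
    capacity_quartiles: Dict[LesionClass, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CAPACITY_QUARTILES_CM3)
    )
    shape_b: LogNormalDist = LogNormalDist(mu=float(np.log(3.0)), sigma=0.3)
    #: growth law producing the data; non-logistic laws are matched to the
    #: drawn logistic parameters (same V(0) and same volume at the last scan)
    generator: ModelKind = ModelKind.LOGISTIC
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "generator", ModelKind(self.generator))
        if len(self.scan_times) < 3:
            raise ValueError("scan schedule must contain at least 3 scans")
        if self.scan_times[0] != 0.0 or np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan times must start at 0 and strictly increase")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cls, (q1, med, q3) in self.capacity_quartiles.items():
            if not 0 < q1 < med < q3:
                raise ValueError(f"capacity quartiles for {cls} must be ordered")


def default_cohort_config(
    n_per_group: int = 20, seed: int = 0, noise_sd: float = 0.1
) -> CohortConfig:
    """Clinical-like cohort: all eight context x lesion-class groups, wide
    inter-patient capacity spread (quartile ratio 4)."""
    sizes = {key: n_per_group for key in DEFAULT_RATE_DISTRIBUTIONS}
    return CohortConfig(group_sizes=sizes, seed=seed, noise_sd=noise_sd)


def recovery_cohort_config(
    n: int = 50,
    seed: int = 0,
    noise_sd: float = 0.1,
    n_scans: int = 5,
    context: TreatmentContext = TreatmentContext.NONE,
    lesion_class: LesionClass = LesionClass.PRIMARY,
) -> CohortConfig:
    """Benchmark cohort for parameter-recovery studies.

    Uses a moderate inter-patient spread (capacity quartiles 50/60/72 cm^3,
    rate sd 0.05) and a fixed logistic shape B = 3, so that recovery of the
    fixed effects measures estimator bias rather than the sqrt(n) sampling
    noise of the population mean, and matches the fitted model's
    fixed-effect-only treatment of B.
    """
    times = tuple(2.0 * k for k in range(n_scans))
    rates = dict(DEFAULT_RATE_DISTRIBUTIONS)
    rates[(context, lesion_class)] = NormalDist(
        rates[(context, lesion_class)].mean, 0.05
    )
    caps = dict(DEFAULT_CAPACITY_QUARTILES_CM3)
    caps[lesion_class] = (50.0, 60.0, 72.0)
    return CohortConfig(
        group_sizes={(context, lesion_class): n},
        scan_times=times,
        noise_sd=noise_sd,
        rate_distributions=rates,
        capacity_quartiles=caps,
        shape_b=LogNormalDist(mu=float(np.log(3.0)), sigma=0.0),
        seed=seed,
    )


def model_selection_cohort_config(
    n: int = 30,
    seed: int = 0,
    noise_sd: float = 0.1,
    generator: ModelKind = ModelKind.LOGISTIC,
) -> "CohortConfig":
    """Benchmark cohort for growth-law comparison.

    Scans every two months through 16 months, so the series approach their
    carrying capacity: the three laws predict nearly identical early-phase
    volumes (over a short window the mid-section of a logistic curve is
    indistinguishable from linear growth), and only the late, saturating
    phase separates them.  Otherwise identical to
    :func:`recovery_cohort_config`.  ``generator`` selects which law
    produces the data (logistic or linear).
    """
    cfg = recovery_cohort_config(n=n, seed=seed, noise_sd=noise_sd, n_scans=9)
    return replace(cfg, generator=ModelKind(generator))


def generate_cohort(config: CohortConfig) -> Tuple[pd.DataFrame, List[VolumeSeries]]:
    """Generate a synthetic cohort.

    Returns ``(truth, series)`` where ``truth`` is a per-lesion table of the
    generating parameters (columns: patient_id, lesion_id, lesion_class,
    context, rate, capacity_cm3, capacity_cells, shape_b) and ``series`` is
    the list of noisy :class:`VolumeSeries`.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    truth_rows = []
    series: List[VolumeSeries] = []
    times = np.asarray(config.scan_times, dtype=float)
    case = 0
    for (context, cls), n in sorted(
        config.group_sizes.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        rate_dist = config.rate_distributions[(context, cls)]
        q1, med, q3 = config.capacity_quartiles[cls]
        cap_dist = lognormal_from_quartiles(med, q1, q3)
        stroma = PRIMARY_STROMAL_FRACTION if cls is LesionClass.PRIMARY else 0.0
        for _ in range(n):
            case += 1
            pid = f"SYN{case:04d}"
            lid = f"{pid}-L1"
            rate = float(rate_dist.sample(rng))
            cap = float(cap_dist.sample(rng))
            b = float(config.shape_b.sample(rng))
            params = GrowthCurveParams(
                model_kind=ModelKind.LOGISTIC, rate=rate, capacity=cap, shape_b=b
            )
            curve = np.asarray(evaluate_growth(params, times))
            if config.generator is ModelKind.LINEAR:
                v0, vlast = curve[0], curve[-1]
                slope = (vlast - v0) / times[-1]
                curve = slope * times + v0
            elif config.generator is ModelKind.EXPONENTIAL:
                v0, vlast = curve[0], curve[-1]
                r_eff = float(np.log(vlast / v0) / times[-1])
                curve = v0 * np.exp(r_eff * times)
            noise = (
                np.exp(rng.normal(0.0, config.noise_sd, size=times.size))
                if config.noise_sd > 0
                else np.ones_like(times)
            )
            series.append(
                VolumeSeries(
                    patient_id=pid,
                    lesion_id=lid,
                    lesion_class=cls,
                    context=context,
                    times=times.copy(),
                    volumes=curve * noise,
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": lid,
                    "lesion_class": cls.value,
                    "context": context.value,
                    "rate": rate,
                    "capacity_cm3": cap,
                    "capacity_cells": cap * (1.0 - stroma) * CELLS_PER_CM3,
                    "shape_b": b,
                }
            )
    return pd.DataFrame(truth_rows), series
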