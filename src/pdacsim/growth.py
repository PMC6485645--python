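"""Deterministic tumor growth laws and volume/cell-number conversions.

Three candidate growth laws describe a lesion's volume as a function of time
since its first scan (in months):

* exponential -- ``V(t) = V0 * exp(rate * t)``; unconstrained growth.
* logistic    -- ``V(t) = K / (1 + B * exp(-rate * t))``; growth slows as the
  lesion approaches its carrying capacity ``K``.  For the primary tumor the
  capacity is called the Local Advancement Index (LAI), for a metastasis the
  Metastatic Advancement Index (MAI).
* linear      -- ``V(t) = slope * t + intercept``.

Volumes are in cm^3 and rates in 1/month.  Rates may be negative (shrinkage
under chemotherapy); a logistic law with a negative rate decays toward zero.

The measurement model used for likelihoods is multiplicative log-normal
noise: volumes are positive and CT segmentation error scales with lesion
size, so residuals are taken on log-volume.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "LesionClass",
    "TreatmentContext",
    "ModelKind",
    "VolumeSeries",
    "GrowthCurveParams",
    "evaluate_growth",
    "cells_from_volume",
    "volume_from_cells",
    "volume_from_diameter",
    "diameter_from_volume",
    "series_loglik",
    "SeriesLogLik",
    "CELLS_PER_CM3",
    "PRIMARY_STROMAL_FRACTION",
]

#: Packing density of tumor cells: 1e9 cells occupy 1 cm^3.
CELLS_PER_CM3 = 1.0e9

#: Default stromal fraction of the primary tumor (desmoplastic stroma);
#: only the remaining 20% of the primary volume is cancer cells.
PRIMARY_STROMAL_FRACTION = 0.8


class LesionClass(str, enum.Enum):
    PRIMARY = "primary"
    METASTASIS = "metastasis"


class TreatmentContext(str, enum.Enum):
    """Treatment context a volume series was acquired under."""

    NONE = "none"
    GEM = "GEM"
    FFX = "FFX"
    GEM_NAB = "GEM+nab"


class ModelKind(str, enum.Enum):
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    LINEAR = "linear"


@dataclass(frozen=True)
class VolumeSeries:
    """One lesion's timestamped volume measurements.

    Times are months since the lesion's first scan (so ``times[0] == 0``),
    volumes in cm^3.  Fitting operations require at least three scans.
    """

    patient_id: str
    lesion_id: str
    lesion_class: LesionClass
    context: TreatmentContext
    times: np.ndarray = field(repr=False)
    volumes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "lesion_class", LesionClass(self.lesion_class))
        object.__setattr__(self, "context", TreatmentContext(self.context))
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if t.size:
            if t[0] != 0.0:
                raise ValueError("first scan time must be 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError("scan times must be strictly increasing")
            if np.any(v <= 0):
                raise ValueError("volumes must be positive")

    @property
    def n_scans(self) -> int:
        return int(self.times.size)

    def require_fittable(self) -> None:
        if self.n_scans < 3:
            raise ValueError(
                f"series {self.patient_id}/{self.lesion_id} has {self.n_scans} "
                "scans; fitting requires at least 3"
            )


@dataclass(frozen=True)
class GrowthCurveParams:
    """Parameters of one growth law.

    Which fields are meaningful depends on ``model_kind``:

    * exponential: ``rate`` (1/month), ``intercept`` (V(0), cm^3, > 0)
    * logistic: ``rate``, ``capacity`` (K, cm^3, > 0), ``shape_b`` (B > 0)
    * linear: ``slope`` (cm^3/month), ``intercept`` (cm^3)

    Accessing a field that does not belong to the model kind raises a
    configuration error at construction.
    """

    model_kind: ModelKind
    rate: float = 0.0
    capacity: float | None = None
    shape_b: float | None = None
    intercept: float | None = None
    slope: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind(self.model_kind))
        kind = self.model_kind
        if kind is ModelKind.LOGISTIC:
            if self.capacity is None or self.shape_b is None:
                raise ValueError("logistic model requires capacity and shape_b")
            if not (math.isfinite(self.capacity) and self.capacity > 0):
                raise ValueError("capacity must be finite and positive")
            if not (math.isfinite(self.shape_b) and self.shape_b > 0):
                raise ValueError("shape_b must be finite and positive")
            if self.intercept is not None or self.slope is not None:
                raise ValueError("logistic model takes no intercept/slope")
        elif kind is ModelKind.EXPONENTIAL:
            if self.intercept is None or self.intercept <= 0:
                raise ValueError("exponential model requires a positive intercept")
            if self.capacity is not None or self.shape_b is not None or self.slope is not None:
                raise ValueError("exponential model takes only rate and intercept")
        else:  # linear
            if self.intercept is None or self.slope is None:
                raise ValueError("linear model requires slope and intercept")
            if self.capacity is not None or self.shape_b is not None:
                raise ValueError("linear model takes no capacity/shape_b")


def evaluate_growth(params: GrowthCurveParams, t):
    """Evaluate a growth law at time(s) ``t`` (months, >= 0).

    Returns volume in cm^3 (scalar for scalar ``t``, else ndarray).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    kind = params.model_kind
    if kind is ModelKind.LOGISTIC:
        out = params.capacity / (1.0 + params.shape_b * np.exp(-params.rate * t_arr))
    elif kind is ModelKind.EXPONENTIAL:
        out = params.intercept * np.exp(params.rate * t_arr)
    else:
        out = params.slope * t_arr + params.intercept
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def cells_from_volume(
    volume,
    cells_per_cm3: float = CELLS_PER_CM3,
    stromal_fraction: float = 0.0,
):
    """Cancer-cell count in a lesion of the given volume (cm^3).

    ``stromal_fraction`` is the proportion of the lesion volume occupied by
    stroma (0.8 for the primary under the desmoplasia assumption; 0 by
    default, appropriate for metastases).
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    if not 0 <= stromal_fraction < 1:
        raise ValueError("stromal_fraction must lie in [0, 1)")
    if cells_per_cm3 <= 0:
        raise ValueError("cells_per_cm3 must be positive")
    out = (1.0 - stromal_fraction) * cells_per_cm3 * v
    return float(out) if v.ndim == 0 else out


def volume_from_cells(
    cells,
    cells_per_cm3: float = CELLS_PER_CM3,
    stromal_fraction: float = 0.0,
):
    """Inverse of :func:`cells_from_volume` (total lesion volume, cm^3)."""
    c = np.asarray(cells, dtype=float)
    if np.any(c < 0):
        raise ValueError("cells must be non-negative")
    if not 0 <= stromal_fraction < 1:
        raise ValueError("stromal_fraction must lie in [0, 1)")
    if cells_per_cm3 <= 0:
        raise ValueError("cells_per_cm3 must be positive")
    out = c / ((1.0 - stromal_fraction) * cells_per_cm3)
    return float(out) if c.ndim == 0 else out


def volume_from_diameter(diameter):
    """Volume of a sphere of the given diameter: V = pi * d^3 / 6."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    out = math.pi * d**3 / 6.0
    return float(out) if d.ndim == 0 else out


def diameter_from_volume(volume):
    """Diameter of a sphere of the given volume."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    out = np.cbrt(6.0 * v / math.pi)
    return float(out) if v.ndim == 0 else out


class SeriesLogLik(NamedTuple):
    """Log-likelihood of a series, with a validity flag.

    ``finite_predictions`` is False when the growth law predicted a
    non-positive volume at some scan time (possible for the linear law), in
    which case ``value`` is ``-inf``.
    """

    value: float
    finite_predictions: bool


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def series_loglik(
    params: GrowthCurveParams, series: VolumeSeries, noise_sd: float
) -> SeriesLogLik:
    """Log-likelihood of a volume series under log-normal measurement noise.

    log(observed volume) ~ Normal(log(predicted volume), noise_sd), summed
    over the scans of the series.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if series.n_scans < 1:
        raise ValueError("series must contain at least one measurement")
    pred = np.asarray(evaluate_growth(params, series.times), dtype=float)
    if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
        return SeriesLogLik(float("-inf"), False)
    resid = np.log(series.volumes) - np.log(pred)
    ll = float(
        -series.n_scans * (_LOG_SQRT_2PI + math.log(noise_sd))
        - np.sum(resid**2) / (2.0 * noise_sd**2)
    )
    return SeriesLogLik(ll, True)
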