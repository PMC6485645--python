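"""Reading and writing the package's plain-text table formats.

Two dialects:

* volume-series CSV: one row per scan, columns
  ``patient_id, lesion_id, lesion_class, context, time_months, volume_cm3``
  (UTF-8, header required, decimal months).
* parameter-table CSV: one row per lesion, columns
  ``patient_id, lesion_class, context, rate_median, rate_q1, rate_q3,
  capacity_median, capacity_q1, capacity_q3, B``.  This is both the export
  of a cohort fit and the import format the simulator accepts as an
  empirical distribution of per-patient growth rates and LAI/MAI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .growth import LesionClass, TreatmentContext, VolumeSeries

__all__ = [
    "series_to_frame",
    "frame_to_series",
    "write_volume_series",
    "read_volume_series",
    "write_parameter_table",
    "read_parameter_table",
]

SERIES_COLUMNS = [
    "patient_id",
    "lesion_id",
    "lesion_class",
    "context",
    "time_months",
    "volume_cm3",
]

PARAMETER_COLUMNS = [
    "patient_id",
    "lesion_class",
    "context",
    "rate_median",
    "rate_q1",
    "rate_q3",
    "capacity_median",
    "capacity_q1",
    "capacity_q3",
    "B",
]


def series_to_frame(series: Iterable[VolumeSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, v in zip(s.times, s.volumes):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "lesion_id": s.lesion_id,
                    "lesion_class": s.lesion_class.value,
                    "context": s.context.value,
                    "time_months": t,
                    "volume_cm3": v,
                }
            )
    return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def frame_to_series(frame: pd.DataFrame) -> List[VolumeSeries]:
    missing = set(SERIES_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"volume-series table missing columns: {sorted(missing)}")
    out: List[VolumeSeries] = []
    for (pid, lid), grp in frame.groupby(["patient_id", "lesion_id"], sort=False):
        grp = grp.sort_values("time_months")
        out.append(
            VolumeSeries(
                patient_id=str(pid),
                lesion_id=str(lid),
                lesion_class=LesionClass(grp["lesion_class"].iloc[0]),
                context=TreatmentContext(grp["context"].iloc[0]),
                times=grp["time_months"].to_numpy(dtype=float),
                volumes=grp["volume_cm3"].to_numpy(dtype=float),
            )
        )
    return out


def write_volume_series(series: Iterable[VolumeSeries], path) -> None:
    # %.17g round-trips float64 exactly
    series_to_frame(series).to_csv(path, index=False, float_format="%.17g")


def read_volume_series(path) -> List[VolumeSeries]:
    return frame_to_series(pd.read_csv(path, float_precision="round_trip"))


def write_parameter_table(table: pd.DataFrame, path) -> None:
    missing = set(PARAMETER_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    table[PARAMETER_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_parameter_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = set(PARAMETER_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return table
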