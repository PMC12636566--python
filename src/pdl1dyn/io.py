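"""Tidy CSV / JSON round-tripping for datasets, trajectories and reports.

Dataset CSV dialect: columns ``therapy_id, day, volume_mm3, include_flag``
(one row per observation).  Trajectory CSV: ``therapy_id, time_day,
V_mm3, T_mm3, A1, A2, eps, Q``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calibrate import FitResult, TherapyDataset
from .simulate import Trajectory

__all__ = [
    "write_datasets_csv",
    "read_datasets_csv",
    "write_trajectory_csv",
    "write_fit_report",
    "write_manifest",
]


def write_datasets_csv(datasets: Mapping[str, TherapyDataset] | TherapyDataset, path) -> None:
    if isinstance(datasets, TherapyDataset):
        datasets = {datasets.therapy_id: datasets}
    frames = []
    for tid in sorted(datasets):
        d = datasets[tid]
        frames.append(
            pd.DataFrame(
                {
                    "therapy_id": tid,
                    "day": d.days,
                    "volume_mm3": d.volumes,
                    "include_flag": d.include.astype(int),
                }
            )
        )
    # %.17g keeps the write -> read round trip bit-exact for doubles
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_datasets_csv(path) -> dict[str, TherapyDataset]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"therapy_id", "day", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset file {path} is missing column(s) {sorted(missing)}")
    if "include_flag" not in df.columns:
        df["include_flag"] = 1
    out = {}
    for tid, grp in df.groupby("therapy_id", sort=True):
        grp = grp.sort_values("day")
        out[str(tid)] = TherapyDataset(
            therapy_id=str(tid),
            days=grp["day"].to_numpy(float),
            volumes=grp["volume_mm3"].to_numpy(float),
            include=grp["include_flag"].to_numpy(int).astype(bool),
        )
    return out


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_fit_report(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, cls=_NumpyEncoder) + "\n")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, cls=_NumpyEncoder) + "\n")
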