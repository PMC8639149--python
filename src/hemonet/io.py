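"""Reading and writing the pipeline's file formats.

Monitoring data lives in long-format CSV with the header
``patient_id,time_min,map_mmHg,hr_bpm`` (UTF-8, '.' decimal), matching
the shape of the public ODC-SCI monitoring deposits; sampling (Q1 or Q5)
is inferred from the median time step.  Clinical tables, feature
matrices, distance matrices and scan results are plain CSV; grids,
configurations and reports are JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CdfFeatureMatrix, MonitoringSeries

__all__ = [
    "read_monitoring",
    "write_monitoring",
    "read_clinical",
    "write_clinical",
    "write_features",
    "read_features",
]

_MONITORING_COLUMNS = ["patient_id", "time_min", "map_mmHg", "hr_bpm"]


def read_monitoring(path: str | Path) -> list[MonitoringSeries]:
    """Parse a long-format monitoring CSV into per-patient series.

    Rows are sorted by time within patient; the sampling interval must be
    a constant 1 or 5 minutes.  An optional ``valid`` 0/1 column is
    honoured (all-valid assumed otherwise).
    """
    df = pd.read_csv(path)
    missing = [c for c in _MONITORING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"monitoring file {path} is missing columns {missing}")
    bad = df[_MONITORING_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"unparseable rows in {path} at lines {lines}")
    cohort = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(float)
        if len(times) > 1:
            step = float(np.median(np.diff(times)))
            if step not in (1.0, 5.0) or not np.allclose(np.diff(times), step):
                raise ValueError(
                    f"patient {pid}: irregular or unsupported time step ({step} min)"
                )
            sampling = "Q1" if step == 1.0 else "Q5"
        else:
            sampling = "Q5"
        valid = (
            grp["valid"].to_numpy(float).astype(bool)
            if "valid" in grp.columns
            else None
        )
        cohort.append(
            MonitoringSeries(
                patient_id=str(pid),
                times_min=times,
                map_mmHg=grp["map_mmHg"].to_numpy(float),
                hr_bpm=grp["hr_bpm"].to_numpy(float),
                sampling=sampling,
                valid=valid,
            )
        )
    return cohort


def write_monitoring(cohort: list[MonitoringSeries], path: str | Path) -> None:
    frames = []
    for s in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "time_min": s.times_min,
                    "map_mmHg": s.map_mmHg,
                    "hr_bpm": s.hr_bpm,
                    "valid": s.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError(f"clinical file {path} lacks a patient_id column")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_features(features: CdfFeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV with the grids in a JSON sidecar."""
    path = Path(path)
    cols = [f"map_cdf_{i + 1}" for i in range(100)] + [f"hr_cdf_{i + 1}" for i in range(100)]
    pd.DataFrame(features.values, index=features.patient_ids, columns=cols).to_csv(
        path, index_label="patient_id"
    )
    sidecar = path.with_suffix(".grid.json")
    sidecar.write_text(
        json.dumps(
            {
                "map_grid_mmHg": features.map_grid_mmHg.tolist(),
                "hr_grid_bpm": features.hr_grid_bpm.tolist(),
            }
        )
    )


def read_features(path: str | Path) -> CdfFeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="patient_id")
    grids = json.loads(path.with_suffix(".grid.json").read_text())
    return CdfFeatureMatrix(
        patient_ids=df.index.tolist(),
        values=df.to_numpy(float),
        map_grid_mmHg=np.array(grids["map_grid_mmHg"]),
        hr_grid_bpm=np.array(grids["hr_grid_bpm"]),
    )
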