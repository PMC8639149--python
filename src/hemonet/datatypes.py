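"""Core containers shared across the pipeline.

Monitoring data travels as :class:`MonitoringSeries` objects (one per
patient); clinical covariates travel as a plain :class:`pandas.DataFrame`
with the columns documented in :data:`CLINICAL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MonitoringSeries",
    "CdfFeatureMatrix",
    "CLINICAL_COLUMNS",
]

#: Expected columns of a clinical covariate table (one row per patient).
#: ``ais_admission`` / ``ais_discharge`` are ordinal grades "A".."E" (may be
#: missing); ``improved`` is a 0/1 flag (missing when either grade is);
#: ``nli`` is "cervical" / "non-cervical".
CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "ais_admission",
    "ais_discharge",
    "improved",
    "nli",
    "surgery_minutes",
    "days_to_discharge",
    "amap_mmHg",
    "ahr_bpm",
)

_SAMPLING_STEP = {"Q1": 1, "Q5": 5}


@dataclass
class MonitoringSeries:
    """One patient's intra-operative MAP/HR record on a regular time grid.

    ``valid`` marks samples that survived artifact filtering; samples are
    never deleted so the time grid stays regular and the point-to-point
    jump rule remains well defined.
    """

    patient_id: str
    times_min: np.ndarray
    map_mmHg: np.ndarray
    hr_bpm: np.ndarray
    sampling: str = "Q5"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.map_mmHg = np.asarray(self.map_mmHg, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times_min.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times_min)
        if not (len(self.map_mmHg) == len(self.hr_bpm) == len(self.valid) == n):
            raise ValueError("times, map, hr and valid must have equal length")
        if self.sampling not in _SAMPLING_STEP:
            raise ValueError(f"unknown sampling {self.sampling!r}")
        if n > 1:
            steps = np.diff(self.times_min)
            if not np.allclose(steps, self.step_min):
                raise ValueError(
                    f"time steps must be constant {self.step_min} min for "
                    f"{self.sampling} sampling"
                )

    @property
    def step_min(self) -> int:
        """Sampling interval in minutes (1 for Q1, 5 for Q5)."""
        return _SAMPLING_STEP[self.sampling]

    def __len__(self) -> int:
        return len(self.times_min)

    def copy(self) -> "MonitoringSeries":
        return replace(
            self,
            times_min=self.times_min.copy(),
            map_mmHg=self.map_mmHg.copy(),
            hr_bpm=self.hr_bpm.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class CdfFeatureMatrix:
    """Patients x 200 empirical-CDF features.

    Columns 0..99 evaluate each patient's MAP CDF on ``map_grid_mmHg``;
    columns 100..199 evaluate the HR CDF on ``hr_grid_bpm``.  Both grids
    have 100 points spanning the cohort-wide range of the measure at a
    spacing of 1% of that range, so the final bin of each block is exactly
    1 for every patient.
    """

    patient_ids: list
    values: np.ndarray
    map_grid_mmHg: np.ndarray
    hr_grid_bpm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), 200):
            raise ValueError("values must be (n_patients, 200)")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)
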