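"""Monitoring-data pre-processing.

Three standardization steps applied before any similarity computation:

1. artifact filtering — MAP values outside a plausible band (default
   10-200 mmHg) and point-to-point changes greater than 40 mmHg are
   invalidated (masked, never deleted, so the time grid stays regular);
2. Q1 -> Q5 downsampling — 1-min records averaged over windows of five
   samples for compatibility with 5-min records;
3. empirical-CDF featurization — each patient's MAP and HR distributions
   evaluated on a shared 100-point grid per measure (bin width 1% of the
   cohort-wide range), yielding a patients x 200 feature matrix that
   discards temporal alignment entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CdfFeatureMatrix, MonitoringSeries

__all__ = [
    "FilterRules",
    "filter_artifacts",
    "downsample_q1_to_q5",
    "cdf_featurize",
    "summarize_averages",
]


@dataclass
class FilterRules:
    """Validity rules for MAP samples.

    The jump rule compares each sample with the most recent *valid*
    predecessor, so a single spike does not cascade invalidations.  HR is
    unfiltered by default; set ``hr_low``/``hr_high`` to enable bounds on it.
    """

    map_low: float = 10.0
    map_high: float = 200.0
    max_jump: float = 40.0
    hr_low: float | None = None
    hr_high: float | None = None


def filter_artifacts(
    series: MonitoringSeries, rules: FilterRules | None = None
) -> MonitoringSeries:
    """Flag artifact samples invalid; timestamps and values are preserved.

    A sample is invalidated when MAP < map_low, MAP > map_high, or its
    absolute change from the last valid sample strictly exceeds
    ``max_jump``.  Idempotent: filtering a filtered series is a no-op.
    """
    if len(series) == 0:
        raise ValueError("cannot filter an empty series")
    rules = rules or FilterRules()
    out = series.copy()
    valid = out.valid
    last_valid_map = None
    for i in range(len(out)):
        if not valid[i]:
            continue
        m = out.map_mmHg[i]
        ok = rules.map_low <= m <= rules.map_high
        if ok and last_valid_map is not None and abs(m - last_valid_map) > rules.max_jump:
            ok = False
        if ok and rules.hr_low is not None and out.hr_bpm[i] < rules.hr_low:
            ok = False
        if ok and rules.hr_high is not None and out.hr_bpm[i] > rules.hr_high:
            ok = False
        if ok:
            last_valid_map = m
        else:
            valid[i] = False
    return out


def downsample_q1_to_q5(series: MonitoringSeries) -> MonitoringSeries:
    """Average five consecutive Q1 samples into one Q5 sample.

    Each Q5 value is the mean of the *valid* members of its window; a
    window with no valid member yields an invalid Q5 sample.  A trailing
    partial window is averaged over the samples it has.
    """
    if series.sampling == "Q5":
        warnings.warn("series already at Q5; downsampling is a no-op")
        return series.copy()
    n = len(series)
    n_out = int(np.ceil(n / 5))
    map_out = np.full(n_out, np.nan)
    hr_out = np.full(n_out, np.nan)
    valid_out = np.zeros(n_out, dtype=bool)
    for j in range(n_out):
        sl = slice(5 * j, min(5 * j + 5, n))
        v = series.valid[sl]
        if v.any():
            map_out[j] = series.map_mmHg[sl][v].mean()
            hr_out[j] = series.hr_bpm[sl][v].mean()
            valid_out[j] = True
    return MonitoringSeries(
        patient_id=series.patient_id,
        times_min=series.times_min[0] + 5.0 * np.arange(n_out),
        map_mmHg=map_out,
        hr_bpm=hr_out,
        sampling="Q5",
        valid=valid_out,
    )


def _cdf_block(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # fraction of samples <= each grid point; searchsorted on sorted values
    s = np.sort(values)
    return np.searchsorted(s, grid, side="right") / len(s)


def cdf_featurize(cohort: list[MonitoringSeries], n_bins: int = 100) -> CdfFeatureMatrix:
    """Build the patients x 200 empirical-CDF feature matrix.

    The evaluation grid for each measure has ``n_bins`` points spanning
    the cohort-wide [min, max] of that measure at a spacing of 1/n_bins of
    the range; the grid starts one bin above the minimum so the first bin
    is informative and the last coincides with the maximum (hence exactly
    1 for every patient).  Grids are cohort-wide, not per patient, so bins
    are comparable across patients — a requirement of the Euclidean
    distance computed downstream.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two patients")
    for s in cohort:
        if not s.valid.any():
            raise ValueError(f"patient {s.patient_id} has no valid samples")
    all_map = np.concatenate([s.map_mmHg[s.valid] for s in cohort])
    all_hr = np.concatenate([s.hr_bpm[s.valid] for s in cohort])

    def make_grid(x: np.ndarray, name: str) -> np.ndarray:
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise ValueError(f"zero cohort-wide range for {name}")
        width = (hi - lo) / n_bins
        grid = lo + width * np.arange(1, n_bins + 1)
        grid[-1] = hi  # guard against float drift so the final bin is exact
        return grid

    map_grid = make_grid(all_map, "MAP")
    hr_grid = make_grid(all_hr, "HR")
    rows = []
    for s in cohort:
        rows.append(
            np.concatenate(
                [
                    _cdf_block(s.map_mmHg[s.valid], map_grid),
                    _cdf_block(s.hr_bpm[s.valid], hr_grid),
                ]
            )
        )
    return CdfFeatureMatrix(
        patient_ids=[s.patient_id for s in cohort],
        values=np.array(rows),
        map_grid_mmHg=map_grid,
        hr_grid_bpm=hr_grid,
    )


def summarize_averages(cohort: list[MonitoringSeries]) -> pd.DataFrame:
    """Per-patient time-averages aMAP and aHR over valid samples."""
    rows = []
    for s in cohort:
        v = s.valid
        rows.append(
            {
                "patient_id": s.patient_id,
                "amap_mmHg": float(np.mean(s.map_mmHg[v])) if v.any() else np.nan,
                "ahr_bpm": float(np.mean(s.hr_bpm[v])) if v.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
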