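"""Moving MAP-range construction and LASSO selection of the optimal range.

The working hypothesis is that *time spent outside* some normotensive MAP
interval, not average MAP alone, predicts neurological improvement.  Two
nested families of candidate intervals are scanned:

* symmetric — (center - s, center + s) for s = 1..S mmHg around a center
  of 90 mmHg (the improver-group mean MAP);
* asymmetric — lower limit fixed at 76 mmHg, upper limit swept upward
  1 mmHg at a time.

For each candidate the per-patient minutes outside the interval are
computed (boundary values count as inside), the network assortativity of
that column is evaluated as an exploratory check, and an L1-penalized
logistic path over a decreasing lambda grid identifies the
"last-standing" predictor: the single column still active at the largest
penalty that retains exactly one non-zero coefficient.  That column is
refit unpenalized as the solo predictor with leave-one-out validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datatypes import MonitoringSeries
from .network import PatientNetwork, assortativity_numeric

__all__ = [
    "RangeDefinition",
    "RangeScanResult",
    "time_out_of_range",
    "build_range_matrix",
    "assortativity_scan",
    "lasso_last_standing",
    "refit_single_range",
]


@dataclass(frozen=True)
class RangeDefinition:
    low_mmHg: float
    high_mmHg: float

    def __post_init__(self) -> None:
        if not self.low_mmHg < self.high_mmHg:
            raise ValueError("range lower limit must be below upper limit")

    @property
    def label(self) -> str:
        return f"{self.low_mmHg:g}-{self.high_mmHg:g}"


@dataclass
class RangeScanResult:
    ranges: list[RangeDefinition]
    minutes_outside: pd.DataFrame  # patients x ranges, columns = labels
    ar_by_range: dict[str, float | None] = field(default_factory=dict)
    lasso_path: pd.DataFrame | None = None
    selected_range: RangeDefinition | None = None
    selected_lambda: float | None = None


def time_out_of_range(series: MonitoringSeries, rng: RangeDefinition) -> float:
    """Minutes with valid MAP strictly outside [low, high].

    Boundary values count as inside (closed interval).  Each valid sample
    contributes its sampling interval (5 min for Q5).
    """
    m = series.map_mmHg[series.valid]
    if len(m) == 0:
        return float("nan")
    outside = np.count_nonzero((m < rng.low_mmHg) | (m > rng.high_mmHg))
    return float(series.step_min * outside)


def build_range_matrix(
    cohort: list[MonitoringSeries],
    mode: str = "symmetric",
    center: float = 90.0,
    n_steps: int = 25,
    fixed_low: float = 76.0,
    upper_sweep: tuple = (91.0, 130.0),
    map_bounds: tuple = (10.0, 200.0),
) -> RangeScanResult:
    """Candidate ranges and the patients x ranges minutes-outside matrix.

    ``symmetric`` widens (center - s, center + s) by 1 mmHg per step;
    ``asymmetric`` fixes the lower limit and sweeps the upper limit by
    1 mmHg.  Candidates escaping ``map_bounds`` are truncated away with a
    warning.
    """
    if mode == "symmetric":
        ranges = [RangeDefinition(center - s, center + s) for s in range(1, n_steps + 1)]
    elif mode == "asymmetric":
        lo, hi = upper_sweep
        ranges = [RangeDefinition(fixed_low, u) for u in np.arange(lo, hi + 0.5)]
    else:
        raise ValueError("mode must be 'symmetric' or 'asymmetric'")
    kept = [r for r in ranges if map_bounds[0] <= r.low_mmHg and r.high_mmHg <= map_bounds[1]]
    if len(kept) < len(ranges):
        warnings.warn(f"truncated {len(ranges) - len(kept)} ranges exiting MAP bounds")
    minutes = pd.DataFrame(
        {r.label: [time_out_of_range(s, r) for s in cohort] for r in kept},
        index=[s.patient_id for s in cohort],
    )
    return RangeScanResult(ranges=kept, minutes_outside=minutes)


def assortativity_scan(network: PatientNetwork, scan: RangeScanResult) -> dict[str, float | None]:
    """Network assortativity of the minutes-outside column for each range."""
    if set(network.ids) != set(scan.minutes_outside.index):
        raise ValueError("network nodes and scan patients must match")
    ar = {}
    for label in scan.minutes_outside.columns:
        col = scan.minutes_outside[label]
        attr = {u: col[network.ids[u]] for u in network.graph.nodes}
        ar[label] = assortativity_numeric(network.graph, attr).ar
    scan.ar_by_range = ar
    return ar


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear", tol=1e-6, max_iter=1000
    )
    model.fit(X, y)
    coef = model.coef_.ravel()
    coef[np.abs(coef) < 1e-9] = 0.0  # numerically-dead coefficients
    return coef


def lasso_last_standing(
    minutes_outside: pd.DataFrame,
    improved: np.ndarray,
    n_lambda: int = 60,
    lambda_floor: float = 0.02,
    loocv: bool = False,
) -> RangeScanResult | tuple:
    """Select the single most predictive range via the L1 logistic path.

    Columns are standardized, then an L1-penalized logistic model is fit
    over a decreasing lambda grid.  The selected column is the one active
    alone at the largest lambda with exactly one non-zero coefficient
    (refined by bisection when the grid jumps past the one-predictor
    region).  The grid spans lambda_max down to ``lambda_floor *
    lambda_max``; selection depends only on the top of the path, the rest
    is diagnostic.  Returns (selected label, path DataFrame, selected
    lambda[, loocv deviance per lambda]).
    """
    y = np.asarray(improved, dtype=float)
    X = minutes_outside.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} all-constant range columns")
    labels = [c for c, k in zip(minutes_outside.columns, keep) if k]
    X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    n = len(y)
    # smallest lambda that zeroes every coefficient, as in coordinate descent
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    grid = np.geomspace(lam_max * 1.1, lam_max * lambda_floor, n_lambda)
    coefs = np.array([_l1_fit(Xs, y, lam) for lam in grid])
    n_active = (coefs != 0).sum(axis=1)

    sel_idx, sel_lam = None, None
    ones = np.flatnonzero(n_active == 1)
    if len(ones):
        g = ones[0]
        sel_idx = int(np.flatnonzero(coefs[g])[0])
        sel_lam = float(grid[g])
    else:
        active_grid = np.flatnonzero(n_active >= 1)
        if not len(active_grid):
            raise ValueError("no coefficient ever becomes active on the path")
        g = active_grid[0]
        lo_lam, hi_lam = grid[g], grid[g - 1] if g > 0 else grid[g] * 2
        for _ in range(40):  # bisect toward a lambda with exactly one active
            mid = np.sqrt(lo_lam * hi_lam)
            c = _l1_fit(Xs, y, mid)
            na = np.count_nonzero(c)
            if na == 1:
                sel_idx, sel_lam = int(np.flatnonzero(c)[0]), float(mid)
                break
            if na == 0:
                hi_lam = mid
            else:
                lo_lam = mid
        if sel_idx is None:  # exactly tied columns enter together
            c = coefs[g]
            sel_idx = int(np.argmax(np.abs(c)))
            sel_lam = float(grid[g])

    path = pd.DataFrame(coefs, index=grid, columns=labels)
    path.index.name = "lambda"
    if not loocv:
        return labels[sel_idx], path, sel_lam
    dev = _loocv_deviance_path(Xs, y, grid)
    return labels[sel_idx], path, sel_lam, pd.Series(dev, index=grid, name="loocv_deviance")


def _loocv_deviance_path(Xs: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    eps = 1e-12
    dev = np.zeros(len(grid))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        for g, lam in enumerate(grid):
            model = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (mask.sum() * lam), solver="liblinear", tol=1e-6
            )
            model.fit(Xs[mask], y[mask])
            p = float(model.predict_proba(Xs[i : i + 1])[0, 1])
            p = min(max(p, eps), 1 - eps)
            dev[g] += -2 * (y[i] * np.log(p) + (1 - y[i]) * np.log(1 - p))
    return dev / len(y)


def refit_single_range(
    minutes_column: np.ndarray, improved: np.ndarray
) -> "object":
    """Unpenalized solo-predictor logistic refit of the selected range.

    Delegates to the model suite so Wald tests and LOOCV metrics use the
    same machinery as every other confirmatory fit.
    """
    from .models import Covariate, ModelSpec, fit_logistic

    data = pd.DataFrame(
        {"minutes_out": np.asarray(minutes_column, float), "improved": np.asarray(improved, int)}
    )
    spec = ModelSpec(response="improved", terms=[Covariate("minutes_out")])
    return fit_logistic(spec, data)
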