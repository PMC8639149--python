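"""Confirmatory and predictive logistic-regression suite.

Model specifications are small declarative objects (polynomial, natural
spline, categorical, plain covariate, interaction terms) compiled to a
design matrix and fit by maximum likelihood through statsmodels.  On top
of the single fit the suite provides likelihood-ratio tests between
nested models, leave-one-out cross-validation (Brier error and
classification metrics), exhaustive best-subset search under AICc,
sensitivity/specificity-balancing threshold calibration, and ROC/AUC.

Polynomial terms default to an orthonormal coding (numerically stable and
orthogonal to the intercept); deviance, AIC and LRT results are invariant
to the coding, individual polynomial coefficients are not.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Covariate",
    "Poly",
    "NaturalSpline",
    "Categorical",
    "Interaction",
    "ModelSpec",
    "ModelFit",
    "fit_logistic",
    "polynomial_basis",
    "natural_spline_basis",
    "likelihood_ratio_test",
    "loocv_error",
    "loocv_classification",
    "exhaustive_model_search",
    "calibrate_threshold",
    "roc_auc",
    "cohort_univariate_table",
]


# ---------------------------------------------------------------- terms

@dataclass(frozen=True)
class Covariate:
    var: str

    def columns(self, data: pd.DataFrame) -> pd.DataFrame:
        return data[[self.var]].astype(float)

    @property
    def vars(self) -> tuple:
        return (self.var,)


@dataclass(frozen=True)
class Poly:
    """Polynomial of one predictor; linear..degree terms enter as a unit."""

    var: str
    degree: int = 2
    coding: str = "orthonormal"

    def columns(self, data: pd.DataFrame) -> pd.DataFrame:
        basis = polynomial_basis(data[self.var].to_numpy(float), self.degree, self.coding)
        return pd.DataFrame(
            basis, index=data.index,
            columns=[f"{self.var}^{j}" for j in range(1, self.degree + 1)],
        )

    @property
    def vars(self) -> tuple:
        return (self.var,)


@dataclass(frozen=True)
class NaturalSpline:
    var: str
    df: int = 2

    def columns(self, data: pd.DataFrame) -> pd.DataFrame:
        basis = natural_spline_basis(data[self.var].to_numpy(float), self.df)
        return pd.DataFrame(
            basis, index=data.index,
            columns=[f"ns({self.var}){j}" for j in range(1, self.df + 1)],
        )

    @property
    def vars(self) -> tuple:
        return (self.var,)


@dataclass(frozen=True)
class Categorical:
    var: str
    reference: str

    def columns(self, data: pd.DataFrame) -> pd.DataFrame:
        levels = [l for l in pd.unique(data[self.var].dropna()) if l != self.reference]
        out = pd.DataFrame(index=data.index)
        for level in sorted(map(str, levels)):
            out[f"{self.var}[{level}]"] = (data[self.var].astype(str) == level).astype(float)
        return out

    @property
    def vars(self) -> tuple:
        return (self.var,)


@dataclass(frozen=True)
class Interaction:
    left: object
    right: object

    def columns(self, data: pd.DataFrame) -> pd.DataFrame:
        lc, rc = self.left.columns(data), self.right.columns(data)
        out = pd.DataFrame(index=data.index)
        for a in lc.columns:
            for b in rc.columns:
                out[f"{a}:{b}"] = lc[a] * rc[b]
        return out

    @property
    def vars(self) -> tuple:
        return tuple(self.left.vars) + tuple(self.right.vars)


@dataclass(frozen=True)
class ModelSpec:
    """Response name plus an ordered tuple of terms (intercept implicit)."""

    response: str
    terms: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))

    def design(self, data: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, int]:
        """Complete-case (y, X) with intercept; returns rows dropped too."""
        used = [self.response] + [v for t in self.terms for v in t.vars]
        cc = data.dropna(subset=sorted(set(used)))
        n_dropped = len(data) - len(cc)
        X = pd.DataFrame({"Intercept": np.ones(len(cc))}, index=cc.index)
        for t in self.terms:
            for name, col in t.columns(cc).items():
                X[name] = col
        y = cc[self.response].to_numpy(float)
        return y, X, n_dropped

    def describe(self) -> str:
        return f"{self.response} ~ " + (" + ".join(repr(t) for t in self.terms) or "1")


# ---------------------------------------------------------------- bases

def polynomial_basis(x: np.ndarray, degree: int, coding: str = "orthonormal") -> np.ndarray:
    """Raw or orthonormal polynomial basis columns (degree 1..degree).

    The orthonormal coding mirrors R's ``poly()``: columns are orthogonal
    to the intercept and each other with unit norm, so high-degree fits
    stay well conditioned.  Fit deviance is identical under both codings.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; polynomial basis undefined")
    if coding == "raw":
        return np.column_stack([x**j for j in range(1, degree + 1)])
    if coding != "orthonormal":
        raise ValueError("coding must be 'raw' or 'orthonormal'")
    V = np.column_stack([x**j for j in range(degree + 1)])
    Q, _ = np.linalg.qr(V)
    B = Q[:, 1:]
    for j in range(B.shape[1]):  # reproducible signs: correlate + with x^(j+1)
        if B[:, j] @ (x ** (j + 1)) < 0:
            B[:, j] = -B[:, j]
    return B


def natural_spline_basis(
    x: np.ndarray, df: int = 2, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns.

    Boundary knots sit at min/max of x and the df-1 interior knots at
    equally spaced quantiles.  The basis is linear beyond the boundary
    knots (second derivative zero), built from the truncated-power
    representation; it spans the same space as R's ``ns()`` so deviance
    and likelihood-ratio results agree even though individual columns
    differ.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if len(np.unique(x)) < df + 1:
        raise ValueError("too few distinct values for the requested df")
    if knots is None:
        qs = np.linspace(0, 1, df + 1)[1:-1]
        knots = np.concatenate([[x.min()], np.quantile(x, qs), [x.max()]])
    knots = np.sort(np.asarray(knots, float))
    K = len(knots)
    if df == 1:
        return x[:, None]

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    dK1 = d(K - 2)
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols)


# ---------------------------------------------------------------- fitting

@dataclass
class ModelFit:
    """A fitted logistic model with the diagnostics the suite reports."""

    spec: ModelSpec
    n: int
    n_dropped: int
    params: pd.DataFrame  # coef, se, z, p per design column
    deviance: float
    null_deviance: float
    aic: float
    aicc: float
    separation: bool = False
    loocv: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)
    threshold: float | None = None

    @property
    def n_params(self) -> int:
        return len(self.params)


def _glm_fit(y: np.ndarray, X: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=200, tol=1e-10)


def fit_logistic(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood Bernoulli-logit fit of a model specification.

    Rows with missing values in any used variable are dropped
    (complete-case analysis; the count is recorded on the fit).  Probable
    separation — fitted probabilities pinned at 0/1 with huge
    coefficients — is flagged rather than hidden.
    """
    y, X, n_dropped = spec.design(data)
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient for {spec.describe()}; "
            "a predictor is constant or collinear"
        )
    res = _glm_fit(y, Xv)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"fit did not converge for {spec.describe()}")
    null_dev = float(_glm_fit(y, np.ones((len(y), 1))).deviance)
    se = np.asarray(res.bse)
    z = np.asarray(res.params) / se
    params = pd.DataFrame(
        {
            "coef": np.asarray(res.params),
            "se": se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=X.columns,
    )
    p = len(params)
    n = len(y)
    aic = float(res.deviance + 2 * p)
    aicc = aic + (2 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else np.inf)
    mu = res.fittedvalues
    separation = bool(np.abs(np.asarray(res.params)).max() > 30) and bool(
        np.any((mu < 1e-8) | (mu > 1 - 1e-8))
    )
    return ModelFit(
        spec=spec,
        n=n,
        n_dropped=n_dropped,
        params=params,
        deviance=float(res.deviance),
        null_deviance=null_dev,
        aic=aic,
        aicc=float(aicc),
        separation=separation,
    )


def likelihood_ratio_test(nested: ModelFit, fuller: ModelFit) -> dict:
    """Deviance-difference chi-square test between nested fits."""
    if nested.n != fuller.n:
        raise ValueError("fits must use the same rows")
    nested_vars = {v for t in nested.spec.terms for v in t.vars}
    fuller_vars = {v for t in fuller.spec.terms for v in t.vars}
    if not nested_vars <= fuller_vars or nested.n_params > fuller.n_params:
        raise ValueError("models are not nested")
    diff = nested.deviance - fuller.deviance
    df = fuller.n_params - nested.n_params
    p = float(stats.chi2.sf(diff, df)) if df > 0 else 1.0
    if df == 0:
        diff = 0.0
    return {"deviance_diff": float(diff), "df_diff": df, "p": p}


# ---------------------------------------------------------------- LOOCV

def _loo_probs(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Held-out probability per row (basis built once on complete cases)."""
    y, X, _ = spec.design(data)
    Xv = X.to_numpy(float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 rows for LOOCV")
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            res = _glm_fit(y[mask], Xv[mask])
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"LOOCV fold {i} failed: {exc}") from exc
        eta = float(Xv[i] @ np.asarray(res.params))
        probs[i] = 1.0 / (1.0 + np.exp(-eta))
    return y, probs


def loocv_error(spec: ModelSpec, data: pd.DataFrame) -> float:
    """LOO mean squared prediction error (Brier): mean of (y_i - p_hat(-i))^2."""
    y, probs = _loo_probs(spec, data)
    return float(np.mean((y - probs) ** 2))


def _cohen_kappa(y: np.ndarray, pred: np.ndarray) -> float:
    po = float(np.mean(y == pred))
    pe = float(np.mean(y) * np.mean(pred) + (1 - np.mean(y)) * (1 - np.mean(pred)))
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def loocv_classification(
    spec: ModelSpec, data: pd.DataFrame, threshold: float = 0.5
) -> dict:
    """Threshold the LOO probabilities: observed accuracy and Cohen's kappa."""
    y, probs = _loo_probs(spec, data)
    pred = (probs >= threshold).astype(float)
    return {
        "accuracy": float(np.mean(pred == y)),
        "kappa": _cohen_kappa(y, pred),
        "probs": probs,
        "labels": y,
    }


# ---------------------------------------------------------------- search

def exhaustive_model_search(
    pool: list, response: str, data: pd.DataFrame
) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit every non-empty subset of the term pool; rank by AICc.

    Grouped terms (a quadratic polynomial, a spline, a categorical block)
    enter or leave as a unit.  Unfittable subsets are logged and skipped.
    Returns the best spec and the full leaderboard.
    """
    if len(pool) > 15:
        raise ValueError("pool too large for exhaustive search")
    rows = []
    best: tuple[float, ModelSpec] | None = None
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            spec = ModelSpec(response=response, terms=combo)
            try:
                fit = fit_logistic(spec, data)
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"skipping {spec.describe()}: {exc}")
                continue
            rows.append(
                {
                    "model": spec.describe(),
                    "n_terms": r,
                    "n_params": fit.n_params,
                    "deviance": fit.deviance,
                    "aic": fit.aic,
                    "aicc": fit.aicc,
                }
            )
            if best is None or fit.aicc < best[0]:
                best = (fit.aicc, spec)
    if best is None:
        raise RuntimeError("no candidate model could be fit")
    leaderboard = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    return best[1], leaderboard


# ---------------------------------------------------------------- metrics

def calibrate_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Threshold balancing sensitivity and specificity on LOO probabilities.

    Candidates are the observed probability values plus 0.5; the candidate
    minimizing |sensitivity - specificity| wins, ties resolved toward 0.5.
    """
    probs, labels = np.asarray(probs, float), np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to calibrate a threshold")
    candidates = np.unique(np.append(probs, 0.5))
    best_t, best_gap = None, np.inf
    for t in candidates:
        pred = probs >= t
        sens = np.mean(pred[labels == 1])
        spec_ = np.mean(~pred[labels == 0])
        gap = abs(sens - spec_)
        if gap < best_gap - 1e-12 or (
            abs(gap - best_gap) <= 1e-12 and abs(t - 0.5) < abs(best_t - 0.5)
        ):
            best_gap, best_t = gap, float(t)
    return best_t


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> dict:
    """ROC points and rank-statistic AUC (ties count one half)."""
    probs, labels = np.asarray(probs, float), np.asarray(labels, float)
    pos, neg = probs[labels == 1], probs[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for ROC")
    ranks = stats.rankdata(probs)
    auc = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    points = []
    for t in np.concatenate([[np.inf], np.unique(probs)[::-1], [-np.inf]]):
        pred = probs >= t
        points.append(
            (
                float(np.mean(pred[labels == 0])),  # FPR
                float(np.mean(pred[labels == 1])),  # TPR
            )
        )
    return {"points": np.array(points), "auc": float(auc)}


# ---------------------------------------------------------------- table 1

_CONTINUOUS = ["age", "surgery_minutes", "days_to_discharge", "amap_mmHg", "ahr_bpm"]
_CATEGORICAL = ["ais_admission", "ais_discharge", "nli"]


def cohort_univariate_table(data: pd.DataFrame) -> pd.DataFrame:
    """Demographics split by improvement with univariate tests.

    Continuous variables: mean (SD), median [min, max], missing count and
    an unpaired two-sided Student's t-test.  Categorical variables: level
    counts and a two-sided Fisher exact test (2x2 levels; larger tables
    fall back to the chi-square test of independence).
    """
    known = data.dropna(subset=["improved"])
    g0 = known[known["improved"] == 0]
    g1 = known[known["improved"] == 1]
    rows = []
    for var in _CONTINUOUS:
        if var not in data.columns:
            continue
        a, b = g0[var].dropna(), g1[var].dropna()
        _, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": var,
                "level": "",
                "no_improve": f"{a.mean():.1f} ({a.std():.1f})",
                "improve": f"{b.mean():.1f} ({b.std():.1f})",
                "no_improve_median": f"{a.median():.1f} [{a.min():.1f}, {a.max():.1f}]",
                "improve_median": f"{b.median():.1f} [{b.min():.1f}, {b.max():.1f}]",
                "missing": int(data[var].isna().sum()),
                "p": float(p),
            }
        )
    for var in _CATEGORICAL:
        if var not in data.columns:
            continue
        tab = pd.crosstab(known[var], known["improved"])
        if tab.shape == (2, 2):
            _, p = stats.fisher_exact(tab.to_numpy(), alternative="two-sided")
        else:
            _, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        for level in tab.index:
            n0 = int(tab.loc[level].get(0, 0))
            n1 = int(tab.loc[level].get(1, 0))
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "no_improve": f"{n0} ({100 * n0 / max(len(g0), 1):.1f}%)",
                    "improve": f"{n1} ({100 * n1 / max(len(g1), 1):.1f}%)",
                    "no_improve_median": "",
                    "improve_median": "",
                    "missing": int(data[var].isna().sum()),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
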