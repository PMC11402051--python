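"""Design-based estimation for stratified multi-PSU survey data.

Implements the population-ratio mean, Taylor-linearized (with-replacement,
first-stage) standard errors, survey-weighted trend regression with a
linearized sandwich covariance, and the paired design-based difference test.
Degrees of freedom follow the SAS survey-procedure convention,
df = (number of PSUs) − (number of strata), and p-values use the t
distribution with that df.  No finite-population correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SurveyDesign",
    "DesignEstimate",
    "TrendResult",
    "EstimationError",
    "LonelyPsuError",
    "population_ratio_mean",
    "taylor_linearized_se",
    "trend_regression",
    "age_group_lsmeans",
    "paired_design_test",
    "percent_change",
]


class EstimationError(ValueError):
    """Raised for invalid estimation inputs (empty data, bad weights...)."""


class LonelyPsuError(EstimationError):
    """Raised when a stratum contributes a single PSU: the between-PSU
    variance within that stratum is undefined."""


@dataclass(frozen=True)
class SurveyDesign:
    """Per-observation survey weights and first-stage design identifiers."""

    weights: np.ndarray
    strata: np.ndarray
    psu: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        s = np.asarray(self.strata)
        p = np.asarray(self.psu)
        if not (len(w) == len(s) == len(p)):
            raise EstimationError("weights, strata and psu must have equal length")
        if len(w) == 0:
            raise EstimationError("empty design")
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise EstimationError("survey weights must be positive and finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "strata", s)
        object.__setattr__(self, "psu", p)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        weight: str = "weight",
        stratum: str = "stratum",
        psu: str = "psu",
    ) -> "SurveyDesign":
        return cls(
            df[weight].to_numpy(float), df[stratum].to_numpy(), df[psu].to_numpy()
        )

    def subset(self, mask) -> "SurveyDesign":
        mask = np.asarray(mask)
        return SurveyDesign(self.weights[mask], self.strata[mask], self.psu[mask])

    @property
    def df(self) -> int:
        """Design degrees of freedom: PSUs − strata."""
        cells = pd.MultiIndex.from_arrays([self.strata, self.psu])
        n_psu = cells.drop_duplicates().shape[0]
        n_strata = pd.unique(self.strata).shape[0]
        return n_psu - n_strata


@dataclass(frozen=True)
class DesignEstimate:
    point: float
    se: float
    df: int
    n: int
    p_value: float | None = None
    degenerate: bool = False

    def __repr__(self) -> str:
        p = "" if self.p_value is None else f", p={self.p_value:.4g}"
        return f"DesignEstimate(point={self.point:.6g}, se={self.se:.3g}, df={self.df}, n={self.n}{p})"


@dataclass(frozen=True)
class TrendResult:
    """Survey-weighted regression summary for an age trend."""

    beta_age: float
    se: float
    p_value: float
    df: int
    n: int
    coefficients: pd.Series = field(repr=False, default=None)
    covariance: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------
# Variance machinery
# ---------------------------------------------------------------------

def _psu_total_variance(u: np.ndarray, strata, psu) -> float:
    """With-replacement stratified between-PSU variance of the total of u.

    For each stratum h with n_h PSUs and PSU totals t_hj:
        v_h = n_h/(n_h−1) · Σ_j (t_hj − t̄_h)²,   v = Σ_h v_h.
    """
    df = pd.DataFrame({"u": u, "s": np.asarray(strata), "p": np.asarray(psu)})
    totals = df.groupby(["s", "p"], sort=False, observed=True)["u"].sum()
    var = 0.0
    for _, t in totals.groupby(level=0, sort=False):
        n_h = len(t)
        if n_h < 2:
            raise LonelyPsuError(
                f"stratum {t.index[0][0]!r} has a single PSU; "
                "between-PSU variance is undefined"
            )
        var += n_h / (n_h - 1) * float(((t - t.mean()) ** 2).sum())
    return var


def taylor_linearized_se(z, weights, strata, psu) -> float:
    """Linearized SE: sqrt of the stratified between-PSU variance of the
    weighted PSU totals of the linearized variate ``z``.

    Invariant to uniform weight rescaling when ``z`` scales inversely (as
    for a ratio estimator's linearized variate).
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(_psu_total_variance(w * z, strata, psu)))


def population_ratio_mean(values, design: SurveyDesign) -> DesignEstimate:
    """Per-capita (population-ratio) mean: Σ wᵢxᵢ / Σ wᵢ over everyone,
    consumers and nonconsumers alike, with a Taylor-linearized SE."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise EstimationError("no observations")
    if len(x) != len(design.weights):
        raise EstimationError("values and design lengths differ")
    w = design.weights
    wsum = w.sum()
    point = float(np.dot(w, x) / wsum)
    z = (x - point) / wsum
    se = taylor_linearized_se(z, w, design.strata, design.psu)
    return DesignEstimate(point=point, se=se, df=design.df, n=len(x))


# ---------------------------------------------------------------------
# Survey-weighted regression
# ---------------------------------------------------------------------

#: Reference levels absorbed into the intercept (the largest groups).
REFERENCE_LEVELS = {
    "gender": "male",
    "ethnicity": "non_hispanic_white",
    "pir_category": ">1.85",
}

DEFAULT_COVARIATES = ("gender", "ethnicity", "pir_category")


def _design_matrix(
    df: pd.DataFrame, covariates, age_col="age", age_as="linear"
) -> pd.DataFrame:
    cols = {}
    cols["intercept"] = np.ones(len(df))
    if age_as == "linear":
        cols["age"] = df[age_col].to_numpy(float)
    elif age_as == "categorical":
        ages = sorted(df[age_col].unique())
        for a in ages[1:]:
            cols[f"age[{a}]"] = (df[age_col] == a).to_numpy(float)
    elif age_as != "none":
        raise ValueError(f"unknown age coding {age_as!r}")
    for cov in covariates:
        ref = REFERENCE_LEVELS.get(cov)
        levels = sorted(df[cov].astype(str).unique())
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        for level in levels[1:]:
            cols[f"{cov}[{level}]"] = (df[cov].astype(str) == level).to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _wls_with_linearized_cov(X: pd.DataFrame, y: np.ndarray, design: SurveyDesign):
    """WLS point estimates with a Taylor-linearized sandwich covariance.

    beta = (X'WX)⁻¹ X'Wy; influence totals per PSU of wᵢeᵢxᵢ feed the
    stratified between-PSU variance, sandwiched with (X'WX)⁻¹.
    """
    Xv = X.to_numpy(float)
    w = design.weights
    A = Xv.T @ (Xv * w[:, None])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[0]:
        raise EstimationError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[0]}); "
            "collinear covariates"
        )
    fit = sm.WLS(y, Xv, weights=w).fit()
    beta = fit.params
    resid = y - Xv @ beta
    score = Xv * (w * resid)[:, None]

    cells = pd.DataFrame({"s": design.strata, "p": design.psu})
    totals = (
        pd.concat([cells, pd.DataFrame(score, columns=X.columns, index=cells.index)], axis=1)
        .groupby(["s", "p"], sort=False, observed=True)
        .sum()
    )
    S = np.zeros((Xv.shape[1], Xv.shape[1]))
    for _, t in totals.groupby(level=0, sort=False):
        n_h = len(t)
        if n_h < 2:
            raise LonelyPsuError(
                f"stratum {t.index[0][0]!r} has a single PSU; "
                "between-PSU variance is undefined"
            )
        d = t.to_numpy(float) - t.to_numpy(float).mean(axis=0)
        S += n_h / (n_h - 1) * d.T @ d
    Ainv = np.linalg.inv(A)
    V = Ainv @ S @ Ainv
    return (
        pd.Series(beta, index=X.columns),
        pd.DataFrame(V, index=X.columns, columns=X.columns),
    )


def trend_regression(
    df: pd.DataFrame,
    outcome: str,
    design: SurveyDesign,
    age_col: str = "age",
    covariates=DEFAULT_COVARIATES,
) -> TrendResult:
    """Survey-weighted linear regression of an outcome on continuous age,
    adjusted for demographic covariates.

    ``beta_age`` is the change per 1 y of age.  The p-value uses a t
    reference with design df = PSUs − strata.
    """
    X = _design_matrix(df, covariates, age_col=age_col, age_as="linear")
    y = df[outcome].to_numpy(float)
    beta, V = _wls_with_linearized_cov(X, y, design)
    dfree = design.df
    b = float(beta["age"])
    se = float(np.sqrt(V.loc["age", "age"]))
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(b) / se, dfree))
    else:
        p = 1.0 if b == 0 else 0.0
    return TrendResult(
        beta_age=b, se=se, p_value=p, df=dfree, n=len(df),
        coefficients=beta, covariance=V,
    )


def age_group_lsmeans(
    df: pd.DataFrame,
    outcome: str,
    design: SurveyDesign,
    age_col: str = "age",
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Covariate-adjusted per-age means (predicted marginal means).

    Fits a saturated age model plus covariates and averages predictions
    over the observed (weighted) covariate distribution with age forced to
    each level in turn; the SE of each LS-mean is that of the linear
    functional c'β.  With no covariates this reproduces the per-age
    weighted means exactly.
    """
    X = _design_matrix(df, covariates, age_col=age_col, age_as="categorical")
    y = df[outcome].to_numpy(float)
    beta, V = _wls_with_linearized_cov(X, y, design)
    w = design.weights
    ages = sorted(df[age_col].unique())
    rows = []
    for a in ages:
        Xa = X.copy()
        for col in X.columns:
            if col.startswith("age["):
                Xa[col] = 1.0 if col == f"age[{a}]" else 0.0
        c = (Xa.to_numpy(float) * w[:, None]).sum(axis=0) / w.sum()
        point = float(c @ beta.to_numpy())
        se = float(np.sqrt(c @ V.to_numpy() @ c))
        rows.append({"age": a, "lsmean": point, "se": se,
                     "n": int((df[age_col] == a).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Paired design-based test and percent change
# ---------------------------------------------------------------------

def paired_design_test(
    baseline, adjusted, design: SurveyDesign, alpha: float = 0.01
) -> DesignEstimate:
    """Design-based paired test of adjusted − baseline.

    Identical to a one-sample design-based test on the per-subject
    differences: weighted ratio-mean difference, linearized SE, two-sided
    t p-value at design df.  A zero-SE difference is degenerate: p = 1 when
    the mean difference is 0, else reported as p → 0 with a flag.
    """
    b = np.asarray(baseline, dtype=float)
    a = np.asarray(adjusted, dtype=float)
    if b.shape != a.shape:
        raise EstimationError("baseline and adjusted must cover the same subjects")
    est = population_ratio_mean(a - b, design)
    # an SE at floating-point noise level means the differences are constant;
    # a constant difference at noise level relative to the data is no change
    scale = max(1.0, float(np.max(np.abs(b))) if len(b) else 1.0)
    if est.se <= max(abs(est.point), 1.0) * 1e-12:
        p = 1.0 if abs(est.point) <= 1e-9 * scale else 0.0
        return DesignEstimate(est.point, 0.0, est.df, est.n, p_value=p, degenerate=True)
    t = est.point / est.se
    p = float(2.0 * stats.t.sf(abs(t), est.df))
    return DesignEstimate(est.point, est.se, est.df, est.n, p_value=p)


def percent_change(first: float, last: float, rounded: bool = True) -> float:
    """Percent change from the age-1 mean to the age-5 mean,
    100·(last − first)/first, rounded half-away-from-zero to an integer
    percent by default."""
    if first == 0:
        raise EstimationError("percent change undefined for a zero first mean")
    pct = 100.0 * (last - first) / first
    if not rounded:
        return pct
    return float(np.sign(pct) * np.floor(abs(pct) + 0.5))
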