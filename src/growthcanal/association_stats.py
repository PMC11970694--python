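"""Inferential layer: OLS of HAZ on THz plus covariates, ANOVA, chi-square.

The central question for the regressions is how strongly the mid-parental
target height z-score (THz) predicts a child's current height-for-age
z-score (HAZ) at different ages: under canalization the THz coefficient
approaches one as children converge to their growth channel by about two
years of age.  Models are fitted separately within three age groups
(0-<6 months, 6-<24 months, 2-5 years) as ordinary least squares with an
intercept; categorical predictors are expanded to indicator contrasts with
the first level as reference.  Because "association between THz and HAZ"
can be read as either a Pearson correlation or a standardized regression
coefficient, :func:`thz_haz_association` reports both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AGE_GROUPS",
    "RegressionSpec",
    "RegressionResult",
    "AnovaResult",
    "fit_ols",
    "one_way_anova",
    "chi_square_test",
    "thz_haz_association",
    "run_default_models",
]

logger = logging.getLogger(__name__)

#: half-open age windows in months
AGE_GROUPS = {"m0_6": (0.0, 6.0), "m6_24": (6.0, 24.0), "y2_5": (24.0, 60.0)}

DEFAULT_PREDICTORS = (
    "thz",
    "residency",
    "island",
    "father_basic_edu",
    "mother_basic_edu",
    "food_share",
    "household_size",
    "wave",
)
DEFAULT_CATEGORICAL = ("residency", "island", "wave")


@dataclass(frozen=True)
class RegressionSpec:
    response: str = "haz"
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    age_group: str | None = None
    categorical: Sequence[str] = DEFAULT_CATEGORICAL

    def __post_init__(self):
        if self.response in self.predictors:
            raise ValueError("response must not be among predictors")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")


@dataclass(frozen=True)
class RegressionResult:
    params: pd.DataFrame = field(repr=False)  # term, estimate, se, p
    r2: float
    adj_r2: float
    n: int
    n_dropped: int

    def estimate(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def _design_matrix(data: pd.DataFrame, predictors, categorical) -> pd.DataFrame:
    parts = []
    for p in predictors:
        col = data[p]
        as_cat = (
            p in categorical
            or col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool
        )
        if as_cat:
            dummies = pd.get_dummies(col.astype("category"), prefix=p, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(col.astype(float))
    X = pd.concat(parts, axis=1)
    return sm.add_constant(X, has_constant="add")


def _collinear_columns(X: pd.DataFrame) -> list:
    arr = X.to_numpy(dtype=float)
    bad = []
    for j in range(1, arr.shape[1]):  # skip the intercept
        prev = arr[:, :j]
        if np.linalg.matrix_rank(np.c_[prev, arr[:, j]]) == np.linalg.matrix_rank(prev):
            bad.append(str(X.columns[j]))
    return bad


def fit_ols(spec: RegressionSpec, cohort: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with intercept for one regression spec.

    Rows with missing values in any used column are dropped (complete-case)
    and counted.  A rank-deficient design raises an error naming the
    collinear columns.  adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).
    """
    cols = [spec.response] + list(spec.predictors)
    df = cohort
    if spec.age_group is not None:
        lo, hi = AGE_GROUPS[spec.age_group]
        df = df[(df["age_months"] >= lo) & (df["age_months"] < hi)]
    data = df[cols].dropna()
    n_dropped = len(df) - len(data)
    if n_dropped:
        logger.info("fit_ols: %d row(s) dropped for missing values", n_dropped)
    X = _design_matrix(data, spec.predictors, spec.categorical)
    if len(data) <= X.shape[1]:
        raise ValueError(f"too few rows ({len(data)}) for {X.shape[1]} parameters")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_collinear_columns(X)}")
    y = data[spec.response].astype(float)
    fit = sm.OLS(y, X).fit()
    params = pd.DataFrame(
        {"term": fit.params.index, "estimate": fit.params.to_numpy(),
         "se": fit.bse.to_numpy(), "p": fit.pvalues.to_numpy()}
    ).reset_index(drop=True)
    return RegressionResult(
        params=params,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        n_dropped=n_dropped,
    )


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA over a collection of real vectors.

    Degenerate cases: all observations identical gives F = 0/0, reported as
    NaN (not computable); zero within-group variance with distinct means
    gives F = inf with p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    N = sum(len(a) for a in arrays)
    grand = sum(a.sum() for a in arrays) / N
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = len(arrays) - 1, N - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(float("nan"), df1, df2, float("nan"))
        return AnovaResult(float("inf"), df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(float(F), df1, df2, float(stats.f.sf(F, df1, df2)))


def chi_square_test(table):
    """Pearson chi-square on a 2-D contingency table, no continuity
    correction.  df = (r - 1)(c - 1).  Zero marginals are an error."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def thz_haz_association(cohort: pd.DataFrame, spec: RegressionSpec | None = None) -> pd.DataFrame:
    """Per-age-group strength of the THz-HAZ association, both readings.

    Returns one row per age group with the Pearson correlation, the raw and
    standardized multivariate OLS coefficient of THz, and the model R^2 /
    adjusted R^2.
    """
    base = spec or RegressionSpec()
    rows = []
    for group in AGE_GROUPS:
        gspec = RegressionSpec(
            response=base.response, predictors=base.predictors,
            age_group=group, categorical=base.categorical,
        )
        res = fit_ols(gspec, cohort)
        lo, hi = AGE_GROUPS[group]
        sub = cohort[(cohort["age_months"] >= lo) & (cohort["age_months"] < hi)]
        sub = sub[[base.response, "thz"]].dropna()
        pearson = float(sub[base.response].corr(sub["thz"]))
        beta = res.estimate("thz")
        std_beta = beta * float(sub["thz"].std(ddof=1) / sub[base.response].std(ddof=1))
        rows.append(
            {"age_group": group, "pearson_r": pearson, "beta_thz": beta,
             "std_beta_thz": std_beta, "r2": res.r2, "adj_r2": res.adj_r2, "n": res.n}
        )
    return pd.DataFrame(rows)


def run_default_models(cohort: pd.DataFrame):
    """The standard model battery for the analysis stage.

    Returns ``(regression_df, tests_df)``: per-age-group OLS terms with the
    two R^2 figures, and a small table of group-comparison tests (ANOVA of
    HAZ and of the discrepancy across waves, chi-square of nutritional
    status and of residency by wave).
    """
    reg_rows = []
    for group in AGE_GROUPS:
        spec = RegressionSpec(age_group=group)
        res = fit_ols(spec, cohort)
        for rec in res.params.itertuples(index=False):
            reg_rows.append(
                {"age_group": group, "term": rec.term, "estimate": rec.estimate,
                 "se": rec.se, "p": rec.p, "r2": res.r2, "adj_r2": res.adj_r2, "n": res.n}
            )
    regression = pd.DataFrame(reg_rows)

    test_rows = []
    usable = cohort.dropna(subset=["haz"])
    groups = [g["haz"].to_numpy() for _, g in usable.groupby("wave", sort=True)]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        F, df1, df2, p = one_way_anova(groups)
        test_rows.append(
            {"test": "anova_haz_by_wave", "statistic": F, "df1": df1, "df2": df2, "p": p}
        )
    if "discrepancy" in cohort.columns:
        usable_d = cohort.dropna(subset=["discrepancy"])
        dgroups = [g["discrepancy"].to_numpy() for _, g in usable_d.groupby("wave", sort=True)]
        if len(dgroups) >= 2 and all(len(g) >= 2 for g in dgroups):
            F, df1, df2, p = one_way_anova(dgroups)
            test_rows.append(
                {"test": "anova_discrepancy_by_wave", "statistic": F, "df1": df1,
                 "df2": df2, "p": p}
            )
    for col, name in (("nutritional_status", "chi2_nutrition_by_wave"),
                      ("residency", "chi2_residency_by_wave")):
        if col in cohort.columns:
            tab = pd.crosstab(cohort[col], cohort["wave"])
            if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.to_numpy().sum(0) > 0).all():
                try:
                    chi2, df, p = chi_square_test(tab.to_numpy())
                except ValueError:
                    continue
                test_rows.append(
                    {"test": name, "statistic": chi2, "df1": df, "df2": np.nan, "p": p}
                )
    tests = pd.DataFrame(test_rows)
    return regression, tests
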