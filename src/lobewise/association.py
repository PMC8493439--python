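"""Cohort-level association models downstream of the vertexwise analysis.

Implements the secondary regressions: cluster-mean cortical thinning as a
predictor of delayed recall memory; race/ethnicity x WMH interaction models
of cluster-mean thinning; the same models stratified by group; and
covariate-adjusted one-way tests of group differences in WMH and thinning.
All models are ordinary least squares with classical t confidence intervals;
standardized coefficients use the b * SD(x)/SD(y) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import (
    COVARIATE_SETS,
    GROUPS,
    build_design,
    check_full_rank,
    group_dummies,
)


@dataclass
class ModelSpec:
    """Which outcome/predictor/covariate-set combination to fit.

    ``covariate_set`` is one of "primary", "primary-minus-entorhinal",
    "primary-plus-education"; ``stratum`` restricts the fit to one
    race/ethnicity group.
    """

    outcome: str
    predictor: str
    covariate_set: str = "primary"
    interaction: bool = False
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set '{self.covariate_set}'")
        if self.stratum is not None and self.stratum not in GROUPS:
            raise ValueError(f"unknown stratum '{self.stratum}'")

    @property
    def covariates(self) -> tuple[str, ...]:
        return COVARIATE_SETS[self.covariate_set]


@dataclass
class FitSummary:
    """Coefficient table (b, 95% CI, p, standardized beta) plus model sizes."""

    coefficients: pd.DataFrame
    n: int
    dof: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]


def _summarize_ols(y: pd.Series, design: pd.DataFrame) -> FitSummary:
    check_full_rank(design)
    yv = np.asarray(y, dtype=float)
    model = sm.OLS(yv, design.to_numpy(dtype=float))
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    sd_y = float(np.std(yv, ddof=1))
    rows = []
    for i, name in enumerate(design.columns):
        x = design[name].to_numpy(dtype=float)
        sd_x = float(np.std(x, ddof=1))
        std_beta = (
            res.params[i] * sd_x / sd_y if (name != "intercept" and sd_y > 0) else np.nan
        )
        rows.append(
            {
                "term": name,
                "b": float(res.params[i]),
                "ci_low": float(ci[i, 0]),
                "ci_high": float(ci[i, 1]),
                "p": float(res.pvalues[i]),
                "beta_std": std_beta,
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    return FitSummary(coefficients=table, n=int(res.nobs), dof=int(res.df_resid))


def fit_memory_model(
    cohort: pd.DataFrame, cluster_col: str, spec: ModelSpec | None = None
) -> FitSummary:
    """OLS of delayed recall on cluster-mean thinning plus covariates.

    Covariates: the configured set (default age, sex/gender, APOE e4,
    baseline entorhinal thickness) plus the time between the memory test and
    the second scan.
    """
    spec = spec or ModelSpec(outcome="delayed_recall", predictor=cluster_col)
    covs = spec.covariates + ("test_scan_interval",)
    design = build_design(cohort, cluster_col, covariates=covs)
    return _summarize_ols(cohort[spec.outcome], design)


def fit_interaction_model(
    cohort: pd.DataFrame,
    cluster_col: str,
    wmh_col: str,
    covariate_set: str = "primary",
) -> FitSummary:
    """Race/ethnicity x WMH interaction model of cluster-mean thinning.

    White is the reference group; the model contains group main effects, the
    WMH volume, group x WMH products, and the primary covariates.  The
    Black x WMH and Hispanic x WMH rows answer whether the WMH-thinning
    slope differs from the White participants'.
    """
    for g, sub in cohort.groupby("race_ethnicity"):
        if sub[wmh_col].nunique() < 2:
            raise ValueError(
                f"stratum '{g}' has fewer than 2 distinct {wmh_col} values"
            )
    design = build_design(
        cohort,
        wmh_col,
        covariates=COVARIATE_SETS[covariate_set],
        include_groups=True,
        interaction=True,
    )
    return _summarize_ols(cohort[cluster_col], design)


def fit_stratified(
    cohort: pd.DataFrame,
    cluster_col: str,
    wmh_col: str,
    stratum: str,
    covariate_set: str = "primary",
) -> FitSummary:
    """WMH -> cluster-mean thinning model within one race/ethnicity group."""
    if stratum not in GROUPS:
        raise ValueError(f"unknown stratum '{stratum}'")
    sub = cohort[cohort["race_ethnicity"] == stratum]
    if len(sub) == 0:
        raise ValueError(f"no subjects in stratum '{stratum}'")
    design = build_design(sub, wmh_col, covariates=COVARIATE_SETS[covariate_set])
    return _summarize_ols(sub[cluster_col], design)


def stratified_table(
    cohort: pd.DataFrame, cluster_cols: Sequence[str], wmh_col: str
) -> pd.DataFrame:
    """Per-(cluster, group) slope table: b, 95% CI and p for the WMH term."""
    rows = []
    for cl in cluster_cols:
        for g in GROUPS:
            s = fit_stratified(cohort, cl, wmh_col, g)[wmh_col]
            rows.append(
                {
                    "cluster": cl,
                    "group": g,
                    "b": s["b"],
                    "ci_low": s["ci_low"],
                    "ci_high": s["ci_high"],
                    "p": s["p"],
                }
            )
    return pd.DataFrame(rows)


def group_difference_tests(
    cohort: pd.DataFrame,
    measures: Sequence[str],
    covariates: tuple[str, ...] = ("age", "female", "apoe4"),
) -> pd.DataFrame:
    """Covariate-adjusted one-way F test of group differences per measure.

    Fits measure ~ group indicators + covariates and tests the joint null
    that both group coefficients are zero (analysis of covariance).
    """
    counts = cohort["race_ethnicity"].value_counts()
    if (counts < 2).any() or counts.size < 2:
        raise ValueError("need at least 2 groups with at least 2 subjects each")
    gd = group_dummies(cohort["race_ethnicity"])
    rows = []
    for m in measures:
        if m not in cohort:
            raise KeyError(f"cohort table lacks measure '{m}'")
        design = pd.concat(
            [
                pd.DataFrame({"intercept": np.ones(len(cohort))}, index=cohort.index),
                gd,
                cohort[list(covariates)].astype(float),
            ],
            axis=1,
        )
        check_full_rank(design)
        res = sm.OLS(
            cohort[m].to_numpy(dtype=float), design.to_numpy(dtype=float)
        ).fit()
        R = np.zeros((2, design.shape[1]))
        R[0, 1] = 1.0  # group_Black
        R[1, 2] = 1.0  # group_Hispanic
        ft = res.f_test(R)
        rows.append({"measure": m, "F": float(ft.fvalue), "p": float(ft.pvalue)})
    return pd.DataFrame(rows)
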