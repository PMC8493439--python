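"""Design-matrix construction shared by the vertexwise and cohort-level models.

The primary covariate set follows the study design: age, sex/gender (women
indicator, men as reference), APOE e4 carrier status, and baseline entorhinal
cortical thickness.  Race/ethnicity is coded with non-Hispanic White as the
reference category (Black and Hispanic indicators); interaction designs add
group x WMH product terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ("White", "Black", "Hispanic")

PRIMARY_COVARIATES = ("age", "female", "apoe4", "entorhinal_baseline")

COVARIATE_SETS = {
    "primary": PRIMARY_COVARIATES,
    "primary-minus-entorhinal": ("age", "female", "apoe4"),
    "primary-plus-education": PRIMARY_COVARIATES + ("education",),
}


class RankDeficientError(ValueError):
    """Raised when a design matrix is not of full column rank."""


def group_dummies(groups: pd.Series) -> pd.DataFrame:
    """Black/Hispanic indicators with White as the reference category."""
    bad = set(groups.unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown race/ethnicity codes: {sorted(bad)}")
    return pd.DataFrame(
        {
            "group_Black": (groups == "Black").astype(float),
            "group_Hispanic": (groups == "Hispanic").astype(float),
        },
        index=groups.index,
    )


def build_design(
    cohort: pd.DataFrame,
    predictor: str,
    covariates: tuple[str, ...] = PRIMARY_COVARIATES,
    include_groups: bool = False,
    interaction: bool = False,
) -> pd.DataFrame:
    """Assemble an intercept-first design matrix from a cohort table.

    With ``include_groups`` the Black/Hispanic main effects are added; with
    ``interaction`` also their products with the focal predictor.
    """
    cols = {"intercept": np.ones(len(cohort))}
    cols[predictor] = cohort[predictor].to_numpy(dtype=float)
    for c in covariates:
        if c not in cohort:
            raise KeyError(f"cohort table lacks required column '{c}'")
        cols[c] = cohort[c].to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=cohort.index)
    if include_groups or interaction:
        gd = group_dummies(cohort["race_ethnicity"])
        design = pd.concat([design, gd], axis=1)
    if interaction:
        for g in ("Black", "Hispanic"):
            design[f"group_{g}:{predictor}"] = (
                design[f"group_{g}"] * design[predictor]
            )
    check_full_rank(design)
    return design


def check_full_rank(design: pd.DataFrame) -> None:
    """Verify full column rank, naming the collinear columns on failure."""
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending columns by greedy elimination
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
        dropped = [design.columns[j] for j in range(X.shape[1]) if j not in keep]
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns: {dropped}"
        )
    if X.shape[0] <= X.shape[1] + 1:
        raise RankDeficientError(
            f"too few rows ({X.shape[0]}) for {X.shape[1]} columns"
        )
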