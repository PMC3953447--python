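"""Residual-method covariate adjustment.

Every predictor and outcome variable is regressed (ordinary least squares,
with intercept) on the adjustment covariates — age and height by default —
and replaced by its residuals.  Downstream correlation and regression
statistics then describe associations free of the variation caused by body
size and age.  BMI is treated like any other variable: although weight/height²
is nominally height-free, it retains a small height correlation (~0.2) within
sex and is therefore residual-adjusted too.

All analyses of the validation design are sex-stratified; adjustment is
performed within sex by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: cohort-CSV columns used as adjustment covariates by default
DEFAULT_COVARIATES = ["age_substudy", "height_cm"]


@dataclass
class AdjustedMatrix:
    """Residualized variable matrix for one stratum.

    ``data`` holds one zero-mean residual column per variable; ``coefficients``
    the per-variable OLS coefficients (intercept first) that were removed.
    """

    labels: list[str]
    data: pd.DataFrame
    covariates: list[str]
    coefficients: pd.DataFrame
    stratum: str = "all"

    @property
    def n(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def column(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy(float)


def _residualize(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef, coef


def residual_adjust(
    cohort: pd.DataFrame,
    variables: list[str],
    covariates: list[str] | None = None,
    stratify_by_sex: bool = True,
) -> dict[str, AdjustedMatrix]:
    """Residual-adjust ``variables`` for ``covariates`` within each sex stratum.

    Parameters
    ----------
    cohort
        Cohort table; must contain ``sex`` when ``stratify_by_sex`` and all
        named columns complete (no missing values — subset first).
    variables, covariates
        Column names; covariates default to sub-study age and height.

    Returns
    -------
    dict mapping stratum name (``male``/``female`` or ``all``) to
    :class:`AdjustedMatrix`.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    needed = list(variables) + covariates
    for col in needed:
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} missing from cohort")
        if cohort[col].isna().any():
            raise ValueError(
                f"column {col!r} contains missing values; subset to complete cases first"
            )
    strata = (
        {str(s): g for s, g in cohort.groupby("sex", sort=True)}
        if stratify_by_sex
        else {"all": cohort}
    )
    out: dict[str, AdjustedMatrix] = {}
    for name, grp in strata.items():
        n = len(grp)
        if n <= len(covariates) + 1:
            raise ValueError(f"stratum {name!r}: n={n} too small for {len(covariates)} covariates")
        design = np.column_stack(
            [np.ones(n)] + [grp[c].to_numpy(float) for c in covariates]
        )
        for c in covariates:
            if np.std(grp[c].to_numpy(float)) == 0:
                raise ValueError(f"zero-variance covariate {c!r} in stratum {name!r}")
        resid = {}
        coefs = {}
        for v in variables:
            r, b = _residualize(grp[v].to_numpy(float), design)
            resid[v], coefs[v] = r, b
        out[name] = AdjustedMatrix(
            labels=list(variables),
            data=pd.DataFrame(resid, index=grp.index),
            covariates=covariates,
            coefficients=pd.DataFrame(coefs, index=["intercept"] + covariates),
            stratum=name,
        )
    return out


def write_adjusted_csv(adjusted: dict[str, AdjustedMatrix], path) -> None:
    """Write residual columns (suffixed ``_adj``) of all strata to one CSV."""
    frames = []
    for name, am in adjusted.items():
        df = am.data.add_suffix("_adj").copy()
        df.insert(0, "stratum", name)
        frames.append(df)
    pd.concat(frames).to_csv(path, index_label="subject_id")
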