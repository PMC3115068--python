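"""ROI statistics and regression of diffusion indices on PMI and SI.

The analysis regresses per-specimen ROI means of FA, MD, axial and radial
diffusivity onto post-mortem interval (hours) and scan interval (months):
single regressions for visualisation, a multiple regression on both
covariates for inference (which linearly adjusts for the PMI--SI
correlation), with multiple-comparison correction across the tested family.
With 11 specimens and two predictors plus intercept the residual degrees of
freedom are 11 - 3 = 8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phantom import WM_ROIS

__all__ = [
    "RegressionResult",
    "roi_means",
    "ols",
    "analyze_cohort",
    "CohortReport",
]

INDICES = ["FA", "MD", "D_ax", "D_rad"]
REPORT_COLUMNS = ["CC", "SLF", "Opt", "Cing", "PLIC", "Average"]


@dataclass
class RegressionResult:
    """Closed-form OLS summary for one response."""

    params: pd.Series          # coefficient per predictor (incl. intercept)
    bse: pd.Series             # standard errors
    tvalues: pd.Series
    pvalues: pd.Series         # two-sided, t-distribution
    df_resid: int
    r_squared: float
    corrected_pvalues: pd.Series | None = None


def ols(y, X: pd.DataFrame) -> RegressionResult:
    """OLS of y on the named predictors plus an intercept.

    Rejects near-collinear designs (condition number > 1e8).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if y.size <= X.shape[1] + 1:
        raise ValueError(
            f"need n > p + 1 (n={y.size}, predictors={X.shape[1]})"
        )
    design = sm.add_constant(X, has_constant="add")
    cond = np.linalg.cond(np.asarray(design, dtype=float))
    if cond > 1e8:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
        pvalues=fit.pvalues, df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
    )


def roi_means(maps, labels: np.ndarray, roi_names: dict) -> pd.DataFrame:
    """Mean FA/MD/D_ax/D_rad over unflagged voxels per labelled ROI.

    ``roi_names`` maps integer label -> ROI name; empty ROIs produce NaN
    rows with a warning.
    """
    rows = []
    ok = ~maps.flags
    for code, name in roi_names.items():
        m = (labels == code) & ok
        if not m.any():
            warnings.warn(f"ROI '{name}' (label {code}) has no usable voxels")
            rows.append({"roi": name, "FA": np.nan, "MD": np.nan,
                         "D_ax": np.nan, "D_rad": np.nan, "n_voxels": 0})
            continue
        rows.append({
            "roi": name,
            "FA": float(maps.fa[m].mean()),
            "MD": float(maps.md[m].mean()),
            "D_ax": float(maps.d_ax[m].mean()),
            "D_rad": float(maps.d_rad[m].mean()),
            "n_voxels": int(m.sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class CohortReport:
    """Regression coefficients laid out as (predictor, index) x ROI."""

    coefficients: pd.DataFrame       # multiple-regression coefficients
    pvalues: pd.DataFrame            # raw p (multiple regression)
    corrected_pvalues: pd.DataFrame
    significant: pd.DataFrame        # corrected p <= alpha
    reported: pd.DataFrame           # coefficients with suppression applied
    single: pd.DataFrame             # long table of single-regression slopes
    alpha: float
    correction: str
    suppress_above: float


def _check_table(table: pd.DataFrame) -> None:
    required = {"specimen", "roi", "pmi_hours", "si_months", *INDICES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    bad = table[table[["pmi_hours", "si_months"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"missing covariates for specimens: {sorted(bad.specimen.unique())}"
        )


def analyze_cohort(table: pd.DataFrame, alpha: float = 0.05,
                   correction: str = "bonferroni",
                   suppress_above: float = 0.25) -> CohortReport:
    """Per-ROI and average-WM regressions of each index on PMI and SI.

    The "Average" column averages the five white-matter ROIs per specimen
    before regressing.  Correction is applied per predictor across the
    family of 4 indices x 6 columns; coefficients whose corrected p exceeds
    ``suppress_above`` are blanked in the ``reported`` table (the
    conventional reporting rule for such tables, configurable).
    """
    _check_table(table)
    n_spec = table["specimen"].nunique()
    if n_spec < 5:
        raise ValueError(f"need at least 5 specimens, got {n_spec}")

    wide = table.pivot_table(index="specimen", columns="roi",
                             values=INDICES, aggfunc="mean")
    cov = table.groupby("specimen")[["pmi_hours", "si_months"]].first()

    def column_values(idx, col):
        if col == "Average":
            present = [r for r in WM_ROIS if (idx, r) in wide.columns]
            return wide[idx][present].mean(axis=1)
        return wide[(idx, col)]

    shape = pd.MultiIndex.from_product(
        [["PMI", "SI"], INDICES], names=["predictor", "index"]
    )
    coef = pd.DataFrame(index=shape, columns=REPORT_COLUMNS, dtype=float)
    pval = coef.copy()
    singles = []
    for idx in INDICES:
        for col in REPORT_COLUMNS:
            if col != "Average" and ("FA", col) not in wide.columns:
                continue
            y = column_values(idx, col).loc[cov.index]
            multi = ols(y, cov.rename(
                columns={"pmi_hours": "PMI", "si_months": "SI"}))
            for pred in ("PMI", "SI"):
                coef.loc[(pred, idx), col] = multi.params[pred]
                pval.loc[(pred, idx), col] = multi.pvalues[pred]
                single = ols(y, cov[[{"PMI": "pmi_hours", "SI": "si_months"}[pred]]])
                singles.append({
                    "index": idx, "roi": col, "predictor": pred,
                    "slope": float(single.params.iloc[1]),
                    "p": float(single.pvalues.iloc[1]),
                    "r_squared": single.r_squared,
                })

    corrected = pval.copy()
    for pred in ("PMI", "SI"):
        block = pval.loc[pred]
        m = block.notna().to_numpy().sum()
        if correction == "bonferroni":
            corrected.loc[pred] = np.minimum(block.to_numpy() * m, 1.0)
        elif correction == "none":
            corrected.loc[pred] = block.to_numpy()
        else:
            raise ValueError(f"unknown correction '{correction}'")

    significant = corrected <= alpha
    reported = coef.where(corrected <= suppress_above)
    return CohortReport(
        coefficients=coef, pvalues=pval, corrected_pvalues=corrected,
        significant=significant, reported=reported,
        single=pd.DataFrame(singles), alpha=alpha, correction=correction,
        suppress_above=suppress_above,
    )
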