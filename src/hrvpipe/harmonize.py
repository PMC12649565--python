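"""Covariate adjustment and standardization of the metric matrix.

Two-step procedure, applied within each measurement timepoint:

1. **Residualization** - each metric is regressed (OLS) on the subject
   covariates (maternal age, gestational age, BMI); the residuals, the
   part of the metric unexplained by the covariates, are carried forward:

       metric = b0 + b1*age + b2*gestational_age + b3*bmi + e

2. **Z-scoring** - residuals are standardized column-wise to mean 0, SD 1
   (population-SD convention), so all metrics enter the PCA on an equal
   footing.

Missing data are handled by listwise deletion on the covariates before
fitting; missing metric entries are excluded per metric and stay missing
in the output.  Adjustment is validated by checking that every residual
column has |r| < 0.1 with every covariate while the metric-metric
correlation structure is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustedMatrix",
    "residualize",
    "zscore",
    "harmonize_matrix",
    "validate_adjustment",
]

DEFAULT_COVARIATES = ("maternal_age", "gestational_age", "bmi")
MIN_SUBJECTS = 5


@dataclass
class AdjustedMatrix:
    """Residualized (optionally z-scored) metric matrix with provenance."""

    values: pd.DataFrame  # subjects x metrics
    coefficients: pd.DataFrame  # metrics x (const + covariates)
    covariates: pd.DataFrame  # subjects x covariates actually used
    timepoint: str = ""
    zscored: bool = False
    constant_columns: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)


def residualize(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
    timepoint: str = "",
) -> AdjustedMatrix:
    """Per-metric OLS residuals on the covariates (pre z-score).

    Rows with any missing covariate are dropped (listwise deletion).
    A constant metric column yields all-zero residuals and is flagged.
    Residualization is idempotent: applying it to its own output changes
    nothing beyond numerical noise.
    """
    cov = covariates.loc[matrix.index, list(covariate_names)]
    keep = cov.notna().all(axis=1)
    if keep.sum() < MIN_SUBJECTS:
        raise ValueError(
            f"only {int(keep.sum())} subjects with complete covariates; "
            f"need at least {MIN_SUBJECTS} for an identifiable fit"
        )
    cov = cov.loc[keep]
    mat = matrix.loc[keep]
    design = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    coef_rows = {}
    resid = pd.DataFrame(np.nan, index=mat.index, columns=mat.columns)
    constants = []
    for col in mat.columns:
        y = mat[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() <= design.shape[1]:
            coef_rows[col] = np.full(design.shape[1], np.nan)
            continue
        if np.nanstd(y[ok]) == 0.0:
            constants.append(col)
            resid.loc[ok, col] = 0.0
            coef_rows[col] = np.concatenate([[y[ok][0]],
                                             np.zeros(design.shape[1] - 1)])
            continue
        beta, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
        resid.loc[ok, col] = y[ok] - design[ok] @ beta
        coef_rows[col] = beta
    coefs = pd.DataFrame(coef_rows, index=["const", *covariate_names]).T
    return AdjustedMatrix(resid, coefs, cov, timepoint=timepoint,
                          constant_columns=constants)


def zscore(adjusted: AdjustedMatrix) -> AdjustedMatrix:
    """Column-wise standardization to mean 0, SD 1 (population SD).

    Flagged constant and all-missing columns are dropped with a log entry;
    missing entries stay missing and are excluded from the moments.
    """
    vals = adjusted.values.copy()
    dropped = list(adjusted.dropped_columns)
    for col in list(vals.columns):
        y = vals[col]
        if y.notna().sum() == 0 or col in adjusted.constant_columns:
            vals = vals.drop(columns=col)
            dropped.append(col)
            logger.info("dropping column %r (constant or all-missing)", col)
            continue
        sd = y.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            vals = vals.drop(columns=col)
            dropped.append(col)
            logger.info("dropping column %r (zero residual variance)", col)
            continue
        vals[col] = (y - y.mean()) / sd
    return AdjustedMatrix(vals, adjusted.coefficients, adjusted.covariates,
                          timepoint=adjusted.timepoint, zscored=True,
                          constant_columns=adjusted.constant_columns,
                          dropped_columns=dropped)


def harmonize_matrix(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
    timepoint: str = "",
) -> AdjustedMatrix:
    """Residualize then z-score: the full two-step adjustment."""
    return zscore(residualize(matrix, covariates, covariate_names, timepoint))


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def validate_adjustment(
    adjusted: AdjustedMatrix,
    original: pd.DataFrame | None = None,
    max_abs_r: float = 0.1,
) -> dict:
    """Report confounder leakage and correlation-structure preservation.

    Returns max |corr(metric, covariate)| per covariate (pass criterion:
    all below ``max_abs_r``) and, when the unadjusted matrix is supplied,
    a Mantel-style Pearson correlation between the vectorized pre- and
    post-adjustment metric-metric correlation matrices.
    """
    vals = adjusted.values
    cov = adjusted.covariates
    leak = {}
    for c in cov.columns:
        rs = vals.corrwith(cov[c])
        leak[c] = float(rs.abs().max())
    report = {
        "max_abs_corr_per_covariate": leak,
        "max_abs_corr": max(leak.values()) if leak else np.nan,
        "passes": all(v < max_abs_r for v in leak.values()),
        "threshold": max_abs_r,
    }
    if original is not None:
        cols = [c for c in vals.columns if c in original.columns]
        pre = original.loc[vals.index, cols].corr().to_numpy()
        post = vals[cols].corr().to_numpy()
        u1, u2 = _upper(pre), _upper(post)
        ok = np.isfinite(u1) & np.isfinite(u2)
        report["structure_preservation"] = float(np.corrcoef(u1[ok], u2[ok])[0, 1])
    return report
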