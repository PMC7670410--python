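"""Plate-reader validation arithmetic for forward-engineered promoters.

Each designed promoter drives mKate2 while a second operon constitutively
expresses sfGFP as an internal reference.  The corrected fluorescence of a
well is the blank-subtracted mKate2 signal over the blank-subtracted sfGFP
signal, which normalises extrinsic effects (plasmid copy number, cell
size).  Per-promoter means over biological replicates are log-transformed
and min-max normalised to [0, 1]; the ordinal agreement between predicted
class and measurement is summarised by Spearman's rho and an ordinary
least-squares fit with confidence and prediction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .evalmetrics import spearman_rank


def corrected_fluorescence(fl_mkate2: float, fl_sfgfp: float,
                           fl_mkate2_medium: float, fl_sfgfp_medium: float) -> float:
    """(mKate2 - blank) / (sfGFP - blank)."""
    denom = fl_sfgfp - fl_sfgfp_medium
    if denom <= 0:
        raise ValueError("invalid_reference_signal")
    return (fl_mkate2 - fl_mkate2_medium) / denom


def corrected_fluorescence_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised corrected fluorescence for a plate table.

    Expects columns fl_mkate2, fl_sfgfp, fl_mkate2_medium, fl_sfgfp_medium.
    """
    denom = df["fl_sfgfp"] - df["fl_sfgfp_medium"]
    if (denom <= 0).any():
        raise ValueError("invalid_reference_signal")
    return (df["fl_mkate2"] - df["fl_mkate2_medium"]) / denom


def log_normalize(values: np.ndarray) -> np.ndarray:
    """x = (log P - log P_min) / (log P_max - log P_min), in [0, 1].

    Scale-invariant (a common multiplicative factor cancels); the extreme
    promoters map exactly to 0 and 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if (values <= 0).any():
        raise ValueError("values must be positive for the log transform")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("degenerate_range")
    logv = np.log(values)
    return (logv - np.log(lo)) / (np.log(hi) - np.log(lo))


@dataclass
class ValidationResult:
    """Regression/correlation summary of predicted class vs measurement."""

    normalized_x: np.ndarray
    predicted_classes: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float
    class_mean_ci95: pd.DataFrame        # class, mean, ci_low, ci_high
    prediction_interval_50: pd.DataFrame  # class, fit, pi_low, pi_high
    ols_results: object = None

    def summary(self) -> str:
        lines = [
            "In vivo panel validation",
            "=" * 40,
            f"promoters        {len(self.normalized_x)}",
            f"Spearman rho     {self.spearman_rho:.3f}",
            f"R-squared        {self.r_squared:.3f}",
            f"slope            {self.slope:.4f}",
            f"intercept        {self.intercept:.4f}",
        ]
        return "\n".join(lines)


def validate_panel(predicted_classes, normalized_x,
                   pi_level: float = 0.50) -> ValidationResult:
    """OLS of normalised measurement on predicted class, with intervals.

    Returns the regression slope/intercept/R², Spearman's rho between class
    and measurement, a 95% t confidence interval for each class mean, and a
    prediction interval (default 50%) around the fitted line computed from
    the regression's residual variance with n - 2 degrees of freedom.
    """
    y = np.asarray(normalized_x, dtype=np.float64)
    c = np.asarray(predicted_classes, dtype=np.float64)
    if y.size != c.size or y.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct predicted classes")

    X = sm.add_constant(c)
    ols = sm.OLS(y, X).fit()
    intercept, slope = ols.params

    rho = spearman_rank(c, y)

    # 95% CI for each class mean (t interval on the within-class replicates)
    rows = []
    for cl in np.unique(c):
        vals = y[c == cl]
        m = vals.mean()
        if vals.size > 1:
            half = sps.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
        else:
            half = np.nan
        rows.append({"class": cl, "mean": m, "ci_low": m - half, "ci_high": m + half})
    ci = pd.DataFrame(rows)

    # prediction interval around the fitted line from residual variance
    n = y.size
    resid_var = ols.ssr / (n - 2)
    x_bar = c.mean()
    sxx = ((c - x_bar) ** 2).sum()
    tcrit = sps.t.ppf(0.5 + pi_level / 2.0, n - 2)
    grid = np.unique(c)
    fit = intercept + slope * grid
    se_pred = np.sqrt(resid_var * (1.0 + 1.0 / n + (grid - x_bar) ** 2 / sxx))
    pi = pd.DataFrame({
        "class": grid, "fit": fit,
        "pi_low": fit - tcrit * se_pred, "pi_high": fit + tcrit * se_pred,
    })

    return ValidationResult(
        normalized_x=y,
        predicted_classes=c,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(ols.rsquared),
        spearman_rho=rho,
        class_mean_ci95=ci,
        prediction_interval_50=pi,
        ols_results=ols,
    )


def validate_plate_table(df: pd.DataFrame, predicted: pd.Series | dict) -> ValidationResult:
    """Full path from a plate TSV to the validation statistics.

    ``df`` columns: promoter_id, replicate, fl_mkate2, fl_sfgfp,
    fl_mkate2_medium, fl_sfgfp_medium.  Per-promoter value = mean corrected
    fluorescence over replicates, then log-normalised across promoters.
    """
    df = df.copy()
    df["fluorescence_c"] = corrected_fluorescence_frame(df)
    per_promoter = df.groupby("promoter_id")["fluorescence_c"].mean()
    x = log_normalize(per_promoter.to_numpy())
    pred = pd.Series(predicted)
    classes = pred.loc[per_promoter.index].to_numpy()
    return validate_panel(classes, x)
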