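"""Weighted least-squares calibration and inverse prediction.

LC-MS/MS quantification with an isotope-labelled internal standard: the
response is the analyte/IS peak-area ratio y = Aa/Ais, fitted against the
nominal calibrator concentration x with weights w_i = 1/x_i^2 (constant
relative response noise). The sample concentration is read off the curve by
inverse prediction, xs = (ys - aw)/bw, and its standard uncertainty follows
the classical weighted inverse-prediction formula

    u(Cc) = (Sw/bw) * sqrt( 1/ws + 1/sum(w) + (ys - ybar_w)^2
                            / (bw^2 * sum(w (x - xbar_w)^2)) )

with Sw the weighted residual SD on n - 2 degrees of freedom and ws the
weighting law evaluated at the predicted concentration (ws = 1/xs^2). The
1/ws term therefore carries the single-measurement response noise of the
sample itself, referred to the concentration axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError, SingularFitError


@dataclass
class CalibrationFit:
    """State of a weighted linear calibration fit."""

    intercept: float  # aw
    slope: float  # bw
    weighted_residual_sd: float  # Sw, on n - 2 dof
    weighted_mean_x: float
    weighted_mean_y: float
    sum_weights: float
    weighted_sxx: float  # sum w (x - xbar_w)^2
    dof: int
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray

    def predict(self, x) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def residuals(self) -> np.ndarray:
        return self.y - self.predict(self.x)


def default_weights(x: np.ndarray) -> np.ndarray:
    """The 1/x^2 weighting law (requires strictly positive concentrations)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise InvalidInputError("1/x^2 weighting requires strictly positive x")
    return 1.0 / x**2


def fit_weighted(x, y, weights=None) -> CalibrationFit:
    """Closed-form weighted least-squares line through calibration points.

    ``weights=None`` applies the 1/x^2 law. Requires at least three points
    with at least two distinct x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 calibration points, got {n}")
    w = default_weights(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0):
        raise InvalidInputError("weights must be positive and match x")
    if np.unique(x).size < 2:
        raise SingularFitError("all calibrator concentrations are equal")

    sw = float(np.sum(w))
    xbar = float(np.sum(w * x) / sw)
    ybar = float(np.sum(w * y) / sw)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    if sxx <= 0:
        raise SingularFitError("no weighted spread in x")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(w * resid**2) / (n - 2))
    return CalibrationFit(
        intercept=intercept,
        slope=slope,
        weighted_residual_sd=float(np.sqrt(max(s2, 0.0))),
        weighted_mean_x=xbar,
        weighted_mean_y=ybar,
        sum_weights=sw,
        weighted_sxx=sxx,
        dof=n - 2,
        x=x,
        y=y,
        weights=w,
    )


def inverse_predict(fit: CalibrationFit, ys: float) -> float:
    """Concentration read off the curve: xs = (ys - aw)/bw.

    A negative prediction is returned as-is with a warning; reporting-limit
    handling is the caller's concern.
    """
    if fit.slope == 0:
        raise SingularFitError("cannot invert a zero-slope calibration curve")
    xs = (ys - fit.intercept) / fit.slope
    if xs < 0:
        warnings.warn(
            f"inverse prediction is negative ({xs:g}); below the calibrated range",
            stacklevel=2,
        )
    return xs


def calibration_uncertainty(
    fit: CalibrationFit, ys: float, ws: float | None = None, xs: float | None = None
) -> tuple[float, float]:
    """Standard and relative uncertainty of the inverse-predicted concentration.

    ``ws`` defaults to the calibration weighting law evaluated at the
    predicted concentration (1/xs^2). Because xs = (ys - aw)/bw does not
    depend on ws, a single evaluation is already the fixed point of the
    xs -> ws -> u(Cc) iteration. Returns ``(u_abs, u_rel)`` in (ng/mL,
    dimensionless).
    """
    if xs is None:
        xs = inverse_predict(fit, ys)
    if ws is None:
        if xs == 0:
            raise InvalidInputError(
                "default ws = 1/xs^2 undefined at xs = 0; pass ws explicitly"
            )
        ws = 1.0 / xs**2
    if ws <= 0:
        raise InvalidInputError("ws must be positive")
    if fit.weighted_sxx <= 0:
        raise SingularFitError("degenerate calibration spread")
    var = (
        1.0 / ws
        + 1.0 / fit.sum_weights
        + (ys - fit.weighted_mean_y) ** 2 / (fit.slope**2 * fit.weighted_sxx)
    )
    u_abs = fit.weighted_residual_sd / abs(fit.slope) * np.sqrt(var)
    if xs == 0:
        raise InvalidInputError("relative uncertainty undefined at xs = 0")
    return float(u_abs), float(u_abs / abs(xs))


# -- tabular I/O -----------------------------------------------------------

#: accepted synonyms for the nominal-concentration column
_X_COLUMNS = ("x", "x_ng_per_mL", "nominal", "concentration")


def average_replicates(data: pd.DataFrame) -> pd.DataFrame:
    """Mean response per calibrator level, preserving level order.

    Returns one row per level with columns ``level_index, x, ratio_mean,
    ratio_sd, n_replicates`` (the per-level SD feeds the Monte Carlo
    response model).
    """
    grouped = (
        data.groupby(["level_index", "x"], as_index=False)
        .agg(ratio_mean=("ratio", "mean"), ratio_sd=("ratio", "std"), n_replicates=("ratio", "size"))
        .sort_values("level_index", ignore_index=True)
    )
    grouped["ratio_sd"] = grouped["ratio_sd"].fillna(0.0)
    return grouped


def read_calibration_csv(path) -> pd.DataFrame:
    """Read calibration data: level_index, x, replicate, and response.

    The response is either a precomputed ``ratio`` column or the pair
    ``area_analyte``/``area_is``. An optional ``analyte`` column allows one
    file to hold several analytes. Nominal concentrations must be positive
    and non-decreasing in ``level_index``.
    """
    df = pd.read_csv(path)
    xcol = next((c for c in _X_COLUMNS if c in df.columns), None)
    if xcol is None:
        raise InvalidInputError(
            f"calibration file needs one of {list(_X_COLUMNS)} columns"
        )
    df = df.rename(columns={xcol: "x"})
    if "ratio" not in df.columns:
        if not {"area_analyte", "area_is"} <= set(df.columns):
            raise InvalidInputError(
                "calibration file needs 'ratio' or 'area_analyte'+'area_is'"
            )
        if np.any(df["area_is"] <= 0):
            raise InvalidInputError("internal-standard areas must be positive")
        df["ratio"] = df["area_analyte"] / df["area_is"]
    if "level_index" not in df.columns:
        df["level_index"] = df.groupby("x", sort=True).ngroup() + 1
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby("level_index").cumcount() + 1
    if np.any(df["x"] <= 0):
        raise InvalidInputError("calibrator concentrations must be positive")
    keys = ["analyte"] if "analyte" in df.columns else []
    for _, sub in df.groupby(keys) if keys else [(None, df)]:
        order = sub.sort_values("level_index")["x"].to_numpy()
        if np.any(np.diff(order) < 0):
            raise InvalidInputError(
                "calibrator concentrations must be non-decreasing in level_index"
            )
    cols = keys + ["level_index", "x", "replicate", "ratio"]
    return df[cols]
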