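"""CI-to-ground-truth calibration: linear and exponential fits with R^2.

Linear fits are ordinary least squares (y = m*x + q). Exponential fits
(y = a * exp(b*x)) are obtained deterministically by OLS on ln(y), with
R^2 reported on the original scale. Reports can be produced at per-sector,
per-vine, per-date and pooled scopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LinearFit",
    "ExponentialFit",
    "fit_linear",
    "fit_exponential",
    "predict",
    "calibration_report",
]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class ExponentialFit:
    a: float
    b: float
    r_squared: float
    n: int

    def __call__(self, x: float) -> float:
        return self.a * np.exp(self.b * x)


def _as_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    return x, y


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")  # zero-variance response: R^2 undefined
    return 1.0 - ss_res / ss_tot


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = m*x + q with R^2 = 1 - SSres/SStot."""
    x, y = _as_xy(x, y)
    if np.all(x == x[0]):
        raise ValueError("degenerate x: all values equal")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    return LinearFit(slope, intercept, _r_squared(y, slope * x + intercept), x.size)


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> ExponentialFit:
    """Log-linear least squares for y = a*exp(b*x); R^2 on the original scale."""
    x, y = _as_xy(x, y)
    if np.any(y <= 0):
        raise ValueError("exponential model requires y > 0; use the linear model")
    if np.all(x == x[0]):
        raise ValueError("degenerate x: all values equal")
    lf = fit_linear(x, np.log(y))
    a, b = float(np.exp(lf.intercept)), lf.slope
    return ExponentialFit(a, b, _r_squared(y, a * np.exp(b * x)), x.size)


def predict(
    fit: Union[LinearFit, ExponentialFit], ci: float, as_percent: bool = False
) -> float:
    """Evaluate a calibration at a CI value; optionally scale fraction -> %."""
    value = float(fit(ci))
    return value * 100.0 if as_percent else value


_GROUND_TRUTH_COLUMNS = (
    "cg",
    "lln",
    "il",
    "cluster_weight_g",
    "berry_weight_g",
    "interception",
)


def calibration_report(
    merged: pd.DataFrame,
    scope: str = "vine",
    x_col: str = "ci",
    y_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Linear + exponential fits per scope for each ground-truth column.

    ``scope``: "vine" (pooled over dates: one point per measuring date,
    the mean over vines), "sector", "date", or "pooled" (all rows).
    Scopes with fewer than 3 points, or degenerate responses, are skipped
    with a warning; rows carry slope/intercept/R^2/Pearson r and, where the
    response is strictly positive, the exponential coefficients.
    """
    if y_cols is None:
        y_cols = [c for c in _GROUND_TRUTH_COLUMNS if c in merged.columns]
    if x_col not in merged.columns:
        raise ValueError(f"missing x column {x_col!r}")

    if scope == "vine":
        # one point per measuring date: mean over vines at that date
        grouped = merged.groupby("date", as_index=False)[[x_col, *y_cols]].mean()
        frames = {"pooled_by_date": grouped}
    elif scope == "sector":
        key = "sector" if "sector" in merged.columns else "level"
        frames = {f"sector={k}": g for k, g in merged.groupby(key)}
    elif scope == "date":
        frames = {f"date={k}": g for k, g in merged.groupby("date")}
    elif scope == "pooled":
        frames = {"pooled": merged}
    else:
        raise ValueError(f"unknown scope: {scope!r}")

    rows = []
    for label, frame in frames.items():
        for y_col in y_cols:
            sub = frame[[x_col, y_col]].dropna()
            if len(sub) < 3:
                warnings.warn(f"scope {label}/{y_col}: fewer than 3 points, skipped",
                              stacklevel=2)
                continue
            x, y = sub[x_col].to_numpy(), sub[y_col].to_numpy()
            if np.all(x == x[0]):
                warnings.warn(f"scope {label}/{y_col}: degenerate x, skipped",
                              stacklevel=2)
                continue
            lf = fit_linear(x, y)
            if np.isnan(lf.r_squared):
                warnings.warn(
                    f"scope {label}/{y_col}: zero-variance response, R^2 undefined",
                    stacklevel=2,
                )
            pearson = (
                float(np.corrcoef(x, y)[0, 1]) if y.std() > 0 else float("nan")
            )
            row = {
                "scope": label,
                "response": y_col,
                "n": lf.n,
                "slope": lf.slope,
                "intercept": lf.intercept,
                "r_squared": lf.r_squared,
                "pearson_r": pearson,
                "exp_a": np.nan,
                "exp_b": np.nan,
                "exp_r_squared": np.nan,
            }
            if np.all(y > 0):
                ef = fit_exponential(x, y)
                row.update(exp_a=ef.a, exp_b=ef.b, exp_r_squared=ef.r_squared)
            rows.append(row)
    return pd.DataFrame(rows)
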