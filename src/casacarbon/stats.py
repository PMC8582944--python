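"""Trend, significance, change classification and NPP–climate correlation.

Pixel- or region-level annual series are characterized by an ordinary
least-squares linear trend (slope in units·yr⁻¹, two-sided t-test on the
slope with n−2 degrees of freedom), a three-way change classification at
α = 0.05, Spearman rank correlation against climate series, and simple
endpoint change summaries. No multiple-testing correction is applied
across pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrendResult",
    "CHANGE_TYPES",
    "ols_trend",
    "classify_change",
    "trend_grids",
    "spearman_correlation",
    "region_series",
    "change_summary",
    "table_extrema",
]

CHANGE_TYPES = ("no change", "significant increase", "significant decrease")


@dataclass(frozen=True)
class TrendResult:
    """OLS linear trend of an annual series on the year index 0..n−1."""

    slope: float
    intercept: float
    p_value: float
    n: int


def ols_trend(series: Sequence[float]) -> TrendResult:
    """Least-squares trend of *series* against its 0-based index.

    Requires at least three finite values so the slope t-test is defined.
    The slope has the units of the series per year; using the index rather
    than the calendar year leaves the slope unchanged.
    """
    y = np.asarray(series, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if y.size < 3:
        raise ValueError(f"need >= 3 values for a trend, got {y.size}")
    x = np.arange(y.size, dtype=np.float64)
    fit = sps.linregress(x, y)
    # constant series: scipy returns slope 0 with p = 1 (nothing to detect)
    p = 1.0 if np.isnan(fit.pvalue) else float(fit.pvalue)
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept),
                       p_value=p, n=int(y.size))


def classify_change(trend: TrendResult, alpha: float = 0.05) -> str:
    """Three-way change type from a trend.

    Significant increase/decrease require both a non-zero-signed slope and
    p ≤ α; a zero slope, or any slope with p > α, is "no change".
    """
    if trend.p_value <= alpha and trend.slope > 0:
        return "significant increase"
    if trend.p_value <= alpha and trend.slope < 0:
        return "significant decrease"
    return "no change"


def trend_grids(annual_stack: np.ndarray, alpha: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-wise trend over a (years, rows, cols) stack.

    Returns (slope, p_value, change_code) grids; change codes are
    0 = no change, 1 = significant increase, 2 = significant decrease.
    Pixels with any nodata year come back NaN / code 0.
    """
    stack = np.asarray(annual_stack, dtype=np.float64)
    n, rows, cols = stack.shape
    if n < 3:
        raise ValueError("need >= 3 years for pixel trends")
    x = np.arange(n, dtype=np.float64)
    y = stack.reshape(n, -1)
    valid = np.all(np.isfinite(y), axis=0)
    slope = np.full(y.shape[1], np.nan)
    pval = np.full(y.shape[1], np.nan)
    if valid.any():
        yv = y[:, valid]
        xm = x - x.mean()
        sxx = float((xm ** 2).sum())
        ym = yv - yv.mean(axis=0)
        b = (xm[:, None] * ym).sum(axis=0) / sxx
        resid = ym - b[None] * xm[:, None]
        sse = (resid ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sse / (n - 2) / sxx)
            t = np.where(se > 0, b / se, np.inf * np.sign(b))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        p = np.where(b == 0, 1.0, p)  # flat series: nothing to detect
        slope[valid] = b
        pval[valid] = p
    code = np.zeros(y.shape[1], dtype=np.uint8)
    sig = valid & np.isfinite(pval) & (pval <= alpha)
    code[sig & (slope > 0)] = 1
    code[sig & (slope < 0)] = 2
    return slope.reshape(rows, cols), pval.reshape(rows, cols), code.reshape(rows, cols)


def spearman_correlation(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Spearman rank correlation coefficient (average ranks for ties)."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need >= 3 paired values")
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def region_series(npp_by_year: Mapping[int, np.ndarray] | Sequence[np.ndarray],
                  region_mask: np.ndarray) -> pd.Series:
    """Annual regional mean NPP series (gC·m⁻²) over a pixel mask.

    With uniform pixel areas the area-weighted regional mean is the simple
    mean over valid region pixels.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    if isinstance(npp_by_year, Mapping):
        items = sorted(npp_by_year.items())
    else:
        items = list(enumerate(npp_by_year))
    out = {}
    for year, grid in items:
        values = grid.values if hasattr(grid, "values") and not isinstance(grid, np.ndarray) else np.asarray(grid)
        sel = region_mask & np.isfinite(values)
        if not sel.any():
            raise ValueError(f"region has no valid pixels in year {year}")
        out[year] = float(values[sel].mean())
    return pd.Series(out, name="npp")


def change_summary(series: pd.Series | Sequence[float]) -> tuple[float, float]:
    """Endpoint change of a regional series: (absolute, relative %).

    Absolute = last − first (series units); relative = 100·(last−first)/first.
    Uses the endpoints only, not fitted values.
    """
    values = np.asarray(pd.Series(series).to_numpy(), dtype=np.float64)
    if values.size < 2:
        raise ValueError("need first and last year")
    first, last = float(values[0]), float(values[-1])
    if first == 0:
        raise ZeroDivisionError("relative change undefined: first value is 0")
    return last - first, 100.0 * (last - first) / first


def table_extrema(table: pd.DataFrame
                  ) -> tuple[tuple[float, str, object], tuple[float, str, object]]:
    """Global max and min of a (year × region) table with their labels.

    Returns ((max_value, region, year), (min_value, region, year)); ties
    resolve to the first occurrence in row-major (year, then region) order.
    """
    if table.size == 0:
        raise ValueError("empty table")
    values = table.to_numpy(dtype=np.float64)
    imax = np.unravel_index(np.nanargmax(values), values.shape)
    imin = np.unravel_index(np.nanargmin(values), values.shape)
    return ((float(values[imax]), str(table.columns[imax[1]]), table.index[imax[0]]),
            (float(values[imin]), str(table.columns[imin[1]]), table.index[imin[0]]))
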