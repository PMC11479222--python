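"""Per-pixel linear trends, the six-class change map, and area summaries.

A pixel's change class is decided by the signs of its NDVI trend and
heterogeneity (CV) trend, gated on *both* trends being significant
(two-sided t-test on the OLS slope, p < alpha), with the multi-year mean
NDVI against the 0.2 sparse-vegetation threshold separating regrowth
from slight degradation (both trends up) and desertification from severe
degradation (both trends down):

    NDVI up,   CV down            -> improving
    NDVI up,   CV up,   mean<0.2  -> regrowing
    NDVI up,   CV up,   mean>=0.2 -> slight degradation
    NDVI down, CV up              -> medium degradation
    NDVI down, CV down, mean>=0.2 -> severe degradation
    NDVI down, CV down, mean<0.2  -> desertification

Everything else that carries data is "not significant".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnualStack, GRASSLAND_LEGEND, RasterGrid
from .synthetic import CLASS_CODES, CLASS_NAMES, NODATA_CODE

__all__ = [
    "TrendSurface",
    "fit_linear_trend",
    "classify_change",
    "summarize_proportions",
    "driver_trend_summary",
]


@dataclass
class TrendSurface:
    """Per-pixel OLS slope and two-sided p-value for one variable."""

    grid: RasterGrid
    variable: str
    slope: np.ndarray
    p_value: np.ndarray
    n_years: np.ndarray


def fit_linear_trend(
    stack: AnnualStack,
    min_valid_years: int = 15,
    variable: str = "",
) -> TrendSurface:
    """Ordinary least squares of the annual value on calendar year.

    Years with nodata are skipped per pixel; pixels with fewer than
    ``max(3, min_valid_years)`` valid years are nodata. The p-value is
    the two-sided t-test on the slope with n-2 degrees of freedom; a
    perfectly constant series (zero residual and zero slope) reports
    p = 1 — a flat line is never evidence of change.
    """
    y = stack.values
    if np.all(np.isnan(y)):
        raise ValueError("all-nodata stack")
    x = np.asarray(stack.years, dtype=float)[:, None, None]
    w = (~np.isnan(y)).astype(float)
    yw = np.where(w > 0, y, 0.0)
    n = w.sum(axis=0)
    min_n = max(3, int(min_valid_years))

    with np.errstate(all="ignore"):
        # centered sums: numerically stable, exact zeros for flat series
        xbar = (w * x).sum(axis=0) / n
        ybar = yw.sum(axis=0) / n
        xc = (x - xbar[None]) * w
        yc = (yw - ybar[None]) * w
        sxx = (xc * xc).sum(axis=0)
        sxy = (xc * yc).sum(axis=0)
        syy = (yc * yc).sum(axis=0)
        slope = sxy / sxx
        rss = np.maximum(syy - slope * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
    # zero-residual (constant or perfectly linear) pixels: se == 0
    exact = (se == 0) & np.isfinite(slope)
    p[exact & (slope != 0)] = 0.0
    p[exact & (slope == 0)] = 1.0
    invalid = n < min_n
    slope[invalid] = np.nan
    p[invalid] = np.nan
    return TrendSurface(stack.grid, variable, slope, p, n.astype(int))


def classify_change(
    ndvi_trend: TrendSurface,
    cv_trend: TrendSurface,
    mean_ndvi: np.ndarray,
    alpha: float = 0.05,
    ndvi_threshold: float = 0.2,
) -> np.ndarray:
    """Apply the dual-significance six-class rules; returns an int16
    raster with codes 1..6, 0 = not significant, -1 = nodata."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if ndvi_trend.grid != cv_trend.grid:
        raise ValueError("trend surfaces on different grids")
    if mean_ndvi.shape != ndvi_trend.grid.shape:
        raise ValueError("mean NDVI surface does not conform to the grid")
    sn, pn = ndvi_trend.slope, ndvi_trend.p_value
    sc, pc = cv_trend.slope, cv_trend.p_value
    valid = ~(np.isnan(sn) | np.isnan(sc) | np.isnan(mean_ndvi))
    out = np.full(sn.shape, NODATA_CODE, dtype=np.int16)
    out[valid] = CLASS_CODES["not_significant"]
    sig = valid & (pn < alpha) & (pc < alpha)
    sparse = mean_ndvi < ndvi_threshold  # the boundary itself counts as vegetated
    out[sig & (sn > 0) & (sc < 0)] = CLASS_CODES["improving"]
    out[sig & (sn > 0) & (sc > 0) & sparse] = CLASS_CODES["regrowing"]
    out[sig & (sn > 0) & (sc > 0) & ~sparse] = CLASS_CODES["slight_degradation"]
    out[sig & (sn < 0) & (sc > 0)] = CLASS_CODES["medium_degradation"]
    out[sig & (sn < 0) & (sc < 0) & ~sparse] = CLASS_CODES["severe_degradation"]
    out[sig & (sn < 0) & (sc < 0) & sparse] = CLASS_CODES["desertification"]
    return out


_SIX = [CLASS_NAMES[c] for c in range(1, 7)]


def summarize_proportions(
    classes: np.ndarray,
    grassland: np.ndarray,
    pixel_size: float,
) -> pd.DataFrame:
    """Class shares of the significantly changed area, overall and by
    grassland type.

    Returns one row per (stratum, class) with the pixel count, the area
    in km^2, the percentage of the stratum's dual-significant area, and
    the percentage of the stratum's total valid (data-carrying) area.
    """
    if classes.shape != grassland.shape:
        raise ValueError("grid mismatch between class and grassland rasters")
    km2 = (pixel_size / 1000.0) ** 2
    strata = {
        "all": np.ones(classes.shape, dtype=bool),
        "steppe": grassland == 1,
        "meadow": grassland == 2,
    }
    rows = []
    for stratum, sel in strata.items():
        sig_total = np.sum(sel & (classes >= 1) & (classes <= 6))
        valid_total = np.sum(sel & (classes != NODATA_CODE))
        for code in range(1, 7):
            count = int(np.sum(sel & (classes == code)))
            rows.append({
                "stratum": stratum,
                "class": CLASS_NAMES[code],
                "count": count,
                "area_km2": count * km2,
                "percent": 100.0 * count / sig_total if sig_total else 0.0,
                "percent_of_valid": 100.0 * count / valid_total if valid_total else 0.0,
            })
        rows.append({
            "stratum": stratum,
            "class": "significant_total",
            "count": int(sig_total),
            "area_km2": sig_total * km2,
            "percent": 100.0 if sig_total else 0.0,
            "percent_of_valid": 100.0 * sig_total / valid_total if valid_total else 0.0,
        })
    return pd.DataFrame(rows)


def driver_trend_summary(
    driver_trends: list[TrendSurface],
    epsilon: dict[str, float] | float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable shares of pixels with increasing / decreasing /
    unchanged trends, plus the significant sub-fractions.

    ``epsilon`` is the absolute slope below which a trend counts as
    unchanged (default 0: only an exactly zero slope is unchanged).
    """
    rows = []
    for ts in driver_trends:
        eps = epsilon.get(ts.variable, 0.0) if isinstance(epsilon, dict) else float(epsilon)
        if eps < 0:
            raise ValueError("epsilon must be >= 0")
        sl, p = ts.slope, ts.p_value
        valid = ~np.isnan(sl)
        n = valid.sum()
        if n == 0:
            continue
        inc = valid & (sl > eps)
        dec = valid & (sl < -eps)
        unc = valid & (np.abs(sl) <= eps)
        rows.append({
            "variable": ts.variable,
            "increase_pct": 100.0 * inc.sum() / n,
            "decrease_pct": 100.0 * dec.sum() / n,
            "unchanged_pct": 100.0 * unc.sum() / n,
            "significant_increase_pct": 100.0 * (inc & (p < alpha)).sum() / n,
            "significant_decrease_pct": 100.0 * (dec & (p < alpha)).sum() / n,
        })
    return pd.DataFrame(rows)
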