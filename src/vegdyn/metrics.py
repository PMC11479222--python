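"""Annual composites and moving-window heterogeneity surfaces.

The analysis works on one annual series per pixel: the growing-season
(May-September) median NDVI composite, and the spatial coefficient of
variation (CV = sample sd / mean over a 3x3 window) of that composite.
Heterogeneity is computed from the annual composite, giving one CV value
per pixel-year; computing the CV per month and taking the growing-season
median instead is available via ``cv_order="monthly"``.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import AnnualStack, MaskSet, MonthlyStack

__all__ = ["growing_season_median", "focal_cv", "focal_cv_monthly", "period_mean"]

#: Windows whose mean NDVI is at or below this floor are treated as
#: nodata: the CV ratio is numerically meaningless near a zero mean.
MEAN_FLOOR = 1e-6


def growing_season_median(
    stack: MonthlyStack,
    months: tuple[int, ...] = (5, 6, 7, 8, 9),
    min_valid_months: int = 3,
) -> AnnualStack:
    """Per pixel-year median of the valid growing-season months.

    Pixel-years with fewer than ``min_valid_months`` valid (non-nodata)
    monthly values become nodata.
    """
    months = tuple(sorted(set(int(m) for m in months)))
    if any(m < 1 or m > 12 for m in months):
        raise ValueError("months must lie in 1..12")
    years = stack.years
    out = np.full((len(years),) + stack.grid.shape, np.nan)
    for i, year in enumerate(years):
        sel = [k for k, (y, m) in enumerate(stack.index) if y == year and m in months]
        if not sel:
            continue
        vals = stack.values[sel]
        n_valid = np.sum(~np.isnan(vals), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(vals, axis=0)
        med[n_valid < min_valid_months] = np.nan
        out[i] = med
    return AnnualStack(stack.grid, years, out)


def _cv_one(raster: np.ndarray, window: int) -> np.ndarray:
    """Focal CV of one 2-D raster; borders and incomplete windows are NaN."""
    half = window // 2
    out = np.full(raster.shape, np.nan)
    w = sliding_window_view(raster, (window, window))
    m = w.mean(axis=(-1, -2))  # NaN if any window value is NaN
    sd = w.std(axis=(-1, -2), ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(m > MEAN_FLOOR, sd / m, np.nan)
    out[half:-half or None, half:-half or None] = cv
    return out


def focal_cv(
    composite: AnnualStack,
    window: int = 3,
    mask: MaskSet | None = None,
) -> AnnualStack:
    """Moving-window coefficient of variation of an annual composite.

    CV = s/m with m the mean and s the sample standard deviation
    (divisor n-1) of the window values. A pixel-year is nodata when any
    of the window values is nodata or masked, when the window exits the
    grid, or when m <= 1e-6.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    values = composite.values.copy()
    if mask is not None:
        values[:, mask.combined] = np.nan
    out = np.stack([_cv_one(values[i], window) for i in range(len(composite.years))])
    return AnnualStack(composite.grid, list(composite.years), out)


def focal_cv_monthly(
    stack: MonthlyStack,
    window: int = 3,
    mask: MaskSet | None = None,
    months: tuple[int, ...] = (5, 6, 7, 8, 9),
    min_valid_months: int = 3,
) -> AnnualStack:
    """Alternative ordering: focal CV per month, then the growing-season
    median of the monthly CV values per year."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    values = stack.values.copy()
    if mask is not None:
        values[:, mask.combined] = np.nan
    monthly_cv = np.stack([_cv_one(values[i], window) for i in range(len(stack.index))])
    cv_stack = MonthlyStack(stack.grid, list(stack.index), monthly_cv)
    return growing_season_median(cv_stack, months=months, min_valid_months=min_valid_months)


def period_mean(composite: AnnualStack, min_valid_years: int = 15) -> np.ndarray:
    """Multi-year mean of an annual composite; pixels with fewer than
    ``min_valid_years`` valid years become nodata."""
    if len(composite.years) == 0:
        raise ValueError("empty stack")
    n_valid = np.sum(~np.isnan(composite.values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(composite.values, axis=0)
    mean[n_valid < min_valid_years] = np.nan
    return mean
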