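"""Driver attribution: correlation summaries and random-forest importances.

Two complementary views of what drives NDVI and heterogeneity (CV)
dynamics: (1) per-pixel Pearson correlations of the annual response
series with each of six drivers, summarised as the share of area with a
significant correlation and the sign split within it; (2) per-stratum
random-forest regressions of the response on all six drivers, with
mean-decrease-in-impurity importances, out-of-bag R^2, and the tree
count selected by cross-validation. Strata are the twelve combinations
of grassland type (steppe, meadow) and significant change class;
over-large strata are capped by seeded random subsampling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score

from .containers import AnnualStack, DRIVER_NAMES, DriverStack, GRASSLAND_LEGEND
from .synthetic import CLASS_NAMES

__all__ = [
    "pixelwise_pearson",
    "summarize_correlations",
    "extract_strata_samples",
    "fit_importance",
    "aggregate_contributions",
    "DEFAULT_TREE_GRID",
    "CLIMATE_FACTORS",
    "HUMAN_FACTORS",
]

logger = logging.getLogger(__name__)

DEFAULT_TREE_GRID = (100, 200, 300, 500, 800)
CLIMATE_FACTORS = ("Pre", "Temp", "RH", "SPEI")
HUMAN_FACTORS = ("Graz", "Pop")


def pixelwise_pearson(
    response: AnnualStack,
    driver: AnnualStack,
    min_valid_years: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Pearson r and two-sided p between two annual stacks.

    Uses the years valid in both series per pixel; fewer than
    ``min_valid_years`` common years, or a zero-variance series, gives
    nodata for that pixel.
    """
    if list(response.years) != list(driver.years):
        raise ValueError("response and driver year axes differ")
    x, y = driver.values, response.values
    w = (~np.isnan(x) & ~np.isnan(y)).astype(float)
    xw = np.where(w > 0, np.nan_to_num(x), 0.0)
    yw = np.where(w > 0, np.nan_to_num(y), 0.0)
    n = w.sum(axis=0)
    with np.errstate(all="ignore"):
        sx, sy = xw.sum(0), yw.sum(0)
        sxx, syy, sxy = (xw * xw).sum(0), (yw * yw).sum(0), (xw * yw).sum(0)
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
        r = np.clip(r, -1.0, 1.0)
        tstat = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
        p[np.abs(r) == 1.0] = 0.0
    bad = (n < max(3, min_valid_years)) | (varx <= 0) | (vary <= 0)
    r[bad] = np.nan
    p[bad] = np.nan
    return r, p


def summarize_correlations(
    results: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate significance and sign shares of (response, driver) r/p maps.

    ``results`` maps (response_name, driver_name) to (r, p) rasters.
    ``percent_significant`` is relative to the valid area; the sign
    split is relative to the significant area (NaN when it is empty).
    """
    rows = []
    for (resp, var), (r, p) in results.items():
        valid = ~np.isnan(r)
        n_valid = valid.sum()
        sig = valid & (p < alpha)
        n_sig = sig.sum()
        rows.append({
            "response": resp,
            "variable": var,
            "percent_significant": 100.0 * n_sig / n_valid if n_valid else 0.0,
            "percent_positive": 100.0 * (sig & (r > 0)).sum() / n_sig if n_sig else np.nan,
            "percent_negative": 100.0 * (sig & (r < 0)).sum() / n_sig if n_sig else np.nan,
        })
    return pd.DataFrame(rows)


def extract_strata_samples(
    classes: np.ndarray,
    grassland: np.ndarray,
    response_ndvi: AnnualStack,
    response_cv: AnnualStack,
    drivers: DriverStack,
    sample_cap: int = 10000,
    seed: int = 0,
    unit: str = "pixel_year",
) -> pd.DataFrame:
    """Build the stratified sample table for the random-forest models.

    The observation unit is the pixel-year (``unit="pixel"`` averages
    each pixel's series instead). Strata are grassland type x change
    class; rows with any missing value are dropped, then strata larger
    than ``sample_cap`` are subsampled uniformly without replacement
    with the given seed. Empty strata are omitted with a warning.
    """
    if classes.shape != grassland.shape or classes.shape != response_ndvi.grid.shape:
        raise ValueError("grid mismatch")
    if unit not in ("pixel_year", "pixel"):
        raise ValueError(f"unknown observation unit {unit!r}")
    years = np.asarray(response_ndvi.years)
    in_stratum = (classes >= 1) & (classes <= 6) & np.isin(grassland, (1, 2))
    rows, cols = np.nonzero(in_stratum)
    if rows.size == 0:
        logger.warning("no dual-significant grassland pixels: empty sample table")
        return pd.DataFrame()

    cols_dict = {
        "pixel_id": rows * classes.shape[1] + cols,
        "grassland": np.vectorize(GRASSLAND_LEGEND.get)(grassland[rows, cols]),
        "change_class": np.vectorize(CLASS_NAMES.get)(classes[rows, cols]),
    }
    if unit == "pixel_year":
        n_y = len(years)
        frame = {
            k: np.repeat(v, n_y) for k, v in cols_dict.items()
        }
        frame["year"] = np.tile(years, rows.size)
        frame["response_ndvi"] = response_ndvi.values[:, rows, cols].T.ravel()
        frame["response_cv"] = response_cv.values[:, rows, cols].T.ravel()
        for name in DRIVER_NAMES:
            frame[name] = drivers.variables[name][:, rows, cols].T.ravel()
    else:
        frame = dict(cols_dict)
        frame["year"] = np.full(rows.size, -1)
        with np.errstate(all="ignore"):
            frame["response_ndvi"] = np.nanmean(response_ndvi.values[:, rows, cols], axis=0)
            frame["response_cv"] = np.nanmean(response_cv.values[:, rows, cols], axis=0)
            for name in DRIVER_NAMES:
                frame[name] = np.nanmean(drivers.variables[name][:, rows, cols], axis=0)
    df = pd.DataFrame(frame)
    df["stratum"] = df["grassland"] + "_" + df["change_class"]
    df = df.dropna()

    rng = np.random.default_rng(seed)
    kept = []
    for stratum, group in df.groupby("stratum", sort=True):
        if len(group) > sample_cap:
            idx = rng.choice(len(group), size=sample_cap, replace=False)
            group = group.iloc[np.sort(idx)]
        kept.append(group)
    out = pd.concat(kept, ignore_index=True)
    for grass in ("steppe", "meadow"):
        for code in range(1, 7):
            name = f"{grass}_{CLASS_NAMES[code]}"
            if name not in set(out["stratum"]):
                logger.warning("stratum %s is empty and was omitted", name)
    return out


def _select_n_trees(X, y, tree_grid, cv_folds, seed) -> int:
    """Pick the tree count minimising cross-validated MSE."""
    best, best_mse = tree_grid[0], np.inf
    for n_trees in tree_grid:
        model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        mse = -cross_val_score(model, X, y, cv=cv, scoring="neg_mean_squared_error").mean()
        if mse < best_mse:
            best, best_mse = n_trees, mse
    return best


def fit_importance(
    samples: pd.DataFrame,
    response: str = "NDVI",
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    min_stratum_size: int = 50,
) -> pd.DataFrame:
    """Per-stratum random-forest importances for one response.

    For each stratum: the tree count is selected from ``tree_grid`` by
    ``cv_folds``-fold cross-validated mean squared error, a forest of
    the six drivers is fitted, and the table reports the normalized
    mean-decrease-in-impurity importance per factor, the out-of-bag R^2
    and the sample and tree counts. Strata smaller than
    ``min_stratum_size`` or with a constant response are skipped with a
    warning.
    """
    col = {"NDVI": "response_ndvi", "CV": "response_cv"}.get(response)
    if col is None:
        raise ValueError("response must be 'NDVI' or 'CV'")
    missing = [v for v in DRIVER_NAMES if v not in samples.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    rows = []
    for stratum, group in samples.groupby("stratum", sort=True):
        if len(group) < min_stratum_size:
            logger.warning("stratum %s has %d < %d samples; skipped", stratum, len(group), min_stratum_size)
            continue
        y = group[col].to_numpy()
        if np.std(y) == 0:
            logger.warning("stratum %s has a constant response; skipped", stratum)
            continue
        X = group[list(DRIVER_NAMES)].to_numpy()
        n_trees = _select_n_trees(X, y, tree_grid, cv_folds, seed)
        forest = RandomForestRegressor(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        forest.fit(X, y)
        imp = forest.feature_importances_
        imp = imp / imp.sum()
        row = {
            "response": response,
            "stratum": stratum,
            "n_samples": len(group),
            "n_trees": n_trees,
            "oob_r2": forest.oob_score_,
        }
        row.update({name: v for name, v in zip(DRIVER_NAMES, imp)})
        rows.append(row)
    return pd.DataFrame(rows)


def oob_predictions(samples: pd.DataFrame, importance_table: pd.DataFrame,
                    response: str = "NDVI", seed: int = 0) -> pd.DataFrame:
    """Out-of-bag predicted vs observed values per stratum, for the
    diagnostic scatter plots."""
    col = {"NDVI": "response_ndvi", "CV": "response_cv"}[response]
    frames = []
    for _, info in importance_table.iterrows():
        group = samples[samples["stratum"] == info["stratum"]]
        X = group[list(DRIVER_NAMES)].to_numpy()
        y = group[col].to_numpy()
        forest = RandomForestRegressor(
            n_estimators=int(info["n_trees"]), oob_score=True, random_state=seed, n_jobs=1
        )
        forest.fit(X, y)
        frames.append(pd.DataFrame({
            "response": response,
            "stratum": info["stratum"],
            "observed": y,
            "oob_predicted": forest.oob_prediction_,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def permutation_check(
    samples: pd.DataFrame,
    importance_table: pd.DataFrame,
    response: str = "NDVI",
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Permutation-importance cross-check of the impurity importances.

    Refits each stratum's forest (same tree count and seed) and reports
    normalized permutation importances; a diagnostic, never the
    headline metric.
    """
    from sklearn.inspection import permutation_importance

    col = {"NDVI": "response_ndvi", "CV": "response_cv"}[response]
    rows = []
    for _, info in importance_table.iterrows():
        group = samples[samples["stratum"] == info["stratum"]]
        X = group[list(DRIVER_NAMES)].to_numpy()
        y = group[col].to_numpy()
        forest = RandomForestRegressor(
            n_estimators=int(info["n_trees"]), random_state=seed, n_jobs=1
        ).fit(X, y)
        perm = permutation_importance(forest, X, y, n_repeats=n_repeats,
                                      random_state=seed, n_jobs=1)
        imp = np.clip(perm.importances_mean, 0, None)
        total = imp.sum()
        row = {"response": response, "stratum": info["stratum"]}
        row.update({
            name: (v / total if total > 0 else np.nan)
            for name, v in zip(DRIVER_NAMES, imp)
        })
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_contributions(importances: pd.DataFrame) -> pd.DataFrame:
    """Climate vs human shares per (response, stratum), plus per-response
    averages (stratum = 'average')."""
    rows = []
    for _, row in importances.iterrows():
        climate = 100.0 * sum(row[v] for v in CLIMATE_FACTORS)
        human = 100.0 * sum(row[v] for v in HUMAN_FACTORS)
        rows.append({
            "response": row["response"],
            "stratum": row["stratum"],
            "climate_share_pct": climate,
            "human_share_pct": human,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        means = out.groupby("response", as_index=False)[["climate_share_pct", "human_share_pct"]].mean()
        means["stratum"] = "average"
        out = pd.concat([out, means], ignore_index=True)
    return out
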