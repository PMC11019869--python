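"""Linking function, diversity and complexity to the latitudinal gradient.

Four tools: ordinary least-squares regression of any per-sample response on
latitude; the multiple-threshold slope curve (per-threshold OLS of function
counts on latitude, the standard way to display how the
diversity-multifunctionality relationship changes with how strictly
"functioning" is defined); Mann–Whitney U contrasts between the low- and
high-latitude groups; and a Spearman correlation screen of responses
against candidate drivers with Benjamini–Hochberg FDR over the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .conetwork import fdr_adjust

__all__ = [
    "RegressionFit",
    "GroupContrast",
    "fit_latitude_regression",
    "threshold_slope_curve",
    "mann_whitney",
    "group_contrast_table",
    "correlation_screen",
]


@dataclass
class RegressionFit:
    """OLS fit of a response on latitude (slope per degree)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class GroupContrast:
    """Mann–Whitney U contrast between two groups for one variable."""

    u: float
    p_value: float
    median_x: float
    median_y: float
    n_x: int
    n_y: int


def _ols(y: np.ndarray, x: np.ndarray, alpha: float = 0.05) -> RegressionFit:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        n=int(model.nobs),
    )


def fit_latitude_regression(
    y: pd.Series | np.ndarray,
    latitude: pd.Series | np.ndarray,
    habitat: pd.Series | None = None,
    stratify: str | None = None,
) -> RegressionFit:
    """OLS of ``y`` on latitude, with a t-based 95% CI for the slope.

    ``stratify`` restricts the fit to one habitat when ``habitat`` labels are
    supplied (the relationship is habitat-dependent in riverine data).
    Missing responses are dropped pairwise.
    """
    y = np.asarray(pd.Series(y), dtype=float)
    lat = np.asarray(pd.Series(latitude), dtype=float)
    if stratify is not None:
        if habitat is None:
            raise ValueError("stratify given without habitat labels")
        mask = np.asarray(pd.Series(habitat).astype(str) == stratify)
        y, lat = y[mask], lat[mask]
    ok = np.isfinite(y) & np.isfinite(lat)
    y, lat = y[ok], lat[ok]
    if y.size < 3:
        raise ValueError(f"need >= 3 observations, got {y.size}")
    if np.ptp(lat) == 0:
        raise ValueError("latitude is constant; slope undefined")
    return _ols(y, lat)


def threshold_slope_curve(
    threshold_counts: pd.DataFrame, latitude: pd.Series
) -> pd.DataFrame:
    """Per-threshold OLS slope of the function count on latitude.

    Returns one row per threshold with slope, 95% CI, p-value and n.  A
    threshold where every sample has the same count gives slope 0 with a
    degenerate (zero-width) CI, flagged in the ``degenerate`` column.
    """
    lat = latitude.reindex(threshold_counts.index).to_numpy(dtype=float)
    rows = []
    for t in threshold_counts.columns:
        counts = threshold_counts[t].to_numpy(dtype=float)
        if np.ptp(counts) == 0:
            rows.append(
                {
                    "threshold": int(t),
                    "slope": 0.0,
                    "ci_low": 0.0,
                    "ci_high": 0.0,
                    "p_value": np.nan,
                    "n": len(counts),
                    "degenerate": True,
                }
            )
            continue
        fit = _ols(counts, lat)
        rows.append(
            {
                "threshold": int(t),
                "slope": fit.slope,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "p_value": fit.p_value,
                "n": fit.n,
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).set_index("threshold")


def mann_whitney(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> GroupContrast:
    """Two-sided Mann–Whitney U test.

    Exact p-values for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's ``method='auto'`` policy).
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return GroupContrast(
        u=float(res.statistic),
        p_value=float(res.pvalue),
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
        n_x=int(x.size),
        n_y=int(y.size),
    )


def group_contrast_table(
    values: pd.DataFrame, groups: pd.Series, low: str = "low", high: str = "high"
) -> pd.DataFrame:
    """Mann–Whitney contrast of every column of ``values`` between two groups."""
    g = groups.reindex(values.index).astype(str)
    rows = []
    for col in values.columns:
        x = values.loc[g == low, col]
        y = values.loc[g == high, col]
        c = mann_whitney(x, y)
        rows.append(
            {
                "variable": col,
                "U": c.u,
                "p_value": c.p_value,
                f"median_{low}": c.median_x,
                f"median_{high}": c.median_y,
                f"n_{low}": c.n_x,
                f"n_{high}": c.n_y,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def correlation_screen(targets: pd.DataFrame, drivers: pd.DataFrame) -> pd.DataFrame:
    """Spearman screen of every target against every driver.

    Samples are aligned on the index; pairs with fewer than 4 complete
    observations are reported with NaN rho/q and ``n`` recorded.  q-values
    are Benjamini–Hochberg over all testable pairs of the screen.
    """
    drivers = drivers.reindex(targets.index)
    rows = []
    for t in targets.columns:
        for d in drivers.columns:
            tv = targets[t].astype(float)
            dv = drivers[d].astype(float)
            ok = tv.notna() & dv.notna()
            n = int(ok.sum())
            if n < 4:
                rows.append({"target": t, "driver": d, "rho": np.nan, "p": np.nan, "n": n})
                continue
            rho, p = stats.spearmanr(tv[ok], dv[ok])
            rows.append({"target": t, "driver": d, "rho": float(rho), "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "q"] = fdr_adjust(out.loc[testable, "p"].to_numpy())
    return out
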