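"""Ecosystem-multifunctionality (EMF) indices.

The workflow is: negate direction ``-1`` variables so larger always means
better functioning, min–max standardize every function to [0, 1] across
samples, then summarize each sample three ways:

* ``emf_average`` — the plain mean of all standardized functions;
* ``emf_weighted`` — the mean of per-category means, so each functional
  category (nitrogen cycling, nutrient pool, plant productivity, water
  quality) carries equal weight regardless of how many variables proxy it;
* a multiple-threshold profile — for every threshold t on a percent grid,
  the number of functions at or above t% of that function's maximum.

Missing measurements are averaged over, never imputed; each score reports
the number of functions actually used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FunctionSchema, FunctionTable

__all__ = [
    "StandardizedTable",
    "EMFResult",
    "DEFAULT_THRESHOLDS",
    "apply_direction",
    "standardize",
    "emf_average",
    "emf_weighted",
    "multi_threshold",
    "compute_emf",
]

logger = logging.getLogger(__name__)

#: Percent thresholds 5, 6, ..., 95 used by the multiple-threshold index.
DEFAULT_THRESHOLDS: np.ndarray = np.arange(5, 96)


@dataclass
class StandardizedTable:
    """Min–max standardized function table with its provenance.

    ``x_min``/``x_max`` record the per-function extrema used, so any value
    can be mapped back to raw units.  Zero-range functions are set to 0.5
    (they carry no ranking information) and listed in ``degenerate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    schema: FunctionSchema
    x_min: pd.Series
    x_max: pd.Series
    degenerate: list[str] = field(default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.values.index


@dataclass
class EMFResult:
    """Per-sample EMF scores and the threshold-count matrix."""

    emf_average: pd.Series
    emf_weighted: pd.Series
    n_functions_used: pd.Series
    threshold_counts: pd.DataFrame  # rows = samples, columns = thresholds (%)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "emf_average": self.emf_average,
                "emf_weighted": self.emf_weighted,
                "n_functions_used": self.n_functions_used,
            }
        )
        counts = self.threshold_counts.copy()
        counts.columns = [f"t{int(t)}" for t in counts.columns]
        return pd.concat([out, counts], axis=1)


def apply_direction(t: FunctionTable) -> FunctionTable:
    """Negate columns whose schema direction is -1 and reset all flags to +1.

    Because the returned schema is all +1, applying the operation a second
    time is the identity — no accidental double flip.
    """
    values = t.values.copy()
    for f in values.columns:
        if t.schema.directions[f] == -1:
            values[f] = -values[f]
    schema = FunctionSchema(
        categories=dict(t.schema.categories),
        directions={f: 1 for f in t.schema.functions},
    )
    return FunctionTable(values=values, metadata=t.metadata.copy(), schema=schema)


def standardize(t: FunctionTable) -> StandardizedTable:
    """Scale each function to [0, 1] via (X - X_min)/(X_max - X_min).

    Extrema are taken over non-missing samples.  A constant (zero-range)
    function is mapped to 0.5 everywhere with a warning.
    """
    x_min = t.values.min(axis=0, skipna=True)
    x_max = t.values.max(axis=0, skipna=True)
    rng = x_max - x_min
    degenerate = [f for f in t.values.columns if rng[f] == 0]
    if degenerate:
        logger.warning("zero-range function(s) set to 0.5: %s", degenerate)
    values = (t.values - x_min) / rng.replace(0, np.nan)
    for f in degenerate:
        values[f] = t.values[f].notna().map({True: 0.5, False: np.nan})
    return StandardizedTable(
        values=values,
        metadata=t.metadata.copy(),
        schema=t.schema,
        x_min=x_min,
        x_max=x_max,
        degenerate=degenerate,
    )


def _check_all_observed(s: StandardizedTable) -> None:
    n_obs = s.values.notna().sum(axis=1)
    empty = n_obs[n_obs == 0]
    if len(empty):
        raise ValueError(f"sample(s) with every function missing: {list(empty.index)}")


def emf_average(s: StandardizedTable) -> pd.Series:
    """Arithmetic mean of the standardized functions observed in each sample."""
    _check_all_observed(s)
    return s.values.mean(axis=1, skipna=True).rename("emf_average")


def emf_weighted(s: StandardizedTable) -> pd.Series:
    """Mean of per-category means: every functional category counts equally.

    A category whose functions are all missing for a sample is dropped from
    that sample's average.
    """
    _check_all_observed(s)
    cats = pd.Series({f: s.schema.categories[f].value for f in s.values.columns})
    cat_means = s.values.T.groupby(cats).mean()  # categories x samples
    return cat_means.mean(axis=0, skipna=True).rename("emf_weighted")


def multi_threshold(
    s: StandardizedTable,
    thresholds: np.ndarray | list[int] = DEFAULT_THRESHOLDS,
    robust_max_k: int = 1,
    strict: bool = False,
) -> pd.DataFrame:
    """Count, per sample and threshold t, the functions at >= t% of their
    maximum.

    The per-function maximum defaults to the observed maximum (k = 1, where
    the standardized maximum is exactly 1); ``robust_max_k`` > 1 instead uses
    the mean of the top-k standardized values.  ``strict`` switches the
    comparison to ``>`` (ties at the threshold excluded).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if robust_max_k < 1:
        raise ValueError("robust_max_k must be >= 1")
    vals = s.values.to_numpy(dtype=float)
    if robust_max_k == 1:
        fmax = np.ones(vals.shape[1])
    else:
        fmax = np.array(
            [
                np.sort(col[~np.isnan(col)])[-robust_max_k:].mean() if np.isfinite(col).any() else np.nan
                for col in vals.T
            ]
        )
    cuts = np.outer(thresholds / 100.0, fmax)  # thresholds x functions
    op = np.greater if strict else np.greater_equal
    counts = np.array([np.nansum(op(vals, cut), axis=1) for cut in cuts]).T
    return pd.DataFrame(counts.astype(int), index=s.samples, columns=thresholds.astype(int))


def compute_emf(
    t: FunctionTable,
    thresholds: np.ndarray | list[int] = DEFAULT_THRESHOLDS,
    robust_max_k: int = 1,
) -> EMFResult:
    """Full EMF computation: direction flip, standardization, all indices."""
    s = standardize(apply_direction(t))
    return EMFResult(
        emf_average=emf_average(s),
        emf_weighted=emf_weighted(s),
        n_functions_used=s.values.notna().sum(axis=1).rename("n_functions_used"),
        threshold_counts=multi_threshold(s, thresholds, robust_max_k=robust_max_k),
    )
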