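import logging

import numpy as np
import pandas as pd
import pytest

from riveremf.data_model import FunctionCategory, FunctionSchema
from riveremf.multifunctionality import (
    apply_direction,
    compute_emf,
    emf_average,
    emf_weighted,
    multi_threshold,
    standardize,
)

from conftest import make_table


def naive_threshold_counts(std: np.ndarray, thresholds) -> np.ndarray:
    """Double loop straight from the definition (max of STD is 1)."""
    out = np.zeros((std.shape[0], len(thresholds)), dtype=int)
    for i in range(std.shape[0]):
        for k, t in enumerate(thresholds):
            for v in std[i]:
                if not np.isnan(v) and v >= t / 100.0:
                    out[i, k] += 1
    return out


def test_apply_direction_flips_and_is_single_shot(tiny_table):
    flipped = apply_direction(tiny_table)
    assert np.allclose(flipped.values["f3"], -tiny_table.values["f3"])
    assert np.allclose(flipped.values["f1"], tiny_table.values["f1"])
    again = apply_direction(flipped)  # all flags reset: identity
    pd.testing.assert_frame_equal(again.values, flipped.values)


def test_standardize_minmax_formula(tiny_table):
    s = standardize(apply_direction(tiny_table))
    assert np.allclose(s.values["f1"], [0.0, 0.5, 1.0])
    assert s.values.min().min() >= 0 and s.values.max().max() <= 1
    assert (s.values.min(axis=0) == 0).all() and (s.values.max(axis=0) == 1).all()


def test_flipped_column_is_one_minus_std(tiny_schema):
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(10, 3))
    t = make_table(vals, tiny_schema)
    s_flipped = standardize(apply_direction(t))
    plus = FunctionSchema(
        categories=dict(tiny_schema.categories), directions={f: 1 for f in tiny_schema.functions}
    )
    s_plain = standardize(make_table(vals, plus))
    assert np.allclose(s_flipped.values["f3"], 1.0 - s_plain.values["f3"], atol=1e-12)


def test_zero_range_function_becomes_half_with_warning(tiny_schema, caplog):
    t = make_table(np.array([[7.0, 1.0, 2.0], [7.0, 2.0, 3.0], [7.0, 3.0, 4.0]]), tiny_schema)
    with caplog.at_level(logging.WARNING):
        s = standardize(t)
    assert (s.values["f1"] == 0.5).all()
    assert "f1" in caplog.text
    assert s.degenerate == ["f1"]


def test_emf_average_is_the_mean(tiny_schema):
    # middle sample standardizes to exactly [0.2, 0.4, 0.9]
    s = standardize(make_table(np.array([[0.0, 0.0, 0.0], [0.2, 0.4, 0.9], [1.0, 1.0, 1.0]]),
                               FunctionSchema(categories=dict(tiny_schema.categories),
                                              directions={f: 1 for f in tiny_schema.functions})))
    avg = emf_average(s)
    assert avg.iloc[1] == pytest.approx(0.5)
    assert avg.iloc[2] == pytest.approx(1.0)


def test_emf_average_bounded_by_row_extrema(tiny_schema):
    rng = np.random.default_rng(42)
    plus = FunctionSchema(
        categories=dict(tiny_schema.categories), directions={f: 1 for f in tiny_schema.functions}
    )
    for _ in range(200):
        s = standardize(make_table(rng.normal(size=(8, 3)), plus))
        avg = emf_average(s)
        assert (avg >= s.values.min(axis=1) - 1e-12).all()
        assert (avg <= s.values.max(axis=1) + 1e-12).all()
        assert avg.between(0, 1).all()


def test_emf_weighted_category_means(tiny_schema):
    # categories: {f1,f2} -> nitrogen_cycling, {f3} -> water_quality
    plus = FunctionSchema(
        categories=dict(tiny_schema.categories), directions={f: 1 for f in tiny_schema.functions}
    )
    s = standardize(make_table(np.array([[0.0, 0.0, 0.0], [0.2, 0.4, 0.9], [1.0, 1.0, 1.0]]), plus))
    w = emf_weighted(s)
    assert w.iloc[1] == pytest.approx((0.3 + 0.9) / 2)


def test_emf_weighted_equals_average_for_equal_category_sizes():
    cats = {
        "a1": FunctionCategory.NITROGEN_CYCLING,
        "a2": FunctionCategory.NITROGEN_CYCLING,
        "b1": FunctionCategory.WATER_QUALITY,
        "b2": FunctionCategory.WATER_QUALITY,
    }
    schema = FunctionSchema(categories=cats, directions={f: 1 for f in cats})
    rng = np.random.default_rng(7)
    for _ in range(50):
        s = standardize(make_table(rng.normal(size=(6, 4)), schema))
        assert np.allclose(emf_weighted(s), emf_average(s), atol=1e-12)


def test_emf_weighted_reduces_to_average_for_single_function_categories():
    cats = {
        "a": FunctionCategory.NITROGEN_CYCLING,
        "b": FunctionCategory.WATER_QUALITY,
        "c": FunctionCategory.NUTRIENT_POOL,
    }
    schema = FunctionSchema(categories=cats, directions={f: 1 for f in cats})
    rng = np.random.default_rng(8)
    s = standardize(make_table(rng.normal(size=(5, 3)), schema))
    assert np.allclose(emf_weighted(s), emf_average(s), atol=1e-12)


def test_all_missing_sample_raises(tiny_schema):
    vals = np.array([[1.0, 2.0, 3.0], [np.nan, np.nan, np.nan], [2.0, 1.0, 0.0]])
    s = standardize(make_table(vals, tiny_schema))
    with pytest.raises(ValueError, match="S1"):
        emf_average(s)


def test_multi_threshold_boundaries(tiny_schema):
    plus = FunctionSchema(
        categories=dict(tiny_schema.categories), directions={f: 1 for f in tiny_schema.functions}
    )
    s = standardize(make_table(np.array([[0.0, 0.0, 0.0], [1.0, 0.2, 0.5], [1.0, 1.0, 1.0]]), plus))
    counts = multi_threshold(s, [5, 50, 95])
    # row 1 standardizes to [1, 0.2, 0.5]: at 50% only f1 and f3... f3=0.5 >= 0.5 counts
    assert counts.loc[counts.index[1], 50] == 2
    assert counts.loc[counts.index[1], 95] == 1
    assert (counts.loc[counts.index[2]] == 3).all()


def test_multi_threshold_matches_naive_enumeration_and_monotone(tiny_schema):
    rng = np.random.default_rng(3)
    plus = FunctionSchema(
        categories=dict(tiny_schema.categories), directions={f: 1 for f in tiny_schema.functions}
    )
    thresholds = list(range(5, 96))
    for _ in range(20):
        s = standardize(make_table(rng.normal(size=(12, 3)), plus))
        counts = multi_threshold(s, thresholds)
        naive = naive_threshold_counts(s.values.to_numpy(), thresholds)
        assert np.array_equal(counts.to_numpy(), naive)
        assert (np.diff(counts.to_numpy(), axis=1) <= 0).all()


def test_multi_threshold_empty_grid_rejected(tiny_table):
    s = standardize(apply_direction(tiny_table))
    with pytest.raises(ValueError, match="empty"):
        multi_threshold(s, [])


def test_compute_emf_reports_functions_used(tiny_schema):
    vals = np.array([[1.0, 2.0, 3.0], [2.0, np.nan, 4.0], [3.0, 4.0, 5.0]])
    res = compute_emf(make_table(vals, tiny_schema))
    assert list(res.n_functions_used) == [3, 2, 3]
    assert res.threshold_counts.shape[1] == 91
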