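from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from riveremf.conetwork import (
    METRIC_NAMES,
    build_network,
    complexity_index,
    fdr_adjust,
    modularity,
    sample_subnetwork,
    spearman_matrix,
    subnetwork_table,
    topological_metrics,
)
from riveremf.data_model import AbundanceMatrix

from oracles import bh_adjust, brute_metrics, newman_girvan_q, spearman_midrank


def make_abundance(arr):
    arr = np.asarray(arr, dtype=float)
    return AbundanceMatrix(
        pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"t{j}" for j in range(arr.shape[1])],
        )
    )


def random_graph(rng, n_max=10):
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return g


# ---------------------------------------------------------------- spearman

def test_spearman_hand_checkable_value():
    x = np.array([1, 2, 3, 4, 5.0])
    y = np.array([5, 6, 7, 8, 7.0])
    rho, _ = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
    assert rho.loc["x", "y"] == pytest.approx(8 / np.sqrt(95))
    assert rho.loc["x", "y"] == pytest.approx(spearman_midrank(x, y))


def test_spearman_monotone_and_antisymmetric():
    x = np.array([3, 1, 4, 1.5, 9, 2.6])
    rho, _ = spearman_matrix(pd.DataFrame({"x": x, "y": np.exp(x), "z": -x}))
    assert rho.loc["x", "y"] == pytest.approx(1.0)
    assert rho.loc["x", "z"] == pytest.approx(-1.0)


def test_spearman_matrix_matches_scipy_pairwise():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.poisson(20, size=(15, 5)).astype(float), columns=list("abcde"))
    rho, p = spearman_matrix(df)
    for i, ci in enumerate(df.columns):
        for j, cj in enumerate(df.columns):
            if i == j:
                continue
            want = spearmanr(df[ci], df[cj])
            assert rho.loc[ci, cj] == pytest.approx(want.statistic, abs=1e-12)
            assert p.loc[ci, cj] == pytest.approx(want.pvalue, rel=1e-9)


def test_spearman_constant_column_is_nan():
    rho, p = spearman_matrix(pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [7.0, 7, 7, 7]}))
    assert np.isnan(rho.loc["x", "c"]) and np.isnan(p.loc["x", "c"])


def test_spearman_needs_four_samples():
    with pytest.raises(ValueError, match="4 samples"):
        spearman_matrix(pd.DataFrame({"x": [1.0, 2, 3], "y": [3.0, 2, 1]}))


# ---------------------------------------------------------------- FDR

def test_bh_known_example_and_oracle():
    q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(fdr_adjust(p), bh_adjust(p), atol=1e-12)


def test_bh_degenerate_cases():
    assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    assert fdr_adjust([0.37])[0] == pytest.approx(0.37)
    with pytest.raises(ValueError):
        fdr_adjust([1.2])


# ---------------------------------------------------------------- network

def test_edge_count_monotone_in_rho_threshold():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(20, 1))
    data = np.exp(base + 0.4 * rng.normal(size=(20, 15)) + 3)
    a = make_abundance(rng.poisson(data))
    prev = None
    for thr in (0.3, 0.5, 0.65, 0.8, 0.95):
        n_edges = build_network(a, rho_threshold=thr, q_threshold=0.2).n_edges
        if prev is not None:
            assert n_edges <= prev
        prev = n_edges


def test_abundance_prefilter_removes_rare_taxa():
    arr = np.ones((6, 4)) * 100.0
    arr[:, 3] = 1e-3  # summed relative abundance far below the cut
    net = build_network(make_abundance(arr), min_rel_abund=1e-4)
    assert "t3" in net.excluded_taxa
    assert net.n_taxa_tested == 3


def test_network_requires_four_samples():
    with pytest.raises(ValueError):
        build_network(make_abundance(np.ones((3, 5))))


# ---------------------------------------------------------------- metrics

def test_triangle_metrics():
    m = topological_metrics(nx.complete_graph(3))
    assert m["connectance"] == 1.0
    assert m["clustering_coefficient"] == 1.0
    assert m["diameter"] == 1.0
    assert m["average_path_length"] == 1.0
    assert m["edge_connectivity"] == 2.0


def test_path_p3_metrics():
    m = topological_metrics(nx.path_graph(3))
    assert m["average_path_length"] == pytest.approx(4 / 3)
    assert m["diameter"] == 2.0
    assert m["clustering_coefficient"] == 0.0
    assert m["connectance"] == pytest.approx(2 / 3)


def test_star_k13_is_maximally_centralized():
    m = topological_metrics(nx.star_graph(3))
    assert m["degree_centralization"] == pytest.approx(1.0)
    assert m["betweenness_centralization"] == pytest.approx(1.0)
    assert m["edge_connectivity"] == 1.0


def test_degenerate_graphs_have_defined_values():
    empty = topological_metrics(nx.empty_graph(0))
    assert empty["node_number"] == 0 and empty["average_path_length"] == 0
    single = topological_metrics(nx.empty_graph(1))
    assert single["node_number"] == 1 and single["edge_number"] == 0
    edgeless = topological_metrics(nx.empty_graph(5))
    assert edgeless["connectance"] == 0 and edgeless["clustering_coefficient"] == 0


def test_metrics_match_brute_force_on_random_graphs():
    rng = np.random.default_rng(9)
    for _ in range(60):
        g = random_graph(rng)
        got = topological_metrics(g)
        want = brute_metrics(g.number_of_nodes(), list(g.edges()))
        for k in METRIC_NAMES:
            assert got[k] == pytest.approx(want[k], abs=1e-9), (k, sorted(g.edges()))


def test_sample_subnetwork_identity_and_degenerate():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(12, 1))
    lam = np.exp(2.5 + base + 0.3 * rng.normal(size=(12, 6)))
    a = make_abundance(rng.poisson(lam) + 1)  # all taxa present everywhere
    net = build_network(a, rho_threshold=0.3, q_threshold=0.5)
    full = topological_metrics(net.graph)
    sub = sample_subnetwork(net, a, "s0")
    assert sub == full
    # one present taxon -> degenerate values
    one = a.data.copy()
    one.loc["s0"] = 0.0
    one.loc["s0", "t0"] = 5.0
    a1 = AbundanceMatrix(one)
    m1 = sample_subnetwork(net, a1, "s0")
    assert m1["node_number"] == 1 and m1["edge_number"] == 0
    assert m1["average_path_length"] == 0 and m1["diameter"] == 0
    with pytest.raises(KeyError):
        sample_subnetwork(net, a, "nope")


def test_subnetwork_table_has_one_row_per_sample():
    rng = np.random.default_rng(3)
    a = make_abundance(rng.poisson(50, size=(8, 6)))
    net = build_network(a, rho_threshold=0.2, q_threshold=0.9)
    tab = subnetwork_table(net, a)
    assert list(tab.index) == [f"s{i}" for i in range(8)]
    assert set(METRIC_NAMES) <= set(tab.columns)


# ---------------------------------------------------------------- modularity

def test_modularity_two_triangles_is_half():
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    q, membership = modularity(g)
    assert q == pytest.approx(0.5)
    assert len({membership[0], membership[3]}) == 2
    assert q == pytest.approx(newman_girvan_q(6, list(g.edges()), membership))


def test_modularity_at_least_trivial_partition_and_complete_graph():
    q, _ = modularity(nx.complete_graph(6))
    assert q >= 0.0 - 1e-12  # one-community partition has Q = 0
    with pytest.raises(ValueError):
        modularity(nx.empty_graph(4))


# ---------------------------------------------------------------- complexity

def _metric_frame(rng, n=12):
    cols = list(METRIC_NAMES)
    return pd.DataFrame(
        rng.random((n, len(cols))) * [5, 50, 1, 4, 3, 1, 6, 2, 1, 1],
        columns=cols,
        index=[f"s{i}" for i in range(n)],
    )


def test_complexity_rank_one_table_explains_everything():
    rng = np.random.default_rng(0)
    base = rng.random(10)
    m = pd.DataFrame(
        {name: base * (i + 1) for i, name in enumerate(METRIC_NAMES)},
        index=[f"s{i}" for i in range(10)],
    )
    ci = complexity_index(m)
    assert ci.variance_explained == pytest.approx(1.0)
    assert abs(ci.scores).sum() > 0
    assert ci.scores.mean() == pytest.approx(0.0, abs=1e-9)


def test_complexity_matches_eigen_oracle():
    rng = np.random.default_rng(4)
    m = _metric_frame(rng)
    ci = complexity_index(m)
    # oracle: flip sparsity columns, z-score, correlation eigendecomposition
    x = m.copy()
    x["average_path_length"] *= -1
    x["diameter"] *= -1
    z = (x - x.mean()) / x.std(ddof=1)
    w, v = np.linalg.eigh(np.corrcoef(z.to_numpy(), rowvar=False))
    axis = v[:, -1]
    if axis[list(x.columns).index("edge_number")] < 0:
        axis = -axis
    assert np.allclose(ci.scores.to_numpy(), z.to_numpy() @ axis, atol=1e-8)
    assert ci.variance_explained == pytest.approx(w[-1] / w.sum())


def test_complexity_internal_flip_applied_exactly_once():
    rng = np.random.default_rng(5)
    m = _metric_frame(rng)
    ci = complexity_index(m)
    pre = m.copy()
    pre["average_path_length"] *= -1
    pre["diameter"] *= -1
    ci_pre = complexity_index(pre)
    # user pre-flip + internal flip = double negation: loadings on the
    # sparsity metrics change sign relative to the single internal flip
    assert np.sign(ci.loadings["average_path_length"]) == -np.sign(
        ci_pre.loadings["average_path_length"]
    ) or ci.loadings["average_path_length"] == pytest.approx(0, abs=1e-12)


def test_complexity_rejects_constant_table():
    m = pd.DataFrame(
        {name: np.ones(5) for name in METRIC_NAMES}, index=[f"s{i}" for i in range(5)]
    )
    with pytest.raises(ValueError):
        complexity_index(m)
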