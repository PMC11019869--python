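"""Microbial co-occurrence networks and network-complexity metrics.

A network is built from a samples x taxa abundance matrix in three steps:

1. rare taxa (summed relative abundance below ``min_rel_abund`` over the
   samples at hand) are removed;
2. all remaining taxon pairs are correlated (Spearman, mid-rank ties) and
   the p-values are Benjamini–Hochberg adjusted over the whole family of
   tested pairs;
3. an edge is kept when |rho| exceeds ``rho_threshold`` and the adjusted
   p-value (q) is below ``q_threshold``.

Per-sample complexity is assigned by inducing the subgraph on the taxa
present in that sample and extracting ten topological characteristics:
node number, edge number, mean degree, connectance, average path length,
diameter, edge connectivity, degree centralization, betweenness
centralization and clustering coefficient.  A composite complexity score is
the first principal axis of the (z-scored) metric table, after negating
average path length and diameter, which measure sparsity rather than
complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import AbundanceMatrix, to_relative

__all__ = [
    "CooccurrenceNetwork",
    "ComplexityIndex",
    "METRIC_NAMES",
    "SPARSITY_METRICS",
    "spearman_matrix",
    "fdr_adjust",
    "build_network",
    "topological_metrics",
    "sample_subnetwork",
    "subnetwork_table",
    "modularity",
    "complexity_index",
]

#: The ten topological characteristics, in reporting order.
METRIC_NAMES = (
    "node_number",
    "edge_number",
    "betweenness_centralization",
    "mean_degree",
    "average_path_length",
    "connectance",
    "diameter",
    "edge_connectivity",
    "degree_centralization",
    "clustering_coefficient",
)

#: Metrics that grow as networks get *sparser*; negated before the
#: composite complexity axis is extracted.
SPARSITY_METRICS = ("average_path_length", "diameter")


@dataclass
class CooccurrenceNetwork:
    """Taxa nodes plus FDR-filtered signed Spearman edges."""

    graph: nx.Graph
    rho_threshold: float
    q_threshold: float
    min_rel_abund: float
    n_samples: int
    n_taxa_tested: int
    excluded_taxa: list[str] = field(default_factory=list)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v, "rho": d["rho"], "q": d["q"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "q"])

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ComplexityIndex:
    """First principal axis of the per-sample topology table."""

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    dropped_constant: list[str] = field(default_factory=list)


def spearman_matrix(a: AbundanceMatrix | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (mid-rank ties) and two-sided p over taxa columns.

    Constant columns have undefined correlations; their rows/columns are NaN
    and are excluded from any downstream edge building.
    """
    df = a.data if isinstance(a, AbundanceMatrix) else a
    n = df.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 samples for stable correlations, got {n}")
    # Pearson correlation of per-column mid-ranks, with the t-approximation
    # for two-sided p-values (the large-sample route scipy itself uses).
    # Computed directly so constant columns yield NaN for their pairs instead
    # of poisoning the whole matrix.
    ranks = np.apply_along_axis(stats.rankdata, 0, df.to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    cols = df.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def fdr_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    a: AbundanceMatrix,
    rho_threshold: float = 0.65,
    q_threshold: float = 0.01,
    min_rel_abund: float = 1e-4,
    positive_only: bool = False,
) -> CooccurrenceNetwork:
    """Construct the co-occurrence network from an abundance matrix.

    ``min_rel_abund`` is the summed relative-abundance cut (default 0.01%)
    applied within the sample set the network is built from.  By default both
    strong co-presence (rho > threshold) and strong exclusion
    (rho < -threshold) edges are kept; ``positive_only`` restricts to the
    former.
    """
    rel = a if a.normalized else to_relative(a)
    keep = rel.data.sum(axis=0) >= min_rel_abund
    excluded = list(rel.data.columns[~keep])
    counts = a.data.loc[:, keep]
    if counts.shape[1] < 2:
        raise ValueError("fewer than two taxa survive the abundance filter")
    rho, p = spearman_matrix(counts)

    taxa = list(counts.columns)
    iu = np.triu_indices(len(taxa), k=1)
    rho_flat = rho.to_numpy()[iu]
    p_flat = p.to_numpy()[iu]
    testable = np.isfinite(rho_flat) & np.isfinite(p_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if testable.any():
        q_flat[testable] = fdr_adjust(p_flat[testable])

    strength = rho_flat if positive_only else np.abs(rho_flat)
    keep_edge = testable & (strength > rho_threshold) & (q_flat < q_threshold)

    g = nx.Graph()
    g.add_nodes_from(taxa)
    for k in np.flatnonzero(keep_edge):
        i, j = iu[0][k], iu[1][k]
        g.add_edge(taxa[i], taxa[j], rho=float(rho_flat[k]), q=float(q_flat[k]))
    return CooccurrenceNetwork(
        graph=g,
        rho_threshold=rho_threshold,
        q_threshold=q_threshold,
        min_rel_abund=min_rel_abund,
        n_samples=counts.shape[0],
        n_taxa_tested=len(taxa),
        excluded_taxa=excluded,
    )


def _freeman_centralization(values: dict, denom: float) -> float:
    if denom <= 0 or not values:
        return 0.0
    vmax = max(values.values())
    return sum(vmax - v for v in values.values()) / denom


def topological_metrics(g: nx.Graph) -> dict[str, float]:
    """The ten topological characteristics of a simple undirected graph.

    Path-based metrics (average path length, diameter) are computed on the
    largest connected component when the graph is disconnected; the number
    of components is reported alongside.  Degenerate graphs (fewer than two
    nodes, or no edges) return 0 for path metrics, centralizations,
    clustering and connectance.
    """
    n = g.number_of_nodes()
    m = g.number_of_edges()
    out: dict[str, float] = {
        "node_number": float(n),
        "edge_number": float(m),
        "mean_degree": 2.0 * m / n if n else 0.0,
        "connectance": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
    }
    if n <= 1 or m == 0:
        out.update(
            {
                k: 0.0
                for k in (
                    "average_path_length",
                    "diameter",
                    "edge_connectivity",
                    "degree_centralization",
                    "betweenness_centralization",
                    "clustering_coefficient",
                )
            }
        )
        out["n_components"] = float(max(n, 0))
        return out

    components = list(nx.connected_components(g))
    lcc = g.subgraph(max(components, key=len))
    if lcc.number_of_nodes() > 1:
        out["average_path_length"] = float(nx.average_shortest_path_length(lcc))
        out["diameter"] = float(nx.diameter(lcc))
    else:
        out["average_path_length"] = 0.0
        out["diameter"] = 0.0
    out["n_components"] = float(len(components))

    # smallest number of edge removals that disconnects; 0 if already disconnected
    out["edge_connectivity"] = float(nx.edge_connectivity(g)) if len(components) == 1 else 0.0

    degrees = dict(g.degree())
    # Freeman star-graph normalization: (n-1)(n-2) for degree
    out["degree_centralization"] = _freeman_centralization(degrees, (n - 1) * (n - 2))

    # unnormalized betweenness over unordered pairs, endpoints excluded;
    # star maximum is (n-1)^2 (n-2) / 2
    btw = nx.betweenness_centrality(g, normalized=False)
    out["betweenness_centralization"] = _freeman_centralization(
        btw, (n - 1) ** 2 * (n - 2) / 2.0
    )

    out["clustering_coefficient"] = float(nx.transitivity(g))
    return out


def sample_subnetwork(
    net: CooccurrenceNetwork, a: AbundanceMatrix, sample: str
) -> dict[str, float]:
    """Topological metrics of the subgraph induced by the taxa present
    (abundance > 0) in one sample."""
    if sample not in a.data.index:
        raise KeyError(f"unknown sample {sample!r}")
    row = a.data.loc[sample]
    present = [t for t in row.index[row > 0] if net.graph.has_node(t)]
    sub = net.graph.subgraph(present)
    return topological_metrics(sub)


def subnetwork_table(net: CooccurrenceNetwork, a: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample subnetwork metrics, one row per sample of ``a``."""
    rows = {s: sample_subnetwork(net, a, s) for s in a.data.index}
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, list(METRIC_NAMES) + ["n_components"]]


def modularity(g: nx.Graph, seed: int | None = None) -> tuple[float, dict]:
    """Greedy agglomerative maximization of Newman–Girvan modularity Q.

    Returns Q and the node -> community-id membership map.  The greedy
    optimizer (Clauset–Newman–Moore) is deterministic; exact maximization is
    NP-hard and Q here is used descriptively (Q > 0.4 is conventionally read
    as modular structure).
    """
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    communities = nx.algorithms.community.greedy_modularity_communities(g)
    q = nx.algorithms.community.modularity(g, communities)
    membership = {node: ci for ci, comm in enumerate(communities) for node in comm}
    return float(q), membership


def complexity_index(m: pd.DataFrame) -> ComplexityIndex:
    """Composite network-complexity score: PCA axis 1 of the metric table.

    ``average_path_length`` and ``diameter`` are negated first (they measure
    sparsity); each metric is then z-scored and the first principal axis of
    the correlation matrix extracted.  The axis is oriented so that its
    loading on ``edge_number`` is non-negative, making larger scores mean
    more complex networks.  Constant metrics are dropped (recorded in
    ``dropped_constant``).
    """
    if m.shape[0] < 3:
        raise ValueError("need at least 3 samples for the complexity index")
    x = m.loc[:, [c for c in m.columns if c in METRIC_NAMES]].astype(float).copy()
    for col in SPARSITY_METRICS:
        if col in x:
            x[col] = -x[col]
    sd = x.std(axis=0, ddof=1)
    dropped = list(x.columns[sd == 0])
    x = x.loc[:, sd > 0]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 metrics with nonzero variance")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    axis = eigvecs[:, -1]
    if "edge_number" in x.columns:
        sign = np.sign(axis[list(x.columns).index("edge_number")]) or 1.0
    else:
        sign = np.sign(axis.sum()) or 1.0
    axis = axis * sign
    scores = z.to_numpy() @ axis
    return ComplexityIndex(
        scores=pd.Series(scores, index=m.index, name="complexity"),
        loadings=pd.Series(axis, index=x.columns, name="loading"),
        variance_explained=float(eigvals[-1] / eigvals.sum()),
        dropped_constant=dropped,
    )
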