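"""Community structure: alpha diversity, Bray–Curtis, NMDS, ANOSIM.

Alpha diversity is observed richness plus the Shannon index in nats (the
usual ecology convention).  Beta diversity is Bray–Curtis dissimilarity,
ordinated by non-metric multidimensional scaling (NMDS) and tested between
groups with the rank-based ANOSIM permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from sklearn.manifold import MDS

from .data_model import AbundanceMatrix

__all__ = [
    "DiversityResult",
    "OrdinationResult",
    "AnosimResult",
    "alpha_diversity",
    "bray_curtis",
    "nmds",
    "anosim",
]


@dataclass
class DiversityResult:
    """Per-sample observed richness and Shannon entropy (nats)."""

    table: pd.DataFrame  # columns: observed_richness, shannon

    @property
    def observed_richness(self) -> pd.Series:
        return self.table["observed_richness"]

    @property
    def shannon(self) -> pd.Series:
        return self.table["shannon"]


@dataclass
class OrdinationResult:
    """NMDS coordinates (centered at the origin) with the final stress."""

    coordinates: pd.DataFrame  # columns NMDS1, NMDS2, ...
    stress: float
    n_restarts: int
    seed: int | None


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def alpha_diversity(a: AbundanceMatrix) -> DiversityResult:
    """Observed richness (taxa with abundance > 0) and Shannon H = -sum p ln p."""
    arr = a.data.to_numpy(dtype=float)
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = list(a.samples[sums <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    richness = (arr > 0).sum(axis=1)
    shannon = np.array([entropy(row[row > 0]) for row in arr])  # nats
    return DiversityResult(
        pd.DataFrame(
            {"observed_richness": richness, "shannon": shannon}, index=a.samples
        )
    )


def bray_curtis(a: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y)."""
    arr = a.data.to_numpy(dtype=float)
    if (arr.sum(axis=1) <= 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    condensed = pdist(arr, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in a.samples])


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    seed: int | None = 0,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> OrdinationResult:
    """Non-metric MDS of a distance matrix.

    Runs ``n_restarts`` random initializations and keeps the configuration
    with the lowest Kruskal stress-1.  Deterministic for a fixed seed.
    """
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-dimensional NMDS")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(np.asarray(d.data))
    coords = coords - coords.mean(axis=0, keepdims=True)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        stress=float(model.stress_),
        n_restarts=n_restarts,
        seed=seed,
    )


def anosim(
    d: DistanceMatrix,
    groups: pd.Series | np.ndarray | list,
    n_perm: int = 999,
    seed: int | None = 0,
) -> AnosimResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (M/4).

    R near 1 means groups are well separated; the p-value is the fraction of
    label permutations (observed included) with R at least as large.
    """
    if isinstance(groups, pd.Series):
        labels = groups.copy()
        labels.index = labels.index.map(str)
        labels = labels.reindex(list(d.ids))
        if labels.isna().any():
            missing = [i for i in d.ids if i not in groups.index.map(str)]
            raise ValueError(f"samples without a group label: {missing}")
    else:
        labels = pd.Series(list(groups), index=list(d.ids))
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        singles = list(counts[counts < 2].index)
        raise ValueError(f"group(s) with fewer than two members: {singles}")
    res = _skbio_anosim(d, list(labels), permutations=n_perm, seed=seed)
    return AnosimResult(
        r=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        seed=seed,
    )
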