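"""Synthetic river-survey generator with known ground truth.

The generator emulates the design of a latitudinal field survey: ~30 river
sites spanning 21.76–45.09°N, each sampled in three habitats (riparian
rhizosphere soil, riparian bulk soil, channel sediment), with

* a function table of 18 ecosystem-function variables whose directional
  (post-flip) values respond linearly to latitude with configurable slope
  and Gaussian noise, and
* a samples x genera count matrix in which taxa have Gaussian niche
  responses to latitude and planted "guilds" — blocks of taxa that share a
  niche optimum and a latent log-abundance factor — so co-occurrence
  networks have recoverable structure.  The guild coupling can differ
  between the low- and high-latitude groups, planting a directional
  contrast in network density between the groups.

Every generated dataset carries a :class:`GroundTruth` describing exactly
what was planted, so recovery can be scored without reference to the
generator internals.  All randomness flows from a single seed; the same
seed reproduces sites, functions and abundances bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_SPLIT_LATITUDE,
    AbundanceMatrix,
    FunctionTable,
    Habitat,
    LatGroup,
    Level,
    default_schema,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_functions",
    "simulate_abundances",
    "sample_metadata",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey.

    Function signal: each function's *directional* value (after the
    undesirable-variable flip) is ``intercept + slope * latitude + offset_h
    + Normal(0, sigma)``.  ``function_slope``/``function_sigma`` apply to all
    functions; per-function overrides go in the ``*_overrides`` maps.

    Abundance signal: log expected abundance of taxon j in sample i is
    ``base_j + site_i + niche_j(L_i) + guild term``; counts are Poisson (or
    negative binomial when ``overdispersion`` > 0).  Guild members share a
    latent factor with correlation ``guild_correlation`` (one value, or one
    per latitude group) and a common niche optimum.
    """

    n_sites: int = 30
    lat_range: tuple[float, float] = (21.76, 45.09)
    habitats: tuple[str, ...] = tuple(h.value for h in Habitat)
    split_latitude: float = DEFAULT_SPLIT_LATITUDE
    group_sizes: tuple[int, int] | None = None  # (n_low, n_high), e.g. (11, 19)

    # function table
    function_slope: float = -0.01  # directional units per degree latitude
    function_sigma: float = 0.05
    function_intercept: float = 1.0
    slope_overrides: Mapping[str, float] = field(default_factory=dict)
    sigma_overrides: Mapping[str, float] = field(default_factory=dict)
    habitat_offsets: Mapping[str, float] = field(default_factory=dict)

    # abundance matrix
    n_taxa: int = 200
    n_guilds: int = 4
    guild_size: int = 10
    guild_correlation: float | Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.5, "high": 0.9}
    )
    turnover_scale: float = 8.0  # niche breadth, degrees latitude
    guild_sigma: float = 1.5  # latent log-abundance factor scale
    site_sigma: float = 0.2  # log-normal site factor scale
    log_mean_range: tuple[float, float] = (3.0, 5.3)  # log expected counts
    overdispersion: float = 0.0  # NB dispersion; 0 = Poisson

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        lo, hi = self.lat_range
        if not hi > lo:
            raise ValueError(f"degenerate lat_range {self.lat_range}")
        if self.n_guilds * self.guild_size > self.n_taxa:
            raise ValueError("n_guilds * guild_size exceeds n_taxa")
        for r in self._guild_corr().values():
            if not 0 <= r < 1:
                raise ValueError(f"guild_correlation must be in [0, 1), got {r}")
        sigmas = dict(self.sigma_overrides)
        if self.function_sigma <= 0 or any(s <= 0 for s in sigmas.values()):
            raise ValueError("function noise sigma must be > 0")
        if self.group_sizes is not None and sum(self.group_sizes) != self.n_sites:
            raise ValueError("group_sizes must sum to n_sites")

    def _guild_corr(self) -> dict[str, float]:
        if isinstance(self.guild_correlation, Mapping):
            return {
                LatGroup.LOW.value: float(self.guild_correlation["low"]),
                LatGroup.HIGH.value: float(self.guild_correlation["high"]),
            }
        r = float(self.guild_correlation)
        return {LatGroup.LOW.value: r, LatGroup.HIGH.value: r}


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    function_slopes: dict[str, float]  # directional (post-flip) scale
    emf_raw_slope: float  # slope of the mean directional function
    guilds: dict[int, list[str]]
    guild_correlation: dict[str, float]
    niche_optima: dict[str, float]
    niche_breadth: float
    seed: int

    def guild_of(self) -> dict[str, int]:
        return {t: g for g, members in self.guilds.items() for t in members}


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _sites(cfg: SimulationConfig) -> pd.DataFrame:
    """Site frame shared by both generators (same seed -> same sites).

    Latitudes are stratified-uniform: one uniform draw per equal-width band,
    which keeps the gradient evenly covered.  ``group_sizes`` instead
    stratifies within each side of the split latitude, reproducing an
    unbalanced field design such as 11 low / 19 high.
    """
    rng = _rng(cfg, 0)
    lo, hi = cfg.lat_range

    def stratified(a: float, b: float, n: int) -> np.ndarray:
        edges = np.linspace(a, b, n + 1)
        return rng.uniform(edges[:-1], edges[1:])

    if cfg.group_sizes is None:
        lats = stratified(lo, hi, cfg.n_sites)
    else:
        n_low, n_high = cfg.group_sizes
        lats = np.concatenate(
            [stratified(lo, cfg.split_latitude, n_low), stratified(cfg.split_latitude, hi, n_high)]
        )
    lons = rng.uniform(100.0, 130.0, size=cfg.n_sites)
    elev = rng.uniform(-1.4, 1000.2, size=cfg.n_sites)
    groups = np.where(lats < cfg.split_latitude, LatGroup.LOW.value, LatGroup.HIGH.value)
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(cfg.n_sites)],
            "latitude": lats,
            "longitude": lons,
            "elevation": elev,
            "lat_group": groups,
        }
    )


def _sample_frame(cfg: SimulationConfig) -> pd.DataFrame:
    sites = _sites(cfg)
    rows = []
    for _, s in sites.iterrows():
        for h in cfg.habitats:
            rows.append({**s.to_dict(), "habitat": h})
    df = pd.DataFrame(rows)
    df.index = pd.MultiIndex.from_arrays(
        [df["site_id"], df["habitat"]], names=["site_id", "habitat"]
    )
    return df


def sample_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-sample metadata keyed by the flat ``site:habitat`` id used on the
    abundance side (same sites as the function table for the same seed)."""
    meta = _sample_frame(cfg)
    out = meta[["site_id", "habitat", "latitude", "longitude", "elevation", "lat_group"]].copy()
    out.index = pd.Index([f"{s}:{h}" for s, h in meta.index], name="sample")
    return out


def simulate_functions(cfg: SimulationConfig) -> tuple[FunctionTable, GroundTruth]:
    """Generate the 18-function table with a planted latitude trend.

    The planted slope is on the directional (post-flip) scale, so a raw
    variable with direction -1 is generated as the negated directional
    value; running the EMF direction flip recovers the planted trend.
    """
    schema = default_schema()
    meta = _sample_frame(cfg)
    rng = _rng(cfg, 1)
    lat = meta["latitude"].to_numpy()

    values = pd.DataFrame(index=meta.index)
    slopes: dict[str, float] = {}
    for f in schema.functions:
        beta = float(cfg.slope_overrides.get(f, cfg.function_slope))
        sigma = float(cfg.sigma_overrides.get(f, cfg.function_sigma))
        offsets = meta["habitat"].map(lambda h: cfg.habitat_offsets.get(h, 0.0)).to_numpy()
        directional = cfg.function_intercept + beta * lat + offsets + rng.normal(0.0, sigma, len(meta))
        values[f] = directional * schema.directions[f]
        slopes[f] = beta

    metadata = meta[["site_id", "habitat", "latitude", "longitude", "elevation", "lat_group"]]
    truth = GroundTruth(
        function_slopes=slopes,
        emf_raw_slope=float(np.mean(list(slopes.values()))),
        guilds={},
        guild_correlation=cfg._guild_corr(),
        niche_optima={},
        niche_breadth=cfg.turnover_scale,
        seed=cfg.seed,
    )
    return FunctionTable(values=values, metadata=metadata, schema=schema), truth


def simulate_abundances(cfg: SimulationConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate a samples x genera count matrix with niche turnover and guilds.

    Log expected abundance: base + site factor + Gaussian niche in latitude
    + guild/idiosyncratic log-normal term.  Guild members share their
    guild's niche optimum and latent factor; the latent-factor coupling is
    ``guild_correlation`` for the sample's latitude group, so group-specific
    couplings plant a between-group contrast in network density.
    """
    meta = _sample_frame(cfg)
    rng = _rng(cfg, 2)
    n_samples = len(meta)
    lat = meta["latitude"].to_numpy()
    group = meta["lat_group"].to_numpy()
    corr = cfg._guild_corr()

    taxa = [f"g{j + 1:04d}" for j in range(cfg.n_taxa)]
    guilds: dict[int, list[str]] = {
        g: taxa[g * cfg.guild_size : (g + 1) * cfg.guild_size] for g in range(cfg.n_guilds)
    }
    guild_of = np.full(cfg.n_taxa, -1)
    for g, members in guilds.items():
        for t in members:
            guild_of[taxa.index(t)] = g

    lo, hi = cfg.lat_range
    optima = rng.uniform(lo, hi, size=cfg.n_taxa)
    guild_optima = rng.uniform(lo, hi, size=cfg.n_guilds)
    for j in range(cfg.n_taxa):
        if guild_of[j] >= 0:
            optima[j] = guild_optima[guild_of[j]]

    base = rng.uniform(*cfg.log_mean_range, size=cfg.n_taxa)
    site_factor = rng.normal(0.0, cfg.site_sigma, size=n_samples)
    z = rng.normal(size=(n_samples, cfg.n_guilds))  # latent guild factors
    eps = rng.normal(size=(n_samples, cfg.n_taxa))  # idiosyncratic noise

    r_sample = np.array([corr[g] for g in group])  # coupling per sample
    sqrt_r = np.sqrt(r_sample)[:, None]
    sqrt_1mr = np.sqrt(1.0 - r_sample)[:, None]

    niche = -((lat[:, None] - optima[None, :]) ** 2) / (2.0 * cfg.turnover_scale**2)
    noise = cfg.guild_sigma * eps
    for g in range(cfg.n_guilds):
        cols = np.flatnonzero(guild_of == g)
        noise[:, cols] = cfg.guild_sigma * (sqrt_r * z[:, [g]] + sqrt_1mr * eps[:, cols])

    lam = np.exp(base[None, :] + site_factor[:, None] + niche + noise)
    if cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        lam = rng.gamma(shape, lam / shape)
    counts = rng.poisson(lam).astype(float)

    data = pd.DataFrame(counts, index=meta.index, columns=taxa)
    # flat string sample ids for the abundance side ("site:habitat")
    data.index = pd.Index(
        [f"{s}:{h}" for s, h in meta.index], name="sample"
    )
    truth = GroundTruth(
        function_slopes={},
        emf_raw_slope=float("nan"),
        guilds=guilds,
        guild_correlation=corr,
        niche_optima=dict(zip(taxa, optima)),
        niche_breadth=cfg.turnover_scale,
        seed=cfg.seed,
    )
    return AbundanceMatrix(data=data, level=Level.GENUS), truth
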