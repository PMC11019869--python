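"""Typed tables shared by every stage of the pipeline.

Two containers carry all data through the analysis:

* :class:`FunctionTable` — one row per (site, habitat) sample, one column per
  raw ecosystem-function variable, plus site metadata and a
  :class:`FunctionSchema` that maps each function to a functional category
  and a direction flag.
* :class:`AbundanceMatrix` — samples x taxa (or KEGG-Orthology) abundances.

Both round-trip through TSV/CSV with ``NA`` marking missing values, so the
pipeline can be driven either from the synthetic generator or from user
tables prepared outside the package.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Habitat",
    "LatGroup",
    "FunctionCategory",
    "Level",
    "FunctionSchema",
    "SiteMetadata",
    "FunctionTable",
    "AbundanceMatrix",
    "DEFAULT_SPLIT_LATITUDE",
    "default_schema",
    "read_function_table",
    "read_abundance",
    "read_schema",
    "write_schema",
    "to_relative",
]

#: Latitude (degrees N) separating the low- and high-latitude site groups.
#: Approximates the Qinling–Huaihe climatic boundary; configurable everywhere
#: it is used, and overridden whenever groups are given explicitly.
DEFAULT_SPLIT_LATITUDE = 33.0


class Habitat(str, enum.Enum):
    RHIZOSPHERE = "rhizosphere"
    BULK = "bulk"
    SEDIMENT = "sediment"


class LatGroup(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


class FunctionCategory(str, enum.Enum):
    NITROGEN_CYCLING = "nitrogen_cycling"
    NUTRIENT_POOL = "nutrient_pool"
    PLANT_PRODUCTIVITY = "plant_productivity"
    WATER_QUALITY = "water_quality"


class Level(str, enum.Enum):
    """Resolution of an abundance table."""

    GENUS = "genus"
    SPECIES = "species"
    KO = "KO"


@dataclass(frozen=True)
class SiteMetadata:
    """Per-sample metadata: location, habitat and latitude group."""

    site_id: str
    latitude: float
    longitude: float = float("nan")
    elevation: float = float("nan")
    habitat: Habitat = Habitat.RHIZOSPHERE
    lat_group: LatGroup | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.latitude):
            raise ValueError(f"latitude of site {self.site_id!r} is not finite")

    def with_group(self, split_latitude: float = DEFAULT_SPLIT_LATITUDE) -> "SiteMetadata":
        """Return a copy whose ``lat_group`` is filled from the split latitude
        (explicit groups are kept)."""
        if self.lat_group is not None:
            return self
        group = LatGroup.LOW if self.latitude < split_latitude else LatGroup.HIGH
        return replace(self, lat_group=group)


@dataclass(frozen=True)
class FunctionSchema:
    """Maps each function variable to a category and a direction flag.

    ``direction`` is +1 for functions whose raw increase is desirable and
    -1 for variables that proxy degradation (the dissolved-solid, nutrient
    and chlorophyll loads of the water column), which are negated before
    standardization so that "more" always means "better functioning".
    """

    categories: Mapping[str, FunctionCategory]
    directions: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.categories) != set(self.directions):
            raise ValueError("schema categories and directions list different functions")
        bad = {f: d for f, d in self.directions.items() if d not in (-1, 1)}
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {bad}")

    @property
    def functions(self) -> list[str]:
        return list(self.categories)

    def __contains__(self, function_id: str) -> bool:
        return function_id in self.categories

    def subset(self, functions: list[str]) -> "FunctionSchema":
        missing = [f for f in functions if f not in self.categories]
        if missing:
            raise KeyError(f"functions not in schema: {missing}")
        return FunctionSchema(
            categories={f: self.categories[f] for f in functions},
            directions={f: self.directions[f] for f in functions},
        )


# The 18-variable scheme used throughout: three nitrogen-transformation rates,
# six soil/sediment nutrient pools, plant biomass, and eight water-column
# variables of which all but dissolved oxygen are flipped.
_DEFAULT_FUNCTIONS: list[tuple[str, FunctionCategory, int]] = [
    ("PN", FunctionCategory.NITROGEN_CYCLING, 1),
    ("DN", FunctionCategory.NITROGEN_CYCLING, 1),
    ("AN", FunctionCategory.NITROGEN_CYCLING, 1),
    ("TC", FunctionCategory.NUTRIENT_POOL, 1),
    ("TOC", FunctionCategory.NUTRIENT_POOL, 1),
    ("TN", FunctionCategory.NUTRIENT_POOL, 1),
    ("NO3", FunctionCategory.NUTRIENT_POOL, 1),
    ("NH4", FunctionCategory.NUTRIENT_POOL, 1),
    ("TP", FunctionCategory.NUTRIENT_POOL, 1),
    ("biomass", FunctionCategory.PLANT_PRODUCTIVITY, 1),
    ("W_DO", FunctionCategory.WATER_QUALITY, 1),
    ("W_TDS", FunctionCategory.WATER_QUALITY, -1),
    ("W_TOC", FunctionCategory.WATER_QUALITY, -1),
    ("W_TN", FunctionCategory.WATER_QUALITY, -1),
    ("W_NH4", FunctionCategory.WATER_QUALITY, -1),
    ("W_NO3", FunctionCategory.WATER_QUALITY, -1),
    ("W_TP", FunctionCategory.WATER_QUALITY, -1),
    ("W_Chla", FunctionCategory.WATER_QUALITY, -1),
]


def default_schema() -> FunctionSchema:
    """The default 18-function schema (nitrogen cycling, nutrient pool,
    plant productivity, water quality)."""
    return FunctionSchema(
        categories={f: c for f, c, _ in _DEFAULT_FUNCTIONS},
        directions={f: d for f, _, d in _DEFAULT_FUNCTIONS},
    )


_META_COLUMNS = ("site_id", "habitat", "latitude", "longitude", "elevation", "lat_group")


@dataclass
class FunctionTable:
    """Samples x function-variables table with metadata and schema.

    ``values`` is indexed by the (site_id, habitat) pair; missing measurements
    are NaN and stay NaN — downstream indices average over the observed subset
    and report how many functions entered each score.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    schema: FunctionSchema

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated (site, habitat) rows: {dups}")
        unknown = [c for c in self.values.columns if c not in self.schema]
        if unknown:
            raise KeyError(f"columns missing from schema: {unknown}")
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("values and metadata must share the same sample index")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def functions(self) -> list[str]:
        return list(self.values.columns)

    def latitude(self) -> pd.Series:
        return self.metadata["latitude"].astype(float)

    def lat_groups(self, split_latitude: float = DEFAULT_SPLIT_LATITUDE) -> pd.Series:
        """Per-sample latitude group; explicit labels win over the split."""
        groups = self.metadata.get("lat_group")
        if groups is not None and groups.notna().all():
            return groups.astype(str)
        derived = np.where(self.latitude() < split_latitude, LatGroup.LOW.value, LatGroup.HIGH.value)
        out = pd.Series(derived, index=self.samples, name="lat_group")
        if groups is not None:
            out = groups.astype("string").fillna(pd.Series(derived, index=self.samples)).astype(str)
        return out

    def write(self, path: str | Path, sep: str = "\t") -> None:
        df = pd.concat([self.metadata, self.values], axis=1).reset_index(drop=True)
        df.to_csv(path, sep=sep, index=False, na_rep="NA")


@dataclass
class AbundanceMatrix:
    """Samples x taxa (or KO) abundance table.

    ``data`` holds non-negative counts or, when ``normalized`` is set,
    relative abundances whose rows sum to one.
    """

    data: pd.DataFrame
    level: Level = Level.GENUS
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[r]!r}, taxon {self.data.columns[c]!r}"
            )
        if self.normalized:
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized flag set but row sums differ from 1")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="sample", na_rep="NA")


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_schema(path: str | Path) -> FunctionSchema:
    """Read a YAML schema: ``function_id: {category: ..., direction: ±1}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"schema file {path} is empty or malformed")
    categories: dict[str, FunctionCategory] = {}
    directions: dict[str, int] = {}
    for fid, entry in raw.items():
        try:
            categories[fid] = FunctionCategory(entry["category"])
            directions[fid] = int(entry["direction"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"bad schema entry for {fid!r}: {entry!r}") from exc
    return FunctionSchema(categories=categories, directions=directions)


def write_schema(schema: FunctionSchema, path: str | Path) -> None:
    raw = {
        f: {"category": schema.categories[f].value, "direction": schema.directions[f]}
        for f in schema.functions
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_function_table(
    path: str | Path,
    schema_path: str | Path | None = None,
    schema: FunctionSchema | None = None,
    sep: str | None = None,
) -> FunctionTable:
    """Read a TSV/CSV function table; every non-metadata column must appear
    in the schema, and non-numeric cells raise with their location."""
    if schema is None:
        schema = read_schema(schema_path) if schema_path else default_schema()
    df = pd.read_csv(path, sep=_sep_for(path, sep), na_values=["NA"], keep_default_na=False)
    for col in ("site_id", "habitat", "latitude"):
        if col not in df.columns:
            raise ValueError(f"function table {path} lacks required column {col!r}")
    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    func_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown = [c for c in func_cols if c not in schema]
    if unknown:
        raise KeyError(f"columns missing from schema: {unknown}")
    values = pd.DataFrame(index=df.index)
    for col in func_cols:
        try:
            values[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric value in column {col!r}, row {row}") from exc
    index = pd.MultiIndex.from_arrays(
        [df["site_id"].astype(str), df["habitat"].astype(str)], names=["site_id", "habitat"]
    )
    values.index = index
    metadata = df[meta_cols].set_index(index)
    return FunctionTable(values=values, metadata=metadata, schema=schema.subset(func_cols))


def read_abundance(
    path: str | Path,
    level: Level | str = Level.GENUS,
    taxa_as_rows: bool = False,
    sep: str | None = None,
) -> AbundanceMatrix:
    """Read a samples-by-taxa table (``taxa_as_rows`` transposes on read)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, na_values=["NA"], keep_default_na=False)
    df = df.apply(pd.to_numeric, errors="raise")
    if taxa_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return AbundanceMatrix(data=df.astype(float), level=Level(level))


def to_relative(a: AbundanceMatrix) -> AbundanceMatrix:
    """Convert counts to per-sample relative abundances (rows sum to one)."""
    sums = a.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    rel = a.data.div(sums, axis=0)
    return AbundanceMatrix(data=rel, level=a.level, normalized=True)
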