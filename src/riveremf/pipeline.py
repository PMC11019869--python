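"""One-shot orchestration: simulate -> EMF -> community -> network -> drivers.

A single YAML config drives the whole chain; every stage writes plain TSV
(or JSON) outputs into the run directory and the manifest records the
config, seeds and a SHA-256 of every file, so a rerun with the same config
is byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import conetwork as net
from . import gradient as grad
from .data_model import AbundanceMatrix, FunctionTable, write_schema
from .multifunctionality import DEFAULT_THRESHOLDS, compute_emf
from .simulate import SimulationConfig, sample_metadata, simulate_abundances, simulate_functions

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("calc", "community", "network", "drivers")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    thresholds: tuple[int, int, int] = (5, 95, 1)  # start, stop, step (%)
    robust_max_k: int = 1
    rho_threshold: float = 0.65
    q_threshold: float = 0.01
    min_rel_abund: float = 1e-4
    nmds_restarts: int = 8
    anosim_permutations: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        seed = int(raw.pop("seed", 0))
        if sim is not None:
            sim.setdefault("seed", seed)
            for key in ("lat_range", "habitats", "group_sizes", "log_mean_range"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        stages = {s: True for s in _STAGES}
        stages.update(raw.pop("stages", {}))
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(out_dir=Path(raw.pop("out_dir", "emf_run")), seed=seed, simulate=sim, stages=stages, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            for k in ("lat_range", "habitats", "group_sizes", "log_mean_range"):
                if d["simulate"].get(k) is not None:
                    d["simulate"][k] = list(d["simulate"][k])
        d["thresholds"] = list(self.thresholds)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = "sample") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def _threshold_grid(grid: tuple[int, int, int]) -> np.ndarray:
    start, stop, step = grid
    return np.arange(start, stop + 1, step)


def run_pipeline(
    cfg: RunConfig,
    functions: FunctionTable | None = None,
    abundance: AbundanceMatrix | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Execute all enabled stages in dependency order; returns the manifest.

    Inputs can be passed directly or come from the simulation stage.  On a
    stage failure the partial outputs are kept next to a ``.partial`` marker
    and the error is re-raised with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()
    written: list[Path] = []
    manifest: dict[str, Any] = {"config": cfg.to_dict(), "stages_run": [], "outputs": {}}

    def save(df: pd.DataFrame, name: str, index_label: str | None = "sample") -> None:
        path = out / name
        _write_tsv(df, path, index_label)
        written.append(path)

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            sim = cfg.simulate
            functions, ftruth = simulate_functions(sim)
            abundance, atruth = simulate_abundances(sim)
            metadata = sample_metadata(sim)
            functions.write(out / "functions.tsv")
            written.append(out / "functions.tsv")
            write_schema(functions.schema, out / "schema.yaml")
            written.append(out / "schema.yaml")
            abundance.write(out / "abundance.tsv")
            written.append(out / "abundance.tsv")
            save(metadata, "metadata.tsv")
            truth = {
                "function_slopes": ftruth.function_slopes,
                "emf_raw_slope": ftruth.emf_raw_slope,
                "guilds": atruth.guilds,
                "guild_correlation": atruth.guild_correlation,
                "niche_breadth": atruth.niche_breadth,
                "seed": sim.seed,
            }
            (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
            written.append(out / "ground_truth.json")
            manifest["stages_run"].append("simulate")
        if functions is None and (cfg.stages.get("calc") or cfg.stages.get("drivers")):
            raise ValueError("no function table: provide one or enable simulation")

        emf = None
        if cfg.stages.get("calc"):
            stage = "calc"
            emf = compute_emf(
                functions, _threshold_grid(cfg.thresholds), robust_max_k=cfg.robust_max_k
            )
            frame = emf.to_frame()
            frame.index = [f"{s}:{h}" for s, h in frame.index]
            save(frame, "emf.tsv")
            manifest["stages_run"].append("calc")

        diversity = None
        if cfg.stages.get("community"):
            stage = "community"
            if abundance is None:
                raise ValueError("community stage needs an abundance matrix")
            diversity = comm.alpha_diversity(abundance)
            save(diversity.table, "diversity.tsv")
            dm = comm.bray_curtis(abundance)
            save(
                pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
                "bray_curtis.tsv",
            )
            ord_res = comm.nmds(dm, n_restarts=cfg.nmds_restarts, seed=cfg.seed)
            coords = ord_res.coordinates.copy()
            save(coords, "ordination.tsv")
            anosim_out = {}
            if metadata is not None:
                for col in ("habitat", "lat_group"):
                    if col in metadata.columns and metadata[col].nunique() > 1:
                        res = comm.anosim(
                            dm,
                            metadata[col],
                            n_perm=cfg.anosim_permutations,
                            seed=cfg.seed,
                        )
                        anosim_out[col] = {"R": res.r, "p": res.p_value}
            (out / "anosim.json").write_text(
                json.dumps({"stress": ord_res.stress, "anosim": anosim_out}, indent=1)
            )
            written.append(out / "anosim.json")
            manifest["stages_run"].append("community")

        complexity = None
        if cfg.stages.get("network"):
            stage = "network"
            if abundance is None:
                raise ValueError("network stage needs an abundance matrix")
            groups = (
                metadata["lat_group"].reindex(abundance.data.index)
                if metadata is not None and "lat_group" in metadata
                else pd.Series("all", index=abundance.data.index)
            )
            metric_rows = []
            group_rows = []
            for gname, samples in groups.groupby(groups):
                sub = AbundanceMatrix(
                    abundance.data.loc[samples.index], level=abundance.level
                )
                network = net.build_network(
                    sub,
                    rho_threshold=cfg.rho_threshold,
                    q_threshold=cfg.q_threshold,
                    min_rel_abund=cfg.min_rel_abund,
                )
                edges = network.edges
                edges.to_csv(out / f"edges_{gname}.tsv", sep="\t", index=False)
                written.append(out / f"edges_{gname}.tsv")
                gm = net.topological_metrics(network.graph)
                if network.n_edges:
                    gm["modularity"], _ = net.modularity(network.graph)
                gm["group"] = gname
                group_rows.append(gm)
                tab = net.subnetwork_table(network, sub)
                metric_rows.append(tab)
            group_table = pd.DataFrame(group_rows).set_index("group")
            save(group_table, "group_networks.tsv", index_label="group")
            metrics = pd.concat(metric_rows).sort_index()
            save(metrics, "subnetwork_metrics.tsv")
            ci = net.complexity_index(metrics)
            save(ci.scores.to_frame(), "complexity.tsv")
            save(ci.loadings.to_frame(), "complexity_loadings.tsv", index_label="metric")
            complexity = ci.scores
            manifest["stages_run"].append("network")

        if cfg.stages.get("drivers"):
            stage = "drivers"
            if emf is None:
                raise ValueError("drivers stage needs the calc stage")
            lat = functions.latitude()
            targets = pd.DataFrame(
                {"emf_average": emf.emf_average, "emf_weighted": emf.emf_weighted}
            )
            flat = pd.Index([f"{s}:{h}" for s, h in targets.index], name="sample")
            targets.index = flat
            lat_flat = pd.Series(lat.to_numpy(), index=flat)
            hab_flat = pd.Series([h for _, h in functions.samples], index=flat)

            reg_rows = []
            for name in targets.columns:
                fit = grad.fit_latitude_regression(targets[name], lat_flat)
                reg_rows.append({"response": name, "habitat": "all", **dataclasses.asdict(fit)})
                for hab in sorted(hab_flat.unique()):
                    fit_h = grad.fit_latitude_regression(
                        targets[name], lat_flat, habitat=hab_flat, stratify=hab
                    )
                    reg_rows.append({"response": name, "habitat": hab, **dataclasses.asdict(fit_h)})
            save(pd.DataFrame(reg_rows), "regression.tsv", index_label=None)

            counts = emf.threshold_counts.copy()
            counts.index = flat
            save(grad.threshold_slope_curve(counts, lat_flat), "threshold_slopes.tsv", index_label="threshold")

            group_series = functions.lat_groups()
            group_flat = pd.Series(group_series.to_numpy(), index=flat)
            contrast_targets = targets.copy()
            if diversity is not None:
                contrast_targets = contrast_targets.join(
                    diversity.table.reindex(flat), how="left"
                )
            if complexity is not None:
                contrast_targets = contrast_targets.join(
                    complexity.rename("complexity").reindex(flat), how="left"
                )
            else:
                logger.info("network stage disabled: drivers skip complexity columns")
            save(
                grad.group_contrast_table(contrast_targets, group_flat),
                "contrasts.tsv",
                index_label="variable",
            )
            drivers = pd.DataFrame(
                {
                    "latitude": lat_flat,
                    "longitude": pd.Series(
                        functions.metadata["longitude"].to_numpy(), index=flat
                    ),
                    "elevation": pd.Series(
                        functions.metadata["elevation"].to_numpy(), index=flat
                    ),
                }
            )
            screen = grad.correlation_screen(contrast_targets, drivers)
            save(screen, "correlation_screen.tsv", index_label=None)
            manifest["stages_run"].append("drivers")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(set(written))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    marker.unlink(missing_ok=True)
    return manifest
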