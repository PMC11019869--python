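# riveremf

Ecosystem multifunctionality (EMF) and microbial co-occurrence network
analysis for site surveys along environmental gradients, built around the
study design of riverine surveys: ~30 river sites spanning a wide
latitudinal range, each sampled in three habitats (riparian rhizosphere
soil, riparian bulk soil, channel sediment), with 18 ecosystem-function
variables and metagenome-derived taxon abundance tables per sample.

It is aimed at microbial ecologists who want a tested, scriptable version
of the standard EMF + network-complexity analysis chain, plus a synthetic
survey generator with known ground truth for validating every step.

## What it computes

**EMF indices.** Raw function variables X are first direction-adjusted
(variables whose increase signals degradation — water TDS, TOC, TN, NH₄⁺,
NO₃⁻, TP and chlorophyll-a — are multiplied by −1), then min–max
standardized across samples:

    STD = (X − X_min) / (X_max − X_min)  ∈ [0, 1]

Three summaries per sample: `EMF_average` = mean of all STD values;
`EMF_weighted` = mean of per-category means, each functional category
(nitrogen cycling, nutrient pool, plant productivity, water quality)
weighted equally; and the multiple-threshold profile — for every threshold
t in 5%…95% (1% steps), the number of functions at ≥ t% of that function's
maximum — whose per-threshold OLS slope against latitude gives the
threshold–slope curve.

**Community structure.** Observed richness and Shannon diversity (nats),
Bray–Curtis dissimilarities, non-metric multidimensional scaling (Kruskal
stress-1, restarted), and ANOSIM permutation tests between groups.

**Co-occurrence networks.** Taxa with summed relative abundance < 0.01%
are removed; all remaining pairs are Spearman-correlated; edges require
|ρ| > 0.65 and Benjamini–Hochberg adjusted p < 0.01 (thresholds
configurable). Per-sample complexity comes from the subgraph induced on
the taxa present in that sample: node number, edge number, mean degree,
connectance, average path length, diameter, edge connectivity, degree and
betweenness centralization (Freeman), clustering coefficient, plus
Newman–Girvan modularity of group networks. A composite complexity score
is PCA axis 1 of the z-scored metric table after negating average path
length and diameter (sparsity measures), oriented so more edges = higher
score.

**Gradient statistics.** OLS of any per-sample response on latitude with
t-based 95% CIs, Mann–Whitney U contrasts between low- and high-latitude
groups (split at 33°N by default, the Qinling–Huaihe line), and a
Spearman/FDR correlation screen against candidate drivers.

**Synthetic surveys.** `simulate_functions` plants a linear latitude trend
(default −0.01 per degree on the directional scale, σ = 0.05) in all 18
functions; `simulate_abundances` gives each genus a Gaussian niche along
latitude and plants correlated "guilds" whose latent-factor coupling can
differ between latitude groups (default 0.9 high vs 0.5 low, producing
denser high-latitude networks). Every dataset ships with its
`GroundTruth`.

## Worked example

```python
import pandas as pd
from riveremf import (SimulationConfig, simulate_functions, compute_emf,
                      fit_latitude_regression)

cfg = SimulationConfig(seed=1)          # 30 sites x 3 habitats, 18 functions
table, truth = simulate_functions(cfg)
emf = compute_emf(table)                # direction flip + min-max + indices
lat = pd.Series(table.latitude().to_numpy(), index=emf.emf_average.index)
fit = fit_latitude_regression(emf.emf_average, lat)
print(f"slope={fit.slope:.4f}  R2={fit.r_squared:.3f}  p={fit.p_value:.2e}")
```

prints

```
slope=-0.0274  R2=0.972  p=5.34e-70
```

i.e. the standardized average multifunctionality of the 90 simulated
samples declines by ≈ 0.027 per degree of latitude (the planted −0.01 per
degree on the raw directional scale, amplified by each function's min–max
rescaling), explaining 97% of the variance. The same run's co-occurrence
networks, built separately per latitude group
(`emf run --config ...`, or `run_pipeline`), give 22 edges in the
low-latitude group versus 181 in the high-latitude group with modularity
0.55 vs 0.75 — the planted group contrast in guild coupling recovered as
network density.

The same chain is available from the shell:

```bash
emf simulate --seed 1 --out data/
emf calc --functions data/functions.tsv --schema data/schema.yaml --out data/emf.tsv
emf community --abundance data/abundance.tsv --groups data/metadata.tsv --out comm/
emf network --abundance data/abundance.tsv --meta data/metadata.tsv --out net/
emf drivers --emf data/emf.tsv --meta data/metadata.tsv --out drv/
emf run --config run.yaml     # everything, with a reproducibility manifest
```

## Layout

- `riveremf.data_model` — typed tables, schema, TSV/CSV + YAML I/O
- `riveremf.simulate` — synthetic survey generator with ground truth
- `riveremf.multifunctionality` — direction flip, standardization, indices
- `riveremf.community` — diversity, Bray–Curtis, NMDS, ANOSIM
- `riveremf.conetwork` — network inference, topology metrics, complexity
- `riveremf.gradient` — regressions, contrasts, correlation screens
- `riveremf.pipeline` / `riveremf.cli` — orchestration and the `emf` CLI

See `docs/methods.md` for the modelling choices and their rationale.
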