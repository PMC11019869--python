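# Methods notes

## The EMF engine

Three index families are computed from a samples × functions table after
two preprocessing steps.

*Direction adjustment.* Functions are tagged +1/−1 in the schema; −1
variables (the water-column load variables: TDS, TOC, TN, NH₄⁺, NO₃⁻, TP,
chlorophyll-a) are negated so that "larger = better functioning" holds for
every column. `apply_direction` resets all flags to +1 on its output, so
applying it twice cannot double-flip.

*Min–max standardization.* STD = (X − X_min)/(X_max − X_min), per function,
extrema over non-missing samples. A zero-range (constant) function carries
no ranking information; it is set to 0.5 everywhere with a logged warning
rather than dropped, keeping the index defined and the function count
stable. Missing cells stay missing: all indices average over the observed
subset and report `n_functions_used`, so users can filter on completeness.

Indices: `emf_average` is the plain mean of STD values; `emf_weighted` is
the mean of per-category means (categories with no observed function in a
sample are dropped for that sample); the multiple-threshold profile counts,
per threshold t on the default grid 5…95% (1% steps), functions at ≥ t% of
the per-function maximum. With the default maximum (observed max, k = 1)
this is simply count(STD ≥ t/100); a Byrnes-style robust maximum (mean of
the top-k values) is available via `robust_max_k`. "Exceeds" is read
inclusively (≥); a strict option exists because threshold ties are the only
place the two conventions differ.

## Community structure

Shannon diversity is in nats (the dominant ecology convention; the log
base only rescales). Bray–Curtis uses scipy's implementation inside a
scikit-bio `DistanceMatrix`. NMDS is scikit-learn's nonmetric MDS on the
precomputed dissimilarities with random restarts (default 8) and a fixed
seed; stress is normalized Kruskal stress-1, and the returned
configuration is centered. ANOSIM delegates to scikit-bio (Clarke's R with
divisor n(n−1)/4, permutation p including the observed statistic) with an
explicit seed so permutation p-values are reproducible.

## Co-occurrence networks

Construction follows the common three-stage recipe: (1) drop taxa whose
summed relative abundance over the sample set at hand is below 0.01%
(`min_rel_abund = 1e-4`), evaluated within each network's own sample set
so per-group networks filter on their own samples; (2) Spearman
correlation of all remaining taxon pairs — computed as Pearson correlation
of mid-ranks with two-sided p from the t approximation, so constant
columns yield NaN for their pairs and are excluded instead of poisoning
the matrix; (3) keep edges with |ρ| > 0.65 and Benjamini–Hochberg adjusted
p < 0.01, the FDR family being all pairs tested in that construction.
Retention uses |ρ| (co-presence and exclusion both count as association);
`positive_only` restricts to co-presence. At least 4 samples are required:
below that rank correlations are degenerate.

The ten topology metrics use networkx with explicit conventions: path
metrics (average path length, diameter) are computed on the largest
connected component when disconnected, with the component count reported;
edge connectivity is 0 for disconnected graphs; degree and betweenness
centralization are Freeman-normalized by their star-graph maxima
((n−1)(n−2) and (n−1)²(n−2)/2 respectively, unnormalized betweenness over
unordered pairs with endpoints excluded); the clustering coefficient is
global transitivity. Degenerate graphs (n ≤ 1 or edgeless) return 0 for
path metrics, centralizations, clustering and connectance so per-sample
tables never contain undefined cells. All ten are verified against
brute-force oracles (Floyd–Warshall with path counting, bipartition
min-cut enumeration, direct triplet counting) on random graphs of ≤ 10
nodes.

Modularity uses deterministic greedy (Clauset–Newman–Moore) maximization
of Newman–Girvan Q; exact maximization is NP-hard and Q is used
descriptively (Q > 0.4 read as modular).

The composite complexity score negates average path length and diameter
(they measure sparsity), z-scores each metric (sample sd, ddof = 1), and
takes the first eigenvector of the correlation matrix; the axis is
oriented so the loading on edge number is ≥ 0, making higher scores mean
denser, more clustered networks. Constant metrics are dropped and
recorded; at least two varying metrics are required.

## Gradient statistics

Latitude regressions are OLS with t-based 95% CIs (n − 2 df). The
threshold–slope curve fits one OLS per threshold; a threshold where every
sample has the same count gets slope 0 with a zero-width CI and a
`degenerate` flag rather than an error, since the extreme ends of the grid
are routinely saturated. Mann–Whitney U uses scipy's auto policy: exact
p-values for small tie-free samples, normal approximation with tie
correction otherwise; all tests are two-sided and no significance stars
are emitted. The driver screen is pairwise Spearman with BH-FDR over all
pairs of one invocation; pairs with < 4 complete observations are flagged
rather than tested. The multiple-threshold gradient analysis is
deliberately per-threshold OLS — the quantity the threshold–slope curve
displays — rather than a mixed model with site random intercepts, which
would need design information the tables do not carry; this is stated as a
scope decision, not an approximation claim.

## The synthetic survey generator

The generator emulates a wide-gradient river survey: default 30 sites with
latitude stratified-uniform over 21.76–45.09°N (one draw per equal-width
band, so the gradient is evenly covered), three habitats per site, split
into low/high groups at 33°N. `group_sizes=(11, 19)` reproduces an
unbalanced two-sided design. A balanced stratified default was chosen
because it makes recovery experiments sharper; the unbalanced option
exists for realism.

*Functions.* Each function's directional value is
`1.0 + β·latitude + habitat offset + N(0, σ)` with defaults β = −0.01 per
degree and σ = 0.05, i.e. a ~0.23 decline across the gradient against
noise of sd 0.05 — a strong but not deterministic trend. Raw values are
the directional values times the schema direction, so the EMF direction
flip exactly recovers the planted trend. Habitat offsets default to 0:
habitat differences exist in real surveys but no generative form for them
is assumed; they are a knob.

Note that min–max standardization rescales each function by its realized
range, so the slope of the *standardized* EMF_average is roughly
β/range ≈ −0.027 per degree, not β. Recovery experiments therefore score
CI coverage on the directional (pre-standardization) mean, whose true
slope is exactly β, and score sign recovery on the standardized index —
the sign survives any per-function positive affine rescaling.

*Abundances.* Log expected abundance of taxon j in sample i is
`base_j + u_i + niche_j(L_i) + guild term`: base log-uniform (mean counts
≈ 20–200), site factor u ~ N(0, 0.2) (a mild sequencing-depth/site
effect), Gaussian niche −(L − μ_j)²/(2·turnover²) with random optima and
default breadth 8° (moderate turnover: compositional change along the
gradient without complete species replacement), and a log-normal term of
scale 1.5 that is idiosyncratic for free-living taxa but shared within
guilds: members of guild g in sample i get
`1.5·(√r·z_ig + √(1−r)·ε_ij)` where r is the guild coupling for the
sample's latitude group. Guild members also share their guild's niche
optimum (a guild is an ecological cohort). Counts are Poisson around the
expectation, with an optional gamma-mixture (negative-binomial)
overdispersion knob; Poisson is the simplest model that exercises the
pipeline and overdispersion is a knob, not a claim about real libraries.
Default coupling is 0.9 in the high-latitude group vs 0.5 in the low —
with the |ρ| > 0.65 edge threshold this puts within-guild correlations
above the cut in the high group and below it in the low group, planting a
recoverable density contrast whose direction matches field reports of
denser high-latitude networks.

What the generator does **not** emulate: compositionality (counts are
independent Poisson given the latent field, not a fixed-depth
multinomial), taxon–taxon interactions beyond block correlation,
habitat-specific communities, zero-inflation, and any mechanistic link
between the abundance and function tables. Passing recovery tests
therefore demonstrate that the pipeline correctly extracts planted linear
and block-correlation structure at realistic noise levels — not that real
rivers behave this way.

## Numerical and testing choices

Simulation sizes in tests and the acceptance script (e.g. 60 sites × 1
habitat for slope recovery, 40 sites for network contrasts, 500 replicates
for type-I calibration, 200 random graphs for oracle equivalence) were
chosen to make Monte-Carlo standard errors small relative to the margins
being checked while keeping each experiment in seconds. All RNG flows
through `numpy.random.default_rng` seeded from explicit seeds; the
pipeline manifest records the config and SHA-256 of every output, and
rerunning a config is byte-identical.

Known limitations: NMDS stress depends on restart count for difficult
configurations (raise `n_restarts`); greedy modularity is a lower bound on
the optimal Q; the complexity axis is only identified up to the stated
orientation rule; and the Spearman p-values use the t approximation, which
is what the FDR filter consumes — exact permutation p-values for small n
are out of scope.
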