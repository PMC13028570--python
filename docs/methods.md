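# Methods

This note records the models, defaults, and numerical choices behind
`fungalnet`, and what the synthetic benchmarks do and do not demonstrate.

## Data model

The primary object is an integer plot-by-OTU count matrix with aligned
per-plot metadata (altitude in metres; zone label LA/MA/HA; optionally an
altitudinal belt label). Counts are kept as integers because the
fixed-margin permutation null is defined on integer contingency tables;
relative abundances are derived views. TSV orientation (OTUs-as-rows by
default) is an explicit flag and never auto-detected — silent transposition
is the classic OTU-table failure mode. A minimal BIOM v1 (JSON) reader
covers the sparse and dense variants.

## Commonness classification

Features per OTU: occupancy fraction across plots, and
log10(1 + mean count over the plots where present). Both are z-scored, then
partitioned by fuzzy c-means with c = 2, fuzzifier m = 2.0, tolerance 1e−6
on the centroid shift, at most 500 iterations, and a seeded k-means++-style
initialisation. Memberships follow u_ik ∝ (1/d_ik²)^{1/(m−1)}. The cluster
with the larger centroid occupancy is called common (frequency is the more
robust axis; occupancy and abundance are strongly coupled in practice). A
membership of exactly 0.5 is labelled rare — the conservative tie rule that
keeps the common set minimal. All-zero OTUs are excluded with a warning; a
feature cloud with fewer than two distinct points has no defined partition
and is refused. A silhouette-like separation score of the hard split is
reported as a diagnostic.

## Co-occupation stage

Togetherness of a pair over n plots is T = S·A (S co-presences, A
co-absences); T is 0 for a perfect checkerboard and ⌊n/2⌋² for identical
half-full columns. The null ensemble redistributes the integer count table
under fixed row (plot total) and column (OTU total) sums via Patefield's
algorithm (scipy's exact sampler), binarising each draw; margin preservation
is asserted on every draw. This is the conditional distribution of an
independence model with Poisson-level cell variance given the margins.
A binary-margin alternative (curveball trades on the presence matrix) is
available behind `null_model="curveball"`.

Empirical inference: p = 2·min(P(T_null ≥ T_obs), P(T_null ≤ T_obs)) with
the add-one rule (1 + #extreme)/(n_null + 1), capped at 1; default
n_null = 999 and α = 0.05, unadjusted (a BH switch exists). Sign is +
when more null draws fall below the observed T than above it (the pair
co-occupies more than expected) — operationally the median rule; at an
exact tie p = 1 and no edge is emitted.

Two properties of this test worth knowing:

- **Calibration holds under Poisson-level noise.** Simulating independent
  taxa from a plot-effect × species-effect Poisson model at ~50 % mean
  occupancy, the measured edge rate at α = 0.05 is ≈ 0.048 (2016 pairs,
  999 draws). Occupancy near 0.5 is the informative operating point for a
  presence–absence statistic; at very high occupancy the discrete doubled
  p-value becomes conservative.
- **Overdispersion breaks it.** If counts are strongly overdispersed
  (negative binomial with small size parameter), the fixed-margin null
  redistributes counts far more evenly than the data generator does,
  destroying zero inflation: essentially every pair then deviates from the
  null. On real amplicon data the co-occupation stage should therefore be
  read as detecting departure from margin-conditional independence at
  Poisson noise levels, not from arbitrary independent overdispersed
  sampling. This is a property of the r2dtable null family itself.

## Co-occurrence stage

Per zone, OTUs present in ≥ ceil(0.5 × n_plots) plots are retained (the
filter is applied per zone; the threshold is configurable), counts are
converted to relative abundance by total-sum scaling, and all pairs are
Spearman-correlated (average ranks, two-sided t approximation). P-values
are BH-adjusted across all tested pairs in the zone (holm/bonferroni/none
available); an edge needs |ρ| ≥ 0.65 and adjusted p ≤ 0.01. Constant
vectors have no rank correlation; such pairs are skipped and logged. The
rank-correlation core is exactly invariant to strictly monotone transforms
of the abundance columns it receives; note, however, that the closure step
is compositional — transforming one OTU's raw counts perturbs every plot
total and hence, slightly, every other OTU's relative abundance. The core
is therefore exposed separately (`edges_from_abundance`) from the
closure-plus-core convenience (`spearman_edges`).

## Topology

Modularity is evaluated by the standard Newman form over ordered node pairs
on the unsigned union of positive and negative edges (a signed variant is a
possible extension, deliberately not the default). Community detection
maximises this quantity: graphs whose non-isolated node set has ≤ 10 nodes
are solved exactly by enumerating all set partitions (Bell(10) ≈ 1.2 × 10⁵,
negligible); larger graphs use seeded greedy Louvain, with a fallback to
the single-module partition if a degenerate run would dip below M = 0.
Isolated nodes form singleton modules; they cannot change M.

Connectance is edges over n(n−1)/2; the negative:positive ratio is
100 × neg/pos and is reported as NA when there are no positive edges; the
clustering coefficient is the mean local clustering with degree-<2 nodes
contributing 0. Levins niche width NW = 1/Σ p_ij² is computed over
altitudinal belts by default (10 equal-width belts; ~10 resource bins keep
NW on an interpretable 1–10 scale, unlike plot-level binning), with zone-
and plot-level binning available. NW is invariant to rescaling a species'
counts and is NA for a zero-total species.

Summaries mirror the conventional reporting shape: one row per
zone × {both, common, rare}, with subgroup metrics computed on induced
subgraphs, means (degree, togetherness, niche width) averaged over the
subgroup's nodes or pairs, and NA rows for absent subgroups.

## Synthetic gradient generator

The default scene emulates a temperate mountain-forest sampling frame:
119 plots evenly spaced over 1020–1770 m, zones as equal-altitude terciles,
10 equal-width belts, soil temperature following the −0.6 °C/100 m lapse
line, and optional monotone/hump-backed covariates with Gaussian noise.
Species respond to altitude through Gaussian niches: expected count of
species s at plot p is scale_s · exp(−(alt_p − opt_s)²/(2 width_s²));
counts are negative binomial (size 2.0 by default — amplicon counts are
overdispersed) via a quantile transform of standard-normal latents, so that
planted pairwise associations can be induced by correlating the latents of
a pair (Gaussian copula, sign and strength controlled, marginals
preserved). Defaults: 50 common species (scale ~ lognormal(ln 80, 0.4),
widths 300–700 m) against 450 rare ones (scale ~ lognormal(ln 4, 0.6),
widths 80–200 m), a shape chosen so the two groups separate in the
abundance–occupancy plane the way field surveys report them (a minority of
abundant generalists, a majority of sparse specialists).

Planted associations are assigned to wide-niche partners at ~50 %
occupancy: an association is only observable where both partners can
occur, and mid occupancy is where presence–absence statistics carry
information — planting associations between narrow-niche specialists with
disjoint ranges would be undetectable by any method. Each OTU joins at most
one planted pair. A separate independence scene (plot-effect ×
species-effect Poisson, ~50 % occupancy) provides the null model for
type-I-error studies, matching the sampling model whose margin-conditional
distribution the r2dtable null reproduces.

What the generator does **not** emulate: spatial autocorrelation between
plots, taxonomic or guild structure, compositional sequencing depth
artefacts, and community-wide covariance beyond the planted pairs and the
shared environmental response. Passing recovery benchmarks on these scenes
therefore demonstrates correctness of the machinery under the stated
models, not performance guarantees on real amplicon surveys.

## Determinism and degenerate inputs

Every stochastic stage takes one integer seed; the pipeline derives
per-stage sub-seeds deterministically (a small string hash of stage and
zone, kept below 2³¹), logs them, and snapshots the resolved configuration
so a run can be replayed bit-identically. Degenerate inputs fail loudly and
early: negative or non-numeric counts name the offending cell; plot-id
mismatches list the orphans; missing zone labels name the plots; an empty
edge set refuses modularity (m = 0); a prevalence filter leaving < 3 OTUs
refuses the correlation network rather than emitting an empty one.

## Problem sizes used by the test and acceptance benchmarks

The shipped benchmarks run the full 119-plot, 3-zone scene with 500 OTUs
and 999-draw null ensembles (the demo, ~1 min on one CPU); calibration uses
2016 pairs at 999 draws; classifier recovery uses 20 independent scenes;
exhaustive modularity checks cover 30 random graphs with up to 8 nodes.
These sizes were chosen so the whole suite runs comfortably on a laptop
while keeping every statistical check at the study-frame scale (119 plots)
where it is meaningful.

## Known limitations

- The co-occupation p-values are unadjusted by default (the correlation
  stage is BH-adjusted); with ~10⁵ pairs an α = 0.05 network is an
  exploratory object, not a set of confirmed interactions.
- The Spearman stage ignores compositionality beyond total-sum scaling; no
  CLR or SparCC-style estimator is provided.
- Signed modularity is not implemented; modularity treats + and − edges
  alike.
- Zone labels are inputs; the package does not infer zonation from the
  community data.
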