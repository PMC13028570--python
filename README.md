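# fungalnet

Common/rare classification and network-stability analysis for soil fungal
communities sampled along altitudinal gradients.

Soil fungal communities typically contain a few **common** taxa — abundant,
high-occupancy species that carry most interspecific interactions — and many
**rare** taxa that carry most of the diversity. How the two groups organise
their spatial associations along an environmental gradient (e.g., a mountain
slope with a −0.6 °C/100 m lapse rate) bears directly on community stability:
high modularity localises disturbances inside interaction modules, and a
higher negative-to-positive association ratio damps synchronised population
fluctuations.

`fungalnet` implements that analysis for plot-by-OTU count tables:

1. **Commonness classification.** Each OTU is placed in the
   (occupancy, log abundance) plane — occupancy fraction and
   log10(1 + mean non-zero count) — and a fuzzy *c*-means partition with
   *c* = 2 splits the pool. The cluster with the larger centroid occupancy is
   "common"; an OTU is common iff its fuzzy membership exceeds 0.5.
2. **Co-occupation networks.** For every OTU pair, togetherness
   *T* = *S* × *A*, where *S* counts plots where both are present and *A*
   plots where both are absent. Observed *T* is compared with 999
   fixed-margin randomisations of the integer count table (the
   r2dtable/Patefield null, preserving every plot total and OTU total
   exactly). The two-sided empirical p-value uses the add-one rule
   *p* = (1 + #extreme)/(999 + 1); pairs with *p* ≤ α become signed edges
   (+ above the null centre, − below).
3. **Co-occurrence networks.** OTUs present in ≥ 50 % of a zone's plots are
   correlated pairwise (Spearman, on per-plot relative abundance); edges
   require |ρ| ≥ 0.65 and Benjamini–Hochberg adjusted *p* ≤ 0.01.
4. **Topology.** Newman modularity
   *M* = (1/2m) Σ<sub>ij</sub> (A<sub>ij</sub> − k<sub>i</sub>k<sub>j</sub>/2m) δ(c<sub>i</sub>, c<sub>j</sub>)
   with seeded community detection (exhaustive for tiny graphs, Louvain
   otherwise); connectance = edges / (n(n−1)/2); negative:positive ratio
   = 100 × neg/pos; Levins niche width NW = 1/Σ<sub>j</sub> p<sub>ij</sub>²
   over altitudinal belts; clustering coefficient and mean degree. All
   metrics are reported per zone for the whole network ("Both") and for the
   common and rare subgroups separately.

Because suitable public datasets rarely ship with ground truth, the package
includes a first-class synthetic generator: 119 plots along 1020–1770 m,
Gaussian niche responses, negative-binomial counts, planted common/rare
labels and planted positive/negative pairwise associations induced through a
Gaussian copula on the abundance latents.

## Worked example

```bash
fungalnet demo --seed 1 --out runs/demo
```

generates the default synthetic scene (119 plots, 3 altitudinal zones,
50 common + 450 rare OTUs, 20 planted associations at copula strength 0.9),
runs every stage, and prints the ground-truth recovery report:

```json
{
 "label_accuracy": 0.994,
 "n_otus": 500,
 "n_planted_associations": 20,
 "planted_edge_recall": 1.0,
 "planted_sign_accuracy": 1.0
}
```

99.4 % of the planted common/rare labels are recovered by the fuzzy
classifier, and all 20 planted associations are detected with the correct
sign by the co-occupation test. The run directory contains the classified
labels (`commonness.tsv`), per-zone edge lists (TSV + GraphML), the run log,
and two topology tables. `topology_cooccupation.tsv` starts:

```
zone  subgroup  n_nodes  n_edges_pos  n_edges_neg  connectance  neg_pos_pct  modularity ...
LA    both      500      24008        338          0.195        1.408        0.064
LA    common    53       0            0            0.000        0.000
LA    rare      447      23080        338          0.235        1.464        0.077
```

i.e., in the low-altitude zone the full network keeps 500 nodes with 24,008
positive and 338 negative co-occupation edges (connectance 0.195,
negative:positive 1.4 %). Python API equivalent:

```python
from fungalnet import default_scene, classify_common_rare, cooccupation_network

table, truth = default_scene(seed=1)
labels = classify_common_rare(table, seed=0)
net = cooccupation_network(table.zone_table("LA"), n_null=999, seed=1)
```

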