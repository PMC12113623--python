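# myconet

Co-occurrence network analysis for soil fungal communities characterized by
amplicon sequencing. `myconet` takes an ASV table (samples × amplicon
sequence variants, read counts), sample metadata (habitat, coordinates,
climate and soil variables), and an optional taxonomy/guild map, and runs a
regional-scale biogeography workflow of the kind used for multi-habitat soil
surveys (alpine meadows, desert steppes, alpine shrublands):

1. **Edge inference** — dual-criterion co-occurrence edges: Spearman's
   |ρ| ≥ 0.6 between taxon abundance profiles *and* symmetrized
   Kullback–Leibler divergence below a divergence threshold, with
   significance from 1000 profile-permutation resamples and
   Benjamini–Hochberg correction (retain q < 0.05). Low-abundance ASVs
   (≤ 0.01 % of all reads) are removed first.
2. **Topology** — modularity-maximizing module detection, node/edge counts,
   mean degree 2E/N, connected-pairs average path length, transitivity, and
   one induced subnetwork per sample (taxa present in that sample).
3. **Keystone roles** — within-module degree z-score Zi and participation
   coefficient Pi = 1 − Σₛ(k_is/k_i)², classifying nodes as network hubs
   (Zi > 2.5, Pi > 0.62), module hubs (Zi > 2.5), connectors (Pi > 0.62),
   or peripherals.
4. **Cohesion stability** — per-taxon connectedness c⁺/c⁻ (mean positive /
   negative edge weights), sample cohesion C⁺ⱼ = Σᵢ aᵢⱼ c⁺ᵢ (and C⁻ⱼ),
   and network stability as either |C⁻|/C⁺ or |C⁻ − C⁺|, regressed on ASV
   richness.
5. **Spatial statistics** — Bray–Curtis dissimilarity, haversine distances,
   distance–decay regression of similarity on (log₁₀) distance, Mantel and
   partial Mantel permutation tests against geographic/climate/soil distance
   matrices, and a z-scored first classical-MDS axis of the coordinate
   distance matrix as a spatial factor.

A synthetic-data generator with *planted* ground truth (signed modular
correlation structure via a Gaussian copula, habitat-dependent richness,
and a transect-scale similarity gradient) backs every stage with testable
truth: edge precision/recall, sign accuracy, and module recovery are
first-class outputs.

## Worked example

The bundled toy configuration simulates ~31 samples × 80 ASVs (4 planted
modules of 10 taxa, Spearman 0.8, 20 % negative edges) and runs every stage:

```bash
myconet all -c examples/toy_config.yaml -o results_toy
```

Selected outputs from this run:

`global_metrics.tsv` — the inferred network has 59 nodes and 202 edges
(mean degree 6.85, average path length 1.53, transitivity 0.90) organized
in modules with modularity Q = 0.798:

```
node_count  edge_count  average_degree  average_path_length  global_clustering  modularity
59          202         6.847           1.531                0.900              0.798
```

`truth_recovery.tsv` — compared with the planted edge set, inference
reaches recall 0.94 and precision 0.84 at this small sample size, with
every recovered edge's sign correct (at the acceptance scale of 200
samples, precision is 1.0 and recall ≥ 0.9):

```
precision  recall  sign_accuracy  n_true  n_inferred  n_true_positive
0.837      0.939   1.0            180     202         169
```

`guild_fractions.tsv` — the simulated community is saprotroph-dominated
(71 % of network nodes), mirroring the guild composition the generator
emulates.

`distance_decay.tsv` / `mantel_results.tsv` — at toy scale the spatial
gradient is too weak to detect (slope ≈ 0.006, p = 0.66); at the full
default scale (92 samples × 500 ASVs) the same pipeline recovers a clear
distance–decay (slope −0.046 per log₁₀ km, p ≪ 0.001; Mantel r = 0.37,
p = 0.005).

Each stage is also available as its own subcommand (`simulate`, `filter`,
`network`, `topology`, `keystone`, `stability`, `spatial`) over the same
file formats, so real ASV tables can enter at any point:

```bash
myconet network -t filtered.tsv --rho-threshold 0.6 --alpha 0.05 \
    --resamples 1000 --seed 1 -o net_out
```

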