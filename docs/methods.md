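# Methods

This note documents the models and procedures `myconet` implements, the
design decisions taken where the methodology is genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Edge inference

Given a samples × ASVs count table, the network stage:

1. **Abundance filter.** An ASV is kept iff its share of the table's grand
   read total is *strictly* greater than the threshold (default 10⁻⁴, i.e.
   0.01 % of all fungal sequences). The denominator is the whole table, not
   the per-sample total; both relative-abundance modes are exposed on
   `AsvTable` and every consumer names which it uses.
2. **Spearman matrix.** Pairwise Spearman ρ between taxon profiles across
   samples, on per-sample relative abundances by default (raw counts
   switchable). Ties get average ranks. Taxa constant across all samples
   have no defined rank correlation; they are flagged NaN and excluded from
   edge candidacy rather than given ρ = NaN edges.
3. **Symmetrized KLD.** Each taxon's profile is shifted by a pseudocount
   (default 10⁻⁶, required > 0) and normalized to a probability vector;
   kld(i,j) = ½[KL(pᵢ‖pⱼ) + KL(pⱼ‖pᵢ)] in nats. The default divergence
   threshold is the *maximum* of the KLD matrix, which by construction
   excludes nothing; this literal convention is retained as the default and
   logged loudly, with `quantile:x` available when the clause should bite.
4. **Permutation p-values.** The null permutes each taxon's profile across
   samples independently per resample (dependence destroyed, marginals
   preserved — chosen over a sample bootstrap because it leaves each
   taxon's rank distribution exactly intact). With B resamples (default
   1000, minimum 100), p = (1 + #{|ρ*| ≥ |ρ|})/(1 + B), so p is never 0.
   Implementation note: ranks are centered/scaled once, so each resample is
   a column permutation plus one matrix product.
5. **BH correction** over the C(n,2) unordered-pair upper triangle only
   (no diagonal, no double counting), via the standard step-up procedure.
6. **Retention.** Edge (i,j) iff |ρ| ≥ ρ_threshold (default 0.6; applied to
   the magnitude so negative associations are retained) AND kld ≤ threshold
   AND q < α (strict; default 0.05). Nodes are taxa with ≥ 1 retained edge;
   the edge weight is the signed ρ. Every build re-checks all three clauses
   post hoc.

No compositional-bias correction (SparCC/SPIEC-EASI style) is applied; the
procedure is deliberately the plain rank-correlation + KLD recipe. Its
compositional behaviour is characterized below.

## Topology and keystone roles

Community detection runs on the unweighted, unsigned graph (signed
modularity is out of scope) with Clauset–Newman–Moore greedy modularity
maximization; nodes and edges are inserted in sorted order so results are
reproducible, and Louvain is available behind a flag (seeded). Module ids
are ordered by each module's smallest node id. Quality is Newman–Girvan
modularity Q.

Average path length is the mean shortest-path length over *connected* pairs
within components — chosen over infinite/harmonic conventions because the
per-sample induced subgraphs are frequently disconnected. Clustering is
transitivity (3 × triangles / connected triples). Metrics of an empty
subnetwork are NaN (undefined), never zero-filled.

Per-sample subnetworks are the induced subgraphs on the taxa with count > 0
in that sample; node/edge counts are monotone in the presence set by
construction (tested).

Zi is the within-module degree z-score: (kᵢ,within − mean)/sd over the
module's nodes, population sd; a module whose within-degrees are constant
assigns Zi = 0 by convention. Pi = 1 − Σₛ(kᵢₛ/kᵢ)²; isolated nodes get
Pi = 0 with a warning. Degrees are unweighted, the standard convention for
this framework. Role thresholds are Zi = 2.5 and Pi = 0.62 with *strict*
inequalities for the special classes, so boundary equality falls to
peripheral. (The peripheral region is Zi ≤ 2.5 and Pi ≤ 0.62; a literal
"Pi < 0" peripheral bound is impossible since Pi ≥ 0.)

## Cohesion-based stability

Connectedness of taxon i is the mean of its positive (c⁺ᵢ ≥ 0) and negative
(c⁻ᵢ ≤ 0) retained-edge weights, 0 where it has none. Sample cohesion
weights connectedness by per-sample relative abundance: C⁺ⱼ = Σᵢ aᵢⱼ c⁺ᵢ and
C⁻ⱼ = Σᵢ aᵢⱼ c⁻ᵢ, making cohesion invariant to rescaling a sample's raw
counts. Two stability variants are emitted side by side because both appear
in the cohesion literature this pipeline follows and they are not
interchangeable: the ratio |C⁻|/C⁺ (NaN-flagged when C⁺ = 0) and the
absolute difference |C⁻ − C⁺|. The pipeline default is the absolute
difference; the CLI switches by flag. Connectedness uses significant
network edges by default (a full-correlation-matrix mode exists); the
Herren–McMahon-style null-model correction of connectedness is *not*
implemented — a documented limitation: cohesion here summarizes the
retained network, not a null-adjusted association strength.

Stability is related to α-diversity by OLS of per-sample stability on ASV
richness (count of taxa with reads > 0), reporting slope, R², and the
slope's two-sided t-test p-value.

## Spatial statistics

* **Bray–Curtis**: BC(j,k) = Σᵢ|xᵢⱼ−xᵢₖ|/Σᵢ(xᵢⱼ+xᵢₖ) on the values handed
  to it — raw counts by default (the convention of community-ecology
  distance functions), per-sample relative abundances in the pipeline.
* **Geographic distance**: haversine, Earth radius 6371.0088 km.
* **Distance–decay**: OLS of similarity (1 − BC) on log₁₀ distance
  (default; identity-km available — which transform produced a given
  literature slope is rarely stated, so both are runnable and the choice is
  recorded in the output) over all unordered pairs; zero-distance pairs are
  dropped under the log transform. Sample pairs share samples and are not
  independent, so the t-test p-value is descriptive; the calibration tests
  therefore use independently constructed pairs.
* **Mantel / partial Mantel**: correlation (Spearman default, matching the
  pipeline's rank-based spirit) of upper triangles; one-sided permutation
  p-value with joint row/column permutation of the second matrix,
  p = (1 + #{r* ≥ r})/(1 + n_perm). The partial statistic is the
  first-order partial correlation of the three matrix correlations,
  recomputed under permutations of the second matrix.
* **MDS spatial axis**: classical (Torgerson) MDS of the Euclidean distance
  matrix of raw (latitude, longitude) pairs — deliberately Euclidean on raw
  coordinates, the convention for deriving a spatial factor from site
  coordinates, not haversine. First-axis scores are z-scored; the variance
  fraction is λ₁/Σλ over positive eigenvalues; the axis sign is fixed to
  correlate non-negatively with latitude (eigenvectors are sign-ambiguous).

## Synthetic data

The generator emulates a three-habitat survey: 33/42/17 sites per habitat
(scalable), a ~1700 km transect with habitats occupying contiguous
segments, log-normal sequencing depth (mean 20 000 reads, CV 0.3),
saprotroph-dominated guilds (70.91/19.33/9.80 %), and Ascomycota-dominated
phyla.

**Planted structure.** A per-module factor model gives every within-module
latent pair correlation exactly r_w; sign-flipping a fraction f of module
taxa (2f(1−f) = target negative-edge fraction, default 0.2) plants negative
edges. Because the pipeline's statistic is rank-based, the user-facing
within/between correlations are *Spearman* targets converted to latent
Pearson via r = 2·sin(πρ/6); log-normal marginals then preserve the planted
rank correlations exactly at the latent level.

**Compositional closure.** Sequencing observes proportions, not
abundances. When planted-module taxa dominate the community, the sample
total co-varies with the module factors and closure visibly distorts the
planted structure — negative pairs planted at ρ = −0.8 are observed near
−0.47 in an all-module community. The generator therefore embeds planted
modules (default 4 × 25 taxa) in a larger background community whose sum
concentrates, keeping closure distortion negligible. This is also the
realistic regime: co-occurring guilds are embedded among thousands of other
taxa.

**Spatial gradient and richness.** Background taxa carry an exponential
spatial kernel around a preferred transect position (default e-folding
1/0.002 km ≈ 500 km, a free parameter chosen to give a clear but not
dominant gradient at the study extent) and a per-habitat occupancy mask
(base 0.9 × habitat multipliers 1.0/0.95/0.75, reproducing the
meadow ≈ steppe > shrubland richness ordering). Module taxa are exempt from
both: a shared spatial factor or habitat masking would attenuate or distort
the planted rank correlations that define the truth set, so planted
interaction modules are treated as cosmopolitan. Consequently the
generator does *not* emulate habitat differences in per-sample subnetwork
size, and truth-recovery / null-calibration experiments switch the spatial
kernel and occupancy masking off entirely (`spatial_decay_rate=0`,
`base_occupancy=1`) — with them on, spatially co-located background taxa
form genuine high-|ρ| pairs that are not planted edges, and "false
positive" stops being well-defined. MAT and NDVI are constructed with known
linear dependence on the habitat richness multipliers, so climate–richness
associations exist by design; the remaining soil variables are habitat-
independent noise with plausible magnitudes.

**What passing tests show.** Recovery and calibration results demonstrate
the inference chain is correct and well-calibrated *under the copula's
assumptions* (monotone marginals, background-dominated composition,
independent samples). They do not certify performance on real sequencing
data, which adds overdispersion, spatial autocorrelation of community
structure (deliberately generated here, and shown to contaminate edge
precision), and taxon-specific amplification biases the generator omits.
The generator starts at the ASV-table level: no reads, chimeras, or
denoising error profiles.

## Problem sizes and determinism

Validation experiments run at desk scale, chosen so each completes in
seconds to a couple of minutes: null calibration at 100 samples × 200 taxa
× 1000 resamples over 20 seeds; recovery at 200 samples × 420 taxa; Mantel
calibration over 500 null replicates of 15 × 15 matrices with 99
permutations; distance–decay coverage over 50 replicates of 210 pairs.

Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by hashing the stage name, so stages
can be rerun in isolation. Artifacts are written with fixed float
formatting and sorted node/edge/key order, and the run manifest contains no
timestamps, so a config + seed reproduces byte-identical outputs.

## Known limitations

* The KLD clause is vacuous under its default (maximum-of-matrix)
  threshold; it exists for fidelity to the stated recipe and only the
  quantile mode makes it informative.
* Cohesion lacks the null-model correction of the original cohesion
  estimator (see above).
* The distance–decay p-value ignores pair dependence.
* Exact modularity values are algorithm-dependent; only the small-graph
  oracles (e.g. two triangles → Q = 0.5) are exact, and greedy vs Louvain
  partitions may differ on large graphs.
* Richness effects act through habitat-level occupancy of background taxa;
  within-habitat richness variation is mostly sampling noise.
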