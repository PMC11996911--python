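# Methods

`ecoassembly` infers which ecological processes structure microbial
communities from three inputs: an OTU count table (samples × taxa), a
rooted phylogeny over the taxa, and sample metadata. Its core is the
null-model chain that partitions community turnover into five assembly
processes; around it sit the standard diversity, ordination,
multivariate-statistics, network, and taxonomy steps of a microbiome
survey, and a synthetic-data generator that produces communities whose
true assembly process is known.

## The assembly-process model

For a pair of communities A and B, the abundance-weighted **beta mean
nearest taxon distance** is

    βMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} δ(i,j)
                   + Σ_{j∈B} f_jB · min_{i∈A} δ(i,j) ],

where δ is the cophenetic (patristic) distance and f the within-sample
relative abundance; a taxon present in both communities contributes 0
(its nearest taxon in the partner is itself). The **beta nearest taxon
index** is the z-score of the observed βMNTD against a null built by
shuffling tip labels across the *entire supplied tree* (999 replicates
by default; every replicate rescores all pairs at once):

    βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null.

Shuffling over all tree tips — not only the taxa observed in the table
— is deliberate: it is what gives the test power against communities
confined to one clade of a larger regional phylogeny, which is the
signature of consistent environmental filtering. When the table's taxa
*are* the whole tree the two choices coincide. Taxon order is
canonicalised (sorted tip labels) before drawing permutations, so
results do not depend on column order.

**RC-Bray** compares the observed Bray-Curtis dissimilarity of a pair
against nulls that reassemble each sample preserving its observed
richness, drawing species with probability proportional to occurrence
frequency across the whole table and filling abundance proportionally
to regional relative abundance (each drawn species is guaranteed one
individual first). With `less`/`equal` the counts of null values below
/ tied with the observed dissimilarity,

    RC = 2 × ( (less + 0.5·equal) / reps − 0.5 )  ∈ [−1, 1].

Ties use exact float equality on identically computed Bray-Curtis
values; they are real events when null draws coincide.

**Classification.** Selection is assigned whenever |βNTI| ≥ 2 (closed
bound), with the sign separating heterogeneous (+) from homogeneous (−)
selection; RC is then ignored. Otherwise RC > 0.95 ⇒ dispersal
limitation, RC < −0.95 ⇒ homogenizing dispersal (both strict), and the
remainder is ecological drift. A NaN βNTI (possible only for a
degenerate phylogeny with zero null spread, e.g. a star tree, or a pair
with identical membership) yields "undetermined" and is excluded from
partitions with a logged count.

**Grouping.** Both null models always treat the full table as the
regional metacommunity — occurrence frequencies, regional abundances
and the taxon pool come from all samples — while classification and the
process partition are restricted to within-group pairs (e.g. within
compartment, or compartment × region). Cross-group pairs are never
pooled. Running the nulls per-group instead would make homogenizing
dispersal undetectable by construction, because a group's own pool
cannot be more homogeneous than itself.

**Seeding.** One master seed drives a single stream of whole-tree
shuffles; each replicate scores every pair simultaneously, so results
are deterministic and independent of pair iteration order.

## Surrounding statistics

* **Alpha diversity**: observed richness (Sobs) and Shannon H′ (natural
  log by default, base 2 by flag).
* **PCoA**: Gower double-centring with eigendecomposition; negative
  eigenvalues are reported as-is by default (proportions over the
  positive part), with Lingoes and Cailliez corrections available.
* **PERMDISP**: distances to group centroids in the full PCoA space
  with the imaginary-axis correction (squared distances on
  negative-eigenvalue axes are subtracted), one-way F, label-permutation
  p. Centroids, not spatial medians.
* **PERMANOVA**: McArdle–Anderson direct decomposition tr(H G) on the
  Gower-centred matrix; one- and two-factor crossed designs with
  interaction, sequential (Type I) sums of squares, raw-label
  permutation. Verified against vegan's `adonis2` during development;
  the label-permutation scheme is a documented limitation for strongly
  unbalanced designs. Note that with perfectly separated groups the
  attainable p-value floor is set by the number of label permutations
  that reproduce the same partition, not 1/(permutations+1).
* **ANOSIM, Mantel**: delegated to scikit-bio (rank-based R; matrix
  correlation with joint row/column permutation).
* **Procrustes/PROTEST**: both configurations centred and scaled to
  unit trace; optimal rotation+scaling via SVD; M² = 1 − (Σ singular
  values)²; p from permuting one configuration's rows. Matches vegan's
  `procrustes(symmetric=TRUE)`.
* **Variance partitioning**: distance-based RDA per block union
  (R² = tr(HG)/tr(G), H from the z-scored predictors), Ezekiel-adjusted
  by predictor rank, decomposed by inclusion–exclusion into unique and
  shared fractions. Small negative fractions are an expected
  adjusted-R² artifact and are reported as-is. Matches vegan's
  `varpart`.
* **Ordination regression**: OLS of one PCoA axis on each environmental
  variable, ranked by R².
* **Rank tests**: Wilcoxon rank-sum (exact distribution for ≤ 10 per
  group, tie-corrected normal approximation otherwise) and
  Kruskal–Wallis with tie correction; Benjamini–Hochberg correction
  optional (off by default).
* **Co-occurrence networks**: pairwise Spearman correlations among OTUs
  passing a prevalence/abundance filter (defaults: prevalence ≥ 0.2,
  |ρ| ≥ 0.6, BH q ≤ 0.05 — conventional microbiome-network choices,
  all configurable and recorded in the manifest); edge sign = sign(ρ);
  metrics are node/edge counts, signed-edge fractions, unweighted
  average local clustering, density 2E/(N(N−1)), and Louvain modularity
  on absolute weights with a fixed seed (module tie-breaks by lowest
  node id).

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not any particular field system. A 300-tip birth–death phylogeny
(λ=1, μ=0.5) carries per-taxon environmental optima evolved along the
tree with a Pagel-δ style depth transform (`conservatism` = 0.3): trait
variance is concentrated on deep branches, so whole clades — not just
sister tips — share niche positions. This "deep niche conservatism"
regime is the one in which phylogenetic turnover metrics are
informative at all; with plain Brownian motion on these trees the
trait–phylogeny correlation is weak and realisation-dependent.

Scenario constructions (defaults; 20 samples/group, depth 2000 reads):

* **Selection scenarios** act on the full 300-species flora: sample
  weights are Gaussian in the environment,
  w ∝ exp(−(optimum − env)²/2σ²) with σ = 0.25 on the standardised
  optimum scale, times a per-sample establishment lottery (each species
  reaches each plot with probability 0.6). The lottery decouples
  membership turnover from the trait, so the taxa a plot lacks still
  have close relatives in other plots — the pattern βNTI reads as
  selection. Fitness, not regional abundance, sets the weights.
  *Homogeneous selection* filters every sample toward the 0.90 quantile
  of the realised optima (an ecologically extreme, clade-concentrated
  niche; under a diffusion only extreme trait values are
  clade-concentrated, because every lineage passes through middling
  values) with micro-heterogeneity sd 0.1 among plots.
  *Heterogeneous selection* assigns samples cyclically to four
  environment levels at the 0.05–0.95 optimum quantiles.
* **Dispersal limitation**: a 150-species regional pool with
  lognormal(σ=1) abundances; samples sit on a line in [0, 1] and draw
  from Gaussian spatial neighbourhoods of radius 0.5·m/(1−m) (m = 0.10)
  around species positions that are independent of the phylogeny,
  producing distance decay without niche structure.
* **Homogenizing dispersal**: four regions of 20 samples; each region
  is a well-mixed 60-species sub-pool sampled multinomially, so
  within-region pairs are far more similar than the
  richness/occupancy-preserving null expects. Detection requires the
  table to span several regions — a single perfectly mixed pool is its
  own null.
* **Drift**: each sample is founded by an independent lottery over the
  regional pool (occupancy 0.6) and then drifts neutrally
  (Wright–Fisher, 5 generations at Nₑ = 20 000) before sequencing.
  The Wright–Fisher variance G/Nₑ = 2.5×10⁻⁴ is deliberately kept below
  the per-read sampling variance 1/depth = 5×10⁻⁴: drift in this
  framework is *defined* as turnover the null models cannot attribute,
  and stronger drift is statistically indistinguishable from dispersal
  limitation under RC-Bray (see Limitations).

Soil covariates are written with field-plausible scales; the selection
environment is exported as a pH-like gradient so the
community–environment analyses have a true driver to find, plus
independent noise covariates (TN, AP, OC, MAT, MAP, …).

What the generator does **not** emulate: compositional sequencing
artefacts, chimeras or clustering error, temporal dynamics, spatially
explicit metacommunity feedbacks, and interaction-driven co-occurrence
(network edges in the neutral scenarios are pure false-discovery
background). Passing tests therefore demonstrate the statistical
machinery is correct and calibrated, not that any particular real
system is dominated by a given process.

## Numerical choices and degenerate inputs

* Rarefaction is a single seeded multivariate-hypergeometric draw
  (exact subsampling without replacement); samples below depth are
  dropped with a warning or raise, by flag.
* βNTI uses the sample standard deviation (ddof = 1) of the null;
  sd = 0 yields NaN with a warning rather than ±∞.
* RC-Bray restricts the null's species pool to taxa observed at least
  once (zero-occurrence taxa are not drawable).
* Permutation p-values are (hits + 1)/(permutations + 1) and can never
  be 0.
* OTUs absent from the tree are excluded from phylogenetic operations
  only, with a logged count; they remain in all compositional analyses.
* Constant vectors: skipped with a warning in ordination regression and
  the Spearman heatmap (NA cells), error in Mantel (undefined r).
* The test suite and release fixtures use 199 null replicates and
  desk-scale simulations (≤ 21 samples for calibrations, the spec-free
  scenario scale of 20 samples/group, 150–300 species); replicate
  counts are configurable and default to 999 in the library.

## Limitations

* Drift vs dispersal limitation is a one-sided boundary: any neutral
  divergence beyond sampling noise raises RC toward +1, so "drift" is
  only identifiable when turnover stays at the null's own scale. This
  is a property of the Raup-Crick construction, not of this
  implementation.
* βNTI's power grows with per-sample richness and with the ratio of
  pool size to community size; at very small richness the null min-
  distance distribution is heavy-tailed and |z| ≥ 2 is rarely
  attainable.
* The two-factor PERMANOVA permutes raw labels; for unbalanced designs
  a residual-permutation scheme would be preferable.
* ITS-derived phylogenies are unreliable deep in the tree; the package
  requires a user-supplied tree and makes no attempt to build one from
  sequences. Interpret βNTI accordingly.
* BH correction is the only multiple-testing option; raw p-values are
  the default to match common reporting practice.
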