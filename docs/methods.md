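# Methods

## Scope and data model

The package analyzes taxa-by-sample read-count tables from time-series
metabarcoding of a microbial (protistan plankton) community, together with
continuous environmental measurements per sample. The node unit is the
network sequence cluster (NSC): first-level sequence clusters merged by
single linkage at ≥ 97% pairwise identity (connected components of the
thresholded similarity graph). The identity threshold is applied
inclusively (≥ 97), configurable; linkage is transitive by construction.
NSCs with fewer than 3 total reads are discarded; a total of exactly 3
survives. Reference-database retention screens are represented by a
pass-through allowlist filter, since they depend on external resources.

## Normalization

Read counts are compositional: each sample's counts are constrained by its
sequencing depth. Before correlation the table is filtered to taxa present
in at least ⌈0.10 · n_samples⌉ samples (taxa in strictly less than 10% of
samples are removed), then transformed as

    v_ij = log(c_ij + 1) − log d_j + log( median_j d_j )

with d_j the column total. This is a log-ratio-style, depth-corrected
transform: with equal depths it reduces to a constant shift of log counts.
The pseudo-count of 1 handles zeros; a zero count in a median-depth sample
maps to 0. Because all downstream statistics are rank-based (Spearman), any
monotone-per-row variant would give identical correlations at equal depths;
the exact variant is therefore low-stakes and is recorded in the
configuration (`log-ratio`, with a `rank` alternative for sensitivity
checks). Environmental parameters are appended as extra rows *untransformed*
(temperatures can be negative, saturations are percentages) and are never
prevalence-filtered; parameters with missing values in the retained samples
are dropped with a warning.

## Null-model thresholds

What counts as a significant Spearman ρ depends on the sample count and tie
structure, so thresholds are determined per dataset. Two randomizations are
deliberately kept separate:

- **Null (shuffle + jitter):** each row's values are independently permuted
  across samples, destroying every inter-row association while preserving
  marginals, and uniform noise of amplitude 10⁻⁶ × the row IQR is added to
  break the heavy ties of sparse counts. All pairwise ρ from
  `n_permutations` such replicates are pooled into a histogram with 4000
  bins (resolution 5·10⁻⁴ in ρ).
- **Thresholds:** ρ⁺ and ρ⁻ are the (1 − α/2) and (α/2) quantiles of the
  pooled null, so the expected number of null edges of *either* sign is at
  most α of the tested pairs. α defaults to 0.01 and is reported in the
  output metadata; per-permutation extreme quantiles are retained as
  evidence. Thresholds are reported rounded to 2 decimals; full precision
  is kept internally.

Defaults: 1000 permutations; at least 100 are required for stable
quantiles (a warning is emitted below that). Constant rows make ρ
undefined; such pairs are recorded as missing, never coerced to zero.

- **Persistence (jitter only):** the observed, unshuffled table is
  re-correlated under `n_jitter` tie-breaking jitter draws; an edge enters
  the consensus network only if it passes the matching threshold in more
  than `persistence_cutoff` (default 0.5) of the replicates. This removes
  edges that exist only under one tie-break configuration of the zero
  counts. Edge weight is the mean ρ over passing replicates; isolated nodes
  are dropped. Co-exclusion edges (ρ ≤ ρ⁻) are retained and flagged by
  sign; environmental rows participate exactly like taxa, with their edges
  flagged via the node attribute.

## Topology

All metrics treat the network as simple, undirected, unweighted (distances
in number of edges). The networks of interest are disconnected, so the mean
shortest-path length is taken over connected pairs only and the diameter is
the largest finite distance. Density and average degree use their closed
forms 2E/N(N−1) and 2E/N. Transitivity is the global clustering coefficient
(3 × triangles / connected triples). Modularity requires a community
partition the analysis itself does not fix; seeded Louvain is used and the
algorithm name and seed are recorded — modularity values are therefore
comparable only within this package, not across partition algorithms.
Component counts are reported by size class (all, > 3 nodes, exactly 2).

## Keystone detection

A keystone is a node whose betweenness centrality (raw Brandes counts,
endpoints excluded) is significantly elevated *and* whose removal would
fragment the network (articulation point). Significance: the vector of
betweenness scores is bootstrapped (default 10,000 resamples) and a node is
significant when its score exceeds the upper bound of the central 95%
percentile interval of the resampled mean. The percentile-of-the-mean
construction is the simplest one consistent with bootstrapping "to achieve
normality"; per-node intervals would be the main alternative and are not
implemented. When all scores are equal the interval collapses and no node
is significant (reported, not an error).

## Extinction scenario

The cascading targeted attack removes, at each step, the node with the
current maximum betweenness (ties broken toward the lexicographically
smallest id, for determinism), recomputes betweenness, and records the
cumulative loss of connectivity. The primary loss metric is the fraction of
the *initial* edges removed, which is non-decreasing and reaches 1 when all
edge-bearing nodes are gone; the fraction of initially connected node pairs
disconnected is emitted as a secondary column because both readings of
"connectivity" are current in the robustness literature. Nodes isolated by
earlier removals stay in the graph; only explicit removals count toward the
rank. This is a whole-network stress test, not a prediction of any
species's extinction probability.

## Synthetic data generator

The generator emulates one seasonal dataset of a biweekly lake survey at
reduced taxon count. Defaults: 36 samples; 500 taxa; 4 guilds × 10 taxa
with within-guild Spearman ρ = 0.9; 5 environmental parameters of which 2
track a guild; mean depth 50,000 reads with CV 0.3; 20% sparse noise taxa.

Construction:

1. One latent Gaussian factor per guild per sample. With two or more
   guilds the realized factor vectors are orthogonalized in-sample
   (centered QR): at n = 36 two independently drawn factors can be
   chance-correlated above 0.4, which would shift every cross-guild pair at
   once and falsify the planted truth that only within-guild pairs are
   associated.
2. Guild members load on their factor through a Gaussian copula with the
   loading chosen via r = 2 sin(π ρ_s / 6) so the *pairwise* Spearman
   correlation between members equals the requested value exactly in the
   latent field. Rank-based planting means the effect is invariant to the
   monotone normalization applied downstream.
3. Base abundances are log-normal with σ = 1.5 across taxa — heavy-tailed,
   but deliberately below the regime where a single taxon dominates sample
   totals: the shared depth denominator would otherwise couple all relative
   abundances and unplanted taxa would no longer be independent. Guild
   members draw their base abundance from the upper part of the
   distribution (log-mean 1.5, σ 1.0) because they emulate the
   network-forming abundant fraction of the community; a taxon with
   near-zero counts cannot carry a planted correlation through read
   sampling.
4. Noise taxa are present in only a random minority of samples (presence
   probability uniform between 1/n and 0.25), exercising the prevalence
   filter.
5. Per-sample depths are log-normal at the requested mean and CV
   (degenerate at CV = 0) and each sample is multinomially resampled to its
   depth, so column totals equal the drawn depths exactly.
6. Environmental parameters linked to a guild are linear (monotone) in the
   guild factor plus Gaussian measurement noise; unlinked parameters are
   independent.

What the generator does *not* emulate: raw reads, chimeras, PCR bias,
taxonomy, temporal autocorrelation within rows, and true ecological
compositionality beyond the multinomial constraint. Passing tests therefore
demonstrate correctness of the inference machinery under planted rank
structure and realistic count sampling, not performance on any particular
real community.

## Validation studies and problem sizes

The benchmark module runs three studies, shared by the test suite and the
reproduction script, sized to complete in minutes on one CPU:

- **Null calibration:** 500 independent taxa × 36 samples, 200
  permutations, α = 0.01, 100 jitter replicates, 20 seeded runs; the
  consensus edge fraction concentrates near α (measured ≈ 0.010–0.014).
- **Planted recovery:** generator defaults; fraction of the 180 planted
  edges recovered and adjusted Rand index between seeded Louvain
  communities and true guild labels (in-house ARI cross-checked against an
  independent implementation in the tests).
- **Attack benchmark:** two 12-node communities (edge probability 0.6)
  joined by one hub bridging 6 members of each; cumulative edge loss of the
  cascading attack over 10 removals versus 50 random removal orders.

Closed-form checks construct random graphs at the reported seasonal network
sizes (946 nodes / 6872 edges; 973 nodes / 5252 edges), where average
degree and density depend only on the counts (14.53 and 0.015; 10.80 and
0.011 — the second of which prints as 10.79 under truncation rather than
rounding).

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive their seeds as SHA-256 of master seed + stage name, so reruns are
  byte-identical and per-stage overrides perturb only that stage.
- Jitter amplitude falls back from IQR to range to 1 for degenerate rows.
- Empty graphs are errors for topology/attack; a single node reports path
  metrics as 0 with a flag; a graph with no edges reports modularity 0.
- Samples with zero total reads are rejected by name during normalization;
  unmapped count rows are rejected by name during aggregation.
- NSC labels are canonical (lexicographically smallest member), making
  clustering invariant to row order.

## Known limitations

- Correlation networks cannot distinguish direct interaction from shared
  environmental response; edges are hypotheses, not mechanisms.
- The log-ratio transform mitigates but does not remove compositional
  coupling; with few taxa or one dominant taxon, spurious positive edges
  among the remainder are expected (visible in the 80-taxon unit tests).
- Modularity values depend on the partition algorithm and are not
  comparable to values produced by other tools.
- The bootstrap significance rule compares each node to the network-wide
  mean; in graphs where betweenness is heavy-tailed by construction this is
  permissive for mid-ranked nodes.
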