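# Methods

## The model

`assemblynet` infers the predominant assembly process of a species community
from the congruence between two weighted, unipartite species networks:

1. **Functional network.** Edge weights are Gower similarity
   `1 − d_G(i, j)` over a mixed-type trait table.  The Gower distance of a
   pair is the mean, over traits observed in both species, of per-trait
   dissimilarities: `|x_i − x_j| / range(trait)` for numeric traits, a 0/1
   mismatch for categorical and binary traits.  Ordinal traits are replaced
   by average ranks of their observed values before range normalization, so
   only their ordering matters.  Traits missing in either member of a pair
   are skipped (pairwise deletion); a pair sharing no observed trait is a
   hard error rather than a silent zero.  A zero-range trait contributes 0
   dissimilarity.  Traits are equally weighted.

2. **Co-occurrence network.** Edge weights are Sørensen similarity
   `2a / (2a + b + c)` (the complement of binary Bray–Curtis dissimilarity)
   computed from a binary species × unit incidence matrix, where a unit is a
   region, sampling site, host species or host individual depending on the
   community scale.  Presence/absence is used rather than abundance because
   parasite counts are aggregated and unreliable; count inputs are coerced
   to presence with a warning.

**Functional groups** are found by best-partitioning of trait space: each
species' row of the functional similarity matrix is its coordinate vector,
rows are clustered by Ward-linkage hierarchical clustering of Euclidean
distances, the tree is cut at every k in 2..min(25, n−1), and each cut is
scored by five internal validity indices — silhouette, Calinski–Harabasz,
Davies–Bouldin, Dunn and the C-index.  Each index votes for its best k and
the majority wins, ties resolved toward smaller k (parsimony).  The index
panel is configurable; five indices spanning the compactness/separation
families stand in for larger panels used by some cluster-number selectors.
Two Ward variants are supported: `ward_d2` feeds raw Euclidean distances to
the standard Ward update; the default `ward_d` feeds square-root-transformed
distances, which reproduces the merge tree of the classical (non-squared)
Ward recurrence applied to the raw distances.

The functional partition is fitted **once on the full species pool** and
then *restricted* to each community: modules containing none of the
community's species are dropped and labels recompacted, but the partition is
never re-fitted per community.  WS and BS report the mean pairwise
functional similarity within and between the restricted modules; a
component with no contributing pairs is NaN, never 0.

**Co-occurrence modules** come from Louvain optimization of weighted Newman
modularity

    Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)

on the complete similarity-weighted graph (no edge thresholding; zero-weight
pairs simply carry no edge, and isolated nodes become singleton modules).
The pass order is seeded; 10 seeded restarts are run by default and the
best-Q partition kept.  The reported M is recomputed exactly from the
formula, independently of the optimizer's internal bookkeeping.

**Congruence.** For each functional group g with n_g ≥ 2 members, the
diversity of its members' co-occurrence-module memberships is the
normalized Shannon entropy

    Dg = [ln n_g − (Σ_k n_gk ln n_gk) / n_g] / ln n_g,

0 when all members share one co-occurrence module and 1 when every member
occupies a different one (attainable only when the community has at least
n_g co-occurrence modules).  This algebraic form makes both boundary values
exact in floating point.  Dg_M is the mean of Dg over non-singleton groups;
singletons are excluded by default because their diversity is vacuously 0
and would bias the average toward filtering (they can be included as zeros
for sensitivity analysis).  If every group is a singleton, Dg_M is
undefined (NaN), never 0.

**Null model and inference.** The functional partition and the
co-occurrence module-size vector are held fixed while species are permuted
uniformly at random among co-occurrence modules; Dg_M is recomputed for
each of 999 replicates (each replicate uses its own seed-derived stream, so
values are independent of evaluation order).  p is the proportion of null
values *strictly below* the observed Dg_M — ties therefore favor smaller p,
matching the one-sided "lower than observed" definition.  p < 0.05 is read
as environmental/host-associated filtering, p > 0.95 as limiting
similarity/competition, anything between as stochasticity or no clear
dominance of either deterministic process.  Both thresholds and the
replicate count are configurable.  No multiple-testing correction is
applied across communities; callers comparing many communities should be
aware of this.

## Community construction

Component communities retain host species whose pooled parasite richness
across a region's sites is at least 8; infracommunities retain
(host species, site, time) groups of conspecific host individuals with at
least 6 parasite species.  Both thresholds are arguments.  Hosts occurring
at multiple sites are pooled for the richness test.  Species present in an
occurrence matrix but absent from the trait table are a hard error
(silently dropping them would bias WS/BS); all-zero species rows are
dropped with a warning; empty units are retained (they carry no pairwise
signal) but logged.

## Synthetic data

The generator emulates a flea-on-small-mammal trait schema: host-species
count (log-normal, rounded, ≥ 1), host phylogenetic diversity and
latitudinal range span (gamma), microhabitat preference (hair/nest/none),
ctenidia count (ordinal 0–3) and body size (truncated normal, > 0).
Occurrence matrices are generated under three mechanisms:

- **filtering** — each unit draws a trait optimum as a pseudo-species and
  admits species with probability `q · exp(−d²/(2σ²))`, d the Gower
  distance to the optimum;
- **limiting similarity** — species are offered to each unit in random
  order with acceptance probability q and rejected when their Gower
  similarity to any resident exceeds τ (a competitive lottery);
- **neutral** — independent Bernoulli(q) occupancy.

Because unit optima are pseudo-species, the species↔optimum distance reuses
the Gower implementation unchanged (ranges are taken over the combined
table).  All draws descend from one master seed, so occurrence matrices are
bitwise reproducible.

The strong-effect grid used by the recovery experiment was calibrated by
pilot simulation of the generator itself: σ = 0.15 with q = 0.6 (60 species
× 30 units) makes each unit admit roughly the most-similar decile of the
pool, and τ = 0.65 with q = 1.0 (150 species × 80 units) makes every unit a
maximal τ-packing of mutually dissimilar species.  The limiting scenario
uses a larger, compound-community-like pool because over-dispersion is a
weaker per-group signal than concentration: detecting it needs more
functional groups to average over.  Neutral calibration uses 60 × 30 with
q = 0.3.  Default replicate counts are 100 per scenario for recovery and
200 for neutral calibration — sizes chosen so a full run completes in a few
minutes on one CPU while keeping binomial error well inside the margins the
checks assert.

What the generator does **not** emulate: host population dynamics,
spatially explicit dispersal, phylogenetic signal in traits, observation
error, or the clumped (multi-modal) trait distributions real flea faunas
show.  Passing recovery tests therefore demonstrates that the pipeline
detects the two deterministic mechanisms when they act alone and strongly
on unimodal trait clouds — not that it would decompose mixed or weak
processes in field data, where the original analyses frequently (and
correctly) return the stochastic verdict.

## Numerical choices and degenerate inputs

- Similarity matrices are kept at full precision; symmetry is enforced by
  averaging with the transpose, the diagonal is set to exactly 1, and
  entries are clipped to [0, 1] against rounding residue.
- All-identical trait profiles yield a single functional module with a
  warning (no structure to partition); fewer than 3 species cannot be
  partitioned and raise.
- A validity index returning NaN on a given dataset (e.g. the C-index when
  all pairwise distances are equal) abstains from the vote.
- A co-occurrence graph with zero total weight has no structure to optimize
  and raises; a single co-occurrence module forces every null Dg_M to 0.
- Missing NA tokens are `"NA"`, `""`, `"na"`, `"NaN"`; unparseable numeric
  cells become missing with a warning.
- Seeds: every stochastic component (Louvain restarts, null replicates,
  generators) derives independent streams from one master seed via
  `numpy.random.SeedSequence`, so partial reruns reproduce exactly.

## Known limitations

- The cluster-number vote uses 5 indices, not the 30-index panels of larger
  selectors; on weakly structured clouds different panels can prefer
  different k.  The chosen k feeds through to Dg_M only via group
  membership, and the null model conditions on it.
- The normalized-Shannon Dg adopted here matches the documented boundary
  behaviour (0 = concentration, 1 = dispersion) of published
  module-diversity indices but is not guaranteed to equal every published
  variant away from the boundaries; it is isolated in one function.
- p is computed with denominator n_null (999 by default), counting strictly
  smaller null values; communities whose Dg_M ties much of the null mass
  are pushed toward the filtering side, which is the documented convention.
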