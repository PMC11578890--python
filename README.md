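# assemblynet

Inference of community assembly processes from the congruence between
trait-based (functional) and co-occurrence networks.

## The problem

Ecologists want to know what assembles a community: does the environment (or
the host, for parasites) *filter* species so that co-occurring species share
the traits needed to persist; does competition enforce *limiting
similarity*, so that only trait-dissimilar species coexist; or is
composition effectively *stochastic*?  Pairwise co-occurrence tests answer
this weakly, because non-randomness is usually carried by a subset of
species.  A group-wise alternative compares the module structure of two
weighted species networks built over the same community:

- a **functional network**, edge weights `1 − Gower distance` over a mixed
  numeric/ordinal/categorical trait table (missing values handled by
  pairwise deletion), partitioned into functional groups by Ward clustering
  with the number of groups chosen by a majority vote of internal validity
  indices;
- a **co-occurrence network**, edge weights `1 − binary Bray–Curtis
  (Sørensen) dissimilarity = 2a/(2a+b+c)` over a binary species × unit
  incidence matrix, partitioned by Louvain optimization of weighted Newman
  modularity `Q = (1/2m) Σ_ij (A_ij − k_i k_j/2m) δ(c_i, c_j)`.

For each functional group *g*, the dispersion of its members over
co-occurrence modules is the normalized Shannon diversity
`Dg = H_g / ln n_g`, and the community-level congruence index **Dg_M** is
the mean of Dg over non-singleton groups: 0 when functionally similar
species always share a co-occurrence module, 1 when they never do.  The
observed Dg_M is ranked against 999 null replicates that permute species
among co-occurrence modules of fixed sizes; with
`p = #(null < observed)/999`, `p < 0.05` indicates environmental/host
filtering, `p > 0.95` limiting similarity/competition, and anything between
stochasticity or no dominant deterministic process.

The package is aimed at parasite (and other metacommunity) data organised
hierarchically — compound communities across regions or host species,
component communities across sampling sites, infracommunities across host
individuals — and ships the standard selection filters for those scales
(≥ 8 parasite species per host for component communities, ≥ 6 for
infracommunity groups), plus a synthetic-data generator with known assembly
mechanisms so the whole pipeline is testable without field data.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from assemblynet import (DEFAULT_RECOVERY_GRID, analyze_standalone,
                         results_to_frame, simulate_community)

cfg = DEFAULT_RECOVERY_GRID["filtering"]          # strong environmental filtering
community = simulate_community(cfg, label="demo-filtering")
result = analyze_standalone(community, seed=0)
print(results_to_frame([result.to_row()]).to_string(index=False))
```

prints

```
         label           scale  n_species        M       WS       BS  n_func_modules  n_cooc_modules      DgM        p   process
demo-filtering component_sites         60 0.249966 0.785812 0.621432               3               3 0.291583 0.004004 filtering
```

Reading the row: the 60-species community's co-occurrence network has
modularity M ≈ 0.25 with 3 Louvain modules; the 3 functional groups are more
similar within than between (WS 0.79 > BS 0.62); their members are
concentrated in few co-occurrence modules (Dg_M ≈ 0.29), lower than nearly
the whole null distribution (p ≈ 0.004 < 0.05) — so the analysis correctly
recovers the filtering mechanism that generated the data.

For field data, read a trait table and an occurrence matrix instead:

```python
from assemblynet import (CommunitySet, analyze_community, best_partition_traits,
                         gower_similarity, read_occurrence_matrix, read_trait_table)

traits = read_trait_table("traits.csv", kinds={"body_size": "numeric",
                                               "ctenidia": "ordinal",
                                               "microhabitat": "categorical"})
global_partition = best_partition_traits(gower_similarity(traits))  # fit once
occ = read_occurrence_matrix("occurrence.csv", scale="component_sites")
result = analyze_community(CommunitySet.from_global("hostX", occ, traits),
                           global_partition, seed=0)
```

A thin CLI mirrors this: `python -m assemblynet simulate ...` writes a
synthetic trait/occurrence pair, and `python -m assemblynet analyze ...`
runs one community end to end.

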