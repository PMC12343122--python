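# chasecluster

Compositional clustering of presence–absence community matrices, built for
the question of how site assemblages group into regions — and how those
groupings change — without anchoring the answer to geography.

The motivating use case is zooarchaeological: fossil mammal assemblages from
Late Pleistocene and Holocene sites, where agriculture and livestock spread
may have rewired which faunas resemble each other across continents. The
machinery is general: any site × species incidence matrix with coordinates
(microbiome samples, vegetation plots, survey routes) can be analysed.

## What it does

**Chase clustering** — an unconstrained, penalized, multi-start stochastic
partition optimizer with an endogenous number of clusters. Given a pairwise
compositional similarity matrix *S* (the "chase matrix"; Jaccard by default),
it maximizes

&nbsp;&nbsp;&nbsp;&nbsp;F(P) = Σ_c Σ_{{i,j}⊆c} (S_ij + γ) − λ·#(singleton clusters)

over partitions P. Clusters are seeded from richness-weighted samples of
compositionally distinct sites, remaining sites are "chased" into the most
similar seed cluster, and assignments are then shuffled (greedy by default,
optionally annealed) over requested k = 2…15 with 250 random starts and
10 000 shuffles each, retaining the best partition visited. The
regularization γ ≤ 0 prices every within-cluster pair: more negative γ
splits weakly overlapping groups, so the data choose the emergent k. The
singleton penalty λ suppresses trivial one-site "clusters".

Around the core:

- **`community_data`** — occurrence/site tables → validated binary
  `SiteMatrix` (minimum-unique-taxa reduction, ≥5-species richness filter,
  domesticate splitting).
- **`ward_geo`** — geography-constrained Ward clustering on the convex
  combination (1−α)·D0 + α·D1 of occupancy (Euclidean) and great-circle
  dissimilarities, with α selected on a 0.01 grid by explained inertia.
- **`compare`** — adjusted Rand index between partitions.
- **`turnover`** — sites grouped into ≤50 km localities, epoch pairs
  compared by Jaccard distance (gained + lost over total species).
- **`synthdata`** — planted-partition generators with regional pools,
  cosmopolitan species, cross-regional domesticate overlays, and epoch
  pairs with closed-form expected turnover.

## Worked example

Simulate a 5-region, 60-site community, cluster it, and compare methods:

```
chasecluster simulate --seed 3 --no-domesticates --out data
chasecluster chase --occurrences data/occurrences.csv --sites data/sites.csv \
    --seed 3 --out chase_out
chasecluster ward  --occurrences data/occurrences.csv --sites data/sites.csv \
    --k 5 --out ward_out
chasecluster compare chase_out/assignments.csv ward_out/assignments.csv
```

The chase log reports the selected partition:

```
selected k=5 gamma=-0.100 objective=80.1020 consistent_fraction=0.483
```

meaning the penalized objective peaked at five clusters (the five planted
regions) with γ = −0.10, and 48 % of sites sat in their matched cluster in
at least 90 % of the 250 random starts (most other starts end in nearby
local optima; the per-site stability column in `assignments.csv` shows
which assignments are fragile). The comparison report starts

```
{
  "ari": 1.0,
  "n_sites": 60,
  ...
}
```

an adjusted Rand index of 1.0: the geography-constrained Ward partition at
k = 5 and the composition-only chase partition agree exactly here, because
the synthetic regions are concordant in composition and space. On real data
the interesting signal is precisely where these two disagree.

The same library calls are available in Python:

```python
from chasecluster import ChaseConfig, run_chase
from chasecluster.synthdata import SyntheticConfig, simulate_sites

matrix, truth = simulate_sites(SyntheticConfig(rng_seed=3))
result = run_chase(matrix, ChaseConfig(gamma=-0.10, rng_seed=3))
print(result.best.k_effective)   # 5
print(result.per_k)              # objective and k_effective per requested k
```

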