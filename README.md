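# islandbeta

Tools for asking what structures insular species assemblages: present-day
environment, spatial processes, or the history of land connections.  The
package implements the full analysis chain used in island biogeography to
answer that question from presence/absence data —

1. **Beta-diversity partitioning.**  Pairwise Jaccard-family dissimilarity
   between assemblages, split additively into a replacement (turnover) and a
   richness-difference component:

   β_total = (b + c) / (a + b + c),  β_repl = 2·min(b, c) / (a + b + c),
   β_rich = |b − c| / (a + b + c),

   where *a* is shared and *b*, *c* unshared diversity.  Both the taxonomic
   form (*a, b, c* = species counts) and the functional form (*a, b, c* =
   branch lengths of a trait dendrogram spanned by each assemblage) are
   provided.
2. **Functional distances.**  Weighted Gower distance over continuous traits
   with weights optimized so every trait correlates equally with the combined
   distance, and the UPGMA tree built from it.
3. **Biogeographical regionalization.**  UPGMA clustering of sites on
   β_repl (or any component), with a concordance score quantifying how well
   a two-cluster cut matches a candidate strait border.
4. **Spatial predictors.**  Moran's eigenvector maps (MEMs) from four
   neighbor-graph constructions (Delaunay, Gabriel, relative neighborhood,
   minimum spanning tree), with Blanchet-style double-stopping forward
   selection and graph choice by adjusted R².
5. **Variation partitioning.**  Distance-based RDA of each beta matrix on
   the spatial (S), environmental (E) and historical (H) predictor sets;
   adjusted-R² inclusion–exclusion into seven unique/shared fractions plus a
   residual; significance by permuting the rows of the community matrix
   (9999 permutations in the full protocol), at two spatial scales (entire
   archipelago vs. main islands only).

A synthetic-archipelago generator produces data with known ground truth — a
latitudinally elongated island chain cut by two straits into three regions,
Gaussian environmental niches, dispersal-distance decay, and strait-bounded
species pools — so every stage of the chain can be validated against
construction.

## Worked example

Generate an archipelago whose only structuring process is history
(species pools disjoint across the southern strait), then partition the
variation in taxonomic β_total:

```python
from islandbeta import (ScenarioConfig, generate, beta_taxonomic,
                        summarize_beta, choose_swm, permutation_test)
from islandbeta.ordination import drop_constant_columns

data = generate(ScenarioConfig(scenario="HIST_ONLY", seed=1))
bt = beta_taxonomic(data.community)
print(summarize_beta(bt).round(2))

D = bt.total
choice = choose_swm(D, data.sites, nperm=199, seed=1)
env, _ = drop_constant_columns(data.factors.environmental)
hist, _ = drop_constant_columns(data.factors.historical)
res = permutation_test(D, choice.spatial_predictors, env, hist,
                       nperm=999, seed=1)
for key, value in {**res.fractions, **res.totals}.items():
    print(f"{key:10s} adjR2 = {value:6.3f}   p = {res.p_values[key]:.3f}")
```

Output:

```
       mean    sd
total  0.61  0.36
repl   0.43  0.27
rich   0.18  0.14

S|(E∩H)    adjR2 =  0.004   p = 0.461
E|(S∩H)    adjR2 =  0.002   p = 0.435
H|(S∩E)    adjR2 =  0.035   p = 0.221
S∩E|H      adjR2 =  0.003   p = 0.498
S∩H|E      adjR2 =  0.571   p = 0.001
E∩H|S      adjR2 = -0.005   p = 0.595
E∩S∩H      adjR2 =  0.073   p = 0.007
Total S    adjR2 =  0.652   p = 0.001
Total E    adjR2 =  0.074   p = 0.023
Total H    adjR2 =  0.674   p = 0.001
```

The partition recovers the construction: almost everything is explained by
the overlap of space and history (`S∩H|E` = 0.57, p = 0.001) — the strait
indicators are themselves spatially structured, so a historical barrier
surfaces in exactly that shared fraction — while the environment-only
fraction is negligible.  `Residuals` (1 − adjusted R² of the full model)
was 0.32 here.

## Command line

```sh
islandbeta simulate --scenario MIXED --seed 7 --out data/
islandbeta functional-tree data/traits.csv --out tree.nwk --weights w.json
islandbeta beta data/community.csv --out-prefix data/beta
islandbeta cluster data/beta_repl.csv --sites data/sites.csv \
    --out-tree dend.nwk --out-clusters clusters.csv
islandbeta pipeline --simulate MIXED --seed 7 --nperm 999 --out run/
```

`pipeline` runs every stage and writes beta matrices, Newick dendrograms,
cluster tables, the long-format fraction table (`table1.csv`) and a JSON
manifest; reruns with the same configuration are byte-identical.

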