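# Methods

This note documents the statistical procedures implemented in
`islandbeta`, the modelling choices behind the synthetic-archipelago
generator, and the numerical conventions that matter when comparing
results against other software.

## Sampling units and scales

A site is either a primary mesh cell of the Japanese national grid
(JIS X 0410: 1° of longitude × 40′ of latitude, ≈6400 km², code
`floor(lat × 1.5) × 100 + (floor(lon) − 100)`) or a whole minor island
keyed by its own identifier.  Cells are closed on the lower-left corner
and open on the upper-right, so point-to-cell assignment is
deterministic.  Fine-grid covariates are aggregated to sites by the
arithmetic mean of contained points; a site with no points is explicitly
missing (NaN), and the ordination stage refuses missing predictors
rather than imputing.

Two analysis scales are supported: the entire archipelago, and the
main-islands subset (`on_main_island` sites only, which excludes the
southern region entirely).  Scale filtering drops species columns that
become empty and reports them; it never alters retained occurrence
values.  Predictor columns that become constant after filtering (e.g.
the Tokara indicator when no southern site remains) are dropped and
logged before model fitting.

## Beta diversity

Pairwise dissimilarity uses Jaccard denominators throughout.  With
shared diversity *a* and unshared *b*, *c*:
β_total = (b+c)/(a+b+c), β_repl = 2·min(b,c)/(a+b+c),
β_rich = |b−c|/(a+b+c); additivity β_total = β_repl + β_rich holds to
1e-12 on every pair by construction and is asserted at run time.  The
functional form replaces counts by branch lengths of the functional tree
spanned by each assemblage (a branch is spanned if any of the
assemblage's species sits below it; the root carries no branch).  On a
star tree with unit branches the functional and taxonomic triplets are
identical, which the tests exploit as an oracle.  A site pair sharing no
diversity at all (a+b+c = 0) is an error; empty assemblages are rejected
at input.

Summaries (mean ± SD per component) are taken over the strict lower
triangle with the sample (n−1) SD.

## Functional distance and tree

Traits are species-level arithmetic means over specimens.  Each
continuous trait yields a range-normalized Gower matrix
d_k = |x_i − x_j| / range(x); zero-range traits are dropped with a
warning.  The combined distance D = Σ w_k d_k uses weights that minimize
the standard deviation of the Pearson correlations r_k = cor(d_k, D) —
the "equal contribution" criterion — over the constrained simplex
w_k ∈ [0.01, 1], Σw = 1.  The dispersion measure (SD rather than range)
and the 0.01 floor (which prevents degenerate zero-weight solutions) are
configurable.  Optimization is multi-start SLSQP (equal-weight start
plus seeded Dirichlet draws), deterministic given the seed; the result
is never worse than equal weights, by explicit comparison.  Exact
equivalence with other implementations of the idea is approximate by
design: the precise dispersion criterion differs between tools.

UPGMA is implemented directly because its contract here includes a
deterministic tie-break (merge the pair whose lexicographically smallest
member id is smallest) and a height convention: merge height equals half
the average inter-cluster distance, so the cophenetic distance between
two clusters equals their average distance.  SciPy's average-linkage
serves as an independent cross-check in the tests on tie-free inputs.
Cuts at k groups undo the last k−1 merges, so equal-height ties resolve
toward the earlier merge.

## Regionalization

Sites are clustered with UPGMA on a beta component; β_repl is the
recommended response for border detection because it is independent of
richness differences.  Border support is quantified (rather than judged
visually): cut the dendrogram at k = 2 and score the fraction of sites
whose cluster matches their side of the candidate strait, maximized over
the two label pairings.  The score is 1.0 for a perfect border and
≈0.5 for random balanced labels.  Species-mode clustering uses Euclidean
distance between occurrence vectors.  Only k = 2 and k = 3 cuts are
exposed; choice-of-k statistics are out of scope.

## Spatial eigenvectors

Neighbor graphs over site centroids: Delaunay triangulation, Gabriel
graph, relative neighborhood graph, minimum spanning tree.  The
geometric predicates (and Delaunay) run on a planar equirectangular
projection, which preserves the exact containment hierarchy
RNG ⊆ Gabriel ⊆ Delaunay; reported edge lengths and the MST objective
use great-circle km, appropriate for a domain spanning ~20° of latitude.
Weights are binary by default (inverse distance available); the
eigen-decomposition of the doubly centered weight matrix H W H yields
the MEMs.  Near-zero eigenvalues (|λ| < 1e-9) are discarded; by default
only positive-λ vectors (positive spatial autocorrelation) are retained,
matching the usual default for detecting positive structure, with an
"all" mode available.  For binary weights Moran's I of each eigenvector
is an increasing function of its eigenvalue, which the tests assert.

Forward selection follows the double-stopping rule: selection starts
only if the global model (all candidates) is significant under row
permutation of the principal coordinates (default α = 0.05); candidates
are added by largest R² gain until the best candidate's permutation p
exceeds α or the cumulative adjusted R² would exceed the global model's
adjusted R² (a 1e-10 tolerance keeps noiseless exact-fit responses from
being rejected by the second rule).  The graph whose selected set
attains the highest adjusted R² is chosen; ties go to the canonical
order (delaunay, gabriel, relative_neighborhood, mst).  Selection is
performed once on the observed data and held fixed during significance
permutations; re-selection per permutation is computationally
prohibitive at 9999 × 6 responses and is not the default anywhere.

## Variation partitioning

Each beta matrix is square-root transformed and double-centered
(Gower) into principal coordinates; the transform makes Jaccard-family
dissimilarities Euclidean-embeddable so no negative eigenvalues arise
(axes with λ ≤ 1e-9 are dropped).  R² of a predictor set is the share
of the coordinate cloud's total sum of squares captured by least-squares
projection; the adjustment is the classical
R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1), with p the number of predictor
columns (for the spatial set, the number of selected eigenvectors).
Seven nested models (S, E, H, SE, SH, EH, SEH) feed the
inclusion–exclusion:

    S_unique = R(SEH) − R(EH)   (and cyclically)
    SE_shared = R(SEH) − R(H) − S_unique − E_unique   (and cyclically)
    SEH_shared = R(SEH) − sum of the previous six
    residual = 1 − R(SEH)

The seven fractions sum to R²_adj(SEH) identically; the implementation
asserts closure to 1e-9 on every call.  Shared fractions may be
negative (suppression).

Significance: the null permutes the site rows of the community matrix,
breaking the site↔predictor linkage, and recomputes every fraction.
Recomputing beta from a row-permuted community matrix is exactly a joint
row/column permutation of the observed dissimilarity matrix, which in
turn is a row permutation of its principal coordinates; the
implementation uses this cheap equivalent (the equivalence is asserted
by a test).  p = (#{statistic_perm ≥ statistic_obs} + 1)/(nperm + 1), so
p is strictly positive with floor 1/(nperm+1) — at 9999 permutations the
smallest reportable value is 0.0001.  The full protocol uses 9999
permutations; interactive and test runs default lower (999 and below)
purely for turnaround.

## The synthetic archipelago

The generator emulates the structure of a long, narrow island chain cut
by two straits (Tsugaru in the north, Tokara in the south) into three
regions, with 15/30/15 sites by default (60 total, ~20% minor islands in
every region; southern sites are never main-island) and 30 species.
Occupancy is logistic-Gaussian:

    p_is = logistic(β₀ − (e_i − μ_s)²/(2σ²)) · admissible(region_i, s)
           · exp(−d(i, center_s)/δ),   β₀ = 2.0

* **Environment.**  e_i = w·g_i + ε_i, where g is the z-scored latitude
  and ε ~ N(0, σ_env) is local (topographic/microclimatic) variation
  invisible to the spatial and historical blocks.  Temperature and
  precipitation observe e with small error; the remaining five
  covariates are realistic extras carrying mostly their own variation.
* **History.**  Each species originates in one region; it crosses a
  strait with probability exp(−gap/γ), so wider straits isolate pools
  more strongly — this is the mechanism behind the monotone increase of
  cross-strait replacement with gap width.  Historical covariates are
  region step functions (past-climate differences) plus the two strait
  indicators.  In the pure historical scenario the Tokara crossing
  probability is zero: pools are disjoint across it by construction and
  cross-strait β_total is exactly 1.
* **Space.**  Dispersal decays exponentially around a center site drawn
  inside the species' region of origin; the niche optimum tracks the
  center's environment (species are adapted to where they originate),
  which keeps the three filters jointly satisfiable.
* **Traits** are a linear map of the niche optimum plus noise
  (SD 0.3 standardized units), so functional structure tracks the
  environmental axis.

Scenario profiles set the parameters left unspecified by the user.  The
three pure scenarios stress the *private* component of their process so
the matching fraction is identifiable: ENV_ONLY (σ = 0.8, no dispersal
or history, gradient weight 0.35, σ_env = 1.0 — the environment is
mostly local), SPACE_ONLY (δ = 1.5°, well below the region scale, no
niches or history), HIST_ONLY (pools only, Tokara crossing zero).
MIXED is the confounded regime: all three processes active but moderate
(σ = 0.5, δ = 7°, gradient weight 1.0, σ_env = 0.3, γ = 6°), each
organizing assemblages along the same latitudinal axis, so the
three-way shared fraction dominates — the situation typical of real
archipelago data.  Empty site rows are redrawn (≤100 retries); a site
whose expected richness is essentially zero raises an error instead,
which genuinely occurs in extreme narrow-niche limits (σ ≲ 0.3).

What the generator does *not* emulate: real coastline geometry and
area-dependent species pools (minor islands host assemblages of the
same richness scale as grid cells), abundance structure, observation
error in presence records, and nonlinear trait–environment relations.
Passing recovery tests therefore demonstrate that the analysis chain
attributes variation correctly when the generating processes match its
linear-predictor assumptions, not that it is robust to everything field
data can do.

## Problem sizes used in validation

All validation runs use the default study conditions (60 sites, 30
species) on one CPU: partition algebra on >1000 random pairs; star-tree
equivalence on 100 random matrices; dense eigen-oracle on all four
graphs for n ≤ 12; null calibration with 100 independent random
communities at 199 permutations (each fraction's rejection rate at
α = 0.05 must lie in [0.01, 0.10]); scenario recovery over 20 seeds per
scenario with 199-permutation forward selection (≥80% of seeds must
place the largest fraction on the scenario's own process); and the
two-scale contrast of history-containing fractions over 20 paired seeds.
The full acceptance sweep completes in roughly half a minute.

## Known limitations

* The equal-contribution weight optimizer matches the published idea,
  not any specific implementation bit-for-bit.
* dbRDA here regresses all retained principal coordinates (a full
  multivariate regression); software that tests constrained axes
  sequentially will report different per-axis statistics, though R² and
  adjusted R² agree.
* When forward selection retains no eigenvector, the three-set partition
  keeps the single broadest eigenvector so the output schema is stable;
  its fractions are expected to be judged nonsignificant.
* k = 2/3 cuts only; no support for counting "major clades" beyond that.
* Mesh arithmetic covers the primary (1°×40′) grid only.
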