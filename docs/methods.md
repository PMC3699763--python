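# Methods

## Model and procedure

The pipeline treats the subjects × ROIs matrix of mean cortical thickness
as the raw observable.  Nuisance variation is removed by one ordinary
least-squares GLM per ROI, fit over **all subjects pooled** (the model has
no group term, so residuals are identical whichever group labels are
attached):

    c(x) = β0 + β1·age + β2·gender + [β3·mean_thickness] + ε

The default covariate list is `(age, gender, mean_thickness)`, where
`mean_thickness` is each subject's mean ROI thickness; a covariate-minimal
`(age, gender)` model is available through the same interface.  The two
readings of "adjusting for the mean of the measures" (per-subject global
thickness vs. grand-mean centering) are both expressible via the covariate
list; the per-subject regressor is the default because global thickness is
the standard nuisance in covariance-network work.

Per group, the network is the Pearson correlation of residuals over all ROI
pairs.  Edge-wise group differences use Fisher's z with the n−3 variance
approximation and two-tailed normal p-values, corrected by
Benjamini–Hochberg FDR over all N(N−1)/2 pairs.

### Cost thresholding

A binary graph at rewiring cost c keeps the K = round(c·N(N−1)/2) largest
**positive** correlations (anti-correlations are never eligible — the
method targets positive morphometric association).  Rounding is
half-away-from-zero; ties between equal correlations break in ascending
(row, column) order so edge selection is deterministic across platforms.
Because the ranking is computed once per network, edge sets are nested
along the cost grid (a graph filtration).  If fewer than K positive entries
exist, all of them become edges, the achieved cost is recorded, and a
warning is logged.

### Efficiency measures

With d_ij the unweighted geodesic distance and the convention 1/∞ = 0:

* `E_glob  = (1/(N(N−1))) Σ_{i≠j} 1/d_ij`
* `E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij`
* `E_nbr(i)` = `E_glob` of the subgraph induced by node i **together with**
  its first neighbors, with `E_nbr = 0` for nodes of degree ≤ 1
* `E_loc = mean_i E_nbr(i)`

Two deliberate conventions deserve note.  First, the neighborhood subgraph
includes the centre node itself; the more common neighbors-only convention
is exposed as `convention="neighbors_only"` (and `nbr_convention` in the
run config) and cross-checked against networkx's local efficiency in the
tests.  Second, a degree-1 node scores 0 even though the inclusive-subgraph
formula with N_i = 2 would give 1; the zero convention (no intra-neighbor
connectivity to speak of) is the documented behavior.

Distances are exact breadth-first-search geodesics per connected component:
a boolean matrix-power BFS for graphs of ≤ 64 nodes (faster at that scale)
and `scipy.sparse.csgraph` above it; the two kernels are asserted identical
in the tests, and all four measures are verified to 1e-12 against a
brute-force Floyd–Warshall oracle on 500 random graphs.

### Null models and the small-world sandwich

Cost-matched benchmarks: uniform random graphs with **exactly** K edges
(sampled without replacement from all unordered pairs — exact-K rather than
G(n,p), so the cost match is exact) and a deterministic 1-D ring lattice
(rings of increasing distance added in full, the final partial ring filled
in ascending node order).  A ring is the standard maximal-clustering
small-world benchmark; higher-dimensional lattices would be an alternative
reading and are out of scope.  Random ensembles default to 100 instances
per cost (configurable up to the full-scale 1000); the lattice is
deterministic, so one instance represents its ensemble.  A network is in
the small-world regime at cost c when
`E_glob(lattice) ≤ E_glob(brain) ≤ E_glob(random)` and
`E_loc(random) ≤ E_loc(brain) ≤ E_loc(lattice)` (flags use a 1e-9 equality
tolerance).

### Permutation inference

Group comparisons permute the group labels and rerun correlation →
binarization → efficiency for each relabeling.  Residuals are computed once:
the GLM is pooled and group-blind, so relabeling cannot change it.  The
two-tailed p-value is the add-one estimator
`p = (#{|null| ≥ |observed|} + 1)/(B + 1)`, valid for any B; B defaults to
200 for desk runs (the full-scale 2000 is a config change).  Differences
are reported as group 2 − group 1, and `signed_log10_p = sign(diff)·
(−log10 p)`.  Node-level p-values are deliberately uncorrected (networks at
adjacent costs are strongly dependent and the disparity analysis is a
spatial-pattern summary, not a localization claim); both per-cost and
cost-averaged (AUC-mean, the arithmetic mean across the discrete grid)
scopes are provided.

### Dorsal/ventral disparity and the degree model

Nodes are dorsal when their centroid Z lies strictly above the median Z of
all ROIs, ventral otherwise (strictly-above keeps the rule deterministic
under ties; an all-equal-Z atlas degenerates to all-ventral with a logged
warning).  The disparity summary splits significant nodes by sign and
location and reports counts and proportions.  The efficiency–degree model

    E(i) = β0 + β1·D(i) + β2·G(i) + β3·D(i)·G(i) + ε

is ordinary least squares over the 2N cost-averaged node observations with
G a 0/1 group indicator; the interaction is tested by a single-coefficient
F-test.  The pipeline fits both linear and log degree and keeps whichever
explains more variance (log requires strictly positive mean degrees).

## Synthetic cohorts

The generator draws age ~ N(24.4, 5²) years, gender ~ Bernoulli(0.33)
(coded 0/1; the GLM needs a numeric column and the coding is otherwise
arbitrary), per-ROI baseline thickness ~ N(2.5, 0.25²) mm, and adds
age·(−0.01 mm/yr) and gender·(0.05 mm) confounds plus a residual field of
scale 0.15 mm — values in the range typical of ROI-averaged cortical
thickness in young adults.  Inter-regional correlation is imposed by one
shared latent factor per block: within a block with target correlation r,
`e_i = √r·f + √(1−r)·ε_i`, giving pairwise population correlation exactly r
at unit variance (simple and analytically invertible).  Blocks are
group-specific and disjoint within a group; `plant_disparity` derives
group-2 blocks from group 1 by lowering within-ventral and raising
within-dorsal correlation by the same δr.  The synthetic atlas places ROIs
on a sphere-like spiral with Z increasing in ROI index, so dorsal/ventral
membership is controllable by index and a 148-ROI atlas splits exactly
74/74 at the median.

`modular_spec` partitions the ROIs into equal modules; its default scale is
20 modules (~7 ROIs each on a 148-ROI atlas).  That choice is what makes
the generator emulate the small-world character of empirical covariance
networks: many small, tightly correlated neighborhoods over a diffuse
sampling-noise background, so that thresholded graphs mix intra-module
clustering with noise-driven shortcuts.  Lobe-scale modules (8–12 on 148
ROIs) would instead produce near-disjoint cliques whose clustering exceeds
even the ring-lattice benchmark and which fragment at low cost — a
covariance profile empirical thickness networks do not show.

What the generator does **not** emulate: spatially smooth,
distance-dependent correlation; hemispheric homotopy; heavy-tailed hub
structure (except when blocks of unequal size are specified explicitly);
scanner/site effects; non-Gaussian thickness noise.  Passing tests
therefore demonstrate that the machinery recovers planted covariance
structure under its own assumptions, not that any particular clinical
finding would replicate.

## Problem sizes and numerical choices

The test-suite and acceptance-script experiments run at sizes chosen to
make Monte-Carlo conclusions stable on a single CPU: oracle agreement on
500 (tests) / 200 (script) random ≤ 7-node graphs at 1e-12; the
small-world sandwich on one 148-ROI cohort at nine costs with 50 null
instances per cost; permutation calibration on 500 (tests) / 150 (script)
null cohorts at 20 ROIs, 5 costs, B = 200, with the Monte-Carlo standard
error computed treating cohorts (not node-tests, which are correlated
within a cohort) as the independent unit; disparity recovery at 40 ROIs
with 60 subjects/group and δr = 0.3 — 40 ROIs as two 20-ROI blocks keeps
the planted blocks exactly aligned with the median-Z split, so location
labels coincide with ground truth.  All randomness flows through explicit
integer seeds; identical spec + seed reproduces cohorts and permutation
runs bitwise.

## Known limitations

* The pipeline starts from ROI-averaged thickness; surface reconstruction,
  smoothing and parcellation are upstream concerns.
* Only positive-correlation networks are analyzed; anti-correlation
  structure is out of scope by design.
* Weighted-graph analysis, degree-preserving rewiring nulls, betweenness /
  information centrality, and community detection are not implemented.
* The edge-wise Fisher-z test assumes approximate normality of residuals;
  heavy-tailed thickness distributions would call for a permutation variant
  at the edge level too.
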