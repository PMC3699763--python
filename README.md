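# thicknet

Structural covariance network analysis of cortical thickness.

Across a cohort, the thicknesses of two cortical regions co-vary when the
regions are anatomically or developmentally linked; treating regions as
nodes and strong thickness correlations as edges yields a *structural
covariance network* that can be compared between clinical groups.
`thicknet` implements that analysis end to end for researchers working with
ROI-averaged thickness tables (e.g., FreeSurfer parcellation output):

1. **Residualization** — per-ROI GLM `c(x) = β₀ + β₁·age + β₂·gender + ε`
   (optionally also mean thickness) fit over all subjects pooled; the
   residuals carry the inter-regional signal.
2. **Correlation networks** — per-group Pearson correlation of residuals
   over all ROI pairs, with edge-wise Fisher-z group comparison under
   Benjamini–Hochberg FDR.
3. **Cost thresholding** — binarization to a prescribed *rewiring cost*
   (edge density) `c = K / (N(N−1)/2)` over a grid of costs (default 0.01
   to 0.50, step 0.01), keeping only positive correlations.
4. **Efficiency measures** — global efficiency
   `E_glob = (1/(N(N−1))) Σ_{i≠j} 1/d_ij`, its node-level version
   `E_nodal(i)`, local efficiency `E_loc`, and *neighboring efficiency*
   `E_nbr(i)` (the efficiency of a node's neighborhood subgraph), all well
   defined on disconnected graphs via `1/∞ = 0`; cost-matched uniform
   random and ring-lattice benchmarks for the small-world sandwich
   `E_glob^lattice ≤ E_glob^brain ≤ E_glob^random` and
   `E_loc^random ≤ E_loc^brain ≤ E_loc^lattice`.
5. **Permutation inference** — group labels are shuffled and the whole
   chain recomputed to get exact two-tailed p-values for group differences,
   per cost or on cost-averaged (AUC-mean) values.
6. **Dorsal/ventral disparity** — nodes classified by centroid Z against
   the median; significant nodes split by difference sign and location,
   plus an efficiency-vs-degree interaction model
   `E(i) = β₀ + β₁D(i) + β₂G(i) + β₃D(i)G(i) + ε`.

A synthetic-cohort generator (`thicknet.simulate`) produces two-group
cohorts with age/gender confounds and block-structured inter-regional
covariance — including plantable dorsal/ventral alterations — so the whole
pipeline is testable without subject data.

## Worked example

```python
import thicknet as tn

# a 148-ROI, 35+32-subject cohort with modular covariance (no group effect)
spec = tn.modular_spec(within_r=0.5, seed=11)
cohort = tn.generate_cohort(spec)

res = tn.residualize(cohort)                     # age, gender, mean thickness
net = tn.correlation_network(res, 1)             # group-1 network
grid = tn.CostGrid.from_range(0.05, 0.45, 0.05)
nets = tn.build_cost_profile(net, grid)
prof = tn.compute_profile(nets, grid)
print(f"mean E_glob = {prof.mean_e_glob:.3f}, mean E_loc = {prof.mean_e_loc:.3f}")

sw = tn.small_world_assessment(nets, grid, n_null=50, seed=3)
print("small-world at all costs:", bool((sw.glob_sandwich & sw.loc_sandwich).all()))
```

prints

```
mean E_glob = 0.588, mean E_loc = 0.751
small-world at all costs: True
```

i.e. the synthetic covariance network transfers information almost as
efficiently as a random graph while keeping lattice-like local
interconnectivity — the economic small-world regime — at every cost
examined.  The same chain with `permutation_test` / `disparity_summary`
localizes planted group differences; see `examples/` for one script per
capability.

There is also a thin CLI (`thicknet simulate | network | efficiency |
permtest | report`); `thicknet report` runs everything and writes all
tables plus a `summary.yaml` into a run directory.

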