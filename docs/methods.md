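# Methods

## Scope and model

`fcnet` implements a weighted graph-theory analysis of resting-state
functional connectivity for a two-group (case vs. control) cohort design,
of the kind used to study mild traumatic brain injury. The package starts
from ROI-averaged time series (preprocessing of imaging data is out of
scope) and runs four stages:

1. **Network construction.** Edges are Pearson correlations between
   regional time series (no Fisher r-to-z transform on edges). Age and sex
   are removed edge-wise across the pooled cohort with an OLS general
   linear model, negative weights are set to zero, and the positive matrix
   is proportionally thresholded: sparsity `s` is the retained edge count
   over `N(N-1)/2`, and thresholding keeps the `round(s·N(N-1)/2)`
   strongest edges with their weights (no binarisation). The group
   sparsity is selected as the smallest `s` at which *every* subject's
   network forms a single connected component (network cost minimised
   while all nodes connected); the minimum over subjects (first subject to
   connect) is reported alongside. Both are reported at 0.1% resolution.
2. **Graph measures.** Betweenness centrality (Brandes' algorithm on
   lengths `L = 1/w`, fractional counting over equal-length shortest
   paths, normalised by `(N-1)(N-2)`), strength (sum of weights), Onnela
   triangle-intensity clustering on max-scaled weights, global efficiency
   (mean inverse shortest-path length over ordered pairs, unreachable
   pairs contributing zero), and local efficiency (global efficiency of
   each node's neighbour subgraph). Each measure is computed at the
   selected sparsity and, optionally, integrated over the 8–26% grid in 1%
   steps (trapezoidal AUC) to remove single-threshold dependence.
3. **Group inference.** Nodal measures: label-permutation null of pooled
   two-sample t values (case minus control), two-tailed nearest-rank
   2.5/97.5 percentile rule, no multiplicity correction by default
   (optional BH-FDR switch). Global efficiency: the same null with a
   one-tailed lower 5th-percentile rule. Node-averaged measures: one-sided
   Wilcoxon rank-sum (a one-sided two-sample t is available as a switch).
   Cognitive t-scores: one-sided two-sample t; clinical scores: two-sided.
4. **Brain–behavior analysis.** Pearson correlation of each nodal measure
   with each of 16 cognitive subtests per group; BH-FDR within the
   16-subtest family for one (node, measure, group); FDR-significant pairs
   proceed to the two-sample Fisher-z difference
   `z_diff = (atanh r_case − atanh r_control) / sqrt(1/(n_case−3) + 1/(n_control−3))`,
   assessed against a label-permutation null (pseudo-correlations
   recomputed per shuffle, two-sided empirical p with the
   `(1+exceedances)/(n_perm+1)` estimator), with the analytic normal p
   reported alongside; plus a sensitivity rerun after median-absolute-
   deviation outlier screening (2.5 robust SDs, consistency factor 1.4826).

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| sparsity grid | 8–26% step 1% (19 levels) | standard proportional-threshold band for ~100-node functional networks |
| fixed sparsity | 26.2% | representative all-subjects-connected level for this design |
| permutations | 10,000 | percentile resolution 0.01% at the 2.5/97.5 rule |
| percentile rule | nearest rank | exact and unambiguous on a sorted null of 10,000 |
| FDR q | 0.05 | conventional |
| MAD multiplier | 2.5 | the moderately conservative robust-screening recommendation |
| length mapping | L = 1/w | toolbox convention for strength-to-length conversion |
| BC normalisation | (N−1)(N−2), ordered pairs | yields values in [0,1] comparable across N |

Design choices made where the procedure was genuinely open:

- **Residualise, then rectify.** The order of age/sex removal and
  negative-edge removal is ambiguous in verbal descriptions of such
  pipelines; regressing on uncensored edge values avoids fitting to
  clipped data, so residualise-first is the default
  (`residualize_before_rectify` switches the order).
- **Edge-wise pooled residualisation, grand mean restored.** The GLM is
  fitted per edge across all subjects with groups pooled; the fitted value
  at the covariate mean is added back so edge means are preserved.
  Per-group residualisation is possible by running the pipeline per group.
- **Local efficiency variant.** The default is the neighbour-subgraph
  (Latora–Marchiori) form — the literal reading of "inverse shortest path
  length between the direct neighbours of a node when it is removed". The
  cube-root weighted toolbox form is available via
  `eloc_variant="toolbox"`.
- **Node-averaged global comparison.** Rank-sum is the default; the
  one-sided t alternative exists because both conventions circulate for
  this comparison.
- **Tie-breaking.** Ties at the proportional-threshold cutoff are broken
  by lexicographic (i, j) edge order — deterministic, and measure-zero for
  real-valued correlation weights. Edge counts use round-half-up.
- **`min_connecting_sparsity` searches at single-edge resolution** (binary
  search over the retained-edge count, valid because the largest-component
  size is nondecreasing in the edge count); a grid step would only
  coarsen an exact search.
- **Degenerate inputs.** An empty graph has largest component size 1; a
  node with no positive edges makes full connection unreachable (sentinel
  `inf`, error at group level naming the subjects); zero pooled variance
  gives t = 0 with a warning; MAD = 0 keeps all points with a warning;
  permutations with |r| → 1 in the z-difference null are redrawn and
  counted.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes: 112 nodes in 7 contiguous modules (echoing canonical large-scale
resting-state networks), within/between-module correlations 0.45/0.12,
150 i.i.d. multivariate-normal time samples per subject, 29 subjects per
group, uniform ages 20–70 with alternating sexes, and optional

- row/column attenuation of chosen effect nodes' couplings in the case
  group (PSD repaired by eigenvalue clipping with diagonal
  renormalisation when attenuation breaks it, reported by warning);
- rank-one edge confounding from a latent signal mixed into all nodes
  with coefficient linear in age and sex — the structure edge
  residualisation is designed to remove;
- cognitive t-scores (mean 50, sd 10) for 16 subtests, with one score
  optionally coupled to a standardized nodal measure in the case group
  only (`slope = r·sd_noise/√(1−r²)` maps a target population correlation
  onto the slope/noise pair).

It deliberately does **not** model temporal autocorrelation, hemodynamics,
motion or scanner noise, or lesions: the pipeline consumes Pearson
correlations only, so i.i.d. samples with the required covariance are the
simplest sufficient model. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the assumed
correlation structure — not that the pipeline is robust to realistic fMRI
artefacts.

## Numerical and statistical notes

- Distances for the efficiency measures come from a vectorised min-plus
  (Floyd–Warshall) recursion; betweenness uses per-source Dijkstra with
  path-multiplicity counts. Both are validated against independent
  implementations and brute-force path enumeration to 1e−9.
- All permutation machinery hangs off one master seed: numpy
  `SeedSequence` substreams give every (measure, node) null an
  independent, reproducible stream, so a report regenerates
  bit-identically.
- The permutation test for the z-difference is exactly calibrated by
  construction (measured null rejection ≈5% at α = 0.05), but its
  conditional null has spread ≠ 1 at n ≈ 29 per group, so the analytic
  normal p agrees with the empirical p only asymptotically (they match
  closely by n ≈ 200 per group). Both are reported.
- BH-FDR adjustment is monotone and order-preserving but not idempotent;
  adjusted values are capped at 1.
- Monte-Carlo experiment sizes (200 null replicates for calibration, 100
  for effect recovery, 50 for behavior recovery, 1,000 permutations inside
  replicated loops) are chosen so the full experiment suite runs on a
  single CPU at desk scale; single analyses default to 10,000
  permutations.

## Known limitations

- The AAL-based 112-region node table is a reconstruction (90 cerebral
  regions, 18 cerebellar lobules, 4 vermis regions) with six-lobe labels;
  region identities matter only for report readability, not for any
  computation.
- Negative-weight network analysis is out of scope (edges are rectified).
- The unplanted-node false-positive rate under planted attenuation is
  slightly above nominal by construction: attenuating a node's row also
  weakens its edges into unplanted nodes, a real spillover rather than a
  test defect.
- Statistical power figures quoted by the experiments refer to the
  synthetic conditions above; real data with weaker module structure or
  fewer timepoints will differ.
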