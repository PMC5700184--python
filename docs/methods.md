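# Methods

This note documents the models, conventions and design choices behind
`modcart`, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the genuinely open choices were resolved.

## Graph construction

Nodes are points with 3-D coordinates in millimetres, normally a regular
lattice (`generate_lattice_nodes`) emulating a down-sampled voxel grid
(default spacing 6 mm). For one subject:

1. **Correlation.** Pairwise Pearson correlation of nodal time series
   (≥ 3 timepoints; zero-variance rows are an error naming the node).
2. **Distance exclusion.** Pairs closer than 20 mm (default) are ineligible
   for edges, guarding against motion artefacts and shared non-biological
   signal in real data. The cutoff is strict "closer than": a pair at
   exactly 20 mm is eligible. The mask defines eligibility *before*
   proportional ranking.
3. **Proportional thresholding.** Among eligible pairs, the
   `floor(fraction × n_eligible)` largest positive correlations become
   edges. Defaults are five fractions (0.10–0.30), producing five nested
   graphs of fixed density per subject; metrics are computed per graph and
   averaged afterwards, which makes the resulting measures robust over a
   range of thresholds. Conventions the literature leaves open, fixed here
   deterministically: floor rounding of the edge count; ties at the cut
   broken by lexicographic node-index order; negative correlations never
   retained (with the fraction still taken of *all* eligible pairs — at
   densities ≤ 30 % the cut does not normally reach them); a shortage of
   positive pairs keeps all positives and warns with the achieved density.
   Binary graphs (weights 1) are the main variant; the weighted variant
   keeps the raw positive correlation as weight (no Fisher-z transform).

## Community detection

Global modularity of a partition is
`Q = Σ_s [l_ins/L − (k_s/2L)²]`; weighted graphs replace edge counts and
degrees by weight sums and strengths. Q is undefined (error) on an empty
graph; a single-module partition always has Q = 0.

`louvain` implements the two-phase procedure: starting from all-singleton
modules, a greedy local-move phase sweeps nodes in a seeded random
permutation (a fixed sweep order can get stuck systematically) and
reassigns each node to the neighbouring module with the largest modularity
gain, ties broken toward the lowest module id; an aggregation phase then
collapses modules into meta-nodes (self-loops carry internal weight), and
the cycle repeats until a full pass improves Q by less than 1e-10. Isolated
nodes — possible at 10 % density — remain singleton modules and contribute
0 to Q; the module census counts them by default, with a flag to exclude
them.

Greedy Louvain only finds local maxima, so `louvain` is best-of-`n_restarts`
(default 5) seeded runs, each ending with one extra local-move pass at the
finest level (a single node may profitably leave a merged module that the
aggregated meta-graph can no longer split). For graphs of ≤ 32 nodes two
further safeguards apply, because at that scale greedy search demonstrably
misses the optimum on a small but real fraction of graphs (e.g. a chain
whose optimal cut is absorbed by an early pairwise merge — no number of
singleton-start restarts recovers it): a Kernighan–Lin-style refinement
(sequences of single-node moves that may be individually Q-decreasing,
keeping the best prefix; O(n³) per round, negligible at this size), applied
both to each restart's result and to two deterministic extra starts (the
one-module and the all-singletons partitions). With these, the search
matched the exhaustive optimum on 1300/1300 random graphs of 4–8 nodes
across 13 independent streams. `brute_force_max_q` enumerates all set
partitions (refusing > 10 nodes; Bell-number growth) and serves as the
independent oracle in tests.

## Nodal metrics and cartography

- Participation coefficient `p_i = 1 − Σ_m (k_i(m)/k_i)²` with `k_i(m)` the
  edges (strengths) from node *i* into module *m*, summed over all modules —
  the standard Guimerà–Amaral definition, which gives the correct limits
  (0 all-intra; → 1 − 1/|M| uniform spread). Nodes with `k_i = 0` get
  p = 0 by convention.
- Within-module degree `z_i` standardises a node's intra-module degree by
  the mean and **population** SD (divisor N) of its module's intra-module
  degree distribution, following the Guimerà–Amaral convention. Modules
  with zero SD (including singletons) give z = 0 for all members.
- The seven node roles tile the (p, z) plane: hubs are `z ≥ 1`; non-hub
  bins at p ≤ 0.05 / ≤ 0.62 / ≤ 0.80 / > 0.80, hub bins at p ≤ 0.30 /
  ≤ 0.75 / > 0.75, all upper-inclusive. The non-hub peripheral range is
  implemented as 0.05 < p ≤ 0.62 so the four non-hub bins tile [0, 1]
  without gap or overlap.
- Per-subject summaries: nodal maps are averaged element-wise across the
  five thresholds; node-type proportions are computed per threshold and the
  *fractions* averaged (a flag instead classifies the threshold-averaged
  map, for sensitivity analysis — the two orders differ when nodes cross
  bin boundaries between thresholds); the four global measures (Q, number
  of modules, mean module size, population SD of module size) are computed
  per threshold and averaged.

## Synthetic cohorts

The generator exists so every stage is testable without imaging data. It
emulates the statistical structure the pipeline consumes — not fMRI
physics.

**Signals.** Node signals follow a factor model: node *i* in planted module
*s* is `x = a·f_s + b·g + c·ε` with a module factor, a global factor and
private noise (all standard normal), and `a² = within − between`,
`b² = between`, `c² = 1 − within`. This yields *exactly* the requested
equicorrelation pattern (within-module correlation `within`, between-module
`between`) and is positive semi-definite by construction for
`0 ≤ between ≤ within < 1`. Signals are Gaussian and serially independent:
the pipeline only consumes Pearson correlations, which Gaussianity
suffices to exercise. No haemodynamics, autocorrelation, motion or scanner
drift are modelled — passing tests demonstrate correctness of the graph
and inference machinery, not robustness to fMRI artefacts.

**Cohorts.** Subjects get an FSIQ-like trait (default mean 99.12, SD 13.23,
matching a healthy adult community sample), ages uniform on 18–60, binary
sex, and three-level handedness (85/7/8 %), all independent of the trait.
Trait–metric coupling at a target node cluster perturbs the cluster nodes'
factor loadings monotonically with a latent score
`u = r′·trait_z + √(1−r′²)·η`: for participation effects, the share of
coupled variance carried by the global factor follows a logistic curve in
`u` (moving connectivity between the node's module and the rest of the
network at constant total coupling); for within-module-degree effects, the
module-factor share relative to private noise does. Mixing (rather than
edge rewiring) was chosen because it acts at the generative level the rest
of the pipeline consumes and keeps the signal model exactly Gaussian. The
measured metric attenuates the latent correlation (finite scan length,
graph estimation noise); a one-time empirical calibration at the default
configuration (48 nodes, 4 modules, 120 timepoints, 5 thresholds) measured
attenuation 0.73 (p) and 0.79 (z), compensated by a single constant 0.76,
giving achieved correlations within ±0.1 of request on average over seeds
at n = 200. Requests with |r′| > 0.99 are clipped with a warning.

**Metric-map cohorts.** For testing the association statistics at realistic
node counts, `generate_metric_cohort` bypasses the graph pipeline and draws
per-subject nodal maps directly as stationary smooth Gaussian random fields
on the lattice (white noise convolved with a Gaussian kernel, default FWHM
2 voxels — about the smoothness real metric maps inherit from spatially
smoothed data — under periodic boundary conditions, rescaled by the exact
kernel norm to unit pointwise variance), with trait effects injected so
the population trait–node correlation equals the request exactly. The
recovery and familywise-error studies run at an 8×8×8 lattice (512 nodes)
with 200 subjects per cohort; pushing tens of thousands of subject-graphs
through Louvain for those studies would be computationally disproportionate,
and the trait-coupled time-series route is validated separately at smaller
node counts.

## Association statistics

- **Outliers:** subjects beyond 3 sample SDs from the mean of the variable
  of interest are excluded, mean/SD computed once (not iteratively),
  analysis-wise per variable; at small n the 3 SD rule is permissive by
  design (a sample of (0,0,0,0,100) retains everyone).
- **Partial correlation:** Pearson correlation of the residuals of both
  variables after least-squares regression on covariates + intercept;
  two-sided p from t with `n − 2 − n_cov` degrees of freedom. Categorical
  covariates (handedness) are dummy-coded. A variable perfectly explained
  by covariates yields r = 0 with a warning; collinear covariates are an
  error naming the columns.
- **Bayes factors:** `BF01` compares the covariates-only regression against
  covariates + predictor under the JZS prior — Cauchy on the standardised
  effect, equivalently a normal prior with an inverse-gamma(1/2, 1/2)
  mixture on its scale — computed from the partial t statistic by
  quadrature (non-convergence raises with diagnostics). The prior scale
  defaults to √2/4, the conventional default for a single regression
  effect, and is exposed as a parameter. BF01 > 3 is read as substantial
  evidence for the null. Whole-brain association tables report raw p
  values; the significance flag uses a Bonferroni-adjusted threshold per
  measure family (0.05/4 for the four global measures, 0.05/7 for the
  seven node-type proportions).
- **Nodewise regression:** mass-univariate OLS of each node's metric on
  trait + covariates + intercept, returning the trait coefficient's t per
  node (constant nodes get t = 0, flagged). The regression t equals the t
  implied by the partial correlation at matching degrees of freedom — an
  identity the tests check to 1e-8.
- **Cluster-extent correction:** the t map is thresholded at a two-sided
  voxel-level p (default 0.005) and face-connected (6-neighbour — the
  conservative connectivity) clusters of at least k nodes are declared
  significant. k is the smallest extent whose familywise probability under
  null fields is ≤ 0.05, estimated from (default) 10,000 Monte-Carlo
  smooth Gaussian fields on the lattice, thresholded per tail with
  clusters formed within a tail. Field smoothness is estimated from the
  regression residual maps by inverting the lag-1 spatial autocorrelation
  of a kernel-smoothed white-noise field (axes averaged; unsmoothed data
  give 0). Both the simulator and the smoothness estimator use periodic
  boundary conditions, keeping the null field exactly stationary on the
  lattice and the two mutually consistent. Because cluster sizes are
  integers, the realised familywise rate sits at or below the nominal 5 %.
- **Conjunction:** the signed significant-cluster masks of the p and z
  analyses are intersected node-wise and re-segmented into face-connected
  components of homogeneous sign pattern (e.g. p-positive/z-negative).

## Numerical and I/O conventions

All randomness flows from explicit per-call seeds (numpy `SeedSequence`
substreams; no global RNG state). CSV uses '.' decimal, comma separator,
mandatory header, `%.17g` floats (lossless for float64; readers use
pandas' round-trip parser, as the default C parser is off by 1 ulp);
adjacency is Matrix Market with a JSON sidecar; partitions are JSON;
optional NIfTI-1 export maps lattice quantities to volumes with the
spacing in the affine. Pipeline runs are driven by a YAML config; the
manifest records the config hash, seed and a checksum per output, and
re-running an identical config reproduces byte-identical outputs.

## Problem sizes in the test suite

Unit tests run on graphs of 2–100 nodes. The oracle-equivalence study uses
100 random graphs of 4–8 nodes against exhaustive enumeration. Planted
partition studies use 100-node graphs (4 modules of 25) over 20 seeds.
Cohort calibration uses 48-node lattices with 200 subjects over 20 seeds
through the full graph pipeline; recovery and error-control studies use
512-node lattices with 200 subjects per cohort (50 effect replicates, 200
null replicates) on metric-map cohorts. These sizes were chosen as the
smallest at which the respective statistical claims are meaningful.

## Known limitations

- The generator's correlation structure is equicorrelated within/between
  modules; real connectomes have heterogeneous, distance-dependent
  correlations. Distance exclusion is therefore exercised geometrically,
  not statistically.
- Modularity maximisation has a resolution limit; small true modules may
  be absorbed. No consensus clustering or resolution sweeps are provided.
- The t-statistic JZS Bayes factor is the standard single-effect
  formulation; software implementing full Bayesian model averaging over
  regression models can give somewhat different values.
- Cluster-extent simulation assumes stationary Gaussian null fields on a
  full rectangular lattice; irregular masks (real grey-matter geometry)
  are not supported.
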