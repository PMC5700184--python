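# modcart

Modular brain-network analysis for resting-state-style data: subject-specific
graph construction, Louvain community detection, nodal connectivity
cartography, and cross-subject brain–behaviour association statistics — with a
synthetic-cohort generator so the whole pipeline is testable end to end
without any imaging data.

## Who this is for

Researchers studying how the modular organisation of functional brain networks
relates to individual differences in behaviour (e.g. an intelligence score).
The package models each subject's brain as a graph whose nodes are grid
points ("voxels") with physical coordinates and whose edges are strong
positive correlations between nodal time series, then asks two questions:

1. Are *whole-brain* features of modular organisation (global modularity,
   number/size of modules, proportions of node roles) associated with the
   behavioural trait?
2. Are *node-specific* features — between-module and within-module
   connectivity — associated with the trait in circumscribed clusters of
   nodes?

## The model

For each subject, pairwise Pearson correlations between nodal time series are
computed; physically short edges (< 20 mm) are excluded; and the strongest 10,
15, 20, 25 and 30 % of eligible positive correlations are retained, giving
five binarised graphs of fixed density per subject (a weighted variant keeps
the correlation values as edge weights). Modules are detected per graph by
Louvain maximisation of the global modularity

```
Q = Σ_s [ l_ins / L − (k_s / 2L)² ]
```

(`l_ins` edges inside module *s*, `L` total edges, `k_s` total degree of
module *s*; Q > 0.3 conventionally indicates modular structure). Each node *i*
is then characterised by

- the **participation coefficient** `p_i = 1 − Σ_m (k_i(m)/k_i)²` —
  between-module connectivity; 0 if all edges stay in the node's own module;
- the **within-module degree** `z_i = (k_i(m_i) − k̄(m_i)) / σ_k(m_i)` —
  within-module connectivity, standardised within the node's module;

and classified into one of seven functional-cartography roles (ultra-
peripheral, peripheral, non-hub connector, non-hub kinless, provincial hub,
connector hub, kinless hub) from its (p, z) pair, with hubs defined by
`z ≥ 1`. Metrics are averaged across the five density thresholds per subject.

Cross-subject inference covers both questions: partial correlations of
whole-brain measures with the trait (controlling age, sex, handedness),
JZS default-prior Bayes factors `BF01` quantifying evidence *for* the null,
and mass-univariate nodewise regression of the p and z maps on the trait with
Monte-Carlo cluster-extent correction on the node lattice (smooth Gaussian
null fields, face adjacency), plus a conjunction analysis of clusters showing
effects in both measures.

## Worked example

```python
from modcart import (
    PlantedDesign, generate_lattice_nodes, generate_modular_timeseries,
    correlation_matrix, distance_mask, build_graph_set, louvain,
    metric_map, average_across_thresholds, global_summaries,
    node_type_proportions,
)

nodes = generate_lattice_nodes(5, 5, 4, spacing_mm=6.0)      # 100-node lattice
design = PlantedDesign(module_sizes=(25, 25, 25, 25),
                       within_corr=0.5, between_corr=0.1)
panel = generate_modular_timeseries(nodes, design, n_timepoints=120, seed=0)

corr = correlation_matrix(panel)
mask = distance_mask(nodes, min_dist_mm=20.0)
graphs = build_graph_set(corr, mask)                          # five densities

partitions = [louvain(g, seed=i) for i, g in enumerate(graphs)]
maps = [metric_map(g, part) for g, part in zip(graphs, partitions)]
mean_map = average_across_thresholds(maps)
summary = global_summaries(partitions)

print(f"Q = {summary.q:.3f}, modules = {summary.n_modules:.1f}, "
      f"mean size = {summary.avg_module_size:.1f} +/- {summary.sd_module_size:.1f} nodes")
print(f"mean participation p = {mean_map.p.mean():.3f}, "
      f"hub fraction (z >= 1) = {(mean_map.z >= 1).mean():.2f}")
```

prints

```
Q = 0.486, modules = 9.6, mean size = 12.3 +/- 12.7 nodes
mean participation p = 0.182, hub fraction (z >= 1) = 0.14
```

The threshold-averaged Q of 0.486 is well above the 0.3 modularity
convention — the planted four-module structure is clearly detected. The
module count of 9.6 includes the four planted modules plus isolated-node
singletons at the sparsest thresholds (a flag excludes them from the census);
the large size SD reflects exactly that mix. Low mean participation (0.18)
says most edges stay within modules, as planted.

## Full pipeline runs

A single YAML config drives end-to-end runs (synthetic cohort → graphs →
partitions → metrics → cartography → association tables) with a manifest of
seeds and output checksums; re-running an identical config reproduces
byte-identical outputs:

```
modcart validate config.yaml
modcart all config.yaml          # or stagewise: simulate, build-graphs,
                                 # detect-modules, metrics, cartography, associate
```

Outputs include per-subject metric maps (CSV, optional NIfTI), a whole-brain
association table (partial r, p, BF01 per measure), per-metric t-maps and
cluster tables (peak coordinates, t_max, extent k, sign), and the p∩z
conjunction clusters.

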