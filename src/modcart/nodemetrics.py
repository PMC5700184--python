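"""Nodal participation coefficient, within-module degree, and whole-brain
modular summaries.

Given a graph and a module partition, each node *i* is characterised by

* the **participation coefficient** ``p_i = 1 - sum_m (k_i(m)/k_i)^2``,
  where ``k_i`` is the degree of node *i* and ``k_i(m)`` the number of its
  edges ending in module *m*: 0 when all edges stay inside the node's own
  module, approaching ``1 - 1/|M|`` when edges spread uniformly over
  modules (between-module connectivity);
* the **within-module degree** ``z_i = (k_i(m_i) - kbar(m_i)) / sigma(m_i)``,
  the node's intra-module degree standardised against the mean and
  *population* standard deviation of intra-module degree within its own
  module (within-module connectivity).

Weighted graphs use strengths in place of degrees throughout. Community
detection and metric computation happen separately per density threshold;
:func:`average_across_thresholds` then forms each subject's mean maps, and
:func:`global_summaries` threshold-averages the four whole-brain measures
(Q, number of modules, average module size, SD of module size).
"""

from __future__ import annotations

import numpy as np

from .core import BrainGraph, GlobalMeasures, ModulePartition, NodalMetricMap

__all__ = [
    "participation_coefficient",
    "within_module_degree",
    "metric_map",
    "global_summaries",
    "average_across_thresholds",
]


def _module_degree_matrix(graph: BrainGraph, labels: np.ndarray) -> np.ndarray:
    """(n_nodes, n_modules) matrix of per-node edge weight into each module."""
    n_modules = int(labels.max()) + 1
    onehot = np.zeros((labels.size, n_modules))
    onehot[np.arange(labels.size), labels] = 1.0
    return graph.adjacency @ onehot


def participation_coefficient(graph: BrainGraph, partition) -> np.ndarray:
    """Participation coefficient per node (strength-based when weighted).

    Nodes with no edges have an undefined coefficient; by convention they
    get p = 0 (they participate in nothing).
    """
    labels = partition.labels if isinstance(partition, ModulePartition) else np.asarray(partition, int)
    k_im = _module_degree_matrix(graph, labels)
    k = k_im.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - np.sum((k_im / np.where(k == 0, 1.0, k)[:, None]) ** 2, axis=1)
    p[k == 0] = 0.0
    return p


def within_module_degree(graph: BrainGraph, partition) -> np.ndarray:
    """Within-module degree z-score per node.

    Standardisation uses the population SD (divisor N) of the intra-module
    degree distribution of the node's own module. Modules whose members all
    share the same intra-module degree (SD 0, including singletons) get
    z = 0 for every member by convention.
    """
    labels = partition.labels if isinstance(partition, ModulePartition) else np.asarray(partition, int)
    k_im = _module_degree_matrix(graph, labels)
    k_within = k_im[np.arange(labels.size), labels]
    z = np.zeros(labels.size)
    for m in range(int(labels.max()) + 1):
        members = labels == m
        vals = k_within[members]
        sd = vals.std()  # population SD
        if sd > 0:
            z[members] = (vals - vals.mean()) / sd
    return z


def metric_map(graph: BrainGraph, partition) -> NodalMetricMap:
    """Both nodal metrics for one graph/partition, as a single map."""
    return NodalMetricMap(
        nodes=graph.nodes,
        p=participation_coefficient(graph, partition),
        z=within_module_degree(graph, partition),
        thresholds_averaged=1,
    )


def global_summaries(
    partitions: list[ModulePartition],
    count_singletons: bool = True,
) -> GlobalMeasures:
    """Threshold-averaged whole-brain measures of modular organisation.

    For each partition (one per density threshold) compute Q, the number of
    modules, the mean module size and the population SD of module sizes,
    then average each measure across thresholds. ``count_singletons=False``
    drops single-node modules (isolated nodes at sparse thresholds) from
    the module census before summarising.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    qs, counts, means, sds = [], [], [], []
    for part in partitions:
        sizes = (
            part.module_sizes()
            if count_singletons
            else part.module_sizes_excluding_singletons()
        )
        if sizes.size == 0:
            raise ValueError("partition has no modules to summarise")
        qs.append(part.q)
        counts.append(sizes.size)
        means.append(sizes.mean())
        sds.append(sizes.std())  # population SD: variability of module size
    return GlobalMeasures(
        q=float(np.mean(qs)),
        n_modules=float(np.mean(counts)),
        avg_module_size=float(np.mean(means)),
        sd_module_size=float(np.mean(sds)),
    )


def average_across_thresholds(maps: list[NodalMetricMap]) -> NodalMetricMap:
    """Element-wise mean of p and z maps across density thresholds."""
    if not maps:
        raise ValueError("need at least one metric map")
    nodes = maps[0].nodes
    for m in maps[1:]:
        if m.nodes != nodes:
            raise ValueError("metric maps are defined over different NodeSets")
    return NodalMetricMap(
        nodes=nodes,
        p=np.mean([m.p for m in maps], axis=0),
        z=np.mean([m.z for m in maps], axis=0),
        thresholds_averaged=int(sum(m.thresholds_averaged for m in maps)),
    )
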