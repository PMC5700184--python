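"""Functional cartography: node-role classification in the (p, z) plane.

Following the Guimera-Amaral scheme, nodes with within-module degree
``z >= 1`` are hubs, nodes with ``z < 1`` non-hubs, and the participation
coefficient subdivides each stratum:

non-hubs
    ultra-peripheral ``p <= 0.05`` | peripheral ``0.05 < p <= 0.62`` |
    non-hub connector ``0.62 < p <= 0.80`` | non-hub kinless ``p > 0.80``
hubs
    provincial ``p <= 0.30`` | connector ``0.30 < p <= 0.75`` |
    kinless ``p > 0.75``

The seven categories tile the (p, z) plane: every ``p`` in [0, 1] with any
finite ``z`` maps to exactly one type. Classification happens per density
threshold, with the per-type proportions averaged across thresholds
afterwards (a flag enables classifying the threshold-averaged map instead,
for sensitivity analysis).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .core import NodalMetricMap

__all__ = [
    "NodeType",
    "classify_node",
    "classify_map",
    "node_type_proportions",
    "HUB_Z_THRESHOLD",
]

HUB_Z_THRESHOLD = 1.0

# Upper p-bin edges (inclusive) for the non-hub and hub strata.
_NONHUB_EDGES = (0.05, 0.62, 0.80)
_HUB_EDGES = (0.30, 0.75)


class NodeType(str, Enum):
    ULTRA_PERIPHERAL = "ultra_peripheral"
    PERIPHERAL = "peripheral"
    NON_HUB_CONNECTOR = "non_hub_connector"
    NON_HUB_KINLESS = "non_hub_kinless"
    PROVINCIAL_HUB = "provincial_hub"
    CONNECTOR_HUB = "connector_hub"
    KINLESS_HUB = "kinless_hub"


_NONHUB_TYPES = (
    NodeType.ULTRA_PERIPHERAL,
    NodeType.PERIPHERAL,
    NodeType.NON_HUB_CONNECTOR,
    NodeType.NON_HUB_KINLESS,
)
_HUB_TYPES = (
    NodeType.PROVINCIAL_HUB,
    NodeType.CONNECTOR_HUB,
    NodeType.KINLESS_HUB,
)


def classify_node(p: float, z: float) -> NodeType:
    """Node type for a single (p, z) pair.

    Bin edges are inclusive on the upper side (e.g. p = 0.30 with z >= 1
    is a provincial hub); p must lie in [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"participation coefficient must lie in [0, 1], got {p}")
    if z >= HUB_Z_THRESHOLD:
        edges, types = _HUB_EDGES, _HUB_TYPES
    else:
        edges, types = _NONHUB_EDGES, _NONHUB_TYPES
    for edge, node_type in zip(edges, types):
        if p <= edge:
            return node_type
    return types[-1]


def classify_map(metric_map: NodalMetricMap) -> np.ndarray:
    """Vectorised classification of a whole metric map.

    Returns an object array of :class:`NodeType` per node.
    """
    p, z = metric_map.p, metric_map.z
    if np.any((p < 0) | (p > 1)):
        raise ValueError("participation coefficients must lie in [0, 1]")
    out = np.empty(p.size, dtype=object)
    hubs = z >= HUB_Z_THRESHOLD
    for mask, edges, types in (
        (hubs, _HUB_EDGES, _HUB_TYPES),
        (~hubs, _NONHUB_EDGES, _NONHUB_TYPES),
    ):
        bins = np.digitize(p[mask], edges, right=True)
        out[np.flatnonzero(mask)] = np.array(types, dtype=object)[bins]
    return out


def _proportions_one(metric_map: NodalMetricMap) -> dict[NodeType, float]:
    types = classify_map(metric_map)
    n = types.size
    return {t: sum(x is t for x in types) / n for t in NodeType}


def node_type_proportions(
    maps: list[NodalMetricMap],
    classify_averaged: bool = False,
) -> dict[NodeType, float]:
    """Whole-brain node-type proportions for one subject.

    By default, nodes are classified separately for each per-threshold map
    and the per-type fractions averaged across thresholds. With
    ``classify_averaged=True`` the maps are first averaged element-wise and
    the averaged (p, z) map classified once.
    """
    if not maps:
        raise ValueError("need at least one metric map")
    if classify_averaged:
        from .nodemetrics import average_across_thresholds

        return _proportions_one(average_across_thresholds(maps))
    per_threshold = [_proportions_one(m) for m in maps]
    return {
        t: float(np.mean([frac[t] for frac in per_threshold])) for t in NodeType
    }
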