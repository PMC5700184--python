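"""Per-subject graph construction from node time series.

The construction mirrors the standard resting-state connectome recipe:

1. pairwise Pearson correlation of node signals;
2. exclusion of physically short edges (Euclidean distance below a cutoff,
   20 mm by default) as motion/shared-signal safeguards;
3. proportional thresholding — retain the strongest positive correlations
   so that every subject's graph has the same edge density — at five
   density levels (10, 15, 20, 25, 30 % of eligible pairs), binarised for
   the main analyses or keeping positive r as weights for the weighted
   variant.

Conventions (the literature leaves these open): the retained edge count is
``floor(fraction * n_eligible_pairs)``; ties at the cut are broken by
lexicographic node-index order; pairs at exactly the distance cutoff are
eligible (the exclusion is strictly "closer than"); negative correlations
are never retained, and the fraction is taken of all eligible pairs, not of
positive pairs only.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import BrainGraph, CorrelationMatrix, NodeSet, TimeSeriesPanel

__all__ = [
    "correlation_matrix",
    "distance_mask",
    "proportional_threshold",
    "build_graph_set",
    "DEFAULT_FRACTIONS",
    "DEFAULT_MIN_DIST_MM",
]

DEFAULT_FRACTIONS: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_MIN_DIST_MM: float = 20.0


def correlation_matrix(panel: TimeSeriesPanel) -> CorrelationMatrix:
    """Pairwise Pearson correlation of the panel's node time series."""
    if panel.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = panel.signals.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance signal for node(s) {flat.tolist()}; "
            "correlation undefined"
        )
    values = np.corrcoef(panel.signals)
    np.clip(values, -1.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(nodes=panel.nodes, values=values)


def distance_mask(nodes: NodeSet, min_dist_mm: float = DEFAULT_MIN_DIST_MM) -> np.ndarray:
    """Boolean eligibility matrix: pairs at Euclidean distance >= cutoff.

    A pair (i, j) is eligible for an edge iff ``i != j`` and the physical
    distance between the nodes is **not** below ``min_dist_mm`` (a pair at
    exactly the cutoff is eligible).
    """
    if min_dist_mm <= 0:
        raise ValueError("min_dist_mm must be positive")
    dist = squareform(pdist(nodes.coords))
    mask = dist >= min_dist_mm
    np.fill_diagonal(mask, False)
    return mask


def _eligible_pairs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(mask.shape[0], 1)
    keep = mask[iu, ju]
    return iu[keep], ju[keep]


def proportional_threshold(
    corr: CorrelationMatrix,
    mask: np.ndarray,
    fraction: float,
    binary: bool = True,
) -> BrainGraph:
    """Retain the strongest positive correlations among eligible pairs.

    Among eligible pairs, the ``floor(fraction * n_eligible)`` largest
    positive correlations become edges (weight 1 if ``binary`` else the
    correlation value). Negative and zero correlations are never retained;
    if there are fewer positive pairs than requested, all positives are
    kept and a warning reports the achieved density.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    n = corr.nodes.n_nodes
    if mask.shape != (n, n):
        raise ValueError("mask shape does not match the correlation matrix")
    iu, ju = _eligible_pairs(np.asarray(mask, dtype=bool))
    n_eligible = iu.size
    if n_eligible == 0:
        raise ValueError("no eligible node pairs under the distance mask")
    r = corr.values[iu, ju]
    n_keep = int(np.floor(fraction * n_eligible))
    positive = r > 0
    n_positive = int(positive.sum())
    if n_positive == 0:
        warnings.warn(
            "no positive correlations among eligible pairs; graph is empty",
            stacklevel=2,
        )
        order = np.empty(0, dtype=int)
    else:
        if n_positive < n_keep:
            warnings.warn(
                f"only {n_positive} positive pairs available for a requested "
                f"{n_keep}; achieved density {n_positive / n_eligible:.4f}",
                stacklevel=2,
            )
            n_keep = n_positive
        # sort by descending r, ties broken by (i, j) lexicographic order
        order = np.lexsort((ju, iu, -r))[:n_keep]
        order = order[r[order] > 0]
    adj = np.zeros((n, n))
    wi, wj = iu[order], ju[order]
    adj[wi, wj] = 1.0 if binary else r[order]
    adj = adj + adj.T
    return BrainGraph(
        nodes=corr.nodes,
        adjacency=adj,
        density_level=float(fraction),
        binary=binary,
    )


def build_graph_set(
    corr: CorrelationMatrix,
    mask: np.ndarray,
    fractions=DEFAULT_FRACTIONS,
    binary: bool = True,
) -> list[BrainGraph]:
    """One graph per density fraction (default: five graphs per subject).

    Fractions must be strictly increasing; because all graphs cut the same
    ranking of correlations, the resulting edge sets are nested.
    """
    fractions = tuple(float(f) for f in fractions)
    if not fractions:
        raise ValueError("need at least one fraction")
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    return [proportional_threshold(corr, mask, f, binary=binary) for f in fractions]
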