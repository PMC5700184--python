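"""Core data containers for modular brain-network analysis.

Nodes are identified by contiguous integer indices ``0..n-1``; every container
carries (or references) the :class:`NodeSet` it is defined over, so that
spatial operations (distance exclusion, cluster-extent inference on the
lattice) always know the physical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NodeSet",
    "TimeSeriesPanel",
    "CorrelationMatrix",
    "BrainGraph",
    "ModulePartition",
    "NodalMetricMap",
    "GlobalMeasures",
]


@dataclass(frozen=True)
class NodeSet:
    """A set of network nodes with 3-D physical coordinates in millimetres.

    Parameters
    ----------
    coords
        ``(n, 3)`` array of node coordinates (mm). Node ids are the row
        indices ``0..n-1``.
    lattice_shape
        Optional ``(nx, ny, nz)`` shape when the nodes form a regular
        lattice (C-order flattening); required for cluster-extent inference.
    spacing_mm
        Lattice spacing in mm, when applicable.
    """

    coords: np.ndarray
    lattice_shape: tuple[int, int, int] | None = None
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("node coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.lattice_shape is not None:
            shape = tuple(int(s) for s in self.lattice_shape)
            if int(np.prod(shape)) != coords.shape[0]:
                raise ValueError(
                    f"lattice shape {shape} does not match {coords.shape[0]} nodes"
                )
            object.__setattr__(self, "lattice_shape", shape)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def __len__(self) -> int:
        return self.n_nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodeSet):
            return NotImplemented
        return (
            self.coords.shape == other.coords.shape
            and np.array_equal(self.coords, other.coords)
            and self.lattice_shape == other.lattice_shape
        )


@dataclass(frozen=True)
class TimeSeriesPanel:
    """One subject's node-by-time signal matrix bound to a :class:`NodeSet`."""

    nodes: NodeSet
    signals: np.ndarray  # (n_nodes, n_timepoints)

    def __post_init__(self) -> None:
        signals = np.asarray(self.signals, dtype=float)
        if signals.ndim != 2:
            raise ValueError("signals must be a 2-D node x time matrix")
        if signals.shape[0] != self.nodes.n_nodes:
            raise ValueError(
                f"signals has {signals.shape[0]} rows for {self.nodes.n_nodes} nodes"
            )
        object.__setattr__(self, "signals", signals)

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric node-by-node matrix of Pearson correlations."""

    nodes: NodeSet
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = self.nodes.n_nodes
        if values.shape != (n, n):
            raise ValueError(f"correlation matrix must be ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(values)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class BrainGraph:
    """Thresholded adjacency over a :class:`NodeSet` at a stated density.

    ``density_level`` is the proportional-threshold fraction used to build
    the graph (e.g. 0.10), or the string ``"custom"`` for graphs built by
    other means (planted-partition fixtures, aggregates).
    """

    nodes: NodeSet
    adjacency: np.ndarray
    density_level: float | str = "custom"
    binary: bool = True

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        n = self.nodes.n_nodes
        if adj.shape != (n, n):
            raise ValueError(f"adjacency must be ({n}, {n})")
        if not np.allclose(adj, adj.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if np.any(adj < 0):
            raise ValueError("edge weights must be nonnegative")
        if self.binary and not np.all(np.isin(adj, (0.0, 1.0))):
            raise ValueError("binary graph adjacency must contain only 0/1")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return self.nodes.n_nodes

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def total_weight(self) -> float:
        """Sum of edge weights, each undirected edge counted once (L)."""
        return float(np.triu(self.adjacency, 1).sum())

    def degrees(self) -> np.ndarray:
        """Node degrees (binary) or strengths (weighted)."""
        return self.adjacency.sum(axis=1)


@dataclass(frozen=True)
class ModulePartition:
    """A node -> module assignment together with its modularity Q.

    Labels are contiguous integers from 0. ``q`` is the global modularity of
    the partition on the graph it was computed for.
    """

    labels: np.ndarray
    q: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        uniq = np.unique(labels)
        if labels.size and not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("module labels must be contiguous integers from 0")
        object.__setattr__(self, "labels", labels)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules)

    def module_sizes_excluding_singletons(self) -> np.ndarray:
        sizes = self.module_sizes()
        return sizes[sizes > 1]


def relabel_contiguous(labels: Sequence[int] | np.ndarray) -> np.ndarray:
    """Map arbitrary module labels to contiguous ids 0..m-1 (order of first
    appearance)."""
    labels = np.asarray(labels)
    _, inverse = np.unique(labels, return_inverse=True)
    # np.unique sorts; re-map to order of first appearance for stability
    order: dict[int, int] = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        key = int(lab)
        if key not in order:
            order[key] = len(order)
        out[i] = order[key]
    return out


@dataclass(frozen=True)
class NodalMetricMap:
    """Per-node participation coefficient (p) and within-module degree (z).

    ``thresholds_averaged`` records over how many density thresholds the map
    has been averaged (1 for a single-threshold map).
    """

    nodes: NodeSet
    p: np.ndarray
    z: np.ndarray
    thresholds_averaged: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        z = np.asarray(self.z, dtype=float)
        n = self.nodes.n_nodes
        if p.shape != (n,) or z.shape != (n,):
            raise ValueError("p and z must be 1-D arrays over the NodeSet")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class GlobalMeasures:
    """Whole-brain summaries of modular organisation, threshold-averaged.

    Fields mirror the four global measures of the analysis: global
    modularity Q, number of modules, average module size and the
    variability (SD) of module size.
    """

    q: float
    n_modules: float
    avg_module_size: float
    sd_module_size: float
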