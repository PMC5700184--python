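"""Readers and writers for on-disk artifacts.

Plain-text conventions throughout: CSV with '.' decimal, comma separator
and a mandatory header row; TSV for signal panels (nodes x time, no
header); JSON for partitions and manifests; Matrix Market for sparse
adjacency; NIfTI-1 (via nibabel) for optional lattice volumes. Node ids
are 0-based; coordinates are millimetres. All writers are deterministic
(stable ordering, ``%.17g`` float formatting, which round-trips float64
exactly).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .core import BrainGraph, ModulePartition, NodalMetricMap, NodeSet, TimeSeriesPanel
from .stats import ClusterResult

__all__ = [
    "write_panel",
    "read_panel",
    "write_coords",
    "read_coords",
    "write_adjacency",
    "read_adjacency",
    "write_partition",
    "read_partition",
    "write_metric_map",
    "read_metric_map",
    "write_cluster_table",
    "read_cluster_table",
    "write_panel_nifti",
    "read_panel_nifti",
    "write_metric_nifti",
    "write_manifest",
    "read_manifest",
    "file_checksum",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# signal panels and coordinates
# ---------------------------------------------------------------------------

def write_panel(panel: TimeSeriesPanel, path) -> None:
    """Write a node x time signal matrix as headerless TSV."""
    np.savetxt(path, panel.signals, delimiter="\t", fmt=_FLOAT_FMT)


def read_panel(path, nodes: NodeSet) -> TimeSeriesPanel:
    """Read a TSV signal panel; rejects ragged rows and NaN cells."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if rows and len(parts) != len(rows[0]):
                raise ValueError(f"{path}: ragged row {i} ({len(parts)} columns)")
            vals = [float(p) for p in parts]
            for j, v in enumerate(vals):
                if not np.isfinite(v):
                    raise ValueError(f"{path}: non-finite value at row {i}, column {j}")
            rows.append(vals)
    return TimeSeriesPanel(nodes=nodes, signals=np.asarray(rows))


def write_coords(nodes: NodeSet, path) -> None:
    """Node coordinates as CSV (id, x, y, z; millimetres)."""
    df = pd.DataFrame(
        {
            "id": nodes.node_ids,
            "x": nodes.coords[:, 0],
            "y": nodes.coords[:, 1],
            "z": nodes.coords[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_coords(path, lattice_shape=None, spacing_mm=None) -> NodeSet:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["id", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if not np.array_equal(df["id"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: node ids must be contiguous from 0")
    return NodeSet(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        lattice_shape=lattice_shape,
        spacing_mm=spacing_mm,
    )


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def write_adjacency(graph: BrainGraph, path) -> None:
    """Sparse adjacency as Matrix Market with a JSON metadata sidecar."""
    path = Path(path)
    mmwrite(str(path), sparse.coo_matrix(graph.adjacency))
    meta = {
        "density_level": graph.density_level,
        "binary": graph.binary,
        "n_nodes": graph.n_nodes,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def read_adjacency(path, nodes: NodeSet) -> BrainGraph:
    path = Path(path)
    adj = np.asarray(mmread(str(path)).todense(), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta["n_nodes"] != nodes.n_nodes:
        raise ValueError(
            f"{path}: adjacency is over {meta['n_nodes']} nodes, "
            f"NodeSet has {nodes.n_nodes}"
        )
    return BrainGraph(
        nodes=nodes,
        adjacency=adj,
        density_level=meta["density_level"],
        binary=meta["binary"],
    )


# ---------------------------------------------------------------------------
# partitions and metric maps
# ---------------------------------------------------------------------------

def write_partition(partition: ModulePartition, path) -> None:
    """Partition as JSON: node-id -> module-id mapping plus Q."""
    payload = {
        "q": partition.q,
        "labels": {str(i): int(lab) for i, lab in enumerate(partition.labels)},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_partition(path) -> ModulePartition:
    payload = json.loads(Path(path).read_text())
    labels_map = payload["labels"]
    n = len(labels_map)
    labels = np.empty(n, dtype=int)
    for key, lab in labels_map.items():
        i = int(key)
        if not 0 <= i < n:
            raise ValueError(f"{path}: unknown node id {key}")
        labels[i] = int(lab)
    return ModulePartition(labels=labels, q=float(payload["q"]))


def write_metric_map(metric_map: NodalMetricMap, path) -> None:
    """Per-node metrics as CSV (node_id, p, z)."""
    df = pd.DataFrame(
        {
            "node_id": np.arange(metric_map.p.size),
            "p": metric_map.p,
            "z": metric_map.z,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_metric_map(path, nodes: NodeSet, thresholds_averaged: int = 1) -> NodalMetricMap:
    df = pd.read_csv(path, float_precision="round_trip")
    if not np.array_equal(df["node_id"].to_numpy(), np.arange(nodes.n_nodes)):
        raise ValueError(
            f"{path}: node ids must be contiguous 0..{nodes.n_nodes - 1}"
        )
    return NodalMetricMap(
        nodes=nodes,
        p=df["p"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
        thresholds_averaged=thresholds_averaged,
    )


# ---------------------------------------------------------------------------
# cluster tables
# ---------------------------------------------------------------------------

CLUSTER_TABLE_COLUMNS = ["cluster_id", "x", "y", "z", "t_max", "k", "sign"]


def cluster_table(clusters: list[ClusterResult], nodes: NodeSet) -> pd.DataFrame:
    """Cluster summary table (peak coordinates, peak t, extent, sign)."""
    rows = []
    for i, c in enumerate(clusters):
        x, y, z = nodes.coords[c.peak_node]
        rows.append(
            {
                "cluster_id": i,
                "x": x,
                "y": y,
                "z": z,
                "t_max": c.peak_t,
                "k": c.size,
                "sign": "positive" if c.sign > 0 else "negative",
            }
        )
    return pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)


def write_cluster_table(clusters: list[ClusterResult], nodes: NodeSet, path) -> None:
    cluster_table(clusters, nodes).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cluster_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != CLUSTER_TABLE_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {CLUSTER_TABLE_COLUMNS}, got {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# NIfTI volumes (optional lattice export)
# ---------------------------------------------------------------------------

def _lattice_affine(nodes: NodeSet) -> np.ndarray:
    spacing = nodes.spacing_mm or 1.0
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing
    return affine


def write_panel_nifti(panel: TimeSeriesPanel, path) -> None:
    """4-D NIfTI of a lattice panel (x, y, z, time), float32."""
    nodes = panel.nodes
    if nodes.lattice_shape is None:
        raise ValueError("NIfTI export requires lattice nodes")
    vol = panel.signals.reshape(*nodes.lattice_shape, panel.n_timepoints)
    img = nib.Nifti1Image(vol.astype(np.float32), _lattice_affine(nodes))
    nib.save(img, str(path))


def read_panel_nifti(path, nodes: NodeSet) -> TimeSeriesPanel:
    if nodes.lattice_shape is None:
        raise ValueError("NIfTI import requires lattice nodes")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[:3] != nodes.lattice_shape:
        raise ValueError(
            f"{path}: volume shape {data.shape} does not match lattice "
            f"{nodes.lattice_shape}"
        )
    return TimeSeriesPanel(
        nodes=nodes, signals=data.reshape(nodes.n_nodes, data.shape[3])
    )


def write_metric_nifti(values: np.ndarray, nodes: NodeSet, path) -> None:
    """3-D NIfTI of a per-node map on the lattice, float32."""
    if nodes.lattice_shape is None:
        raise ValueError("NIfTI export requires lattice nodes")
    vol = np.asarray(values, dtype=np.float32).reshape(nodes.lattice_shape)
    nib.save(nib.Nifti1Image(vol, _lattice_affine(nodes)), str(path))


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
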