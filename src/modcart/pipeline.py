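"""End-to-end orchestration: cohort -> graphs -> modules -> metrics ->
cartography -> association statistics.

A :class:`RunConfig` (loadable from YAML) fully determines a run; every
stochastic stage derives its generator from the single config seed, so an
identical config reproduces identical outputs byte for byte. Stages are
file-based (each reads its predecessor's outputs from the run directory),
which lets the CLI expose them individually; :func:`run_pipeline` executes
them in order and writes a manifest with the config hash, seeds and output
checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphbuild, io_formats, nodemetrics, stats, synthdata
from .cartography import NodeType, node_type_proportions
from .community import louvain
from .core import GlobalMeasures, NodalMetricMap, NodeSet
from .synthdata import CohortSpec, MetricEffect, PlantedDesign

__all__ = [
    "RunConfig",
    "ValidationResult",
    "PipelineError",
    "validate_config",
    "run_pipeline",
    "load_config",
    "save_config",
    "STAGES",
]

GLOBAL_MEASURE_NAMES = ["q", "n_modules", "avg_module_size", "sd_module_size"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending subject."""


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    output_dir: str
    seed: int = 0
    mode: str = "synthetic"  # "synthetic" | "files"

    # node lattice (always required: cluster inference needs the geometry)
    lattice: tuple[int, int, int] = (4, 5, 5)
    spacing_mm: float = 6.0

    # synthetic cohort
    n_subjects: int = 20
    n_timepoints: int = 120
    module_sizes: tuple[int, ...] = (25, 25, 25, 25)
    within_corr: float = 0.5
    between_corr: float = 0.1
    noise_sd: float = 1.0
    trait_mean: float = 99.12
    trait_sd: float = 13.23
    effect_map: tuple[dict, ...] = ()  # [{"cluster": [...], "metric": "p", "r": 0.3}]

    # files mode inputs
    coords_csv: str | None = None
    cohort_csv: str | None = None
    panels_dir: str | None = None  # contains panel_<subject_id>.tsv

    # graph construction
    fractions: tuple[float, ...] = graphbuild.DEFAULT_FRACTIONS
    min_dist_mm: float = graphbuild.DEFAULT_MIN_DIST_MM
    binary: bool = True

    # community detection
    louvain_restarts: int = 5

    # association statistics
    voxel_p: float = 0.005
    fwe_p: float = 0.05
    n_sims: int = 10000
    prior_scale: float = stats.DEFAULT_PRIOR_SCALE

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lattice"] = list(self.lattice)
        d["module_sizes"] = list(self.module_sizes)
        d["fractions"] = list(self.fractions)
        d["effect_map"] = [dict(e) for e in self.effect_map]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("lattice", "module_sizes", "fractions", "effect_map"):
            if key in d and d[key] is not None:
                d[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in d[key]
                ) if key != "effect_map" else tuple(dict(e) for e in d[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.lattice))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class ValidationResult:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_config(config: RunConfig) -> ValidationResult:
    """Check the config, returning all violations (and warnings) at once."""
    res = ValidationResult()
    err, warn = res.errors.append, res.warnings.append
    if config.mode not in ("synthetic", "files"):
        err(f"mode must be 'synthetic' or 'files', got {config.mode!r}")
    if config.seed is None:
        err("seed must be set (every stochastic stage derives from it)")
    if any(s < 1 for s in config.lattice) or config.n_nodes < 2:
        err(f"lattice {config.lattice} must have at least 2 nodes")
    if not config.fractions:
        err("at least one density fraction is required")
    else:
        if any(not 0 < f <= 1 for f in config.fractions):
            err(f"fractions must lie in (0, 1]: {config.fractions}")
        if any(b <= a for a, b in zip(config.fractions, config.fractions[1:])):
            err(f"fractions must be strictly increasing: {config.fractions}")
    if config.mode == "synthetic":
        if sum(config.module_sizes) != config.n_nodes:
            err(
                f"module_sizes sum to {sum(config.module_sizes)} but the "
                f"lattice has {config.n_nodes} nodes"
            )
        if not 0 <= config.between_corr <= config.within_corr < 1:
            err(
                "need 0 <= between_corr <= within_corr < 1, got "
                f"within={config.within_corr}, between={config.between_corr}"
            )
        for e in config.effect_map:
            if e.get("metric") not in ("p", "z"):
                err(f"effect metric must be 'p' or 'z': {e}")
            if not -1 <= e.get("r", 0) <= 1:
                err(f"effect correlation must lie in [-1, 1]: {e}")
            if any(not 0 <= i < config.n_nodes for i in e.get("cluster", [])):
                err(f"effect cluster has node ids outside the lattice: {e}")
    else:
        for name in ("coords_csv", "cohort_csv", "panels_dir"):
            if getattr(config, name) is None:
                err(f"files mode requires {name}")
    if config.min_dist_mm <= 0:
        err("min_dist_mm must be positive")
    if not 0 < config.voxel_p < 1:
        err(f"voxel_p must lie in (0, 1), got {config.voxel_p}")
    elif config.voxel_p > 0.01:
        warn(
            f"voxel-level threshold p={config.voxel_p} is anticonservative; "
            "cluster correction may need very large extents"
        )
    if not 0 < config.fwe_p <= 1:
        err(f"fwe_p must lie in (0, 1], got {config.fwe_p}")
    if config.n_sims < 100:
        err("n_sims must be at least 100")
    if config.louvain_restarts < 1:
        err("louvain_restarts must be positive")
    return res


# ---------------------------------------------------------------------------
# stage implementations (file-based)
# ---------------------------------------------------------------------------

def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _nodes(config: RunConfig) -> NodeSet:
    nx, ny, nz = config.lattice
    return synthdata.generate_lattice_nodes(nx, ny, nz, config.spacing_mm)


def _cohort_paths(config: RunConfig) -> tuple[Path, Path, Path]:
    """(coords_csv, cohort_csv, panels_dir) for the configured input mode."""
    if config.mode == "files":
        paths = (
            Path(config.coords_csv),
            Path(config.cohort_csv),
            Path(config.panels_dir),
        )
    else:
        out = _outdir(config)
        paths = (out / "coords.csv", out / "cohort.csv", out / "panels")
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(
                f"required input {p} not found (run the simulate stage, or "
                "point the config at existing files)"
            )
    return paths


def _load_cohort_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "trait", "age", "sex", "handedness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {sorted(missing)}")
    return df


def stage_simulate(config: RunConfig) -> None:
    """Generate the synthetic cohort and write coords / cohort / panels."""
    if config.mode != "synthetic":
        raise PipelineError("stage simulate: only available in synthetic mode")
    out = _outdir(config)
    nodes = _nodes(config)
    design = PlantedDesign(
        module_sizes=config.module_sizes,
        within_corr=config.within_corr,
        between_corr=config.between_corr,
        noise_sd=config.noise_sd,
    )
    spec = CohortSpec(
        n_subjects=config.n_subjects,
        trait_mean=config.trait_mean,
        trait_sd=config.trait_sd,
        effect_map=tuple(
            MetricEffect(cluster=tuple(e["cluster"]), metric=e["metric"], r=e["r"])
            for e in config.effect_map
        ),
        seed=config.seed,
    )
    subjects = synthdata.generate_cohort(nodes, design, spec, config.n_timepoints)
    io_formats.write_coords(nodes, out / "coords.csv")
    synthdata.cohort_table(subjects).to_csv(
        out / "cohort.csv", index=False, float_format="%.17g"
    )
    panels = out / "panels"
    panels.mkdir(exist_ok=True)
    for s in subjects:
        io_formats.write_panel(s.panel, panels / f"panel_{s.subject_id}.tsv")


def stage_build_graphs(config: RunConfig) -> None:
    """Correlate, distance-mask and threshold each subject's panel."""
    out = _outdir(config)
    coords_csv, cohort_csv, panels_dir = _cohort_paths(config)
    nodes = io_formats.read_coords(
        coords_csv, lattice_shape=tuple(config.lattice), spacing_mm=config.spacing_mm
    )
    cohort = _load_cohort_table(cohort_csv)
    mask = graphbuild.distance_mask(nodes, config.min_dist_mm)
    gdir = out / "graphs"
    gdir.mkdir(exist_ok=True)
    for sid in cohort["subject_id"]:
        try:
            panel = io_formats.read_panel(panels_dir / f"panel_{sid}.tsv", nodes)
            corr = graphbuild.correlation_matrix(panel)
            graphs = graphbuild.build_graph_set(
                corr, mask, config.fractions, binary=config.binary
            )
            for frac, graph in zip(config.fractions, graphs):
                io_formats.write_adjacency(
                    graph, gdir / f"subj{sid}_f{int(round(frac * 100)):02d}.mtx"
                )
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise PipelineError(f"stage build-graphs, subject {sid}: {exc}") from exc


def stage_detect_modules(config: RunConfig) -> None:
    """Louvain partition per subject and density threshold."""
    out = _outdir(config)
    _, cohort_csv, _ = _cohort_paths(config)
    nodes = _nodes(config)
    cohort = _load_cohort_table(cohort_csv)
    pdir = out / "partitions"
    pdir.mkdir(exist_ok=True)
    for sid in cohort["subject_id"]:
        for t_idx, frac in enumerate(config.fractions):
            tag = f"subj{sid}_f{int(round(frac * 100)):02d}"
            try:
                graph = io_formats.read_adjacency(out / "graphs" / f"{tag}.mtx", nodes)
                part = louvain(
                    graph,
                    seed=np.random.SeedSequence((config.seed, int(sid), t_idx)),
                    n_restarts=config.louvain_restarts,
                )
                io_formats.write_partition(part, pdir / f"{tag}.json")
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(
                    f"stage detect-modules, subject {sid}: {exc}"
                ) from exc


def _subject_maps_and_globals(
    config: RunConfig, nodes: NodeSet, sid: int
) -> tuple[list[NodalMetricMap], GlobalMeasures]:
    out = Path(config.output_dir)
    maps, parts = [], []
    for frac in config.fractions:
        tag = f"subj{sid}_f{int(round(frac * 100)):02d}"
        graph = io_formats.read_adjacency(out / "graphs" / f"{tag}.mtx", nodes)
        part = io_formats.read_partition(out / "partitions" / f"{tag}.json")
        maps.append(nodemetrics.metric_map(graph, part))
        parts.append(part)
    return maps, nodemetrics.global_summaries(parts)


def stage_metrics(config: RunConfig) -> None:
    """Nodal metric maps (threshold-averaged) and global measures."""
    out = _outdir(config)
    _, cohort_csv, _ = _cohort_paths(config)
    nodes = _nodes(config)
    cohort = _load_cohort_table(cohort_csv)
    mdir = out / "metrics"
    mdir.mkdir(exist_ok=True)
    rows = []
    for sid in cohort["subject_id"]:
        try:
            maps, glob = _subject_maps_and_globals(config, nodes, sid)
            mean_map = nodemetrics.average_across_thresholds(maps)
            io_formats.write_metric_map(mean_map, mdir / f"subj{sid}_mean.csv")
            for frac, m in zip(config.fractions, maps):
                io_formats.write_metric_map(
                    m, mdir / f"subj{sid}_f{int(round(frac * 100)):02d}.csv"
                )
            rows.append(
                {
                    "subject_id": sid,
                    "q": glob.q,
                    "n_modules": glob.n_modules,
                    "avg_module_size": glob.avg_module_size,
                    "sd_module_size": glob.sd_module_size,
                }
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage metrics, subject {sid}: {exc}") from exc
    pd.DataFrame(rows).to_csv(
        out / "global_measures.csv", index=False, float_format="%.17g"
    )


def stage_cartography(config: RunConfig) -> None:
    """Node-type proportions per subject (threshold-averaged)."""
    out = _outdir(config)
    _, cohort_csv, _ = _cohort_paths(config)
    nodes = _nodes(config)
    cohort = _load_cohort_table(cohort_csv)
    rows = []
    for sid in cohort["subject_id"]:
        try:
            maps = [
                io_formats.read_metric_map(
                    out / "metrics" / f"subj{sid}_f{int(round(f * 100)):02d}.csv",
                    nodes,
                )
                for f in config.fractions
            ]
            props = node_type_proportions(maps)
            rows.append({"subject_id": sid, **{t.value: props[t] for t in NodeType}})
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage cartography, subject {sid}: {exc}") from exc
    pd.DataFrame(rows).to_csv(
        out / "node_type_proportions.csv", index=False, float_format="%.17g"
    )


def stage_associate(config: RunConfig) -> None:
    """Trait associations: whole-brain tables and nodewise cluster stats."""
    out = _outdir(config)
    _, cohort_csv, _ = _cohort_paths(config)
    nodes = _nodes(config)
    cohort = _load_cohort_table(cohort_csv)
    trait = cohort["trait"].to_numpy(dtype=float)
    covariates = cohort[["age", "sex", "handedness"]]

    globals_df = pd.read_csv(out / "global_measures.csv", float_precision="round_trip")
    props_df = pd.read_csv(out / "node_type_proportions.csv", float_precision="round_trip")
    # two Bonferroni families: 4 global measures, 7 node-type proportions
    table_glob = stats.global_association_table(
        globals_df[GLOBAL_MEASURE_NAMES], trait, covariates,
        prior_scale=config.prior_scale,
    )
    table_prop = stats.global_association_table(
        props_df[[t.value for t in NodeType]], trait, covariates,
        prior_scale=config.prior_scale,
    )
    pd.concat([table_glob, table_prop], ignore_index=True).to_csv(
        out / "global_associations.csv", index=False, float_format="%.17g"
    )

    maps = {
        metric: np.stack(
            [
                getattr(
                    io_formats.read_metric_map(
                        out / "metrics" / f"subj{sid}_mean.csv", nodes
                    ),
                    metric,
                )
                for sid in cohort["subject_id"]
            ]
        )
        for metric in ("p", "z")
    }
    results = {}
    for i, metric in enumerate(("p", "z")):
        res = stats.nodewise_association(
            maps[metric],
            trait,
            covariates,
            nodes,
            voxel_p=config.voxel_p,
            fwe_p=config.fwe_p,
            n_sims=config.n_sims,
            seed=np.random.SeedSequence((config.seed, 7001 + i)).generate_state(1)[0],
        )
        results[metric] = res
        pd.DataFrame({"node_id": np.arange(nodes.n_nodes), "t": res.t_map}).to_csv(
            out / f"tmap_{metric}.csv", index=False, float_format="%.17g"
        )
        io_formats.write_cluster_table(
            res.clusters, nodes, out / f"clusters_{metric}.csv"
        )
    conj = stats.conjunction(results["p"].clusters, results["z"].clusters, nodes)
    conj_rows = [
        {
            "cluster_id": i,
            "k": c.size,
            "sign_p": "positive" if c.sign_p > 0 else "negative",
            "sign_z": "positive" if c.sign_z > 0 else "negative",
            "nodes": ";".join(map(str, c.nodes)),
        }
        for i, c in enumerate(conj)
    ]
    pd.DataFrame(
        conj_rows, columns=["cluster_id", "k", "sign_p", "sign_z", "nodes"]
    ).to_csv(out / "conjunction.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "build-graphs": stage_build_graphs,
    "detect-modules": stage_detect_modules,
    "metrics": stage_metrics,
    "cartography": stage_cartography,
    "associate": stage_associate,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the run manifest.

    Returns the manifest: config hash, seed, and a checksum for every
    written output file. Re-running the identical config reproduces
    byte-identical outputs.
    """
    validation = validate_config(config)
    for w in validation.warnings:
        warnings.warn(w, stacklevel=2)
    if not validation.ok:
        raise PipelineError("invalid config: " + "; ".join(validation.errors))
    out = _outdir(config)
    stage_names = list(STAGES)
    if config.mode == "files":
        stage_names.remove("simulate")
    for name in stage_names:
        STAGES[name](config)
    checksums = {
        str(p.relative_to(out)): io_formats.file_checksum(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stage_names,
        "outputs": checksums,
    }
    io_formats.write_manifest(manifest, out / "manifest.json")
    return manifest
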