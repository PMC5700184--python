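"""Synthetic cohorts for modular brain-network analysis.

The generators here stand in for resting-state fMRI data so that every
downstream stage — graph construction, community detection, nodal metrics,
cartography and the association statistics — can be exercised and validated
without any imaging data:

* :func:`generate_lattice_nodes` — a regular 3-D lattice of "voxel" nodes
  with physical coordinates, emulating a down-sampled grey-matter grid.
* :func:`generate_modular_timeseries` — Gaussian signals with planted
  modular correlation structure (high within-module, low between-module
  Pearson correlation), via a shared-factor model.
* :func:`generate_planted_partition_graph` — a graph-level fixture with
  known community labels for community-detection tests.
* :func:`generate_cohort` — a cohort of subjects whose within-/between-
  module coupling at designated node clusters varies monotonically with a
  behavioural trait (an FSIQ-like score), plus age/sex/handedness
  covariates.
* :func:`generate_metric_cohort` — a cohort of per-subject nodal metric
  maps (p, z) with trait-linked effects injected directly, for testing the
  association statistics at realistic node counts.

All randomness flows from an explicit seed per call; no global RNG state is
touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import BrainGraph, NodeSet, TimeSeriesPanel

__all__ = [
    "PlantedDesign",
    "MetricEffect",
    "CohortSpec",
    "CohortSubject",
    "MetricCohort",
    "generate_lattice_nodes",
    "generate_modular_timeseries",
    "generate_planted_partition_graph",
    "generate_cohort",
    "generate_metric_cohort",
    "cohort_table",
]

# FWHM of a Gaussian in units of its standard deviation
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Handedness categories (right, left, ambidextrous) with frequencies close
# to what a healthy adult community sample shows.
HANDEDNESS_LEVELS = ("right", "left", "ambidextrous")
_HANDEDNESS_PROBS = (0.85, 0.07, 0.08)


@dataclass(frozen=True)
class PlantedDesign:
    """Planted modular correlation structure for synthetic signals.

    Signals follow a factor model: node *i* in module *s* is
    ``x_i = a*f_s + b*g + c*eps_i`` with a module factor ``f_s``, a global
    factor ``g`` and private noise, all standard normal. Choosing
    ``a^2 = within_corr - between_corr``, ``b^2 = between_corr`` and
    ``c^2 = 1 - within_corr`` yields exactly the requested equicorrelation
    pattern, and the implied covariance is positive semi-definite by
    construction whenever ``0 <= between_corr <= within_corr < 1``.
    """

    module_sizes: tuple[int, ...]
    within_corr: float = 0.5
    between_corr: float = 0.1
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.module_sizes)
        if not sizes or any(s < 1 for s in sizes):
            raise ValueError("module_sizes must be positive counts")
        object.__setattr__(self, "module_sizes", sizes)
        if not (0.0 <= self.between_corr <= self.within_corr < 1.0):
            raise ValueError(
                "need 0 <= between_corr <= within_corr < 1 for a positive "
                f"semi-definite target (got within={self.within_corr}, "
                f"between={self.between_corr})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_nodes(self) -> int:
        return int(sum(self.module_sizes))

    def module_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


@dataclass(frozen=True)
class MetricEffect:
    """A requested trait-metric association at a node cluster.

    ``metric`` is ``"p"`` (participation coefficient, between-module
    connectivity) or ``"z"`` (within-module degree); ``r`` is the target
    cross-subject Pearson correlation between the trait and the designated
    nodal metric at the cluster.
    """

    cluster: tuple[int, ...]
    metric: str
    r: float

    def __post_init__(self) -> None:
        if self.metric not in ("p", "z"):
            raise ValueError("metric must be 'p' or 'z'")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("effect correlation must lie in [-1, 1]")
        object.__setattr__(self, "cluster", tuple(int(i) for i in self.cluster))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level configuration: sample size, trait distribution,
    covariates and the trait-metric effect map.

    Default trait distribution emulates an FSIQ-like score in a healthy
    adult community sample (mean 99.12, SD 13.23); ages are uniform on
    18-60 years; sex is binary; handedness has three levels.
    """

    n_subjects: int
    trait_mean: float = 99.12
    trait_sd: float = 13.23
    age_range: tuple[float, float] = (18.0, 60.0)
    effect_map: tuple[MetricEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        object.__setattr__(self, "effect_map", tuple(self.effect_map))


@dataclass(frozen=True)
class CohortSubject:
    """One synthetic subject: signals, trait value and covariates."""

    subject_id: int
    panel: TimeSeriesPanel
    trait: float
    covariates: dict


@dataclass(frozen=True)
class MetricCohort:
    """A cohort of per-subject nodal metric maps with trait and covariates.

    ``p_maps`` and ``z_maps`` are ``(n_subjects, n_nodes)`` arrays.
    """

    nodes: NodeSet
    traits: np.ndarray
    covariates: pd.DataFrame
    p_maps: np.ndarray
    z_maps: np.ndarray


def generate_lattice_nodes(
    nx: int, ny: int, nz: int, spacing_mm: float = 6.0
) -> NodeSet:
    """Regular ``nx x ny x nz`` lattice of nodes with the given spacing.

    Emulates a down-sampled voxel grid (e.g. 6 x 6 x 6 mm) as the spatial
    substrate for distance-based edge exclusion. Nodes are ordered in
    C order (x slowest); at least two nodes are required.
    """
    nx, ny, nz = int(nx), int(ny), int(nz)
    if nx < 1 or ny < 1 or nz < 1 or spacing_mm <= 0:
        raise ValueError("lattice dimensions and spacing must be positive")
    if nx * ny * nz < 2:
        raise ValueError("lattice must contain at least 2 nodes")
    grid = np.indices((nx, ny, nz)).reshape(3, -1).T.astype(float)
    return NodeSet(
        coords=grid * float(spacing_mm),
        lattice_shape=(nx, ny, nz),
        spacing_mm=float(spacing_mm),
    )


def _component_sds(design: PlantedDesign) -> tuple[float, float, float]:
    """(module, global, private) component standard deviations."""
    a2 = design.within_corr - design.between_corr
    b2 = design.between_corr
    c2 = 1.0 - design.within_corr
    return np.sqrt(a2), np.sqrt(b2), np.sqrt(c2)


def _assemble_signals(
    rng: np.random.Generator,
    labels: np.ndarray,
    n_timepoints: int,
    mod_sd: np.ndarray,
    glob_sd: np.ndarray,
    priv_sd: np.ndarray,
    noise_sd: float,
) -> np.ndarray:
    """Draw factor-model signals with per-node component loadings."""
    n_modules = int(labels.max()) + 1
    factors = rng.standard_normal((n_modules, n_timepoints))
    global_factor = rng.standard_normal(n_timepoints)
    private = rng.standard_normal((labels.size, n_timepoints))
    signals = (
        mod_sd[:, None] * factors[labels]
        + glob_sd[:, None] * global_factor[None, :]
        + priv_sd[:, None] * private
    )
    return signals * noise_sd


def generate_modular_timeseries(
    nodes: NodeSet,
    design: PlantedDesign,
    n_timepoints: int = 120,
    seed: int | None = None,
) -> TimeSeriesPanel:
    """Gaussian node signals whose correlation matrix has the planted
    modular structure of ``design``.

    The population Pearson correlation equals ``within_corr`` for node
    pairs inside a planted module and ``between_corr`` across modules.
    The same seed always yields bit-identical output.
    """
    if design.n_nodes != nodes.n_nodes:
        raise ValueError(
            f"design covers {design.n_nodes} nodes but NodeSet has {nodes.n_nodes}"
        )
    if n_timepoints < 10:
        raise ValueError("need at least 10 timepoints")
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    labels = design.module_labels()
    a, b, c = _component_sds(design)
    n = nodes.n_nodes
    signals = _assemble_signals(
        rng,
        labels,
        int(n_timepoints),
        np.full(n, a),
        np.full(n, b),
        np.full(n, c),
        design.noise_sd,
    )
    # private noise keeps rows from being constant unless within_corr == 1,
    # which the design forbids; guard anyway for tiny-T pathologies
    if np.any(signals.std(axis=1) == 0):
        raise RuntimeError("generated a zero-variance signal row")
    return TimeSeriesPanel(nodes=nodes, signals=signals)


def generate_planted_partition_graph(
    module_sizes,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> tuple[BrainGraph, np.ndarray]:
    """Undirected binary planted-partition graph and its true labels.

    Each within-module pair is an edge with probability ``p_in``, each
    between-module pair with probability ``p_out`` (``p_in > p_out`` unless
    both equal). Nodes get placeholder coordinates on a line; the fixture is
    purely graph-level.
    """
    sizes = tuple(int(s) for s in module_sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("module sizes must be positive counts")
    if not (0.0 <= p_out <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ValueError("edge probabilities must lie in [0, 1]")
    if p_in < p_out:
        raise ValueError("p_in must be >= p_out for a planted structure")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    probs = np.where(labels[iu] == labels[ju], p_in, p_out)
    edges = rng.random(iu.size) < probs
    adj = np.zeros((n, n))
    adj[iu[edges], ju[edges]] = 1.0
    adj += adj.T
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    graph = BrainGraph(
        nodes=NodeSet(coords=coords), adjacency=adj, density_level="custom", binary=True
    )
    return graph, labels


def _draw_covariates(rng: np.random.Generator, spec: CohortSpec, n: int):
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)
    handed = rng.choice(len(HANDEDNESS_LEVELS), size=n, p=_HANDEDNESS_PROBS)
    return age, sex, handed


def _sigmoid(x: np.ndarray | float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# Gain of the trait-dependent mixing (log-odds shift per SD of the effect
# score) and the empirical attenuation between the latent effect score and
# the measured nodal metric at the package's default panel length. Both are
# fixed design constants; see docs/methods.md for the calibration procedure.
_MIXING_SLOPE = 1.0
_EFFECT_ATTENUATION = 0.76


def generate_cohort(
    nodes: NodeSet,
    design: PlantedDesign,
    spec: CohortSpec,
    n_timepoints: int = 120,
) -> list[CohortSubject]:
    """Synthesise a cohort of subjects with trait-linked modular coupling.

    Every subject receives factor-model signals as in
    :func:`generate_modular_timeseries`. For each entry of
    ``spec.effect_map``, the component loadings of the target cluster's
    nodes are perturbed monotonically with a latent effect score
    ``u = r*t + sqrt(1-r^2)*eta`` (``t`` the subject's standardised trait,
    ``eta`` independent noise), so that across subjects the designated
    nodal metric correlates with the trait at approximately the requested
    ``r``:

    * metric ``p`` — the share of the node's coupled variance carried by
      the *global* (between-module) factor follows a logistic curve in
      ``u``, moving connectivity between the node's own module and the
      rest of the network while keeping total coupling fixed;
    * metric ``z`` — the share of the node's *module-factor* variance
      relative to private noise follows a logistic curve in ``u``, making
      the node more (or less) correlated with its module mates.

    The latent score correlates with the trait at exactly ``r``; the
    measured metric attenuates this slightly (finite scan length, graph
    estimation noise), which the generator compensates with a fixed
    calibration constant. Requested ``|r|`` close to 1 cannot be realised
    and triggers a best-effort warning.
    """
    if design.n_nodes != nodes.n_nodes:
        raise ValueError("design does not cover the NodeSet")
    for eff in spec.effect_map:
        if any(i < 0 or i >= nodes.n_nodes for i in eff.cluster):
            raise ValueError("effect cluster contains node ids outside the NodeSet")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    traits = spec.trait_mean + spec.trait_sd * rng.standard_normal(n)
    age, sex, handed = _draw_covariates(rng, spec, n)
    trait_z = (traits - traits.mean()) / traits.std()

    labels = design.module_labels()
    a, b, c = _component_sds(design)
    n_nodes = nodes.n_nodes

    # per-effect latent scores, correlated with the trait at the (possibly
    # calibration-boosted) target r
    effect_scores = []
    for eff in spec.effect_map:
        r_latent = eff.r / _EFFECT_ATTENUATION
        if abs(r_latent) > 0.99:
            warnings.warn(
                f"requested effect r={eff.r:+.2f} is too large to realise "
                "exactly given measurement noise; generating at the maximum "
                "achievable coupling",
                stacklevel=2,
            )
            r_latent = np.sign(r_latent) * 0.99
        eta = rng.standard_normal(n)
        effect_scores.append(r_latent * trait_z + np.sqrt(1 - r_latent**2) * eta)

    subjects: list[CohortSubject] = []
    for s in range(n):
        mod_sd = np.full(n_nodes, a)
        glob_sd = np.full(n_nodes, b)
        priv_sd = np.full(n_nodes, c)
        for eff, score in zip(spec.effect_map, effect_scores):
            u = float(score[s])
            idx = np.asarray(eff.cluster, dtype=int)
            if eff.metric == "p":
                coupled = a**2 + b**2
                if coupled <= 0:
                    continue
                share = _sigmoid(_logit(max(b**2 / coupled, 1e-6)) + _MIXING_SLOPE * u)
                glob_sd[idx] = np.sqrt(share * coupled)
                mod_sd[idx] = np.sqrt((1.0 - share) * coupled)
            else:  # metric "z"
                pool = a**2 + c**2
                if pool <= 0:
                    continue
                share = _sigmoid(_logit(max(a**2 / pool, 1e-6)) + _MIXING_SLOPE * u)
                mod_sd[idx] = np.sqrt(share * pool)
                priv_sd[idx] = np.sqrt((1.0 - share) * pool)
        signals = _assemble_signals(
            rng, labels, int(n_timepoints), mod_sd, glob_sd, priv_sd, design.noise_sd
        )
        subjects.append(
            CohortSubject(
                subject_id=s,
                panel=TimeSeriesPanel(nodes=nodes, signals=signals),
                trait=float(traits[s]),
                covariates={
                    "age": float(age[s]),
                    "sex": int(sex[s]),
                    "handedness": HANDEDNESS_LEVELS[int(handed[s])],
                },
            )
        )
    return subjects


def cohort_table(subjects: list[CohortSubject]) -> pd.DataFrame:
    """Subject-level table (subject_id, trait, age, sex, handedness)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "trait": [s.trait for s in subjects],
            "age": [s.covariates["age"] for s in subjects],
            "sex": [s.covariates["sex"] for s in subjects],
            "handedness": [s.covariates["handedness"] for s in subjects],
        }
    )


def smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, int, int], fwhm_vox: float
) -> np.ndarray:
    """A stationary Gaussian random field with unit pointwise variance.

    White noise is convolved with a Gaussian kernel of the given FWHM (in
    voxels) under periodic boundary conditions, then rescaled by the exact
    kernel norm so every voxel keeps unit variance. ``fwhm_vox = 0`` gives
    plain white noise.
    """
    field = rng.standard_normal(shape)
    if fwhm_vox <= 0:
        return field
    sigma = fwhm_vox / _FWHM_PER_SIGMA
    field = gaussian_filter(field, sigma=sigma, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma, mode="wrap")
    norm = np.sqrt(np.sum(kernel**2))
    return field / norm


def generate_metric_cohort(
    nodes: NodeSet,
    spec: CohortSpec,
    noise_fwhm_vox: float = 2.0,
    p_base: float = 0.5,
    p_scale: float = 0.1,
    seed: int | None = None,
) -> MetricCohort:
    """Per-subject nodal metric maps with trait effects injected directly.

    Each subject's p and z maps are independent stationary Gaussian random
    fields on the node lattice (spatially smooth, FWHM ``noise_fwhm_vox``
    voxels, emulating the smoothness of real nodal metric maps). For each
    entry of ``spec.effect_map`` the cluster's nodes receive a trait
    component so that the population cross-subject correlation between
    trait and nodal metric equals the requested ``r`` exactly:
    ``value = r * trait_z + sqrt(1 - r^2) * field``.

    p maps are affinely placed around ``p_base`` with spread ``p_scale``
    (affine maps preserve all correlations); z maps are left standardised.
    This generator bypasses the graph pipeline and is intended for testing
    the nodewise association statistics at realistic node counts.
    """
    if nodes.lattice_shape is None:
        raise ValueError("metric cohorts require lattice nodes")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    traits = spec.trait_mean + spec.trait_sd * rng.standard_normal(n)
    age, sex, handed = _draw_covariates(rng, spec, n)
    trait_z = (traits - traits.mean()) / traits.std()

    shape = nodes.lattice_shape
    maps = {}
    for metric in ("p", "z"):
        fields = np.stack(
            [smooth_unit_field(rng, shape, noise_fwhm_vox).ravel() for _ in range(n)]
        )
        for eff in spec.effect_map:
            if eff.metric != metric:
                continue
            idx = np.asarray(eff.cluster, dtype=int)
            fields[:, idx] = (
                eff.r * trait_z[:, None]
                + np.sqrt(1.0 - eff.r**2) * fields[:, idx]
            )
        maps[metric] = fields

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "handedness": [HANDEDNESS_LEVELS[int(h)] for h in handed],
        }
    )
    return MetricCohort(
        nodes=nodes,
        traits=traits,
        covariates=covariates,
        p_maps=p_base + p_scale * maps["p"],
        z_maps=maps["z"],
    )
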