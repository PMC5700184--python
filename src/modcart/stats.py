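"""Brain-behaviour association statistics.

Implements the individual-differences inference used on modular-network
measures:

* outlier exclusion (values more than 3 SD from the mean);
* partial correlation between a measure and the trait, controlling for
  age, sex and handedness, with a two-sided t test;
* Jeffreys-Zellner-Siow (JZS) Bayes factors ``BF01`` in favour of the
  null (no association) for Bayesian linear regression with a Cauchy
  prior on the standardised effect, by numerical integration;
* nodewise regression of metric maps on the trait with covariates of no
  interest, returning a per-node t map;
* Monte-Carlo cluster-extent correction on the node lattice (smooth
  Gaussian null fields, face adjacency), yielding the minimum cluster
  size ``k`` that controls the familywise error rate;
* conjunction analysis: overlap of suprathreshold clusters from the p
  and z analyses, annotated with the sign pattern of the two effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps
from scipy.ndimage import label as ndi_label

from .core import NodeSet
from .synthdata import smooth_unit_field

__all__ = [
    "exclude_outliers",
    "design_matrix",
    "partial_correlation",
    "PartialCorrelation",
    "bf01_regression",
    "nodewise_regression",
    "NodewiseResult",
    "estimate_smoothness_fwhm",
    "null_max_cluster_sizes",
    "cluster_extent_threshold",
    "find_clusters",
    "ClusterResult",
    "nodewise_association",
    "AssociationResult",
    "conjunction",
    "ConjunctionCluster",
    "global_association_table",
    "DEFAULT_PRIOR_SCALE",
]

# Conventional default Cauchy prior scale for a single standardised
# regression effect (as used by default-prior Bayesian regression software).
DEFAULT_PRIOR_SCALE = float(np.sqrt(2.0) / 4.0)


# ---------------------------------------------------------------------------
# outliers & design matrices
# ---------------------------------------------------------------------------

def exclude_outliers(values, n_sd: float = 3.0) -> np.ndarray:
    """Boolean mask retaining subjects within ``n_sd`` sample SDs of the mean.

    Mean and SD are computed once over all subjects (not iteratively); a
    zero-variance variable retains everyone.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 subjects for outlier screening")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.size, dtype=bool)
    return np.abs(values - values.mean()) <= n_sd * sd


def design_matrix(covariates) -> np.ndarray:
    """Numeric covariate matrix (no intercept column).

    Accepts an array, or a DataFrame whose non-numeric columns (e.g. a
    3-level handedness factor) are dummy-coded with the first level as
    reference.
    """
    if covariates is None:
        return np.empty((0, 0))
    if isinstance(covariates, pd.DataFrame):
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        return enc.to_numpy(dtype=float)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _check_full_rank(X: np.ndarray) -> None:
    if X.size == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max())
        raise ValueError(
            f"covariate matrix is rank deficient (collinear columns {bad.tolist()})"
        )


def _residualise(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


# ---------------------------------------------------------------------------
# partial correlation & Bayes factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrelation:
    r: float
    p: float
    t: float
    df: int


def partial_correlation(x, y, covariates=None) -> PartialCorrelation:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualised on the covariates plus an intercept;
    the two-sided p value comes from the t distribution with
    ``n - 2 - n_covariates`` degrees of freedom. A variable that is an
    exact linear combination of the covariates leaves a zero-variance
    residual; the correlation is then defined as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    C = design_matrix(covariates)
    if C.size and C.shape[0] != x.size:
        raise ValueError("covariates do not match the number of subjects")
    n_cov = C.shape[1] if C.size else 0
    n = x.size
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"not enough subjects (n={n}) for {n_cov} covariates")
    X = np.column_stack([np.ones(n)] + ([C] if C.size else []))
    _check_full_rank(X)
    rx = _residualise(x, X)
    ry = _residualise(y, X)
    # residual variance at floating-point noise level means the variable is
    # an exact linear combination of the covariates
    x_scale = max(float(np.abs(x).max()), 1.0)
    y_scale = max(float(np.abs(y).max()), 1.0)
    if rx.std() <= 1e-12 * x_scale or ry.std() <= 1e-12 * y_scale:
        warnings.warn(
            "a variable is perfectly explained by the covariates; partial "
            "correlation defined as 0",
            stacklevel=2,
        )
        return PartialCorrelation(r=0.0, p=1.0, t=0.0, df=df)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return PartialCorrelation(r=r, p=0.0, t=np.inf * np.sign(r), df=df)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PartialCorrelation(r=r, p=float(p), t=float(t), df=df)


def _jzs_bf10(t: float, n: int, df: int, prior_scale: float) -> float:
    """JZS Bayes factor (alternative over null) from a t statistic.

    The standardised effect carries a Cauchy(0, prior_scale) prior,
    equivalently a normal prior with variance ``g * prior_scale**2`` where
    ``g`` follows an inverse-gamma(1/2, 1/2) mixing distribution; the
    marginal likelihood ratio is obtained by quadrature over g.
    """
    r2 = prior_scale * prior_scale

    def integrand(g: float) -> float:
        a = 1.0 + n * g * r2
        return (
            a ** -0.5
            * (1.0 + t * t / (a * df)) ** (-(df + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, num_err = integrate.quad(integrand, 0, np.inf, limit=200)
    if not np.isfinite(num) or (num > 0 and num_err / num > 1e-4):
        raise RuntimeError(
            f"JZS integration did not converge (value {num}, abserr {num_err})"
        )
    den = (1.0 + t * t / df) ** (-(df + 1) / 2.0)
    return float(num / den)


def bf01_regression(
    y,
    x,
    covariates=None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """Bayes factor in favour of the null for adding x to the regression.

    Compares the covariates-only linear model for ``y`` against the model
    additionally containing ``x``, under the JZS default prior on the
    standardised coefficient of ``x``. ``BF01 > 1`` favours the absence of
    an association; ``BF01 > 3`` is conventionally read as substantial
    evidence for the null.
    """
    pc = partial_correlation(x, y, covariates)
    n = np.asarray(y).size
    bf10 = _jzs_bf10(pc.t, n=n, df=pc.df, prior_scale=prior_scale)
    return 1.0 / bf10


# ---------------------------------------------------------------------------
# nodewise regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodewiseResult:
    """Per-node trait effect from mass-univariate linear regression."""

    t: np.ndarray
    beta: np.ndarray
    df: int
    residuals: np.ndarray  # (n_subjects, n_nodes)
    constant_nodes: np.ndarray  # boolean flag per node


def nodewise_regression(metric_maps, trait, covariates=None) -> NodewiseResult:
    """Least-squares regression of each node's metric on the trait.

    ``metric_maps`` is ``(n_subjects, n_nodes)``; the design contains an
    intercept, the trait, and the covariates of no interest. Returns the
    trait coefficient's t statistic per node. Nodes with a constant metric
    across subjects get t = 0 and are flagged.
    """
    Y = np.asarray(metric_maps, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != trait.size:
        raise ValueError("metric_maps must be (n_subjects, n_nodes)")
    n = trait.size
    C = design_matrix(covariates)
    if C.size and C.shape[0] != n:
        raise ValueError("covariates do not match the number of subjects")
    X = np.column_stack([np.ones(n), trait] + ([C] if C.size else []))
    _check_full_rank(X)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need more than {p} subjects, got {n}")
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (p, n_nodes)
    resid = Y - X @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df
    var_trait = xtx_inv[1, 1] * sigma2
    constant = Y.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / np.sqrt(var_trait)
    t[constant | ~np.isfinite(t)] = 0.0
    return NodewiseResult(
        t=t, beta=beta[1], df=df, residuals=resid, constant_nodes=constant
    )


# ---------------------------------------------------------------------------
# cluster-extent correction on the lattice
# ---------------------------------------------------------------------------

def estimate_smoothness_fwhm(maps, lattice_shape) -> float:
    """Kernel-equivalent smoothness (FWHM, voxels) of stacked lattice maps.

    For a white-noise field convolved with a Gaussian kernel of standard
    deviation ``s`` (voxels), the lag-1 spatial autocorrelation is
    ``rho = exp(-1/(4 s^2))``; inverting the observed ``rho`` (from the
    variance of first differences relative to the field variance, averaged
    over the three axes) recovers the kernel FWHM. Unsmoothed data give 0.
    Differences wrap around the lattice, matching the periodic convention
    of the null-field simulator.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    shape = tuple(int(s) for s in lattice_shape)
    fields = maps.reshape(maps.shape[0], *shape)
    var = fields.var()
    if var == 0:
        return 0.0
    rhos = []
    for axis in range(3):
        if shape[axis] < 2:
            continue
        diff = fields - np.roll(fields, 1, axis=axis + 1)
        rhos.append(1.0 - diff.var() / (2.0 * var))
    rho = float(np.mean(rhos))
    if rho <= 0:
        return 0.0
    sigma = np.sqrt(-1.0 / (4.0 * np.log(rho)))
    return float(sigma * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def _max_cluster_size(mask: np.ndarray) -> int:
    labelled, n = ndi_label(mask)  # default structure: face adjacency
    if n == 0:
        return 0
    return int(np.bincount(labelled.ravel())[1:].max())


def null_max_cluster_sizes(
    lattice_shape,
    voxel_p: float = 0.005,
    n_sims: int = 10000,
    smoothness_fwhm_vox: float = 0.0,
    seed: int | None = None,
    two_sided: bool = True,
) -> np.ndarray:
    """Maximum suprathreshold cluster size per simulated null field.

    Each simulation draws a stationary Gaussian field on the lattice
    (periodic boundary), thresholds it at the voxel-level p (split over
    both tails when two-sided, clusters formed within a tail), and records
    the largest face-connected cluster.
    """
    shape = tuple(int(s) for s in lattice_shape)
    rng = np.random.default_rng(seed)
    zcrit = sps.norm.isf(voxel_p / 2.0) if two_sided else sps.norm.isf(voxel_p)
    out = np.empty(int(n_sims), dtype=int)
    for i in range(int(n_sims)):
        f = smooth_unit_field(rng, shape, smoothness_fwhm_vox)
        size = _max_cluster_size(f > zcrit)
        if two_sided:
            size = max(size, _max_cluster_size(f < -zcrit))
        out[i] = size
    return out


def cluster_extent_threshold(
    lattice_shape,
    voxel_p: float = 0.005,
    fwe_p: float = 0.05,
    n_sims: int = 10000,
    smoothness_fwhm_vox: float = 0.0,
    seed: int | None = None,
    two_sided: bool = True,
) -> int:
    """Smallest cluster extent k controlling familywise error at ``fwe_p``.

    Monte-Carlo simulation of smooth Gaussian null fields on the lattice;
    k is the smallest extent whose probability of occurring anywhere in a
    null field thresholded at ``voxel_p`` is at most ``fwe_p``. At least
    100 simulations are required for a stable tail estimate.
    """
    if n_sims < 100:
        raise ValueError("n_sims < 100 gives an unstable tail estimate")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must lie in (0, 1)")
    if fwe_p >= 1.0:
        return 1
    sizes = null_max_cluster_sizes(
        lattice_shape, voxel_p, n_sims, smoothness_fwhm_vox, seed, two_sided
    )
    for k in range(1, int(sizes.max()) + 2):
        if np.mean(sizes >= k) <= fwe_p:
            return k
    return int(sizes.max()) + 1  # pragma: no cover


# ---------------------------------------------------------------------------
# clusters, association pipeline, conjunction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    """A suprathreshold, face-connected cluster of nodes on the lattice."""

    nodes: np.ndarray  # node indices
    peak_node: int
    peak_t: float
    size: int
    sign: int  # +1 or -1


def find_clusters(
    values: np.ndarray,
    lattice_shape,
    threshold: float,
    min_size: int = 1,
    two_sided: bool = True,
) -> list[ClusterResult]:
    """Face-connected clusters of |values| > threshold, split by sign."""
    shape = tuple(int(s) for s in lattice_shape)
    vol = np.asarray(values, dtype=float).reshape(shape)
    clusters: list[ClusterResult] = []
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        mask = sign * vol > threshold
        labelled, n = ndi_label(mask)
        for lab in range(1, n + 1):
            idx = np.flatnonzero(labelled.ravel() == lab)
            if idx.size < min_size:
                continue
            tvals = np.asarray(values).ravel()[idx]
            peak = idx[np.argmax(sign * tvals)]
            clusters.append(
                ClusterResult(
                    nodes=idx,
                    peak_node=int(peak),
                    peak_t=float(np.asarray(values).ravel()[peak]),
                    size=int(idx.size),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: (-c.size, c.peak_node))
    return clusters


@dataclass(frozen=True)
class AssociationResult:
    """Nodewise trait association with cluster-extent-corrected clusters."""

    t_map: np.ndarray
    df: int
    t_critical: float
    extent_k: int
    smoothness_fwhm_vox: float
    clusters: list[ClusterResult] = field(default_factory=list)

    def significant_mask(self, n_nodes: int) -> np.ndarray:
        """Signed per-node mask (+1/-1 inside significant clusters, else 0)."""
        mask = np.zeros(n_nodes, dtype=int)
        for c in self.clusters:
            mask[c.nodes] = c.sign
        return mask


def nodewise_association(
    metric_maps,
    trait,
    covariates,
    nodes: NodeSet,
    voxel_p: float = 0.005,
    fwe_p: float = 0.05,
    n_sims: int = 10000,
    seed: int | None = None,
    extent_k: int | None = None,
) -> AssociationResult:
    """Full nodewise association analysis with cluster-extent correction.

    Regresses each node's metric on the trait (with covariates of no
    interest), thresholds the t map at the two-sided voxel-level p, and
    keeps face-connected clusters of at least ``extent_k`` nodes. When
    ``extent_k`` is not supplied it is determined by Monte-Carlo
    simulation of null fields whose smoothness is estimated from the
    regression residual maps.
    """
    if nodes.lattice_shape is None:
        raise ValueError("cluster-extent inference requires lattice nodes")
    res = nodewise_regression(metric_maps, trait, covariates)
    t_crit = float(sps.t.isf(voxel_p / 2.0, res.df))
    smoothness = estimate_smoothness_fwhm(res.residuals, nodes.lattice_shape)
    if extent_k is None:
        extent_k = cluster_extent_threshold(
            nodes.lattice_shape,
            voxel_p=voxel_p,
            fwe_p=fwe_p,
            n_sims=n_sims,
            smoothness_fwhm_vox=smoothness,
            seed=seed,
        )
    clusters = find_clusters(
        res.t, nodes.lattice_shape, t_crit, min_size=int(extent_k)
    )
    return AssociationResult(
        t_map=res.t,
        df=res.df,
        t_critical=t_crit,
        extent_k=int(extent_k),
        smoothness_fwhm_vox=smoothness,
        clusters=clusters,
    )


@dataclass(frozen=True)
class ConjunctionCluster:
    """A cluster showing effects in both metrics, with their sign pattern."""

    nodes: np.ndarray
    size: int
    sign_p: int
    sign_z: int


def conjunction(
    clusters_p: list[ClusterResult],
    clusters_z: list[ClusterResult],
    nodes: NodeSet,
) -> list[ConjunctionCluster]:
    """Overlap of significant clusters from the p and z analyses.

    The node-wise intersection of the two signed suprathreshold masks is
    re-segmented into face-connected components of homogeneous sign
    pattern, e.g. p-positive/z-negative.
    """
    if nodes.lattice_shape is None:
        raise ValueError("conjunction requires lattice nodes")
    n = nodes.n_nodes
    mask_p = np.zeros(n, dtype=int)
    for c in clusters_p:
        mask_p[c.nodes] = c.sign
    mask_z = np.zeros(n, dtype=int)
    for c in clusters_z:
        mask_z[c.nodes] = c.sign
    out: list[ConjunctionCluster] = []
    for sp in (1, -1):
        for sz in (1, -1):
            both = (mask_p == sp) & (mask_z == sz)
            if not both.any():
                continue
            labelled, ncomp = ndi_label(both.reshape(nodes.lattice_shape))
            for lab in range(1, ncomp + 1):
                idx = np.flatnonzero(labelled.ravel() == lab)
                out.append(
                    ConjunctionCluster(
                        nodes=idx, size=int(idx.size), sign_p=sp, sign_z=sz
                    )
                )
    out.sort(key=lambda c: (-c.size, c.nodes[0]))
    return out


# ---------------------------------------------------------------------------
# whole-brain association table
# ---------------------------------------------------------------------------

def global_association_table(
    measures: pd.DataFrame,
    trait,
    covariates,
    alpha: float = 0.05,
    bonferroni: bool = True,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> pd.DataFrame:
    """Partial correlation, p value and BF01 per whole-brain measure.

    One row per column of ``measures``: outliers (> 3 SD on the measure or
    the trait) are excluded analysis-wise, then the trait association is
    quantified by the covariate-adjusted partial correlation and by the
    JZS Bayes factor for the null. The significance flag uses the
    Bonferroni-adjusted threshold ``alpha / n_measures`` when requested
    (raw p values are always reported).
    """
    trait = np.asarray(trait, dtype=float)
    C = covariates
    rows = []
    n_tests = measures.shape[1]
    threshold = alpha / n_tests if bonferroni else alpha
    for name in measures.columns:
        vals = measures[name].to_numpy(dtype=float)
        keep = exclude_outliers(vals) & exclude_outliers(trait)
        Ck = C.iloc[keep] if isinstance(C, pd.DataFrame) else (
            None if C is None else np.asarray(C)[keep]
        )
        pc = partial_correlation(vals[keep], trait[keep], Ck)
        bf01 = bf01_regression(trait[keep], vals[keep], Ck, prior_scale=prior_scale)
        rows.append(
            {
                "measure": name,
                "n": int(keep.sum()),
                "r_part": pc.r,
                "p_part": pc.p,
                "bf01": bf01,
                "significant": pc.p < threshold,
            }
        )
    return pd.DataFrame(rows)
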