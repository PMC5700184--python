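"""Association statistics: outliers, partial correlation, Bayes factors,
nodewise regression, cluster-extent correction, conjunction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from modcart.stats import (
    DEFAULT_PRIOR_SCALE,
    ClusterResult,
    _jzs_bf10,
    bf01_regression,
    cluster_extent_threshold,
    conjunction,
    estimate_smoothness_fwhm,
    exclude_outliers,
    find_clusters,
    global_association_table,
    nodewise_regression,
    null_max_cluster_sizes,
    partial_correlation,
)
from modcart.synthdata import generate_lattice_nodes


class TestExcludeOutliers:
    def test_three_sd_is_permissive_at_small_n(self):
        # sample SD of (0,0,0,0,100) is ~44.7; |100-20| = 80 < 3*44.7
        mask = exclude_outliers([0, 0, 0, 0, 100])
        assert mask.all()

    def test_constant_values_all_retained(self):
        assert exclude_outliers([5.0, 5.0, 5.0]).all()

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal(10000)
        excluded = (~exclude_outliers(values)).mean()
        assert excluded == pytest.approx(2 * sps.norm.sf(3), abs=0.002)

    def test_clear_outlier_removed(self):
        values = np.concatenate([np.zeros(50), [50.0]])
        mask = exclude_outliers(values)
        assert not mask[-1] and mask[:-1].all()


class TestPartialCorrelation:
    def test_orthogonal_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        # covariate orthogonal to both x and y by construction
        cov = np.ones((40, 1)) * 0  # zero column would be collinear; residualise
        basis = np.linalg.qr(np.column_stack([np.ones(40), x, y, rng.standard_normal(40)]))[0]
        cov = basis[:, 3:4]  # orthogonal to intercept, x and y
        plain = np.corrcoef(x, y)[0, 1]
        pc = partial_correlation(x, y, cov)
        assert pc.r == pytest.approx(plain, abs=1e-10)

    def test_variable_equal_to_covariate_is_degenerate(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        cov = rng.standard_normal((20, 1))
        y = 2.0 * cov[:, 0] - 1.0
        with pytest.warns(UserWarning, match="perfectly explained"):
            pc = partial_correlation(x, y, cov)
        assert pc.r == 0.0

    def test_eight_subject_fixture_against_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        cov = rng.standard_normal((8, 2))
        # oracle: explicit normal equations for both residualisations
        X = np.column_stack([np.ones(8), cov])
        bx = np.linalg.solve(X.T @ X, X.T @ x)
        by = np.linalg.solve(X.T @ X, X.T @ y)
        rx, ry = x - X @ bx, y - X @ by
        r_expected = (rx - rx.mean()) @ (ry - ry.mean()) / (
            np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        )
        pc = partial_correlation(x, y, cov)
        assert pc.r == pytest.approx(r_expected, abs=1e-12)
        assert pc.df == 8 - 2 - 2

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(50),
                "y": rng.standard_normal(50),
                "c1": rng.standard_normal(50),
                "c2": rng.standard_normal(50),
            }
        )
        df["y"] += 0.4 * df["x"]
        expected = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pc = partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        assert pc.r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)
        assert pc.p == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        c = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank deficient"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestBayesFactor:
    def test_null_association_supports_null_at_n300(self):
        # x constructed with exactly zero residual association with y
        rng = np.random.default_rng(6)
        n = 300
        y = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        X = np.column_stack([np.ones(n), cov])
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        x = rng.standard_normal(n)
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        x = x - (rx @ ry) / (ry @ ry) * ry  # remove any sample association
        bf01 = bf01_regression(y, x, cov)
        assert bf01 > 3.0

    def test_strong_effect_crushes_the_null(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        assert bf01_regression(y, x) < 1e-6

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(80)
        y = 0.3 * x + rng.standard_normal(80)
        cov = rng.standard_normal((80, 1))
        a = bf01_regression(y, x, cov)
        b = bf01_regression(5.0 * y - 2.0, -0.25 * x + 7.0, cov)
        assert a == pytest.approx(b, rel=1e-8)

    def test_quadrature_matches_monte_carlo_oracle(self):
        # independent route: g ~ inverse-gamma(1/2, 1/2) Monte Carlo average
        rng = np.random.default_rng(9)
        g = sps.invgamma(0.5, scale=0.5).rvs(size=400000, random_state=rng)
        for t, n, df in [(0.0, 300, 296), (1.7, 120, 116), (3.2, 80, 76)]:
            r2 = DEFAULT_PRIOR_SCALE**2
            a = 1 + n * g * r2
            num = np.mean(a**-0.5 * (1 + t * t / (a * df)) ** (-(df + 1) / 2))
            bf10_mc = num / (1 + t * t / df) ** (-(df + 1) / 2)
            bf10 = _jzs_bf10(t, n, df, DEFAULT_PRIOR_SCALE)
            assert bf10 == pytest.approx(bf10_mc, rel=0.02)


class TestNodewiseRegression:
    def test_null_suprathreshold_fraction(self):
        rng = np.random.default_rng(10)
        n_subj, n_nodes = 100, 4000
        Y = rng.standard_normal((n_subj, n_nodes))
        trait = rng.standard_normal(n_subj)
        cov = rng.standard_normal((n_subj, 2))
        res = nodewise_regression(Y, trait, cov)
        crit = sps.t.isf(0.005 / 2, res.df)
        frac = np.mean(np.abs(res.t) > crit)
        assert frac == pytest.approx(0.005, abs=0.004)

    def test_injected_effect_recovered_inside_cluster(self):
        rng = np.random.default_rng(11)
        n_subj, n_nodes = 150, 200
        trait = rng.standard_normal(n_subj)
        Y = rng.standard_normal((n_subj, n_nodes))
        inside = np.arange(20)
        Y[:, inside] += 0.6 * trait[:, None]
        res = nodewise_regression(Y, trait, None)
        assert res.t[inside].mean() > 3.0
        assert abs(res.t[20:].mean()) < 0.5

    def test_duplicating_subjects_preserves_coefficient_signs(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((30, 50))
        trait = rng.standard_normal(30)
        r1 = nodewise_regression(Y, trait, None)
        r2 = nodewise_regression(
            np.vstack([Y, Y]), np.concatenate([trait, trait]), None
        )
        np.testing.assert_array_equal(np.sign(r1.beta), np.sign(r2.beta))

    def test_constant_node_flagged_with_zero_t(self):
        rng = np.random.default_rng(13)
        Y = rng.standard_normal((20, 5))
        Y[:, 2] = 7.0
        res = nodewise_regression(Y, rng.standard_normal(20), None)
        assert res.t[2] == 0.0 and res.constant_nodes[2]

    def test_t_matches_partial_correlation_t(self):
        rng = np.random.default_rng(14)
        n = 60
        Y = rng.standard_normal((n, 10))
        trait = rng.standard_normal(n)
        cov = rng.standard_normal((n, 3))
        res = nodewise_regression(Y, trait, cov)
        for node in range(10):
            pc = partial_correlation(Y[:, node], trait, cov)
            assert res.t[node] == pytest.approx(pc.t, abs=1e-8)


def _bfs_components(mask3d):
    """Independent face-adjacency component sizes via breadth-first search."""
    shape = mask3d.shape
    seen = np.zeros(shape, dtype=bool)
    sizes = []
    for start in zip(*np.nonzero(mask3d)):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in (
                (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
            ):
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < shape[0]
                    and 0 <= p[1] < shape[1]
                    and 0 <= p[2] < shape[2]
                    and mask3d[p]
                    and not seen[p]
                ):
                    seen[p] = True
                    stack.append(p)
        sizes.append(size)
    return sizes


class TestClusterExtent:
    def test_no_correction_when_fwe_is_one(self):
        assert cluster_extent_threshold((4, 4, 4), fwe_p=1.0, n_sims=200, seed=0) == 1

    def test_too_few_simulations_refused(self):
        with pytest.raises(ValueError, match="unstable"):
            cluster_extent_threshold((4, 4, 4), n_sims=50)

    def test_monotone_in_smoothness(self):
        ks = [
            cluster_extent_threshold(
                (8, 8, 8), n_sims=1500, smoothness_fwhm_vox=s, seed=1
            )
            for s in (0.0, 1.5, 3.0)
        ]
        assert ks == sorted(ks)

    def test_unsmoothed_tail_matches_independent_bfs_oracle(self):
        # implementation's null tail vs a from-scratch BFS re-simulation
        shape, voxel_p, n_sims = (5, 5, 5), 0.02, 3000
        sizes = null_max_cluster_sizes(shape, voxel_p, n_sims, 0.0, seed=2)
        rng = np.random.default_rng(3)
        zcrit = sps.norm.isf(voxel_p / 2)
        oracle = []
        for _ in range(n_sims):
            f = rng.standard_normal(shape)
            comp = _bfs_components(f > zcrit) + _bfs_components(f < -zcrit)
            oracle.append(max(comp) if comp else 0)
        oracle = np.asarray(oracle)
        for k in (1, 2, 3):
            p_impl = np.mean(sizes >= k)
            p_orac = np.mean(oracle >= k)
            se = np.sqrt(p_orac * (1 - p_orac) / n_sims + p_impl * (1 - p_impl) / n_sims)
            assert abs(p_impl - p_orac) <= 4 * max(se, 1e-3)

    def test_smoothness_estimator_recovers_kernel(self):
        rng = np.random.default_rng(4)
        from modcart.synthdata import smooth_unit_field

        maps = np.stack(
            [smooth_unit_field(rng, (10, 10, 10), 2.0).ravel() for _ in range(200)]
        )
        est = estimate_smoothness_fwhm(maps, (10, 10, 10))
        assert est == pytest.approx(2.0, abs=0.2)

    def test_white_noise_estimates_zero_smoothness(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((100, 6 * 6 * 6))
        assert estimate_smoothness_fwhm(maps, (6, 6, 6)) < 0.5


class TestClustersAndConjunction:
    def _cluster(self, nodes, sign, peak=0):
        nodes = np.asarray(nodes)
        return ClusterResult(
            nodes=nodes, peak_node=int(nodes[0]), peak_t=3.0 * sign,
            size=nodes.size, sign=sign,
        )

    def test_find_clusters_respects_min_size_and_sign(self):
        values = np.zeros(27)
        values[[0, 1, 2]] = 5.0   # x-column: face-connected on 3x3x3
        values[26] = -5.0
        clusters = find_clusters(values, (3, 3, 3), threshold=2.0, min_size=2)
        assert len(clusters) == 1
        assert clusters[0].sign == 1 and clusters[0].size == 3

    def test_disjoint_masks_empty_conjunction(self):
        nodes = generate_lattice_nodes(3, 3, 3, 6.0)
        a = [self._cluster([0, 1], 1)]
        b = [self._cluster([25, 26], -1)]
        assert conjunction(a, b, nodes) == []

    def test_identical_masks_conjunction_equals_input(self):
        nodes = generate_lattice_nodes(3, 3, 3, 6.0)
        a = [self._cluster([0, 1, 2], 1)]
        b = [self._cluster([0, 1, 2], -1)]
        out = conjunction(a, b, nodes)
        assert len(out) == 1
        assert np.array_equal(out[0].nodes, [0, 1, 2])
        assert out[0].sign_p == 1 and out[0].sign_z == -1


class TestGlobalAssociationTable:
    def test_null_measures_mostly_nonsignificant_with_null_support(self):
        rng = np.random.default_rng(15)
        n = 200
        measures = pd.DataFrame(
            {f"m{i}": rng.standard_normal(n) for i in range(4)}
        )
        trait = rng.standard_normal(n)
        cov = pd.DataFrame(
            {
                "age": rng.uniform(18, 60, n),
                "sex": rng.integers(0, 2, n),
                "handedness": rng.choice(["right", "left", "ambi"], n),
            }
        )
        table = global_association_table(measures, trait, cov)
        assert list(table.columns) == [
            "measure", "n", "r_part", "p_part", "bf01", "significant",
        ]
        assert (table["bf01"] > 1).all()
        assert not table["significant"].any()

    def test_real_effect_detected(self):
        rng = np.random.default_rng(16)
        n = 200
        trait = rng.standard_normal(n)
        measures = pd.DataFrame(
            {"coupled": 0.5 * trait + rng.standard_normal(n) * np.sqrt(0.75)}
        )
        table = global_association_table(measures, trait, None)
        assert table["significant"].iloc[0]
        assert table["bf01"].iloc[0] < 1 / 3
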