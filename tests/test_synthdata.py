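"""Synthetic generators: lattices, modular signals, planted graphs, cohorts."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from modcart import graphbuild, nodemetrics
from modcart.community import louvain
from modcart.core import NodeSet
from modcart.synthdata import (
    CohortSpec,
    MetricEffect,
    PlantedDesign,
    generate_cohort,
    generate_lattice_nodes,
    generate_metric_cohort,
    generate_modular_timeseries,
    generate_planted_partition_graph,
    smooth_unit_field,
)


class TestLattice:
    def test_two_node_lattice_spacing(self):
        nodes = generate_lattice_nodes(2, 1, 1, 6.0)
        assert nodes.n_nodes == 2
        assert pdist(nodes.coords)[0] == pytest.approx(6.0)

    def test_cube_lattice_max_distance(self):
        # 3x3x3 at 6 mm: corner-to-corner distance is 6 * sqrt(2^2 * 3)
        nodes = generate_lattice_nodes(3, 3, 3, 6.0)
        assert nodes.n_nodes == 27
        assert pdist(nodes.coords).max() == pytest.approx(6.0 * np.sqrt(12.0))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            generate_lattice_nodes(1, 1, 1, 6.0)

    @pytest.mark.parametrize("dims", [(0, 2, 2), (2, 2, -1)])
    def test_nonpositive_dimensions_rejected(self, dims):
        with pytest.raises(ValueError):
            generate_lattice_nodes(*dims, 6.0)


class TestModularTimeseries:
    def test_sample_correlations_match_design(self):
        # long panel: sample within/between correlations converge to target
        design = PlantedDesign(module_sizes=(20, 20), within_corr=0.6, between_corr=0.1)
        nodes = generate_lattice_nodes(5, 4, 2, 6.0)
        panel = generate_modular_timeseries(nodes, design, n_timepoints=5000, seed=3)
        corr = np.corrcoef(panel.signals)
        labels = design.module_labels()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(40, dtype=bool)
        assert corr[same & off].mean() == pytest.approx(0.6, abs=0.05)
        assert corr[~same].mean() == pytest.approx(0.1, abs=0.05)

    def test_long_run_convergence_to_design(self):
        design = PlantedDesign(module_sizes=(10, 10), within_corr=0.5, between_corr=0.2)
        nodes = generate_lattice_nodes(5, 2, 2, 6.0)
        panel = generate_modular_timeseries(nodes, design, n_timepoints=5000, seed=11)
        corr = np.corrcoef(panel.signals)
        labels = design.module_labels()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(20, dtype=bool)
        assert abs(corr[same & off].mean() - 0.5) < 0.02
        assert abs(corr[~same].mean() - 0.2) < 0.02

    def test_independent_noise_design(self):
        design = PlantedDesign(module_sizes=(15, 15), within_corr=0.0, between_corr=0.0)
        nodes = generate_lattice_nodes(5, 3, 2, 6.0)
        panel = generate_modular_timeseries(nodes, design, n_timepoints=2000, seed=4)
        corr = np.corrcoef(panel.signals)
        off = ~np.eye(30, dtype=bool)
        assert abs(corr[off].mean()) < 3.0 / np.sqrt(2000)

    def test_determinism(self):
        design = PlantedDesign(module_sizes=(5, 5), within_corr=0.4, between_corr=0.1)
        nodes = generate_lattice_nodes(5, 2, 1, 6.0)
        a = generate_modular_timeseries(nodes, design, 50, seed=9)
        b = generate_modular_timeseries(nodes, design, 50, seed=9)
        assert np.array_equal(a.signals, b.signals)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            PlantedDesign(module_sizes=(5, 5), within_corr=0.2, between_corr=0.5)
        with pytest.raises(ValueError):
            PlantedDesign(module_sizes=(5, 5), within_corr=1.0, between_corr=0.1)
        with pytest.raises(ValueError):
            PlantedDesign(module_sizes=(), within_corr=0.5, between_corr=0.1)

    def test_no_constant_rows(self):
        design = PlantedDesign(module_sizes=(10,), within_corr=0.9, between_corr=0.0)
        nodes = generate_lattice_nodes(5, 2, 1, 6.0)
        panel = generate_modular_timeseries(nodes, design, 30, seed=0)
        assert np.all(panel.signals.std(axis=1) > 0)


class TestPlantedPartitionGraph:
    def test_degenerate_probabilities_give_cliques(self):
        graph, labels = generate_planted_partition_graph([10, 10], 1.0, 0.0, seed=0)
        adj = graph.adjacency
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(20, dtype=bool)
        assert np.all(adj[same & off] == 1.0)
        assert np.all(adj[~same] == 0.0)

    def test_expected_edge_count(self):
        # 4 modules of 25: within pairs 4*C(25,2)=1200, between 3750
        counts = [
            generate_planted_partition_graph([25] * 4, 0.8, 0.05, seed=s)[0].n_edges
            for s in range(10)
        ]
        expected = 1200 * 0.8 + 3750 * 0.05
        sd = np.sqrt(1200 * 0.8 * 0.2 + 3750 * 0.05 * 0.95)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(10)

    def test_within_between_densities_within_binomial_error(self):
        graph, labels = generate_planted_partition_graph([30, 30, 30], 0.6, 0.1, seed=7)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(90, 1)
        within = same[iu]
        edges = graph.adjacency[iu]
        for mask, p in [(within, 0.6), (~within, 0.1)]:
            n = mask.sum()
            observed = edges[mask].mean()
            assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            generate_planted_partition_graph([5, 5], 1.2, 0.1)
        with pytest.raises(ValueError):
            generate_planted_partition_graph([5, 5], 0.2, 0.5)


def _measured_cluster_metric(subjects, cluster, metric, seed):
    """Trait vs threshold-averaged nodal metric at a cluster, via the graph
    pipeline (the measurement the cohort generator targets)."""
    mask = graphbuild.distance_mask(subjects[0].panel.nodes, 20.0)
    vals = []
    for s in subjects:
        corr = graphbuild.correlation_matrix(s.panel)
        graphs = graphbuild.build_graph_set(corr, mask)
        maps = []
        for ti, g in enumerate(graphs):
            part = louvain(
                g, seed=np.random.SeedSequence((seed, s.subject_id, ti)), n_restarts=3
            )
            maps.append(nodemetrics.metric_map(g, part))
        mm = nodemetrics.average_across_thresholds(maps)
        vals.append(getattr(mm, metric)[list(cluster)].mean())
    traits = np.array([s.trait for s in subjects])
    return float(np.corrcoef(traits, np.array(vals))[0, 1])


# spacing larger than the 20 mm cutoff so every node pair is edge-eligible
_COHORT_NODES = dict(nx=4, ny=4, nz=3, spacing_mm=30.0)
_COHORT_DESIGN = PlantedDesign(
    module_sizes=(12, 12, 12, 12), within_corr=0.5, between_corr=0.1
)


class TestCohort:
    def test_determinism(self):
        nodes = generate_lattice_nodes(**_COHORT_NODES)
        spec = CohortSpec(n_subjects=3, seed=5)
        a = generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=40)
        b = generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=40)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.panel.signals, sb.panel.signals)
            assert sa.trait == sb.trait and sa.covariates == sb.covariates

    def test_null_design_has_no_trait_metric_association(self):
        nodes = generate_lattice_nodes(**_COHORT_NODES)
        spec = CohortSpec(n_subjects=60, seed=21)
        subjects = generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=120)
        r = _measured_cluster_metric(subjects, range(12), "p", seed=21)
        assert abs(r) < 3.0 / np.sqrt(60)

    def test_effect_recovery_at_requested_correlation(self):
        # target r = +0.4 on participation at one module's nodes, n = 200
        nodes = generate_lattice_nodes(**_COHORT_NODES)
        cluster = tuple(range(6))
        spec = CohortSpec(
            n_subjects=200,
            effect_map=(MetricEffect(cluster, "p", 0.4),),
            seed=1,
        )
        subjects = generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=120)
        r = _measured_cluster_metric(subjects, cluster, "p", seed=1)
        assert r == pytest.approx(0.4, abs=0.12)

    def test_mean_achieved_effect_over_seeds(self):
        # requested effect is realised within +/- 0.1 on average over seeds
        nodes = generate_lattice_nodes(**_COHORT_NODES)
        cluster = tuple(range(6))
        achieved = []
        for seed in range(20):
            spec = CohortSpec(
                n_subjects=200,
                effect_map=(MetricEffect(cluster, "z", 0.4),),
                seed=seed,
            )
            subjects = generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=120)
            achieved.append(_measured_cluster_metric(subjects, cluster, "z", seed))
        assert np.mean(achieved) == pytest.approx(0.4, abs=0.1)

    def test_unrealisable_effect_warns(self):
        nodes = generate_lattice_nodes(**_COHORT_NODES)
        spec = CohortSpec(
            n_subjects=5,
            effect_map=(MetricEffect((0, 1), "p", 0.99),),
            seed=0,
        )
        with pytest.warns(UserWarning, match="too large"):
            generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=40)

    def test_invalid_cluster_rejected(self):
        nodes = generate_lattice_nodes(**_COHORT_NODES)
        spec = CohortSpec(
            n_subjects=2, effect_map=(MetricEffect((999,), "p", 0.3),), seed=0
        )
        with pytest.raises(ValueError, match="outside"):
            generate_cohort(nodes, _COHORT_DESIGN, spec, n_timepoints=40)


class TestMetricCohort:
    def test_injected_correlation_is_exact_in_population(self):
        nodes = generate_lattice_nodes(6, 6, 6, 6.0)
        cluster = tuple(np.arange(216).reshape(6, 6, 6)[1:3, 1:3, 1:3].ravel())
        spec = CohortSpec(
            n_subjects=500, effect_map=(MetricEffect(cluster, "p", 0.5),), seed=2
        )
        cohort = generate_metric_cohort(nodes, spec)
        rs = [
            np.corrcoef(cohort.traits, cohort.p_maps[:, i])[0, 1] for i in cluster
        ]
        assert np.mean(rs) == pytest.approx(0.5, abs=3.0 / np.sqrt(500))

    def test_smooth_unit_field_variance_and_smoothness(self):
        rng = np.random.default_rng(0)
        fields = np.stack(
            [smooth_unit_field(rng, (8, 8, 8), 2.0).ravel() for _ in range(300)]
        )
        assert fields.var() == pytest.approx(1.0, abs=0.05)

    def test_requires_lattice(self):
        nodes = NodeSet(coords=np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="lattice"):
            generate_metric_cohort(nodes, CohortSpec(n_subjects=5, seed=0))
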