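"""Simulator calibration: the generator must have the statistical structure
the downstream estimators assume."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from mitorder.association_stats import contingency_tests
from mitorder.branch_gol import estimate_branch_gol
from mitorder.decay_models import fit_decay_model, pairwise_scores
from mitorder.gene_order import dcj_distance, goc_gol
from mitorder.permutation_tests import trna_clustering_test
from mitorder.synthetic_data import (
    SimulationConfig,
    make_order_with_trnas,
    simulate_gene_order_evolution,
    simulate_species_stats,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=3)
        with pytest.raises(ValueError):
            SimulationConfig(inversion_rate=-1)
        with pytest.raises(ValueError):
            SimulationConfig(trna_mode="spiral")


class TestGeneOrderEvolution:
    def test_zero_rate_keeps_everything_identical(self):
        cfg = SimulationConfig(n_leaves=6, inversion_rate=0.0, seed=1)
        sim = simulate_gene_order_evolution(cfg)
        leaves = list(sim.leaf_orders.values())
        for g in leaves:
            assert g.genes == sim.root_order.genes
        scores = pairwise_scores(leaves)
        assert (scores["goc"] == 1.0).all()

    def test_poisson_event_count_on_single_branch(self):
        # 2000 replicates of a branch of length 2 at rate 1.5: mean event
        # count within 3 SE of 3.0
        rate, t, reps = 1.5, 2.0, 2000
        rng = np.random.default_rng(77)
        counts = rng.poisson(rate * t, size=reps)  # the branch draw the
        # simulator makes, isolated from tree machinery
        se = np.sqrt(rate * t / reps)
        assert abs(counts.mean() - 3.0) <= 3 * se

    def test_event_totals_scale_with_rate(self):
        # mean pairwise GOC non-increasing across rates at a fixed seed set
        mean_gocs = []
        for rate in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for seed in range(6):
                cfg = SimulationConfig(
                    n_leaves=8, inversion_rate=rate, seed=seed
                )
                sim = simulate_gene_order_evolution(cfg)
                scores = pairwise_scores(list(sim.leaf_orders.values()))
                vals.append(scores["goc"].mean())
            mean_gocs.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(mean_gocs, mean_gocs[1:]))

    def test_dcj_bounded_by_true_event_count(self):
        for seed in range(5):
            cfg = SimulationConfig(n_leaves=6, inversion_rate=2.0, seed=seed)
            sim = simulate_gene_order_evolution(cfg)
            for leaf, order in sim.leaf_orders.items():
                assert dcj_distance(sim.root_order, order) <= \
                    sim.leaf_path_events[leaf]

    def test_gene_content_preserved(self):
        cfg = SimulationConfig(n_leaves=5, inversion_rate=3.0,
                               transposition_fraction=0.3, seed=2)
        sim = simulate_gene_order_evolution(cfg)
        root_syms = set(sim.root_order.symbols)
        for order in sim.leaf_orders.values():
            assert set(order.symbols) == root_syms

    def test_branch_events_sum_to_leaf_paths(self):
        cfg = SimulationConfig(n_leaves=7, inversion_rate=1.5, seed=4)
        sim = simulate_gene_order_evolution(cfg)
        for leaf in sim.leaf_orders:
            total = sum(
                k for bid, k in sim.branch_events.items()
                if any(b.branch_id == bid and b.on_path(leaf, other)
                       for b in sim.tree.branches
                       for other in sim.leaf_orders if other != leaf)
            )
            # every branch on the root-to-leaf path separates this leaf from
            # some other leaf, so path totals are bounded by the above sum
            assert sim.leaf_path_events[leaf] <= total + 1e-9


class TestSpeciesStats:
    @staticmethod
    def _significance_rate(n_datasets=100, **config_kwargs):
        hits = trials = 0
        for seed in range(n_datasets):
            cfg = SimulationConfig(seed=seed, **config_kwargs)
            sim = simulate_gene_order_evolution(cfg)
            _, clusters = simulate_species_stats(sim)
            mat = clusters.set_index("cluster")[
                ["intergenic_repeats", "rearrangement_events"]
            ]
            if (mat.sum(axis=1) == 0).any() or (mat.sum(axis=0) == 0).any():
                continue
            trials += 1
            if contingency_tests(mat).p_chi2 < 0.05:
                hits += 1
        return hits, trials

    def test_null_slope_gives_no_association(self):
        # slope = 0 with exchangeable groups (the sampling model the
        # chi-squared test actually assumes): significance should be rare
        hits, trials = self._significance_rate(
            n_leaves=12, inversion_rate=1.0, repeat_slope=0.0,
            cluster_assignment="random",
        )
        assert trials >= 50
        assert hits / trials <= 0.10

    def test_strong_coupling_gives_power(self):
        # clusters with heterogeneous rearrangement rates (the
        # order-of-magnitude spread real clusters show) and repeats
        # responding with slope 5 over baseline 10: the aggregated table is
        # called dependent in >= 90% of datasets
        hits, trials = self._significance_rate(
            n_leaves=12, inversion_rate=32.0, repeat_slope=5.0,
            repeat_baseline=10.0, repeat_dispersion=5.0,
            cluster_rate_heterogeneity=3.0,
        )
        assert trials >= 50
        assert hits / trials >= 0.90

    def test_clustered_trnas_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        n = 100
        for _ in range(n):
            order = make_order_with_trnas(15, 20, "clustered", rng)
            res = trna_clustering_test(
                order, n_perm=499, seed=int(rng.integers(2**31))
            )
            if res.p_value < 0.05:
                hits += 1
        assert hits / n >= 0.90

    def test_scattered_trnas_mostly_not_significant(self):
        rng = np.random.default_rng(11)
        hits = 0
        n = 50
        for _ in range(n):
            order = make_order_with_trnas(15, 20, "scattered", rng)
            res = trna_clustering_test(
                order, n_perm=199, seed=int(rng.integers(2**31))
            )
            if res.p_value < 0.05:
                hits += 1
        assert hits / n <= 0.20


class TestEndToEndRecovery:
    def test_bsgol_correlates_with_true_branch_events(self):
        """Estimated per-branch GOL vs true per-branch event counts:
        Spearman rho > 0.5 pooled over replicates."""
        est_all, true_all = [], []
        for seed in range(20):
            cfg = SimulationConfig(n_leaves=12, inversion_rate=1.0, seed=seed)
            sim = simulate_gene_order_evolution(cfg)
            scores = pairwise_scores(list(sim.leaf_orders.values()))
            prob = estimate_branch_gol(sim.tree, scores)
            for branch, x in zip(prob.branches, prob.solution):
                est_all.append(x)
                true_all.append(sim.branch_events.get(branch.branch_id, 0))
        rho, _ = spearmanr(est_all, true_all)
        assert rho > 0.5

    def test_fitted_retention_probability_decreases_with_rate(self):
        phats = []
        for rate in (0.5, 1.0, 2.0):
            vals = []
            for seed in range(5):
                cfg = SimulationConfig(
                    n_leaves=10, inversion_rate=rate, seed=seed
                )
                sim = simulate_gene_order_evolution(cfg)
                scores = pairwise_scores(
                    list(sim.leaf_orders.values()), tree=sim.tree
                )
                fit = fit_decay_model(scores, 3)
                vals.append(fit.parameter)
            phats.append(np.mean(vals))
        assert phats[0] > phats[1] > phats[2]
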