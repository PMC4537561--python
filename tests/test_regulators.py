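import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acidnet.regulators import (
    RegulatorConfig,
    SampleTreeNode,
    assign_regulators,
    attach_sample_trees,
    build_sample_tree,
    calibrate_with_controls,
    consensus_tight_clusters,
    gibbs_cluster_genes,
    score_regulator,
    select_candidates_by_annotation,
)


def block_values(rng, sizes, n_samples=12, noise=0.0):
    rows, labels = [], []
    for b, size in enumerate(sizes):
        base = rng.normal(size=n_samples) * 2
        for _ in range(size):
            rows.append(base + noise * rng.normal(size=n_samples))
            labels.append(b)
    values = pd.DataFrame(
        np.exp(rows),  # positive, lognormal-like
        index=[f"g{i}" for i in range(len(rows))],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return values, np.asarray(labels)


class TestGibbsClustering:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        values, _ = block_values(rng, (8, 8), noise=0.3)
        a = gibbs_cluster_genes(values, seed=5, n_sweeps=10, burn_in=5)
        b = gibbs_cluster_genes(values, seed=5, n_sweeps=10, burn_in=5)
        assert a.equals(b)

    def test_noiseless_blocks_separated(self):
        rng = np.random.default_rng(1)
        values, labels = block_values(rng, (10, 10), noise=0.01)
        part = gibbs_cluster_genes(values, seed=0, n_sweeps=20, burn_in=10)
        # the two blocks end up in two distinct clusters
        c0 = set(part[labels == 0])
        c1 = set(part[labels == 1])
        assert len(c0) == 1 and len(c1) == 1 and c0 != c1

    def test_five_module_partition_quality(self, small_dataset):
        """A single Gibbs run recovers the planted partition well
        (adjusted Rand index >= 0.8)."""
        from sklearn.metrics import adjusted_rand_score

        values = small_dataset.expression.values
        truth = small_dataset.truth.labels_for(values.index)
        part = gibbs_cluster_genes(values, seed=11)
        assert adjusted_rand_score(truth, part.to_numpy()) >= 0.8


class TestConsensusClusters:
    def test_identical_partitions_reproduce_blocks(self):
        genes = [f"g{i}" for i in range(30)]
        labels = pd.Series([0] * 12 + [1] * 12 + [2] * 6, index=genes)
        clusters = consensus_tight_clusters(
            [labels] * 4, RegulatorConfig(min_cluster_size=10)
        )
        sizes = sorted(len(c.genes) for c in clusters)
        assert sizes == [12, 12]  # the 6-gene block is below min size
        assert clusters[0].cluster_id == 0

    def test_single_run_consensus_is_the_partition(self):
        genes = [f"g{i}" for i in range(25)]
        labels = pd.Series([0] * 15 + [1] * 10, index=genes)
        clusters = consensus_tight_clusters(
            [labels], RegulatorConfig(min_cluster_size=10)
        )
        assert [set(c.genes) for c in clusters] == [
            set(genes[:15]), set(genes[15:])
        ]

    def test_random_partitions_yield_nothing(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        partitions = [
            pd.Series(rng.permutation(np.arange(40) % 20), index=genes)
            for _ in range(8)
        ]
        clusters = consensus_tight_clusters(
            partitions, RegulatorConfig(min_cluster_size=10)
        )
        assert clusters == []

    def test_clusters_are_disjoint(self, small_dataset):
        values = small_dataset.expression.values
        parts = [
            gibbs_cluster_genes(values, seed=s, n_sweeps=10, burn_in=5)
            for s in range(3)
        ]
        clusters = consensus_tight_clusters(parts, RegulatorConfig())
        seen = set()
        for c in clusters:
            assert not (seen & set(c.genes))
            seen |= set(c.genes)


class TestSampleTree:
    def test_bimodal_profile_splits_at_the_gap(self):
        samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        profile = pd.Series([2.0 + 0.01 * i for i in range(6)]
                            + [-2.0 - 0.01 * i for i in range(6)],
                            index=samples)
        tree = build_sample_tree(profile, max_depth=1)
        high = {s for s in tree.right.samples} | set()
        sides = [set(tree.left.samples), set(tree.right.samples)]
        assert set(samples[:6]) in sides and set(samples[6:]) in sides
        assert tree.score > 0

    def test_constant_profile_single_leaf(self):
        profile = pd.Series(1.0, index=[f"s{i}" for i in range(8)])
        tree = build_sample_tree(profile)
        assert tree.is_leaf

    def test_max_depth_respected(self):
        rng = np.random.default_rng(4)
        profile = pd.Series(rng.normal(size=32),
                            index=[f"s{i}" for i in range(32)])
        tree = build_sample_tree(profile, max_depth=2)
        depths = []

        def walk(node, d):
            if node.is_leaf:
                depths.append(d)
            else:
                walk(node.left, d + 1)
                walk(node.right, d + 1)

        walk(tree, 0)
        assert max(depths) <= 2

    def test_root_split_matches_genotype_on_clean_cluster(self):
        """With a strongly bimodal module (clean group separation) the root
        split reproduces the genotype partition in >= 90 % of seeds."""
        from acidnet.simulate import RegulatorSpec, SimConfig, simulate_dataset

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(
                module_sizes=(20,), n_background_genes=0, seed=seed,
                trait_coefficients={0: 1.0}, group_separation=6.0,
                baseline_rpkm=100.0,  # keeps the low group well-expressed
                regulators=RegulatorSpec(module_indices=(0,)),
            )
            ds = simulate_dataset(cfg)
            genes = [g for g in ds.truth.module_genes(0)
                     if not g.startswith("REG_")]
            from acidnet.regulators import _prepare_rows

            values = ds.expression.values.loc[genes]
            prepared = pd.DataFrame(
                _prepare_rows(values), index=values.index,
                columns=values.columns,
            )
            tree = build_sample_tree(prepared.mean(axis=0), max_depth=1)
            if tree.is_leaf:
                continue
            sides = [set(tree.left.samples), set(tree.right.samples)]
            groups = ds.expression.sample_group
            ga = set(groups.index[groups == "Ma_"])
            gb = set(groups.index[groups == "mama"])
            if ga in sides and gb in sides:
                wins += 1
        assert wins >= 0.9 * n_seeds


class TestScoreRegulator:
    def _tree(self):
        samples = [f"s{i}" for i in range(10)]
        node = SampleTreeNode(samples=samples, score=1.0)
        node.left = SampleTreeNode(samples=samples[:5])
        node.right = SampleTreeNode(samples=samples[5:])
        return node, samples

    def test_single_leaf_scores_zero(self):
        tree = SampleTreeNode(samples=[f"s{i}" for i in range(5)])
        candidate = pd.Series(np.arange(5.0), index=tree.samples)
        assert score_regulator(candidate, tree) == 0.0

    def test_affine_invariance(self):
        tree, samples = self._tree()
        rng = np.random.default_rng(5)
        candidate = pd.Series(rng.normal(size=10), index=samples)
        s1 = score_regulator(candidate, tree)
        s2 = score_regulator(3.5 * candidate - 7.0, tree)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_zero_variance_candidate_scores_zero(self):
        tree, samples = self._tree()
        candidate = pd.Series(2.0, index=samples)
        assert score_regulator(candidate, tree) == 0.0

    def test_profile_matching_candidate_is_maximal(self):
        """The gene equal to the cluster's mean profile outscores every
        other gene of the fixture on that cluster's tree."""
        rng = np.random.default_rng(6)
        n_samples = 16
        profile = np.concatenate([np.full(8, 2.0), np.full(8, -2.0)])
        rows = [profile + 0.3 * rng.normal(size=n_samples) for _ in range(9)]
        rows.append(profile)  # the perfect tracker
        values = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        tree = build_sample_tree(values.mean(axis=0), max_depth=1)
        scores = {g: score_regulator(values.loc[g], tree) for g in values.index}
        assert max(scores, key=scores.get) == "g9"

    def test_permutation_destroys_signal(self):
        """Permuting a candidate's samples removes its association with the
        tree splits: the true candidate beats essentially all permutations,
        and independent permutation batches share one null distribution."""
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(20)]
        profile = pd.Series(
            np.concatenate([np.full(10, 1.5), np.full(10, -1.5)]),
            index=samples,
        )
        tree = build_sample_tree(profile, max_depth=2)
        candidate = profile + 0.2 * rng.normal(size=20)
        true_score = score_regulator(candidate, tree)

        def permuted_batch(n):
            return [
                score_regulator(
                    pd.Series(rng.permutation(candidate.to_numpy()),
                              index=samples),
                    tree,
                )
                for _ in range(n)
            ]

        batch1 = permuted_batch(200)
        batch2 = permuted_batch(200)
        assert true_score > np.quantile(batch1, 0.99)
        assert stats.ks_2samp(batch1, batch2).pvalue > 0.01


class TestAssignAndCalibrate:
    def _clusters_and_values(self, seed=0):
        rng = np.random.default_rng(seed)
        values, labels = block_values(rng, (12, 12), n_samples=14, noise=0.3)
        clusters = consensus_tight_clusters(
            [pd.Series(labels, index=values.index)],
            RegulatorConfig(min_cluster_size=10),
        )
        attach_sample_trees(clusters, values)
        return clusters, values

    def test_all_equal_scores_flag_nothing(self, caplog):
        clusters, values = self._clusters_and_values()
        flat = values.copy()
        flat.iloc[:] = 1.0  # every candidate constant: all scores zero
        with caplog.at_level("WARNING"):
            out = assign_regulators(
                list(flat.index[:5]), clusters, flat, RegulatorConfig()
            )
        assert not out["is_regulator"].any()

    def test_cutoff_is_top_percentile(self):
        clusters, values = self._clusters_and_values()
        cfg = RegulatorConfig(top_percent=10.0)
        out = assign_regulators(list(values.index), clusters, values, cfg)
        cutoff = np.percentile(out["p_score"], 90.0)
        assert set(out[out["p_score"] >= cutoff].index) == set(
            out[out["is_regulator"]].index
        )

    def test_empty_candidates_rejected(self):
        clusters, values = self._clusters_and_values()
        with pytest.raises(ValueError):
            assign_regulators([], clusters, values, RegulatorConfig())

    def test_calibration_degenerate_scores_not_computable(self):
        clusters, values = self._clusters_and_values()
        flat = values.copy()
        flat.iloc[:] = 1.0
        asg = assign_regulators(
            list(flat.index[:5]), clusters, flat,
            RegulatorConfig(n_controls=10),
        )
        cal = calibrate_with_controls(
            asg, flat, clusters, RegulatorConfig(n_controls=10)
        )
        assert cal["computable"] is False

    def test_calibration_insufficient_pool_rejected(self):
        clusters, values = self._clusters_and_values()
        asg = assign_regulators(
            list(values.index[:20]), clusters, values, RegulatorConfig()
        )
        with pytest.raises(ValueError, match="non-candidate"):
            calibrate_with_controls(asg, values, clusters, RegulatorConfig())

    def test_default_control_and_candidate_counts(self):
        cfg = RegulatorConfig()
        assert cfg.n_controls == 96 and cfg.n_candidates == 96
        assert cfg.n_runs == 10 and cfg.n_clusters_select == 50
        assert cfg.min_cluster_size == 10 and cfg.top_percent == 1.0


class TestCandidateSelection:
    def test_term_based_selection_respects_universe_and_cap(self, small_dataset):
        truth = small_dataset.truth
        universe = small_dataset.expression.gene_ids
        cands = select_candidates_by_annotation(
            small_dataset.annotation, universe, [truth.candidate_term],
            namespace="MapMan",
        )
        assert len(cands) <= 96
        for rid in truth.regulator_ids.values():
            assert rid in cands
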