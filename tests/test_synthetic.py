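"""The synthetic host-tree / virome generator and its statistical contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, ks_2samp

from phylosym.coverage import call_presence, partition_shared
from phylosym.dendrogram import cophenetic
from phylosym.diversity import bray_curtis
from phylosym.io import tree_to_newick
from phylosym.synthetic import (
    SyntheticConfig,
    make_core_fixture,
    simulate_coverage_table,
    simulate_host_tree,
    simulate_virome_counts,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_hosts": 1},
            {"n_contigs": 0},
            {"sequencing_depth": 0},
            {"signal_sd": -0.1},
            {"noise_sd": -1.0},
            {"contig_length_range": (0, 10)},
            {"contig_length_range": (100, 50)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestHostTree:
    def test_two_hosts_is_a_cherry(self):
        t = simulate_host_tree(2, seed=0)
        assert sorted(x.name for x in t.tips()) == ["H1", "H2"]
        assert t.count(tips=True) == 2

    def test_binary_tree_node_counts(self):
        t = simulate_host_tree(5, seed=1)
        tips = list(t.tips())
        internals = list(t.non_tips(include_self=True))
        assert len(tips) == 5 and len(internals) == 4  # n-1 internal nodes

    def test_strictly_positive_branch_lengths(self):
        t = simulate_host_tree(8, seed=2)
        assert all(
            node.length > 0 for node in t.traverse(include_self=False)
        )

    def test_same_seed_identical_newick(self):
        assert tree_to_newick(simulate_host_tree(6, seed=3)) == tree_to_newick(
            simulate_host_tree(6, seed=3)
        )

    def test_too_few_hosts_rejected(self):
        with pytest.raises(ValueError):
            simulate_host_tree(1, seed=0)


class TestViromeCounts:
    def cfg(self, **kw):
        base = dict(n_hosts=4, n_contigs=100, sequencing_depth=2_000, seed=11)
        base.update(kw)
        return SyntheticConfig(**base)

    def test_column_sums_equal_depth(self):
        cfg = self.cfg()
        tree = simulate_host_tree(4, cfg.seed)
        counts = simulate_virome_counts(tree, cfg)
        assert (counts.sum(axis=0) == cfg.sequencing_depth).all()

    def test_bit_identical_across_runs(self):
        cfg = self.cfg()
        tree = simulate_host_tree(4, cfg.seed)
        pd.testing.assert_frame_equal(
            simulate_virome_counts(tree, cfg), simulate_virome_counts(tree, cfg)
        )

    def test_leaf_count_mismatch_rejected(self):
        tree = simulate_host_tree(3, 0)
        with pytest.raises(ValueError, match="leaves"):
            simulate_virome_counts(tree, self.cfg())

    def test_no_signal_no_noise_communities_converge(self):
        """signal_sd = noise_sd = 0: all hosts share one multinomial law.

        By the law of large numbers pairwise Bray-Curtis shrinks with depth;
        at depth 1e5 the mean over 20 replicates is below 0.05.
        """
        dists = []
        for rep in range(20):
            cfg = self.cfg(signal_sd=0.0, noise_sd=0.0, sequencing_depth=100_000,
                           seed=100 + rep)
            tree = simulate_host_tree(4, cfg.seed)
            dm = bray_curtis(simulate_virome_counts(tree, cfg))
            dists.append(dm.condensed_form().mean())
        assert np.mean(dists) < 0.05

    def test_signal_increases_tree_distance_correlation(self):
        """Stronger signal raises the host-tree vs Bray-Curtis rank correlation."""
        tree = simulate_host_tree(5, seed=21)
        coph = cophenetic(tree)
        order = list(coph.ids)
        host_d = coph.condensed_form()
        mean_taus = []
        for signal in (0.0, 0.5, 2.0):
            taus = []
            for rep in range(100):
                cfg = SyntheticConfig(n_hosts=5, n_contigs=150, signal_sd=signal,
                                      noise_sd=0.3, sequencing_depth=3_000,
                                      seed=1_000 * rep + 17)
                bc = bray_curtis(simulate_virome_counts(tree, cfg)).filter(order)
                taus.append(kendalltau(host_d, bc.condensed_form()).statistic)
            mean_taus.append(np.mean(taus))
        assert mean_taus[0] < mean_taus[1] < mean_taus[2]

    def test_exchangeable_hosts_without_signal(self):
        """signal_sd=0: pairwise BC has the same law for any label pair."""
        tree = simulate_host_tree(4, seed=5)
        near, far = [], []
        for rep in range(200):
            cfg = SyntheticConfig(n_hosts=4, n_contigs=80, signal_sd=0.0,
                                  noise_sd=0.8, sequencing_depth=1_500, seed=7_000 + rep)
            dm = bray_curtis(simulate_virome_counts(tree, cfg))
            near.append(dm["H1", "H2"])
            far.append(dm["H3", "H4"])
        assert ks_2samp(near, far).pvalue > 0.01


class TestCoverageTable:
    def cfg(self, **kw):
        base = dict(n_hosts=2, n_contigs=3, sequencing_depth=10, read_length=100,
                    seed=1)
        base.update(kw)
        return SyntheticConfig(**base)

    def abundance(self, rows):
        return pd.DataFrame(rows, index=[f"c{i+1}" for i in range(len(rows))],
                            columns=["H1", "H2"])

    def test_zero_reads_zero_coverage(self):
        cov = simulate_coverage_table(self.abundance([[0, 0]] * 3), self.cfg())
        assert (cov[["reads", "bases_covered", "mean_depth"]] == 0).all().all()

    def test_lander_waterman_formula(self):
        # 100 reads x 100 bp on a 10 kb contig: depth 1, breadth 1 - 1/e
        cov = simulate_coverage_table(
            self.abundance([[100, 0], [0, 0], [0, 0]]),
            self.cfg(),
            lengths={"c1": 10_000, "c2": 1_000, "c3": 1_000},
        )
        row = cov[(cov["sample"] == "H1") & (cov["contig"] == "c1")].iloc[0]
        assert row["mean_depth"] == pytest.approx(1.0)
        assert row["bases_covered"] == round((1 - np.exp(-1)) * 10_000)

    def test_breadth_saturates_at_high_depth(self):
        cov = simulate_coverage_table(
            self.abundance([[10**6, 0], [0, 0], [0, 0]]),
            self.cfg(),
            lengths={"c1": 1_000, "c2": 1_000, "c3": 1_000},
        )
        row = cov[(cov["sample"] == "H1") & (cov["contig"] == "c1")].iloc[0]
        assert row["bases_covered"] == 1_000

    def test_breadth_monotone_in_reads(self):
        reads = np.array([[0, 1], [10, 100], [1_000, 10_000]])
        cov = simulate_coverage_table(
            self.abundance(reads), self.cfg(), lengths={c: 5_000 for c in ["c1", "c2", "c3"]}
        )
        by_reads = cov.sort_values("reads")["bases_covered"].to_numpy()
        assert (np.diff(by_reads) >= 0).all()

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError, match="length"):
            simulate_coverage_table(
                self.abundance([[1, 1]] * 3), self.cfg(),
                lengths={"c1": 0, "c2": 100, "c3": 100},
            )

    def test_deterministic_given_config(self):
        ab = self.abundance([[5, 1], [2, 8], [0, 3]])
        pd.testing.assert_frame_equal(
            simulate_coverage_table(ab, self.cfg()),
            simulate_coverage_table(ab, self.cfg()),
        )


class TestCoreFixture:
    def test_designed_partition_recovered_end_to_end(self):
        design = {"S1": {"c1", "c2"}, "S2": {"c1", "c3"}, "S3": {"c1"}}
        tabl, expected = make_core_fixture(design)
        part = partition_shared(call_presence(tabl))
        assert part.core == expected["core"] == frozenset({"c1"})
        assert part.regions[frozenset({"S2"})] == frozenset({"c3"})
        assert {k: len(v) for k, v in part.regions.items()} == expected["sizes"]

    def test_all_shared_and_none_shared(self):
        tabl, exp = make_core_fixture({"S1": {"c1", "c2"}, "S2": {"c1", "c2"}})
        assert len(exp["core"]) == 2
        assert partition_shared(call_presence(tabl)).core == exp["core"]
        tabl2, exp2 = make_core_fixture({"S1": {"c1"}, "S2": {"c2"}})
        assert exp2["core"] == frozenset()
        assert partition_shared(call_presence(tabl2)).core == frozenset()

    def test_contradictory_design_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            make_core_fixture({"S1": {"c1"}, "S2": set()}, absent={"S1": {"c1"}})
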