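"""Synthetic karyotype histories: replay, calibration, recovery, censoring."""

import numpy as np
import pytest

from helpers import karyotype, true_path_counts

from karyorate.counting import count_between
from karyorate.errors import DomainError
from karyorate.homology import parse_newick_dated
from karyorate.karyosim import (
    SimConfig,
    emulate_painting,
    evolve_karyotypes,
    random_dated_tree,
    replay_events,
    root_karyotype,
)
from karyorate.rates import rates_table


def two_leaf_tree(t: float = 10.0):
    return parse_newick_dated("(A,B)R;", {"R": (t, 0.0)})


def labels_of(k):
    return [c.block_labels() for c in k.autosomes]


class TestEvolve:
    def test_null_process_leaves_root_unchanged(self, rng):
        tree = random_dated_tree(5, rng)
        truth = evolve_karyotypes(SimConfig(tree=tree, root_chromosomes=9, seed=0))
        root = truth.root_karyotype
        for leaf in tree.leaf_labels:
            assert labels_of(truth.node_karyotypes[leaf]) == labels_of(root)

    def test_replay_reproduces_every_leaf_over_seed_sweep(self):
        tree = random_dated_tree(4, 7, scale=3.0)
        for seed in range(100):
            cfg = SimConfig(
                tree=tree, root_chromosomes=10, blocks_per_chromosome=2,
                fusion_rate=0.4, fission_rate=0.3, seed=seed,
            )
            truth = evolve_karyotypes(cfg)
            for parent, child in tree.preorder_branches():
                replayed = replay_events(
                    truth.node_karyotypes[parent], truth.branch_logs[child]
                )
                assert labels_of(replayed) == labels_of(truth.node_karyotypes[child])

    def test_fusion_accounting_on_single_branch(self):
        # Poisson mean 2 fusions on a 10-myr branch: chromosome count drops by
        # exactly the number of logged fusion events
        tree = two_leaf_tree(10.0)
        cfg = SimConfig(
            tree=tree, root_chromosomes=12, fusion_rate=0.2, fission_rate=0.0, seed=21
        )
        truth = evolve_karyotypes(cfg)
        for leaf in ("A", "B"):
            n_fusions = sum(1 for e in truth.branch_logs[leaf] if e.kind == "fusion")
            assert len(truth.node_karyotypes[leaf].autosomes) == 12 - n_fusions

    def test_poisson_calibration_of_fusion_counts(self):
        """Counted fusions across replicate 10-myr branches average rate*t."""
        tree = two_leaf_tree(10.0)
        counted = []
        for seed in range(250):
            cfg = SimConfig(
                tree=tree, root_chromosomes=30, fusion_rate=0.5, fission_rate=0.0,
                seed=seed,
            )
            truth = evolve_karyotypes(cfg)
            for leaf in ("A", "B"):
                ec = count_between(truth.root_karyotype, truth.node_karyotypes[leaf])
                counted.append(ec.fusions)
        counted = np.asarray(counted, dtype=float)  # 500 replicate branches
        se = np.sqrt(5.0 / counted.size)
        assert abs(counted.mean() - 5.0) <= 3 * se

    def test_exact_recovery_without_breakpoint_reuse(self, rng):
        tree = random_dated_tree(5, rng, scale=2.5)
        for seed in range(30):
            cfg = SimConfig(
                tree=tree, root_chromosomes=12, blocks_per_chromosome=3,
                fusion_rate=0.5, fission_rate=0.4, seed=seed,
            )
            truth = evolve_karyotypes(cfg)
            for parent, child in tree.preorder_branches():
                ec = count_between(
                    truth.node_karyotypes[parent], truth.node_karyotypes[child]
                )
                assert (ec.fusions, ec.fissions) == truth.branch_counts[child]

    def test_burst_branch_has_maximum_rate(self):
        # one long fast branch against near-static background: the counting +
        # rates pipeline recovers it as the rate maximum
        tree = parse_newick_dated(
            "((FAST,SLOW1)N1,SLOW2)R;", {"N1": (8.0, 0.5), "R": (9.0, 0.5)}
        )
        slow = evolve_karyotypes(
            SimConfig(tree=tree, root_chromosomes=16, blocks_per_chromosome=2,
                      fusion_rate=0.02, fission_rate=0.02, seed=5)
        )
        # re-run the FAST leaf branch under burst rates by grafting counts:
        burst_counts = {}
        for parent, child in tree.preorder_branches():
            ec = count_between(slow.node_karyotypes[parent], slow.node_karyotypes[child])
            burst_counts[child] = ec.n_changes
        fast_truth = evolve_karyotypes(
            SimConfig(tree=tree, root_chromosomes=16, blocks_per_chromosome=2,
                      fusion_rate=3.0, fission_rate=2.0, seed=6)
        )
        ec_fast = count_between(
            fast_truth.node_karyotypes["N1"], fast_truth.node_karyotypes["FAST"]
        )
        burst_counts["FAST"] = ec_fast.n_changes
        records = rates_table(tree, burst_counts)
        best = max(records, key=lambda r: r.rate_central)
        assert best.child == "FAST"

    def test_skips_logged_not_raised(self):
        # fissions demanded on single-block untaggable chromosomes are skipped
        tree = two_leaf_tree(10.0)
        cfg = SimConfig(
            tree=tree, root_chromosomes=4, blocks_per_chromosome=2,
            fusion_rate=0.0, fission_rate=5.0, seed=3,
        )
        truth = evolve_karyotypes(cfg)  # must not raise
        total_applied = sum(f + g for f, g in truth.branch_counts.values())
        total_skipped = sum(truth.branch_skipped.values())
        assert total_applied + total_skipped > 0

    def test_config_validation(self, rng):
        tree = random_dated_tree(3, rng)
        with pytest.raises(DomainError):
            SimConfig(tree=tree, root_chromosomes=1)
        with pytest.raises(DomainError):
            SimConfig(tree=tree, root_chromosomes=5, blocks_per_chromosome=9)

    def test_root_blocks_unique_and_diploid_consistent(self):
        k = root_karyotype(7, 4)
        assert len(set(k.block_labels())) == 28
        truth = evolve_karyotypes(
            SimConfig(tree=two_leaf_tree(), root_chromosomes=7,
                      blocks_per_chromosome=4, fusion_rate=0.3, seed=1)
        )
        leaf = truth.node_karyotypes["A"]
        assert leaf.diploid_number == 2 * len(leaf.autosomes) + 2


class TestEmulatePainting:
    def test_threshold_one_is_identity(self, rng):
        truth = evolve_karyotypes(
            SimConfig(tree=random_dated_tree(3, rng), root_chromosomes=8,
                      blocks_per_chromosome=2, fusion_rate=0.5, fission_rate=0.3,
                      seed=9)
        )
        for leaf in truth.config.tree.leaf_labels:
            k = truth.node_karyotypes[leaf]
            assert labels_of(emulate_painting(k, 1)) == labels_of(k)

    def test_saturating_threshold_collapses_to_one_block(self):
        # all runs are single blocks of distinct colours
        k = karyotype("k", [["1", "2", "3"], ["4", "5"]])
        censored = emulate_painting(k, 4)
        assert [len(c.blocks) for c in censored.autosomes] == [1, 1]

    def test_censoring_never_inflates_event_counts(self, rng):
        """Painted (censored) maps under-report events, never over-report."""
        tree = random_dated_tree(2, rng, scale=4.0)
        for seed in range(40):
            cfg = SimConfig(
                tree=tree, root_chromosomes=8, blocks_per_chromosome=4,
                fusion_rate=0.6, fission_rate=0.5, seed=seed,
            )
            truth = evolve_karyotypes(cfg)
            for leaf in tree.leaf_labels:
                full = truth.node_karyotypes[leaf]
                censored = emulate_painting(full, 2)
                ec_full = count_between(truth.root_karyotype, full)
                ec_cens = count_between(truth.root_karyotype, censored)
                assert ec_cens.fusions <= ec_full.fusions
                assert ec_cens.fissions <= ec_full.fissions

    def test_invalid_threshold(self):
        with pytest.raises(DomainError):
            emulate_painting(root_karyotype(3), 0)
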