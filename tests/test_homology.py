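"""Karyotype data model, homology-table I/O and dated-tree parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import chrom, karyotype

from karyorate.errors import (
    ChronologyError,
    FormatError,
    InputError,
    UniquenessError,
)
from karyorate.homology import (
    DatedTree,
    SyntenicBlock,
    associations_of,
    compute_fn,
    parse_homology_table,
    parse_newick_dated,
    write_homology_table,
)
from karyorate.karyosim import random_dated_tree

HEADER = "species\tchrom_id\tposition\tblock\tarm\tsegment\tcentromere_flag\tmorphology"


def table(*rows: str) -> str:
    return HEADER + "\n" + "\n".join(rows) + "\n"


class TestBlocks:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("16", ("16", "", "")),
            ("2q", ("2", "q", "")),
            ("16a", ("16", "", "a")),
            ("3px", ("3", "p", "x")),
        ],
    )
    def test_label_round_trip(self, label, expected):
        block = SyntenicBlock.from_label(label)
        assert (block.chrom, block.arm, block.segment) == expected
        assert block.label == label

    def test_base_strips_segment_only(self):
        assert SyntenicBlock.from_label("16a").base == "16"
        assert SyntenicBlock.from_label("2q").base == "2q"

    def test_invalid_fields_rejected(self):
        with pytest.raises(InputError):
            SyntenicBlock("", "", "")
        with pytest.raises(InputError):
            SyntenicBlock("1", "z", "")


class TestParseTable:
    def test_minimal_single_row(self):
        ks = parse_homology_table(table("TSA\t1\t0\t11\t\t\t0\tA"))
        assert len(ks) == 1
        k = ks[0]
        assert k.species == "TSA" and len(k.autosomes) == 1
        assert k.autosomes[0].block_labels() == ("11",)

    def test_row_order_defines_block_order(self):
        # a chromosome carrying outgroup blocks 5 then 16, in table order
        k = parse_homology_table(
            table("TSA\t3\t0\t5\t\t\t0\tSM", "TSA\t3\t1\t16\t\t\t0\t")
        )[0]
        assert k.autosomes[0].block_labels() == ("5", "16")

    def test_duplicate_block_is_uniqueness_error(self):
        text = table("TSA\t1\t0\t7\t\t\t0\tA", "TSA\t2\t0\t7\t\t\t0\tA")
        with pytest.raises(UniquenessError, match="TSA.*'7'"):
            parse_homology_table(text)

    def test_non_consecutive_positions_report_line(self):
        text = table("TSA\t1\t0\t1\t\t\t0\tA", "TSA\t1\t2\t2\t\t\t0\t")
        with pytest.raises(FormatError, match="line 3"):
            parse_homology_table(text)

    def test_missing_column_rejected(self):
        with pytest.raises(FormatError, match="morphology"):
            parse_homology_table("species\tchrom_id\tposition\tblock\n")

    def test_comments_and_sex_chromosomes(self):
        text = table(
            "# painted map",
            "TSA\t1\t0\t17\t\t\tL\tA",
            "TSA\tX\t0\tX\t\t\t0\tSM",
        )
        k = parse_homology_table(text)[0]
        assert len(k.autosomes) == 1 and len(k.sex_chromosomes) == 1
        assert k.autosomes[0].centromere_index == 0

    def test_round_trip_is_canonical_fixed_point(self):
        text = table(
            "TSA\t1\t0\t17\t\t\tL\tA",
            "TSA\t1\t1\t18\t\t\t0\t",
            "TSA\t2\t0\t16\t\ta\t1\tSM",
            "LOC\t1\t0\t2\tq\t\tR\tM",
        )
        once = write_homology_table(parse_homology_table(text))
        twice = write_homology_table(parse_homology_table(once))
        assert once == twice
        # field-identical content after canonicalization
        k1 = parse_homology_table(text)
        k2 = parse_homology_table(once)
        assert [k.autosomes for k in k1] == [k.autosomes for k in k2]


class TestAssociations:
    def test_adjacent_pair(self):
        assert associations_of(karyotype("k", [["17", "18"]])) == {"17+18"}

    def test_single_block_contributes_nothing(self):
        assert associations_of(karyotype("k", [["9"]])) == set()

    def test_orientation_blind_canonical_rendering(self):
        assert associations_of(karyotype("k", [["12", "2q"]])) == {"12+2q"}
        assert associations_of(karyotype("k", [["2q", "12"]])) == {"12+2q"}

    def test_count_identity_and_block_conservation(self, rng):
        # |associations| == sum over chromosomes of (blocks - 1), and the block
        # multiset is invariant under chromosome reordering
        labels = [str(i) for i in range(1, 13)]
        for _ in range(25):
            perm = list(rng.permutation(labels))
            cuts = sorted(rng.choice(range(1, 12), size=3, replace=False))
            chroms = [
                perm[i:j] for i, j in zip([0] + cuts, cuts + [12])
            ]
            k = karyotype("k", chroms)
            assert len(associations_of(k)) == sum(len(c) - 1 for c in chroms)
            shuffled = karyotype("k", [chroms[i] for i in rng.permutation(len(chroms))])
            assert sorted(shuffled.block_labels()) == sorted(k.block_labels())


class TestFundamentalNumber:
    def test_all_acrocentric(self):
        k = karyotype("k", [chrom([str(i)], str(i), morphology="A") for i in range(1, 8)])
        assert compute_fn(k) == 14

    def test_mixed_morphologies(self):
        # 4 biarmed + 3 acrocentric pairs: 4*2*2 + 3*1*2 = 22 arms
        chroms = [chrom([str(i)], str(i), morphology="SM") for i in range(1, 5)]
        chroms += [chrom([str(i)], str(i), morphology="A") for i in range(5, 8)]
        assert compute_fn(karyotype("k", chroms)) == 22

    def test_unspecified_morphology_is_error(self):
        k = karyotype("k", [chrom(["1"], "1", morphology="A"), chrom(["2"], "2")])
        with pytest.raises(InputError, match="chromosome 2"):
            compute_fn(k)

    def test_all_arms_includes_sex_chromosomes(self):
        k = karyotype(
            "k",
            [chrom(["1"], "1", morphology="A")],
            sex=(chrom(["X"], "X", morphology="SM"),),
        )
        assert compute_fn(k, "autosomal_arms") == 2
        assert compute_fn(k, "all_arms") == 4


class TestDatedTree:
    def test_branch_time_from_ages(self):
        tree = parse_newick_dated("((A:1,B:1)N1:1,C:2)R;", {"N1": (1, 0.2), "R": (2, 0.3)})
        assert tree.branch_time("N1") == pytest.approx(1.0)
        assert tree.branch_se("N1") == pytest.approx(np.hypot(0.2, 0.3))
        assert tree.root == "R" and set(tree.leaf_labels) == {"A", "B", "C"}

    def test_child_older_than_parent_is_chronology_error(self):
        with pytest.raises(ChronologyError):
            parse_newick_dated("((A,B)N1,C)R;", {"N1": (3, 0.1), "R": (2, 0.1)})

    def test_unlabeled_internal_node_is_format_error(self):
        with pytest.raises(FormatError):
            parse_newick_dated("((A,B),C)R;", {"R": (2, 0.1)})

    def test_ten_leaf_round_trip(self, rng):
        tree = random_dated_tree(10, rng, age_se=0.5)
        back = parse_newick_dated(tree.to_newick(), tree.ages_table())
        assert back.preorder_branches() == tree.preorder_branches()
        for child in back.labels:
            if back.parent(child):
                assert back.branch_time(child) == pytest.approx(tree.branch_time(child))
                assert back.age_se(child) == pytest.approx(tree.age_se(child))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_random_karyotype_table_round_trip(data):
    """write -> parse -> write is a fixed point for arbitrary valid karyotypes."""
    n_blocks = data.draw(st.integers(2, 10))
    labels = [str(i) for i in range(1, n_blocks + 1)]
    n_chroms = data.draw(st.integers(1, n_blocks))
    cuts = sorted(
        data.draw(
            st.lists(
                st.integers(1, n_blocks - 1),
                min_size=n_chroms - 1,
                max_size=n_chroms - 1,
                unique=True,
            )
        )
    ) if n_chroms > 1 else []
    chroms = [labels[i:j] for i, j in zip([0] + cuts, cuts + [n_blocks])]
    k = karyotype("SPX", chroms)
    text = write_homology_table([k])
    parsed = parse_homology_table(text)
    assert len(parsed) == 1
    assert write_homology_table(parsed) == text
    assert parsed[0].block_labels() == k.block_labels()
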