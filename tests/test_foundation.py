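"""Foundation stage: column filtering, JC69 distances, neighbor joining."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from helpers import unrooted_splits
from treegraft.foundation import (
    FilterParams,
    build_foundation_tree,
    column_stats,
    filter_alignment,
    jc69_distance,
    jc69_distance_matrix,
    neighbor_joining,
)
from treegraft.io_formats import Alignment, SequenceRecord, parse_taxonomy_map
from treegraft.simcom import random_tree


def aln_from_columns(*cols: str) -> Alignment:
    """Build an alignment whose j-th column is the j-th argument string."""
    rows = ["".join(col[i] for col in cols) for i in range(len(cols[0]))]
    return Alignment(tuple(SequenceRecord(f"r{i}", row) for i, row in enumerate(rows)))


class TestColumnStats:
    def test_worked_columns(self):
        stats = column_stats(aln_from_columns("AAAA", "ACGT", "A-A-"))
        assert stats[0].gap_fraction == 0 and stats[0].entropy_bits == 0.0
        assert stats[1].entropy_bits == pytest.approx(2.0)
        assert stats[2].gap_fraction == 0.5 and stats[2].entropy_bits == 0.0

    def test_two_state_column_is_one_bit(self):
        stats = column_stats(aln_from_columns("AACC"))
        assert stats[0].entropy_bits == pytest.approx(1.0)

    def test_ambiguity_codes_excluded_from_entropy(self):
        stats = column_stats(aln_from_columns("AANN"))
        assert stats[0].entropy_bits == 0.0
        assert stats[0].gap_fraction == 0.0


class TestFilterAlignment:
    def test_vacuous_thresholds_keep_everything(self):
        aln = aln_from_columns("AAAA", "ACGT", "A-A-")
        out, report = filter_alignment(
            aln, FilterParams(max_gap_fraction=1.0, max_entropy=2.0, entropy_quantile=None)
        )
        assert out.n_cols == 3 and report.columns_kept == 3

    def test_entropy_cutoff_drops_variable_column(self):
        aln = aln_from_columns("AAAA", "ACGT")
        out, _ = filter_alignment(
            aln, FilterParams(max_gap_fraction=1.0, max_entropy=1.0, entropy_quantile=None)
        )
        assert out.n_cols == 1
        assert all(r.seq == "A" for r in out.records)

    def test_gap_cutoff(self):
        aln = aln_from_columns("AAAA", "A---")
        out, _ = filter_alignment(
            aln, FilterParams(max_gap_fraction=0.5, max_entropy=2.0, entropy_quantile=None)
        )
        assert out.n_cols == 1

    def test_all_gap_rows_removed_and_reported(self):
        aln = Alignment((SequenceRecord("a", "A-"), SequenceRecord("b", "A-"),
                         SequenceRecord("c", "A-"), SequenceRecord("d", "-C")))
        out, report = filter_alignment(
            aln, FilterParams(max_gap_fraction=0.5, max_entropy=2.0, entropy_quantile=None)
        )
        # only column 0 survives the gap filter; row d becomes all-gap
        assert out.ids == ["a", "b", "c"]
        assert report.dropped_all_gap_rows == ["d"]

    def test_no_surviving_columns_is_hard_error(self):
        aln = aln_from_columns("A---")
        with pytest.raises(ValueError, match="relax"):
            filter_alignment(
                aln, FilterParams(max_gap_fraction=0.1, max_entropy=2.0, entropy_quantile=None)
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_kept_set_monotone_in_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ACGT-"))
        rows = ["".join(rng.choice(chars, size=40)) for _ in range(8)]
        aln = Alignment(tuple(SequenceRecord(f"r{i}", s) for i, s in enumerate(rows)))
        stats = column_stats(aln)

        def kept(g, h):
            return {s.index for s in stats if s.gap_fraction <= g and s.entropy_bits <= h}

        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for lo, hi in zip(grid, grid[1:]):
            assert kept(lo, 2.0) <= kept(hi, 2.0)
            assert kept(1.0, 2.0 * lo) <= kept(1.0, 2.0 * hi)

    def test_exactly_one_entropy_criterion_enforced(self):
        with pytest.raises(ValueError, match="exactly one"):
            FilterParams(max_entropy=1.0, entropy_quantile=0.9)
        with pytest.raises(ValueError, match="exactly one"):
            FilterParams(max_entropy=None, entropy_quantile=None)


class TestJC69:
    def test_identical_is_zero(self):
        assert jc69_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_quarter_mismatch_closed_form(self):
        d = jc69_distance("AAAA", "AAAT")
        assert d == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-12)

    def test_closed_form_on_p_grid(self):
        n = 400
        for k in range(0, 280, 7):  # p from 0 to 0.6975
            a = "A" * n
            b = "C" * k + "A" * (n - k)
            p = k / n
            expected = -0.75 * math.log1p(-4 * p / 3)
            assert jc69_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_of_gaps(self):
        assert jc69_distance("AC-T", "ACGT") == 0.0
        assert jc69_distance("ACNT", "ACGT") == 0.0

    def test_no_valid_sites_is_error(self):
        with pytest.raises(ValueError, match="valid"):
            jc69_distance("----", "ACGT")

    def test_saturation_ceiling(self):
        assert jc69_distance("AAAA", "CCCC") == 5.0
        assert jc69_distance("AAAA", "CCCC", saturation_ceiling=9.0) == 9.0

    def test_symmetric_and_increasing_in_p(self):
        n = 100
        prev = -1.0
        for k in range(0, 75, 5):
            a, b = "A" * n, "C" * k + "A" * (n - k)
            assert jc69_distance(a, b) == jc69_distance(b, a)
            assert jc69_distance(a, b) > prev
            prev = jc69_distance(a, b)


class TestNeighborJoining:
    def test_two_taxa_midpoint(self):
        tree = neighbor_joining(DistanceMatrix([[0, 0.4], [0.4, 0]], ["A", "B"]))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.2, "B": 0.2}

    def test_additive_four_taxon_matrix(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(d, ids))
        splits = unrooted_splits(tree)
        assert frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}) in splits
        # NJ is exact on additive matrices: patristic distances reproduce d
        tipdm = tree.tip_tip_distances()
        got = np.array([[tipdm[i, j] for j in ids] for i in ids])
        np.testing.assert_allclose(got, d, atol=1e-12)
        # Tip branch lengths of the generating tree are recovered; the tip
        # adjacent to the root (D) has its terminal edge bisected by the
        # midpoint rooting, so its length is recovered as the two root edges.
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        internal_root_edge = next(c.length for c in tree.children if not c.is_tip())
        assert lengths["D"] + internal_root_edge == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        truth = random_tree([f"t{i}" for i in range(n)], rng, 1.0)
        dm = truth.tip_tip_distances()
        tree = neighbor_joining(dm)
        assert unrooted_splits(tree) == unrooted_splits(truth)

    def test_matches_skbio_nj_topology(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        truth = random_tree([f"t{i}" for i in range(8)], rng, 1.0)
        dm = truth.tip_tip_distances()
        assert unrooted_splits(neighbor_joining(dm)) == unrooted_splits(skbio_nj(dm))

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ["a", "b", "c", "d"])
        from treegraft.io_formats import serialize_newick

        assert serialize_newick(neighbor_joining(dm)) == serialize_newick(neighbor_joining(dm))

    def test_single_id_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            neighbor_joining(DistanceMatrix([[0.0]], ["A"]))


TAX = parse_taxonomy_map(
    "\n".join([
        "A1\tk__F;p__P;c__C;o__O;f__X;g__Ga;s__Ga s1",
        "Z9\tk__F;p__P;c__C;o__O;f__X;g__Ga;s__Ga s2",
        "B1\tk__F;p__P;c__C;o__O;f__X;g__Gb;s__Gb s1",
        "C1\tk__F;p__P;c__C;o__O;f__X;g__Gc;s__Gc s1",
        "U1\tk__F;p__P;c__C;o__O;f__X;g__;s__",
    ])
)

VACUOUS = FilterParams(max_gap_fraction=1.0, max_entropy=2.0, entropy_quantile=None)


class TestBuildFoundationTree:
    def test_three_genera_tree_labeled_by_genus(self):
        aln = Alignment((
            SequenceRecord("A1", "AAAAAAAAAA"),
            SequenceRecord("B1", "AAAAACCCCC"),
            SequenceRecord("C1", "CCCCCCCCCC"),
        ))
        tree, report = build_foundation_tree(aln, TAX, VACUOUS)
        assert sorted(t.name for t in tree.tips()) == ["Ga", "Gb", "Gc"]
        assert report.representatives == {"Ga": "A1", "Gb": "B1", "Gc": "C1"}

    def test_representative_tie_breaks_to_smallest_accession(self):
        aln = Alignment((
            SequenceRecord("Z9", "AAAAAAAAAA"),
            SequenceRecord("A1", "AAAAAAAAAA"),
            SequenceRecord("B1", "AAAAACCCCC"),
        ))
        _, report = build_foundation_tree(aln, TAX, VACUOUS)
        assert report.representatives["Ga"] == "A1"

    def test_longest_ungapped_sequence_wins(self):
        aln = Alignment((
            SequenceRecord("A1", "AAAA--AAAA"),
            SequenceRecord("Z9", "AAAAAAAAAA"),
            SequenceRecord("B1", "AAAAACCCCC"),
        ))
        _, report = build_foundation_tree(aln, TAX, VACUOUS)
        assert report.representatives["Ga"] == "Z9"

    def test_unidentified_genus_dropped_and_reported(self):
        aln = Alignment((
            SequenceRecord("A1", "AAAAAAAAAA"),
            SequenceRecord("B1", "AAAAACCCCC"),
            SequenceRecord("U1", "GGGGGGGGGG"),
        ))
        tree, report = build_foundation_tree(aln, TAX, VACUOUS)
        assert report.dropped_unidentified == ["U1"]
        assert sorted(t.name for t in tree.tips()) == ["Ga", "Gb"]

    def test_fewer_than_two_genera_is_error(self):
        aln = Alignment((SequenceRecord("A1", "AAAA"), SequenceRecord("Z9", "AAAT")))
        with pytest.raises(ValueError, match="at least 2"):
            build_foundation_tree(aln, TAX, VACUOUS)

    def test_missing_taxonomy_entry_is_error(self):
        aln = Alignment((SequenceRecord("A1", "AAAA"), SequenceRecord("QQ", "AAAT")))
        with pytest.raises(KeyError, match="QQ"):
            build_foundation_tree(aln, TAX, VACUOUS)

    def test_external_tree_cmd_fasttree(self):
        # FastTree reads aligned FASTA on stdin and writes Newick on stdout.
        rng = np.random.default_rng(3)
        chars = np.array(list("ACGT"))
        base = rng.choice(chars, size=80)
        recs = []
        for acc in ("A1", "B1", "C1"):
            seq = base.copy()
            idx = rng.choice(80, size=12, replace=False)
            seq[idx] = rng.choice(chars, size=12)
            recs.append(SequenceRecord(acc, "".join(seq)))
        tree, _ = build_foundation_tree(
            Alignment(tuple(recs)), TAX, VACUOUS,
            external_tree_cmd="fasttree -nt -quiet -nopr",
        )
        assert sorted(t.name for t in tree.tips()) == ["Ga", "Gb", "Gc"]
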