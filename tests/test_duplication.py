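"""Collinearity detection, pair typing, epochs and methylation switches."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methyldup import duplication as dup


def _hits(pairs):
    return pd.DataFrame(
        [(q, s, 1e-50) for q, s in pairs], columns=["query", "subject", "evalue"]
    )


def _two_genome_ranks(n_a, n_b):
    ranks_a = {f"A{i}": ("a1", i) for i in range(n_a)}
    ranks_b = {f"B{i}": ("b1", i) for i in range(n_b)}
    return ranks_a, ranks_b


class TestCollinearity:
    def test_perfect_diagonal_is_one_same_block(self):
        ra, rb = _two_genome_ranks(10, 10)
        hits = _hits([(f"A{i}", f"B{i}") for i in range(10)])
        blocks = dup.detect_collinear_blocks(hits, ra, rb)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].score == 10

    def test_four_anchors_below_minimum(self):
        ra, rb = _two_genome_ranks(4, 4)
        hits = _hits([(f"A{i}", f"B{i}") for i in range(4)])
        assert dup.detect_collinear_blocks(hits, ra, rb) == []

    def test_reversed_order_is_inverted(self):
        ra, rb = _two_genome_ranks(10, 10)
        hits = _hits([(f"A{i}", f"B{9 - i}") for i in range(10)])
        blocks = dup.detect_collinear_blocks(hits, ra, rb)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        assert blocks[0].score == 10

    def test_gap_larger_than_max_breaks_chain(self):
        ra = {f"A{i}": ("a1", i) for i in range(100)}
        rb = {f"B{i}": ("b1", i) for i in range(100)}
        # two runs of 5 separated by a 30-rank jump on both axes
        pairs = [(f"A{i}", f"B{i}") for i in range(5)]
        pairs += [(f"A{i + 40}", f"B{i + 40}") for i in range(5)]
        blocks = dup.detect_collinear_blocks(_hits(pairs), ra, rb, max_gap=25)
        assert sorted(b.score for b in blocks) == [5, 5]

    def test_zero_hits_empty_result(self):
        assert dup.detect_collinear_blocks(_hits([]), {}, {}) == []

    def test_self_diagonal_local_duplicates_do_not_chain(self):
        # ten independent tandem pairs along one chromosome must not form
        # a collinear "block" in the self comparison
        ranks = {f"G{i}": ("c1", i) for i in range(40)}
        pairs = [(f"G{2 * i}", f"G{2 * i + 1}") for i in range(10)]
        assert dup.detect_collinear_blocks(_hits(pairs), ranks) == []

    def test_intra_genome_duplicated_segment_found(self):
        ranks = {f"G{i}": ("c1", i) for i in range(100)}
        hits = _hits([(f"G{i}", f"G{i + 60}") for i in range(8)])
        blocks = dup.detect_collinear_blocks(hits, ranks)
        assert len(blocks) == 1 and blocks[0].score == 8


def _best_chain_exhaustive(matches, orientation, max_gap):
    """Oracle: longest valid chain by full depth-first enumeration."""

    def ok(m1, m2):
        da = m2[0] - m1[0]
        db = m2[1] - m1[1] if orientation == "same" else m1[1] - m2[1]
        return 1 <= da <= max_gap and 1 <= db <= max_gap

    best = 0

    def extend(last, length):
        nonlocal best
        best = max(best, length)
        for m in matches:
            if ok(last, m):
                extend(m, length + 1)

    for m in matches:
        extend(m, 1)
    return best


class TestCollinearityOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_dp_chain_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 15))
        pts = {(int(rng.integers(0, 30)), int(rng.integers(0, 30))) for _ in range(n)}
        matches = sorted((ra, rb, f"A{ra}", f"B{rb}_{i}") for i, (ra, rb) in enumerate(pts))
        for orientation in ("same", "inverted"):
            dp_idx = dup._best_chain(matches, orientation, max_gap=10)
            assert len(dp_idx) == _best_chain_exhaustive(matches, orientation, 10)


class TestUniquePairs:
    def test_lowest_evalue_pair_retained(self):
        hits = pd.DataFrame(
            [("A", "B", 1e-50), ("A", "C", 1e-20)],
            columns=["query", "subject", "evalue"],
        )
        out = dup.select_unique_pairs(hits)
        pairs = set(map(tuple, out[["gene1", "gene2"]].values))
        # A's (and B's) best pair is A-B; A-C survives only as C's own best pair
        assert ("A", "B") in pairs
        assert pairs == {("A", "B"), ("A", "C")}

    def test_single_hit_kept(self):
        hits = pd.DataFrame([("A", "B", 1e-10)], columns=["query", "subject", "evalue"])
        out = dup.select_unique_pairs(hits)
        assert out.values.tolist() == [["A", "B", 1e-10]]

    def test_tie_breaks_lexicographically_and_is_order_invariant(self):
        rows = [("A", "B", 1e-50), ("A", "C", 1e-50)]
        results = []
        for perm in itertools.permutations(rows):
            hits = pd.DataFrame(perm, columns=["query", "subject", "evalue"])
            out = dup.select_unique_pairs(hits)
            results.append(sorted(map(tuple, out[["gene1", "gene2"]].values)))
        assert all(r == results[0] for r in results)
        assert ("A", "B") in results[0]  # lexicographically smaller partner wins for A


class TestClassifyPairs:
    INDEX = {
        "W1": ("c1", 0), "W2": ("c2", 0),  # WGD anchors
        "T1": ("c1", 5), "T2": ("c1", 6),  # adjacent
        "P1": ("c1", 7), "P2": ("c1", 13),  # 5 intervening
        "D1": ("c1", 7), "D2": ("c1", 19),  # 11 intervening
        "X1": ("c1", 30), "X2": ("c2", 30),
    }

    def _classify(self, pairs, wgd=frozenset(), syntenic=frozenset()):
        df = pd.DataFrame(pairs, columns=["gene1", "gene2"])
        df["evalue"] = 1e-50
        return dup.classify_pairs(df, self.INDEX, set(wgd), set(syntenic))

    def test_priority_wgd_beats_tandem(self):
        out = self._classify([("T1", "T2")], wgd={frozenset(("T1", "T2"))})
        assert out.loc[0, "dup_type"] == "WGD"

    def test_tandem_adjacent_ranks(self):
        assert self._classify([("T1", "T2")]).loc[0, "dup_type"] == "tandem"

    def test_proximal_within_ten_intervening(self):
        assert self._classify([("P1", "P2")]).loc[0, "dup_type"] == "proximal"

    def test_eleven_intervening_is_dispersed(self):
        assert self._classify([("D1", "D2")]).loc[0, "dup_type"] == "dispersed"

    def test_translocated_assigns_parent(self):
        out = self._classify([("X1", "X2")], syntenic={"X1"})
        assert out.loc[0, "dup_type"] == "translocated"
        assert out.loc[0, "parent"] == "X1"
        assert out.loc[0, "daughter"] == "X2"

    def test_both_syntenic_is_dispersed(self):
        out = self._classify([("X1", "X2")], syntenic={"X1", "X2"})
        assert out.loc[0, "dup_type"] == "dispersed"

    def test_symmetric_under_gene_swap(self):
        for pair in [("T1", "T2"), ("P1", "P2"), ("X1", "X2")]:
            a = self._classify([pair], syntenic={"X1"}).loc[0, "dup_type"]
            b = self._classify([pair[::-1]], syntenic={"X1"}).loc[0, "dup_type"]
            assert a == b

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError, match="ZZ"):
            self._classify([("ZZ", "T1")])


class TestEpoch:
    def test_rule_matches_exhaustive_enumeration(self):
        for flags in itertools.product([False, True], repeat=3):
            expected = 0
            for j, f in enumerate(flags, start=1):
                if f:
                    expected = j
                    break
            assert dup.assign_epoch(list(flags)) == expected

    def test_empty_ladder_undefined(self):
        assert dup.assign_epoch([]) is None

    @pytest.mark.parametrize(
        "flags,epoch", [([False] * 3, 0), ([False, True, True], 2), ([True, False, False], 1)]
    )
    def test_examples(self, flags, epoch):
        assert dup.assign_epoch(flags) == epoch


class TestPairClassAndSwitch:
    @pytest.mark.parametrize(
        "l1,l2,cls,flag",
        [
            ("gbM", "teM", "gbM-teM", "different"),
            ("teM", "gbM", "gbM-teM", "different"),
            ("unM", "unM", "unM-unM", "same"),
            ("unM", "teM", "unM-teM", "different"),
        ],
    )
    def test_pair_class(self, l1, l2, cls, flag):
        assert dup.pair_meth_class(l1, l2) == (cls, flag)

    def test_unclassified_gene_excludes_pair(self):
        assert dup.pair_meth_class("gbM", "unclassified") == (None, None)
        assert dup.pair_meth_class("missing", "teM") == (None, None)

    @pytest.mark.parametrize(
        "parent,daughter,expected",
        [("gbM", "teM", "to-teM"), ("unM", "unM", "same"), ("teM", "gbM", "to-gbM")],
    )
    def test_switch_direction(self, parent, daughter, expected):
        assert dup.switch_direction(parent, daughter) == expected

    def test_switch_requires_classified_labels(self):
        with pytest.raises(ValueError):
            dup.switch_direction("gbM", "missing")


class TestPlantedRecovery:
    def test_noise_free_recovery_is_exact(self, small_dataset):
        from methyldup import core_io

        g = small_dataset.genome
        hits = core_io.filter_hits(g.hits)
        blocks = dup.detect_collinear_blocks(hits, g.gene_index)
        oblocks = dup.detect_collinear_blocks(
            core_io.filter_hits(g.outgroup_hits), g.gene_index, g.outgroup_index
        )
        syntenic = dup.anchor_genes(blocks) | dup.anchor_genes(oblocks, side="a")
        pairs = dup.classify_pairs(
            dup.select_unique_pairs(hits), g.gene_index, dup.anchor_pairs(blocks), syntenic
        )
        got = {
            frozenset((r.gene1, r.gene2)): r.dup_type for r in pairs.itertuples()
        }
        for r in g.truth_pairs.itertuples():
            assert got[frozenset((r.gene1, r.gene2))] == r.dup_type
        # the five types partition the retained pairs
        assert pairs["dup_type"].isin(dup.DUP_TYPES).all()
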