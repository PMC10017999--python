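import itertools

import numpy as np
import pytest

from nlrevo import duptype
from nlrevo.io import GeneModel, HomologyPair


def gene(gene_id, start, seq_id="chr1", mapped=True, species="X"):
    return GeneModel(gene_id, species, seq_id, start, start + 999, "+",
                     is_chromosome=mapped)


def pair(a, b, identity=90.0, e=1e-50):
    a, b = sorted((a, b))
    return HomologyPair(a, b, identity, e)


class TestRankGenome:
    def test_ranks_follow_start_order(self):
        ranks = duptype.rank_genome([gene("a", 10), gene("b", 5), gene("c", 99)])
        assert [ranks[g].rank for g in ("a", "b", "c")] == [1, 0, 2]

    def test_independent_rank_spaces_per_seq(self):
        ranks = duptype.rank_genome([gene("a", 10), gene("b", 5, seq_id="chr2")])
        assert ranks["a"].rank == 0 and ranks["b"].rank == 0

    def test_tie_on_start_breaks_by_end_then_id(self):
        g1 = GeneModel("z", "X", "chr1", 10, 500, "+")
        g2 = GeneModel("a", "X", "chr1", 10, 900, "+")
        ranks = duptype.rank_genome([g1, g2])
        assert ranks["z"].rank == 0 and ranks["a"].rank == 1

    def test_unmapped_excluded(self):
        ranks = duptype.rank_genome([gene("a", 10, seq_id="sc", mapped=False)])
        assert ranks == {}


def brute_force_longest_chain(dots, max_gap):
    """Exhaustive best chain over all subsets (oracle for tiny instances)."""
    best = 0
    for r in range(1, len(dots) + 1):
        for combo in itertools.combinations(sorted(set(dots)), r):
            for sign in (+1, -1):
                chain = sorted(combo, key=lambda d: (d[0], sign * d[1]))
                ok = all(
                    1 <= b[0] - a[0] <= max_gap
                    and 1 <= sign * (b[1] - a[1]) <= max_gap
                    for a, b in zip(chain, chain[1:])
                )
                if ok:
                    best = max(best, r)
    return best


class TestChainCollinearBlocks:
    def _setup(self, positions_a, positions_b):
        genes = [gene(f"a{i}", 1000 * (i + 1)) for i in range(len(positions_a))]
        genes += [gene(f"b{i}", 1000 * (i + 1), seq_id="chr2")
                  for i in range(len(positions_b))]
        ranks = duptype.rank_genome(genes)
        return ranks

    def test_five_ordered_pairs_form_one_block(self):
        ranks = self._setup(range(5), range(5))
        pairs = [pair(f"a{i}", f"b{i}") for i in range(5)]
        (block,) = duptype.chain_collinear_blocks(pairs, ranks)
        assert len(block.pairs) == 5 and block.orientation == "+"
        assert len(block.pairs) == brute_force_longest_chain(
            [(i, i, "", "") for i in range(5)], 25)

    def test_four_pairs_below_threshold(self):
        ranks = self._setup(range(4), range(4))
        pairs = [pair(f"a{i}", f"b{i}") for i in range(4)]
        assert duptype.chain_collinear_blocks(pairs, ranks) == []

    def test_reversed_order_gives_inverted_block(self):
        ranks = self._setup(range(5), range(5))
        pairs = [pair(f"a{i}", f"b{4 - i}") for i in range(5)]
        (block,) = duptype.chain_collinear_blocks(pairs, ranks)
        assert len(block.pairs) == 5 and block.orientation == "-"
        assert brute_force_longest_chain(
            [(i, 4 - i, "", "") for i in range(5)], 25) == 5

    def test_gap_limit_splits_chains(self):
        # second dot jumps 30 ranks on axis b: exceeds max_gap_ranks=25
        genes = [gene(f"a{i}", 1000 * (i + 1)) for i in range(6)]
        genes += [gene(f"b{i}", 1000 * (i + 1), seq_id="chr2")
                  for i in range(40)]
        ranks = duptype.rank_genome(genes)
        mapping = [0, 1, 2, 3, 34, 35]
        pairs = [pair(f"a{i}", f"b{mapping[i]}") for i in range(6)]
        assert duptype.chain_collinear_blocks(pairs, ranks) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_first_block_matches_exhaustive_chain_length(self, seed):
        rng = np.random.default_rng(seed)
        n_dots = int(rng.integers(5, 11))
        genes = [gene(f"a{i}", 1000 * (i + 1)) for i in range(12)]
        genes += [gene(f"b{i}", 1000 * (i + 1), seq_id="chr2")
                  for i in range(12)]
        ranks = duptype.rank_genome(genes)
        coords = set()
        while len(coords) < n_dots:
            coords.add((int(rng.integers(0, 12)), int(rng.integers(0, 12))))
        pairs = [pair(f"a{x}", f"b{y}") for x, y in coords]
        blocks = duptype.chain_collinear_blocks(pairs, ranks,
                                                min_block_pairs=2, max_gap_ranks=4)
        expected = brute_force_longest_chain(
            [(x, y, "", "") for x, y in coords], 4)
        got = max((len(b.pairs) for b in blocks), default=0)
        if expected >= 2:
            assert got == expected
        else:
            assert blocks == []


class TestClassifyDuplications:
    def _ranks(self, n=20):
        genes = [gene(f"g{i}", 1000 * (i + 1)) for i in range(n)]
        return genes, duptype.rank_genome(genes)

    def test_adjacent_paralogs_are_tandem(self):
        genes, ranks = self._ranks()
        nlr = [genes[7], genes[8]]
        calls = duptype.classify_duplications(nlr, [pair("g7", "g8")], ranks, [])
        assert {c.dup_type for c in calls} == {"tandem"}

    def test_rank_distance_five_is_proximal(self):
        genes, ranks = self._ranks()
        nlr = [genes[7], genes[12]]
        calls = duptype.classify_duplications(nlr, [pair("g7", "g12")], ranks, [])
        assert {c.dup_type for c in calls} == {"proximal"}

    def test_beyond_proximal_gap_is_dispersed(self):
        genes, ranks = self._ranks()
        nlr = [genes[0], genes[15]]
        calls = duptype.classify_duplications(nlr, [pair("g0", "g15")], ranks, [])
        assert {c.dup_type for c in calls} == {"dispersed"}

    def test_no_paralog_is_singleton(self):
        genes, ranks = self._ranks()
        calls = duptype.classify_duplications([genes[3]], [], ranks, [])
        assert calls == [duptype.DuplicationCall("g3", "singleton")]

    def test_block_membership_outranks_tandem(self):
        genes, ranks = self._ranks()
        block = duptype.CollinearBlock(1, "chr1", "chr2", "+",
                                       [("g7", "other1")])
        nlr = [genes[7], genes[8]]
        calls = {c.gene_id: c.dup_type for c in duptype.classify_duplications(
            nlr, [pair("g7", "g8")], ranks, [block])}
        assert calls == {"g7": "wgd_segmental", "g8": "tandem"}

    def test_weak_homology_edges_ignored(self):
        genes, ranks = self._ranks()
        weak = HomologyPair("g7", "g8", 20.0, 1e-50)  # identity below cutoff
        calls = duptype.classify_duplications([genes[7], genes[8]], [weak],
                                              ranks, [])
        assert {c.dup_type for c in calls} == {"singleton"}

    def test_unmapped_genes_not_classified(self):
        genes, ranks = self._ranks()
        scaffold_gene = gene("u1", 5, seq_id="sc", mapped=False)
        calls = duptype.classify_duplications([scaffold_gene], [], ranks, [])
        assert calls == []

    def test_raising_min_block_pairs_never_adds_wgd_calls(self):
        genes = [gene(f"a{i}", 1000 * (i + 1)) for i in range(8)]
        genes += [gene(f"b{i}", 1000 * (i + 1), seq_id="chr2") for i in range(8)]
        ranks = duptype.rank_genome(genes)
        pairs = [pair(f"a{i}", f"b{i}") for i in range(6)]
        nlr = genes[:8]
        previous = None
        for mbp in (3, 5, 7):
            blocks = duptype.chain_collinear_blocks(pairs, ranks,
                                                    min_block_pairs=mbp)
            n_wgd = sum(
                c.dup_type == "wgd_segmental"
                for c in duptype.classify_duplications(nlr, pairs, ranks, blocks)
            )
            if previous is not None:
                assert n_wgd <= previous
            previous = n_wgd


class TestDuplicationSummary:
    @pytest.mark.parametrize("count,total,expected", [
        (58, 91, 63.74), (4, 149, 2.68), (89, 149, 59.73),
        (51, 102, 50.0), (58, 149, 38.93), (6, 102, 5.88), (1, 149, 0.67),
        (0, 7, 0.0),
    ])
    def test_worked_percentages(self, count, total, expected):
        summary = duptype.duplication_summary(
            {"dispersed": count, "singleton": total - count}, total)
        assert summary["dispersed"]["percent"] == expected

    def test_types_partition_classified_total(self):
        calls = ([duptype.DuplicationCall(f"t{i}", "tandem") for i in range(3)]
                 + [duptype.DuplicationCall("d1", "dispersed")])
        summary = duptype.duplication_summary(calls)
        assert sum(v["count"] for v in summary.values()) == 4
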