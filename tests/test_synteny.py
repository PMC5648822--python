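import numpy as np
import pytest

from syntelog_phylo.errors import ConfigurationError, ValidationError
from syntelog_phylo.synteny import (Anchor, _best_chain, build_anchors,
                                    chain_anchors, extract_syntelogs,
                                    infer_syntelogs, pairwise_syntelog_table,
                                    quota_filter)

from conftest import hit, make_annotation


def anchor(ra, rb, ga=None, gb=None, chrom_a="c1", chrom_b="c1", score=100.0):
    return Anchor(ga or f"a{ra}", gb or f"b{rb}", ra, rb, chrom_a, chrom_b, score)


class TestBuildAnchors:
    def setup_method(self):
        self.annot_a = make_annotation("A", {"c1": 20})
        self.annot_b = make_annotation("B", {"c1": 20})

    def test_best_bitscore_hit_wins_per_pair(self):
        hits = [hit("A_c1_000", "B_c1_000", bitscore=100.0),
                hit("A_c1_000", "B_c1_000", bitscore=80.0)]
        anchors = build_anchors(hits, self.annot_a, self.annot_b)
        assert len(anchors) == 1 and anchors[0].score == 100.0

    def test_evalue_threshold_excludes(self):
        hits = [hit("A_c1_000", "B_c1_000", evalue=1e-3)]
        assert build_anchors(hits, self.annot_a, self.annot_b) == []

    def test_identity_threshold_excludes(self):
        hits = [hit("A_c1_000", "B_c1_000", pident=80.0)]
        assert build_anchors(hits, self.annot_a, self.annot_b) == []
        kept = build_anchors(hits, self.annot_a, self.annot_b,
                             min_identity_pct=75.0)
        assert len(kept) == 1

    def test_empty_hits_give_empty_anchors(self):
        assert build_anchors([], self.annot_a, self.annot_b) == []

    def test_unknown_gene_id_is_validation_error(self):
        with pytest.raises(ValidationError, match="ghost"):
            build_anchors([hit("ghost", "B_c1_000")], self.annot_a, self.annot_b)


class TestChaining:
    def test_collinear_run_is_one_forward_block(self):
        anchors = [anchor(i, i) for i in range(10)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "+" and blocks[0].n_anchors == 10

    def test_large_rank_gap_splits_into_two_blocks(self):
        # first five consecutive, then a 26-rank jump in genome B
        anchors = [anchor(i, i) for i in range(5)]
        anchors += [anchor(5 + i, 30 + i) for i in range(5)]
        blocks = chain_anchors(anchors, min_anchors_per_block=5, max_gap_ranks=20)
        assert sorted(b.n_anchors for b in blocks) == [5, 5]

    def test_descending_rank_b_gives_reverse_orientation(self):
        anchors = [anchor(i, 10 - i) for i in range(6)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1 and blocks[0].orientation == "-"
        assert blocks[0].span_b == (5, 10)

    def test_short_chains_are_discarded(self):
        anchors = [anchor(i, i) for i in range(4)]
        assert chain_anchors(anchors, min_anchors_per_block=5) == []

    def test_decoy_anchor_leaves_other_blocks_unchanged(self, rng):
        base = [anchor(i, i) for i in range(12)]
        ref = chain_anchors(base)
        for _ in range(10):
            ra, rb = int(rng.integers(40, 90)), int(rng.integers(40, 90))
            noisy = base + [anchor(ra, rb, ga=f"x{ra}", gb=f"y{rb}")]
            got = chain_anchors(noisy)
            kept = [b for b in got
                    if all(a.gene_a.startswith("a") for a in b.anchors)]
            assert [(b.span_a, b.span_b, b.orientation) for b in kept] == \
                   [(b.span_a, b.span_b, b.orientation) for b in ref]

    def test_chain_score_matches_exhaustive_enumeration_small(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 11))
            anchors = [anchor(int(rng.integers(0, 15)), int(rng.integers(0, 15)),
                              ga=f"a{i}", gb=f"b{i}")
                       for i, _ in enumerate(range(k))]
            best_dp = max(_best_chain(anchors, 5, o)[0] for o in "+-")
            assert best_dp == brute_force_best_chain(anchors, 5)


def brute_force_best_chain(anchors, max_gap):
    """Exhaustive search over all monotone subsequences (oracle)."""
    order = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    best = 1 if order else 0

    def extend(idx, length, sign):
        nonlocal best
        best = max(best, length)
        for j in range(idx + 1, len(order)):
            da = order[j].rank_a - order[idx].rank_a
            db = sign * (order[j].rank_b - order[idx].rank_b)
            if 1 <= da <= max_gap and 1 <= db <= max_gap:
                extend(j, length + 1, sign)

    for sign in (1, -1):
        for i in range(len(order)):
            extend(i, 1, sign)
    return best


class TestQuotaFilter:
    def test_higher_score_block_wins_overlap(self):
        b = chain_anchors([anchor(i, i) for i in range(10)]
                          + [anchor(i, 40 + i, gb=f"bb{i}") for i in range(6)],
                          min_anchors_per_block=5)
        assert len(b) == 2  # both chains found before quota
        kept = quota_filter(b)
        assert len(kept) == 1 and kept[0].n_anchors == 10

    def test_disjoint_blocks_all_retained(self):
        anchors = [anchor(i, i) for i in range(5)]
        anchors += [anchor(50 + i, 50 + i, ga=f"c{i}", gb=f"d{i}") for i in range(5)]
        blocks = chain_anchors(anchors)
        assert len(quota_filter(blocks)) == len(blocks) == 2

    def test_non_unity_quota_not_implemented(self):
        with pytest.raises(NotImplementedError):
            quota_filter([], quota=(2, 1))


class TestExtractSyntelogs:
    def test_unique_anchors_become_pairs(self):
        blocks = quota_filter(chain_anchors([anchor(i, i) for i in range(5)]))
        pairs = extract_syntelogs(blocks)
        assert len(pairs) == 5
        assert {p.gene_a for p in pairs} == {f"a{i}" for i in range(5)}

    def test_gene_in_two_anchors_drops_both_pairs(self):
        blocks = [type("B", (), {"block_id": "b1", "anchors": [
            anchor(0, 0, ga="g7", gb="x1"),
            anchor(1, 1, ga="g8", gb="x2"),
        ]})(), type("B", (), {"block_id": "b2", "anchors": [
            anchor(5, 5, ga="g7", gb="x3"),
        ]})()]
        pairs = extract_syntelogs(blocks)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {("g8", "x2")}

    def test_one_to_one_invariant_on_simulation(self):
        from syntelog_phylo.simdata import emit_genome_hits, simulate_genome_pair
        a, b, truth = simulate_genome_pair(n_chromosomes=2,
                                           genes_per_chromosome=150, seed=9)
        _, pairs = infer_syntelogs(emit_genome_hits(truth, seed=10), a, b)
        ga = [p.gene_a for p in pairs]
        gb = [p.gene_b for p in pairs]
        assert len(ga) == len(set(ga)) and len(gb) == len(set(gb))


class TestPairwiseTable:
    def _scenario(self):
        pivot = make_annotation("P", {"c1": 30})
        g1 = make_annotation("G1", {"c1": 30})
        g2 = make_annotation("G2", {"c1": 30})
        mk = lambda other: [hit(f"P_c1_{i:03d}", f"{other}_c1_{i:03d}")
                            for i in range(30)]
        return pivot, [g1, g2], {"G1": mk("G1"), "G2": mk("G2")}

    def test_per_genome_tables_satisfy_one_to_one(self):
        pivot, others, tables = self._scenario()
        out = pairwise_syntelog_table(pivot, others, tables)
        assert set(out) == {"G1", "G2"}
        for pairs in out.values():
            assert len({p.gene_a for p in pairs}) == len(pairs) == 30

    def test_missing_hit_table_is_configuration_error(self):
        pivot, others, tables = self._scenario()
        del tables["G2"]
        with pytest.raises(ConfigurationError, match="G2"):
            pairwise_syntelog_table(pivot, others, tables)
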