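import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_longest_chain
from synkaryo.collinearity import (
    AnchorPair,
    CollinearBlock,
    block_census,
    block_significance,
    detect_blocks,
    longest_chain_length,
    read_blocks,
    write_blocks,
)
from synkaryo.genome_model import Gene, GenomePanel, HomologyHit


def panels_with_dots(dots, len_a=20, len_b=20):
    """Panels plus hits realizing the given (order_a, order_b) anchor dots."""
    pa = GenomePanel(
        "A", [Gene(f"a{i}", "ca", 10 * i + 1, 10 * i + 5, "+") for i in range(len_a)]
    )
    pb = GenomePanel(
        "B", [Gene(f"b{i}", "cb", 10 * i + 1, 10 * i + 5, "+") for i in range(len_b)]
    )
    hits = [HomologyHit(f"a{x}", f"b{y}", 90.0, 1e-20, 100.0) for x, y in dots]
    return pa, pb, hits


class TestDetectBlocks:
    def test_perfect_diagonal_one_same_block(self):
        pa, pb, hits = panels_with_dots([(1, 1), (2, 2), (3, 3)])
        blocks = detect_blocks(
            hits, pa, pb, min_len=3, p_threshold=1.01, permutations=100
        )
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "same" and b.length == 3
        assert [(p.order_a, p.order_b) for p in b.pairs] == [(1, 1), (2, 2), (3, 3)]

    def test_antidiagonal_inverted_block(self):
        pa, pb, hits = panels_with_dots([(1, 10), (2, 8), (3, 6)])
        blocks = detect_blocks(
            hits, pa, pb, min_len=3, p_threshold=1.01, permutations=100
        )
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_gap_bound_splits_distant_runs(self):
        # two diagonal runs separated by a rank jump far beyond max_gap
        pa, pb, hits = panels_with_dots(
            [(0, 0), (1, 1), (2, 2), (15, 15), (16, 16), (17, 17)], 20, 20
        )
        blocks = detect_blocks(
            hits, pa, pb, max_gap=5, min_len=3, p_threshold=1.01, permutations=100
        )
        assert sorted(b.length for b in blocks) == [3, 3]

    def test_max_gap_validation(self, tiny_panels):
        pa, pb = tiny_panels
        with pytest.raises(ValueError):
            detect_blocks([], pa, pb, max_gap=0)

    def test_self_comparison_drops_self_diagonal(self):
        pa = GenomePanel(
            "A", [Gene(f"a{i}", "ca", 10 * i + 1, 10 * i + 5, "+") for i in range(6)]
        )
        hits = [HomologyHit(f"a{i}", f"a{i}", 100.0, 0.0, 500.0) for i in range(6)]
        assert detect_blocks(hits, pa, pa, min_len=3, p_threshold=1.01) == []

    def test_emitted_blocks_satisfy_monotonicity_and_gap_bound(self, wgd_sim):
        res = wgd_sim
        max_gap = 50
        blocks = detect_blocks(
            res.hits_ab, res.panel_a, res.panel_b, max_gap=max_gap, permutations=150
        )
        assert blocks, "expected blocks from a WGD simulation"
        for b in blocks:
            oa = [p.order_a for p in b.pairs]
            ob = [p.order_b for p in b.pairs]
            assert all(x < y <= x + max_gap + 1 for x, y in zip(oa, oa[1:]))
            sb = ob if b.orientation == "same" else [-v for v in ob]
            assert all(x < y <= x + max_gap + 1 for x, y in zip(sb, sb[1:]))
            assert 0.0 <= b.p_value <= 1.0

    @pytest.mark.parametrize("trial", range(40))
    def test_dp_equals_exhaustive_longest_chain(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(2, 51))
        oa = rng.integers(0, 60, size=n)
        ob = rng.integers(0, 60, size=n)
        max_gap = int(rng.integers(1, 20))
        assert longest_chain_length(oa, ob, max_gap) == oracle_longest_chain(
            oa.tolist(), ob.tolist(), max_gap
        )


class TestSignificance:
    def test_long_block_among_few_anchors_significant(self):
        p = block_significance(
            20, 30, (1000, 1000), max_gap=50, permutations=500, seed=1
        )
        assert p < 0.05

    def test_trivial_two_anchor_block_not_significant(self):
        p = block_significance(2, 2, (10, 10), max_gap=50, permutations=500, seed=1)
        assert p > 0.5

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            block_significance(5, 10, (100, 100), permutations=0)

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            block_significance(5, 10, (100, 100), permutations=50, seed=0)

    def test_deterministic_given_seed(self):
        args = dict(max_gap=30, permutations=300, seed=9)
        assert block_significance(8, 20, (200, 200), **args) == block_significance(
            8, 20, (200, 200), **args
        )


def _dummy_block(length, ca="c1", cb="c2"):
    pairs = [AnchorPair(f"x{i}", f"y{i}", i, i) for i in range(length)]
    return CollinearBlock(ca, cb, pairs, "same", 0.001)


class TestCensus:
    def test_census_counts_by_threshold(self):
        blocks = [_dummy_block(n) for n in (3, 12, 60)]
        tab = block_census(blocks)
        assert tab.block_count.tolist() == [2, 2, 1, 1]
        assert tab.threshold.tolist() == [4, 10, 20, 50]
        assert tab.largest_block.iloc[0] == 60

    def test_empty_census_all_zero(self):
        tab = block_census([])
        assert tab.block_count.tolist() == [0, 0, 0, 0]
        assert tab.gene_pair_count.tolist() == [0, 0, 0, 0]

    @given(st.lists(st.integers(1, 80), max_size=15))
    @settings(max_examples=40, deadline=None)
    def test_census_monotone_in_threshold(self, lengths):
        tab = block_census([_dummy_block(n) for n in lengths])
        counts = tab.block_count.tolist()
        assert counts == sorted(counts, reverse=True)

    def test_simulated_census_matches_planted_structure(self, lossless_sim):
        # lossless WGD: every query chromosome pairs with both copies,
        # each a full-length diagonal
        res = lossless_sim
        blocks = detect_blocks(
            res.hits_ab, res.panel_a, res.panel_b, permutations=150
        )
        g = res.config.genes_per_chromosome
        assert len(blocks) == 2 * res.config.ancestral_chromosomes
        assert all(b.length == g for b in blocks)
        tab = block_census(blocks)
        assert tab.loc[tab.threshold == 10, "block_count"].item() == len(blocks)


def test_block_write_read_round_trip(tmp_path):
    blocks = [_dummy_block(4), _dummy_block(6, "c3", "c4")]
    path = tmp_path / "blocks.tsv"
    write_blocks(blocks, str(path))
    back = read_blocks(str(path))
    assert len(back) == 2
    assert back[1].chrom_a == "c3" and back[1].length == 6
    assert back[0].pairs == blocks[0].pairs
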