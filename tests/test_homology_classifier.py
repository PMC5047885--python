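import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synkaryo.collinearity import AnchorPair, CollinearBlock, detect_blocks
from synkaryo.homology_classifier import (
    CorrespondenceMap,
    DepthExpectation,
    build_correspondence,
    classify_by_ks,
    depth_check,
    resolve_by_sharing,
    shared_gene_percentage,
)


def _block(query_chrom, subject_chrom, query_genes, start=0):
    pairs = [
        AnchorPair(q, f"{subject_chrom}:{i}", start + i, start + i)
        for i, q in enumerate(query_genes)
    ]
    return CollinearBlock(query_chrom, subject_chrom, pairs, "same", 0.001)


class TestClassifyByKs:
    @pytest.mark.parametrize(
        "ks,label",
        [
            (1.05, "orthologous"),
            (0.95, "orthologous"),
            (1.20, "orthologous"),
            (1.5, "outparalogous"),
            (1.36, "outparalogous"),
            (1.30, "ambiguous"),
            (2.0, "ambiguous"),
            (0.4, "ambiguous"),
            (None, "ambiguous"),
        ],
    )
    def test_window_labels(self, ks, label):
        bc = classify_by_ks(_block("q", "s", ["g1"]), ks)
        assert bc.label == label

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            classify_by_ks(_block("q", "s", ["g1"]), 1.0, ortho_window=(1.2, 0.9))

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    @settings(max_examples=80, deadline=None)
    def test_monotone_no_outpara_to_ortho_on_increase(self, k1, k2):
        lo, hi = sorted((k1, k2))
        rank = {"orthologous": 0, "ambiguous": 1, "outparalogous": 2}
        b = _block("q", "s", ["g1"])
        l_lo = classify_by_ks(b, lo).label
        l_hi = classify_by_ks(b, hi).label
        if l_lo == "outparalogous":
            assert rank[l_hi] >= 1 or hi <= 1.65  # never back into the window above it
        if lo >= 1.20:  # beyond the orthology window nothing maps back to it
            assert l_lo != "orthologous" or lo <= 1.20
            if l_hi == "orthologous":
                assert hi <= 1.20


class TestResolveBySharing:
    def ac19_blocks(self):
        """The printed worked example: 107, 51 and 135 collinear genes of one
        query chromosome against three subject chromosomes; the big pair
        shares 45 query genes, the third shares only 5 with each."""
        q = [f"ac19_g{i}" for i in range(300)]
        os02 = q[:107]
        os06 = q[:45] + q[107 : 107 + 90]  # 45 shared with Os02, 135 total
        os04 = q[:5] + q[200 : 200 + 46]  # 5 shared with each, 51 total
        return [
            _block("Ac19", "Os02", os02),
            _block("Ac19", "Os06", os06),
            _block("Ac19", "Os04", os04),
        ]

    def test_worked_example_resolution(self):
        out = resolve_by_sharing("Ac19", ["Os02", "Os04", "Os06"], self.ac19_blocks())
        assert out["Os02"]["label"] == "orthologous"
        assert out["Os06"]["label"] == "orthologous"
        assert out["Os04"]["label"] == "outparalogous"
        assert out["Os02"]["anchors"] == 107
        assert out["Os04"]["anchors"] == 51
        assert out["Os06"]["anchors"] == 135
        assert "42.1%" in out["Os02"]["evidence"]

    def test_printed_percentages(self):
        assert shared_gene_percentage(5, 107) == 4.7
        assert shared_gene_percentage(45, 107) == 42.1

    def test_full_mutual_sharing_both_coortholog(self):
        q = [f"g{i}" for i in range(30)]
        blocks = [_block("qc", "s1", q), _block("qc", "s2", q)]
        out = resolve_by_sharing("qc", ["s1", "s2"], blocks)
        assert {v["label"] for v in out.values()} == {"orthologous"}

    def test_candidate_order_invariance(self):
        blocks = self.ac19_blocks()
        a = resolve_by_sharing("Ac19", ["Os02", "Os04", "Os06"], blocks)
        b = resolve_by_sharing("Ac19", ["Os06", "Os02", "Os04"], blocks)
        assert a == b

    def test_zero_anchor_candidate_excluded_with_warning(self):
        blocks = self.ac19_blocks()
        with pytest.warns(UserWarning, match="Os99"):
            out = resolve_by_sharing("Ac19", ["Os02", "Os06", "Os99"], blocks)
        assert out["Os99"]["label"] == "excluded"

    def test_planted_truth_recovered_on_simulation(self):
        from synkaryo.synthetic_data import SimulationConfig, simulate

        cfg = SimulationConfig(
            seed=3,
            ancestral_chromosomes=2,
            genes_per_chromosome=100,
            codons_per_gene=120,
            wgd_in_lineage_b=True,
            per_copy_loss_rate=0.4,
            ks_split=1.05,
            ks_wgd=0.6,
            ancient_dup_chrom="chr1",
            ks_ancient=1.5,
            ancient_loss_rate=0.8,
        )
        res = simulate(cfg)
        blocks = detect_blocks(
            res.hits_ab, res.panel_a, res.panel_b, permutations=150, seed=3
        )
        out = resolve_by_sharing("chr1", ["chr1a", "chr1b", "chr1da", "chr1db"], blocks)
        assert out["chr1a"]["label"] == "orthologous"
        assert out["chr1b"]["label"] == "orthologous"
        assert out["chr1da"]["label"] in ("outparalogous", "excluded")
        assert out["chr1db"]["label"] in ("outparalogous", "excluded")


class TestCorrespondence:
    def _classified(self, blocks, label="orthologous"):
        return [classify_by_ks(b, 1.0 if label == "orthologous" else 1.5) for b in blocks]

    def test_two_blocks_build_expected_map(self):
        blocks = [
            _block("Ac08", "Os10", [f"a{i}" for i in range(30)]),
            _block("Ac15", "Os10", [f"b{i}" for i in range(25)]),
        ]
        cmap = build_correspondence(self._classified(blocks))
        assert cmap.corr("Os10") == {"Ac08", "Ac15"}
        assert cmap.anchors["Os10"]["Ac08"] == 30

    def test_small_scrap_excluded_by_min_anchor(self):
        blocks = [
            _block("Ac08", "Os10", [f"a{i}" for i in range(30)]),
            _block("Ac03", "Os10", ["s1", "s2", "s3"]),
        ]
        cmap = build_correspondence(self._classified(blocks), min_anchor=10)
        assert cmap.corr("Os10") == {"Ac08"}
        assert cmap.query_corr("Ac03") == set()

    def test_outparalogous_blocks_do_not_contribute(self):
        blocks = [_block("Ac08", "Os10", [f"a{i}" for i in range(30)])]
        cmap = build_correspondence(self._classified(blocks, "outparalogous"))
        assert cmap.corr("Os10") == set()


class TestDepthCheck:
    def test_empty_map_all_zero(self):
        report = depth_check(CorrespondenceMap(), [f"g{i}" for i in range(5)])
        assert report["histogram"] == {"0": 5, "1": 0, "2": 0, ">2": 0}

    def test_lossless_wgd_all_depth_two(self, lossless_sim):
        res = lossless_sim
        blocks = detect_blocks(
            res.hits_ab, res.panel_a, res.panel_b, permutations=150
        )
        classified = [classify_by_ks(b, 1.0) for b in blocks]
        cmap = build_correspondence(classified)
        report = depth_check(cmap, sorted(res.panel_a.genes))
        assert report["histogram"]["2"] == report["n_genes"]
        assert report["over_expectation"] == []

    def test_depth_expectation_validation(self):
        with pytest.raises(ValueError):
            DepthExpectation(0, 2)
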