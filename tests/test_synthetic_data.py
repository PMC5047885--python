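import dataclasses

import numpy as np
import pytest

from synkaryo.genome_model import write_annotations, write_cds
from synkaryo.synthetic_data import (
    ConfigError,
    EventLog,
    IncompleteLogError,
    SimulationConfig,
    derive_trios,
    replay,
    scenario_presets,
    simulate,
)


class TestDeterminism:
    def test_same_seed_same_genomes_and_files(self, tmp_path):
        cfg = SimulationConfig(
            seed=99, ancestral_chromosomes=2, genes_per_chromosome=25,
            codons_per_gene=60, wgd_in_lineage_b=True, per_copy_loss_rate=0.3,
            translocation_rate=0.02, inversion_rate=0.01,
        )
        r1, r2 = simulate(cfg), simulate(cfg)
        assert r1.panel_a.cds == r2.panel_a.cds
        assert r1.panel_b.cds == r2.panel_b.cds
        assert r1.event_log.events == r2.event_log.events
        assert r1.hits_ab == r2.hits_ab
        for res, d in ((r1, "one"), (r2, "two")):
            out = tmp_path / d
            out.mkdir()
            write_annotations(res.panel_b, str(out / "b.gff3"))
            write_cds(res.panel_b.cds, str(out / "b.fa"))
        assert (tmp_path / "one/b.gff3").read_bytes() == (tmp_path / "two/b.gff3").read_bytes()
        assert (tmp_path / "one/b.fa").read_bytes() == (tmp_path / "two/b.fa").read_bytes()

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(seed=1, ancestral_chromosomes=1,
                               genes_per_chromosome=10, codons_per_gene=30)
        r1 = simulate(cfg)
        r2 = simulate(dataclasses.replace(cfg, seed=2))
        assert r1.panel_a.cds != r2.panel_a.cds


class TestStructure:
    def test_no_events_identical_gene_orders(self):
        cfg = SimulationConfig(
            seed=4, ancestral_chromosomes=2, genes_per_chromosome=15,
            codons_per_gene=30, wgd_in_lineage_b=False,
            per_copy_loss_rate=0.0, ks_split=0.0, ks_wgd=0.0,
        )
        res = simulate(cfg)
        for chrom in res.panel_a.chromosomes:
            a_units = [g.id.split("_", 1)[1] for g in res.panel_a.gene_order(chrom)]
            b_units = [g.id.split("_", 1)[1] for g in res.panel_b.gene_order(chrom)]
            assert a_units == b_units
        # zero divergence: identical sequences
        for gid, seq in res.panel_a.cds.items():
            unit = res.event_log.ancestry[gid]["ancestral_gene"]
            assert res.panel_b.cds["B1_" + unit] == seq

    def test_wgd_with_two_fusions_gives_twelve_chromosomes(self):
        cfg = SimulationConfig(
            seed=8, ancestral_chromosomes=7, genes_per_chromosome=20,
            codons_per_gene=30, wgd_in_lineage_b=True,
            fusion_events=[("chr1a", "chr2a"), ("chr3a", "chr4a")],
        )
        res = simulate(cfg)
        assert len(res.panel_b.chromosomes) == 12
        assert len(res.panel_a.chromosomes) == 7

    def test_cej_trim_drops_terminal_genes(self):
        cfg = SimulationConfig(
            seed=8, ancestral_chromosomes=2, genes_per_chromosome=20,
            codons_per_gene=30, wgd_in_lineage_b=True,
            fusion_events=[("chr1a", "chr2a")], cej_trim=2,
        )
        res = simulate(cfg)
        ev = res.event_log.events_of("fusion")[0]
        assert len(ev["trimmed"]) == 4
        assert ev["junction_rank"] == 18
        assert len(res.panel_b.gene_order("chr1a-chr2a")) == 36

    def test_fission_breakpoint_validation(self):
        cfg = SimulationConfig(
            seed=1, ancestral_chromosomes=1, genes_per_chromosome=10,
            codons_per_gene=30, fission_events=[("B:chr1a", 25)],
        )
        with pytest.raises(ConfigError, match="breakpoint"):
            simulate(cfg)

    def test_conservation_against_event_log(self):
        cfg = SimulationConfig(
            seed=13, ancestral_chromosomes=2, genes_per_chromosome=30,
            codons_per_gene=30, wgd_in_lineage_b=True, per_copy_loss_rate=0.4,
            fusion_events=[("chr1a", "chr2a")],
        )
        res = simulate(cfg)
        log = res.event_log
        n_lost = sum(len(e["genes"]) for e in log.events_of("loss"))
        n_trimmed = sum(len(e["trimmed"]) for e in log.events_of("fusion"))
        ancestral_units = 2 * 30
        assert len(res.panel_a) == ancestral_units
        assert len(res.panel_b) == ancestral_units * 2 - n_lost - n_trimmed


class TestReplay:
    def test_replay_reproduces_simulation(self, wgd_sim):
        pa, pb = replay(wgd_sim.event_log, wgd_sim.ancestor)
        assert pa.cds == wgd_sim.panel_a.cds
        assert pb.cds == wgd_sim.panel_b.cds
        for chrom in wgd_sim.panel_b.chromosomes:
            assert [g.id for g in pb.gene_order(chrom)] == [
                g.id for g in wgd_sim.panel_b.gene_order(chrom)
            ]

    def test_truncated_log_raises_incompleteness(self, wgd_sim):
        broken = EventLog(wgd_sim.config, wgd_sim.event_log.events[:-1])
        with pytest.raises(IncompleteLogError):
            replay(broken, wgd_sim.ancestor)


class TestDivergence:
    def test_hits_respect_top_n_and_family_truth(self, wgd_sim):
        res = wgd_sim
        per_query = {}
        for h in res.hits_ab:
            per_query.setdefault(h.query_gene, []).append(h)
            assert h.evalue <= 1e-5
        assert max(len(v) for v in per_query.values()) <= 5
        for q, hs in list(per_query.items())[:50]:
            fam = res.event_log.ancestry[q]["family"]
            for h in hs:
                assert res.event_log.ancestry[h.subject_gene]["family"] == fam

    def test_wgd_paralog_divergence_below_ortholog(self, wgd_sim):
        from synkaryo.ks_estimator import pairwise_ks

        res = wgd_sim
        ortho, para = [], []
        for gid in sorted(res.panel_a.genes)[:60]:
            unit = res.event_log.ancestry[gid]["ancestral_gene"]
            b1, b2 = "B1_" + unit, "B2_" + unit
            if b1 in res.panel_b.cds:
                ortho.append(pairwise_ks(res.panel_a.cds[gid], res.panel_b.cds[b1]).ks)
            if b1 in res.panel_b.cds and b2 in res.panel_b.cds:
                para.append(pairwise_ks(res.panel_b.cds[b1], res.panel_b.cds[b2]).ks)
        ortho = [k for k in ortho if k is not None]
        para = [k for k in para if k is not None]
        assert abs(np.mean(ortho) - res.config.ks_split) < 0.15
        assert abs(np.mean(para) - res.config.ks_wgd) < 0.15


class TestPresets:
    def test_preset_catalog(self):
        presets = scenario_presets()
        assert {"fusion_C", "fission_A", "fission_B", "grass_like"} <= set(presets)
        grass = presets["grass_like"]
        assert grass.ancestral_chromosomes == 7
        assert grass.wgd_in_lineage_b and len(grass.fusion_events) == 2
        assert grass.per_copy_loss_rate == 0.4 and grass.loss_timing == "before_merge"

    def test_grass_like_reaches_twelve_chromosomes(self):
        cfg = dataclasses.replace(scenario_presets()["grass_like"], seed=0)
        res = simulate(cfg)
        assert len(res.panel_b.chromosomes) == 12

    def test_fission_preset_logs_exactly_one_fission(self):
        cfg = dataclasses.replace(scenario_presets()["fission_A"], seed=0)
        res = simulate(cfg)
        assert len(res.event_log.events_of("fission")) == 1

    def test_derived_trios_name_expected_verdicts(self):
        presets = scenario_presets()
        assert derive_trios(presets["fusion_C"]) == [
            ("chr1a-chr2a", "chr1b", "chr2b", "fusion")
        ]
        (merged, p1, p2, truth), = derive_trios(presets["fission_A"])
        assert truth == "fission" and merged == "chr1a"
        assert {p1, p2} == {"chr1b.1", "chr1b.2"}

    def test_config_round_trips_through_json(self, tmp_path):
        cfg = scenario_presets()["grass_like"]
        rebuilt = SimulationConfig.from_dict(cfg.to_dict())
        assert rebuilt == cfg

    def test_loss_timing_recorded(self):
        cfg = dataclasses.replace(
            scenario_presets()["fusion_C"], seed=3, loss_timing="after_merge"
        )
        res = simulate(cfg)
        kinds = [e["kind"] for e in res.event_log.events]
        assert kinds.index("fusion") < kinds.index("loss")
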