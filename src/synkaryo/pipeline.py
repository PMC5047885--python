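"""End-to-end orchestration: collinearity -> Ks -> classification ->
correspondence -> trio tests -> fractionation, with a written report bundle.

Every stage writes its table into the output directory; ``manifest.json``
records all parameters, the package version and per-stage status, and is
sufficient to reproduce the run exactly (all randomness flows from the one
seed). Reports contain no timestamps, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

from . import __version__
from .collinearity import CollinearBlock, block_census, detect_blocks, write_blocks
from .fractionation import absent_gene_triage, retention_census
from .fusion_fission import (
    AncestralCount,
    FusionModelSpec,
    TrioVerdict,
    infer_ancestral_count,
    test_trio,
)
from .genome_model import GenomePanel, HomologyHit
from .homology_classifier import (
    BlockClassification,
    build_correspondence,
    classify_by_ks,
)
from .ks_estimator import KsEstimate, block_ks_median, pairwise_ks

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters plus the input objects of one comparison run."""

    panel_query: GenomePanel
    panel_subject: GenomePanel
    hits: Sequence[HomologyHit]
    outdir: str
    hits_reverse: Sequence[HomologyHit] | None = None
    seed: int = 0
    max_gap: int = 50
    p_threshold: float = 0.05
    min_len: int = 5
    permutations: int = 1000
    census_thresholds: tuple[int, ...] = (4, 10, 20, 50)
    ortho_window: tuple[float, float] = (0.95, 1.20)
    outpara_center: float = 1.5
    outpara_margin: float = 0.15
    min_anchor: int = 10
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    wgd: bool = True
    triage_evalue: float = 1e-10

    def params_dict(self) -> dict:
        skip = {"panel_query", "panel_subject", "hits", "hits_reverse", "outdir"}
        d = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in skip
        }
        d["trios"] = [list(t) for t in self.trios]
        d["census_thresholds"] = list(self.census_thresholds)
        d["ortho_window"] = list(self.ortho_window)
        return d


@dataclass
class PipelineReport:
    blocks: list[CollinearBlock] = field(default_factory=list)
    census: object = None
    ks_by_pair: dict[tuple[str, str], KsEstimate] = field(default_factory=dict)
    classifications: list[BlockClassification] = field(default_factory=list)
    cmap: object = None
    trio_verdicts: list[TrioVerdict] = field(default_factory=list)
    ancestral: AncestralCount | None = None
    retention_records: list = field(default_factory=list)
    retention_summary: object = None
    triage_counts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute all stages; partial outputs are preserved on failure and the
    manifest records the failure point before the exception propagates."""
    os.makedirs(cfg.outdir, exist_ok=True)
    rep = PipelineReport()
    manifest: dict = {
        "package": "synkaryo",
        "version": __version__,
        "parameters": cfg.params_dict(),
        "inputs": {
            "query_species": cfg.panel_query.species,
            "subject_species": cfg.panel_subject.species,
            "n_query_genes": len(cfg.panel_query),
            "n_subject_genes": len(cfg.panel_subject),
            "n_hits": len(cfg.hits),
        },
        "stages": {},
    }
    rep.manifest = manifest

    def out(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    stage = "collinearity"
    try:
        rep.blocks = detect_blocks(
            cfg.hits,
            cfg.panel_query,
            cfg.panel_subject,
            max_gap=cfg.max_gap,
            p_threshold=cfg.p_threshold,
            min_len=cfg.min_len,
            permutations=cfg.permutations,
            seed=cfg.seed,
        )
        write_blocks(rep.blocks, out("blocks.tsv"))
        rep.census = block_census(rep.blocks, cfg.census_thresholds)
        rep.census.to_csv(out("census.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = "ok"

        stage = "ks"
        cds_q, cds_s = cfg.panel_query.cds, cfg.panel_subject.cds
        with open(out("ks_pairs.tsv"), "w") as fh:
            fh.write("block_id\tgene_a\tgene_b\tS\tN\tsd\tpS\tks\tka\n")
            for b in rep.blocks:
                for p in b.pairs:
                    key = (p.gene_a, p.gene_b)
                    if key in rep.ks_by_pair:
                        continue
                    if p.gene_a not in cds_q or p.gene_b not in cds_s:
                        continue
                    est = pairwise_ks(cds_q[p.gene_a], cds_s[p.gene_b])
                    rep.ks_by_pair[key] = est
                    fh.write(
                        f"{b.block_id}\t{p.gene_a}\t{p.gene_b}\t{est.S:.2f}\t"
                        f"{est.N:.2f}\t{est.sd:.2f}\t{est.pS:.4f}\t"
                        f"{'' if est.ks is None else f'{est.ks:.4f}'}\t"
                        f"{'' if est.ka is None else f'{est.ka:.4f}'}\n"
                    )
        manifest["stages"][stage] = "ok"

        stage = "classification"
        for b in rep.blocks:
            ks_vals = [
                rep.ks_by_pair[(p.gene_a, p.gene_b)].ks
                for p in b.pairs
                if (p.gene_a, p.gene_b) in rep.ks_by_pair
            ]
            med = block_ks_median(ks_vals)
            rep.classifications.append(
                classify_by_ks(
                    b,
                    med,
                    ortho_window=cfg.ortho_window,
                    outpara_center=cfg.outpara_center,
                    margin=cfg.outpara_margin,
                )
            )
        with open(out("classification.tsv"), "w") as fh:
            fh.write("block_id\tchrom_query\tchrom_subject\tlength\tks_median\tlabel\tevidence\n")
            for c in rep.classifications:
                med = "" if c.ks_median is None else f"{c.ks_median:.4f}"
                fh.write(
                    f"{c.block.block_id}\t{c.block.chrom_a}\t{c.block.chrom_b}\t"
                    f"{c.block.length}\t{med}\t{c.label}\t{c.evidence}\n"
                )
        manifest["stages"][stage] = "ok"

        stage = "correspondence"
        rep.cmap = build_correspondence(rep.classifications, min_anchor=cfg.min_anchor)
        with open(out("correspondence.tsv"), "w") as fh:
            fh.write("subject_chrom\tquery_chrom\torthologous_anchors\n")
            for s, q, n in rep.cmap.to_table():
                fh.write(f"{s}\t{q}\t{n}\n")
        _write_json(
            {s: sorted(rep.cmap.corr(s)) for s in rep.cmap.subject_chromosomes},
            out("correspondence.json"),
        )
        manifest["stages"][stage] = "ok"

        stage = "trio_tests"
        for merged, pa, pb in cfg.trios:
            rep.trio_verdicts.append(
                test_trio(FusionModelSpec(merged, pa, pb), rep.cmap)
            )
        with open(out("trios.tsv"), "w") as fh:
            fh.write("merged\tpart_a\tpart_b\tjaccard_parts\tcoverage\tverdict\treason\n")
            for v in rep.trio_verdicts:
                fh.write(
                    f"{v.spec.merged}\t{v.spec.part_a}\t{v.spec.part_b}\t"
                    f"{v.jaccard_parts:.4f}\t{v.coverage:.4f}\t{v.verdict}\t{v.reason}\n"
                )
        rep.ancestral = infer_ancestral_count(
            len(cfg.panel_subject.chromosomes), rep.trio_verdicts, wgd=cfg.wgd
        )
        _write_json(
            {
                "x": rep.ancestral.x,
                "x_interval": list(rep.ancestral.x_interval),
                "two_n_pre": rep.ancestral.two_n_pre,
                "two_n_post": rep.ancestral.two_n_post,
                "n_fusions": rep.ancestral.n_fusions,
                "n_fissions": rep.ancestral.n_fissions,
                "n_undetermined": rep.ancestral.n_undetermined,
                "observed_subject_chromosomes": len(cfg.panel_subject.chromosomes),
            },
            out("ancestral.json"),
        )
        manifest["stages"][stage] = "ok"

        stage = "fractionation"
        ortho_blocks = [c.block for c in rep.classifications if c.label == "orthologous"]
        rep.retention_records, rep.retention_summary = retention_census(
            cfg.panel_query, ortho_blocks
        )
        rep.triage_counts = absent_gene_triage(
            rep.retention_records,
            cfg.hits if cfg.hits else None,
            reverse_hits=cfg.hits_reverse,
            evalue_max=cfg.triage_evalue,
        )
        with open(out("retention.tsv"), "w") as fh:
            fh.write("gene\tclass\tsubject_chromosomes\tsubclass\tunplaced\n")
            for r in rep.retention_records:
                fh.write(
                    f"{r.gene_id}\t{r.retention_class}\t"
                    f"{','.join(r.subject_chromosomes)}\t{r.subclass or ''}\t"
                    f"{int(r.unplaced)}\n"
                )
        _write_json(
            {
                "total_query_genes": rep.retention_summary.total,
                "counts": rep.retention_summary.counts,
                "proportions": {
                    k: round(v, 6) for k, v in rep.retention_summary.proportions.items()
                },
                "absent_triage": rep.triage_counts,
                "n_unplaced": rep.retention_summary.n_unplaced,
            },
            out("fractionation.json"),
        )
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_json(manifest, out("manifest.json"))
        raise
    _write_json(manifest, out("manifest.json"))
    return rep
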