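"""Formal fusion-vs-fission test on chromosome trios and ancestral counts.

A trio is (merged P1; parts P2, P3) in the post-WGD subject genome, judged
against the outgroup query genome through the orthologous correspondence
map:

* **fusion**: P2 and P3 correspond to disjoint sets of query chromosomes
  (Jaccard of their correspondence sets <= ``disjoint_max``) and together
  they tile the merged chromosome's correspondence (coverage >=
  ``coverage_min``). P1 then arose by joining copies of two independent
  ancestral chromosomes.
* **fission**: some query chromosome is seen by P2, P3 *and* P1 -- the parts
  are two halves of one ancestral chromosome whose intact duplicate is P1.
* otherwise **undetermined** (with the reason recorded).

The ancestral basic number x follows by arithmetic on the verdicts: each
fusion adds one pre-rearrangement unit back, each fission removes one;
after a WGD the unit count is twice x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .collinearity import CollinearBlock
from .homology_classifier import CorrespondenceMap

__all__ = [
    "FusionModelSpec",
    "TrioVerdict",
    "AncestralCount",
    "test_trio",
    "infer_ancestral_count",
    "fusion_mechanism_trace",
]


@dataclass(frozen=True)
class FusionModelSpec:
    """A candidate trio: one merged subject chromosome and its two parts."""

    merged: str
    part_a: str
    part_b: str

    def __post_init__(self) -> None:
        if len({self.merged, self.part_a, self.part_b}) != 3:
            raise ValueError("trio chromosomes must be three distinct names")


@dataclass
class TrioVerdict:
    spec: FusionModelSpec
    corr_merged: set[str]
    corr_p2: set[str]
    corr_p3: set[str]
    jaccard_parts: float
    coverage: float
    verdict: str  # "fusion" | "fission" | "undetermined"
    reason: str = ""


def test_trio(
    spec: FusionModelSpec,
    cmap: CorrespondenceMap,
    disjoint_max: float = 0.10,
    coverage_min: float = 0.80,
) -> TrioVerdict:
    """Judge one trio against the orthologous correspondence map.

    Symmetric under swapping the two parts.
    """
    cm = cmap.corr(spec.merged)
    c2 = cmap.corr(spec.part_a)
    c3 = cmap.corr(spec.part_b)
    union = c2 | c3
    jac = len(c2 & c3) / len(union) if union else 0.0
    cov = len(cm & union) / len(cm) if cm else 0.0

    if not cm or not c2 or not c3:
        empty = [
            n
            for n, s in (("merged", cm), ("part_a", c2), ("part_b", c3))
            if not s
        ]
        return TrioVerdict(
            spec, cm, c2, c3, jac, cov, "undetermined",
            f"empty correspondence set for {', '.join(empty)}",
        )
    if jac <= disjoint_max and cov >= coverage_min:
        return TrioVerdict(
            spec, cm, c2, c3, jac, cov, "fusion",
            f"parts disjoint (jaccard {jac:.3f} <= {disjoint_max}) and cover "
            f"{cov:.2f} of the merged chromosome's correspondence",
        )
    shared = c2 & c3 & cm
    if shared:
        return TrioVerdict(
            spec, cm, c2, c3, jac, cov, "fission",
            f"parts and merged all correspond to {sorted(shared)}",
        )
    return TrioVerdict(
        spec, cm, c2, c3, jac, cov, "undetermined",
        f"jaccard {jac:.3f}, coverage {cov:.2f}: neither model's signature",
    )


@dataclass
class AncestralCount:
    """Inferred basic chromosome number with pre/post-WGD diploid counts."""

    x: int | None  # point estimate; None when only an interval is available
    x_interval: tuple[int, int]
    two_n_pre: int | None
    two_n_post: int | None
    n_fusions: int
    n_fissions: int
    n_undetermined: int


def infer_ancestral_count(
    n_observed_chromosomes: int,
    trio_verdicts: Sequence[TrioVerdict],
    wgd: bool = True,
) -> AncestralCount:
    """Basic number x implied by the observed karyotype and trio verdicts.

    Each fusion verdict restores one pre-rearrangement unit
    (units = observed + fusions - fissions); with a WGD the unit count is
    2x. Undetermined trios propagate as an interval (each could have been a
    fusion or a fission), not a point estimate.
    """
    fus = sum(1 for v in trio_verdicts if v.verdict == "fusion")
    fis = sum(1 for v in trio_verdicts if v.verdict == "fission")
    und = sum(1 for v in trio_verdicts if v.verdict == "undetermined")
    units = n_observed_chromosomes + fus - fis
    lo_u, hi_u = units - und, units + und
    ploidy = 2 if wgd else 1
    lo_x = lo_u // ploidy
    hi_x = -(-hi_u // ploidy)
    point = units // ploidy if (und == 0 and units % ploidy == 0) else None
    return AncestralCount(
        x=point,
        x_interval=(lo_x, hi_x),
        two_n_pre=2 * point if point is not None else None,
        two_n_post=4 * point if (point is not None and wgd) else None,
        n_fusions=fus,
        n_fissions=fis,
        n_undetermined=und,
    )


# ---------------------------------------------------------------------------
# junction trace (CEJ mechanism)
# ---------------------------------------------------------------------------

@dataclass
class JunctionReport:
    """Breakpoint structure of a merged chromosome in gene-rank coordinates."""

    merged: str
    junctions: list[tuple[int, int]]  # (last rank of a run, first rank of next)
    segments: list[tuple[str, int, int]]  # (part label, first rank, last rank)
    cej_consistent: dict[str, bool | None]
    error: str = ""


def fusion_mechanism_trace(
    verdict: TrioVerdict,
    blocks: Sequence[CollinearBlock],
    subject_side: str = "b",
    telomere_window: int = 10,
) -> JunctionReport:
    """Localize the junction(s) between the two parts' segments on the merged
    chromosome, and check whether they join the parts' chromosome ends
    (consistent with chromosome end-end joining).

    Anchors on the merged chromosome are labeled by which part's query
    correspondence their query chromosome belongs to; maximal runs of one
    label are segments and every label change is a candidate junction. A
    part is CEJ-consistent when its anchors adjacent to the junction map
    near a chromosome end of the part itself (within ``telomere_window``
    gene ranks), which requires blocks for the part chromosomes too.
    """
    if verdict.verdict != "fusion":
        return JunctionReport(
            verdict.spec.merged, [], [], {}, error="verdict is not fusion"
        )
    spec = verdict.spec
    only2 = verdict.corr_p2 - verdict.corr_p3
    only3 = verdict.corr_p3 - verdict.corr_p2

    def anchors_on(chrom: str) -> list[tuple[int, str, str]]:
        """(rank on subject chrom, query chrom, query gene) sorted by rank."""
        out = []
        for b in blocks:
            sc, qc = (b.chrom_b, b.chrom_a) if subject_side == "b" else (b.chrom_a, b.chrom_b)
            if sc != chrom:
                continue
            for p in b.pairs:
                rank, qg = (p.order_b, p.gene_a) if subject_side == "b" else (p.order_a, p.gene_b)
                out.append((rank, qc, qg))
        return sorted(out)

    labeled = []
    for rank, qc, qg in anchors_on(spec.merged):
        if qc in only2:
            labeled.append((rank, spec.part_a, qg))
        elif qc in only3:
            labeled.append((rank, spec.part_b, qg))
    if not labeled:
        return JunctionReport(spec.merged, [], [], {}, error="no labeled anchors")

    segments: list[tuple[str, int, int]] = []
    junctions: list[tuple[int, int]] = []
    cur_label, seg_start, prev_rank = labeled[0][1], labeled[0][0], labeled[0][0]
    for rank, label, _qg in labeled[1:]:
        if label != cur_label:
            segments.append((cur_label, seg_start, prev_rank))
            junctions.append((prev_rank, rank))
            cur_label, seg_start = label, rank
        prev_rank = rank
    segments.append((cur_label, seg_start, prev_rank))
    if not junctions:
        return JunctionReport(
            spec.merged, [], segments, {},
            error="merged chromosome traces to one part only; no junction",
        )

    # CEJ check: junction-adjacent query genes should sit near an end of the
    # sister part chromosome
    part_anchor_rank: dict[str, dict[str, int]] = {}
    part_len: dict[str, int] = {}
    for part in (spec.part_a, spec.part_b):
        ranks = {qg: rank for rank, _qc, qg in anchors_on(part)}
        part_anchor_rank[part] = ranks
        part_len[part] = max(ranks.values()) + 1 if ranks else 0

    near: dict[str, bool | None] = {}
    j_lo, j_hi = junctions[0]
    for part in (spec.part_a, spec.part_b):
        seg = [s for s in segments if s[0] == part]
        if not seg or not part_anchor_rank[part]:
            near[part] = None
            continue
        # query genes of this part's segment nearest the junction
        edge_genes = [
            qg
            for rank, label, qg in labeled
            if label == part and min(abs(rank - j_lo), abs(rank - j_hi)) <= telomere_window
        ]
        ranks = [
            part_anchor_rank[part][qg]
            for qg in edge_genes
            if qg in part_anchor_rank[part]
        ]
        if not ranks:
            near[part] = None
        else:
            L = part_len[part]
            near[part] = any(r <= telomere_window or r >= L - 1 - telomere_window for r in ranks)
    return JunctionReport(spec.merged, junctions, segments, near)
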