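"""Census of duplicate-gene retention in the polyploid lineage.

Relative to the unduplicated outgroup (query), every query gene region is
expected at depth 2 in the post-WGD subject genome. The census classifies
each query gene by how many subject copies it still anchors in orthologous
collinear blocks ("expected locations"):

* ``both_copies`` -- anchors on two distinct subject chromosomes;
* ``one_copy``    -- exactly one;
* ``absent``      -- none: the collinear ortholog was lost or moved.

Absent genes are triaged against a protein-level hit table: a hit at
``evalue <= evalue_max`` anywhere in the subject genome means the ortholog
likely still exists but was translocated (``translocated_hit``;
``translocated_bbh`` when it is also a bidirectional best hit), otherwise
the gene is a candidate true loss (``no_hit``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .collinearity import CollinearBlock
from .genome_model import GenomePanel, HomologyHit

__all__ = [
    "RetentionRecord",
    "FractionationSummary",
    "retention_census",
    "absent_gene_triage",
]

_UNPLACED_PREFIXES = ("scaffold", "contig", "un")


@dataclass
class RetentionRecord:
    gene_id: str
    retention_class: str  # "both_copies" | "one_copy" | "absent"
    subject_chromosomes: tuple[str, ...] = ()
    subclass: str | None = None  # for absent: translocated_hit/_bbh, no_hit, untriaged
    unplaced: bool = False


@dataclass
class FractionationSummary:
    total: int
    counts: dict[str, int]
    proportions: dict[str, float]
    subclass_counts: dict[str, int] = field(default_factory=dict)
    n_unplaced: int = 0

    def check(self) -> None:
        assert abs(sum(self.proportions.values()) - 1.0) < 1e-9


def retention_census(
    query_panel: GenomePanel,
    orthologous_blocks: Sequence[CollinearBlock],
    query_side: str = "a",
    unplaced_prefixes: Sequence[str] = _UNPLACED_PREFIXES,
) -> tuple[list[RetentionRecord], FractionationSummary]:
    """Classify every query gene by its surviving subject copy count.

    A gene on an unplaced scaffold stays in the denominator but is flagged.
    The copy count is the number of distinct subject chromosomes the gene
    anchors across the orthologous blocks (capped interpretation: >=2 counts
    as both copies).
    """
    subj: dict[str, set[str]] = {g: set() for g in query_panel.genes}
    for b in orthologous_blocks:
        for p in b.pairs:
            qg, sc = (p.gene_a, b.chrom_b) if query_side == "a" else (p.gene_b, b.chrom_a)
            if qg in subj:
                subj[qg].add(sc)
    records = []
    counts = {"both_copies": 0, "one_copy": 0, "absent": 0}
    n_unplaced = 0
    for gid in sorted(query_panel.genes):
        chroms = tuple(sorted(subj[gid]))
        cls = ("absent", "one_copy", "both_copies")[min(len(chroms), 2)]
        unplaced = query_panel.genes[gid].chromosome.lower().startswith(
            tuple(unplaced_prefixes)
        )
        n_unplaced += unplaced
        counts[cls] += 1
        records.append(RetentionRecord(gid, cls, chroms, unplaced=unplaced))
    total = len(records)
    summary = FractionationSummary(
        total=total,
        counts=counts,
        proportions={k: (v / total if total else 0.0) for k, v in counts.items()},
        n_unplaced=n_unplaced,
    )
    if total:
        summary.check()
    return records, summary


def _best_hits(
    hits: Sequence[HomologyHit], max_evalue: float
) -> dict[str, str]:
    """Best subject per query by bitscore; ties by evalue then subject id."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        cur = best.get(h.query_gene)
        if cur is None or (-h.bitscore, h.evalue, h.subject_gene) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_gene,
        ):
            best[h.query_gene] = h
    return {q: h.subject_gene for q, h in best.items()}


def absent_gene_triage(
    absent_records: Sequence[RetentionRecord],
    protein_hits: Sequence[HomologyHit] | None,
    reverse_hits: Sequence[HomologyHit] | None = None,
    evalue_max: float = 1e-10,
) -> dict[str, int]:
    """Split absent genes into translocated (hit / BBH) vs candidate losses.

    ``protein_hits`` is query->subject; ``reverse_hits`` (subject->query)
    enables the bidirectional-best-hit call. With no hit table at all,
    absent genes are reported ``untriaged`` rather than assumed lost.
    Subclasses are written back onto the records. ``translocated_bbh`` is a
    subset of the hits: counts report hit-any, bbh and no-hit separately.
    """
    absent = [r for r in absent_records if r.retention_class == "absent"]
    if protein_hits is None:
        for r in absent:
            r.subclass = "untriaged"
        return {"translocated_hit": 0, "translocated_bbh": 0, "no_hit": 0,
                "untriaged": len(absent)}

    with_hit: dict[str, set[str]] = {}
    for h in protein_hits:
        if h.evalue <= evalue_max:
            with_hit.setdefault(h.query_gene, set()).add(h.subject_gene)
    fwd_best = _best_hits(protein_hits, evalue_max)
    rev_best = (
        _best_hits(reverse_hits, evalue_max) if reverse_hits is not None else {}
    )

    counts = {"translocated_hit": 0, "translocated_bbh": 0, "no_hit": 0, "untriaged": 0}
    for r in absent:
        subjects = with_hit.get(r.gene_id)
        if not subjects:
            r.subclass = "no_hit"
            counts["no_hit"] += 1
            continue
        best = fwd_best.get(r.gene_id)
        if best is not None and rev_best.get(best) == r.gene_id:
            r.subclass = "translocated_bbh"
            counts["translocated_bbh"] += 1
        else:
            r.subclass = "translocated_hit"
        counts["translocated_hit"] += 1
    return counts
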