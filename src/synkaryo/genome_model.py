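"""Data model and I/O for gene orders, coding sequences and homology hit tables.

Conventions
-----------
* File coordinates are 1-based inclusive (GFF3 style).
* In memory every gene carries a 0-based ``order_index``: its rank along its
  chromosome by start coordinate (ties broken by gene id). All collinearity
  arithmetic downstream is done in these gene-rank units, not base pairs.
* Homology hit tables use the 12-column BLAST tabular dialect
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Gene",
    "GenomePanel",
    "HomologyHit",
    "read_annotations",
    "write_annotations",
    "read_cds",
    "write_cds",
    "read_hits",
    "write_hits",
    "filter_hits",
]

_VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class Gene:
    """One gene feature on a chromosome.

    ``start``/``end`` are 1-based inclusive base-pair coordinates;
    ``order_index`` is the 0-based rank of the gene along its chromosome.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.id}: unknown strand symbol {self.strand!r}")


class GenomePanel:
    """Ordered genes on named chromosomes for one species, plus optional CDS.

    Parameters
    ----------
    species
        Species label carried into reports.
    genes
        Iterable of :class:`Gene`. ``order_index`` is (re)assigned here: genes
        are ranked per chromosome by start coordinate, ties broken by id.
    """

    def __init__(self, species: str, genes: Iterable[Gene] = ()) -> None:
        self.species = species
        self.genes: dict[str, Gene] = {}
        self._by_chrom: dict[str, list[Gene]] = {}
        self.cds: dict[str, str] = {}
        self.frame_broken: set[str] = set()
        self.ambiguous_cds: set[str] = set()
        staged: dict[str, list[Gene]] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValueError(f"duplicate gene id {g.id!r} in panel {species!r}")
            self.genes[g.id] = g
            staged.setdefault(g.chromosome, []).append(g)
        for chrom in staged:
            ranked = sorted(staged[chrom], key=lambda g: (g.start, g.id))
            ordered = [
                Gene(g.id, g.chromosome, g.start, g.end, g.strand, i)
                for i, g in enumerate(ranked)
            ]
            self._by_chrom[chrom] = ordered
            for g in ordered:
                self.genes[g.id] = g

    # -- queries ---------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def gene_order(self, chromosome: str) -> list[Gene]:
        """Genes of one chromosome in rank order."""
        return list(self._by_chrom.get(chromosome, []))

    def chromosome_length_genes(self, chromosome: str) -> int:
        return len(self._by_chrom.get(chromosome, []))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    # -- CDS -------------------------------------------------------------
    def attach_cds(self, cds: Mapping[str, str]) -> list[str]:
        """Attach coding sequences; returns ids absent from the panel.

        Sequences are uppercased. A CDS whose length is not a multiple of 3
        is kept but flagged frame-broken; non-ACGT characters are preserved
        but the gene is flagged ambiguous.
        """
        missing = []
        for gid, seq in cds.items():
            if gid not in self.genes:
                missing.append(gid)
                continue
            s = seq.upper()
            self.cds[gid] = s
            if len(s) % 3 != 0:
                self.frame_broken.add(gid)
            if set(s) - set("ACGT"):
                self.ambiguous_cds.add(gid)
        if missing:
            warnings.warn(
                f"{len(missing)} CDS ids not present in panel {self.species!r}: "
                + ", ".join(sorted(missing)[:5])
                + ("..." if len(missing) > 5 else "")
            )
        return missing


@dataclass(frozen=True)
class HomologyHit:
    """One filtered all-vs-all homology search hit (BLAST outfmt-6 row)."""

    query_gene: str
    subject_gene: str
    identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _sniff_format(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##gff-version"):
                    return "gff3"
                continue
            ncol = len(line.split("\t"))
            if ncol == 9:
                return "gff3"
            if ncol == 5:
                return "bed"
            raise ValueError(
                f"{path}: cannot sniff annotation format ({ncol} columns; "
                "expected 9-column GFF3 or 5-column chrom/start/end/strand/id TSV)"
            )
    return "empty"


def read_annotations(path: str, species: str, fmt: str | None = None) -> GenomePanel:
    """Read gene annotations (GFF3 gene features, or a 5-column TSV) into a panel.

    The TSV dialect is ``chromosome  start  end  strand  gene_id`` with 1-based
    inclusive coordinates. An empty file yields an empty panel.
    """
    fmt = fmt or _sniff_format(path)
    if fmt == "empty":
        return GenomePanel(species)
    if fmt == "gff3":
        genes = _read_gff3_genes(path)
    elif fmt == "bed":
        genes = _read_bed_genes(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return GenomePanel(species, genes)


def _read_gff3_genes(path: str) -> list[Gene]:
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except ValueError as exc:  # gffutils raises ValueError on duplicate IDs
        raise ValueError(f"{path}: {exc}") from exc
    genes = []
    for f in db.features_of_type("gene"):
        if f.strand not in _VALID_STRANDS:
            raise ValueError(f"{path}: gene {f.id}: unknown strand symbol {f.strand!r}")
        genes.append(Gene(f.id, f.seqid, f.start, f.end, f.strand))
    return genes


def _read_bed_genes(path: str) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            chrom, start, end, strand, gid = cols
            genes.append(Gene(gid, chrom, int(start), int(end), strand))
    return genes


def write_annotations(panel: GenomePanel, path: str, fmt: str = "gff3") -> None:
    """Write a panel back to GFF3 (gene features) or the 5-column TSV."""
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for chrom in panel.chromosomes:
                for g in panel.gene_order(chrom):
                    fh.write(
                        f"{chrom}\tsynkaryo\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                        f"ID={g.id}\n"
                    )
        elif fmt == "bed":
            for chrom in panel.chromosomes:
                for g in panel.gene_order(chrom):
                    fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.id}\n")
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# CDS FASTA
# ---------------------------------------------------------------------------

def read_cds(path: str) -> dict[str, str]:
    """Read a CDS FASTA keyed by gene id; sequences are uppercased."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    if os.path.getsize(path) == 0:
        return out
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_cds(cds: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gid in sorted(cds):
            fh.write(f">{gid}\n")
            seq = cds[gid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

_N_HIT_COLS = 12


def read_hits(
    path: str,
    max_evalue: float = 1e-5,
    top_n: int = 5,
    filter: bool = True,
) -> list[HomologyHit]:
    """Read a BLAST outfmt-6 table and apply the standard hit filter.

    Filtering keeps, per query gene, at most ``top_n`` subject genes ranked by
    descending bitscore (ties by subject id), after dropping self-hits and hits
    with ``evalue > max_evalue``.
    """
    raw: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _N_HIT_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_N_HIT_COLS} tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hit = HomologyHit(
                    query_gene=cols[0],
                    subject_gene=cols[1],
                    identity=float(cols[2]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            raw.append(hit)
    if not filter:
        return raw
    return filter_hits(raw, max_evalue=max_evalue, top_n=top_n)


def filter_hits(
    hits: Sequence[HomologyHit],
    max_evalue: float = 1e-5,
    top_n: int = 5,
    remove_tandem: bool = False,
    panel: GenomePanel | None = None,
) -> list[HomologyHit]:
    """Apply the e-value / top-N / self-hit filter. Idempotent.

    With ``remove_tandem=True`` (requires ``panel`` holding both genes),
    within-genome hits between genes adjacent in gene order on the same
    chromosome are dropped as tandem artefacts. Default keeps them.
    """
    per_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query_gene == h.subject_gene:
            continue
        if h.evalue > max_evalue:
            continue
        if remove_tandem and panel is not None:
            ga = panel.genes.get(h.query_gene)
            gb = panel.genes.get(h.subject_gene)
            if (
                ga is not None
                and gb is not None
                and ga.chromosome == gb.chromosome
                and abs(ga.order_index - gb.order_index) == 1
            ):
                continue
        per_query.setdefault(h.query_gene, []).append(h)
    out: list[HomologyHit] = []
    for q in per_query:
        ranked = sorted(per_query[q], key=lambda h: (-h.bitscore, h.subject_gene))
        out.extend(ranked[:top_n])
    return out


def write_hits(hits: Sequence[HomologyHit], path: str, aln_length: int = 0) -> None:
    """Write hits as 12-column BLAST outfmt-6 (placeholder coordinate columns)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_gene,
                        h.subject_gene,
                        f"{h.identity:.2f}",
                        str(aln_length),
                        "0",
                        "0",
                        "1",
                        str(max(aln_length, 1)),
                        "1",
                        str(max(aln_length, 1)),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
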