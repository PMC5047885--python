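"""Separate orthologous from out-paralogous blocks and build correspondence maps.

After a whole-genome duplication in the subject lineage that the query
lineage escaped, every query region is expected to have two orthologous
subject copies (a 1:2 depth ratio) plus possibly deeper out-paralogous
layers from older duplications. Three instruments implement the separation:

* a block-level Ks window test (:func:`classify_by_ks`): split-era blocks
  carry Ks medians inside the orthology window (default 0.95-1.20); blocks
  near the older-event value (default 1.5 +/- 0.15) are out-paralogous;
* a shared-collinear-gene tie-break (:func:`resolve_by_sharing`) for the
  cases where Ks medians are too close to call: the two WGD co-ortholog
  chromosomes cover the same ancestral segment, so they share a large
  fraction of the query's collinear genes, while an out-paralog shares few;
* a chromosome-level correspondence map (:func:`build_correspondence`)
  listing, per subject chromosome, the query chromosomes with at least
  ``min_anchor`` orthologous anchors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .collinearity import CollinearBlock

__all__ = [
    "BlockClassification",
    "CorrespondenceMap",
    "DepthExpectation",
    "classify_by_ks",
    "resolve_by_sharing",
    "build_correspondence",
    "depth_check",
    "shared_gene_percentage",
]

ORTHO_WINDOW = (0.95, 1.20)
OUTPARA_CENTER = 1.5
OUTPARA_MARGIN = 0.15
SHARE_THRESHOLD = 0.20


@dataclass
class BlockClassification:
    """A block labeled by its homology layer, with the evidence trail."""

    block: CollinearBlock
    ks_median: float | None
    label: str  # "orthologous" | "outparalogous" | "ambiguous"
    evidence: str = ""


@dataclass
class DepthExpectation:
    """Expected orthology depth ratio query:subject (1:2 after one WGD)."""

    query_copies: int = 1
    subject_copies: int = 2

    def __post_init__(self) -> None:
        if self.query_copies < 1 or self.subject_copies < 1:
            raise ValueError("depth ratio must use positive integers")


@dataclass
class CorrespondenceMap:
    """Per subject chromosome: query chromosomes with orthologous correspondence.

    ``anchors[subject_chrom][query_chrom]`` is the summed orthologous anchor
    count; only entries with at least ``min_anchor`` anchors enter
    :meth:`corr`. The contributing blocks are retained for per-gene depth
    work downstream.
    """

    anchors: dict[str, dict[str, int]] = field(default_factory=dict)
    min_anchor: int = 10
    blocks: list[CollinearBlock] = field(default_factory=list)

    def corr(self, subject_chrom: str) -> set[str]:
        return {
            q
            for q, n in self.anchors.get(subject_chrom, {}).items()
            if n >= self.min_anchor
        }

    def query_corr(self, query_chrom: str) -> set[str]:
        return {
            s
            for s, qmap in self.anchors.items()
            if qmap.get(query_chrom, 0) >= self.min_anchor
        }

    @property
    def subject_chromosomes(self) -> list[str]:
        return sorted(self.anchors)

    def to_table(self) -> list[tuple[str, str, int]]:
        rows = []
        for s in sorted(self.anchors):
            for q in sorted(self.anchors[s]):
                rows.append((s, q, self.anchors[s][q]))
        return rows


# ---------------------------------------------------------------------------
# Ks-window classification
# ---------------------------------------------------------------------------

def classify_by_ks(
    block: CollinearBlock,
    ks_median: float | None,
    ortho_window: tuple[float, float] = ORTHO_WINDOW,
    outpara_center: float = OUTPARA_CENTER,
    margin: float = OUTPARA_MARGIN,
) -> BlockClassification:
    """Label one block by where its Ks median falls.

    Inside ``ortho_window`` -> orthologous; within ``margin`` of
    ``outpara_center`` -> outparalogous; anywhere else (or saturated)
    -> ambiguous. The orthology window wins if the zones overlap.
    """
    lo, hi = ortho_window
    if lo > hi:
        raise ValueError(f"orthology window inverted: {ortho_window}")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if ks_median is None:
        return BlockClassification(block, None, "ambiguous", "ks saturated")
    if lo <= ks_median <= hi:
        return BlockClassification(
            block, ks_median, "orthologous", f"ks_median {ks_median:.3f} in [{lo}, {hi}]"
        )
    if abs(ks_median - outpara_center) <= margin:
        return BlockClassification(
            block,
            ks_median,
            "outparalogous",
            f"ks_median {ks_median:.3f} within {margin} of {outpara_center}",
        )
    return BlockClassification(
        block, ks_median, "ambiguous", f"ks_median {ks_median:.3f} outside both zones"
    )


# ---------------------------------------------------------------------------
# shared-collinear-gene tie-break
# ---------------------------------------------------------------------------

def shared_gene_percentage(shared: int, total: int, decimals: int = 1) -> float:
    """Shared collinear genes as a percentage, rounded half-up (5/107 -> 4.7)."""
    if total <= 0:
        raise ValueError("total must be positive")
    scale = 10**decimals
    return math.floor(100.0 * shared / total * scale + 0.5) / scale


def _anchor_sets(
    query_chrom: str,
    candidates: Sequence[str],
    blocks: Sequence[CollinearBlock],
) -> dict[str, set[str]]:
    """Query genes of ``query_chrom`` anchored to each candidate subject chromosome."""
    sets: dict[str, set[str]] = {c: set() for c in candidates}
    for b in blocks:
        if b.chrom_a == query_chrom and b.chrom_b in sets:
            sets[b.chrom_b].update(p.gene_a for p in b.pairs)
        elif b.chrom_b == query_chrom and b.chrom_a in sets:
            sets[b.chrom_a].update(p.gene_b for p in b.pairs)
    return sets


def resolve_by_sharing(
    query_chrom: str,
    candidate_subject_chroms: Sequence[str],
    blocks: Sequence[CollinearBlock],
    share_threshold: float = SHARE_THRESHOLD,
) -> dict[str, BlockClassification | dict]:
    """Tie-break candidate subject chromosomes by shared collinear genes.

    For each candidate pair (X, Y) the sharing fraction is the proportion of
    X's collinear genes on ``query_chrom`` whose query genes also anchor to
    Y. Mutual sharing of a pair is the smaller of its two directions. The
    pair with the highest mutual sharing above ``share_threshold`` are the
    WGD co-orthologs (they tile the same ancestral segment); a candidate
    whose mutual sharing with both co-orthologs stays below the threshold
    is out-paralogous. Candidate order does not affect the result.

    Returns ``{candidate: {"label", "anchors", "evidence"}}``.
    """
    if len(candidate_subject_chroms) < 2:
        raise ValueError("need at least two candidate subject chromosomes")
    sets = _anchor_sets(query_chrom, candidate_subject_chroms, blocks)
    live = sorted(c for c in sets if sets[c])
    for c in sorted(sets):
        if not sets[c]:
            warnings.warn(f"candidate {c} has zero anchors on {query_chrom}; excluded")

    def share(x: str, y: str) -> float:
        return len(sets[x] & sets[y]) / len(sets[x])

    # candidate co-ortholog pair: mutual sharing (the smaller direction) must
    # clear the threshold; among qualifying pairs the best-supported one wins
    # (anchor counts weigh in exactly as they do when reading the dotplot)
    best_pair: tuple[str, str] | None = None
    best_key: tuple[int, float] | None = None
    best_mutual = 0.0
    for i, x in enumerate(live):
        for y in live[i + 1 :]:
            mutual = min(share(x, y), share(y, x))
            if mutual < share_threshold:
                continue
            key = (min(len(sets[x]), len(sets[y])), mutual)
            if best_key is None or key > best_key:
                best_key, best_pair, best_mutual = key, (x, y), mutual

    out: dict[str, dict] = {}
    for c in sorted(sets):
        if c not in live:
            out[c] = {"label": "excluded", "anchors": 0, "evidence": "zero anchors"}
            continue
        if best_pair is not None and c in best_pair:
            other = best_pair[0] if c == best_pair[1] else best_pair[1]
            pct = shared_gene_percentage(len(sets[c] & sets[other]), len(sets[c]))
            out[c] = {
                "label": "orthologous",
                "anchors": len(sets[c]),
                "evidence": (
                    f"shares {len(sets[c] & sets[other])}/{len(sets[c])} "
                    f"({pct}%) collinear genes with {other}"
                ),
            }
        else:
            shares = {
                o: shared_gene_percentage(len(sets[c] & sets[o]), len(sets[c]))
                for o in live
                if o != c
            }
            below_all = all(
                min(share(c, o), share(o, c)) < share_threshold
                for o in (best_pair or ())
                if o != c
            )
            label = "outparalogous" if best_pair and below_all else "ambiguous"
            out[c] = {
                "label": label,
                "anchors": len(sets[c]),
                "evidence": "sharing " + ", ".join(f"{o}: {p}%" for o, p in sorted(shares.items())),
            }
    return out


# ---------------------------------------------------------------------------
# correspondence map and depth census
# ---------------------------------------------------------------------------

def build_correspondence(
    classified_blocks: Sequence[BlockClassification],
    min_anchor: int = 10,
    query_side: str = "a",
) -> CorrespondenceMap:
    """Correspondence map from the blocks labeled orthologous.

    ``query_side`` names which block side carries the query genome ("a" by
    convention: blocks are detected query-vs-subject).
    """
    cmap = CorrespondenceMap(min_anchor=min_anchor)
    for bc in classified_blocks:
        if bc.label != "orthologous":
            continue
        b = bc.block
        q, s = (b.chrom_a, b.chrom_b) if query_side == "a" else (b.chrom_b, b.chrom_a)
        cmap.anchors.setdefault(s, {})
        cmap.anchors[s][q] = cmap.anchors[s].get(q, 0) + b.length
        cmap.blocks.append(b)
    return cmap


def depth_check(
    cmap: CorrespondenceMap,
    query_gene_ids: Sequence[str],
    expectation: DepthExpectation | None = None,
    query_side: str = "a",
) -> dict:
    """Per-query-gene count of orthologous subject copies (0, 1, 2, >2).

    Depth is the number of distinct subject chromosomes a query gene anchors
    in the map's orthologous blocks. Returns the per-gene depth map, the
    histogram over the four classes and the genes exceeding the expected
    subject copy number.
    """
    expectation = expectation or DepthExpectation()
    subj_of: dict[str, set[str]] = {g: set() for g in query_gene_ids}
    for b in cmap.blocks:
        for p in b.pairs:
            qg, sc = (p.gene_a, b.chrom_b) if query_side == "a" else (p.gene_b, b.chrom_a)
            if qg in subj_of:
                subj_of[qg].add(sc)
    depth = {g: len(s) for g, s in subj_of.items()}
    hist = {"0": 0, "1": 0, "2": 0, ">2": 0}
    for d in depth.values():
        hist[str(d) if d <= 2 else ">2"] += 1
    over = sorted(g for g, d in depth.items() if d > expectation.subject_copies)
    return {
        "depth": depth,
        "histogram": hist,
        "n_genes": len(depth),
        "expected_copies": expectation.subject_copies,
        "over_expectation": over,
    }
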