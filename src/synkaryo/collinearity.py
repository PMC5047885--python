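"""ColinearScan-style detection of statistically significant collinear blocks.

Anchors (homologous gene pairs) are dots in gene-rank space for each
chromosome pair. Blocks are maximal-length monotone chains found by sparse
dynamic programming: a dot extends a chain iff both rank gaps (number of
intervening gene ranks, on each genome independently) are <= ``max_gap`` and
the order on the second genome matches the chain orientation (strictly
increasing for ``same``, strictly decreasing for ``inverted``).

Significance is a permutation null: the same number of anchors is placed
uniformly at random on the two chromosomes and the longest chain recomputed;
p = (#permutations with longest chain >= observed + 1) / (N + 1). The null
distribution is computed once per chromosome pair and shared by all of its
blocks. Anchor-to-block assignment is greedy by descending chain length;
anchors of an accepted chain are removed before the next search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomePanel, HomologyHit

__all__ = [
    "AnchorPair",
    "CollinearBlock",
    "detect_blocks",
    "block_significance",
    "longest_chain_length",
    "block_census",
    "write_blocks",
    "read_blocks",
]


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair with its gene-rank coordinates."""

    gene_a: str
    gene_b: str
    order_a: int
    order_b: int


@dataclass
class CollinearBlock:
    """A significance-tested chain of anchors between two chromosomes."""

    chrom_a: str
    chrom_b: str
    pairs: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    p_value: float = float("nan")
    block_id: str = ""

    @property
    def length(self) -> int:
        return len(self.pairs)

    def gene_ids_a(self) -> list[str]:
        return [p.gene_a for p in self.pairs]

    def gene_ids_b(self) -> list[str]:
        return [p.gene_b for p in self.pairs]


# ---------------------------------------------------------------------------
# chain dynamic programming
# ---------------------------------------------------------------------------

def _best_chain(oa: np.ndarray, ob: np.ndarray, max_gap: int) -> list[int]:
    """Longest strictly-increasing chain (indices into oa/ob) with gap bound.

    ``gap`` between consecutive anchors is the number of intervening gene
    ranks, i.e. delta - 1; the bound is gap <= max_gap on both axes.
    O(n^2) with a vectorized inner scan. Deterministic tie-break: earliest
    sorted dot wins.
    """
    n = len(oa)
    if n == 0:
        return []
    order = np.lexsort((ob, oa))
    sa = oa[order]
    sb = ob[order]
    L = np.ones(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    step = max_gap + 1
    for j in range(1, n):
        ok = (
            (sa[:j] < sa[j])
            & (sa[j] - sa[:j] <= step)
            & (sb[:j] < sb[j])
            & (sb[j] - sb[:j] <= step)
        )
        if ok.any():
            cand = np.where(ok, L[:j], 0)
            i = int(np.argmax(cand))
            L[j] = cand[i] + 1
            parent[j] = i
    end = int(np.argmax(L))
    chain = []
    while end >= 0:
        chain.append(end)
        end = parent[end]
    chain.reverse()
    return [int(order[k]) for k in chain]


def _best_chain_both(oa: np.ndarray, ob: np.ndarray, max_gap: int) -> tuple[list[int], str]:
    fwd = _best_chain(oa, ob, max_gap)
    rev = _best_chain(oa, -ob, max_gap)
    if len(rev) > len(fwd):
        return rev, "inverted"
    return fwd, "same"


def longest_chain_length(
    order_a: Sequence[int], order_b: Sequence[int], max_gap: int
) -> int:
    """Length of the longest max-gap-bounded monotone chain (either orientation)."""
    oa = np.asarray(order_a, dtype=np.int64)
    ob = np.asarray(order_b, dtype=np.int64)
    chain, _ = _best_chain_both(oa, ob, max_gap)
    return len(chain)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def null_chain_lengths(
    n_anchors: int,
    len_a: int,
    len_b: int,
    max_gap: int,
    permutations: int,
    seed: int,
) -> np.ndarray:
    """Null distribution of the longest chain among uniformly placed anchors."""
    rng = np.random.default_rng(seed)
    out = np.empty(permutations, dtype=np.int64)
    for k in range(permutations):
        oa = rng.integers(0, max(len_a, 1), size=n_anchors)
        ob = rng.integers(0, max(len_b, 1), size=n_anchors)
        chain, _ = _best_chain_both(oa, ob, max_gap)
        out[k] = len(chain)
    return out


def block_significance(
    block_length: int,
    n_anchors_on_chrom_pair: int,
    chrom_lengths_in_genes: tuple[int, int],
    max_gap: int = 50,
    permutations: int = 1000,
    seed: int = 0,
    null: np.ndarray | None = None,
) -> float:
    """Permutation p-value of a block of the given length.

    ``null`` may carry a precomputed null distribution (shared across the
    blocks of one chromosome pair); otherwise it is generated here.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if permutations < 100:
        warnings.warn(f"only {permutations} permutations; p-values are coarse")
    if null is None:
        null = null_chain_lengths(
            n_anchors_on_chrom_pair,
            chrom_lengths_in_genes[0],
            chrom_lengths_in_genes[1],
            max_gap,
            permutations,
            seed,
        )
    exceed = int(np.sum(null >= block_length))
    return (exceed + 1) / (len(null) + 1)


# ---------------------------------------------------------------------------
# block detection
# ---------------------------------------------------------------------------

def detect_blocks(
    hits: Sequence[HomologyHit],
    panel_a: GenomePanel,
    panel_b: GenomePanel,
    max_gap: int = 50,
    p_threshold: float = 0.05,
    min_len: int = 5,
    permutations: int = 1000,
    seed: int = 0,
) -> list[CollinearBlock]:
    """Detect significant collinear blocks between (or within) two panels.

    Within-genome runs (``panel_a is panel_b`` or equal species) exclude the
    trivial self-diagonal (anchors with ``gene_a == gene_b``). Blocks with
    p >= ``p_threshold`` or fewer than ``min_len`` anchors are discarded.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    self_cmp = panel_a is panel_b or panel_a.species == panel_b.species

    # bucket anchors by chromosome pair
    dots: dict[tuple[str, str], list[AnchorPair]] = {}
    seen: set[tuple[str, str]] = set()
    for h in hits:
        ga = panel_a.genes.get(h.query_gene)
        gb = panel_b.genes.get(h.subject_gene)
        if ga is None or gb is None:
            continue
        if self_cmp and ga.id == gb.id:
            continue
        key = (ga.id, gb.id)
        if key in seen:
            continue
        seen.add(key)
        dots.setdefault((ga.chromosome, gb.chromosome), []).append(
            AnchorPair(ga.id, gb.id, ga.order_index, gb.order_index)
        )

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(dots):
        anchors = dots[(ca, cb)]
        if self_cmp and cb < ca:
            continue  # mirror pair; keep one triangle
        n_pair = len(anchors)
        if n_pair < min_len:
            continue
        la = panel_a.chromosome_length_genes(ca)
        lb = panel_b.chromosome_length_genes(cb)
        pair_seed = (seed + 1_000_003 * (hash((ca, cb)) % 65_521)) % (2**31)
        null = None
        remaining = list(anchors)
        while len(remaining) >= min_len:
            oa = np.array([p.order_a for p in remaining], dtype=np.int64)
            ob = np.array([p.order_b for p in remaining], dtype=np.int64)
            idx, orientation = _best_chain_both(oa, ob, max_gap)
            if len(idx) < min_len:
                break
            chain = [remaining[i] for i in idx]
            if null is None:
                null = null_chain_lengths(n_pair, la, lb, max_gap, permutations, pair_seed)
            p = block_significance(
                len(chain), n_pair, (la, lb), max_gap, permutations, pair_seed, null=null
            )
            taken = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]
            if p < p_threshold:
                blocks.append(CollinearBlock(ca, cb, chain, orientation, p))
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, -b.length, b.pairs[0].order_a))
    for i, b in enumerate(blocks):
        b.block_id = f"blk{i:04d}"
    return blocks


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def block_census(
    blocks: Sequence[CollinearBlock],
    thresholds: Sequence[int] = (4, 10, 20, 50),
) -> pd.DataFrame:
    """Census of blocks with length > threshold (counts of blocks and anchor pairs).

    Reports, per threshold: number of blocks, total collinear gene pairs in
    them, and the largest block's length and chromosome pair.
    """
    rows = []
    largest = max(blocks, key=lambda b: b.length, default=None)
    for t in thresholds:
        sel = [b for b in blocks if b.length > t]
        rows.append(
            {
                "threshold": t,
                "block_count": len(sel),
                "gene_pair_count": sum(b.length for b in sel),
                "largest_block": largest.length if largest else 0,
                "largest_block_chroms": (
                    f"{largest.chrom_a}-{largest.chrom_b}" if largest else ""
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# text I/O (one header line per block + one line per anchor)
# ---------------------------------------------------------------------------

def write_blocks(blocks: Sequence[CollinearBlock], path: str) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"#block\t{b.block_id}\t{b.chrom_a}\t{b.chrom_b}\t{b.length}\t"
                f"{b.orientation}\t{b.p_value:.6g}\n"
            )
            for p in b.pairs:
                fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.order_a}\t{p.order_b}\n")


def read_blocks(path: str) -> list[CollinearBlock]:
    blocks: list[CollinearBlock] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#block\t"):
                _, bid, ca, cb, _length, orient, p = line.split("\t")
                blocks.append(CollinearBlock(ca, cb, [], orient, float(p), bid))
            else:
                ga, gb, oa, ob = line.split("\t")
                blocks[-1].pairs.append(AnchorPair(ga, gb, int(oa), int(ob)))
    return blocks
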