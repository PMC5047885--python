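"""Gene-rank dotplots of homology hits and collinear blocks.

Axes are gene ranks (not base pairs), concatenated chromosome by chromosome
in sorted name order, matching the gap-in-genes convention used by the
collinearity stage. Dots are colored by match rank per query gene (best /
second best / other, by bitscore).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .collinearity import CollinearBlock
from .genome_model import GenomePanel, HomologyHit

__all__ = ["dotplot_coordinates", "render_dotplot"]

_RANK_COLORS = {"best": "#d62728", "second": "#1f77b4", "other": "#bbbbbb"}


def _offsets(panel: GenomePanel) -> dict[str, int]:
    off, cum = {}, 0
    for chrom in panel.chromosomes:
        off[chrom] = cum
        cum += panel.chromosome_length_genes(chrom)
    return off


def dotplot_coordinates(
    hits: Sequence[HomologyHit],
    panel_a: GenomePanel,
    panel_b: GenomePanel,
) -> pd.DataFrame:
    """Dot coordinates (x = query rank, y = subject rank, concatenated) with
    per-query match-rank class by descending bitscore."""
    off_a, off_b = _offsets(panel_a), _offsets(panel_b)
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query_gene in panel_a.genes and h.subject_gene in panel_b.genes:
            by_query.setdefault(h.query_gene, []).append(h)
    rows = []
    for q in sorted(by_query):
        ranked = sorted(by_query[q], key=lambda h: (-h.bitscore, h.subject_gene))
        for i, h in enumerate(ranked):
            ga, gb = panel_a.genes[h.query_gene], panel_b.genes[h.subject_gene]
            rows.append(
                {
                    "query_gene": h.query_gene,
                    "subject_gene": h.subject_gene,
                    "x": off_a[ga.chromosome] + ga.order_index,
                    "y": off_b[gb.chromosome] + gb.order_index,
                    "rank_class": ("best", "second")[i] if i < 2 else "other",
                }
            )
    return pd.DataFrame(
        rows, columns=["query_gene", "subject_gene", "x", "y", "rank_class"]
    )


def render_dotplot(
    hits: Sequence[HomologyHit],
    panel_a: GenomePanel,
    panel_b: GenomePanel,
    highlight: Sequence[str] = ("best", "second", "other"),
    blocks: Sequence[CollinearBlock] | None = None,
    ks_medians: dict[str, float] | None = None,
    path: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Rank-colored gene-order dotplot, optionally boxing collinear blocks
    (labeled with their Ks medians keyed by block id)."""
    coords = dotplot_coordinates(hits, panel_a, panel_b)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 7))
    if coords.empty:
        warnings.warn("no dots to plot; rendering empty axes")
    for cls in ("other", "second", "best"):  # draw best last
        if cls not in highlight:
            continue
        sub = coords[coords.rank_class == cls]
        if len(sub):
            ax.scatter(sub.x, sub.y, s=4, c=_RANK_COLORS[cls], label=cls, lw=0)
    off_a, off_b = _offsets(panel_a), _offsets(panel_b)
    for chrom, off in list(off_a.items())[1:]:
        ax.axvline(off - 0.5, color="0.85", lw=0.6)
    for chrom, off in list(off_b.items())[1:]:
        ax.axhline(off - 0.5, color="0.85", lw=0.6)
    if blocks:
        for b in blocks:
            xs = [off_a[b.chrom_a] + p.order_a for p in b.pairs]
            ys = [off_b[b.chrom_b] + p.order_b for p in b.pairs]
            x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
            ax.add_patch(
                plt.Rectangle(
                    (x0 - 0.5, y0 - 0.5), x1 - x0 + 1, y1 - y0 + 1,
                    fill=False, edgecolor="green", lw=0.8,
                )
            )
            if ks_medians and b.block_id in ks_medians:
                ax.text(
                    x1 + 1, y1, f"{ks_medians[b.block_id]:.2f}",
                    color="green", fontsize=6,
                )
    ax.set_xlabel(f"{panel_a.species} gene rank")
    ax.set_ylabel(f"{panel_b.species} gene rank")
    ax.set_xlim(-1, sum(panel_a.chromosome_length_genes(c) for c in panel_a.chromosomes) + 1)
    ax.set_ylim(-1, sum(panel_b.chromosome_length_genes(c) for c in panel_b.chromosomes) + 1)
    if len(coords):
        ax.legend(fontsize=7, loc="upper right")
    if path:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
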