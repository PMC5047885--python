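"""Synonymous/nonsynonymous substitution rates by the Nei–Gojobori (1986) method.

The estimator is counting-based: per-codon synonymous *site* fractions from
the standard genetic code, observed differences averaged with equal weight
over all minimal mutational pathways between two codons (pathways through
stop codons excluded), and Jukes–Cantor multiple-hit correction

    Ks = -(3/4) * ln(1 - (4/3) * pS),   pS = Sd / S

(undefined/saturated when pS >= 3/4; same formula for Ka from pN).

Site-counting convention: at each codon position the synonymous fraction is
(number of synonymous one-step changes) / 3; changes that create a stop codon
count as nonsynonymous. This keeps S + N = 3 * n_codon_pairs exactly.

Codon alignment is protein-guided: the translated sequences are globally
aligned (match +1, mismatch -1, linear gap -2) and back-translated; columns
containing a gap, an ambiguous base, or a stop codon are excluded from
counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "align_codons",
    "nei_gojobori",
    "block_ks_median",
    "SATURATION_PS",
]

_BASES = "ACGT"
STOP_CODONS = set(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)  # sense codons -> amino acid
SENSE_CODONS = sorted(_AA)
SATURATION_PS = 0.75


def _is_codon(c: str) -> bool:
    return len(c) == 3 and all(b in _BASES for b in c)


def _syn_fraction_per_codon() -> dict[str, float]:
    """NG86 synonymous site count s(codon) = sum over positions of syn/3."""
    out = {}
    for codon in SENSE_CODONS:
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in STOP_CODONS and _AA[alt] == _AA[codon]:
                    s += 1.0 / 3.0
        out[codon] = s
    return out


_SYN_SITES = _syn_fraction_per_codon()


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) differences between two sense codons.

    Averages with equal weight over all orderings of the differing positions;
    pathways whose intermediate codons are stops are excluded. If every
    pathway is blocked by a stop, all pathways are used and stop-crossing
    steps count as nonsynonymous.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if (
                nxt not in STOP_CODONS
                and cur not in STOP_CODONS
                and _AA[nxt] == _AA[cur]
            ):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    for allow_stops in (False, True):
        results = [r for o in permutations(diff) if (r := walk(o, allow_stops))]
        if results:
            sd = sum(r[0] for r in results) / len(results)
            nd = sum(r[1] for r in results) / len(results)
            return sd, nd
    raise AssertionError("unreachable")


# precomputed pair table: (sd, nd) for every ordered sense-codon pair
_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs(a: str, b: str) -> tuple[float, float]:
    key = (a, b) if a <= b else (b, a)  # symmetric
    got = _PAIR_DIFFS.get(key)
    if got is None:
        got = _PAIR_DIFFS[key] = _pathway_counts(*key)
    return got


@dataclass
class CodonAlignment:
    """Gap-free aligned codon columns of two CDS."""

    codons_a: list[str]
    codons_b: list[str]
    n_excluded: int = 0  # columns dropped (gap / ambiguity / stop)
    internal_stops: bool = False

    @property
    def n_codon_pairs(self) -> int:
        return len(self.codons_a)


@dataclass
class KsEstimate:
    """NG86 counts and JC-corrected rates for one aligned gene pair."""

    S: float
    N: float
    sd: float
    nd: float
    pS: float
    pN: float
    ks: float | None  # None when saturated (pS >= 3/4)
    ka: float | None

    @property
    def saturated(self) -> bool:
        return self.ks is None


def _trim_frame(cds: str) -> str:
    return cds[: len(cds) - (len(cds) % 3)]


def align_codons(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided pairwise codon alignment of two coding sequences.

    Incomplete terminal codons are trimmed. Internal stop codons are flagged
    and their columns excluded from counting, as are columns with a gap or an
    ambiguous (non-ACGT) base.
    """
    from Bio.Align import PairwiseAligner
    from Bio.Seq import Seq

    a = _trim_frame(cds_a.upper())
    b = _trim_frame(cds_b.upper())
    if not a or not b:
        raise ValueError("empty coding sequence after frame trimming")
    cod_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    cod_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    # translate with ambiguity/stop placeholders
    prot_a = "".join(_AA.get(c, "*" if c in STOP_CODONS else "X") for c in cod_a)
    prot_b = "".join(_AA.get(c, "*" if c in STOP_CODONS else "X") for c in cod_b)
    # drop trailing stop from alignment input but remember internal ones
    internal_stops = "*" in prot_a[:-1] or "*" in prot_b[:-1]

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(Seq(prot_a), Seq(prot_b))[0]
    idx_a, idx_b = aln.indices  # -1 marks a gap

    keep_a: list[str] = []
    keep_b: list[str] = []
    excluded = 0
    for ia, ib in zip(idx_a, idx_b):
        if ia < 0 or ib < 0:
            excluded += 1
            continue
        ca, cb = cod_a[ia], cod_b[ib]
        if not (_is_codon(ca) and _is_codon(cb)):
            excluded += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            excluded += 1
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    return CodonAlignment(keep_a, keep_b, excluded, internal_stops)


def _jc(p: float) -> float | None:
    if p >= SATURATION_PS:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def nei_gojobori(alignment: CodonAlignment) -> KsEstimate:
    """NG86 S/N site and difference counts plus JC-corrected Ks and Ka."""
    n = alignment.n_codon_pairs
    if n < 1:
        raise ValueError("alignment has no gap-free codon pairs")
    S = 0.0
    sd = nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        S += 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        d_s, d_n = _pair_diffs(ca, cb)
        sd += d_s
        nd += d_n
    N = 3.0 * n - S
    pS = sd / S if S > 0 else float("inf")
    pN = nd / N if N > 0 else float("inf")
    return KsEstimate(S=S, N=N, sd=sd, nd=nd, pS=pS, pN=pN, ks=_jc(pS), ka=_jc(pN))


def pairwise_ks(cds_a: str, cds_b: str) -> KsEstimate:
    """Convenience: align then estimate."""
    return nei_gojobori(align_codons(cds_a, cds_b))


def block_ks_median(ks_values: Iterable[float | None]) -> float | None:
    """Median of the finite (non-saturated) Ks values of a block's anchor pairs.

    Returns ``None`` (block flagged saturated) when no finite value exists.
    Even count: mean of the central two.
    """
    finite = sorted(v for v in ks_values if v is not None and math.isfinite(v))
    if not finite:
        return None
    m = len(finite)
    mid = m // 2
    if m % 2:
        return finite[mid]
    return 0.5 * (finite[mid - 1] + finite[mid])
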