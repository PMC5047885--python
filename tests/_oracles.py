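"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: chain search goes
through networkx longest-path on an explicit compatibility DAG, codon
counting enumerates mutational pathways recursively with Biopython
translation, and protein alignment is a plain Needleman-Wunsch table.
"""

from __future__ import annotations

from itertools import permutations

import networkx as nx
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# longest max-gap-bounded monotone chain (exhaustive DAG search)
# ---------------------------------------------------------------------------

def oracle_longest_chain(order_a, order_b, max_gap: int) -> int:
    """Longest chain over both orientations via networkx dag_longest_path."""
    best = 0
    for flip in (1, -1):
        dots = sorted(zip(order_a, [flip * b for b in order_b]))
        g = nx.DiGraph()
        g.add_nodes_from(range(len(dots)))
        for i, (ai, bi) in enumerate(dots):
            for j, (aj, bj) in enumerate(dots):
                if (
                    ai < aj <= ai + max_gap + 1
                    and bi < bj <= bi + max_gap + 1
                ):
                    g.add_edge(i, j)
        if dots:
            best = max(best, nx.dag_longest_path_length(g) + 1)
    return best


# ---------------------------------------------------------------------------
# Nei-Gojobori counts by explicit enumeration
# ---------------------------------------------------------------------------

def oracle_syn_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOPS and aa(alt) == aa(codon):
                s += 1 / 3
    return s


def oracle_pair_diffs(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences, stop pathways excluded."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, sd, nd = a, 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS and not allow_stops:
                return None
            if nxt not in STOPS and cur not in STOPS and aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    for allow in (False, True):
        paths = [w for o in permutations(diff) if (w := walk(o, allow)) is not None]
        if paths:
            return (
                sum(p[0] for p in paths) / len(paths),
                sum(p[1] for p in paths) / len(paths),
            )
    raise AssertionError


def oracle_ng_counts(codons_a, codons_b) -> tuple[float, float, float, float]:
    """(S, N, sd, nd) for an aligned gap-free codon list pair."""
    S = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        d_s, d_n = oracle_pair_diffs(ca, cb)
        sd += d_s
        nd += d_n
    return S, 3.0 * len(codons_a) - S, sd, nd


# ---------------------------------------------------------------------------
# Needleman-Wunsch protein alignment score (linear gaps)
# ---------------------------------------------------------------------------

def oracle_nw_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]
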