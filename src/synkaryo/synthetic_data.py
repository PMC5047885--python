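"""Forward simulator of two genomes descending from a common ancestor.

One lineage (A, outgroup-like) keeps the ancestral karyotype; the other (B)
may undergo a whole-genome duplication followed by chromosome end-end joining
(CEJ) fusions, fissions, biased duplicate loss, translocations and
inversions. Coding sequences diverge clock-like: synonymous substitutions are
Poisson-placed over codons weighted by their Nei-Gojobori synonymous site
fractions, so the NG86/Jukes-Cantor pipeline estimate of Ks has the
configured expectation; nonsynonymous changes are added at a fixed fraction
of the synonymous rate mass.

Divergence targets are met on a three-leaf additive tree over (A, B1, B2):
if ``ks_wgd <= ks_split`` the duplication nests inside the B lineage
(autopolyploid-like); if ``ks_wgd > ks_split`` the second subgenome branches
basal to the A/B split (allopolyploid with a divergent parent). An optional
pre-speciation chromosome duplication (``ancient_dup_chrom``) plants an
out-paralogy layer at divergence ``ks_ancient`` with heavy fractionation of
the duplicated copy -- the test bed for ortholog/out-paralog classification.

Ground truth is carried by an :class:`EventLog`: every structural event with
full coordinates and gene ids, plus an ancestry map from every extant gene to
its ancestral gene, family and subgenome. ``replay(log, ancestor)``
re-applies the log deterministically and reproduces the extant genomes
byte-for-byte (sequence divergence is a pure function of the master seed).

Chromosome naming: ancestral chromosomes ``chr1..chrN``; the ancient
duplicate of ``chrK`` is ``chrKd``. Lineage A keeps ancestral names; lineage
B subgenome copies are ``chrKa`` / ``chrKb``; a fusion of X and Y is ``X-Y``;
a fission of X yields ``X.1`` / ``X.2``. Gene ids are ``A_``, ``B1_`` or
``B2_`` plus the ancestral gene id.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .genome_model import Gene, GenomePanel, HomologyHit, filter_hits
from .ks_estimator import SENSE_CODONS, STOP_CODONS, _AA, _SYN_SITES

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "EventLog",
    "AncestralGenome",
    "ConfigError",
    "IncompleteLogError",
    "simulate",
    "replay",
    "make_hits",
    "scenario_presets",
    "derive_trios",
    "sister_chromosome",
]

_BASES = "ACGT"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class IncompleteLogError(ValueError):
    """Event log is truncated or inconsistent with the ancestor/config."""


# one-step mutation option tables (derived from the standard genetic code)
def _option_tables() -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    syn: dict[str, list[str]] = {}
    non: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        s_opts, n_opts = [], []
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                (s_opts if _AA[alt] == _AA[codon] else n_opts).append(alt)
        syn[codon] = s_opts
        non[codon] = n_opts
    return syn, non


_SYN_OPTIONS, _NONSYN_OPTIONS = _option_tables()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one simulated species pair."""

    seed: int = 0
    ancestral_chromosomes: int = 7
    genes_per_chromosome: int = 100
    codons_per_gene: int = 200
    wgd_in_lineage_b: bool = True
    fusion_events: list[tuple[str, str]] = field(default_factory=list)
    fission_events: list[tuple[str, int]] = field(default_factory=list)
    per_copy_loss_rate: float = 0.0
    loss_timing: str = "before_merge"  # or "after_merge"
    translocation_rate: float = 0.0
    inversion_rate: float = 0.0
    ks_split: float = 1.0
    ks_wgd: float = 0.6
    nonsyn_fraction: float = 0.3
    ancient_dup_chrom: str | None = None
    ks_ancient: float = 1.5
    ancient_loss_rate: float = 0.8
    cej_trim: int = 2
    decoy_hit_rate: float = 0.0
    species_a: str = "A"
    species_b: str = "B"

    def validate(self) -> None:
        if self.ancestral_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigError("need at least one chromosome and one gene")
        if self.codons_per_gene < 2:
            raise ConfigError("codons_per_gene must be >= 2")
        for r in (
            self.per_copy_loss_rate,
            self.translocation_rate,
            self.inversion_rate,
            self.ancient_loss_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rate {r} outside [0, 1]")
        if min(self.ks_split, self.ks_wgd, self.ks_ancient) < 0:
            raise ConfigError("ks values must be >= 0")
        if self.loss_timing not in ("before_merge", "after_merge"):
            raise ConfigError(f"unknown loss_timing {self.loss_timing!r}")
        if self.ancient_dup_chrom is not None:
            if self.ancient_dup_chrom not in self._ancestral_chrom_names():
                raise ConfigError(f"ancient_dup_chrom {self.ancient_dup_chrom!r} not ancestral")
            if self.ks_ancient < self.ks_split:
                raise ConfigError("ks_ancient must be >= ks_split (duplication predates the split)")
        if self.cej_trim < 0:
            raise ConfigError("cej_trim must be >= 0")
        if self.fusion_events and not self.wgd_in_lineage_b:
            # fusions are defined on post-WGD copy names here
            for ci, cj in self.fusion_events:
                if ci.endswith(("a", "b")) or cj.endswith(("a", "b")):
                    raise ConfigError("fusion targets use WGD copy names but wgd is off")

    def _ancestral_chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.ancestral_chromosomes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fusion_events"] = [list(t) for t in self.fusion_events]
        d["fission_events"] = [list(t) for t in self.fission_events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["fusion_events"] = [tuple(t) for t in d.get("fusion_events", [])]
        d["fission_events"] = [(t[0], int(t[1])) for t in d.get("fission_events", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

@dataclass
class AncestralGenome:
    """Pre-duplication ancestor: gene order, strands and root CDS per family."""

    chroms: dict[str, list[tuple[str, str]]]  # chrom -> [(unit_id, strand), ...]
    cds: dict[str, list[str]]  # family id -> codon list
    serial: dict[str, int]  # unit id -> stable integer (seeds sequence evolution)
    family_of: dict[str, str]  # unit id -> family id
    dup_families: set[str] = field(default_factory=set)


def build_ancestor(config: SimulationConfig) -> AncestralGenome:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    chroms: dict[str, list[tuple[str, str]]] = {}
    cds: dict[str, list[str]] = {}
    serial: dict[str, int] = {}
    family_of: dict[str, str] = {}
    sense = np.array(SENSE_CODONS)
    for c in range(1, config.ancestral_chromosomes + 1):
        name = f"chr{c}"
        entries = []
        for i in range(config.genes_per_chromosome):
            uid = f"g{c}_{i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            entries.append((uid, strand))
            serial[uid] = c * 1_000_000 + i
            family_of[uid] = uid
            body = rng.choice(sense, size=config.codons_per_gene - 1)
            cds[uid] = ["ATG"] + [str(x) for x in body]
        chroms[name] = entries
    return AncestralGenome(chroms, cds, serial, family_of)


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------

@dataclass
class EventLog:
    """Ground-truth record: ordered events plus extant-gene ancestry."""

    config: SimulationConfig
    events: list[dict] = field(default_factory=list)
    ancestry: dict[str, dict] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return bool(self.events) and self.events[-1].get("kind") == "end"

    def events_of(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["kind"] == kind]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config.to_dict(),
                    "events": self.events,
                    "ancestry": self.ancestry,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "EventLog":
        with open(path) as fh:
            d = json.load(fh)
        return cls(SimulationConfig.from_dict(d["config"]), d["events"], d["ancestry"])


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _evolve_seq(
    codons: Sequence[str], d: float, rng: np.random.Generator, nonsyn_fraction: float
) -> list[str]:
    """Apply Poisson synonymous + nonsynonymous substitutions of total depth d.

    Substitution counts are allocated multinomially over codons by their
    one-step option weights; within-codon hits are applied sequentially so
    multiple hits at a site behave as in the Jukes-Cantor model the estimator
    corrects for.
    """
    cods = list(codons)
    if d <= 0 or not cods:
        return cods
    syn_w = np.array([len(_SYN_OPTIONS[c]) for c in cods], dtype=float)
    s0 = syn_w.sum() / 3.0
    n_syn = rng.poisson(d * s0) if s0 > 0 else 0
    if n_syn:
        alloc = rng.multinomial(n_syn, syn_w / syn_w.sum())
        for i in np.nonzero(alloc)[0]:
            for _ in range(int(alloc[i])):
                opts = _SYN_OPTIONS[cods[i]]
                if opts:
                    cods[i] = opts[int(rng.integers(len(opts)))]
    n0 = 3.0 * len(cods) - s0
    n_non = rng.poisson(nonsyn_fraction * d * n0) if n0 > 0 else 0
    if n_non:
        non_w = np.array([len(_NONSYN_OPTIONS[c]) for c in cods], dtype=float)
        if non_w.sum() > 0:
            alloc = rng.multinomial(n_non, non_w / non_w.sum())
            for i in np.nonzero(alloc)[0]:
                for _ in range(int(alloc[i])):
                    opts = _NONSYN_OPTIONS[cods[i]]
                    if opts:
                        cods[i] = opts[int(rng.integers(len(opts)))]
    return cods


# stage codes keying the per-branch random streams
_ST_ANC_ORIG, _ST_ANC_COPY, _ST_MID, _ST_A, _ST_B1, _ST_B2 = 1, 2, 3, 4, 5, 6


class _SeqEvolver:
    """Deterministic per-gene sequence evolution along the divergence tree."""

    def __init__(self, config: SimulationConfig, ancestor: AncestralGenome) -> None:
        self.cfg = config
        self.anc = ancestor
        self.h = (
            (config.ks_ancient - config.ks_split) / 2.0
            if config.ancient_dup_chrom is not None
            else 0.0
        )
        self.allo = config.wgd_in_lineage_b and config.ks_wgd > config.ks_split
        self._split: dict[str, list[str]] = {}
        self._mid: dict[str, list[str]] = {}
        self._leaf: dict[tuple[str, str], list[str]] = {}

    def _rng(self, stage: int, unit: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(
                entropy=self.cfg.seed, spawn_key=(stage, self.anc.serial[unit])
            )
        )

    def _evolve(self, seq: Sequence[str], d: float, stage: int, unit: str) -> list[str]:
        return _evolve_seq(seq, d, self._rng(stage, unit), self.cfg.nonsyn_fraction)

    def _split_state(self, unit: str) -> list[str]:
        got = self._split.get(unit)
        if got is None:
            fam = self.anc.family_of[unit]
            root = self.anc.cds[fam]
            if fam in self.anc.dup_families:
                stage = _ST_ANC_COPY if unit != fam else _ST_ANC_ORIG
                got = self._evolve(root, self.h, stage, unit)
            else:
                got = list(root)
            self._split[unit] = got
        return got

    def _mid_state(self, unit: str) -> list[str]:
        got = self._mid.get(unit)
        if got is None:
            cfg = self.cfg
            d = (
                (cfg.ks_wgd - cfg.ks_split) / 2.0
                if self.allo
                else (cfg.ks_split - cfg.ks_wgd) / 2.0
            )
            got = self._mid[unit] = self._evolve(self._split_state(unit), d, _ST_MID, unit)
        return got

    def leaf(self, unit: str, leaf: str) -> str:
        """Extant CDS (string) of one ancestral gene unit in leaf A, B1 or B2."""
        key = (unit, leaf)
        got = self._leaf.get(key)
        if got is None:
            cfg = self.cfg
            half_split, half_wgd = cfg.ks_split / 2.0, cfg.ks_wgd / 2.0
            if not cfg.wgd_in_lineage_b:
                stage = {"A": _ST_A, "B1": _ST_B1}[leaf]
                got = self._evolve(self._split_state(unit), half_split, stage, unit)
            elif self.allo:
                if leaf == "B2":
                    got = self._evolve(self._split_state(unit), half_wgd, _ST_B2, unit)
                else:
                    stage = _ST_A if leaf == "A" else _ST_B1
                    got = self._evolve(self._mid_state(unit), half_split, stage, unit)
            else:
                if leaf == "A":
                    got = self._evolve(self._split_state(unit), half_split, _ST_A, unit)
                else:
                    stage = _ST_B1 if leaf == "B1" else _ST_B2
                    got = self._evolve(self._mid_state(unit), half_wgd, stage, unit)
            self._leaf[key] = got
        return "".join(got)


def expected_pair_distance(
    config: SimulationConfig, leaf_x: str, role_x: str, leaf_y: str, role_y: str
) -> float:
    """Expected synonymous divergence between two extant family members."""
    allo = config.wgd_in_lineage_b and config.ks_wgd > config.ks_split
    depth = (config.ks_wgd if allo else config.ks_split) / 2.0

    def leaf_dist(x: str, y: str) -> float:
        if x == y:
            return 0.0
        pair = frozenset((x, y))
        if pair == {"A", "B1"}:
            return config.ks_split
        if pair == {"A", "B2"}:
            return config.ks_wgd if allo else config.ks_split
        return config.ks_wgd  # B1 vs B2

    if role_x != role_y:  # through the ancient duplication node
        return (config.ks_ancient - config.ks_split) + 2.0 * depth
    return leaf_dist(leaf_x, leaf_y)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    ancestor: AncestralGenome
    panel_a: GenomePanel
    panel_b: GenomePanel
    hits_ab: list[HomologyHit]
    hits_ba: list[HomologyHit]
    event_log: EventLog

    @property
    def cds_a(self) -> dict[str, str]:
        return self.panel_a.cds

    @property
    def cds_b(self) -> dict[str, str]:
        return self.panel_b.cds

    @property
    def hit_table(self) -> list[HomologyHit]:
        return self.hits_ab

    def write(self, outdir: str) -> None:
        """Write GFF3 + CDS FASTA per species, the A->B hit table and the log."""
        import os

        from .genome_model import write_annotations, write_cds, write_hits

        os.makedirs(outdir, exist_ok=True)
        for panel, tag in ((self.panel_a, self.config.species_a), (self.panel_b, self.config.species_b)):
            write_annotations(panel, os.path.join(outdir, f"{tag}.gff3"))
            write_cds(panel.cds, os.path.join(outdir, f"{tag}.cds.fa"))
        write_hits(
            self.hits_ab,
            os.path.join(outdir, "hits_ab.tsv"),
            aln_length=self.config.codons_per_gene,
        )
        self.event_log.to_json(os.path.join(outdir, "events.json"))


class _EventTape:
    """Records events when simulating; replays them verbatim when replaying."""

    def __init__(self, log: EventLog, replaying: bool) -> None:
        self.log = log
        self.replaying = replaying
        self._iter: Iterator[dict] | None = iter(log.events) if replaying else None

    def push(self, sampler) -> dict:
        if self.replaying:
            ev = next(self._iter, None)
            if ev is None:
                raise IncompleteLogError("event log is truncated")
            return ev
        ev = sampler()
        self.log.events.append(ev)
        return ev


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the forward simulation; deterministic given ``config.seed``."""
    config.validate()
    ancestor = build_ancestor(config)
    log = EventLog(config)
    panel_a, panel_b = _run(config, ancestor, log, replaying=False)
    hits_ab = make_hits(config, log.ancestry, panel_a, panel_b, seed_offset=71)
    hits_ba = make_hits(config, log.ancestry, panel_b, panel_a, seed_offset=72)
    return SimulationResult(config, ancestor, panel_a, panel_b, hits_ab, hits_ba, log)


def replay(log: EventLog, ancestor: AncestralGenome) -> tuple[GenomePanel, GenomePanel]:
    """Re-apply a complete event log to the ancestor; byte-identical genomes."""
    if not log.complete:
        raise IncompleteLogError("event log lacks the terminal 'end' event")
    fresh = EventLog(log.config, list(log.events))
    return _run(log.config, ancestor, fresh, replaying=True)


def _run(
    config: SimulationConfig,
    ancestor: AncestralGenome,
    log: EventLog,
    replaying: bool,
) -> tuple[GenomePanel, GenomePanel]:
    tape = _EventTape(log, replaying)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(9_001,)))

    # working ancestral state (ancient duplication happens pre-split)
    anc_chroms = {c: list(v) for c, v in ancestor.chroms.items()}
    ancestor.dup_families.clear()

    if config.ancient_dup_chrom is not None:
        src = config.ancient_dup_chrom

        def _dup() -> dict:
            return {"kind": "ancient_dup", "chrom": src, "copy_chrom": src + "d"}

        ev = tape.push(_dup)
        copy_name = ev["copy_chrom"]
        copy_entries = []
        for uid, strand in anc_chroms[src]:
            cid = uid.replace("_", "d_", 1)  # g1_0007 -> g1d_0007
            ancestor.family_of[cid] = uid
            ancestor.serial[cid] = ancestor.serial[uid] + 500_000
            ancestor.dup_families.add(uid)
            copy_entries.append((cid, strand))
        anc_chroms[copy_name] = copy_entries

        def _anc_loss() -> dict:
            lost = [
                cid
                for cid, _ in copy_entries
                if rng.random() < config.ancient_loss_rate
            ]
            return {"kind": "ancient_loss", "genes": lost}

        ev = tape.push(_anc_loss)
        lost = set(ev["genes"])
        anc_chroms[copy_name] = [e for e in anc_chroms[copy_name] if e[0] not in lost]

    tape.push(lambda: {"kind": "speciation"})

    # lineage A inherits the (possibly duplicated) ancestral karyotype
    a_chroms: dict[str, list[tuple[str, str]]] = {
        c: list(v) for c, v in sorted(anc_chroms.items())
    }

    # lineage B: optional WGD into subgenomes B1 ('a' copies) and B2 ('b')
    b_chroms: dict[str, list[tuple[str, str, str]]] = {}
    if config.wgd_in_lineage_b:
        tape.push(lambda: {"kind": "wgd"})
        for c, entries in sorted(anc_chroms.items()):
            b_chroms[c + "a"] = [(u, s, "B1") for u, s in entries]
            b_chroms[c + "b"] = [(u, s, "B2") for u, s in entries]
    else:
        for c, entries in sorted(anc_chroms.items()):
            b_chroms[c] = [(u, s, "B1") for u, s in entries]

    def apply_loss() -> None:
        def _loss() -> dict:
            lost = []
            for c in sorted(b_chroms):
                for u, _s, sub in b_chroms[c]:
                    if rng.random() < config.per_copy_loss_rate:
                        lost.append(f"{sub}_{u}")
            return {"kind": "loss", "timing": config.loss_timing, "genes": lost}

        ev = tape.push(_loss)
        lost = set(ev["genes"])
        for c in list(b_chroms):
            b_chroms[c] = [e for e in b_chroms[c] if f"{e[2]}_{e[0]}" not in lost]

    if config.per_copy_loss_rate > 0 and config.loss_timing == "before_merge":
        apply_loss()

    for ci, cj in config.fusion_events:
        if ci not in b_chroms or cj not in b_chroms:
            raise ConfigError(f"fusion target {ci!r}/{cj!r} not present in lineage B")
        trim = config.cej_trim
        left = b_chroms[ci][: len(b_chroms[ci]) - trim if trim else None]
        right = b_chroms[cj][trim:]
        trimmed = [f"{e[2]}_{e[0]}" for e in b_chroms[ci][len(left):]] + [
            f"{e[2]}_{e[0]}" for e in b_chroms[cj][:trim]
        ]
        merged = f"{ci}-{cj}"
        tape.push(
            lambda ci=ci, cj=cj, merged=merged, trimmed=trimmed, left=left: {
                "kind": "fusion",
                "left": ci,
                "right": cj,
                "merged": merged,
                "junction_rank": len(left),
                "trimmed": trimmed,
            }
        )
        b_chroms[merged] = left + right
        del b_chroms[ci], b_chroms[cj]

    for target, rank in config.fission_events:
        lineage, _, chrom = target.partition(":")
        if lineage not in ("A", "B") or not chrom:
            raise ConfigError(f"fission target {target!r}: use 'A:chrom' or 'B:chrom'")
        store = a_chroms if lineage == "A" else b_chroms
        if chrom not in store:
            raise ConfigError(f"fission target {chrom!r} not present in lineage {lineage}")
        if not 0 < rank < len(store[chrom]):
            raise ConfigError(
                f"fission breakpoint {rank} outside chromosome {chrom!r} "
                f"(length {len(store[chrom])})"
            )
        tape.push(
            lambda lineage=lineage, chrom=chrom, rank=rank: {
                "kind": "fission",
                "lineage": lineage,
                "chrom": chrom,
                "rank": rank,
            }
        )
        store[chrom + ".1"] = store[chrom][:rank]
        store[chrom + ".2"] = store[chrom][rank:]
        del store[chrom]

    if config.per_copy_loss_rate > 0 and config.loss_timing == "after_merge":
        apply_loss()

    n_b_genes = sum(len(v) for v in b_chroms.values())

    def _inversions() -> dict:
        events = []
        n = rng.poisson(config.inversion_rate * n_b_genes)
        names = sorted(b_chroms)
        sizes = np.array([len(b_chroms[c]) for c in names], dtype=float)
        if sizes.sum() > 0:
            for _ in range(int(n)):
                c = names[int(rng.choice(len(names), p=sizes / sizes.sum()))]
                length = len(b_chroms[c])
                if length < 3:
                    continue
                span = int(rng.integers(2, min(30, length) + 1))
                start = int(rng.integers(0, length - span + 1))
                events.append({"chrom": c, "start": start, "end": start + span - 1})
        return {"kind": "inversions", "events": events}

    for ev in tape.push(_inversions)["events"]:
        c, s, e = ev["chrom"], ev["start"], ev["end"]
        seg = b_chroms[c][s : e + 1][::-1]
        b_chroms[c][s : e + 1] = [
            (u, "-" if st == "+" else "+", sub) for u, st, sub in seg
        ]

    def _translocations() -> dict:
        events = []
        n = rng.poisson(config.translocation_rate * n_b_genes)
        for _ in range(int(n)):
            names = sorted(c for c in b_chroms if b_chroms[c])
            if not names:
                break
            sizes = np.array([len(b_chroms[c]) for c in names], dtype=float)
            src = names[int(rng.choice(len(names), p=sizes / sizes.sum()))]
            pos = int(rng.integers(len(b_chroms[src])))
            dest = sorted(b_chroms)[int(rng.integers(len(b_chroms)))]
            ins = int(rng.integers(len(b_chroms[dest]) + 1))
            events.append(
                {"src": src, "pos": pos, "dest": dest, "insert_at": ins}
            )
        return {"kind": "translocations", "events": events}

    for ev in tape.push(_translocations)["events"]:
        entry = b_chroms[ev["src"]].pop(ev["pos"])
        b_chroms[ev["dest"]].insert(ev["insert_at"], entry)

    tape.push(lambda: {"kind": "end"})

    # ---- materialize panels + sequences -------------------------------
    evolver = _SeqEvolver(config, ancestor)
    gene_span = 3 * config.codons_per_gene

    def make_panel(
        species: str,
        chrom_map: dict,
        lineage_a: bool,
    ) -> GenomePanel:
        genes: list[Gene] = []
        cds: dict[str, str] = {}
        for chrom in sorted(chrom_map):
            for rank, entry in enumerate(chrom_map[chrom]):
                if lineage_a:
                    unit, strand = entry
                    sub = "A"
                else:
                    unit, strand, sub = entry
                gid = f"{sub}_{unit}"
                start = rank * 3000 + 1
                genes.append(Gene(gid, chrom, start, start + gene_span - 1, strand))
                cds[gid] = evolver.leaf(unit, "A" if lineage_a else sub)
                fam = ancestor.family_of[unit]
                log.ancestry[gid] = {
                    "family": fam,
                    "ancestral_gene": unit,
                    "subgenome": sub,
                    "species": species,
                }
        panel = GenomePanel(species, genes)
        panel.attach_cds(cds)
        return panel

    panel_a = make_panel(config.species_a, a_chroms, lineage_a=True)
    panel_b = make_panel(config.species_b, b_chroms, lineage_a=False)
    return panel_a, panel_b


# ---------------------------------------------------------------------------
# hit tables from true homology
# ---------------------------------------------------------------------------

def make_hits(
    config: SimulationConfig,
    ancestry: dict[str, dict],
    panel_x: GenomePanel,
    panel_y: GenomePanel,
    max_evalue: float = 1e-5,
    top_n: int = 5,
    seed_offset: int = 71,
) -> list[HomologyHit]:
    """Noise-free hit table from the ancestry map (optionally plus decoys).

    Bitscores decay exponentially with the expected pairwise divergence, so
    ortholog hits outrank ancient out-paralog hits; the standard
    e-value/top-N filter is then applied.
    """
    fam_x: dict[str, list[str]] = {}
    fam_y: dict[str, list[str]] = {}
    for gid in sorted(panel_x.genes):
        fam_x.setdefault(ancestry[gid]["family"], []).append(gid)
    for gid in sorted(panel_y.genes):
        fam_y.setdefault(ancestry[gid]["family"], []).append(gid)

    def role(gid: str) -> str:
        a = ancestry[gid]
        return "copy" if a["ancestral_gene"] != a["family"] else "orig"

    hits: list[HomologyHit] = []
    for fam in sorted(set(fam_x) & set(fam_y)):
        for qx in fam_x[fam]:
            for sy in fam_y[fam]:
                if qx == sy:
                    continue
                d = expected_pair_distance(
                    config,
                    ancestry[qx]["subgenome"],
                    role(qx),
                    ancestry[sy]["subgenome"],
                    role(sy),
                )
                bits = max(50.0, 2.0 * config.codons_per_gene * math.exp(-d))
                hits.append(
                    HomologyHit(
                        query_gene=qx,
                        subject_gene=sy,
                        identity=round(100.0 * math.exp(-0.5 * d), 2),
                        evalue=10.0 ** (-min(180.0, bits / 4.0)),
                        bitscore=round(bits, 1),
                    )
                )
    if config.decoy_hit_rate > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(9_100 + seed_offset,))
        )
        qs = sorted(panel_x.genes)
        ss = sorted(panel_y.genes)
        n = rng.poisson(config.decoy_hit_rate * len(qs))
        for _ in range(int(n)):
            qx = qs[int(rng.integers(len(qs)))]
            sy = ss[int(rng.integers(len(ss)))]
            if qx == sy or ancestry[qx]["family"] == ancestry[sy]["family"]:
                continue
            hits.append(HomologyHit(qx, sy, 30.0, 1e-6, 45.0))
    return filter_hits(hits, max_evalue=max_evalue, top_n=top_n)


# ---------------------------------------------------------------------------
# scenario presets and ground-truth trios
# ---------------------------------------------------------------------------

def sister_chromosome(chrom: str) -> str:
    """The other WGD copy of a lineage-B chromosome (chr1a <-> chr1b)."""
    if chrom.endswith("a"):
        return chrom[:-1] + "b"
    if chrom.endswith("b"):
        return chrom[:-1] + "a"
    raise ValueError(f"{chrom!r} is not a WGD copy name")


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study conditions for the fusion/fission and grass-like scenarios.

    ``ks_split`` is set to 1.05, the centre of the split-era synonymous
    divergence window used by the classifier; ``ks_wgd`` 0.6 places the
    duplication after the split.
    """
    return {
        "fusion_C": SimulationConfig(
            ancestral_chromosomes=2,
            genes_per_chromosome=80,
            codons_per_gene=400,
            wgd_in_lineage_b=True,
            fusion_events=[("chr1a", "chr2a")],
            per_copy_loss_rate=0.3,
            loss_timing="before_merge",
            ks_split=1.05,
            ks_wgd=0.6,
        ),
        "fission_A": SimulationConfig(
            ancestral_chromosomes=2,
            genes_per_chromosome=120,
            codons_per_gene=400,
            wgd_in_lineage_b=True,
            fission_events=[("B:chr1b", 42)],
            per_copy_loss_rate=0.3,
            loss_timing="before_merge",
            ks_split=1.05,
            ks_wgd=0.6,
        ),
        "fission_B": SimulationConfig(
            ancestral_chromosomes=2,
            genes_per_chromosome=120,
            codons_per_gene=400,
            wgd_in_lineage_b=True,
            fission_events=[("B:chr1b", 28), ("A:chr1", 85)],
            per_copy_loss_rate=0.3,
            loss_timing="before_merge",
            ks_split=1.05,
            ks_wgd=0.6,
        ),
        "grass_like": SimulationConfig(
            ancestral_chromosomes=7,
            genes_per_chromosome=90,
            codons_per_gene=400,
            wgd_in_lineage_b=True,
            fusion_events=[("chr1a", "chr2a"), ("chr3a", "chr4a")],
            per_copy_loss_rate=0.4,
            loss_timing="before_merge",
            translocation_rate=0.02,
            inversion_rate=0.005,
            ks_split=1.05,
            ks_wgd=0.6,
        ),
    }


def derive_trios(config: SimulationConfig) -> list[tuple[str, str, str, str]]:
    """Ground-truth (merged, part, part, expected_verdict) trios for a config."""
    trios = []
    for ci, cj in config.fusion_events:
        trios.append(
            (f"{ci}-{cj}", sister_chromosome(ci), sister_chromosome(cj), "fusion")
        )
    for target, rank in config.fission_events:
        lineage, _, chrom = target.partition(":")
        if lineage != "B":
            continue
        trios.append(
            (sister_chromosome(chrom), f"{chrom}.1", f"{chrom}.2", "fission")
        )
    return trios
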