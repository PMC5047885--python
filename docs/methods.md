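# Methods

This note documents the models and procedures implemented in `synkaryo`,
the defaults that matter, and what the built-in simulator does and does not
emulate.

## Coordinates and data model

Files use 1-based inclusive base-pair coordinates (GFF3 convention); in
memory every gene carries a 0-based `order_index`, its rank along its
chromosome by start coordinate (ties broken lexicographically by gene id).
All collinearity arithmetic — gaps, chains, junctions — is done in these
gene-rank units. Homology hits use the 12-column BLAST tabular dialect and
are filtered to e-value ≤ 1e-5 and, per query gene, the five best subjects
by bitscore (ties by subject id; the ranking key is our choice, stated here
because the convention is not universal). Self-hits are always dropped;
removal of within-genome hits between rank-adjacent genes (tandem
artefacts) is available behind a flag and off by default.

## Collinear block detection

Anchors between two chromosomes form dots (rank_query, rank_subject). A
block is a strictly monotone chain (both orientations searched) in which
consecutive anchors are separated by at most `max_gap` intervening gene
ranks on *each* genome independently (default 50). Chains are found by
O(n²) sparse dynamic programming with chain length as score; anchors are
assigned greedily to the longest remaining chain, which is removed before
the next search, so no anchor belongs to two blocks. Blocks shorter than
`min_len` (default 5, i.e. the census class "more than 4") are discarded.

Significance is a permutation test: the same number of anchors is placed
uniformly at random on the two chromosomes (positions drawn with
replacement; ties cannot chain, matching the observed-data rule) and the
longest chain length recomputed; `p = (#null ≥ observed + 1) / (N + 1)`
with N = 1000 permutations by default, seeded and therefore reproducible.
The null distribution is computed once per chromosome pair and shared by
all of that pair's blocks. A permutation null was chosen over an analytic
one because it is assumption-light and exactly matched to the chain
statistic actually used; the 0.05 threshold is the conventional one.
Within-genome runs exclude the self-diagonal and evaluate each unordered
chromosome pair once.

## Ks estimation (Nei–Gojobori with Jukes–Cantor correction)

Codon alignment is protein-guided: translated sequences are globally
aligned with match +1, mismatch −1, linear gap −2 (constants chosen for
transparency, not sensitivity — inputs here are confidently homologous
CDS), then back-translated. Columns with a gap, a non-ACGT base, or a stop
codon are excluded; incomplete terminal codons are trimmed; internal stops
are flagged.

Per-codon synonymous site counts follow the standard genetic code: at each
position the synonymous fraction is (number of synonymous one-step
changes)/3, averaged over the two sequences; changes that create a stop
codon count as nonsynonymous, which keeps S + N = 3 × (codon pairs)
exactly. Observed differences between codons differing at k positions are
averaged with equal weight over all k! mutational pathways; pathways
passing through a stop codon are excluded (if every pathway is blocked —
possible only for rare multi-hit pairs — all pathways are used with
stop-crossing steps counted nonsynonymous). Jukes–Cantor correction maps
pS = Sd/S to Ks (and pN to Ka); pS ≥ 3/4 is reported as saturated rather
than raising or returning a number. Saturated pairs are excluded from
block medians; an all-saturated block is flagged undefined.

This is deliberately the counting method, not a maximum-likelihood
codon-model estimate: it is self-contained, exactly checkable against a
brute-force pathway enumerator (the test suite does so), and sufficient for
median-of-block dating.

## Orthology layering

After one WGD in the subject lineage the expected orthology depth is 1:2.
Blocks are labeled by Ks median: inside [0.95, 1.20] → orthologous
(split-era); within 1.5 ± 0.15 → out-paralogous (older duplication);
otherwise ambiguous. The window bounds are the split-era range used
throughout this analysis; the half-width 0.15 around 1.5 is our
operationalization (configurable) since only the center is meaningful a
priori. The orthology window wins if a configuration makes the zones
overlap, and raising a median can never promote a block from out-paralog
to ortholog (tested as a property).

Where Ks medians cannot separate candidate subject chromosomes, the
shared-collinear-gene tie-break applies: for candidates X, Y against one
query chromosome, sharing(X→Y) is the fraction of X's collinear query
genes that also anchor Y, and the mutual sharing of a pair is the smaller
direction. The pair with the highest mutual sharing above
`share_threshold` = 0.20 — best-supported first, i.e. largest minimum
anchor count — are the WGD co-orthologs; a candidate whose mutual sharing
with both co-orthologs stays below the threshold is out-paralogous. The
support weighting matters because an older duplicate's own two WGD copies
are also a mutually-sharing pair; anchor counts (typically several-fold
lower for the ancient layer) disambiguate, exactly as they do when reading
a dotplot. The 0.20 default sits far from both observed regimes (~0.4 for
co-orthologs, ~0.05 for out-paralogs in the worked example).

Correspondence maps list, per subject chromosome, the query chromosomes
contributing at least `min_anchor` = 10 orthologous anchors — small enough
to keep real segments, large enough to exclude stray translocated genes.

## Fusion vs fission on trios

For a trio (merged P1; parts P2, P3), with corr(·) the orthologous
correspondence sets: **fusion** iff Jaccard(corr P2, corr P3) ≤ 0.10 and
corr P2 ∪ corr P3 covers ≥ 0.80 of corr P1; **fission** iff some query
chromosome lies in all three sets; otherwise **undetermined**, with the
reason recorded. The fusion condition is checked first; the verdict is
symmetric in the parts. The thresholds quantify "perfect independent
correspondence" and are reported with every verdict. A genuine degeneracy
remains: a fission in the subject lineage whose breakpoint coincides with
an independent fission in the query lineage is indistinguishable from a
fusion; the simulator's fission scenarios therefore place the two
breakpoints apart, which is also the generic case in nature.

Ancestral counts follow by unit arithmetic: units = observed chromosomes +
fusions − fissions; with a WGD, x = units/2, 2n_pre = 2x, 2n_post = 4x.
Undetermined trios widen the estimate to an interval instead of a point.
The junction trace labels the merged chromosome's anchors by which part's
correspondence their query chromosome belongs to; maximal runs are
segments, label changes are candidate junctions (all reported when
segments interleave), and a junction is CEJ-consistent when its adjacent
query genes map within 10 gene ranks of a chromosome end of the part.

## Fractionation census

Per query gene, the surviving subject copy count is the number of distinct
subject chromosomes the gene anchors within orthologous blocks ("expected
locations"): 2+ → both copies, 1 → one copy, 0 → absent. The denominator
(all query genes, unplaced scaffolds flagged but counted) is always
printed. Absent genes with any protein-level hit at e-value ≤ 1e-10 are
translocation candidates; those that are bidirectional best hits (best by
bitscore, ties by e-value then subject id) are the strong subset; the
remainder are candidate true losses. With no hit table the absent class is
reported untriaged rather than presumed lost. Counting distinct subject
chromosomes undercounts only if both WGD copies of a region end up on one
chromosome, which none of the modeled rearrangements produce.

## Simulator

The simulator is the test bed for every other module: two genomes descend
from an ancestor of `x` chromosomes × `genes_per_chromosome` genes with
random sense-codon CDS. Lineage A keeps the ancestral karyotype; lineage B
optionally duplicates (subgenomes B1/B2), then applies CEJ fusions (the
joined ends each lose `cej_trim` = 2 genes), fissions (breakpoints in
extant gene-rank coordinates at event time), per-copy Bernoulli gene loss
timed before or after the merges, Poisson-count inversions and single-gene
translocations. An optional pre-speciation chromosome duplication plants
an out-paralogy layer at divergence `ks_ancient` whose copy is heavily
fractionated (`ancient_loss_rate` = 0.8) before the split — the realistic
signature that makes ancient layers sparse and poorly shared.

Sequence divergence lives on a three-leaf additive tree over (A, B1, B2):
with `ks_wgd ≤ ks_split` the duplication nests inside the B lineage; with
`ks_wgd > ks_split` the second subgenome branches basal to the split (an
allopolyploid with a divergent parent). Along each branch, synonymous
substitution counts are Poisson with mean (branch length × synonymous
sites), allocated over codons by their synonymous-site weights and applied
sequentially within codons, so multiple hits occur exactly as the
Jukes–Cantor correction assumes; nonsynonymous changes are added at
`nonsyn_fraction` = 0.3 of the equivalent nonsynonymous rate mass,
avoiding stops. Cross-codon site-count drift within a branch is ignored —
an approximation that leaves mean pipeline-recovered Ks within a few
percent of the target (the residual upward bias is the usual convexity
effect of correcting noisy pS). Hit tables are generated from true
ancestry with bitscores decaying in expected divergence (so ortholog hits
outrank ancient-paralog hits), then passed through the standard filter;
optional decoy hits exercise the significance filter. This keeps tests
fast and focused on downstream inference rather than search sensitivity.

Ground truth is an event log holding every structural event with full
coordinates and gene ids plus an ancestry map; `replay` re-applies a
complete log to the ancestor and reproduces the genomes byte for byte
(sequence evolution is a pure function of the master seed, keyed per gene
and branch). A log without its terminal sentinel raises an incompleteness
error.

### Preset study conditions

| preset | x | genes/chrom | events | loss | ks_split / ks_wgd |
|---|---|---|---|---|---|
| `fusion_C` | 2 | 80 | 1 CEJ fusion post-WGD | 0.30 before merge | 1.05 / 0.6 |
| `fission_A` | 2 | 120 | 1 fission of a WGD copy | 0.30 | 1.05 / 0.6 |
| `fission_B` | 2 | 120 | fission of a WGD copy + an independent fission in the outgroup | 0.30 | 1.05 / 0.6 |
| `grass_like` | 7 | 90 | WGD + 2 CEJ fusions (14 → 12 chromosomes) | 0.40 before merge | 1.05 / 0.6 |

`ks_split` = 1.05 is the center of the split-era orthology window —
the generating value a practitioner would call realistic for this species
pair; `ks_wgd` = 0.6 places the duplication comfortably after the split.
Genes are 400 codons (typical plant CDS scale), which keeps block Ks
medians well inside the window. Fission breakpoints are placed so that
every resulting correspondence segment carries comfortably more than
`min_anchor` anchors after loss; sizes overall are chosen so a full
preset run (simulation + pipeline) completes in seconds on one core —
large enough for stable verdicts, small enough for many seeded replicates.
`grass_like` adds translocation (0.02/gene) and inversion (0.005/gene)
noise.

## What passing tests do and do not show

The simulator emulates gene-order evolution and clock-like synonymous
divergence, not sequence search: hits are ancestry-derived, e-values are
synthetic, and there are no tandem arrays, transposons, codon-usage bias,
or assembly artifacts. Recovery results therefore validate the inference
chain downstream of homology search — block calling, dating,
classification, trio logic, censuses — under known truth; they do not
certify performance on noisy real annotations, fragmented assemblies, or
homology tables from permissive search parameters. The fission/fusion
degeneracy under coincident breakpoints is inherent to the method, not an
implementation limit. Ks dating assumes the standard genetic code and
near-neutral synonymous sites; saturated pairs are excluded rather than
modeled.

## Numerical and reproducibility notes

All randomness (simulator, permutation nulls) flows from explicit integer
seeds through independent spawned streams; reports contain no timestamps
or absolute paths, so a rerun with the same config and seed is
byte-identical (tested). Chain DP tie-breaks prefer the earliest dot in
(rank_a, rank_b) order; equal-length chains prefer the "same" orientation.
Percentages in sharing evidence are rounded half-up to one decimal.
Degenerate inputs — empty hit tables, empty chromosomes, all-saturated
blocks, zero-anchor candidates — produce empty-but-well-formed outputs or
flagged records, not exceptions; genuinely invalid configuration
(inverted windows, out-of-range breakpoints, non-positive permutation
counts) raises immediately.
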