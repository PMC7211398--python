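# Methods

This note documents the models, conventions and numerical choices behind
`donorforge`, in the order a design runs through them. Coordinates are
0-based half-open throughout; sequences are uppercased on input and
soft-masked (lowercase) bases are treated as their uppercase equivalents.

## Linker layout and enumeration

A linker pair is two 30-bp oligos carrying eight restriction sites: AgeI
(`ACCGGT`) anchored at the 5' terminus of linker a, XhoI (`CTCGAG`) at the
3' terminus of linker b, and three further sites on each linker. The
default internal set — NheI, SalI, BamHI on linker a; SpeI, MluI, EcoRV on
linker b — consists of common palindromic 6-bp cutters; how rare each site
is in a particular genome can be checked directly with
`genome_screen.res_density` (occurrences per Mb, both strands, palindromes
counted once per locus). Four 6-bp sites leave 6 free bases per linker;
the default geometry fills the three inter-site gaps with 2-bp spacers
(three single-base gaps cannot absorb six bases), keeping both anchor
sites flush with their termini. Layouts are fully configurable: any enzyme
list, gap distribution and linker length that adds up is accepted.

Enumeration assigns {A,C,G,T} to every spacer position: exhaustively when
4^budget ≤ `max_candidates`, otherwise by seeded uniform sampling without
replacement (the switch is logged). An assignment is discarded when any
layout site — or its reverse complement — appears anywhere beyond its
designated slot in either linker, so every emitted pair has exactly eight
cut sites, each unique within the pair.

## The six-filter screen

Screening is sequence-level run counting, not nearest-neighbour
thermodynamics: for 30-bp oligos the adverse structures of practical
concern (stable hairpins, extensible dimers) are dominated by exact
Watson–Crick runs, and exact counting is reproducible and
parameter-transparent. Ambiguity codes never pair.

- **Hairpin**: any maximal self-complementary stem ≥ 4 bp with a loop
  ≥ 3 nt. Maximality means the stem extends neither outward nor inward
  (inward extension is also blocked when it would shrink the loop below
  the minimum).
- **Self-dimer / cross-dimer**: maximal antiparallel complementary runs
  between two oligos (the same oligo twice for self-dimers), reported at
  ≥ 8 bp anywhere, or at ≥ 7 bp when the run overlaps the last 5 bases of
  either 3' end. The 3'-anchored threshold sits at 7 deliberately: every
  palindromic 6-bp restriction site self-anneals over exactly 6 bp, and
  the mandated terminal sites (XhoI on linker b, BamHI on the default
  linker a) would otherwise reject every layout-conforming candidate.
  Only anneals *longer* than one intact site — i.e. extended by spacer
  bases — are treated as adverse.
- **Melting temperature**: the long-oligo salt-adjusted closed form
  T_m = 81.5 + 16.6·log10([Na+]) + 0.41·(%GC) − 600/L, default
  [Na+] = 0.05 M, valid for L ≥ 14. The published screening criterion is
  one-sided ("high" T_m); the filter is a two-sided 55–68 °C window for
  usability, with the upper bound carrying that criterion.
- **GC content**: (ΣG + ΣC)/ΣN × 100 with N counting *every* character —
  ambiguity codes (including S) contribute to the denominator only. The
  accepted window is 40–60%, mirroring the unbalanced-flank definition.
- **Repeats**: homopolymer runs > 4 nt, or a dinucleotide unit (two
  distinct bases) tandemly repeated > 3 times.
- **GC clamp**: more than 4 G/C among the terminal 5 bases of either end.
  The threshold is 4, not 3, because the anchored AgeI terminus contributes
  ACCGG = 4 G/C to every candidate's first window; 5-of-5 G/C termini
  (spacer-extended) are rejected.

All cutoffs live in `FilterThresholds` and are overridable from YAML or
CLI flags; reports list every failing filter with the offending span and
measured value, never just the first.

## Genome identity ranking

"Identity to the genome" is operationalised as the length of the longest
substring of the query occurring exactly in the genome on either strand,
computed by k-mer seeding plus maximal ungapped extension (default k = 12
for real genomes, k = 8 in tests; queries are scanned on both strands, so
scores are strand-symmetric). For 30-bp queries, low-identity local
alignments are dominated by exact seed matches, so this statistic is a
faithful, aligner-free proxy for a BLAST-style ranking; it is documented
as a proxy, and external alignment scores can be substituted upstream of
`rank_pairs` by setting `pair.identity` directly. When no k-mer seeds,
the score is below the seed length and reported as k − 1 with zero hits
("< k"). Ranking is ascending by identity with deterministic tie-breaks:
|T_m(a) − T_m(b)| (a balanced pair amplifies both arms under one cycling
program), then lexicographic sequence order.

## CDS-flank GC survey

Per-chromosome GenBank files are parsed with Biopython; join-locations
resolve to the feature's overall start/end. Deduplication keeps the first
CDS entry per (chromosome, start, end, strand) — isoform bookkeeping
commonly repeats identical coordinates — and is idempotent. Each codon's
flank window spans the codon's first base ± width (default 750 bp, 1500 bp
total), strand-aware: on the minus strand the start codon sits at the CDS
end coordinate and the window is reverse-complemented (GC itself is
strand-symmetric, so the convention affects sequences, not calls). Windows
clipped at a contig edge are measured on the clipped sequence and flagged
`truncated` rather than dropped — silently discarding edge genes would
bias the unbalanced fraction — with `drop_truncated=True` available.
Unbalanced means either window strictly > 60% or < 40% GC; an
`inclusive` flag covers the alternative reading of the bounds. Named
contigs (alternate assemblies, unplaced scaffolds) can be excluded.
The distribution is histogrammed in 1% bins over [0, 100].

## Digestion and assembly model

Digestion cuts at every exact site occurrence (both orientations for
non-palindromic enzymes) using per-enzyme top/bottom cut offsets from a
bundled editable table; fragment top-strand lengths always sum to the
input length, and each end records its overhang (blunt, 5' or 3') in
top-strand coordinates. An uncut circular input is an error; cuts within
1 bp of a linear end are flagged unstable.

Assembly joins fragments where one terminal ≥ `min_overlap` (default
20 bp; the designed linkers give 30 bp) stretch exactly equals another
fragment's opposite terminus — the chew-back chemistry is abstracted to
overlap identity, which determines both the product sequence and the
ambiguity structure — and additionally where digestion left complementary
sticky ends. The sticky route is what makes the hierarchical protocol's
digestion-plus-assembly rounds simulable: a singly cut plasmid
re-circularises to exactly its original sequence, which a seamless-overlap
join alone cannot do (it would necessarily remove one overlap copy).
Success requires every terminus to have exactly one partner (fragment
self-circularisation counts as a competing partner) and a unique circular
ordering over all fragments; otherwise a `HazardReport` enumerates the
ambiguous junctions and counts the alternative orderings. Orderings are
enumerated exactly (supported to 9 fragments — donor constructs use 3–5);
fragments are used in the orientation given. Circular products compare by
canonical (lexicographically least) rotation, computed with Booth's
algorithm.

`detect_hazards` is the pre-flight version of the same concern: it scans
the terminal `window` (default 40 bp, always ≥ k) of every fragment end
for substrings ≥ k (default 15 bp, either strand) shared with any end that
is not an intended junction partner. The 34-bp LoxP site flanking a
removable selectable marker is the canonical trigger — one copy on a
homology arm plus two on the marker yields three pairwise terminal
matches — but any motif works.

The one- vs two-step decision is a pure rule: two-step iff either arm's
GC is unbalanced (> 60 / < 40) or the insert carries a LoxP-flanked
marker, with every trigger listed. Two-step digests at AgeI and
integrates the 5' arm, then repeats with XhoI and the 3' arm. sgRNA
recognition sites are target (20 nt, validated) + PAM (NGG, validated)
= 23 nt; `insert_flanking_sites` places one copy immediately inside each
of two unique enzyme loci, preserving both sites (the exact offset
relative to each locus is configurable territory; preserving re-cuttable
loci while flanking the IF is the committed contract).

## Synthetic data

`fixtures.make_genome` builds contigs of spaced genes whose start- and
stop-codon windows are drawn at a programmed GC: skewed genes at 70%
(the regime of reported hard targets, e.g. homology arms at ~70–73%),
balanced genes at 50%, with an unbalanced fraction defaulting to 0.45 —
the scale reported for human genes. The default CDS length is 1602 bp so
the two 1500-bp codon windows do not overlap and each flank's composition
can be programmed independently; at these lengths the sampling noise of a
window's GC is ~1.2 percentage points, so programmed classes are
recovered essentially deterministically (tests allow 3 binomial SD).
Bases are drawn independently per region — no codon structure beyond the
planted start/stop codons, no introns/UTRs, no repeat families — so
passing tests validate the measurement and decision machinery, not
performance on real genomic sequence composition. `make_genbank` writes
one minimal GenBank per contig (LOCUS, source, CDS with location and gene
qualifier, both strands, optional duplicated entries to exercise
deduplication); `make_plasmid` concatenates labelled elements with a
coordinate table. All generators are pure functions of (spec, seed).

## Problem sizes and verification

The test suite validates the hairpin and dimer scanners against
exhaustive brute-force oracles (10^4 randomized cases at lengths ≤ 20),
the identity score against naive longest-shared-substring search (10^3
30-mers vs a 30-kb genome), digestion cut positions against Biopython's
REBASE tables, and fraction recovery on 200-gene synthetic genomes at
programmed fractions {0, 0.25, 0.5, 1.0}. `scripts/acceptance.py` runs
the pipeline at a 100-kb reference with 2000 sampled candidates and the
survey at 200 genes across 3 contigs; these sizes exercise every code
path while keeping a full run in seconds, and scale linearly for larger
inputs.

## Known limitations

- Structure detection is exact-complementarity counting; no ΔG folding,
  no mismatch-tolerant dimers or seeds.
- Identity is exact-substring length, not gapped percent identity;
  E-values and bit scores are out of scope.
- Assembly ignores fragment orientation flipping, ligation efficiency,
  and Cas9/Cre enzymology beyond sequence-level hazard flagging.
- The flank survey is CDS-feature-based, not transcript-isoform-aware.
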