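"""Reference-genome similarity scoring for short queries, self-contained.

The "identity" of a 30-bp linker candidate to a genome is operationalised as
the length of the longest substring of the query that occurs exactly in the
genome on either strand, found by k-mer seeding and maximal ungapped
extension.  For queries this short, low-identity local alignments are
dominated by exact seed matches, so the exact statistic is a reproducible
proxy for an aligner's ranking and needs no external database.  Occurrence
density of restriction sites (per Mb, both strands, palindromes counted once
per locus) supports choosing enzymes that are rare in the target genome.
"""

from __future__ import annotations

import gzip
import os
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .enzymes import RestrictionEnzyme
from .seq_metrics import IUPAC_DNA, as_dna, revcomp

__all__ = [
    "KmerIndex",
    "IdentityScore",
    "build_index",
    "identity_score",
    "res_density",
    "load_contigs",
]


def load_contigs(genome) -> list[tuple[str, str]]:
    """Normalise a genome argument to ``[(name, uppercase_sequence), ...]``.

    Accepts a FASTA path (plain or gzipped), a dict of name -> sequence, a
    list of ``(name, seq)`` pairs or SeqRecords, or a raw sequence string.
    """
    if isinstance(genome, (str, Path)) and os.path.exists(str(genome)):
        path = str(genome)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    elif isinstance(genome, dict):
        contigs = [(name, str(seq).upper()) for name, seq in genome.items()]
    elif isinstance(genome, str):
        if not set(genome.upper()) <= IUPAC_DNA:
            raise FileNotFoundError(f"no such FASTA file: {genome!r}")
        contigs = [("seq", genome.upper())]
    else:
        contigs = []
        for item in genome:
            if hasattr(item, "seq"):
                contigs.append((item.id, str(item.seq).upper()))
            else:
                name, seq = item
                contigs.append((name, str(seq).upper()))
    if not contigs or all(len(s) == 0 for _, s in contigs):
        raise ValueError("empty genome")
    return contigs


class KmerIndex:
    """Exact k-mer position index over a set of contigs.

    Forward-strand k-mers are stored; queries are looked up on both of their
    strands, which covers both genome strands without doubling the index.
    K-mers containing ambiguity codes are never indexed (a conservative
    choice: an ambiguous genome base matches no query base).
    """

    def __init__(self, genome, k: int):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.contigs = load_contigs(genome)
        if k > max(len(s) for _, s in self.contigs):
            raise ValueError("k is longer than every contig")
        self.k = k
        self.genome_length = sum(len(s) for _, s in self.contigs)
        self._map: dict[str, list[tuple[int, int]]] = {}
        acgt = frozenset("ACGT")
        for ci, (_, seq) in enumerate(self.contigs):
            for p in range(len(seq) - k + 1):
                kmer = seq[p : p + k]
                if set(kmer) <= acgt:
                    self._map.setdefault(kmer, []).append((ci, p))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        """Forward-strand positions of ``kmer`` as ``(contig_idx, pos)``."""
        return self._map.get(kmer, [])

    @property
    def n_kmers(self) -> int:
        return sum(len(v) for v in self._map.values())


def build_index(genome, k: int = 12) -> KmerIndex:
    """Index every k-mer of the genome; deterministic for a given input."""
    return KmerIndex(genome, k)


@dataclass(frozen=True)
class IdentityScore:
    """Longest exact shared substring between a query and the genome.

    When no k-mer of either query strand seeds, the true longest match is
    below the seed length; that floor is reported as ``k - 1`` with
    ``n_hits_at_max == 0`` (rendered "< k").
    """

    longest_shared_substring: int
    n_hits_at_max: int

    @property
    def is_seed_floor(self) -> bool:
        return self.n_hits_at_max == 0


def identity_score(query, index: KmerIndex) -> IdentityScore:
    """Score a query against the index by seeding + maximal extension.

    Both query strands are scanned, so the score is strand-symmetric.
    Distinct maximal genomic intervals achieving the maximum are counted in
    ``n_hits_at_max`` (a long match is counted once, not once per seed).
    """
    q = as_dna(query)
    k = index.k
    if len(q) < k:
        raise ValueError(f"query shorter than k={k}")
    best = 0
    best_hits: set[tuple[int, int, int]] = set()
    for qs in (q, revcomp(q)):
        n = len(qs)
        for i in range(n - k + 1):
            for ci, p in index.lookup(qs[i : i + k]):
                contig = index.contigs[ci][1]
                left = 0
                while i - left - 1 >= 0 and p - left - 1 >= 0 and qs[i - left - 1] == contig[p - left - 1]:
                    left += 1
                right = 0
                while (
                    i + k + right < n
                    and p + k + right < len(contig)
                    and qs[i + k + right] == contig[p + k + right]
                ):
                    right += 1
                m = k + left + right
                hit = (ci, p - left, m)
                if m > best:
                    best, best_hits = m, {hit}
                elif m == best:
                    best_hits.add(hit)
    if best == 0:
        return IdentityScore(k - 1, 0)
    return IdentityScore(best, len(best_hits))


def _count_occurrences(seq: str, site: str) -> int:
    """Overlapping exact occurrences of ``site`` in ``seq``."""
    return len(re.findall(f"(?={re.escape(site)})", seq))


def res_density(enzyme: RestrictionEnzyme, genome) -> float:
    """Occurrences of a recognition site per Mb of genome, both strands.

    Palindromic sites are counted once per locus; non-palindromic sites add
    their reverse-complement occurrences.
    """
    if len(enzyme.site) < 4:
        raise ValueError("site length must be >= 4")
    contigs = load_contigs(genome)
    count = 0
    for _, seq in contigs:
        count += _count_occurrences(seq, enzyme.site)
        if not enzyme.is_palindromic:
            count += _count_occurrences(seq, revcomp(enzyme.site))
    total_mb = sum(len(s) for _, s in contigs) / 1e6
    return count / total_mb
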