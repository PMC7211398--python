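"""Primitive sequence measures and the adverse-factor filters for oligo screening.

Linker candidates (and primers generally) are rejected on six grounds that
compromise PCR and overlap-directed assembly: single-stranded hairpin
structure, self/cross dimerisation, an out-of-range salt-adjusted melting
temperature, unbalanced GC content, nucleotide repeats (homopolymer runs and
tandem dinucleotides), and a GC clamp at a terminus.  Structure detection here
is exact Watson-Crick run counting, not nearest-neighbour thermodynamics: the
screen is a sequence-level heuristic, and every threshold is configurable
through :class:`FilterThresholds`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields

from Bio.Seq import Seq

__all__ = [
    "IUPAC_DNA",
    "as_dna",
    "revcomp",
    "gc_percent",
    "salt_adjusted_tm",
    "Hairpin",
    "find_hairpins",
    "DimerRun",
    "find_dimers",
    "has_repeats",
    "has_gc_clamp",
    "FilterThresholds",
    "FilterFailure",
    "FilterReport",
    "screen_sequence",
]

#: IUPAC DNA alphabet (unambiguous bases plus ambiguity codes).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def as_dna(seq) -> str:
    """Normalise ``seq`` (str, Seq or SeqRecord) to an uppercase DNA string.

    Lowercase (soft-masked) input is accepted and uppercased.  Raises
    ``ValueError`` for empty input or characters outside the IUPAC alphabet.
    """
    if hasattr(seq, "seq"):
        seq = seq.seq
    s = str(seq).strip().upper()
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC DNA characters: {sorted(bad)}")
    return s


def revcomp(seq) -> str:
    """Reverse complement (IUPAC-aware, via Biopython)."""
    return str(Seq(as_dna(seq)).reverse_complement())


def _pairs(a: str, b: str) -> bool:
    """Strict Watson-Crick pairing; ambiguity codes never pair."""
    return _WC.get(a) == b


def gc_percent(seq) -> float:
    """GC content as (G + C) / N * 100 with N counting every base.

    Ambiguity codes (including S and N) contribute to the denominator only;
    only literal G and C count in the numerator.
    """
    s = as_dna(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def salt_adjusted_tm(seq, na_molar: float = 0.05) -> float:
    """Salt-adjusted melting temperature for long oligos (degrees C).

    Uses the closed form ``81.5 + 16.6*log10([Na+]) + 0.41*%GC - 600/L``,
    the standard regime for oligos of >= 14 nt such as 30-bp linkers.
    Strictly increasing in GC content and in log-salt.
    """
    s = as_dna(seq)
    if len(s) < 14:
        raise ValueError("salt-adjusted long-oligo formula requires length >= 14")
    if na_molar <= 0:
        raise ValueError("sodium concentration must be positive")
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * gc_percent(s) - 600.0 / len(s)


@dataclass(frozen=True)
class Hairpin:
    """A maximal self-complementary stem within one strand.

    ``stem_start_5p``/``stem_start_3p`` are 0-based starts of the paired
    substrings; the 3' stem equals the reverse complement of the 5' stem.
    """

    stem_start_5p: int
    stem_start_3p: int
    stem_len: int
    loop_len: int


def find_hairpins(seq, min_stem: int = 4, min_loop: int = 3) -> list[Hairpin]:
    """Report every maximal hairpin stem of ``>= min_stem`` bp with a loop
    of ``>= min_loop`` nt.

    A hairpin pairs position ``p`` with position ``c - p`` along an
    anti-diagonal ``c``; each maximal complementary run on a diagonal yields
    at most one reported stem, trimmed inward so the loop constraint holds.
    Maximality: the stem can be extended neither outward (flanking bases not
    complementary or out of range) nor inward (next bases not complementary,
    or the loop would drop below ``min_loop``).
    """
    s = as_dna(seq)
    if min_stem < 2:
        raise ValueError("min_stem must be >= 2")
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    L = len(s)
    out: list[Hairpin] = []
    for c in range(2 * L - 1):
        lo = max(0, c - L + 1)
        hi = (c - 1) // 2                # innermost geometric 5' position
        cap = (c - 1 - min_loop) // 2    # innermost 5' position honouring the loop
        p = lo
        while p <= hi:
            if _pairs(s[p], s[c - p]):
                q = p
                while q + 1 <= hi and _pairs(s[q + 1], s[c - q - 1]):
                    q += 1
                inner = min(q, cap)
                stem = inner - p + 1
                if stem >= min_stem:
                    j = c - inner
                    out.append(Hairpin(p, j, stem, j - inner - 1))
                p = q + 1
            p += 1
    return out


@dataclass(frozen=True)
class DimerRun:
    """A maximal antiparallel complementary run between two oligos.

    ``pos1``/``pos2`` are 0-based starts of the paired stretches in seq1 and
    seq2 respectively (both in their own 5'->3' coordinates).
    """

    pos1: int
    pos2: int
    run_len: int
    is_3prime_anchored: bool


def find_dimers(
    seq1,
    seq2,
    min_run: int = 8,
    win3: int = 5,
    min_run3: int = 7,
) -> list[DimerRun]:
    """Scan all antiparallel alignments of two oligos for complementary runs.

    Reports maximal runs of length ``>= min_run`` anywhere, plus runs of
    length ``>= min_run3`` that overlap the last ``win3`` bases of either
    oligo's 3' end (those are flagged ``is_3prime_anchored`` -- the
    extension-competent, most dangerous geometry).  Self-dimers are scanned
    by passing the same sequence twice.
    """
    s1, s2 = as_dna(seq1), as_dna(seq2)
    if min_run < 4:
        raise ValueError("min_run must be >= 4")
    L1, L2 = len(s1), len(s2)
    out: list[DimerRun] = []
    for c in range(L1 + L2 - 1):
        lo, hi = max(0, c - L2 + 1), min(L1 - 1, c)
        i = lo
        while i <= hi:
            if _pairs(s1[i], s2[c - i]):
                q = i
                while q + 1 <= hi and _pairs(s1[q + 1], s2[c - q - 1]):
                    q += 1
                run = q - i + 1
                anchored = (q >= L1 - win3 or c - i >= L2 - win3) and run >= min_run3
                if run >= min_run or anchored:
                    out.append(DimerRun(i, c - q, run, anchored))
                i = q + 1
            i += 1
    return out


def has_repeats(
    seq,
    homopolymer_max: int = 4,
    dinucleotide_repeat_max: int = 3,
) -> tuple[bool, tuple[int, int] | None]:
    """Flag homopolymer runs longer than ``homopolymer_max`` and dinucleotide
    units tandemly repeated more than ``dinucleotide_repeat_max`` times.

    Returns ``(flag, span)`` where span is the first offending half-open
    interval, or ``None``.  Units of two identical bases are homopolymers,
    not dinucleotide repeats.
    """
    s = as_dna(seq)
    if homopolymer_max < 2 or dinucleotide_repeat_max < 2:
        raise ValueError("repeat thresholds must be >= 2")
    for m in re.finditer(r"A+|C+|G+|T+", s):
        if m.end() - m.start() > homopolymer_max:
            return True, (m.start(), m.end())
    for i in range(len(s) - 1):
        a, b = s[i], s[i + 1]
        if a == b:
            continue
        n = 1
        while s[i + 2 * n : i + 2 * n + 2] == a + b:
            n += 1
        if n > dinucleotide_repeat_max:
            return True, (i, i + 2 * n)
    return False, None


def has_gc_clamp(seq, window: int = 5, max_gc: int = 4) -> bool:
    """True if either terminal ``window`` contains more than ``max_gc`` G/C.

    GC-rich termini over-stabilise mispriming and are treated as adverse.
    """
    s = as_dna(seq)
    if window > len(s):
        raise ValueError("window longer than sequence")

    def n_gc(x: str) -> int:
        return x.count("G") + x.count("C")

    return n_gc(s[:window]) > max_gc or n_gc(s[-window:]) > max_gc


@dataclass
class FilterThresholds:
    """All tunable cutoffs for the six-filter screen.

    Defaults suit 30-bp restriction-site linkers: a 40-60% GC window (the
    same bounds used to call flank GC unbalanced), a 55-68 C Tm window at
    50 mM Na+, exact-complementarity structure thresholds, and terminal
    composition limits chosen so that the mandatory palindromic terminal
    restriction sites are not self-rejecting (a 6-bp palindromic site always
    self-anneals over 6 bp and carries up to 4 G/C in its outer 5 bases).
    """

    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 55.0
    tm_max: float = 68.0
    na_molar: float = 0.05
    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    dimer_min_run: int = 8
    dimer_3prime_window: int = 5
    dimer_3prime_min_run: int = 7
    homopolymer_max: int = 4
    dinucleotide_repeat_max: int = 3
    gc_clamp_window: int = 5
    gc_clamp_max_gc: int = 4

    def __post_init__(self) -> None:
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")
        if self.na_molar <= 0:
            raise ValueError("na_molar must be positive")
        for f in fields(self):
            if f.type == "int" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class FilterFailure:
    filter_name: str
    offending_span: tuple[int, int]
    measured_value: float


@dataclass
class FilterReport:
    """Outcome of the full screen; ``passed`` iff no filter failed."""

    passed: bool
    failures: list[FilterFailure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failures):
            raise ValueError("passed must be true iff failures is empty")

    @classmethod
    def from_failures(cls, failures: list[FilterFailure]) -> "FilterReport":
        return cls(passed=not failures, failures=failures)

    def failed_filters(self) -> list[str]:
        return [f.filter_name for f in self.failures]


def screen_sequence(seq, thresholds: FilterThresholds | None = None) -> FilterReport:
    """Apply all six adverse-factor filters and report every failure.

    The report is exhaustive (all failing filters are listed, not just the
    first), so ``passed`` is exactly the conjunction of the individual
    filter outcomes.
    """
    th = thresholds or FilterThresholds()
    s = as_dna(seq)
    L = len(s)
    failures: list[FilterFailure] = []

    hairpins = find_hairpins(s, th.hairpin_min_stem, th.hairpin_min_loop)
    if hairpins:
        worst = max(hairpins, key=lambda h: h.stem_len)
        failures.append(
            FilterFailure(
                "hairpin",
                (worst.stem_start_5p, worst.stem_start_3p + worst.stem_len),
                worst.stem_len,
            )
        )

    dimers = find_dimers(
        s, s, th.dimer_min_run, th.dimer_3prime_window, th.dimer_3prime_min_run
    )
    if dimers:
        worst_d = max(dimers, key=lambda d: d.run_len)
        failures.append(
            FilterFailure(
                "self_dimer", (worst_d.pos1, worst_d.pos1 + worst_d.run_len), worst_d.run_len
            )
        )

    tm = salt_adjusted_tm(s, th.na_molar)
    if not th.tm_min <= tm <= th.tm_max:
        failures.append(FilterFailure("tm", (0, L), round(tm, 2)))

    gc = gc_percent(s)
    if not th.gc_min <= gc <= th.gc_max:
        failures.append(FilterFailure("gc", (0, L), round(gc, 2)))

    rep_flag, rep_span = has_repeats(s, th.homopolymer_max, th.dinucleotide_repeat_max)
    if rep_flag:
        assert rep_span is not None
        failures.append(FilterFailure("repeats", rep_span, rep_span[1] - rep_span[0]))

    if has_gc_clamp(s, th.gc_clamp_window, th.gc_clamp_max_gc):
        w = th.gc_clamp_window
        head = s[:w].count("G") + s[:w].count("C")
        tail = s[-w:].count("G") + s[-w:].count("C")
        span = (0, w) if head > th.gc_clamp_max_gc else (L - w, L)
        failures.append(FilterFailure("gc_clamp", span, max(head, tail)))

    return FilterReport.from_failures(failures)
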