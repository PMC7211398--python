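"""Genome-wide GC content of CDS start/stop-codon flanking regions.

Knock-in insertion points sit next to a gene's start or stop codon, so the
homology arms of a donor construct are drawn from the +-750 bp around those
codons.  This module parses annotated GenBank chromosomes, keeps one CDS
entry per unique (chrom, start, end, strand), measures the GC content of a
window centred on each codon's first base (750 bp each side, 1500 bp total,
strand-aware), and classifies a gene "unbalanced" when either window's GC is
strictly above 60% or strictly below 40% -- the regime where one-step
overlap assembly tends to fail.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

from .seq_metrics import gc_percent, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "CdsRecord",
    "CdsFlankRecord",
    "read_genbank",
    "parse_cds",
    "dedup_unique_positions",
    "extract_flanks",
    "classify_unbalanced",
    "summarize_genome",
]


@dataclass(frozen=True)
class CdsRecord:
    """One CDS feature in 0-based half-open genome coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


@dataclass
class CdsFlankRecord:
    cds: CdsRecord
    start_flank_gc: float
    stop_flank_gc: float
    unbalanced: bool
    truncated: bool


def _open_text(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_genbank(path) -> tuple[dict[str, str], list[CdsRecord]]:
    """Parse a GenBank file into contig sequences plus CDS records.

    Join-locations are resolved to the feature's overall start/end.
    Malformed features are skipped with a logged warning; a record without
    sequence raises ``ValueError``.
    """
    contigs: dict[str, str] = {}
    records: list[CdsRecord] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "genbank"):
            try:
                contigs[rec.id] = str(rec.seq).upper()
            except UndefinedSequenceError:
                raise ValueError(f"GenBank record {rec.id} carries no sequence") from None
            if not contigs[rec.id]:
                raise ValueError(f"GenBank record {rec.id} carries no sequence")
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                try:
                    loc = feat.location
                    strand = "-" if loc.strand == -1 else "+"
                    gene = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", [""]))[0]
                    records.append(
                        CdsRecord(rec.id, int(loc.start), int(loc.end), strand, gene)
                    )
                except (AttributeError, TypeError, ValueError) as exc:
                    logger.warning("skipping malformed CDS in %s: %s", rec.id, exc)
    return contigs, records


def parse_cds(path) -> list[CdsRecord]:
    """Extract the CDS features of a GenBank file as :class:`CdsRecord` s."""
    return read_genbank(path)[1]


def dedup_unique_positions(records: Iterable[CdsRecord]) -> list[CdsRecord]:
    """Keep one CDS entry per unique (chrom, start, end, strand).

    Genes commonly carry several CDS entries with identical start/stop
    positions (isoform bookkeeping); the first occurrence wins and the
    number removed is logged.  Idempotent.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[CdsRecord] = []
    dropped = 0
    for r in records:
        key = (r.chrom, r.start, r.end, r.strand)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(r)
    if dropped:
        logger.info("dedup_unique_positions removed %d duplicate CDS entries", dropped)
    return out


def _window(seq: str, lo: int, hi: int) -> tuple[str, bool]:
    clo, chi = max(lo, 0), min(hi, len(seq))
    return seq[clo:chi], (clo != lo or chi != hi)


def extract_flanks(cds: CdsRecord, genome, width: int = 750) -> dict:
    """Windows of ``width`` bp either side of the start and stop codons.

    Each window spans the codon's first base minus ``width`` through plus
    ``width`` (total ``2*width`` bp), in transcript orientation: on the
    minus strand the start codon sits at the CDS end coordinate and the
    window is reverse-complemented.  Windows clipped at a contig edge are
    returned shorter with ``truncated=True``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    seq = genome[cds.chrom] if isinstance(genome, dict) else str(genome).upper()
    if cds.end > len(seq):
        raise ValueError(f"CDS {cds} outside contig of length {len(seq)}")
    if cds.strand == "+":
        start_lo = cds.start - width
        stop_lo = cds.end - 3 - width
        start_seq, t1 = _window(seq, start_lo, start_lo + 2 * width)
        stop_seq, t2 = _window(seq, stop_lo, stop_lo + 2 * width)
    else:
        start_lo = cds.end - width
        stop_lo = cds.start + 3 - width
        start_seq, t1 = _window(seq, start_lo, start_lo + 2 * width)
        stop_seq, t2 = _window(seq, stop_lo, stop_lo + 2 * width)
        start_seq, stop_seq = revcomp(start_seq), revcomp(stop_seq)
    return {
        "start_flank_seq": start_seq,
        "stop_flank_seq": stop_seq,
        "truncated": t1 or t2,
    }


def classify_unbalanced(
    start_gc: float,
    stop_gc: float,
    hi: float = 60.0,
    lo: float = 40.0,
    inclusive: bool = False,
) -> bool:
    """True iff either flank's GC is above ``hi`` or below ``lo``.

    Strict inequalities by default (exactly 60% or 40% is balanced);
    ``inclusive=True`` treats the bounds themselves as unbalanced.
    """
    for gc in (start_gc, stop_gc):
        if not 0.0 <= gc <= 100.0:
            raise ValueError("GC values must be in [0, 100]")
        if inclusive:
            if gc >= hi or gc <= lo:
                return True
        elif gc > hi or gc < lo:
            return True
    return False


def summarize_genome(
    genbank_files: Iterable,
    width: int = 750,
    hi: float = 60.0,
    lo: float = 40.0,
    inclusive: bool = False,
    exclude_contigs: set[str] | None = None,
    drop_truncated: bool = False,
) -> dict:
    """Run parse -> dedup -> flank GC -> classify over per-chromosome files.

    Each file is processed independently (mirroring a genome split into one
    GenBank per chromosome) and aggregated.  ``exclude_contigs`` drops
    records on named contigs (e.g. alternate assemblies); truncated edge
    windows are kept and flagged by default, or dropped entirely with
    ``drop_truncated=True``.

    Returns n_cds / n_unique / n_unbalanced / fraction_unbalanced, the
    per-record table (pandas DataFrame) and a 1%-bin histogram over all
    flank GC values.
    """
    files = [genbank_files] if isinstance(genbank_files, (str, Path)) else list(genbank_files)
    if not files:
        raise ValueError("at least one GenBank file is required")
    exclude = exclude_contigs or set()
    n_cds = 0
    rows: list[dict] = []
    for path in files:
        contigs, records = read_genbank(path)
        records = [r for r in records if r.chrom not in exclude]
        n_cds += len(records)
        for r in dedup_unique_positions(records):
            fl = extract_flanks(r, contigs, width)
            if drop_truncated and fl["truncated"]:
                continue
            sgc = gc_percent(fl["start_flank_seq"])
            pgc = gc_percent(fl["stop_flank_seq"])
            rows.append(
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "gene_id": r.gene_id,
                    "start_gc": sgc,
                    "stop_gc": pgc,
                    "unbalanced": classify_unbalanced(sgc, pgc, hi, lo, inclusive),
                    "truncated": fl["truncated"],
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "gene_id",
            "start_gc", "stop_gc", "unbalanced", "truncated",
        ],
    )
    n_unique = len(table)
    n_unbalanced = int(table["unbalanced"].sum()) if n_unique else 0
    gc_values = (
        np.concatenate([table["start_gc"].to_numpy(), table["stop_gc"].to_numpy()])
        if n_unique
        else np.array([])
    )
    counts, edges = np.histogram(gc_values, bins=np.arange(0.0, 101.0, 1.0))
    return {
        "n_cds": n_cds,
        "n_unique": n_unique,
        "n_unbalanced": n_unbalanced,
        "fraction_unbalanced": (n_unbalanced / n_unique) if n_unique else 0.0,
        "table": table,
        "histogram": {"counts": counts, "bin_edges": edges},
    }
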