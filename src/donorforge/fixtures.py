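"""Seeded synthetic genomes, GenBank annotation and plasmids for testing.

Every generator is a pure function of its spec (including the seed), and the
truth tables it emits are sufficient to compute the downstream expected
values -- which gene was given skewed flanks, where a motif was planted --
without re-deriving anything from sequence.  Bases are drawn independently
with a per-region GC parameter; there is no higher-order composition
structure, repeat families or realistic gene anatomy (no introns/UTRs), so
passing tests demonstrate correctness of the measurement and classification
machinery, not performance on real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = ["FixtureSpec", "SyntheticGenome", "make_genome", "make_genbank", "make_plasmid"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic annotated genome.

    Defaults mirror the measured conditions the flank survey targets: a 45%
    unbalanced-gene fraction with skewed flanks near 70% GC (the regime of
    hard homology arms) against a 50% balanced background, +-750 bp flank
    windows, and a CDS long enough (1602 bp) that the start- and
    stop-centred windows do not overlap, so each flank's composition can be
    programmed independently.
    """

    seed: int = 0
    n_contigs: int = 1
    contig_length: int | None = None
    n_genes: int = 200
    fraction_unbalanced_flanks: float = 0.45
    skew_gc: float = 70.0
    balanced_gc: float = 50.0
    flank_width: int = 750
    cds_length: int = 1602
    intergenic: int = 300
    skew_which: str = "both"  # "both" | "start" | "stop"
    duplicate_cds: int = 0
    plant_sequences: list = field(default_factory=list)  # [(seq, count), ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_unbalanced_flanks <= 1.0:
            raise ValueError("fraction_unbalanced_flanks must be in [0, 1]")
        for name in ("n_contigs", "n_genes", "flank_width", "cds_length", "intergenic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cds_length % 3:
            raise ValueError("cds_length must be a multiple of 3")
        if self.skew_which not in {"both", "start", "stop"}:
            raise ValueError("skew_which must be 'both', 'start' or 'stop'")


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    genes: pd.DataFrame     # contig, start, end, strand, gene_id, unbalanced, start_skewed, stop_skewed
    planted: pd.DataFrame   # seq, contig, start, end
    spec: FixtureSpec

    def write_fasta(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        return path


def _draw(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p_gc = gc / 100.0
    return rng.choice(
        np.array(list("ACGT")), size=n, p=[(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    )


def make_genome(spec: FixtureSpec) -> SyntheticGenome:
    """Build contigs of spaced genes with programmed flank GC classes.

    Each gene block is upstream-flank + CDS + downstream-flank; the regions
    covered by the start-codon and stop-codon windows are drawn at the
    gene's programmed GC (skewed or balanced), strand-aware.  Exactly
    ``round(fraction * n_genes)`` genes are marked unbalanced in the truth
    table.  Planted sequences are appended on dedicated padding of the
    first contig with their coordinates recorded.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    w, cl = spec.flank_width, spec.cds_length
    n_unbal = round(spec.fraction_unbalanced_flanks * n)
    flags = np.zeros(n, dtype=bool)
    flags[:n_unbal] = True
    rng.shuffle(flags)
    strands = rng.choice(np.array(["+", "-"]), size=n)

    contig_parts: dict[int, list[str]] = {i: [] for i in range(spec.n_contigs)}
    offsets = {i: 0 for i in range(spec.n_contigs)}
    gene_rows = []

    for g in range(n):
        ci = g % spec.n_contigs
        unbal = bool(flags[g])
        strand = str(strands[g])
        start_skew = unbal and spec.skew_which in {"both", "start"}
        stop_skew = unbal and spec.skew_which in {"both", "stop"}
        # genome-forward regions: seg1 = upstream + first `w` of CDS,
        # seg2 = CDS middle, seg3 = last (w+3) of CDS + downstream.
        left_class = start_skew if strand == "+" else stop_skew
        right_class = stop_skew if strand == "+" else start_skew
        gc_left = spec.skew_gc if left_class else spec.balanced_gc
        gc_right = spec.skew_gc if right_class else spec.balanced_gc
        seg1 = _draw(rng, w + w, gc_left)
        seg2 = _draw(rng, max(cl - w - (w + 3), 0), spec.balanced_gc)
        seg3 = _draw(rng, (w + 3) + w, gc_right)
        block = np.concatenate([seg1, seg2, seg3])
        cds_start_in_block = w
        cds_end_in_block = w + cl
        if strand == "+":
            block[cds_start_in_block : cds_start_in_block + 3] = list("ATG")
            block[cds_end_in_block - 3 : cds_end_in_block] = list("TAA")
        else:
            block[cds_end_in_block - 3 : cds_end_in_block] = list("CAT")
            block[cds_start_in_block : cds_start_in_block + 3] = list("TTA")
        pad = _draw(rng, spec.intergenic, spec.balanced_gc)
        base = offsets[ci]
        contig_parts[ci] += ["".join(pad), "".join(block)]
        cds_start = base + spec.intergenic + cds_start_in_block
        gene_rows.append(
            {
                "contig": f"chrS{ci + 1}",
                "start": cds_start,
                "end": cds_start + cl,
                "strand": strand,
                "gene_id": f"gene{g:04d}",
                "unbalanced": unbal,
                "start_skewed": start_skew,
                "stop_skewed": stop_skew,
            }
        )
        offsets[ci] += spec.intergenic + len(block)

    planted_rows = []
    tail_parts = []
    tail_off = offsets[0]
    for seq, count in spec.plant_sequences:
        seq = str(seq).upper()
        for _ in range(int(count)):
            pad = "".join(_draw(rng, 25, spec.balanced_gc))
            tail_parts.append(pad)
            tail_off += len(pad)
            tail_parts.append(seq)
            planted_rows.append(
                {"seq": seq, "contig": "chrS1", "start": tail_off, "end": tail_off + len(seq)}
            )
            tail_off += len(seq)
    contig_parts[0] += tail_parts
    offsets[0] = tail_off

    contigs: dict[str, str] = {}
    for ci in range(spec.n_contigs):
        name = f"chrS{ci + 1}"
        seq = "".join(contig_parts[ci])
        if spec.contig_length is not None:
            if len(seq) > spec.contig_length:
                raise ValueError(
                    f"contig {name}: content ({len(seq)} bp) exceeds contig_length "
                    f"{spec.contig_length}; planted/gene content does not fit"
                )
            seq += "".join(_draw(rng, spec.contig_length - len(seq), spec.balanced_gc))
        contigs[name] = seq

    return SyntheticGenome(
        contigs=contigs,
        genes=pd.DataFrame(gene_rows),
        planted=pd.DataFrame(planted_rows, columns=["seq", "contig", "start", "end"]),
        spec=spec,
    )


def make_genbank(genome: SyntheticGenome, out_dir) -> list[Path]:
    """Write one GenBank file per contig with CDS features on both strands.

    The first ``spec.duplicate_cds`` genes re-emit their CDS feature with an
    identical location, exercising unique-position deduplication downstream.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dup_ids = set(genome.genes["gene_id"].head(genome.spec.duplicate_cds))
    paths = []
    for name, seq in genome.contigs.items():
        rec = SeqRecord(Seq(seq), id=name, name=name[:16], description="synthetic contig")
        rec.annotations["molecule_type"] = "DNA"
        rec.features.append(SeqFeature(FeatureLocation(0, len(seq)), type="source"))
        sub = genome.genes[genome.genes["contig"] == name]
        for _, row in sub.iterrows():
            loc = FeatureLocation(int(row["start"]), int(row["end"]),
                                  strand=1 if row["strand"] == "+" else -1)
            feat = SeqFeature(loc, type="CDS", qualifiers={"gene": [row["gene_id"]]})
            rec.features.append(feat)
            if row["gene_id"] in dup_ids:
                rec.features.append(
                    SeqFeature(loc, type="CDS", qualifiers={"gene": [row["gene_id"]]})
                )
        path = out_dir / f"{name}.gb"
        SeqIO.write(rec, str(path), "genbank")
        paths.append(path)
    return paths


def make_plasmid(elements: list, circular: bool = True) -> tuple[str, pd.DataFrame]:
    """Concatenate labelled elements into a plasmid plus a coordinate table.

    ``elements`` is an ordered list of ``(label, sequence)``; the returned
    table records each element's half-open interval on the top strand.
    """
    if not elements:
        raise ValueError("element list must be non-empty")
    rows = []
    parts = []
    pos = 0
    for label, seq in elements:
        seq = str(seq).upper()
        rows.append({"label": label, "start": pos, "end": pos + len(seq)})
        parts.append(seq)
        pos += len(seq)
    table = pd.DataFrame(rows)
    table.attrs["circular"] = circular
    return "".join(parts), table
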