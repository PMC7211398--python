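"""Design of 30-bp restriction-site linker pairs for overlap-directed assembly.

A linker pair (a, b) carries eight restriction enzyme sites: AgeI anchored at
the 5' terminus of linker a, XhoI at the 3' terminus of linker b, and three
further sites on each linker.  Spacer bases between the sites are the free
positions that generate candidate diversity; candidates are enumerated
(exhaustively, or by seeded sampling when the space is large), screened with
the six adverse-factor filters plus a cross-dimer check, and survivors are
ranked by how little exact identity they share with a reference genome so
the linkers neither misprime nor template spurious assembly junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .enzymes import DEFAULT_ENZYMES, RestrictionEnzyme
from .genome_screen import IdentityScore, KmerIndex, identity_score
from .seq_metrics import (
    FilterFailure,
    FilterReport,
    FilterThresholds,
    as_dna,
    find_dimers,
    revcomp,
    salt_adjusted_tm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LinkerLayout",
    "LinkerPair",
    "default_layout",
    "enumerate_candidates",
    "screen_pair",
    "rank_pairs",
    "design_primers",
    "run_pipeline",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class LinkerLayout:
    """Slot geometry of a linker pair.

    ``gaps_a[i]`` is the spacer length after the i-th site of linker a (the
    last entry is a trailing spacer, 0 to anchor the last site at the 3'
    end); ``gaps_b[i]`` is the spacer length *before* the i-th site of
    linker b (the first entry is a leading spacer).  Site lengths plus gaps
    must equal ``linker_len`` for each linker.
    """

    enzymes_a: tuple[RestrictionEnzyme, ...]
    enzymes_b: tuple[RestrictionEnzyme, ...]
    gaps_a: tuple[int, ...]
    gaps_b: tuple[int, ...]
    linker_len: int = 30

    def __post_init__(self) -> None:
        if len(self.gaps_a) != len(self.enzymes_a):
            raise ValueError("gaps_a must have one entry per site of linker a")
        if len(self.gaps_b) != len(self.enzymes_b):
            raise ValueError("gaps_b must have one entry per site of linker b")
        if any(g < 0 for g in self.gaps_a + self.gaps_b):
            raise ValueError("spacer lengths must be >= 0")
        for enzymes, gaps, name in (
            (self.enzymes_a, self.gaps_a, "a"),
            (self.enzymes_b, self.gaps_b, "b"),
        ):
            total = sum(len(e.site) for e in enzymes) + sum(gaps)
            if total != self.linker_len:
                raise ValueError(
                    f"linker {name}: sites + spacers = {total}, expected {self.linker_len}"
                )

    @property
    def n_spacers_a(self) -> int:
        return sum(self.gaps_a)

    @property
    def n_spacers_b(self) -> int:
        return sum(self.gaps_b)

    @property
    def spacer_budget(self) -> int:
        return self.n_spacers_a + self.n_spacers_b

    @property
    def enzymes(self) -> tuple[RestrictionEnzyme, ...]:
        return self.enzymes_a + self.enzymes_b

    def build_linker_a(self, spacers: str) -> str:
        return self._build(self.enzymes_a, self.gaps_a, spacers, leading=False)

    def build_linker_b(self, spacers: str) -> str:
        return self._build(self.enzymes_b, self.gaps_b, spacers, leading=True)

    @staticmethod
    def _build(enzymes, gaps, spacers: str, leading: bool) -> str:
        parts: list[str] = []
        pos = 0
        for enz, gap in zip(enzymes, gaps):
            chunk = spacers[pos : pos + gap]
            pos += gap
            parts += [chunk, enz.site] if leading else [enz.site, chunk]
        if pos != len(spacers):
            raise ValueError("wrong number of spacer bases for layout")
        return "".join(parts)


def default_layout() -> LinkerLayout:
    """The default 30-bp pair: AgeI/NheI/SalI/BamHI on linker a (AgeI at the
    5' terminus), SpeI/MluI/EcoRV/XhoI on linker b (XhoI at the 3'
    terminus); the six spare bases of each linker fill the three inter-site
    gaps as 2-bp spacers."""
    e = DEFAULT_ENZYMES
    return LinkerLayout(
        enzymes_a=(e["AgeI"], e["NheI"], e["SalI"], e["BamHI"]),
        enzymes_b=(e["SpeI"], e["MluI"], e["EcoRV"], e["XhoI"]),
        gaps_a=(2, 2, 2, 0),
        gaps_b=(0, 2, 2, 2),
    )


@dataclass
class LinkerPair:
    linker_a: str
    linker_b: str
    layout: LinkerLayout
    report_a: FilterReport | None = None
    report_b: FilterReport | None = None
    report_cross: FilterReport | None = None
    identity: IdentityScore | None = None
    rank: int | None = None

    @property
    def screened(self) -> bool:
        return None not in (self.report_a, self.report_b, self.report_cross)

    @property
    def passed(self) -> bool:
        return self.screened and all(
            r.passed for r in (self.report_a, self.report_b, self.report_cross)  # type: ignore[union-attr]
        )


def _count_overlapping(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


def _sites_unique(layout: LinkerLayout, linker_a: str, linker_b: str) -> bool:
    """Each site exactly once in its designated linker, absent from the other.

    Counts include reverse-complement occurrences for non-palindromic sites,
    so spacer fills cannot smuggle in a cryptic cut site on either strand.
    """
    for enzymes, own, other in (
        (layout.enzymes_a, linker_a, linker_b),
        (layout.enzymes_b, linker_b, linker_a),
    ):
        expected = {}
        for e in enzymes:
            expected[e.site] = expected.get(e.site, 0) + 1
        for site, n_expected in expected.items():
            variants = {site, revcomp(site)}
            n_own = sum(_count_overlapping(own, v) for v in variants)
            n_other = sum(_count_overlapping(other, v) for v in variants)
            if n_own != n_expected or n_other != 0:
                return False
    return True


def enumerate_candidates(
    layout: LinkerLayout,
    mode: str = "exhaustive",
    seed: int | None = None,
    max_candidates: int = 100_000,
    stats: dict | None = None,
) -> Iterator[LinkerPair]:
    """Yield candidate pairs over all spacer assignments.

    Exhaustive mode walks every assignment of {A,C,G,T} to the spacer
    positions exactly once; if the space exceeds ``max_candidates`` it
    automatically switches to seeded uniform sampling without replacement
    (logged).  Assignments that duplicate a layout site anywhere in the pair
    are discarded and counted in ``stats['discarded']``.
    """
    if mode not in {"exhaustive", "sampled"}:
        raise ValueError("mode must be 'exhaustive' or 'sampled'")
    n = layout.spacer_budget
    total = 4**n
    if mode == "exhaustive" and total > max_candidates:
        logger.warning(
            "4^%d = %d assignments exceed max_candidates=%d; switching to seeded sampling",
            n, total, max_candidates,
        )
        mode = "sampled"

    if mode == "exhaustive":
        indices: Iterator[int] = iter(range(total))
    else:
        rng = np.random.default_rng(seed)
        size = min(max_candidates, total)
        if total <= 4 * max_candidates:
            indices = iter(int(i) for i in rng.choice(total, size=size, replace=False))
        else:
            seen: set[int] = set()
            def _draw() -> Iterator[int]:
                while len(seen) < size:
                    i = int(rng.integers(total))
                    if i not in seen:
                        seen.add(i)
                        yield i
            indices = _draw()

    if stats is not None:
        stats.update({"generated": 0, "discarded": 0, "emitted": 0})
    na = layout.n_spacers_a
    for idx in indices:
        bases = []
        x = idx
        for _ in range(n):
            bases.append(_BASES[x & 3])
            x >>= 2
        spacers = "".join(bases)
        if stats is not None:
            stats["generated"] += 1
        linker_a = layout.build_linker_a(spacers[:na])
        linker_b = layout.build_linker_b(spacers[na:])
        if not _sites_unique(layout, linker_a, linker_b):
            if stats is not None:
                stats["discarded"] += 1
            continue
        if stats is not None:
            stats["emitted"] += 1
        yield LinkerPair(linker_a, linker_b, layout)


def screen_pair(pair: LinkerPair, thresholds: FilterThresholds | None = None) -> LinkerPair:
    """Screen both linkers individually plus their cross-dimer potential."""
    from .seq_metrics import screen_sequence

    th = thresholds or FilterThresholds()
    pair.report_a = screen_sequence(pair.linker_a, th)
    pair.report_b = screen_sequence(pair.linker_b, th)
    cross = find_dimers(
        pair.linker_a,
        pair.linker_b,
        th.dimer_min_run,
        th.dimer_3prime_window,
        th.dimer_3prime_min_run,
    )
    failures = []
    if cross:
        worst = max(cross, key=lambda d: d.run_len)
        failures.append(
            FilterFailure("cross_dimer", (worst.pos1, worst.pos1 + worst.run_len), worst.run_len)
        )
    pair.report_cross = FilterReport.from_failures(failures)
    return pair


def _pair_identity(pair: LinkerPair, index: KmerIndex) -> IdentityScore:
    sa = identity_score(pair.linker_a, index)
    sb = identity_score(pair.linker_b, index)
    worse = max((sa, sb), key=lambda s: (s.longest_shared_substring, s.n_hits_at_max))
    return worse


def rank_pairs(
    pairs: list[LinkerPair],
    index: KmerIndex,
    na_molar: float = 0.05,
) -> list[LinkerPair]:
    """Order screened, passing pairs by ascending genome identity.

    The pair score is the worse (longer) of the two linkers' longest shared
    substrings.  Ties break on |Tm_a - Tm_b| (a balanced pair amplifies both
    arms under one cycling program) and then lexicographically, so the
    ranking is a pure function of the input set.
    """
    for p in pairs:
        if not p.screened:
            raise ValueError("rank_pairs requires screened pairs")
        if not p.passed:
            raise ValueError("rank_pairs requires pairs that passed screening")
        if p.identity is None:
            p.identity = _pair_identity(p, index)

    def key(p: LinkerPair):
        assert p.identity is not None
        dtm = abs(salt_adjusted_tm(p.linker_a, na_molar) - salt_adjusted_tm(p.linker_b, na_molar))
        return (p.identity.longest_shared_substring, dtm, p.linker_a, p.linker_b)

    ordered = sorted(pairs, key=key)
    for i, p in enumerate(ordered, start=1):
        p.rank = i
    return ordered


def design_primers(arm_annealing_seq, linker, orientation: str) -> str:
    """Build a 60-bp arm-amplification primer: 30-bp linker tail + 30-bp
    annealing segment.

    The linker forms the 5' tail (reverse-complemented for the 3p primer so
    the tail reads sense on the final construct's top strand); the 3'
    half anneals to the target gene.
    """
    arm = as_dna(arm_annealing_seq)
    lnk = as_dna(linker)
    if len(arm) != 30:
        raise ValueError(f"annealing segment must be exactly 30 bp, got {len(arm)}")
    if len(lnk) != 30:
        raise ValueError(f"linker must be exactly 30 bp, got {len(lnk)}")
    if orientation == "5p":
        tail = lnk
    elif orientation == "3p":
        tail = revcomp(lnk)
    else:
        raise ValueError("orientation must be '5p' or '3p'")
    return tail + arm


@dataclass
class PipelineResult:
    pairs: list[LinkerPair]
    stats: dict = field(default_factory=dict)


def run_pipeline(
    index: KmerIndex,
    layout: LinkerLayout | None = None,
    thresholds: FilterThresholds | None = None,
    mode: str = "exhaustive",
    seed: int | None = None,
    max_candidates: int = 100_000,
    top: int | None = None,
) -> PipelineResult:
    """Enumerate -> screen -> rank; a pure function of its arguments.

    Returns the ranked passing pairs (optionally truncated to ``top``) plus
    enumeration/screening counters.
    """
    layout = layout or default_layout()
    thresholds = thresholds or FilterThresholds()
    stats: dict = {}
    survivors = [
        p
        for p in (
            screen_pair(c, thresholds)
            for c in enumerate_candidates(layout, mode, seed, max_candidates, stats)
        )
        if p.passed
    ]
    stats["screened_out"] = stats.get("emitted", 0) - len(survivors)
    stats["passed"] = len(survivors)
    stats["thresholds"] = thresholds.to_dict()
    logger.info("linker pipeline: %s", {k: v for k, v in stats.items() if k != "thresholds"})
    ranked = rank_pairs(survivors, index)
    if top is not None:
        ranked = ranked[:top]
    return PipelineResult(pairs=ranked, stats=stats)
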