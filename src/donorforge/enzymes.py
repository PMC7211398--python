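"""Restriction enzymes: recognition sites and cut geometry.

Cut offsets follow the REBASE convention expressed relative to the start of
the recognition site on the top strand: ``cut_top`` is the number of bases
before the top-strand cut and ``cut_bottom`` the same for the bottom strand
(so AgeI, A^CCGGT, has ``cut_top=1`` / ``cut_bottom=5`` and leaves a CCGG
5' overhang; blunt EcoRV has ``cut_top == cut_bottom == 3``).

The bundled table holds the default eight-enzyme set used for linker layout:
AgeI and XhoI as the mandatory terminal anchors plus six common palindromic
6-bp cutters with low occurrence density in mammalian genomes (checkable per
genome with :func:`donorforge.genome_screen.res_density`).  The set is fully
user-editable via a plain tab-delimited file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .seq_metrics import as_dna, revcomp

__all__ = [
    "RestrictionEnzyme",
    "DEFAULT_ENZYMES",
    "get_enzyme",
    "load_enzyme_table",
    "write_enzyme_table",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", as_dna(self.site))
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: recognition site must be >= 4 bp")
        for off in (self.cut_top, self.cut_bottom):
            if not 0 <= off <= len(self.site):
                raise ValueError(f"{self.name}: cut offset {off} outside the site")

    @property
    def is_palindromic(self) -> bool:
        return self.site == revcomp(self.site)

    @property
    def is_blunt(self) -> bool:
        return self.cut_top == self.cut_bottom

    @property
    def overhang_len(self) -> int:
        """Positive for 5' overhangs, negative for 3' overhangs, 0 if blunt."""
        return self.cut_bottom - self.cut_top


_DEFAULTS = [
    ("AgeI", "ACCGGT", 1, 5),
    ("XhoI", "CTCGAG", 1, 5),
    ("NheI", "GCTAGC", 1, 5),
    ("SalI", "GTCGAC", 1, 5),
    ("BamHI", "GGATCC", 1, 5),
    ("SpeI", "ACTAGT", 1, 5),
    ("MluI", "ACGCGT", 1, 5),
    ("EcoRV", "GATATC", 3, 3),
]

DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {
    name: RestrictionEnzyme(name, site, t, b) for name, site, t, b in _DEFAULTS
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return DEFAULT_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; supply a custom table via load_enzyme_table"
        ) from None


def load_enzyme_table(path) -> dict[str, RestrictionEnzyme]:
    """Read a tab-delimited enzyme table: name, site, cut_top, cut_bottom."""
    out: dict[str, RestrictionEnzyme] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site, top, bottom = line.split("\t")
        out[name] = RestrictionEnzyme(name, site, int(top), int(bottom))
    if not out:
        raise ValueError(f"no enzymes found in {path}")
    return out


def write_enzyme_table(enzymes: dict[str, RestrictionEnzyme], path) -> None:
    lines = ["#name\tsite\tcut_top\tcut_bottom"]
    lines += [f"{e.name}\t{e.site}\t{e.cut_top}\t{e.cut_bottom}" for e in enzymes.values()]
    Path(path).write_text("\n".join(lines) + "\n")
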