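"""In silico donor-construct assembly: digestion, Gibson joining, hazards.

A donor template is assembled from a vector backbone, an inserted fragment
(IF), and 5'/3' homology arms.  Digestion is modelled exactly from each
enzyme's cut geometry; Gibson assembly is modelled as exact suffix-prefix
overlap matching between fragment top strands (the chew-back chemistry is
abstracted away: the product sequence and the ambiguity structure are
determined by overlap identity).  Complementary sticky ends left by a digest
also join, which covers the hierarchical digestion-plus-assembly rounds of
the two-step protocol, including re-circularising a singly cut plasmid.

Repeated terminal motifs -- canonically the 34-bp LoxP sites flanking a
removable selectable marker -- create ambiguous junctions; those are
detected both by a quick terminal scan (:func:`detect_hazards`) and by full
ordering enumeration inside :func:`gibson_assemble`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import permutations

from .enzymes import RestrictionEnzyme
from .seq_metrics import as_dna, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "LOXP",
    "End",
    "BLUNT",
    "Fragment",
    "AssemblyError",
    "AssemblyProduct",
    "HazardReport",
    "AssemblyStep",
    "AssemblyPlan",
    "digest",
    "gibson_assemble",
    "detect_hazards",
    "plan_assembly",
    "make_sgrna_site",
    "insert_flanking_sites",
    "verify_construct",
    "canonical_rotation",
    "circular_equal",
]

#: Cre recombinase recognition site; tandem copies are the canonical
#: ambiguous-overlap hazard in selectable-marker donor constructs.
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"


@dataclass(frozen=True)
class End:
    """A fragment terminus: blunt, or a 5'/3' overhang.

    ``seq`` stores the overhang in top-strand coordinates, so two ends are
    ligatable exactly when their kinds and sequences are equal.
    """

    kind: str  # "blunt" | "5p" | "3p"
    seq: str = ""

    def ligatable(self, other: "End") -> bool:
        return self.kind != "blunt" and self.kind == other.kind and self.seq == other.seq


BLUNT = End("blunt")


@dataclass
class Fragment:
    """A linear double-stranded fragment, top strand 5'->3'."""

    seq: str
    end5: End = BLUNT
    end3: End = BLUNT
    label: str = ""

    def __post_init__(self) -> None:
        self.seq = as_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


class AssemblyError(ValueError):
    """Raised when fragments cannot form a unique circular product."""

    def __init__(self, message: str, partial_chain: list[str] | None = None):
        super().__init__(message)
        self.partial_chain = partial_chain or []


@dataclass
class AssemblyProduct:
    seq: str  # circular top strand, in assembly order
    junctions: list[dict] = field(default_factory=list)

    @property
    def canonical(self) -> str:
        return canonical_rotation(self.seq)


@dataclass
class HazardReport:
    """Ambiguous-overlap diagnosis; empty iff every pairing is unique."""

    ambiguous_junctions: list[dict] = field(default_factory=list)
    alternative_products: int | None = None

    @property
    def is_empty(self) -> bool:
        return not self.ambiguous_junctions


def canonical_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm, O(n))."""
    n = len(s)
    if n == 0:
        return s
    s2 = s + s
    f = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k : k + n]


def circular_equal(a: str, b: str) -> bool:
    return len(a) == len(b) and canonical_rotation(as_dna(a)) == canonical_rotation(as_dna(b))


def _site_positions(seq: str, site: str, circular: bool) -> list[int]:
    space = seq + seq[: len(site) - 1] if circular else seq
    return [m.start() for m in re.finditer(f"(?={re.escape(site)})", space) if m.start() < len(seq)]


def digest(construct, enzyme: RestrictionEnzyme, circular: bool = True) -> list[Fragment]:
    """Cut at every site occurrence; returns fragments in genome order.

    Both site orientations are cut for non-palindromic enzymes.  A circular
    construct with one site yields one linear fragment carrying the
    enzyme's overhangs on both ends; an uncut circular input is an error.
    Top-strand fragment lengths always sum to the input length.
    """
    s = as_dna(construct)
    L = len(s)
    slen = len(enzyme.site)
    cuts: set[tuple[int, int]] = set()  # (top_cut, bottom_cut)
    for p in _site_positions(s, enzyme.site, circular):
        cuts.add((p + enzyme.cut_top, p + enzyme.cut_bottom))
    if not enzyme.is_palindromic:
        for p in _site_positions(s, revcomp(enzyme.site), circular):
            cuts.add((p + slen - enzyme.cut_bottom, p + slen - enzyme.cut_top))

    if not cuts:
        if circular:
            raise AssemblyError(f"site not found: {enzyme.name} does not cut this construct")
        return [Fragment(s, BLUNT, BLUNT, label="uncut")]

    def end_of(top: int, bottom: int) -> End:
        if top == bottom:
            return BLUNT
        lo, hi = sorted((top, bottom))
        oh = (s + s)[lo:hi]
        return End("5p" if bottom > top else "3p", oh)

    ordered = sorted(cuts, key=lambda c: c[0] % L)
    frags: list[Fragment] = []
    if circular:
        for i, (t, b) in enumerate(ordered):
            t_next = ordered[(i + 1) % len(ordered)][0]
            length = (t_next % L - t % L) % L or L
            frags.append(
                Fragment(
                    (s + s)[t % L : t % L + length],
                    end5=end_of(t, b),
                    end3=end_of(*ordered[(i + 1) % len(ordered)]),
                    label=f"frag{i}",
                )
            )
    else:
        bounds = [0] + [t for t, _ in ordered] + [L]
        for t, _ in ordered:
            if t <= 1 or t >= L - 1:
                logger.warning("%s cut within 1 bp of a linear end: unstable", enzyme.name)
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            e5 = BLUNT if i == 0 else end_of(*ordered[i - 1])
            e3 = BLUNT if i == len(bounds) - 2 else end_of(*ordered[i])
            frags.append(Fragment(s[lo:hi], end5=e5, end3=e3, label=f"frag{i}"))
    return frags


def _overlap_len(a: str, b: str, min_overlap: int, cap: int | None = None) -> int:
    """Longest v with suffix(a, v) == prefix(b, v), v in [min_overlap, cap]."""
    hi = min(len(a), len(b))
    if cap is not None:
        hi = min(hi, cap)
    for v in range(hi, min_overlap - 1, -1):
        if a[-v:] == b[:v]:
            return v
    return 0


def gibson_assemble(fragments: list[Fragment], min_overlap: int = 20):
    """Join fragments into a unique circular product, or diagnose why not.

    Junctions form where one fragment's terminal ``>= min_overlap`` bases
    exactly equal another's opposite terminus (seamless: the overlap appears
    once in the product), or where digestion left complementary sticky
    ends.  Success requires every terminus to have exactly one partner and
    the junction graph to close into a single cycle; a terminus with
    multiple partners yields a :class:`HazardReport` enumerating the
    alternative orderings instead of a product.  A single fragment
    self-circularises through either mechanism.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    if not fragments:
        raise ValueError("no fragments")
    n = len(fragments)

    if n == 1:
        f = fragments[0]
        v = _overlap_len(f.seq, f.seq, min_overlap, cap=len(f.seq) - 1)
        if v:
            return AssemblyProduct(
                f.seq[: len(f.seq) - v],
                junctions=[{"between": (f.label, f.label), "overlap": v, "type": "homology"}],
            )
        if f.end3.ligatable(f.end5):
            return AssemblyProduct(
                f.seq,
                junctions=[{"between": (f.label, f.label), "overlap": len(f.end5.seq), "type": "sticky"}],
            )
        raise AssemblyError("incompatible ends: single fragment cannot circularise", [f.label])
    if n > 9:
        raise ValueError("ordering enumeration supports at most 9 fragments")

    edges: dict[tuple[int, int], dict] = {}
    self_loops: list[int] = []
    for i, fi in enumerate(fragments):
        for j, fj in enumerate(fragments):
            cap = len(fi.seq) - 1 if i == j else None
            v = _overlap_len(fi.seq, fj.seq, min_overlap, cap=cap)
            if v:
                edges[(i, j)] = {"overlap": v, "type": "homology", "shared": fj.seq[:v]}
            elif fi.end3.ligatable(fj.end5):
                edges[(i, j)] = {"overlap": 0, "type": "sticky", "shared": fj.end5.seq}
            if i == j and (i, j) in edges:
                self_loops.append(i)  # the fragment can also circularise alone

    cycles = []
    for perm in permutations(range(1, n)):
        order = (0, *perm)
        if all(
            (order[idx], order[(idx + 1) % n]) in edges for idx in range(n)
        ):
            cycles.append(order)

    out_deg: dict[int, list[int]] = {}
    in_deg: dict[int, list[int]] = {}
    for (i, j) in edges:
        out_deg.setdefault(i, []).append(j)
        in_deg.setdefault(j, []).append(i)
    ambiguous = [i for i, js in out_deg.items() if len(js) > 1]
    ambiguous += [j for j, is_ in in_deg.items() if len(is_) > 1]

    if ambiguous or len(cycles) > 1:
        junctions = []
        for (i, j), info in sorted(edges.items()):
            if len(out_deg.get(i, [])) > 1 or len(in_deg.get(j, [])) > 1:
                junctions.append(
                    {
                        "fragments": (fragments[i].label or str(i), fragments[j].label or str(j)),
                        "shared_terminal_sequence": info["shared"],
                        "length": info["overlap"] or len(info["shared"]),
                    }
                )
        return HazardReport(
            ambiguous_junctions=junctions,
            alternative_products=len(cycles) + len(self_loops),
        )

    if not cycles:
        chain = _best_partial_chain(fragments, edges)
        raise AssemblyError(
            "incompatible ends: no circular ordering closes; best partial chain "
            + " -> ".join(chain),
            chain,
        )

    order = cycles[0]
    parts = []
    junctions = []
    for idx in range(n):
        i, j = order[idx], order[(idx + 1) % n]
        info = edges[(i, j)]
        junctions.append(
            {"between": (fragments[i].label or str(i), fragments[j].label or str(j)),
             "overlap": info["overlap"], "type": info["type"]}
        )
    for idx in range(n):
        j = order[idx]
        v_in = edges[(order[idx - 1], j)]["overlap"]
        parts.append(fragments[j].seq[v_in:])
    return AssemblyProduct("".join(parts), junctions=junctions)


def _best_partial_chain(fragments: list[Fragment], edges: dict) -> list[str]:
    best: list[int] = []

    def extend(path: list[int]) -> None:
        nonlocal best
        if len(path) > len(best):
            best = list(path)
        for j in range(len(fragments)):
            if j not in path and (path[-1], j) in edges:
                extend(path + [j])

    for i in range(len(fragments)):
        extend([i])
    return [fragments[i].label or str(i) for i in best]


def _longest_common_substring(a: str, b: str) -> str:
    best = ""
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > len(best):
                    best = a[i - cur[j] : i]
        prev = cur
    return best


def detect_hazards(
    fragments: list[Fragment],
    k: int = 15,
    window: int = 40,
    intended_order: bool = True,
) -> HazardReport:
    """Quick terminal scan for shared motifs without attempting assembly.

    Every pair of fragment termini that is not an intended junction (the
    declared list order, circularly, when ``intended_order``) is checked for
    a shared substring of ``>= k`` bp within the terminal ``window`` bases,
    on either strand.  LoxP-flanked selectable markers are the canonical
    trigger.  The report is symmetric in fragment order.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    window = max(window, k)
    n = len(fragments)
    termini = []
    for i, f in enumerate(fragments):
        termini.append((i, "5p", f.seq[:window]))
        termini.append((i, "3p", f.seq[-window:]))
    intended = set()
    if intended_order and n > 1:
        for i in range(n):
            j = (i + 1) % n
            intended.add(((i, "3p"), (j, "5p")))
            intended.add(((j, "5p"), (i, "3p")))
    entries = []
    for a in range(len(termini)):
        for b in range(a + 1, len(termini)):
            ia, enda, wa = termini[a]
            ib, endb, wb = termini[b]
            if ((ia, enda), (ib, endb)) in intended:
                continue
            shared = _longest_common_substring(wa, wb)
            shared_rc = _longest_common_substring(wa, revcomp(wb))
            if len(shared_rc) > len(shared):
                shared = shared_rc
            if len(shared) >= k:
                la = fragments[ia].label or str(ia)
                lb = fragments[ib].label or str(ib)
                entries.append(
                    {
                        "fragments": (f"{la}:{enda}", f"{lb}:{endb}"),
                        "shared_terminal_sequence": shared,
                        "length": len(shared),
                    }
                )
    return HazardReport(ambiguous_junctions=entries)


@dataclass(frozen=True)
class AssemblyStep:
    op: str  # "digest" | "gibson"
    enzyme: str | None = None
    fragments: tuple[str, ...] = ()


@dataclass
class AssemblyPlan:
    steps: list[AssemblyStep]
    mode: str  # "one_step" | "two_step"
    rationale: list[str] = field(default_factory=list)


def plan_assembly(
    arm5_gc: float,
    arm3_gc: float,
    if_has_loxp_sm: bool,
    hi: float = 60.0,
    lo: float = 40.0,
) -> AssemblyPlan:
    """Choose one-step vs hierarchical two-step donor assembly.

    Two-step is triggered by an unbalanced homology arm (GC > hi or < lo)
    or by a LoxP-flanked selectable marker in the insert; it digests at
    AgeI and integrates the 5' arm first, then repeats with XhoI and the 3'
    arm.  Balanced, marker-free constructs assemble in one pot.
    """
    triggers = []
    if not 0.0 <= arm5_gc <= 100.0 or not 0.0 <= arm3_gc <= 100.0:
        raise ValueError("arm GC values must be in [0, 100]")
    if arm5_gc > hi or arm5_gc < lo:
        triggers.append("arm5_gc")
    if arm3_gc > hi or arm3_gc < lo:
        triggers.append("arm3_gc")
    if if_has_loxp_sm:
        triggers.append("loxp_sm")
    if triggers:
        steps = [
            AssemblyStep("digest", enzyme="AgeI", fragments=("if_vector",)),
            AssemblyStep("gibson", fragments=("if_vector", "arm5")),
            AssemblyStep("digest", enzyme="XhoI", fragments=("intermediate",)),
            AssemblyStep("gibson", fragments=("intermediate", "arm3")),
        ]
        return AssemblyPlan(steps, "two_step", triggers)
    steps = [
        AssemblyStep("digest", enzyme="AgeI", fragments=("if_vector",)),
        AssemblyStep("gibson", fragments=("if_vector", "arm5", "arm3")),
    ]
    return AssemblyPlan(steps, "one_step", [])


def make_sgrna_site(sgrna, pam) -> str:
    """Build the 23-nt sgRNA recognition site: 20-nt target + 3' NGG PAM."""
    s = as_dna(sgrna)
    p = as_dna(pam)
    if len(s) != 20:
        raise ValueError(f"sgRNA must be 20 nt, got {len(s)}")
    if not re.fullmatch("[ACGT]GG", p):
        raise ValueError(f"PAM must match NGG, got {p}")
    return s + p


def insert_flanking_sites(
    donor,
    site_seq,
    enzyme_left: RestrictionEnzyme,
    enzyme_right: RestrictionEnzyme,
) -> str:
    """Insert ``site_seq`` just inside two unique enzyme loci of a circular
    donor, flanking the inserted fragment, with both loci preserved.

    The product is returned rotated to start at the left enzyme's site and
    is longer than the donor by exactly twice ``len(site_seq)``.
    """
    s = as_dna(donor)
    L = len(s)
    for enz in (enzyme_left, enzyme_right):
        hits = _site_positions(s, enz.site, circular=True)
        if len(hits) != 1:
            raise ValueError(
                f"{enz.name} site must occur exactly once in the donor (found {len(hits)})"
            )
    if hasattr(site_seq, "__len__") and len(site_seq) == 0:
        return s
    ins = as_dna(site_seq)
    left = _site_positions(s, enzyme_left.site, circular=True)[0]
    rot = (s + s)[left : left + L]
    right = _site_positions(rot, enzyme_right.site, circular=True)[0]
    lsl = len(enzyme_left.site)
    return rot[:lsl] + ins + rot[lsl:right] + ins + rot[right:]


def verify_construct(construct, expected_elements) -> tuple[bool, str | None]:
    """Check that each expected element occurs exactly once, in circular order.

    ``expected_elements`` is an ordered list of sequences (or (label, seq)
    pairs).  Returns ``(ok, first_violation)``.
    """
    s = as_dna(construct)
    elems = []
    for e in expected_elements:
        if isinstance(e, (tuple, list)):
            elems.append((str(e[0]), as_dna(e[1])))
        else:
            elems.append((as_dna(e)[:12] + "...", as_dna(e)))
    positions = []
    for label, seq in elems:
        hits = _site_positions(s, seq, circular=True)
        if len(hits) != 1:
            return False, f"element {label} occurs {len(hits)} times (expected 1)"
        positions.append(hits[0])
    n = len(elems)
    ranks = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: positions[i]))}
    for i in range(n):
        if (ranks[i] - ranks[0]) % n != i:
            return False, f"element {elems[i][0]} out of circular order"
    return True, None
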