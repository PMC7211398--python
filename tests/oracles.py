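"""Independent brute-force oracles used to validate the fast scanners.

These deliberately re-derive each quantity from its definition (exhaustive
enumeration over substrings / alignments) rather than sharing any code with
the implementations they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_hairpins(s: str, min_stem: int, min_loop: int) -> set[tuple[int, int, int, int]]:
    """All maximal (stem5_start, stem3_start, stem_len, loop_len) hairpins."""
    L = len(s)
    out = set()
    for l in range(min_stem, L):
        for i in range(0, L - l + 1):
            for j in range(i + l + min_loop, L - l + 1):
                if s[j : j + l] != _rc(s[i : i + l]):
                    continue
                outward = (
                    i - 1 >= 0
                    and j + l < L
                    and _COMP.get(s[i - 1]) == s[j + l]
                )
                loop = j - (i + l)
                inward = (
                    _COMP.get(s[i + l]) == s[j - 1] and loop - 2 >= min_loop
                )
                if not outward and not inward:
                    out.add((i, j, l, loop))
    return out


def brute_dimers(
    s1: str, s2: str, min_run: int, win3: int, min_run3: int
) -> set[tuple[int, int, int, bool]]:
    """All reportable (pos1, pos2, run_len, anchored) antiparallel runs,
    found by sliding s1 along the reversed second strand."""
    L1, L2 = len(s1), len(s2)
    r2 = s2[::-1]
    out = set()
    for d in range(-(L2 - 1), L1):
        lo, hi = max(0, d), min(L1, L2 + d)
        t = lo
        while t < hi:
            if _COMP.get(s1[t]) == r2[t - d]:
                t1 = t
                while t1 + 1 < hi and _COMP.get(s1[t1 + 1]) == r2[t1 + 1 - d]:
                    t1 += 1
                run = t1 - t + 1
                pos2 = L2 - 1 - (t1 - d)
                j_hi = L2 - 1 - (t - d)
                anchored = (t1 >= L1 - win3 or j_hi >= L2 - win3) and run >= min_run3
                if run >= min_run or anchored:
                    out.add((t, pos2, run, anchored))
                t = t1 + 1
            t += 1
    return out


def brute_longest_shared(query: str, contigs: list[str]) -> int:
    """Length of the longest substring of query occurring exactly in any
    contig on either strand (naive descending-length search)."""
    for l in range(len(query), 0, -1):
        for i in range(len(query) - l + 1):
            sub = query[i : i + l]
            rc = _rc(sub)
            for c in contigs:
                if sub in c or rc in c:
                    return l
    return 0
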