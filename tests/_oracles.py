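"""Independent brute-force oracles used only by the test suite.

These re-derive expected results from first principles (explicit
enumeration over decompositions, naive double loops) so that the package
implementation is checked against logic it does not share.
"""

from __future__ import annotations

import re


def oracle_g4_matches(
    seq: str,
    min_run: int = 3,
    n_tracts: int = 4,
    loop_min: int = 1,
    loop_max: int | None = 12,
) -> list[tuple[int, int]]:
    """Enumerate G4 matches by explicit decomposition over G-runs.

    A candidate motif is any ordered choice of ``n_tracts`` maximal G-runs of
    length >= ``min_run`` whose successive gaps (loops) lie within
    [loop_min, loop_max]. Among candidates the leftmost start wins, loops are
    shortest-first (lexicographically minimal run choice), and selected
    occurrences never overlap. Restricted to loop_min == 1, where a maximal
    run is never entered mid-way (any suffix decomposition has the same
    remainder and therefore the same fate).
    """
    if loop_min != 1:
        raise NotImplementedError("oracle assumes loop_min == 1")
    s = seq.upper()
    if loop_max is None:
        loop_max = len(s)
    # a motif needs n_tracts runs of >= min_run G, hence this many G overall
    if s.count("G") < n_tracts * min_run or "G" * min_run not in s:
        return []
    runs = [(m.start(), m.end()) for m in re.finditer(f"G{{{min_run},}}", s)]

    def complete(prev: int, left: int) -> list[int] | None:
        if left == 0:
            return []
        for r in range(prev + 1, len(runs)):
            gap = runs[r][0] - runs[prev][1]
            if gap > loop_max:
                break
            rest = complete(r, left - 1)
            if rest is not None:
                return [r] + rest
        return None

    matches: list[tuple[int, int]] = []
    i = 0
    while i < len(runs):
        tail = complete(i, n_tracts - 1)
        if tail is None:
            i += 1
            continue
        last = tail[-1]
        matches.append((runs[i][0], runs[last][1]))
        i = last + 1
    return matches


def oracle_containment_count(
    intervals: list[tuple[int, int]], lo: int, hi: int
) -> int:
    """Naive per-interval containment scan."""
    return sum(1 for s, e in intervals if lo <= s and e <= hi)
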