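"""Strand-aware detection of putative G-quadruplex (G4) motifs.

A putative quadruplex sequence (PQS) is four tracts of at least ``min_run``
consecutive guanines separated by loops of 1..``loop_max`` arbitrary bases
(G3+N1-12 in the loose definition; unbounded loops for density profiling).
Matching is leftmost, non-overlapping, with lazy (shortest) loops and
maximal G-tracts: a single run of G is never split into two tracts of the
same motif, and N is accepted in loops but never inside a tract.

Coordinates are 0-based half-open. ``strand_class`` is defined relative to
the scanned sequence's own 5'->3' orientation (the gene's coding strand when
scanning promoters): ``coding`` matches lie on the given sequence,
``template`` matches are G-tracts on its reverse complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

CODING = "coding"
TEMPLATE = "template"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifSpec:
    """Parameters of the G4 regular expression.

    ``loop_max=None`` means unbounded loops (capped internally at the
    scanned sequence length, which has no functional effect).
    """

    min_run: int = 3
    n_tracts: int = 4
    loop_min: int = 1
    loop_max: int | None = 12
    name: str = "G3+L1-12"

    def __post_init__(self) -> None:
        if self.min_run < 3:
            raise ValueError(f"min_run must be >= 3, got {self.min_run}")
        if self.n_tracts < 2:
            raise ValueError(f"n_tracts must be >= 2, got {self.n_tracts}")
        if self.loop_min < 1:
            raise ValueError(f"loop_min must be >= 1, got {self.loop_min}")
        if self.loop_max is not None and self.loop_max < self.loop_min:
            raise ValueError(
                f"loop_max ({self.loop_max}) < loop_min ({self.loop_min})"
            )

    def min_length(self) -> int:
        """Shortest sequence that can contain one match."""
        return self.n_tracts * self.min_run + (self.n_tracts - 1) * self.loop_min

    def pattern(self, seq_len: int) -> re.Pattern[str]:
        cap = seq_len if self.loop_max is None else self.loop_max
        cap = max(cap, self.loop_min)
        return _compile(self.min_run, self.n_tracts, self.loop_min, cap)


# Loose G4 definition used for cumulative motif counts (loops 1-12) and the
# unbounded-loop variant used for sliding-window densities.
LOOSE_G4 = MotifSpec(loop_max=12, name="G3+L1-12")
DENSITY_G4 = MotifSpec(loop_max=None, name="G3+L1+")


@lru_cache(maxsize=64)
def _compile(min_run: int, n_tracts: int, loop_min: int, loop_max: int) -> re.Pattern[str]:
    # Possessive G-tracts keep a maximal G-run as a single tract; lazy loops
    # give shortest-loop (leftmost) decompositions.
    tract = f"G{{{min_run},}}+"
    loop = f"[ACGTN]{{{loop_min},{loop_max}}}?"
    return re.compile(f"{tract}(?:{loop}{tract}){{{n_tracts - 1}}}")


@dataclass(frozen=True)
class G4Match:
    """One motif occurrence.

    ``matched`` is the G-rich string as matched: the sequence slice for
    coding matches, its reverse complement for template matches.
    """

    start: int
    end: int
    strand_class: str
    matched: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid match interval [{self.start}, {self.end})")
        if self.strand_class not in (CODING, TEMPLATE):
            raise ValueError(f"unknown strand_class {self.strand_class!r}")


def _validate_seq(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"invalid nucleotide symbol(s) {sorted(bad)}; alphabet is A/C/G/T/N"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (case-insensitive).

    Returns upper case; an involution on upper-case input.
    """
    s = _validate_seq(seq)
    return s.translate(_COMPLEMENT)[::-1]


def find_g4(seq: str, spec: MotifSpec = LOOSE_G4) -> list[G4Match]:
    """Leftmost non-overlapping G4 matches on the given (coding) strand."""
    s = _validate_seq(seq)
    pat = spec.pattern(len(s))
    return [
        G4Match(m.start(), m.end(), CODING, m.group()) for m in pat.finditer(s)
    ]


def find_g4_both_strands(seq: str, spec: MotifSpec = LOOSE_G4) -> list[G4Match]:
    """G4 matches on both strands, in the input sequence's coordinate frame.

    Template matches are found on the reverse complement and mapped back via
    start' = L - end, end' = L - start. The combined list is sorted by start
    (coding before template on ties).
    """
    s = _validate_seq(seq)
    n = len(s)
    out = list(find_g4(s, spec))
    for m in find_g4(revcomp(s), spec):
        out.append(G4Match(n - m.end, n - m.start, TEMPLATE, m.matched))
    out.sort(key=lambda m: (m.start, m.strand_class, m.end))
    return out


def count_in_interval(matches: list[G4Match], interval: tuple[int, int]) -> int:
    """Number of matches fully contained in a 0-based half-open interval."""
    lo, hi = interval
    if lo > hi:
        raise ValueError(f"inverted interval [{lo}, {hi})")
    return sum(1 for m in matches if m.start >= lo and m.end <= hi)
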