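"""TSS-centred promoter extraction, G4 metagene densities and GC profiles.

Promoters are represented gene-oriented: the stored sequence runs 5'->3'
along the gene's coding strand, centred on the transcription start site
(TSS), so "downstream of the TSS" is always to the right of the midpoint.
Profiles are computed in sliding windows (default 50 nt stepping by 10 nt)
and normalised to the number of promoters analysed, separately for the
coding and template strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .scan import CODING, TEMPLATE, MotifSpec, LOOSE_G4, DENSITY_G4, find_g4_both_strands, revcomp


@dataclass(frozen=True)
class PromoterRecord:
    """A TSS-flanking sequence oriented along the gene's coding strand."""

    gene_id: str
    gene_strand: str  # '+' or '-' in the reference frame
    tss: int  # reference coordinate of the TSS
    seq: str

    @property
    def flank(self) -> int:
        return len(self.seq) // 2


@dataclass(frozen=True)
class MetageneProfile:
    """Per-window fraction of promoters with >=1 fully contained G4 match."""

    positions: np.ndarray  # window-centre offsets relative to the TSS
    coding_density: np.ndarray
    template_density: np.ndarray
    window_size: int
    step: int
    n_promoters: int


@dataclass(frozen=True)
class CumulativeCountCurve:
    """Complementary cumulative curve: fraction of genes with >= n motifs.

    ``fraction_at_n[n]`` is the fraction of genes whose promoter carries at
    least n motifs, so enrichment reads as an upward shift.
    """

    fraction_at_n: np.ndarray
    n_genes: int

    @property
    def max_n(self) -> int:
        return len(self.fraction_at_n) - 1


@dataclass(frozen=True)
class CumulativeCountResult:
    curve: CumulativeCountCurve
    per_gene_counts: pd.Series
    excluded: list[str] = field(default_factory=list)


def extract_promoters(
    genome,
    annotation: pd.DataFrame,
    flank: int = 1500,
    out_of_bounds: str = "skip",
) -> list[PromoterRecord]:
    """Extract TSS +/- flank sequences, oriented along each gene.

    Parameters
    ----------
    genome
        A FASTA path (opened via pyfaidx) or a mapping from chromosome
        name to sequence (a ``pyfaidx.Fasta`` handle or a plain ``dict``).
    annotation
        Table with columns ``gene_id``, ``chrom``, ``tss``, ``strand``
        ('+'/'-'); the TSS is a 0-based reference coordinate.
    flank
        Nucleotides retained on each side of the TSS.
    out_of_bounds
        ``"skip"`` drops genes whose window leaves the chromosome;
        ``"clip"`` keeps the truncated (flagged-short) sequence.

    Minus-strand genes are reverse complemented so that position ``flank``
    in every record corresponds to the TSS and downstream is rightward.
    Records are returned sorted by ``gene_id``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(genome, (str, Path)):
        genome = Fasta(str(genome))
    if out_of_bounds not in ("skip", "clip"):
        raise ValueError("out_of_bounds must be 'skip' or 'clip'")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation lacks column(s) {sorted(missing)}")

    records: list[PromoterRecord] = []
    for i, row in enumerate(annotation.itertuples(index=False)):
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise ValueError(
                f"annotation row {i}: strand must be '+' or '-', got {strand!r}"
            )
        try:
            tss = int(row.tss)
        except (TypeError, ValueError):
            raise ValueError(f"annotation row {i}: non-integer tss {row.tss!r}")
        chrom = str(row.chrom)
        if chrom not in genome:
            warnings.warn(f"chromosome {chrom!r} absent from genome; skipping {row.gene_id}")
            continue
        chrom_seq = genome[chrom]
        chrom_len = len(chrom_seq)
        lo, hi = tss - flank, tss + flank
        if lo < 0 or hi > chrom_len:
            if out_of_bounds == "skip":
                warnings.warn(
                    f"promoter window of {row.gene_id} outside chromosome bounds; skipped"
                )
                continue
            lo, hi = max(lo, 0), min(hi, chrom_len)
        piece = str(chrom_seq[lo:hi]).upper()
        if strand == "-":
            piece = revcomp(piece)
        records.append(PromoterRecord(str(row.gene_id), strand, tss, piece))
    records.sort(key=lambda r: r.gene_id)
    return records


def _select(promoters: list[PromoterRecord], gene_set, allow_missing: bool):
    by_id = {p.gene_id: p for p in promoters}
    chosen, missing = [], []
    for g in gene_set:
        if g in by_id:
            chosen.append(by_id[g])
        else:
            missing.append(g)
    if missing and not allow_missing:
        raise ValueError(f"gene id(s) not among promoters: {missing[:10]}")
    return chosen, missing


def cumulative_counts(
    promoters: list[PromoterRecord],
    gene_set,
    spec: MotifSpec = LOOSE_G4,
    flank_used: int | None = None,
) -> CumulativeCountResult:
    """Per-gene G4 counts near the TSS and the fraction-with->=n curve.

    Counts combine coding- and template-strand matches fully contained in
    [TSS - flank_used, TSS + flank_used) (default: the full promoter).
    Unknown gene ids are excluded and reported, not fatal.
    """
    chosen, missing = _select(promoters, gene_set, allow_missing=True)
    if not chosen:
        raise ValueError("no promoters selected")
    counts = {}
    for p in chosen:
        fu = p.flank if flank_used is None else min(flank_used, p.flank)
        lo, hi = p.flank - fu, p.flank + fu
        matches = find_g4_both_strands(p.seq, spec)
        counts[p.gene_id] = sum(1 for m in matches if m.start >= lo and m.end <= hi)
    series = pd.Series(counts, name="g4_count").sort_index()
    max_n = int(series.max())
    frac = np.array(
        [(series >= n).mean() for n in range(max_n + 1)], dtype=float
    )
    curve = CumulativeCountCurve(fraction_at_n=frac, n_genes=len(series))
    return CumulativeCountResult(curve=curve, per_gene_counts=series, excluded=missing)


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if window > length:
        raise ValueError(f"window ({window}) exceeds sequence length ({length})")
    return np.arange(0, length - window + 1, step)


def metagene_density(
    promoters: list[PromoterRecord],
    gene_set,
    spec: MotifSpec = DENSITY_G4,
    window: int = 50,
    step: int = 10,
) -> MetageneProfile:
    """Strand-resolved sliding-window G4 density around the TSS.

    For each window the density on a strand is the fraction of promoters in
    ``gene_set`` carrying at least one match fully contained in that window
    on that strand. Matches straddling a window edge do not count for it.
    """
    chosen, _ = _select(promoters, gene_set, allow_missing=False)
    if not chosen:
        raise ValueError("empty gene set")
    length = len(chosen[0].seq)
    if any(len(p.seq) != length for p in chosen):
        raise ValueError("promoters have unequal lengths")
    starts = _window_starts(length, window, step)
    n_win = len(starts)
    hit = {CODING: np.zeros(n_win, dtype=np.int64), TEMPLATE: np.zeros(n_win, dtype=np.int64)}
    for p in chosen:
        seen = {CODING: np.zeros(n_win, dtype=bool), TEMPLATE: np.zeros(n_win, dtype=bool)}
        for m in find_g4_both_strands(p.seq, spec):
            # windows [lo, lo+window) with lo <= m.start and lo+window >= m.end
            lo_min = max(m.end - window, 0)
            lo_max = min(m.start, length - window)
            if lo_min > lo_max:
                continue
            i0 = -(-lo_min // step)  # ceil division
            i1 = lo_max // step
            if i0 <= i1:
                seen[m.strand_class][i0 : i1 + 1] = True
        for strand in (CODING, TEMPLATE):
            hit[strand] += seen[strand]
    flank = length // 2
    positions = starts + window // 2 - flank
    n = len(chosen)
    return MetageneProfile(
        positions=positions,
        coding_density=hit[CODING] / n,
        template_density=hit[TEMPLATE] / n,
        window_size=window,
        step=step,
        n_promoters=n,
    )


def gc_profile(
    promoters: list[PromoterRecord],
    gene_set,
    window: int = 50,
    step: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean GC fraction per sliding window around the TSS.

    Returns ``(positions, gc)`` where positions are window centres relative
    to the TSS and gc values lie in [0, 1].
    """
    chosen, _ = _select(promoters, gene_set, allow_missing=False)
    if not chosen:
        raise ValueError("empty gene set")
    length = len(chosen[0].seq)
    if any(len(p.seq) != length for p in chosen):
        raise ValueError("promoters have unequal lengths")
    starts = _window_starts(length, window, step)
    total = np.zeros(len(starts), dtype=float)
    for p in chosen:
        is_gc = np.frombuffer(p.seq.upper().encode(), dtype=np.uint8)
        is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        total += (cum[starts + window] - cum[starts]) / window
    flank = length // 2
    positions = starts + window // 2 - flank
    return positions, total / len(chosen)
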