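"""Synthetic data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here with
known, recoverable structure: promoter sequences with planted G4 motifs
(downstream-biased, coding-strand-biased), EBseq-style differential
expression tables with configured DE counts and correlated fold changes,
anisotropy titrations from the depletion isotherm, and marker-loss
fluctuation clones from a heritable branching process.

All generators are deterministic given their seed; per-gene / per-clone
substreams are derived from the global seed so records are independent of
each other and of the total count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, predict_anisotropy
from .profiles import PromoterRecord
from .scan import CODING, TEMPLATE, LOOSE_G4, find_g4_both_strands, revcomp

_LOOP_ALPHABET = "ACT"  # no G: keeps planted tracts unambiguous on both strands


@dataclass(frozen=True)
class PromoterSimConfig:
    """Knobs of the promoter generator.

    ``position_concentration`` is the per-nucleotide success probability of
    the truncated geometric law for the planted-motif offset downstream of
    the TSS: larger values cluster motifs more tightly just after the TSS.
    """

    n_genes: int
    flank: int = 1500
    gc_background: float = 0.5
    planted_rate_enriched: float = 2.0
    planted_rate_background: float = 0.2
    p_coding_strand: float = 0.75
    position_concentration: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        for name in ("gc_background", "p_coding_strand"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("planted_rate_enriched", "planted_rate_background"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be a non-negative real")
        if not (0.0 < self.position_concentration <= 1.0):
            raise ValueError("position_concentration must lie in (0, 1]")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Knobs of the paired differential-expression table generator.

    PPDE values are Beta(alpha, 1): ``ppde_de_alpha`` large concentrates
    true-DE genes near 1; ``ppde_null_alpha`` sets the null tail,
    P(PPDE >= t) = 1 - t**alpha.
    """

    n_genes: int
    n_de_a: int = 400
    n_de_b: int = 300
    n_de_both: int = 200
    lfc_sd: float = 1.5
    lfc_correlation: float = 0.8
    ppde_de_alpha: float = 80.0
    ppde_null_alpha: float = 0.2
    tpm_lognormal_params: tuple[float, float] = (3.0, 1.2)
    null_lfc_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("n_de_a", "n_de_b", "n_de_both"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_de_both > min(self.n_de_a, self.n_de_b):
            raise ValueError("n_de_both exceeds a marginal DE count")
        if max(self.n_de_a, self.n_de_b) > self.n_genes:
            raise ValueError("DE counts exceed n_genes")
        if self.n_de_a + self.n_de_b - self.n_de_both > self.n_genes:
            raise ValueError("DE sets do not fit in n_genes")
        if not abs(self.lfc_correlation) <= 1.0:
            raise ValueError("|lfc_correlation| must be <= 1")
        if self.lfc_sd < 0 or self.null_lfc_sd < 0:
            raise ValueError("fold-change SDs must be non-negative")
        if self.ppde_de_alpha <= 0 or self.ppde_null_alpha <= 0:
            raise ValueError("PPDE shape parameters must be positive")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside synthetic datasets.

    Only the fields relevant to the generator that produced it are filled:
    ``motifs`` has one row per planted motif (gene_id, start, end, strand,
    matched -- coordinates in the promoter frame, strand relative to the
    gene); ``enriched`` flags motif-enriched genes; ``de`` has one row per
    gene with true DE flags and log2 fold changes; ``titration`` holds the
    generating isotherm parameters.
    """

    motifs: pd.DataFrame | None = None
    enriched: dict = field(default_factory=dict)
    de: pd.DataFrame | None = None
    titration: dict = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _random_motif(rng: np.random.Generator) -> str:
    """A canonical-loop G4: four G3 tracts, loops of 1-7 non-G bases."""
    parts = ["GGG"]
    for _ in range(3):
        loop_len = int(rng.integers(1, 8))
        loop = "".join(rng.choice(list(_LOOP_ALPHABET), size=loop_len))
        parts.append(loop)
        parts.append("GGG")
    return "".join(parts)


def _truncated_geometric(rng: np.random.Generator, p: float, high: int) -> int:
    """Geometric offset (support 0..high), resampled into range."""
    for _ in range(1000):
        off = int(rng.geometric(p)) - 1
        if off <= high:
            return off
    return int(rng.integers(0, high + 1))


def _plant_one_gene(
    cfg: PromoterSimConfig, rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, str, str]]] | None:
    """One attempt at a promoter; None if planted motifs are not cleanly
    recoverable (background interference) and the caller should retry."""
    length = 2 * cfg.flank
    gc = cfg.gc_background
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=length, p=probs)

    n_mot = int(rng.poisson(rate))
    planted: list[tuple[int, int, str, str]] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(n_mot):
        motif = _random_motif(rng)
        mlen = len(motif)
        max_off = length - cfg.flank - mlen - 1
        if max_off < 0:
            continue
        for _ in range(200):
            off = _truncated_geometric(rng, cfg.position_concentration, max_off)
            pos = cfg.flank + off
            if all(pos >= e + 2 or pos + mlen <= s - 2 for s, e in occupied):
                break
        else:
            continue
        strand = CODING if rng.random() < cfg.p_coding_strand else TEMPLATE
        insert = motif if strand == CODING else revcomp(motif)
        seq[pos : pos + mlen] = list(insert)
        # A/T guard bases stop background Gs (or Cs) extending a tract on
        # either strand.
        if pos > 0:
            seq[pos - 1] = "A" if rng.random() < 0.5 else "T"
        if pos + mlen < length:
            seq[pos + mlen] = "A" if rng.random() < 0.5 else "T"
        occupied.append((pos, pos + mlen))
        planted.append((pos, pos + mlen, strand, motif))

    s = "".join(seq)
    if planted:
        found = {(m.start, m.end, m.strand_class) for m in find_g4_both_strands(s, LOOSE_G4)}
        if any((p0, p1, st) not in found for p0, p1, st, _ in planted):
            return None
    return s, sorted(planted)


def gen_promoters(
    cfg: PromoterSimConfig, enriched_gene_fraction: float = 0.5
) -> tuple[list[PromoterRecord], PlantedTruth]:
    """Promoters with planted G4 motifs and their ground truth.

    The first ``round(n_genes * enriched_gene_fraction)`` genes are
    motif-enriched (expected ``planted_rate_enriched`` motifs each), the
    rest receive ``planted_rate_background``. Background sequence is i.i.d.
    with the configured GC fraction; planted positions are geometrically
    biased downstream of the TSS and the planting is locally rejected and
    resampled whenever background context would perturb the recorded
    coordinates, so every truth row is recoverable verbatim by the scanner.
    """
    if not (0.0 <= enriched_gene_fraction <= 1.0):
        raise ValueError("enriched_gene_fraction must lie in [0, 1]")
    ids = _gene_ids(cfg.n_genes)
    n_enriched = round(cfg.n_genes * enriched_gene_fraction)
    records: list[PromoterRecord] = []
    rows = []
    enriched = {}
    for i, gid in enumerate(ids):
        is_enriched = i < n_enriched
        enriched[gid] = is_enriched
        rate = cfg.planted_rate_enriched if is_enriched else cfg.planted_rate_background
        for attempt in range(100):
            rng = np.random.default_rng([abs(cfg.seed) % (2**31), i, attempt])
            result = _plant_one_gene(cfg, rate, rng)
            if result is not None:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"could not plant motifs cleanly for {gid}")
        seq, planted = result
        records.append(PromoterRecord(gene_id=gid, gene_strand="+", tss=cfg.flank, seq=seq))
        for start, end, strand, motif in planted:
            rows.append({"gene_id": gid, "start": start, "end": end, "strand": strand, "matched": motif})
    motifs = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "matched"])
    return records, PlantedTruth(motifs=motifs, enriched=enriched)


def gen_expression_tables(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Paired EBseq-style DE tables for two mutants against one wild type.

    Exactly ``n_de_a`` / ``n_de_b`` genes are truly DE per mutant with
    ``n_de_both`` shared; shared genes draw their true log2 fold changes
    from a bivariate normal with correlation ``lfc_correlation``. PostFC is
    2**lfc; mutant TPM is wild-type TPM scaled by PostFC; PPDE is
    Beta(alpha, 1) with the DE or null shape per the true flag.
    """
    rng = np.random.default_rng(abs(cfg.seed) % (2**31))
    n = cfg.n_genes
    ids = np.array(_gene_ids(n))
    perm = rng.permutation(n)
    n_both = cfg.n_de_both
    shared = perm[:n_both]
    a_only = perm[n_both : cfg.n_de_a]
    b_only = perm[cfg.n_de_a : cfg.n_de_a + cfg.n_de_b - n_both]

    is_de_a = np.zeros(n, dtype=bool)
    is_de_b = np.zeros(n, dtype=bool)
    is_de_a[shared] = is_de_a[a_only] = True
    is_de_b[shared] = is_de_b[b_only] = True

    lfc_a = rng.normal(0.0, cfg.null_lfc_sd, size=n)
    lfc_b = rng.normal(0.0, cfg.null_lfc_sd, size=n)
    rho, sd = cfg.lfc_correlation, cfg.lfc_sd
    z1 = rng.normal(size=n_both)
    z2 = rng.normal(size=n_both)
    lfc_a[shared] = sd * z1
    lfc_b[shared] = sd * (rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * z2)
    lfc_a[a_only] = rng.normal(0.0, sd, size=a_only.size)
    lfc_b[b_only] = rng.normal(0.0, sd, size=b_only.size)

    loc, scale = cfg.tpm_lognormal_params
    tpm_wt = rng.lognormal(loc, scale, size=n)

    def ppde(is_de: np.ndarray) -> np.ndarray:
        out = rng.beta(cfg.ppde_null_alpha, 1.0, size=n)
        out[is_de] = rng.beta(cfg.ppde_de_alpha, 1.0, size=int(is_de.sum()))
        return out

    def table(lfc: np.ndarray, is_de: np.ndarray) -> pd.DataFrame:
        postfc = np.exp2(lfc)
        return pd.DataFrame(
            {
                "gene_id": ids,
                "tpm_wt": tpm_wt,
                "tpm_mut": tpm_wt * postfc,
                "postfc": postfc,
                "ppde": ppde(is_de),
            }
        )

    truth = PlantedTruth(
        de=pd.DataFrame(
            {
                "gene_id": ids,
                "is_de_a": is_de_a,
                "is_de_b": is_de_b,
                "lfc_a": lfc_a,
                "lfc_b": lfc_b,
            }
        )
    )
    return table(lfc_a, is_de_a), table(lfc_b, is_de_b), truth


def gen_titration(
    kd: float,
    r_free: float,
    r_bound: float,
    l_total: float,
    protein_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TitrationSeries, PlantedTruth]:
    """Anisotropy titration from the depletion isotherm plus Gaussian noise."""
    if kd <= 0 or l_total <= 0:
        raise ValueError("kd and l_total must be positive")
    if r_bound <= r_free:
        raise ValueError("r_bound must exceed r_free for a binding event")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = np.asarray(protein_grid, dtype=float)
    rng = np.random.default_rng(abs(seed) % (2**31))
    readings = predict_anisotropy(grid, l_total, kd, r_free, r_bound)
    if noise_sd > 0:
        readings = readings + rng.normal(0.0, noise_sd, size=grid.shape)
    series = TitrationSeries(protein_totals=grid, readings=readings, l_total=l_total)
    truth = PlantedTruth(
        titration={"kd": kd, "r_free": r_free, "r_bound": r_bound, "l_total": l_total}
    )
    return series, truth


def gen_fluctuation_clones(
    n_clones: int,
    loss_rate_per_division: float,
    n_generations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Percent marker-loss per clone from a heritable branching process.

    Each clone starts from one unconverted cell; every division each
    daughter independently converts to the (heritable) lost state with the
    given per-division probability. Expected loss after g generations is
    1 - (1 - rate)**g.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if not (0.0 <= loss_rate_per_division <= 1.0):
        raise ValueError("loss_rate_per_division must lie in [0, 1]")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    out = np.empty(n_clones, dtype=float)
    for c in range(n_clones):
        rng = np.random.default_rng([abs(seed) % (2**31), c])
        unlost, lost = 1, 0
        for _ in range(n_generations):
            daughters = 2 * unlost
            converted = int(rng.binomial(daughters, loss_rate_per_division))
            unlost = daughters - converted
            lost = 2 * lost + converted
        out[c] = 100.0 * lost / (lost + unlost)
    return out
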