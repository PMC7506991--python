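"""Differential-expression table filtering and gene-set statistics.

Operates on EBseq-style result tables (one row per gene: mean TPM in each
condition, posterior fold change PostFC, posterior probability of
differential expression PPDE). Provides the expression filter (TPM >= 1 in
both conditions), the dysregulated-gene call (PPDE >= 0.95 split by PostFC
direction), one-sided Fisher exact overlap tests, two-sample
Kolmogorov-Smirnov comparisons of per-gene motif-count distributions, and
Spearman correlation of log2 fold changes between mutants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TABLE_COLUMNS = ["gene_id", "tpm_wt", "tpm_mut", "postfc", "ppde"]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks column(s) {sorted(missing)}")
    if (table["tpm_wt"] < 0).any() or (table["tpm_mut"] < 0).any():
        raise ValueError("negative TPM value(s) in expression table")
    if ((table["ppde"] < 0) | (table["ppde"] > 1)).any():
        raise ValueError("PPDE outside [0, 1]")
    if (table["postfc"] <= 0).any():
        raise ValueError("PostFC must be positive")
    return table


@dataclass(frozen=True)
class DEGeneSet:
    """Dysregulated genes of one mutant, split by fold-change direction."""

    label: str
    up: frozenset
    down: frozenset
    universe: frozenset
    ambiguous: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError("dysregulated genes not contained in universe")

    @property
    def genes(self) -> frozenset:
        return self.up | self.down


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    odds_ratio: float
    p_value: float
    table: tuple = ()


def filter_expressed(
    table: pd.DataFrame, tpm_min: float = 1.0, strict: bool = False
) -> pd.DataFrame:
    """Keep genes expressed in both conditions (TPM >= tpm_min, inclusive).

    ``strict=True`` switches to a strict ``>`` comparison. Row order is
    preserved.
    """
    _check_table(table)
    if strict:
        keep = (table["tpm_wt"] > tpm_min) & (table["tpm_mut"] > tpm_min)
    else:
        keep = (table["tpm_wt"] >= tpm_min) & (table["tpm_mut"] >= tpm_min)
    return table.loc[keep].copy()


def call_dysregulated(
    table: pd.DataFrame, ppde_min: float = 0.95, label: str = ""
) -> DEGeneSet:
    """Call up-/down-regulated genes at PPDE >= ppde_min (inclusive).

    Direction comes from PostFC (mutant vs wild type): >1 up, <1 down.
    Genes passing the PPDE threshold with PostFC exactly 1 carry no
    direction; they are reported as ``ambiguous`` and belong to neither set.
    The universe is every gene in the (already expression-filtered) table.
    """
    _check_table(table)
    sig = table.loc[table["ppde"] >= ppde_min]
    up = frozenset(sig.loc[sig["postfc"] > 1, "gene_id"])
    down = frozenset(sig.loc[sig["postfc"] < 1, "gene_id"])
    ambiguous = frozenset(sig.loc[sig["postfc"] == 1, "gene_id"])
    return DEGeneSet(
        label=label,
        up=up,
        down=down,
        universe=frozenset(table["gene_id"]),
        ambiguous=ambiguous,
    )


def overlap_test(set_a, set_b, universe, alternative: str = "greater") -> OverlapResult:
    """Fisher exact test of the overlap between two gene sets.

    The 2x2 table is (|a&b|, |a-b|; |b-a|, |U-(a|b)|) and the default
    alternative is one-sided enrichment, i.e. the exact hypergeometric
    upper tail of the overlap count.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(f"gene(s) outside universe: {sorted(stray)[:10]}")
    k = len(a & b)
    tab = [[k, len(a) - k], [len(b) - k, len(u) - len(a | b)]]
    odds, p = stats.fisher_exact(tab, alternative=alternative)
    return OverlapResult(overlap=k, odds_ratio=float(odds), p_value=float(p), table=tuple(map(tuple, tab)))


def ks_compare(counts_set, counts_background) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov-Smirnov test on count distributions.

    D is the supremum of the ECDF difference over the pooled support (ties
    from integer counts are handled by evaluating both ECDFs at the pooled
    sample points); the p-value uses the asymptotic Kolmogorov distribution
    with the standard two-sample effective size.
    """
    x = np.asarray(counts_set, dtype=float)
    y = np.asarray(counts_background, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    d = float(res.statistic)
    # limiting Kolmogorov distribution at sqrt(nm/(n+m)) * D (the classic
    # asymptotic convention, as in R's ks.test with exact = FALSE)
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    p = float(stats.kstwobign.sf(en * d))
    return d, min(max(p, 0.0), 1.0)


def spearman_fc(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    gene_selection: str = "either",
    ppde_min: float = 0.95,
) -> tuple[float, float, int]:
    """Spearman correlation of log2 fold changes between two mutants.

    ``gene_selection`` picks the compared genes among those present in both
    (already expression-filtered) tables: ``"either"`` (default) keeps genes
    called dysregulated in at least one mutant, ``"both"`` in both mutants,
    ``"all-shared"`` keeps every shared gene. Returns (rho, p, n); average
    ranks are used for ties and p comes from the large-sample t
    approximation.
    """
    _check_table(table_a)
    _check_table(table_b)
    if gene_selection not in ("either", "both", "all-shared"):
        raise ValueError(f"unknown gene_selection {gene_selection!r}")
    a = table_a.set_index("gene_id")
    b = table_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    if gene_selection != "all-shared":
        de_a = set(a.index[a["ppde"] >= ppde_min])
        de_b = set(b.index[b["ppde"] >= ppde_min])
        wanted = (de_a | de_b) if gene_selection == "either" else (de_a & de_b)
        shared = shared.intersection(wanted)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    lfc_a = np.log2(a.loc[shared, "postfc"].to_numpy(dtype=float))
    lfc_b = np.log2(b.loc[shared, "postfc"].to_numpy(dtype=float))
    rho, p = stats.spearmanr(lfc_a, lfc_b)
    return float(rho), float(p), int(len(shared))


def summarize_set(de_set: DEGeneSet) -> dict:
    """Cardinalities of a dysregulated-gene set."""
    n_up, n_down = len(de_set.up), len(de_set.down)
    return {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}
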