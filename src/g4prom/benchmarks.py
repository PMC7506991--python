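"""Reproducible synthetic-benchmark experiments.

Each function runs a complete generate -> analyse -> measure experiment on
synthetic data with known ground truth and returns the measured quantity:
type-I error calibration of the overlap and KS tests, detection power for
motif-count enrichment, recovery of the configured fold-change correlation
and of a planted dissociation constant. The test suite and the acceptance
script both drive these entry points.

Null-calibration designs use large gene sets (10% null call rate over 5,000
genes) so that the discreteness of the exact hypergeometric tail is
negligible and the attained level of a correctly implemented test can be
read against its nominal level. Exact conditional tests remain inherently
conservative on coarsely discrete data; see the methods note.
"""

from __future__ import annotations

import math

import numpy as np

from .binding import fit_isotherm
from .genesets import call_dysregulated, filter_expressed, ks_compare, overlap_test, spearman_fc
from .profiles import cumulative_counts
from .scan import LOOSE_G4
from .simulate import (
    ExpressionSimConfig,
    PromoterSimConfig,
    gen_expression_tables,
    gen_promoters,
    gen_titration,
)

# Null PPDE shape giving P(PPDE >= 0.95) = 0.10: calibration sets of ~500
# genes out of 5,000 keep the hypergeometric overlap effectively continuous.
CALIBRATION_NULL_ALPHA = math.log(0.9) / math.log(0.95)


def _subseed(seed: int, k: int) -> int:
    return (abs(seed) + 7919 * k) % (2**31)


def fisher_null_rejection_rate(
    n_reps: int = 1000,
    n_genes: int = 5000,
    null_alpha: float = CALIBRATION_NULL_ALPHA,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the one-sided overlap test on independent tables.

    Generates paired expression tables with zero planted DE genes, calls
    dysregulated sets in each (all calls are PPDE-noise false positives),
    and measures how often the Fisher enrichment p-value falls at or below
    ``alpha``.
    """
    hits = 0
    for rep in range(n_reps):
        cfg = ExpressionSimConfig(
            n_genes=n_genes,
            n_de_a=0,
            n_de_b=0,
            n_de_both=0,
            ppde_null_alpha=null_alpha,
            seed=_subseed(seed, rep),
        )
        tab_a, tab_b, _ = gen_expression_tables(cfg)
        fa, fb = filter_expressed(tab_a), filter_expressed(tab_b)
        set_a, set_b = call_dysregulated(fa), call_dysregulated(fb)
        universe = set_a.universe & set_b.universe
        res = overlap_test(set_a.genes & universe, set_b.genes & universe, universe)
        hits += res.p_value <= alpha
    return hits / n_reps


def promoter_g4_counts(
    n_genes: int, rate: float, seed: int, flank: int = 1500
) -> np.ndarray:
    """Per-gene G4 counts (loops 1-12, both strands) of simulated promoters
    all planted at one motif rate."""
    cfg = PromoterSimConfig(
        n_genes=n_genes,
        flank=flank,
        planted_rate_enriched=rate,
        planted_rate_background=rate,
        seed=seed,
    )
    records, _ = gen_promoters(cfg, enriched_gene_fraction=1.0)
    result = cumulative_counts(records, [r.gene_id for r in records], LOOSE_G4)
    return result.per_gene_counts.to_numpy()


def ks_null_rejection_rate(
    n_reps: int = 1000,
    pool_size: int = 2000,
    sample_size: int = 500,
    rate: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the KS comparison on same-distribution count samples.

    A pool of promoters is simulated at one planted-motif rate; each
    replicate compares two disjoint random subsets of the pooled per-gene
    counts (jointly an i.i.d. pair of samples from the planted count
    distribution).
    """
    counts = promoter_g4_counts(pool_size, rate, seed=_subseed(seed, 0))
    rng = np.random.default_rng(_subseed(seed, 1))
    hits = 0
    for _ in range(n_reps):
        idx = rng.permutation(pool_size)
        _, p = ks_compare(counts[idx[:sample_size]], counts[idx[sample_size : 2 * sample_size]])
        hits += p <= alpha
    return hits / n_reps


def ks_power_rate(
    n_seeds: int = 20,
    n_genes_per_set: int = 500,
    rate_enriched: float = 2.0,
    rate_background: float = 0.2,
    p_threshold: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of seeds in which KS detects motif-count enrichment."""
    hits = 0
    for k in range(n_seeds):
        enriched = promoter_g4_counts(n_genes_per_set, rate_enriched, seed=_subseed(seed, 2 * k))
        background = promoter_g4_counts(
            n_genes_per_set, rate_background, seed=_subseed(seed, 2 * k + 1)
        )
        _, p = ks_compare(enriched, background)
        hits += p < p_threshold
    return hits / n_seeds


def spearman_recovery(
    n_seeds: int = 20,
    n_genes: int = 5000,
    n_shared: int = 1000,
    lfc_correlation: float = 0.8,
    seed: int = 0,
) -> float:
    """Mean recovered Spearman rho on shared dysregulated genes."""
    rhos = []
    for k in range(n_seeds):
        cfg = ExpressionSimConfig(
            n_genes=n_genes,
            n_de_a=n_shared + 300,
            n_de_b=n_shared + 200,
            n_de_both=n_shared,
            lfc_correlation=lfc_correlation,
            seed=_subseed(seed, k),
        )
        tab_a, tab_b, _ = gen_expression_tables(cfg)
        rho, _, _ = spearman_fc(
            filter_expressed(tab_a), filter_expressed(tab_b), gene_selection="both"
        )
        rhos.append(rho)
    return float(np.mean(rhos))


def kd_recovery(
    kd: float = 1e-6,
    l_total: float = 10e-9,
    r_free: float = 0.05,
    r_bound: float = 0.25,
    n_points: int = 12,
    noise_frac: float = 0.02,
    n_seeds: int = 20,
    seed: int = 0,
) -> dict:
    """Relative Kd recovery error, noiseless and at 2%-of-range noise.

    The protein grid spans kd/100 .. 100*kd logarithmically. Returns the
    noiseless relative error and the median relative error over seeds at
    Gaussian noise of ``noise_frac`` times the dynamic range.
    """
    grid = np.geomspace(kd / 100, kd * 100, n_points)
    series, _ = gen_titration(kd, r_free, r_bound, l_total, grid, noise_sd=0.0, seed=seed)
    fit = fit_isotherm(series)
    noiseless_err = abs(fit.kd - kd) / kd
    noise_sd = noise_frac * (r_bound - r_free)
    errs = []
    for k in range(n_seeds):
        series, _ = gen_titration(
            kd, r_free, r_bound, l_total, grid, noise_sd=noise_sd, seed=_subseed(seed, k)
        )
        fit = fit_isotherm(series)
        errs.append(abs(fit.kd - kd) / kd if fit.status == "ok" else np.inf)
    return {
        "noiseless_rel_error": float(noiseless_err),
        "noisy_median_rel_error": float(np.median(errs)),
    }
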