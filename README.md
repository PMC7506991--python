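# g4prom

Analysis toolkit for studying G-quadruplex (G4) motifs in gene promoters and
their association with gene dysregulation, built around the question of how
replisome-coupled G4 processing shapes expression stability. It provides,
as a reusable library plus a `g4prom` command line tool:

- **Strand-aware G4 motif scanning.** A putative quadruplex sequence is four
  tracts of at least three guanines separated by short loops,
  d(G₃₊N₁₋₁₂G₃₊N₁₋₁₂G₃₊N₁₋₁₂G₃₊) in the loose definition used for motif
  counts, and the unbounded-loop variant d(G₃₊N₁₊…G₃₊) used for densities.
  Matching is leftmost and non-overlapping with lazy loops and maximal
  G-tracts, reported separately for the coding and template strands.
- **TSS metagene profiles.** Gene-oriented promoter windows (TSS ± 1.5 kb by
  default), per-gene cumulative G4 counts ("fraction of genes with ≥ n
  motifs"), strand-resolved G4 densities in 50-nt windows sliding by 10 nt
  normalised to the number of promoters, and GC-content profiles.
- **Dysregulated-gene-set statistics** on EBseq-style differential
  expression tables: expression filter (TPM ≥ 1 in both conditions),
  dysregulation call (PPDE ≥ 0.95, direction from PostFC), one-sided Fisher
  exact overlap tests (exact hypergeometric tail), two-sample
  Kolmogorov–Smirnov comparison of motif-count distributions, and Spearman
  correlation of log₂ fold changes between mutants.
- **Ligand-depletion binding isotherms** for fluorescence anisotropy: the
  quadratic (Morrison) one-to-one solution
  f = 2PL / (L·[(P+L+K_d) + √((P+L+K_d)² − 4PL)]), linear anisotropy mixing,
  and non-linear least-squares K_d fitting with standard errors.
- **Assay formulas**: doubling time `duration·log 2 / (log C_final − log
  C_initial)`, viability `% = test/control · 100`, and median/IQR summaries
  of marker-loss fluctuation analyses.
- **Synthetic data generators** for all of the above, with planted ground
  truth (motif coordinates and strands, true DE sets and fold changes,
  generating isotherm parameters) so every pipeline stage can be validated
  by recovery.

## Worked example

```python
import g4prom as g

# simulate 500 promoters: half enriched (2.0 planted motifs expected),
# half background (0.2), downstream-biased and mostly on the coding strand
cfg = g.PromoterSimConfig(n_genes=500, seed=1)
records, truth = g.gen_promoters(cfg, enriched_gene_fraction=0.5)

matches = g.find_g4_both_strands(records[0].seq, g.LOOSE_G4)
print(len(truth.motifs), len(matches))
# 487 0    -> 487 motifs planted overall; none in the first promoter

enriched = [gid for gid, flag in truth.enriched.items() if flag]
background = [gid for gid, flag in truth.enriched.items() if not flag]
res_e = g.cumulative_counts(records, enriched)
res_b = g.cumulative_counts(records, background)
print(round(res_e.curve.fraction_at_n[1], 3), round(res_b.curve.fraction_at_n[1], 3))
# 0.864 0.28  -> 86% of enriched vs 28% of background promoters carry >= 1 motif

counts_e = res_e.per_gene_counts.to_numpy()
counts_b = res_b.per_gene_counts.to_numpy()
d, p = g.ks_compare(counts_e, counts_b)
print(round(d, 3), p < 1e-10)
# 0.584 True  -> the two count distributions differ decisively
```

The same pipeline is available from the shell:

```sh
g4prom simulate --kind promoters --n-genes 500 --seed 1 --out-dir sim/
g4prom scan sim/promoters.fa --out-bed matches.bed --out-counts counts.tsv
g4prom profile sim/promoters.fa --out-profile profile.tsv --out-counts gene_counts.tsv
g4prom simulate --kind expression --n-genes 2000 --seed 1 --out-dir expr/
g4prom stats expr/expression_mutantA.tsv expr/expression_mutantB.tsv --out-json stats.json
g4prom fit-kd titration.csv --l-total 10e-9 --out-json fit.json
```

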