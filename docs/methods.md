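# Methods

## G4 motif model and matching convention

A putative G-quadruplex sequence is modelled as four guanine tracts of at
least `min_run = 3` consecutive G separated by three loops. Two loop
conventions are exposed: loops of 1–12 arbitrary bases (the loose
definition used for per-gene motif counts) and loops of at least one base
with no upper bound (used for sliding-window densities, where the 50-nt
window itself bounds the loops that can matter; the unbounded cap is set to
the scanned sequence length, which has no functional effect but keeps the
regular expression well behaved).

"The number of sequences of the form …" underdetermines a counting rule,
so the scanner fixes one and documents it:

- **Leftmost, non-overlapping.** Matches are taken scanning left to right;
  a reported match consumes its span and the next search starts after it.
  This is the native semantics of standard regex engines and is exactly
  reproducible.
- **Lazy loops.** Within a match, each loop is as short as possible (the
  decomposition is lexicographically minimal in loop lengths).
- **Maximal tracts.** A run of G is consumed whole by the tract it serves
  (possessive quantifier). A single long G-run therefore never splits into
  two tracts of the same motif, which would otherwise inflate counts on
  G-rich sequence degenerately.
- **N policy.** `N` is accepted in loops ("any base") but never inside a
  tract, which must be literal G. Input is case-insensitive; any symbol
  outside A/C/G/T/N is an error naming the offender.

Template-strand matches are found by scanning the reverse complement and
mapping spans back (`start' = L − end`), so `strand_class` is always
relative to the gene's own coding strand, not the reference strand.
Coordinates are 0-based half-open throughout.

The test suite checks this convention against an independent oracle that
enumerates all decompositions over maximal G-runs and applies the same
selection rule explicitly — exhaustively over every {A,G} string up to
length 24 and on random sequences — so the regex implementation and the
declared convention cannot drift apart silently.

## TSS profiles

Promoters are extracted as TSS ± flank (default 1,500 nt) and oriented
5'→3' along the gene, reverse-complementing minus-strand genes, so
"downstream" is always rightward of the array midpoint. Windows of 50 nt
sliding by 10 nt are labelled by their centre offset from the TSS. A window
counts a promoter when at least one match is *fully contained* in it on the
relevant strand; matches straddling a window edge do not count, consistent
with the interval-counting primitive used everywhere else. Densities are
fractions of the promoters analysed, so they are comparable across gene
sets of different size.

The cumulative motif-count curve is reported in complementary form — the
fraction of genes with **at least** n motifs within the TSS flank — so that
enrichment reads as an upward shift; the value at n = 0 is 1 by
construction and the curve is non-increasing.

## Expression filtering and gene-set statistics

Tables carry one row per gene: mean TPM per condition, PostFC (posterior
fold change, mutant over wild type) and PPDE (posterior probability of
differential expression), i.e. the output schema of an EBseq analysis; the
package consumes such tables and never re-derives the posteriors. The
expression filter keeps genes with TPM ≥ 1 in both conditions (inclusive by
default, strict `>` by flag, since both conventions appear in practice).
Dysregulated genes are those with PPDE ≥ 0.95 (inclusive), split by PostFC
direction; a gene at PostFC exactly 1 has no direction and is reported
separately as ambiguous.

Overlap between two dysregulated sets is tested with a one-sided Fisher
exact test — the exact hypergeometric upper tail of the observed overlap
given both set sizes and the universe — because enrichment is the only
scientifically meaningful direction for shared dysregulation; a two-sided
variant is available. The default universe is the genes passing the
expression filter in both tables. Count-distribution differences use the
two-sample, two-sided Kolmogorov–Smirnov statistic with the classic
asymptotic p-value (limiting Kolmogorov distribution evaluated at
√(nm/(n+m))·D, the convention of R's `ks.test` with `exact = FALSE`).
Fold-change concordance is the Spearman correlation of log₂ PostFC over a
selectable gene set: dysregulated in either mutant (default), in both, or
all shared genes — the selection is exposed because published analyses are
frequently ambiguous on this point. No multiple-testing correction is
applied; the statistics are reported raw.

**A calibration caveat.** Both tests are exact/conservative on discrete
data. With gene sets of a few hundred out of a few thousand genes the
hypergeometric overlap is effectively continuous and the attained type-I
error of the Fisher test sits near its nominal level (the calibration
benchmark uses a 10% null call rate over 5,000 genes for precisely this
reason). The KS test on small-integer count data, however, is intrinsically
conservative at any sample size — ties compress the null distribution of D
— so its attained rejection rate at nominal α = 0.05 is of order 1%. This
is a property of the test on this data type, not an implementation issue;
the calibration benchmark reports the measured rate rather than hiding it,
and power against the planted enrichment (2.0 vs 0.2 motifs per promoter,
500 genes per set) is essentially 100% despite the conservativeness.

## Binding isotherm

One-to-one binding of protein P to labelled DNA L at fixed total L (10 nM
in the assays this models) in the ligand-depletion regime uses the
quadratic mass-action solution, written in the numerically stable form
C = 2PL / [(P+L+K_d) + √((P+L+K_d)² − 4PL)] to avoid cancellation at small
bound fraction. Anisotropy mixes linearly between the free and bound end
states, valid when quantum yield is insensitive to binding. Fitting is
unweighted least squares (readings are replicate means; per-point weights
are used when replicate spreads are supplied) over (log K_d, r_free,
r_bound) — the log parameterisation enforces K_d > 0 — with tolerances of
1e-14 on the relative objective and steps. Initial values are r_free = min
reading, r_bound = max reading and K_d at the half-maximal grid point.
Standard errors come from the Gauss–Newton curvature at the optimum (delta
method for K_d). A series with zero dynamic range returns an explicit
`no-binding-detected` status rather than a meaningless K_d, and failed
optimisations are flagged, never silently returned.

## Assay formulas and fluctuation summaries

Doubling time is `duration · log 2 / (log C_final − log C_initial)`
(negative for declining cultures, which callers should flag rather than
average); viability is `test/control · 100`. Fluctuation analyses are
summarised by the median and interquartile range of per-clone loss
percentages, with quartiles by linear interpolation between order
statistics (the default of mainstream statistical environments; declared
because plotting-tool conventions differ).

## Synthetic data generators

The generators exist to make every pipeline stage testable by recovery;
their defaults are the package's declared study conditions.

- **Promoters.** Background sequence is i.i.d. with P(G) = P(C) = gc/2
  (default 0.5); no dinucleotide structure is modelled, which is sufficient
  for validating the scanner and the statistics but does not reproduce the
  CpG-island composition of real vertebrate promoters — conclusions about
  real promoter G4 density must come from real sequence. Planted motifs are
  canonical four-tract G₃ motifs with loops of 1–7 non-G bases. Enriched
  genes (a configurable fraction, default half) receive Poisson(2.0)
  motifs, background genes Poisson(0.2). Positions are offset from the TSS
  by a truncated geometric law (default success 0.005 per nt, mean ≈ 200
  nt), emulating clustering just downstream of the TSS without claiming a
  specific spatial law; motifs land on the coding strand with probability
  0.75. Planted motifs never overlap, are flanked by A/T guard bases, and
  any promoter whose random background would perturb the recorded match
  coordinates (checked by re-scanning) is resampled under a derived
  sub-seed — so the planted truth is recoverable verbatim by construction,
  and the recovery benchmark validates the coordinate bookkeeping of the
  whole chain rather than scanner sensitivity (which the oracle tests
  cover).
- **Expression tables.** Exactly the configured numbers of genes are truly
  DE in each mutant with a configured shared subset; shared true log₂ fold
  changes are bivariate normal (sd 1.5, correlation 0.8 by default), other
  DE genes independent, null genes near-zero (sd 0.1). PostFC is exactly
  2^lfc and mutant TPM is wild-type TPM (log-normal, location 3.0, scale
  1.2 — median ≈ 20 TPM, typical of expressed genes) scaled by PostFC.
  PPDE is simulated directly as Beta(α, 1) — concentrated near 1 for true
  DE genes (α = 80) and heavy-tailed-near-0 for null genes (α = 0.2,
  giving P(PPDE ≥ 0.95) ≈ 1%) — rather than re-implementing the posterior
  inference the tables emulate. The recovered Spearman correlation on
  shared dysregulated genes is expected slightly below the configured
  Pearson correlation of the generating normals (the population Spearman of
  a bivariate normal is (6/π)·asin(ρ/2) ≈ 0.787 at ρ = 0.8, further diluted
  by the few false-positive pairs), which the recovery benchmark bears out.
- **Titrations** evaluate the isotherm on a supplied grid and add Gaussian
  noise; noiseless generation inverts exactly under the fitter.
- **Fluctuation clones** follow a branching process: each division, each
  daughter cell independently and heritably converts with the per-division
  loss rate; the expected per-clone loss after g generations is
  1 − (1 − rate)^g (≈ 1.98% at rate 0.001 over 20 generations). This is a
  deliberately simple stand-in — no quantitative loss mechanism is implied —
  used only to exercise the summary statistics.

All generators are deterministic given their seed, with per-gene/per-clone
substreams derived from it so individual records do not depend on how many
others were generated.

## Benchmark problem sizes

The bundled benchmarks (`g4prom.benchmarks`, driven by the test suite and
`scripts/acceptance.py`) use: exhaustive scanner validation over all {A,G}
strings to length 24 plus 1,000 random 200-nt sequences; 500 promoters for
planted recovery and enrichment dominance; 1,000 replicates for each null
calibration (5,000 genes for the Fisher design; a 2,000-promoter count pool
resampled 500-vs-500 for the KS design); 20 seeds each for KS power,
Spearman recovery and noisy K_d recovery (12-point titrations spanning
K_d/100 to 100·K_d at 2%-of-range noise). These sizes make the Monte-Carlo
error small relative to every decision threshold while keeping a full run
in minutes on one CPU.

## Known limitations

- The scanner counts sequence motifs; it does not score thermodynamic G4
  stability (no G4Hunter/pqsfinder-style scoring) or predict folding
  topology, and RNA G4s are out of scope.
- The i.i.d. background model understates the G4 and GC clustering of real
  promoters; statistical power estimates on synthetic data therefore do not
  transfer to real genomes.
- The KS p-value is asymptotic; exact small-sample p-values are not
  implemented.
- Fisher overlap testing assumes a well-defined gene universe; the choice
  of universe materially affects p-values and is left explicit in the API.
- The binding model is strictly one-to-one; cooperative or competition
  binding requires a different model class.
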