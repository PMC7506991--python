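"""Promoter extraction and TSS profile tests, including naive-recount
oracles and the strand-swap / shift-equivariance / partition properties."""

import numpy as np
import pandas as pd
import pytest

from g4prom.profiles import (
    PromoterRecord,
    cumulative_counts,
    extract_promoters,
    gc_profile,
    metagene_density,
)
from g4prom.scan import (
    CODING,
    TEMPLATE,
    LOOSE_G4,
    DENSITY_G4,
    count_in_interval,
    find_g4_both_strands,
    revcomp,
)
from g4prom.simulate import PromoterSimConfig, gen_promoters


def naive_metagene(records, spec, window, step):
    """Per-promoter / per-window double loop over full-containment counts."""
    length = len(records[0].seq)
    starts = list(range(0, length - window + 1, step))
    coding = np.zeros(len(starts))
    template = np.zeros(len(starts))
    for rec in records:
        matches = find_g4_both_strands(rec.seq, spec)
        cod = [m for m in matches if m.strand_class == CODING]
        tem = [m for m in matches if m.strand_class == TEMPLATE]
        for i, lo in enumerate(starts):
            if count_in_interval(cod, (lo, lo + window)) > 0:
                coding[i] += 1
            if count_in_interval(tem, (lo, lo + window)) > 0:
                template[i] += 1
    return coding / len(records), template / len(records)


class TestExtractPromoters:
    genome = {"chr1": "AACCGGTTAA"}

    def test_plus_strand_slice(self):
        ann = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "tss": 5, "strand": "+"}]
        )
        (rec,) = extract_promoters(self.genome, ann, flank=3)
        assert rec.seq == self.genome["chr1"][2:8]

    def test_minus_strand_is_reverse_complement(self):
        ann = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "tss": 5, "strand": "-"}]
        )
        (rec,) = extract_promoters(self.genome, ann, flank=3)
        assert rec.seq == revcomp(self.genome["chr1"][2:8])

    def test_out_of_bounds_skip_and_clip(self):
        ann = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "tss": 1, "strand": "+"}]
        )
        with pytest.warns(UserWarning):
            assert extract_promoters(self.genome, ann, flank=3) == []
        (rec,) = extract_promoters(self.genome, ann, flank=3, out_of_bounds="clip")
        assert rec.seq == self.genome["chr1"][0:4]

    def test_missing_chromosome_warns_not_fatal(self):
        ann = pd.DataFrame(
            [
                {"gene_id": "g1", "chrom": "chrZ", "tss": 5, "strand": "+"},
                {"gene_id": "g2", "chrom": "chr1", "tss": 5, "strand": "+"},
            ]
        )
        with pytest.warns(UserWarning, match="chrZ"):
            recs = extract_promoters(self.genome, ann, flank=3)
        assert [r.gene_id for r in recs] == ["g2"]

    def test_malformed_strand_is_an_error(self):
        ann = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "tss": 5, "strand": "*"}]
        )
        with pytest.raises(ValueError, match="row 0"):
            extract_promoters(self.genome, ann, flank=3)

    def test_fasta_path_input_via_faidx(self, tmp_path):
        path = tmp_path / "genome.fa"
        path.write_text(">chr1\nAACCGGTTAA\n")
        ann = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "tss": 5, "strand": "+"}]
        )
        (rec,) = extract_promoters(str(path), ann, flank=3)
        assert rec.seq == "CCGGTT"

    def test_round_trip_through_concatenated_genome(self, small_promoters):
        records, _ = small_promoters
        spacer = "T" * 40
        chrom = spacer
        ann_rows = []
        for r in records[:20]:
            ann_rows.append(
                {
                    "gene_id": r.gene_id,
                    "chrom": "chrS",
                    "tss": len(chrom) + r.flank,
                    "strand": "+",
                }
            )
            chrom += r.seq + spacer
        extracted = extract_promoters({"chrS": chrom}, pd.DataFrame(ann_rows), flank=records[0].flank)
        by_id = {r.gene_id: r.seq for r in extracted}
        for r in records[:20]:
            assert by_id[r.gene_id] == r.seq


class TestCumulativeCounts:
    def test_zero_match_promoters(self):
        records = [PromoterRecord(f"g{i}", "+", 50, "AT" * 50) for i in range(5)]
        res = cumulative_counts(records, [r.gene_id for r in records], LOOSE_G4)
        assert res.curve.fraction_at_n[0] == 1.0
        assert res.curve.max_n == 0
        assert (res.per_gene_counts == 0).all()

    def test_counts_match_independent_recount(self, small_promoters):
        records, _ = small_promoters
        gene_ids = [r.gene_id for r in records]
        res = cumulative_counts(records, gene_ids, LOOSE_G4)
        for r in records:
            matches = find_g4_both_strands(r.seq, LOOSE_G4)
            assert res.per_gene_counts[r.gene_id] == count_in_interval(
                matches, (0, len(r.seq))
            )

    def test_curve_is_monotone_with_unit_head(self, small_promoters):
        records, _ = small_promoters
        res = cumulative_counts(records, [r.gene_id for r in records], LOOSE_G4)
        frac = res.curve.fraction_at_n
        assert frac[0] == 1.0
        assert (np.diff(frac) <= 0).all()
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_unknown_genes_reported_not_fatal(self, small_promoters):
        records, _ = small_promoters
        res = cumulative_counts(records, [records[0].gene_id, "nope"], LOOSE_G4)
        assert res.excluded == ["nope"]

    def test_enriched_dominates_background(self):
        cfg = PromoterSimConfig(
            n_genes=120, flank=400, planted_rate_enriched=2.0,
            planted_rate_background=0.2, seed=9,
        )
        records, truth = gen_promoters(cfg, enriched_gene_fraction=0.5)
        enriched = [g for g, f in truth.enriched.items() if f]
        background = [g for g, f in truth.enriched.items() if not f]
        res_e = cumulative_counts(records, enriched, LOOSE_G4)
        res_b = cumulative_counts(records, background, LOOSE_G4)
        n = min(res_e.curve.max_n, res_b.curve.max_n)
        assert (res_e.curve.fraction_at_n[1 : n + 1] >= res_b.curve.fraction_at_n[1 : n + 1]).all()
        assert res_e.curve.fraction_at_n[1] > res_b.curve.fraction_at_n[1]


class TestMetageneDensity:
    def test_no_g_no_c_promoters_give_zero(self):
        records = [PromoterRecord(f"g{i}", "+", 100, "AT" * 100) for i in range(4)]
        prof = metagene_density(records, [r.gene_id for r in records], window=50, step=10)
        assert (prof.coding_density == 0).all()
        assert (prof.template_density == 0).all()

    def test_planted_window_reaches_density_one(self):
        motif = "GGGAGGGAGGGAGGG"
        flank = 100
        seqs = []
        for i in range(6):
            base = list("AT" * flank)
            base[flank + 5 : flank + 5 + len(motif)] = list(motif)
            seqs.append("".join(base))
        records = [PromoterRecord(f"g{i}", "+", flank, s) for i, s in enumerate(seqs)]
        prof = metagene_density(records, [r.gene_id for r in records], window=50, step=10)
        # window [100,150) holds the motif [105,120) in every promoter
        idx = list(prof.positions).index(100 - flank + 25)
        assert prof.coding_density[idx] == 1.0
        assert prof.template_density[idx] == 0.0

    def test_matches_naive_double_loop(self, small_promoters):
        records, _ = small_promoters
        prof = metagene_density(records, [r.gene_id for r in records], window=50, step=10)
        coding, template = naive_metagene(records, DENSITY_G4, 50, 10)
        np.testing.assert_array_equal(prof.coding_density, coding)
        np.testing.assert_array_equal(prof.template_density, template)

    def test_strand_swap_reflects_and_exchanges(self, small_promoters):
        records, _ = small_promoters
        gene_ids = [r.gene_id for r in records]
        prof = metagene_density(records, gene_ids, window=50, step=10)
        flipped = [
            PromoterRecord(r.gene_id, r.gene_strand, r.tss, revcomp(r.seq)) for r in records
        ]
        prof_f = metagene_density(flipped, gene_ids, window=50, step=10)
        np.testing.assert_array_equal(prof_f.coding_density, prof.template_density[::-1])
        np.testing.assert_array_equal(prof_f.template_density, prof.coding_density[::-1])

    def test_shift_equivariance_by_one_step(self):
        motif = "GGGTGGGTGGGTGGG"
        flank, step = 150, 10
        rng = np.random.default_rng(5)
        recs, recs_shifted = [], []
        for i in range(10):
            background = "".join(rng.choice(list("AT"), size=2 * flank))
            pos = 40 + 7 * i
            s0 = background[:pos] + motif + background[pos + len(motif) :]
            s1 = (
                background[: pos + step]
                + motif
                + background[pos + step + len(motif) :]
            )
            recs.append(PromoterRecord(f"g{i}", "+", flank, s0))
            recs_shifted.append(PromoterRecord(f"g{i}", "+", flank, s1))
        ids = [r.gene_id for r in recs]
        p0 = metagene_density(recs, ids, window=50, step=step)
        p1 = metagene_density(recs_shifted, ids, window=50, step=step)
        np.testing.assert_array_equal(p1.coding_density[1:], p0.coding_density[:-1])

    def test_partition_average(self, small_promoters):
        records, _ = small_promoters
        ids = [r.gene_id for r in records]
        half = len(ids) // 2
        whole = metagene_density(records, ids, window=50, step=10)
        part1 = metagene_density(records, ids[:half], window=50, step=10)
        part2 = metagene_density(records, ids[half:], window=50, step=10)
        weighted = (part1.coding_density * half + part2.coding_density * (len(ids) - half)) / len(ids)
        np.testing.assert_allclose(whole.coding_density, weighted, atol=1e-12)

    def test_empty_gene_set_is_an_error(self, small_promoters):
        records, _ = small_promoters
        with pytest.raises(ValueError):
            metagene_density(records, [], window=50, step=10)


class TestGCProfile:
    def test_extreme_compositions(self):
        all_a = [PromoterRecord("a", "+", 100, "A" * 200)]
        all_g = [PromoterRecord("g", "+", 100, "G" * 200)]
        _, gc_a = gc_profile(all_a, ["a"], window=50, step=10)
        _, gc_g = gc_profile(all_g, ["g"], window=50, step=10)
        assert (gc_a == 0).all()
        assert (gc_g == 1).all()

    def test_mean_tracks_background_gc(self):
        cfg = PromoterSimConfig(
            n_genes=500, flank=300, gc_background=0.6,
            planted_rate_enriched=0.0, planted_rate_background=0.0, seed=7,
        )
        records, _ = gen_promoters(cfg, enriched_gene_fraction=0.5)
        _, gc = gc_profile(records, [r.gene_id for r in records], window=50, step=10)
        assert abs(gc.mean() - 0.6) < 0.02
        assert ((gc >= 0) & (gc <= 1)).all()

    def test_matches_naive_window_means(self, small_promoters):
        records, _ = small_promoters
        positions, gc = gc_profile(records, [r.gene_id for r in records], window=50, step=10)
        length = len(records[0].seq)
        naive = []
        for lo in range(0, length - 50 + 1, 10):
            vals = [
                sum(c in "GC" for c in r.seq[lo : lo + 50]) / 50 for r in records
            ]
            naive.append(np.mean(vals))
        np.testing.assert_allclose(gc, naive, atol=1e-12)
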