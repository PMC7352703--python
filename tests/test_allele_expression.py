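import numpy as np
import pytest
from scipy import stats

from endotx.allele_expression import (HARD_FILTER_THRESHOLDS, VariantSite,
                                      aaf, aaf_vector, ase_cascade,
                                      classify_het, classify_region,
                                      find_ssrs, hard_filter, imbalance_test,
                                      passes_hard_filter, positional_filter)
from endotx.genomic_core import GeneModel, GenomicInterval, TranscriptModel
from endotx.stats2x2 import chi2_2x2

MASKS = {"CTR": np.array([True] * 3 + [False] * 3),
         "LPS": np.array([False] * 3 + [True] * 3)}

GOOD_STATS = {"DP": 50.0, "MQ": 55.0, "QD": 10.0,
              "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


def site(chrom="chr1", pos=100, ref="A", alt="G", ref_counts=(10,) * 6,
         alt_counts=(5,) * 6, stats_=None, rsid=None):
    return VariantSite(chrom, pos, ref, alt, np.array(ref_counts),
                       np.array(alt_counts),
                       quality_stats=dict(GOOD_STATS if stats_ is None
                                          else stats_),
                       known_snp_id=rsid)


class TestHardFilter:
    def test_low_depth_dropped(self):
        s = site(stats_={**GOOD_STATS, "DP": 9})
        assert not passes_hard_filter(s)

    def test_exact_thresholds_kept(self):
        s = site(stats_={"DP": 10, "MQ": 40, "QD": 2,
                         "MQRankSum": -12.5, "ReadPosRankSum": -8})
        assert passes_hard_filter(s)

    def test_missing_ranksum_passes(self):
        s = site(stats_={"DP": 50, "MQ": 55, "QD": 10})
        assert passes_hard_filter(s)

    def test_missing_depth_fails(self):
        s = site(stats_={"MQ": 55, "QD": 10})
        assert not passes_hard_filter(s)

    def test_matches_brute_force_predicate(self, rng):
        sites = []
        for _ in range(300):
            stats_ = {"DP": float(rng.integers(1, 30)),
                      "MQ": float(rng.uniform(20, 60)),
                      "QD": float(rng.uniform(0, 10)),
                      "MQRankSum": float(rng.uniform(-20, 5)),
                      "ReadPosRankSum": float(rng.uniform(-12, 5))}
            sites.append(site(pos=int(rng.integers(1, 10_000)), stats_=stats_))
        survivors, drops = hard_filter(sites)
        want = [s for s in sites
                if all(s.quality_stats[k] >= t
                       for k, t in HARD_FILTER_THRESHOLDS.items())]
        assert [s.pos for s in survivors] == [s.pos for s in want]
        assert len(survivors) + sum(drops.values()) == len(sites)


def two_exon_gene(gid="g1", chrom="chr1", e1=(1000, 1200), e2=(1500, 1700),
                  strand="+", biotype="protein_coding", cds=None):
    exons = [GenomicInterval(chrom, *e1, strand), GenomicInterval(chrom, *e2, strand)]
    cds_ivs = [GenomicInterval(chrom, *c, strand) for c in (cds or [])]
    tx = TranscriptModel(f"{gid}.t", gid, exons, cds=cds_ivs, biotype=biotype)
    return GeneModel(gene_id=gid, transcripts=[tx], biotype=biotype)


class TestPositionalFilter:
    def test_junction_pad_boundary(self):
        gene = two_exon_gene()  # junction at exon end 1200 (0-based)
        # 4 bp inside the exon end -> within the 5 bp window -> dropped
        inside4 = site(pos=1200 - 4 + 1)   # 0-based 1196
        # 6 bp inside -> kept
        inside6 = site(pos=1200 - 6 + 1)   # 0-based 1194
        surv, _ = positional_filter([inside4, inside6], [gene], [], [])
        assert [s.pos for s in surv] == [inside6.pos]

    def test_bidirectional_overlap_dropped(self):
        plus = two_exon_gene("gp", e1=(1000, 1200), e2=(1500, 1700), strand="+")
        minus = two_exon_gene("gm", e1=(1100, 1300), e2=(1800, 2000), strand="-")
        inside = site(pos=1650 + 1)   # within both spans, away from junctions
        outside = site(pos=1750 + 1)  # only inside the minus gene intron
        surv, drops = positional_filter([inside, outside], [plus, minus], [], [])
        assert [s.pos for s in surv] == [outside.pos]
        assert drops["bidirectional"] == 1

    def test_paralog_padding(self):
        par = GenomicInterval("chr1", 5000, 5100)
        in_pad = site(pos=4951)      # 0-based 4950 = start - 50
        out_pad = site(pos=4950)     # 0-based 4949, one base further out
        surv, _ = positional_filter([in_pad, out_pad], [], [par], [])
        assert [s.pos for s in surv] == [out_pad.pos]

    def test_ssr_region_dropped(self):
        ssr = GenomicInterval("chr1", 300, 320)
        surv, _ = positional_filter([site(pos=301), site(pos=321)], [], [],
                                    [ssr])
        assert [s.pos for s in surv] == [321]

    def test_matches_brute_force_four_predicate_scan(self, rng,
                                                     small_annotation):
        from endotx.allele_expression import (_bidirectional_regions,
                                              _junction_windows)
        genes = small_annotation.genes
        paralog = small_annotation.paralog_intervals
        ssrs = [GenomicInterval(c, s, e)
                for c, s, e in small_annotation.truth.ssr_intervals]
        sites = [site(chrom=f"chr{rng.integers(1, 3)}",
                      pos=int(rng.integers(1, 40_000)))
                 for _ in range(500)]
        surv, _ = positional_filter(sites, genes, paralog, ssrs)

        junctions = _junction_windows(genes, 5)
        bidir = _bidirectional_regions(genes)
        want = []
        for s in sites:
            p = s.pos0
            if junctions.query_point(s.chrom, p):
                continue
            if bidir.query_point(s.chrom, p):
                continue
            if any(iv.chrom == s.chrom and iv.start - 50 <= p < iv.end + 50
                   for iv in paralog):
                continue
            if any(iv.chrom == s.chrom and iv.contains(p) for iv in ssrs):
                continue
            want.append(s)
        assert [x.pos for x in surv] == [x.pos for x in want]


class TestFindSsrs:
    def test_mononucleotide_run(self):
        rng = np.random.default_rng(123)
        seq = list(rng.choice(list("ACGT"), size=220))
        seq[100:112] = list("A" * 12)
        seq[99], seq[112] = "C", "G"  # keep the run exactly 12 bp
        (iv,) = find_ssrs("".join(seq), "chr1")
        assert (iv.start, iv.end) == (100, 112)

    def test_dinucleotide_below_threshold_ignored(self):
        assert find_ssrs("GGTT" + "AC" * 5 + "GGTT", "chr1") == []

    def test_dinucleotide_at_threshold_called(self):
        seq = "GGTT" + "AC" * 6 + "GGTT"
        (iv,) = find_ssrs(seq, "chr1")
        assert (iv.start, iv.end) == (4, 16)

    def test_n_breaks_repeat(self):
        assert find_ssrs("A" * 6 + "N" + "A" * 6, "chr1") == []

    def test_planted_ssrs_recovered_no_extras(self, rng):
        """20 planted repeats in random sequence: all recovered, no extras."""
        rng2 = np.random.default_rng(77)
        seq = list(rng2.choice(list("ACGT"), size=20_000))
        motifs = ["A", "AG", "ACT", "AGTC", "ACGTG", "AACGTC"]
        need = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
        planted = []
        for k in range(20):
            m = motifs[k % len(motifs)]
            copies = need[len(m)] + 2
            start = 900 * k + 100
            rep = m * copies
            seq[start:start + len(rep)] = list(rep)
            planted.append((start, start + len(rep)))
        found = find_ssrs("".join(seq), "chr1")
        for start, end in planted:
            assert any(iv.start <= start and iv.end >= end for iv in found), \
                (start, end)
        # no call outside a planted neighbourhood (random flanks may extend
        # a planted repeat by chance, so allow a small margin)
        for iv in found:
            assert any(abs(iv.start - s) <= 10 and abs(iv.end - e) <= 10
                       for s, e in planted), (iv.start, iv.end)


class TestAaf:
    @pytest.mark.parametrize("ref,alt,want", [
        (10, 0, 0.0), (8, 3, 3 / 11), (0, 5, 1.0),
    ])
    def test_fraction(self, ref, alt, want):
        s = site(ref_counts=(ref,) * 6, alt_counts=(alt,) * 6)
        assert aaf(s, 0) == pytest.approx(want)

    def test_zero_depth_undefined(self):
        s = site(ref_counts=(0, 10, 10, 10, 10, 10),
                 alt_counts=(0, 5, 5, 5, 5, 5))
        assert np.isnan(aaf(s, 0))
        assert np.isnan(aaf_vector(s)[0])


class TestImbalanceTest:
    def test_identical_groups_null(self):
        s = site(ref_counts=(10,) * 6, alt_counts=(10,) * 6)
        stat, p, delta = imbalance_test(s, MASKS, "CTR")
        assert stat == 0 and p == 1 and delta == 0

    def test_hand_computed_two_by_two(self):
        # CTR pooled (ref 50, alt 50) vs LPS pooled (ref 20, alt 80)
        s = site(ref_counts=(20, 15, 15, 10, 5, 5),
                 alt_counts=(20, 15, 15, 30, 25, 25))
        stat, p, delta = imbalance_test(s, MASKS, "CTR")
        assert stat == pytest.approx(19.78, abs=0.01)
        assert p == pytest.approx(8.7e-6, rel=0.02)
        assert delta == pytest.approx(0.30)

    def test_zero_marginal_degenerates(self):
        s = site(ref_counts=(0,) * 6, alt_counts=(5,) * 6)
        stat, p, _ = imbalance_test(s, MASKS, "CTR")
        assert stat == 0 and p == 1

    def test_closed_form_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 100, 4)
            stat, p = chi2_2x2(int(a), int(b), int(c), int(d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_sites_rarely_reach_editing_fdr(self):
        """Over 2000 null binomial sites the fraction passing FDR < 0.001
        is essentially zero."""
        from endotx.expression_de import bh_adjust
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(2000):
            af = rng.uniform(0.3, 0.7)
            alt = rng.binomial(60, af, 6)
            s = site(ref_counts=tuple(60 - alt), alt_counts=tuple(alt))
            _, p, _ = imbalance_test(s, MASKS, "CTR")
            pvals.append(p)
        fdr = bh_adjust(np.array(pvals))
        assert (fdr < 0.001).mean() <= 0.005


class TestClassifyHet:
    @pytest.mark.parametrize("aafs,want", [
        ([0.5] * 6, "true"), ([0.1] * 6, "heteroref"), ([0.9] * 6, "heteroalt"),
        ([0.4] * 6, "true"), ([0.6] * 6, "true"),
    ])
    def test_binning(self, aafs, want):
        assert classify_het(np.array(aafs)) == want

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            classify_het(np.array([np.nan] * 6))

    def test_classes_partition_any_fixture(self, rng):
        counts = {"heteroref": 0, "heteroalt": 0, "true": 0}
        n = 500
        for _ in range(n):
            counts[classify_het(rng.uniform(0, 1, 6))] += 1
        assert sum(counts.values()) == n


class TestClassifyRegion:
    def setup_method(self):
        # +strand coding gene: exon1 [1000,1200) with CDS from 1100,
        # exon2 [1500,1800) with CDS to 1700 (3'UTR [1700,1800))
        self.coding = two_exon_gene("gc", e1=(1000, 1200), e2=(1500, 1800),
                                    cds=[(1100, 1200), (1500, 1700)])
        self.nc = GeneModel(
            gene_id="gn", biotype="lncRNA",
            transcripts=[TranscriptModel(
                "gn.t", "gn", [GenomicInterval("chr1", 20_000, 20_500, "+")],
                biotype="lncRNA")])

    def test_cds_and_utrs(self):
        assert classify_region(site(pos=1151), [self.coding])[0] == "CDS"
        assert classify_region(site(pos=1051), [self.coding])[0] == "5'UTR"
        assert classify_region(site(pos=1751), [self.coding])[0] == "3'UTR"
        assert classify_region(site(pos=1351), [self.coding])[0] == "intron"

    def test_cds_beats_other_genes_intron(self):
        host = two_exon_gene("big", e1=(500, 600), e2=(3000, 3100))
        region, gene = classify_region(site(pos=1151), [host, self.coding])
        assert region == "CDS" and gene == "gc"

    def test_flank_boundary(self):
        # gene span ends at 1800 (0-based exclusive)
        just_in = site(pos=1800 + 4999 + 1)
        just_out = site(pos=1800 + 5001 + 1)
        assert classify_region(just_in, [self.coding])[0] == "downstream"
        assert classify_region(just_out, [self.coding])[0] == "intergenic"

    def test_strand_aware_flanks(self):
        minus = two_exon_gene("gm", e1=(1000, 1200), e2=(1500, 1800),
                              strand="-")
        assert classify_region(site(pos=500), [minus])[0] == "downstream"
        assert classify_region(site(pos=2500), [minus])[0] == "upstream"

    def test_ncrna_exon(self):
        assert classify_region(site(pos=20_101), [self.nc])[0] == "ncRNA"

    def test_annotation_string_vocabulary_maps_one_to_one(self):
        from endotx.rna_editing import ANNOTATION_TO_REGION
        assert ANNOTATION_TO_REGION["3_prime_UTR_variant"] == "UTR"
        assert ANNOTATION_TO_REGION["splice_region_variant&intron_variant"] \
            == "intron"
        assert ANNOTATION_TO_REGION["downstream_gene_variant"] == "downstream"
        assert ANNOTATION_TO_REGION["upstream_gene_variant"] == "upstream"


class TestAseCascade:
    def test_sparse_site_excluded_before_testing(self):
        s = site(ref_counts=(10, 10, 0, 0, 0, 0),
                 alt_counts=(5, 5, 0, 0, 0, 0))
        assert ase_cascade([s], MASKS, "CTR") == []

    def test_monotone_filtering(self, rng):
        """Adding the observation filter never increases the tested set."""
        sites = [site(pos=i + 1,
                      ref_counts=tuple(rng.integers(0, 30, 6)),
                      alt_counts=tuple(rng.integers(0, 30, 6)))
                 for i in range(200)]
        all_tested = ase_cascade(sites, MASKS, "CTR",
                                 min_observed_fraction=0.0)
        half_tested = ase_cascade(sites, MASKS, "CTR",
                                  min_observed_fraction=0.5)
        assert len(half_tested) <= len(all_tested)

    def test_spiked_sites_recovered(self):
        """AAF 0.2 vs 0.55 at depth 60: >= 80% of 300 spikes called ASE."""
        rng = np.random.default_rng(6)
        sites, truth = [], []
        for i in range(300):
            alt_c = rng.binomial(60, 0.2, 3)
            alt_t = rng.binomial(60, 0.55, 3)
            alt = np.concatenate([alt_c, alt_t])
            sites.append(site(pos=i + 1, ref_counts=tuple(60 - alt),
                              alt_counts=tuple(alt)))
            truth.append(i + 1)
        for i in range(700):  # null background
            af = rng.uniform(0.3, 0.7)
            alt = rng.binomial(60, af, 6)
            sites.append(site(pos=1000 + i, ref_counts=tuple(60 - alt),
                              alt_counts=tuple(alt)))
        calls = ase_cascade(sites, MASKS, "CTR")
        called = {c.site.pos for c in calls if c.is_ase}
        assert len(called & set(truth)) / len(truth) >= 0.8

    def test_null_run_emits_no_calls(self):
        """Zero-spike null config: ASE count at FDR 0.001 is <= 1 per 1000."""
        rng = np.random.default_rng(8)
        sites = []
        for i in range(1000):
            af = rng.uniform(0.3, 0.7)
            alt = rng.binomial(60, af, 6)
            sites.append(site(pos=i + 1, ref_counts=tuple(60 - alt),
                              alt_counts=tuple(alt)))
        calls = ase_cascade(sites, MASKS, "CTR")
        assert sum(c.is_ase for c in calls) <= 1

    def test_het_class_partitions_calls(self, rng):
        sites = [site(pos=i + 1,
                      ref_counts=tuple(rng.integers(1, 40, 6)),
                      alt_counts=tuple(rng.integers(1, 40, 6)))
                 for i in range(100)]
        calls = ase_cascade(sites, MASKS, "CTR")
        assert all(c.het_class in ("heteroref", "heteroalt", "true")
                   for c in calls)
        tally = {k: sum(c.het_class == k for c in calls)
                 for k in ("heteroref", "heteroalt", "true")}
        assert sum(tally.values()) == len(calls)
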