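"""Seven-way classification: flank arithmetic, precedence, and the
per-base painter oracle."""

import numpy as np
import pytest

from regcons.annotate import (
    RegionCategory,
    build_annotation_index,
    category_fractions,
    classify_peak,
    count_peak_overlaps,
    enrichment_histogram_stats,
    gene_region_ranges,
)
from regcons.io import GeneModel, GenomicInterval, ValidationError
from regcons.simulate import _make_gene, category_at, paint_categories
from tests.conftest import make_peak

CHROM_SIZES = {"chr1": 200_000}


def ranges_of(gene, cat, **kw):
    return sorted(
        (s, e) for s, e, c in gene_region_ranges(gene, chrom_size=200_000, **kw) if c is cat
    )


class TestFlankArithmetic:
    def test_plus_strand_upstream(self, plus_gene):
        assert ranges_of(plus_gene, RegionCategory.UPSTREAM_10KB) == [(10000, 20000)]
        assert ranges_of(plus_gene, RegionCategory.DOWNSTREAM_10KB) == [(25000, 35000)]

    def test_upstream_clamped_at_chromosome_start(self):
        g = GeneModel(
            "g", GenomicInterval("chr1", 4000, 9000, "+"), exons=((4000, 9000),)
        )
        assert ranges_of(g, RegionCategory.UPSTREAM_10KB) == [(0, 4000)]

    def test_minus_strand_flanks_flip(self, minus_gene):
        # - strand gene [40000,45000): upstream runs right of the TSS
        assert ranges_of(minus_gene, RegionCategory.UPSTREAM_10KB) == [(45000, 55000)]
        assert ranges_of(minus_gene, RegionCategory.DOWNSTREAM_10KB) == [(30000, 40000)]

    def test_utr_split_plus(self, plus_gene):
        assert ranges_of(plus_gene, RegionCategory.UTR5) == [(20000, 20500)]
        assert ranges_of(plus_gene, RegionCategory.UTR3) == [(24500, 25000)]
        assert ranges_of(plus_gene, RegionCategory.INTRON) == [(21500, 23000)]

    def test_utr_split_minus(self, minus_gene):
        # on - strand the 5'UTR sits at the high-coordinate end
        assert ranges_of(minus_gene, RegionCategory.UTR5) == [(44500, 45000)]
        assert ranges_of(minus_gene, RegionCategory.UTR3) == [(40000, 40500)]

    def test_noncoding_exons_count_as_exon_category(self, noncoding_gene):
        assert ranges_of(noncoding_gene, RegionCategory.CODING_EXON) == [
            (70000, 70800),
            (71200, 72000),
        ]
        assert ranges_of(noncoding_gene, RegionCategory.UTR5) == []


class TestClassification:
    def test_summit_upstream_of_lone_gene(self, plus_gene):
        index = build_annotation_index([plus_gene], CHROM_SIZES)
        cat, gene = classify_peak(make_peak("chr1", 14000, 16000), index)
        assert cat is RegionCategory.UPSTREAM_10KB and gene == "gplus"

    def test_summit_far_from_genes_is_other(self, plus_gene):
        index = build_annotation_index([plus_gene], CHROM_SIZES)
        cat, gene = classify_peak(make_peak("chr1", 120000, 121000), index)
        assert cat is RegionCategory.OTHER and gene is None

    def test_intron_beats_neighbor_upstream_flank(self, plus_gene):
        # neighbor whose upstream window covers plus_gene's intron
        neighbor = GeneModel(
            "gnb", GenomicInterval("chr1", 26000, 30000, "+"), exons=((26000, 30000),),
            cds_start=26500, cds_end=29500,
        )
        index = build_annotation_index([plus_gene, neighbor], CHROM_SIZES)
        cat, gene = classify_peak(make_peak("chr1", 22000, 22200, summit=22100), index)
        assert cat is RegionCategory.INTRON and gene == "gplus"

    def test_upstream_beats_downstream(self, plus_gene):
        follower = GeneModel(
            "gfo", GenomicInterval("chr1", 30000, 33000, "+"), exons=((30000, 33000),),
        )
        # 26000 is downstream of gplus (ends 25000) and upstream of gfo
        index = build_annotation_index([plus_gene, follower], CHROM_SIZES)
        cat, gene = classify_peak(make_peak("chr1", 25900, 26100), index)
        assert cat is RegionCategory.UPSTREAM_10KB and gene == "gfo"

    def test_tie_same_category_goes_to_nearest_tss(self):
        left = GeneModel("ga", GenomicInterval("chr1", 30000, 32000, "-"), exons=((30000, 32000),))
        right = GeneModel("gb", GenomicInterval("chr1", 40000, 42000, "+"), exons=((40000, 42000),))
        # 36000 is upstream of both; gb's TSS (40000) is 4000 away, ga's (31999) is 4001
        index = build_annotation_index([left, right], CHROM_SIZES)
        cat, gene = classify_peak(make_peak("chr1", 35900, 36100), index)
        assert cat is RegionCategory.UPSTREAM_10KB and gene == "gb"

    def test_gene_on_unknown_chromosome_rejected(self, plus_gene):
        with pytest.raises(ValidationError, match="unknown chromosome"):
            build_annotation_index([plus_gene], {"chr9": 1000})


class TestCategoryFractions:
    def test_planted_half_upstream_half_intron(self, plus_gene):
        index = build_annotation_index([plus_gene], CHROM_SIZES)
        peaks = [make_peak("chr1", 14000 + i, 14100 + i, name=f"u{i}") for i in range(5)]
        peaks += [make_peak("chr1", 22000 + i, 22100 + i, name=f"i{i}") for i in range(5)]
        fractions, counts = category_fractions(peaks, index)
        assert fractions[RegionCategory.UPSTREAM_10KB] == 0.5
        assert fractions[RegionCategory.INTRON] == 0.5
        assert sum(counts.values()) == 10
        assert abs(sum(fractions.values()) - 1.0) < 1e-9

    def test_empty_peak_list_rejected(self, plus_gene):
        index = build_annotation_index([plus_gene], CHROM_SIZES)
        with pytest.raises(ValidationError):
            category_fractions([], index)


class TestPainterOracle:
    """classify_peak must agree with the per-base brute-force painter."""

    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_on_crowded_genomes(self, seed):
        rng = np.random.default_rng(seed)
        size = 80_000
        chrom_sizes = {"c": size}
        genes, pos = [], 12_000
        k = 0
        while pos + 5_000 < size - 12_000:
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() > 0.2
            genes.append(_make_gene(f"g{k:02d}", "c", pos, strand, coding))
            pos += 4_800 + int(rng.integers(0, 6_000))  # flanks collide freely
            k += 1
        paint = paint_categories(genes, chrom_sizes)
        index = build_annotation_index(genes, chrom_sizes)
        for summit in rng.integers(0, size, size=300):
            summit = int(summit)
            got, _ = classify_peak(
                make_peak("c", max(0, summit - 10), summit + 11, summit=summit), index
            )
            assert got is category_at(paint, "c", summit), f"disagree at {summit}"

    def test_strand_mirror_antisymmetry(self):
        """Mirroring genes through the chromosome midpoint preserves categories."""
        size = 60_000
        gene = _make_gene("g", "c", 25_000, "+", True)
        mirrored = GeneModel(
            "g",
            GenomicInterval("c", size - gene.interval.end, size - gene.interval.start, "-"),
            exons=tuple(sorted((size - e, size - s) for s, e in gene.exons)),
            cds_start=size - gene.cds_end,
            cds_end=size - gene.cds_start,
        )
        fwd = build_annotation_index([gene], {"c": size})
        rev = build_annotation_index([mirrored], {"c": size})
        for summit in range(100, size - 100, 257):
            cat_f, _ = classify_peak(make_peak("c", summit - 5, summit + 6, summit=summit), fwd)
            m = size - 1 - summit
            cat_r, _ = classify_peak(make_peak("c", m - 5, m + 6, summit=m), rev)
            assert cat_f is cat_r, f"strand asymmetry at {summit}"


class TestPeakOverlaps:
    def test_basic_overlap(self):
        a = [make_peak("chr1", 100, 200)]
        b = [make_peak("chr1", 150, 250)]
        assert count_peak_overlaps(a, b) == (1, 1, 1)

    def test_half_open_abutment_does_not_overlap(self):
        a = [make_peak("chr1", 100, 200)]
        b = [make_peak("chr1", 200, 300)]
        assert count_peak_overlaps(a, b) == (0, 0, 0)

    def test_three_a_over_one_b(self):
        a = [make_peak("chr1", s, s + 50, name=f"a{s}") for s in (100, 120, 140)]
        b = [make_peak("chr1", 90, 200)]
        assert count_peak_overlaps(a, b) == (3, 1, 3)

    def test_min_overlap_threshold(self):
        a = [make_peak("chr1", 100, 200)]
        b = [make_peak("chr1", 195, 300)]
        assert count_peak_overlaps(a, b, min_overlap_bp=5) == (1, 1, 1)
        assert count_peak_overlaps(a, b, min_overlap_bp=6) == (0, 0, 0)


class TestEnrichmentStats:
    def test_moments_of_one_to_five(self):
        peaks = [make_peak("chr1", i * 10, i * 10 + 5, name=str(i), fe=float(i))
                 for i in range(1, 6)]
        res = enrichment_histogram_stats(peaks, bin_width=1.0)
        assert res.skewness == pytest.approx(0.0, abs=1e-12)
        assert res.kurtosis == pytest.approx(1.7)

    def test_half_open_bin_convention(self):
        peaks = [make_peak("chr1", i * 100, i * 100 + 50, name=str(i), fe=fe)
                 for i, fe in enumerate([12.0, 17.0, 15.0])]
        res = enrichment_histogram_stats(peaks, bin_width=5.0)
        h = res.histogram.set_index("bin_left")["count"]
        assert h[10.0] == 1  # [10,15): 12
        assert h[15.0] == 2  # [15,20): 15 and 17 (15 is left-closed)

    def test_zero_variance_rejected(self):
        peaks = [make_peak("chr1", i * 100, i * 100 + 50, name=str(i), fe=3.0)
                 for i in range(4)]
        with pytest.raises(ValidationError, match="variance"):
            enrichment_histogram_stats(peaks)
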