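"""Genomic-position classification of ChIP-seq peaks.

Each peak is assigned, by its summit base, to exactly one of seven
categories: up to 10 kb upstream of the TSS, 5'UTR, coding exon, intron,
3'UTR, up to 10 kb downstream of the transcript end, or "other" (distant
from every gene).  When a summit lies in ranges of several categories the
fixed precedence UTR5 > UTR3 > CODING_EXON > INTRON > UPSTREAM >
DOWNSTREAM applies; within a category the gene with the nearest TSS wins,
then the smallest gene id.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, Peak, ValidationError


class RegionCategory(enum.Enum):
    UPSTREAM_10KB = "upstream_10kb"
    UTR5 = "utr5"
    CODING_EXON = "coding_exon"
    INTRON = "intron"
    UTR3 = "utr3"
    DOWNSTREAM_10KB = "downstream_10kb"
    OTHER = "other"


#: Classification precedence, highest first (OTHER is the fallback).
PRECEDENCE: tuple[RegionCategory, ...] = (
    RegionCategory.UTR5,
    RegionCategory.UTR3,
    RegionCategory.CODING_EXON,
    RegionCategory.INTRON,
    RegionCategory.UPSTREAM_10KB,
    RegionCategory.DOWNSTREAM_10KB,
)

_RANK = {cat: i for i, cat in enumerate(PRECEDENCE)}


def gene_region_ranges(
    gene: GeneModel,
    upstream_bp: int = 10_000,
    downstream_bp: int = 10_000,
    chrom_size: int | None = None,
    noncoding_exons_as_exon: bool = True,
) -> list[tuple[int, int, RegionCategory]]:
    """Labeled half-open ranges contributed by one gene.

    Flanks are strand-aware (upstream runs off the TSS, downstream off the
    transcript end) and clipped at chromosome bounds.  Exons of CDS-less
    genes count as the exon category when ``noncoding_exons_as_exon``.
    """
    iv = gene.interval
    size = chrom_size if chrom_size is not None else np.iinfo(np.int64).max
    ranges: list[tuple[int, int, RegionCategory]] = []

    if iv.strand == "+":
        up = (max(0, iv.start - upstream_bp), iv.start)
        down = (iv.end, min(size, iv.end + downstream_bp))
    else:
        up = (iv.end, min(size, iv.end + upstream_bp))
        down = (max(0, iv.start - downstream_bp), iv.start)
    for (s, e), cat in ((up, RegionCategory.UPSTREAM_10KB), (down, RegionCategory.DOWNSTREAM_10KB)):
        if s < e:
            ranges.append((s, e, cat))

    # introns: gaps between merged exons
    for (s1, e1), (s2, _) in zip(gene.exons, gene.exons[1:]):
        if e1 < s2:
            ranges.append((e1, s2, RegionCategory.INTRON))

    if gene.is_coding:
        cs, ce = gene.cds_start, gene.cds_end
        left_utr = RegionCategory.UTR5 if iv.strand == "+" else RegionCategory.UTR3
        right_utr = RegionCategory.UTR3 if iv.strand == "+" else RegionCategory.UTR5
        for s, e in gene.exons:
            if s < cs:
                ranges.append((s, min(e, cs), left_utr))
            if max(s, cs) < min(e, ce):
                ranges.append((max(s, cs), min(e, ce), RegionCategory.CODING_EXON))
            if e > ce:
                ranges.append((max(s, ce), e, right_utr))
    elif noncoding_exons_as_exon:
        for s, e in gene.exons:
            ranges.append((s, e, RegionCategory.CODING_EXON))

    return ranges


class AnnotationIndex:
    """Interval store mapping genomic ranges to (category, gene)."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        chrom_sizes: Mapping[str, int],
        upstream_bp: int,
        downstream_bp: int,
        include_noncoding: bool,
    ):
        self.genes = list(genes)
        self.chrom_sizes = dict(chrom_sizes)
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        self._tss = np.array([g.tss for g in self.genes], dtype=np.int64)
        self._gene_ids = [g.gene_id for g in self.genes]

        rows: dict[str, list[tuple[int, int, int, int]]] = {}
        for gi, gene in enumerate(self.genes):
            chrom = gene.interval.chrom
            if chrom not in chrom_sizes:
                raise ValidationError(f"gene {gene.gene_id} on unknown chromosome {chrom}")
            if not include_noncoding and not gene.is_coding:
                continue
            for s, e, cat in gene_region_ranges(
                gene, upstream_bp, downstream_bp, chrom_sizes[chrom]
            ):
                rows.setdefault(chrom, []).append((s, e, _RANK[cat], gi))
        for chrom, recs in rows.items():
            arr = np.array(recs, dtype=np.int64)
            self._by_chrom[chrom] = {
                "start": arr[:, 0],
                "end": arr[:, 1],
                "rank": arr[:, 2],
                "gene": arr[:, 3],
            }

    def hits_at(self, chrom: str, pos: int) -> np.ndarray:
        """Indices (into the chrom table) of ranges containing pos."""
        tab = self._by_chrom.get(chrom)
        if tab is None:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero((tab["start"] <= pos) & (pos < tab["end"]))

    def best_at(self, chrom: str, pos: int) -> tuple[RegionCategory, str | None]:
        tab = self._by_chrom.get(chrom)
        idx = self.hits_at(chrom, pos)
        if idx.size == 0:
            return RegionCategory.OTHER, None
        ranks = tab["rank"][idx]
        genes = tab["gene"][idx]
        tss_dist = np.abs(self._tss[genes] - pos)
        keys = sorted(
            (int(r), int(d), self._gene_ids[g], int(g))
            for r, d, g in zip(ranks, tss_dist, genes)
        )
        rank, _, _, gi = keys[0]
        return PRECEDENCE[rank], self._gene_ids[gi]


def build_annotation_index(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    upstream_bp: int = 10_000,
    downstream_bp: int = 10_000,
    include_noncoding: bool = True,
) -> AnnotationIndex:
    """Build the classification substrate from validated gene models."""
    return AnnotationIndex(genes, chrom_sizes, upstream_bp, downstream_bp, include_noncoding)


def classify_peak(peak: Peak, index: AnnotationIndex) -> tuple[RegionCategory, str | None]:
    """Classify one peak by its summit position (total over valid peaks)."""
    return index.best_at(peak.chrom, peak.summit)


def classify_peaks(peaks: Sequence[Peak], index: AnnotationIndex) -> pd.DataFrame:
    """Annotated-peak table: chrom, start, end, name, summit, category, gene_id."""
    recs = []
    for p in peaks:
        cat, gene = classify_peak(p, index)
        recs.append(
            {
                "chrom": p.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "name": p.name,
                "summit": p.summit,
                "category": cat.value,
                "gene_id": gene if gene is not None else "",
            }
        )
    df = pd.DataFrame(
        recs, columns=["chrom", "start", "end", "name", "summit", "category", "gene_id"]
    )
    return df.sort_values(["chrom", "start", "name"], kind="stable").reset_index(drop=True)


def category_fractions(
    peaks: Sequence[Peak], index: AnnotationIndex
) -> tuple[dict[RegionCategory, float], dict[RegionCategory, int]]:
    """Fractions (and raw counts) of peaks per category, over all seven."""
    if not peaks:
        raise ValidationError("category_fractions needs at least one peak")
    counts = {cat: 0 for cat in RegionCategory}
    for p in peaks:
        cat, _ = classify_peak(p, index)
        counts[cat] += 1
    n = len(peaks)
    fractions = {cat: c / n for cat, c in counts.items()}
    return fractions, counts


def count_peak_overlaps(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak], min_overlap_bp: int = 1
) -> tuple[int, int, int]:
    """Count A peaks overlapping B, B peaks overlapping A, and distinct pairs.

    Overlap is measured in shared bases of the half-open intervals, so
    abutting peaks ([100,200) vs [200,300)) do not overlap.
    """
    by_chrom_b: dict[str, list[Peak]] = {}
    for p in peaks_b:
        by_chrom_b.setdefault(p.chrom, []).append(p)

    a_hit = np.zeros(len(peaks_a), dtype=bool)
    b_hit: dict[str, np.ndarray] = {
        c: np.zeros(len(ps), dtype=bool) for c, ps in by_chrom_b.items()
    }
    n_pairs = 0
    for ai, pa in enumerate(peaks_a):
        bs = by_chrom_b.get(pa.chrom)
        if not bs:
            continue
        starts = np.array([p.interval.start for p in bs])
        ends = np.array([p.interval.end for p in bs])
        ov = np.minimum(ends, pa.interval.end) - np.maximum(starts, pa.interval.start)
        mask = ov >= min_overlap_bp
        if mask.any():
            a_hit[ai] = True
            b_hit[pa.chrom] |= mask
            n_pairs += int(mask.sum())
    n_a = int(a_hit.sum())
    n_b = int(sum(m.sum() for m in b_hit.values()))
    return n_a, n_b, n_pairs


@dataclass(frozen=True)
class EnrichmentStats:
    histogram: pd.DataFrame  # bin_left, bin_right, count
    skewness: float
    kurtosis: float  # Pearson convention: normal distribution -> 3


def enrichment_histogram_stats(peaks: Sequence[Peak], bin_width: float = 5.0) -> EnrichmentStats:
    """Fold-enrichment histogram with moment skewness g1 and Pearson kurtosis g2.

    Bins are half-open ``[k*w, (k+1)*w)`` so a value of 15 with width 5
    falls in [15, 20).  g1 = m3/m2^1.5, g2 = m4/m2^2 (biased sample
    moments; a normal sample gives g2 near 3).
    """
    values = np.array(
        [p.fold_enrichment for p in peaks if p.fold_enrichment is not None], dtype=float
    )
    if values.size < 3:
        raise ValidationError("need >= 3 peaks with fold enrichment")
    if np.var(values) == 0:
        raise ValidationError("fold enrichment has zero variance")
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")

    idx = np.floor(values / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    hist = pd.DataFrame(
        {
            "bin_left": np.arange(n_bins) * bin_width,
            "bin_right": (np.arange(n_bins) + 1) * bin_width,
            "count": counts,
        }
    )
    g1 = float(stats.skew(values, bias=True))
    g2 = float(stats.kurtosis(values, fisher=False, bias=True))
    return EnrichmentStats(histogram=hist, skewness=g1, kurtosis=g2)
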