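"""Two-species synthetic dataset generator with a ground-truth manifest.

The generator emits everything the pipeline reads — genomes (FASTA), gene
models (GTF), peak tables (MACS-style TSV), conservation tracks (wiggle),
expression tables, ortholog and GO maps — with every analysis-relevant
property planted and recorded:

* peak summits are placed on bases whose genomic category is known from a
  per-base category painter (an implementation of the seven-way
  classification independent of the interval-index classifier, so the two
  can be checked against each other);
* motif content is planted at summits, and chance motif hits in peaks
  that are *not* supposed to contain a motif are mutated away, so motif
  frequencies are exact by construction at the stated >75% threshold;
* per-peak conservation window means are drawn from planted group means
  and written as constant-score windows, so window averaging recovers
  them exactly;
* the target set is computed from the realized peak placement, and the
  expressed / regulated / conserved-ortholog structure is built on top of
  it, so with noise off the full pipeline reproduces the manifest
  exactly.

All randomness flows from one numpy Generator seeded from the config, and
every stochastic choice is drawn in a fixed documented order, so a fixed
seed yields byte-identical output bundles.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as gio
from .annotate import RegionCategory
from .io import ExpressionRecord, GeneModel, GenomicInterval, Peak, ValidationError
from .motifs import PWM, build_palindrome_pwm, build_pwm, iupac_match_positions, revcomp, scan_sequence

# ---------------------------------------------------------------------------
# Defaults: the stated world
# ---------------------------------------------------------------------------

#: Aligned sites realizing the SOX consensus (A/T)(A/T)CAA(T/A)G.
DEFAULT_SOX_SITES: tuple[str, ...] = (
    "AACAATG", "AACAAAG", "ATCAATG", "ATCAAAG",
    "TACAATG", "TACAAAG", "TTCAATG", "TTCAAAG",
)

#: Roughly limb-bud-like genomic category mix (upstream-heavy but with a
#: large intronic and distal component).
DEFAULT_CATEGORY_FRACTIONS: dict[str, float] = {
    "upstream_10kb": 0.30,
    "utr5": 0.03,
    "coding_exon": 0.07,
    "intron": 0.25,
    "utr3": 0.05,
    "downstream_10kb": 0.10,
    "other": 0.20,
}

CCAAT = "CCAAT"

_BASES_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Painter codes: precedence rank (0 = highest) with OTHER = 6.
_CAT_RANK = {
    RegionCategory.UTR5: 0,
    RegionCategory.UTR3: 1,
    RegionCategory.CODING_EXON: 2,
    RegionCategory.INTRON: 3,
    RegionCategory.UPSTREAM_10KB: 4,
    RegionCategory.DOWNSTREAM_10KB: 5,
    RegionCategory.OTHER: 6,
}
_RANK_CAT = {v: k for k, v in _CAT_RANK.items()}


@dataclass
class MotifPlan:
    """Fractions of peaks carrying planted motif instances.

    Palindrome-planted peaks necessarily contain a single half-site too,
    so the single-site fraction seen by the scanner is
    ``frac_palindrome + frac_single_extra``.
    """

    frac_palindrome: float = 0.20
    frac_single_extra: float = 0.30
    frac_ccaat: float = 0.25


@dataclass
class ConservationPlan:
    """Two planted window-mean groups (conserved vs background)."""

    frac_high: float = 0.5
    mean_high: float = 0.6
    mean_low: float = 0.3
    sd: float = 0.15


@dataclass
class ExpressionPlan:
    """How many genes pass the expression filter and with what margins."""

    n_regulated: int = 20
    n_expressed_extra: int = 10  # expressed but not ChIP targets
    fpkm_lo: float = 2.0
    fpkm_hi: float = 50.0
    fc_lo: float = 2.0
    fc_hi: float = 6.0


@dataclass
class SpeciesConfig:
    name: str = "species"
    n_chromosomes: int = 5
    chrom_length: int = 200_000
    n_genes: int = 100
    n_peaks: int = 300
    peak_width: int = 500
    frac_noncoding: float = 0.10
    gc: float = 0.5
    category_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    motif: MotifPlan = field(default_factory=MotifPlan)
    conservation: ConservationPlan = field(default_factory=ConservationPlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)


@dataclass
class OrthologPlan:
    n_conserved_regulated: int = 8
    n_extra_pairs: int = 40  # ortholog pairs beyond the regulated-gene pairing
    go_term: str = "GO:0001501"
    frac_conserved_annotated: float = 0.3


@dataclass
class SyntheticConfig:
    seed: int = 0
    upstream_bp: int = 10_000
    downstream_bp: int = 10_000
    min_summit_separation: int = 750
    species_a: SpeciesConfig = field(default_factory=lambda: SpeciesConfig(name="mus"))
    species_b: SpeciesConfig = field(default_factory=lambda: SpeciesConfig(name="gallus"))
    ortholog: OrthologPlan = field(default_factory=OrthologPlan)

    def validate(self) -> None:
        for sp in (self.species_a, self.species_b):
            total = sum(sp.category_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{sp.name}: category fractions sum to {total}, not 1"
                )
            known = {c.value for c in RegionCategory}
            unknown = set(sp.category_fractions) - known
            if unknown:
                raise ValidationError(f"{sp.name}: unknown categories {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Per-base category painter (brute-force oracle)
# ---------------------------------------------------------------------------

def paint_categories(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    upstream_bp: int = 10_000,
    downstream_bp: int = 10_000,
) -> dict[str, np.ndarray]:
    """Paint every base of every chromosome with its best category rank.

    Painting proceeds from lowest to highest precedence so later strokes
    win; the result per base is the category the seven-way classification
    should assign to a summit at that base.  Deliberately independent of
    the interval-index classifier: the same rules, a different algorithm.
    """
    paint = {
        chrom: np.full(size, _CAT_RANK[RegionCategory.OTHER], dtype=np.uint8)
        for chrom, size in chrom_sizes.items()
    }

    def strokes(gene: GeneModel, rank: int) -> list[tuple[int, int]]:
        iv = gene.interval
        if rank == 5:  # downstream flank, off the transcript end
            if iv.strand == "+":
                return [(iv.end, min(chrom_sizes[iv.chrom], iv.end + downstream_bp))]
            return [(max(0, iv.start - downstream_bp), iv.start)]
        if rank == 4:  # upstream flank, off the TSS
            if iv.strand == "+":
                return [(max(0, iv.start - upstream_bp), iv.start)]
            return [(iv.end, min(chrom_sizes[iv.chrom], iv.end + upstream_bp))]
        if rank == 3:  # introns
            return [
                (e1, s2) for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:]) if e1 < s2
            ]
        if not gene.is_coding:
            # CDS-less genes: exons count as the exon category, no UTRs
            return list(gene.exons) if rank == 2 else []
        cs, ce = gene.cds_start, gene.cds_end
        if rank == 2:  # coding exon
            return [(max(s, cs), min(e, ce)) for s, e in gene.exons if max(s, cs) < min(e, ce)]
        left, right = ([], [])
        for s, e in gene.exons:
            if s < cs:
                left.append((s, min(e, cs)))
            if e > ce:
                right.append((max(s, ce), e))
        if rank == 1:  # 3'UTR: right of CDS on +, left on -
            return right if iv.strand == "+" else left
        return left if iv.strand == "+" else right  # rank 0: 5'UTR

    for rank in (5, 4, 3, 2, 1, 0):
        for gene in genes:
            arr = paint[gene.interval.chrom]
            for s, e in strokes(gene, rank):
                arr[s:e] = rank
    return paint


def category_at(paint: Mapping[str, np.ndarray], chrom: str, pos: int) -> RegionCategory:
    return _RANK_CAT[int(paint[chrom][pos])]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _largest_remainder(fractions: Mapping[str, float], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` following the given fractions."""
    keys = sorted(fractions)
    raw = {k: fractions[k] * total for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = total - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


_GENE_SPAN = 4600
_EXONS = ((0, 1200), (2000, 2600), (3400, 4600))  # relative to gene start


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, coding: bool
) -> GeneModel:
    """A three-exon gene; UTRs sit at the strand-appropriate ends."""
    exons = tuple((start + s, start + e) for s, e in _EXONS)
    if coding:
        if strand == "+":
            cds_start, cds_end = start + 400, start + 3800
        else:
            cds_start, cds_end = start + 800, start + 4200
    else:
        cds_start = cds_end = None
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, start + _GENE_SPAN, strand),
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        biotype="protein_coding" if coding else "non_coding",
        transcript_id=f"{gene_id}_t1",
    )


def plant_motif(
    genome_codes: Mapping[str, np.ndarray],
    planted: dict[str, list[tuple[int, int]]],
    chrom: str,
    pos: int,
    instance: str,
) -> None:
    """Overwrite genome bases with a motif instance; overlapping plants are errors."""
    arr = genome_codes[chrom]
    end = pos + len(instance)
    if pos < 0 or end > arr.size:
        raise ValidationError(f"plant at {chrom}:{pos} does not fit the chromosome")
    for s, e in planted.get(chrom, ()):
        if pos < e and s < end:
            raise ValidationError(
                f"plant at {chrom}:{pos}-{end} overlaps existing plant {s}-{e}"
            )
    codes = np.frombuffer(instance.upper().encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr[pos:end] = lut[codes]
    planted.setdefault(chrom, []).append((pos, end))


def _decode(codes: np.ndarray) -> str:
    return _BASES_ARR[codes].tobytes().decode("ascii")


def realize_expression_plan(
    plan: ExpressionPlan,
    gene_ids: Sequence[str],
    rng: np.random.Generator,
    expressed_ids: Sequence[str] | None = None,
) -> list[ExpressionRecord]:
    """Expression table in which exactly ``expressed_ids`` pass the filter.

    Planted-expressed genes get FPKM, fold change and q comfortably past
    the strict thresholds; every other gene violates one criterion
    (chosen at random): FPKM <= 1, fold change <= 1.5, or q >= 0.05.
    """
    if expressed_ids is None:
        n = plan.n_regulated + plan.n_expressed_extra
        order = rng.permutation(len(gene_ids))
        expressed_ids = [gene_ids[i] for i in order[:n]]
    expressed = set(expressed_ids)
    if not expressed <= set(gene_ids):
        raise ValidationError("expressed_ids must be a subset of gene_ids")
    records = []
    for gid in gene_ids:
        if gid in expressed:
            fpkm = rng.uniform(plan.fpkm_lo, plan.fpkm_hi)
            fc = rng.uniform(plan.fc_lo, plan.fc_hi)
            q = rng.uniform(1e-6, 0.049)
            rec = ExpressionRecord(gid, fpkm, fpkm / fc, q)
        else:
            mode = int(rng.integers(3))
            if mode == 0:  # FPKM criterion fails (<= 1.0)
                rec = ExpressionRecord(
                    gid, rng.uniform(0.0, 1.0), rng.uniform(0.0, 1.0), rng.uniform(0, 1)
                )
            elif mode == 1:  # fold-change criterion fails (<= 1.5)
                fpkm = rng.uniform(1.5, 20.0)
                rec = ExpressionRecord(
                    gid, fpkm, fpkm / rng.uniform(0.5, 1.5), rng.uniform(0, 1)
                )
            else:  # q criterion fails (>= 0.05)
                fpkm = rng.uniform(1.5, 20.0)
                rec = ExpressionRecord(
                    gid, fpkm, fpkm / rng.uniform(2.0, 6.0), rng.uniform(0.05, 1.0)
                )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Per-species generation
# ---------------------------------------------------------------------------

@dataclass
class _SpeciesBundle:
    config: SpeciesConfig
    genome_codes: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    peak_truth: list[dict]  # name, category, motif flags, conservation group/mean
    track_scores: dict[str, dict[int, float]]
    targets: list[str]

    def genome(self) -> dict[str, str]:
        return {c: _decode(codes) for c, codes in self.genome_codes.items()}


def _generate_species(
    sp: SpeciesConfig,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    monomer: PWM,
    composite: PWM,
) -> _SpeciesBundle:
    # 1. genome
    p_gc = sp.gc / 2
    probs = [(1 - sp.gc) / 2, p_gc, p_gc, (1 - sp.gc) / 2]  # A C G T
    genome_codes = {}
    chrom_sizes = {}
    for ci in range(sp.n_chromosomes):
        chrom = f"{sp.name}_chr{ci + 1}"
        genome_codes[chrom] = rng.choice(4, size=sp.chrom_length, p=probs).astype(np.uint8)
        chrom_sizes[chrom] = sp.chrom_length

    # 2. gene grid (strand alternates by chromosome; UTRs face the TSS)
    margin_left = cfg.upstream_bp + 2_000
    tail = cfg.upstream_bp + 15_000
    chroms = sorted(chrom_sizes)
    per_chrom = {c: sp.n_genes // sp.n_chromosomes for c in chroms}
    for c in chroms[: sp.n_genes % sp.n_chromosomes]:
        per_chrom[c] += 1
    genes: list[GeneModel] = []
    # planted count of non-coding genes (deterministic, not Bernoulli-drawn)
    n_noncoding = int(round(sp.frac_noncoding * sp.n_genes))
    coding_flags = np.ones(sp.n_genes, dtype=bool)
    coding_flags[rng.permutation(sp.n_genes)[:n_noncoding]] = False
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom[chrom]
        if n_here == 0:
            continue
        usable = sp.chrom_length - margin_left - tail
        pitch = usable // n_here
        if pitch < _GENE_SPAN + 200:
            raise ValidationError(
                f"{sp.name}/{chrom}: {n_here} genes do not fit "
                f"(pitch {pitch} < {_GENE_SPAN + 200})"
            )
        strand = "+" if ci % 2 == 0 else "-"
        for k in range(n_here):
            genes.append(
                _make_gene(
                    f"{sp.name}_g{gi:04d}",
                    chrom,
                    margin_left + k * pitch,
                    strand,
                    bool(coding_flags[gi]),
                )
            )
            gi += 1

    # 3. paint categories and place summits
    paint = paint_categories(genes, chrom_sizes, cfg.upstream_bp, cfg.downstream_bp)
    counts = _largest_remainder(sp.category_fractions, sp.n_peaks)
    edge = 300  # keeps conservation windows and peak intervals inside the chromosome
    summits_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    placements: list[tuple[str, int, str]] = []  # (chrom, summit, category)

    def separated(chrom: str, pos: int) -> bool:
        lst = summits_by_chrom[chrom]
        i = bisect_left(lst, pos)
        for j in (i - 1, i):
            if 0 <= j < len(lst) and abs(lst[j] - pos) < cfg.min_summit_separation:
                return False
        return True

    # scarcest categories first so packing succeeds
    order = ["utr5", "utr3", "coding_exon", "downstream_10kb", "other", "intron", "upstream_10kb"]
    for cat_name in order:
        need = counts.get(cat_name, 0)
        if need == 0:
            continue
        rank = _CAT_RANK[RegionCategory(cat_name)]
        cand_chroms = []
        cand_pos = []
        for chrom in chroms:
            pos = np.flatnonzero(paint[chrom][edge : sp.chrom_length - edge] == rank) + edge
            if pos.size:
                cand_chroms.append(chrom)
                cand_pos.append(pos)
        total = sum(p.size for p in cand_pos)
        if total == 0:
            raise ValidationError(
                f"{sp.name}: no bases painted {cat_name}; cannot place {need} peaks"
            )
        cum = np.cumsum([p.size for p in cand_pos])
        placed = 0
        tries = 0
        while placed < need:
            tries += 1
            if tries > 400 * need:
                raise ValidationError(
                    f"{sp.name}: cannot place {need} {cat_name} summits "
                    f"with {cfg.min_summit_separation} bp separation"
                )
            flat = int(rng.integers(total))
            ci = int(np.searchsorted(cum, flat, side="right"))
            chrom = cand_chroms[ci]
            pos = int(cand_pos[ci][flat - (cum[ci - 1] if ci else 0)])
            if not separated(chrom, pos):
                continue
            insort(summits_by_chrom[chrom], pos)
            placements.append((chrom, pos, cat_name))
            placed += 1

    # 4. peak intervals + fold enrichment (sorted by position for stable names)
    placements.sort(key=lambda t: (t[0], t[1]))
    peaks: list[Peak] = []
    peak_truth: list[dict] = []
    for i, (chrom, summit, cat_name) in enumerate(placements):
        jitter = int(rng.integers(-100, 101))
        start = summit - sp.peak_width // 2 + jitter
        start = max(0, min(start, summit))
        end = start + sp.peak_width
        if end > chrom_sizes[chrom]:
            end = chrom_sizes[chrom]
            start = end - sp.peak_width
        fe = float(rng.gamma(shape=12.0, scale=1.2))
        name = f"{sp.name}_p{i:04d}"
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), name=name, summit=summit, fold_enrichment=fe)
        )
        peak_truth.append({"name": name, "chrom": chrom, "summit": summit, "category": cat_name})

    # 5. motif plants
    n = sp.n_peaks
    n_pal = int(round(sp.motif.frac_palindrome * n))
    n_single_extra = int(round(sp.motif.frac_single_extra * n))
    n_ccaat = int(round(sp.motif.frac_ccaat * n))
    perm = rng.permutation(n)
    pal_idx = set(perm[:n_pal].tolist())
    single_idx = set(perm[n_pal : n_pal + n_single_extra].tolist())
    ccaat_idx = set(rng.permutation(n)[:n_ccaat].tolist())

    planted: dict[str, list[tuple[int, int]]] = {}
    protected: dict[str, set[int]] = {c: set() for c in chroms}

    def plant(chrom: str, pos: int, instance: str) -> None:
        plant_motif(genome_codes, planted, chrom, pos, instance)
        protected[chrom].update(range(pos, pos + len(instance)))

    sites = list(DEFAULT_SOX_SITES)
    for i, peak in enumerate(peaks):
        truth = peak_truth[i]
        truth["planted_palindrome"] = i in pal_idx
        truth["planted_single"] = (i in pal_idx) or (i in single_idx)
        truth["planted_ccaat"] = i in ccaat_idx
        chrom, summit = peak.chrom, peak.summit
        if i in pal_idx:
            site = sites[int(rng.integers(len(sites)))]
            spacer = _decode(rng.integers(0, 4, size=4).astype(np.uint8))
            inst = site + spacer + revcomp(site)
            plant(chrom, summit - len(inst) // 2, inst)
        elif i in single_idx:
            site = sites[int(rng.integers(len(sites)))]
            if rng.random() < 0.5:
                site = revcomp(site)
            plant(chrom, summit - len(site) // 2, site)
        if i in ccaat_idx:
            inst = CCAAT if rng.random() < 0.5 else revcomp(CCAAT)
            plant(chrom, summit + 40, inst)

    # 6. chance-hit cleanup: absence of a motif is a planted property too
    for i, peak in enumerate(peaks):
        _scrub_peak(
            genome_codes[peak.chrom],
            peak.interval.start,
            peak.interval.end,
            protected[peak.chrom],
            want_single=peak_truth[i]["planted_single"],
            want_pal=peak_truth[i]["planted_palindrome"],
            want_ccaat=peak_truth[i]["planted_ccaat"],
            monomer=monomer,
            composite=composite,
            rng=rng,
        )

    # 7. conservation: constant-score windows drawn from planted group means
    n_high = int(round(sp.conservation.frac_high * n))
    high_idx = set(rng.permutation(n)[:n_high].tolist())
    track_scores: dict[str, dict[int, float]] = {}
    for i, peak in enumerate(peaks):
        group = "high" if i in high_idx else "low"
        mu = sp.conservation.mean_high if group == "high" else sp.conservation.mean_low
        mean = float(np.clip(rng.normal(mu, sp.conservation.sd), 0.0, 1.0))
        peak_truth[i]["conservation_group"] = group
        peak_truth[i]["conservation_mean"] = mean
        chrom_scores = track_scores.setdefault(peak.chrom, {})
        for pos in range(peak.summit - 100, peak.summit + 101):
            chrom_scores[pos] = mean

    # 8. targets from the realized placement (independent span arithmetic)
    targets = []
    for gene in genes:
        if gene.biotype != "protein_coding":
            continue
        iv = gene.interval
        if iv.strand == "+":
            lo, hi = max(0, iv.start - cfg.upstream_bp), iv.end
        else:
            lo, hi = iv.start, min(chrom_sizes[iv.chrom], iv.end + cfg.upstream_bp)
        lst = summits_by_chrom[iv.chrom]
        if bisect_left(lst, hi) - bisect_left(lst, lo) > 0:
            targets.append(gene.gene_id)

    return _SpeciesBundle(
        config=sp,
        genome_codes=genome_codes,
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks=peaks,
        peak_truth=peak_truth,
        track_scores=track_scores,
        targets=sorted(targets),
    )


def _scrub_peak(
    chrom_codes: np.ndarray,
    start: int,
    end: int,
    protected: set[int],
    want_single: bool,
    want_pal: bool,
    want_ccaat: bool,
    monomer: PWM,
    composite: PWM,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate away chance motif hits a peak is not supposed to contain."""
    for _ in range(max_rounds):
        seq = _decode(chrom_codes[start:end])
        windows: list[tuple[int, int]] = []
        if not want_pal:
            windows += [(h.offset, len(composite)) for h in scan_sequence(composite, seq)]
        if not want_single:
            windows += [(h.offset, len(monomer)) for h in scan_sequence(monomer, seq)]
        if not want_ccaat:
            windows += [(off, len(CCAAT)) for off, _ in iupac_match_positions(seq, CCAAT)]
        if not windows:
            return
        for off, length in windows:
            free = [
                start + off + k
                for k in range(length)
                if (start + off + k) not in protected
            ]
            if not free:
                raise ValidationError("chance motif hit overlaps only planted bases")
            pos = free[int(rng.integers(len(free)))]
            shift = int(rng.integers(1, 4))
            chrom_codes[pos] = (chrom_codes[pos] + shift) % 4
    raise ValidationError("motif cleanup did not converge")


# ---------------------------------------------------------------------------
# Cross-species plan and bundle output
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[dict[str, Path], dict]:
    """Generate the full two-species bundle; returns (paths, manifest)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    monomer = build_pwm(list(DEFAULT_SOX_SITES), name="SOX_monomer")
    composite = build_palindrome_pwm(monomer, spacer=4).composite

    bundle_a = _generate_species(config.species_a, config, rng, monomer, composite)
    bundle_b = _generate_species(config.species_b, config, rng, monomer, composite)

    plan = config.ortholog
    reg = {}
    cons_genes = {}
    for key, bundle in (("A", bundle_a), ("B", bundle_b)):
        sp = bundle.config
        n_reg = sp.expression.n_regulated
        if len(bundle.targets) < n_reg:
            raise ValidationError(
                f"{sp.name}: only {len(bundle.targets)} targets realized, "
                f"need {n_reg} regulated genes"
            )
        order = rng.permutation(len(bundle.targets))
        chosen = [bundle.targets[i] for i in order[:n_reg]]
        cons_genes[key] = sorted(chosen[: plan.n_conserved_regulated])
        reg[key] = sorted(chosen)
    if plan.n_conserved_regulated > min(len(reg["A"]), len(reg["B"])):
        raise ValidationError("conserved-regulated plan exceeds regulated set size")

    # ortholog pairs: conserved pairs first, then 1:1 pairs that are never
    # conserved (at most one side regulated)
    pairs: list[tuple[str, str, str]] = [
        (a, b, "ortholog_one2one") for a, b in zip(cons_genes["A"], cons_genes["B"])
    ]
    all_a = sorted(g.gene_id for g in bundle_a.genes)
    all_b = sorted(g.gene_id for g in bundle_b.genes)
    rest_reg_a = [g for g in reg["A"] if g not in set(cons_genes["A"])]
    rest_reg_b = [g for g in reg["B"] if g not in set(cons_genes["B"])]
    nonreg_a = [g for g in all_a if g not in set(reg["A"])]
    nonreg_b = [g for g in all_b if g not in set(reg["B"])]
    rng.shuffle(nonreg_a)
    rng.shuffle(nonreg_b)
    for a, b in zip(rest_reg_a, nonreg_b):
        pairs.append((a, b, "ortholog_one2one"))
    used_b = {p[1] for p in pairs}
    nonreg_b_left = [g for g in nonreg_b if g not in used_b]
    for b, a in zip(rest_reg_b, nonreg_a):
        pairs.append((a, b, "ortholog_one2one"))
    used_a = {p[0] for p in pairs}
    nonreg_a_left = [g for g in nonreg_a if g not in used_a]
    for a, b in zip(nonreg_a_left[: plan.n_extra_pairs], nonreg_b_left[: plan.n_extra_pairs]):
        pairs.append((a, b, "ortholog_one2one"))
    omap = gio.OrthologMap(pairs)

    # expressed = regulated + non-target extras, per species
    expressed = {}
    expression_tables = {}
    for key, bundle in (("A", bundle_a), ("B", bundle_b)):
        sp = bundle.config
        non_targets = [
            g.gene_id for g in bundle.genes if g.gene_id not in set(bundle.targets)
        ]
        if len(non_targets) < sp.expression.n_expressed_extra:
            raise ValidationError(
                f"{sp.name}: not enough non-target genes for expressed extras"
            )
        order = rng.permutation(len(non_targets))
        extras = [non_targets[i] for i in order[: sp.expression.n_expressed_extra]]
        expressed[key] = sorted(set(reg[key]) | set(extras))
        gene_ids = [g.gene_id for g in bundle.genes]
        expression_tables[key] = realize_expression_plan(
            sp.expression, gene_ids, rng, expressed_ids=expressed[key]
        )

    # GO map: annotate a fraction of conserved A-side genes, plus decoys
    go_map: dict[str, set[str]] = {}
    n_annot = int(round(plan.frac_conserved_annotated * len(cons_genes["A"])))
    for g in cons_genes["A"][:n_annot]:
        go_map.setdefault(g, set()).add(plan.go_term)
    decoys = [g for g in all_a if g not in set(cons_genes["A"])]
    order = rng.permutation(len(decoys))
    for i in order[:5]:
        go_map.setdefault(decoys[i], set()).add("GO:0003006")

    # ---- write the bundle -------------------------------------------------
    paths: dict[str, Path] = {}
    for key, bundle in (("A", bundle_a), ("B", bundle_b)):
        sp_dir = out_dir / f"species_{key}"
        sp_dir.mkdir(exist_ok=True)
        gio.write_genome(bundle.genome(), sp_dir / "genome.fa")
        gio.write_gene_models(bundle.genes, sp_dir / "genes.gtf")
        gio.write_peak_table(bundle.peaks, sp_dir / "peaks.tsv", dialect="macs_tsv")
        gio.write_conservation_track(
            gio.ConservationTrack(bundle.track_scores), sp_dir / "conservation.wig"
        )
        gio.write_expression_table(expression_tables[key], sp_dir / "expression.tsv")
        for stem in ("genome.fa", "genes.gtf", "peaks.tsv", "conservation.wig", "expression.tsv"):
            paths[f"{key}/{stem}"] = sp_dir / stem
    gio.write_ortholog_map(omap, out_dir / "orthologs.tsv")
    gio.write_go_map(go_map, out_dir / "go_terms.tsv")
    paths["orthologs"] = out_dir / "orthologs.tsv"
    paths["go_terms"] = out_dir / "go_terms.tsv"

    manifest = _build_manifest(
        config, bundle_a, bundle_b, reg, expressed, cons_genes, omap, go_map, n_annot
    )
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    return paths, manifest


def _build_manifest(
    config: SyntheticConfig,
    bundle_a: _SpeciesBundle,
    bundle_b: _SpeciesBundle,
    reg: dict,
    expressed: dict,
    cons_genes: dict,
    omap: gio.OrthologMap,
    go_map: dict,
    n_go_annotated: int,
) -> dict:
    species = {}
    for key, bundle in (("A", bundle_a), ("B", bundle_b)):
        n = len(bundle.peaks)
        cat_counts: dict[str, int] = {c.value: 0 for c in RegionCategory}
        for t in bundle.peak_truth:
            cat_counts[t["category"]] += 1
        species[key] = {
            "name": bundle.config.name,
            "n_peaks": n,
            "n_genes": len(bundle.genes),
            "category_counts": cat_counts,
            "category_fractions": {k: v / n for k, v in cat_counts.items()},
            "motif_frequency_pct": {
                "single": 100.0 * sum(t["planted_single"] for t in bundle.peak_truth) / n,
                "palindrome": 100.0
                * sum(t["planted_palindrome"] for t in bundle.peak_truth) / n,
                "ccaat": 100.0 * sum(t["planted_ccaat"] for t in bundle.peak_truth) / n,
            },
            "peaks": bundle.peak_truth,
            "targets": bundle.targets,
            "expressed": expressed[key],
            "regulated": reg[key],
        }
    conserved_pairs = sorted(zip(cons_genes["A"], cons_genes["B"]))
    return {
        "seed": config.seed,
        "config": asdict(config),
        "species": species,
        "ortholog_pairs": [list(p) for p in omap.pairs],
        "conserved_pairs": [list(p) for p in conserved_pairs],
        "n_conserved": len(conserved_pairs),
        "go": {
            "term": config.ortholog.go_term,
            "n_conserved_a_annotated": n_go_annotated,
            "map": {g: sorted(t) for g, t in sorted(go_map.items())},
        },
    }
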