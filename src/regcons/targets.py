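"""Peak-to-gene target assignment and expression-filtered regulated sets.

A gene is a putative target when a ChIP-seq peak falls in its
cis-regulatory span: 10 kb upstream of the TSS through the end of the
transcript (3'UTR included, downstream flank excluded).  Membership is
summit-based by default, mirroring the annotator; an any-overlap mode is
available for sensitivity analysis.  Genes passing the expression filter
(cell FPKM > 1.0, fold change over whole embryo > 1.5, q < 0.05, all
strict) and carrying a peak are the regulated set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import ExpressionRecord, GeneModel, GenomicInterval, Peak, ValidationError


def cis_regulatory_span(
    gene: GeneModel,
    upstream_bp: int = 10_000,
    chrom_size: int | None = None,
) -> GenomicInterval:
    """10 kb upstream of the TSS through the transcript end (strand-aware)."""
    iv = gene.interval
    if iv.strand == "+":
        start = max(0, iv.start - upstream_bp)
        end = iv.end
    else:
        start = iv.start
        end = iv.end + upstream_bp
        if chrom_size is not None:
            end = min(end, chrom_size)
    return GenomicInterval(iv.chrom, start, end)


@dataclass(frozen=True)
class TargetAssignment:
    """A putative target gene and the peaks supporting it."""

    gene_id: str
    peaks: tuple[str, ...]

    @property
    def putative_target(self) -> bool:
        return len(self.peaks) > 0


def assign_putative_targets(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream_bp: int = 10_000,
    mode: str = "summit",
    protein_coding_only: bool = True,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, TargetAssignment]:
    """Map each gene to the peaks inside its cis-regulatory span.

    A peak may support several genes whose spans overlap.  ``mode``
    chooses summit membership (default) or any-bp interval overlap.
    Only protein-coding genes are considered by default.
    """
    if mode not in ("summit", "overlap"):
        raise ValidationError(f"unknown assignment mode {mode!r}")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    out: dict[str, TargetAssignment] = {}
    for gene in genes:
        if protein_coding_only and gene.biotype != "protein_coding":
            continue
        size = chrom_sizes.get(gene.interval.chrom) if chrom_sizes else None
        span = cis_regulatory_span(gene, upstream_bp=upstream_bp, chrom_size=size)
        supporting = []
        for p in by_chrom.get(span.chrom, ()):
            if mode == "summit":
                hit = span.contains(p.summit)
            else:
                hit = span.overlap_bp(p.interval) > 0
            if hit:
                supporting.append(p.name)
        if supporting:
            out[gene.gene_id] = TargetAssignment(gene.gene_id, tuple(sorted(supporting)))
    return out


def call_highly_expressed(
    records: Iterable[ExpressionRecord],
    fpkm_min: float = 1.0,
    fc_min: float = 1.5,
    q_max: float = 0.05,
) -> frozenset[str]:
    """Genes passing FPKM > fpkm_min, fold change > fc_min and q < q_max.

    All three comparisons are strict.  A zero whole-embryo denominator
    with positive cell expression counts as infinite induction (passes
    the fold-change criterion).
    """
    passed = set()
    for r in records:
        if not r.fpkm_cell > fpkm_min:
            continue
        if r.fpkm_whole_embryo == 0:
            fc = float("inf") if r.fpkm_cell > 0 else 0.0
        else:
            fc = r.fpkm_cell / r.fpkm_whole_embryo
        if not fc > fc_min:
            continue
        if not r.q_value < q_max:
            continue
        passed.add(r.gene_id)
    return frozenset(passed)


@dataclass(frozen=True)
class RegulatedGeneSet:
    """ChIP-bound and highly expressed genes for one cell type."""

    species: str
    genes: frozenset[str]
    n_targets: int
    n_expressed: int

    @property
    def n_regulated(self) -> int:
        return len(self.genes)


def call_regulated(
    target_genes: Iterable[str],
    expressed_genes: Iterable[str],
    species: str = "",
) -> RegulatedGeneSet:
    """Intersection of putative targets with highly expressed genes."""
    targets = frozenset(target_genes)
    expressed = frozenset(expressed_genes)
    return RegulatedGeneSet(
        species=species,
        genes=targets & expressed,
        n_targets=len(targets),
        n_expressed=len(expressed),
    )
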