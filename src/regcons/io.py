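"""Readers and writers for the genomic text formats the pipeline touches.

Every coordinate held in memory is 0-based half-open, regardless of the
source format.  1-based sources (GTF/GFF3, wiggle) are shifted on read and
unshifted on write, so all interval arithmetic downstream happens in a
single frame.

Formats handled: BED3+/BED12, MACS-style peak TSV, GTF/GFF3, FASTA,
wiggle (fixedStep/variableStep), bedGraph, and headered TSVs for
expression values, ortholog pairs, and GO annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not follow the layout its dialect promises."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq binding region with its summit and enrichment metadata."""

    interval: GenomicInterval
    name: str
    summit: int
    fold_enrichment: float | None = None
    call_stats: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"peak {self.name}: summit {self.summit} outside "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.fold_enrichment is not None and self.fold_enrichment < 0:
            raise ValidationError(f"peak {self.name}: negative fold enrichment")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """One representative transcript per gene.

    ``exons`` are merged, sorted, pairwise disjoint sub-intervals of
    ``interval``; ``cds_start``/``cds_end`` bound the coding region when the
    gene is protein coding.  The TSS is the strand-dependent end of the
    transcript interval.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "protein_coding"
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: gene models must be stranded")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.interval.start <= s < e <= self.interval.end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside transcript bounds"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"gene {self.gene_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.interval.start <= self.cds_start < self.cds_end <= self.interval.end):
                raise ValidationError(f"gene {self.gene_id}: CDS outside transcript")
            if not any(s <= self.cds_start < e for s, e in self.exons) or not any(
                s < self.cds_end <= e for s, e in self.exons
            ):
                raise ValidationError(f"gene {self.gene_id}: CDS bounds not in exons")

    @property
    def tss(self) -> int:
        """Transcription start site: interval.start on +, interval.end-1 on -."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


class ConservationTrack:
    """Sparse per-base conservation scores in [0, 1].

    Positions absent from the source file have *no* score at this layer;
    the distinction between "missing" and 0 is resolved downstream.
    """

    def __init__(self, scores: Mapping[str, Mapping[int, float]]):
        self._pos: dict[str, np.ndarray] = {}
        self._score: dict[str, np.ndarray] = {}
        for chrom, chrom_scores in scores.items():
            if not chrom_scores:
                continue
            pos = np.fromiter(chrom_scores.keys(), dtype=np.int64)
            val = np.fromiter(chrom_scores.values(), dtype=np.float64)
            order = np.argsort(pos)
            pos, val = pos[order], val[order]
            if val.size and (val.min() < 0.0 or val.max() > 1.0):
                bad = val[(val < 0) | (val > 1)][0]
                raise ValidationError(f"conservation score {bad} outside [0, 1] on {chrom}")
            self._pos[chrom] = pos
            self._score[chrom] = val

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._pos))

    def get(self, chrom: str, pos: int) -> float | None:
        """Score at a single base, or None when the base is unscored."""
        arr = self._pos.get(chrom)
        if arr is None:
            return None
        i = np.searchsorted(arr, pos)
        if i < arr.size and arr[i] == pos:
            return float(self._score[chrom][i])
        return None

    def n_scored(self, chrom: str, start: int, end: int) -> int:
        arr = self._pos.get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))

    def sum_in(self, chrom: str, start: int, end: int) -> float:
        """Sum of stored scores over [start, end)."""
        arr = self._pos.get(chrom)
        if arr is None:
            return 0.0
        lo, hi = np.searchsorted(arr, start), np.searchsorted(arr, end)
        return float(self._score[chrom][lo:hi].sum())

    def items(self, chrom: str) -> Iterable[tuple[int, float]]:
        pos = self._pos.get(chrom, np.empty(0, dtype=np.int64))
        val = self._score.get(chrom, np.empty(0))
        return zip(pos.tolist(), val.tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConservationTrack):
            return NotImplemented
        if set(self._pos) != set(other._pos):
            return False
        return all(
            np.array_equal(self._pos[c], other._pos[c])
            and np.allclose(self._score[c], other._score[c], atol=1e-9)
            for c in self._pos
        )


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression: cell FPKM, whole-embryo FPKM and a q-value."""

    gene_id: str
    fpkm_cell: float
    fpkm_whole_embryo: float
    q_value: float

    def __post_init__(self) -> None:
        if self.fpkm_cell < 0 or self.fpkm_whole_embryo < 0:
            raise ValidationError(f"{self.gene_id}: negative FPKM")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"{self.gene_id}: q-value {self.q_value} outside [0, 1]")


class OrthologMap:
    """Many-to-many gene pairing between species A and species B."""

    def __init__(self, pairs: Iterable[tuple[str, str] | tuple[str, str, str]]):
        seen: dict[tuple[str, str], str] = {}
        for rec in pairs:
            a, b = rec[0], rec[1]
            htype = rec[2] if len(rec) > 2 else "ortholog"
            seen.setdefault((a, b), htype)
        self._pairs = seen
        self._a2b: dict[str, set[str]] = {}
        self._b2a: dict[str, set[str]] = {}
        for a, b in seen:
            self._a2b.setdefault(a, set()).add(b)
            self._b2a.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._pairs))

    def homology_type(self, a: str, b: str) -> str:
        return self._pairs[(a, b)]

    def partners_of_a(self, a: str) -> frozenset[str]:
        return frozenset(self._a2b.get(a, ()))

    def partners_of_b(self, b: str) -> frozenset[str]:
        return frozenset(self._b2a.get(b, ()))

    def genes_a(self) -> frozenset[str]:
        return frozenset(self._a2b)

    def genes_b(self) -> frozenset[str]:
        return frozenset(self._b2a)

    def restricted(self, homology_types: Iterable[str]) -> "OrthologMap":
        keep = set(homology_types)
        return OrthologMap(
            (a, b, t) for (a, b), t in self._pairs.items() if t in keep
        )


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")

MACS_REQUIRED = ("chrom", "start", "end", "summit")


def read_peak_table(path: str | Path, dialect: str = "bed") -> list[Peak]:
    """Read a peak table in BED (>=3 columns) or MACS-style TSV layout.

    BED rows have no summit column; the summit defaults to the interval
    midpoint.  MACS-style rows carry the summit as an offset from ``start``
    (``summit`` column), plus optional ``fold_enrichment`` and arbitrary
    extra columns preserved as ``call_stats``.
    """
    path = Path(path)
    if dialect == "bed":
        return _read_bed_peaks(path)
    if dialect == "macs_tsv":
        return _read_macs_peaks(path)
    raise FormatError(f"unknown peak-table dialect {dialect!r}")


def _read_bed_peaks(path: Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"peak_{lineno}"
            fe = None
            if len(cols) > 4 and cols[4] not in ("", "."):
                try:
                    fe = float(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score column") from exc
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    name=name,
                    summit=(start + end) // 2,
                    fold_enrichment=fe,
                )
            )
    return peaks


def _read_macs_peaks(path: Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {"chr": "chrom", "-10*log10(pvalue)": "neg_log10_pvalue", "fdr(%)": "fdr_pct"}
    df = df.rename(columns=aliases)
    for col in MACS_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: macs_tsv is missing required column {col!r}")
    peaks: list[Peak] = []
    known = {"chrom", "start", "end", "summit", "name", "fold_enrichment", "length"}
    extra_cols = [c for c in df.columns if c not in known]
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        start, end = int(rec["start"]), int(rec["end"])
        if start >= end:
            raise FormatError(f"{path}: row {i}: start >= end ({start} >= {end})")
        name = str(rec.get("name") or f"peak_{i - 1}")
        fe = rec.get("fold_enrichment")
        fe = None if fe is None or pd.isna(fe) else float(fe)
        stats = {c: float(rec[c]) for c in extra_cols if pd.notna(rec[c])}
        peaks.append(
            Peak(
                GenomicInterval(str(rec["chrom"]), start, end),
                name=name,
                summit=start + int(rec["summit"]),
                fold_enrichment=fe,
                call_stats=stats,
            )
        )
    return peaks


def write_peak_table(peaks: Sequence[Peak], path: str | Path, dialect: str = "macs_tsv") -> None:
    """Write peaks; macs_tsv preserves summit/enrichment, bed does not."""
    path = Path(path)
    peaks = sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.name))
    if dialect == "bed":
        with open(path, "w") as fh:
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}\n")
    elif dialect == "macs_tsv":
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tlength\tsummit\tname\tfold_enrichment\n")
            for p in peaks:
                fe = "" if p.fold_enrichment is None else f"{p.fold_enrichment:.6g}"
                fh.write(
                    f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                    f"{p.interval.length}\t{p.summit - p.interval.start}\t{p.name}\t{fe}\n"
                )
    else:
        raise FormatError(f"unknown peak-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, fmt: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF, GFF3 or BED12 into one model per gene.

    When a gene has several transcripts, the transcript with the longest
    genomic span is kept; ties break to the lexicographically smallest
    transcript id.  Exons are merged and sorted.  Genes without CDS are
    flagged non-coding (unless the source names a biotype).
    """
    path = Path(path)
    if fmt in ("gtf", "gff3"):
        return _read_gxf(path, fmt)
    if fmt == "bed12":
        return _read_bed12(path)
    raise FormatError(f"unknown gene-model format {fmt!r}")


def _read_gxf(path: Path, fmt: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript id -> gene id (explicit transcript features, GFF3 Parent chains)
    tx2gene: dict[str, str] = {}
    tx_bounds: dict[str, tuple[int, int]] = {}
    tx_biotype: dict[str, str] = {}
    for ftype in ("transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            tid = _attr(f, "transcript_id") or _attr(f, "ID")
            gid = _attr(f, "gene_id") or _attr(f, "Parent")
            if tid and gid:
                tx2gene[tid] = gid
                tx_bounds[tid] = (f.start - 1, f.end)
            bt = _attr(f, "gene_biotype") or _attr(f, "biotype")
            if tid and bt:
                tx_biotype[tid] = bt

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (chrom, strand)
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for f in db.features_of_type(ftype):
            tid = _attr(f, "transcript_id") or _attr(f, "Parent")
            if tid is None:
                raise FormatError(f"{path}: {ftype} feature without transcript id/Parent")
            gid = _attr(f, "gene_id") or tx2gene.get(tid)
            if gid is None:
                raise FormatError(f"{path}: {ftype} of {tid} has no gene id")
            tx2gene.setdefault(tid, gid)
            bt = _attr(f, "gene_biotype") or _attr(f, "biotype")
            if bt:
                tx_biotype.setdefault(tid, bt)
            store.setdefault(tid, []).append((f.start - 1, f.end))
            meta.setdefault(tid, (f.seqid, f.strand))

    models: dict[str, GeneModel] = {}
    for tid, tx_exons in exons.items():
        gid = tx2gene[tid]
        chrom, strand = meta[tid]
        merged = merge_intervals(tx_exons)
        lo, hi = merged[0][0], merged[-1][1]
        if tid in tx_bounds:
            blo, bhi = tx_bounds[tid]
            if lo < blo or hi > bhi:
                raise ValidationError(
                    f"gene {gid}: exon outside transcript bounds of {tid}"
                )
            lo, hi = blo, bhi
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        biotype = tx_biotype.get(
            tid, "protein_coding" if cds_start is not None else "non_coding"
        )
        model = GeneModel(
            gene_id=gid,
            interval=GenomicInterval(chrom, lo, hi, strand),
            exons=tuple(merged),
            cds_start=cds_start,
            cds_end=cds_end,
            biotype=biotype,
            transcript_id=tid,
        )
        models[tid] = model

    return _select_transcripts(models.values())


def _attr(feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def _read_bed12(path: Path) -> list[GeneModel]:
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            strand = cols[5]
            thick_start, thick_end = int(cols[6]), int(cols[7])
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = merge_intervals(
                [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            )
            coding = thick_end > thick_start
            models.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=tuple(exons),
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                    biotype="protein_coding" if coding else "non_coding",
                    transcript_id=name,
                )
            )
    return _select_transcripts(models)


def _select_transcripts(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Longest-genomic-span transcript per gene; ties to smallest transcript id."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key = (-m.interval.length, m.transcript_id or "")
        cur_key = (-cur.interval.length, cur.transcript_id or "")
        if key < cur_key:
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting half-open intervals into a sorted list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive on disk)."""
    with open(Path(path), "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id)):
            tid = g.transcript_id or f"{g.gene_id}_t1"
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                f'gene_biotype "{g.biotype}";'
            )
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tregcons\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{iv.chrom}\tregcons\texon\t{s + 1}\t{e}\t.\t{iv.strand}\t.\t{attrs}\n"
                )
            if g.is_coding:
                for s, e in g.exons:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{iv.chrom}\tregcons\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{iv.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as a chrom -> sequence dict (case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(genome[chrom]), id=chrom, description="")
        for chrom in sorted(genome)
    ]
    SeqIO.write(records, str(path), "fasta")


def chrom_sizes_of(genome: Mapping[str, str]) -> dict[str, int]:
    return {chrom: len(seq) for chrom, seq in genome.items()}


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------

def read_conservation_track(path: str | Path, fmt: str | None = None) -> ConservationTrack:
    """Read a wiggle (fixedStep/variableStep) or bedGraph conservation track.

    Wiggle positions are 1-based on disk and shifted to the 0-based frame;
    bedGraph is already 0-based half-open.  Scores must lie in [0, 1].
    """
    path = Path(path)
    if fmt is None:
        fmt = "bedgraph" if path.suffix.lower() in (".bedgraph", ".bg") else "wig"
    if fmt not in ("wig", "bedgraph"):
        raise FormatError(f"unknown conservation format {fmt!r}")

    scores: dict[str, dict[int, float]] = {}

    def put(chrom: str, pos0: int, span: int, value: float, lineno: int) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{path}:{lineno}: score {value} outside [0, 1]")
        chrom_scores = scores.setdefault(chrom, {})
        for p in range(pos0, pos0 + span):
            chrom_scores[p] = value

    if fmt == "bedgraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(_SKIP_PREFIXES):
                    continue
                cols = line.split()
                if len(cols) < 4:
                    raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
                start, end = int(cols[1]), int(cols[2])
                if start >= end:
                    raise FormatError(f"{path}:{lineno}: start >= end")
                put(cols[0], start, end - start, float(cols[3]), lineno)
        return ConservationTrack(scores)

    mode = chrom = None
    step = span = 1
    nxt = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            if line.startswith("fixedStep"):
                kv = _wig_header(line)
                mode, chrom = "fixed", kv["chrom"]
                nxt = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
            elif line.startswith("variableStep"):
                kv = _wig_header(line)
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
            elif mode == "fixed":
                put(chrom, nxt, span, float(line), lineno)
                nxt += step
            elif mode == "variable":
                cols = line.split()
                if len(cols) != 2:
                    raise FormatError(f"{path}:{lineno}: variableStep needs 'pos value'")
                put(chrom, int(cols[0]) - 1, span, float(cols[1]), lineno)
            else:
                raise FormatError(f"{path}:{lineno}: data before wiggle header")
    return ConservationTrack(scores)


def _wig_header(line: str) -> dict[str, str]:
    return dict(tok.split("=", 1) for tok in line.split()[1:])


def write_conservation_track(track: ConservationTrack, path: str | Path) -> None:
    """Write a track as variableStep wiggle (1-based on disk)."""
    with open(Path(path), "w") as fh:
        for chrom in track.chroms:
            fh.write(f"variableStep chrom={chrom}\n")
            for pos, val in track.items(chrom):
                fh.write(f"{pos + 1}\t{val:.10g}\n")


# ---------------------------------------------------------------------------
# Expression / ortholog / GO tables
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ("gene_id", "fpkm_cell", "fpkm_whole_embryo", "q_value")


def _read_headered_tsv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    df = _read_headered_tsv(Path(path), EXPRESSION_COLUMNS)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate gene rows: {sorted(set(dup))[:5]}")
    return [
        ExpressionRecord(
            gene_id=str(r.gene_id),
            fpkm_cell=float(r.fpkm_cell),
            fpkm_whole_embryo=float(r.fpkm_whole_embryo),
            q_value=float(r.q_value),
        )
        for r in df.itertuples(index=False)
    ]


def write_expression_table(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            fh.write(
                f"{r.gene_id}\t{r.fpkm_cell:.6g}\t{r.fpkm_whole_embryo:.6g}\t"
                f"{r.q_value:.6g}\n"
            )


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = _read_headered_tsv(Path(path), ("gene_a", "gene_b"))
    has_type = "homology_type" in df.columns
    return OrthologMap(
        (str(r.gene_a), str(r.gene_b), str(r.homology_type) if has_type else "ortholog")
        for r in df.itertuples(index=False)
    )


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("gene_a\tgene_b\thomology_type\n")
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\t{omap.homology_type(a, b)}\n")


def read_go_map(path: str | Path) -> dict[str, frozenset[str]]:
    df = _read_headered_tsv(Path(path), ("gene_id", "go_term"))
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.gene_id), set()).add(str(r.go_term))
    return {g: frozenset(t) for g, t in out.items()}


def write_go_map(go_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("gene_id\tgo_term\n")
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping | None = None,
) -> list[Path]:
    """Write report tables as deterministic TSVs plus a JSON run summary.

    Row order must already be stable in each frame (callers sort by
    chrom/start/gene_id); writing the same report twice yields
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        p = out_dir / f"{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
    if summary is not None:
        p = out_dir / "run_summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
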