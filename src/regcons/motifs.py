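"""Position-weight-matrix construction and both-strand scanning.

PWMs here are *count* matrices: weight(i, base) is the number of aligned
binding sites showing that base at position i.  A window's raw score is
the sum of the weights of its bases, and the relative score is that raw
score as a percentage of the maximum attainable score (the consensus
scores 100).  Hits are windows whose relative score is strictly above the
threshold (default 75), searched on the plus strand and, via the
reverse-complemented matrix, on the minus strand.

A palindromic dimer motif (the footprint of a transcription-factor
homodimer such as SOX9) is composed from a monomer half-site PWM, a
score-neutral spacer (default 4 bp), and the reverse complement of the
half-site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Peak, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC nucleotide codes -> the set of plain bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PWM:
    """Per-position nonnegative base weights with relative-score semantics."""

    def __init__(self, weights: np.ndarray, name: str = "motif"):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != 4:
            raise ValidationError("PWM weights must have shape (L, 4)")
        if (weights < 0).any():
            raise ValidationError("PWM weights must be nonnegative")
        self.weights = weights
        self.name = name
        self.max_score = float(weights.max(axis=1).sum())
        self.min_score = float(weights.min(axis=1).sum())
        if not self.max_score > self.min_score:
            raise ValidationError("degenerate PWM: max_score must exceed min_score")

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-weight base per position (ties break to ACGT order)."""
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.weights[::-1, ::-1].copy(), name=f"{self.name}_rc")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return self.weights.shape == other.weights.shape and np.allclose(
            self.weights, other.weights
        )


def build_pwm(aligned_sites: Sequence[str], name: str = "motif") -> PWM:
    """Count matrix from equal-length aligned ACGT sites (case-folded)."""
    if not aligned_sites:
        raise ValidationError("need at least one aligned site")
    length = len(aligned_sites[0])
    if any(len(s) != length for s in aligned_sites):
        raise ValidationError("aligned sites have unequal lengths")
    weights = np.zeros((length, 4))
    for site in aligned_sites:
        for i, base in enumerate(site.upper()):
            if base not in _BASE_INDEX:
                raise ValidationError(f"non-ACGT character {base!r} in site {site!r}")
            weights[i, _BASE_INDEX[base]] += 1
    return PWM(weights, name=name)


def _encode(seq: str) -> np.ndarray:
    """Sequence -> base codes; non-ACGT (N etc.) become -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def relative_score(pwm: PWM, window: str) -> float:
    """Percent-of-maximum score of one window (consensus scores 100)."""
    if len(window) != len(pwm):
        raise ValidationError(
            f"window length {len(window)} != PWM length {len(pwm)}"
        )
    codes = _encode(window)
    if (codes < 0).any():
        raise ValidationError(f"non-ACGT character in window {window!r}")
    raw = float(pwm.weights[np.arange(len(pwm)), codes].sum())
    return 100.0 * raw / pwm.max_score


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold window, in plus-strand coordinates."""

    seq_name: str
    offset: int
    strand: str
    score: float


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Relative scores of all windows; windows containing non-ACGT get -inf."""
    L = len(pwm)
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    raw = pwm.weights[np.arange(L)[None, :], safe].sum(axis=1)
    rel = 100.0 * raw / pwm.max_score
    rel[~valid] = -np.inf
    return rel


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold: float = 75.0,
    strands: str = "both",
    seq_name: str = "",
) -> list[MotifHit]:
    """All windows scoring strictly above threshold on the requested strands.

    Minus-strand hits are windows whose reverse complement matches the
    motif; their offsets are reported in plus-strand coordinates.
    Windows containing non-ACGT characters are skipped.
    """
    if strands not in ("both", "+", "-"):
        raise ValidationError(f"invalid strands setting {strands!r}")
    codes = _encode(seq)
    hits: list[MotifHit] = []
    if strands in ("both", "+"):
        scores = _window_scores(pwm, codes)
        for off in np.flatnonzero(scores > threshold):
            hits.append(MotifHit(seq_name, int(off), "+", float(scores[off])))
    if strands in ("both", "-"):
        scores = _window_scores(pwm.reverse_complement(), codes)
        for off in np.flatnonzero(scores > threshold):
            hits.append(MotifHit(seq_name, int(off), "-", float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass(frozen=True)
class PalindromeMotif:
    """Two inverted monomer half-sites around a score-neutral spacer."""

    monomer: PWM
    spacer: int
    composite: PWM


def build_palindrome_pwm(monomer: PWM, spacer: int = 4) -> PalindromeMotif:
    """Compose monomer + spacer + reverse-complemented monomer.

    Spacer columns carry uniform weights (each base gets a quarter of the
    largest monomer column total), so every spacer base contributes the
    column maximum and the spacer is score-neutral: any half-site pair at
    the right distance scores as if the spacer were absent.
    """
    if spacer < 0:
        raise ValidationError("spacer must be nonnegative")
    col_total = float(monomer.weights.sum(axis=1).max())
    spacer_block = np.full((spacer, 4), col_total / 4.0)
    composite = np.vstack(
        [monomer.weights, spacer_block, monomer.weights[::-1, ::-1]]
    )
    return PalindromeMotif(
        monomer=monomer,
        spacer=spacer,
        composite=PWM(composite, name=f"{monomer.name}_palindrome"),
    )


def extract_peak_sequence(
    peak: Peak,
    genome: Mapping[str, str],
    window: str = "peak",
    summit_flank: int = 50,
) -> str:
    """Sequence under a peak: the whole interval, or summit +/- flank."""
    if peak.chrom not in genome:
        raise ValidationError(f"peak {peak.name}: chromosome {peak.chrom} not in genome")
    chrom_seq = genome[peak.chrom]
    if window == "peak":
        lo, hi = peak.interval.start, peak.interval.end
    elif window == "summit50":
        lo = max(0, peak.summit - summit_flank)
        hi = min(len(chrom_seq), peak.summit + summit_flank + 1)
    else:
        raise ValidationError(f"unknown scan window {window!r}")
    if hi > len(chrom_seq):
        raise ValidationError(
            f"peak {peak.name} extends beyond end of {peak.chrom} "
            f"({hi} > {len(chrom_seq)})"
        )
    return chrom_seq[lo:hi]


def scan_peaks(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float = 75.0,
    window: str = "peak",
) -> pd.DataFrame:
    """Hit table over peaks: peak, offset (within scanned window), strand, score."""
    recs = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.name)):
        seq = extract_peak_sequence(p, genome, window=window)
        for h in scan_sequence(pwm, seq, threshold=threshold, seq_name=p.name):
            recs.append(
                {"peak": p.name, "offset": h.offset, "strand": h.strand, "score": h.score}
            )
    return pd.DataFrame(recs, columns=["peak", "offset", "strand", "score"])


def motif_peak_frequency(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float = 75.0,
    window: str = "peak",
) -> float:
    """Percent of peaks containing at least one above-threshold hit."""
    if not peaks:
        raise ValidationError("motif_peak_frequency needs at least one peak")
    n_hit = 0
    for p in peaks:
        seq = extract_peak_sequence(p, genome, window=window)
        if scan_sequence(pwm, seq, threshold=threshold):
            n_hit += 1
    return 100.0 * n_hit / len(peaks)


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for code in pattern.upper():
        if code not in IUPAC:
            raise ValidationError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences all count
    return re.compile(f"(?={''.join(parts)})")


def iupac_match_count(seq: str, pattern: str) -> int:
    """Occurrences of an IUPAC pattern on both strands (overlaps allowed)."""
    rx = _iupac_regex(pattern)
    fwd = len(rx.findall(seq.upper()))
    rev = len(rx.findall(revcomp(seq).upper()))
    return fwd + rev


def iupac_match_positions(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Plus-strand start offsets of matches on each strand.

    Minus-strand matches are reported by the plus-strand start of the
    matched window, mirroring scan_sequence conventions.
    """
    rx = _iupac_regex(pattern)
    n, L = len(seq), len(pattern)
    out = [(m.start(), "+") for m in rx.finditer(seq.upper())]
    for m in rx.finditer(revcomp(seq).upper()):
        out.append((n - m.start() - L, "-"))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme(path) -> dict[str, PWM]:
    """Read PWMs from MEME minimal format (probabilities x nsites -> counts)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out: dict[str, PWM] = {}
    for m in parsed:
        weights = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        out[m.name] = PWM(weights, name=m.name)
    return out


def write_meme(pwms: Iterable[PWM], path) -> None:
    """Write PWMs as MEME minimal format with uniform background."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            totals = pwm.weights.sum(axis=1)
            nsites = int(round(totals.max())) or 1
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= {nsites} E= 0\n"
            )
            for row, total in zip(pwm.weights, totals):
                probs = row / total if total > 0 else np.full(4, 0.25)
                fh.write(" ".join(f"{p:.6f}" for p in probs) + "\n")
            fh.write("\n")
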