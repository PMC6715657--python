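"""Evolutionary-conservation scoring of summit-centered windows.

Each peak gets the mean per-base conservation score (phastCons-style,
in [0, 1]) over the window summit +/- flank (201 bases for the default
flank of 100).  Bases without a stored score count as 0 — unaligned bases
carry no evidence of conservation — and the denominator is the full
(chromosome-clipped) window length.  Distributions are summarized in
fixed-width bins and two peak sets are compared with the Mann-Whitney
U rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ConservationTrack, Peak, ValidationError


def peak_average_conservation(
    track: ConservationTrack,
    peak: Peak,
    flank: int = 100,
    chrom_size: int | None = None,
) -> float:
    """Mean score over [summit-flank, summit+flank], clipped at chromosome bounds."""
    lo = max(0, peak.summit - flank)
    hi = peak.summit + flank + 1
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    denom = hi - lo
    return track.sum_in(peak.chrom, lo, hi) / denom


#: Default bin edges matching 0.2-wide conservation classes.
DEFAULT_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _bin_edges(bin_width: float) -> np.ndarray:
    """Exact-looking bin edges over [0, 1]; rounding keeps k*0.2 boundaries
    free of accumulated float error so boundary values bin by convention."""
    n_bins = int(round(1.0 / bin_width))
    if abs(n_bins * bin_width - 1.0) > 1e-9 or n_bins < 1:
        raise ValidationError("bin width must evenly divide [0, 1]")
    edges = np.round(np.arange(n_bins + 1) * bin_width, 12)
    edges[-1] = 1.0
    return edges


def score_distribution(
    means: Sequence[float],
    bin_width: float = 0.2,
    left_closed: bool = True,
) -> np.ndarray:
    """Fractions of values per fixed-width bin over [0, 1].

    With ``left_closed`` (default) bins are [0,0.2), ..., [0.8,1.0] — the
    last bin is closed, so 0.8 belongs to the top bin.  With
    ``left_closed=False`` the convention flips to (0,0.2], ..., (0.8,1.0]
    with the first bin closed at 0.
    """
    values = np.asarray(means, dtype=float)
    if values.size == 0:
        raise ValidationError("score_distribution needs at least one value")
    if (values < 0).any() or (values > 1).any():
        raise ValidationError("conservation means must lie in [0, 1]")
    edges = _bin_edges(bin_width)
    n_bins = edges.size - 1
    side = "right" if left_closed else "left"
    idx = np.clip(np.searchsorted(edges[1:], values, side=side), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / values.size


@dataclass(frozen=True)
class ConservationSummary:
    """Per-peak window means, their binned distribution, and the grand mean."""

    peak_means: Mapping[str, float]
    bin_fractions: np.ndarray
    bin_edges: tuple[float, ...]
    grand_mean: float


def summarize_conservation(
    track: ConservationTrack,
    peaks: Sequence[Peak],
    flank: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
    bin_width: float = 0.2,
    left_closed: bool = True,
) -> ConservationSummary:
    if not peaks:
        raise ValidationError("summarize_conservation needs at least one peak")
    means: dict[str, float] = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.name)):
        size = chrom_sizes.get(p.chrom) if chrom_sizes else None
        means[p.name] = peak_average_conservation(track, p, flank=flank, chrom_size=size)
    vals = np.array(list(means.values()))
    return ConservationSummary(
        peak_means=means,
        bin_fractions=score_distribution(vals, bin_width=bin_width, left_closed=left_closed),
        bin_edges=tuple(_bin_edges(bin_width)),
        grand_mean=float(vals.mean()),
    )


@dataclass(frozen=True)
class RankTestResult:
    u: float  # U statistic of the first sample
    z: float  # normal approximation with tie and continuity correction
    p: float  # two-sided (or one-sided when requested)
    method: str  # "normal" or "exact"


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> RankTestResult:
    """Mann-Whitney U from midranks, with a tie- and continuity-corrected
    normal approximation.

    ``method="auto"`` switches to exact enumeration (no ties, min sample
    size <= 8); ``"normal"``/``"exact"`` force the choice.  When both
    samples are constant and identical the test is degenerate and p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"invalid alternative {alternative!r}")

    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)

    if var <= 0:
        # both samples constant and equal: no evidence either way
        return RankTestResult(u=float(u1), z=0.0, p=1.0, method="normal")

    diff = u1 - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)

    use_exact = method == "exact" or (
        method == "auto" and not has_ties and min(n1, n2) <= 8
    )
    if use_exact:
        if has_ties:
            raise ValidationError("exact method requires tie-free samples")
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        return RankTestResult(u=float(u1), z=float(z), p=float(res.pvalue), method="exact")

    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return RankTestResult(u=float(u1), z=float(z), p=float(min(p, 1.0)), method="normal")
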