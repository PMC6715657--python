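# Methods

## Coordinate conventions

All in-memory coordinates are 0-based half-open. GTF/GFF3 and wiggle are
1-based on disk and are shifted on read and unshifted on write; BED,
bedGraph and the MACS-style peak TSV are consumed as 0-based. In the
MACS-style dialect the `summit` column is an offset from `start`, and
`start` is taken in the same 0-based frame as the rest of the table
(verify this against your peak caller's output before importing real
tables; callers differ). A peak's summit must lie inside its interval;
BED peaks without a summit column get the interval midpoint.

When a gene has several transcripts, the model keeps the transcript with
the longest genomic span, breaking ties to the lexicographically
smallest transcript id. Exons are merged; 5′/3′UTRs are derived from the
CDS bounds relative to strand. Genes without CDS are non-coding: their
exons still paint the exon category for peak classification (switchable)
but they are excluded from target calling by default.

## Seven-way classification

The genome is partitioned, per summit query, into upstream-10kb (off the
TSS, strand-aware), 5′UTR, coding exon, intron, 3′UTR, downstream-10kb
(off the transcript end), and other. Because UTRs are subsets of exons
and flanks of neighboring genes overlap freely in compact genomes, a
summit can sit in several labeled ranges; classification is made unique
by the fixed precedence **UTR5 > UTR3 > coding exon > intron > upstream >
downstream**, then nearest TSS, then smallest gene id. Gene-internal
categories outranking flanks keeps a peak inside gene A's intron from
being absorbed by gene B's promoter window; the UTR-over-exon ordering
is forced by the subset relation. The classification is summit-based
(not whole-peak overlap) so every peak lands in exactly one pie-chart
slice.

Two independent implementations exist: an interval-index classifier
(production path) and a per-base painter that colors every base of the
genome in reverse precedence order (used by the synthetic generator to
place summits, and by the tests as a brute-force oracle). The suite
checks they agree on randomly laid-out crowded genomes.

## Motif model and scanning

PWMs are **count matrices**: weight(i, a) = number of aligned sites with
base a at position i. A window scores `100 · raw / max_score` where raw
sums the weights of the window's bases and max_score sums the
per-position maxima; the consensus scores 100 and the score is invariant
to per-column rescaling (so MEME-minimal probability matrices read back
identically). This percent-of-maximum definition is the natural reading
of a "relative profile score" for nonnegative frequency matrices; tools
differ in the exact formula, so absolute frequencies on real data can
shift by a few points between implementations. Hits are strictly above
threshold (default > 75%), scanned on the plus strand and, via the
reverse-complemented matrix, on the minus strand, with offsets reported
in plus-strand coordinates; windows containing non-ACGT characters are
skipped, and soft-masked lowercase is folded rather than skipped (repeat
policy of the inputs is unknowable here; folding is the less destructive
default).

The palindromic dimer motif is monomer + spacer + reverse-complemented
monomer. Spacer columns (default 4, the homodimer footprint spacing)
carry uniform weights equal to a quarter of the largest monomer column
total, so any spacer sequence contributes exactly the column maximum:
only the two half-sites and their distance constrain the score, and the
composite consensus scores 100 for every spacer. The default half-site
is the 7-bp SOX consensus (A/T)(A/T)CAA(T/A)G instantiated as the eight
unambiguous sites, giving the degenerate W positions half the weight of
the invariant CAA⋅G core. The CCAAT box (a common partner-factor motif)
is counted as an exact IUPAC string on both strands rather than through
the 75% PWM route, because a 5-mer count matrix at 75% admits any 4/5
match and ceases to be informative.

The scan window is the full peak interval by default; a summit ± 50 bp
mode exists for sensitivity analysis.

## Conservation

Per-peak conservation is the mean score over summit ± 100 bp (201
bases), clipped at chromosome bounds with the denominator following the
clip. Bases absent from the track contribute 0: unaligned bases carry no
conservation evidence, and scoring them as conserved would inflate
means. Distributions use 0.2-wide bins, left-closed with the top bin
`[0.8, 1.0]` closed (so a mean of exactly 0.8 is "highly conserved"); a
flag flips to right-closed bins. Bin edges are computed as rounded
multiples of the width so that boundary values bin by convention rather
than by accumulated float error.

Two peak sets are compared with a Mann–Whitney U test built from
midranks, with the tie-corrected variance and a 0.5 continuity
correction; U, z and the (default two-sided) p are all reported. For
tie-free samples with min(n₁, n₂) ≤ 8 an exact-enumeration p (via
scipy's exact method) replaces the approximation. Measured accuracy of
the approximation against exact enumeration, computed by the test suite:
|p_normal − p_exact| ≤ 0.02 whenever min(n) ≥ 5, and ≤ 0.04 down to
n = 3 (the worst case, 0.0375, is at n₁ = n₂ = 3 and is intrinsic to the
approximation, not to this implementation). Degenerate input (both
samples constant and equal) returns p = 1 by convention.

## Target and regulated-gene calling

The cis-regulatory span of a gene runs from 10 kb upstream of the TSS
(strand-aware, clipped at chromosome bounds) through the transcript end,
i.e. the downstream flank is *not* cis-regulatory. Membership is
summit-in-span, mirroring the classifier, with an any-overlap mode
available; one peak may support several genes with overlapping spans.
Only protein-coding genes are considered by default.

The expression filter is strict on all three criteria — FPKM > 1.0, fold
change > 1.5, q < 0.05 — matching "more than"/"smaller than" wording. A
zero whole-embryo denominator with positive cell FPKM counts as infinite
induction and passes the fold-change criterion: a gene silent in the
whole embryo but expressed in the sorted cell is maximally specific.
q-values are consumed, never computed; differential testing is upstream
of this package.

Cross-species conservation is counted both as distinct species-A genes
(the one-row-per-pair presentation natural for 1:1 ortholog tables) and
as raw pairs; the two differ only for many-to-many maps, and both are
reported. No homology-type filter is applied by default (a flag
restricts to `ortholog_one2one`). GO tallies are flat set membership
against the supplied annotation file, with no ontology-graph
propagation.

## Synthetic data: what is emulated, and what a green test establishes

The generator writes a complete two-species bundle in exactly the
formats the readers consume. Defaults describe a desk-scale world: per
species 5 chromosomes × 200 kb, 100 three-exon genes (10% non-coding) on
a uniform-pitch grid with strand alternating by chromosome, 300 peaks of
500 bp, uniform ACGT background (GC = 0.5, configurable since PWM
false-positive rates depend on composition). Category fractions default
to a limb-bud-like mix (upstream 0.30, intron 0.25, other 0.20,
downstream 0.10, exon 0.07, 3′UTR 0.05, 5′UTR 0.03). Motif plan:
palindromes planted in 20% of peaks (the published limb-bud-scale
frequency), an extra 30% with single half-sites (palindrome peaks
necessarily contain a half-site, so the single-site frequency is 50%),
CCAAT in 25%. Conservation plan: half the peaks draw their window mean
from N(0.6, 0.15), half from N(0.3, 0.15), truncated to [0, 1] — an
exaggerated version of the published 0.317 vs 0.268 contrast chosen so
the planted effect is detectable at desk scale. Expression plan: 20
regulated plus 10 expressed-but-unbound genes per species; 8 conserved
regulated ortholog pairs; fold enrichment from a Gamma(12, 1.2), whose
histogram mass sits in the 10–15 and 15–20 bins.

Construction order matters and is deliberate:

1. Summits are placed on bases whose painted category matches the plan
   (scarcest categories first, ≥ 750 bp apart so peaks and conservation
   windows never overlap).
2. Motif instances are planted at summits; then every peak is rescanned
   and *chance* hits of motifs the peak is not supposed to contain are
   mutated away (never touching planted bases). On uniform background a
   500 bp window contains ≈ 1.3 chance 6/7 half-site matches and ≈ 1
   chance CCAAT, so without this step exact frequency recovery would be
   impossible at the stated threshold; absence of a motif is treated as
   a planted property, with the threshold, PWM and peak width untouched.
3. Conservation windows are written as constant-score 201-base blocks,
   so window averaging recovers the drawn mean exactly.
4. The target set is *computed* from the realized placement by
   independent span arithmetic (in a compact genome the 10 kb spans of
   neighboring genes overlap, so one peak legitimately supports several
   genes), and the expressed/regulated/conserved-ortholog structure is
   built on top of it: regulated = a chosen subset of realized targets,
   expressed = regulated ∪ non-target extras, ortholog pairs arranged so
   exactly the planned pairs are conserved.

All randomness flows from a single `numpy` Generator seeded from the
config, drawn in a fixed documented order; a fixed seed yields
byte-identical bundles.

What this world does **not** emulate: read-level noise and peak-shape
artifacts, realistic genome composition (repeats, GC heterogeneity, real
gene architecture), phylogenetically structured conservation, dosage
between expression and binding, and many-to-many ortholog structure
(the generator writes 1:1 pairs; many-to-many behavior is covered by
unit tests of the comparator). A green recovery test therefore
establishes that the analysis operations are correct and internally
consistent on data whose ground truth is known — not that published
genome-scale frequencies will be reproduced, which additionally depends
on the exact de novo matrices, annotation release, and scanner scoring
formula used upstream.

## Numerical and degenerate-input choices

* Strict `>` threshold comparisons throughout (motif score, FPKM, fold
  change; `<` for q), matching the stated definitions.
* Pearson kurtosis (normal → 3) and moment skewness (g₁ = m₃/m₂^1.5,
  biased sample moments) for the fold-enrichment histograms; bins are
  half-open `[k·w, (k+1)·w)`.
* Fold-enrichment histograms refuse < 3 values or zero variance.
* Empty peak lists are errors for fraction/frequency operations (a
  fraction of nothing is undefined), while overlap counting and target
  assignment are total and return zeros/empty maps.
* Writers emit rows sorted by (chrom, start, name/gene_id) and
  `run_summary.json` with sorted keys, so identical runs are
  byte-identical.

## Known limitations

* The scanner's percent-of-maximum score is a documented stand-in for
  the unpublished scoring of the original profile-scanning tool;
  real-data motif frequencies can deviate by implementation detail.
* bigWig/BAM are out of scope (text wiggle/bedGraph and peak tables
  only), as is everything upstream: alignment, peak calling, FPKM and
  q-value estimation, de novo motif discovery, and phastCons model
  fitting.
* GTF attribute handling covers `gene_id`/`transcript_id`/biotype plus
  GFF3 `ID`/`Parent`; exotic dialects are not parsed.
* The normal-approximation rank test is accurate to 0.02 only for
  min(n) ≥ 5; below that the exact mode is used automatically.
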