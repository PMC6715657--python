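# regcons

Comparative downstream analysis of transcription-factor ChIP-seq, built
around the kind of question asked of SOX9 in developing chondrocytes and
Sertoli cells: where does a factor bind relative to genes, how often do
its binding regions carry single versus palindromic (homodimer) motifs,
how evolutionarily conserved are the bound regions, which genes does the
factor plausibly regulate in each cell type, and how conserved is that
regulated gene set between two species?

The package is aimed at people who already have peak calls, gene models,
expression tables and a per-base conservation track, and want the
downstream comparative analysis to be reproducible and testable on
desk-scale data.

## What it computes

**Genomic position classification.** Each peak is assigned by its summit
to exactly one of seven categories: up to 10 kb upstream of the TSS,
5′UTR, coding exon, intron, 3′UTR, up to 10 kb downstream of the
transcript end, or *other*. Where categories overlap, the precedence
UTR5 > UTR3 > coding exon > intron > upstream > downstream applies, then
nearest TSS.

**PWM motif scanning.** Position weight matrices are count matrices built
from aligned sites; a window of sequence *w* against a PWM of length *L*
scores

&nbsp;&nbsp;&nbsp;&nbsp;relative score = 100 · Σᵢ w(i, wᵢ) / Σᵢ maxₐ w(i, a)

and both strands are scanned with hits at relative score strictly > 75%.
A palindromic dimer motif is composed as monomer + score-neutral spacer
(default 4 bp) + reverse-complemented monomer, so the footprint of a
factor homodimer can be counted separately from single half-sites. Peak
motif frequency is the percentage of peaks with at least one hit.

**Conservation scoring.** Each peak's conservation is the mean score over
summit ± 100 bp (201 bases; unscored bases count as 0), summarized in
0.2-wide bins and compared between peak sets with a Mann–Whitney U test
(midranks, tie and continuity corrected; exact enumeration for small
tie-free samples).

**Target and regulated-gene calling.** A gene is a putative target when a
peak summit falls in its cis-regulatory span (10 kb upstream of the TSS
through the transcript end). A gene is highly expressed when cell
FPKM > 1.0, fold change over whole embryo > 1.5, and q < 0.05 (all
strict). The regulated set is the intersection.

**Cross-species conservation.** Regulated sets from two species are
mapped through an ortholog table; conserved pairs, Venn counts, and flat
GO-term tallies are reported.

**Synthetic data.** A first-class generator emits a complete two-species
bundle (FASTA genomes, GTF gene models, MACS-style peak tables, wiggle
conservation tracks, expression/ortholog/GO TSVs) in which every
analysis-relevant property is planted and recorded in a ground-truth
manifest, so the entire pipeline can be validated by exact recovery.

## Worked example

```sh
regcons simulate --seed 1 --out bundle/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (abridged):

```
[regcons:annotate] A: fractions {'upstream_10kb': 0.3, 'utr5': 0.03, 'coding_exon': 0.07,
                                 'intron': 0.25, 'utr3': 0.05, 'downstream_10kb': 0.1, 'other': 0.2}
[regcons:scan] A: single 50.00%, palindrome 20.00%, CCAAT 25.00%
[regcons:conserve] A: grand mean 0.4544
[regcons:targets] A: 90 targets, 30 expressed, 20 regulated
[regcons:compare] A vs B: 8/20 vs 8/20 conserved
species A: categories recovered=True, palindrome 20.00% (planted 20.00%), regulated 20 (planted 20)
conserved regulated pairs: 8 (planted 8); rank test p = 0.443
```

Reading this: the classifier reproduced the planted category mix exactly
(30% of peaks upstream, 25% intronic, 20% distal); motif scanning at the
>75% threshold found the palindromic dimer motif in exactly the 20% of
peaks it was planted in; target calling recovered 90 putative targets of
which 20 intersect the highly expressed set; and the two species share 8
conserved regulated ortholog pairs, exactly as planted. The rank test
compares the two species' per-peak conservation means (both species were
generated from the same high/low mixture, so a non-significant p is the
correct answer here).

The same pipeline runs on real inputs through a YAML config:

```sh
regcons run-all --config run.yaml --out report/
```

with per-stage subcommands (`annotate`, `scan`, `conserve`, `targets`,
`compare`) available for partial reproductions from intermediate tables.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
regenerates the synthetic two-species bundle from scratch at the stated
scale (2 species × 5 chromosomes × 200 kb, 100 genes, 300 peaks), runs
the complete analysis on the emitted files, prints the recovery summary
against the ground-truth manifest, and writes the results JSON.

See `docs/methods.md` for the model, parameter defaults, numerical
conventions, and known limitations.
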