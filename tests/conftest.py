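"""Shared fixtures: hand-built gene models and seeded synthetic bundles."""

import pytest

from regcons.io import GeneModel, GenomicInterval, Peak
from regcons.simulate import SyntheticConfig, generate_dataset


def make_peak(chrom, start, end, name="p", summit=None, fe=None):
    return Peak(
        GenomicInterval(chrom, start, end),
        name=name,
        summit=(start + end) // 2 if summit is None else summit,
        fold_enrichment=fe,
    )


@pytest.fixture
def plus_gene():
    """+ strand coding gene [20000, 25000): 5'UTR, 2 coding exons, intron, 3'UTR."""
    return GeneModel(
        gene_id="gplus",
        interval=GenomicInterval("chr1", 20000, 25000, "+"),
        exons=((20000, 21500), (23000, 25000)),
        cds_start=20500,
        cds_end=24500,
        transcript_id="gplus_t1",
    )


@pytest.fixture
def minus_gene():
    """- strand coding gene [40000, 45000) on the same chromosome."""
    return GeneModel(
        gene_id="gminus",
        interval=GenomicInterval("chr1", 40000, 45000, "-"),
        exons=((40000, 41500), (43000, 45000)),
        cds_start=40500,
        cds_end=44500,
        transcript_id="gminus_t1",
    )


@pytest.fixture
def noncoding_gene():
    return GeneModel(
        gene_id="gnc",
        interval=GenomicInterval("chr1", 70000, 72000, "+"),
        exons=((70000, 70800), (71200, 72000)),
        biotype="non_coding",
        transcript_id="gnc_t1",
    )


def small_config(seed=11):
    """Desk-scale two-species config that generates in well under a second."""
    cfg = SyntheticConfig(seed=seed)
    for sp in (cfg.species_a, cfg.species_b):
        sp.n_chromosomes = 2
        sp.chrom_length = 120_000
        sp.n_genes = 16
        sp.n_peaks = 40
        sp.expression.n_regulated = 5
        sp.expression.n_expressed_extra = 2
    cfg.ortholog.n_conserved_regulated = 3
    cfg.ortholog.n_extra_pairs = 6
    return cfg


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """(bundle_dir, manifest) for a small seeded two-species dataset."""
    out = tmp_path_factory.mktemp("bundle_small")
    _, manifest = generate_dataset(small_config(), out)
    return out, manifest


@pytest.fixture(scope="session")
def full_bundle(tmp_path_factory):
    """(bundle_dir, manifest) at the full stated scale: 2 x (5 x 200 kb,
    100 genes, 300 peaks)."""
    out = tmp_path_factory.mktemp("bundle_full")
    _, manifest = generate_dataset(SyntheticConfig(seed=20_190_829), out)
    return out, manifest
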