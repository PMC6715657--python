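"""Generator contracts: determinism, planted properties, manifest consistency."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from regcons import io as gio
from regcons.annotate import RegionCategory, build_annotation_index, classify_peak
from regcons.io import ValidationError
from regcons.motifs import build_pwm, scan_sequence
from regcons.simulate import (
    DEFAULT_SOX_SITES,
    ExpressionPlan,
    SyntheticConfig,
    generate_dataset,
    plant_motif,
    realize_expression_plan,
)
from regcons.targets import call_highly_expressed
from tests.conftest import small_config


def tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_twice_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "one", tmp_path / "two"
        generate_dataset(small_config(seed=5), d1)
        generate_dataset(small_config(seed=5), d2)
        assert tree_digest(d1) == tree_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "one", tmp_path / "two"
        generate_dataset(small_config(seed=5), d1)
        generate_dataset(small_config(seed=6), d2)
        assert tree_digest(d1) != tree_digest(d2)


class TestPlantMotif:
    def test_plant_then_scan_finds_hit(self):
        genome = {"c": np.zeros(100, dtype=np.uint8)}  # all A
        planted = {}
        plant_motif(genome, planted, "c", 40, "CCGGTTCC")
        seq = "".join("ACGT"[i] for i in genome["c"])
        pwm = build_pwm(["CCGGTTCC"])
        assert any(h.offset == 40 and h.strand == "+" for h in scan_sequence(pwm, seq))

    def test_minus_strand_plant_reports_minus_hit(self):
        genome = {"c": np.zeros(100, dtype=np.uint8)}
        planted = {}
        plant_motif(genome, planted, "c", 40, "CCAACGGG")  # revcomp of CCCGTTGG
        seq = "".join("ACGT"[i] for i in genome["c"])
        pwm = build_pwm(["CCCGTTGG"])
        assert any(h.offset == 40 and h.strand == "-" for h in scan_sequence(pwm, seq))

    def test_overlapping_plants_rejected(self):
        genome = {"c": np.zeros(100, dtype=np.uint8)}
        planted = {}
        plant_motif(genome, planted, "c", 40, "CCCC")
        with pytest.raises(ValidationError, match="overlap"):
            plant_motif(genome, planted, "c", 42, "GGGG")

    def test_plant_beyond_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="fit"):
            plant_motif({"c": np.zeros(10, dtype=np.uint8)}, {}, "c", 8, "ACGT")


class TestExpressionPlan:
    def test_noise_free_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        gene_ids = [f"g{i}" for i in range(50)]
        expressed = ["g3", "g7", "g11"]
        records = realize_expression_plan(ExpressionPlan(), gene_ids, rng, expressed)
        assert call_highly_expressed(records) == frozenset(expressed)

    def test_all_null_plan_calls_nothing(self):
        rng = np.random.default_rng(1)
        records = realize_expression_plan(
            ExpressionPlan(), [f"g{i}" for i in range(100)], rng, expressed_ids=[]
        )
        assert call_highly_expressed(records) == frozenset()

    def test_default_draw_respects_plan_size(self):
        rng = np.random.default_rng(2)
        plan = ExpressionPlan(n_regulated=4, n_expressed_extra=2)
        records = realize_expression_plan(plan, [f"g{i}" for i in range(30)], rng)
        assert len(call_highly_expressed(records)) == 6


class TestGeneratedBundle:
    def test_all_other_config_classifies_every_peak_other(self, tmp_path):
        cfg = small_config(seed=9)
        for sp in (cfg.species_a, cfg.species_b):
            sp.category_fractions = {"other": 1.0}
            sp.n_peaks = 12
            sp.expression.n_regulated = 0
        cfg.ortholog.n_conserved_regulated = 0
        out = tmp_path / "other"
        _, manifest = generate_dataset(cfg, out)
        sp_dir = out / "species_A"
        genome = gio.read_genome(sp_dir / "genome.fa")
        genes = gio.read_gene_models(sp_dir / "genes.gtf")
        peaks = gio.read_peak_table(sp_dir / "peaks.tsv", dialect="macs_tsv")
        index = build_annotation_index(genes, gio.chrom_sizes_of(genome))
        for p in peaks:
            cat, gene = classify_peak(p, index)
            assert cat is RegionCategory.OTHER and gene is None

    def test_bundle_reparses_and_matches_manifest_counts(self, small_bundle):
        bundle_dir, manifest = small_bundle
        for key in ("A", "B"):
            sp_dir = bundle_dir / f"species_{key}"
            man = manifest["species"][key]
            genome = gio.read_genome(sp_dir / "genome.fa")
            genes = gio.read_gene_models(sp_dir / "genes.gtf")
            peaks = gio.read_peak_table(sp_dir / "peaks.tsv", dialect="macs_tsv")
            track = gio.read_conservation_track(sp_dir / "conservation.wig")
            records = gio.read_expression_table(sp_dir / "expression.tsv")
            assert len(genes) == man["n_genes"]
            assert len(peaks) == man["n_peaks"]
            assert len(records) == man["n_genes"]
            assert set(track.chroms) <= set(genome)
        omap = gio.read_ortholog_map(bundle_dir / "orthologs.tsv")
        assert [list(p) for p in omap.pairs] == manifest["ortholog_pairs"]

    def test_manifest_internal_consistency(self, small_bundle):
        _, manifest = small_bundle
        pair_set = {tuple(p) for p in manifest["ortholog_pairs"]}
        for a, b in manifest["conserved_pairs"]:
            assert (a, b) in pair_set
            assert a in manifest["species"]["A"]["regulated"]
            assert b in manifest["species"]["B"]["regulated"]
        for key in ("A", "B"):
            man = manifest["species"][key]
            targets, expressed = set(man["targets"]), set(man["expressed"])
            assert set(man["regulated"]) == targets & expressed
            fracs = man["category_fractions"]
            assert abs(sum(fracs.values()) - 1.0) < 1e-9

    def test_infeasible_gene_grid_rejected(self, tmp_path):
        cfg = small_config()
        cfg.species_a.chrom_length = 40_000  # margins leave no room
        with pytest.raises(ValidationError, match="fit|genes"):
            generate_dataset(cfg, tmp_path / "x")

    def test_infeasible_category_plan_rejected(self, tmp_path):
        cfg = small_config()
        # no gene-free painted bases exist for this many OTHER peaks
        cfg.species_a.category_fractions = {"utr5": 1.0}
        cfg.species_a.n_peaks = 400
        with pytest.raises(ValidationError, match="utr5|separation"):
            generate_dataset(cfg, tmp_path / "y")
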