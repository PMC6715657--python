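"""Per-species analysis orchestration and cross-species comparison.

``run_species`` sequences the downstream analysis for one species/cell
type — classify peaks by genomic position, scan for single and
palindromic SOX motifs and the CCAAT box, score summit-window
conservation, and call target/expressed/regulated gene sets.
``run_compare`` maps two regulated sets through an ortholog table and
tallies conserved targets and GO membership.

Configuration is a YAML file; every numeric constant of the method
(10 kb flanks, +/-100 bp conservation window, >75% motif threshold,
FPKM > 1.0, fold change > 1.5, q < 0.05) lives under ``params`` and is
echoed into the run summary, so reports are self-describing.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as gio
from .annotate import (
    RegionCategory,
    build_annotation_index,
    category_fractions,
    classify_peaks,
    count_peak_overlaps,
    enrichment_histogram_stats,
)
from .conservation import mann_whitney_u, summarize_conservation
from .io import ValidationError
from .motifs import build_palindrome_pwm, build_pwm, iupac_match_count, motif_peak_frequency, read_meme
from .orthologs import conserved_regulated, count_go_annotated
from .simulate import CCAAT, DEFAULT_SOX_SITES
from .targets import assign_putative_targets, call_highly_expressed, call_regulated

logger = logging.getLogger("regcons")
if not logger.handlers:  # stage-tagged logging to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[regcons:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


DEFAULT_PARAMS: dict = {
    "upstream_bp": 10_000,
    "downstream_bp": 10_000,
    "flank_bp": 100,
    "motif_threshold": 75.0,
    "motif_window": "peak",  # or "summit50"
    "palindrome_spacer": 4,
    "fpkm_min": 1.0,
    "fc_min": 1.5,
    "q_max": 0.05,
    "overlap_mode": "summit",  # or "overlap"
    "bin_left_closed": True,
    "include_noncoding": True,
    "protein_coding_only": True,
    "ortholog_one2one_only": False,
    "go_term": "GO:0001501",
}

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved run configuration: per-species input paths plus thresholds."""

    species: dict[str, dict[str, str]]
    params: dict = field(default_factory=dict)
    orthologs: str | None = None
    go: str | None = None
    motifs: str | None = None  # optional MEME-minimal PWM file
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for key in ("upstream_bp", "downstream_bp", "flank_bp"):
            if self.params[key] <= 0:
                raise ValidationError(f"param {key} must be positive")

    def path(self, rel: str | None) -> Path | None:
        return None if rel is None else (self.base_dir / rel)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValidationError(f"unsupported config schema version {version}")
        return cls(
            species=raw.get("species", {}),
            params=raw.get("params", {}) or {},
            orthologs=raw.get("orthologs"),
            go=raw.get("go"),
            motifs=raw.get("motifs"),
            base_dir=path.parent,
        )


def default_run_config(bundle_dir: str | Path, **param_overrides) -> RunConfig:
    """RunConfig pointing at a generated synthetic bundle directory."""
    bundle_dir = Path(bundle_dir)
    species = {}
    for key in ("A", "B"):
        sp_dir = bundle_dir / f"species_{key}"
        species[key] = {
            "genome": f"species_{key}/genome.fa",
            "genes": f"species_{key}/genes.gtf",
            "genes_format": "gtf",
            "peaks": f"species_{key}/peaks.tsv",
            "peaks_dialect": "macs_tsv",
            "conservation": f"species_{key}/conservation.wig",
            "expression": f"species_{key}/expression.tsv",
            "name": key,
        }
        if not sp_dir.is_dir():
            raise ValidationError(f"bundle directory {sp_dir} missing")
    return RunConfig(
        species=species,
        params=dict(param_overrides),
        orthologs="orthologs.tsv",
        go="go_terms.tsv",
        base_dir=bundle_dir,
    )


def _motif_models(config: RunConfig):
    """(single-site PWM, palindrome composite PWM) from config or defaults."""
    spacer = int(config.params["palindrome_spacer"])
    if config.motifs:
        pwms = read_meme(config.path(config.motifs))
        if not pwms:
            raise ValidationError(f"no motifs in {config.motifs}")
        monomer = pwms[sorted(pwms)[0]]
    else:
        monomer = build_pwm(list(DEFAULT_SOX_SITES), name="SOX_monomer")
    return monomer, build_palindrome_pwm(monomer, spacer=spacer).composite


def run_species(config: RunConfig, species_key: str) -> dict:
    """Annotate -> scan -> conserve -> targets for one species.

    Returns a report dict with result tables (DataFrames) under
    ``tables`` and a JSON-serializable ``summary``.  A missing
    conservation track marks that section "skipped" without failing the
    rest.
    """
    if species_key not in config.species:
        raise ValidationError(f"species {species_key!r} not in config")
    sp = config.species[species_key]
    params = config.params
    name = sp.get("name", species_key)

    stage = "load"
    try:
        genome = gio.read_genome(config.path(sp["genome"]))
        chrom_sizes = gio.chrom_sizes_of(genome)
        genes = gio.read_gene_models(
            config.path(sp["genes"]), fmt=sp.get("genes_format", "gtf")
        )
        peaks = gio.read_peak_table(
            config.path(sp["peaks"]), dialect=sp.get("peaks_dialect", "macs_tsv")
        )
        _log(stage, f"{name}: {len(genes)} genes, {len(peaks)} peaks")

        stage = "annotate"
        index = build_annotation_index(
            genes,
            chrom_sizes,
            upstream_bp=params["upstream_bp"],
            downstream_bp=params["downstream_bp"],
            include_noncoding=params["include_noncoding"],
        )
        annotated = classify_peaks(peaks, index)
        fractions, counts = category_fractions(peaks, index)
        enrich = None
        if sum(p.fold_enrichment is not None for p in peaks) >= 3:
            enrich = enrichment_histogram_stats(peaks)
        _log(stage, f"{name}: fractions {({c.value: round(f, 3) for c, f in fractions.items()})}")

        stage = "scan"
        monomer, composite = _motif_models(config)
        thr = params["motif_threshold"]
        window = params["motif_window"]
        freq_single = motif_peak_frequency(peaks, genome, monomer, threshold=thr, window=window)
        freq_pal = motif_peak_frequency(peaks, genome, composite, threshold=thr, window=window)
        n_ccaat = sum(
            1
            for p in peaks
            if iupac_match_count(
                genome[p.chrom][p.interval.start : p.interval.end], CCAAT
            )
            > 0
        )
        freq_ccaat = 100.0 * n_ccaat / len(peaks)
        _log(
            stage,
            f"{name}: single {freq_single:.2f}%, palindrome {freq_pal:.2f}%, "
            f"CCAAT {freq_ccaat:.2f}%",
        )

        stage = "conserve"
        conservation_summary = None
        cons_rel = sp.get("conservation")
        if cons_rel and config.path(cons_rel).exists():
            track = gio.read_conservation_track(config.path(cons_rel))
            conservation_summary = summarize_conservation(
                track,
                peaks,
                flank=params["flank_bp"],
                chrom_sizes=chrom_sizes,
                left_closed=params["bin_left_closed"],
            )
            _log(stage, f"{name}: grand mean {conservation_summary.grand_mean:.4f}")
        else:
            _log(stage, f"{name}: no conservation track, section skipped")

        stage = "targets"
        assignments = assign_putative_targets(
            peaks,
            genes,
            upstream_bp=params["upstream_bp"],
            mode=params["overlap_mode"],
            protein_coding_only=params["protein_coding_only"],
            chrom_sizes=chrom_sizes,
        )
        target_genes = frozenset(assignments)
        records = gio.read_expression_table(config.path(sp["expression"]))
        expressed = call_highly_expressed(
            records,
            fpkm_min=params["fpkm_min"],
            fc_min=params["fc_min"],
            q_max=params["q_max"],
        )
        regulated = call_regulated(target_genes, expressed, species=name)
        _log(
            stage,
            f"{name}: {len(target_genes)} targets, {len(expressed)} expressed, "
            f"{regulated.n_regulated} regulated",
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed for species {name}: {exc}") from exc

    tables: dict[str, pd.DataFrame] = {"annotated_peaks": annotated}
    tables["category_fractions"] = pd.DataFrame(
        {
            "category": [c.value for c in RegionCategory],
            "count": [counts[c] for c in RegionCategory],
            "fraction": [fractions[c] for c in RegionCategory],
        }
    )
    tables["targets"] = pd.DataFrame(
        [
            {
                "gene_id": g,
                "n_supporting_peaks": len(assignments[g].peaks),
                "peaks": ",".join(assignments[g].peaks),
            }
            for g in sorted(assignments)
        ],
        columns=["gene_id", "n_supporting_peaks", "peaks"],
    )
    tables["regulated"] = pd.DataFrame(
        {"gene_id": sorted(regulated.genes)}, columns=["gene_id"]
    )
    if enrich is not None:
        tables["enrichment_histogram"] = enrich.histogram
    if conservation_summary is not None:
        tables["conservation"] = pd.DataFrame(
            {
                "peak": list(conservation_summary.peak_means),
                "mean_score": list(conservation_summary.peak_means.values()),
            }
        )

    summary = {
        "species": name,
        "params": dict(params),
        "inputs": {k: str(v) for k, v in sp.items()},
        "n_peaks": len(peaks),
        "n_genes": len(genes),
        "category_counts": {c.value: counts[c] for c in RegionCategory},
        "category_fractions": {c.value: fractions[c] for c in RegionCategory},
        "motif_frequency_pct": {
            "single": freq_single,
            "palindrome": freq_pal,
            "ccaat": freq_ccaat,
        },
        "n_targets": len(target_genes),
        "n_expressed": len(expressed),
        "n_regulated": regulated.n_regulated,
        "conservation": (
            {
                "grand_mean": conservation_summary.grand_mean,
                "bin_fractions": conservation_summary.bin_fractions.tolist(),
            }
            if conservation_summary is not None
            else "skipped"
        ),
    }
    if enrich is not None:
        summary["fold_enrichment"] = {
            "skewness": enrich.skewness,
            "kurtosis": enrich.kurtosis,
        }
    return {
        "name": name,
        "tables": tables,
        "summary": summary,
        "genes": genes,
        "peaks": peaks,
        "target_genes": target_genes,
        "expressed_genes": expressed,
        "regulated": regulated,
        "conservation_summary": conservation_summary,
    }


def run_compare(
    report_a: Mapping,
    report_b: Mapping,
    omap: gio.OrthologMap,
    go_map: Mapping[str, frozenset[str]] | None = None,
    go_term: str = "GO:0001501",
    one2one_only: bool = False,
) -> dict:
    """Cross-species conservation of regulated gene sets.

    When the two reports describe two tissues of one species (same gene
    universe), peak-overlap counts between the tissues are reported too.
    """
    if one2one_only:
        omap = omap.restricted(["ortholog_one2one"])
    set_a = report_a["regulated"].genes
    set_b = report_b["regulated"].genes
    comparison = conserved_regulated(set_a, set_b, omap)
    _log(
        "compare",
        f"{report_a['name']} vs {report_b['name']}: "
        f"{comparison.n_conserved_a}/{comparison.n_a_with_ortholog} vs "
        f"{comparison.n_conserved_b}/{comparison.n_b_with_ortholog} conserved",
    )

    conservation_test = None
    sa = report_a.get("conservation_summary")
    sb = report_b.get("conservation_summary")
    if sa is not None and sb is not None:
        res = mann_whitney_u(
            list(sa.peak_means.values()), list(sb.peak_means.values()), method="normal"
        )
        conservation_test = {"u": res.u, "z": res.z, "p": res.p}

    peak_overlap = None
    genes_a = {g.gene_id for g in report_a["genes"]}
    genes_b = {g.gene_id for g in report_b["genes"]}
    if genes_a == genes_b:  # two tissues of one species
        peak_overlap = count_peak_overlaps(report_a["peaks"], report_b["peaks"])

    go_count = None
    if go_map is not None:
        go_count = count_go_annotated(
            {a for a, _ in comparison.conserved_pairs}, go_map, go_term
        )

    tables = {
        "conserved_pairs": pd.DataFrame(
            list(comparison.conserved_pairs), columns=["gene_a", "gene_b"]
        )
    }
    summary = {
        "species_a": report_a["name"],
        "species_b": report_b["name"],
        "n_a_regulated": comparison.n_a_regulated,
        "n_b_regulated": comparison.n_b_regulated,
        "n_a_with_ortholog": comparison.n_a_with_ortholog,
        "n_b_with_ortholog": comparison.n_b_with_ortholog,
        "n_conserved_a": comparison.n_conserved_a,
        "n_conserved_b": comparison.n_conserved_b,
        "n_conserved_pairs": comparison.n_pairs,
        "venn": comparison.venn,
        "conservation_rank_test": conservation_test,
        "go_term": go_term,
        "n_conserved_a_go_annotated": go_count,
        "peak_overlap_counts": peak_overlap,
    }
    return {"comparison": comparison, "tables": tables, "summary": summary}


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Both species plus the comparison; optionally write all reports."""
    keys = sorted(config.species)
    if len(keys) != 2:
        raise ValidationError(f"run_all needs exactly two species, got {keys}")
    report_a = run_species(config, keys[0])
    report_b = run_species(config, keys[1])
    omap = gio.read_ortholog_map(config.path(config.orthologs))
    go_map = gio.read_go_map(config.path(config.go)) if config.go else None
    compare = run_compare(
        report_a,
        report_b,
        omap,
        go_map=go_map,
        go_term=config.params["go_term"],
        one2one_only=config.params["ortholog_one2one_only"],
    )
    result = {"species": {keys[0]: report_a, keys[1]: report_b}, "compare": compare}
    if out_dir is not None:
        out_dir = Path(out_dir)
        for key, rep in result["species"].items():
            gio.write_tables(rep["tables"], out_dir / f"species_{key}", rep["summary"])
        gio.write_tables(
            compare["tables"], out_dir / "compare", compare["summary"]
        )
    return result
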