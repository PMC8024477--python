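"""Stage orchestration: stats -> variants -> scan -> design -> tree.

Each stage writes its outputs into the run directory and appends an entry
(inputs, parameters, sha256 of every output) to a JSON manifest, so a run is
reproducible from the manifest alone.  Re-running with the same config and
inputs produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import genome_io, genome_stats, marker_scan, phylo, primer_design, synthetic_data, variants

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Fully resolved configuration of a pipeline run."""

    reference: str
    annotations: str
    strain_fastas: dict[str, str] = field(default_factory=dict)
    strain_vcfs: dict[str, str] = field(default_factory=dict)
    outdir: str = "mtmarker_run"
    seed: int = 0
    window_len: int = 400
    step: int = 1
    circular: bool = True
    top: int = 10
    min_hom_freq: float = 0.85
    flank_search_len: int = 150
    primer_len: int = 18
    max_degenerate_positions: int = 1
    ispcr_max_mismatch: int = 2
    ispcr_min_len: int = 100
    ispcr_max_len: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        for label, p in [("reference", self.reference), ("annotations", self.annotations),
                         *[(f"strain {s}", p) for s, p in self.strain_fastas.items()],
                         *[(f"vcf {s}", p) for s, p in self.strain_vcfs.items()]]:
            if not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
        if not self.strain_fastas and not self.strain_vcfs:
            raise ConfigError("no strain inputs (strain_fastas or strain_vcfs)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.entries: list[dict] = []

    def add(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.entries.append({
            "stage": stage,
            "parameters": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
        })
        self.write()

    def write(self, failed_stage: str | None = None) -> None:
        doc = {"entries": self.entries}
        if failed_stage:
            doc["failed_stage"] = failed_stage
        (self.outdir / "manifest.json").write_text(json.dumps(doc, indent=2) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order and return the manifest document."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
    manifest = Manifest(outdir)
    stage = "init"
    try:
        # --- stats ----------------------------------------------------------
        stage = "stats"
        reference = genome_io.read_fasta(cfg.reference, is_circular=cfg.circular)[0]
        ann = genome_io.read_features(cfg.annotations, reference)
        report = genome_stats.genome_report(reference, ann)
        stats_path = outdir / "genome_stats.json"
        stats_path.write_text(json.dumps(report, indent=2) + "\n")
        manifest.add("stats", {"reference": cfg.reference}, [stats_path])

        # --- variants -------------------------------------------------------
        stage = "variants"
        per_strain: dict[str, list[variants.SnvRecord]] = {}
        for strain, path in cfg.strain_fastas.items():
            strain_genome = genome_io.read_fasta(path, is_circular=cfg.circular)[0]
            strain_genome.id = reference.id  # calls are relative to the reference
            calls = variants.call_snvs_from_genomes(reference, strain_genome)
            per_strain[strain] = [
                variants.SnvRecord(reference.id, r.pos, r.ref_allele, r.alt_allele, strain)
                for r in calls
            ]
        if cfg.strain_vcfs:
            vcf_calls = variants.read_vcf_per_strain(cfg.strain_vcfs, reference)
            for strain, records in vcf_calls.items():
                per_strain[strain] = variants.filter_homozygous(records, cfg.min_hom_freq)
        matrix = variants.build_snv_matrix(reference, per_strain)
        matrix_tsv = outdir / "snv_matrix.tsv"
        variants.matrix_to_frame(matrix).to_csv(matrix_tsv, sep="\t", index=False)
        matrix_vcf = outdir / "snv_matrix.vcf"
        variants.write_matrix_vcf(matrix, reference, matrix_vcf)
        manifest.add("variants", {"n_strains": len(per_strain),
                                  "n_positions": matrix.n_positions},
                     [matrix_tsv, matrix_vcf])

        # --- scan -----------------------------------------------------------
        stage = "scan"
        scan_cfg = marker_scan.ScanConfig(
            window_len=cfg.window_len, step=cfg.step, circular=cfg.circular,
            include_reference=False,
        )
        scores = marker_scan.window_scan(matrix, reference.length, scan_cfg)
        ranked = marker_scan.rank_windows(scores)
        top = ranked[0]
        marker = marker_scan.extract_marker(reference, matrix, top,
                                            include_reference=False)
        scores_tsv = outdir / "window_scores.tsv"
        marker_scan.scores_to_frame(ranked[: max(cfg.top, 1)]).to_csv(
            scores_tsv, sep="\t", index=False)
        bed_path = outdir / "windows.bed"
        marker_scan.windows_to_bed(ranked[: max(cfg.top, 1)], reference.id,
                                   reference.length, bed_path)
        hap_fasta = outdir / "marker_haplotypes.fasta"
        genome_io.write_fasta(marker.haplotypes, hap_fasta)
        manifest.add("scan", {"window_len": cfg.window_len, "step": cfg.step,
                              "top_start": top.start, "top_end": top.end,
                              "top_density": top.density,
                              "top_resolution": top.resolution},
                     [scores_tsv, bed_path, hap_fasta])

        # --- design ---------------------------------------------------------
        stage = "design"
        primer_cfg = primer_design.PrimerConfig(
            primer_len=cfg.primer_len, flank_search_len=cfg.flank_search_len,
            max_degenerate_positions=cfg.max_degenerate_positions,
            circular=cfg.circular,
        )
        pair = primer_design.propose_primers(reference, matrix, top, primer_cfg)
        primer_tsv = outdir / "primers.tsv"
        with open(primer_tsv, "w") as fh:
            fh.write("name\tforward\treverse\tfwd_start\trev_start\texpected_len\n")
            fh.write(f"marker\t{pair.forward}\t{pair.reverse}\t{pair.fwd_start}"
                     f"\t{pair.rev_start}\t{pair.expected_amplicon_len}\n")
        templates = [reference]
        for strain, path in cfg.strain_fastas.items():
            g = genome_io.read_fasta(path, is_circular=cfg.circular)[0]
            g.id = strain
            templates.append(g)
        amplicons = primer_design.in_silico_pcr(
            pair, templates, cfg.ispcr_max_mismatch,
            cfg.ispcr_min_len, cfg.ispcr_max_len)
        amp_tsv = outdir / "amplicons.tsv"
        with open(amp_tsv, "w") as fh:
            fh.write("template\tstart\tend\tlength\tfwd_mismatches\trev_mismatches\tstrand\n")
            for a in amplicons:
                fh.write(f"{a.template_id}\t{a.start}\t{a.end}\t{a.length}"
                         f"\t{a.fwd_mismatches}\t{a.rev_mismatches}\t{a.strand}\n")
        manifest.add("design", {"forward": pair.forward, "reverse": pair.reverse,
                                "n_amplicons": len(amplicons)},
                     [primer_tsv, amp_tsv])

        # --- tree -----------------------------------------------------------
        stage = "tree"
        labels, dmat = phylo.p_distance_matrix(marker.haplotypes)
        tree = phylo.nj_tree(labels, dmat)
        tree_path = outdir / "marker_tree.nwk"
        genome_io.write_newick(tree, tree_path)
        dm_tsv = outdir / "marker_distances.tsv"
        phylo.distance_frame(labels, dmat).to_csv(dm_tsv, sep="\t")
        manifest.add("tree", {"n_leaves": len(labels),
                              "distinct": phylo.resolution_count(marker.haplotypes)},
                     [tree_path, dm_tsv])
    except Exception:
        manifest.write(failed_stage=stage)
        logger.exception("pipeline failed at stage %r", stage)
        raise
    return {"entries": manifest.entries}


def run_simulation(cfg: synthetic_data.SimConfig, outdir: str | Path) -> synthetic_data.TruthSet:
    """Generate a truth set and write its artifacts (FASTA/GFF3/VCF/TSV/YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, ann = synthetic_data.generate_reference(cfg)
    truth = synthetic_data.generate_strains(reference, ann, cfg)
    genome_io.write_fasta([reference], outdir / "reference.fasta")
    genome_io.write_features(ann, outdir / "reference.gff3")
    for strain, genome in truth.strain_genomes.items():
        genome_io.write_fasta([genome], outdir / f"{strain}.fasta")
        variants.write_strain_vcf(truth.truth_snvs[strain], reference,
                                  outdir / f"{strain}.truth.vcf", strain=strain)
    with open(outdir / "hotspot.tsv", "w") as fh:
        fh.write("start\tend\n")
        fh.write(f"{truth.hotspot_window[0]}\t{truth.hotspot_window[1]}\n")
    (outdir / "sim_config.yaml").write_text(
        yaml.safe_dump(asdict(cfg), sort_keys=True))
    return truth
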