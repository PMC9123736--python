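"""End-to-end orchestration: digest -> bulks -> filter -> scan -> regions.

A run is described by a flat YAML config (paths plus the per-stage
parameters, all defaulting to the study's printed values), executes the
stages in order, and records every output file with a SHA-256 content hash
in a JSON manifest so identical config + seed reproduce identical runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import digest as dg
from . import phenotypes as ph
from . import qc, regions as rg, scan as sc, vcfio


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    # inputs (any may be omitted; stages needing them are skipped)
    fasta: str | None = None
    gff: str | None = None
    vcf: str | None = None
    phenotypes: str | None = None
    out_dir: str = "slafbsa_out"
    # digestion
    enzymes: list[str] = field(default_factory=lambda: ["RsaI", "HaeIII"])
    size_min: int = 314
    size_max: int = 364
    flank_rule: str = "internal_only"
    # bulks
    bulk_size: int = 30
    # SNP filters
    min_support: int = 4
    qual_min: float = 30.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    # scan
    window_snps: int = 10
    step_snps: int = 1
    n_replicates: int = 10_000
    design: str = sc.F1_DESIGN
    confidences: list[float] = field(default_factory=lambda: [0.90, 0.95, 0.99])
    region_confidence: float = 0.99
    orientation: str = sc.REF_ALT
    informative_only: bool = False  # scan only unambiguously polarized markers
    max_gap_snps: int = 0
    parents: list[str] = field(default_factory=lambda: ["R01", "R02"])
    bulks: list[str] = field(default_factory=lambda: ["aa", "ab"])
    seed: int = 0
    plot: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    def add_file(path: Path) -> None:
        manifest["files"][str(path)] = _sha256(path)

    gene_models: list[rg.GeneModel] = []
    if config.gff:
        if not Path(config.gff).exists():
            raise PipelineError("inputs", f"GFF3 not found: {config.gff}")
        gene_models = rg.read_genes_gff3(config.gff)

    # --- digest -----------------------------------------------------------
    if config.fasta:
        if not Path(config.fasta).exists():
            raise PipelineError("digest", f"FASTA not found: {config.fasta}")
        try:
            enzymes = [dg.get_enzyme(e) for e in config.enzymes]
            gene_iv: dict[str, list[tuple[int, int]]] = {}
            for g in gene_models:
                gene_iv.setdefault(g.chrom, []).append((g.start, g.end))
            fragments, report = dg.digest_genome(
                config.fasta,
                enzymes,
                (config.size_min, config.size_max),
                config.flank_rule,
                gene_iv,
            )
            tags = dg.select_tags(
                fragments, (config.size_min, config.size_max), config.flank_rule
            )
            bed = out_dir / "tags.bed"
            dg.write_tags_bed(tags, bed)
            rpt = out_dir / "digest_report.tsv"
            dg.write_report_tsv(report, rpt)
            per_chrom = out_dir / "tags_per_chrom.tsv"
            dg.write_per_chrom_tsv(report, per_chrom)
            for p in (bed, rpt, per_chrom):
                add_file(p)
            record(
                "digest",
                n_fragments=report.n_fragments,
                n_tags=report.n_tags_in_window,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("digest", str(exc)) from exc

    # --- bulks ------------------------------------------------------------
    if config.phenotypes:
        if not Path(config.phenotypes).exists():
            raise PipelineError("bulks", f"phenotype table not found: {config.phenotypes}")
        try:
            phenos = ph.read_phenotypes(config.phenotypes)
            assignment = ph.select_bulks(phenos, config.bulk_size)
            out = out_dir / "bulk_assignment.tsv"
            ph.write_assignment(assignment, out)
            add_file(out)
            record("bulks", n_plants=len(phenos), bulk_size=config.bulk_size)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("bulks", str(exc)) from exc

    # --- filter / scan / regions -----------------------------------------
    if config.vcf:
        if not Path(config.vcf).exists():
            raise PipelineError("filter", f"VCF not found: {config.vcf}")
        try:
            records = vcfio.read_snp_records(
                config.vcf, parents=config.parents, bulks=config.bulks
            )
            params = qc.SnpFilterParams(
                min_support=config.min_support,
                qual_min=config.qual_min,
                qd_min=config.qd_min,
                fs_max=config.fs_max,
                mq_min=config.mq_min,
            )
            retained, ledger = qc.filter_snps(records, params)
            filtered = out_dir / "filtered_snps.tsv"
            vcfio.write_snp_tsv(retained, filtered)
            ledger_path = out_dir / "filter_ledger.tsv"
            qc.write_ledger_tsv(ledger, ledger_path)
            add_file(filtered)
            add_file(ledger_path)
            record("filter", **ledger.table1_row())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("filter", str(exc)) from exc

        try:
            points = sc.compute_index_points(retained, orientation=config.orientation)
            scan_points = (
                sc.select_informative(points)
                if config.informative_only
                else [p for p in points if not p.masked]
            )
            windows = sc.sliding_window(scan_points, config.window_snps, config.step_snps)
            observed_depths = [(p.depth_high, p.depth_low) for p in scan_points]
            thresholds = sc.simulate_null_threshold(
                bulk_size=config.bulk_size,
                depths=observed_depths,
                window_snps=config.window_snps,
                n_replicates=config.n_replicates,
                design=config.design,
                confidences=config.confidences,
                seed=config.seed,
            )
            paths = sc.write_scan_tables(points, windows, thresholds, out_dir / "scan")
            for p in paths.values():
                add_file(p)
            if config.plot and windows:
                from .plotting import plot_scan

                png = out_dir / "scan.png"
                chosen = [
                    t for t in thresholds if t.confidence == config.region_confidence
                ]
                plot_scan(points, windows, chosen[0] if chosen else None, png)
                add_file(png)
            record("scan", n_points=len(points), n_windows=len(windows))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("scan", str(exc)) from exc

        try:
            chosen = [t for t in thresholds if t.confidence == config.region_confidence]
            if not chosen:
                raise ValueError(
                    f"region_confidence {config.region_confidence} not among "
                    f"computed confidences {config.confidences}"
                )
            called = rg.call_regions(windows, chosen[0], config.max_gap_snps)
            if gene_models:
                called = rg.annotate_regions(called, gene_models)
            total_mb, _ = rg.summarize_regions(called)
            bed = out_dir / "regions.bed"
            rg.write_regions_bed(called, bed)
            tsv = out_dir / "regions.tsv"
            rg.write_regions_tsv(called, tsv)
            genes_tsv = out_dir / "region_genes.tsv"
            rg.write_region_genes_tsv(called, genes_tsv)
            for p in (bed, tsv, genes_tsv):
                add_file(p)
            record(
                "regions",
                n_regions=len(called),
                total_length_mb=total_mb,
                threshold=chosen[0].threshold,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("regions", str(exc)) from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
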