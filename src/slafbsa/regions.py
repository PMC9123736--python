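"""Candidate-region calling and gene annotation.

Maximal runs of sliding windows whose |m| reaches the significance
threshold become candidate regions; a region spans from the first member
window's first SNP to the last member window's last SNP (0-based
half-open).  Genes from a GFF3 are assigned to a region when their
intervals overlap by at least one base, strand-ignorant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .scan import NullThreshold, WindowPoint


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene requires start < end")


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_windows: int = 0
    n_snps: int = 0
    peak_m: float = 0.0
    genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region requires start < end")

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


def call_regions(
    windows: Sequence[WindowPoint],
    threshold: float | NullThreshold,
    max_gap_snps: int = 0,
) -> list[CandidateRegion]:
    """Merge above-threshold windows into regions.

    A run may bridge up to ``max_gap_snps`` consecutive below-threshold
    windows (default 0: strictly contiguous runs).  Regions are returned
    sorted and disjoint per chromosome.
    """
    thr = threshold.threshold if isinstance(threshold, NullThreshold) else float(threshold)
    if max_gap_snps < 0:
        raise ValueError("max_gap_snps must be >= 0")

    by_chrom: dict[str, list[WindowPoint]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    regions: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.window_index)
        runs: list[list[WindowPoint]] = []
        run: list[WindowPoint] = []
        gap = 0
        pending: list[WindowPoint] = []
        for w in ws:
            if abs(w.m) >= thr:
                if run:
                    run.extend(pending)
                    pending = []
                run.append(w)
                gap = 0
            elif run:
                gap += 1
                pending.append(w)
                if gap > max_gap_snps:
                    runs.append(run)
                    run, gap, pending = [], 0, []
        if run:
            runs.append(run)

        # distinct runs still share member SNPs when separated by fewer
        # below-threshold windows than the window width, so their genomic
        # spans can overlap; union such runs to keep regions disjoint
        merged: list[list[WindowPoint]] = []
        for r in runs:
            if merged and r[0].start_pos <= merged[-1][-1].end_pos:
                merged[-1].extend(r)
            else:
                merged.append(r)

        width = ws[0].n_snps if ws else 0
        for r in merged:
            above = [w for w in r if abs(w.m) >= thr]
            first_i = min(w.window_index for w in r)
            last_i = max(w.window_index for w in r)
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start=min(w.start_pos for w in r) - 1,  # 1-based SNP -> 0-based
                    end=max(w.end_pos for w in r),
                    n_windows=len(above),
                    n_snps=last_i - first_i + width,
                    peak_m=max(r, key=lambda w: abs(w.m)).m,
                )
            )
    return regions


def summarize_regions(
    regions: Sequence[CandidateRegion],
) -> tuple[float, pd.DataFrame]:
    """Total length in Mb plus a per-region table."""
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length_mb": [r.length_mb for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "peak_m": [r.peak_m for r in regions],
            "n_genes": [len(r.genes) for r in regions],
        }
    )
    total = float(df["length_mb"].sum()) if len(df) else 0.0
    return total, df


def annotate_regions(
    regions: Sequence[CandidateRegion],
    genes: Sequence[GeneModel],
) -> list[CandidateRegion]:
    """Attach overlapping gene ids (>= 1 bp, half-open intervals).

    Duplicate gene ids keep the first occurrence with a warning.
    """
    seen: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in seen:
            warnings.warn(f"duplicate gene id {g.gene_id}; keeping first", stacklevel=2)
            continue
        seen[g.gene_id] = g
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in seen.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)

    out = []
    for r in regions:
        hits = tuple(
            g.gene_id
            for g in by_chrom.get(r.chrom, [])
            if g.start < r.end and r.start < g.end
        )
        out.append(replace(r, genes=hits))
    return out


def gene_union_count(regions: Sequence[CandidateRegion]) -> int:
    """Distinct genes across regions (a gene overlapping two regions counts once)."""
    return len({g for r in regions for g in r.genes})


def read_genes_gff3(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Gene models from a GFF3 (coordinates converted to 0-based half-open)."""
    import pyranges as pr

    gr = pr.read_gff3(str(path))
    df = gr.df
    df = df[df["Feature"] == feature].sort_values(["Chromosome", "Start", "End"])
    id_col = "ID" if "ID" in df.columns else "gene_id"
    genes = []
    for r in df.itertuples():
        gid = getattr(r, id_col, None)
        if gid is None or (isinstance(gid, float) and pd.isna(gid)):
            gid = f"{r.Chromosome}:{r.Start}-{r.End}"
        genes.append(
            GeneModel(
                gene_id=str(gid),
                chrom=str(r.Chromosome),
                start=int(r.Start),
                end=int(r.End),
                strand=str(getattr(r, "Strand", ".")),
            )
        )
    return genes


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{r.peak_m:.4f}\n")


def write_regions_tsv(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    _, df = summarize_regions(regions)
    df.to_csv(path, sep="\t", index=False)


def write_region_genes_tsv(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    rows = []
    for i, r in enumerate(regions, 1):
        for g in r.genes:
            rows.append({"region": f"region_{i}", "chrom": r.chrom, "gene_id": g})
    pd.DataFrame(rows, columns=["region", "chrom", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
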