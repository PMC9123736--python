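"""Read-level QC and the five-stage SNP hard-filter cascade.

The read rules drop a read when undetermined bases exceed 10% of its length
or when bases at phred quality Q <= 10 make up at least half of it.  The
SNP cascade removes, in fixed order: multiallelic sites, sites with
insufficient read support, sites where the two pools are genotypically
uniform, sites whose bulk alleles cannot derive from the parents, and sites
failing the GATK-style hard filters (QUAL < 30, QD < 2.0, FS > 60.0,
MQ < 40.0).  Each site is attributed to the FIRST stage it fails, so the
per-stage ledger always conserves the input total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .vcfio import HIGH, LOW, SnpRecord


@dataclass(frozen=True)
class ReadQcRule:
    """Thresholds for dropping raw reads.

    ``max_low_qual_fraction`` is applied as "at least", the conservative
    reading of a rule phrased around exceeding half of the read.
    """

    max_n_fraction: float = 0.10
    low_qual_threshold: int = 10  # phred
    max_low_qual_fraction: float = 0.50

    def __post_init__(self) -> None:
        for f in (self.max_n_fraction, self.max_low_qual_fraction):
            if not 0 < f <= 1:
                raise ValueError("fractions must lie in (0, 1]")


@dataclass
class ReadQcCounts:
    total: int = 0
    kept: int = 0
    dropped_n: int = 0
    dropped_low_qual: int = 0
    rejected_malformed: int = 0


def read_passes(seq: str, quals: Sequence[int], rule: ReadQcRule) -> bool:
    """True when a read violates neither QC rule."""
    n = len(seq)
    if n == 0:
        return False
    n_frac = seq.upper().count("N") / n
    if n_frac > rule.max_n_fraction:
        return False
    low = sum(1 for q in quals if q <= rule.low_qual_threshold)
    if low / n >= rule.max_low_qual_fraction:
        return False
    return True


def filter_reads(
    fastq_in: str | Path | TextIO,
    rule: ReadQcRule = ReadQcRule(),
    fastq_out: str | Path | TextIO | None = None,
) -> ReadQcCounts:
    """Stream a FASTQ (phred+33), dropping reads that violate the rules.

    Records whose sequence and quality strings differ in length are
    rejected individually and counted separately; reading continues with
    the next record.  Input must use the four-line record layout (the
    universal modern form) — per-record error recovery rules out wrapped
    multi-line FASTQ.  When ``fastq_out`` is given the surviving reads are
    written there.
    """
    import gzip

    def _open(p, mode):
        p = Path(p)
        return gzip.open(p, mode + "t") if p.suffix == ".gz" else open(p, mode)

    def _records(handle):
        while True:
            title = handle.readline()
            if not title.strip():
                return
            seq = handle.readline().rstrip("\n")
            handle.readline()  # the '+' separator
            qual = handle.readline().rstrip("\n")
            yield title.rstrip("\n").lstrip("@"), seq, qual

    close_in = close_out = False
    if isinstance(fastq_in, (str, Path)):
        fastq_in = _open(fastq_in, "r")
        close_in = True
    out = None
    if fastq_out is not None:
        if isinstance(fastq_out, (str, Path)):
            out = _open(fastq_out, "w")
            close_out = True
        else:
            out = fastq_out

    counts = ReadQcCounts()
    try:
        for title, seq, qual in _records(fastq_in):
            counts.total += 1
            if len(seq) != len(qual):
                counts.rejected_malformed += 1
                continue
            quals = [ord(c) - 33 for c in qual]
            n = len(seq)
            if n and seq.upper().count("N") / n > rule.max_n_fraction:
                counts.dropped_n += 1
                continue
            if n == 0 or sum(
                q <= rule.low_qual_threshold for q in quals
            ) / n >= rule.max_low_qual_fraction:
                counts.dropped_low_qual += 1
                continue
            counts.kept += 1
            if out is not None:
                out.write(f"@{title}\n{seq}\n+\n{qual}\n")
    finally:
        if close_in:
            fastq_in.close()
        if close_out and out is not None:
            out.close()
    return counts


# ---------------------------------------------------------------------------
# SNP filter cascade

STAGES = (
    "multiallelic",
    "low_support",
    "uniform_pools",
    "parent_inconsistent",
    "quality",
)


@dataclass
class FilterLedger:
    """Per-stage removal accounting; retained + removals == total, always."""

    total: int = 0
    removed_multiallelic: int = 0
    removed_low_support: int = 0
    removed_uniform_pools: int = 0
    removed_parent_inconsistent: int = 0
    removed_quality: int = 0
    retained: int = 0

    def removed(self) -> int:
        return (
            self.removed_multiallelic
            + self.removed_low_support
            + self.removed_uniform_pools
            + self.removed_parent_inconsistent
            + self.removed_quality
        )

    def validate(self) -> None:
        if self.total != self.retained + self.removed():
            raise AssertionError(
                f"ledger violates conservation: total {self.total} != "
                f"retained {self.retained} + removed {self.removed()}"
            )

    def table1_row(self) -> dict[str, int]:
        """Four-removal-column shape: the parent-consistency and quality
        stages are reported as one combined "filtered by the parent" column,
        matching the conventional published layout of this accounting."""
        return {
            "total_snp": self.total,
            "multiple_alleles": self.removed_multiallelic,
            "read_support_lt_4": self.removed_low_support,
            "pool_genotypic_uniformity": self.removed_uniform_pools,
            "filtered_by_parent": self.removed_parent_inconsistent
            + self.removed_quality,
            "high_quality_snp": self.retained,
        }


@dataclass(frozen=True)
class SnpFilterParams:
    min_support: int = 4
    qual_min: float = 30.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    support_mode: str = "per_bulk"  # or "summed"
    strict_parents: bool = False


def _major_allele(ref_d: int, alt_d: int) -> str:
    # tie -> ref, a fixed convention so uniformity is well defined
    return "alt" if alt_d > ref_d else "ref"


def failing_stage(rec: SnpRecord, params: SnpFilterParams) -> str | None:
    """Name of the first cascade stage ``rec`` fails, or None if retained."""
    if len(rec.alt_alleles) > 1:
        return "multiallelic"

    th, tl = rec.total_depth(HIGH), rec.total_depth(LOW)
    if params.support_mode == "per_bulk":
        if th < params.min_support or tl < params.min_support:
            return "low_support"
    elif params.support_mode == "summed":
        if th + tl < params.min_support:
            return "low_support"
    else:
        raise ValueError(f"unknown support_mode {params.support_mode!r}")

    rh, ah = rec.bulk_depths[HIGH]
    rl, al = rec.bulk_depths[LOW]
    if th > 0 and tl > 0:
        same_major = _major_allele(rh, ah) == _major_allele(rl, al)
        # exact index equality at integer-depth resolution, cross-multiplied
        same_index = ah * tl == al * th
        if same_major and same_index:
            return "uniform_pools"

    parent_gts = [
        rec.parent_genotypes.get(k) for k in ("male", "female")
    ]
    if any(g is None for g in parent_gts):
        if params.strict_parents:
            return "parent_inconsistent"
    else:
        parental_alleles = {a for g in parent_gts for a in g}
        alt = rec.alt_alleles[0] if rec.alt_alleles else None
        for depth, allele in ((rh, rec.ref_allele), (ah, alt), (rl, rec.ref_allele), (al, alt)):
            if allele is not None and depth >= params.min_support:
                if allele not in parental_alleles:
                    return "parent_inconsistent"

    if rec.qual is not None and rec.qual < params.qual_min:
        return "quality"
    if rec.qd is not None and rec.qd < params.qd_min:
        return "quality"
    if rec.fs is not None and rec.fs > params.fs_max:
        return "quality"
    if rec.mq is not None and rec.mq < params.mq_min:
        return "quality"
    return None


def filter_snps(
    records: Sequence[SnpRecord],
    params: SnpFilterParams = SnpFilterParams(),
) -> tuple[list[SnpRecord], FilterLedger]:
    """Apply the cascade to coordinate-sorted records.

    Returns the retained records (input order preserved) and the per-stage
    ledger.  Unsorted input is rejected: downstream windowing requires
    (chrom, pos) order and silent re-sorting would hide caller bugs.
    """
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")

    ledger = FilterLedger(total=len(records))
    retained: list[SnpRecord] = []
    for rec in records:
        stage = failing_stage(rec, params)
        if stage is None:
            retained.append(rec)
        else:
            setattr(
                ledger,
                f"removed_{stage}",
                getattr(ledger, f"removed_{stage}") + 1,
            )
    ledger.retained = len(retained)
    ledger.validate()
    return retained, ledger


def write_ledger_tsv(ledger: FilterLedger, path: str | Path) -> None:
    pd.DataFrame([ledger.table1_row()]).to_csv(path, sep="\t", index=False)
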