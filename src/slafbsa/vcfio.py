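"""The SNP record container and its VCF / TSV interfaces.

A :class:`SnpRecord` is one biallelic-or-multiallelic site with the two
parent genotypes, per-bulk ref/alt read depths (from the VCF AD field) and
the hard-filter annotations QUAL, QD, FS and MQ.  VCF reading and writing
go through pysam; the TSV form is a flat headered table for spreadsheets
and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

MALE, FEMALE = "male", "female"
HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]
    parent_genotypes: dict  # {male|female: (allele, allele) | None}
    bulk_depths: dict  # {high|low: (ref_depth, alt_depth)}
    qual: float | None = None
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None

    def __post_init__(self) -> None:
        for bulk, (r, a) in self.bulk_depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth in bulk {bulk}")

    def total_depth(self, bulk: str) -> int:
        r, a = self.bulk_depths[bulk]
        return r + a

    def with_depths(self, high: tuple[int, int], low: tuple[int, int]) -> "SnpRecord":
        return replace(self, bulk_depths={HIGH: high, LOW: low})


def _gt_alleles(sample, rec) -> tuple[str, str] | None:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return None
    alleles = rec.alleles
    return tuple(alleles[a] for a in gt)


def read_snp_records(
    path: str | Path,
    parents: Sequence[str] = ("R01", "R02"),
    bulks: Sequence[str] = ("aa", "ab"),
) -> list[SnpRecord]:
    """Read SNP records from a VCF with per-sample AD fields.

    ``parents`` are the (male, female) sample names, ``bulks`` the
    (high, low) pool sample names.  Only the first ALT depth is used for
    the bulk ref/alt pair; multiallelic sites keep all ALT alleles so the
    filter cascade can reject them.
    """
    male, female = parents
    high, low = bulks
    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue

            def depths(sample_name: str) -> tuple[int, int]:
                ad = rec.samples[sample_name].get("AD")
                if ad is None or ad[0] is None:
                    return (0, 0)
                ref_d = int(ad[0])
                alt_d = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                return (ref_d, alt_d)

            records.append(
                SnpRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts),
                    parent_genotypes={
                        MALE: _gt_alleles(rec.samples[male], rec),
                        FEMALE: _gt_alleles(rec.samples[female], rec),
                    },
                    bulk_depths={HIGH: depths(high), LOW: depths(low)},
                    qual=rec.qual,
                    qd=rec.info.get("QD"),
                    fs=rec.info.get("FS"),
                    mq=rec.info.get("MQ"),
                )
            )
    return records


def _build_header(
    contigs: Iterable[tuple[str, int]],
    parents: Sequence[str],
    bulks: Sequence[str],
) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs:
        h.contigs.add(name, length=length)
    h.info.add("QD", 1, "Float", "Variant quality by depth")
    h.info.add("FS", 1, "Float", "Fisher strand bias (phred)")
    h.info.add("MQ", 1, "Float", "RMS mapping quality")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt...)")
    h.formats.add("DP", 1, "Integer", "Read depth")
    for s in (*parents, *bulks):
        h.add_sample(s)
    return h


def write_snp_records(
    records: Sequence[SnpRecord],
    path: str | Path,
    parents: Sequence[str] = ("R01", "R02"),
    bulks: Sequence[str] = ("aa", "ab"),
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as an uncompressed VCF (parents + two bulk samples)."""
    male, female = parents
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.chrom] = max(contig_lengths.get(r.chrom, 0), r.pos + 1)
    header = _build_header(sorted(contig_lengths.items()), parents, bulks)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref_allele),
                alleles=(r.ref_allele, *r.alt_alleles),
                qual=r.qual,
            )
            if r.qd is not None:
                rec.info["QD"] = r.qd
            if r.fs is not None:
                rec.info["FS"] = r.fs
            if r.mq is not None:
                rec.info["MQ"] = r.mq
            allele_index = {a: i for i, a in enumerate(rec.alleles)}
            for sample_name, key in ((male, MALE), (female, FEMALE)):
                gt = r.parent_genotypes.get(key)
                if gt is not None:
                    rec.samples[sample_name]["GT"] = tuple(
                        allele_index[a] for a in gt
                    )
                else:
                    rec.samples[sample_name]["GT"] = (None, None)
            for sample_name, key in zip(bulks, (HIGH, LOW)):
                ref_d, alt_d = r.bulk_depths[key]
                ad = [ref_d] + [0] * len(r.alt_alleles)
                if r.alt_alleles:
                    ad[1] = alt_d
                rec.samples[sample_name]["AD"] = tuple(ad)
                rec.samples[sample_name]["DP"] = ref_d + alt_d
                rec.samples[sample_name]["GT"] = (0, 1) if alt_d > 0 else (0, 0)
            out.write(rec)


def records_to_frame(records: Sequence[SnpRecord]) -> pd.DataFrame:
    def fmt_gt(gt):
        return "/".join(gt) if gt is not None else "./."

    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref_allele for r in records],
            "alt": [",".join(r.alt_alleles) for r in records],
            "male_gt": [fmt_gt(r.parent_genotypes.get(MALE)) for r in records],
            "female_gt": [fmt_gt(r.parent_genotypes.get(FEMALE)) for r in records],
            "high_ref_depth": [r.bulk_depths[HIGH][0] for r in records],
            "high_alt_depth": [r.bulk_depths[HIGH][1] for r in records],
            "low_ref_depth": [r.bulk_depths[LOW][0] for r in records],
            "low_alt_depth": [r.bulk_depths[LOW][1] for r in records],
            "qual": [r.qual for r in records],
            "qd": [r.qd for r in records],
            "fs": [r.fs for r in records],
            "mq": [r.mq for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[SnpRecord]:
    def parse_gt(s):
        if s in ("./.", ".", "", None) or pd.isna(s):
            return None
        return tuple(s.split("/"))

    records = []
    for r in df.itertuples():
        records.append(
            SnpRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref_allele=r.ref,
                alt_alleles=tuple(str(r.alt).split(",")) if r.alt else (),
                parent_genotypes={MALE: parse_gt(r.male_gt), FEMALE: parse_gt(r.female_gt)},
                bulk_depths={
                    HIGH: (int(r.high_ref_depth), int(r.high_alt_depth)),
                    LOW: (int(r.low_ref_depth), int(r.low_alt_depth)),
                },
                qual=None if pd.isna(r.qual) else float(r.qual),
                qd=None if pd.isna(r.qd) else float(r.qd),
                fs=None if pd.isna(r.fs) else float(r.fs),
                mq=None if pd.isna(r.mq) else float(r.mq),
            )
        )
    return records


def read_snp_tsv(path: str | Path) -> list[SnpRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))


def write_snp_tsv(records: Sequence[SnpRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
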