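"""SNP-index, Δ(SNP-index), sliding windows and null thresholds.

The per-bulk SNP-index at a site is the fraction of reads carrying the
oriented allele; Δ(SNP-index) is high-bulk minus low-bulk.  A sliding
window value m averages Δ over ``window_snps`` consecutive SNPs (step 1
SNP, windows never span chromosomes).  Significance thresholds on |m| come
either from a permutation-style simulation of the unselected F1 null or
from an empirical percentile of the observed windows.

The F1 null models markers heterozygous in one parent and homozygous in
the other: each bulk plant carries the segregating allele at dose 0 or 0.5
(alt-allele fraction of a diploid genotype) with probability 1/2, the pool
allele frequency is the mean plant dose, and read counts are binomial at
that frequency.  The F2 null uses doses {0, 0.5, 1} with probabilities
1/4, 1/2, 1/4.  Window sites are drawn independently, so thresholds are
calibrated for loosely linked markers and are anti-conservative on very
dense maps (as for any method that assumes within-window independence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .vcfio import HIGH, LOW, MALE, FEMALE, SnpRecord

REF_ALT = "ref_alt"
HIGH_PARENT = "high_parent"

F1_DESIGN = "F1_pseudo_testcross"
F2_DESIGN = "F2"


@dataclass(frozen=True)
class SnpIndexPoint:
    chrom: str
    pos: int
    index_high: float
    index_low: float
    delta: float
    depth_high: int
    depth_low: int
    masked: bool = False
    polarization_fallback: bool = False


@dataclass(frozen=True)
class WindowPoint:
    chrom: str
    window_index: int
    midpoint_pos: int
    m: float
    n_snps: int
    start_pos: int  # position of the first member SNP
    end_pos: int  # position of the last member SNP


@dataclass(frozen=True)
class NullThreshold:
    confidence: float
    threshold: float
    method: str  # "simulation" | "empirical_percentile"
    n_replicates: int | None = None
    seed: int | None = None


def _high_parent_allele(rec: SnpRecord, high_parent: str) -> str | None:
    """Allele unique to the high-trait parent, or None if ambiguous."""
    low_parent = FEMALE if high_parent == MALE else MALE
    gt_high = rec.parent_genotypes.get(high_parent)
    gt_low = rec.parent_genotypes.get(low_parent)
    if gt_high is None or gt_low is None:
        return None
    unique = set(gt_high) - set(gt_low)
    if len(unique) != 1:
        return None
    allele = unique.pop()
    if allele not in (rec.ref_allele, *rec.alt_alleles):
        return None
    return allele


def snp_index(
    rec: SnpRecord,
    orientation: str = REF_ALT,
    high_parent: str = MALE,
) -> SnpIndexPoint:
    """Per-bulk SNP-index and Δ at one site.

    ``ref_alt`` orients by the ALT allele (what the VCF gives);
    ``high_parent`` re-polarizes by the allele carried only by the
    high-trait parent when that allele is unambiguous, else falls back to
    ref_alt and marks the point.  A bulk with zero total depth masks the
    whole point — masked points are excluded from windows rather than
    scored 0, which would fake a signal of equality.
    """
    rh, ah = rec.bulk_depths[HIGH]
    rl, al = rec.bulk_depths[LOW]
    th, tl = rh + ah, rl + al
    if th == 0 or tl == 0:
        return SnpIndexPoint(rec.chrom, rec.pos, math.nan, math.nan, math.nan, th, tl, masked=True)

    fallback = False
    orient_alt = True
    if orientation == HIGH_PARENT:
        allele = _high_parent_allele(rec, high_parent)
        if allele is None:
            fallback = True
        else:
            orient_alt = allele != rec.ref_allele
    elif orientation != REF_ALT:
        raise ValueError(f"unknown orientation {orientation!r}")

    if orient_alt:
        ih, il = ah / th, al / tl
    else:
        ih, il = rh / th, rl / tl
    return SnpIndexPoint(
        rec.chrom, rec.pos, ih, il, ih - il, th, tl,
        polarization_fallback=fallback,
    )


def compute_index_points(
    records: Sequence[SnpRecord],
    orientation: str = REF_ALT,
    high_parent: str = MALE,
) -> list[SnpIndexPoint]:
    return [snp_index(r, orientation, high_parent) for r in records]


def select_informative(points: Sequence[SnpIndexPoint]) -> list[SnpIndexPoint]:
    """Points that are unmasked and unambiguously polarized.

    In an F1 pseudo-testcross only markers heterozygous in the scanned
    (high-trait) parent and homozygous in the other segregate with the
    selected gametes; markers segregating from the other parent contribute
    pure bulk-composition noise and markers heterozygous in both parents
    have a different null variance.  Scanning the informative class alone
    (the standard two-way pseudo-testcross practice) is what the simulated
    F1 null is calibrated for.  Requires points computed with the
    ``high_parent`` orientation, where ambiguous markers are flagged.
    """
    return [p for p in points if not p.masked and not p.polarization_fallback]


def sliding_window(
    points: Sequence[SnpIndexPoint],
    window_snps: int = 10,
    step_snps: int = 1,
) -> list[WindowPoint]:
    """Mean Δ over ``window_snps`` consecutive unmasked SNPs per chromosome.

    Points must be sorted by (chrom, pos).  A chromosome with fewer
    unmasked points than the window yields no windows.  The window midpoint
    is the median member position.
    """
    if window_snps < 1 or step_snps < 1:
        raise ValueError("window_snps and step_snps must be >= 1")
    keys = [(p.chrom, p.pos) for p in points]
    if keys != sorted(keys):
        raise ValueError("points must be sorted by (chrom, pos)")

    windows: list[WindowPoint] = []
    by_chrom: dict[str, list[SnpIndexPoint]] = {}
    for p in points:
        if not p.masked:
            by_chrom.setdefault(p.chrom, []).append(p)

    for chrom, pts in by_chrom.items():
        if len(pts) < window_snps:
            continue
        deltas = np.array([p.delta for p in pts])
        positions = np.array([p.pos for p in pts])
        for w, i in enumerate(range(0, len(pts) - window_snps + 1, step_snps)):
            member_d = deltas[i : i + window_snps]
            member_p = positions[i : i + window_snps]
            windows.append(
                WindowPoint(
                    chrom=chrom,
                    window_index=w,
                    midpoint_pos=int(np.median(member_p)),
                    m=float(member_d.mean()),
                    n_snps=window_snps,
                    start_pos=int(member_p[0]),
                    end_pos=int(member_p[-1]),
                )
            )
    return windows


def _nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th order statistic."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q * n))
    return float(sorted_values[min(rank, n) - 1])


def _null_pool_freq(
    rng: np.random.Generator, design: str, bulk_size: int, shape: tuple[int, ...]
) -> np.ndarray:
    if design == F1_DESIGN:
        # dose 0 or 0.5 per plant with p=1/2 (het x hom marker, 1:1)
        return 0.5 * rng.binomial(bulk_size, 0.5, size=shape) / bulk_size
    if design == F2_DESIGN:
        # dose sum = half the count of 2*bulk_size fair alleles
        return rng.binomial(2 * bulk_size, 0.5, size=shape) / (2 * bulk_size)
    raise ValueError(f"unknown design {design!r}")


def simulate_null_threshold(
    bulk_size: int = 30,
    depths: int | Sequence[tuple[int, int]] = 45,
    window_snps: int = 10,
    n_replicates: int = 10_000,
    design: str = F1_DESIGN,
    confidences: Sequence[float] = (0.90, 0.95, 0.99),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[NullThreshold]:
    """Two-sided |m| thresholds from a simulated unselected-population null.

    Each replicate draws ``window_snps`` unlinked sites; at each site both
    bulks independently realise a pool allele frequency for the stated
    cross design and binomial read counts at the given depth.  ``depths``
    is either a constant per-bulk depth or a pool of observed
    (high, low) depth pairs resampled with replacement, preserving the
    data's depth distribution.  Thresholds are nearest-rank quantiles of
    the null |m| sample, so they are monotone in confidence and
    bit-reproducible for a fixed seed.
    """
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    if n_replicates < 1 or window_snps < 1:
        raise ValueError("n_replicates and window_snps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    shape = (n_replicates, window_snps)
    freq_h = _null_pool_freq(rng, design, bulk_size, shape)
    freq_l = _null_pool_freq(rng, design, bulk_size, shape)

    if np.isscalar(depths):
        if int(depths) < 1:
            raise ValueError("depth must be >= 1")
        dh = np.full(shape, int(depths))
        dl = np.full(shape, int(depths))
    else:
        pool = np.asarray(list(depths), dtype=int)
        if pool.ndim != 2 or pool.shape[1] != 2 or len(pool) == 0:
            raise ValueError("depths must be a non-empty sequence of (high, low) pairs")
        pool = pool[(pool[:, 0] >= 1) & (pool[:, 1] >= 1)]
        if len(pool) == 0:
            raise ValueError("no usable depth pairs (all below 1)")
        idx = rng.integers(0, len(pool), size=shape)
        dh, dl = pool[idx, 0], pool[idx, 1]

    alt_h = rng.binomial(dh, freq_h)
    alt_l = rng.binomial(dl, freq_l)
    m = np.abs((alt_h / dh - alt_l / dl).mean(axis=1))
    m.sort()
    return [
        NullThreshold(
            confidence=float(c),
            threshold=_nearest_rank(m, float(c)),
            method="simulation",
            n_replicates=n_replicates,
            seed=seed,
        )
        for c in sorted(confidences)
    ]


def empirical_threshold(
    windows: Sequence[WindowPoint], percentile: float = 99.0
) -> NullThreshold:
    """Nearest-rank percentile of |m| over the observed windows."""
    if not windows:
        raise ValueError("no windows to take a percentile over")
    values = np.sort(np.abs([w.m for w in windows]))
    return NullThreshold(
        confidence=percentile / 100.0,
        threshold=_nearest_rank(values, percentile / 100.0),
        method="empirical_percentile",
    )


# ---------------------------------------------------------------------------
# tabular output


def points_frame(points: Sequence[SnpIndexPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in points],
            "pos": [p.pos for p in points],
            "index_high": [p.index_high for p in points],
            "index_low": [p.index_low for p in points],
            "delta": [p.delta for p in points],
            "depth_high": [p.depth_high for p in points],
            "depth_low": [p.depth_low for p in points],
            "masked": [p.masked for p in points],
        }
    )


def windows_frame(windows: Sequence[WindowPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "window_index": [w.window_index for w in windows],
            "midpoint_pos": [w.midpoint_pos for w in windows],
            "m": [w.m for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "start_pos": [w.start_pos for w in windows],
            "end_pos": [w.end_pos for w in windows],
        }
    )


def windows_from_frame(df: pd.DataFrame) -> list[WindowPoint]:
    return [
        WindowPoint(
            chrom=str(r.chrom),
            window_index=int(r.window_index),
            midpoint_pos=int(r.midpoint_pos),
            m=float(r.m),
            n_snps=int(r.n_snps),
            start_pos=int(r.start_pos),
            end_pos=int(r.end_pos),
        )
        for r in df.itertuples()
    ]


def thresholds_frame(thresholds: Sequence[NullThreshold]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "confidence": [t.confidence for t in thresholds],
            "threshold": [t.threshold for t in thresholds],
            "method": [t.method for t in thresholds],
            "n_replicates": [t.n_replicates for t in thresholds],
            "seed": [t.seed for t in thresholds],
        }
    )


def write_scan_tables(
    points: Sequence[SnpIndexPoint],
    windows: Sequence[WindowPoint],
    thresholds: Sequence[NullThreshold],
    out_prefix: str | Path,
) -> dict[str, Path]:
    out_prefix = Path(out_prefix)
    paths = {
        "points": out_prefix.with_suffix(".snp_index.tsv"),
        "windows": out_prefix.with_suffix(".windows.tsv"),
        "thresholds": out_prefix.with_suffix(".thresholds.tsv"),
    }
    points_frame(points).to_csv(paths["points"], sep="\t", index=False)
    windows_frame(windows).to_csv(paths["windows"], sep="\t", index=False)
    thresholds_frame(thresholds).to_csv(paths["thresholds"], sep="\t", index=False)
    return paths
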