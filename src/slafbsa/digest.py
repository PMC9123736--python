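"""In-silico restriction digestion and SLAF tag prediction.

Reduced-representation libraries of the SLAF / ddRAD family sequence only
restriction fragments falling in a narrow size window.  This module predicts
those fragments ("tags") from a reference genome: it scans for enzyme
recognition motifs, partitions each sequence at the cut positions, selects
fragments by length and flank composition, and scores an enzyme combination
by its repeat content and gene-region coverage.

Coordinates are 0-based half-open throughout; BED output follows the same
convention.
"""

from __future__ import annotations

import gzip
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

SEQ_END = "SEQ_END"

# IUPAC nucleotide codes expanded over the unambiguous alphabet only, so a
# motif letter (including N) never matches an N in the target sequence.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif and top-strand cut offset.

    ``cut_offset`` is the number of bases from the motif start to the cut
    position.  Both built-ins (RsaI GT^AC, HaeIII GG^CC) are blunt cutters
    with palindromic 4-base motifs, so a forward-strand scan finds every
    site.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition motif must be non-empty")
        bad = set(self.recognition) - set(_IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC letters in motif: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the motif")

    def motif_regex(self) -> re.Pattern:
        body = "".join(
            c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in self.recognition
        )
        # lookahead so overlapping occurrences of ambiguous motifs all match
        return re.compile(f"(?={body})")


RSAI = EnzymeSpec("RsaI", "GTAC", 2)
HAEIII = EnzymeSpec("HaeIII", "GGCC", 2)

BUILTIN_ENZYMES = {e.name: e for e in (RSAI, HAEIII)}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: {sorted(BUILTIN_ENZYMES)}"
        ) from None


@dataclass(frozen=True)
class SlafFragment:
    """A predicted restriction fragment (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    left_enzyme: str = SEQ_END
    right_enzyme: str = SEQ_END

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment requires start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_internal(self) -> bool:
        return self.left_enzyme != SEQ_END and self.right_enzyme != SEQ_END


@dataclass
class DigestReport:
    """Summary of one enzyme-combination digest over a genome."""

    n_fragments: int
    n_tags_in_window: int
    size_window: tuple[int, int]
    per_chrom_counts: dict[str, int] = field(default_factory=dict)
    repeat_fraction: float | None = None
    gene_coverage: float | None = None


def find_cut_sites(
    seq: str, enzymes: Sequence[EnzymeSpec]
) -> list[tuple[int, EnzymeSpec]]:
    """All cut positions of ``enzymes`` on the forward strand, sorted.

    The sequence is uppercase-normalised before matching; characters other
    than A/C/G/T/N are rejected.  N never matches any motif letter.
    """
    seq = seq.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    sites: list[tuple[int, EnzymeSpec]] = []
    for enz in enzymes:
        pat = enz.motif_regex()
        sites.extend((m.start() + enz.cut_offset, enz) for m in pat.finditer(seq))
    sites.sort(key=lambda t: (t[0], t[1].name))
    return sites


def digest(seq: str, enzymes: Sequence[EnzymeSpec], chrom: str = "seq") -> list[SlafFragment]:
    """Partition ``seq`` into fragments at every cut site.

    Fragments tile the sequence exactly: they are pairwise disjoint and
    their lengths sum to ``len(seq)``.  An empty sequence yields no
    fragments; a sequence with no sites yields one fragment flanked by
    sequence ends.
    """
    if not seq:
        return []
    n = len(seq)
    boundaries: list[tuple[int, str]] = []
    last_pos = -1
    for pos, enz in find_cut_sites(seq, enzymes):
        if pos <= 0 or pos >= n:
            continue  # cut at a sequence end produces no new fragment
        if pos == last_pos:
            continue  # two enzymes cutting the same position: one boundary
        boundaries.append((pos, enz.name))
        last_pos = pos
    fragments = []
    prev, left = 0, SEQ_END
    for pos, name in boundaries:
        fragments.append(SlafFragment(chrom, prev, pos, left, name))
        prev, left = pos, name
    fragments.append(SlafFragment(chrom, prev, n, left, SEQ_END))
    return fragments


def select_tags(
    fragments: Iterable[SlafFragment],
    size_window: tuple[int, int],
    flank_rule: str = "internal_only",
) -> list[SlafFragment]:
    """Fragments inside the inclusive size window satisfying ``flank_rule``.

    flank_rule:
      ``any``           — size alone decides;
      ``internal_only`` — both flanks must be cut sites (default);
      ``mixed_enzymes`` — internal and the two flanking enzymes differ.
    """
    lo, hi = size_window
    if lo > hi:
        raise ValueError("size window requires min <= max")
    if flank_rule not in ("any", "internal_only", "mixed_enzymes"):
        raise ValueError(f"unknown flank_rule {flank_rule!r}")

    def ok(f: SlafFragment) -> bool:
        if not lo <= f.length <= hi:
            return False
        if flank_rule == "any":
            return True
        if not f.is_internal:
            return False
        if flank_rule == "mixed_enzymes":
            return f.left_enzyme != f.right_enzyme
        return True

    return [f for f in fragments if ok(f)]


def softmask_intervals(raw_seq: str, chrom: str = "seq") -> list[tuple[int, int]]:
    """0-based half-open runs of soft-masked (lowercase) bases."""
    return [(m.start(), m.end()) for m in re.finditer(r"[acgtn]+", raw_seq)]


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_bases(start: int, end: int, merged: list[tuple[int, int]]) -> int:
    starts = [s for s, _ in merged]
    total = 0
    i = max(bisect_right(starts, start) - 1, 0)
    while i < len(merged) and merged[i][0] < end:
        s, e = merged[i]
        total += max(0, min(end, e) - max(start, s))
        i += 1
    return total


def score_enzyme_combination(
    fragments: Iterable[SlafFragment],
    gene_intervals: Mapping[str, Sequence[tuple[int, int]]],
    mask_intervals: Mapping[str, Sequence[tuple[int, int]]],
    size_window: tuple[int, int],
    flank_rule: str = "internal_only",
) -> DigestReport:
    """Score a digest by repeat content and gene coverage of selected tags.

    ``repeat_fraction`` is the proportion of tag bases falling in soft-mask
    intervals; ``gene_coverage`` the proportion of tags overlapping at least
    one gene interval.  With no selected tags both are reported missing
    (None).
    """
    fragments = list(fragments)
    tags = select_tags(fragments, size_window, flank_rule)
    per_chrom: dict[str, int] = {}
    for t in tags:
        per_chrom[t.chrom] = per_chrom.get(t.chrom, 0) + 1
    report = DigestReport(
        n_fragments=len(fragments),
        n_tags_in_window=len(tags),
        size_window=(size_window[0], size_window[1]),
        per_chrom_counts=per_chrom,
    )
    if not tags:
        return report
    mask_merged = {c: _merge(iv) for c, iv in mask_intervals.items()}
    gene_merged = {c: _merge(iv) for c, iv in gene_intervals.items()}
    tag_bases = sum(t.length for t in tags)
    masked = sum(
        _overlap_bases(t.start, t.end, mask_merged.get(t.chrom, [])) for t in tags
    )
    in_gene = sum(
        1
        for t in tags
        if _overlap_bases(t.start, t.end, gene_merged.get(t.chrom, [])) > 0
    )
    report.repeat_fraction = masked / tag_bases
    report.gene_coverage = in_gene / len(tags)
    return report


# ---------------------------------------------------------------------------
# genome-level convenience + file interfaces


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA file, gzip-transparent.

    Sequences are returned as stored (soft-masking preserved).
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def digest_genome(
    fasta: str | Path,
    enzymes: Sequence[EnzymeSpec],
    size_window: tuple[int, int] = (314, 364),
    flank_rule: str = "internal_only",
    gene_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[list[SlafFragment], DigestReport]:
    """Digest every sequence of a FASTA and score the combination.

    Soft-mask intervals are taken from lowercase runs in the FASTA itself.
    """
    all_fragments: list[SlafFragment] = []
    mask: dict[str, list[tuple[int, int]]] = {}
    for name, raw in read_fasta(fasta):
        mask[name] = softmask_intervals(raw)
        all_fragments.extend(digest(raw, enzymes, chrom=name))
    report = score_enzyme_combination(
        all_fragments, gene_intervals or {}, mask, size_window, flank_rule
    )
    return all_fragments, report


def write_tags_bed(tags: Iterable[SlafFragment], path: str | Path) -> None:
    """BED (0-based half-open): name = left/right enzyme, score = length."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t"
                f"{t.left_enzyme}/{t.right_enzyme}\t{t.length}\n"
            )


def write_report_tsv(report: DigestReport, path: str | Path) -> None:
    import pandas as pd

    row = {
        "n_fragments": report.n_fragments,
        "n_tags_in_window": report.n_tags_in_window,
        "window_min_bp": report.size_window[0],
        "window_max_bp": report.size_window[1],
        "repeat_fraction": "NA" if report.repeat_fraction is None else report.repeat_fraction,
        "gene_coverage": "NA" if report.gene_coverage is None else report.gene_coverage,
    }
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def write_per_chrom_tsv(report: DigestReport, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"chrom": c, "n_tags": n} for c, n in sorted(report.per_chrom_counts.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "n_tags"]).to_csv(path, sep="\t", index=False)
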