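"""Forward simulation of an F1 bulked-segregant experiment.

Two heterozygous outcrossing parents are crossed; every F1 plant receives
one recombinant gamete from each parent (Haldane map function, no
interference).  Markers heterozygous in exactly one parent segregate 1:1
in the F1 (pseudo-testcross); markers heterozygous in both segregate
1:2:1; markers homozygous for different alleles in the two parents are
monomorphic in the F1 and exist to exercise the pool-uniformity filter.

One causal locus plus Gaussian environmental noise produces a 0-100%
quantitative trait; the phenotypic extremes form the bulks, and pooled
read depths are Poisson/binomial with optional sequencing error.  All
outputs round-trip through the package's own FASTA/GFF3/VCF/TSV readers,
so every pipeline stage is testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import digest as dg
from . import phenotypes as ph
from .vcfio import FEMALE, HIGH, LOW, MALE, SnpRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: a 305-plant F1, 30+30 extreme bulks,
    ~45X pooled and ~10X parental depth, one causal locus on a dense
    single-chromosome marker map."""

    seed: int = 0
    n_plants: int = 305
    bulk_size: int = 30
    n_chroms: int = 1
    chrom_length_bp: int = 80_000_000
    n_markers: int = 2000
    marker_het_fraction: float = 0.45  # per parent, independently
    causal_pos: int | None = None  # None -> middle of chromosome 1
    causal_effect: float = 12.0  # trait units per unit alt-allele dose
    trait_mean: float = 28.0
    trait_sd: float = 6.0  # environmental
    recomb_rate: float = 1.25e-8  # Morgans per bp
    # Probability that a heterozygous marker carries its alt allele on the
    # first (founder) haplotype.  Divergent-cultivar parents are effectively
    # founder-line hybrids, so their heterozygous markers share linkage
    # phase; 1.0 models that fully coherent case, 0.5 random phase (which
    # makes window-averaged delta self-cancelling and the scan powerless).
    phase_coherence: float = 1.0
    bulk_depth_mean: float = 45.0
    parent_depth_mean: float = 10.0
    seq_error: float = 0.001
    violation_fraction: float = 0.0  # sites given a planted filter violation

    def __post_init__(self) -> None:
        if self.n_plants < 2 * self.bulk_size:
            raise ValueError("n_plants must be >= 2 * bulk_size")
        if not 0 <= self.marker_het_fraction <= 1:
            raise ValueError("marker_het_fraction must lie in [0, 1]")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if not 0 <= self.violation_fraction <= 1:
            raise ValueError("violation_fraction must lie in [0, 1]")
        if not 0 <= self.phase_coherence <= 1:
            raise ValueError("phase_coherence must lie in [0, 1]")
        if self.bulk_depth_mean <= 0 or self.parent_depth_mean <= 0:
            raise ValueError("depth means must be > 0")


@dataclass
class SimTruth:
    """Ground truth stored alongside outputs for recovery tests."""

    seed: int
    causal_chrom: str
    causal_pos: int
    causal_marker_index: int
    high_ids: list[str]
    low_ids: list[str]
    trait_values: list[float]
    expected_delta_at_causal: float
    n_markers: int
    planted_in_window_fragments: int | None = None

    def to_json_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimTruth":
        return cls(**d)


@dataclass
class F1Population:
    chroms: list[str]
    marker_chrom: np.ndarray  # (M,) int chromosome index
    positions: np.ndarray  # (M,) 1-based bp
    male_haplotypes: np.ndarray  # (2, M) 0/1 alleles
    female_haplotypes: np.ndarray
    doses: np.ndarray  # (n_plants, M) alt-allele fraction in {0, 0.5, 1}
    causal_marker_index: int
    male_gametes: np.ndarray | None = None  # (n_plants, M) transmitted alleles
    female_gametes: np.ndarray | None = None

    @property
    def causal_doses(self) -> np.ndarray:
        return self.doses[:, self.causal_marker_index]


def _marker_positions(config: SimulationConfig, rng: np.random.Generator):
    per = [config.n_markers // config.n_chroms] * config.n_chroms
    for i in range(config.n_markers % config.n_chroms):
        per[i] += 1
    chrom_idx, positions = [], []
    for c, n in enumerate(per):
        pos = np.sort(rng.integers(1, config.chrom_length_bp, size=n))
        # bump duplicates so positions are strictly increasing
        for i in range(1, n):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        chrom_idx.extend([c] * n)
        positions.extend(pos.tolist())
    return np.array(chrom_idx), np.array(positions)


def _meiosis(
    hap: np.ndarray,
    marker_chrom: np.ndarray,
    positions: np.ndarray,
    n_gametes: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamete alleles (n_gametes, M) from a phased diploid parent.

    Crossovers between adjacent markers occur with the Haldane
    recombination fraction r = (1 - exp(-2 d)) / 2 for map distance d in
    Morgans; chromosomes assort independently.
    """
    m = hap.shape[1]
    out = np.empty((n_gametes, m), dtype=np.int8)
    for c in np.unique(marker_chrom):
        idx = np.flatnonzero(marker_chrom == c)
        d = np.diff(positions[idx]) * recomb_rate
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        start = rng.integers(0, 2, size=(n_gametes, 1))
        switches = (rng.random((n_gametes, len(d))) < r).astype(np.int8)
        states = np.cumsum(np.hstack([start, switches]), axis=1) % 2
        out[:, idx] = hap[states, idx[None, :]]
    return out


def simulate_parents_and_f1(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[F1Population, SimTruth]:
    """Parent haplotypes and the F1 genotype (dose) matrix.

    The causal marker is forced to the pseudo-testcross class
    (heterozygous in the male parent, homozygous reference in the female)
    so it segregates 1:1 and its alt-allele dose is 0 or 0.5.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marker_chrom, positions = _marker_positions(config, rng)
    m = config.n_markers

    het_m = rng.random(m) < config.marker_het_fraction
    het_f = rng.random(m) < config.marker_het_fraction

    def phased(het: np.ndarray, hom_allele: np.ndarray) -> np.ndarray:
        hap = np.tile(hom_allele, (2, 1)).astype(np.int8)
        on_first = rng.random(m) < config.phase_coherence
        hap[0, het] = np.where(on_first[het], 1, 0)
        hap[1, het] = 1 - hap[0, het]
        return hap

    # markers het in neither parent: fixed for different alleles so the F1
    # is uniformly heterozygous there (pool-uniformity fodder)
    neither = ~het_m & ~het_f
    hom_m = np.zeros(m, dtype=np.int8)
    hom_f = np.zeros(m, dtype=np.int8)
    hom_f[neither] = 1

    # causal marker: het male x hom-ref female
    causal_pos = config.causal_pos
    if causal_pos is None:
        causal_pos = config.chrom_length_bp // 2
    chrom0 = marker_chrom == 0
    causal_idx = int(
        np.flatnonzero(chrom0)[np.argmin(np.abs(positions[chrom0] - causal_pos))]
    )
    het_m[causal_idx] = True
    het_f[causal_idx] = False
    hom_f[causal_idx] = 0

    male_hap = phased(het_m, hom_m)
    female_hap = phased(het_f, hom_f)

    gam_m = _meiosis(
        male_hap, marker_chrom, positions, config.n_plants, config.recomb_rate, rng
    )
    gam_f = _meiosis(
        female_hap, marker_chrom, positions, config.n_plants, config.recomb_rate, rng
    )
    doses = (gam_m + gam_f) / 2.0

    chroms = [f"chr{c + 1}" for c in range(config.n_chroms)]
    pop = F1Population(
        chroms=chroms,
        marker_chrom=marker_chrom,
        positions=positions,
        male_haplotypes=male_hap,
        female_haplotypes=female_hap,
        doses=doses,
        causal_marker_index=causal_idx,
        male_gametes=gam_m,
        female_gametes=gam_f,
    )
    truth = SimTruth(
        seed=config.seed,
        causal_chrom=chroms[0],
        causal_pos=int(positions[causal_idx]),
        causal_marker_index=causal_idx,
        high_ids=[],
        low_ids=[],
        trait_values=[],
        expected_delta_at_causal=0.0,
        n_markers=m,
    )
    return pop, truth


def simulate_trait(
    pop: F1Population, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Trait = mean + effect x causal dose + N(0, sd), clipped to [0, 100]."""
    trait = (
        config.trait_mean
        + config.causal_effect * pop.causal_doses
        + (rng.normal(0.0, config.trait_sd, size=config.n_plants) if config.trait_sd > 0 else 0.0)
    )
    return np.clip(trait, 0.0, 100.0)


def _parent_gt(hap: np.ndarray, j: int, ref: str, alt: str) -> tuple[str, str]:
    return tuple(alt if a else ref for a in hap[:, j])


def simulate_pooled_reads(
    pop: F1Population,
    high_idx: np.ndarray,
    low_idx: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SnpRecord]:
    """Pooled read counts per site per bulk, as VCF-shaped SNP records.

    True pool allele frequency is the mean plant dose; total depth is
    Poisson around the configured mean; alt counts are binomial at the
    error-adjusted frequency.  Parent samples get their true genotypes.
    Hard-filter annotations are drawn comfortably inside the retention
    thresholds; a configured fraction of sites instead receives one
    planted violation so the filter cascade has true positives to find.
    """
    m = config.n_markers
    freq_h = pop.doses[high_idx].mean(axis=0)
    freq_l = pop.doses[low_idx].mean(axis=0)
    e = config.seq_error
    obs_h = freq_h * (1 - e) + (1 - freq_h) * e
    obs_l = freq_l * (1 - e) + (1 - freq_l) * e

    depth_h = rng.poisson(config.bulk_depth_mean, size=m)
    depth_l = rng.poisson(config.bulk_depth_mean, size=m)
    alt_h = rng.binomial(depth_h, obs_h)
    alt_l = rng.binomial(depth_l, obs_l)

    ref_base = rng.integers(0, 4, size=m)
    alt_base = (ref_base + rng.integers(1, 4, size=m)) % 4

    qual = np.clip(rng.normal(500.0, 120.0, size=m), 50.0, None)
    qd = np.clip(rng.normal(25.0, 5.0, size=m), 5.0, 40.0)
    fs = rng.exponential(4.0, size=m)
    mq = np.clip(rng.normal(59.0, 1.0, size=m), 45.0, 60.0)

    violate = rng.random(m) < config.violation_fraction
    kind = rng.integers(0, 5, size=m)  # which violation a flagged site gets

    records: list[SnpRecord] = []
    # order by chromosome NAME then position, matching the (chrom, pos)
    # string sort the filter cascade enforces
    labels = np.array([pop.chroms[c] for c in pop.marker_chrom])
    order = np.lexsort((pop.positions, labels))
    for j in order:
        chrom = pop.chroms[pop.marker_chrom[j]]
        ref, alt = _BASES[ref_base[j]], _BASES[alt_base[j]]
        alts: tuple[str, ...] = (alt,)
        q, qdj, fsj, mqj = qual[j], qd[j], fs[j], mq[j]
        dh, ah = int(depth_h[j]), int(alt_h[j])
        dl, al = int(depth_l[j]), int(alt_l[j])
        if violate[j]:
            k = kind[j]
            if k == 0:  # multiallelic
                third = _BASES[(ref_base[j] + alt_base[j]) % 4]
                if third not in (ref, alt):
                    alts = (alt, third)
            elif k == 1:  # insufficient support in one bulk
                dh, ah = 3, min(ah, 3)
            elif k == 2:
                q = 10.0
            elif k == 3:
                qdj = 1.0
            else:
                mqj = 20.0
        records.append(
            SnpRecord(
                chrom=chrom,
                pos=int(pop.positions[j]),
                ref_allele=str(ref),
                alt_alleles=alts,
                parent_genotypes={
                    MALE: _parent_gt(pop.male_haplotypes, j, ref, alt),
                    FEMALE: _parent_gt(pop.female_haplotypes, j, ref, alt),
                },
                bulk_depths={HIGH: (dh - ah, ah), LOW: (dl - al, al)},
                qual=float(q),
                qd=float(qdj),
                fs=float(fsj),
                mq=float(mqj),
            )
        )
    return records


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    population: F1Population
    phenotypes: list[ph.PlantPhenotype]
    assignment: ph.BulkAssignment
    records: list[SnpRecord]
    truth: SimTruth


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedExperiment:
    """Genotypes -> trait -> extreme bulks -> pooled reads, with truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop, truth = simulate_parents_and_f1(config, rng)
    trait = simulate_trait(pop, config, rng)

    width = len(str(config.n_plants))
    ids = [f"F1-{i + 1:0{width}d}" for i in range(config.n_plants)]
    stem = rng.uniform(80.0, 120.0, size=config.n_plants)
    phenos = [
        ph.PlantPhenotype(ids[i], float(stem[i]), float(stem[i] * trait[i] / 100.0))
        for i in range(config.n_plants)
    ]
    assignment = ph.select_bulks(phenos, config.bulk_size)
    id_to_idx = {pid: i for i, pid in enumerate(ids)}
    high_idx = np.array([id_to_idx[i] for i in assignment.high_ids])
    low_idx = np.array([id_to_idx[i] for i in assignment.low_ids])

    records = simulate_pooled_reads(pop, high_idx, low_idx, config, rng)

    truth.high_ids = list(assignment.high_ids)
    truth.low_ids = list(assignment.low_ids)
    truth.trait_values = [float(t) for t in trait]
    cd = pop.causal_doses
    truth.expected_delta_at_causal = float(cd[high_idx].mean() - cd[low_idx].mean())
    return SimulatedExperiment(config, pop, phenos, assignment, records, truth)


# ---------------------------------------------------------------------------
# planted-digest toy genome


def _scrub_motifs(seq: list[str], protected: set[int], motifs: Sequence[str], rng) -> None:
    """Mutate bases until no motif occurs outside the protected positions."""
    text = "".join(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        for motif in motifs:
            start = text.find(motif)
            while start != -1:
                span = set(range(start, start + len(motif)))
                free = sorted(span - protected)
                if free:
                    i = free[0]
                    old = seq[i]
                    choices = [b for b in "ACGT" if b != old]
                    seq[i] = choices[int(rng.integers(0, 3))]
                    changed = True
                start = text.find(motif, start + 1)
        if changed:
            continue
    # final verification
    text = "".join(seq)
    for motif in motifs:
        i = text.find(motif)
        while i != -1:
            if not set(range(i, i + len(motif))) <= protected:
                raise AssertionError("motif scrubbing failed to converge")
            i = text.find(motif, i + 1)


def build_planted_genome(
    rng: np.random.Generator,
    n_in_window: int = 7,
    n_out_window: int = 13,
    size_window: tuple[int, int] = (314, 364),
    enzymes: Sequence[dg.EnzymeSpec] = (dg.RSAI, dg.HAEIII),
) -> tuple[str, int]:
    """A synthetic sequence whose internal fragments are known by construction.

    Returns (sequence, number of internal fragments inside the size
    window).  Fragment lengths are chosen first; enzyme motifs are then
    planted at the implied cut positions and all accidental motif
    occurrences elsewhere are scrubbed, so an exact digest must recover
    exactly the planted fragments.
    """
    lo, hi = size_window
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_in_window)]
    for _ in range(n_out_window):
        if rng.random() < 0.5:
            lengths.append(int(rng.integers(30, lo - len(max(e.recognition for e in enzymes)) - 1)))
        else:
            lengths.append(int(rng.integers(hi + 2, hi + 400)))
    lengths = [lengths[i] for i in rng.permutation(len(lengths))]

    lead, tail = int(rng.integers(50, 150)), int(rng.integers(50, 150))
    cuts = [lead]
    for L in lengths:
        cuts.append(cuts[-1] + L)
    total = cuts[-1] + tail

    seq = [str(_BASES[i]) for i in rng.integers(0, 4, size=total)]
    protected: set[int] = set()
    motifs = [e.recognition for e in enzymes]
    for c in cuts:
        enz = enzymes[int(rng.integers(0, len(enzymes)))]
        start = c - enz.cut_offset
        for k, base in enumerate(enz.recognition):
            seq[start + k] = base
            protected.add(start + k)
    _scrub_motifs(seq, protected, motifs, rng)
    n_in = sum(1 for L in lengths if lo <= L <= hi)
    assert n_in == n_in_window
    return "".join(seq), n_in


# ---------------------------------------------------------------------------
# fixture emission


def _write_fasta(path: Path, entries: Sequence[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in entries],
        str(path),
        "fasta",
    )


def _write_gff3(path: Path, genes: Sequence[tuple[str, int, int, str, str]]) -> None:
    """genes: (chrom, start0, end0, strand, gene_id) in 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, gid in genes:
            fh.write(
                f"{chrom}\tslafbsa_sim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid};Name={gid}\n"
            )


def _random_genes(
    rng: np.random.Generator,
    chrom: str,
    chrom_length: int,
    n_genes: int,
    min_len: int = 20_000,
    max_len: int = 200_000,
) -> list[tuple[str, int, int, str, str]]:
    """Non-overlapping genes placed left to right with random gaps."""
    genes = []
    slot = max(chrom_length // max(n_genes, 1), min_len + 2)
    cursor = int(rng.integers(0, max(slot // 2, 1)))
    for i in range(n_genes):
        length = int(rng.integers(min_len, max_len))
        if cursor + length >= chrom_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((chrom, cursor, cursor + length, strand, f"{chrom}_g{i + 1:04d}"))
        gap_hi = max(slot - length, 2)
        cursor += length + int(rng.integers(1, gap_hi))
    return genes


def emit_fixtures(
    config: SimulationConfig,
    out_dir: str | Path,
    force: bool = False,
    n_genes_per_chrom: int = 120,
) -> dict[str, Path]:
    """Write a complete synthetic study to ``out_dir``.

    Files: genome.fasta (a miniature contig with planted restriction
    fragments, for the digestion stage), genes.gff3 (random non-overlapping
    genes on the simulated chromosomes plus the demo contig),
    variants.vcf (parents + two bulk pools with AD), phenotypes.tsv and
    truth.json.  Refuses a non-empty output directory unless ``force``.
    """
    from . import vcfio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")

    rng = np.random.default_rng(config.seed)
    exp = simulate_experiment(config, rng)

    demo_seq, n_in_window = build_planted_genome(rng)
    exp.truth.planted_in_window_fragments = n_in_window

    paths = {
        "fasta": out_dir / "genome.fasta",
        "gff3": out_dir / "genes.gff3",
        "vcf": out_dir / "variants.vcf",
        "phenotypes": out_dir / "phenotypes.tsv",
        "truth": out_dir / "truth.json",
    }
    _write_fasta(paths["fasta"], [("digest_demo", demo_seq)])

    genes: list[tuple[str, int, int, str, str]] = []
    for chrom in exp.population.chroms:
        genes.extend(
            _random_genes(rng, chrom, config.chrom_length_bp, n_genes_per_chrom)
        )
    genes.extend(_random_genes(rng, "digest_demo", len(demo_seq), 5, 200, 800))
    _write_gff3(paths["gff3"], genes)

    vcfio.write_snp_records(
        exp.records,
        paths["vcf"],
        contig_lengths={c: config.chrom_length_bp for c in exp.population.chroms},
    )
    ph.phenotype_frame(exp.phenotypes)[
        ["plant_id", "stem_weight_g", "bast_weight_g"]
    ].to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(exp.truth.to_json_dict(), fh, indent=1)
    return paths


def load_truth(path: str | Path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_json_dict(json.load(fh))
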