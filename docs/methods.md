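# Methods

## Scope

`slafbsa` implements the computational core of a SLAF-seq + bulked-segregant
(BSA) study of a quantitative trait in an outcrossing F1 population:

1. in-silico double restriction digestion of a reference genome and SLAF tag
   prediction by fragment size selection;
2. fiber-content phenotyping and extreme-bulk selection;
3. read-level QC rules and a five-stage SNP hard-filter cascade with exact
   per-stage accounting;
4. the SNP-index / Δ(SNP-index) sliding-window scan with simulation-derived
   significance thresholds;
5. candidate-region calling and gene annotation;
6. a forward simulator of the whole experiment, used for testing, calibration
   checks and power analysis.

Alignment, variant calling, duplicate marking, effect prediction and
functional enrichment are upstream/downstream of this package and are not
reimplemented.

## Tag prediction

Recognition motifs (IUPAC, expanded over A/C/G/T only — an N in the target
never matches) are located on the forward strand; RsaI (GT^AC) and HaeIII
(GG^CC) are palindromic blunt cutters, so the forward scan finds every
genomic site. Cut positions partition each sequence into fragments that tile
it exactly; fragments are selected as tags when their length falls in the
inclusive window (default 314–364 bp) and their flanks satisfy one of three
rules (`any`, `internal_only` — the default, requiring both flanks to be cut
sites — or `mixed_enzymes`). Repeat content is measured against soft-masked
(lowercase) reference bases; gene coverage is the fraction of tags
overlapping at least one GFF3 gene interval. Coordinates are 0-based
half-open everywhere, including BED output.

## Filter cascade

Stages run in a fixed order and each SNP is charged to the *first* stage it
fails, so `retained + Σ removed = total` holds by construction (the ledger
refuses to report otherwise). The stages: (1) more than one ALT allele;
(2) read support below 4 in either bulk (a per-bulk reading of "read support
less than four"; a summed mode is available); (3) genotypic uniformity of
the two pools — same major allele and exactly equal SNP-index at
integer-depth resolution, the weakest rule consistent with "consistent
genotypes between pools"; (4) parental provenance — every allele observed at
≥ 4 reads in a bulk must be carried by at least one parent; (5) the hard
filters QUAL < 30, QD < 2.0, FS > 60.0, MQ < 40.0, applied exactly at those
printed boundaries. Missing parent genotypes pass stage 4 unless
`strict_parents` is set; missing quality annotations pass stage 5.
The four-column report combines stages 4–5 into one "filtered by the
parent" column to match the conventional table shape, while the in-memory
ledger keeps them separate.

Read QC drops a read when undetermined bases exceed 10% of its length or
when bases at Q ≤ 10 make up at least 50% of it ("more than half" is applied
inclusively, the conservative reading). Records whose sequence and quality
lengths disagree are rejected individually; this requires the four-line
FASTQ layout.

## The scan statistic and its null

Per bulk, the SNP-index at a site is the fraction of reads carrying the
oriented allele; Δ(SNP-index) = index(high bulk) − index(low bulk). The
`ref_alt` orientation uses the ALT allele as the VCF gives it; the
`high_parent` orientation re-polarizes by the allele carried only by the
high-trait parent when that allele is unambiguous and flags the point
otherwise. A bulk with zero depth masks the whole point (scored-as-zero
would fabricate equality). The window statistic m averages Δ over 10
consecutive unmasked SNPs, step 1, never across chromosomes; the window
midpoint is the median member position.

Thresholds on |m| come from a 10,000-replicate simulation of the unselected
null. For the F1 pseudo-testcross design, each of the 10 window sites draws
each bulk's pool allele frequency as the mean of 30 plant doses taking
values 0 or 0.5 (the alt-allele fraction of a diploid genotype heterozygous
in one parent, segregating 1:1) and then binomial read counts at the site's
depth; the F2 design uses doses {0, 0.5, 1} with probabilities ¼, ½, ¼.
Depths are either constant (unit tests) or resampled with replacement from
the observed per-site bulk depth pairs, preserving the data's depth
distribution. Thresholds are nearest-rank quantiles of |m| — monotone in
confidence and bit-reproducible per seed. At 30+30 bulks and ~45X pools the
99% threshold computes to ≈ 0.09–0.10 on the Δ scale. An empirical
percentile of the observed |m| distribution is available as the alternative
thresholding method.

Two modelling notes. First, the dose scale: a 1:1-segregating marker in a
het × hom cross yields genotype alt-fractions of 0 or 0.5, which is the
scale used here (consistent with the F2 doses); treating plant doses as 0/1
would double the segregation variance and push the 99% threshold to ≈ 0.14,
inconsistent with the ≈ 0.10 the statistic produces at these designs and
depths. Second, window sites are drawn *independently* in the null. On
densely linked maps the members of a real window are correlated, so the
threshold is anti-conservative there — a property of any method with this
independence assumption. The calibration test therefore uses marker maps
whose adjacent spacing is large in map units; on dense maps the threshold
should be read as a screening device, as reflected in the region-level
candidate counts.

## Informative-marker scanning

In an F1 pseudo-testcross only markers heterozygous in the scanned parent
and homozygous in the other segregate with the gametes that selection acts
on. Markers segregating only from the other parent contribute pure
bulk-composition noise, and markers heterozygous in both parents have twice
the null's segregation variance. The recommended scan for F1 designs
(`orientation=high_parent` plus `select_informative`, or
`informative_only: true` in the pipeline config) therefore keeps only
unambiguously polarized markers — the class the simulated null is
calibrated for. Empirically this mode is both calibrated (see below) and
markedly more powerful than scanning every marker.

## Region calling

Maximal runs of windows with |m| ≥ threshold become candidate regions; a
run may bridge up to `max_gap_snps` consecutive below-threshold windows
(default 0). Runs whose genomic spans overlap (possible because
neighbouring runs share member SNPs) are unioned, so regions per chromosome
are disjoint and sorted. A region spans from its first member window's
first SNP to its last member window's last SNP — anchored at SNP positions,
not window midpoints. Genes overlap a region when their half-open intervals
share ≥ 1 bp, strand ignored; duplicate gene ids keep the first occurrence.
Both the per-region gene counts and the deduplicated union are reported,
since a gene can straddle two regions.

## The simulator

`SimulationConfig` defaults emulate the study conditions: 305 F1 plants from
two heterozygous outcrossing parents, 30+30 extreme bulks, pooled
sequencing at 45X per bulk and 10X per parent, 2,000 markers on one
80 Mb chromosome at 1.25 cM/Mb (≈ 1 Morgan), one causal locus on a 0–100%
trait with mean 28, environmental SD 6 and effect 12 trait units per unit
alt dose (locus h² = 0.2, a major QTL at the detection floor — see Power).

Markers are heterozygous in each parent independently with probability
0.45; markers heterozygous in neither are fixed for different alleles
(monomorphic in the F1 — fodder for the uniformity filter). The causal
marker is forced into the pseudo-testcross class (het in the male parent,
hom-ref in the female). Gametes recombine under the Haldane map function
with no interference; chromosomes assort independently. Linkage phase is
founder-coherent by default (`phase_coherence = 1.0`): each parent's alt
alleles sit on one designated haplotype, as expected for parents that are
hybrids of divergent breeding lines. This matters: with random phase the
window-averaged Δ self-cancels around a causal locus (marker signs
alternate) and no window scan of this type can work — coherent phase is the
implicit assumption that makes the published design meaningful.

Pool allele frequency at a site is the mean plant dose; total depth is
Poisson, alt counts binomial at the error-adjusted frequency (sequencing
error 0.001 flips alleles symmetrically). Parents are emitted with their
true genotypes; QUAL/QD/FS/MQ are drawn comfortably inside the retention
thresholds except for a configurable fraction of sites given one planted
violation. Fixture emission writes FASTA (a miniature contig whose
restriction fragments are planted by construction, with accidental motif
occurrences scrubbed), GFF3 (non-overlapping random genes), VCF, a
phenotype TSV whose bast/stem weights reproduce the simulated trait
exactly, and a truth JSON for recovery tests.

What the simulator deliberately omits: read-level FASTQ of tags, mapping
and calling artefacts (depth is Poisson, not clustered; no strand bias),
sex chromosomes and dioecy, multi-QTL architectures (single locus by
default), and non-uniform recombination. Passing tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to alignment or calling pathologies.

## Calibration and power (computed by the test suite and acceptance script)

*Type I:* with no causal locus, 30+30 bulks, 45X depth and 2,000 markers
spaced to be effectively unlinked, the fraction of windows above the 99%
simulated threshold pools to ≈ 0.011–0.012 over 10 seeds, within
0.01 + 3·SE.

*Power:* with effect/sd = 2 on the dense default map, the spec of the
20-seed check (top-scoring region contains the causal position, regions
merged across gaps of ≤ 10 windows) passes at ≥ 95% on the canonical seed
sequence; the long-run rate measured over 60 seeds is ≈ 88%, i.e. this
effect size sits at the detection edge for top-region localisation, and the
causal locus lies in *some* called region in nearly every replicate.
Stronger loci (effect/sd ≥ 2.5) localise in the top region essentially
always. Localisation precision at these designs is a few Mb — candidate
regions are screening intervals, not fine-mapped loci.

## Numerical conventions

Nearest-rank percentiles throughout (platform-reproducible); exact integer
cross-multiplication for SNP-index equality in the uniformity filter; ties
in bulk selection broken by plant id (ascending into the high bulk,
descending into the low, so complete ties still give disjoint bulks); all
randomness flows through one seeded NumPy generator per run, and identical
config + seed reproduce outputs byte-for-byte (content-hashed in the
pipeline manifest).
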