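"""The F1 forward simulator: segregation, trait model, pooled reads, fixtures."""

import json

import numpy as np
import pytest

from slafbsa import digest as dg
from slafbsa import qc, regions as rg, scan as sc, vcfio
from slafbsa.simulate import (
    F1Population,
    SimulationConfig,
    build_planted_genome,
    emit_fixtures,
    load_truth,
    simulate_experiment,
    simulate_parents_and_f1,
    simulate_pooled_reads,
    simulate_trait,
)


def tiny_config(**kw):
    base = dict(
        seed=5,
        n_plants=100,
        bulk_size=10,
        n_markers=200,
        chrom_length_bp=10_000_000,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestMeiosis:
    def test_no_recombination_transmits_intact_haplotypes(self):
        config = tiny_config(recomb_rate=0.0, n_chroms=2)
        pop, _ = simulate_parents_and_f1(config)
        for c in np.unique(pop.marker_chrom):
            idx = pop.marker_chrom == c
            for plant in range(config.n_plants):
                gam = pop.male_gametes[plant, idx]
                h0 = pop.male_haplotypes[0, idx]
                h1 = pop.male_haplotypes[1, idx]
                assert np.array_equal(gam, h0) or np.array_equal(gam, h1)

    def test_one_to_one_segregation_frequency(self):
        # pseudo-testcross causal marker: E[dose] = 0.25 over many plants
        config = tiny_config(n_plants=10_000, bulk_size=10, n_markers=50)
        pop, _ = simulate_parents_and_f1(config)
        doses = pop.causal_doses
        assert set(np.unique(doses)) <= {0.0, 0.5}
        se = np.sqrt(0.0625 / config.n_plants)
        assert abs(doses.mean() - 0.25) < 3 * se

    def test_fixed_seed_reproduces_matrix(self):
        config = tiny_config()
        a, _ = simulate_parents_and_f1(config)
        b, _ = simulate_parents_and_f1(config)
        assert np.array_equal(a.doses, b.doses)
        assert np.array_equal(a.positions, b.positions)

    def test_recombination_decorrelates_distant_markers(self):
        config = tiny_config(n_plants=2000, recomb_rate=5e-7)  # 5 Morgan map
        pop, _ = simulate_parents_and_f1(config)
        gam = pop.male_gametes
        het = pop.male_haplotypes[0] != pop.male_haplotypes[1]
        idx = np.flatnonzero(het)
        first, last = idx[0], idx[-1]
        r = np.corrcoef(gam[:, first], gam[:, last])[0, 1]
        assert abs(r) < 0.1  # ~unlinked across 5 Morgans


class TestTrait:
    def test_no_noise_yields_discrete_classes(self, rng):
        config = tiny_config(trait_sd=0.0, causal_effect=10.0)
        pop, _ = simulate_parents_and_f1(config)
        trait = simulate_trait(pop, config, rng)
        assert 2 <= len(np.unique(trait)) <= 3

    def test_null_effect_gives_no_bulk_separation_at_causal(self):
        config = tiny_config(causal_effect=0.0, n_plants=305, bulk_size=30)
        exp = simulate_experiment(config)
        # random bulks: delta at causal is pure drift, SD ~ 0.065
        assert abs(exp.truth.expected_delta_at_causal) < 0.2

    def test_locus_heritability_matches_analytic_ratio(self):
        config = SimulationConfig(seed=9, n_plants=2000, bulk_size=30,
                                  n_markers=200, chrom_length_bp=10_000_000,
                                  causal_effect=12.0, trait_sd=6.0)
        rng = np.random.default_rng(config.seed)
        pop, _ = simulate_parents_and_f1(config, rng)
        trait = simulate_trait(pop, config, rng)
        genetic = config.causal_effect * pop.causal_doses
        h2 = genetic.var() / trait.var()
        # analytic: var(effect*dose)/(var(effect*dose)+sd^2) = 9/45 = 0.2
        assert h2 == pytest.approx(0.2, abs=0.04)

    def test_trait_clipped_to_percent_scale(self, rng):
        config = tiny_config(trait_mean=95.0, causal_effect=30.0, trait_sd=20.0)
        pop, _ = simulate_parents_and_f1(config)
        trait = simulate_trait(pop, config, rng)
        assert trait.max() <= 100.0 and trait.min() >= 0.0


def constant_pop(n_plants=20, n_markers=30, dose=1.0):
    return F1Population(
        chroms=["chr1"],
        marker_chrom=np.zeros(n_markers, dtype=int),
        positions=np.arange(1, n_markers + 1) * 100,
        male_haplotypes=np.ones((2, n_markers), dtype=np.int8),
        female_haplotypes=np.ones((2, n_markers), dtype=np.int8),
        doses=np.full((n_plants, n_markers), dose),
        causal_marker_index=0,
    )


class TestPooledReads:
    def test_fixed_pool_all_alt(self, rng):
        config = tiny_config(n_plants=20, bulk_size=5, n_markers=30, seq_error=0.0)
        pop = constant_pop()
        records = simulate_pooled_reads(pop, np.arange(5), np.arange(5, 10), config, rng)
        for rec in records:
            for bulk in ("high", "low"):
                ref_d, alt_d = rec.bulk_depths[bulk]
                assert ref_d == 0  # frequency 1.0: every read is alt

    def test_depth_mean_matches_poisson_oracle(self, rng):
        config = tiny_config(n_plants=20, bulk_size=5, n_markers=1000)
        pop = constant_pop(n_markers=1000, dose=0.5)
        records = simulate_pooled_reads(pop, np.arange(5), np.arange(5, 10), config, rng)
        depths = np.array([sum(r.bulk_depths["high"]) for r in records])
        se = np.sqrt(config.bulk_depth_mean / len(records))
        assert abs(depths.mean() - config.bulk_depth_mean) < 3 * se

    def test_records_sorted_for_cascade(self):
        config = tiny_config(n_chroms=3, n_markers=300)
        exp = simulate_experiment(config)
        keys = [(r.chrom, r.pos) for r in exp.records]
        assert keys == sorted(keys)

    def test_planted_violations_are_found_by_cascade(self):
        config = tiny_config(violation_fraction=0.3, n_markers=1000)
        exp = simulate_experiment(config)
        _, ledger = qc.filter_snps(exp.records)
        assert ledger.removed() > 0.2 * ledger.total
        clean = simulate_experiment(tiny_config(n_markers=1000))
        _, clean_ledger = qc.filter_snps(clean.records)
        assert clean_ledger.removed() < 0.05 * clean_ledger.total


class TestPlantedGenome:
    def test_digest_recovers_planted_fragment_count(self, rng):
        seq, n_in = build_planted_genome(rng, n_in_window=7, n_out_window=13)
        frags = dg.digest(seq, [dg.RSAI, dg.HAEIII])
        tags = dg.select_tags(frags, (314, 364), "internal_only")
        assert len(tags) == n_in == 7

    def test_no_stray_motifs(self, rng):
        seq, _ = build_planted_genome(rng, n_in_window=3, n_out_window=3)
        cuts = dg.find_cut_sites(seq, [dg.RSAI, dg.HAEIII])
        frags = dg.digest(seq, [dg.RSAI, dg.HAEIII])
        assert len(frags) == len(cuts) + 1  # every motif is a planted boundary


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    config = tiny_config(n_markers=400)
    paths = emit_fixtures(config, out / "study")
    return config, paths


class TestFixtures:
    def test_truth_roundtrip(self, fixture_dir):
        _, paths = fixture_dir
        truth = load_truth(paths["truth"])
        with open(paths["truth"]) as fh:
            raw = json.load(fh)
        assert truth.to_json_dict() == raw
        assert truth.causal_pos > 0
        assert len(truth.high_ids) == len(truth.low_ids) == 10

    def test_fasta_planted_fragments_match_digest(self, fixture_dir):
        _, paths = fixture_dir
        truth = load_truth(paths["truth"])
        _, report = dg.digest_genome(paths["fasta"], [dg.RSAI, dg.HAEIII])
        assert report.n_tags_in_window == truth.planted_in_window_fragments

    def test_vcf_roundtrip_preserves_depths(self, fixture_dir):
        config, paths = fixture_dir
        exp = simulate_experiment(config)
        back = vcfio.read_snp_records(paths["vcf"])
        assert len(back) == len(exp.records)
        for a, b in zip(exp.records, back):
            assert (a.chrom, a.pos) == (b.chrom, b.pos)
            assert a.bulk_depths == b.bulk_depths
            assert a.parent_genotypes == b.parent_genotypes
            assert a.qd == pytest.approx(b.qd, rel=1e-5)

    def test_phenotypes_reproduce_trait(self, fixture_dir):
        from slafbsa import phenotypes as ph

        config, paths = fixture_dir
        truth = load_truth(paths["truth"])
        phenos = ph.read_phenotypes(paths["phenotypes"])
        contents = [p.fiber_content for p in phenos]
        assert contents == pytest.approx(truth.trait_values, abs=1e-6)

    def test_gff_readable(self, fixture_dir):
        _, paths = fixture_dir
        genes = rg.read_genes_gff3(paths["gff3"])
        assert len(genes) > 10
        assert all(g.start < g.end for g in genes)

    def test_refuses_nonempty_dir(self, fixture_dir, tmp_path):
        config, _ = fixture_dir
        (tmp_path / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            emit_fixtures(config, tmp_path)


class TestEndToEndRecovery:
    def test_pipeline_recovers_causal_locus(self):
        """simulate -> filter -> scan -> regions localises the planted QTL."""
        config = SimulationConfig(seed=1)
        exp = simulate_experiment(config)
        retained, _ = qc.filter_snps(exp.records)
        points = sc.compute_index_points(retained, orientation=sc.HIGH_PARENT)
        informative = sc.select_informative(points)
        windows = sc.sliding_window(informative, 10)
        depths = [(p.depth_high, p.depth_low) for p in informative]
        th = sc.simulate_null_threshold(
            bulk_size=config.bulk_size,
            depths=depths,
            n_replicates=10_000,
            confidences=(0.99,),
            seed=101,
        )[0]
        regions = rg.call_regions(windows, th, max_gap_snps=10)
        assert regions
        top = max(regions, key=lambda r: abs(r.peak_m))
        assert top.start <= exp.truth.causal_pos <= top.end
        assert np.sign(top.peak_m) == np.sign(exp.truth.expected_delta_at_causal)
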