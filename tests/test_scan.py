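"""SNP-index arithmetic, sliding windows and null thresholds."""

import numpy as np
import pytest

from slafbsa import scan as sc
from slafbsa.vcfio import HIGH, LOW, MALE, FEMALE, SnpRecord


def make_record(pos, high, low, male=("A", "G"), female=("A", "A"), chrom="chr1"):
    return SnpRecord(
        chrom=chrom,
        pos=pos,
        ref_allele="A",
        alt_alleles=("G",),
        parent_genotypes={MALE: male, FEMALE: female},
        bulk_depths={HIGH: high, LOW: low},
        qual=100.0,
        qd=20.0,
        fs=1.0,
        mq=59.0,
    )


class TestSnpIndex:
    def test_forced_arithmetic(self):
        p = sc.snp_index(make_record(1, (10, 30), (30, 10)))
        assert p.index_high == 0.75
        assert p.index_low == 0.25
        assert p.delta == 0.50

    def test_symmetric_depths_zero_delta(self):
        p = sc.snp_index(make_record(1, (20, 20), (10, 10)))
        assert p.delta == 0.0

    def test_zero_depth_masks_point(self):
        p = sc.snp_index(make_record(1, (0, 0), (10, 10)))
        assert p.masked
        assert np.isnan(p.delta)

    def test_random_records_match_raw_ad_recomputation(self, rng):
        records = [
            make_record(
                int(pos),
                (int(a), int(b)),
                (int(c), int(d)),
            )
            for pos, (a, b, c, d) in enumerate(rng.integers(1, 60, size=(100, 4)), 1)
        ]
        points = sc.compute_index_points(records)
        for rec, p in zip(records, points):
            rh, ah = rec.bulk_depths[HIGH]
            rl, al = rec.bulk_depths[LOW]
            assert p.delta == pytest.approx(ah / (rh + ah) - al / (rl + al))
            assert -1 <= p.delta <= 1

    def test_high_parent_orientation_flips_to_parent_allele(self):
        # male parent carries ref-only relative to female -> orient by ref
        rec = make_record(1, (30, 10), (10, 30), male=("A", "G"), female=("G", "G"))
        p = sc.snp_index(rec, orientation=sc.HIGH_PARENT)
        assert not p.polarization_fallback
        assert p.index_high == 0.75  # ref fraction, not alt
        assert p.delta == 0.50

    def test_high_parent_ambiguous_falls_back(self):
        rec = make_record(1, (10, 30), (30, 10), male=("A", "G"), female=("A", "G"))
        p = sc.snp_index(rec, orientation=sc.HIGH_PARENT)
        assert p.polarization_fallback
        assert p.index_high == 0.75  # ref_alt fallback

    def test_select_informative_drops_fallback_and_masked(self):
        records = [
            make_record(1, (10, 30), (30, 10)),  # informative
            make_record(2, (10, 30), (30, 10), female=("A", "G")),  # ambiguous
            make_record(3, (0, 0), (30, 10)),  # masked
        ]
        pts = sc.compute_index_points(records, orientation=sc.HIGH_PARENT)
        kept = sc.select_informative(pts)
        assert [p.pos for p in kept] == [1]


class TestSlidingWindow:
    def _points(self, deltas, chrom="chr1", start_pos=1):
        return [
            sc.SnpIndexPoint(chrom, start_pos + i, 0.5 + d / 2, 0.5 - d / 2, d, 40, 40)
            for i, d in enumerate(deltas)
        ]

    def test_single_window_mean(self):
        ws = sc.sliding_window(self._points([0.2] * 10), 10)
        assert len(ws) == 1
        assert ws[0].m == pytest.approx(0.2)
        assert ws[0].n_snps == 10

    def test_window_count_with_step_one(self):
        ws = sc.sliding_window(self._points([0.1] * 12), 10)
        assert len(ws) == 3

    def test_short_chromosome_yields_no_windows(self):
        ws = sc.sliding_window(self._points([0.1] * 9), 10)
        assert ws == []

    def test_windows_never_span_chromosomes(self):
        pts = self._points([0.1] * 10, chrom="chr1") + self._points(
            [0.3] * 10, chrom="chr2"
        )
        ws = sc.sliding_window(pts, 10)
        assert len(ws) == 2
        assert {w.chrom for w in ws} == {"chr1", "chr2"}
        assert ws[0].m != ws[1].m

    def test_masked_points_excluded(self):
        pts = self._points([0.4] * 5) + [
            sc.SnpIndexPoint("chr1", 6, np.nan, np.nan, np.nan, 0, 40, masked=True)
        ] + self._points([0.4] * 6, start_pos=7)
        ws = sc.sliding_window(pts, 10)
        assert len(ws) == 2  # 11 unmasked points -> 2 windows of 10
        assert all(w.m == pytest.approx(0.4) for w in ws)

    def test_random_windows_match_naive_means(self, rng):
        deltas = rng.uniform(-1, 1, size=200)
        pts = self._points(list(deltas))
        ws = sc.sliding_window(pts, 10)
        assert len(ws) == 191
        for i, w in enumerate(ws):
            assert w.m == pytest.approx(np.mean(deltas[i : i + 10]))
            assert abs(w.m) <= 1
            assert w.start_pos == pts[i].pos
            assert w.end_pos == pts[i + 9].pos
            assert w.midpoint_pos == int(np.median([p.pos for p in pts[i : i + 10]]))

    def test_unsorted_points_rejected(self):
        pts = self._points([0.1] * 10)[::-1]
        with pytest.raises(ValueError, match="sorted"):
            sc.sliding_window(pts, 10)


class TestSimulatedNullThreshold:
    def test_monotone_in_confidence(self):
        ths = sc.simulate_null_threshold(
            n_replicates=2000, confidences=(0.90, 0.95, 0.99), seed=5
        )
        values = [t.threshold for t in ths]
        assert values == sorted(values)

    def test_seed_determinism_bit_for_bit(self):
        a = sc.simulate_null_threshold(n_replicates=2000, seed=7)
        b = sc.simulate_null_threshold(n_replicates=2000, seed=7)
        assert [t.threshold for t in a] == [t.threshold for t in b]

    def test_self_consistent_across_seeds(self):
        # two independent simulations agree within Monte-Carlo error
        a = sc.simulate_null_threshold(n_replicates=10_000, seed=1)
        b = sc.simulate_null_threshold(n_replicates=10_000, seed=2)
        for ta, tb in zip(a, b):
            assert ta.threshold == pytest.approx(tb.threshold, abs=0.005)

    def test_large_bulk_and_depth_limit_shrinks_threshold(self):
        ths = sc.simulate_null_threshold(
            bulk_size=20_000,
            depths=50_000,
            n_replicates=2000,
            confidences=(0.99,),
            seed=3,
        )
        assert ths[0].threshold < 0.01

    def test_f2_null_wider_than_f1(self):
        f1 = sc.simulate_null_threshold(
            n_replicates=5000, design=sc.F1_DESIGN, confidences=(0.99,), seed=4
        )
        f2 = sc.simulate_null_threshold(
            n_replicates=5000, design=sc.F2_DESIGN, confidences=(0.99,), seed=4
        )
        # 1:2:1 segregation has twice the dose variance of 1:1
        assert f2[0].threshold > f1[0].threshold

    def test_depth_pair_resampling_mode(self):
        pairs = [(40, 50)] * 10
        ths = sc.simulate_null_threshold(
            depths=pairs, n_replicates=2000, confidences=(0.99,), seed=6
        )
        assert 0 < ths[0].threshold < 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bulk_size": 0},
            {"depths": 0},
            {"n_replicates": 0},
            {"design": "backcross"},
            {"depths": []},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        args = {"n_replicates": 100, **kwargs}
        with pytest.raises(ValueError):
            sc.simulate_null_threshold(**args)


class TestEmpiricalThreshold:
    def _windows(self, ms):
        return [
            sc.WindowPoint("chr1", i, i * 10 + 5, m, 10, i * 10 + 1, i * 10 + 10)
            for i, m in enumerate(ms)
        ]

    def test_constant_m(self):
        th = sc.empirical_threshold(self._windows([0.3] * 20), 99)
        assert th.threshold == pytest.approx(0.3)
        assert th.method == "empirical_percentile"

    def test_nearest_rank_on_uniform_grid(self):
        # |m| = 0.01..1.00; nearest-rank 99th percentile = 99th order stat
        ms = [i / 100 for i in range(1, 101)]
        th = sc.empirical_threshold(self._windows(ms), 99)
        assert th.threshold == pytest.approx(0.99)
        th90 = sc.empirical_threshold(self._windows(ms), 90)
        assert th90.threshold == pytest.approx(0.90)

    def test_sign_ignored(self):
        th = sc.empirical_threshold(self._windows([-0.5, 0.1, 0.2]), 99)
        assert th.threshold == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.empirical_threshold([], 99)


class TestScanOnSimulatedData:
    def test_points_and_windows_bounded(self, small_experiment):
        from slafbsa import qc

        retained, _ = qc.filter_snps(small_experiment.records)
        points = sc.compute_index_points(retained)
        ws = sc.sliding_window(points, 10)
        assert all(abs(p.delta) <= 1 for p in points if not p.masked)
        assert all(abs(w.m) <= 1 for w in ws)

    def test_tables_roundtrip(self, small_experiment, tmp_path):
        from slafbsa import qc

        retained, _ = qc.filter_snps(small_experiment.records)
        points = sc.compute_index_points(retained)
        ws = sc.sliding_window(points, 10)
        ths = sc.simulate_null_threshold(n_replicates=500, seed=0)
        paths = sc.write_scan_tables(points, ws, ths, tmp_path / "scan")
        import pandas as pd

        back = sc.windows_from_frame(pd.read_csv(paths["windows"], sep="\t"))
        assert len(back) == len(ws)
        assert back[0].m == pytest.approx(ws[0].m)
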