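import numpy as np
import pytest
from scipy import stats

from hervlink.core import GenomeLayout, GenomicInterval, GeneAnnotation, ValidationError
from hervlink.parclip import (
    Peak,
    WindowedTrack,
    bound_fraction_by_expression,
    call_enriched_windows,
    classify_peak_context,
    peak_conversion_rate,
    read_peaks,
    stringent_peak_set,
    write_peaks,
)

from conftest import random_intervals
from oracles import brute_stringent


def make_peak(chrom="chr1", start=0, end=500, reads=100.0, conv=0,
              lib=1_000_000, pid=None):
    return Peak(
        GenomicInterval(chrom, start, end, id=pid),
        read_counts=(reads,),
        library_sizes=(lib,),
        conversion_count=conv,
    )


class TestPeakModel:
    def test_replicate_arity_enforced(self):
        with pytest.raises(ValidationError):
            Peak(GenomicInterval("chr1", 0, 100), (10.0, 20.0), (1_000_000,))

    def test_rpkm_is_mean_of_per_replicate_rpkm(self):
        p = Peak(
            GenomicInterval("chr1", 0, 1000),
            read_counts=(10.0, 40.0),
            library_sizes=(1_000_000, 2_000_000),
        )
        assert p.rpkm == pytest.approx((10.0 + 20.0) / 2)

    def test_conversion_rate(self):
        assert peak_conversion_rate(make_peak(reads=100, conv=10)) == 0.1
        assert peak_conversion_rate(make_peak(reads=50, conv=0)) == 0.0
        with pytest.raises(ValueError):
            peak_conversion_rate(make_peak(reads=0))


class TestWindowCaller:
    @pytest.fixture
    def layout(self):
        return GenomeLayout({"chr1": 10_000})

    def track(self, layout, values):
        return WindowedTrack(layout, 100, {"chr1": np.asarray(values, float)})

    def test_no_enrichment_no_peaks(self, layout):
        flat = self.track(layout, np.full(100, 5.0))
        assert call_enriched_windows(flat, flat) == []

    def test_binomial_tail_oracle(self, layout):
        # one window with IP 50 over input 5: strong fold enrichment and a
        # conditional binomial upper tail below 1e-5, so it must be called
        ip = np.full(100, 5.0)
        ip[7] = 50.0
        control = np.full(100, 5.0)
        scale = ip.sum() / control.sum()
        share = scale / (1 + scale)
        assert stats.binom.sf(49, 55, share) < 1e-5
        peaks = call_enriched_windows(
            self.track(layout, ip), self.track(layout, control),
            min_fold=2, alpha=1e-5,
        )
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (700, 800)

    def test_adjacent_windows_merge(self, layout):
        ip = np.full(100, 5.0)
        ip[10] = 60.0
        ip[11] = 70.0
        peaks = call_enriched_windows(
            self.track(layout, ip), self.track(layout, np.full(100, 5.0))
        )
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (1000, 1200)
        assert peaks[0].read_total == pytest.approx(130.0)

    def test_mismatched_grid_rejected(self, layout):
        other = GenomeLayout({"chr1": 10_000})
        with pytest.raises(ValueError):
            call_enriched_windows(
                self.track(layout, np.zeros(100)),
                WindowedTrack(other, 200, {"chr1": np.ones(50)}),
            )

    def test_false_call_rate_bounded_under_exchangeable_null(self, layout):
        # IP and input both Poisson(20): called fraction <= alpha within
        # 3 binomial SEs
        rng = np.random.default_rng(0)
        alpha = 0.01
        n_windows, n_rep = 100, 50
        called = 0
        for _ in range(n_rep):
            ip = self.track(layout, rng.poisson(20.0, n_windows).astype(float))
            ct = self.track(layout, rng.poisson(20.0, n_windows).astype(float))
            for p in call_enriched_windows(ip, ct, min_fold=1.0, alpha=alpha):
                called += p.interval.length // 100
        total = n_windows * n_rep
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert called / total <= alpha + 3 * se


class TestStringentSet:
    def test_three_rules_worked_example(self):
        rep1 = [make_peak(start=100, end=600, reads=12, pid="p1")]  # rpkm 24
        rep2 = [make_peak(start=150, end=650, reads=10)]
        cluster = [make_peak(start=300, end=340, reads=5, conv=2, pid="c1")]
        kept = stringent_peak_set(rep1, rep2, cluster)
        assert [p.interval.id for p in kept] == ["p1"]
        assert kept[0].supporting_clusters == ("c1",)
        # RPKM below the cutoff: excluded
        low = [make_peak(start=100, end=600, reads=4, pid="p1")]  # rpkm 8
        assert stringent_peak_set(low, rep2, cluster) == []
        # no conversion-cluster support: excluded
        assert stringent_peak_set(rep1, rep2, [make_peak(start=5000, end=5040, conv=1)]) == []

    def test_cluster_without_conversions_rejected(self):
        with pytest.raises(ValidationError):
            stringent_peak_set([], [], [make_peak(conv=0)])

    def test_matches_brute_force_on_random_instances(self, toy_layout):
        rng = np.random.default_rng(21)
        for _ in range(100):
            def peaks(n, prefix, conv=0):
                ivs = random_intervals(rng, toy_layout, n, prefix=prefix)
                return [
                    Peak(iv, (float(rng.integers(1, 40)),), (1_000_000,),
                         conversion_count=conv)
                    for iv in ivs
                ]
            rep1 = peaks(15, "r1")
            rep2 = peaks(15, "r2")
            clusters = peaks(10, "c", conv=1)
            cutoff = float(rng.uniform(0, 30))
            got = [p.interval.id for p in
                   stringent_peak_set(rep1, rep2, clusters, cutoff)]
            assert got == brute_stringent(rep1, rep2, clusters, cutoff)

    def test_output_subset_and_order_invariance(self, toy_layout):
        rng = np.random.default_rng(9)
        rep1 = [make_peak(start=s, end=s + 200, reads=30, pid=f"p{s}")
                for s in range(0, 4000, 400)]
        rep2 = [make_peak(start=s + 50, end=s + 250) for s in range(0, 4000, 800)]
        clusters = [make_peak(start=s + 10, end=s + 60, conv=1)
                    for s in range(0, 4000, 800)]
        kept = stringent_peak_set(rep1, rep2, clusters)
        ids1 = {p.interval.id for p in kept}
        assert ids1 <= {p.interval.id for p in rep1}
        shuffled = stringent_peak_set(
            rep1,
            [rep2[i] for i in rng.permutation(len(rep2))],
            [clusters[i] for i in rng.permutation(len(clusters))],
        )
        assert {p.interval.id for p in shuffled} == ids1

    def test_monotone_in_rpkm_cutoff(self, toy_layout):
        rng = np.random.default_rng(13)
        rep1 = [
            Peak(iv, (float(rng.integers(1, 50)),), (1_000_000,))
            for iv in random_intervals(rng, toy_layout, 30, prefix="p")
        ]
        rep2 = [Peak(iv, (1.0,), (1_000_000,))
                for iv in random_intervals(rng, toy_layout, 30)]
        clusters = [Peak(iv, (1.0,), (1_000_000,), conversion_count=1)
                    for iv in random_intervals(rng, toy_layout, 20)]
        sizes = [
            len(stringent_peak_set(rep1, rep2, clusters, cutoff))
            for cutoff in (50, 20, 10, 5, 0)
        ]
        assert sizes == sorted(sizes)


class TestContextClassification:
    def test_precedence_coding_over_lincRNA_over_intergenic(self):
        genes = [
            GeneAnnotation(GenomicInterval("chr1", 0, 1000, "+"), "c1", "coding"),
            GeneAnnotation(GenomicInterval("chr1", 500, 2000, "+"), "l1", "lincRNA"),
        ]
        peaks = [
            make_peak(start=600, end=700),    # overlaps both -> coding
            make_peak(start=1500, end=1600),  # lincRNA only
            make_peak(start=5000, end=5100),  # nothing
        ]
        summary = classify_peak_context(peaks, genes)
        assert (summary.coding, summary.lincRNA, summary.intergenic) == (1, 1, 1)
        assert summary.total == len(peaks)


class TestBoundFractionByExpression:
    def test_fraction_and_empty_bin(self):
        expr = {f"g{i}": float(i) for i in range(10)}  # 0..9
        bound = {"g1", "g2", "g3", "g8"}
        fr = bound_fraction_by_expression(bound, expr, bins=[0, 5, 10, 20])
        assert fr[0] == pytest.approx(3 / 5)
        assert fr[1] == pytest.approx(1 / 5)
        assert fr[2] is None  # empty bin is undefined, never 0

    def test_unknown_bound_id_rejected(self):
        with pytest.raises(ValidationError):
            bound_fraction_by_expression({"gX"}, {"g1": 1.0}, [0, 10])

    def test_planted_monotone_binding_recovered(self):
        # binding probability rising with expression bin should give
        # non-decreasing fractions up to binomial noise at n=200/bin
        rng = np.random.default_rng(2)
        bins = [0, 1, 10, 50, 1000]
        probs = [0.05, 0.2, 0.5, 0.9]
        expr, bound = {}, set()
        gid = 0
        for k, p in enumerate(probs):
            lo, hi = bins[k], min(bins[k + 1], 200)
            for _ in range(200):
                g = f"g{gid}"; gid += 1
                expr[g] = float(rng.uniform(lo, hi))
                if rng.random() < p:
                    bound.add(g)
        fr = bound_fraction_by_expression(bound, expr, bins)
        assert all(f is not None for f in fr)
        tol = 3 * np.sqrt(0.25 / 200)
        assert all(b >= a - 2 * tol for a, b in zip(fr, fr[1:]))


class TestPeakIO:
    def test_nine_column_round_trip(self, tmp_path):
        peaks = [make_peak(start=100, end=600, reads=42, conv=5, pid="pk1"),
                 make_peak(start=900, end=1200, reads=7, conv=1, pid="pk2")]
        path = tmp_path / "peaks.bed"
        write_peaks(peaks, path)
        back = read_peaks(path)
        assert [(p.interval.id, p.read_total, p.conversion_count) for p in back] == [
            ("pk1", 42.0, 5), ("pk2", 7.0, 1)
        ]
        for orig, rt in zip(peaks, back):
            assert rt.rpkm == pytest.approx(orig.rpkm, rel=0.01)
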