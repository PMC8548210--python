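import math

import numpy as np
import pytest
from scipy import stats

from hervlink.core import GeneAnnotation, GenomicInterval, ValidationError
from hervlink.diffsignal import (
    PSEUDOCOUNT_RPKM,
    SampleInfo,
    SignalMatrix,
    bh_fdr,
    bound_region_fraction,
    call_degs,
    differential_regions,
    differential_to_tsv,
    estimate_common_dispersion,
    hervh_copy_table,
    quantile_normalize,
    read_signal_matrix,
    region_metaprofile,
    signal_correlation,
    specificity_filter,
    write_signal_matrix,
)
from hervlink.diffsignal import _exact_test_pvalue, _pooled_dispersion
from hervlink.parclip import Peak


def sample(i, condition="WT", antibody="H3K27ac", lib=1_000_000):
    return SampleInfo(f"{condition}_rep{i}", condition, antibody, i, lib)


def matrix_from(values, conditions, antibody="H3K27ac", libs=None, regions=None):
    values = np.asarray(values, dtype=float)
    n_regions, n_samples = values.shape
    if regions is None:
        regions = tuple(
            GenomicInterval("chr1", 1000 * i, 1000 * i + 500, id=f"r{i}")
            for i in range(n_regions)
        )
    reps = {}
    samples = []
    for j, cond in enumerate(conditions):
        reps[cond] = reps.get(cond, 0) + 1
        lib = libs[j] if libs else 1_000_000
        samples.append(SampleInfo(f"{cond}_rep{reps[cond]}", cond, antibody, reps[cond], lib))
    return SignalMatrix(regions, tuple(samples), values)


class TestSignalMatrix:
    def test_shape_and_negativity_validated(self):
        with pytest.raises(ValidationError):
            matrix_from(np.ones((2, 3)), ["WT", "WT"])
        with pytest.raises(ValidationError):
            matrix_from([[-1.0, 2.0]], ["WT", "KO"])

    def test_rpkm_cells(self):
        m = matrix_from([[10.0, 20.0]], ["WT", "KO"], libs=[1_000_000, 2_000_000])
        # region length 500 bp
        assert m.rpkm()[0, 0] == pytest.approx(10 / 0.5 / 1.0)
        assert m.rpkm()[0, 1] == pytest.approx(20 / 0.5 / 2.0)

    def test_sample_index_filters(self):
        m = matrix_from(np.ones((1, 4)), ["WT", "WT", "KO", "KO"])
        assert m.sample_index(condition="KO") == [2, 3]
        assert m.sample_index(condition="KO", replicate=1) == [2]


class TestQuantileNormalize:
    def test_worked_example(self):
        m = matrix_from(np.array([[1.0, 4.0], [2.0, 6.0], [3.0, 8.0]]), ["WT", "KO"])
        out = quantile_normalize(m)
        assert out.normalized and not m.normalized
        expected = np.array([[2.5, 2.5], [4.0, 4.0], [5.5, 5.5]])
        np.testing.assert_allclose(out.values, expected)

    def test_columns_identical_after_normalization(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.gamma(2, 50, size=(100, 4)), ["WT", "WT", "KO", "KO"])
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_ties_share_reference_mean(self):
        m = matrix_from(np.array([[5.0, 1.0], [5.0, 2.0], [9.0, 3.0]]), ["WT", "KO"])
        out = quantile_normalize(m)
        # the two tied 5s span reference ranks 1-2 -> both get their mean
        assert out.values[0, 0] == out.values[1, 0]

    def test_groups_normalized_separately(self, caplog):
        vals = np.array([[1.0, 100.0, 7.0], [2.0, 200.0, 7.0]])
        m = SignalMatrix(
            (
                GenomicInterval("chr1", 0, 500, id="r0"),
                GenomicInterval("chr1", 1000, 1500, id="r1"),
            ),
            (sample(1, antibody="A"), sample(2, antibody="A"), sample(1, antibody="B")),
            vals,
        )
        out = quantile_normalize(m, group_by="antibody")
        # antibody B has one sample: untouched, with a warning
        np.testing.assert_allclose(out.values[:, 2], [7.0, 7.0])
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])


class TestSpecificityFilter:
    def test_worked_example(self):
        # region lengths 500 bp, libraries 1e6 -> rpkm = count * 2
        vals = np.array(
            [
                [10.0, 10.0, 1.0, 1.0],   # wt rpkm 20, ko rpkm 2 -> keep
                [10.0, 10.0, 8.0, 8.0],   # fold ~1.2 -> drop
                [0.2, 0.2, 0.0, 0.0],     # wt rpkm 0.4 < 1 -> drop
            ]
        )
        m = matrix_from(vals, ["WT", "WT", "KO", "KO"])
        assert specificity_filter(m, "WT", "KO") == [0]

    def test_missing_condition_rejected(self):
        m = matrix_from(np.ones((1, 2)), ["WT", "WT"])
        with pytest.raises(ValueError):
            specificity_filter(m, "WT", "KO")


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(400, 4)).astype(float)
        assert estimate_common_dispersion(counts) < 0.02

    def test_pooled_estimator_recovers_nb_dispersion(self):
        rng = np.random.default_rng(2)
        phi, mu = 0.1, 100.0
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(3000, 4)).astype(float)
        est = _pooled_dispersion(counts)
        assert est == pytest.approx(phi, rel=0.15)

    def test_median_estimator_is_spec_contract(self):
        counts = np.array([[10.0, 10.0, 10.0]])  # zero variance
        assert estimate_common_dispersion(counts) == 0.0
        with pytest.raises(ValueError):
            estimate_common_dispersion(np.array([1.0, 2.0]))


class TestExactTest:
    def test_symmetric_in_group_labels(self):
        p1 = _exact_test_pvalue(30, 70, 3, 3, 0.05)
        p2 = _exact_test_pvalue(70, 30, 3, 3, 0.05)
        assert p1 == pytest.approx(p2)

    def test_balanced_observation_is_not_significant(self):
        assert _exact_test_pvalue(50, 50, 3, 3, 0.05) > 0.5
        assert _exact_test_pvalue(0, 0, 3, 3, 0.05) == 1.0

    def test_poisson_limit_matches_binomial(self):
        # phi -> 0 reduces to an exact binomial two-sided test
        pmf = stats.binom.pmf(np.arange(61), 60, 0.5)
        expected = pmf[pmf <= pmf[40] * (1 + 1e-12)].sum()
        assert _exact_test_pvalue(40, 20, 2, 2, 0.0) == pytest.approx(expected)

    def test_overdispersion_weakens_evidence(self):
        p_poisson = _exact_test_pvalue(80, 40, 3, 3, 0.0)
        p_nb = _exact_test_pvalue(80, 40, 3, 3, 0.3)
        assert p_nb > p_poisson


class TestBhFdr:
    def test_textbook_oracle(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            bh_fdr([0.001, 0.5]), [0.002, 0.5]
        )

    def test_monotone_in_rank_and_validated(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])
        assert bh_fdr([]).size == 0


class TestDifferentialRegions:
    def _planted_matrix(self, seed=0, n=200, fold=4.0, n_diff=10):
        rng = np.random.default_rng(seed)
        mu = np.full(n, 100.0)
        vals = np.empty((n, 6))
        r = 1 / 0.05
        for j in range(6):
            m = mu.copy()
            if j >= 3:  # second condition
                m[:n_diff] *= fold
            vals[:, j] = rng.negative_binomial(r, r / (r + m))
        return matrix_from(vals, ["WT", "WT", "WT", "KO", "KO", "KO"])

    def test_planted_regions_called_with_correct_direction(self):
        m = self._planted_matrix()
        res = differential_regions(m, "KO", "WT", min_fc=1.5, max_fdr=0.01)
        called_up = {r.id for r in res if r.direction == "up"}
        planted = {f"r{i}" for i in range(10)}
        assert len(called_up & planted) >= 8
        false = called_up - planted
        assert len(false) <= 2
        for r in res:
            if r.id in planted and r.direction == "up":
                assert r.log2_fold_change == pytest.approx(2.0, abs=0.6)

    def test_requires_two_replicates_per_group(self):
        m = matrix_from(np.ones((2, 3)), ["WT", "WT", "KO"])
        with pytest.raises(ValueError):
            differential_regions(m, "WT", "KO")

    def test_sign_consistency_vetoes_conflicting_replicates(self):
        # large mean difference driven by one wild replicate
        vals = np.array([[400.0, 10.0, 20.0, 30.0]])
        m = matrix_from(vals, ["WT", "WT", "KO", "KO"])
        strict = differential_regions(m, "WT", "KO", min_fc=1.5, max_fdr=0.5)
        loose = differential_regions(
            m, "WT", "KO", min_fc=1.5, max_fdr=0.5, require_consistent_sign=False
        )
        assert strict[0].direction == "ns"
        assert loose[0].direction == "up"

    def test_call_degs_uses_stricter_fold(self):
        m = self._planted_matrix(fold=1.8)
        degs = call_degs(m, "KO", "WT", min_fc=2.0, max_fdr=0.01)
        # 1.8-fold plantings cannot clear a 2-fold threshold on average
        assert sum(d.direction == "up" for d in degs) <= 4


class TestDescriptiveHelpers:
    def test_bound_region_fraction_threshold(self):
        regions = (
            GenomicInterval("chr1", 0, 1000, id="a"),
            GenomicInterval("chr1", 2000, 3000, id="b"),
        )
        m = SignalMatrix(regions, (sample(1), sample(2)), np.array([[30.0, 30.0], [1.0, 1.0]]))
        # background 0.01 reads/bp -> expected 10/region; min_fold 1.5 -> cut 15
        frac, bound, total = bound_region_fraction(list(regions), m, 0.01, 1.5)
        assert (frac, bound, total) == (0.5, 1, 2)
        with pytest.raises(ValueError):
            bound_region_fraction(list(regions), m, 0.0)

    def test_signal_correlation_monotone_and_constant(self):
        x = np.arange(100.0)
        rho, binned = signal_correlation(x, 3 * x + 1)
        assert rho == pytest.approx(1.0)
        assert np.all(np.diff(binned) > 0)
        rho_c, _ = signal_correlation(np.ones(10), np.arange(10.0))
        assert math.isnan(rho_c)

    def test_region_metaprofile_minus_strand_reversed(self):
        cov = {"chr1": np.arange(1000.0)}
        plus = region_metaprofile(cov, [GenomicInterval("chr1", 100, 200, "+")], n_bins=10)
        minus = region_metaprofile(cov, [GenomicInterval("chr1", 100, 200, "-")], n_bins=10)
        np.testing.assert_allclose(plus, minus[::-1])
        assert np.all(np.diff(plus) > 0)

    def test_hervh_copy_table_fields(self):
        loci = [GenomicInterval("chr1", 1000, 2000, id="L1")]
        genes = [GeneAnnotation(GenomicInterval("chr1", 5000, 6000, "+"), "gA")]
        peaks = [Peak(GenomicInterval("chr1", 1200, 1300), (20.0,), (1_000_000,))]
        df = hervh_copy_table(loci, {"L1": 8.0}, {"L1": 1.0}, peaks, genes)
        row = df.iloc[0]
        assert row["parclip_overlap"] == "YES"
        assert row["closest_gene"] == "gA" and row["closest_gene_distance"] == 3000
        expected_lfc = math.log2((1 + PSEUDOCOUNT_RPKM) / (8 + PSEUDOCOUNT_RPKM))
        assert row["log2fc_kd_vs_wt"] == pytest.approx(expected_lfc)
        assert bool(row["kd_responsive"]) is True


class TestSignalIO:
    def test_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = matrix_from(rng.integers(0, 200, size=(6, 4)).astype(float),
                        ["WT", "WT", "KO", "KO"])
        write_signal_matrix(m, tmp_path / "v.tsv", tmp_path / "s.tsv", tmp_path / "r.bed")
        back = read_signal_matrix(tmp_path / "v.tsv", tmp_path / "s.tsv", tmp_path / "r.bed")
        np.testing.assert_allclose(back.values, m.values)
        assert back.region_ids() == m.region_ids()
        assert [s.sample_id for s in back.samples] == [s.sample_id for s in m.samples]
        assert [s.library_size for s in back.samples] == [s.library_size for s in m.samples]

    def test_differential_tsv_written(self, tmp_path):
        m = matrix_from(np.ones((2, 4)) * 50, ["WT", "WT", "KO", "KO"])
        res = differential_regions(m, "WT", "KO", max_fdr=0.5)
        path = tmp_path / "d.tsv"
        differential_to_tsv(res, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["id", "log2_fold_change", "p_value", "fdr", "direction"]
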