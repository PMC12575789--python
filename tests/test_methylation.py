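"""Bin methylation, cohort matrix, PCA/Ward, HRD grouping, group tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score, silhouette_score

from repeatscape import (
    GenomicInterval,
    MethylationMatrix,
    SampleMeta,
    bin_methylation,
    build_methylation_matrix,
    genome_cpg_summary,
    group_mean_test,
    hrd_group,
    run_pca,
    ward_cluster,
)
from repeatscape.io import BEDMETHYL_COLUMNS


def _sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "n_valid", "n_mod"])
    df["end"] = df["start"] + 2
    df["strand"] = "+"
    df["haplotype"] = "unphased"
    return df[BEDMETHYL_COLUMNS]


BIN = GenomicInterval("chr1", 0, 1000, "x")


class TestBinMethylation:
    def test_pooled_ratio(self):
        records = _sites([("chr1", 10, 10, 3), ("chr1", 20, 10, 7)])
        (v,) = bin_methylation(records, [BIN])
        assert v == 0.5  # 10/20, read-weighted

    def test_mean_of_sites_variant(self):
        records = _sites([("chr1", 10, 10, 1), ("chr1", 20, 40, 36)])
        (v,) = bin_methylation(records, [BIN], method="mean_of_sites")
        assert v == pytest.approx((0.1 + 0.9) / 2)

    def test_empty_bin_missing(self):
        records = _sites([("chr1", 5000, 10, 3)])
        (v,) = bin_methylation(records, [BIN])
        assert np.isnan(v)

    def test_zero_coverage_only_bin_missing(self):
        records = _sites([("chr1", 10, 0, 0)])
        (v,) = bin_methylation(records, [BIN])
        assert np.isnan(v)

    def test_expansion_oracle(self, rng):
        n = 400
        starts = np.sort(rng.choice(20_000, size=n, replace=False))
        n_valid = rng.integers(0, 40, n)
        n_mod = rng.integers(0, n_valid + 1)
        records = _sites(list(zip(["chr1"] * n, starts, n_valid, n_mod)))
        bins = [GenomicInterval("chr1", s, s + 1000, "x") for s in range(0, 20_000, 1000)]
        got = bin_methylation(records, bins)
        for b, v in zip(bins, got):
            inside = (starts >= b.start) & (starts < b.end)
            tot = n_valid[inside].sum()
            if tot > 0:
                assert v == pytest.approx(n_mod[inside].sum() / tot, abs=1e-12)
            else:
                assert np.isnan(v)

    def test_pooled_within_site_ratio_range(self, rng):
        n = 50
        starts = np.sort(rng.choice(900, size=n, replace=False))
        n_valid = rng.integers(1, 40, n)
        n_mod = rng.integers(0, n_valid + 1)
        records = _sites(list(zip(["chr1"] * n, starts, n_valid, n_mod)))
        (v,) = bin_methylation(records, [BIN])
        ratios = n_mod / n_valid
        assert ratios.min() - 1e-12 <= v <= ratios.max() + 1e-12


class TestGenomeSummary:
    def test_fully_methylated(self):
        records = _sites([("chr1", i * 10, 10, 10) for i in range(5)])
        assert genome_cpg_summary(records)["mean"] == 1.0

    def test_order_invariance(self, rng):
        rows = [("chr1", int(s), 10, int(m)) for s, m in
                zip(rng.choice(10_000, 50, replace=False), rng.integers(0, 11, 50))]
        a = genome_cpg_summary(_sites(rows))
        b = genome_cpg_summary(_sites(rows[::-1]))
        pd.testing.assert_series_equal(a, b)

    def test_planted_hypomethylation_recovered(self, rng):
        n = 20_000
        def cohort_mean(true_mean):
            n_valid = rng.poisson(30, n)
            p = rng.beta(true_mean * 30, (1 - true_mean) * 30, n)
            n_mod = rng.binomial(n_valid, p)
            rows = list(zip(["chr1"] * n, np.arange(n) * 5, n_valid, n_mod))
            return genome_cpg_summary(_sites(rows))["mean"]
        assert cohort_mean(0.75) == pytest.approx(0.75, abs=0.02)
        assert cohort_mean(0.55) == pytest.approx(0.55, abs=0.02)


class TestMatrix:
    BINS = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000, "active_hor") for i in range(3)]

    def test_complete_case_drops_missing_rows(self):
        per_sample = {
            "s1": np.array([0.5, 0.6, 0.7]),
            "s2": np.array([0.4, np.nan, 0.6]),
        }
        mat = build_methylation_matrix(per_sample, self.BINS)
        assert mat.values.shape == (2, 2)

    def test_class_restriction(self):
        bins = self.BINS + [GenomicInterval("chr1", 9000, 10_000, "hsat2")]
        per_sample = {"s1": np.full(4, 0.5), "s2": np.full(4, 0.6)}
        mat = build_methylation_matrix(per_sample, bins, classes=("active_hor",))
        assert len(mat.bins) == 3
        assert set(mat.classes) == {"active_hor"}

    def test_full_matrix_passes_through(self):
        per_sample = {"s1": np.array([0.1, 0.2, 0.3]), "s2": np.array([0.4, 0.5, 0.6])}
        mat = build_methylation_matrix(per_sample, self.BINS)
        np.testing.assert_array_equal(mat.values["s1"], [0.1, 0.2, 0.3])

    def test_no_surviving_rows_rejected(self):
        per_sample = {"s1": np.array([np.nan] * 3), "s2": np.array([0.1, 0.2, 0.3])}
        with pytest.raises(ValueError):
            build_methylation_matrix(per_sample, self.BINS)


def _matrix_from(data: dict[str, np.ndarray], label="active_hor"):
    n = len(next(iter(data.values())))
    bins = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000, label) for i in range(n)]
    return build_methylation_matrix(data, bins)


class TestPca:
    def test_identical_samples_at_origin(self):
        mat = _matrix_from({"a": np.full(10, 0.5), "b": np.full(10, 0.5)})
        coords, ev = run_pca(mat)
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-12)
        assert ev.sum() == 0

    def test_explained_variance_fractions_bounded(self, rng):
        data = {f"s{i}": rng.uniform(0, 1, 50) for i in range(6)}
        _, ev = run_pca(_matrix_from(data))
        assert 0 <= ev.sum() <= 1 + 1e-12

    def test_planted_two_group_shift_separates(self, rng):
        base = rng.uniform(0.3, 0.7, 500)
        data = {}
        groups = []
        for i in range(8):
            shift = 0.15 if i < 4 else -0.15
            groups.append(int(i < 4))
            data[f"s{i}"] = np.clip(base + shift + rng.normal(0, 0.02, 500), 0, 1)
        coords, _ = run_pca(_matrix_from(data))
        assert silhouette_score(coords.to_numpy(), groups) > 0.5

    def test_row_order_invariance(self, rng):
        data = {f"s{i}": rng.uniform(0, 1, 40) for i in range(5)}
        mat = _matrix_from(data)
        coords, _ = run_pca(mat)
        perm = rng.permutation(len(mat.bins))
        mat_p = MethylationMatrix([mat.bins[i] for i in perm], mat.values.iloc[perm])
        coords_p, _ = run_pca(mat_p)
        np.testing.assert_allclose(coords.to_numpy(), coords_p.to_numpy(), atol=1e-9)


class TestWard:
    def test_planted_partition_recovered(self, rng):
        data = {}
        truth = []
        for i, s in enumerate("ABCDEF"):
            center = 0.8 if i < 3 else 0.2
            truth.append(int(i < 3))
            data[s] = np.clip(rng.normal(center, 0.01, 100), 0, 1)
        clusters, Z = ward_cluster(_matrix_from(data), k=2)
        assert adjusted_rand_score(truth, clusters.to_numpy()) == 1.0

    def test_singletons_at_k_equals_n(self, rng):
        data = {f"s{i}": rng.uniform(0, 1, 30) for i in range(4)}
        clusters, _ = ward_cluster(_matrix_from(data), k=4)
        assert sorted(clusters) == [1, 2, 3, 4]

    def test_merge_heights_non_decreasing(self, rng):
        data = {f"s{i}": rng.uniform(0, 1, 30) for i in range(7)}
        _, Z = ward_cluster(_matrix_from(data), k=2)
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_exceeding_samples_rejected(self, rng):
        data = {f"s{i}": rng.uniform(0, 1, 30) for i in range(3)}
        with pytest.raises(ValueError):
            ward_cluster(_matrix_from(data), k=4)

    def test_sample_order_invariance(self, rng):
        data = {f"s{i}": rng.normal(0.5 if i < 3 else 0.1, 0.01, 60) for i in range(6)}
        mat = _matrix_from(data)
        c1, _ = ward_cluster(mat, k=2)
        reordered = MethylationMatrix(mat.bins, mat.values[list(reversed(mat.values.columns))])
        c2, _ = ward_cluster(reordered, k=2)
        assert adjusted_rand_score(c1[sorted(data)], c2[sorted(data)]) == 1.0


class TestHrdGroup:
    def _meta(self, sid, score):
        return SampleMeta(sid, "tumor", f"P_{sid}", hrd_score=score)

    def test_printed_cohort_scores_partition(self):
        # the six published tumor scores split 3 high / 3 low at cutoff 63
        scores = {"T1": 70, "T2": 65, "T3": 34, "T4": 88, "T5": 52, "T6": 26}
        labels = {g.sample_id: g.group
                  for g in hrd_group([self._meta(s, v) for s, v in scores.items()])}
        assert {s for s, g in labels.items() if g == "high"} == {"T1", "T2", "T4"}
        assert {s for s, g in labels.items() if g == "low"} == {"T3", "T5", "T6"}

    def test_boundary_score_is_high(self):
        (g,) = hrd_group([self._meta("T", 63)])
        assert g.group == "high"

    def test_missing_score_names_sample(self):
        with pytest.raises(ValueError, match="Tx"):
            hrd_group([SampleMeta("Tx", "tumor", "P1")])

    def test_normals_ignored(self):
        metas = [SampleMeta("N1", "normal", "P1"), self._meta("T1", 70)]
        assert [g.sample_id for g in hrd_group(metas)] == ["T1"]


class TestGroupMeanTest:
    def test_identical_groups(self):
        t, p = group_mean_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_three_plus_three(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        # pooled-variance Student t by the textbook formula
        sa2 = np.var(a, ddof=1)
        sb2 = np.var(b, ddof=1)
        sp2 = (2 * sa2 + 2 * sb2) / 4
        expected_t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, p = group_mean_test(a, b)
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(expected_t), 4), rel=1e-12)

    def test_paired_matches_scipy(self, rng):
        a = rng.normal(0.5, 0.1, 12)
        b = a + rng.normal(0.1, 0.05, 12)
        t, p = group_mean_test(a, b, paired=True)
        t_ref, p_ref = scipy.stats.ttest_rel(a, b)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_planted_gap_over_thousand_bins(self, rng):
        a = rng.normal(0.55, 0.08, 3000)
        b = rng.normal(0.35, 0.08, 3000)
        _, p = group_mean_test(a, b)
        assert p < 1e-20

    def test_zero_variance_equal_means(self):
        t, p = group_mean_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_mean_test([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)
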