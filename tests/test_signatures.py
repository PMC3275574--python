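import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfanca import (
    associate_status,
    build_report,
    cluster_samples,
    derive_status_signature,
    normalize_to_reference,
    status_rates_by_group,
    tfa_correlation,
    tfa_ttest,
)


from conftest import two_block_tfa


class TestClusterSamples:
    def test_duplicated_sample_merges_first(self):
        tfa = np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 5.0]])
        res = cluster_samples(tfa, 2)
        assert res.group_labels[0] == res.group_labels[1]
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_samples_have_unit_distance(self):
        from scipy.spatial.distance import cosine

        assert cosine([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
        res = cluster_samples(np.array([[1.0, 0.0], [0.0, 1.0]]), 2)
        assert len(set(res.group_labels)) == 2

    def test_planted_two_block_cohort_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(10):
            tfa, status = two_block_tfa(seed=seed)
            res = cluster_samples(tfa, 2)
            assert adjusted_rand_score(status, res.group_labels) == 1.0

    def test_invariant_to_positive_per_sample_rescaling(self):
        rng = np.random.default_rng(5)
        tfa, _ = two_block_tfa(seed=5)
        scales = rng.uniform(0.2, 5.0, tfa.shape[1])
        a = cluster_samples(tfa, 3).group_labels
        b = cluster_samples(tfa * scales[None, :], 3).group_labels
        np.testing.assert_array_equal(a, b)

    def test_all_zero_sample_rejected(self):
        tfa = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero"):
            cluster_samples(tfa, 2)

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(np.ones((3, 2)), 3)


class TestAssociateStatus:
    def test_perfect_split_matches_closed_form(self):
        groups = np.array([1] * 10 + [2] * 10)
        status = np.array([1] * 10 + [0] * 10)
        res = associate_status(groups, status)
        # closed 2x2 formula n(ad-bc)^2 / (r1 r2 c1 c2) = 20
        assert res.chi2 == pytest.approx(20.0)

    def test_independent_status_gives_zero_statistic(self):
        groups = np.array([1, 1, 2, 2, 3, 3] * 2)
        status = np.array([0, 1] * 6)
        res = associate_status(groups, status)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_prostate_copy_number_table(self):
        # group 1: 9 altered / 4 normal; groups 2+3 pooled: 14 altered / 85 normal
        groups = np.array([1] * 13 + [2] * 35 + [3] * 64)
        status = np.array([1] * 9 + [0] * 4 + [1] * 11 + [0] * 24
                          + [1] * 3 + [0] * 61)
        res = associate_status(groups, status)
        assert res.chi2 == pytest.approx(21.370471465244304, rel=1e-12)
        assert res.p == pytest.approx(3.7855686637794704e-06, rel=1e-9)
        rates = status_rates_by_group(groups, status)
        assert (rates[1], rates[2], rates[3]) == (69.2, 31.4, 4.7)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="binary|marginal"):
            associate_status(np.array([1, 1, 2, 2]), np.array([1, 1, 1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_transpose_and_label_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = rng.integers(1, 4, 40)
        status = rng.integers(0, 2, 40)
        if len(np.unique(status)) < 2 or len(np.unique(groups)) < 2:
            return
        if not np.any(groups == 1):
            return
        a = associate_status(groups, status)
        b = associate_status(groups, 1 - status)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)
        assert a.p == pytest.approx(b.p, rel=1e-9)
        # transpose invariance via the scipy statistic itself
        from scipy.stats import chi2_contingency

        assert chi2_contingency(a.table.T, correction=False)[0] == \
            pytest.approx(a.chi2, rel=1e-12)


class TestTTestsAndSignature:
    def test_identical_groups_are_null(self):
        tfa = np.tile(np.arange(8.0), (3, 1))
        res = tfa_ttest(tfa, np.arange(4), np.arange(4))
        np.testing.assert_allclose(res.t, 0.0)
        np.testing.assert_allclose(res.p, 1.0)

    def test_strong_separation_is_detected(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((2, 20))
        tfa = np.hstack([a, a + 10.0])
        res = tfa_ttest(tfa, np.arange(20), np.arange(20, 40))
        assert np.all(res.p < 1e-10)

    def test_null_pvalues_are_uniform(self):
        """Two-sample t on N(0,1) groups: p ~ U(0,1) by KS at 1000 reps."""
        from scipy.stats import kstest

        rng = np.random.default_rng(1)
        tfa = rng.standard_normal((1000, 24))
        res = tfa_ttest(tfa, np.arange(12), np.arange(12, 24))
        assert kstest(res.p, "uniform").pvalue > 0.01

    def test_zero_variance_rows_flagged(self):
        tfa = np.vstack([np.ones(8), np.arange(8.0)])
        res = tfa_ttest(tfa, np.arange(4), np.arange(4, 8))
        assert res.undefined[0] and not res.undefined[1]
        assert np.isnan(res.p[0])

    def test_signature_finds_exactly_the_shifted_tfs(self):
        deviations = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tfa = 0.3 * rng.standard_normal((20, 60))
            status = np.array([0] * 30 + [1] * 30)
            tfa[:5, status == 1] += 2.0
            got = set(derive_status_signature(tfa, status, alpha=1e-4))
            expected = {f"TF{i + 1:03d}" for i in range(5)}
            deviations += len(got ^ expected)
        assert deviations <= 1

    def test_alpha_one_returns_every_testable_tf(self):
        rng = np.random.default_rng(3)
        tfa = rng.standard_normal((7, 12))
        status = np.array([0, 1] * 6)
        assert len(derive_status_signature(tfa, status, alpha=1.0)) == 7

    def test_no_difference_gives_empty_signature(self):
        tfa = np.tile(np.arange(10.0), (4, 1))
        status = np.array([0, 1] * 5)
        assert derive_status_signature(tfa, status, alpha=1e-4) == []


class TestCorrelation:
    def test_duplicate_and_negated_rows_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        tfa = np.vstack([x, x, -x])
        res = tfa_correlation(tfa)
        assert res.matrix[0, 1] == pytest.approx(1.0)
        assert res.matrix[0, 2] == pytest.approx(1.0)

    def test_independent_rows_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        res = tfa_correlation(rng.standard_normal((10, 200)))
        off = res.matrix[~np.eye(10, dtype=bool)]
        assert off.mean() < 0.1

    def test_symmetric_unit_diagonal_and_flagged_constants(self):
        tfa = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]])
        res = tfa_correlation(tfa, tf_ids=("c", "a", "b"))
        np.testing.assert_allclose(res.matrix, res.matrix.T)
        np.testing.assert_allclose(np.diag(res.matrix), 1.0)
        assert res.constant_tfs == ("c",)
        assert res.order[-1] == 0  # constant row sorts last

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tfa_correlation(np.ones((3, 2)))


class TestNormalizeToReference:
    def test_reference_mean_is_subtracted_per_tf(self):
        rng = np.random.default_rng(4)
        tfa = rng.standard_normal((3, 4))
        ref = np.array([0, 2])
        out = normalize_to_reference(tfa, ref)
        # independent arithmetic oracle, cell by cell
        for i in range(3):
            m = (tfa[i, 0] + tfa[i, 2]) / 2.0
            for j in range(4):
                assert out[i, j] == pytest.approx(tfa[i, j] - m)

    def test_all_samples_as_reference_centres_rows(self):
        rng = np.random.default_rng(5)
        tfa = rng.standard_normal((4, 6))
        out = normalize_to_reference(tfa, np.arange(6))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_single_reference_sample_becomes_zero_column(self):
        rng = np.random.default_rng(6)
        tfa = rng.standard_normal((4, 6))
        out = normalize_to_reference(tfa, np.array([2]))
        np.testing.assert_allclose(out[:, 2], 0.0, atol=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(np.ones((2, 3)), np.array([], dtype=int))


def test_cohort_report_bundles_consistent_pieces():
    tfa, status = two_block_tfa(seed=9)
    rep = build_report(tfa, status, k=2)
    assert rep.association.p < 1e-6
    assert rep.cluster.group_labels.shape == status.shape
    assert sorted(rep.group_status_rates) == [1, 2]
    assert rep.correlation.matrix.shape == (12, 12)
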