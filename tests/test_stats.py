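"""Paired t-test, ROC/AUROC and Youden threshold against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pancedge.stats import (
    PairedSample,
    cohort_report,
    paired_t_test,
    roc_curve,
    youden_threshold,
)


def _pairs(tumor, healthy):
    return [
        PairedSample(f"P{i}", float(t), float(h))
        for i, (t, h) in enumerate(zip(tumor, healthy))
    ]


def _auc_bruteforce(cancer, healthy):
    """Mann-Whitney pair count: P(healthy > cancer) with half credit for ties."""
    wins = sum(1.0 for c in cancer for h in healthy if h > c)
    ties = sum(1.0 for c in cancer for h in healthy if h == c)
    return (wins + 0.5 * ties) / (len(cancer) * len(healthy))


class TestPairedTTest:
    def test_symmetric_differences(self):
        result = paired_t_test(_pairs([1, 2], [2, 1]))
        assert result.t == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)
        assert result.df == 1

    def test_closed_form_example(self):
        result = paired_t_test(_pairs([1, 2, 3], [2, 4, 9]))
        expected_t = -3 * np.sqrt(3) / np.sqrt(7)
        assert result.t == pytest.approx(expected_t, abs=1e-12)
        assert result.df == 2
        assert result.mean_diff == pytest.approx(-3.0)

    def test_matches_scipy_on_random_vectors(self, rng):
        for _ in range(100):
            n = rng.integers(3, 30)
            tumor = rng.normal(0.5, 0.2, n)
            healthy = rng.normal(1.2, 0.5, n)
            mine = paired_t_test(_pairs(tumor, healthy))
            ref = sps.ttest_rel(tumor, healthy)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_sign_symmetry(self, rng):
        tumor = rng.normal(0.5, 0.1, 12)
        healthy = rng.normal(1.2, 0.3, 12)
        fwd = paired_t_test(_pairs(tumor, healthy))
        rev = paired_t_test(_pairs(healthy, tumor))
        assert rev.t == pytest.approx(-fwd.t)
        assert rev.p == pytest.approx(fwd.p)

    def test_degenerate_zero_variance(self):
        nonzero = paired_t_test(_pairs([2, 2], [1, 1]))
        assert nonzero.degenerate and nonzero.p == 0.0
        zero = paired_t_test(_pairs([1, 1], [1, 1]))
        assert zero.degenerate and zero.t == 0.0 and zero.p == 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test(_pairs([1], [2]))

    def test_large_paired_effect_is_significant(self, rng):
        tumor = rng.normal(0.50, 0.12, 50)
        healthy = rng.normal(1.27, 0.50, 50)
        assert paired_t_test(_pairs(tumor, healthy)).p < 0.001


class TestROCCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.1, 0.2], [1.0, 1.1])
        assert roc.auc == pytest.approx(1.0)

    def test_reversed_separation(self):
        roc = roc_curve([1.0, 1.1], [0.1, 0.2])
        assert roc.auc == pytest.approx(0.0)

    def test_mixed_example_brute_forced(self):
        cancer = [0.4, 0.5, 0.7, 1.1]
        healthy = [1.0, 1.3, 0.9, 1.6]
        roc = roc_curve(cancer, healthy)
        assert roc.auc == pytest.approx(14 / 16)
        assert roc.auc == pytest.approx(_auc_bruteforce(cancer, healthy))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([], [1.0])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        cancer=st.lists(st.sampled_from([round(0.1 * k, 1) for k in range(12)]),
                        min_size=2, max_size=15),
        healthy=st.lists(st.sampled_from([round(0.1 * k, 1) for k in range(12)]),
                         min_size=2, max_size=15),
    )
    def test_auc_equals_mann_whitney(self, cancer, healthy):
        roc = roc_curve(cancer, healthy)
        assert roc.auc == pytest.approx(_auc_bruteforce(cancer, healthy), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        cancer = rng.normal(0.5, 0.2, 20)
        healthy = rng.normal(1.0, 0.4, 25)
        base = roc_curve(cancer, healthy)
        warped = roc_curve(np.exp(cancer), np.exp(healthy))
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)
        assert np.allclose(sorted(warped.sens), sorted(base.sens))
        assert np.allclose(sorted(warped.spec), sorted(base.spec))


class TestYoudenThreshold:
    def test_perfect_separation_midpoint(self):
        roc = roc_curve([0.1, 0.2], [1.0, 1.1])
        thr, sens, spec = youden_threshold(roc)
        assert thr == pytest.approx(0.6)
        assert sens == 1.0 and spec == 1.0

    def test_overlapping_groups_brute_forced(self):
        # exhaustive check over all candidate cutoffs gives J*=0.75 at 0.8
        roc = roc_curve([0.4, 0.5, 0.7, 1.1], [1.0, 1.3, 0.9, 1.6])
        thr, sens, spec = youden_threshold(roc)
        assert thr == pytest.approx(0.8)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(1.0)

    def test_single_scores(self):
        roc = roc_curve([0.5], [1.0])
        thr, sens, spec = youden_threshold(roc)
        assert thr == pytest.approx(0.75)
        assert sens == 1.0 and spec == 1.0


class TestCohortReport:
    def test_separated_cohort(self, rng):
        tumor = rng.normal(0.5, 0.05, 30)
        healthy = tumor + 1.0
        report = cohort_report(_pairs(tumor, healthy))
        assert report.roc.auc == pytest.approx(1.0)
        assert report.sens_at_threshold == 1.0
        assert report.spec_at_threshold == 1.0
        assert report.ttest.p < 1e-6
        assert report.confusion == {"tp": 30, "fn": 0, "tn": 30, "fp": 0}

    def test_exchangeable_arms_give_chance_auc(self, rng):
        scores = rng.normal(1.0, 0.3, 200)
        report = cohort_report(_pairs(scores, scores[::-1]))
        assert abs(report.roc.auc - 0.5) < 0.1

    def test_external_threshold_is_used(self, rng):
        tumor = rng.normal(0.5, 0.1, 20)
        healthy = rng.normal(1.3, 0.3, 20)
        report = cohort_report(_pairs(tumor, healthy), threshold=0.6855)
        assert report.threshold_used == pytest.approx(0.6855)

    def test_summary_dict_is_json_ready(self, rng):
        import json

        tumor = rng.normal(0.5, 0.1, 10)
        healthy = rng.normal(1.3, 0.3, 10)
        payload = cohort_report(_pairs(tumor, healthy)).to_dict()
        json.dumps(payload)
        assert payload["n"] == 10
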