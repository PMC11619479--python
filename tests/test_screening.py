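"""ROC machinery, cut-off selection, metrics and workload accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from uroscreen import screening
from uroscreen.screening import ConfusionCounts


def brute_force_auc(scores, labels) -> float:
    """Concordance-pair counting with ties counted half (independent oracle)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_cutoff(scores, labels, target):
    """Exhaustive search over distinct scores for the largest cutoff with
    sensitivity >= target percent."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    passing = [
        c for c in np.unique(s) if np.mean(pos >= c) * 100 >= target
    ]
    return max(passing)


binary_instances = st.integers(2, 60).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 20), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < len(y)
        ),
    )
)


class TestConfusionCounts:
    @pytest.mark.parametrize(
        "scores,labels,cutoff,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 3, (2, 0, 2, 0)),
            ([1, 2, 3, 4], [0, 1, 0, 1], 3, (1, 1, 1, 1)),
            ([1, 2, 3, 4], [0, 0, 1, 1], -math.inf, (2, 0, 0, 2)),
        ],
    )
    def test_partitions_samples(self, scores, labels, cutoff, expected):
        c = screening.confusion_counts(scores, labels, cutoff)
        assert (c.tp, c.fn, c.tn, c.fp) == expected

    def test_rejects_non_binary_labels(self):
        with pytest.raises(ValueError, match="binary"):
            screening.confusion_counts([1, 2], [0, 2], 1)

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError, match="empty"):
            screening.confusion_counts([], [], 1)


class TestDiagnosticMetrics:
    def test_npv_of_screening_operating_point(self):
        m = screening.diagnostic_metrics(ConfusionCounts(tp=240, fn=12, tn=325, fp=215))
        assert m.rounded()["npv"] == 96.4

    def test_ppv_of_gram_neg_flag(self):
        m = screening.diagnostic_metrics(ConfusionCounts(tp=109, fn=78, tn=252, fp=16))
        assert m.rounded()["ppv"] == 87.2

    def test_zero_denominator_is_undefined_not_zero(self):
        m = screening.diagnostic_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(50.0)

    @given(
        st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    )
    @settings(deadline=None, max_examples=100)
    def test_bayes_identity_links_ppv_to_prevalence(self, counts):
        tp, fn, tn, fp = counts
        c = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
        m = screening.diagnostic_metrics(c)
        if None in (m.sensitivity, m.specificity, m.ppv) or c.total == 0:
            return
        sen, spe = m.sensitivity / 100, m.specificity / 100
        pi = c.positives / c.total
        denom = sen * pi + (1 - spe) * (1 - pi)
        if denom > 0:
            assert m.ppv / 100 == pytest.approx(sen * pi / denom, abs=1e-12)


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        assert screening.empirical_roc([1, 2, 10, 11], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties(self):
        assert screening.empirical_roc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_hand_counted_concordance(self):
        roc = screening.empirical_roc([1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1])
        assert roc.auc == pytest.approx(8 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            screening.empirical_roc([1, 2], [1, 1])

    def test_sensitivity_monotone_in_cutoff(self):
        roc = screening.empirical_roc([1, 2, 2, 3, 4, 5], [0, 1, 0, 1, 0, 1])
        by_cutoff = sorted(roc.points)
        senss = [p[1] for p in by_cutoff]
        assert all(a >= b for a, b in zip(senss[:-1], senss[1:]))

    @given(binary_instances)
    @settings(deadline=None, max_examples=80)
    def test_auc_equals_brute_force_concordance(self, inst):
        scores, labels = inst
        roc = screening.empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=300) + np.repeat([0, 1], 150)
        labels = np.repeat([0, 1], 150)
        assert screening.empirical_roc(scores, labels).auc == pytest.approx(
            sklearn.roc_auc_score(labels, scores)
        )


class TestAucCi:
    def test_deterministic_and_bounded(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.repeat([0, 1], 50)
        lo, hi = screening.auc_ci(scores, labels)
        assert (lo, hi) == screening.auc_ci(scores, labels)
        assert 0.0 <= lo <= hi <= 1.0

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            screening.auc_ci([1, 2, 3, 4], [0, 0, 1, 1])

    def test_coverage_of_generator_asymptotic_auc(self):
        # scores drawn from the default generator's stratum laws; the
        # asymptotic AUC has the binormal closed form on the log scale
        mu0, s0, mu1, s1 = 3.14, 2.34, 8.55, 2.92
        true_auc = norm.cdf((mu1 - mu0) / math.hypot(s0, s1))
        rng = np.random.default_rng(2024)
        n, prev = 10_000, 0.318
        hits = 0
        for _ in range(100):
            y = rng.random(n) < prev
            s = np.where(y, rng.lognormal(mu1, s1, n), rng.lognormal(mu0, s0, n))
            lo, hi = screening.auc_ci(s, y.astype(int))
            hits += lo <= true_auc <= hi
        assert hits >= 90


class TestCutoffAtSensitivity:
    def test_exhaustive_example(self):
        row = screening.cutoff_at_sensitivity([1, 2, 3, 4, 5], [0, 0, 1, 1, 1], 100)
        assert row.cutoff == 3
        assert row.metrics.specificity == pytest.approx(100.0)

    def test_floor_not_met_by_higher_cutoff(self):
        row = screening.cutoff_at_sensitivity([1, 2, 3, 4, 5], [0, 0, 1, 1, 1], 80)
        assert row.cutoff == 3  # cutoff 4 only reaches 2/3 sensitivity

    def test_achieved_sensitivity_meets_floor(self):
        row = screening.cutoff_at_sensitivity([1, 1, 2, 3, 8, 9], [0, 1, 0, 1, 0, 1], 66)
        assert row.metrics.sensitivity >= 66

    def test_no_positives_is_an_error(self):
        with pytest.raises(ValueError, match="no positive"):
            screening.cutoff_at_sensitivity([1, 2], [0, 0], 95)

    @given(binary_instances, st.sampled_from([50.0, 80.0, 90.0, 95.0, 99.0, 100.0]))
    @settings(deadline=None, max_examples=80)
    def test_agrees_with_exhaustive_search(self, inst, target):
        scores, labels = inst
        row = screening.cutoff_at_sensitivity(scores, labels, target)
        assert row.cutoff == brute_force_cutoff(scores, labels, target)


class TestSensitivityTable:
    def test_cutoffs_non_increasing_with_target(self, small_cohort):
        from uroscreen.records import CultureStatus

        bact = [s.bact_per_ul for s in small_cohort.samples]
        labels = [
            int(c.status is CultureStatus.POSITIVE) for c in small_cohort.cultures
        ]
        rows = screening.sensitivity_table(bact, labels, [80, 85, 90, 95, 97.5, 99])
        assert len(rows) == 6
        cutoffs = [r.cutoff for r in rows]
        assert all(a >= b for a, b in zip(cutoffs[:-1], cutoffs[1:]))

    def test_single_target_consistency(self):
        scores, labels = [1, 2, 3, 4, 5], [0, 0, 1, 1, 1]
        assert screening.sensitivity_table(scores, labels, [90])[0] == \
            screening.cutoff_at_sensitivity(scores, labels, 90)

    def test_empty_target_list(self):
        assert screening.sensitivity_table([1, 2], [0, 1], []) == []


class TestWorkloadReduction:
    @pytest.mark.parametrize(
        "counts,reduction,fnr",
        [
            (ConfusionCounts(tp=240, fn=12, tn=325, fp=215), 42.6, 3.6),
            (ConfusionCounts(tp=212, fn=11, tn=406, fp=163), 52.7, 2.6),
        ],
    )
    def test_published_operating_points(self, counts, reduction, fnr):
        wl = screening.workload_reduction(counts)
        assert wl.rounded() == (reduction, fnr)

    def test_all_positive_calls(self):
        wl = screening.workload_reduction(ConfusionCounts(tp=5, fn=0, tn=0, fp=5))
        assert wl.culture_reduction == 0.0
        assert wl.false_negative_rate is None

    @given(
        st.tuples(st.integers(0, 99), st.integers(0, 99), st.integers(0, 99), st.integers(0, 99))
        .filter(lambda t: sum(t) > 0)
    )
    @settings(deadline=None, max_examples=100)
    def test_reduction_times_total_recovers_avoided_count(self, t):
        c = ConfusionCounts(*t)
        wl = screening.workload_reduction(c)
        assert wl.culture_reduction * c.total / 100 == pytest.approx(c.tn + c.fn, abs=1e-9)


class TestCombineMarkers:
    def test_constant_wbc_degenerates_to_bact_ordering(self, rng):
        bact = rng.lognormal(3, 1, 200)
        labels = (bact + rng.normal(0, 5, 200) > np.median(bact)).astype(int)
        wbc = np.full(200, 7.0)
        combined = screening.combine_markers(bact, wbc, labels)
        assert screening.empirical_roc(combined, labels).auc == pytest.approx(
            screening.empirical_roc(bact, labels).auc
        )

    def test_shuffled_labels_give_chance_auc(self, rng):
        n = 2000
        bact, wbc = rng.lognormal(3, 1, n), rng.lognormal(2, 1, n)
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        auc = screening.empirical_roc(screening.combine_markers(bact, wbc, labels), labels).auc
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_separable_marker_gives_perfect_auc(self, rng):
        labels = np.repeat([0, 1], 50)
        bact = np.where(labels, 1000.0, 1.0) * rng.lognormal(0, 0.1, 100)
        wbc = rng.lognormal(2, 1, 100)
        auc = screening.empirical_roc(screening.combine_markers(bact, wbc, labels), labels).auc
        assert auc == 1.0


class TestCompareGroups:
    def test_identical_groups(self):
        _, _, p = screening.compare_groups([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert p >= 0.99

    def test_exact_enumeration_small_sample(self):
        m0, m1, p = screening.compare_groups([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert (m0, m1) == (2, 11)
        assert p == pytest.approx(0.1)

    def test_one_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            screening.compare_groups([1, 2], [0, 0])

    def test_power_to_separate_gram_class_channels(self):
        # default generator channel laws at the published 80 GN / 15 GP sizes
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(100):
            gn = rng.lognormal(math.log(31.6), 0.28, 80)
            gp = rng.lognormal(math.log(59.8), 0.12, 15)
            _, _, p = screening.compare_groups(
                np.concatenate([gp, gn]), np.concatenate([np.zeros(15), np.ones(80)])
            )
            hits += p < 0.001
        assert hits >= 95
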