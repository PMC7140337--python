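"""Per-threshold metrics, the four cut-off strategies, and predictive values."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cogscreen.cutoffs import (
    balanced_cutoff,
    cutoff_label,
    display_percent,
    evaluate_cutoff,
    fixed_cutoff,
    metrics_at_all_thresholds,
    percentile_cutoff,
    ppv_npv,
    prevalence,
    youden_cutoff,
)

scores_lists = st.lists(st.integers(0, 30), min_size=1, max_size=12)


class TestEvaluateCutoff:
    def test_hand_enumerated_confusion_table(self):
        m = evaluate_cutoff([20, 25], [27, 28], t=23)
        assert (m.tp, m.fn, m.tn, m.fp) == (1, 1, 2, 0)
        assert m.sensitivity == 0.5 and m.specificity == 1.0

    def test_perfect_test(self):
        m = evaluate_cutoff([10, 11], [25, 26], t=20)
        assert m.ccr == 1.0 and m.youden_j == 1.0

    def test_clopper_pearson_attached_on_request(self):
        m = evaluate_cutoff([20, 25], [27, 28], t=23, ci_level=0.95)
        assert m.ci_sens.method == "clopper_pearson"
        assert m.ci_sens.lower <= m.sensitivity <= m.ci_sens.upper

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            evaluate_cutoff([], [1], 5)

    @given(pos=scores_lists, neg=scores_lists, t=st.integers(-1, 30))
    def test_count_and_rate_identities(self, pos, neg, t):
        m = evaluate_cutoff(pos, neg, t)
        assert m.tp + m.fn == len(pos)
        assert m.tn + m.fp == len(neg)
        assert m.ccr == pytest.approx((m.sensitivity + m.specificity) / 2)
        assert m.ccr == pytest.approx((m.youden_j + 1) / 2)  # CCR = (J+1)/2


class TestDisplayRounding:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.84, 0.92, 88), (0.94, 0.63, 79), (0.90, 0.74, 82), (0.86, 0.86, 86)],
    )
    def test_ccr_percent_rounds_half_away_from_zero(self, sens, spec, expected):
        assert display_percent((sens + spec) / 2) == expected

    def test_cutoff_labels(self):
        assert cutoff_label(23) == "23/24"
        assert cutoff_label(-1.36) == "<= -1.36"


class TestMetricsGrid:
    def test_bounded_scores_give_32_entries(self):
        ms = metrics_at_all_thresholds([20, 25], [27, 28])
        assert len(ms) == 32
        assert [m.threshold for m in ms] == list(range(-1, 31))

    def test_grid_entries_match_single_evaluation(self, rng):
        pos = rng.integers(0, 31, 40)
        neg = rng.integers(0, 31, 40)
        ms = metrics_at_all_thresholds(pos, neg)
        for m in ms[::7]:
            single = evaluate_cutoff(pos, neg, m.threshold)
            assert (m.tp, m.fp, m.tn, m.fn) == (single.tp, single.fp, single.tn, single.fn)

    def test_sens_nondecreasing_spec_nonincreasing(self, rng):
        pos = rng.integers(0, 31, 30)
        neg = rng.integers(0, 31, 30)
        ms = metrics_at_all_thresholds(pos, neg)
        sens = [m.sensitivity for m in ms]
        spec = [m.specificity for m in ms]
        assert sens == sorted(sens)
        assert spec == sorted(spec, reverse=True)


def brute_force_balanced(metrics):
    best = None
    for m in sorted(metrics, key=lambda m: m.threshold):
        gap = abs(m.sensitivity - m.specificity)
        if best is None or gap < best[0]:
            best = (gap, m.threshold)
    return best[1]


def brute_force_youden(metrics):
    best = None
    for m in sorted(metrics, key=lambda m: m.threshold):
        if best is None or m.youden_j > best[0]:
            best = (m.youden_j, m.threshold)
    return best[1]


class TestStrategySelection:
    @given(pos=scores_lists, neg=scores_lists)
    def test_balanced_equals_exhaustive_search(self, pos, neg):
        ms = metrics_at_all_thresholds(pos, neg)
        assert balanced_cutoff(ms).threshold == brute_force_balanced(ms)

    @given(pos=scores_lists, neg=scores_lists)
    def test_youden_equals_exhaustive_search(self, pos, neg):
        ms = metrics_at_all_thresholds(pos, neg)
        assert youden_cutoff(ms).threshold == brute_force_youden(ms)

    def test_youden_tie_breaks_toward_lower_threshold(self):
        # all patients <= 20, all controls >= 25: J = 1 on t in 20..24
        ms = metrics_at_all_thresholds([18, 20], [25, 27])
        assert youden_cutoff(ms).threshold == 20

    def test_balanced_tie_breaks_toward_lower_threshold(self):
        ms = metrics_at_all_thresholds([18, 20], [25, 27])
        assert balanced_cutoff(ms).threshold == 20

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            youden_cutoff([])

    def test_fixed_strategy_evaluates_requested_threshold(self):
        choice = fixed_cutoff([20, 25], [27, 28], t=25)
        assert choice.strategy == "fixed"
        assert choice.label == "25/26"
        assert choice.metrics.sensitivity == 1.0


class TestPercentileCutoff:
    def test_hand_computed_linear_quantile(self):
        # ten equally spaced controls: 10th percentile interpolates to 20.9
        c = percentile_cutoff(range(20, 30), q=0.10)
        assert c.strategy_params["quantile"] == pytest.approx(20.9)
        assert c.threshold == 20

    def test_q_zero_returns_floor_of_minimum(self):
        c = percentile_cutoff([22, 25, 28], q=0.0)
        assert c.threshold == 22

    def test_large_control_sample_recovers_normal_quantile(self):
        """round(Normal(26.5, 2.4)) controls: the 10th percentile sits at score
        23 (continuous quantile 26.5 - 1.2816*2.4 = 23.4), giving cut-off 23/24."""
        rng = np.random.default_rng(77)
        controls = np.clip(np.round(rng.normal(26.5, 2.4, 10_000)), 0, 30)
        c = percentile_cutoff(controls, q=0.10)
        assert c.threshold == 23
        assert c.label == "23/24"

    @given(neg=scores_lists, q=st.floats(0.01, 0.99))
    def test_threshold_never_exceeds_control_maximum(self, neg, q):
        assert percentile_cutoff(neg, q).threshold <= max(neg)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percentile_cutoff([], 0.1)


class TestPredictiveValues:
    def test_perfect_test_has_perfect_predictive_values(self):
        assert ppv_npv(1, 1, 0.3) == (1.0, 1.0)

    def test_zero_prevalence_convention(self):
        ppv, npv = ppv_npv(0.8, 0.9, 0.0)
        assert ppv == 0.0 and npv == 1.0

    def test_unit_prevalence_convention(self):
        ppv, npv = ppv_npv(0.8, 0.9, 1.0)
        assert ppv == 1.0 and npv == 0.0

    def test_memory_clinic_prevalence_example(self):
        ppv, _ = ppv_npv(0.84, 0.92, 0.901)
        assert ppv == pytest.approx(0.9896, abs=2e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            ppv_npv(0.5, 0.5, 1.2)

    @given(pos=scores_lists, neg=scores_lists, t=st.integers(0, 30))
    def test_conservation_against_confusion_table(self, pos, neg, t):
        """At the sample's own prevalence, PPV and NPV reduce to tp/(tp+fp)
        and tn/(tn+fn)."""
        m = evaluate_cutoff(pos, neg, t)
        prev = (m.tp + m.fn) / (m.tp + m.fn + m.tn + m.fp)
        ppv, npv = ppv_npv(m.sensitivity, m.specificity, prev)
        if m.tp + m.fp > 0:
            assert ppv == pytest.approx(m.tp / (m.tp + m.fp))
        if m.tn + m.fn > 0:
            assert npv == pytest.approx(m.tn / (m.tn + m.fn))


class TestPrevalence:
    def test_clinic_sample_values(self):
        assert round(100 * prevalence(447, 49), 1) == 90.1
        assert round(100 * prevalence(159, 337), 1) == 32.1

    def test_edge_cases(self):
        assert prevalence(0, 49) == 0.0
        with pytest.raises(ValueError):
            prevalence(0, 0)
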