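"""Confusion metrics, AUC, threshold selection, calibration, Boyce index,
and the LOOCV driver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wadihsi.synthetic import generate_prediction_sets
from wadihsi.validation import (
    ConfusionCounts,
    auc,
    boyce_index,
    calibration_ratio,
    confusion_metrics,
    loocv,
    select_threshold,
)

counts_st = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
).filter(lambda t: sum(t) > 0)


class TestConfusionMetrics:
    def test_twelve_site_survey_outcome(self):
        """4 TP, 6 TN, 2 FN, 0 FP over twelve sites."""
        rep = confusion_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=2))
        assert rep.sensitivity == pytest.approx(2 / 3)
        assert rep.specificity == 1.0
        assert rep.accuracy == pytest.approx(10 / 12)
        assert rep.precision == 1.0
        assert rep.f1 == pytest.approx(0.8)
        assert rep.tss == pytest.approx(2 / 3)
        # predicted prevalence 4/12 vs observed 6/12: gap 0.167 > 0.10
        assert rep.prevalence_mismatch

    def test_all_positive_degenerate(self):
        rep = confusion_metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=0))
        assert rep.sensitivity == 1.0
        assert math.isnan(rep.specificity)
        assert "specificity" in rep.undefined

    def test_perfect_classifier_tss_one(self):
        rep = confusion_metrics(ConfusionCounts(tp=3, fp=0, tn=7, fn=0))
        assert rep.tss == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)

    @given(counts_st)
    @settings(max_examples=200, deadline=None)
    def test_tss_and_balanced_accuracy_identities(self, counts):
        tp, fp, tn, fn = counts
        rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if not (math.isnan(rep.sensitivity) or math.isnan(rep.specificity)):
            assert rep.tss == pytest.approx(rep.sensitivity + rep.specificity - 1)
            assert rep.balanced_accuracy == pytest.approx((rep.tss + 1) / 2)
        assert rep.predicted_prevalence + 1e-12 >= 0
        assert rep.observed_prevalence <= 1

    @given(counts_st)
    @settings(max_examples=100, deadline=None)
    def test_prevalence_flag_threshold(self, counts):
        tp, fp, tn, fn = counts
        rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        gap = abs(rep.predicted_prevalence - rep.observed_prevalence)
        assert rep.prevalence_mismatch == (gap > 0.10)


def _auc_bruteforce(p, b):
    wins = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in p for y in b)
    return wins / (len(p) * len(b))


class TestAuc:
    def test_four_pair_enumeration(self):
        assert auc([0.8, 0.6], [0.7, 0.1]) == pytest.approx(0.75)

    def test_disjoint_and_identical(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0
        assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    @given(
        p=st.lists(st.floats(0, 1, width=16), min_size=1, max_size=25),
        b=st.lists(st.floats(0, 1, width=16), min_size=1, max_size=25),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_pair_counting_oracle(self, p, b):
        assert auc(p, b) == pytest.approx(_auc_bruteforce(p, b))


class TestThresholdSelection:
    def test_default_ignores_data(self):
        assert select_threshold([0.9], [0.1], "default").threshold == 0.5
        assert select_threshold([0.2], [0.8], "default").threshold == 0.5

    def test_perfect_separation_methods_converge(self):
        p, b = [0.8, 0.9, 0.95], [0.1, 0.2, 0.3]
        t_maxss = select_threshold(p, b, "MaxSS")
        t_roc = select_threshold(p, b, "MinROCdist")
        assert t_maxss.threshold == t_roc.threshold
        assert 0.3 < t_maxss.threshold < 0.8
        assert t_maxss.objective == pytest.approx(2.0)  # sens + spec

    def test_maxss_against_exhaustive_scan(self):
        p = np.array([0.9, 0.8, 0.4])
        b = np.array([0.5, 0.3, 0.2])
        choice = select_threshold(p, b, "MaxSS")
        # brute force over a fine grid can do no better
        grid = np.linspace(0, 1, 2001)
        best = max(np.mean(p >= t) + np.mean(b < t) for t in grid)
        assert choice.objective == pytest.approx(best)
        # the optimum (sens+spec = 5/3) is attained both between 0.3|0.4 and
        # between 0.5|0.8; the tie breaks toward the lower cut
        assert choice.threshold == pytest.approx(0.35)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            select_threshold([0.5], [0.5], "magic")


class TestCalibrationRatio:
    def test_closed_forms(self):
        assert calibration_ratio([0.4, 0.6], [0.5, 0.5]) == pytest.approx(0.0)
        assert calibration_ratio([0.9, 0.9], [0.3, 0.3]) == pytest.approx(0.5)
        assert calibration_ratio([0.0], [0.5]) == pytest.approx(-1.0)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            calibration_ratio([0.5], [0.0, 0.0])


class TestBoyceIndex:
    def test_monotone_pe_gives_one(self):
        # presence density rises linearly with suitability -> P/E = a + b
        # in every window [a, b]: strictly increasing, Spearman rho = 1
        u = np.linspace(1e-4, 1, 4000)
        presence = np.sqrt(u)
        background = np.linspace(0, 1, 4000)
        assert boyce_index(presence, background) == pytest.approx(1.0)

    def test_reversed_suitability_is_negative(self):
        u = np.linspace(1e-4, 1, 4000)
        assert boyce_index(1 - np.sqrt(u), np.linspace(0, 1, 4000)) < 0

    def test_null_is_centred_on_zero(self):
        """Presence drawn identically to background: the index averages to
        ~0 over seeds (single seeds are noisy: rank correlation of 10
        near-equal ratios)."""
        vals = [
            boyce_index(*generate_prediction_sets(10000, 10000, 0.0, seed))
            for seed in range(25)
        ]
        assert abs(np.mean(vals)) < 0.3


class TestLoocv:
    def test_oracle_predictor_perfect_score(self):
        obs = [0.2, 0.5, 0.9, 0.4]
        rep = loocv(list("abcd"), obs, predictor=lambda i: obs[i])
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0 and rep.mae == 0.0

    def test_constant_predictor_r2_nonpositive(self):
        obs = np.array([0.1, 0.5, 0.9])
        mean = obs.mean()
        rep = loocv(list("abc"), obs, predictor=lambda i: mean)
        assert rep.r2 <= 0.0 + 1e-12

    def test_rmse_at_least_mae_and_mean_residual(self, rng):
        obs = rng.uniform(0, 1, 10)
        pred = obs + rng.normal(0, 0.1, 10)
        rep = loocv(range(10), obs, predictor=lambda i: pred[i])
        assert rep.rmse >= rep.mae >= 0.0
        assert rep.mean_residual == pytest.approx(np.mean(obs - pred))

    def test_failing_fold_flagged_not_skipped_silently(self):
        obs = [0.1, 0.2, 0.3, 0.4]

        def predictor(i):
            if i == 2:
                raise RuntimeError("degenerate re-fit")
            return obs[i]

        rep = loocv(list("abcd"), obs, predictor)
        assert rep.flagged_folds == [("c", "degenerate re-fit")]
        assert math.isnan(rep.predicted[2])
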