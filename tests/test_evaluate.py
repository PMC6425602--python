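"""Outcomes, metrics, paired comparison and confidence machinery."""

import numpy as np
import pytest
from scipy import stats

from dsindex import (
    PROGRESSED,
    STABLE,
    classify_dsi,
    confidence_analysis,
    confusion_metrics,
    define_outcome,
    evaluate_study,
    paired_compare,
    prediction_to_binary,
    subgroup_extreme,
)


class TestOutcome:
    @pytest.mark.parametrize(
        "baseline,followup,label,subtype",
        [
            ("SCD", "MCI", PROGRESSED, "to_MCI"),
            ("SCD", "AD", PROGRESSED, "to_AD"),
            ("SCD", "NONAD", PROGRESSED, "to_nonAD"),
            ("SCD", "SCD", STABLE, None),
            ("MCI", "AD", PROGRESSED, "to_AD"),
            ("MCI", "NONAD", PROGRESSED, "to_nonAD"),
            ("MCI", "MCI", STABLE, None),
            ("MCI", "SCD", STABLE, None),  # improvement handled as stable
        ],
    )
    def test_progression_rule(self, baseline, followup, label, subtype):
        out = define_outcome(baseline, followup)
        assert (out.label, out.subtype) == (label, subtype)

    def test_dementia_at_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            define_outcome("AD", "AD")

    @pytest.mark.parametrize(
        "baseline,pred,expected",
        [
            ("SCD", "MCI", PROGRESSED),
            ("SCD", "DEM", PROGRESSED),
            ("SCD", "SCD", STABLE),
            ("MCI", "MCI", STABLE),
            ("MCI", "DEM", PROGRESSED),
            ("MCI", "AD", PROGRESSED),
            ("MCI", "SCD", STABLE),
        ],
    )
    def test_prediction_mapping(self, baseline, pred, expected):
        assert prediction_to_binary(baseline, pred) == expected


class TestDsiClassification:
    def test_cutoff_boundary_is_inclusive(self):
        assert classify_dsi(0.50) == PROGRESSED
        assert classify_dsi(0.49) == STABLE
        assert classify_dsi(None) is None
        assert classify_dsi(float("nan")) is None

    def test_progressed_calls_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        counts = []
        for cutoff in np.arange(0.3, 0.71, 0.05):
            calls = [classify_dsi(s, cutoff) for s in scores]
            counts.append(sum(c == PROGRESSED for c in calls))
            assert counts[-1] == int(np.sum(scores >= cutoff))  # brute force
        assert counts == sorted(counts, reverse=True)

    def test_subgroup_bounds_inclusive(self):
        assert subgroup_extreme([0.1, 0.5, 0.85]) == [0, 2]
        assert subgroup_extreme([0.2, 0.8]) == [0, 1]
        assert subgroup_extreme([0.4, 0.5, None]) == []
        with pytest.raises(ValueError):
            subgroup_extreme([0.5], low=0.9, high=0.1)


class TestMetrics:
    def test_hand_counted_confusion(self):
        preds = [PROGRESSED] * 3 + [STABLE] * 1 + [STABLE] * 4 + [PROGRESSED] * 2
        truth = [PROGRESSED] * 4 + [STABLE] * 6
        m = confusion_metrics(preds, truth)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 4, 2)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.ppv == pytest.approx(0.6)
        assert m.npv == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.7)

    def test_perfect_predictor(self):
        truth = [PROGRESSED, STABLE, PROGRESSED, STABLE]
        m = confusion_metrics(truth, truth)
        assert (
            m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy, m.balanced_accuracy
        ) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_ratios_flagged_not_faked(self):
        m = confusion_metrics([STABLE, STABLE], [STABLE, STABLE])
        assert m.sensitivity is None and m.ppv is None and m.balanced_accuracy is None
        assert m.specificity == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([STABLE], [STABLE, STABLE])


def _correctness(both: int, neither: int, b: int, c: int):
    without = [True] * both + [False] * neither + [False] * b + [True] * c
    with_ = [True] * both + [False] * neither + [True] * b + [False] * c
    return without, with_


class TestPairedCompare:
    def test_symmetric_discordance_is_null(self):
        res = paired_compare(*_correctness(40, 40, 10, 10))
        assert res.diff == 0.0
        assert res.p == 1.0

    def test_no_discordance_p_is_one(self):
        res = paired_compare(*_correctness(5, 5, 0, 0))
        assert res.p == 1.0 and res.statistic is None

    def test_chi_square_against_oracle(self):
        res = paired_compare(*_correctness(50, 44, 5, 1))
        assert res.statistic == pytest.approx(16 / 6)
        assert res.p == pytest.approx(0.1025, abs=5e-4)
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        oracle = sm.mcnemar([[50, 5], [1, 44]], exact=False, correction=False)
        assert res.p == pytest.approx(float(oracle.pvalue))

    def test_exact_variant_uses_binomial(self):
        res = paired_compare(*_correctness(10, 10, 5, 1), exact=True)
        assert res.p == pytest.approx(float(stats.binomtest(1, 6, 0.5).pvalue))

    def test_accuracy_difference_identity(self):
        res = paired_compare(*_correctness(17, 3, 7, 2))
        n = res.n
        assert res.diff == (res.changed_correct - res.changed_incorrect) / n
        assert res.acc_with - res.acc_without == pytest.approx(res.diff)
        assert res.ci_low <= res.diff <= res.ci_high

    def test_ci_width_shrinks_with_n(self):
        narrow = paired_compare(*_correctness(860, 100, 20, 20))
        wide = paired_compare(*_correctness(86, 10, 2, 2))
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_compare([True], [True, False])


class TestConfidence:
    def test_zero_variance_flagged(self):
        res = confidence_analysis([50.0, 60.0], [50.0, 60.0], [True, False])
        assert res.mean_delta_vas == 0.0
        assert res.t_statistic is None and res.p is None

    def test_balanced_shift_means_zero(self):
        res = confidence_analysis([40.0, 60.0], [50.0, 50.0], [True, True])
        assert res.mean_delta_vas == 0.0

    def test_recovers_known_mean_shift(self):
        # 429 paired scores with a true +4 shift (sd 13); estimate must land
        # inside the 95% CI of the generative mean
        rng = np.random.default_rng(99)
        base = np.clip(rng.normal(65, 15, size=429), 0, 95)
        delta = rng.normal(4.0, 13.0, size=429)
        res = confidence_analysis(base, np.clip(base + delta, 0, 100), rng.random(429) < 0.7)
        half = 1.959964 * 13.0 / np.sqrt(429)
        assert abs(res.mean_delta_vas - 4.0) < half
        assert res.p < 0.05

    def test_categorical_shifts_partition(self):
        cats_wo = ["low", "moderate", "high", "moderate"]
        cats_wt = ["moderate", "low", "high", "high"]
        res = confidence_analysis(
            [10.0, 60.0, 80.0, 60.0],
            [55.0, 40.0, 80.0, 80.0],
            [True, False, True, False],
            cats_wo,
            cats_wt,
        )
        total = (
            res.increase_correct + res.increase_incorrect
            + res.decrease_correct + res.decrease_incorrect
            + res.stable_correct + res.stable_incorrect
        )
        assert total == res.n == 4
        assert res.increase_correct == 1 and res.increase_incorrect == 1
        assert res.decrease_incorrect == 1 and res.stable_correct == 1

    def test_vas_bounds_enforced(self):
        with pytest.raises(ValueError, match="0, 100"):
            confidence_analysis([120.0], [50.0], [True])


class TestEvaluateStudy:
    def test_copied_predictions_give_null_comparison(self, default_study):
        cohort, model, _ = default_study
        from dataclasses import replace

        clone = type(cohort)(
            patients=[replace(p, pred_with_tool=p.pred_without_tool) for p in cohort.patients],
            provenance=dict(cohort.provenance),
        )
        rep = evaluate_study(clone, model)
        pr = rep.strata["all"].paired_without_with
        assert pr.changed_correct == pr.changed_incorrect == 0
        assert pr.diff == 0.0 and pr.p == 1.0

    def test_strata_partition_cohort(self, default_study):
        cohort, model, _ = default_study
        rep = evaluate_study(cohort, model)
        assert rep.strata["scd"].n + rep.strata["mci"].n == rep.strata["all"].n == len(cohort)

    def test_undefined_scores_excluded_and_counted(self, default_study):
        cohort, model, _ = default_study
        from dataclasses import replace

        # blank every variable of the first three patients -> undefined index
        patients = [
            replace(p, values={k: None for k in p.values}) if i < 3 else p
            for i, p in enumerate(cohort.patients)
        ]
        rep = evaluate_study(type(cohort)(patients=patients), model)
        s = rep.strata["all"]
        assert s.n_unclassifiable_dsi == 3
        assert s.metrics_dsi.n == s.n - 3
        assert s.metrics_without.n == s.n  # clinician analysis keeps everyone

    def test_sweep_table_consistent_with_direct_threshold(self, default_study):
        cohort, model, _ = default_study
        rep = evaluate_study(cohort, model)
        from dsindex import compute_dsi

        scores = np.array([compute_dsi(p, model) for p in cohort.patients], dtype=float)
        truth = np.array(
            [define_outcome(p.baseline_dx, p.followup_dx).label == PROGRESSED for p in cohort.patients]
        )
        row = rep.sweep[rep.sweep.cutoff == 0.5].iloc[0]
        assert row.tp == int(np.sum((scores >= 0.5) & truth))
        assert row.tn == int(np.sum((scores < 0.5) & ~truth))

    def test_missing_followup_rejected(self, default_study):
        cohort, model, _ = default_study
        from dataclasses import replace

        patients = [replace(cohort.patients[0], followup_dx=None)] + cohort.patients[1:]
        with pytest.raises(ValueError, match="follow-up"):
            evaluate_study(type(cohort)(patients=patients), model)
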