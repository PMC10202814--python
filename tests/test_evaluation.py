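import itertools

import numpy as np
import pytest

from trajrisk.evaluation import (
    IntervalOutcome,
    bootstrap_ci,
    compute_auprc,
    compute_auroc,
    compute_rr_curve,
    f1_operational_point,
    interval_outcomes,
    recall_by_time_to_cancer,
    surveillance_scenario,
    top_n_operational_point,
)

from conftest import random_trajectory


def outcomes_from(scores, labels, ttc=None):
    ttc = ttc or [None] * len(scores)
    return [IntervalOutcome(score=s, label=l, time_to_cancer=t,
                            patient_id=f"o{i}")
            for i, (s, l, t) in enumerate(zip(scores, labels, ttc))]


# ------------------------------------------------------- brute-force oracles
def auroc_oracle(scores, labels):
    """Pair counting: P(random positive outscores random negative)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def auprc_oracle(scores, labels):
    """Step-wise area: sum of (recall step) x precision over distinct
    thresholds, descending."""
    total_pos = sum(labels)
    area, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
        flagged = sum(1 for s in scores if s >= thr)
        recall = tp / total_pos
        area += (recall - prev_recall) * (tp / flagged)
        prev_recall = recall
    return area


def f1_oracle(scores, labels):
    best = 0.0
    for thr in sorted(set(scores)):
        flagged = [s >= thr for s in scores]
        tp = sum(1 for f, l in zip(flagged, labels) if f and l)
        fp = sum(1 for f, l in zip(flagged, labels) if f and not l)
        fn = sum(1 for f, l in zip(flagged, labels) if not f and l)
        if tp:
            p, r = tp / (tp + fp), tp / (tp + fn)
            best = max(best, 2 * p * r / (p + r))
    return best


def rr_oracle(scores, labels, n):
    order = np.argsort(-np.asarray(scores), kind="stable")[:n]
    precision = np.asarray(labels)[order].mean()
    return precision / np.mean(labels)


def random_instance(rng, max_n=12):
    n = rng.integers(3, max_n + 1)
    labels = np.zeros(n, dtype=int)
    labels[:rng.integers(1, n)] = 1
    rng.shuffle(labels)
    # half-point grid forces plenty of score ties
    scores = rng.integers(0, 7, size=n) / 6.0
    return scores.tolist(), labels.tolist()


class TestMetricOracles:
    def test_auroc_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            scores, labels = random_instance(rng)
            if len(set(labels)) < 2:
                continue
            got = compute_auroc(outcomes_from(scores, labels))
            assert got == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)

    def test_auprc_matches_threshold_sweep_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            scores, labels = random_instance(rng)
            got = compute_auprc(outcomes_from(scores, labels))
            assert got == pytest.approx(auprc_oracle(scores, labels), abs=1e-12)

    def test_f1_point_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            scores, labels = random_instance(rng)
            got = f1_operational_point(outcomes_from(scores, labels))
            assert got.f1 == pytest.approx(f1_oracle(scores, labels), abs=1e-12)

    def test_perfect_separation_extremes(self):
        outc = outcomes_from([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert compute_auroc(outc) == 1.0
        assert compute_auprc(outc) == 1.0
        assert f1_operational_point(outc).f1 == 1.0

    def test_constant_scores_give_chance_level(self):
        outc = outcomes_from([0.5] * 8, [1, 0, 0, 1, 0, 0, 0, 0])
        assert compute_auroc(outc) == 0.5
        assert compute_auprc(outc) == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc(outcomes_from([0.1, 0.2], [0, 0]))
        with pytest.raises(ValueError):
            compute_auprc(outcomes_from([0.1, 0.2], [0, 0]))

    def test_rank_metrics_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(14)
        scores, labels = random_instance(rng, max_n=10)
        outc = outcomes_from(scores, labels)
        warped = outcomes_from([np.expm1(3 * s) for s in scores], labels)
        assert compute_auroc(outc) == pytest.approx(compute_auroc(warped))
        assert compute_auprc(outc) == pytest.approx(compute_auprc(warped))


class TestRRCurve:
    def test_hand_computed_example(self):
        # 10 outcomes, 2 positives; the top-5 contains both
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        labels = [1, 0, 0, 1, 0, 0, 0, 0, 0, 0]
        curve = compute_rr_curve(outcomes_from(scores, labels), n_values=[5])
        assert curve.precision[0] == pytest.approx(0.4)
        assert curve.incidence == pytest.approx(0.2)
        assert curve.rr[0] == pytest.approx(2.0)

    def test_full_set_has_rr_one_and_top_all_positives_hits_max(self):
        scores = [0.9, 0.8, 0.3, 0.2, 0.1]
        labels = [1, 1, 0, 0, 0]
        curve = compute_rr_curve(outcomes_from(scores, labels),
                                 n_values=[2, 5])
        assert curve.rr[0] == pytest.approx(1 / curve.incidence)
        assert curve.rr[1] == pytest.approx(1.0)

    def test_rr_bounded_by_inverse_incidence(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            scores, labels = random_instance(rng)
            curve = compute_rr_curve(outcomes_from(scores, labels),
                                     n_values=range(1, len(scores) + 1))
            assert np.all(curve.rr >= 0)
            assert np.all(curve.rr <= 1 / curve.incidence + 1e-12)

    def test_random_ranking_averages_to_rr_one(self):
        rng = np.random.default_rng(16)
        labels = [1] * 5 + [0] * 45
        vals = []
        for _ in range(400):
            scores = rng.random(50).tolist()
            vals.append(rr_oracle(scores, labels, 10))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            scores, labels = random_instance(rng)
            n = int(rng.integers(1, len(scores) + 1))
            curve = compute_rr_curve(outcomes_from(scores, labels), [n])
            assert curve.rr[0] == pytest.approx(
                rr_oracle(scores, labels, n), abs=1e-12)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(18)
        outc = outcomes_from(rng.random(60).tolist(),
                             (rng.random(60) < 0.3).astype(int).tolist())
        a = bootstrap_ci(outc, compute_auroc, seed=4)
        b = bootstrap_ci(outc, compute_auroc, seed=4)
        assert a == b

    def test_interval_contains_point_and_collapses_when_separated(self):
        scores = list(np.linspace(0.6, 1.0, 40)) + list(np.linspace(0, 0.4, 160))
        labels = [1] * 40 + [0] * 160
        point, lo, hi = bootstrap_ci(outcomes_from(scores, labels),
                                     compute_auroc, seed=0)
        assert lo <= point <= hi
        assert point == 1.0 and hi - lo < 1e-9

    def test_interval_widens_as_sample_shrinks(self):
        rng = np.random.default_rng(19)

        def make(n):
            labels = (rng.random(n) < 0.3).astype(int)
            scores = labels * 0.3 + rng.random(n) * 0.7
            return outcomes_from(scores.tolist(), labels.tolist())

        _, lo_big, hi_big = bootstrap_ci(make(400), compute_auroc, seed=1)
        _, lo_small, hi_small = bootstrap_ci(make(25), compute_auroc, seed=1)
        assert (hi_small - lo_small) > (hi_big - lo_big)


class TestOperationalPoints:
    def test_single_positive_ranked_first_gets_f1_one(self):
        scores = [0.99] + list(np.linspace(0.1, 0.5, 9))
        labels = [1] + [0] * 9
        point = f1_operational_point(outcomes_from(scores, labels))
        assert point.f1 == 1.0 and point.n_flagged == 1

    def test_top_n_point_flags_exactly_n(self):
        rng = np.random.default_rng(20)
        scores, labels = random_instance(rng, max_n=10)
        point = top_n_operational_point(outcomes_from(scores, labels), 3)
        assert point.n_flagged == 3

    def test_recall_by_bin_perfect_and_zero_thresholds(self):
        outc = outcomes_from([0.9, 0.8, 0.7], [1, 1, 1], ttc=[2, 8, 30])
        full = recall_by_time_to_cancer(outc, threshold=0.0)
        assert all(v == 1.0 for v in full.values() if v is not None)
        none = recall_by_time_to_cancer(outc, threshold=1.1)
        assert none["0-6"] == 0.0 and none["24-36"] == 0.0
        assert none["12-24"] is None  # empty bin reported absent


class TestSurveillanceScenario:
    def test_discussion_arithmetic(self):
        assert surveillance_scenario(1_000_000, 1000, 0.32)[
            "expected_true_positives"] == 320
        assert surveillance_scenario(1_000_000, 1000, 0.07)[
            "expected_true_positives"] == 70

    def test_zero_flagged_zero_yield(self):
        assert surveillance_scenario(100, 0, 0.5)["expected_true_positives"] == 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            surveillance_scenario(10, 20, 0.5)
        with pytest.raises(ValueError):
            surveillance_scenario(10, 5, 1.5)


class TestIntervalOutcomes:
    def test_label_follows_interval_membership(self, tiny_model):
        trajs = [random_trajectory(1, cancer_months=40),
                 random_trajectory(2)]
        out36 = interval_outcomes(tiny_model, trajs, 36)
        out60 = interval_outcomes(tiny_model, trajs, 60)
        assert [o.label for o in out36] == [0, 0]  # cancer at 40 months
        assert [o.label for o in out60] == [1, 0]

    def test_age_filter_can_empty_the_set(self, tiny_model):
        trajs = [random_trajectory(3)]
        trajs[0].assessment_age = 45.0
        assert interval_outcomes(tiny_model, trajs, 36, age_min=50) == []

    def test_unknown_horizon_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            interval_outcomes(tiny_model, [random_trajectory(1)], 24)

    def test_patient_level_takes_max_score_per_patient(self, tiny_model):
        t1 = random_trajectory(4)
        t2 = random_trajectory(5)
        t2.patient_id = t1.patient_id
        out = interval_outcomes(tiny_model, [t1, t2], 36, patient_level=True)
        assert len(out) == 1
        both = interval_outcomes(tiny_model, [t1, t2], 36)
        assert out[0].score == max(o.score for o in both)
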