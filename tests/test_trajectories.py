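import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajrisk.codes import Vocabulary
from trajrisk.dates import add_months
from trajrisk.trajectories import (
    apply_exclusion_window,
    balanced_batch_sampler,
    eligibility_filter,
    enumerate_partial_trajectories,
    label_horizons,
    split_by_patient,
)

from conftest import make_patient, monthly_dates, random_trajectory


VOCAB = Vocabulary.build(("icd10", f"A{i:02d}") for i in range(40))


# ---------------------------------------------------------------- labelling
class TestLabelHorizons:
    def test_control_all_zero_fully_unmasked(self):
        labels = label_horizons(dt.date(2010, 1, 1), None)
        assert labels.y.tolist() == [0] * 5
        assert labels.mask.tolist() == [1] * 5

    @pytest.mark.parametrize("months, expected", [
        (2, [1, 1, 1, 1, 1]),
        (8, [0, 0, 1, 1, 1]),
        (20, [0, 0, 0, 1, 1]),
        (48, [0, 0, 0, 0, 1]),
        (70, [0, 0, 0, 0, 0]),
    ])
    def test_step_function_at_time_to_cancer(self, months, expected):
        assess = dt.date(2010, 1, 15)
        labels = label_horizons(assess, add_months(assess, months))
        assert labels.y.tolist() == expected

    def test_mask_keeps_zeros_and_first_positive_only(self):
        assess = dt.date(2010, 1, 15)
        labels = label_horizons(assess, add_months(assess, 8))
        # y = (0,0,1,1,1): mask covers 3,6 (zeros) and 12 (first positive)
        assert labels.mask.tolist() == [1, 1, 1, 0, 0]

    def test_mask_mode_all_unmasks_everything(self):
        assess = dt.date(2010, 1, 15)
        labels = label_horizons(assess, add_months(assess, 8), mask_mode="all")
        assert labels.mask.tolist() == [1] * 5

    def test_assessment_on_or_after_cancer_rejected(self):
        with pytest.raises(ValueError):
            label_horizons(dt.date(2010, 1, 1), dt.date(2010, 1, 1))

    @given(st.integers(min_value=1, max_value=120))
    @settings(max_examples=50, deadline=None)
    def test_labels_always_non_decreasing(self, months):
        assess = dt.date(2005, 3, 31)
        labels = label_horizons(assess, add_months(assess, months))
        assert np.all(np.diff(labels.y) >= 0)


# -------------------------------------------------------------- enumeration
class TestEnumeration:
    def test_control_trajectory_count_is_n_minus_4(self):
        start = dt.date(2000, 1, 1)
        p = make_patient(event_dates=monthly_dates(start, 7),
                         end=dt.date(2018, 1, 1))
        trajs = enumerate_partial_trajectories(p, VOCAB)
        assert len(trajs) == 3  # endpoints at events 5, 6, 7
        assert all(t.token_indices[0] == trajs[0].token_indices[0]
                   for t in trajs)  # every prefix starts at event 1

    def test_minimum_length_control_yields_one(self):
        p = make_patient(event_dates=monthly_dates(dt.date(2000, 1, 1), 5))
        assert len(enumerate_partial_trajectories(p, VOCAB)) == 1

    def test_cancer_endpoints_strictly_before_diagnosis(self):
        start = dt.date(2000, 1, 1)
        dates = monthly_dates(start, 8)
        cancer = dates[6] - dt.timedelta(days=1)  # events 7-8 after diagnosis
        p = make_patient(event_dates=dates, cancer=cancer)
        trajs = enumerate_partial_trajectories(p, VOCAB)
        assert len(trajs) == 2  # endpoints 5 and 6
        assert all(t.assessment_date < cancer for t in trajs)

    def test_control_buffer_blocks_late_endpoints(self):
        end = dt.date(2018, 1, 1)
        # 6 events, all within 12 months of end of data
        dates = monthly_dates(end - dt.timedelta(days=330), 6, step_days=30)
        p = make_patient(event_dates=dates, end=end)
        assert enumerate_partial_trajectories(p, VOCAB) == []

    @given(st.integers(min_value=0, max_value=15))
    @settings(max_examples=30, deadline=None)
    def test_augmentation_count_max_n_minus_4(self, n):
        # all events comfortably clear of the buffer
        p = make_patient(event_dates=monthly_dates(dt.date(1995, 1, 1), n)) \
            if n else make_patient(event_dates=[])
        trajs = enumerate_partial_trajectories(p, VOCAB)
        assert len(trajs) == max(0, n - 4)

    def test_ages_and_deltas_derive_from_dates(self):
        dates = [dt.date(2000, 1, 1), dt.date(2000, 1, 1),
                 dt.date(2001, 1, 1), dt.date(2002, 6, 1),
                 dt.date(2003, 1, 1)]
        p = make_patient(birth=dt.date(1960, 1, 1), event_dates=dates)
        (traj,) = enumerate_partial_trajectories(p, VOCAB)
        assert traj.deltas[0] == 0.0
        assert traj.deltas[1] == 0.0  # same-day pair
        assert traj.deltas[2] == 366.0  # 2000 is a leap year
        assert traj.ages[0] == pytest.approx(40.0, abs=0.01)
        assert np.all(np.diff(traj.ages) >= 0)


# ---------------------------------------------------------------- exclusion
class TestExclusionWindow:
    def _cancer_patient(self):
        cancer = dt.date(2015, 6, 1)
        offsets = [14, 8, 2]  # months before diagnosis
        dates = [add_months(cancer, -m) for m in offsets]
        dates = sorted(dates) + [cancer]
        return make_patient(event_dates=sorted(dates), cancer=cancer,
                            codes=["A01"] * 4, end=dt.date(2016, 1, 1))

    def test_zero_exclusion_is_identity(self):
        p = self._cancer_patient()
        assert apply_exclusion_window(p, 0) is p

    def test_window_drops_only_near_diagnosis_events(self):
        p = self._cancer_patient()
        out = apply_exclusion_window(p, 3)
        kept = [e.date for e in out.events if e.date < p.cancer_date]
        assert len(kept) == 2  # 14- and 8-month-old events survive

    def test_controls_unchanged(self):
        p = make_patient(event_dates=monthly_dates(dt.date(2000, 1, 1), 6))
        assert apply_exclusion_window(p, 12) is p

    def test_exclusion_windows_nest(self):
        p = self._cancer_patient()
        sets = []
        for m in (0, 3, 6, 12):
            out = apply_exclusion_window(p, m)
            sets.append({(e.code, e.date) for e in out.events})
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger


# -------------------------------------------------------------- eligibility
class TestEligibility:
    def test_too_few_events_excluded(self):
        p = make_patient(event_dates=monthly_dates(dt.date(2000, 1, 1), 4))
        kept, tally = eligibility_filter([p])
        assert kept == [] and tally["too_few_events"] == 1

    def test_cancer_patient_with_five_precancer_events_retained(self):
        dates = monthly_dates(dt.date(2000, 1, 1), 5)
        p = make_patient(event_dates=dates, cancer=dt.date(2005, 1, 1),
                         end=dt.date(2005, 6, 1))
        kept, _ = eligibility_filter([p])
        assert kept == [p]

    def test_control_crowded_at_end_of_data_excluded(self):
        end = dt.date(2018, 1, 1)
        dates = monthly_dates(end - dt.timedelta(days=330), 6, step_days=30)
        p = make_patient(event_dates=dates, end=end)
        kept, tally = eligibility_filter([p])
        assert kept == [] and tally["no_admissible_endpoint"] == 1


# ------------------------------------------------------------------- splits
class TestSplit:
    def test_exact_ratios_on_ten_patients(self):
        split = split_by_patient([f"p{i}" for i in range(10)], seed=1)
        groups = list(split.assignment.values())
        assert (groups.count("train"), groups.count("dev"),
                groups.count("test")) == (8, 1, 1)

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(57)]
        a = split_by_patient(ids, seed=9).assignment
        b = split_by_patient(ids, seed=9).assignment
        assert a == b
        c = split_by_patient(ids, seed=10).assignment
        assert a != c

    def test_partition_covers_every_patient_once(self):
        ids = [f"p{i}" for i in range(101)]
        split = split_by_patient(ids, seed=3)
        assert set(split.assignment) == set(ids)
        sizes = [len(split.ids(g)) for g in ("train", "dev", "test")]
        assert sum(sizes) == 101
        for size, ratio in zip(sizes, (0.8, 0.1, 0.1)):
            assert abs(size - ratio * 101) <= 1

    def test_fewer_than_three_patients_rejected(self):
        with pytest.raises(ValueError):
            split_by_patient(["a", "b"], seed=0)


# ------------------------------------------------------------------ sampler
class TestBalancedSampler:
    def _pool(self, n_pos, n_neg):
        pos = [random_trajectory(i, cancer_months=10) for i in range(n_pos)]
        neg = [random_trajectory(1000 + i) for i in range(n_neg)]
        return pos + neg

    def test_every_batch_half_positive(self):
        pool = self._pool(3, 200)
        for batch in balanced_batch_sampler(pool, 8, seed=0, n_batches=20):
            assert sum(t.is_case for t in batch) == 4
            assert len(batch) == 8

    def test_odd_batch_size_rounds_positives_up(self):
        pool = self._pool(5, 50)
        batch = next(iter(balanced_batch_sampler(pool, 7, seed=0)))
        assert sum(t.is_case for t in batch) == 4

    def test_deterministic_stream(self):
        pool = self._pool(4, 60)
        a = [[t.patient_id for t in b]
             for b in balanced_batch_sampler(pool, 6, seed=5, n_batches=10)]
        b = [[t.patient_id for t in b]
             for b in balanced_batch_sampler(pool, 6, seed=5, n_batches=10)]
        assert a == b

    def test_missing_class_named_in_error(self):
        with pytest.raises(ValueError, match="positive"):
            list(balanced_batch_sampler(self._pool(0, 10), 4))
        with pytest.raises(ValueError, match="negative"):
            list(balanced_batch_sampler(self._pool(10, 0), 4))
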