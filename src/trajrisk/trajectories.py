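"""Partial-trajectory enumeration, horizon labels, exclusion windows, splits.

The model's unit of training and evaluation is the *partial trajectory*: a
contiguous prefix of a patient's diagnosis history ending at an assessment
date, labelled with cancer occurrence within each prediction horizon
(3, 6, 12, 36, 60 months after assessment). Every patient contributes all
prefixes of length >= 5 as data augmentation, subject to:

* cancer patients: prefixes must end strictly before the cancer diagnosis;
* controls: prefixes must end at least a buffer (default 24 months) before
  the end of the patient's records, so an undiagnosed cancer just past the
  record end cannot silently contaminate the negative class.

Splitting into train/dev/test is at the patient level so that no patient's
trajectories leak across splits.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .codes import Vocabulary
from .dates import add_months, months_between, years_between
from .records import DiseaseEvent, PatientRecord

__all__ = [
    "HORIZONS",
    "HorizonLabelSet",
    "PartialTrajectory",
    "CohortSplit",
    "label_horizons",
    "apply_exclusion_window",
    "eligibility_filter",
    "enumerate_partial_trajectories",
    "split_by_patient",
    "balanced_batch_sampler",
]

HORIZONS: tuple[int, ...] = (3, 6, 12, 36, 60)


@dataclass(frozen=True)
class HorizonLabelSet:
    """Step-function outcome per horizon plus a loss mask.

    ``y[t] = 1`` iff the cancer diagnosis falls within ``horizons[t]`` months
    of the assessment date, so ``y`` is non-decreasing along horizons.
    ``mask[t] = 1`` marks horizons that contribute to the loss.
    """

    y: np.ndarray
    mask: np.ndarray
    horizons: tuple[int, ...] = HORIZONS

    def __post_init__(self):
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=np.float64))
        if np.any(np.diff(self.y) < 0):
            raise ValueError("horizon labels must be non-decreasing")


@dataclass
class PartialTrajectory:
    """A labelled prefix of one patient's history.

    ``token_indices``, ``ages`` and ``deltas`` are aligned per event: the
    vocabulary index of the code, the patient's age at the event in fractional
    years, and the gap to the previous event in days (0 for the first).
    """

    patient_id: str
    token_indices: np.ndarray
    ages: np.ndarray
    deltas: np.ndarray
    assessment_date: dt.date
    assessment_age: float
    labels: HorizonLabelSet
    time_to_cancer: float | None = None  # months; None for controls
    split: str | None = None

    def __len__(self) -> int:
        return len(self.token_indices)

    @property
    def is_case(self) -> bool:
        return self.time_to_cancer is not None


@dataclass
class CohortSplit:
    """Patient-level train/dev/test assignment."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, group: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == group]


def label_horizons(
    assessment_date: dt.date,
    cancer_date: dt.date | None,
    horizons: tuple[int, ...] = HORIZONS,
    mask_mode: str = "first_positive",
) -> HorizonLabelSet:
    """Build the step-function label and loss mask for one assessment date.

    Controls get all-zero labels with every horizon unmasked. For cancer
    patients, ``y[t] = 1`` iff ``cancer_date <= assessment_date + t months``
    (calendar-month addition). The mask convention for cancer patients:

    * ``"first_positive"`` (default): all horizons before the diagnosis plus
      the first positive horizon contribute; later positives are masked out,
      so each cancer trajectory trains on every informative 0-label and
      exactly one 1-label.
    * ``"all"``: every horizon contributes.
    """
    k = len(horizons)
    if cancer_date is None:
        return HorizonLabelSet(np.zeros(k), np.ones(k), tuple(horizons))
    if assessment_date >= cancer_date:
        raise ValueError(
            f"assessment {assessment_date} not before cancer date {cancer_date}"
        )
    y = np.array(
        [1.0 if cancer_date <= add_months(assessment_date, t) else 0.0 for t in horizons]
    )
    if mask_mode == "all":
        mask = np.ones(k)
    elif mask_mode == "first_positive":
        mask = np.ones(k)
        pos = np.flatnonzero(y)
        if len(pos) > 1:
            mask[pos[1]:] = 0.0
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    return HorizonLabelSet(y, mask, tuple(horizons))


def apply_exclusion_window(patient: PatientRecord, exclusion_months: int) -> PatientRecord:
    """Drop a cancer patient's events from the last `exclusion_months` before
    diagnosis (the window ``[cancer_date - k months, cancer_date)``).

    Controls are returned unchanged, as is the cancer date itself. Used to
    retrain without near-diagnosis symptom codes and measure how much of the
    performance rests on them.
    """
    if exclusion_months < 0:
        raise ValueError("exclusion_months must be non-negative")
    if exclusion_months == 0 or patient.cancer_date is None:
        return patient
    start = add_months(patient.cancer_date, -exclusion_months)
    kept = [
        e for e in patient.events
        if not (start <= e.date < patient.cancer_date)
    ]
    return patient.copy_with_events(kept)


def _latest_control_assessment(patient: PatientRecord, buffer_months: int) -> dt.date:
    return add_months(patient.end_of_data, -buffer_months)


def _admissible_endpoint(patient: PatientRecord, event: DiseaseEvent,
                         buffer_months: int) -> bool:
    if patient.cancer_date is not None:
        return event.date < patient.cancer_date
    return event.date <= _latest_control_assessment(patient, buffer_months)


def eligibility_filter(
    patients: list[PatientRecord],
    min_events: int = 5,
    control_buffer_months: int = 24,
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Drop patients that cannot yield a single admissible trajectory.

    A patient is kept iff at least ``min_events`` of their events are
    admissible assessment endpoints — before the cancer date for cases, at
    least ``control_buffer_months`` before end-of-data for controls. Returns
    the eligible patients plus a tally of exclusion reasons.
    """
    eligible: list[PatientRecord] = []
    tally = {"kept": 0, "too_few_events": 0, "no_admissible_endpoint": 0}
    for p in patients:
        if len(p.events) < min_events:
            tally["too_few_events"] += 1
            continue
        n_admissible = sum(
            _admissible_endpoint(p, e, control_buffer_months) for e in p.events
        )
        if n_admissible < min_events:
            tally["no_admissible_endpoint"] += 1
            continue
        tally["kept"] += 1
        eligible.append(p)
    return eligible, tally


def enumerate_partial_trajectories(
    patient: PatientRecord,
    vocab: Vocabulary,
    min_len: int = 5,
    control_buffer_months: int = 24,
    mask_mode: str = "first_positive",
    horizons: tuple[int, ...] = HORIZONS,
) -> list[PartialTrajectory]:
    """All admissible prefixes of one patient's history, labelled.

    Each prefix starts at the first event and ends at endpoint index
    ``k in [min_len, n]``; a control with ``n`` admissible events therefore
    yields ``max(0, n - min_len + 1)`` trajectories. Cancer patients' prefixes
    end strictly before the cancer date; controls' prefixes end at least the
    buffer before end-of-data.
    """
    events = patient.events
    n = len(events)
    if n < min_len:
        return []
    token_idx = np.array([vocab.encode(e.token) for e in events], dtype=np.int64)
    ages = np.array(
        [years_between(patient.birth_date, e.date) for e in events], dtype=np.float64
    )
    days = np.array([e.date.toordinal() for e in events], dtype=np.float64)
    deltas = np.concatenate([[0.0], np.diff(days)])

    out: list[PartialTrajectory] = []
    for k in range(min_len, n + 1):
        end_event = events[k - 1]
        if not _admissible_endpoint(patient, end_event, control_buffer_months):
            continue
        labels = label_horizons(end_event.date, patient.cancer_date,
                                horizons=horizons, mask_mode=mask_mode)
        ttc = (
            months_between(end_event.date, patient.cancer_date)
            if patient.cancer_date is not None
            else None
        )
        out.append(
            PartialTrajectory(
                patient_id=patient.patient_id,
                token_indices=token_idx[:k],
                ages=ages[:k],
                deltas=deltas[:k],
                assessment_date=end_event.date,
                assessment_age=float(ages[k - 1]),
                labels=labels,
                time_to_cancer=ttc,
            )
        )
    return out


def split_by_patient(
    patient_ids,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> CohortSplit:
    """Random patient-level train/dev/test partition.

    Deterministic given the seed; realized group sizes are within one patient
    of the exact ratios. All of a patient's trajectories inherit the split.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < 3:
        raise ValueError("need at least 3 patients to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = round(ratios[0] * n)
    n_dev = round((ratios[0] + ratios[1]) * n) - n_train
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            group = "train"
        elif rank < n_train + n_dev:
            group = "dev"
        else:
            group = "test"
        assignment[ids[idx]] = group
    return CohortSplit(assignment=assignment, ratios=tuple(ratios), seed=seed)


def balanced_batch_sampler(
    trajectories: list[PartialTrajectory],
    batch_size: int,
    seed: int = 0,
    n_batches: int | None = None,
):
    """Yield class-balanced batches from a rare-outcome trajectory pool.

    Every batch holds ``ceil(batch_size/2)`` positive (cancer-patient) and
    ``floor(batch_size/2)`` negative trajectories; the minority class is
    resampled with replacement. One epoch (the default ``n_batches``) is the
    number of batches needed to cover the majority negative class once.
    """
    positives = [t for t in trajectories if t.is_case]
    negatives = [t for t in trajectories if not t.is_case]
    if not positives:
        raise ValueError("no positive (cancer) trajectories to sample")
    if not negatives:
        raise ValueError("no negative (control) trajectories to sample")
    n_pos = -(-batch_size // 2)  # ceil
    n_neg = batch_size // 2
    if n_neg == 0:
        raise ValueError("batch_size must be at least 2 for balanced batches")
    rng = np.random.default_rng(seed)
    if n_batches is None:
        n_batches = -(-len(negatives) // n_neg)
    neg_order = rng.permutation(len(negatives))
    neg_cursor = 0
    for _ in range(n_batches):
        if neg_cursor + n_neg > len(negatives):
            neg_order = rng.permutation(len(negatives))
            neg_cursor = 0
        neg_idx = neg_order[neg_cursor:neg_cursor + n_neg]
        neg_cursor += n_neg
        pos_idx = rng.integers(0, len(positives), size=n_pos)
        yield [positives[i] for i in pos_idx] + [negatives[i] for i in neg_idx]
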