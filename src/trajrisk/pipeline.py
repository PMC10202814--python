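"""End-to-end cohort preparation: records in, labelled trajectory splits out.

``prepare_cohort`` applies, in order: the exclusion window (cancer patients'
last k months of events removed), the eligibility filter (>= 5 admissible
events), vocabulary construction, a patient-level train/dev/test split, and
partial-trajectory enumeration with horizon labels. Exclusion precedes the
length filter, so heavily excluded patients can drop out entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codes import Vocabulary
from .records import PatientRecord
from .trajectories import (
    HORIZONS,
    CohortSplit,
    PartialTrajectory,
    apply_exclusion_window,
    eligibility_filter,
    enumerate_partial_trajectories,
    split_by_patient,
)

__all__ = ["PreparedCohort", "prepare_cohort"]


@dataclass
class PreparedCohort:
    """Vocabulary, split and labelled trajectories ready for training."""

    vocab: Vocabulary
    split: CohortSplit
    trajectories: dict[str, list[PartialTrajectory]]
    tally: dict[str, int]
    exclusion_months: int = 0

    @property
    def train(self) -> list[PartialTrajectory]:
        return self.trajectories["train"]

    @property
    def dev(self) -> list[PartialTrajectory]:
        return self.trajectories["dev"]

    @property
    def test(self) -> list[PartialTrajectory]:
        return self.trajectories["test"]

    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for group, trajs in self.trajectories.items():
            out[group] = {
                "trajectories": len(trajs),
                "positives": sum(t.is_case for t in trajs),
            }
        return out


def prepare_cohort(
    patients: list[PatientRecord],
    min_events: int = 5,
    control_buffer_months: int = 24,
    exclusion_months: int = 0,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    mask_mode: str = "first_positive",
    horizons: tuple[int, ...] = HORIZONS,
    vocab: Vocabulary | None = None,
    split: CohortSplit | None = None,
) -> PreparedCohort:
    """Build labelled trajectory splits from raw patient records.

    A caller-supplied ``vocab`` (e.g. from a trained checkpoint) freezes the
    token indexing; otherwise the vocabulary is built from the eligible
    patients' events in first-seen order. A caller-supplied ``split`` pins
    the patient assignment — essential when comparing exclusion windows, so
    both conditions are evaluated on the same held-out patients. Eligible
    patients missing from a supplied split are dropped.
    """
    excluded = [apply_exclusion_window(p, exclusion_months) for p in patients]
    eligible, tally = eligibility_filter(
        excluded, min_events=min_events, control_buffer_months=control_buffer_months
    )
    if vocab is None:
        vocab = Vocabulary.build(
            e.token for p in eligible for e in p.events
        )
    if split is None:
        split = split_by_patient([p.patient_id for p in eligible], ratios, seed)
    else:
        eligible = [p for p in eligible if p.patient_id in split.assignment]
    trajectories: dict[str, list[PartialTrajectory]] = {
        "train": [], "dev": [], "test": []
    }
    for p in eligible:
        group = split.assignment[p.patient_id]
        for traj in enumerate_partial_trajectories(
            p, vocab, min_len=min_events,
            control_buffer_months=control_buffer_months,
            mask_mode=mask_mode, horizons=horizons,
        ):
            traj.split = group
            trajectories[group].append(traj)
    return PreparedCohort(
        vocab=vocab,
        split=split,
        trajectories=trajectories,
        tally=tally,
        exclusion_months=exclusion_months,
    )
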