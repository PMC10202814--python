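"""Shared fixtures: handcrafted patients and a small trained model."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from trajrisk.codes import Vocabulary
from trajrisk.estimator import TrajectoryRiskClassifier
from trajrisk.records import DiseaseEvent, PatientRecord
from trajrisk.trajectories import PartialTrajectory, label_horizons


def make_patient(patient_id="p1", birth=dt.date(1950, 1, 1),
                 event_dates=(), codes=None, end=dt.date(2018, 1, 1),
                 cancer=None):
    codes = codes or [f"A{i:02d}" for i in range(len(event_dates))]
    events = [DiseaseEvent(code=c, date=d) for c, d in zip(codes, event_dates)]
    return PatientRecord(patient_id=patient_id, birth_date=birth,
                         end_of_data=end, cancer_date=cancer, events=events)


def monthly_dates(start: dt.date, n: int, step_days: int = 90):
    return [start + dt.timedelta(days=i * step_days) for i in range(n)]


def random_trajectory(seed, n=6, vocab_size=12, cancer_months=None):
    """A synthetic labelled trajectory with plausible ages and gaps."""
    rng = np.random.default_rng(seed)
    toks = rng.integers(1, vocab_size, size=n)
    ages = np.sort(rng.uniform(30.0, 70.0, size=n))
    deltas = np.concatenate([[0.0], rng.uniform(1.0, 500.0, size=n - 1)])
    assess = dt.date(2012, 6, 1)
    cancer = None
    ttc = None
    if cancer_months is not None:
        cancer = assess + dt.timedelta(days=int(cancer_months * 30.4375))
        ttc = float(cancer_months)
    labels = label_horizons(assess, cancer)
    return PartialTrajectory(
        patient_id=f"p{seed}", token_indices=toks, ages=ages, deltas=deltas,
        assessment_date=assess, assessment_age=float(ages[-1]), labels=labels,
        time_to_cancer=ttc,
    )


@pytest.fixture(scope="session")
def toy_vocab():
    return Vocabulary.build(("icd10", f"A{i:02d}") for i in range(11))


@pytest.fixture(scope="session")
def separable_trajectories():
    """Small pool where token 5 perfectly marks future cancer."""
    pool = []
    for i in range(80):
        case = i % 4 == 0
        t = random_trajectory(seed=100 + i, n=7, cancer_months=10 if case else None)
        if case:
            t.token_indices = t.token_indices.copy()
            t.token_indices[[1, 4]] = 5
        else:
            t.token_indices = np.where(t.token_indices == 5, 3,
                                       t.token_indices)
        pool.append(t)
    return pool


@pytest.fixture(scope="session")
def tiny_model(separable_trajectories):
    """A small GRU fitted on the separable pool (shared across tests)."""
    est = TrajectoryRiskClassifier(
        architecture="gru", embedding_dim=8, hidden_dim=8, n_frequencies=16,
        batch_size=16, max_epochs=10, batches_per_epoch=10, seed=0,
    )
    est.fit(separable_trajectories, vocab_size=12)
    return est
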