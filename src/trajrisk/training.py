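"""Training-run management and hyperparameter search.

Thin procedural layer over :class:`~trajrisk.estimator.TrajectoryRiskClassifier`:
``train_model`` fits one configuration on a prepared cohort and returns a
:class:`TrainingRun`; ``hyperparameter_search`` fits a grid and ranks the runs
by development-set AUPRC, the model-selection metric.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field

import numpy as np

from .estimator import TrajectoryRiskClassifier
from .pipeline import PreparedCohort

__all__ = ["TrainingRun", "train_model", "hyperparameter_search"]


@dataclass
class TrainingRun:
    """Outcome of fitting one configuration."""

    estimator: TrajectoryRiskClassifier | None
    params: dict = field(default_factory=dict)
    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_dev_auprc: float = float("nan")
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def train_model(prepared: PreparedCohort, seed: int = 0,
                **estimator_params) -> TrainingRun:
    """Fit one model on the prepared cohort's train split.

    Selection and early stopping use the dev split; the returned run carries
    the estimator with its best-dev-AUPRC checkpoint restored.
    """
    est = TrajectoryRiskClassifier(seed=seed, **estimator_params)
    est.fit(
        prepared.train,
        dev=prepared.dev or None,
        vocab_size=len(prepared.vocab),
    )
    return TrainingRun(
        estimator=est,
        params=est.get_params(),
        history=est.history_,
        best_epoch=est.best_epoch_,
        best_dev_auprc=est.best_dev_auprc_,
    )


def hyperparameter_search(grid: list[dict], prepared: PreparedCohort,
                          seed: int = 0) -> list[TrainingRun]:
    """Fit every configuration in `grid` and rank by dev AUPRC (descending).

    ``grid`` is a list of estimator-parameter dicts. Per-run failures are
    captured, not raised; failed runs rank last. Execution order is the grid
    order, so results are deterministic given the seed.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    runs: list[TrainingRun] = []
    for cfg in grid:
        try:
            runs.append(train_model(prepared, seed=seed, **cfg))
        except Exception:
            runs.append(TrainingRun(estimator=None, params=dict(cfg),
                                    error=traceback.format_exc()))
    def key(run: TrainingRun) -> float:
        if run.failed or not np.isfinite(run.best_dev_auprc):
            return -np.inf
        return run.best_dev_auprc
    return sorted(runs, key=key, reverse=True)
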