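"""Per-interval evaluation: AUROC/AUPRC with bootstrap CIs, relative-risk
curves over top-n operational points, F1 operational point, recall by time to
cancer, and surveillance-program arithmetic.

Evaluation is carried out separately for each prediction interval (0-3, 0-6,
0-12, 0-36, 0-60 months): a trajectory counts as a positive for interval ``h``
iff the patient's cancer diagnosis falls within ``h`` months of the
assessment date. The enrichment of a high-risk set over random selection is
the relative risk

    RR = precision / incidence = (TP/(TP+FP)) / ((TP+FN)/(TP+FP+TN+FN)),

so RR of the full set is exactly 1 and the maximum attainable RR is
1/incidence. The evaluation unit is the trajectory; an optional patient-level
mode reduces each patient to their highest-scoring trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "IntervalOutcome",
    "RRCurve",
    "OperationalPoint",
    "EvaluationReport",
    "interval_outcomes",
    "compute_auroc",
    "compute_auprc",
    "bootstrap_ci",
    "compute_rr_curve",
    "f1_operational_point",
    "recall_by_time_to_cancer",
    "surveillance_scenario",
    "evaluate_model",
]


@dataclass(frozen=True)
class IntervalOutcome:
    """One scored trajectory at one prediction interval."""

    score: float
    label: int
    time_to_cancer: float | None = None  # months
    age_at_assessment: float | None = None
    patient_id: str | None = None


@dataclass
class RRCurve:
    n_values: np.ndarray
    rr: np.ndarray
    precision: np.ndarray
    incidence: float


@dataclass
class OperationalPoint:
    kind: str
    threshold: float
    precision: float
    recall: float
    f1: float
    rr: float
    n_flagged: int


@dataclass
class EvaluationReport:
    """Full metric suite for one model on one split."""

    per_horizon: dict[int, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


# ------------------------------------------------------------------ outcomes
def interval_outcomes(model, trajectories, horizon: int,
                      age_min: float | None = None,
                      patient_level: bool = False) -> list[IntervalOutcome]:
    """Score trajectories and label them for one prediction interval.

    ``label = 1`` iff the cancer diagnosis occurred within ``horizon`` months
    of assessment. ``age_min`` drops trajectories assessed below that age
    before scoring (e.g. a >= 50-years surveillance population).
    ``patient_level`` keeps only each patient's highest-scoring trajectory.
    """
    horizons = model.config_.horizons
    if horizon not in horizons:
        raise ValueError(f"horizon {horizon} not among model horizons {horizons}")
    if age_min is not None:
        trajectories = [t for t in trajectories if t.assessment_age >= age_min]
    if not trajectories:
        return []
    scores = model.predict_proba(trajectories)[:, horizons.index(horizon)]
    outcomes = [
        IntervalOutcome(
            score=float(s),
            label=int(t.time_to_cancer is not None and t.time_to_cancer <= horizon),
            time_to_cancer=t.time_to_cancer,
            age_at_assessment=t.assessment_age,
            patient_id=t.patient_id,
        )
        for s, t in zip(scores, trajectories)
    ]
    if patient_level:
        best: dict[str, IntervalOutcome] = {}
        for o in outcomes:
            cur = best.get(o.patient_id)
            if cur is None or o.score > cur.score:
                best[o.patient_id] = o
        outcomes = list(best.values())
    return outcomes


def _scores_labels(outcomes) -> tuple[np.ndarray, np.ndarray]:
    return (np.array([o.score for o in outcomes]),
            np.array([o.label for o in outcomes]))


# ------------------------------------------------------------------- metrics
def compute_auroc(outcomes: list[IntervalOutcome]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    scores, labels = _scores_labels(outcomes)
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def compute_auprc(outcomes: list[IntervalOutcome]) -> float:
    """Area under precision-recall by the step-wise (non-interpolated)
    convention, i.e. average precision."""
    _, labels = _scores_labels(outcomes)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined: no positives")
    scores = np.array([o.score for o in outcomes])
    return float(average_precision_score(labels, scores))


def bootstrap_ci(outcomes: list[IntervalOutcome], metric,
                 n_resamples: int = 200, seed: int = 0,
                 max_redraws: int = 10) -> tuple[float, float, float]:
    """Percentile 95% CI over `n_resamples` bootstrap resamples.

    Resamples on which the metric is undefined (e.g. single-class) are redrawn
    up to ``max_redraws`` times, then counted as failures; more than 50%
    failures aborts.
    """
    rng = np.random.default_rng(seed)
    point = metric(outcomes)
    n = len(outcomes)
    values = []
    failures = 0
    for _ in range(n_resamples):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            sample = [outcomes[i] for i in idx]
            try:
                values.append(metric(sample))
                break
            except ValueError:
                continue
        else:
            failures += 1
    if failures > n_resamples / 2:
        raise ValueError(
            f"metric undefined on {failures}/{n_resamples} bootstrap resamples"
        )
    low, high = np.percentile(values, [2.5, 97.5])
    return float(point), float(low), float(high)


def _rank_order(scores: np.ndarray) -> np.ndarray:
    """Indices by score descending; ties broken by position (stable)."""
    return np.argsort(-scores, kind="stable")


def compute_rr_curve(outcomes: list[IntervalOutcome],
                     n_values=None) -> RRCurve:
    """Relative risk of the top-n highest-risk set, for each n.

    For each ``n`` the ``n`` top-scored outcomes are the predicted positives;
    RR = precision / incidence. ``n`` beyond the sample size is truncated.
    """
    scores, labels = _scores_labels(outcomes)
    if labels.min() == labels.max():
        raise ValueError("RR undefined: only one class present")
    total = len(labels)
    incidence = labels.mean()
    if n_values is None:
        n_values = np.unique(np.geomspace(1, total, 50).astype(int))
    n_values = np.array([min(int(n), total) for n in n_values])
    order = _rank_order(scores)
    cum_pos = np.cumsum(labels[order])
    precision = cum_pos[n_values - 1] / n_values
    return RRCurve(
        n_values=n_values,
        rr=precision / incidence,
        precision=precision,
        incidence=float(incidence),
    )


def _point_at_mask(labels: np.ndarray, flagged: np.ndarray, kind: str,
                   threshold: float) -> OperationalPoint:
    tp = int((flagged & (labels == 1)).sum())
    fp = int((flagged & (labels == 0)).sum())
    fn = int((~flagged & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    incidence = labels.mean()
    return OperationalPoint(
        kind=kind, threshold=float(threshold), precision=precision,
        recall=recall, f1=f1, rr=float(precision / incidence) if incidence else 0.0,
        n_flagged=int(flagged.sum()),
    )


def f1_operational_point(outcomes: list[IntervalOutcome]) -> OperationalPoint:
    """Threshold maximizing F1, found by exhaustive sweep over distinct
    scores; ties resolved toward the lowest threshold."""
    scores, labels = _scores_labels(outcomes)
    if labels.sum() == 0:
        raise ValueError("F1 undefined: no positives")
    best = None
    for thr in np.unique(scores):  # ascending: later ties don't replace
        point = _point_at_mask(labels, scores >= thr, "f1_max", thr)
        if best is None or point.f1 > best.f1:
            best = point
    return best


def top_n_operational_point(outcomes: list[IntervalOutcome],
                            top_n: int) -> OperationalPoint:
    """Flag the `top_n` highest-scored outcomes (deterministic tie order)."""
    scores, labels = _scores_labels(outcomes)
    top_n = min(top_n, len(scores))
    order = _rank_order(scores)
    flagged = np.zeros(len(scores), dtype=bool)
    flagged[order[:top_n]] = True
    thr = scores[order[top_n - 1]] if top_n else np.inf
    return _point_at_mask(labels, flagged, "top_n", thr)


def recall_by_time_to_cancer(outcomes: list[IntervalOutcome],
                             threshold: float,
                             bin_edges=(0, 6, 12, 24, 36)) -> dict[str, float | None]:
    """Recall among cancer outcomes within each [edge_i, edge_{i+1}) months-
    to-cancer bin, at a fixed score threshold. Empty bins report None."""
    edges = list(bin_edges)
    out: dict[str, float | None] = {}
    for lo, hi in zip(edges, edges[1:]):
        in_bin = [o for o in outcomes
                  if o.label == 1 and o.time_to_cancer is not None
                  and lo <= o.time_to_cancer < hi]
        key = f"{lo}-{hi}"
        if not in_bin:
            out[key] = None
        else:
            out[key] = float(np.mean([o.score >= threshold for o in in_bin]))
    return out


def surveillance_scenario(cohort_size: int, top_n: int, ppv: float) -> dict:
    """Expected yield of a surveillance program flagging the top-n of a cohort.

    With a positive predictive value ``ppv`` at that operational point,
    ``round(top_n * ppv)`` of the flagged patients are expected to develop
    the cancer. Also reports the implied flag fraction ``top_n/cohort_size``.
    """
    if not 0 <= ppv <= 1:
        raise ValueError("ppv must lie in [0, 1]")
    if top_n > cohort_size:
        raise ValueError("top_n cannot exceed cohort_size")
    if top_n < 0 or cohort_size <= 0:
        raise ValueError("cohort_size must be positive and top_n non-negative")
    return {
        "expected_true_positives": round(top_n * ppv),
        "flag_fraction": top_n / cohort_size,
        "top_n": top_n,
        "cohort_size": cohort_size,
        "ppv": ppv,
    }


# -------------------------------------------------------------------- report
def evaluate_model(model, trajectories, horizons=None, age_min=None,
                   top_n: int | None = None, top_fraction: float = 0.001,
                   n_resamples: int = 200, seed: int = 0,
                   patient_level: bool = False) -> EvaluationReport:
    """Full per-horizon report: AUROC/AUPRC with bootstrap CIs, RR curve,
    F1 and top-n operational points."""
    horizons = horizons or model.config_.horizons
    report = EvaluationReport(metadata={
        "n_trajectories": len(trajectories),
        "age_min": age_min,
        "patient_level": patient_level,
    })
    for h in horizons:
        outcomes = interval_outcomes(model, trajectories, h, age_min=age_min,
                                     patient_level=patient_level)
        if not outcomes:
            report.per_horizon[h] = {"error": "no outcomes after filtering"}
            continue
        labels = np.array([o.label for o in outcomes])
        entry: dict = {"n": len(outcomes), "n_positive": int(labels.sum())}
        if 0 < labels.sum() < len(labels):
            entry["auroc"] = bootstrap_ci(outcomes, compute_auroc,
                                          n_resamples, seed)
            entry["auprc"] = bootstrap_ci(outcomes, compute_auprc,
                                          n_resamples, seed)
            curve = compute_rr_curve(outcomes)
            entry["rr_curve"] = {
                "n_values": curve.n_values.tolist(),
                "rr": curve.rr.tolist(),
                "incidence": curve.incidence,
            }
            f1pt = f1_operational_point(outcomes)
            entry["f1_point"] = vars(f1pt)
            n_flag = top_n if top_n is not None else max(
                1, round(top_fraction * len(outcomes)))
            entry["top_n_point"] = vars(top_n_operational_point(outcomes, n_flag))
            entry["recall_by_time_to_cancer"] = recall_by_time_to_cancer(
                outcomes, f1pt.threshold)
        else:
            entry["error"] = "single-class interval"
        report.per_horizon[h] = entry
    return report
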