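"""Integrated-gradients attribution of risk to individual diagnosis codes.

Gradients cannot be taken with respect to the integer token indices, so the
attribution input is the *output of the embedding layer*: integrated
gradients are computed along the straight path from a baseline (zero
embedding, by default) to the trajectory's embedded sequence, for the
36-month risk output. Per-event scores are the per-dimension attributions
summed over embedding dimensions; the age input is attributed through its
own channel the same way. The path integral is approximated by a midpoint
Riemann sum, which satisfies the completeness axiom (attributions sum to
F(input) - F(baseline)) up to discretization error.

For cohort-level interpretation, per-event scores from cancer trajectories
are summed per (token, time-to-cancer bin), exposing which codes drive
predictions close to diagnosis versus years ahead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .model import embed_batch, forward, pack_batch
from .trajectories import PartialTrajectory

__all__ = [
    "AttributionRecord",
    "integrated_gradients_embedding",
    "age_attribution",
    "aggregate_by_time_to_cancer_bin",
]


@dataclass
class AttributionRecord:
    """Summed contribution of one code within one time-to-cancer bin."""

    token: tuple[str, str]
    bin: str
    contribution: float
    n_occurrences: int

    @property
    def per_occurrence(self) -> float:
        return self.contribution / self.n_occurrences if self.n_occurrences else 0.0


def _ig_pass(model, trajectory: PartialTrajectory, n_steps: int,
             baseline: np.ndarray | None, horizon: int):
    """Shared midpoint-rule IG computation over event and age channels.

    Returns (per_event_scores, age_score, completeness_gap)."""
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    params, config = model.params_, model.config_
    h_idx = config.horizons.index(horizon)
    single = pack_batch([trajectory], config.max_seq_len)
    x0 = embed_batch(params, single, config).data  # (1, T, E)
    base = np.zeros_like(x0) if baseline is None else np.broadcast_to(
        baseline, x0.shape)
    age0 = single["age_assess"]
    age_base = np.zeros_like(age0)

    # all Riemann steps evaluated as one batch
    alphas = (np.arange(n_steps) + 0.5)[:, None, None] / n_steps
    batch = pack_batch([trajectory] * n_steps, config.max_seq_len)
    x_path = Tensor(base + alphas * (x0 - base), requires_grad=True)
    age_path = Tensor(age_base + alphas[:, :, 0] * (age0 - age_base),
                      requires_grad=True)
    probs = forward(params, batch, config, embedded=x_path, age_assess=age_path)
    probs[:, h_idx].sum().backward()
    if not (np.all(np.isfinite(x_path.grad)) and np.all(np.isfinite(age_path.grad))):
        raise FloatingPointError("non-finite gradients during integrated gradients")

    attr = x_path.grad.mean(axis=0) * (x0[0] - base[0])  # (T, E)
    per_event = attr.sum(axis=1)  # sum over embedding dimensions
    age_score = float(age_path.grad.mean(axis=0)[0] * (age0 - age_base)[0, 0])

    L = min(len(trajectory), config.max_seq_len)
    per_event = per_event[:L]

    with_input = forward(params, single, config).data[0, h_idx]
    base_probs = forward(params, single, config,
                         embedded=Tensor(base), age_assess=Tensor(age_base))
    gap = float(with_input - base_probs.data[0, h_idx]
                - per_event.sum() - age_score)
    return per_event, age_score, gap


def integrated_gradients_embedding(
    model,
    trajectory: PartialTrajectory,
    n_steps: int = 128,
    baseline: np.ndarray | None = None,
    horizon: int = 36,
) -> np.ndarray:
    """Per-event attribution of the `horizon`-month risk; shape (n_events,).

    If the trajectory exceeds the model's sequence cap only the most recent
    events (the ones the model saw) are scored.
    """
    per_event, _, _ = _ig_pass(model, trajectory, n_steps, baseline, horizon)
    return per_event


def age_attribution(
    model,
    trajectory: PartialTrajectory,
    n_steps: int = 128,
    baseline: np.ndarray | None = None,
    horizon: int = 36,
) -> float:
    """Attribution of the risk output to the age-at-assessment input."""
    _, age_score, _ = _ig_pass(model, trajectory, n_steps, baseline, horizon)
    return age_score


def completeness_gap(model, trajectory, n_steps=128, baseline=None,
                     horizon: int = 36) -> float:
    """F(x)-F(baseline) minus the summed attributions; → 0 as n_steps grows."""
    _, _, gap = _ig_pass(model, trajectory, n_steps, baseline, horizon)
    return gap


def aggregate_by_time_to_cancer_bin(
    model,
    trajectories: list[PartialTrajectory],
    vocab,
    bin_edges=(0, 6, 12, 24, 36),
    n_steps: int = 64,
    horizon: int = 36,
    baseline: np.ndarray | None = None,
) -> list[AttributionRecord]:
    """Summed per-token attribution over cancer trajectories, per bin.

    Each cancer trajectory whose time to cancer falls in ``[edge_i,
    edge_{i+1})`` contributes its events' attribution scores to that bin's
    (token, bin) totals. Records are sorted by contribution (descending)
    within each bin; padding never appears. Raw signed sums are reported;
    a per-occurrence normalized view is available on each record.
    """
    edges = list(bin_edges)
    bins = [(lo, hi, f"{lo}-{hi}") for lo, hi in zip(edges, edges[1:])]
    sums: dict[tuple[str, tuple[str, str]], float] = {}
    counts: dict[tuple[str, tuple[str, str]], int] = {}
    for traj in trajectories:
        if traj.time_to_cancer is None:
            continue
        label = next((name for lo, hi, name in bins
                      if lo <= traj.time_to_cancer < hi), None)
        if label is None:
            continue
        scores = integrated_gradients_embedding(
            model, traj, n_steps=n_steps, baseline=baseline, horizon=horizon)
        L = len(scores)
        for idx, score in zip(traj.token_indices[-L:], scores):
            if idx == vocab.pad_index:
                continue
            key = (label, vocab.decode(int(idx)))
            sums[key] = sums.get(key, 0.0) + float(score)
            counts[key] = counts.get(key, 0) + 1
    records = [
        AttributionRecord(token=tok, bin=label, contribution=sums[(label, tok)],
                          n_occurrences=counts[(label, tok)])
        for (label, tok) in sums
    ]
    records.sort(key=lambda r: (r.bin, -r.contribution))
    return records


def top_k_by_bin(records: list[AttributionRecord], k: int = 10
                 ) -> dict[str, list[AttributionRecord]]:
    """Top-k positively contributing codes per time-to-cancer bin."""
    out: dict[str, list[AttributionRecord]] = {}
    for rec in records:  # records already sorted within bin
        out.setdefault(rec.bin, [])
        if len(out[rec.bin]) < k:
            out[rec.bin].append(rec)
    return out
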