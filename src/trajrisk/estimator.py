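"""Scikit-learn-style estimator wrapping the trajectory risk model.

:class:`TrajectoryRiskClassifier` follows the sklearn estimator contract —
constructor stores hyperparameters untouched, ``fit`` learns and sets
trailing-underscore attributes, ``get_params``/``set_params`` work with
``sklearn.base.clone`` and model-selection utilities. The sample unit is a
:class:`~trajrisk.trajectories.PartialTrajectory`; labels travel inside the
trajectories, so ``y`` is accepted and ignored.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score

from .autodiff import Tensor
from .model import (
    ModelConfig,
    forward,
    init_params,
    multi_horizon_loss,
    pack_batch,
)
from .trajectories import HORIZONS, PartialTrajectory, balanced_batch_sampler

__all__ = ["TrajectoryRiskClassifier", "AdamState"]


class AdamState:
    """Adaptive-moment gradient descent over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, params: dict[str, Tensor]) -> None:
        self.t += 1
        for k, p in params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            p.grad = None


class TrajectoryRiskClassifier(ClassifierMixin, BaseEstimator):
    """Multi-horizon cancer-risk classifier over diagnosis-code trajectories.

    Parameters mirror :class:`~trajrisk.model.ModelConfig` plus optimizer
    settings. Training uses class-balanced batches (equal numbers of cancer
    and control trajectories per batch), the masked multi-horizon
    cross-entropy loss with L2-norm regularization, and early stopping on
    development-set AUPRC at ``selection_horizon`` months.

    Attributes set by :meth:`fit`
    -----------------------------
    params_ : dict of name -> Tensor — trained parameters (best dev epoch).
    config_ : ModelConfig — resolved architecture configuration.
    history_ : list of dict — per-epoch train loss and dev metrics.
    best_epoch_, best_dev_auprc_ : model-selection outcome.
    vocab_size_ : vocabulary size the embedding was built for.
    classes_ : np.array([0, 1]) — binary outcome per horizon.
    """

    def __init__(
        self,
        architecture: str = "gru",
        embedding_dim: int = 24,
        hidden_dim: int = 32,
        n_layers: int = 1,
        n_attention_heads: int = 2,
        n_frequencies: int = 128,
        dropout: float = 0.0,
        lambda2: float = 0.0,
        monotone_head: bool = False,
        temporal_mode: str = "multiplicative",
        max_seq_len: int = 300,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 20,
        batches_per_epoch: int | None = None,
        patience: int = 5,
        selection_horizon: int = 36,
        dev_max_size: int = 8000,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.architecture = architecture
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.n_attention_heads = n_attention_heads
        self.n_frequencies = n_frequencies
        self.dropout = dropout
        self.lambda2 = lambda2
        self.monotone_head = monotone_head
        self.temporal_mode = temporal_mode
        self.max_seq_len = max_seq_len
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.batches_per_epoch = batches_per_epoch
        self.patience = patience
        self.selection_horizon = selection_horizon
        self.dev_max_size = dev_max_size
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def _make_config(self) -> ModelConfig:
        return ModelConfig(
            architecture=self.architecture,
            embedding_dim=self.embedding_dim,
            hidden_dim=self.hidden_dim,
            n_layers=self.n_layers,
            n_attention_heads=self.n_attention_heads,
            n_frequencies=self.n_frequencies,
            dropout=self.dropout,
            lambda2=self.lambda2,
            monotone_head=self.monotone_head,
            temporal_mode=self.temporal_mode,
            max_seq_len=self.max_seq_len,
            seed=self.seed,
        )

    @staticmethod
    def _infer_vocab_size(*traj_lists) -> int:
        top = 0
        for trajs in traj_lists:
            for t in trajs or []:
                if len(t.token_indices):
                    top = max(top, int(t.token_indices.max()))
        return top + 1

    def _dev_auprc(self, dev: list[PartialTrajectory], h_idx: int) -> float:
        scores = self._score(dev)[:, h_idx]
        labels = np.array([t.labels.y[h_idx] for t in dev])
        if labels.min() == labels.max():
            return float("nan")
        return float(average_precision_score(labels, scores))

    def fit(self, X: list[PartialTrajectory], y=None,
            dev: list[PartialTrajectory] | None = None,
            vocab_size: int | None = None):
        """Train on a list of labelled partial trajectories.

        ``dev`` enables per-epoch AUPRC monitoring, early stopping and best-
        checkpoint selection; without it, training runs all epochs and keeps
        the final parameters.
        """
        if not X:
            raise ValueError("no training trajectories")
        self.config_ = self._make_config()
        self.vocab_size_ = vocab_size or self._infer_vocab_size(X, dev)
        self.classes_ = np.array([0, 1])
        self.params_ = init_params(self.config_, self.vocab_size_)
        try:
            h_idx = self.config_.horizons.index(self.selection_horizon)
        except ValueError:
            raise ValueError(
                f"selection_horizon {self.selection_horizon} not among "
                f"horizons {self.config_.horizons}"
            ) from None

        if dev and len(dev) > self.dev_max_size:
            # monitoring subsample: keep every positive, thin the negatives
            pos = [t for t in dev if t.is_case]
            neg = [t for t in dev if not t.is_case]
            keep = np.random.default_rng(self.seed).choice(
                len(neg), size=self.dev_max_size - len(pos), replace=False)
            dev = pos + [neg[i] for i in keep]

        n_neg = sum(1 for t in X if not t.is_case)
        per_epoch = self.batches_per_epoch or max(
            1, -(-n_neg // (self.batch_size // 2))
        )
        optimizer = AdamState(self.params_, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)

        self.history_ = []
        best = {"epoch": 0, "auprc": -np.inf, "params": _copy_params(self.params_)}
        dev_auprc = self._dev_auprc(dev, h_idx) if dev else float("nan")
        self.history_.append({"epoch": 0, "train_loss": float("nan"),
                              "dev_auprc": dev_auprc})
        if dev and not np.isnan(dev_auprc):
            best = {"epoch": 0, "auprc": dev_auprc,
                    "params": _copy_params(self.params_)}

        stale = 0
        for epoch in range(1, self.max_epochs + 1):
            epoch_seed = int(rng.integers(0, 2 ** 31))
            losses = []
            drop_rng = np.random.default_rng(epoch_seed + 1)
            for batch_trajs in balanced_batch_sampler(
                X, self.batch_size, seed=epoch_seed, n_batches=per_epoch
            ):
                batch = pack_batch(batch_trajs, self.config_.max_seq_len)
                if self.dropout > 0.0:
                    # event dropout: hide a random subset of diagnoses, but
                    # never empty a trajectory
                    keep = drop_rng.random(batch["seq_mask"].shape) >= self.dropout
                    keep[:, 0] = True
                    batch["seq_mask"] = batch["seq_mask"] * keep
                p_hat = forward(self.params_, batch, self.config_)
                loss = multi_horizon_loss(
                    p_hat, batch["y"], batch["mask"],
                    params=self.params_, lambda2=self.lambda2,
                )
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss.data}"
                    )
                loss.backward()
                optimizer.step(self.params_)
                losses.append(float(loss.data))
            dev_auprc = self._dev_auprc(dev, h_idx) if dev else float("nan")
            self.history_.append({
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "dev_auprc": dev_auprc,
            })
            if self.verbose:
                print(f"epoch {epoch}: loss={np.mean(losses):.4f} "
                      f"dev_auprc={dev_auprc:.4f}")
            if dev and not np.isnan(dev_auprc):
                if dev_auprc > best["auprc"]:
                    best = {"epoch": epoch, "auprc": dev_auprc,
                            "params": _copy_params(self.params_)}
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break

        if dev and np.isfinite(best["auprc"]):
            self.params_ = best["params"]
            self.best_epoch_ = best["epoch"]
            self.best_dev_auprc_ = float(best["auprc"])
        else:
            self.best_epoch_ = len(self.history_) - 1
            self.best_dev_auprc_ = float("nan")
        return self

    # -------------------------------------------------------------- predict
    def _score(self, X: list[PartialTrajectory], chunk: int = 512) -> np.ndarray:
        out = np.empty((len(X), len(self.config_.horizons)))
        for start in range(0, len(X), chunk):
            part = X[start:start + chunk]
            batch = pack_batch(part, self.config_.max_seq_len)
            out[start:start + chunk] = forward(
                self.params_, batch, self.config_
            ).data
        return out

    def predict_proba(self, X: list[PartialTrajectory]) -> np.ndarray:
        """Risk score in (0,1) per trajectory and horizon; shape (n, 5)."""
        self._check_fitted()
        if not X:
            return np.empty((0, len(self.config_.horizons)))
        return self._score(X)

    def decision_function(self, X, horizon: int = 36) -> np.ndarray:
        self._check_fitted()
        return self.predict_proba(X)[:, self.config_.horizons.index(horizon)]

    def predict(self, X, horizon: int = 36, threshold: float = 0.5) -> np.ndarray:
        return (self.decision_function(X, horizon) >= threshold).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit first")


def _copy_params(params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {k: Tensor(p.data.copy(), requires_grad=True) for k, p in params.items()}
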