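"""Sequence models over coded disease trajectories.

The model has three parts:

1. **Embedding** — each level-3 diagnosis code is a trainable vector; temporal
   information (age at diagnosis, gap since the previous diagnosis) enters
   through a bank of cosine waveforms at ``n_frequencies`` geometrically
   spaced periods, projected to the embedding dimension and combined with the
   token embedding as multiplicative weights (additive combination available).
2. **Encoder** — the embedded sequence is summarized into a fixed-length
   trajectory fingerprint by one of four interchangeable architectures:
   order-invariant pooling (``bag_of_codes``), pooling + feed-forward
   (``mlp``), a recurrent pass (``gru``), or a self-attention stack
   (``transformer``).
3. **Head** — the fingerprint, concatenated with the patient's age at
   assessment, feeds a small feed-forward network that outputs one risk score
   per prediction horizon (3, 6, 12, 36, 60 months). The bag-of-codes model
   uses a single linear layer. An optional monotone head forces scores to be
   non-decreasing over horizons by accumulating softplus increments.

Training minimizes masked multi-horizon cross-entropy plus an L2-norm penalty
on all parameters (``lambda2 * ||theta||_2``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dates import DAYS_PER_YEAR
from .trajectories import HORIZONS, PartialTrajectory

__all__ = [
    "ModelConfig",
    "init_params",
    "pack_batch",
    "temporal_feature_matrix",
    "embed_batch",
    "encode_trajectory",
    "predict_multi_horizon",
    "forward",
    "multi_horizon_loss",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("bag_of_codes", "mlp", "gru", "transformer")
EPS_CLIP = 1e-7
MAX_AGE_YEARS = 110.0


@dataclass
class ModelConfig:
    """Hyperparameters of the risk model."""

    architecture: str = "gru"
    embedding_dim: int = 24
    hidden_dim: int = 32
    n_layers: int = 1
    n_attention_heads: int = 2
    n_frequencies: int = 128
    dropout: float = 0.0
    lambda2: float = 0.0
    horizons: tuple[int, ...] = HORIZONS
    monotone_head: bool = False
    temporal_mode: str = "multiplicative"  # or "additive", "none"
    period_min_days: float = 1.0
    period_max_days: float = 36500.0
    max_seq_len: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be non-negative")
        if self.embedding_dim % self.n_attention_heads != 0:
            raise ValueError("embedding_dim must be divisible by n_attention_heads")
        self.horizons = tuple(self.horizons)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------- parameters
def _init(rng: np.random.Generator, *shape) -> Tensor:
    """Fan-in scaled normal init."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def init_params(config: ModelConfig, vocab_size: int) -> dict[str, Tensor]:
    """Seeded parameter initialization; the padding embedding row stays zero."""
    rng = np.random.default_rng(config.seed)
    E, H = config.embedding_dim, config.hidden_dim
    params: dict[str, Tensor] = {}
    emb = rng.normal(0.0, 1.0 / np.sqrt(E), size=(vocab_size, E))
    emb[0] = 0.0  # padding token
    params["emb"] = Tensor(emb, requires_grad=True)

    if config.temporal_mode != "none":
        # small weights + unit bias: temporal weighting starts near identity
        params["time_W"] = Tensor(
            rng.normal(0.0, 0.02, size=(2 * config.n_frequencies, E)),
            requires_grad=True,
        )
        params["time_b"] = Tensor(
            np.ones(E) if config.temporal_mode == "multiplicative" else np.zeros(E),
            requires_grad=True,
        )

    arch = config.architecture
    if arch == "mlp":
        params["mlp_W1"] = _init(rng, E, H)
        params["mlp_b1"] = _zeros(H)
    elif arch == "gru":
        for layer in range(config.n_layers):
            d_in = E if layer == 0 else H
            for gate in ("z", "r", "h"):
                params[f"gru{layer}_W{gate}"] = _init(rng, d_in, H)
                params[f"gru{layer}_U{gate}"] = _init(rng, H, H)
                params[f"gru{layer}_b{gate}"] = _zeros(H)
    elif arch == "transformer":
        for layer in range(config.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                params[f"att{layer}_{name}"] = _init(rng, E, E)
            params[f"att{layer}_ff_W1"] = _init(rng, E, H)
            params[f"att{layer}_ff_b1"] = _zeros(H)
            params[f"att{layer}_ff_W2"] = _init(rng, H, E)
            params[f"att{layer}_ff_b2"] = _zeros(E)
        params["pool_W"] = _init(rng, E, H)
        params["pool_b"] = _zeros(H)

    n_out = len(config.horizons)
    fp_dim = E if arch == "bag_of_codes" else H
    if arch == "bag_of_codes":
        # single linear layer head
        params["head_W"] = _init(rng, fp_dim + 1, n_out)
        params["head_b"] = _zeros(n_out)
    else:
        params["head_W1"] = _init(rng, fp_dim + 1, H)
        params["head_b1"] = _zeros(H)
        params["head_W2"] = _init(rng, H, n_out)
        params["head_b2"] = _zeros(n_out)
    return params


# -------------------------------------------------------------------- inputs
def pack_batch(
    trajectories: list[PartialTrajectory],
    max_seq_len: int = 300,
) -> dict[str, np.ndarray]:
    """Right-pad a list of trajectories into rectangular arrays.

    Trajectories longer than ``max_seq_len`` keep their most recent events.
    Returns tokens (B,T), ages (B,T) in years, deltas (B,T) in days,
    seq_mask (B,T), assessment ages (B,1), labels y and loss mask (B,K).
    """
    B = len(trajectories)
    lengths = [min(len(t), max_seq_len) for t in trajectories]
    T = max(lengths)
    K = len(trajectories[0].labels.y)
    tokens = np.zeros((B, T), dtype=np.int64)
    ages = np.zeros((B, T))
    deltas = np.zeros((B, T))
    seq_mask = np.zeros((B, T))
    age_assess = np.zeros((B, 1))
    y = np.zeros((B, K))
    m = np.zeros((B, K))
    for i, (traj, L) in enumerate(zip(trajectories, lengths)):
        tokens[i, :L] = traj.token_indices[-L:]
        ages[i, :L] = traj.ages[-L:]
        deltas[i, :L] = traj.deltas[-L:]
        seq_mask[i, :L] = 1.0
        age_assess[i, 0] = traj.assessment_age
        y[i] = traj.labels.y
        m[i] = traj.labels.mask
    return {
        "tokens": tokens,
        "ages": ages,
        "deltas": deltas,
        "seq_mask": seq_mask,
        "age_assess": age_assess,
        "y": y,
        "mask": m,
    }


def temporal_feature_matrix(
    ages_years: np.ndarray,
    deltas_days: np.ndarray,
    n_frequencies: int = 128,
    period_min_days: float = 1.0,
    period_max_days: float = 36500.0,
) -> np.ndarray:
    """Cosine waveform features of the two per-event times.

    For each time input u (age at diagnosis, converted to days, and the gap
    to the previous diagnosis in days) the feature vector is
    ``cos(u / T_k)`` over ``n_frequencies`` geometrically spaced periods
    spanning ``period_min_days`` to ``period_max_days`` — day-to-lifetime
    scales. Output shape: ``(..., 2 * n_frequencies)``.
    """
    if np.any(ages_years < 0) or np.any(deltas_days < 0):
        raise ValueError("ages and inter-event gaps must be non-negative")
    periods = np.geomspace(period_min_days, period_max_days, n_frequencies)
    age_days = np.asarray(ages_years, dtype=np.float64)[..., None] * DAYS_PER_YEAR
    delta = np.asarray(deltas_days, dtype=np.float64)[..., None]
    return np.concatenate(
        [np.cos(age_days / periods), np.cos(delta / periods)], axis=-1
    )


def embed_batch(
    params: dict[str, Tensor],
    batch: dict[str, np.ndarray],
    config: ModelConfig,
) -> Tensor:
    """Token embeddings combined with temporal weights; padded rows are zero.

    Returns the embedded sequence (B, T, E) — the "output of the embedding
    layer" that attribution treats as the model input.
    """
    tokens = batch["tokens"]
    if tokens.max(initial=0) >= params["emb"].shape[0]:
        raise IndexError("token index outside vocabulary")
    x = params["emb"][tokens]  # (B, T, E)
    if config.temporal_mode != "none":
        feats = temporal_feature_matrix(
            batch["ages"], batch["deltas"], config.n_frequencies,
            config.period_min_days, config.period_max_days,
        )
        w = Tensor(feats) @ params["time_W"] + params["time_b"]
        x = x * w if config.temporal_mode == "multiplicative" else x + w
    return x * batch["seq_mask"][:, :, None]


# ------------------------------------------------------------------ encoders
def _masked_mean(x: Tensor, seq_mask: np.ndarray) -> Tensor:
    denom = np.maximum(seq_mask.sum(axis=1, keepdims=True), 1.0)
    return (x * seq_mask[:, :, None]).sum(axis=1) * (1.0 / denom)


def _gru_pass(params, x: Tensor, seq_mask: np.ndarray, layer: int,
              hidden_dim: int) -> tuple[Tensor, list[Tensor]]:
    B, T, _ = x.shape
    h = Tensor(np.zeros((B, hidden_dim)))
    Wz, Uz, bz = (params[f"gru{layer}_{n}"] for n in ("Wz", "Uz", "bz"))
    Wr, Ur, br = (params[f"gru{layer}_{n}"] for n in ("Wr", "Ur", "br"))
    Wh, Uh, bh = (params[f"gru{layer}_{n}"] for n in ("Wh", "Uh", "bh"))
    states = []
    for t in range(T):
        xt = x[:, t, :]
        z = ad.sigmoid(xt @ Wz + h @ Uz + bz)
        r = ad.sigmoid(xt @ Wr + h @ Ur + br)
        hh = ad.tanh(xt @ Wh + (r * h) @ Uh + bh)
        h_new = (1.0 - z) * h + z * hh
        m = seq_mask[:, t:t + 1]
        h = h_new * m + h * (1.0 - m)  # padded steps carry state through
        states.append(h)
    return h, states


def _transformer_pass(params, x: Tensor, seq_mask: np.ndarray,
                      config: ModelConfig) -> Tensor:
    B, T, E = x.shape
    n_heads = config.n_attention_heads
    d = E // n_heads
    att_bias = (1.0 - seq_mask)[:, None, :] * (-1e9)  # (B, 1, T)
    for layer in range(config.n_layers):
        Q = x @ params[f"att{layer}_Wq"]
        K = x @ params[f"att{layer}_Wk"]
        V = x @ params[f"att{layer}_Wv"]
        head_outs = []
        for hidx in range(n_heads):
            sl = slice(hidx * d, (hidx + 1) * d)
            q, k, v = Q[:, :, sl], K[:, :, sl], V[:, :, sl]
            scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d)) + att_bias
            att = ad.softmax(scores, axis=-1)
            head_outs.append(att @ v)
        attended = ad.concat(head_outs, axis=-1) @ params[f"att{layer}_Wo"]
        x = x + attended * seq_mask[:, :, None]
        ff = ad.relu(x @ params[f"att{layer}_ff_W1"] + params[f"att{layer}_ff_b1"])
        x = x + (ff @ params[f"att{layer}_ff_W2"] + params[f"att{layer}_ff_b2"]) \
            * seq_mask[:, :, None]
    pooled = _masked_mean(x, seq_mask)
    return ad.relu(pooled @ params["pool_W"] + params["pool_b"])


def encode_trajectory(
    params: dict[str, Tensor],
    x: Tensor,
    seq_mask: np.ndarray,
    config: ModelConfig,
) -> Tensor:
    """Summarize an embedded sequence (B,T,E) into fingerprints (B,H).

    Padding positions contribute nothing in any architecture.
    """
    if seq_mask.sum() == 0:
        raise ValueError("cannot encode an empty (fully padded) sequence")
    arch = config.architecture
    if arch == "bag_of_codes":
        return _masked_mean(x, seq_mask)
    if arch == "mlp":
        pooled = _masked_mean(x, seq_mask)
        return ad.relu(pooled @ params["mlp_W1"] + params["mlp_b1"])
    if arch == "gru":
        h = x
        for layer in range(config.n_layers):
            final, states = _gru_pass(params, h, seq_mask, layer,
                                      config.hidden_dim)
            h = ad.stack(states, axis=1)  # (B, T, H) feeds the next layer
        return final
    if arch == "transformer":
        return _transformer_pass(params, x, seq_mask, config)
    raise ValueError(f"unknown architecture {arch!r}")


# ---------------------------------------------------------------------- head
def predict_multi_horizon(
    params: dict[str, Tensor],
    fingerprint: Tensor,
    age_assess: Tensor | np.ndarray,
    config: ModelConfig,
) -> Tensor:
    """Risk scores in (0,1) per horizon from fingerprint + assessment age.

    Age is scaled to [0,1] over [0, 110] years before entering the head. With
    ``monotone_head`` the logits accumulate softplus increments so scores are
    non-decreasing over horizons.
    """
    if not isinstance(age_assess, Tensor):
        age_assess = Tensor(age_assess)
    age_scaled = age_assess * (1.0 / MAX_AGE_YEARS)
    z = ad.concat([fingerprint, age_scaled], axis=-1)
    if config.architecture == "bag_of_codes":
        logits = z @ params["head_W"] + params["head_b"]
    else:
        hdn = ad.relu(z @ params["head_W1"] + params["head_b1"])
        logits = hdn @ params["head_W2"] + params["head_b2"]
    if config.monotone_head:
        base = logits[:, 0:1]
        cols = [base]
        acc = base
        for j in range(1, len(config.horizons)):
            acc = acc + ad.softplus(logits[:, j:j + 1])
            cols.append(acc)
        logits = ad.concat(cols, axis=-1)
    return ad.sigmoid(logits)


def forward(
    params: dict[str, Tensor],
    batch: dict[str, np.ndarray],
    config: ModelConfig,
    embedded: Tensor | None = None,
    age_assess: Tensor | None = None,
) -> Tensor:
    """Full forward pass batch → risk scores (B, n_horizons).

    ``embedded`` / ``age_assess`` let callers substitute leaf tensors for the
    embedding output or age input (used by integrated gradients).
    """
    x = embed_batch(params, batch, config) if embedded is None else embedded
    fp = encode_trajectory(params, x, batch["seq_mask"], config)
    age = batch["age_assess"] if age_assess is None else age_assess
    return predict_multi_horizon(params, fp, age, config)


# ---------------------------------------------------------------------- loss
def l2_norm(params: dict[str, Tensor]) -> Tensor:
    total = None
    for p in params.values():
        sq = (p * p).sum()
        total = sq if total is None else total + sq
    return total ** 0.5


def multi_horizon_loss(
    p_hat: Tensor,
    y: np.ndarray,
    mask: np.ndarray,
    params: dict[str, Tensor] | None = None,
    lambda2: float = 0.0,
) -> Tensor:
    """Masked multi-horizon cross-entropy plus L2-norm regularization.

    Each sample's cross-entropy is summed over its unmasked horizons and
    normalized by that sample's unmasked-horizon count N_T (5 for controls,
    <= 5 for cancer trajectories); the batch term is the mean over samples.
    The penalty is ``lambda2 * ||theta||_2`` (the norm, not its square).
    """
    mask = np.asarray(mask, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n_t = mask.sum(axis=1)
    if np.all(n_t == 0):
        raise ValueError("all horizons masked in batch")
    p = p_hat.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    ce = (p.log() * y + (1.0 - p).log() * (1.0 - y)) * (-1.0)
    per_sample = (ce * mask).sum(axis=1) * (1.0 / np.maximum(n_t, 1.0))
    loss = per_sample.mean()
    if lambda2 > 0.0:
        if params is None:
            raise ValueError("params required for lambda2 > 0")
        loss = loss + lambda2 * l2_norm(params)
    return loss


# --------------------------------------------------------------- persistence
def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig,
                    vocab_hash: str) -> None:
    """Single-file archive: config (JSON), vocabulary hash, parameter arrays."""
    meta = json.dumps({"config": config.to_dict(), "vocab_hash": vocab_hash})
    arrays = {f"param_{k}": v.data for k, v in params.items()}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path, vocab_hash: str | None = None):
    """Load (params, config, vocab_hash); refuses a vocabulary-hash mismatch."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {
            k[len("param_"):]: Tensor(archive[k], requires_grad=True)
            for k in archive.files
            if k.startswith("param_")
        }
    if vocab_hash is not None and meta["vocab_hash"] != vocab_hash:
        raise ValueError(
            f"checkpoint vocabulary hash {meta['vocab_hash']} does not match "
            f"current vocabulary {vocab_hash}"
        )
    return params, ModelConfig.from_dict(meta["config"]), meta["vocab_hash"]
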