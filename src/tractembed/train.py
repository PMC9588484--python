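"""Half-streamline pair preparation and the optimisation loop.

Each streamline is split at its midpoint: the first half plus a terminating
(0,0,0) token goes to the encoder, the bare second half is the decoder
target (odd lengths give the encoder the extra point). During training
every streamline has a ``reversal_prob`` chance per epoch of being flipped
head-to-tail before splitting, so the encoder sees both directions of a
corpus that has no canonical orientation. Batches are zero-padded to the
longest member with boolean masks marking genuine steps; the loss ignores
padding entirely.

Optimisation follows the reference recipe: Adam at learning rate 1e-3,
batch size 128, global gradient-norm clipping at 1.0, random reshuffling
every epoch, an 80/20 train/validation split, and selection of the
checkpoint with minimal validation loss (earliest epoch on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ModelConfig, SeqAEModel
from .tracts import Streamline, Tractogram

__all__ = [
    "TrainingPair",
    "TrainConfig",
    "TrainingLog",
    "make_pair",
    "collate_batch",
    "split_train_val",
    "eligible_streamlines",
    "train",
    "MIN_TRAINABLE_POINTS",
]

logger = logging.getLogger(__name__)

# a streamline must split into two non-empty halves around the token
MIN_TRAINABLE_POINTS = 4

END_TOKEN = np.zeros((1, 3))


@dataclass(frozen=True)
class TrainingPair:
    """One encoder-input / decoder-target pair derived from a streamline."""

    enc_input: np.ndarray   # (ceil(L/2) + 1, 3), last row the (0,0,0) token
    dec_target: np.ndarray  # (floor(L/2), 3)
    source_id: int
    reversed_flag: bool


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference recipe)."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    grad_clip: float = 1.0
    reversal_prob: float = 0.5
    max_epochs: int = 10
    val_fraction: float = 0.2
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversal_prob <= 1.0:
            raise ValueError("reversal_prob must be in [0, 1]")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingLog:
    """Per-epoch record of the run."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    initial_val_loss: float = float("nan")
    best_epoch: int = -1
    grad_norms: List[float] = field(default_factory=list)  # post-clip, per step
    n_skipped_short: int = 0

    def as_rows(self) -> List[Dict[str, float]]:
        return [{"epoch": e + 1, "train_loss": tr, "val_loss": va}
                for e, (tr, va) in enumerate(zip(self.train_loss, self.val_loss))]


def make_pair(s: Streamline, reverse: bool) -> TrainingPair:
    """Split a streamline into its training pair (optionally flipping first)."""
    L = len(s)
    if L < MIN_TRAINABLE_POINTS:
        raise ValueError(f"streamline {s.id}: {L} points, needs >= {MIN_TRAINABLE_POINTS}")
    pts = s.points[::-1] if reverse else s.points
    n_first = (L + 1) // 2  # odd lengths: encoder gets the extra point
    enc_input = np.vstack([pts[:n_first], END_TOKEN])
    dec_target = np.array(pts[n_first:], dtype=np.float64)
    return TrainingPair(enc_input, dec_target, s.id, reverse)


def collate_batch(pairs: Sequence[TrainingPair]):
    """Zero-pad a list of pairs to common lengths.

    Returns ``(enc_X, enc_mask, dec_target, dec_mask)`` with shapes
    (B, Te, 3), (B, Te), (B, Td, 3), (B, Td); masks are True on genuine steps.
    """
    if not pairs:
        raise ValueError("empty batch")
    B = len(pairs)
    Te = max(p.enc_input.shape[0] for p in pairs)
    Td = max(p.dec_target.shape[0] for p in pairs)
    enc_X = np.zeros((B, Te, 3))
    enc_mask = np.zeros((B, Te), dtype=bool)
    dec_target = np.zeros((B, Td, 3))
    dec_mask = np.zeros((B, Td), dtype=bool)
    for b, p in enumerate(pairs):
        ne, nd = p.enc_input.shape[0], p.dec_target.shape[0]
        enc_X[b, :ne] = p.enc_input
        enc_mask[b, :ne] = True
        dec_target[b, :nd] = p.dec_target
        dec_mask[b, :nd] = True
    return enc_X, enc_mask, dec_target, dec_mask


def eligible_streamlines(data: Tractogram) -> Tuple[List[Streamline], int]:
    """Streamlines long enough to train on, plus the skipped count."""
    ok = [s for s in data if len(s) >= MIN_TRAINABLE_POINTS]
    return ok, len(data) - len(ok)


def split_train_val(data: Tractogram, val_fraction: float, seed: int
                    ) -> Tuple[List[Streamline], List[Streamline]]:
    """Disjoint per-streamline split, stratified by bundle label when present."""
    streamlines, n_short = eligible_streamlines(data)
    if not streamlines:
        raise ValueError("no streamlines with enough points to train on")
    if n_short:
        logger.info("excluded %d streamline(s) shorter than %d points from training",
                    n_short, MIN_TRAINABLE_POINTS)
    rng = np.random.default_rng(seed)
    groups: Dict[str, List[Streamline]] = {}
    for s in streamlines:
        groups.setdefault(data.labels.get(s.id, ""), []).append(s)
    train_set: List[Streamline] = []
    val_set: List[Streamline] = []
    for label in sorted(groups):
        members = groups[label]
        order = rng.permutation(len(members))
        n_val = int(round(val_fraction * len(members)))
        n_val = min(max(n_val, 1 if len(members) > 1 else 0), len(members) - 1)
        for j, idx in enumerate(order):
            (val_set if j < n_val else train_set).append(members[idx])
    return train_set, val_set


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.adam_beta1 ** self.t
        bc2 = 1.0 - c.adam_beta2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def _clip_gradients(grads: Dict[str, np.ndarray], max_norm: float) -> float:
    """Scale gradients so the global L2 norm is at most ``max_norm``;
    returns the post-clip norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale
        return max_norm
    return total


def _validation_loss(model: SeqAEModel, val_set: Sequence[Streamline],
                     batch_size: int) -> float:
    """Masked MSE over the validation split, unreversed, weighted by valid steps."""
    total_sq = 0.0
    total_steps = 0
    for start in range(0, len(val_set), batch_size):
        chunk = val_set[start:start + batch_size]
        pairs = [make_pair(s, reverse=False) for s in chunk]
        enc_X, enc_mask, dec_target, dec_mask = collate_batch(pairs)
        loss = model.batch_loss(enc_X, enc_mask, dec_target, dec_mask)
        n = int(dec_mask.sum())
        total_sq += loss * n
        total_steps += n
    return total_sq / total_steps


def train(model: SeqAEModel, data: Tractogram, cfg: TrainConfig
          ) -> Tuple[SeqAEModel, TrainingLog]:
    """End-to-end optimisation; returns the minimal-validation-loss checkpoint.

    Per epoch the training set is reshuffled and each streamline is
    independently reversed with probability ``reversal_prob`` (resampled
    every epoch). The returned model is a copy of the parameters at the
    best epoch; ``model`` itself ends up at the final epoch.
    """
    train_set, val_set = split_train_val(data, cfg.val_fraction, cfg.seed)
    _, n_short = eligible_streamlines(data)
    log = TrainingLog(n_skipped_short=n_short)
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = _Adam(model.params, cfg)

    log.initial_val_loss = _validation_loss(model, val_set, cfg.batch_size)
    best_val = np.inf
    best_model = model.copy()

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        reversals = rng.random(len(train_set)) < cfg.reversal_prob
        epoch_sq = 0.0
        epoch_steps = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pairs = [make_pair(train_set[i], bool(reversals[i])) for i in idx]
            enc_X, enc_mask, dec_target, dec_mask = collate_batch(pairs)
            loss, grads = model.loss_and_grads(enc_X, enc_mask, dec_target, dec_mask)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}; aborting")
            log.grad_norms.append(_clip_gradients(grads, cfg.grad_clip))
            optimizer.step(model.params, grads)
            n = int(dec_mask.sum())
            epoch_sq += loss * n
            epoch_steps += n
        train_loss = epoch_sq / epoch_steps
        val_loss = _validation_loss(model, val_set, cfg.batch_size)
        log.train_loss.append(train_loss)
        log.val_loss.append(val_loss)
        logger.info("epoch %d: train %.4f  val %.4f", epoch + 1, train_loss, val_loss)
        if val_loss < best_val:  # strict: ties keep the earliest epoch
            best_val = val_loss
            best_epoch = epoch
            best_model = model.copy()
            log.best_epoch = epoch + 1
    best_model.metadata.update({
        "best_epoch": log.best_epoch,
        "best_val_loss": best_val,
        "train_seed": cfg.seed,
    })
    return best_model, log
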