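"""LSTM sequence-to-sequence autoencoder over streamline point sequences.

The encoder consumes the first half of a streamline one 3D point at a time,
``h(t) = LSTM(h(t-1), x(t))``, and its final hidden/cell states initialise
the decoder, which predicts the second half point by point. No teacher
forcing is used: after the (0,0,0) start token, each decoder input is the
model's own previous output, so training rolls the decoder out exactly as
inference would. The final encoder hidden state is the fixed-size latent
vector regardless of input length — the property the whole framework rests
on.

The network is implemented directly in numpy, including
backpropagation-through-time (verified against numerical differentiation in
the test suite). Parameter conventions mirror the common deep-learning
layout: per LSTM layer a ``W_ih (4H, I)``, ``W_hh (4H, H)`` and two bias
vectors ``b_ih``, ``b_hh`` with gate order (input, forget, cell, output);
the decoder adds a linear readout ``H -> 3``. Under this convention a
1-layer model with 128 hidden units has exactly 136,579 trainable scalars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "ModelConfig",
    "EncoderState",
    "SeqAEModel",
    "count_parameters",
    "encode",
    "decode_teacherless",
    "reconstruction_loss",
    "START_TOKEN",
]

START_TOKEN = np.zeros(3)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    hidden_dim is both the LSTM state width and the latent dimension;
    n_layers applies to encoder and decoder alike (1 or 2).
    """

    input_dim: int = 3
    hidden_dim: int = 128
    n_layers: int = 1

    def __post_init__(self) -> None:
        if self.input_dim != 3:
            raise ValueError("input_dim is fixed to 3 (x, y, z coordinates)")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.n_layers not in (1, 2):
            raise ValueError("n_layers must be 1 or 2")

    def to_dict(self) -> Dict[str, int]:
        return {"input_dim": self.input_dim, "hidden_dim": self.hidden_dim,
                "n_layers": self.n_layers}


def count_parameters(config: ModelConfig) -> int:
    """Exact trainable-scalar count of the full encoder-decoder model.

    Each LSTM layer holds ``4*(H*I + H*H + 2H)`` scalars (I = 3 for the
    first layer, H above it); encoder and decoder each carry a full stack,
    and the decoder adds the ``H*3 + 3`` readout.
    """
    H = config.hidden_dim
    per_stack = 0
    for layer in range(config.n_layers):
        I = config.input_dim if layer == 0 else H
        per_stack += 4 * (H * I + H * H + 2 * H)
    return 2 * per_stack + (H * 3 + 3)


@dataclass(frozen=True)
class EncoderState:
    """Per-layer final (hidden, cell) states for one sequence; shape (L, H)."""

    hidden: np.ndarray
    cell: np.ndarray

    def __post_init__(self) -> None:
        h = np.atleast_2d(np.asarray(self.hidden, dtype=np.float64))
        c = np.atleast_2d(np.asarray(self.cell, dtype=np.float64))
        if h.shape != c.shape:
            raise ValueError(f"hidden {h.shape} and cell {c.shape} shapes differ")
        if not (np.all(np.isfinite(h)) and np.all(np.isfinite(c))):
            raise ValueError("non-finite encoder state")
        object.__setattr__(self, "hidden", h)
        object.__setattr__(self, "cell", c)

    @property
    def top_hidden(self) -> np.ndarray:
        return self.hidden[-1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _layer_input_dim(config: ModelConfig, layer: int) -> int:
    return config.input_dim if layer == 0 else config.hidden_dim


class SeqAEModel:
    """The encoder/decoder parameter container plus forward/backward passes."""

    def __init__(self, config: ModelConfig, params: Dict[str, np.ndarray],
                 metadata: Optional[Dict] = None) -> None:
        self.config = config
        self.params = params
        self.metadata = dict(metadata or {})

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, config: ModelConfig, seed: int = 0) -> "SeqAEModel":
        """Fresh model with U(-1/sqrt(H), 1/sqrt(H)) weights (the usual
        recurrent-layer default)."""
        rng = np.random.default_rng(seed)
        H = config.hidden_dim
        k = 1.0 / np.sqrt(H)
        params: Dict[str, np.ndarray] = {}
        for role in ("enc", "dec"):
            for layer in range(config.n_layers):
                I = _layer_input_dim(config, layer)
                params[f"{role}{layer}_W_ih"] = rng.uniform(-k, k, size=(4 * H, I))
                params[f"{role}{layer}_W_hh"] = rng.uniform(-k, k, size=(4 * H, H))
                params[f"{role}{layer}_b_ih"] = rng.uniform(-k, k, size=4 * H)
                params[f"{role}{layer}_b_hh"] = rng.uniform(-k, k, size=4 * H)
        params["out_W"] = rng.uniform(-k, k, size=(3, H))
        params["out_b"] = rng.uniform(-k, k, size=3)
        return cls(config, params, metadata={"init_seed": seed})

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_like_grads(self) -> Dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def copy(self) -> "SeqAEModel":
        return SeqAEModel(self.config, {k: v.copy() for k, v in self.params.items()},
                          dict(self.metadata))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = json.dumps({"config": self.config.to_dict(), "metadata": self.metadata})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.params)
        if path.suffix != ".npz":  # np.savez appends .npz
            Path(str(path) + ".npz").replace(path)
        return path

    @classmethod
    def load(cls, path) -> "SeqAEModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            params = {k: data[k] for k in data.files if k != "__header__"}
        return cls(ModelConfig(**header["config"]), params, header.get("metadata"))

    # -- single LSTM step ---------------------------------------------------

    def _step(self, role: str, layer: int, x: np.ndarray, h: np.ndarray,
              c: np.ndarray):
        """One LSTM cell update on a batch; returns new states plus the
        forward cache needed for backprop."""
        p = self.params
        key = f"{role}{layer}"
        z = x @ p[f"{key}_W_ih"].T + h @ p[f"{key}_W_hh"].T \
            + p[f"{key}_b_ih"] + p[f"{key}_b_hh"]
        H = self.config.hidden_dim
        i = _sigmoid(z[:, 0 * H:1 * H])
        f = _sigmoid(z[:, 1 * H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:4 * H])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache = (x, h, c, i, f, g, o, c_new)
        return h_new, c_new, cache

    def _step_backward(self, role: str, layer: int, cache, dh_new: np.ndarray,
                       dc_new: np.ndarray, grads: Dict[str, np.ndarray]):
        """Backward through one LSTM cell update; returns (dx, dh_prev, dc_prev)."""
        x, h_prev, c_prev, i, f, g, o, c_new = cache
        p = self.params
        key = f"{role}{layer}"
        tc = np.tanh(c_new)
        do = dh_new * tc
        dc = dc_new + dh_new * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_prev = dc * f
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        grads[f"{key}_W_ih"] += dz.T @ x
        grads[f"{key}_W_hh"] += dz.T @ h_prev
        grads[f"{key}_b_ih"] += dz.sum(axis=0)
        grads[f"{key}_b_hh"] += dz.sum(axis=0)
        dx = dz @ p[f"{key}_W_ih"]
        dh_prev = dz @ p[f"{key}_W_hh"]
        return dx, dh_prev, dc_prev

    # -- batched encoder ----------------------------------------------------

    def encode_batch(self, X: np.ndarray, mask: np.ndarray, keep_cache: bool = False):
        """Run the encoder over a zero-padded batch.

        ``X`` is (B, T, 3), ``mask`` (B, T) with True on genuine steps. At
        padded steps the states are carried over unchanged, so each
        sequence's final state equals what an unpadded run would produce.
        Returns per-layer states h, c of shape (L, B, H) (+ caches when
        ``keep_cache``).
        """
        B, T, _ = X.shape
        L, H = self.config.n_layers, self.config.hidden_dim
        # per-layer state arrays are rebound (never mutated): forward caches
        # hold references to the pre-step states
        hs = [np.zeros((B, H)) for _ in range(L)]
        cs = [np.zeros((B, H)) for _ in range(L)]
        caches: List = []
        for t in range(T):
            m = mask[:, t].astype(float)[:, None]
            x = X[:, t, :]
            step_caches = []
            for layer in range(L):
                h_new, c_new, cache = self._step("enc", layer, x, hs[layer], cs[layer])
                step_caches.append(cache)
                hs[layer] = m * h_new + (1.0 - m) * hs[layer]
                cs[layer] = m * c_new + (1.0 - m) * cs[layer]
                x = hs[layer]
            if keep_cache:
                caches.append(step_caches)
        h, c = np.stack(hs), np.stack(cs)
        return (h, c, caches) if keep_cache else (h, c)

    def _encode_backward(self, caches, mask: np.ndarray, dh_final: np.ndarray,
                         dc_final: np.ndarray, grads: Dict[str, np.ndarray]) -> None:
        B = mask.shape[0]
        L, H = self.config.n_layers, self.config.hidden_dim
        dh = dh_final.copy()  # (L, B, H)
        dc = dc_final.copy()
        for t in range(len(caches) - 1, -1, -1):
            m = mask[:, t].astype(float)[:, None]
            dx_above = None
            for layer in range(L - 1, -1, -1):
                # gradient arriving at this layer's blended output: the carry
                # into step t+1 plus, below the top, the layer above's input
                dh_t = dh[layer] if dx_above is None else dh[layer] + dx_above
                dc_t = dc[layer]
                dh_new = m * dh_t
                dc_new = m * dc_t
                dh_carry = (1.0 - m) * dh_t
                dc_carry = (1.0 - m) * dc_t
                dx, dh_prev, dc_prev = self._step_backward(
                    "enc", layer, caches[t][layer], dh_new, dc_new, grads)
                dh[layer] = dh_carry + dh_prev
                dc[layer] = dc_carry + dc_prev
                dx_above = dx  # feeds the layer below's blended output
            # dx_above for layer 0 is the gradient w.r.t. the input points; unused

    # -- decoder ------------------------------------------------------------

    def decode_batch(self, h0: np.ndarray, c0: np.ndarray, n_steps: int,
                     keep_cache: bool = False):
        """Teacherless rollout: start token, then feed back own outputs.

        ``h0``, ``c0`` are (L, B, H); returns predictions (B, n_steps, 3)
        (+ caches).
        """
        L, B, H = h0.shape
        hs = [h0[l].copy() for l in range(L)]
        cs = [c0[l].copy() for l in range(L)]
        x = np.zeros((B, 3))  # the (0,0,0) start token
        Y = np.zeros((B, n_steps, 3))
        caches: List = []
        for t in range(n_steps):
            step_caches = []
            inp = x
            for layer in range(L):
                h_new, c_new, cache = self._step("dec", layer, inp, hs[layer], cs[layer])
                step_caches.append(cache)
                hs[layer], cs[layer] = h_new, c_new
                inp = h_new
            y = hs[L - 1] @ self.params["out_W"].T + self.params["out_b"]
            Y[:, t, :] = y
            if keep_cache:
                caches.append((step_caches, hs[L - 1]))
            x = y  # no teacher forcing
        return (Y, caches) if keep_cache else Y

    def _decode_backward(self, caches, dY: np.ndarray, grads: Dict[str, np.ndarray]):
        """Backward through the rollout, including the output-feedback path.

        Returns gradients w.r.t. the decoder's initial (h0, c0), each (L, B, H).
        """
        L, H = self.config.n_layers, self.config.hidden_dim
        n_steps = dY.shape[1]
        B = dY.shape[0]
        dh = np.zeros((L, B, H))
        dc = np.zeros((L, B, H))
        dx_next = np.zeros((B, 3))  # dL/d(input at step t+1) == dL/dy_t via feedback
        for t in range(n_steps - 1, -1, -1):
            step_caches, h_top = caches[t]
            dy = dY[:, t, :] + dx_next
            grads["out_W"] += dy.T @ h_top
            grads["out_b"] += dy.sum(axis=0)
            d_inp = None
            for layer in range(L - 1, -1, -1):
                dh_t = dh[layer] + (d_inp if d_inp is not None else 0)
                if layer == L - 1:
                    dh_t = dh_t + dy @ self.params["out_W"]
                dx, dh_prev, dc_prev = self._step_backward(
                    "dec", layer, step_caches[layer], dh_t, dc[layer], grads)
                dh[layer] = dh_prev
                dc[layer] = dc_prev
                d_inp = dx
            dx_next = d_inp  # gradient w.r.t. this step's input = previous output
        return dh, dc

    # -- training objective -------------------------------------------------

    def loss_and_grads(self, enc_X: np.ndarray, enc_mask: np.ndarray,
                       dec_target: np.ndarray, dec_mask: np.ndarray):
        """Masked-MSE loss on a padded batch and its parameter gradients."""
        h, c, enc_caches = self.encode_batch(enc_X, enc_mask, keep_cache=True)
        n_steps = dec_target.shape[1]
        Y, dec_caches = self.decode_batch(h, c, n_steps, keep_cache=True)
        m = dec_mask.astype(float)[:, :, None]
        n_valid = float(dec_mask.sum())
        if n_valid == 0:
            raise ValueError("all decoder steps are masked; loss undefined")
        diff = (Y - dec_target) * m
        loss = float(np.sum(diff * diff) / (3.0 * n_valid))
        grads = self.zero_like_grads()
        dY = 2.0 * diff / (3.0 * n_valid)
        dh0, dc0 = self._decode_backward(dec_caches, dY, grads)
        self._encode_backward(enc_caches, enc_mask, dh0, dc0, grads)
        return loss, grads

    def batch_loss(self, enc_X, enc_mask, dec_target, dec_mask) -> float:
        """Forward-only masked MSE (validation)."""
        h, c = self.encode_batch(enc_X, enc_mask)
        Y = self.decode_batch(h, c, dec_target.shape[1])
        return reconstruction_loss_batch(Y, dec_target, dec_mask)


# -- public functional surface ---------------------------------------------

def encode(model: SeqAEModel, seq: np.ndarray) -> EncoderState:
    """Encode one point sequence into its final per-layer (hidden, cell) states."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[1] != 3 or seq.shape[0] < 1:
        raise ValueError(f"sequence must be (n>=1, 3), got {seq.shape}")
    if not np.all(np.isfinite(seq)):
        raise ValueError("non-finite input sequence")
    X = seq[None, :, :]
    mask = np.ones((1, seq.shape[0]), dtype=bool)
    h, c = model.encode_batch(X, mask)
    return EncoderState(hidden=h[:, 0, :], cell=c[:, 0, :])


def decode_teacherless(model: SeqAEModel, init: EncoderState, n_steps: int) -> np.ndarray:
    """Roll the decoder out ``n_steps`` points from an encoder state."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    h0 = init.hidden[:, None, :]
    c0 = init.cell[:, None, :]
    Y = model.decode_batch(h0, c0, n_steps)
    return Y[0]


def reconstruction_loss(pred: np.ndarray, target: np.ndarray,
                        mask: Optional[np.ndarray] = None) -> float:
    """Mean squared error over valid steps and the 3 coordinates.

    Padded (masked-out) steps contribute nothing to numerator or
    denominator, so the value is independent of what the padding contains.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if mask is None:
        mask = np.ones(pred.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != pred.shape[0]:
        raise ValueError("mask length must match number of steps")
    if not mask.any():
        raise ValueError("all steps masked; loss undefined")
    diff = pred[mask] - target[mask]
    return float(np.mean(diff * diff))


def reconstruction_loss_batch(Y: np.ndarray, target: np.ndarray,
                              mask: np.ndarray) -> float:
    m = mask.astype(float)[:, :, None]
    n_valid = float(mask.sum())
    if n_valid == 0:
        raise ValueError("all decoder steps are masked; loss undefined")
    diff = (Y - target) * m
    return float(np.sum(diff * diff) / (3.0 * n_valid))
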