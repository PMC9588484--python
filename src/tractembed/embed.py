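"""Streamline and bundle embeddings from a trained encoder.

A streamline embedding is the encoder's final top-layer hidden state on the
first half of the streamline (terminated by the (0,0,0) token) — exactly
the sequence the encoder saw at training time. Because the corpus was
augmented with random reversals, the reversed streamline's first half (i.e.
the second half, traversed backwards) is in-distribution too, which gives
three modes:

``uni``
    encode one direction only; latent dimension = hidden_dim.
``bi_avg`` (default)
    elementwise mean of the forward and reversed encodings; same dimension,
    invariant to head-to-tail flips.
``bi_concat``
    their concatenation; dimension = 2 * hidden_dim.

A bundle embedding is the arithmetic mean of its member streamline
embeddings, ``B = (1/n) * sum_i S_i``, which lives in the same space, so
streamline-to-bundle and bundle-to-bundle distances are all plain Euclidean
distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .model import SeqAEModel
from .tracts import Streamline, Tractogram

__all__ = ["MODES", "BundleEmbedding", "embed_streamline", "embed_many",
           "embed_bundle", "bundle_embeddings_from_labels"]

MODES = ("uni", "bi_avg", "bi_concat")


@dataclass(frozen=True)
class BundleEmbedding:
    """The mean latent vector of a bundle plus its member count."""

    label: str
    vector: np.ndarray
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("bundle vector must be 1-D")
        if self.n < 1:
            raise ValueError("a bundle embedding needs n >= 1 members")
        object.__setattr__(self, "vector", v)


def _first_half_with_token(points: np.ndarray) -> np.ndarray:
    n_first = (points.shape[0] + 1) // 2
    return np.vstack([points[:n_first], np.zeros((1, 3))])


def _encode_halves(model: SeqAEModel, streamlines: Sequence[np.ndarray],
                   reverse: bool, batch_size: int) -> np.ndarray:
    """Batched encoder run over first halves; returns (n, H) top hidden states."""
    halves = [_first_half_with_token(p[::-1] if reverse else p) for p in streamlines]
    H = model.config.hidden_dim
    out = np.empty((len(halves), H))
    for start in range(0, len(halves), batch_size):
        chunk = halves[start:start + batch_size]
        T = max(h.shape[0] for h in chunk)
        X = np.zeros((len(chunk), T, 3))
        mask = np.zeros((len(chunk), T), dtype=bool)
        for b, hseq in enumerate(chunk):
            X[b, :hseq.shape[0]] = hseq
            mask[b, :hseq.shape[0]] = True
        h, _ = model.encode_batch(X, mask)
        out[start:start + len(chunk)] = h[-1]  # top layer
    return out


def embed_streamline(model: SeqAEModel, s: Streamline, mode: str = "bi_avg") -> np.ndarray:
    """Embed one streamline into its fixed-size latent vector."""
    vecs = embed_many(model, Tractogram([Streamline(0, s.points)]), mode)
    return vecs[0]


def embed_many(model: SeqAEModel, t: Tractogram, mode: str = "bi_avg",
               batch_size: int = 256) -> Dict[int, np.ndarray]:
    """Embed every streamline of a tractogram; returns id -> latent vector.

    Batched execution pads sequences but carries encoder states through the
    padding, so results match one-by-one execution.
    """
    if mode not in MODES:
        raise ValueError(f"unknown embedding mode {mode!r}; choose from {MODES}")
    if len(t) == 0:
        raise ValueError("empty tractogram")
    points = [s.points for s in t]
    fwd = _encode_halves(model, points, reverse=False, batch_size=batch_size)
    if mode == "uni":
        mat = fwd
    else:
        bwd = _encode_halves(model, points, reverse=True, batch_size=batch_size)
        mat = (fwd + bwd) / 2.0 if mode == "bi_avg" else np.hstack([fwd, bwd])
    return {sid: mat[i] for i, sid in enumerate(t.ids)}


def embed_bundle(vectors: Sequence[np.ndarray], label: str = "",
                 ) -> BundleEmbedding:
    """Average streamline embeddings into a bundle embedding."""
    vectors = [np.asarray(v, dtype=np.float64) for v in vectors]
    if not vectors:
        raise ValueError("cannot embed an empty bundle")
    dims = {v.shape for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"mixed embedding dimensions: {sorted(dims)}")
    return BundleEmbedding(label=label, vector=np.mean(vectors, axis=0), n=len(vectors))


def bundle_embeddings_from_labels(vectors: Dict[int, np.ndarray],
                                  labels: Dict[int, str]) -> List[BundleEmbedding]:
    """One bundle embedding per label value, sorted by label name."""
    groups: Dict[str, List[np.ndarray]] = {}
    for sid, vec in vectors.items():
        if sid in labels:
            groups.setdefault(labels[sid], []).append(vec)
    return [embed_bundle(groups[name], label=name) for name in sorted(groups)]
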