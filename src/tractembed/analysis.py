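"""Quantitative analysis in the latent space.

Everything here operates on plain latent vectors: Euclidean distances
between streamlines and bundles, top-k nearest-bundle classification,
distance-threshold querying, flat k-means clustering, recursive (binary or
wider) hierarchical dissection into sub-bundles, bundle-wise distance
matrices, quantile-based outlier screening for false-connection candidates,
and t-SNE projection for figures. Ties on exact distance are always broken
toward the lower label/index so every result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .embed import BundleEmbedding

__all__ = [
    "DistanceMatrix", "ClusterTree", "TopKResult",
    "latent_distance", "classify_topk", "topk_accuracy", "query_by_distance",
    "cluster_kmeans", "hierarchical_dissect", "bundle_distance_matrix",
    "flag_outlier_streamlines", "project_2d",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise distances with row/column identifiers."""

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    values: np.ndarray

    def off_diagonal(self) -> np.ndarray:
        v = self.values
        return v[~np.eye(v.shape[0], dtype=bool)]

    def lookup(self, row: str, col: str) -> float:
        return float(self.values[self.row_labels.index(row), self.col_labels.index(col)])


@dataclass
class ClusterTree:
    """Recursive dissection of a streamline set; children partition the parent."""

    node_id: str
    member_ids: Tuple[int, ...]
    level: int
    children: List["ClusterTree"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["ClusterTree"]:
        if self.is_leaf:
            return [self]
        out: List[ClusterTree] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def to_dict(self) -> Dict:
        return {"node_id": self.node_id, "level": self.level,
                "member_ids": list(self.member_ids),
                "children": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class TopKResult:
    """Bundle labels ranked by ascending latent distance for one streamline."""

    streamline_id: int
    ranked_labels: Tuple[str, ...]
    distances: Tuple[float, ...]


def latent_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two latent vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def classify_topk(v: np.ndarray, bundles: Sequence[BundleEmbedding], k: int,
                  streamline_id: int = -1) -> TopKResult:
    """The k nearest bundle embeddings to ``v``, ascending by distance.

    Exact distance ties rank the bundle that comes earlier in ``bundles``
    first, so results are deterministic.
    """
    if not bundles:
        raise ValueError("no bundle embeddings to classify against")
    if not 1 <= k <= len(bundles):
        raise ValueError(f"k must be in [1, {len(bundles)}], got {k}")
    d = np.array([latent_distance(v, b.vector) for b in bundles])
    order = np.lexsort((np.arange(len(bundles)), d))[:k]
    return TopKResult(
        streamline_id=streamline_id,
        ranked_labels=tuple(bundles[i].label for i in order),
        distances=tuple(float(d[i]) for i in order),
    )


def topk_accuracy(results: Sequence[TopKResult], truth: Mapping[int, str],
                  ks: Iterable[int]) -> Dict[int, float]:
    """Fraction of streamlines whose true bundle appears in the first k ranks.

    A k beyond the number of ranked labels falls back to the largest
    available rank (with a warning), so the metric stays defined when fewer
    bundles than k exist.
    """
    results = list(results)
    missing = [r.streamline_id for r in results if r.streamline_id not in truth]
    if missing:
        raise KeyError(f"no ground-truth label for streamline ids {missing[:5]}")
    if not results:
        raise ValueError("no results to score")
    out: Dict[int, float] = {}
    for k in sorted(set(ks)):
        hits = 0
        for r in results:
            kk = min(k, len(r.ranked_labels))
            if kk < k:
                logger.warning("top-%d requested but only %d bundles ranked; using top-%d",
                               k, kk, kk)
            hits += truth[r.streamline_id] in r.ranked_labels[:kk]
        out[k] = hits / len(results)
    return out


def query_by_distance(seed: np.ndarray, pool: Mapping[int, np.ndarray],
                      threshold: float) -> Set[int]:
    """All ids whose latent distance to ``seed`` is at most ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return {sid for sid, v in pool.items() if latent_distance(seed, v) <= threshold}


def _as_matrix(vectors: Mapping[int, np.ndarray]) -> Tuple[List[int], np.ndarray]:
    ids = sorted(vectors)
    return ids, np.asarray([vectors[i] for i in ids], dtype=np.float64)


def cluster_kmeans(vectors: Mapping[int, np.ndarray], k: int, seed: int = 0
                   ) -> Dict[int, int]:
    """Flat k-means partition of latent vectors (k-means++, 10 restarts).

    The fixed seed makes results reproducible; cluster indices are
    relabelled so that index order follows the smallest member id of each
    cluster, giving a deterministic labelling.
    """
    ids, X = _as_matrix(vectors)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available vectors")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    # canonical relabelling: clusters ordered by first occurrence
    remap: Dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
    return {sid: remap[lab] for sid, lab in zip(ids, raw)}


def hierarchical_dissect(vectors: Mapping[int, np.ndarray], branching: int = 2,
                         depth: int = 3, min_leaf: int = 10, seed: int = 0
                         ) -> ClusterTree:
    """Recursive k-means dissection into sub-bundles.

    Each non-leaf node is split into ``branching`` children; recursion
    stops at ``depth`` or when a node holds fewer than
    ``min_leaf * branching`` members. Children partition their parent at
    every level.
    """
    if branching < 2:
        raise ValueError("branching must be >= 2")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def build(node_id: str, ids: Tuple[int, ...], level: int, node_seed: int) -> ClusterTree:
        node = ClusterTree(node_id=node_id, member_ids=ids, level=level)
        if level >= depth or len(ids) < min_leaf * branching:
            return node
        sub = {i: vectors[i] for i in ids}
        assign = cluster_kmeans(sub, branching, seed=node_seed)
        for j in range(branching):
            child_ids = tuple(i for i in ids if assign[i] == j)
            if child_ids:
                node.children.append(
                    build(f"{node_id}.{j}", child_ids, level + 1, node_seed * branching + j + 1))
        if len(node.children) < 2:  # degenerate split; keep as leaf
            node.children = []
        return node

    all_ids = tuple(sorted(vectors))
    return build("root", all_ids, 0, seed)


def bundle_distance_matrix(bundles: Sequence[BundleEmbedding]) -> DistanceMatrix:
    """Symmetric matrix of pairwise Euclidean distances between bundles."""
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles")
    dims = {b.vector.shape for b in bundles}
    if len(dims) != 1:
        raise ValueError(f"mixed bundle dimensions: {sorted(dims)}")
    X = np.asarray([b.vector for b in bundles])
    vals = cdist(X, X)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    names = tuple(b.label for b in bundles)
    return DistanceMatrix(row_labels=names, col_labels=names, values=vals)


def flag_outlier_streamlines(vectors: Mapping[int, np.ndarray],
                             labels: Mapping[int, int],
                             quantile: float = 0.99) -> Set[int]:
    """Screen for streamlines unusually far from their own cluster centroid.

    Within each cluster, ids whose centroid distance exceeds the cluster's
    ``quantile`` distance quantile are flagged. This is a screening aid for
    the visual inspection step that identifies false connections — the
    default quantile of 0.99 is a convenience choice, not a calibrated
    detection rule. Single-member clusters are never flagged.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    flagged: Set[int] = set()
    clusters: Dict[int, List[int]] = {}
    for sid, lab in labels.items():
        clusters.setdefault(lab, []).append(sid)
    for lab, ids in clusters.items():
        if len(ids) < 2:
            continue
        X = np.asarray([vectors[i] for i in ids], dtype=np.float64)
        centroid = X.mean(axis=0)
        d = np.linalg.norm(X - centroid, axis=1)
        cut = float(np.quantile(d, quantile))
        flagged.update(i for i, di in zip(ids, d) if di > cut)
    return flagged


def project_2d(vectors: Mapping[int, np.ndarray], seed: int = 0,
               perplexity: float = 30.0) -> Dict[int, np.ndarray]:
    """t-SNE layout of the latent vectors for visual inspection only.

    Stochastic but reproducible under a fixed seed; perplexity is capped
    below the sample count as t-SNE requires.
    """
    ids, X = _as_matrix(vectors)
    if len(ids) < 3:
        raise ValueError("t-SNE projection needs at least 3 vectors")
    perp = min(perplexity, (len(ids) - 1) / 3.0)
    ts = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
    Y = ts.fit_transform(X)
    return {sid: Y[i] for i, sid in enumerate(ids)}
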