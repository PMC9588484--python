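"""In-memory containers for streamlines and tractograms.

A streamline is an ordered polyline of 3D points in world (scanner RAS)
millimetre coordinates, the raw object every other module consumes. A
tractogram is a collection of streamlines with optional per-streamline
bundle labels and the voxel-to-world transform carried over from the source
file. Coordinates are kept exactly as stored on disk: no resampling, no
normalisation, no voxel-space conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np

__all__ = ["Streamline", "Tractogram"]


@dataclass(frozen=True)
class Streamline:
    """One tractography streamline.

    Parameters
    ----------
    id:
        Identifier, unique within its tractogram.
    points:
        ``(n, 3)`` float array of world-millimetre coordinates, ``n >= 2``.
    """

    id: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"streamline {self.id}: points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError(f"streamline {self.id}: needs >= 2 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"streamline {self.id}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    def reversed(self) -> "Streamline":
        return Streamline(self.id, self.points[::-1].copy())


class Tractogram:
    """A labelled collection of streamlines.

    ``labels`` maps a subset of streamline ids to bundle names; ``affine``
    is the voxel-to-world transform of the source image grid (identity when
    the data never lived on a grid, e.g. synthetic streamlines).
    """

    def __init__(
        self,
        streamlines: Iterable[Streamline],
        labels: Optional[Dict[int, str]] = None,
        affine: Optional[np.ndarray] = None,
    ) -> None:
        self.streamlines: List[Streamline] = list(streamlines)
        ids = [s.id for s in self.streamlines]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate streamline ids in tractogram")
        self.labels: Dict[int, str] = dict(labels) if labels else {}
        unknown = set(self.labels) - set(ids)
        if unknown:
            raise ValueError(f"labels refer to unknown streamline ids: {sorted(unknown)[:5]}")
        self.affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    @property
    def ids(self) -> List[int]:
        return [s.id for s in self.streamlines]

    def label_of(self, sid: int) -> Optional[str]:
        return self.labels.get(sid)

    @property
    def label_names(self) -> List[str]:
        return sorted(set(self.labels.values()))

    def subset(self, ids: Sequence[int]) -> "Tractogram":
        """Streamlines with the given ids, in the given order."""
        by_id = {s.id: s for s in self.streamlines}
        sub = [by_id[i] for i in ids]
        labels = {i: self.labels[i] for i in ids if i in self.labels}
        return Tractogram(sub, labels, self.affine)

    def with_label(self, label: str) -> "Tractogram":
        ids = [i for i in self.ids if self.labels.get(i) == label]
        return self.subset(ids)

    @staticmethod
    def merge(parts: Sequence["Tractogram"], reindex: bool = True) -> "Tractogram":
        """Concatenate tractograms; ``reindex`` assigns fresh sequential ids."""
        if not parts:
            raise ValueError("nothing to merge")
        streamlines: List[Streamline] = []
        labels: Dict[int, str] = {}
        nxt = 0
        for part in parts:
            for s in part:
                sid = nxt if reindex else s.id
                streamlines.append(Streamline(sid, s.points))
                if s.id in part.labels:
                    labels[sid] = part.labels[s.id]
                nxt += 1
        return Tractogram(streamlines, labels, parts[0].affine)
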