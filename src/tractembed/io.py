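"""Reading and writing tractography files and embedding tables.

TCK (MRtrix) is the canonical format: read and write, world millimetre
coordinates as stored. TRK (TrackVis) is read-only; nibabel applies the
header transform so streamlines always arrive in world (RAS mm) space.
Embeddings travel as plain CSV so that generic tabular tools can consume
them: one row per streamline, an ``id`` column followed by the latent
features.

The exact point ``(0, 0, 0)`` is reserved by the sequence model as its
start/end token, so a genuine origin point is perturbed by 1e-6 mm on load
(and counted in the log); in world millimetre space the collision is
physically negligible but must never silently truncate a sequence.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .tracts import Streamline, Tractogram

__all__ = [
    "TractogramFormatError",
    "read_tractogram",
    "read_bundle_dir",
    "write_tractogram",
    "write_bundles",
    "export_embeddings",
    "read_embeddings",
    "write_label_manifest",
    "read_label_manifest",
]

logger = logging.getLogger(__name__)

ZERO_TOKEN_EPS = 1e-6


class TractogramFormatError(Exception):
    """A file that cannot be parsed as a streamline format."""


def _sanitize_points(points: np.ndarray, sid: int, counter: List[int]) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    zero_rows = np.all(pts == 0.0, axis=1)
    if np.any(zero_rows):
        pts = pts.copy()
        pts[zero_rows] += ZERO_TOKEN_EPS
        counter[0] += int(zero_rows.sum())
    return pts


def read_tractogram(path: os.PathLike, label: Optional[str] = None) -> Tractogram:
    """Load a TCK or TRK file into a :class:`Tractogram`.

    Coordinates are returned in world millimetres (RAS); on-disk streamline
    order and within-streamline point order are preserved. When ``label``
    is given every streamline carries it (the one-file-per-bundle layout).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    TractogramFormatError
        If the file is empty or cannot be parsed (the underlying parser
        error, which names the offending offset where known, is chained).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TractogramFormatError(f"{path}: file is empty (zero bytes), not a valid track file")
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/DataError/ValueError
        raise TractogramFormatError(f"{path}: cannot parse track file: {exc}") from exc

    perturbed = [0]
    streamlines = []
    for i, pts in enumerate(tfile.tractogram.streamlines):
        streamlines.append(Streamline(i, _sanitize_points(pts, i, perturbed)))
    if perturbed[0]:
        logger.info("%s: perturbed %d exact-origin point(s) by %.0e mm (reserved token)",
                    path, perturbed[0], ZERO_TOKEN_EPS)
    labels = {s.id: label for s in streamlines} if label is not None else {}
    affine = getattr(tfile.header, "get", lambda *_: None)("voxel_to_rasmm", None)
    if affine is None:
        affine = np.eye(4)
    return Tractogram(streamlines, labels, affine)


def read_bundle_dir(directory: os.PathLike, pattern: str = "*.tck") -> Tractogram:
    """Load a directory of per-bundle files, labelling each by file stem."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no files matching {pattern} in {directory}")
    parts = [read_tractogram(f, label=f.stem) for f in files]
    return Tractogram.merge(parts)


def write_tractogram(t: Tractogram, path: os.PathLike) -> Path:
    """Write a non-empty tractogram as a TCK file and return the path."""
    path = Path(path)
    if len(t) == 0:
        raise ValueError("refusing to write an empty tractogram")
    if path.suffix.lower() != ".tck":
        raise ValueError(f"{path}: only TCK is supported for writing (got {path.suffix!r})")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = [s.points.astype(np.float32) for s in t]
    nib_t = nib.streamlines.Tractogram(arrays, affine_to_rasmm=np.eye(4))
    try:
        nib.streamlines.save(nib_t, str(path))
    except OSError as exc:
        raise OSError(f"{path}: cannot write track file: {exc}") from exc
    return path


def write_bundles(t: Tractogram, directory: os.PathLike) -> Dict[str, Path]:
    """Write one TCK per bundle label; returns label -> file path."""
    directory = Path(directory)
    out: Dict[str, Path] = {}
    for name in t.label_names:
        sub = t.with_label(name)
        if len(sub):
            out[name] = write_tractogram(sub, directory / f"{name}.tck")
    return out


def export_embeddings(ids: Sequence[int], vectors: Sequence[np.ndarray],
                      path: os.PathLike) -> Path:
    """Write latent vectors as CSV: ``id`` column then feature columns.

    Full float precision is written so a read-back reproduces the vectors.
    """
    if len(ids) != len(vectors):
        raise ValueError(f"{len(ids)} ids but {len(vectors)} vectors")
    if len(ids) == 0:
        raise ValueError("refusing to export an empty embedding table")
    dims = {np.asarray(v).shape for v in vectors}
    if len(dims) != 1 or len(next(iter(dims))) != 1:
        raise ValueError(f"ragged or non-1D vector shapes: {sorted(dims)}")
    mat = np.asarray(vectors, dtype=np.float64)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(mat, columns=[f"f{j}" for j in range(mat.shape[1])])
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_embeddings(path: os.PathLike) -> Tuple[List[int], np.ndarray]:
    """Read an embedding CSV back into (ids, (n, D) matrix)."""
    df = pd.read_csv(path)
    ids = df["id"].tolist()
    mat = df.drop(columns=["id"]).to_numpy(dtype=np.float64)
    return ids, mat


def write_label_manifest(t: Tractogram, path: os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [(sid, t.labels.get(sid, "")) for sid in t.ids]
    pd.DataFrame(rows, columns=["id", "label"]).to_csv(path, index=False)
    return path


def read_label_manifest(path: os.PathLike) -> Dict[int, str]:
    df = pd.read_csv(path, keep_default_na=False)
    return {int(r.id): str(r.label) for r in df.itertuples() if str(r.label)}
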