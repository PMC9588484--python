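"""Synthetic tractograms with controllable bundle geometry.

Every downstream stage of the package (training, embedding, clustering,
querying, filtering) is exercised on data from this module, so it emulates
the geometric structure the method relies on without pretending to be a
brain: bundles are noisy tubes swept along smooth 3D parametric curves in
world millimetre coordinates, left/right pairs are mirror images across the
mid-sagittal plane (x = 0), streamlines have variable point counts and no
canonical head-to-tail direction, and an optional fraction of spurious
"false connection" streamlines run along one bundle, make a hairpin turn
and finish along another — the artifact that latent-space filtering is
meant to catch.

Within a bundle, each streamline is the centerline plus a constant random
tube offset (scale ``radius``) plus a smaller smooth lateral wander
(spline-interpolated low-frequency noise), so member streamlines are
locally smooth parallel tracks rather than rough resamples of one curve;
sharp turning angles are then a reliable signature of the injected false
streamlines alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import make_interp_spline

from .tracts import Streamline, Tractogram

__all__ = [
    "GeometryError",
    "BundleSpec",
    "SyntheticTractogramSpec",
    "generate_bundle",
    "generate_tractogram",
    "load_spec",
    "synthetic_atlas_spec",
    "generate_synthetic_atlas",
    "turning_angles",
    "max_turning_angle",
    "FALSE_LABEL",
]

FALSE_LABEL = "false"

MIRROR_AXES = {"x": 0, "y": 1, "z": 2}


class GeometryError(Exception):
    """A degenerate bundle centerline (e.g. repeated control points)."""


@dataclass(frozen=True)
class BundleSpec:
    """Recipe for one synthetic bundle (plus its optional mirror twin).

    ``centerline`` holds spline control points in mm; ``radius`` sets the
    lateral tube scale; streamline point counts are drawn uniformly from
    ``length_range``; ``mirror`` names a coordinate axis ('x', 'y' or 'z')
    across whose zero-plane a second, independently sampled twin bundle
    named ``<name>_mirrored`` is generated.
    """

    name: str
    centerline: np.ndarray
    radius: float = 2.0
    n_streamlines: int = 200
    length_range: Tuple[int, int] = (20, 60)
    mirror: Optional[str] = None

    def __post_init__(self) -> None:
        cps = np.atleast_2d(np.asarray(self.centerline, dtype=np.float64))
        if cps.ndim != 2 or cps.shape[1] != 3 or cps.shape[0] < 2:
            raise GeometryError(f"{self.name}: centerline must be (k>=2, 3) control points")
        if np.any(np.linalg.norm(np.diff(cps, axis=0), axis=1) < 1e-9):
            raise GeometryError(f"{self.name}: repeated consecutive control points")
        object.__setattr__(self, "centerline", cps)
        if self.n_streamlines < 1:
            raise ValueError(f"{self.name}: n_streamlines must be >= 1")
        if self.length_range[0] < 4 or self.length_range[1] < self.length_range[0]:
            raise ValueError(f"{self.name}: invalid length_range {self.length_range}")
        if self.radius <= 0:
            raise ValueError(f"{self.name}: radius must be positive")
        if self.mirror is not None and self.mirror not in MIRROR_AXES:
            raise ValueError(f"{self.name}: mirror axis must be one of {sorted(MIRROR_AXES)}")


@dataclass(frozen=True)
class SyntheticTractogramSpec:
    """A whole synthetic tractogram: bundles plus spurious streamlines.

    ``false_fraction`` is the number of injected false-connection
    streamlines relative to the genuine count (rounded to nearest); the
    seed fixes the full output bit-for-bit.
    """

    bundles: Tuple[BundleSpec, ...]
    false_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bundles", tuple(self.bundles))
        if not self.bundles:
            raise ValueError("at least one bundle is required")
        if not 0.0 <= self.false_fraction < 1.0:
            raise ValueError(f"false_fraction must be in [0, 1), got {self.false_fraction}")


def _fit_spline(cps: np.ndarray):
    """Smooth curve through the control points, parametrised by arc length.

    The returned callable maps u in [0, 1] (fraction of total arc length)
    to a 3D point; uniform u therefore gives uniformly spaced points, so
    point spacing never collapses where the interpolating spline slows
    down.
    """
    chord = np.linalg.norm(np.diff(cps, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    t /= t[-1]
    k = min(3, cps.shape[0] - 1)
    spline = make_interp_spline(t, cps, k=k)
    dense_t = np.linspace(0.0, 1.0, 1024)
    dense_pts = spline(dense_t)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense_pts, axis=0), axis=1))])
    s /= s[-1]

    def curve(u):
        return spline(np.interp(u, s, dense_t))

    return curve


def _smooth_jitter(ts: np.ndarray, scale: float, rng: np.random.Generator,
                   n_knots: int = 6) -> np.ndarray:
    """Lateral wander that is smooth in arc length.

    Gaussian values of the given scale are drawn at a few evenly spaced
    knots along the curve parameter and interpolated with a cubic spline,
    so local curvature stays low no matter how densely the streamline is
    sampled (i.i.d. per-point noise would dominate the turning angles of
    densely sampled streamlines).
    """
    knots = np.linspace(0.0, 1.0, n_knots)
    values = rng.normal(0.0, scale, size=(n_knots, 3))
    return make_interp_spline(knots, values, k=3)(np.clip(ts, 0.0, 1.0))


def _sweep_streamline(spline, n_pts: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    t0 = rng.uniform(0.0, 0.04)
    t1 = 1.0 - rng.uniform(0.0, 0.04)
    ts = np.linspace(t0, t1, n_pts)
    pts = spline(ts)
    tube_offset = rng.normal(0.0, radius, size=3)
    pts = pts + tube_offset + _smooth_jitter(ts, radius / 3.0, rng)
    if rng.random() < 0.5:  # corpus carries no canonical direction
        pts = pts[::-1]
    # (0,0,0) is reserved downstream as the sequence token
    zero = np.all(pts == 0.0, axis=1)
    pts[zero] += 1e-6
    return pts


def _reflect(cps: np.ndarray, axis: str) -> np.ndarray:
    out = cps.copy()
    out[:, MIRROR_AXES[axis]] *= -1.0
    return out


def generate_bundle(spec: BundleSpec, seed: int) -> Tractogram:
    """Generate one bundle (and its mirror twin when requested).

    Deterministic in ``seed``: the same spec and seed reproduce the output
    bit for bit.
    """
    rng = np.random.default_rng(seed)
    jobs = [(spec.name, _fit_spline(spec.centerline))]
    if spec.mirror is not None:
        jobs.append((f"{spec.name}_mirrored", _fit_spline(_reflect(spec.centerline, spec.mirror))))
    streamlines: List[Streamline] = []
    labels = {}
    sid = 0
    lo, hi = spec.length_range
    for name, spline in jobs:
        for _ in range(spec.n_streamlines):
            n_pts = int(rng.integers(lo, hi + 1))
            streamlines.append(Streamline(sid, _sweep_streamline(spline, n_pts, spec.radius, rng)))
            labels[sid] = name
            sid += 1
    return Tractogram(streamlines, labels)


def _false_streamline(spline_a, spline_b, radius: float, length_range: Tuple[int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """A spurious streamline: half of bundle A, a hairpin, half of bundle B.

    The hairpin (a short doubled-back run along A, laterally offset so the
    track does not retrace itself exactly) guarantees a turning angle near
    180 degrees, far above anything a genuine tube streamline produces.
    """
    lo, hi = length_range
    n_total = int(rng.integers(max(lo, 8), hi + 1))
    n_a = n_total // 2
    n_b = max(n_total - n_a - 3, 2)
    ts_a = np.linspace(0.0, 0.55, n_a)
    half_a = spline_a(ts_a) + _smooth_jitter(ts_a, radius / 3.0, rng)
    # hairpin apex: double straight back along the final segment, with a
    # small perpendicular offset so the track does not retrace itself
    seg = half_a[-1] - half_a[-2]
    perp = np.cross(seg, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(seg, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp) * 0.3 * radius
    back = np.array([half_a[-1] - (k * 0.9) * seg + perp for k in (1, 2, 3)])
    ts_b = np.linspace(0.55, 0.0, n_b)
    half_b = spline_b(ts_b) + _smooth_jitter(ts_b, radius / 3.0, rng)
    pts = np.vstack([half_a, back, half_b])
    return pts + rng.normal(0.0, radius, size=3)


def generate_tractogram(spec: SyntheticTractogramSpec) -> Tractogram:
    """Generate all bundles plus the requested fraction of false streamlines."""
    master = np.random.default_rng(spec.seed)
    seeds = master.integers(0, 2**31 - 1, size=len(spec.bundles))
    parts = [generate_bundle(b, int(s)) for b, s in zip(spec.bundles, seeds)]
    merged = Tractogram.merge(parts)
    n_genuine = len(merged)
    n_false = int(round(spec.false_fraction * n_genuine))
    if n_false:
        splines = []
        for b in spec.bundles:
            splines.append((_fit_spline(b.centerline), b.radius, b.length_range))
            if b.mirror is not None:
                splines.append((_fit_spline(_reflect(b.centerline, b.mirror)), b.radius, b.length_range))
        false_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        streamlines = list(merged.streamlines)
        labels = dict(merged.labels)
        sid = n_genuine
        for _ in range(n_false):
            ia, ib = false_rng.choice(len(splines), size=2, replace=False)
            (sa, ra, lr), (sb, _, _) = splines[ia], splines[ib]
            pts = _false_streamline(sa, sb, ra, lr, false_rng)
            streamlines.append(Streamline(sid, pts))
            labels[sid] = FALSE_LABEL
            sid += 1
        merged = Tractogram(streamlines, labels)
    return merged


def turning_angles(points: np.ndarray) -> np.ndarray:
    """Angle (degrees) between successive segments of a polyline."""
    seg = np.diff(np.asarray(points, dtype=float), axis=0)
    norm = np.linalg.norm(seg, axis=1)
    keep = norm > 1e-12
    seg, norm = seg[keep], norm[keep]
    if seg.shape[0] < 2:
        return np.zeros(0)
    cosang = np.sum(seg[:-1] * seg[1:], axis=1) / (norm[:-1] * norm[1:])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def max_turning_angle(points: np.ndarray) -> float:
    ang = turning_angles(points)
    return float(ang.max()) if ang.size else 0.0


def load_spec(path) -> SyntheticTractogramSpec:
    """Read a tractogram spec from a YAML (or JSON) file.

    Expected layout::

        seed: 0
        false_fraction: 0.1
        bundles:
          - name: arc
            centerline: [[30, -20, 0], [30, 0, 15], [30, 20, 0]]
            radius: 2.0
            n_streamlines: 100
            length_range: [20, 60]
            mirror: x
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bundles = []
    for b in raw.get("bundles", []):
        kw = dict(b)
        if "length_range" in kw:
            kw["length_range"] = tuple(kw["length_range"])
        bundles.append(BundleSpec(**kw))
    return SyntheticTractogramSpec(bundles=tuple(bundles),
                                   false_fraction=raw.get("false_fraction", 0.0),
                                   seed=raw.get("seed", 0))


# ---------------------------------------------------------------------------
# The "synthetic atlas" preset: 4 mirror pairs + 2 midline bundles laid out
# on a brain-scale grid with inter-centerline separations >= 20 mm, so the
# latent space has the clearly separable regime that the clustering and
# classification analyses assume.
# ---------------------------------------------------------------------------

def _local(center: Sequence[float], pts: Sequence[Sequence[float]]) -> np.ndarray:
    return np.asarray(pts, dtype=float) + np.asarray(center, dtype=float)


def _atlas_bundle_specs(n_per_bundle: int) -> Tuple[BundleSpec, ...]:
    c_arc = [[0, -15, -8], [0, -10, 8], [0, 0, 14], [0, 10, 8], [0, 15, -8]]
    u_small = [[0, -8, 8], [0, -7, -4], [0, 0, -9], [0, 7, -4], [0, 8, 8]]
    u_large = [[0, -16, 14], [0, -14, -6], [0, 0, -16], [0, 14, -6], [0, 16, 14]]
    s_curve = [[0, -16, -12], [0, -8, -8], [0, 0, 0], [0, 8, 8], [0, 16, 12]]
    cc_arc = [[-16, 0, -6], [-10, 0, 8], [0, 0, 14], [10, 0, 8], [16, 0, -6]]
    mid_arc = [[-12, -8, 0], [-6, 4, 0], [0, 8, 0], [6, 4, 0], [12, -8, 0]]
    mk = lambda name, center, pts, mirror=None: BundleSpec(
        name=name, centerline=_local(center, pts), radius=2.0,
        n_streamlines=n_per_bundle, length_range=(20, 60), mirror=mirror)
    return (
        mk("c_arc_right", (40, -40, 40), c_arc, mirror="x"),
        mk("u_small_right", (40, 40, 40), u_small, mirror="x"),
        mk("u_large_right", (40, -40, -40), u_large, mirror="x"),
        mk("s_curve_right", (40, 40, -40), s_curve, mirror="x"),
        mk("mid_arc_sup", (0, 0, 40), cc_arc),
        mk("mid_arc_inf", (0, 0, -40), mid_arc),
    )


def synthetic_atlas_spec(seed: int = 0, n_per_bundle: int = 200,
                         false_fraction: float = 0.0) -> SyntheticTractogramSpec:
    """The default desk-scale fixture: 10 bundles (4 mirror pairs + 2 midline),
    ``n_per_bundle`` streamlines each, 20-60 points, radius 2 mm."""
    return SyntheticTractogramSpec(
        bundles=_atlas_bundle_specs(n_per_bundle),
        false_fraction=false_fraction,
        seed=seed,
    )


def generate_synthetic_atlas(seed: int = 0, n_per_bundle: int = 200,
                             false_fraction: float = 0.0) -> Tractogram:
    return generate_tractogram(synthetic_atlas_spec(seed, n_per_bundle, false_fraction))
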