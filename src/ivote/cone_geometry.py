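"""Vote-cone membership tests and axis-aligned bounding volumes.

A voter at lattice position ``t`` with unit direction ``d`` casts votes
into the solid cone of full opening angle ``phi`` and length ``r``
(micrometers) opening along ``d``.  A lattice site ``p`` receives the vote
iff, measured in physical space,

    cos(angle(p - t, d)) > cos(phi / 2)   and   0 < |p - t| < r.

Both inequalities are strict and the apex itself is never a member.  The
same cosine-form predicate is used in 2D and 3D.  Candidate sites are
pruned with the tight axis-aligned bounding box of the cone-plus-spherical-
cap solid, which is a guaranteed superset of the lattice membership set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConeSpec",
    "BoundingBox",
    "cone_contains",
    "cone_contains_many",
    "cone_bounding_box",
    "cone_member_sites",
]


@dataclass(frozen=True)
class ConeSpec:
    """A single voter's cone: apex (pixels), unit direction (physical
    space), length ``radius_um`` (micrometers) and full aperture
    ``aperture_phi`` (radians, 0 < phi <= pi/2)."""

    apex: tuple[float, ...]
    direction: tuple[float, ...]
    radius_um: float
    aperture_phi: float

    def __post_init__(self) -> None:
        apex = tuple(float(a) for a in self.apex)
        direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(direction))
        if norm == 0:
            raise ValueError("cone direction must be nonzero")
        if abs(norm - 1.0) > 1e-9:
            direction = direction / norm
        object.__setattr__(self, "apex", apex)
        object.__setattr__(self, "direction", tuple(direction))
        if len(self.apex) != len(self.direction):
            raise ValueError("apex and direction dimensionality differ")
        if not (0.0 < self.aperture_phi <= np.pi / 2 + 1e-12):
            raise ValueError("aperture must satisfy 0 < phi <= pi/2")
        if self.radius_um <= 0:
            raise ValueError("cone radius must be positive")

    @property
    def ndim(self) -> int:
        return len(self.apex)


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive per-axis integer corner pair, possibly clipped to a
    lattice.  ``lower > upper`` on any axis marks an empty box (a cone
    clipped entirely outside the image)."""

    lower: tuple[int, ...]
    upper: tuple[int, ...]

    @property
    def is_empty(self) -> bool:
        return any(lo > hi for lo, hi in zip(self.lower, self.upper))


def _offsets_um(cone: ConeSpec, points: np.ndarray, spacing) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    apex = np.asarray(cone.apex, dtype=float)
    return (np.atleast_2d(points) - apex) * spacing


def cone_contains_many(cone: ConeSpec, points, spacing) -> np.ndarray:
    """Vectorized membership test for an (n, ndim) array of lattice points."""
    off = _offsets_um(cone, np.asarray(points, dtype=float), spacing)
    d = np.asarray(cone.direction)
    dist2 = np.sum(off * off, axis=1)
    dot = off @ d
    cos_half = np.cos(cone.aperture_phi / 2.0)
    # strict on both angle and distance; apex (dist 0) is excluded by dot<=0
    return (dot > 0) & (dist2 < cone.radius_um**2) & (dot * dot > cos_half**2 * dist2)


def cone_contains(cone: ConeSpec, p, spacing) -> bool:
    """True iff lattice position ``p`` lies strictly inside the vote cone."""
    p = np.asarray(p, dtype=float)
    if p.shape != (cone.ndim,):
        raise ValueError("point dimensionality does not match the cone")
    return bool(cone_contains_many(cone, p[None, :], spacing)[0])


def _axis_extent(d_i: float, cos_half: float, sin_half: float) -> tuple[float, float]:
    """Support of the unit cone+cap solid along +/- one coordinate axis.

    Returns nonnegative (lo, hi) such that the solid spans
    [-r*lo, +r*hi] about the apex on this axis.  The support along a unit
    axis e is r*cos(max(0, angle(d, e) - phi/2)), clamped at zero when the
    whole cap faces away (apex is then the extreme point).
    """
    s = np.sqrt(max(0.0, 1.0 - d_i * d_i))
    hi = 1.0 if d_i >= cos_half else d_i * cos_half + s * sin_half
    lo = 1.0 if -d_i >= cos_half else -d_i * cos_half + s * sin_half
    return max(0.0, lo), max(0.0, hi)


def cone_bounding_box(cone: ConeSpec, image_shape, spacing) -> BoundingBox:
    """Tight axis-aligned lattice bounding box of the cone solid.

    Pass ``image_shape=None`` for an unclipped box.  Every lattice site
    passing :func:`cone_contains` lies inside the returned box.
    """
    spacing = np.asarray(spacing, dtype=float)
    cos_half = np.cos(cone.aperture_phi / 2.0)
    sin_half = np.sin(cone.aperture_phi / 2.0)
    lower, upper = [], []
    eps = 1e-9
    for axis in range(cone.ndim):
        lo_f, hi_f = _axis_extent(cone.direction[axis], cos_half, sin_half)
        a = cone.apex[axis]
        lo = int(np.ceil(a - cone.radius_um * lo_f / spacing[axis] - eps))
        hi = int(np.floor(a + cone.radius_um * hi_f / spacing[axis] + eps))
        if image_shape is not None:
            lo = max(lo, 0)
            hi = min(hi, int(image_shape[axis]) - 1)
        lower.append(lo)
        upper.append(hi)
    return BoundingBox(tuple(lower), tuple(upper))


def cone_member_sites(cone: ConeSpec, image_shape, spacing) -> np.ndarray:
    """All lattice sites inside the cone, in lexicographic order.

    Enumerates the bounding box (clipped to ``image_shape`` unless None)
    and filters with the membership predicate.  Returns an (k, ndim) int
    array, possibly empty.
    """
    box = cone_bounding_box(cone, image_shape, spacing)
    if box.is_empty:
        return np.empty((0, cone.ndim), dtype=np.int64)
    axes = [np.arange(lo, hi + 1) for lo, hi in zip(box.lower, box.upper)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, cone.ndim)  # meshgrid 'ij' + reshape = lexicographic
    mask = cone_contains_many(cone, pts, spacing)
    return pts[mask]
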