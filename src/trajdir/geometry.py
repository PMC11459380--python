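"""Spherical geometry of trajectories.

A direction in N-dimensional attribute space is a point on the unit
(N-1)-sphere.  A path that proceeds in a well-defined direction projects,
relative to its starting point, onto a tight cluster of such directions.
This module projects paths onto the sphere and summarizes the cluster by an
optimal center and its radius (mean or maximum geodesic distance): a small
radius means strong directionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._sphere import solve_centers

__all__ = [
    "Path",
    "SphericalData",
    "DegeneratePathError",
    "project_to_sphere",
    "spherical_distance",
    "find_center",
    "path_to_spherical_data",
]

#: Points closer than this to the base point are dropped before projection.
COINCIDENCE_TOL = 1e-12

#: Statistics supported by :func:`find_center`.
STATISTICS = ("mean", "max")


class DegeneratePathError(ValueError):
    """Raised when every point of a (sub)path coincides with its base point."""


@dataclass
class Path:
    """An ordered sequence of points in attribute space.

    Parameters
    ----------
    points
        ``(m, N)`` array, one row per sampled cell/observation, ordered by
        pseudotime.  ``m >= 2``; all entries finite.
    point_labels
        Optional identifiers, one per row.
    from_idx, to_idx
        Optional default sub-path bounds (0-based, inclusive).
    """

    points: np.ndarray
    point_labels: Optional[Sequence[str]] = None
    from_idx: Optional[int] = None
    to_idx: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D (m, N) array")
        m = self.points.shape[0]
        if m < 2:
            raise ValueError(f"a path needs at least 2 points, got {m}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("path points must be finite")
        if self.point_labels is not None and len(self.point_labels) != m:
            raise ValueError("point_labels length must match point count")
        if (self.from_idx is None) != (self.to_idx is None):
            raise ValueError("set both from_idx and to_idx or neither")
        if self.from_idx is not None:
            self._check_bounds(self.from_idx, self.to_idx)

    def _check_bounds(self, from_idx: int, to_idx: int) -> None:
        m = self.points.shape[0]
        if not (0 <= from_idx < m and 0 <= to_idx < m):
            raise IndexError(
                f"sub-path bounds ({from_idx}, {to_idx}) outside [0, {m - 1}]")
        if from_idx >= to_idx:
            raise IndexError(
                f"from_idx ({from_idx}) must be < to_idx ({to_idx})")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_dims(self) -> int:
        return self.points.shape[1]

    def resolve_bounds(self, from_idx: Optional[int],
                       to_idx: Optional[int]) -> tuple[int, int]:
        """Fill missing bounds from the path's own, else the full range."""
        if from_idx is None:
            from_idx = self.from_idx if self.from_idx is not None else 0
        if to_idx is None:
            to_idx = (self.to_idx if self.to_idx is not None
                      else self.n_points - 1)
        self._check_bounds(from_idx, to_idx)
        return from_idx, to_idx


@dataclass
class SphericalData:
    """Unit-sphere projections of a path and their optimal center.

    ``radius`` is the minimized ``statistic`` ("mean" or "max") of geodesic
    distances from ``center`` to the projections, in radians.
    ``low_confidence`` flags point sets so dispersed that even the optimal
    center lies more than a quarter-turn from some projections on average
    (radius > pi/2): the "direction" is then not meaningful.
    """

    projections: np.ndarray
    center: np.ndarray
    radius: float
    statistic: str
    n_dropped: int = 0
    low_confidence: bool = False

    def distances(self) -> np.ndarray:
        """Geodesic distance from the center to each projection."""
        chord = np.linalg.norm(self.projections - self.center, axis=1)
        return 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


def _project(points: np.ndarray, from_idx: int,
             to_idx: int) -> tuple[np.ndarray, int]:
    base = points[from_idx]
    diffs = points[from_idx + 1:to_idx + 1] - base
    norms = np.linalg.norm(diffs, axis=1)
    keep = norms >= COINCIDENCE_TOL
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise DegeneratePathError(
            "all points coincide with the base point; the sub-path has no "
            "extent")
    return diffs[keep] / norms[keep, None], n_dropped


def project_to_sphere(path: Path, from_idx: Optional[int] = None,
                      to_idx: Optional[int] = None) -> np.ndarray:
    """Project the points of a (sub)path onto the unit sphere.

    Each point after the base (the first point of the sub-path) is mapped to
    the unit vector from the base toward it.  Points coincident with the
    base (distance < 1e-12) are silently dropped.

    Returns a ``(k, N)`` array of unit vectors.
    """
    from_idx, to_idx = path.resolve_bounds(from_idx, to_idx)
    proj, _ = _project(path.points, from_idx, to_idx)
    return proj


def spherical_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Geodesic (arc) distance between two unit vectors, in [0, pi]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    for name, vec in (("u", u), ("v", v)):
        nrm = np.linalg.norm(vec)
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a unit vector (norm {nrm:.3g})")
    return float(np.arccos(np.clip(u @ v, -1.0, 1.0)))


def find_center(projections: np.ndarray,
                statistic: str = "mean") -> tuple[np.ndarray, float]:
    """Optimal center direction and radius for a set of unit vectors.

    statistic="mean" minimizes the mean geodesic distance (spherical
    geometric median); statistic="max" minimizes the maximum geodesic
    distance (minimal enclosing spherical cap).
    """
    projections = np.atleast_2d(np.asarray(projections, dtype=float))
    if projections.shape[0] == 0:
        raise ValueError("find_center needs at least one projection")
    if statistic not in STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    center, radius = solve_centers(projections, statistic)
    return center, float(radius)


def path_to_spherical_data(path: Path, from_idx: Optional[int] = None,
                           to_idx: Optional[int] = None,
                           statistic: str = "mean") -> SphericalData:
    """Project a (sub)path and find its optimal center and radius."""
    from_idx, to_idx = path.resolve_bounds(from_idx, to_idx)
    proj, n_dropped = _project(path.points, from_idx, to_idx)
    center, radius = find_center(proj, statistic)
    return SphericalData(
        projections=proj,
        center=center,
        radius=radius,
        statistic=statistic,
        n_dropped=n_dropped,
        low_confidence=bool(radius > np.pi / 2 + 1e-9),
    )
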