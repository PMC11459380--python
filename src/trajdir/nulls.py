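"""Null models for trajectory directionality.

An observed radius means little on its own: sampled single-cell paths are
noisy, and even random walks have some apparent direction over a few steps.
The comparison population is a set of randomized paths derived from the
observed one — either by permuting each attribute column independently
across the path's steps (``byPermutation``: preserves the per-coordinate
value multisets) or by re-drawing every step direction uniformly on the
sphere while preserving the ordered step lengths (``bySteps``).  The
directionality P-value is the add-one rank of the observed radius within
the null radii.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._sphere import solve_centers
from .geometry import (COINCIDENCE_TOL, DegeneratePathError, Path,
                       path_to_spherical_data)

__all__ = [
    "RandomizationSpec",
    "DirectionalityTest",
    "randomize_by_permutation",
    "randomize_by_steps",
    "generate_random_paths",
    "p_value_for_radius",
    "test_path_for_directionality",
]

METHODS = ("byPermutation", "bySteps")


@dataclass
class RandomizationSpec:
    """How to build randomized comparison paths.

    method : "byPermutation" or "bySteps"
    seed : integer seed for the null-path generator
    """

    method: str = "byPermutation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown randomization method {self.method!r}; "
                f"choose from {METHODS}")


@dataclass
class DirectionalityTest:
    """Result of testing one path against its randomized nulls."""

    observed_radius: float
    null_radii: np.ndarray
    p_value: float
    statistic: str
    spec: RandomizationSpec
    center: np.ndarray
    n_dropped: int = 0


def randomize_by_permutation(path: Path, rng: np.random.Generator) -> Path:
    """Independently permute each attribute column across the path's rows."""
    pts = path.points
    out = np.empty_like(pts)
    for j in range(pts.shape[1]):
        out[:, j] = pts[rng.permutation(pts.shape[0]), j]
    return Path(points=out)


def randomize_by_steps(path: Path, rng: np.random.Generator) -> Path:
    """Keep the ordered step lengths, re-draw step directions uniformly.

    The output starts at the original first point; each consecutive step
    has the original length but an i.i.d. uniform direction on the sphere
    (a normalized standard Gaussian vector).  Zero-length steps stay zero.
    """
    pts = path.points
    steps = np.diff(pts, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    gauss = rng.standard_normal(steps.shape)
    norms = np.linalg.norm(gauss, axis=1, keepdims=True)
    dirs = gauss / np.maximum(norms, 1e-300)
    new_steps = lengths[:, None] * dirs
    out = np.vstack([pts[0], pts[0] + np.cumsum(new_steps, axis=0)])
    return Path(points=out)


def generate_random_paths(path: Path, spec: RandomizationSpec,
                          n_null: int = 1000) -> list[Path]:
    """Draw ``n_null`` independent randomizations of ``path`` (seeded)."""
    if n_null < 0:
        raise ValueError("n_null must be >= 0")
    rng = np.random.default_rng(spec.seed)
    if spec.method == "byPermutation":
        draw = randomize_by_permutation
    else:
        draw = randomize_by_steps
    return [draw(path, rng) for _ in range(n_null)]


def p_value_for_radius(observed: float,
                       null_radii: Sequence[float]) -> float:
    """Add-one rank P-value: (1 + #{null <= observed}) / (n_null + 1).

    Ties count toward the numerator (conservative); the P-value is never
    exactly zero.
    """
    null_radii = np.asarray(null_radii, dtype=float)
    if null_radii.size == 0:
        raise ValueError("null_radii must be non-empty")
    return float((1 + np.sum(null_radii <= observed))
                 / (null_radii.size + 1))


def _batched_radii(paths: list[Path], from_idx: int, to_idx: int,
                   statistic: str) -> np.ndarray:
    """Radii of many same-shape paths over a common index range.

    Projects every path relative to its own base point and solves all the
    spherical-center problems in vectorized batches (grouped by the number
    of surviving projections, since coincident points are dropped).
    """
    stack = np.stack([p.points for p in paths])          # (B, m, N)
    base = stack[:, from_idx:from_idx + 1, :]
    diffs = stack[:, from_idx + 1:to_idx + 1, :] - base  # (B, k, N)
    norms = np.linalg.norm(diffs, axis=2)
    keep = norms >= COINCIDENCE_TOL
    radii = np.empty(len(paths))
    counts = keep.sum(axis=1)
    if (counts == 0).any():
        raise DegeneratePathError(
            "a randomized path collapsed onto its base point")
    for k in np.unique(counts):
        idx = np.flatnonzero(counts == k)
        sel = np.empty((idx.size, k, stack.shape[2]))
        for i, b in enumerate(idx):
            m = keep[b]
            sel[i] = diffs[b, m] / norms[b, m, None]
        _, r = solve_centers(sel, statistic)
        radii[idx] = r
    return radii


def test_path_for_directionality(path: Path,
                                 from_idx: Optional[int] = None,
                                 to_idx: Optional[int] = None,
                                 statistic: str = "mean",
                                 spec: Optional[RandomizationSpec] = None,
                                 n_null: int = 1000) -> DirectionalityTest:
    """Test whether a (sub)path proceeds in a well-defined direction.

    The observed radius comes from the spherical projection of the sub-path;
    the null radii from the identical computation applied to each randomized
    path over the same index range, so the comparison is like-for-like.
    """
    if spec is None:
        spec = RandomizationSpec()
    from_idx, to_idx = path.resolve_bounds(from_idx, to_idx)
    sd = path_to_spherical_data(path, from_idx, to_idx, statistic)
    nulls = generate_random_paths(path, spec, n_null)
    null_radii = _batched_radii(nulls, from_idx, to_idx, statistic)
    p = p_value_for_radius(sd.radius, null_radii)
    return DirectionalityTest(
        observed_radius=sd.radius,
        null_radii=null_radii,
        p_value=p,
        statistic=statistic,
        spec=spec,
        center=sd.center,
        n_dropped=sd.n_dropped,
    )
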