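"""Trajectory-level directionality analysis.

A pseudotemporally ordered cell ensemble is not itself a path: cells
scatter around the underlying trajectory.  The analysis therefore samples
many discrete paths (one random cell per pseudotime window), tests each for
directionality against its own randomized nulls, and aggregates.  A scan
over successively later pseudotime start points distinguishes branching
from bifurcation: an arm that merely *branches off* a straight default
trajectory becomes more directional (smaller radius, more significant) as
the start approaches its departure point, while the default arm is
directional throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .geometry import Path
from .nulls import (DirectionalityTest, RandomizationSpec,
                    test_path_for_directionality)

__all__ = [
    "CellEnsemble",
    "TrajectoryResult",
    "BranchScan",
    "SamplingError",
    "sample_path",
    "analyse_trajectory",
    "compare_trajectories",
    "branch_point_scan",
]


class SamplingError(RuntimeError):
    """Raised when an ensemble cannot supply enough windows for a path."""


@dataclass
class CellEnsemble:
    """Cells x features matrix with a per-cell pseudotime.

    ``attributes`` rows are cells, columns are features (principal
    components or log-normalized genes).  Pseudotime is an input, never
    inferred here.
    """

    attributes: np.ndarray
    pseudotime: np.ndarray
    cell_ids: Optional[Sequence[str]] = None
    feature_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.attributes = np.asarray(self.attributes, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if self.attributes.ndim != 2:
            raise ValueError("attributes must be a 2-D (cells, features) "
                             "array")
        c = self.attributes.shape[0]
        if self.pseudotime.shape != (c,):
            raise ValueError(
                f"pseudotime length {self.pseudotime.shape} does not match "
                f"{c} cells")
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValueError("pseudotime must be finite")
        if c and self.pseudotime.max() <= self.pseudotime.min():
            raise ValueError("pseudotime must be non-constant")
        if self.cell_ids is not None and len(self.cell_ids) != c:
            raise ValueError("cell_ids length mismatch")
        if (self.feature_ids is not None
                and len(self.feature_ids) != self.attributes.shape[1]):
            raise ValueError("feature_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.attributes.shape[0]

    @property
    def n_features(self) -> int:
        return self.attributes.shape[1]

    def truncated(self, first_k: int) -> "CellEnsemble":
        """Restrict to the first ``first_k`` feature columns."""
        if not 1 <= first_k <= self.n_features:
            raise ValueError(
                f"first_k_components {first_k} outside [1, "
                f"{self.n_features}]")
        fids = (None if self.feature_ids is None
                else list(self.feature_ids)[:first_k])
        return CellEnsemble(self.attributes[:, :first_k], self.pseudotime,
                            self.cell_ids, fids)

    def restricted(self, min_pseudotime: float) -> "CellEnsemble":
        """Keep cells with pseudotime >= ``min_pseudotime``."""
        mask = self.pseudotime >= min_pseudotime
        cids = (None if self.cell_ids is None
                else [c for c, m in zip(self.cell_ids, mask) if m])
        return CellEnsemble(self.attributes[mask], self.pseudotime[mask],
                            cids, self.feature_ids)


@dataclass
class TrajectoryResult:
    """Aggregate of many sampled-path directionality tests."""

    per_path_tests: list[DirectionalityTest]
    sampled_radii: np.ndarray
    pooled_null_radii: np.ndarray
    aggregate_p: float
    centers: np.ndarray
    parameters: dict

    @property
    def median_radius(self) -> float:
        return float(np.median(self.sampled_radii))

    @property
    def mean_center(self) -> np.ndarray:
        """Normalized Euclidean mean of the per-path centers."""
        m = self.centers.mean(axis=0)
        return m / np.linalg.norm(m)


@dataclass
class BranchScan:
    """Directionality summaries over successively later pseudotime starts."""

    start_values: np.ndarray
    start_fractions: np.ndarray
    median_radii: np.ndarray
    aggregate_ps: np.ndarray
    neg_log10_ps: np.ndarray
    results: list[Optional[TrajectoryResult]]
    skipped: dict = field(default_factory=dict)


def sample_path(ensemble: CellEnsemble, n_windows: int,
                rng: np.random.Generator) -> Path:
    """Sample one path: one random cell from each pseudotime window.

    The pseudotime range is split into ``n_windows`` equal-width half-open
    windows (the last closed on the right); from each non-empty window one
    cell is drawn uniformly and the chosen cells are ordered by window.
    Empty windows are skipped; fewer than 3 non-empty windows is an error.
    """
    if n_windows < 3:
        raise ValueError("n_windows must be >= 3")
    t = ensemble.pseudotime
    tmin, tmax = t.min(), t.max()
    width = (tmax - tmin) / n_windows
    win = np.minimum(((t - tmin) / width).astype(int), n_windows - 1)
    chosen: list[int] = []
    labels: list[str] = []
    usable = 0
    for w in range(n_windows):
        members = np.flatnonzero(win == w)
        if members.size == 0:
            continue
        usable += 1
        pick = int(members[rng.integers(members.size)])
        chosen.append(pick)
        if ensemble.cell_ids is not None:
            labels.append(ensemble.cell_ids[pick])
    if usable < 3:
        raise SamplingError(
            f"only {usable} non-empty pseudotime windows (need >= 3)")
    return Path(points=ensemble.attributes[chosen],
                point_labels=labels or None)


def analyse_trajectory(ensemble: CellEnsemble,
                       n_samples: int = 1000,
                       n_windows: int = 10,
                       statistic: str = "mean",
                       method: str = "byPermutation",
                       n_null: int = 1000,
                       first_k_components: Optional[int] = None,
                       seed: int = 0) -> TrajectoryResult:
    """Sample paths from the ensemble and test each for directionality.

    The aggregate P-value is the median of the per-path P-values; the full
    radius and null-radius distributions are retained for violin-style
    reporting and trajectory comparison.
    """
    if first_k_components is not None:
        ensemble = ensemble.truncated(first_k_components)
    rng = np.random.default_rng(seed)
    tests: list[DirectionalityTest] = []
    for _ in range(n_samples):
        path = sample_path(ensemble, n_windows, rng)
        null_seed = int(rng.integers(2**31))
        spec = RandomizationSpec(method=method, seed=null_seed)
        tests.append(test_path_for_directionality(
            path, statistic=statistic, spec=spec, n_null=n_null))
    if not tests:
        raise SamplingError("no paths were sampled (n_samples = 0)")
    radii = np.array([t.observed_radius for t in tests])
    pvals = np.array([t.p_value for t in tests])
    return TrajectoryResult(
        per_path_tests=tests,
        sampled_radii=radii,
        pooled_null_radii=np.concatenate([t.null_radii for t in tests]),
        aggregate_p=float(np.median(pvals)),
        centers=np.array([t.center for t in tests]),
        parameters={
            "n_samples": n_samples,
            "n_windows": n_windows,
            "statistic": statistic,
            "method": method,
            "n_null": n_null,
            "first_k_components": first_k_components,
            "seed": seed,
        },
    )


def compare_trajectories(result_a: TrajectoryResult,
                         result_b: TrajectoryResult) -> dict:
    """Two-sided rank-sum comparison of two sampled-radius distributions.

    Returns the Mann-Whitney U statistic, its P-value, and which input has
    the smaller median radius (i.e. the more directional trajectory).
    """
    ra, rb = result_a.sampled_radii, result_b.sampled_radii
    if ra.size == 0 or rb.size == 0:
        raise ValueError("both results must contain sampled radii")
    u, p = stats.mannwhitneyu(ra, rb, alternative="two-sided")
    med_a, med_b = np.median(ra), np.median(rb)
    if med_a < med_b:
        direction = "a"
    elif med_b < med_a:
        direction = "b"
    else:
        direction = "tie"
    return {"statistic": float(u), "p_value": float(p),
            "smaller_median": direction,
            "median_a": float(med_a), "median_b": float(med_b)}


def branch_point_scan(ensemble: CellEnsemble,
                      start_fractions: Optional[Sequence[float]] = None,
                      **analyse_kwargs) -> BranchScan:
    """Re-analyse the trajectory from successively later pseudotime starts.

    For each fraction f the threshold is min_pt + f * (max_pt - min_pt);
    cells before the threshold are discarded and the pseudotime windows are
    recomputed on the restricted range, keeping path lengths comparable
    across starts.  Starts that leave too few cells are skipped with a
    recorded reason rather than failing the whole scan.
    """
    if start_fractions is None:
        start_fractions = np.arange(0.0, 0.51, 0.05)
    start_fractions = np.asarray(list(start_fractions), dtype=float)
    if start_fractions.size and np.any(np.diff(start_fractions) <= 0):
        raise ValueError("start_fractions must be strictly increasing")
    if np.any((start_fractions < 0) | (start_fractions >= 1)):
        raise ValueError("start_fractions must lie in [0, 1)")
    tmin, tmax = ensemble.pseudotime.min(), ensemble.pseudotime.max()
    start_values, med, aggp, results = [], [], [], []
    skipped: dict = {}
    for f in start_fractions:
        threshold = tmin + f * (tmax - tmin)
        try:
            sub = ensemble.restricted(threshold)
            res = analyse_trajectory(sub, **analyse_kwargs)
        except (SamplingError, ValueError) as exc:
            skipped[float(f)] = str(exc)
            results.append(None)
            start_values.append(threshold)
            med.append(np.nan)
            aggp.append(np.nan)
            continue
        results.append(res)
        start_values.append(threshold)
        med.append(res.median_radius)
        aggp.append(res.aggregate_p)
    aggp_arr = np.array(aggp)
    return BranchScan(
        start_values=np.array(start_values),
        start_fractions=start_fractions,
        median_radii=np.array(med),
        aggregate_ps=aggp_arr,
        neg_log10_ps=-np.log10(aggp_arr),
        results=results,
        skipped=skipped,
    )
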