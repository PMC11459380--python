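"""Synthetic cell ensembles with known trajectory geometry.

Three generative models cover the hypotheses the analysis is meant to
distinguish, plus a null substrate for calibration:

* **branching** — a straight default arm along direction ``u``; a branch
  arm that follows ``u`` up to a per-cell departure point and then travels
  along ``v``.  With ``branch_region_width = 0`` all branch cells depart at
  the same decision point; with a positive width the departure points are
  drawn uniformly from a region around it.
* **bifurcation** — a shared progenitor trunk along ``u`` up to the
  decision point, after which two arms depart symmetrically about ``u``.
* **null** — i.i.d. Gaussian attributes with pseudotime independent of
  them; no directionality signal at all.

Pseudotime is the ground-truth normalized arc-length position along each
cell's own backbone (never re-inferred), and isotropic Gaussian noise is
added around the piecewise-linear backbones.  All generators are pure
functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .analysis import CellEnsemble
from .geometry import Path

__all__ = [
    "SyntheticSpec",
    "LabelledEnsemble",
    "make_branching",
    "make_bifurcation",
    "make_null_ensemble",
    "make_straight_path",
    "select_arm",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic branching / bifurcation generators.

    Each cell's backbone has total arc length ``arm_length`` in attribute
    units, and ``noise_sd`` is the isotropic per-coordinate dispersion
    around it in the same units; only their ratio matters downstream
    (every analysis statistic is scale invariant).  The defaults describe
    tight tubes around long arms — trajectories an order of magnitude
    longer than the within-stage scatter.
    """

    n_cells_per_arm: int = 500
    n_dims: int = 3
    dp_fraction: float = 0.5
    branch_region_width: float = 0.0
    angle_between_arms: float = np.pi / 2
    noise_sd: float = 0.1
    arm_length: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_arm < 1:
            raise ValueError("n_cells_per_arm must be >= 1")
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        if not 0.0 < self.dp_fraction < 1.0:
            raise ValueError("dp_fraction must lie in (0, 1)")
        if self.branch_region_width < 0:
            raise ValueError("branch_region_width must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabelledEnsemble:
    """A CellEnsemble with per-cell arm labels and backbone positions."""

    ensemble: CellEnsemble
    labels: np.ndarray          # default | branch | progenitor | arm1 | arm2
    backbone_positions: np.ndarray  # ground truth, in [0, 1]
    spec: Optional[SyntheticSpec] = None
    model: str = ""


def _arm_directions(n_dims: int, angle: float,
                    symmetric: bool) -> tuple[np.ndarray, ...]:
    # Oblique (non-axis-aligned) directions: a real trajectory is
    # generically oblique to the attribute axes, and an axis-aligned
    # backbone would make the column-permutation null degenerate (every
    # off-axis column constant, hence invariant under permutation).
    u = np.ones(n_dims) / np.sqrt(n_dims)
    e1 = np.zeros(n_dims)
    e1[0] = 1.0
    perp = e1 - (e1 @ u) * u
    perp /= np.linalg.norm(perp)
    if symmetric:
        half = angle / 2.0
        v1 = np.cos(half) * u + np.sin(half) * perp
        v2 = np.cos(half) * u - np.sin(half) * perp
        return u, v1, v2
    return u, np.cos(angle) * u + np.sin(angle) * perp


#: Post-departure backbone length, as a fraction of ``arm_length``.  A cell
#: that branches off initiates a complete new expression programme, so its
#: new leg spans a full arm length regardless of where it departed.
POST_DEPARTURE_LENGTH = 1.0


def make_branching(spec: SyntheticSpec) -> LabelledEnsemble:
    """Default arm straight along u; branch arm departs along v.

    Branch-arm departure points are drawn uniformly from
    ``[dp_fraction - w/2, dp_fraction + w/2]`` along the *default* backbone
    (clipped away from 0 and 1); width 0 collapses the region to a single
    decision point.  After departing, a branch cell travels a further
    ``POST_DEPARTURE_LENGTH * arm_length`` along v, and its pseudotime is
    the normalized arc-length position along its own (longer) backbone.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_cells_per_arm, spec.n_dims
    u, v = _arm_directions(d, spec.angle_between_arms, symmetric=False)

    a_def = rng.uniform(0.0, 1.0, size=n)
    pos_def = a_def[:, None] * u
    pt_def = a_def

    w = spec.branch_region_width
    lo = np.clip(spec.dp_fraction - w / 2.0, 1e-6, 1.0 - 1e-6)
    hi = np.clip(spec.dp_fraction + w / 2.0, 1e-6, 1.0 - 1e-6)
    dep = (rng.uniform(lo, hi, size=n) if w > 0
           else np.full(n, spec.dp_fraction))
    total = dep + POST_DEPARTURE_LENGTH
    a_br = rng.uniform(0.0, total)            # arc position, own backbone
    along_u = np.minimum(a_br, dep)
    along_v = np.maximum(0.0, a_br - dep)
    pos_br = along_u[:, None] * u + along_v[:, None] * v
    pt_br = a_br / total

    coords = np.vstack([pos_def, pos_br]) * spec.arm_length
    coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    pseudotime = np.concatenate([pt_def, pt_br])
    labels = np.array(["default"] * n + ["branch"] * n)
    cell_ids = [f"cell{i:05d}" for i in range(2 * n)]
    feature_ids = [f"dim{j + 1}" for j in range(d)]
    ens = CellEnsemble(coords, pseudotime.copy(), cell_ids, feature_ids)
    return LabelledEnsemble(ens, labels, pseudotime, spec, model="branching")


def make_bifurcation(spec: SyntheticSpec) -> LabelledEnsemble:
    """Shared trunk to the decision point; two symmetric arms beyond it.

    Both post-decision legs span ``POST_DEPARTURE_LENGTH * arm_length``
    (each outcome unfolds a complete new programme), mirroring the
    branch-arm convention of :func:`make_branching`.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_cells_per_arm, spec.n_dims
    dp = spec.dp_fraction
    total = dp + POST_DEPARTURE_LENGTH
    u, v1, v2 = _arm_directions(d, spec.angle_between_arms, symmetric=True)

    a_pro = rng.uniform(0.0, dp, size=n)
    pos_pro = a_pro[:, None] * u
    a1 = rng.uniform(dp, total, size=n)
    pos1 = dp * u + (a1 - dp)[:, None] * v1
    a2 = rng.uniform(dp, total, size=n)
    pos2 = dp * u + (a2 - dp)[:, None] * v2

    coords = np.vstack([pos_pro, pos1, pos2]) * spec.arm_length
    coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    pseudotime = np.concatenate([a_pro, a1, a2]) / total
    labels = np.array(["progenitor"] * n + ["arm1"] * n + ["arm2"] * n)
    cell_ids = [f"cell{i:05d}" for i in range(3 * n)]
    feature_ids = [f"dim{j + 1}" for j in range(d)]
    ens = CellEnsemble(coords, pseudotime.copy(), cell_ids, feature_ids)
    return LabelledEnsemble(ens, labels, pseudotime, spec,
                            model="bifurcation")


def make_null_ensemble(n_cells: int, n_dims: int,
                       seed: int = 0) -> LabelledEnsemble:
    """I.i.d. Gaussian attributes, pseudotime independent of them."""
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((n_cells, n_dims))
    pt = rng.uniform(0.0, 1.0, size=n_cells)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    feature_ids = [f"dim{j + 1}" for j in range(n_dims)]
    ens = CellEnsemble(coords, pt, cell_ids, feature_ids)
    return LabelledEnsemble(ens, np.array(["default"] * n_cells),
                            pt.copy(), None, model="null")


def make_straight_path(n_points: int, n_dims: int,
                       direction: Optional[Sequence[float]] = None,
                       step: float = 1.0, noise_sd: float = 0.0,
                       seed: int = 0) -> Path:
    """Evenly spaced points along one direction, plus optional noise."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if direction is None:
        direction = np.zeros(n_dims)
        direction[0] = 1.0
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-300:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / nrm
    pts = np.arange(n_points)[:, None] * step * direction[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return Path(points=pts)


def select_arm(labelled: LabelledEnsemble, arm: str) -> CellEnsemble:
    """Extract the cell ensemble of one arm's full trajectory.

    For the branching model each arm's cells carry its whole trajectory
    (branch cells travel along the trunk before departing), so ``default``
    and ``branch`` select by label.  For the bifurcation model the trunk is
    shared: ``arm1`` / ``arm2`` include the progenitor cells.
    """
    ens = labelled.ensemble
    if arm in ("default", "branch"):
        mask = labelled.labels == arm
    elif arm in ("arm1", "arm2"):
        mask = (labelled.labels == arm) | (labelled.labels == "progenitor")
    else:
        raise ValueError(f"unknown arm {arm!r}")
    if not mask.any():
        raise ValueError(f"no cells labelled for arm {arm!r}")
    cids = (None if ens.cell_ids is None
            else [c for c, m in zip(ens.cell_ids, mask) if m])
    return CellEnsemble(ens.attributes[mask], ens.pseudotime[mask],
                        cids, ens.feature_ids)
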