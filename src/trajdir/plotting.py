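"""Diagnostic plots: sphere projections, radius violins, scan lines."""

from __future__ import annotations

import logging
from pathlib import Path as FilePath
from typing import Optional

import numpy as np
import matplotlib
import matplotlib.pyplot as plt

from .analysis import BranchScan, TrajectoryResult
from .geometry import SphericalData

logger = logging.getLogger("trajdir")

__all__ = [
    "plot_sphere_projections",
    "plot_radius_violins",
    "plot_scan",
    "plot_diagnostics",
]


def _circle_about(center: np.ndarray, radius: float,
                  n: int = 200) -> np.ndarray:
    """Points at geodesic distance ``radius`` around ``center`` on S^2."""
    # Orthonormal basis of the tangent plane at the center.
    a = np.array([1.0, 0.0, 0.0])
    if abs(center @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = a - (a @ center) * center
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(center, e1)
    t = np.linspace(0, 2 * np.pi, n)
    return (np.cos(radius) * center[None, :]
            + np.sin(radius) * (np.cos(t)[:, None] * e1[None, :]
                                + np.sin(t)[:, None] * e2[None, :]))


def plot_sphere_projections(sd: SphericalData, out_path) -> Optional[str]:
    """3-D view of projections on the 2-sphere with center and radius circle.

    Only meaningful in a 3-dimensional analysis space; higher dimensions
    are skipped with a log note.
    """
    if sd.projections.shape[1] != 3:
        logger.info("sphere panel skipped: analysis dimension is %d, not 3",
                    sd.projections.shape[1])
        return None
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="3d")
    phi, theta = np.mgrid[0:np.pi:15j, 0:2 * np.pi:30j]
    ax.plot_wireframe(np.sin(phi) * np.cos(theta),
                      np.sin(phi) * np.sin(theta), np.cos(phi),
                      color="lightgray", linewidth=0.3)
    p = sd.projections
    ax.scatter(p[:, 0], p[:, 1], p[:, 2], s=12, c="steelblue",
               depthshade=False, label="projections")
    c = sd.center
    ax.scatter([c[0]], [c[1]], [c[2]], s=60, c="red", label="center")
    if sd.radius > 1e-12:
        ring = _circle_about(c, sd.radius)
        ax.plot(ring[:, 0], ring[:, 1], ring[:, 2], c="k", lw=1.0,
                label=f"{sd.statistic} radius = {sd.radius:.3f} rad")
    ax.set_box_aspect((1, 1, 1))
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return str(out_path)


def plot_radius_violins(result: TrajectoryResult, out_path) -> str:
    """Sampled-path radii next to the pooled null radii."""
    fig, ax = plt.subplots(figsize=(4, 4))
    data = [result.sampled_radii, result.pooled_null_radii]
    parts = ax.violinplot(data, showmedians=True)
    for body, color in zip(parts["bodies"], ("mediumpurple", "lightgray")):
        body.set_facecolor(color)
    ax.set_xticks([1, 2], ["sampled", "random"])
    ax.set_ylabel("spherical radius (rad)")
    ax.set_title(f"aggregate P = {result.aggregate_p:.4g}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return str(out_path)


def plot_scan(scan: BranchScan, out_path) -> str:
    """-log10 aggregate P against the scan's pseudotime start values."""
    ok = ~np.isnan(scan.aggregate_ps)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x, y = scan.start_values[ok], scan.neg_log10_ps[ok]
    ax.plot(x, y, marker="o", color="darkorange")
    ax.set_xlabel("pseudotime start")
    ax.set_ylabel(r"$-\log_{10}$(aggregate P)")
    ax2 = ax.twinx()
    ax2.plot(x, scan.median_radii[ok], marker="s", color="steelblue",
             alpha=0.6)
    ax2.set_ylabel("median radius (rad)", color="steelblue")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return str(out_path)


def plot_diagnostics(result: Optional[TrajectoryResult] = None,
                     scan: Optional[BranchScan] = None,
                     out_dir=".", prefix: str = "trajdir",
                     fmt: str = "png") -> list[str]:
    """Emit every panel the supplied objects support; returns file paths."""
    out_dir = FilePath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    if result is not None:
        if result.centers.shape[1] == 3 and result.per_path_tests:
            t = result.per_path_tests[0]
            sd = SphericalData(
                projections=np.array([c for c in result.centers]),
                center=result.mean_center,
                radius=float(result.median_radius),
                statistic=result.parameters.get("statistic", "mean"),
            )
            f = plot_sphere_projections(sd, out_dir / f"{prefix}_sphere.{fmt}")
            if f:
                files.append(f)
        files.append(plot_radius_violins(
            result, out_dir / f"{prefix}_radii.{fmt}"))
    if scan is not None:
        files.append(plot_scan(scan, out_dir / f"{prefix}_scan.{fmt}"))
    return files
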