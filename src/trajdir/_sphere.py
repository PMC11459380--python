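"""Batched solvers for the spherical center problems.

Two summaries of how tightly a set of unit vectors clusters are supported:

* ``mean`` — the spherical geometric median: the unit vector minimizing the
  mean geodesic (arc) distance to the points.
* ``max`` — the center of the minimal enclosing spherical cap: the unit
  vector minimizing the maximum geodesic distance.

Both objectives are non-convex once the points spread beyond a hemisphere,
so each solver refines a small set of starting candidates (the normalized
Euclidean mean plus every data point) and keeps the best.  Solvers operate
on a batch of point sets of identical shape ``(B, k, N)`` so the many
randomized comparison paths of a permutation test are handled in one
vectorized pass.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

_EPS = 1e-12


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def _geodesic_all(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Geodesic distances, points (B,k,N) against centers (B,N) -> (B,k).

    Computed from the chord length, 2*arcsin(||x - c|| / 2), which keeps
    full precision for nearly coincident directions where arccos of the
    inner product loses ~8 digits.
    """
    chord = np.linalg.norm(points - centers[..., None, :], axis=-1)
    return 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


def _retract(c: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Exponential map on the sphere: move from c along tangent step."""
    snorm = np.linalg.norm(step, axis=-1, keepdims=True)
    unit = step / np.maximum(snorm, _EPS)
    return _normalize_rows(np.cos(snorm) * c + np.sin(snorm) * unit)


def _mean_inits(points: np.ndarray) -> np.ndarray:
    """Candidate starts: normalized Euclidean mean, then each point."""
    c = points.mean(axis=1)
    nrm = np.linalg.norm(c, axis=-1, keepdims=True)
    bad = nrm[:, 0] < 1e-9
    if np.any(bad):
        c = c.copy()
        c[bad] = points[bad, 0]
        nrm = np.linalg.norm(c, axis=-1, keepdims=True)
    return np.concatenate([(c / nrm)[:, None, :], points], axis=1)


def _expand_starts(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Tile each point set once per candidate start."""
    inits = _mean_inits(points)                    # (B, S, N)
    B, S, N = inits.shape
    k = points.shape[1]
    rep = np.repeat(points, S, axis=0)             # (B*S, k, N)
    return rep, inits.reshape(B * S, N), S


def _weiszfeld(points: np.ndarray, c: np.ndarray, tol: float,
               max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Damped Riemannian Weiszfeld descent from the given starts.

    Update direction: weighted mean of the tangent-space logarithms of the
    points (weights 1/distance), retracted along the exponential map; the
    tangent step is halved while the objective fails to decrease.  Stops
    when the mean distance improves by less than ``tol``.
    """
    B = points.shape[0]
    d = _geodesic_all(points, c)
    radius = d.mean(axis=1)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        ca, pa, da = c[active], points[active], d[active]
        dots = np.clip(np.einsum("bkn,bn->bk", pa, ca), -1.0, 1.0)
        tang = pa - dots[..., None] * ca[:, None, :]
        tnorm = np.linalg.norm(tang, axis=-1)            # = sin(distance)
        unit = tang / np.maximum(tnorm, _EPS)[..., None]
        w = 1.0 / np.maximum(da, 1e-9)
        step = unit.sum(axis=1) / w.sum(axis=1)[:, None]
        new_c = _retract(ca, step)
        new_d = _geodesic_all(pa, new_c)
        new_r = new_d.mean(axis=1)
        worse = new_r > radius[active]
        halvings = 0
        while worse.any() and halvings < 30:
            step[worse] *= 0.5
            cand = _retract(ca[worse], step[worse])
            new_c[worse] = cand
            nd = _geodesic_all(pa[worse], cand)
            new_d[worse] = nd
            new_r[worse] = nd.mean(axis=1)
            worse = new_r > radius[active]
            halvings += 1
        improved = radius[active] - new_r
        idx = np.flatnonzero(active)
        c[idx], d[idx] = new_c, new_d
        radius[idx] = new_r
        active[idx] = improved > tol
    return c, radius


def mean_center(points: np.ndarray, tol: float = 1e-12,
                max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Spherical geometric median of each point set in the batch.

    Returns ``(centers (B,N), radii (B,))`` (squeezed if the input was a
    single ``(k, N)`` set).
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 2
    if squeeze:
        pts = pts[None]
    B, k, N = pts.shape
    rep, starts, S = _expand_starts(pts)
    c, radius = _weiszfeld(rep, starts, tol, max_iter)
    c = c.reshape(B, S, N)
    radius = radius.reshape(B, S)
    best = _first_within_tol(radius)
    c_best = c[np.arange(B), best]
    r_best = radius[np.arange(B), best]
    if squeeze:
        return c_best[0], r_best[0]
    return c_best, r_best


def _first_within_tol(radius: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Earliest start within tol of each row's optimum.

    Start 0 is the normalized Euclidean mean, so exact ties between
    multiple optima are broken deterministically in its favor.
    """
    return np.argmax(radius <= radius.min(axis=1, keepdims=True) + tol,
                     axis=1)


def _badoiu_clarkson(points: np.ndarray, c: np.ndarray,
                     n_iter: int) -> np.ndarray:
    """Geodesic step toward the farthest point with a 1/(k+1) schedule."""
    B = points.shape[0]
    rows = np.arange(B)
    for it in range(n_iter):
        d = _geodesic_all(points, c)
        far = d.argmax(axis=1)
        dmax = d[rows, far]
        xf = points[rows, far]
        dots = np.clip(np.einsum("bn,bn->b", xf, c), -1.0, 1.0)
        tang = xf - dots[:, None] * c
        tnorm = np.linalg.norm(tang, axis=-1, keepdims=True)
        unit = tang / np.maximum(tnorm, _EPS)
        c = _retract(c, (dmax / (it + 2.0))[:, None] * unit)
    return c


def _softmax_refine(x: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Minimize a softmax upper bound of the max distance from c0."""
    def obj(v):
        nrm = np.linalg.norm(v)
        if nrm < 1e-9:
            return np.pi
        d = np.arccos(np.clip(x @ (v / nrm), -1.0, 1.0))
        return logsumexp(200.0 * d) / 200.0
    res = minimize(obj, c0, method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-8, "fatol": 1e-10})
    v = res.x
    nrm = np.linalg.norm(v)
    return c0 if nrm < 1e-9 else v / nrm


def _polish_max(x: np.ndarray, c0: np.ndarray,
                r0: float) -> tuple[np.ndarray, float]:
    """SLSQP solve of ``maximize t s.t. X c >= t, ||c|| <= 1``.

    This convex program is exactly the minimal-cap problem whenever the
    optimal cap is smaller than a hemisphere; outside that regime the warm
    start is simply kept if the polish does not improve.
    """
    n = x.shape[1]
    z0 = np.concatenate([c0, [np.cos(r0)]])
    cons = [
        {"type": "ineq",
         "fun": lambda z: x @ z[:n] - z[-1],
         "jac": lambda z: np.hstack([x, -np.ones((x.shape[0], 1))])},
        {"type": "ineq",
         "fun": lambda z: 1.0 - z[:n] @ z[:n],
         "jac": lambda z: np.hstack([-2.0 * z[:n], [0.0]])},
    ]
    grad = np.zeros(n + 1)
    grad[-1] = -1.0
    try:
        res = minimize(lambda z: -z[-1], z0, jac=lambda z: grad,
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 200, "ftol": 1e-14})
    except Exception:
        return c0, r0
    cand = res.x[:n]
    nrm = np.linalg.norm(cand)
    if not np.isfinite(nrm) or nrm < 1e-6:
        return c0, r0
    cand = cand / nrm
    r = float(_geodesic_all(x[None], cand[None]).max())
    return (cand, r) if r < r0 else (c0, r0)


def max_center(points: np.ndarray,
               bc_iters: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Center of the minimal enclosing spherical cap for each point set."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 2
    if squeeze:
        pts = pts[None]
    B, k, N = pts.shape
    rep, starts, S = _expand_starts(pts)
    c = _badoiu_clarkson(rep, starts, bc_iters)
    radius = _geodesic_all(rep, c).max(axis=1)
    c = c.reshape(B, S, N)
    radius = radius.reshape(B, S)
    best = _first_within_tol(radius, tol=1e-7)
    c_best = c[np.arange(B), best].copy()
    r_best = radius[np.arange(B), best].copy()
    for b in range(B):
        cb, rb = _polish_max(pts[b], c_best[b], r_best[b])
        if rb >= np.pi / 2 - 1e-6 or rb > r_best[b] - 1e-12:
            cs = _softmax_refine(pts[b], c_best[b])
            rs = float(_geodesic_all(pts[b][None], cs[None]).max())
            if rs < rb:
                cb, rb = cs, rs
            cb, rb = _polish_max(pts[b], cb, min(rb, r_best[b]))
        if rb < r_best[b]:
            c_best[b], r_best[b] = cb, rb
    if squeeze:
        return c_best[0], r_best[0]
    return c_best, r_best


def solve_centers(points: np.ndarray, statistic: str,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the solver for ``statistic`` in {"mean", "max"}."""
    if statistic == "mean":
        return mean_center(points)
    if statistic == "max":
        return max_center(points)
    raise ValueError(f"unknown statistic {statistic!r}; use 'mean' or 'max'")
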