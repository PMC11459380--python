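import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def sphere_grid(step_deg: float = 2.0) -> np.ndarray:
    """Dense grid of unit vectors on S^2 for brute-force center search."""
    theta = np.deg2rad(np.arange(0.0, 180.0 + 1e-9, step_deg))
    phi = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    T, P = np.meshgrid(theta, phi, indexing="ij")
    return np.stack([np.sin(T) * np.cos(P),
                     np.sin(T) * np.sin(P),
                     np.cos(T)], axis=-1).reshape(-1, 3)


def grid_search_center(points: np.ndarray, statistic: str,
                       step_deg: float = 2.0):
    """Independent brute-force oracle for the optimal spherical center."""
    grid = sphere_grid(step_deg)
    d = np.arccos(np.clip(grid @ points.T, -1.0, 1.0))
    vals = d.mean(axis=1) if statistic == "mean" else d.max(axis=1)
    i = int(vals.argmin())
    return grid[i], float(vals[i])


@pytest.fixture
def grid_oracle():
    return grid_search_center
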