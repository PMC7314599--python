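"""Separable Matern(space) x AR1(time) Gaussian-process utilities.

Shared between the truth-surface simulator and the geostatistical model so that
the forward model and the fitted model use the same covariance family.  Matern
smoothness is fixed at nu = 3/2 throughout (once-differentiable fields with a
closed-form correlation), which is the common default for prevalence mapping.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "matern32_correlation",
    "ar1_correlation",
    "grid_coords",
    "sample_separable_field",
]

SQRT3 = np.sqrt(3.0)


def matern32_correlation(coords: np.ndarray, range_: float) -> np.ndarray:
    """Matern nu=3/2 correlation matrix for points ``coords`` (n x d).

    ``range_`` uses the same length unit as ``coords``; correlation at distance
    d is (1 + sqrt(3) d / range) * exp(-sqrt(3) d / range).
    """
    if range_ <= 0:
        raise ValueError(f"spatial range must be positive, got {range_}")
    d = cdist(coords, coords) * (SQRT3 / range_)
    return (1.0 + d) * np.exp(-d)


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix rho^{|i-j|} over ``n`` time points."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"temporal rho must lie in (-1, 1), got {rho}")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def grid_coords(nrows: int, ncols: int) -> np.ndarray:
    """Cell-centroid coordinates in cell units, row-major from the NW corner."""
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _eigh_clipped(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(mat)
    return np.clip(vals, 0.0, None), vecs


def sample_separable_field(
    coords: np.ndarray,
    n_times: int,
    spatial_range: float,
    spatial_sd: float,
    temporal_rho: float,
    rng: np.random.Generator,
    n_samples: int = 1,
) -> np.ndarray:
    """Draw realisations of a zero-mean separable space-time GP.

    Covariance is ``spatial_sd**2 * Matern32(space) (x) AR1(time)``; sampling
    uses the Kronecker eigendecomposition, so only the (ncells x ncells) and
    (ntimes x ntimes) factors are ever factorised.

    Returns an array of shape (n_samples, ncells, n_times); squeeze for one.
    """
    if spatial_sd < 0:
        raise ValueError(f"spatial sd must be non-negative, got {spatial_sd}")
    n_cells = coords.shape[0]
    if spatial_sd == 0.0:
        return np.zeros((n_samples, n_cells, n_times))
    ls, qs = _eigh_clipped(matern32_correlation(coords, spatial_range))
    lt, qt = _eigh_clipped(ar1_correlation(n_times, temporal_rho))
    scale = np.sqrt(np.outer(ls, lt))  # (ncells, ntimes)
    out = np.empty((n_samples, n_cells, n_times))
    for k in range(n_samples):
        z = rng.standard_normal((n_cells, n_times))
        out[k] = spatial_sd * (qs @ (scale * z) @ qt.T)
    return out
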