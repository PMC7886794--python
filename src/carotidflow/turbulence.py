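"""Turbulent kinetic energy from intravoxel velocity standard deviations
and its projection to the wall (nwTKE).

Phase-contrast MRI encodes the within-voxel spread of velocities; per
encoding direction i the intravoxel standard deviation (IVSD) sigma_i
estimates the turbulent velocity fluctuation, giving the turbulent
kinetic energy density

    TKE = (rho / 2) * (sigma_1^2 + sigma_2^2 + sigma_3^2)   [J/m^3].

Near-wall TKE (nwTKE) summarises TKE around each surface vertex with a
spherical kernel: the unweighted mean of TKE over lumen voxels whose
centres lie within the kernel radius (default 2.5 mm) of the vertex.
Only lumen voxels enter the average -- TKE is undefined in background.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .core import LumenSurface, WallScalarSeries


def tke_from_ivsd(ivsd: np.ndarray, rho: float = 1060.0,
                  lumen_mask: np.ndarray | None = None) -> np.ndarray:
    """TKE volume (J/m^3) from a per-direction IVSD field.

    ``ivsd`` has shape ``(nx, ny, nz, 3)`` or ``(nx, ny, nz, nt, 3)``
    (m/s); the result drops the trailing component axis. Masked to the
    lumen when a mask is given.
    """
    ivsd = np.asarray(ivsd, dtype=float)
    if np.any(ivsd < 0):
        raise ValueError("IVSD values must be non-negative")
    tke = 0.5 * rho * np.sum(ivsd ** 2, axis=-1)
    if lumen_mask is not None:
        tke = tke * (np.asarray(lumen_mask) > 0)[..., None] if tke.ndim == 4 \
            else tke * (np.asarray(lumen_mask) > 0)
    return tke


def nwtke(tke: np.ndarray, surface: LumenSurface, lumen_mask: np.ndarray,
          spacing, radius: float = 2.5,
          times: np.ndarray | None = None) -> WallScalarSeries:
    """Near-wall TKE at every surface vertex via a spherical kernel.

    Parameters
    ----------
    tke : array, (nx, ny, nz) or (nx, ny, nz, nt), J/m^3.
    surface : LumenSurface in the same world frame as the TKE grid.
    lumen_mask : labelled or binary lumen mask on the TKE grid.
    spacing : voxel spacing of the TKE grid, mm.
    radius : kernel radius, mm (default 2.5).
    times : timeframe times for the output series; defaults to a single
        frame for volume TKE or ``arange(nt)`` for time-resolved TKE.

    Vertices with no in-lumen voxel centre within the kernel are
    flagged invalid.
    """
    spacing = np.asarray(spacing, dtype=float)
    if radius <= 0:
        raise ValueError("kernel radius must be positive")
    if radius < np.max(spacing) / 2:
        raise ValueError(
            f"kernel radius {radius} mm is below half the largest voxel "
            f"dimension ({np.max(spacing) / 2:.2f} mm); the kernel could be "
            "empty everywhere")
    tke = np.asarray(tke, dtype=float)
    time_resolved = tke.ndim == 4
    lumen = np.asarray(lumen_mask) > 0
    if tke.shape[:3] != lumen.shape:
        raise ValueError("TKE grid and lumen mask shapes differ")

    vox = np.argwhere(lumen)
    centers = (vox + 0.5) * spacing
    tree = cKDTree(centers)
    neighbours = tree.query_ball_point(surface.vertices, radius)

    nv = surface.n_vertices
    counts = np.array([len(nb) for nb in neighbours])
    valid = counts > 0
    rows = np.repeat(np.arange(nv), counts)
    cols = np.concatenate([nb for nb in neighbours if nb]) if valid.any() \
        else np.array([], dtype=int)
    kernel = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(nv, len(vox)))

    flat = tke[vox[:, 0], vox[:, 1], vox[:, 2]]  # (nvox,) or (nvox, nt)
    if not time_resolved:
        flat = flat[:, None]
    sums = kernel @ flat
    means = np.zeros_like(sums)
    means[valid] = sums[valid] / counts[valid, None]

    if times is None:
        times = np.arange(means.shape[1], dtype=float)
    return WallScalarSeries(means, valid, np.asarray(times, dtype=float),
                            kernel_radius=radius)


def constant_in_time(series: WallScalarSeries, times) -> WallScalarSeries:
    """Broadcast a single-frame wall scalar to a set of timeframes."""
    times = np.asarray(times, dtype=float)
    if series.values.shape[1] != 1:
        raise ValueError("series already time-resolved")
    vals = np.repeat(series.values, times.size, axis=1)
    return WallScalarSeries(vals, series.valid.copy(), times,
                            series.kernel_radius)
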