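"""Velocity-field preprocessing: background phase-offset correction and
cubic spatial up-sampling.

Phase-contrast velocity data carry slowly varying background offsets
(eddy currents, uncompensated gradient terms). These are removed by
fitting a full 3-variable polynomial of total degree 4 (35 terms) to
the time-averaged velocity of static tissue, per component, by weighted
least squares, and subtracting the fitted surface everywhere. The fit
uses coordinates normalised to [-1, 1] per axis for conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import VelocityField, voxel_centers, world_to_index

POLY_DEGREE = 4


def polynomial_exponents(degree: int = POLY_DEGREE) -> np.ndarray:
    """All (i, j, k) with i + j + k <= degree, in a fixed order."""
    return np.array([(i, j, k)
                     for i in range(degree + 1)
                     for j in range(degree + 1 - i)
                     for k in range(degree + 1 - i - j)], dtype=int)


def polynomial_design(points: np.ndarray, degree: int = POLY_DEGREE) -> np.ndarray:
    """Design matrix of monomials x^i y^j z^k for points in [-1, 1]^3."""
    expo = polynomial_exponents(degree)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    return (x[:, None] ** expo[None, :, 0]
            * y[:, None] ** expo[None, :, 1]
            * z[:, None] ** expo[None, :, 2])


def normalized_coords(shape, spacing) -> np.ndarray:
    """Voxel-centre coordinates mapped to [-1, 1] per axis, shape (*shape, 3)."""
    centers = voxel_centers(shape, spacing)
    extent = np.array(shape) * np.asarray(spacing, dtype=float)
    return 2.0 * centers / extent - 1.0


def static_tissue_mask(lumen_mask: np.ndarray, dilation: int = 2) -> np.ndarray:
    """Background voxels safely away from the lumen.

    Everything outside a ``dilation``-voxel dilation of the lumen counts
    as static tissue; the dilation shell excludes partial-volume voxels
    whose signal mixes blood and tissue.
    """
    lumen = lumen_mask > 0
    grown = ndimage.binary_dilation(lumen, iterations=dilation)
    static = ~grown
    if not np.any(static):
        raise ValueError("no static tissue left after dilation")
    return static


@dataclass
class OffsetFit:
    """Fitted background offset: coefficients over the degree-4 basis."""

    coeffs: np.ndarray        # (3, n_terms), m/s
    exponents: np.ndarray     # (n_terms, 3)
    std_errors: np.ndarray    # (3, n_terms)
    rms_residual: np.ndarray  # (3,) m/s over static voxels

    def evaluate(self, shape, spacing) -> np.ndarray:
        """Reconstruct the subtracted offset surface, shape (*shape, 3)."""
        coords = normalized_coords(shape, spacing).reshape(-1, 3)
        design = polynomial_design(coords)
        return (design @ self.coeffs.T).reshape(*shape, 3)


def correct_phase_offsets(field: VelocityField, static: np.ndarray,
                          weights: np.ndarray | None = None):
    """Remove the background phase offset estimated from static tissue.

    Per velocity component, a degree-4 polynomial is fitted by weighted
    least squares to the time-averaged velocity at static voxels and
    subtracted from all voxels at all timeframes (offsets are
    reconstruction artifacts and approximately steady, so a
    time-constant surface is fitted).

    Parameters
    ----------
    field : VelocityField
    static : bool array
        Static-tissue voxels, aligned to the velocity grid.
    weights : array, optional
        Per-voxel weights in [0, 1] on the same grid; default all-ones.

    Returns
    -------
    corrected : VelocityField
    fit : OffsetFit
    """
    static = np.asarray(static, dtype=bool)
    if static.shape != field.shape:
        raise ValueError("static mask shape must match the velocity grid")
    n_terms = polynomial_exponents().shape[0]
    n_static = int(static.sum())
    if n_static < n_terms:
        raise ValueError(
            f"phase-offset fit needs at least {n_terms} static voxels, got "
            f"{n_static}; enlarge the static-tissue mask")

    coords = normalized_coords(field.shape, field.spacing)
    design = polynomial_design(coords[static])
    if weights is None:
        w = np.ones(n_static)
    else:
        w = np.asarray(weights, dtype=float)[static]
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    sw = np.sqrt(w)
    aw = design * sw[:, None]

    vbar = field.data.mean(axis=3)  # time-averaged, (nx, ny, nz, 3)
    ys = vbar[static]               # (n_static, 3)

    coeffs = np.empty((3, n_terms))
    ses = np.empty((3, n_terms))
    rms = np.empty(3)
    # shared normal-equations factorisation across components
    u, s, vt = np.linalg.svd(aw, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError(
            "degenerate static-tissue geometry: the degree-4 design matrix "
            "is rank deficient; enlarge or diversify the static mask")
    for c in range(3):
        bw = ys[:, c] * sw
        coef = vt.T @ ((u.T @ bw) / s)
        coeffs[c] = coef
        resid = ys[:, c] - design @ coef
        rms[c] = np.sqrt(np.average(resid ** 2, weights=w))
        dof = max(n_static - n_terms, 1)
        sigma2 = float(np.sum(w * resid ** 2) / dof)
        # cov = sigma^2 (A_w^T A_w)^-1 = sigma^2 V S^-2 V^T
        ses[c] = np.sqrt(sigma2 * np.sum((vt.T / s[None, :]) ** 2, axis=1))

    fit = OffsetFit(coeffs, polynomial_exponents(), ses, rms)
    offset = fit.evaluate(field.shape, field.spacing)
    corrected = field.data.astype(float, copy=True)
    corrected -= offset[:, :, :, None, :]
    return VelocityField(corrected, field.spacing.copy(), field.times.copy(),
                         field.cycle), fit


def sample_field(field: VelocityField, points: np.ndarray, frame: int,
                 order: int = 1) -> np.ndarray:
    """Interpolate velocity components at world points (mm) for one frame.

    ``order=1`` is linear, ``order=3`` cubic B-spline. Points outside
    the grid get zero (the field is zero outside the lumen anyway).
    """
    idx = world_to_index(points, field.spacing).T  # (3, npts)
    out = np.empty((points.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            field.data[:, :, :, frame, c], idx, order=order,
            mode="grid-constant", cval=0.0)
    return out


def upsample(field: VelocityField, target_spacing,
             dtype=None) -> VelocityField:
    """Cubic spatial up-sampling of each component at every timeframe.

    The new grid covers the same physical extent; the requested spacing
    is adjusted minimally so an integer number of voxels fits. Cubic
    B-spline interpolation is interpolating, so values at source voxel
    centres are preserved.
    """
    target = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    if np.any(target > field.spacing + 1e-9):
        raise ValueError("up-sampling only: target spacing must not exceed "
                         "the source spacing")
    if np.allclose(target, field.spacing):
        return field.copy()

    extent = field.extent()
    new_shape = tuple(int(round(e / t)) for e, t in zip(extent, target))
    new_spacing = extent / np.array(new_shape)

    # fractional source indices of the new voxel centres, per axis
    axes_idx = [((np.arange(n) + 0.5) * ns) / s - 0.5
                for n, ns, s in zip(new_shape, new_spacing, field.spacing)]
    grid = np.meshgrid(*axes_idx, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])

    out_dtype = dtype or field.data.dtype
    nt = field.n_timeframes
    out = np.empty((*new_shape, nt, 3), dtype=out_dtype)
    for t in range(nt):
        for c in range(3):
            vol = ndimage.map_coordinates(
                field.data[:, :, :, t, c].astype(float), coords, order=3,
                mode="nearest")
            out[:, :, :, t, c] = vol.reshape(new_shape)
    return VelocityField(out, new_spacing, field.times.copy(), field.cycle)
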