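"""Wall shear stress from a velocity field sampled along inward normals.

For every vertex of the lumen surface, velocity is interpolated at a
small number of points along the inward normal (default 3 points over
3 mm). With the velocity defined to be zero at the wall, a cubic
smoothing spline is fitted through the wall anchor and the samples for
each velocity component; the spline's slope at the wall gives the wall
velocity-gradient vector. Its component normal to the wall is removed,
the magnitude of the tangential remainder is the wall shear rate, and
multiplying the tangential gradient by the shear-dependent
Carreau-Yasuda viscosity yields the WSS vector tau (Pa).

The smoothing spline is the classical natural cubic smoothing spline
(penalised least squares with an integrated-squared-second-derivative
penalty), solved in closed form for the handful of probe points; the
wall slope is a linear functional of the sampled velocities, so per
probe layout a weight vector is precomputed and the whole surface is
reduced to a matrix product.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import (FluidModel, LumenSurface, VelocityField, WallVectorSeries,
                   WSSProbe, world_to_index)
from .geometry import _points_in_lumen, lumen_indicator
from .preprocess import sample_field


def carreau_yasuda(shear_rate, fm: FluidModel) -> np.ndarray:
    """Carreau-Yasuda apparent viscosity mu(gamma_dot), Pa s.

    mu = mu_inf + (mu0 - mu_inf) * [1 + (lam*g)^a]^((n-1)/a); the
    zero-shear limit is mu0 and the infinite-shear limit mu_inf.
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    return fm.mu_inf + (fm.mu0 - fm.mu_inf) * (
        1.0 + (fm.lam * g) ** fm.a) ** ((fm.n - 1.0) / fm.a)


def _natural_smoothing_spline(x, y, lam):
    """Fit the natural cubic smoothing spline to (x, y).

    Minimises sum (y_i - f(x_i))^2 + lam * int f''^2 (Green-Silverman
    band form). Returns fitted values at the knots and the second
    derivatives at interior knots (natural: zero at the ends). Needs at
    least 3 points; lam = 0 gives the interpolating natural spline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("smoothing spline needs at least 3 points")
    h = np.diff(x)
    if np.any(h <= 0):
        raise ValueError("abscissas must be strictly increasing")
    m = n - 2
    delta = np.zeros((m, n))
    for i in range(m):
        delta[i, i] = 1.0 / h[i]
        delta[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        delta[i, i + 2] = 1.0 / h[i + 1]
    w = np.zeros((m, m))
    for i in range(m):
        w[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < m:
            w[i, i + 1] = w[i + 1, i] = h[i + 1] / 6.0
    k = delta.T @ np.linalg.solve(w, delta)
    fhat = np.linalg.solve(np.eye(n) + lam * k, y)
    gamma = np.linalg.solve(w, delta @ fhat)
    return fhat, gamma


def spline_wall_slope(x, y, lam) -> float:
    """Slope of the smoothing spline at the first knot (the wall)."""
    x = np.asarray(x, dtype=float)
    fhat, gamma = _natural_smoothing_spline(x, y, lam)
    h0 = x[1] - x[0]
    # cubic on the first interval with f''(x0) = 0 (natural)
    return float((fhat[1] - fhat[0]) / h0 - h0 * gamma[0] / 6.0)


@lru_cache(maxsize=256)
def _slope_weights(x_key, lam) -> np.ndarray:
    """Weights w with slope-at-wall = w . y, for fixed knots and penalty.

    The smoothing-spline fit is linear in the ordinates, so the wall
    slope is too; the weights are recovered by pushing unit vectors
    through the fit.
    """
    x = np.array(x_key)
    n = x.size
    w = np.empty(n)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        w[j] = spline_wall_slope(x, e, lam)
    return w


def sample_wall_velocity(field: VelocityField, vertex, inward_normal,
                         probe: WSSProbe, lumen_mask, mask_spacing=None,
                         frame: int = 0, mask_sigma: float = 1.0):
    """Velocities at the probe points along one vertex's inward normal.

    Returns a list of ``(distance_mm, velocity_vector)`` pairs; probe
    points falling outside the lumen are dropped. The caller should
    treat the vertex as invalid if fewer than 2 points remain.
    """
    vertex = np.asarray(vertex, dtype=float)
    nrm = np.asarray(inward_normal, dtype=float)
    mask_spacing = field.spacing if mask_spacing is None else \
        np.asarray(mask_spacing, dtype=float)
    dists = probe.distances()
    pts = vertex[None, :] + dists[:, None] * nrm[None, :]
    indicator = lumen_indicator(lumen_mask, mask_sigma)
    keep = _points_in_lumen(pts, indicator, mask_spacing)
    vels = sample_field(field, pts[keep], frame, order=1)
    return list(zip(dists[keep], vels))


def wall_shear_vector(samples, fm: FluidModel, probe: WSSProbe,
                      inward_normal, viscosity: str = "carreau-yasuda"):
    """WSS vector tau (Pa) from one vertex's probe samples.

    ``samples`` is the output of :func:`sample_wall_velocity`. Fits the
    smoothing spline through the zero-at-wall anchor and the samples per
    component, takes the wall slope, removes the wall-normal component,
    and multiplies the tangential gradient by the viscosity (Carreau-
    Yasuda at the tangential shear-rate magnitude, or the constant
    reference viscosity in ``viscosity="constant"`` mode).

    Returns ``(tau, valid)``; ``valid`` is False with a zero tau when
    fewer than 2 samples are available or the fit is degenerate.
    """
    if len(samples) < 2:
        return np.zeros(3), False
    dists = np.array([s[0] for s in samples], dtype=float)
    vels = np.array([s[1] for s in samples], dtype=float)
    order = np.argsort(dists)
    dists, vels = dists[order], vels[order]
    x = np.concatenate([[0.0], dists])
    try:
        w = _slope_weights(tuple(np.round(x, 9)), float(probe.smoothing))
    except (ValueError, np.linalg.LinAlgError):
        return np.zeros(3), False
    slope_mm = w[1:] @ vels           # (3,), m/s per mm; anchor y = 0
    grad = slope_mm * 1000.0          # 1/s
    nrm = np.asarray(inward_normal, dtype=float)
    grad_t = grad - (grad @ nrm) * nrm
    shear_rate = float(np.linalg.norm(grad_t))
    if viscosity == "constant":
        mu = fm.mu_ref
    elif viscosity == "carreau-yasuda":
        mu = float(carreau_yasuda(shear_rate, fm))
    else:
        raise ValueError(f"unknown viscosity mode: {viscosity!r}")
    return mu * grad_t, True


def compute_wss(field: VelocityField, surface: LumenSurface, fm: FluidModel,
                probe: WSSProbe, lumen_mask, mask_spacing=None,
                viscosity: str = "carreau-yasuda",
                mask_sigma: float = 1.0) -> WallVectorSeries:
    """Time-resolved WSS vectors at every surface vertex.

    Vectorised equivalent of :func:`sample_wall_velocity` +
    :func:`wall_shear_vector` over all vertices and timeframes.
    Vertices with fewer than 2 in-lumen probe points are flagged
    invalid and carry zeros.
    """
    if viscosity not in ("carreau-yasuda", "constant"):
        raise ValueError(f"unknown viscosity mode: {viscosity!r}")
    mask_spacing = field.spacing if mask_spacing is None else \
        np.asarray(mask_spacing, dtype=float)
    extent = field.extent()
    v = surface.vertices
    if np.any(v < -1e-6) or np.any(v > extent + 1e-6):
        raise ValueError("surface vertices fall outside the velocity grid: "
                         "are the coordinate frames matched?")

    dists = probe.distances()
    nv, k = surface.n_vertices, dists.size
    pts = v[:, None, :] + dists[None, :, None] * surface.normals[:, None, :]
    indicator = lumen_indicator(lumen_mask, mask_sigma)
    in_lumen = _points_in_lumen(pts.reshape(-1, 3), indicator,
                                mask_spacing).reshape(nv, k)
    valid = in_lumen.sum(axis=1) >= 2

    # one slope-weight vector per distinct probe-point validity pattern
    pattern_id = in_lumen @ (1 << np.arange(k))
    weights = np.zeros((nv, k))
    for pid in np.unique(pattern_id[valid]):
        sel = in_lumen[pattern_id == pid][0]
        x = np.concatenate([[0.0], dists[sel]])
        w = _slope_weights(tuple(np.round(x, 9)), float(probe.smoothing))
        rows = pattern_id == pid
        weights[np.ix_(rows, sel)] = w[1:]
    weights[~valid] = 0.0

    flat_pts = pts[in_lumen]                      # (n_in, 3)
    scatter = np.zeros((nv, k, 3))
    nt = field.n_timeframes
    nrm = surface.normals
    tau = np.zeros((nv, nt, 3))
    for t in range(nt):
        vel = sample_field(field, flat_pts, t, order=1)
        scatter[in_lumen] = vel
        slope_mm = np.einsum("vkc,vk->vc", scatter, weights)
        grad = slope_mm * 1000.0                  # 1/s
        grad_t = grad - np.sum(grad * nrm, axis=1, keepdims=True) * nrm
        if viscosity == "constant":
            mu = fm.mu_ref
        else:
            shear = np.linalg.norm(grad_t, axis=1)
            mu = carreau_yasuda(shear, fm)[:, None]
        tau[:, t, :] = mu * grad_t
    tau[~valid] = 0.0
    return WallVectorSeries(tau, valid, field.times.copy())
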