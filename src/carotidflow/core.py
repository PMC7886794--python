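"""Shared containers and grid conventions.

All world coordinates are in millimetres. A voxel with 0-based index
``(i, j, k)`` has its centre at ``(i + 0.5, j + 0.5, k + 0.5) * spacing``.
Velocities are in m/s, stresses in Pa, turbulent kinetic energy in J/m^3.

Branch labels follow the carotid naming: 1 = common carotid artery (CCA),
2 = internal carotid artery (ICA), 3 = external carotid artery (ECA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Integer labels used in lumen masks and on surfaces/centerlines.
CCA, ICA, ECA = 1, 2, 3
BRANCH_NAMES = {CCA: "CCA", ICA: "ICA", ECA: "ECA"}
BRANCH_LABELS = {v: k for k, v in BRANCH_NAMES.items()}


def voxel_centers(shape, spacing):
    """World coordinates (mm) of all voxel centres, shape ``(*shape, 3)``."""
    spacing = np.asarray(spacing, dtype=float)
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack(grids, axis=-1)


def world_to_index(points, spacing):
    """Fractional array indices for world points (inverse of the centre rule)."""
    return np.asarray(points, dtype=float) / np.asarray(spacing, dtype=float) - 0.5


@dataclass
class VelocityField:
    """Time-resolved three-component velocity field on a regular voxel grid.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, nt, 3)
        Velocity components along the grid axes, m/s.
    spacing : ndarray, shape (3,)
        Voxel spacing per axis, mm.
    times : ndarray, shape (nt,)
        Timeframe times within one cardiac cycle, s. Uniformly spaced.
    cycle : float
        Cardiac cycle duration, s.
    """

    data: np.ndarray
    spacing: np.ndarray
    times: np.ndarray
    cycle: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValueError("velocity data must have shape (nx, ny, nz, nt, 3)")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.data.shape[3] != self.times.size:
            raise ValueError("times length must match the number of timeframes")
        if not np.all(np.isfinite(self.spacing)):
            raise ValueError("spacing must be finite")

    @property
    def shape(self):
        return self.data.shape[:3]

    @property
    def n_timeframes(self) -> int:
        return self.data.shape[3]

    def extent(self):
        """Physical grid extent per axis, mm."""
        return np.array(self.shape) * self.spacing

    def copy(self) -> "VelocityField":
        return VelocityField(self.data.copy(), self.spacing.copy(),
                             self.times.copy(), self.cycle)


@dataclass
class LumenSurface:
    """Triangulated lumen wall with per-vertex attributes.

    ``normals`` are unit vectors pointing into the lumen; ``areas`` are
    one third of the summed incident-triangle areas (mm^2) so that they
    total the mesh area; ``labels`` carry the branch of the nearest
    labelled voxel.
    """

    vertices: np.ndarray      # (nv, 3) mm
    faces: np.ndarray         # (nf, 3) int
    normals: np.ndarray       # (nv, 3) unit, inward
    areas: np.ndarray         # (nv,) mm^2
    labels: np.ndarray        # (nv,) int

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class Centerlines:
    """Per-branch ordered centreline points, from the bifurcation outward.

    ``points[label]`` is an ``(n, 3)`` array in mm; ``diameters[label]``
    holds the equivalent-circle diameter at each point. ``bifurcation``
    is ``None`` for a single-branch lumen.
    """

    points: dict
    diameters: dict
    bifurcation: Optional[np.ndarray]

    def arc_length(self, label) -> np.ndarray:
        """Cumulative arc length (mm) along a branch, starting at 0."""
        p = self.points[label]
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class WallVectorSeries:
    """Per-vertex, per-timeframe wall shear stress vectors, Pa."""

    values: np.ndarray   # (nv, nt, 3)
    valid: np.ndarray    # (nv,) bool
    times: np.ndarray    # (nt,) s

    def magnitudes(self) -> np.ndarray:
        """|tau| per vertex and timeframe, shape (nv, nt)."""
        return np.linalg.norm(self.values, axis=-1)

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.valid.mean())


@dataclass
class WallScalarSeries:
    """Per-vertex, per-timeframe wall scalar (e.g. nwTKE, J/m^3)."""

    values: np.ndarray   # (nv, nt)
    valid: np.ndarray    # (nv,) bool
    times: np.ndarray    # (nt,) s
    kernel_radius: float = np.nan  # mm, for provenance

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.valid.mean())


@dataclass
class FluidModel:
    """Blood rheology: Carreau–Yasuda parameters plus reference constants.

    The Carreau–Yasuda law interpolates between the zero-shear viscosity
    ``mu0`` and the infinite-shear viscosity ``mu_inf``:

        mu(g) = mu_inf + (mu0 - mu_inf) * [1 + (lam*g)^a]^((n-1)/a)

    Defaults are standard whole-blood values. ``mu_ref`` is the constant
    dynamic viscosity used for Reynolds numbers (3.2e-3 Pa s) and for the
    constant-viscosity mode of the WSS computation.
    """

    mu0: float = 0.056        # Pa s
    mu_inf: float = 0.00345   # Pa s
    lam: float = 3.313        # s
    a: float = 2.0
    n: float = 0.3568
    rho: float = 1060.0       # kg/m^3
    mu_ref: float = 3.2e-3    # Pa s

    def __post_init__(self):
        if not (self.mu0 > self.mu_inf > 0):
            raise ValueError("require mu0 > mu_inf > 0")
        if self.lam <= 0 or self.a <= 0:
            raise ValueError("lam and a must be positive")
        if not (0 < self.n <= 1):
            raise ValueError("power index n must be in (0, 1]")
        if self.rho <= 0:
            raise ValueError("density must be positive")


@dataclass
class WSSProbe:
    """Geometry of the inward-normal velocity probe.

    ``n_points`` samples are placed at equal spacing along the inward
    normal out to ``length`` mm (defaults: 3 points over 3 mm, i.e. at
    1, 2 and 3 mm from the wall). ``smoothing`` is the penalty weight of
    the cubic smoothing spline fitted through the wall anchor and the
    samples (units mm^3; 0 gives the natural interpolating spline).
    """

    n_points: int = 3
    length: float = 3.0       # mm
    smoothing: float = 1e-3

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("probe needs at least 2 sample points")
        if self.length <= 0:
            raise ValueError("probe length must be positive")
        if self.smoothing < 0:
            raise ValueError("smoothing penalty must be non-negative")

    def distances(self) -> np.ndarray:
        """Sample distances from the wall, mm (wall anchor excluded)."""
        return self.length * (np.arange(1, self.n_points + 1) / self.n_points)
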