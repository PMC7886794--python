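"""Synthetic carotid-bifurcation phantoms with analytic ground truth.

Generates co-registered labelled lumen masks, quasi-steady pulsatile
velocity fields, intravoxel velocity standard deviation (IVSD) fields,
and measurement-corrupted variants (Gaussian noise plus a smooth
polynomial background phase offset). Geometry defaults emulate the
carotid bifurcation of a mid-size adult cohort (CCA diameter ~8.7 mm,
ICA ~7.5 mm, ECA ~5.7 mm, bifurcation angle ~49.5 deg) sampled on a
~1.1 x 1.1 x 1.2 mm grid with 40 timeframes per cardiac cycle, i.e. the
acquisition geometry of a carotid 4D Flow MRI exam.

The pulsatility is quasi-steady: a fixed spatial profile (parabolic or
plug) scaled by a periodic waveform. This sacrifices Womersley-type
phase lag for closed-form wall shear at every timeframe, which is what
makes the phantoms usable as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np

from .core import (CCA, ECA, ICA, BRANCH_NAMES, FluidModel, VelocityField,
                   voxel_centers)

#: Carotid-like flow waveform, (phase in [0,1], scale) samples. Sharp
#: systolic peak at phase 0.15 (frame 6 of 40), diastolic plateau ~0.35.
DEFAULT_WAVEFORM = (
    (0.00, 0.35), (0.08, 0.55), (0.15, 1.00), (0.22, 0.70),
    (0.30, 0.50), (0.45, 0.40), (0.70, 0.36), (1.00, 0.35),
)

VENC = 1.2  # m/s, velocity-encoding analogue: aliasing threshold


@dataclass
class BranchSpec:
    """One cylindrical branch: an axis segment with a radius.

    ``half_angle`` (degrees off the parent axis) is informational ground
    truth for daughter branches; the direction vector is authoritative.
    """

    label: int
    origin: np.ndarray        # mm
    direction: np.ndarray     # unit
    radius: float             # mm
    length: float             # mm
    half_angle: Optional[float] = None  # deg, daughters only

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("branch direction must be nonzero")
        self.direction = d / nrm
        if self.radius <= 0:
            raise ValueError(f"{BRANCH_NAMES.get(self.label, self.label)}: "
                             "radius must be positive")
        if self.length < 0:
            raise ValueError("branch length must be non-negative")

    @property
    def end(self) -> np.ndarray:
        return self.origin + self.length * self.direction


@dataclass
class VesselSpec:
    """A bifurcating (or single-tube) vessel on a regular voxel grid."""

    branches: Sequence[BranchSpec]
    spacing: np.ndarray       # mm per axis
    shape: tuple              # grid dimensions

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel sizes must be positive")
        labels = [b.label for b in self.branches]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate branch labels")

    @property
    def parent(self) -> BranchSpec:
        for b in self.branches:
            if b.label == CCA:
                return b
        raise ValueError("spec has no CCA branch")

    def daughters(self):
        return [b for b in self.branches if b.label != CCA and b.length > 0]

    def true_angle(self) -> Optional[float]:
        """Ground-truth bifurcation angle (deg) between the daughter axes."""
        ds = self.daughters()
        if len(ds) != 2:
            return None
        c = float(np.clip(ds[0].direction @ ds[1].direction, -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))


@dataclass
class FlowSpec:
    """Pulsatile flow parameters: profile shape x periodic waveform."""

    v_max: float = 0.8                     # m/s peak centreline velocity
    waveform: Sequence = DEFAULT_WAVEFORM  # (phase, scale) samples
    n_timeframes: int = 40
    cycle: float = 1.0                     # s
    profile: str = "parabolic"             # or "plug"

    def __post_init__(self):
        wf = np.asarray(self.waveform, dtype=float)
        if np.any(wf[:, 1] < 0):
            raise ValueError("waveform scales must be non-negative")
        if self.n_timeframes < 1:
            raise ValueError("need at least one timeframe")
        if self.profile not in ("parabolic", "plug"):
            raise ValueError(f"unknown profile kind: {self.profile!r}")

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_timeframes) / self.n_timeframes * self.cycle

    def scales(self) -> np.ndarray:
        """Waveform scale at each frame time (periodic linear interpolation)."""
        wf = np.asarray(self.waveform, dtype=float)
        order = np.argsort(wf[:, 0])
        ph, sc = wf[order, 0], wf[order, 1]
        phases = (np.arange(self.n_timeframes) / self.n_timeframes) % 1.0
        return np.interp(phases, ph, sc, period=1.0)


@dataclass
class CorruptionSpec:
    """Measurement corruption: polynomial phase offset + Gaussian noise.

    ``offset_coeffs`` has shape (3, 35): per velocity component, the
    coefficients of a full 3-variable polynomial up to total degree 4
    over coordinates normalised to [-1, 1] per axis (m/s). Zero
    coefficients and zero noise give the identity corruption.
    """

    noise_sd: float = 0.0                 # m/s
    offset_coeffs: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be non-negative")
        if self.offset_coeffs is not None:
            self.offset_coeffs = np.asarray(self.offset_coeffs, dtype=float)


@dataclass
class Hotspot:
    """Spherical isotropic turbulence patch: centre (mm), radius (mm), sigma (m/s)."""

    center: np.ndarray
    radius: float
    sigma: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.sigma < 0:
            raise ValueError("IVSD sigma must be non-negative")
        if self.radius <= 0:
            raise ValueError("hotspot radius must be positive")


def symmetric_y_phantom(d_cca=8.7, d_ica=7.5, d_eca=5.7, angle=49.5,
                        ica_fraction=0.5, parent_length=25.0,
                        daughter_length=30.0, spacing=(1.1, 1.1, 1.2),
                        margin=5.0) -> VesselSpec:
    """Build a Y-shaped carotid phantom from branch diameters and angle.

    The CCA runs along +z; the daughters leave its distal end in the
    x-z plane, the ICA tilted by ``angle * ica_fraction`` and the ECA by
    the rest, so the ground-truth bifurcation angle equals ``angle``.
    The grid is sized to contain every branch plus ``margin`` mm (>= the
    3 mm wall-probe length).

    At small angles with wide daughters, the two tubes overlap for a
    long way past the carina; the daughter length is extended when
    needed so that at least ~1.5 daughter diameters of cleanly
    separated vessel exist beyond the overlap zone (as in a real
    carotid, where the branches run well past the bulb).
    """
    spacing = np.asarray(spacing, dtype=float)
    a_ica = np.radians(angle * ica_fraction)
    a_eca = np.radians(angle * (1 - ica_fraction))
    r = {CCA: d_cca / 2, ICA: d_ica / 2, ECA: d_eca / 2}

    sep_rate = np.sin(a_ica) + np.sin(a_eca)  # axis separation per mm
    if sep_rate > 1e-6:
        overlap = (r[ICA] + r[ECA]) / sep_rate
        daughter_length = max(daughter_length,
                              overlap + 1.5 * max(d_ica, d_eca))

    d_ica_dir = np.array([np.sin(a_ica), 0.0, np.cos(a_ica)])
    d_eca_dir = np.array([-np.sin(a_eca), 0.0, np.cos(a_eca)])

    # Extents needed on each side of the CCA axis.
    x_plus = daughter_length * np.sin(a_ica) + r[ICA] + margin
    x_minus = daughter_length * np.sin(a_eca) + r[ECA] + margin
    x_minus = max(x_minus, r[CCA] + margin)
    x_plus = max(x_plus, r[CCA] + margin)
    y_half = max(r.values()) + margin
    z_top = (parent_length + margin
             + max(daughter_length * np.cos(a_ica) + r[ICA] * np.sin(a_ica),
                   daughter_length * np.cos(a_eca) + r[ECA] * np.sin(a_eca)))
    z_extent = z_top + margin

    shape = tuple(int(np.ceil(e / s)) for e, s in
                  zip((x_plus + x_minus, 2 * y_half, z_extent), spacing))
    origin = np.array([x_minus, y_half, margin])
    cca = BranchSpec(CCA, origin, (0, 0, 1), r[CCA], parent_length)
    bif = cca.end
    branches = [
        cca,
        BranchSpec(ICA, bif, d_ica_dir, r[ICA], daughter_length,
                   half_angle=angle * ica_fraction),
        BranchSpec(ECA, bif, d_eca_dir, r[ECA], daughter_length,
                   half_angle=angle * (1 - ica_fraction)),
    ]
    return VesselSpec(branches, spacing, shape)


def cylinder_phantom(radius=3.0, length=30.0, spacing=(1.1, 1.1, 1.1),
                     margin=5.0) -> VesselSpec:
    """A single straight tube along +z (no bifurcation); the simplest
    phantom, used wherever a closed-form Poiseuille oracle is wanted."""
    spacing = np.asarray(spacing, dtype=float)
    extent = (2 * (radius + margin), 2 * (radius + margin),
              length + 2 * margin)
    shape = tuple(int(np.ceil(e / s)) for e, s in zip(extent, spacing))
    origin = np.array([radius + margin, radius + margin, margin])
    return VesselSpec([BranchSpec(CCA, origin, (0, 0, 1), radius, length)],
                      spacing, shape)


def _axis_coords(points, branch):
    """Axial coordinate s and radial distance r of points w.r.t. a branch axis."""
    rel = points - branch.origin
    s = rel @ branch.direction
    radial = rel - s[..., None] * branch.direction
    return s, np.linalg.norm(radial, axis=-1)


def make_bifurcation_mask(spec: VesselSpec, margin=3.0):
    """Voxelise the analytic tube union into a labelled lumen mask.

    A voxel is labelled iff its centre lies inside a branch tube
    (voxel-centre membership; no partial volume). Voxels inside both
    daughter tubes at the carina go to the branch whose axis is nearest
    in radius-normalised distance, ties to the ICA.

    Returns
    -------
    mask : uint8 array
        0 background, else the branch label.
    truth : dict
        Ground-truth radii/diameters (mm), bifurcation point (mm),
        bifurcation angle (deg), and branch axes.
    """
    extent = np.array(spec.shape) * spec.spacing
    for b in spec.branches:
        if b.length == 0:
            continue
        pts = np.stack([b.origin, b.end])
        radial = b.radius * np.sqrt(np.maximum(0.0, 1.0 - b.direction ** 2))
        lo = pts.min(axis=0) - radial - margin
        hi = pts.max(axis=0) + radial + margin
        if np.any(lo < 0) or np.any(hi > extent):
            raise ValueError(
                f"branch {BRANCH_NAMES.get(b.label, b.label)} exits the grid "
                f"(needs {margin} mm margin)")

    centers = voxel_centers(spec.shape, spec.spacing)
    mask = np.zeros(spec.shape, dtype=np.uint8)

    parent = spec.parent
    s, r = _axis_coords(centers, parent)
    inside_parent = (s >= 0) & (s <= parent.length) & (r <= parent.radius)
    mask[inside_parent] = CCA

    daughters = spec.daughters()
    inside = {}
    reldist = {}
    for b in daughters:
        s, r = _axis_coords(centers, b)
        inside[b.label] = (s >= 0) & (s <= b.length) & (r <= b.radius)
        reldist[b.label] = r / b.radius
    if len(daughters) == 2:
        la, lb = (d.label for d in daughters)
        both = inside[la] & inside[lb] & ~inside_parent
        only_a = inside[la] & ~inside[lb] & ~inside_parent
        only_b = inside[lb] & ~inside[la] & ~inside_parent
        mask[only_a] = la
        mask[only_b] = lb
        # nearest-axis rule in units of the branch radius; ties -> ICA
        prefer_a = reldist[la] < reldist[lb]
        if la == ICA:
            prefer_a = reldist[la] <= reldist[lb]
        mask[both & prefer_a] = la
        mask[both & ~prefer_a] = lb
    elif len(daughters) == 1:
        b = daughters[0]
        mask[inside[b.label] & ~inside_parent] = b.label

    truth = {
        "radii_mm": {b.label: b.radius for b in spec.branches if b.length > 0},
        "diameters_mm": {b.label: 2 * b.radius for b in spec.branches
                         if b.length > 0},
        "bifurcation_point_mm": (parent.end.tolist() if daughters else None),
        "bifurcation_angle_deg": spec.true_angle(),
        "axes": {b.label: {"origin_mm": b.origin.tolist(),
                           "direction": b.direction.tolist(),
                           "length_mm": b.length}
                 for b in spec.branches if b.length > 0},
    }
    return mask, truth


def make_velocity_field(spec: VesselSpec, flow: FlowSpec,
                        mask: Optional[np.ndarray] = None,
                        dtype=np.float64) -> VelocityField:
    """Quasi-steady pulsatile velocity field on the phantom grid.

    Inside each branch, velocity is axial with a parabolic (Poiseuille)
    or plug profile scaled by the waveform; it is exactly zero outside
    the lumen. ``v(r, t) = v_max * w(t) * (1 - r^2/R^2)`` for the
    parabolic kind.
    """
    if mask is None:
        mask, _ = make_bifurcation_mask(spec)
    centers = voxel_centers(spec.shape, spec.spacing)
    scales = flow.scales()
    nt = flow.n_timeframes
    data = np.zeros((*spec.shape, nt, 3), dtype=dtype)

    for b in spec.branches:
        if b.length == 0:
            continue
        sel = mask == b.label
        if not np.any(sel):
            continue
        _, r = _axis_coords(centers[sel], b)
        if flow.profile == "parabolic":
            prof = flow.v_max * np.maximum(0.0, 1.0 - (r / b.radius) ** 2)
        else:  # plug
            prof = np.full(r.shape, flow.v_max)
        # (nsel, nt, 3) = profile x waveform x axis direction
        data[sel] = (prof[:, None, None] * scales[None, :, None]
                     * b.direction[None, None, :])

    return VelocityField(data, spec.spacing.copy(), flow.frame_times(),
                         flow.cycle)


def make_ivsd_field(mask: np.ndarray, spacing,
                    hotspots: Sequence[Hotspot],
                    background_sigma: float = 0.0) -> np.ndarray:
    """Per-direction IVSD field (m/s), shape ``(*mask.shape, 3)``.

    Each hotspot sets an identical sigma in all three directions
    (isotropic turbulence) inside its sphere; overlapping hotspots take
    the pointwise maximum; everything outside the lumen is zero.
    ``background_sigma`` adds a uniform floor inside the lumen (the
    baseline velocity fluctuation any in vivo measurement carries).
    """
    if background_sigma < 0:
        raise ValueError("IVSD sigma must be non-negative")
    spacing = np.asarray(spacing, dtype=float)
    extent = np.array(mask.shape) * spacing
    sigma = np.full(mask.shape, float(background_sigma))
    centers = None
    for h in hotspots:
        if np.any(h.center < 0) or np.any(h.center > extent):
            raise ValueError("hotspot centre outside the grid")
        if centers is None:
            centers = voxel_centers(mask.shape, spacing)
        d2 = np.sum((centers - h.center) ** 2, axis=-1)
        inside = d2 <= h.radius ** 2
        sigma[inside] = np.maximum(sigma[inside], h.sigma)
    sigma[mask == 0] = 0.0
    return np.repeat(sigma[..., None], 3, axis=-1)


def corrupt(field: VelocityField, c: CorruptionSpec) -> VelocityField:
    """Apply the corruption model: polynomial offset + i.i.d. Gaussian noise.

    The offset is added everywhere -- lumen and static background alike,
    constant over time -- which is exactly what the degree-4 static
    tissue fit in :mod:`carotidflow.preprocess` is meant to remove.
    Bit-reproducible for a fixed seed.
    """
    from .preprocess import normalized_coords, polynomial_design

    data = field.data.astype(float, copy=True)
    if c.offset_coeffs is not None and np.any(c.offset_coeffs != 0):
        coeffs = c.offset_coeffs
        if coeffs.shape[0] != 3:
            raise ValueError("offset_coeffs must have shape (3, n_terms)")
        coords = normalized_coords(field.shape, field.spacing)
        design = polynomial_design(coords.reshape(-1, 3))
        if coeffs.shape[1] != design.shape[1]:
            raise ValueError(f"expected {design.shape[1]} coefficients per "
                             f"component, got {coeffs.shape[1]}")
        offset = (design @ coeffs.T).reshape(*field.shape, 3)
        data += offset[:, :, :, None, :]
    if c.noise_sd > 0:
        rng = np.random.default_rng(c.seed)
        data += rng.normal(0.0, c.noise_sd, size=data.shape)
    return VelocityField(data, field.spacing.copy(), field.times.copy(),
                         field.cycle)


# -- cohort generation -------------------------------------------------------

#: Cohort geometry distributions: mean and SD of branch diameters (mm)
#: and bifurcation angle (deg) for a mid-size atherosclerosis cohort.
COHORT_GEOMETRY = {
    "d_cca": (8.7, 1.1),
    "d_ica": (7.5, 1.4),
    "d_eca": (5.7, 1.0),
    "angle": (49.5, 13.4),
}


@dataclass
class BifurcationCase:
    """One synthetic subject: geometry + flow + turbulence + corruption."""

    case_id: int
    vessel: VesselSpec
    flow: FlowSpec
    hotspots: list
    corruption: CorruptionSpec


def make_cohort(n_bifurcations: int, seed: int = 0, n_timeframes: int = 40,
                spacing=(1.1, 1.1, 1.2), noise_sd=0.03,
                offset_scale=0.01) -> list:
    """Sample a cohort of bifurcation cases with realistic variation.

    Diameters and angles are drawn from the cohort distributions
    (truncated at +-2 SD); peak velocities vary around 0.8 m/s staying
    under the 1.2 m/s VENC analogue; each case gets turbulence hotspots
    in the daughter branches just distal to the bifurcation (where
    post-stenotic and flow-separation turbulence occurs) and its own
    noise/offset realisation. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_bifurcations):
        def trunc(mean, sd, lo=None, hi=None):
            lo = mean - 2 * sd if lo is None else lo
            hi = mean + 2 * sd if hi is None else hi
            return float(np.clip(rng.normal(mean, sd), lo, hi))

        d_cca = trunc(*COHORT_GEOMETRY["d_cca"])
        d_ica = trunc(*COHORT_GEOMETRY["d_ica"])
        d_eca = trunc(*COHORT_GEOMETRY["d_eca"])
        angle = trunc(*COHORT_GEOMETRY["angle"], lo=25.0, hi=75.0)
        vessel = symmetric_y_phantom(
            d_cca=d_cca, d_ica=d_ica, d_eca=d_eca, angle=angle,
            ica_fraction=float(rng.uniform(0.35, 0.55)), spacing=spacing)
        v_max = trunc(0.8, 0.15, lo=0.5, hi=1.1)
        flow = FlowSpec(v_max=v_max, n_timeframes=n_timeframes,
                        cycle=float(rng.uniform(0.8, 1.1)))

        hotspots = []
        for b in vessel.daughters():
            n_h = rng.integers(1, 3)
            for _ in range(n_h):
                along = rng.uniform(3.0, 0.6 * b.length)
                off = rng.uniform(-0.4, 0.4) * b.radius
                perp = np.array([b.direction[2], 0, -b.direction[0]])
                center = b.origin + along * b.direction + off * perp
                hotspots.append(Hotspot(center, rng.uniform(2.0, 3.5),
                                        v_max * rng.uniform(0.05, 0.18)))

        coeffs = rng.normal(0.0, offset_scale, size=(3, 35))
        corruption = CorruptionSpec(noise_sd=noise_sd, offset_coeffs=coeffs,
                                    seed=int(rng.integers(0, 2 ** 31)))
        cases.append(BifurcationCase(i, vessel, flow, hotspots, corruption))
    return cases
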