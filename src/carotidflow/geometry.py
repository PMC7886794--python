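"""Vessel morphometry from a labelled lumen mask.

The wall surface is the 0.5 isosurface of the Gaussian-smoothed binary
mask (marching cubes); centerlines are minimal-cost paths between
branch tips through the 26-connected lumen voxel graph, with edge costs
penalised by the inverse squared distance-to-wall so paths hug the
medial axis, and the bifurcation point where the CCA-to-ICA and
CCA-to-ECA paths separate (refined from the daughter centrelines).
Branch diameter is the equivalent-circle diameter ``2*sqrt(A/pi)`` of
the lumen cross-section in the plane normal to the local centreline
tangent -- robust for non-circular lumens. The bifurcation angle is
measured between vectors that run from each daughter's centreline point
nearest the bifurcation to the arc-length midpoint of that daughter's
centreline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage import measure

from .core import CCA, ECA, ICA, BRANCH_NAMES, Centerlines, LumenSurface


def extract_surface(mask: np.ndarray, spacing, smoothing_sigma: float = 1.0,
                    check_normals: bool = True) -> LumenSurface:
    """Triangulate the lumen wall with inward per-vertex normals.

    Parameters
    ----------
    mask : labelled (or binary) lumen mask.
    spacing : voxel spacing, mm.
    smoothing_sigma : Gaussian smoothing of the binary mask in voxels
        before marching cubes; reduces voxelisation staircase.
    check_normals : verify that a 0.5 mm step along the inward normal
        lands in the lumen for >= 99% of vertices.
    """
    spacing = np.asarray(spacing, dtype=float)
    lumen = (np.asarray(mask) > 0).astype(float)
    if not np.any(lumen):
        raise ValueError("empty lumen mask")
    lab, n_comp = ndimage.label(lumen)
    if n_comp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        raise ValueError("lumen mask has multiple connected components "
                         f"(sizes: {sorted(sizes, reverse=True)})")

    smooth = lumen_indicator(mask, smoothing_sigma)
    verts, faces, norms, _ = measure.marching_cubes(smooth, level=0.5,
                                                    spacing=tuple(spacing))
    # marching_cubes works in index*spacing coordinates; voxel centres sit
    # at (index + 0.5)*spacing in world coordinates.
    verts = verts + 0.5 * spacing

    # skimage normals follow the gradient of the scalar field; orient them
    # into the lumen (toward increasing indicator) and re-normalise.
    norms = norms / np.maximum(np.linalg.norm(norms, axis=1, keepdims=True),
                               1e-12)
    probe = verts + 0.5 * norms
    inside = _points_in_lumen(probe, smooth, spacing)
    if inside.mean() < 0.5:
        norms = -norms
        inside = ~inside
    if check_normals and inside.mean() < 0.99:
        raise ValueError(
            f"only {100 * inside.mean():.1f}% of inward normals point into "
            "the lumen; the mask may be too thin or too noisy")

    # per-vertex area: one third of incident triangle areas
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(len(verts))
    np.add.at(areas, faces.ravel(), np.repeat(tri_area / 3.0, 3))

    labels = _nearest_labels(verts, mask, spacing)
    return LumenSurface(verts, faces, norms, areas, labels)


def lumen_indicator(mask, smoothing_sigma: float = 1.0) -> np.ndarray:
    """Gaussian-smoothed lumen indicator whose 0.5 level set is the wall.

    The same volume drives surface extraction and in-lumen membership
    tests, so "inside the lumen" and "inside the extracted wall" agree
    by construction.
    """
    return ndimage.gaussian_filter((np.asarray(mask) > 0).astype(float),
                                   sigma=smoothing_sigma, mode="constant")


def _points_in_lumen(points, indicator, spacing, level=0.5):
    """Membership of world points w.r.t. a smoothed lumen indicator."""
    idx = np.asarray(points) / np.asarray(spacing, dtype=float) - 0.5
    vals = ndimage.map_coordinates(np.asarray(indicator, dtype=float),
                                   idx.T, order=1, mode="grid-constant",
                                   cval=0.0)
    return vals >= level


def _nearest_labels(points, mask, spacing):
    lab_idx = np.argwhere(mask > 0)
    centers = (lab_idx + 0.5) * spacing
    tree = cKDTree(centers)
    _, nn = tree.query(points)
    return mask[tuple(lab_idx[nn].T)].astype(int)


# -- centerlines -------------------------------------------------------------

def _lumen_graph(mask, spacing):
    """Sparse 26-connected graph over lumen voxels with centred costs.

    Edge cost = step length / (mean wall distance)^2, so minimal-cost
    paths run along the medial axis of the vessel (the standard
    freespace-centerline construction). Returns (cost graph, voxel
    coordinates, wall-distance map per node).
    """
    lumen = np.asarray(mask) > 0
    coords = np.argwhere(lumen)
    ids = -np.ones(lumen.shape, dtype=np.int64)
    ids[tuple(coords.T)] = np.arange(len(coords))
    dt = ndimage.distance_transform_edt(lumen, sampling=spacing)
    node_dt = dt[tuple(coords.T)]

    rows, cols, costs = [], [], []
    eps = 0.25 * float(np.min(spacing))
    offsets = [o for o in np.ndindex(3, 3, 3) if o > (1, 1, 1)]
    for off in offsets:
        o = np.array(off) - 1
        nb = coords + o
        ok = np.all((nb >= 0) & (nb < lumen.shape), axis=1)
        j = ids[tuple(nb[ok].T)]
        valid = j >= 0
        i = ids[tuple(coords[ok][valid].T)]
        j = j[valid]
        step = float(np.linalg.norm(o * spacing))
        mean_dt = 0.5 * (node_dt[i] + node_dt[j])
        w = step / (mean_dt + eps) ** 2
        rows.append(i)
        cols.append(j)
        costs.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    costs = np.concatenate(costs)
    n = len(coords)
    g = coo_matrix((np.concatenate([costs, costs]),
                    (np.concatenate([rows, cols]),
                     np.concatenate([cols, rows]))), shape=(n, n)).tocsr()
    return g, coords, node_dt


def _extract_path(predecessors, target):
    path = [target]
    while predecessors[path[-1]] >= 0:
        path.append(int(predecessors[path[-1]]))
    return path[::-1]


def extract_centerlines(mask: np.ndarray, spacing,
                        smooth_window: int = 5) -> Centerlines:
    """Branch centerlines and the bifurcation point from a labelled mask.

    Each branch is traced independently inside its own label region: a
    minimal-cost path (edge costs penalised by inverse squared wall
    distance, so the path follows the medial axis) runs from the branch
    tip to the end nearest the bifurcation, and is then pulled onto the
    cross-section centroids. The bifurcation point is where straight
    lines fitted to the CCA and daughter centrelines meet; points
    within about one diameter of it are discarded (their cross-sections
    cut several branches) and every branch is attached to it. Point
    lists run from the bifurcation outward; per-point diameters are
    equivalent-circle diameters from slab-counted cross-sectional
    areas.
    """
    spacing = np.asarray(spacing, dtype=float)
    mask = np.asarray(mask)
    labels_present = sorted(int(v) for v in np.unique(mask) if v > 0)
    if not labels_present:
        raise ValueError("empty lumen mask")
    if np.any(mask > 0) and ndimage.label(mask > 0)[1] > 1:
        raise ValueError("lumen mask is disconnected")

    all_world = (np.argwhere(mask > 0) + 0.5) * spacing
    centroid = all_world.mean(axis=0)

    raw, skip = {}, {}
    for lab in labels_present:
        g, coords, node_dt = _lumen_graph(mask == lab, spacing)
        if len(coords) < 3:
            raise ValueError(f"branch {BRANCH_NAMES.get(lab, lab)} has "
                             "too few voxels")
        world = (coords + 0.5) * spacing
        # tip: farthest from the lumen centroid, deepest inside the vessel
        d = np.linalg.norm(world - centroid, axis=1)
        far = np.where(d >= d.max() - 1.5 * spacing.max())[0]
        tip = int(far[np.argmax(node_dt[far])])

        dist, pred = dijkstra(g, indices=tip, return_predecessors=True)
        finite = np.isfinite(dist)
        if len(labels_present) == 1 or lab == CCA and len(labels_present) > 1:
            # proximal end: voxel nearest the daughters (CCA) or simply
            # the farthest reachable end (single tube)
            if len(labels_present) == 1:
                target = int(np.argmax(np.where(finite, dist, -np.inf)))
            else:
                other = (np.argwhere((mask > 0) & (mask != lab)) + 0.5) \
                    * spacing
                t2 = cKDTree(other)
                dd, _ = t2.query(world)
                dd[~finite] = np.inf
                target = int(np.argmin(dd))
        else:
            # daughter: proximal end is the voxel nearest the CCA
            parent = (np.argwhere(mask == CCA) + 0.5) * spacing
            t2 = cKDTree(parent)
            dd, _ = t2.query(world)
            dd[~finite] = np.inf
            target = int(np.argmin(dd))
        nodes = _extract_path(pred, target)[::-1]  # proximal -> tip
        if len(nodes) < 2:
            raise ValueError(f"branch {BRANCH_NAMES.get(lab, lab)} is too "
                             "short to trace")
        pts = _smooth_path(world[nodes], smooth_window)
        pts = _recenter_path(pts, mask, spacing, lab)
        pts = _median_filter_path(pts)
        pts = _smooth_path(pts, smooth_window)
        # trim the tube-cap end(s), where no full cross-section exists
        radius = float(node_dt.max())
        pts = _trim_end(pts, radius)
        if len(labels_present) == 1:
            pts = _trim_end(pts[::-1], radius)[::-1]
        raw[lab] = pts
        # ~one diameter: how far from the bifurcation the cross-sections
        # stop being single-branch
        skip[lab] = 2.0 * float(node_dt.max())

    if len(labels_present) == 1:
        lab = labels_present[0]
        dia = _path_diameters(raw[lab], mask, spacing, lab)
        return Centerlines({lab: raw[lab]}, {lab: dia}, None)

    if CCA not in raw:
        raise ValueError("labelled mask must contain a CCA branch")
    daughters = [lab for lab in (ICA, ECA) if lab in raw]

    # Bifurcation point: each daughter line meets the CCA line; the
    # estimates are averaged. Carina-adjacent points are excluded from
    # the fits, and estimates far from the branches' proximal ends are
    # rejected as ill-conditioned.
    proximal = raw[CCA][0]
    meets = []
    for lab in daughters:
        m = _line_meeting_point(raw[CCA], raw[lab],
                                skip_a=skip[CCA], skip_b=skip[lab])
        if m is not None and np.linalg.norm(m - proximal) < \
                2.0 * max(skip.values()):
            meets.append(m)
    bif_point = np.mean(meets, axis=0) if meets else None
    if bif_point is None and len(daughters) == 2:
        bif_point = _carina_apex(mask, spacing)
    if bif_point is None:
        bif_point = proximal.copy()

    points, diameters = {}, {}
    for lab, pts in raw.items():
        # drop carina-zone points -- near the bifurcation point or still
        # inside the overlap with another branch -- then attach the
        # branch to the common bifurcation point
        keep = np.linalg.norm(pts - bif_point, axis=1) >= skip[lab]
        other = (np.argwhere((mask > 0) & (mask != lab)) + 0.5) * spacing
        if len(other):
            d_other, _ = cKDTree(other).query(pts)
            keep &= d_other >= 0.4 * skip[lab]
        if keep.sum() >= 2:
            pts = pts[keep]
        pts = np.vstack([bif_point, pts])
        points[lab] = pts
        diameters[lab] = _path_diameters(pts, mask, spacing, lab)
    return Centerlines(points, diameters, np.asarray(bif_point).copy())


def _smooth_path(points, window):
    """Moving-average smoothing of an ordered polyline (endpoint-preserving)."""
    if window <= 1 or len(points) <= window:
        return points
    kernel = np.ones(window) / window
    sm = np.empty_like(points, dtype=float)
    for d in range(3):
        sm[:, d] = np.convolve(np.pad(points[:, d], window // 2, mode="edge"),
                               kernel, mode="valid")[:len(points)]
    sm[0], sm[-1] = points[0], points[-1]
    return sm


def _trim_end(points, margin):
    """Drop trailing points within ``margin`` mm of the path's last point."""
    if len(points) < 4:
        return points
    d = np.linalg.norm(points - points[-1], axis=1)
    keep = d >= margin
    keep[: max(2, int(keep.sum()))] = True  # never drop below 2 points
    last = np.where(d >= margin)[0]
    if len(last) < 2:
        return points
    return points[: last[-1] + 1]


def _median_filter_path(points, size: int = 3):
    """Componentwise running median; knocks out single off-axis nodes."""
    if len(points) < size:
        return points
    out = points.astype(float).copy()
    out[:, :] = ndimage.median_filter(points, size=(size, 1), mode="nearest")
    out[0], out[-1] = points[0], points[-1]
    return out


def _line_meeting_point(pts_a, pts_b, skip_a=2.5, skip_b=2.5):
    """Mutual closest point of lines fitted to two centrelines.

    The first ``skip`` mm of arc length (the bifurcation end) are
    excluded from each fit. Returns None when either line is missing,
    too short, or the lines are near parallel.
    """
    lines = []
    for pts, skip in ((pts_a, skip_a), (pts_b, skip_b)):
        if pts is None or len(pts) < 4:
            return None
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        # trim the carina zone and the far end (tube-cap points are
        # unreliable too)
        sel = pts[(arc >= skip) & (arc <= arc[-1] - 0.5 * skip)]
        if len(sel) < 3:
            sel = pts[len(pts) // 3: -max(1, len(pts) // 6)]
        if len(sel) < 3:
            return None
        c = sel.mean(axis=0)
        _, _, vt = np.linalg.svd(sel - c)
        d = vt[0]
        if d @ (sel[-1] - sel[0]) < 0:
            d = -d
        lines.append((c, d))
    (c1, d1), (c2, d2) = lines
    b = float(d1 @ d2)
    denom = 1.0 - b * b
    if denom < 1e-4:
        return None
    w = c1 - c2
    s = (b * (d2 @ w) - (d1 @ w)) / denom
    t = ((d2 @ w) - b * (d1 @ w)) / denom
    return 0.5 * ((c1 + s * d1) + (c2 + t * d2))


def _carina_apex(mask, spacing):
    """The flow-divider apex: centroid of the ICA/ECA label-interface
    voxels closest to the CCA. Returns None if the labels never touch."""
    ica = mask == ICA
    eca = mask == ECA
    if not (ica.any() and eca.any()):
        return None
    touch = ica & ndimage.binary_dilation(eca)
    touch |= eca & ndimage.binary_dilation(ica)
    if not touch.any():
        return None
    iface = (np.argwhere(touch) + 0.5) * spacing
    cca_vox = np.argwhere(mask == CCA)
    if len(cca_vox) == 0:
        return None
    tree = cKDTree((cca_vox + 0.5) * spacing)
    d, _ = tree.query(iface)
    sel = d <= d.min() + float(np.max(spacing))
    return iface[sel].mean(axis=0)


def _path_tangents(points):
    t = np.gradient(points, axis=0)
    return t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)


def _recenter_path(points, mask, spacing, label, iterations=2,
                   max_radius=12.0):
    """Pull path points onto the axis of their branch.

    Within the slab normal to the local tangent, a circle is fitted
    (linear Kasa least squares) to the branch's outer-wall voxels --
    its boundary with the background. Near the carina a branch's
    cross-section is only part of the merged lumen, which biases any
    centroid; the outer-wall arc is an arc of the true tube circle
    there regardless, so the fitted centre is not. Falls back to the
    same-label slab centroid when the arc is too small or the fit too
    poor.
    """
    spacing = np.asarray(spacing, dtype=float)
    own = np.asarray(mask) == label
    if not own.any():
        return points
    interior = ndimage.binary_erosion(np.asarray(mask) > 0)
    wall_vox = np.argwhere(own & ~interior)
    wall = (wall_vox + 0.5) * spacing
    own_centers = (np.argwhere(own) + 0.5) * spacing
    wall_tree = cKDTree(wall)
    own_tree = cKDTree(own_centers)
    h = float(np.min(spacing))
    pts = points.astype(float).copy()
    for _ in range(iterations):
        tangents = _path_tangents(pts)
        for i, (p, t) in enumerate(zip(pts, tangents)):
            moved = False
            near = wall_tree.query_ball_point(p, max_radius)
            if len(near) >= 6:
                rel = wall[near] - p
                sel = rel[np.abs(rel @ t) <= 0.6 * h]
                if len(sel) >= 6:
                    u = np.cross(t, [1.0, 0.0, 0.0])
                    if np.linalg.norm(u) < 1e-6:
                        u = np.cross(t, [0.0, 1.0, 0.0])
                    u /= np.linalg.norm(u)
                    v = np.cross(t, u)
                    q = np.stack([sel @ u, sel @ v], axis=1)
                    center, radius, rms = _fit_circle(q)
                    if (center is not None and radius < max_radius
                            and rms < 0.75 * h
                            and np.linalg.norm(center) < max_radius):
                        pts[i] = p + center[0] * u + center[1] * v
                        moved = True
            if not moved:
                near = own_tree.query_ball_point(p, max_radius)
                if near:
                    rel = own_centers[near] - p
                    in_slab = np.abs(rel @ t) <= h / 2
                    if in_slab.sum() >= 3:
                        pts[i] = own_centers[near][in_slab].mean(axis=0)
    return pts


def _fit_circle(q):
    """Kasa least-squares circle fit to 2-D points.

    Returns (centre, radius, rms residual); centre is None for a
    degenerate system (e.g. collinear points).
    """
    a = np.column_stack([2 * q, np.ones(len(q))])
    b = (q ** 2).sum(axis=1)
    try:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:
        return None, np.inf, np.inf
    cx, cy, k = sol
    r2 = k + cx ** 2 + cy ** 2
    if r2 <= 0 or not np.isfinite(r2):
        return None, np.inf, np.inf
    radius = float(np.sqrt(r2))
    d = np.linalg.norm(q - [cx, cy], axis=1)
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return np.array([cx, cy]), radius, rms


def _path_diameters(points, mask, spacing, label, max_radius=12.0):
    """Equivalent-circle diameter at each centreline point.

    Counts same-label voxels whose centres lie in a one-voxel-thick slab
    normal to the local tangent (within ``max_radius`` mm of the point);
    the slab voxel count times voxel volume over slab thickness estimates
    the cross-sectional area A, and D = 2*sqrt(A/pi).
    """
    vox = np.argwhere(mask == label)
    centers = (vox + 0.5) * spacing
    tree = cKDTree(centers)
    voxvol = float(np.prod(spacing))
    h = float(np.min(spacing))

    tangents = np.gradient(points, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True),
                           1e-12)
    dia = np.empty(len(points))
    for i, (p, t) in enumerate(zip(points, tangents)):
        near = tree.query_ball_point(p, max_radius)
        if not near:
            dia[i] = np.nan
            continue
        rel = centers[near] - p
        in_slab = np.abs(rel @ t) <= h / 2
        area = in_slab.sum() * voxvol / h
        dia[i] = 2.0 * np.sqrt(area / np.pi)
    return dia


def mean_branch_diameter(c: Centerlines, label: int,
                         exclusion_diameters: float = 1.0) -> float:
    """Arithmetic-mean equivalent-circle diameter of a branch, mm.

    Points within ``exclusion_diameters`` branch diameters of the
    bifurcation are excluded: cross-sections there cut through more than
    one branch and are not representative.
    """
    if label not in c.points:
        raise ValueError(f"branch {BRANCH_NAMES.get(label, label)} not in "
                         "centerlines")
    dia = np.asarray(c.diameters[label], dtype=float)
    pts = c.points[label]
    if len(pts) < 3:
        raise ValueError("too few centreline points for a mean diameter")
    keep = np.isfinite(dia)
    if c.bifurcation is not None:
        arc = c.arc_length(label)
        rough = np.nanmedian(dia)
        keep &= arc > exclusion_diameters * rough
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable centreline points after the "
                         "bifurcation exclusion zone")
    return float(np.mean(dia[keep]))


def bifurcation_angle(c: Centerlines) -> float:
    """Angle (degrees) between the daughter-branch centreline vectors.

    Each vector originates at the daughter's centreline point nearest
    the bifurcation and points to the arc-length midpoint of that
    daughter's centreline.
    """
    for lab in (ICA, ECA):
        if lab not in c.points:
            raise ValueError(f"bifurcation angle needs both daughters; "
                             f"{BRANCH_NAMES[lab]} missing")
    vecs = []
    for lab in (ICA, ECA):
        pts = c.points[lab]
        arc = c.arc_length(lab)
        mid = _point_at_arc(pts, arc, arc[-1] / 2.0)
        v = mid - pts[0]
        if np.linalg.norm(v) < 1e-9:
            raise ValueError(f"degenerate centreline vector for "
                             f"{BRANCH_NAMES[lab]}")
        vecs.append(v / np.linalg.norm(v))
    cosang = float(np.clip(vecs[0] @ vecs[1], -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _point_at_arc(points, arc, s):
    """Interpolate a polyline point at arc length s."""
    i = int(np.searchsorted(arc, s))
    if i <= 0:
        return points[0].astype(float)
    if i >= len(points):
        return points[-1].astype(float)
    f = (s - arc[i - 1]) / max(arc[i] - arc[i - 1], 1e-12)
    return points[i - 1] + f * (points[i] - points[i - 1])
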