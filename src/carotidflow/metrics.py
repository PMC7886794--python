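"""Per-branch hemodynamic descriptors.

Reduces the per-vertex, per-timeframe wall series to the standard
whole-cycle and time-resolved descriptors of carotid wall stress
studies: time-averaged WSS and nwTKE (TAWSS, TAnwTKE), the oscillatory
shear index (OSI), systolic and peak values, 10%/90% "minimum" and
"maximum" values (percentiles, to suppress noise outliers), the SA80
surface-area exposure threshold, Reynolds numbers, and the coefficient
of variation.

Conventions
-----------
* TAWSS is the time average of |tau(t)| (mean of magnitudes), the
  convention consistent with reporting a separate OSI.
* OSI = 1/2 * (1 - ||mean_t tau|| / mean_t ||tau||), in [0, 0.5].
* "Minimum"/"maximum" per branch are the 10th/90th percentile over
  valid vertices (linear interpolation), unweighted; SA80 is
  area-weighted because its definition is explicitly in surface area.
* The systolic timeframe is the frame maximising the CCA lumen-mean
  velocity magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (CCA, BRANCH_NAMES, FluidModel, LumenSurface,
                   VelocityField, WallScalarSeries, WallVectorSeries)


def time_average(series) -> np.ndarray:
    """Per-vertex time average: of |tau(t)| for vector series, of the
    value for scalar series. Invalid vertices yield NaN."""
    if isinstance(series, WallVectorSeries):
        vals = series.magnitudes()
    else:
        vals = series.values
    out = vals.mean(axis=1)
    out = np.where(series.valid, out, np.nan)
    return out


def osi(series: WallVectorSeries) -> np.ndarray:
    """Oscillatory shear index per vertex, in [0, 0.5]; NaN where the
    cycle-integrated shear magnitude is zero (undefined) or the vertex
    is invalid."""
    if series.values.shape[1] < 2:
        raise ValueError("OSI needs at least 2 timeframes")
    mean_vec = series.values.mean(axis=1)
    mean_mag = series.magnitudes().mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.5 * (1.0 - np.linalg.norm(mean_vec, axis=1) / mean_mag)
    val = np.where(series.valid & (mean_mag > 0), val, np.nan)
    return np.clip(val, 0.0, 0.5, out=val, where=np.isfinite(val))


def branch_descriptives(values: np.ndarray, labels: np.ndarray,
                        min_vertices: int = 10) -> pd.DataFrame:
    """Min(P10)/median/mean/SD/max(P90) per branch over valid vertices.

    ``values`` may contain NaN for invalid vertices; those are dropped.
    Branches with fewer than ``min_vertices`` usable vertices are
    returned with NaN statistics and ``complete=False``.
    """
    rows = []
    for lab in sorted(np.unique(labels)):
        v = values[(labels == lab)]
        v = v[np.isfinite(v)]
        if v.size < min_vertices:
            rows.append({"branch": BRANCH_NAMES.get(lab, str(lab)),
                         "n": v.size, "complete": False,
                         "min": np.nan, "median": np.nan, "mean": np.nan,
                         "sd": np.nan, "max": np.nan})
            continue
        rows.append({
            "branch": BRANCH_NAMES.get(lab, str(lab)), "n": v.size,
            "complete": True,
            "min": float(np.percentile(v, 10)),
            "median": float(np.median(v)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "max": float(np.percentile(v, 90)),
        })
    return pd.DataFrame(rows)


def lumen_mean_speed(field: VelocityField, lumen_mask: np.ndarray,
                     label: int | None = None) -> np.ndarray:
    """Lumen-mean velocity magnitude per timeframe, m/s."""
    mask = np.asarray(lumen_mask)
    sel = mask > 0 if label is None else mask == label
    if not np.any(sel):
        raise ValueError("no lumen voxels for the requested branch")
    speed = np.linalg.norm(field.data[sel], axis=-1)  # (nvox, nt)
    return speed.mean(axis=0)


def systolic_frame(field: VelocityField, lumen_mask: np.ndarray) -> int:
    """The timeframe of peak CCA lumen-mean velocity magnitude."""
    mask = np.asarray(lumen_mask)
    label = CCA if np.any(mask == CCA) else None
    return int(np.argmax(lumen_mean_speed(field, mask, label)))


def branch_mean_series(series, labels: np.ndarray) -> pd.DataFrame:
    """Branch mean of the wall quantity at every timeframe.

    Returns a frame indexed by timeframe with one column per branch.
    """
    vals = series.magnitudes() if isinstance(series, WallVectorSeries) \
        else series.values
    cols = {}
    for lab in sorted(np.unique(labels)):
        sel = (labels == lab) & series.valid
        cols[BRANCH_NAMES.get(lab, str(lab))] = vals[sel].mean(axis=0) \
            if np.any(sel) else np.full(vals.shape[1], np.nan)
    return pd.DataFrame(cols)


def systolic_values(series, labels: np.ndarray, frame: int) -> dict:
    """Branch mean of the wall quantity at the systolic timeframe."""
    bm = branch_mean_series(series, labels)
    return {name: float(bm[name].iloc[frame]) for name in bm.columns}


@dataclass
class SA80Result:
    """SA80 thresholds and per-bifurcation surface-area exposures.

    ``thresholds``: per-branch pooled TAWSS value (Pa) below which 80%
    of the cohort's cumulative surface area lies. ``exposure``: per
    (bifurcation, branch), the percent of that bifurcation's branch
    area with TAWSS at or below the threshold. ``cov``: cohort
    coefficient of variation (%) of the exposure per branch.
    """

    thresholds: pd.Series
    exposure: pd.DataFrame
    cov: pd.Series


def sa80(vertex_table: pd.DataFrame, fraction: float = 0.8) -> SA80Result:
    """Pooled surface-area exposure thresholds (SA80).

    ``vertex_table`` needs columns ``bifurcation``, ``branch``,
    ``tawss`` and ``area``. Per branch, vertices of all bifurcations
    are pooled and sorted by TAWSS; the threshold is the smallest TAWSS
    at which the cumulative area fraction reaches ``fraction`` (a step
    rule, so the pooled exposure equals the target up to one vertex's
    area share). Exposure per bifurcation is the percent of its branch
    area with TAWSS <= threshold.
    """
    need = {"bifurcation", "branch", "tawss", "area"}
    missing = need - set(vertex_table.columns)
    if missing:
        raise ValueError(f"vertex table lacks columns: {sorted(missing)}")
    if vertex_table["bifurcation"].nunique() < 2:
        raise ValueError("SA80 pooling needs at least 2 bifurcations")

    thresholds, cov, rows = {}, {}, []
    for branch, grp in vertex_table.groupby("branch"):
        grp = grp.dropna(subset=["tawss"]).sort_values("tawss")
        cum = grp["area"].cumsum() / grp["area"].sum()
        thr = float(grp["tawss"].iloc[int(np.searchsorted(cum.values,
                                                          fraction))])
        thresholds[branch] = thr
        exposures = []
        for bif, sub in grp.groupby("bifurcation"):
            exp = 100.0 * sub.loc[sub["tawss"] <= thr, "area"].sum() \
                / sub["area"].sum()
            rows.append({"bifurcation": bif, "branch": branch,
                         "exposure_pct": float(exp)})
            exposures.append(exp)
        cov[branch] = coefficient_of_variation(np.array(exposures))
    return SA80Result(pd.Series(thresholds, name="sa80_threshold_pa"),
                      pd.DataFrame(rows), pd.Series(cov, name="cov_pct"))


def pooled_exposure(vertex_table: pd.DataFrame, thresholds: pd.Series) -> dict:
    """Percent of pooled area at or below the SA80 threshold, per branch."""
    out = {}
    for branch, grp in vertex_table.groupby("branch"):
        grp = grp.dropna(subset=["tawss"])
        out[branch] = float(100.0 * grp.loc[grp["tawss"] <=
                                            thresholds[branch], "area"].sum()
                            / grp["area"].sum())
    return out


def reynolds(diameter_mm: float, mean_speed: np.ndarray,
             fm: FluidModel | None = None) -> np.ndarray:
    """Reynolds number Re = rho * v * D / mu per timeframe.

    Diameter in mm, speed in m/s; rho and the constant dynamic
    viscosity mu come from the fluid model (defaults 1060 kg/m^3 and
    3.2e-3 Pa s).
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    fm = fm or FluidModel()
    return fm.rho * np.asarray(mean_speed, dtype=float) \
        * (diameter_mm * 1e-3) / fm.mu_ref


def coefficient_of_variation(values) -> float:
    """CoV = 100 * sample SD / mean, percent."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def summarize_bifurcation(bif_id, wss_series: WallVectorSeries,
                          nwtke_series: WallScalarSeries,
                          surface: LumenSurface, field: VelocityField,
                          lumen_mask: np.ndarray, diameters: dict,
                          angle: float, fm: FluidModel | None = None):
    """All per-branch descriptors for one bifurcation.

    Returns
    -------
    summary : DataFrame, one row per branch (the Table-2-style row unit).
    timecourse : DataFrame, one row per (branch, timeframe) with branch
        means and per-frame P10/P90 values (for time-resolved
        correlations).
    vertices : DataFrame with per-vertex TAWSS and area (SA80 input).
    """
    fm = fm or FluidModel()
    labels = surface.labels
    sys_frame = systolic_frame(field, lumen_mask)

    tawss = time_average(wss_series)
    tanwtke = time_average(nwtke_series)
    osi_v = osi(wss_series)
    wss_mag = wss_series.magnitudes()
    nwt_val = nwtke_series.values

    summary_rows, time_rows = [], []
    for lab in sorted(np.unique(labels)):
        name = BRANCH_NAMES.get(lab, str(lab))
        on_branch = labels == lab
        w_ok = on_branch & wss_series.valid
        n_ok = on_branch & nwtke_series.valid

        w_t = wss_mag[w_ok]        # (nvert, nt)
        n_t = nwt_val[n_ok]
        if w_t.shape[0] < 10 or n_t.shape[0] < 10:
            continue
        wmean_t = w_t.mean(axis=0)
        nmean_t = n_t.mean(axis=0)
        w90_t = np.percentile(w_t, 90, axis=0)
        w10_t = np.percentile(w_t, 10, axis=0)
        n90_t = np.percentile(n_t, 90, axis=0)
        n10_t = np.percentile(n_t, 10, axis=0)

        speed_t = lumen_mean_speed(field, lumen_mask, lab)
        re_t = reynolds(diameters[lab], speed_t, fm)

        summary_rows.append({
            "bifurcation": bif_id, "branch": name,
            "tawss_pa": float(np.nanmean(tawss[w_ok])),
            "tawss_median_pa": float(np.nanmedian(tawss[w_ok])),
            "tawss_sd_pa": float(np.nanstd(tawss[w_ok], ddof=1)),
            "systolic_wss_pa": float(wmean_t[sys_frame]),
            "max_wss_pa": float(w90_t.max()),
            "min_wss_pa": float(w10_t.min()),
            "peak_wss_pa": float(wmean_t.max()),
            "osi": float(np.nanmean(osi_v[w_ok])),
            "tanwtke_jm3": float(np.nanmean(tanwtke[n_ok])),
            "systolic_nwtke_jm3": float(nmean_t[sys_frame]),
            "max_nwtke_jm3": float(n90_t.max()),
            "min_nwtke_jm3": float(n10_t.min()),
            "peak_nwtke_jm3": float(nmean_t.max()),
            "reynolds_mean": float(re_t.mean()),
            "reynolds_systolic": float(re_t[sys_frame]),
            "diameter_mm": float(diameters[lab]),
            "bifurcation_angle_deg": float(angle),
            "systolic_frame": sys_frame,
            "n_vertices": int(w_ok.sum()),
        })
        for t in range(w_t.shape[1]):
            time_rows.append({
                "bifurcation": bif_id, "branch": name, "frame": t,
                "wss_t": float(wmean_t[t]), "nwtke_t": float(nmean_t[t]),
                "max_wss_t": float(w90_t[t]), "min_wss_t": float(w10_t[t]),
                "max_nwtke_t": float(n90_t[t]),
                "min_nwtke_t": float(n10_t[t]),
            })

    vert = pd.DataFrame({
        "bifurcation": bif_id,
        "branch": [BRANCH_NAMES.get(l, str(l)) for l in labels],
        "tawss": tawss,
        "area": surface.areas,
    })
    return (pd.DataFrame(summary_rows), pd.DataFrame(time_rows),
            vert[np.isfinite(vert["tawss"])])
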