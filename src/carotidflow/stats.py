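"""Cohort statistics: Spearman correlation tables, branch t-tests, CoV.

Correlations use the Spearman rank coefficient with midrank ties and a
two-sided large-sample p-value, labelled on the conventional strength
scale (|rho| in [0, 0.2) very weak, [0.2, 0.4) weak, [0.4, 0.6)
moderate, [0.6, 0.8) strong, [0.8, 1] very strong; boundary values go
to the higher bracket). Branch comparisons use Welch two-sample
t-tests at alpha = 0.05. No multiple-testing correction is applied by
default (an option exists), matching common reporting practice in this
literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

_STRENGTH_BOUNDS = ((0.8, "very strong"), (0.6, "strong"),
                    (0.4, "moderate"), (0.2, "weak"), (0.0, "very weak"))


def strength_label(rho: float) -> str:
    """Qualitative label for |rho|; boundaries go to the higher bracket."""
    a = abs(float(rho))
    if a > 1:
        raise ValueError("|rho| cannot exceed 1")
    for bound, label in _STRENGTH_BOUNDS:
        if a >= bound:
            return label
    return "very weak"


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int

    @property
    def label(self) -> str:
        return strength_label(self.rho)


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete observations.

    Entries where either variable is NaN are dropped jointly; at least
    5 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError(f"need at least 5 complete pairs, got {x.size}")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(x_name, y_name, float(rho), float(p), int(x.size))


@dataclass
class BranchComparison:
    parameter: str
    branch_a: str
    branch_b: str
    t: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def branch_ttests(summary: pd.DataFrame, parameters,
                  branch_col: str = "branch") -> pd.DataFrame:
    """Welch two-sample t-tests between branches for each parameter.

    ``summary`` holds one row per (bifurcation, branch); all branch
    pairs present are compared. Returns a tidy frame with t, p and the
    significance flag at alpha = 0.05.
    """
    branches = sorted(summary[branch_col].unique())
    rows = []
    for param in parameters:
        for i, a in enumerate(branches):
            for b in branches[i + 1:]:
                va = summary.loc[summary[branch_col] == a, param].dropna()
                vb = summary.loc[summary[branch_col] == b, param].dropna()
                if len(va) < 2 or len(vb) < 2:
                    raise ValueError(f"need >=2 values per branch for {param}")
                if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
                    raise ValueError(
                        f"zero variance in both groups for {param} ({a}-{b})")
                t, p = sps.ttest_ind(va, vb, equal_var=False)
                rows.append({"parameter": param, "branch_a": a, "branch_b": b,
                             "t": float(t), "p": float(p),
                             "significant": bool(p < ALPHA)})
    return pd.DataFrame(rows)


def correlation_matrix(df: pd.DataFrame, columns) -> tuple:
    """Symmetric Spearman rho and p matrices over the given columns."""
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    k = len(columns)
    rho = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    pval = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = spearman(df[a].values, df[b].values, a, b)
            rho.loc[a, b] = rho.loc[b, a] = r.rho
            pval.loc[a, b] = pval.loc[b, a] = r.p_value
    return rho, pval


#: Column sets for the three standard correlation tables.
TIME_RESOLVED_COLUMNS = ["wss_t", "nwtke_t", "max_wss_t", "max_nwtke_t",
                         "min_wss_t", "min_nwtke_t"]
WHOLE_CYCLE_COLUMNS = ["tawss_pa", "tanwtke_jm3", "osi", "sa80_exposure_pct",
                       "peak_wss_pa", "peak_nwtke_jm3"]
GEOMETRY_PARAMS = ["tawss_pa", "tanwtke_jm3", "systolic_wss_pa",
                   "systolic_nwtke_jm3", "osi"]
TTEST_PARAMS = ["tawss_pa", "systolic_wss_pa", "max_wss_pa", "osi",
                "tanwtke_jm3", "max_nwtke_jm3", "systolic_nwtke_jm3"]


def build_tables(summary: pd.DataFrame, timecourse: pd.DataFrame) -> dict:
    """The cohort's correlation and comparison tables.

    Parameters
    ----------
    summary : one row per (bifurcation, branch) with the whole-cycle
        descriptors (including ``sa80_exposure_pct``).
    timecourse : one row per (bifurcation, branch, frame) with branch
        means and per-frame P10/P90 values. Time-resolved correlations
        pool these branch-mean-per-timeframe rows.

    Returns a dict with ``time_resolved`` and ``whole_cycle`` entries
    (each ``(rho, p)`` matrices), ``geometry`` (a tidy per-branch frame
    of hemodynamic-vs-diameter/angle correlations with strength
    labels), and ``ttests``.
    """
    if summary["bifurcation"].nunique() < 5:
        raise ValueError("cohort tables need at least 5 bifurcations")

    t_rho, t_p = correlation_matrix(timecourse, TIME_RESOLVED_COLUMNS)
    w_rho, w_p = correlation_matrix(summary, WHOLE_CYCLE_COLUMNS)

    geo_rows = []
    for param in GEOMETRY_PARAMS:
        for geo in ("diameter_mm", "bifurcation_angle_deg"):
            for branch, grp in summary.groupby("branch"):
                r = spearman(grp[geo].values, grp[param].values,
                             geo, param)
                geo_rows.append({
                    "parameter": param, "geometric": geo, "branch": branch,
                    "rho": r.rho, "p": r.p_value, "n": r.n,
                    "strength": r.label,
                })
    tests = branch_ttests(summary,
                          [p for p in TTEST_PARAMS if p in summary.columns])
    return {
        "time_resolved": (t_rho, t_p),
        "whole_cycle": (w_rho, w_p),
        "geometry": pd.DataFrame(geo_rows),
        "ttests": tests,
    }


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Optional multiple-testing adjustment (off by default upstream)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p, dtype=float), method=method)[1]
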