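"""Descriptive surfaces: pooled pressure-binned tables, lowess fits,
and time-since-insertion trend checks.

The pooled tables mirror the field's customary presentation of hourly
microdialysis binned by concurrent ICP or CPP interval.  Because the
rows are repeated measures, a patient's hours land unevenly across bins
and can dominate them; the tables therefore carry that caveat and a
``per_patient`` weighting variant (each patient contributes each bin
once, via their own bin means) is provided alongside the raw pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MARKERS

DEFAULT_ICP_EDGES = (15.0, 20.0, 25.0, 30.0)
DEFAULT_CPP_EDGES = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
TABLE_VARS = list(MARKERS) + ["lp_ratio", "lg_ratio"]

POOLED_TABLE_CAVEAT = (
    "Pooled repeated measures: a patient's hours are unevenly distributed "
    "across bins and can affect bins disproportionally; interpret with caution."
)


def _bin_labels(edges) -> list:
    labels = [f"< {edges[0]:g}"]
    labels += [f"{a:g} to {b:g}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"> {edges[-1]:g}")
    return labels


@dataclass
class BinnedTable:
    variable: str
    edges: tuple
    table: pd.DataFrame  # location, marker, bin, mean, sd, n
    weighting: str
    caveat: str = POOLED_TABLE_CAVEAT

    def counts(self, location: str) -> pd.Series:
        sub = self.table[(self.table["location"] == location)
                         & (self.table["marker"] == TABLE_VARS[0])]
        return sub.set_index("bin")["n"]


def bin_pooled(frame: pd.DataFrame, variable: str = "icp_hour",
               edges=None, weighting: str = "samples",
               variables=None) -> BinnedTable:
    """Mean +/- SD of raw-unit markers and ratios per pressure bin.

    Bins are left-open at the bottom and right-open at the top:
    (-inf, e1], (e1, e2], ..., (ek, inf); together they partition the
    rows of each location stratum exactly.
    """
    if edges is None:
        edges = DEFAULT_ICP_EDGES if variable == "icp_hour" else DEFAULT_CPP_EDGES
    edges = tuple(edges)
    if list(edges) != sorted(edges):
        raise ValueError("bin edges must be ascending")
    variables = TABLE_VARS if variables is None else list(variables)
    labels = _bin_labels(edges)

    full_edges = [-np.inf, *edges, np.inf]
    work = frame.copy()
    work["_bin"] = pd.cut(work[variable], bins=full_edges, labels=labels,
                          include_lowest=True)
    rows = []
    for loc in sorted(work["location"].unique()):
        sub = work[work["location"] == loc]
        if not len(sub):
            continue
        for m in variables:
            for lab in labels:
                vals = sub.loc[sub["_bin"] == lab, [m, "patient_id"]]
                if weighting == "per_patient" and len(vals):
                    per = vals.groupby("patient_id")[m].mean()
                    mean = float(per.mean())
                    sd = float(per.std(ddof=1)) if len(per) > 1 else np.nan
                    n = int(len(per))
                else:
                    v = vals[m].to_numpy(dtype=float)
                    mean = float(np.mean(v)) if len(v) else np.nan
                    sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
                    n = int(len(v))
                rows.append({"location": loc, "marker": m, "bin": lab,
                             "mean": mean, "sd": sd, "n": n})
    return BinnedTable(variable, edges, pd.DataFrame(rows), weighting)


# ---------------------------------------------------------------------------
# lowess


def lowess_fit(x, y, span: float = 2.0 / 3.0, grid=None, iters: int = 2
               ) -> pd.DataFrame:
    """Locally weighted linear regression (tricube weights) with an SE band.

    Degree-1 local fits with ``iters`` robustifying iterations
    (bisquare-downweighted residuals), evaluated on ``grid`` (default: 50
    points across the x range).  The band is the standard error of the
    local weighted mean of squared residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("lowess needs >= 10 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    import statsmodels.api as sm

    grid = np.linspace(x.min(), x.max(), 50) if grid is None else np.asarray(grid, dtype=float)
    fit_grid = sm.nonparametric.lowess(y, x, frac=span, it=iters, xvals=grid)
    fit_data = sm.nonparametric.lowess(y, x, frac=span, it=iters, xvals=x)
    resid2 = (y - fit_data) ** 2

    k = max(2, int(np.ceil(span * len(x))))
    se = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        w = (1 - np.clip(d / h if h > 0 else d * np.inf, 0, 1) ** 3) ** 3
        sw = w.sum()
        if sw <= 0:
            se[i] = np.nan
            continue
        s2 = float(np.sum(w * resid2) / sw)
        neff = sw**2 / float(np.sum(w**2))
        se[i] = np.sqrt(s2 / neff)
    return pd.DataFrame({"x": grid, "fit": fit_grid, "se": se})


# ---------------------------------------------------------------------------
# trend check


def trend_check(frame: pd.DataFrame, markers=None, max_order: int = 3,
                pressures=("icp_hour", "cpp_hour"), tol: float = 0.02
                ) -> pd.DataFrame:
    """Polynomial time-since-insertion trends and their downstream impact.

    For each transformed marker, fits pooled polynomials of order
    2..max_order on the hour-since-insertion and reports r²; also
    reports how much detrending (removing the fitted polynomial) changes
    the pooled marker-pressure correlation, flagging changes beyond
    ``tol``.
    """
    from .preprocess import MARKER_T

    markers = list(MARKER_T) + ["lp_ratio", "lg_ratio"] if markers is None else list(markers)
    t = frame["hour"].to_numpy(dtype=float)
    rows = []
    for m in markers:
        y = frame[m].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(t)
        yv, tv = y[ok], t[ok]
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        for order in range(2, max_order + 1):
            if ss_tot == 0:
                r2 = 0.0
                detrended = yv - yv.mean()
            else:
                coeffs = np.polyfit(tv, yv, order)
                fitted = np.polyval(coeffs, tv)
                r2 = 1.0 - float(np.sum((yv - fitted) ** 2)) / ss_tot
                detrended = yv - fitted
            row = {"marker": m, "order": order, "r2": max(r2, 0.0)}
            for pcol in pressures:
                p = frame[pcol].to_numpy(dtype=float)[ok]
                r_raw = np.corrcoef(yv, p)[0, 1] if np.std(yv) > 0 else np.nan
                r_det = (np.corrcoef(detrended, p)[0, 1]
                         if np.std(detrended) > 0 else np.nan)
                row[f"corr_change_{pcol}"] = (abs(r_det - r_raw)
                                              if np.isfinite(r_raw) and np.isfinite(r_det)
                                              else np.nan)
            row["detrending_matters"] = any(
                np.isfinite(row[f"corr_change_{p}"]) and row[f"corr_change_{p}"] > tol
                for p in pressures)
            rows.append(row)
    return pd.DataFrame(rows)
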