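"""Short-term (differenced / normalized) and per-subject mean analyses.

Because marker levels are dominated by slow, subject-specific processes,
three complementary probes isolate the short-term signal:

* k-hour differences (k = 1..4) of markers paired with pressure levels
  and pressure differences, computed only across *exact* k-hour spacings
  within a patient (gaps break pairs rather than bridging them);
* per-subject z-normalization (each patient rescaled to mean 0, SD 1),
  which removes subject means before pooled regression;
* per-subject whole-period means regressed on mean pressures, with
  significance referred to the number of patients and influential
  patients screened by Cook's distance > 1 (excluded on refit and
  reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import ANALYSIS_VARS, MARKER_T


@dataclass
class RegressionReport:
    design: str
    response: str
    predictors: list
    mode: str                  # pooled | subject_means
    stratum: str | None
    coef: pd.Series
    se: pd.Series
    p: pd.Series
    r2: float
    p_model: float             # F-test of the full design
    n: int
    excluded: list = field(default_factory=list)  # (patient_id, cooks_d)

    def to_row(self) -> dict:
        return {
            "design": self.design, "response": self.response,
            "predictors": "+".join(self.predictors), "mode": self.mode,
            "stratum": self.stratum or "all", "r2": self.r2,
            "p_model": self.p_model, "n": self.n,
            "n_excluded": len(self.excluded),
        }


def difference_series(frame: pd.DataFrame, k: int,
                      columns=None) -> pd.DataFrame:
    """Within-patient k-hour differences over exact k-hour gaps.

    Returns one row per valid (t-k, t) pair with ``d_<col>`` difference
    columns plus the level columns at time t.  Pairs spanning dropped
    hours (actual gap != k) are excluded.
    """
    if not 1 <= k <= 4:
        raise ValueError("difference order k must be in 1..4")
    columns = list(ANALYSIS_VARS) + ["icp_hour", "cpp_hour"] if columns is None else list(columns)
    cur = frame[["patient_id", "location", "hour"] + columns].copy()
    prev = cur.copy()
    prev["hour"] = prev["hour"] + k
    merged = cur.merge(prev, on=["patient_id", "location", "hour"],
                       suffixes=("", "_prev"))
    for c in columns:
        merged[f"d_{c}"] = merged[c] - merged[f"{c}_prev"]
    return merged.drop(columns=[f"{c}_prev" for c in columns])


def normalize_per_subject(frame: pd.DataFrame, columns=None,
                          min_rows: int = 3) -> pd.DataFrame:
    """Per-patient z-scores; patients with < min_rows rows or a constant
    variable are dropped (they carry no within-subject information)."""
    columns = list(ANALYSIS_VARS) + ["icp_hour", "cpp_hour"] if columns is None else list(columns)
    out = []
    for pid, g in frame.groupby("patient_id", sort=True):
        if len(g) < min_rows:
            continue
        z = g.copy()
        keep = True
        for c in columns:
            v = g[c].to_numpy(dtype=float)
            sd = np.std(v, ddof=0)
            if sd == 0 or not np.isfinite(sd):
                keep = False
                break
            z[c] = (v - v.mean()) / sd
        if keep:
            out.append(z)
    if not out:
        return frame.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


def _ols_report(y, X, names, design, response, mode, stratum,
                df_resid=None) -> tuple:
    A = sm.add_constant(X)
    cond = np.linalg.cond(A.T @ A)
    if cond > 1e12:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    model = sm.OLS(y, A)
    res = model.fit()
    if df_resid is not None and df_resid != res.df_resid:
        # re-reference t / F statistics to the stated residual df
        from scipy import stats as sps
        p = pd.Series(2 * sps.t.sf(np.abs(np.asarray(res.tvalues)), df_resid),
                      index=["intercept"] + names)
        p_model = float(sps.f.sf(res.fvalue, res.df_model, df_resid))
    else:
        p = pd.Series(np.asarray(res.pvalues), index=["intercept"] + names)
        p_model = float(res.f_pvalue)
    coef = pd.Series(np.asarray(res.params), index=["intercept"] + names)
    se = pd.Series(np.asarray(res.bse), index=["intercept"] + names)
    return res, coef, se, p, float(res.rsquared), p_model


def regress(frame: pd.DataFrame, response: str, predictors,
            mode: str = "pooled", stratum: str | None = None,
            cooks_threshold: float = 1.0, design: str = "") -> RegressionReport:
    """OLS probe of MD vs. pressure.

    ``mode='pooled'`` treats rows as observations.  ``mode='subject_means'``
    first collapses each patient to their whole-period mean, tests
    against n_patients (residual df = n_patients - p - 1), screens
    influential patients with Cook's distance > ``cooks_threshold`` and
    refits without them, reporting every exclusion with its distance.
    """
    predictors = list(predictors)
    if stratum is not None:
        frame = frame[frame["location"] == stratum]

    if mode == "subject_means":
        data = frame.groupby("patient_id")[[response] + predictors].mean().reset_index()
    elif mode == "pooled":
        data = frame[["patient_id", response] + predictors].dropna().reset_index(drop=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(data) <= len(predictors) + 2:
        raise ValueError("too few observations for the design")
    y = data[response].to_numpy(dtype=float)
    X = data[predictors].to_numpy(dtype=float)

    res, coef, se, p, r2, p_model = _ols_report(
        y, X, predictors, design, response, mode, stratum)

    excluded = []
    if mode == "subject_means":
        cooks = res.get_influence().cooks_distance[0]
        bad = np.flatnonzero(cooks > cooks_threshold)
        if len(bad):
            excluded = [(data["patient_id"].iloc[i], float(cooks[i])) for i in bad]
            keep = np.ones(len(y), dtype=bool)
            keep[bad] = False
            y, X = y[keep], X[keep]
            data = data[keep]
            res, coef, se, p, r2, p_model = _ols_report(
                y, X, predictors, design, response, mode, stratum)

    return RegressionReport(
        design=design or f"{response}~{'+'.join(predictors)}",
        response=response, predictors=predictors, mode=mode, stratum=stratum,
        coef=coef, se=se, p=p, r2=r2, p_model=p_model, n=len(y),
        excluded=excluded,
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def delta_report(frame: pd.DataFrame, ks=(1, 2, 3, 4),
                 responses=("icp_hour", "cpp_hour"),
                 markers=None) -> pd.DataFrame:
    """Grid of differenced regressions: Delta-markers vs. pressure levels
    and pressure differences, per stratum, univariate and multivariate.

    Reports raw model p-values alongside Holm-adjusted ones across the
    whole design grid.
    """
    markers = list(MARKER_T) + ["lp_ratio", "lg_ratio"] if markers is None else list(markers)
    rows = []
    strata = [None] + sorted(frame["location"].unique().tolist())
    for k in ks:
        for stratum in strata:
            sub = frame if stratum is None else frame[frame["location"] == stratum]
            if not len(sub):
                continue
            dk = difference_series(sub, k, columns=markers + list(responses))
            for resp_kind in ("level", "delta"):
                for response in responses:
                    ycol = response if resp_kind == "level" else f"d_{response}"
                    designs = [[f"d_{m}"] for m in markers]
                    if len(markers) > 1:
                        designs.append([f"d_{m}" for m in markers])
                    for preds in designs:
                        try:
                            rep = regress(dk, ycol, preds, mode="pooled",
                                          design=f"k={k},{resp_kind}")
                        except ValueError:
                            continue
                        row = rep.to_row()
                        row.update({"k": k, "response_kind": resp_kind,
                                    "stratum": stratum or "all",
                                    "univariate": len(preds) == 1})
                        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p_model"].fillna(1.0).to_numpy())
    return out
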