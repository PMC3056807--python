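"""Autocorrelation, lagged cross-correlation and permutation nulls.

The central question these tools answer is whether an apparent
correlation between a slowly-varying biomarker and a co-monitored
pressure reflects hour-to-hour (within-subject) dynamics or merely
differences between subjects' long-run means.  Three ingredients:

* pooled / per-patient lagged correlations over an unbalanced panel
  (pairs are always formed within a patient, never across patients);
* a within-subject permutation null: each patient's marker values are
  re-ordered uniformly at random while the pressure series stays fixed,
  which destroys temporal alignment but preserves every subject's
  marginal distribution (and hence all between-subject structure) — the
  Monte-Carlo percentile band of the re-computed correlogram is the
  reference against which the observed curve is judged;
* a full-scramble control permuting values across the whole cohort,
  which destroys between-subject structure too and should sit at zero;
* the subject-identity variance decomposition: the r-squared of
  regressing a variable on patient-indicator dummies, i.e.
  1 - SS_within / SS_total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# panel layout


def panel_matrix(frame: pd.DataFrame, column: str) -> tuple[np.ndarray, list]:
    """Patients x hours matrix (NaN padded) keyed on the ``hour`` index."""
    pids = list(pd.unique(frame["patient_id"]))
    n_hours = int(frame["hour"].max()) + 1 if len(frame) else 0
    mat = np.full((len(pids), n_hours), np.nan)
    idx = {p: i for i, p in enumerate(pids)}
    rows = frame["patient_id"].map(idx).to_numpy()
    cols = frame["hour"].to_numpy(dtype=int)
    mat[rows, cols] = frame[column].to_numpy(dtype=float)
    return mat, pids


def _corr_from_sums(n, sx, sy, sxx, syy, sxy):
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r = cov / np.sqrt(vx * vy)
    return r


def _lagged_slices(X: np.ndarray, Y: np.ndarray, lag: int):
    """Aligned views pairing X at hour t with Y at hour t + lag."""
    H = X.shape[1]
    if abs(lag) >= H:
        return None, None
    if lag >= 0:
        return X[:, : H - lag], Y[:, lag:]
    return X[:, -lag:], Y[:, : H + lag]


def pooled_lagged_corr(X: np.ndarray, Y: np.ndarray, lags, min_pairs: int = 30) -> np.ndarray:
    """Pearson correlation of (x_t, y_{t+lag}) pooled over all subject-hours."""
    out = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        xs, ys = _lagged_slices(X, Y, int(lag))
        if xs is None:
            continue
        m = np.isfinite(xs) & np.isfinite(ys)
        n = int(m.sum())
        if n < min_pairs:
            continue
        x = np.where(m, xs, 0.0)
        y = np.where(m, ys, 0.0)
        out[i] = _corr_from_sums(n, x.sum(), y.sum(), (x * x).sum(),
                                 (y * y).sum(), (x * y).sum())
    return out


def per_patient_lagged_corr(X: np.ndarray, Y: np.ndarray, lags,
                            min_pairs: int = 3) -> np.ndarray:
    """Per-patient Pearson correlations combined by pair-count weighting."""
    out = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        xs, ys = _lagged_slices(X, Y, int(lag))
        if xs is None:
            continue
        m = np.isfinite(xs) & np.isfinite(ys)
        n = m.sum(axis=1).astype(float)
        x = np.where(m, xs, 0.0)
        y = np.where(m, ys, 0.0)
        r = _corr_from_sums(n, x.sum(axis=1), y.sum(axis=1), (x * x).sum(axis=1),
                            (y * y).sum(axis=1), (x * y).sum(axis=1))
        ok = np.isfinite(r) & (n >= min_pairs)
        if ok.any():
            out[i] = np.average(r[ok], weights=n[ok])
    return out


# ---------------------------------------------------------------------------
# public surfaces


def acf(frame: pd.DataFrame, variable: str, max_lag: int = 30,
        pooling: str = "pooled", min_pairs: int = 3) -> pd.DataFrame:
    """Autocorrelation of ``variable`` at lags 0..max_lag.

    ``pooling='pooled'`` computes one Pearson correlation over all
    in-patient hour pairs of the cohort; ``'per_patient'`` computes the
    correlation per patient and averages with pair-count weights.
    Constant series yield missing (NaN) lags, never zero.
    """
    X, _ = panel_matrix(frame, variable)
    lags = np.arange(max_lag + 1)
    fn = pooled_lagged_corr if pooling == "pooled" else per_patient_lagged_corr
    r = fn(X, X, lags, min_pairs=min_pairs)
    r[0] = 1.0 if np.isfinite(X).any() else np.nan
    return pd.DataFrame({"lag": lags, "r": r})


def ccf(frame: pd.DataFrame, md_variable: str, pressure_variable: str,
        max_lag: int = 35, pooling: str = "pooled",
        min_pairs: int = 30) -> pd.DataFrame:
    """Lagged cross-correlation; positive lag = pressure AFTER the MD sample."""
    X, _ = panel_matrix(frame, md_variable)
    Y, _ = panel_matrix(frame, pressure_variable)
    lags = np.arange(-max_lag, max_lag + 1)
    fn = pooled_lagged_corr if pooling == "pooled" else per_patient_lagged_corr
    kw = {"min_pairs": min_pairs} if pooling == "pooled" else {}
    return pd.DataFrame({"lag": lags, "r": fn(X, Y, lags, **kw)})


@dataclass
class Correlogram:
    """Observed lagged correlations plus their permutation-null band."""

    md_variable: str
    pressure_variable: str
    lags: np.ndarray
    r: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scramble_r: np.ndarray
    pooling: str
    n_permutations: int
    level: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lag": self.lags, "r": self.r, "lo": self.lower, "hi": self.upper,
            "scramble_r": self.scramble_r,
        })

    def outside_band(self) -> np.ndarray:
        """Boolean mask of lags where the observed r escapes the null band."""
        ok = np.isfinite(self.r) & np.isfinite(self.lower) & np.isfinite(self.upper)
        out = np.zeros(len(self.lags), dtype=bool)
        out[ok] = (self.r[ok] < self.lower[ok]) | (self.r[ok] > self.upper[ok])
        return out


def _permute_rows_within(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle each row's observed values among its observed positions."""
    out = M.copy()
    for i in range(M.shape[0]):
        obs = np.flatnonzero(np.isfinite(M[i]))
        if len(obs) > 1:
            out[i, obs] = M[i, obs[rng.permutation(len(obs))]]
    return out


def _scramble_all(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle observed values across the whole cohort (between subjects too)."""
    out = M.copy()
    obs = np.isfinite(M)
    vals = M[obs]
    out[obs] = vals[rng.permutation(len(vals))]
    return out


def _conditional_band(X, Y, lags, B, level, rng, min_pairs):
    """Per-lag within-subject permutation band (pointwise-exact null).

    At lag l the statistic pairs each patient's marker values at hours t
    with pressures at t + l; the conditional null permutes each patient's
    marker values among exactly the rows that enter that lag's pairing.
    Because the pooled marker and pressure marginals are then invariant,
    only the cross-moment varies across replicates.  This coincides with
    the naive whole-series scramble at lag 0 and, unlike it, stays
    calibrated at long lags, where the naive null fills the shortened
    pairing window with an unrepresentatively well-mixed subset of an
    autocorrelated series.
    """
    alpha = (1.0 - level) / 2.0
    lower = np.full(len(lags), np.nan)
    upper = np.full(len(lags), np.nan)
    for li, lag in enumerate(lags):
        xs, ys = _lagged_slices(X, Y, int(lag))
        if xs is None:
            continue
        m = np.isfinite(xs) & np.isfinite(ys)
        n = int(m.sum())
        if n < min_pairs:
            continue
        xcat = xs[m]
        ycat = ys[m]
        sx, sy = xcat.sum(), ycat.sum()
        denom = math.sqrt((np.dot(xcat, xcat) - sx**2 / n)
                          * (np.dot(ycat, ycat) - sy**2 / n))
        if denom <= 0:
            continue
        cross = np.zeros(B)
        for i in range(xs.shape[0]):
            xi = xs[i][m[i]]
            yi = ys[i][m[i]]
            k = len(xi)
            if k == 0:
                continue
            if k == 1:
                cross += xi[0] * yi[0]
                continue
            perm = np.argsort(rng.random((B, k)), axis=1)
            cross += (xi[perm] * yi).sum(axis=1)
        r_null = (cross - sx * sy / n) / denom
        lower[li] = np.percentile(r_null, 100 * alpha)
        upper[li] = np.percentile(r_null, 100 * (1 - alpha))
    return lower, upper


def permute_within_subjects(frame: pd.DataFrame, md_variable: str,
                            pressure_variable: str, max_lag: int = 35,
                            B: int = 1000, level: float = 0.95, seed: int = 0,
                            pooling: str = "pooled", n_scramble: int | None = None,
                            min_pairs: int = 30) -> Correlogram:
    """Observed cross-correlogram with a within-subject permutation band.

    The Monte-Carlo band re-orders every patient's marker values uniformly
    at random while the pressure series stays fixed and reads off the
    pointwise percentile interval at ``level``.  In pooled mode the band
    is the per-lag conditional permutation null (see
    :func:`_conditional_band`); in per-patient mode B whole-series
    scrambles are used.  A full cross-patient scramble control (mean over
    ``n_scramble`` replicates, default min(B, 100)) is reported alongside.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile band")
    if not 0 < level < 1 or B * (1 - level) / 2 < 1:
        raise ValueError(f"B={B} too small for level={level}")
    rng = np.random.default_rng(seed)
    X, _ = panel_matrix(frame, md_variable)
    Y, _ = panel_matrix(frame, pressure_variable)
    lags = np.arange(-max_lag, max_lag + 1)
    fn = pooled_lagged_corr if pooling == "pooled" else per_patient_lagged_corr
    kw = {"min_pairs": min_pairs} if pooling == "pooled" else {}

    r_obs = fn(X, Y, lags, **kw)
    if pooling == "pooled":
        lower, upper = _conditional_band(X, Y, lags, B, level, rng, min_pairs)
    else:
        null = np.empty((B, len(lags)))
        for b in range(B):
            null[b] = fn(_permute_rows_within(X, rng), Y, lags, **kw)
        alpha = (1.0 - level) / 2.0
        lower = np.nanpercentile(null, 100 * alpha, axis=0)
        upper = np.nanpercentile(null, 100 * (1 - alpha), axis=0)

    n_scramble = min(B, 100) if n_scramble is None else n_scramble
    scr = np.empty((n_scramble, len(lags)))
    for b in range(n_scramble):
        scr[b] = fn(_scramble_all(X, rng), Y, lags, **kw)
    return Correlogram(md_variable, pressure_variable, lags, r_obs, lower, upper,
                       np.nanmean(scr, axis=0), pooling, B, level, seed)


@dataclass
class IdentityVarianceReport:
    """r² of subject-indicator regressions, one per analysis variable."""

    r2: dict
    n_patients: int
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": list(self.r2), "r2": list(self.r2.values()),
                             "n_patients": self.n_patients, "n_samples": self.n_samples})


def identity_variance(frame: pd.DataFrame, variables) -> IdentityVarianceReport:
    """Share of variance explained by subject identity alone.

    Equivalent to OLS of the variable on patient dummies:
    r² = 1 - SS_within / SS_total.
    """
    if frame["patient_id"].nunique() < 2:
        raise ValueError("identity variance needs >= 2 patients")
    if isinstance(variables, str):
        variables = [variables]
    r2 = {}
    for v in variables:
        x = frame[v].to_numpy(dtype=float)
        ok = np.isfinite(x)
        x = x[ok]
        g = frame["patient_id"].to_numpy()[ok]
        ss_total = float(np.sum((x - x.mean()) ** 2))
        df = pd.DataFrame({"x": x, "g": g})
        within = df.groupby("g")["x"].transform("mean")
        ss_within = float(np.sum((x - within.to_numpy()) ** 2))
        r2[v] = 1.0 - ss_within / ss_total if ss_total > 0 else np.nan
    return IdentityVarianceReport(r2, int(frame["patient_id"].nunique()), int(len(frame)))
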