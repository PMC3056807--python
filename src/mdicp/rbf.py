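"""Radial-basis-function network regression with leave-one-subject-out CV.

A deliberately classical RBF regressor: Gaussian bases whose centers come
from k-means on the standardized predictors, per-center widths set to the
mean distance to the two nearest other centers, and a ridge-regularized
linear output layer (bias unpenalized).  Model capacity (number of nodes,
ridge strength) is chosen by nested, patient-grouped cross-validation so
that held-out patients never influence either the fitted weights or the
model selection — the property that separates genuine, transferable
marker-pressure coupling from subject-mean memorisation.

The permuted control re-runs the identical procedure after shuffling each
patient's marker rows against their own pressure hours; any predictive
skill that survives it rests on subject means, not on temporal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .preprocess import ANALYSIS_VARS


@dataclass
class RBFModel:
    centers: np.ndarray        # (k, d) in standardized predictor space
    widths: np.ndarray         # (k,) Gaussian scales
    weights: np.ndarray        # (k,) output layer
    bias: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    n_nodes: int
    ridge: float
    feature_names: list = field(default_factory=list)

    def _design(self, Z: np.ndarray) -> np.ndarray:
        d2 = cdist(Z, self.centers, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.widths[None, :] ** 2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.x_mean) / self.x_scale
        return self._design(Z) @ self.weights + self.bias


def _widths_from_centers(centers: np.ndarray, Z: np.ndarray) -> np.ndarray:
    k = len(centers)
    if k >= 3:
        d = cdist(centers, centers)
        np.fill_diagonal(d, np.inf)
        w = np.sort(d, axis=1)[:, :2].mean(axis=1)
    elif k == 2:
        w = np.full(2, float(np.linalg.norm(centers[0] - centers[1])))
    else:
        w = np.array([float(np.mean(np.linalg.norm(Z - centers[0], axis=1)))])
    w = np.where(w > 0, w, 1.0)
    return w


def fit_rbf(X: np.ndarray, y: np.ndarray, n_nodes: int, seed: int = 0,
            ridge: float = 1e-3, feature_names=None) -> RBFModel:
    """Fit a Gaussian RBF network (k-means centers + ridge output layer)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_nodes > n:
        raise ValueError(f"n_nodes={n_nodes} exceeds {n} training rows")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    if n_nodes == n:
        centers = Z.copy()
    else:
        km = KMeans(n_clusters=n_nodes, n_init=4, random_state=int(seed) % (2**31))
        km.fit(Z)
        centers = km.cluster_centers_
    widths = _widths_from_centers(centers, Z)

    model = RBFModel(centers, widths, np.zeros(n_nodes), 0.0, mu, sd,
                     n_nodes, ridge, list(feature_names or []))
    Phi = model._design(Z)
    A = np.column_stack([Phi, np.ones(n)])
    D = np.eye(n_nodes + 1) * ridge
    D[-1, -1] = 0.0  # bias unpenalized
    coefs = np.linalg.solve(A.T @ A + D, A.T @ y)
    model.weights = coefs[:-1]
    model.bias = float(coefs[-1])
    return model


@dataclass
class CVPrediction:
    """Pooled held-out performance of the LOSO procedure."""

    response: str
    stratum: str | None
    r_per_repeat: list
    r_mean: float
    r_sd: float
    predictions: pd.DataFrame  # patient_id, hour, true, pred (first repeat)
    chosen_nodes: dict         # node count -> times selected (first repeat)
    permuted: bool
    seed: int
    n_patients: int
    n_rows: int

    @property
    def r(self) -> float:
        return self.r_mean


def _pooled_r(y_true, y_pred) -> float:
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return np.nan
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def _grouped_folds(pids: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Patients shuffled then dealt into n_folds groups."""
    u = np.array(sorted(set(pids)))
    order = rng.permutation(len(u))
    return [u[order[f::n_folds]] for f in range(n_folds)]


def _select_model(X, y, pids, node_grid, ridge_grid, seed, rng):
    """Inner patient-grouped CV over (nodes, ridge); returns the best pair."""
    n_pat = len(set(pids))
    n_folds = min(5, n_pat)
    folds = _grouped_folds(pids, n_folds, rng)
    best, best_mse = None, np.inf
    for nodes in node_grid:
        for ridge in ridge_grid:
            sse = 0.0
            n_tot = 0
            ok = True
            for hold in folds:
                tr = ~np.isin(pids, hold)
                if nodes > tr.sum() or tr.sum() == 0 or (~tr).sum() == 0:
                    ok = False
                    break
                m = fit_rbf(X[tr], y[tr], nodes, seed=seed, ridge=ridge)
                pred = m.predict(X[~tr])
                sse += float(np.sum((y[~tr] - pred) ** 2))
                n_tot += int((~tr).sum())
            if ok and n_tot and sse / n_tot < best_mse:
                best_mse = sse / n_tot
                best = (nodes, ridge)
    if best is None:
        raise ValueError("no feasible (nodes, ridge) combination in the grid")
    return best


def loso_cv(frame: pd.DataFrame, response: str, predictors=None,
            stratum: str | None = None, node_grid=(2, 4, 8),
            ridge_grid=(1e-3,), repeats: int = 5, seed: int = 0,
            permute_within: bool = False) -> CVPrediction:
    """Leave-one-patient-out cross-validated RBF prediction.

    The outer loop holds out one patient entirely; the inner loop selects
    (nodes, ridge) by patient-grouped CV on the remaining patients only.
    The pooled Pearson r of true vs. predicted over all held-out rows is
    reported, with spread (mean +/- SD) over ``repeats`` re-runs differing
    in RNG stream (k-means initialisation, fold assignment, permutation).
    """
    if not len(node_grid):
        raise ValueError("node_grid is empty")
    predictors = list(ANALYSIS_VARS) if predictors is None else list(predictors)
    if stratum is not None:
        frame = frame[frame["location"] == stratum]
    frame = frame.reset_index(drop=True)
    pids_all = frame["patient_id"].to_numpy()
    if len(set(pids_all)) < 5:
        raise ValueError("need >= 5 patients for LOSO CV")

    rs, first_preds, chosen = [], None, {}
    for rep in range(repeats):
        rng = np.random.default_rng([int(seed), rep])
        work = frame
        if permute_within:
            work = frame.copy()
            for pid in pd.unique(pids_all):
                rows = np.flatnonzero(pids_all == pid)
                perm = rows[rng.permutation(len(rows))]
                work.loc[rows, predictors] = frame.loc[perm, predictors].to_numpy()
        X = work[predictors].to_numpy(dtype=float)
        y = work[response].to_numpy(dtype=float)
        pids = work["patient_id"].to_numpy()

        y_true, y_pred, rec_pid, rec_hour = [], [], [], []
        for pid in sorted(set(pids)):
            hold = pids == pid
            tr = ~hold
            nodes, ridge = _select_model(X[tr], y[tr], pids[tr], node_grid,
                                         ridge_grid, seed + rep, rng)
            model = fit_rbf(X[tr], y[tr], nodes, seed=seed + rep, ridge=ridge,
                            feature_names=predictors)
            pred = model.predict(X[hold])
            y_true.append(y[hold])
            y_pred.append(pred)
            rec_pid.extend([pid] * int(hold.sum()))
            rec_hour.extend(work.loc[hold, "hour"].tolist())
            if rep == 0:
                chosen[nodes] = chosen.get(nodes, 0) + 1
        y_true = np.concatenate(y_true)
        y_pred = np.concatenate(y_pred)
        rs.append(_pooled_r(y_true, y_pred))
        if rep == 0:
            first_preds = pd.DataFrame({"patient_id": rec_pid, "hour": rec_hour,
                                        "true": y_true, "pred": y_pred})

    rs_arr = np.asarray(rs, dtype=float)
    return CVPrediction(
        response=response, stratum=stratum, r_per_repeat=rs,
        r_mean=float(np.nanmean(rs_arr)),
        r_sd=float(np.nanstd(rs_arr, ddof=1)) if len(rs) > 1 else 0.0,
        predictions=first_preds, chosen_nodes=chosen, permuted=permute_within,
        seed=seed, n_patients=len(set(pids_all)), n_rows=len(frame),
    )


def permuted_control(frame: pd.DataFrame, response: str, **kwargs) -> CVPrediction:
    """LOSO CV after per-patient scrambling of marker rows vs. their hours."""
    return loso_cv(frame, response, permute_within=True, **kwargs)


# ---------------------------------------------------------------------------
# representation search


DEFAULT_CUTOFFS = {"icp_hour": (15.0, 20.0, 25.0, 30.0),
                   "cpp_hour": (40.0, 50.0, 60.0, 70.0, 80.0, 90.0)}


def _loo_linear_r(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out linear-regression correlation of true vs. predicted."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        m = np.ones(n, dtype=bool)
        m[i] = False
        A = np.column_stack([np.ones(m.sum()), X[m]])
        coef, *_ = np.linalg.lstsq(A, y[m], rcond=None)
        preds[i] = coef[0] + X[i] @ coef[1:]
    return _pooled_r(y, preds)


def representation_search(frame: pd.DataFrame, pressure: str = "icp_hour",
                          cutoffs=None, predictors=None,
                          stratum: str | None = None) -> pd.DataFrame:
    """Rank response representations by cross-validated predictability.

    Candidate representations of each patient's pressure exposure: the
    whole-period hourly mean, hours above / below each cutoff, and the
    percentage of monitored (complete-set) hours above / below each
    cutoff.  Each is predicted from the patient's mean MD profile by
    leave-one-patient-out linear regression; zero-variance
    representations are flagged and skipped.
    """
    predictors = list(ANALYSIS_VARS) if predictors is None else list(predictors)
    cutoffs = (DEFAULT_CUTOFFS.get(pressure, ()) if cutoffs is None else cutoffs)
    if stratum is not None:
        frame = frame[frame["location"] == stratum]

    g = frame.groupby("patient_id")
    X = g[predictors].mean().to_numpy()
    press = {"hourly_mean": g[pressure].mean().to_numpy()}
    for c in cutoffs:
        above = g[pressure].apply(lambda s: float((s > c).sum()))
        press[f"hours_above_{c:g}"] = above.to_numpy()
        press[f"hours_below_{c:g}"] = (g[pressure].count() - above).to_numpy()
        press[f"pct_above_{c:g}"] = (above / g[pressure].count() * 100.0).to_numpy()
        press[f"pct_below_{c:g}"] = 100.0 - press[f"pct_above_{c:g}"]

    rows = []
    for name, y in press.items():
        if np.std(y) == 0:
            rows.append({"representation": name, "r": np.nan, "degenerate": True})
            continue
        rows.append({"representation": name, "r": _loo_linear_r(X, y),
                     "degenerate": False})
    out = pd.DataFrame(rows)
    out["rank"] = (-out["r"]).rank(method="min", na_option="bottom").astype(int)
    return out.sort_values("rank").reset_index(drop=True)
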