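"""Linear mixed models with ARMA(1,1) within-patient residual correlation.

Model: for patient i with observations at hour offsets h_1 < ... < h_{n_i},

    y_i = X_i beta + b_i 1 + e_i,   b_i ~ N(0, sigma_b^2),
    e_i ~ N(0, sigma^2 R_i),        R_i[a, c] = rho(|h_a - h_c|),

where rho is the stationary ARMA(1,1) autocorrelation

    rho(0) = 1,   rho(k) = gamma * phi^(k-1),
    gamma = (1 + phi*theta) * (phi + theta) / (1 + 2*phi*theta + theta^2).

Estimation is restricted maximum likelihood (REML): beta is profiled out
by generalized least squares at each set of covariance parameters, and

    -2 l_R = (n - p) log 2 pi + sum_i log|Sigma_i| + log|X' Sigma^-1 X|
             + r' Sigma^-1 r,       Sigma_i = sigma_b^2 J + sigma^2 R_i,

is minimised over (log sigma_b, log sigma, atanh phi, atanh theta), the
transforms enforcing positivity and stationarity.  Observed hour offsets
(not row indices) enter R_i, so gaps from dropped vials decay the
correlation by the true elapsed time.  Fixed-effect inference is by Wald
z tests against a normal reference.

This module deliberately avoids any mixed-model library; the likelihood
and its optimisation are implemented directly so they can be audited
against a dense multivariate-normal evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .preprocess import ANALYSIS_VARS


class ConvergenceError(RuntimeError):
    pass


def arma11_correlation(phi: float, theta: float, lag) -> np.ndarray | float:
    """Stationary ARMA(1,1) autocorrelation at integer lag(s) >= 0."""
    if not abs(phi) < 1 or not abs(theta) < 1:
        raise ValueError(f"non-stationary ARMA parameters phi={phi}, theta={theta}")
    k = np.asarray(lag)
    if np.any(k < 0):
        raise ValueError("lag must be >= 0")
    gamma = (1 + phi * theta) * (phi + theta) / (1 + 2 * phi * theta + theta**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # phi ** (k-1) with the k=0 slot overwritten below; guard phi=0
        base = np.where(k >= 1, gamma * np.float_power(phi, np.maximum(k - 1, 0)), 1.0)
    out = np.where(k == 0, 1.0, base)
    return float(out) if np.isscalar(lag) or np.ndim(lag) == 0 else out


@dataclass
class MixedFit:
    """REML fit summary: fixed effects, variance components, ARMA parameters."""

    response: str
    predictors: list
    stratum: str | None
    beta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    sigma_b: float
    sigma: float
    phi: float
    theta: float
    rho1: float  # implied adjacent-hour residual correlation
    loglik_reml: float
    converged: bool
    n_obs: int
    n_patients: int
    grad_norm: float
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.beta, "se": self.se, "z": self.z, "p": self.p})

    def to_dict(self) -> dict:
        return {
            "response": self.response, "stratum": self.stratum,
            "predictors": list(self.predictors),
            "beta": self.beta.to_dict(), "se": self.se.to_dict(), "p": self.p.to_dict(),
            "sigma_b": self.sigma_b, "sigma": self.sigma,
            "phi": self.phi, "theta": self.theta, "rho1": self.rho1,
            "loglik_reml": self.loglik_reml, "converged": self.converged,
            "n_obs": self.n_obs, "n_patients": self.n_patients,
        }


# ---------------------------------------------------------------------------
# likelihood machinery


def _blocks_from_frame(frame, response, predictors):
    """Per-patient (X, y, hour offsets) with an intercept column prepended."""
    blocks = []
    for _, g in frame.groupby("patient_id", sort=True):
        g = g.sort_values("hour")
        X = np.column_stack([np.ones(len(g))] +
                            [g[p].to_numpy(dtype=float) for p in predictors])
        y = g[response].to_numpy(dtype=float)
        h = g["hour"].to_numpy(dtype=float)
        blocks.append((X, y, h))
    return blocks


def _neg2_reml(params, blocks, free, fixed, p_dim):
    """-2 REML log-likelihood (without the 2-pi constant) at transformed params."""
    vals = dict(fixed)
    for name, v in zip(free, params):
        if name in ("sigma_b", "sigma"):
            vals[name] = math.exp(v)
        else:
            vals[name] = math.tanh(v)
    sb2 = vals["sigma_b"] ** 2
    s2 = vals["sigma"] ** 2
    phi, theta = vals["phi"], vals["theta"]

    logdet = 0.0
    XtWX = np.zeros((p_dim, p_dim))
    XtWy = np.zeros(p_dim)
    ytWy = 0.0
    cache = {}
    for X, y, h in blocks:
        key = tuple(h - h[0])
        L = cache.get(key)
        if L is None:
            lagmat = np.abs(h[:, None] - h[None, :])
            R = arma11_correlation(phi, theta, np.round(lagmat).astype(int))
            Sigma = sb2 + s2 * R
            try:
                L = linalg.cholesky(Sigma, lower=True)
            except linalg.LinAlgError:
                return np.inf, None, None
            cache[key] = L
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        Xs = linalg.solve_triangular(L, X, lower=True)
        ys = linalg.solve_triangular(L, y, lower=True)
        XtWX += Xs.T @ Xs
        XtWy += Xs.T @ ys
        ytWy += ys @ ys
    try:
        cF = linalg.cho_factor(XtWX)
    except linalg.LinAlgError:
        return np.inf, None, None
    beta = linalg.cho_solve(cF, XtWy)
    logdet_X = 2.0 * float(np.sum(np.log(np.diag(cF[0]))))
    quad = ytWy - float(beta @ XtWy)
    return logdet + logdet_X + quad, beta, XtWX


def reml_loglik(frame, response, predictors, sigma_b, sigma, phi, theta):
    """REML log-likelihood (with constant) at fixed parameter values."""
    blocks = _blocks_from_frame(frame, response, predictors)
    p_dim = len(predictors) + 1
    n = sum(len(y) for _, y, _ in blocks)
    n2, _, _ = _neg2_reml([], blocks, [],
                          {"sigma_b": sigma_b, "sigma": sigma, "phi": phi,
                           "theta": theta}, p_dim)
    return -0.5 * (n2 + (n - p_dim) * math.log(2 * math.pi))


def _standardize(frame, predictors):
    out = frame.copy()
    scale = {}
    for p in predictors:
        v = out[p].to_numpy(dtype=float)
        mu, sd = float(np.mean(v)), float(np.std(v))
        sd = sd if sd > 0 else 1.0
        out[p] = (v - mu) / sd
        scale[p] = (mu, sd)
    return out, scale


def fit_reml(frame: pd.DataFrame, response: str, predictors=None,
             stratum: str | None = None, fixed: dict | None = None,
             n_starts: int = 3, standardize: bool = True,
             gtol: float = 1e-4) -> MixedFit:
    """Fit the random-intercept + ARMA(1,1) model by REML.

    ``fixed`` pins covariance parameters (e.g. ``{'sigma_b': 0, 'phi': 0,
    'theta': 0}`` reduces the fit to pooled OLS).  Predictors default to
    the transformed markers plus both ratios; they are standardized for
    optimisation and coefficients are reported on the original scale.
    """
    predictors = list(ANALYSIS_VARS) if predictors is None else list(predictors)
    if stratum is not None:
        frame = frame[frame["location"] == stratum]
    n_pat = frame["patient_id"].nunique()
    if n_pat < 5 and not (fixed and "sigma_b" in fixed):
        raise ValueError("need >= 5 patients for a mixed fit")

    work, scale = _standardize(frame, predictors) if standardize else (frame, None)
    blocks = _blocks_from_frame(work, response, predictors)
    p_dim = len(predictors) + 1
    n = sum(len(y) for _, y, _ in blocks)

    X_all = np.vstack([b[0] for b in blocks])
    cond = np.linalg.cond(X_all.T @ X_all)
    if cond > 1e10:
        raise ValueError(f"predictors are collinear (condition number {cond:.3g})")

    fixed = dict(fixed or {})
    free = [k for k in ("sigma_b", "sigma", "phi", "theta") if k not in fixed]

    # moment-based starting values
    y_all = np.concatenate([b[1] for b in blocks])
    beta0, *_ = np.linalg.lstsq(X_all, y_all, rcond=None)
    resid = y_all - X_all @ beta0
    sd_tot = float(np.std(resid)) or 1.0
    means = [float(np.mean(y - X @ beta0)) for X, y, _ in blocks]
    sb0 = max(float(np.std(means)), 0.05 * sd_tot)
    sw0 = max(math.sqrt(max(sd_tot**2 - sb0**2, 1e-4 * sd_tot**2)), 1e-3)
    starts = [
        {"sigma_b": sb0, "sigma": sw0, "phi": 0.5, "theta": 0.0},
        {"sigma_b": 0.5 * sd_tot, "sigma": 0.8 * sd_tot, "phi": 0.8, "theta": 0.1},
        {"sigma_b": 0.2 * sd_tot, "sigma": sd_tot, "phi": 0.2, "theta": -0.1},
    ][:max(1, n_starts)]

    def pack(d):
        out = []
        for name in free:
            v = d[name]
            if name in ("sigma_b", "sigma"):
                out.append(math.log(max(v, 1e-6)))
            else:
                out.append(math.atanh(np.clip(v, -0.99, 0.99)))
        return np.array(out)

    def obj(params):
        val, _, _ = _neg2_reml(params, blocks, free, fixed, p_dim)
        return val

    best = None
    for s in starts:
        if free:
            res = optimize.minimize(obj, pack(s), method="L-BFGS-B",
                                    options={"maxiter": 200, "gtol": gtol})
            if best is None or res.fun < best.fun:
                best = res
        else:
            class _R:  # all parameters fixed: single evaluation
                x = np.zeros(0)
                fun = obj(np.zeros(0))
                success = True
                jac = np.zeros(0)
                message = "all covariance parameters fixed"
            best = _R()
            break

    n2, beta, XtWX = _neg2_reml(best.x, blocks, free, fixed, p_dim)
    vals = dict(fixed)
    for name, v in zip(free, best.x):
        vals[name] = math.exp(v) if name in ("sigma_b", "sigma") else math.tanh(v)
    grad_norm = float(np.linalg.norm(getattr(best, "jac", np.zeros(0)))) if free else 0.0
    converged = bool(getattr(best, "success", True))

    cov_beta = np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    names = ["intercept"] + predictors
    beta_s = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    if standardize:
        # back-scale: y = b0 + sum b_j (x_j - mu_j)/sd_j
        for pcol in predictors:
            mu, sd = scale[pcol]
            beta_s["intercept"] -= beta_s[pcol] * mu / sd
            beta_s[pcol] /= sd
            se_s[pcol] /= sd
    z = beta_s / se_s
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)

    phi, theta = vals["phi"], vals["theta"]
    rho1 = float(arma11_correlation(phi, theta, 1)) if abs(phi) < 1 and abs(theta) < 1 else np.nan
    return MixedFit(
        response=response, predictors=predictors, stratum=stratum,
        beta=beta_s, se=se_s, z=z, p=pvals,
        sigma_b=vals["sigma_b"], sigma=vals["sigma"], phi=phi, theta=theta,
        rho1=rho1,
        loglik_reml=-0.5 * (n2 + (n - p_dim) * math.log(2 * math.pi)),
        converged=converged, n_obs=n, n_patients=n_pat,
        grad_norm=grad_norm, message=str(getattr(best, "message", "")),
    )


def effect_size_report(fit: MixedFit, perturbations: dict) -> pd.DataFrame:
    """Predicted change of the response for given predictor perturbations.

    For each predictor, delta = beta * perturbation with a 95% Wald CI —
    the scale on which 'extreme marker changes predict minor pressure
    changes' is judged.
    """
    rows = []
    for pred, delta_x in perturbations.items():
        b = fit.beta[pred]
        s = fit.se[pred]
        rows.append({
            "predictor": pred, "perturbation": delta_x,
            "delta_response": b * delta_x,
            "ci_lower": (b - 1.96 * s) * delta_x,
            "ci_upper": (b + 1.96 * s) * delta_x,
        })
    out = pd.DataFrame(rows)
    lo = out[["ci_lower", "ci_upper"]].min(axis=1)
    hi = out[["ci_lower", "ci_upper"]].max(axis=1)
    out["ci_lower"], out["ci_upper"] = lo, hi
    return out


# ---------------------------------------------------------------------------
# model-based simulation (calibration / parameter-recovery harness)


def simulate_lmm_frame(n_patients: int, n_hours: int, beta: dict,
                       sigma_b: float, sigma: float, phi: float, theta: float,
                       seed: int = 0, response: str = "icp_hour",
                       intercept: float = 0.0) -> pd.DataFrame:
    """Draw a balanced panel directly from the mixed model.

    Predictors are iid standard normal, the residual ARMA(1,1) is scaled
    to marginal SD ``sigma``; used to check that `fit_reml` recovers known
    truth.  Returns an aligned-frame-shaped DataFrame.
    """
    rng = np.random.default_rng(seed)
    marg = math.sqrt((1 + 2 * phi * theta + theta**2) / (1 - phi**2))
    innov = sigma / marg
    frames = []
    for i in range(n_patients):
        X = {p: rng.normal(size=n_hours) for p in beta}
        e = np.empty(n_hours)
        eps = rng.normal(0.0, innov, size=n_hours + 200)
        x = np.empty(n_hours + 200)
        x[0] = eps[0]
        for t in range(1, n_hours + 200):
            x[t] = phi * x[t - 1] + eps[t] + theta * eps[t - 1]
        e = x[200:]
        y = intercept + rng.normal(0.0, sigma_b) + e
        for p, b in beta.items():
            y = y + b * X[p]
        df = pd.DataFrame(X)
        df["patient_id"] = f"S{i + 1:03d}"
        df["location"] = "pericontusional"
        df["hour"] = np.arange(n_hours)
        df[response] = y
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
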