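"""Synthetic cohorts of TBI neuromonitoring records.

Generates patients carrying hourly cerebral microdialysis (MD) vials
(glucose, lactate, pyruvate, glycerol), minute-resolution intracranial
pressure (ICP) and mean arterial pressure (MAP) streams, a catheter-location
flag (pericontusional / nonpericontusional) and Glasgow Outcome Scale (GOS)
scores.  The generative model is second-order realistic rather than
physiological: each transformed marker is

    m_ij(t) = alpha_j(location) + a_ij + b_icp * (ICP_i(t) - icp_mean)
              + b_cpp * (CPP_i(t) - cpp_ref) + s_ij(t)

with a_ij a patient random intercept (optionally correlated with the
patient's mean pressures), s_ij a stationary ARMA(1,1) deviation, and
ICP_i(t)/CPP_i(t) the mean pressure over the hour preceding the vial's
membrane time.  Raw concentrations are recovered by squaring
(glucose/lactate/pyruvate, modelled on the square-root scale) or raising
ten to the value (glycerol, modelled on the log10 scale).

The defaults target a ~90-patient cohort with a mean of ~84 complete
hourly vials per patient, strong within-patient autocorrelation, subject
identity explaining roughly half to three quarters of marker variance,
weak MD-pressure coupling, pressures hovering around the clinical targets
(ICP <= 20 mmHg, CPP 60-70 mmHg), and outcome driven by mean pressures
but not by MD.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MARKERS = ("glucose", "lactate", "pyruvate", "glycerol")
RATIOS = ("lp_ratio", "lg_ratio")
LOCATIONS = ("pericontusional", "nonpericontusional")
GOS_EPOCHS = ("discharge", "3to6m", "1y")

_EPOCH0 = pd.Timestamp("2021-01-01 08:00:00")


class CohortError(ValueError):
    """Invalid cohort configuration or malformed cohort files."""


# ---------------------------------------------------------------------------
# modelling-scale transforms (shared with preprocess)

def to_modeling_scale(marker: str, x):
    """Square root for glucose/lactate/pyruvate, log10 for glycerol."""
    x = np.asarray(x, dtype=float)
    if marker == "glycerol":
        return np.log10(x)
    return np.sqrt(x)


def from_modeling_scale(marker: str, m):
    m = np.asarray(m, dtype=float)
    if marker == "glycerol":
        return 10.0 ** m
    return m**2


def arma11_marginal_sd(innov_sd: float, phi: float, theta: float) -> float:
    """Stationary SD of an ARMA(1,1) process with innovation SD ``innov_sd``."""
    return innov_sd * math.sqrt((1.0 + 2.0 * phi * theta + theta**2) / (1.0 - phi**2))


def _per_marker(value) -> dict:
    if isinstance(value, Mapping):
        missing = set(MARKERS) - set(value)
        if missing:
            raise CohortError(f"per-marker mapping missing {sorted(missing)}")
        return {m: float(value[m]) for m in MARKERS}
    return {m: float(value) for m in MARKERS}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Marker parameters are on the modelling scale (sqrt mM or sqrt uM for
    glucose/lactate/pyruvate, log10 uM for glycerol).  ``md_resid_sd`` is the
    ARMA *innovation* SD; the stationary within-patient SD is
    ``arma11_marginal_sd(md_resid_sd, md_phi, md_theta)``.  Coupling
    coefficients are per mmHg of hour-mean pressure, per location group.
    """

    n_patients: int = 90
    hours_mean: float = 84.0
    hours_dispersion: float = 10.0  # negative-binomial size; larger = tighter
    hours_min: int = 5

    md_alpha: dict = field(
        default_factory=lambda: {
            "glucose": 1.30,
            "lactate": 2.20,
            "pyruvate": 12.5,
            "glycerol": 2.30,
        }
    )
    # additive shift of alpha for pericontusional catheters
    md_alpha_peri_shift: dict = field(
        default_factory=lambda: {
            "glucose": -0.05,
            "lactate": 0.15,
            "pyruvate": 0.3,
            "glycerol": 0.05,
        }
    )
    md_phi: dict = field(
        default_factory=lambda: {
            "glucose": 0.78,
            "lactate": 0.82,
            "pyruvate": 0.80,
            "glycerol": 0.83,
        }
    )
    md_theta: dict = field(default_factory=lambda: dict.fromkeys(MARKERS, 0.0))
    md_subject_sd: dict = field(
        default_factory=lambda: {
            "glucose": 0.26,
            "lactate": 0.48,
            "pyruvate": 2.1,
            "glycerol": 0.36,
        }
    )
    md_resid_sd: dict = field(
        default_factory=lambda: {
            "glucose": 0.157,
            "lactate": 0.160,
            "pyruvate": 0.90,
            "glycerol": 0.151,
        }
    )

    # hourly coupling: location -> marker -> mmHg^-1 coefficient
    coupling_icp: dict = field(
        default_factory=lambda: {
            "pericontusional": {
                "glucose": -0.008,
                "lactate": 0.004,
                "pyruvate": 0.0,
                "glycerol": 0.0,
            },
            "nonpericontusional": {
                "glucose": -0.006,
                "lactate": 0.004,
                "pyruvate": 0.0,
                "glycerol": 0.006,
            },
        }
    )
    coupling_cpp: dict = field(
        default_factory=lambda: {
            "pericontusional": {
                "glucose": 0.005,
                "lactate": -0.003,
                "pyruvate": 0.0,
                "glycerol": 0.0,
            },
            "nonpericontusional": {
                "glucose": 0.0,
                "lactate": 0.0,
                "pyruvate": 0.0,
                "glycerol": 0.0,
            },
        }
    )
    # subject-level coupling: marker intercept per mmHg of the patient's
    # *mean* pressure (creates between-subject association without any
    # within-subject, hour-to-hour signal)
    subject_coupling_icp: dict = field(default_factory=lambda: dict.fromkeys(MARKERS, 0.0))
    subject_coupling_cpp: dict = field(default_factory=lambda: dict.fromkeys(MARKERS, 0.0))

    # pressure streams: patient level mu_i plus an AR(1) deviation at the
    # sampling resolution (phi per sample step); an optional slow hourly
    # level component (off by default) adds hour-scale persistence.
    icp_mean: float = 14.0
    icp_between_sd: float = 4.0
    icp_phi: float = 0.8       # AR(1) per pressure sample
    icp_sd: float = 3.0        # marginal SD of the sample-level deviation
    icp_slow_sd: float = 0.0   # optional hourly-level AR(1) component
    icp_slow_phi: float = 0.8
    map_mean: float = 80.0
    map_between_sd: float = 7.0
    map_phi: float = 0.8
    map_sd: float = 4.0
    map_slow_sd: float = 0.0
    map_slow_phi: float = 0.8
    pressure_dt_minutes: float = 1.0

    frac_pericontusional: float = 64.0 / 90.0

    # ordinal-logistic outcome model on centred mean ICP / mean CPP
    gos_coef_icp: float = -0.25
    gos_coef_cpp: float = 0.08
    gos_cutpoints: tuple = (-1.75, -1.45, -0.25, 1.0)

    missing_rate: float = 0.05
    transfer_delay_minutes: float = 17.0
    seed: int = 0

    def __post_init__(self):
        for name in ("md_alpha", "md_alpha_peri_shift", "md_phi", "md_theta",
                     "md_subject_sd", "md_resid_sd",
                     "subject_coupling_icp", "subject_coupling_cpp"):
            setattr(self, name, _per_marker(getattr(self, name)))
        for name in ("coupling_icp", "coupling_cpp"):
            raw = getattr(self, name)
            if not isinstance(raw, Mapping) or set(raw) != set(LOCATIONS):
                # allow a flat per-marker mapping or scalar applied to both groups
                raw = {loc: raw for loc in LOCATIONS}
            setattr(self, name, {loc: _per_marker(raw[loc]) for loc in LOCATIONS})
        self.validate()

    def validate(self) -> None:
        for m in MARKERS:
            if not abs(self.md_phi[m]) < 1 or not abs(self.md_theta[m]) < 1:
                raise CohortError(
                    f"non-stationary ARMA parameters for {m}: "
                    f"phi={self.md_phi[m]}, theta={self.md_theta[m]} (need |.|<1)"
                )
            if self.md_subject_sd[m] < 0 or self.md_resid_sd[m] < 0:
                raise CohortError(f"negative SD for {m}")
        for phi in (self.icp_phi, self.map_phi, self.icp_slow_phi, self.map_slow_phi):
            if not abs(phi) < 1:
                raise CohortError(f"non-stationary pressure AR coefficient {phi}")
        for sd in (self.icp_between_sd, self.icp_sd, self.icp_slow_sd,
                   self.map_between_sd, self.map_sd, self.map_slow_sd):
            if sd < 0:
                raise CohortError("pressure SDs must be >= 0")
        if not 0.0 <= self.frac_pericontusional <= 1.0:
            raise CohortError("frac_pericontusional must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortError("missing_rate must be in [0, 1)")
        if self.n_patients < 1:
            raise CohortError("n_patients must be >= 1")
        if list(self.gos_cutpoints) != sorted(self.gos_cutpoints):
            raise CohortError("gos_cutpoints must be ascending")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gos_cutpoints"] = list(self.gos_cutpoints)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "gos_cutpoints" in d:
            d["gos_cutpoints"] = tuple(d["gos_cutpoints"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def icc(self, marker: str) -> float:
        """Implied intraclass correlation of a marker on the modelling scale."""
        sw = arma11_marginal_sd(self.md_resid_sd[marker], self.md_phi[marker],
                                self.md_theta[marker])
        sb = self.md_subject_sd[marker]
        return sb**2 / (sb**2 + sw**2)

    def with_icc(self, marker: str, icc: float) -> "CohortConfig":
        """Copy of the config with ``md_subject_sd[marker]`` set to hit ``icc``."""
        if not 0.0 <= icc < 1.0:
            raise CohortError("icc must be in [0, 1)")
        sw = arma11_marginal_sd(self.md_resid_sd[marker], self.md_phi[marker],
                                self.md_theta[marker])
        new = dataclasses.replace(self)
        new.md_subject_sd = dict(new.md_subject_sd)
        new.md_subject_sd[marker] = sw * math.sqrt(icc / (1.0 - icc))
        return new


# ---------------------------------------------------------------------------
# records


@dataclass
class PatientRecord:
    """One patient's monitoring data.

    ``md_samples`` has columns vial_time, glucose, lactate, pyruvate,
    glycerol (raw units; NaN where a vial component is missing);
    ``icp_stream``/``map_stream`` have columns timestamp, value (mmHg);
    ``gos_scores`` maps epoch label -> score in 1..5.
    """

    patient_id: str
    location: str
    md_samples: pd.DataFrame
    icp_stream: pd.DataFrame
    map_stream: pd.DataFrame
    gos_scores: dict

    def validate(self) -> None:
        if self.location not in LOCATIONS:
            raise CohortError(f"{self.patient_id}: unknown location {self.location!r}")
        t = self.md_samples["vial_time"].to_numpy()
        if len(t) > 1 and not (np.diff(t.astype("datetime64[ns]")) > np.timedelta64(0)).all():
            raise CohortError(f"{self.patient_id}: vial times not strictly increasing")
        for m in MARKERS:
            v = self.md_samples[m].to_numpy(dtype=float)
            if np.any(v[np.isfinite(v)] <= 0):
                raise CohortError(f"{self.patient_id}: nonpositive {m} value")
        for s in (self.gos_scores or {}).values():
            if not 1 <= int(s) <= 5:
                raise CohortError(f"{self.patient_id}: GOS score {s} outside 1..5")


# ---------------------------------------------------------------------------
# simulation internals


def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_sd: float) -> np.ndarray:
    """Stationary AR(1) path with the given marginal SD."""
    if n == 0:
        return np.zeros(0)
    innov_sd = marginal_sd * math.sqrt(1.0 - phi**2)
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd) if marginal_sd > 0 else 0.0
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def _arma11(rng: np.random.Generator, n: int, phi: float, theta: float,
            innov_sd: float, burn: int = 150) -> np.ndarray:
    """ARMA(1,1) path, approximately stationary via burn-in."""
    m = n + burn
    e = rng.normal(0.0, innov_sd, size=m)
    x = np.empty(m)
    x[0] = e[0]
    for t in range(1, m):
        x[t] = phi * x[t - 1] + e[t] + theta * e[t - 1]
    return x[burn:]


def _hourly_means(times_ns: np.ndarray, values: np.ndarray,
                  anchors_ns: np.ndarray, window_ns: int) -> np.ndarray:
    """Mean of ``values`` over (anchor - window, anchor] for each anchor."""
    lo = np.searchsorted(times_ns, anchors_ns - window_ns, side="right")
    hi = np.searchsorted(times_ns, anchors_ns, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, (csum[hi] - csum[lo]) / n, np.nan)


def _simulate_patient(cfg: CohortConfig, idx: int, rng: np.random.Generator) -> PatientRecord:
    # monitoring length: hours_mean targets the expected number of
    # COMPLETE marker sets per patient, so vials are drawn at the rate
    # needed to survive marker-wise missingness
    target = cfg.hours_mean / max((1.0 - cfg.missing_rate) ** len(MARKERS), 1e-6)
    r = cfg.hours_dispersion
    p = r / (r + target)
    n_hours = max(cfg.hours_min, int(rng.negative_binomial(r, p)))

    location = LOCATIONS[0] if rng.random() < cfg.frac_pericontusional else LOCATIONS[1]

    start = _EPOCH0 + pd.Timedelta(days=idx) + pd.Timedelta(minutes=int(rng.integers(0, 60)))

    # --- pressures: patient level + AR(1) sample deviations ---------------
    mu_icp = max(1.0, rng.normal(cfg.icp_mean, cfg.icp_between_sd))
    mu_map = max(45.0, rng.normal(cfg.map_mean, cfg.map_between_sd))
    level_icp = mu_icp + _ar1(rng, n_hours + 1, cfg.icp_slow_phi, cfg.icp_slow_sd)
    level_map = mu_map + _ar1(rng, n_hours + 1, cfg.map_slow_phi, cfg.map_slow_sd)

    dt = cfg.pressure_dt_minutes
    n_min = int(round(n_hours * 60.0 / dt)) + 1
    t_min = np.arange(n_min) * dt  # minutes since start
    hour_grid = np.arange(n_hours + 1) * 60.0
    icp_min = np.interp(t_min, hour_grid, level_icp) + _ar1(
        rng, n_min, cfg.icp_phi, cfg.icp_sd)
    map_min = np.interp(t_min, hour_grid, level_map) + _ar1(
        rng, n_min, cfg.map_phi, cfg.map_sd)
    icp_min = np.clip(icp_min, 0.0, None)
    map_min = np.maximum(map_min, icp_min + 5.0)  # keep CPP physiologic

    stamps = start + pd.to_timedelta(t_min, unit="m")
    stamps_ns = stamps.asi8

    # membrane times of vials: hourly from start+1h
    membrane = start + pd.to_timedelta(np.arange(1, n_hours + 1), unit="h")
    membrane_ns = membrane.asi8
    window_ns = int(60 * 60 * 1e9)
    icp_hour = _hourly_means(stamps_ns, icp_min, membrane_ns, window_ns)
    cpp_hour = _hourly_means(stamps_ns, map_min - icp_min, membrane_ns, window_ns)

    cpp_ref = cfg.map_mean - cfg.icp_mean
    mean_icp = float(np.mean(icp_hour))
    mean_cpp = float(np.mean(cpp_hour))

    # --- markers on the modelling scale -----------------------------------
    md = {"vial_time": membrane + pd.Timedelta(minutes=cfg.transfer_delay_minutes)}
    for m in MARKERS:
        alpha = cfg.md_alpha[m]
        if location == "pericontusional":
            alpha += cfg.md_alpha_peri_shift[m]
        a_i = rng.normal(0.0, cfg.md_subject_sd[m]) if cfg.md_subject_sd[m] > 0 else 0.0
        a_i += cfg.subject_coupling_icp[m] * (mean_icp - cfg.icp_mean)
        a_i += cfg.subject_coupling_cpp[m] * (mean_cpp - cpp_ref)
        dev = _arma11(rng, n_hours, cfg.md_phi[m], cfg.md_theta[m], cfg.md_resid_sd[m])
        beta_i = cfg.coupling_icp[location][m]
        beta_c = cfg.coupling_cpp[location][m]
        model = (alpha + a_i + beta_i * (icp_hour - cfg.icp_mean)
                 + beta_c * (cpp_hour - cpp_ref) + dev)
        if m == "glycerol":
            raw = 10.0 ** model
        else:
            raw = np.clip(model, 0.05, None) ** 2
        if cfg.missing_rate > 0:
            raw = np.where(rng.random(n_hours) < cfg.missing_rate, np.nan, raw)
        md[m] = raw

    # --- outcome ----------------------------------------------------------
    latent = (cfg.gos_coef_icp * (mean_icp - cfg.icp_mean)
              + cfg.gos_coef_cpp * (mean_cpp - cpp_ref)
              + rng.logistic(0.0, 1.0))
    best = 1 + int(np.sum(latent > np.asarray(cfg.gos_cutpoints)))
    if best == 1:
        gos = {e: 1 for e in GOS_EPOCHS}
    else:
        drop_d = int(rng.choice([0, 1, 2], p=[0.35, 0.45, 0.20]))
        drop_m = int(rng.choice([0, 1], p=[0.5, 0.5]))
        gos = {
            "discharge": max(1, best - drop_d),
            "3to6m": max(1, best - min(drop_d, drop_m)),
            "1y": best,
        }
        if rng.random() < 0.05:  # lost to late follow-up
            del gos["1y"]

    return PatientRecord(
        patient_id=f"P{idx + 1:03d}",
        location=location,
        md_samples=pd.DataFrame(md),
        icp_stream=pd.DataFrame({"timestamp": stamps, "value": icp_min}),
        map_stream=pd.DataFrame({"timestamp": stamps, "value": map_min}),
        gos_scores=gos,
    )


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` records; deterministic in ``config.seed``.

    Each patient draws from an independent substream spawned from the
    config seed, so cohorts of different sizes share their leading patients.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    return [
        _simulate_patient(config, i, np.random.default_rng(s))
        for i, s in enumerate(streams)
    ]


# ---------------------------------------------------------------------------
# tidy CSV round trip


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write ``md.csv``, ``pressures.csv`` and ``patients.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    md_rows = []
    for rec in records:
        for m in MARKERS:
            sub = rec.md_samples[["vial_time", m]]
            for t, v in zip(sub["vial_time"], sub[m]):
                md_rows.append((rec.patient_id, t.isoformat(), m,
                                "" if not np.isfinite(v) else repr(float(v))))
    pd.DataFrame(md_rows, columns=["patient_id", "vial_time", "marker", "value"]).to_csv(
        path / "md.csv", index=False)

    press = [pd.DataFrame(columns=["patient_id", "timestamp", "variable", "value"])]
    for rec in records:
        for var, stream in (("ICP", rec.icp_stream), ("MAP", rec.map_stream)):
            df = pd.DataFrame({
                "patient_id": rec.patient_id,
                "timestamp": stream["timestamp"].map(pd.Timestamp.isoformat),
                "variable": var,
                "value": stream["value"].map(lambda v: repr(float(v))),
            })
            press.append(df)
    pd.concat(press, ignore_index=True).to_csv(path / "pressures.csv", index=False)

    pat_rows = []
    for rec in records:
        g = rec.gos_scores or {}
        pat_rows.append((rec.patient_id, rec.location,
                         g.get("discharge", ""), g.get("3to6m", ""), g.get("1y", "")))
    pd.DataFrame(pat_rows, columns=["patient_id", "location", "gos_discharge",
                                    "gos_3to6m", "gos_1y"]).to_csv(
        path / "patients.csv", index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read the three tidy CSVs back into validated PatientRecords."""
    path = Path(path)
    md = pd.read_csv(path / "md.csv", dtype={"patient_id": str, "marker": str},
                     float_precision="round_trip")
    press = pd.read_csv(path / "pressures.csv",
                        dtype={"patient_id": str, "variable": str},
                        float_precision="round_trip")
    pats = pd.read_csv(path / "patients.csv", dtype={"patient_id": str, "location": str})

    for i, row in md.iterrows():
        v = row["value"]
        if pd.notna(v) and float(v) <= 0:
            raise CohortError(
                f"md.csv line {i + 2}: nonpositive {row['marker']} value {v} "
                f"for patient {row['patient_id']} at {row['vial_time']}")
        if row["marker"] not in MARKERS:
            raise CohortError(f"md.csv line {i + 2}: unknown marker {row['marker']!r}")

    md["vial_time"] = pd.to_datetime(md["vial_time"])
    press["timestamp"] = pd.to_datetime(press["timestamp"])

    records = []
    for _, prow in pats.iterrows():
        pid = prow["patient_id"]
        wide = (md[md["patient_id"] == pid]
                .pivot(index="vial_time", columns="marker", values="value")
                .reindex(columns=list(MARKERS))
                .reset_index())
        wide.columns.name = None
        p = press[press["patient_id"] == pid]
        gos = {}
        for epoch, col in zip(GOS_EPOCHS, ("gos_discharge", "gos_3to6m", "gos_1y")):
            if pd.notna(prow[col]) and str(prow[col]) != "":
                gos[epoch] = int(float(prow[col]))
        rec = PatientRecord(
            patient_id=pid,
            location=prow["location"],
            md_samples=wide,
            icp_stream=p[p["variable"] == "ICP"][["timestamp", "value"]].reset_index(drop=True),
            map_stream=p[p["variable"] == "MAP"][["timestamp", "value"]].reset_index(drop=True),
            gos_scores=gos,
        )
        rec.validate()
        records.append(rec)
    return records
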