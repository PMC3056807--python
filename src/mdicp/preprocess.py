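"""Cleaning and alignment of microdialysis records into hourly frames.

The pipeline mirrors standard bedside practice for catheter microdialysis:
vial timestamps are shifted back by the membrane-to-vial transfer time,
assay out-of-range values are clamped to configurable limits, the
lactate:pyruvate and lactate:glucose ratios are computed from raw
concentrations, markers are variance-stabilised (square root for glucose,
lactate and pyruvate; log10 for glycerol), each vial is paired with the
mean ICP and CPP over the hour preceding its membrane time, and only
"complete sets" (all four markers plus aligned pressures) are retained.

The product is a tidy per-patient hourly table (the *aligned frame*) with
columns::

    patient_id, location, hour, membrane_time,
    glucose, lactate, pyruvate, glycerol,          (raw units, limited)
    glucose_t, lactate_t, pyruvate_t, glycerol_t,  (modelling scale)
    lp_ratio, lg_ratio, icp_hour, cpp_hour
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import MARKERS, PatientRecord, to_modeling_scale

#: default assay limits (raw units); chosen to bracket the reportable range
#: of bedside enzymatic analyzers and keep ratios finite (denominator
#: markers floored at their detection limits).
DEFAULT_LIMITS = {
    "glucose": (0.1, 25.0),
    "lactate": (0.1, 30.0),
    "pyruvate": (10.0, 1500.0),
    "glycerol": (1.0, 5000.0),
}

MARKER_T = tuple(f"{m}_t" for m in MARKERS)
ANALYSIS_VARS = MARKER_T + ("lp_ratio", "lg_ratio")


@dataclass
class PreprocessConfig:
    transfer_delay_minutes: float = 17.0
    limits: dict = field(default_factory=lambda: dict(DEFAULT_LIMITS))
    window_minutes: float = 60.0
    coverage: float = 0.5  # minimum fraction of the window with pressure data
    matched_pair_cpp: bool = True  # CPP from timestamp-matched MAP-ICP pairs
    transform_ratios: bool = False
    # optional exclusion intervals: list of (patient_id, start, end)
    exclusions: list = field(default_factory=list)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["limits"] = {k: list(v) for k, v in d["limits"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "limits" in d:
            d["limits"] = {k: tuple(v) for k, v in d["limits"].items()}
        return cls(**d)


@dataclass
class PreprocessReport:
    """Per-patient bookkeeping of what was clamped or dropped and why."""

    clamped: dict = field(default_factory=lambda: dict.fromkeys(MARKERS, 0))
    dropped: dict = field(default_factory=dict)  # reason -> count
    n_vials: int = 0
    n_retained: int = 0

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n


# ---------------------------------------------------------------------------
# individual operations


def shift_transfer_time(md_samples: pd.DataFrame, delay_minutes: float = 17.0) -> pd.DataFrame:
    """Add ``membrane_time = vial_time - delay`` (catheter transfer lag)."""
    if delay_minutes < 0:
        raise ValueError("transfer delay must be >= 0")
    out = md_samples.copy()
    out["membrane_time"] = out["vial_time"] - pd.Timedelta(minutes=delay_minutes)
    return out


def apply_limiters(md_samples: pd.DataFrame, limits=None,
                   report: PreprocessReport | None = None) -> pd.DataFrame:
    """Clamp out-of-range marker values to the nearer limit; log each clamp."""
    limits = DEFAULT_LIMITS if limits is None else limits
    out = md_samples.copy()
    for m, (lo, hi) in limits.items():
        if m not in out.columns:
            continue
        v = out[m].to_numpy(dtype=float)
        n_clamped = int(np.sum((v < lo) | (v > hi)))
        out[m] = np.clip(v, lo, hi)
        if report is not None:
            report.clamped[m] = report.clamped.get(m, 0) + n_clamped
    return out


def compute_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """LP ratio = lactate[mM] * 1000 / pyruvate[uM]; LG = lactate / glucose.

    Ratios are computed from raw (limited, untransformed) concentrations.
    Rows with nonpositive inputs get NaN ratios (and fall out of the
    complete-set filter downstream).
    """
    out = df.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        lact = out["lactate"].to_numpy(dtype=float)
        pyr = out["pyruvate"].to_numpy(dtype=float)
        gluc = out["glucose"].to_numpy(dtype=float)
        lp = np.where(pyr > 0, lact * 1000.0 / pyr, np.nan)
        lg = np.where(gluc > 0, lact / gluc, np.nan)
        lp = np.where(lact > 0, lp, np.nan)
        lg = np.where(lact > 0, lg, np.nan)
    out["lp_ratio"] = lp
    out["lg_ratio"] = lg
    return out


def transform_markers(df: pd.DataFrame, transform_ratios: bool = False) -> pd.DataFrame:
    """Append modelling-scale columns ``<marker>_t`` (sqrt / log10)."""
    out = df.copy()
    for m in MARKERS:
        v = out[m].to_numpy(dtype=float)
        bad = np.isfinite(v) & (v <= 0)
        v = np.where(bad, np.nan, v)
        out[f"{m}_t"] = to_modeling_scale(m, v)
    if transform_ratios:
        for r in ("lp_ratio", "lg_ratio"):
            out[f"{r}_t"] = np.log10(out[r].to_numpy(dtype=float))
    return out


def _window_mean(times_ns, values, anchor_ns, window_ns):
    lo = np.searchsorted(times_ns, anchor_ns - window_ns, side="right")
    hi = np.searchsorted(times_ns, anchor_ns, side="right")
    if hi <= lo:
        return np.nan, 0
    return float(np.mean(values[lo:hi])), hi - lo


def align_pressures(md_df: pd.DataFrame, icp_stream: pd.DataFrame,
                    map_stream: pd.DataFrame, *, window_minutes: float = 60.0,
                    coverage: float = 0.5, matched_pair_cpp: bool = True,
                    report: PreprocessReport | None = None) -> pd.DataFrame:
    """Attach hour-prior mean ICP and CPP to each vial row.

    For membrane time t the window is the half-open interval
    ``(t - window, t]``.  CPP is the mean of MAP - ICP over
    timestamp-matched pairs (or the difference of the separate stream
    means when ``matched_pair_cpp`` is False).  A row is dropped when
    fewer than ``coverage`` of the expected pressure samples (window /
    median sampling interval) are present, or when no samples overlap.
    """
    out = md_df.copy()
    if len(icp_stream) == 0 or len(map_stream) == 0 or len(out) == 0:
        out["icp_hour"] = np.nan
        out["cpp_hour"] = np.nan
        if report is not None:
            report.drop("no_pressure_overlap", len(out))
        return out.iloc[0:0] if len(out) else out

    icp = icp_stream.sort_values("timestamp")
    mp = map_stream.sort_values("timestamp")
    icp_t = icp["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    icp_v = icp["value"].to_numpy(dtype=float)
    if matched_pair_cpp:
        pairs = pd.merge(icp, mp, on="timestamp", suffixes=("_icp", "_map"))
        cpp_t = pairs["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        cpp_v = (pairs["value_map"] - pairs["value_icp"]).to_numpy(dtype=float)
    else:
        cpp_t = mp["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        cpp_v = mp["value"].to_numpy(dtype=float)

    window_ns = int(window_minutes * 60 * 1e9)
    dt_ns = np.median(np.diff(icp_t)) if len(icp_t) > 1 else window_ns
    expected = max(1.0, window_ns / float(dt_ns))

    anchors = out["membrane_time"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    icp_hour = np.full(len(out), np.nan)
    cpp_hour = np.full(len(out), np.nan)
    keep = np.zeros(len(out), dtype=bool)
    for i, a in enumerate(anchors):
        mi, ni = _window_mean(icp_t, icp_v, a, window_ns)
        mc, nc = _window_mean(cpp_t, cpp_v, a, window_ns)
        if not matched_pair_cpp:
            mic, _ = _window_mean(icp_t, icp_v, a, window_ns)
            mc = mc - mic if np.isfinite(mc) and np.isfinite(mic) else np.nan
        ok = (ni / expected >= coverage) and (nc / expected >= coverage)
        if ok:
            icp_hour[i] = mi
            cpp_hour[i] = mc
            keep[i] = True
    out["icp_hour"] = icp_hour
    out["cpp_hour"] = cpp_hour
    n_dropped = int((~keep).sum())
    if report is not None and n_dropped:
        report.drop("pressure_coverage", n_dropped)
    return out[keep].reset_index(drop=True)


def extract_complete_sets(df: pd.DataFrame,
                          report: PreprocessReport | None = None) -> pd.DataFrame:
    """Keep rows where all four markers and both aligned pressures are finite."""
    cols = list(MARKERS) + ["icp_hour", "cpp_hour"]
    present = [c for c in cols if c in df.columns]
    mask = np.ones(len(df), dtype=bool)
    for c in present:
        mask &= np.isfinite(df[c].to_numpy(dtype=float))
    if report is not None:
        n_dropped = int((~mask).sum())
        if n_dropped:
            report.drop("incomplete_set", n_dropped)
    return df[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline


def preprocess_patient(record: PatientRecord,
                       config: PreprocessConfig | None = None
                       ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full per-patient pipeline; returns (aligned rows, report)."""
    cfg = config or PreprocessConfig()
    report = PreprocessReport(n_vials=len(record.md_samples))

    df = shift_transfer_time(record.md_samples, cfg.transfer_delay_minutes)
    for pid, start, end in cfg.exclusions:
        if pid == record.patient_id:
            inside = ((df["membrane_time"] >= pd.Timestamp(start))
                      & (df["membrane_time"] <= pd.Timestamp(end)))
            report.drop("artifact_exclusion", int(inside.sum()))
            df = df[~inside].reset_index(drop=True)
    df = apply_limiters(df, cfg.limits, report)
    df = compute_ratios(df)
    df = transform_markers(df, cfg.transform_ratios)
    df = align_pressures(df, record.icp_stream, record.map_stream,
                         window_minutes=cfg.window_minutes, coverage=cfg.coverage,
                         matched_pair_cpp=cfg.matched_pair_cpp, report=report)
    df = extract_complete_sets(df, report)

    if len(df):
        t0 = df["membrane_time"].iloc[0]
        hours = ((df["membrane_time"] - t0) / pd.Timedelta(hours=1)).round().astype(int)
    else:
        hours = pd.Series([], dtype=int)
    df = df.assign(patient_id=record.patient_id, location=record.location, hour=hours)
    report.n_retained = len(df)

    cols = ["patient_id", "location", "hour", "membrane_time",
            *MARKERS, *MARKER_T, "lp_ratio", "lg_ratio", "icp_hour", "cpp_hour"]
    extra = [c for c in df.columns if c.endswith("_t") and c not in cols]
    return df[cols + extra], report


def preprocess_cohort(records: Sequence[PatientRecord],
                      config: PreprocessConfig | None = None,
                      return_reports: bool = False):
    """Preprocess every record and concatenate into one aligned frame."""
    frames, reports = [], {}
    for rec in records:
        df, rep = preprocess_patient(rec, config)
        frames.append(df)
        reports[rec.patient_id] = rep
    aligned = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if return_reports:
        return aligned, reports
    return aligned


def write_aligned(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["membrane_time"] = out["membrane_time"].map(pd.Timestamp.isoformat)
    out.to_csv(path, index=False, float_format="%.12g")


def read_aligned(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "location": str})
    df["membrane_time"] = pd.to_datetime(df["membrane_time"])
    return df
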