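"""Outcome analyses: per-subject monitoring summaries versus GOS score.

Each patient is collapsed to whole-period summaries (mean ICP, mean CPP,
mean markers and ratios, and the burden of raised lactate:pyruvate ratio
as hours / percentage of monitored complete-set hours above a threshold)
and compared across Glasgow Outcome Scale groups with one-way ANOVA and
the (tie-corrected) Kruskal-Wallis test.  The best GOS over the available
follow-up epochs is used; patients with fewer than 12 complete MD hours,
or with no GOS score at all, are excluded with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MARKERS
from .preprocess import ANALYSIS_VARS

#: conventional clinical cutoff for a raised lactate:pyruvate ratio
DEFAULT_LP_THRESHOLD = 25.0
MIN_MD_HOURS = 12

SUMMARY_COLUMNS = (
    "mean_icp", "mean_cpp",
    *(f"mean_{m}" for m in MARKERS),
    "mean_lp_ratio", "mean_lg_ratio",
    "hours_lp_above", "pct_lp_above",
)


def best_gos(scores: dict) -> int | None:
    """Best (= highest) GOS over the recorded follow-up epochs."""
    vals = [int(v) for v in (scores or {}).values() if v is not None]
    return max(vals) if vals else None


def build_outcome_table(frame: pd.DataFrame, gos_scores: dict,
                        lp_threshold: float = DEFAULT_LP_THRESHOLD,
                        min_hours: int = MIN_MD_HOURS) -> pd.DataFrame:
    """Per-patient outcome summary table.

    ``gos_scores`` maps patient_id -> {epoch: score}.  Means of markers
    are in natural units; the LP-ratio burden counts complete-set hours
    with lp_ratio > ``lp_threshold``.
    """
    rows = []
    for pid, g in frame.groupby("patient_id", sort=True):
        lp = g["lp_ratio"].to_numpy(dtype=float)
        n_hours = len(g)
        gos = best_gos(gos_scores.get(pid, {}))
        included, reason = True, ""
        if n_hours < min_hours:
            included, reason = False, "insufficient_md_hours"
        elif gos is None:
            included, reason = False, "no_gos"
        rows.append({
            "patient_id": pid,
            "location": g["location"].iloc[0],
            "gos": gos,
            "monitored_hours": n_hours,
            "mean_icp": g["icp_hour"].mean(),
            "mean_cpp": g["cpp_hour"].mean(),
            **{f"mean_{m}": g[m].mean() for m in MARKERS},
            "mean_lp_ratio": g["lp_ratio"].mean(),
            "mean_lg_ratio": g["lg_ratio"].mean(),
            "hours_lp_above": float(np.sum(lp > lp_threshold)),
            "pct_lp_above": float(np.mean(lp > lp_threshold) * 100.0),
            "included": included,
            "exclusion_reason": reason,
        })
    return pd.DataFrame(rows)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    ``groups`` is an iterable of 1-D arrays.  Identical groups give
    F = 0, p = 1; a singleton group contributes to the between-group
    sum of squares only.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 non-empty groups")
    n = sum(len(g) for g in groups)
    if n <= len(groups):
        raise ValueError("ANOVA needs more observations than groups")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0
    if np.isinf(f):  # zero within-group variance but distinct means
        return float(f), 0.0
    return float(f), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class OutcomeScreen:
    tests: pd.DataFrame
    skipped: list

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.tests[self.tests["concordant_significant"]]


def outcome_screen(table: pd.DataFrame, columns=SUMMARY_COLUMNS,
                   alpha: float = 0.05) -> OutcomeScreen:
    """Both tests for every summary column against GOS groups.

    A finding counts as concordantly significant only when ANOVA and
    Kruskal-Wallis agree at ``alpha``.  Degenerate groupings (a single
    GOS level present) are skipped with a warning entry.
    """
    inc = table[table["included"]].copy()
    rows, skipped = [], []
    levels = sorted(inc["gos"].dropna().unique())
    for col in columns:
        groups = [inc.loc[inc["gos"] == lv, col].dropna().to_numpy() for lv in levels]
        groups = [g for g in groups if len(g)]
        if len(groups) < 2:
            skipped.append((col, "single GOS group present"))
            continue
        try:
            f, p_a = anova_oneway(groups)
            h, p_k = kruskal_wallis(groups)
        except ValueError as e:
            skipped.append((col, str(e)))
            continue
        rows.append({
            "column": col, "F": f, "p_anova": p_a, "H": h, "p_kw": p_k,
            "concordant_significant": (p_a < alpha) and (p_k < alpha),
        })
    return OutcomeScreen(pd.DataFrame(rows), skipped)
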