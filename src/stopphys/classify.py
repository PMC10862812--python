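"""Per-participant effect sizes of stop-related CSE suppression and the
temporal-profile classification.

For each stim time, Cohen's d contrasts go against successful-stop MEP
amplitudes (positive d = suppression on stop trials).  The vocal-task d
(hand probe, task-unrelated) indexes non-selective suppression; the manual
d minus the vocal d at the same time indexes additional selective
suppression.  A suppression type counts as "shown" when any timepoint's
d exceeds the threshold (default 0.2); when both types are shown, the
timepoint of greatest qualifying increase (relative to earlier timepoints)
decides the temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AnalysisSettings

CATEGORIES = (
    "global-then-selective",
    "selective-then-global",
    "same-time",
    "global-only",
    "selective-only",
    "neither",
)


def cohens_d(go_amplitudes, stop_amplitudes) -> float:
    """Two-sample Cohen's d, ``(mean_go - mean_stop) / pooled SD``.

    Positive values mean smaller MEPs (suppression) on stop trials.  The
    pooled SD uses the usual (n1 + n2 - 2)-denominator estimate.
    """
    a = np.asarray(list(go_amplitudes), dtype=float)
    b = np.asarray(list(stop_amplitudes), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    pooled_var = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    if pooled_var <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def selective_adjustment(manual_d, vocal_d) -> np.ndarray:
    """Elementwise manual minus vocal d over aligned stim-time grids: the
    suppression beyond the non-selective level at the same time."""
    m = np.asarray(list(manual_d), dtype=float)
    v = np.asarray(list(vocal_d), dtype=float)
    if m.shape != v.shape:
        raise ValueError("manual and vocal d grids are misaligned")
    return m - v


def _increases(d: np.ndarray, rule: str) -> np.ndarray:
    """Increase of each timepoint relative to earlier ones.

    ``running-max``: d(t) minus the running maximum of earlier d (floored at
    0; the first timepoint compares against 0).  ``pairwise``: d(t) - d(t-1).
    """
    if rule == "running-max":
        prior = np.array([0.0] + [max(0.0, float(np.max(d[:i])))
                                  for i in range(1, d.size)])
        return d - prior
    if rule == "pairwise":
        return np.diff(np.concatenate([[0.0], d]))
    raise ValueError(f"unknown increase rule {rule!r}")


def _peak_timepoint(d: np.ndarray, threshold: float, rule: str) -> int:
    """Timepoint of greatest qualifying increase (ties -> earliest).

    Increases at or below the threshold disqualify a timepoint; if no
    timepoint qualifies the argmax increase is used so every profile still
    maps to a timepoint.
    """
    inc = _increases(d, rule)
    qualifying = np.flatnonzero(inc > threshold)
    pool = qualifying if qualifying.size else np.arange(d.size)
    best = pool[np.argmax(inc[pool])]  # argmax returns the first maximum
    return int(best)


def classify_participant(nonselective_d, selective_d, threshold: float = 0.2,
                         increase_rule: str = "running-max") -> str:
    """Map a participant's d-profiles to one of the six suppression
    categories."""
    g = np.asarray(list(nonselective_d), dtype=float)
    s = np.asarray(list(selective_d), dtype=float)
    if g.size < 2 or s.size < 2 or g.size != s.size:
        raise ValueError("need aligned d vectors of length >= 2")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(s))):
        raise ValueError("d vectors must be finite")
    global_shown = bool(np.any(g > threshold))
    selective_shown = bool(np.any(s > threshold))
    if not global_shown and not selective_shown:
        return "neither"
    if global_shown and not selective_shown:
        return "global-only"
    if selective_shown and not global_shown:
        return "selective-only"
    tg = _peak_timepoint(g, threshold, increase_rule)
    ts = _peak_timepoint(s, threshold, increase_rule)
    if tg < ts:
        return "global-then-selective"
    if tg > ts:
        return "selective-then-global"
    return "same-time"


@dataclass
class EffectProfile:
    """Per-participant effect sizes by stim time and the derived category."""

    participant_id: str
    stim_times_ms: tuple
    nonselective_d: tuple
    selective_d: tuple
    category: str


def profile_participant(measurements: pd.DataFrame, events: pd.DataFrame,
                        participant_id: str = "p0",
                        settings: AnalysisSettings | None = None,
                        pulse_type: str = "single") -> EffectProfile:
    """Build one participant's effect profile from per-trial measurements.

    Uses retained (non-rejected) single-pulse task MEPs: for each modality and
    stim time, Cohen's d of go vs successful-stop amplitudes; the vocal d is
    the non-selective profile, manual minus vocal the selective one.
    """
    s = settings or AnalysisSettings()
    df = measurements.merge(events, on="trial", how="left")
    df = df[(~df["rejected"]) & (df["tms_role"] == "task-pulse")
            & (df["pulse_type"] == pulse_type)]
    stim_times = sorted(df["tms_time_ms"].dropna().unique())
    d = {}
    for modality in ("manual", "vocal"):
        vals = []
        for t in stim_times:
            cell = df[(df["modality"] == modality) & (df["tms_time_ms"] == t)]
            go = cell.loc[cell["trial_type"] == "go", "amplitude_mv"]
            stop = cell.loc[cell["outcome"] == "stop-success", "amplitude_mv"]
            vals.append(cohens_d(go, stop))
        d[modality] = np.asarray(vals)
    nonsel = d["vocal"]
    sel = selective_adjustment(d["manual"], d["vocal"])
    category = classify_participant(nonsel, sel, s.d_threshold, s.increase_rule)
    return EffectProfile(participant_id, tuple(stim_times),
                         tuple(np.round(nonsel, 6)), tuple(np.round(sel, 6)),
                         category)


def tabulate_categories(profiles) -> pd.DataFrame:
    """Counts and percentages per category (every category listed, zeros
    included)."""
    cats = [p.category if isinstance(p, EffectProfile) else str(p)
            for p in profiles]
    if not cats:
        raise ValueError("need at least one profile")
    n = len(cats)
    rows = [{"category": c, "count": cats.count(c),
             "percent": cats.count(c) / n * 100.0} for c in CATEGORIES]
    return pd.DataFrame(rows)


def profiles_table(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"participant": p.participant_id, "category": p.category}
        for t, g, s in zip(p.stim_times_ms, p.nonselective_d, p.selective_d):
            row[f"nonselective_d_{int(t)}"] = g
            row[f"selective_d_{int(t)}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
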