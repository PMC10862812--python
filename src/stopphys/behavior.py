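"""Behavioral measures: vocal onset detection, RT summaries, p(inhibit),
and SSRT via the integration method.

The integration method takes the nth fastest go RT at rank
``ceil(p(respond|signal) * N)`` — omissions first replaced by the maximum
observed go RT — and subtracts the mean stop-signal delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def detect_voice_onset(envelope: np.ndarray, threshold_amp: float,
                       sampling_rate_hz: float) -> float | None:
    """Response time (ms) of the first sample strictly exceeding the
    threshold, or ``None`` when no sample crosses it."""
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    if threshold_amp <= 0:
        raise ValueError("threshold must be positive")
    if not np.all(np.isfinite(env)):
        raise ValueError("envelope contains non-finite samples")
    above = np.flatnonzero(env > threshold_amp)
    if above.size == 0:
        return None
    return float(above[0] / sampling_rate_hz * 1000.0)


def compute_ssrt_integration(go_rts, omission_count: int,
                             p_respond_given_signal: float,
                             mean_ssd_ms: float) -> float:
    """Integration-method stop-signal reaction time.

    Omitted go trials enter as copies of the maximum observed go RT; the go RT
    distribution is sorted and the RT at (1-based) rank
    ``ceil(p_respond * N)`` is taken; SSRT is that RT minus the mean SSD.
    """
    rts = np.asarray(list(go_rts), dtype=float)
    if rts.size == 0:
        raise ValueError("need at least one go RT")
    if not (0.0 < p_respond_given_signal < 1.0):
        raise ValueError("p(respond|signal) must lie strictly in (0, 1)")
    if omission_count < 0:
        raise ValueError("omission_count must be non-negative")
    if omission_count:
        rts = np.concatenate([rts, np.full(omission_count, rts.max())])
    rts.sort()
    rank = math.ceil(p_respond_given_signal * rts.size)
    rank = min(max(rank, 1), rts.size)
    return float(rts[rank - 1] - mean_ssd_ms)


@dataclass
class BehavioralSummary:
    """Per-modality behavioral summary of one participant."""

    modality: str
    n_trials: int
    mean_go_rt_ms: float
    mean_failed_stop_rt_ms: float  # NaN when no failed stops
    p_inhibit: float
    mean_ssd_ms: float
    ssrt_ms: float  # NaN when p(respond) is degenerate
    omission_rate: float


def summarize_behavior(events: pd.DataFrame) -> dict[str, BehavioralSummary]:
    """Behavioral summary per modality from a parsed events table.

    Go RT means cover correct go trials; p(inhibit) is the proportion of stop
    trials successfully withheld; mean SSD covers all stop trials; SSRT uses
    the integration method (all responded go trials included).
    """
    out: dict[str, BehavioralSummary] = {}
    for modality, df in events.groupby("modality", sort=True):
        stops = df[df["trial_type"] == "stop"]
        if stops.empty:
            raise ValueError(f"no stop trials for modality {modality!r}")
        gos = df[df["trial_type"] == "go"]
        go_rts = gos.loc[gos["outcome"] == "go-correct", "rt_ms"].to_numpy(float)
        omissions = int((gos["outcome"] == "go-omission").sum())
        n_success = int((stops["outcome"] == "stop-success").sum())
        p_inhibit = n_success / len(stops)
        failed = stops.loc[stops["outcome"] == "stop-fail", "rt_ms"].to_numpy(float)
        mean_ssd = float(stops["ssd_ms"].astype(float).mean())
        p_respond = 1.0 - p_inhibit
        if 0.0 < p_respond < 1.0 and go_rts.size:
            ssrt = compute_ssrt_integration(go_rts, omissions, p_respond, mean_ssd)
        else:
            ssrt = float("nan")
        out[modality] = BehavioralSummary(
            modality=modality,
            n_trials=len(df),
            mean_go_rt_ms=float(go_rts.mean()) if go_rts.size else float("nan"),
            mean_failed_stop_rt_ms=float(failed.mean()) if failed.size else float("nan"),
            p_inhibit=p_inhibit,
            mean_ssd_ms=mean_ssd,
            ssrt_ms=ssrt,
            omission_rate=omissions / len(gos) if len(gos) else float("nan"),
        )
    return out


def behavior_table(summaries: dict[str, BehavioralSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries.values()])
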