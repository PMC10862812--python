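"""Per-trial TMS/EMG measurement: pulse-artifact localization, MEP amplitude,
rejection filtering, extreme trimming, inclusion thresholds, baseline-normalized
corticospinal excitability (CSE), short-interval intracortical inhibition
(SICI), and cortical silent period (CSP) duration.

Conventions: MEP amplitude is peak-to-peak over the 10-50 ms post-pulse window
(closed on both ends); pre-pulse EMG is the RMS of the 80 ms before the pulse;
a trial is rejected when the MEP is below 0.05 mV, the pre-pulse RMS exceeds
0.05 mV, or the response occurred at or before the pulse.  Times in ms are
converted to samples by rounding to the nearest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .params import AnalysisSettings


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def find_tms_artifact(trace: np.ndarray, expected_pulse_sample: int,
                      search_radius_samples: int,
                      detection_floor_mv: float = 0.5) -> tuple[int, bool]:
    """Locate the stimulation artifact near its scheduled position.

    Returns ``(pulse_sample, low_confidence)`` where the pulse sample is the
    maximum absolute deflection within the search radius and the flag marks
    deflections below the detection floor (e.g. a flat trace).
    """
    trace = np.asarray(trace, dtype=float)
    lo = expected_pulse_sample - search_radius_samples
    hi = expected_pulse_sample + search_radius_samples + 1
    if lo < 0 or hi > trace.size:
        raise ValueError("artifact search window extends outside the trace")
    seg = np.abs(trace[lo:hi])
    idx = int(np.argmax(seg))
    return lo + idx, bool(seg[idx] < detection_floor_mv)


def extract_mep(trace: np.ndarray, pulse_sample: int, sampling_rate_hz: float,
                window_ms: tuple[float, float] = (10.0, 50.0)) -> float:
    """Peak-to-peak MEP amplitude (mV) in the post-pulse window, endpoints
    inclusive."""
    trace = np.asarray(trace, dtype=float)
    lo = pulse_sample + _ms_to_samples(window_ms[0], sampling_rate_hz)
    hi = pulse_sample + _ms_to_samples(window_ms[1], sampling_rate_hz) + 1
    if lo < 0 or hi > trace.size:
        raise ValueError("MEP window extends outside the trace")
    seg = trace[lo:hi]
    return float(seg.max() - seg.min())


def prepulse_rms(trace: np.ndarray, pulse_sample: int, sampling_rate_hz: float,
                 span_ms: float = 80.0) -> float:
    """RMS of the raw trace over the ``span_ms`` immediately before the pulse
    (pulse sample excluded)."""
    trace = np.asarray(trace, dtype=float)
    lo = pulse_sample - _ms_to_samples(span_ms, sampling_rate_hz)
    if lo < 0 or pulse_sample > trace.size:
        raise ValueError("pre-pulse span extends outside the trace")
    seg = trace[lo:pulse_sample]
    return float(np.sqrt(np.mean(seg**2)))


@dataclass
class MEPMeasurement:
    """One trial's MEP measurement and rejection status."""

    trial_index: int
    pulse_time_ms: float
    amplitude_mv: float
    prepulse_rms_mv: float
    rejected: bool = False
    reject_reason: str = "none"  # small-mep | prepulse-emg | rt-at-or-before-pulse | trimmed


def apply_rejection(m: MEPMeasurement, rt_ms: float | None,
                    settings: AnalysisSettings | None = None) -> MEPMeasurement:
    """Mark a measurement rejected per the automated rules.

    Reasons are checked in order: MEP amplitude below threshold, pre-pulse EMG
    above threshold, then response at or before the pulse (a trial whose
    response has already begun by pulse time yields a movement-contaminated
    MEP; this is why fast failed-stop trials drop out preferentially).
    """
    s = settings or AnalysisSettings()
    if m.amplitude_mv < s.min_mep_amp_mv:
        m.rejected, m.reject_reason = True, "small-mep"
    elif m.prepulse_rms_mv > s.max_prepulse_rms_mv:
        m.rejected, m.reject_reason = True, "prepulse-emg"
    elif rt_ms is not None and rt_ms <= m.pulse_time_ms:
        m.rejected, m.reject_reason = True, "rt-at-or-before-pulse"
    else:
        m.rejected, m.reject_reason = False, "none"
    return m


def trim_extremes(amplitudes, tail_fraction: float = 0.05,
                  enabled: bool = True) -> np.ndarray:
    """Boolean keep-mask dropping ``floor(n * tail_fraction)`` smallest and
    largest values; identity when disabled."""
    amps = np.asarray(list(amplitudes), dtype=float)
    keep = np.ones(amps.size, dtype=bool)
    if not enabled or amps.size == 0:
        return keep
    k = int(np.floor(amps.size * tail_fraction))
    if k > 0:
        order = np.argsort(amps, kind="stable")
        keep[order[:k]] = False
        keep[order[-k:]] = False
    return keep


def enforce_inclusion(condition_counts: dict, min_per_condition: int,
                      ) -> tuple[bool, list]:
    """Participant-level inclusion: include iff every required cell has at
    least ``min_per_condition`` usable measurements."""
    failing = []
    for cell, count in condition_counts.items():
        if count is None:
            raise ValueError(f"missing count for condition cell {cell!r}")
        if count < min_per_condition:
            failing.append(cell)
    return (len(failing) == 0), failing


def normalize_cse(condition_mean_mv: float, baseline_mean_mv: float) -> float:
    """Condition mean MEP amplitude as a ratio to the active baseline mean."""
    if not np.isfinite(baseline_mean_mv) or baseline_mean_mv <= 0:
        raise ValueError("baseline mean amplitude must be positive")
    return float(condition_mean_mv / baseline_mean_mv)


def compute_sici(mean_test_amp_mv: float, mean_conditioned_amp_mv: float) -> float:
    """Short-interval intracortical inhibition as percent inhibition,
    ``(TS - CS) / TS * 100``; conditioned MEPs larger than the test MEP give
    negative values (facilitation)."""
    if mean_test_amp_mv <= 0:
        raise ValueError("test-stimulus mean amplitude must be positive")
    return float((mean_test_amp_mv - mean_conditioned_amp_mv)
                 / mean_test_amp_mv * 100.0)


@dataclass
class CSPMeasurement:
    """Silent-period presence and duration for one trial (times after pulse)."""

    trial_index: int
    present: bool
    resume_time_ms: float | None = None
    duration_ms: float | None = None
    flag: str = "none"  # not-contracting | no-silence | no-resumption | none


def _moving_rms(x: np.ndarray, win_samples: int) -> np.ndarray:
    win = max(int(win_samples), 1)
    return np.sqrt(uniform_filter1d(x * x, size=win, mode="nearest"))


def detect_csp(trace: np.ndarray, pulse_sample: int, sampling_rate_hz: float,
               tonic_reference_rms: float,
               settings: AnalysisSettings | None = None,
               trial_index: int = -1) -> CSPMeasurement:
    """Automated stand-in for the analyst's silent-period marking.

    A 25-ms moving-RMS envelope must fall below a fraction of the pre-pulse
    tonic level for a minimum silent interval and then re-exceed it for a
    minimum hold time; the resumption is localized with a short 5-ms envelope
    and finally snapped to the maximum absolute deflection within +/-2 ms,
    mirroring the manual-mark-then-refine procedure.  Duration is measured
    from the pulse to the refined resumption point.
    """
    s = settings or AnalysisSettings()
    trace = np.asarray(trace, dtype=float)
    fs = sampling_rate_hz
    if tonic_reference_rms <= s.csp_noise_floor_mv:
        return CSPMeasurement(trial_index, present=False, flag="not-contracting")

    thr = s.csp_threshold_frac * tonic_reference_rms
    coarse = _moving_rms(trace, _ms_to_samples(s.csp_coarse_win_ms, fs))
    s0 = pulse_sample + _ms_to_samples(s.csp_search_start_ms, fs)
    s1 = min(pulse_sample + _ms_to_samples(s.csp_max_ms, fs), trace.size)
    if s0 >= s1:
        raise ValueError("silent-period search window extends outside the trace")

    hold_n = max(_ms_to_samples(s.csp_hold_ms, fs), 1)
    above = coarse[s0:s1] >= thr
    candidate = _first_run_start(above, hold_n)
    if candidate is None:
        return CSPMeasurement(trial_index, present=False, flag="no-resumption")
    candidate += s0

    min_sil_n = max(_ms_to_samples(s.csp_min_silence_ms, fs), 1)
    below = coarse[s0:candidate] < thr
    if _longest_run(below) < min_sil_n:
        return CSPMeasurement(trial_index, present=False, flag="no-silence")

    # the coarse candidate leads the true resumption by up to half the coarse
    # window; re-localize with the fine envelope on a symmetric neighbourhood
    fine = _moving_rms(trace, _ms_to_samples(s.csp_fine_win_ms, fs))
    half = _ms_to_samples(s.csp_coarse_win_ms, fs)
    f0 = max(candidate - half, s0)
    f1 = min(candidate + half, trace.size)
    fine_above = np.flatnonzero(fine[f0:f1] >= thr)
    onset = f0 + int(fine_above[0]) if fine_above.size else candidate
    # a centred-RMS crossing leads the true resumption by roughly a quarter
    # of the fine window at the 50% threshold; re-centre before snapping
    onset += max(_ms_to_samples(s.csp_fine_win_ms / 4.0, fs), 0)

    ref_n = _ms_to_samples(s.csp_refine_ms, fs)
    r0, r1 = max(onset - ref_n, 0), min(onset + ref_n + 1, trace.size)
    resume = r0 + int(np.argmax(np.abs(trace[r0:r1])))

    duration = (resume - pulse_sample) / fs * 1000.0
    return CSPMeasurement(trial_index, present=True,
                          resume_time_ms=duration, duration_ms=duration)


def _first_run_start(mask: np.ndarray, run_len: int) -> int | None:
    count = 0
    for i, v in enumerate(mask):
        count = count + 1 if v else 0
        if count >= run_len:
            return i - run_len + 1
    return None


def _longest_run(mask: np.ndarray) -> int:
    best = count = 0
    for v in mask:
        count = count + 1 if v else 0
        best = max(best, count)
    return best


# ---------------------------------------------------------------------------
# participant-level measurement and condition summaries


def measure_participant(traces: np.ndarray, sidecar: dict, events: pd.DataFrame,
                        settings: AnalysisSettings | None = None) -> pd.DataFrame:
    """Measure every TMS trial of one participant.

    ``traces`` is the (trials x samples) matrix from the simulator (or real
    recordings mapped to the same layout); ``sidecar`` supplies the sampling
    rate and, per trace row, the trial index, scheduled pulse sample and the
    trial-relative time of sample 0.  The silent period is evaluated only on
    accepted-MEP manual-task single-pulse trials, using the measured pre-pulse
    RMS as the tonic reference.
    """
    s = settings or AnalysisSettings()
    fs = float(sidecar["sampling_rate_hz"])
    ev = events.set_index("trial")
    radius = _ms_to_samples(s.artifact_search_ms, fs)

    rows = []
    for k in range(traces.shape[0]):
        trial = int(sidecar["trial_index"][k])
        expected = int(sidecar["pulse_sample_index"][k])
        onset_ms = float(sidecar["trace_onset_ms"][k])
        trace = traces[k]

        pulse_idx, lowconf = find_tms_artifact(trace, expected, radius,
                                               s.artifact_floor_mv)
        amp = extract_mep(trace, pulse_idx, fs, s.mep_window_ms)
        rms = prepulse_rms(trace, pulse_idx, fs, s.prepulse_span_ms)
        pulse_trial_ms = onset_ms + pulse_idx / fs * 1000.0

        erow = ev.loc[trial]
        rt = erow["rt_ms"]
        rt = None if pd.isna(rt) else float(rt)
        m = MEPMeasurement(trial, pulse_trial_ms, amp, rms)
        apply_rejection(m, rt, s)

        csp = CSPMeasurement(trial, present=False, flag="not-evaluated")
        if (erow["modality"] == "manual" and erow["pulse_type"] == "single"
                and not m.rejected):
            csp = detect_csp(trace, pulse_idx, fs, rms, s, trial_index=trial)

        rows.append({
            "trial": trial, "pulse_sample": pulse_idx,
            "pulse_trial_time_ms": pulse_trial_ms,
            "amplitude_mv": m.amplitude_mv, "prepulse_rms_mv": m.prepulse_rms_mv,
            "low_confidence_artifact": lowconf,
            "rejected": m.rejected, "reject_reason": m.reject_reason,
            "csp_present": csp.present, "csp_duration_ms": csp.duration_ms,
            "csp_flag": csp.flag,
        })
    return pd.DataFrame(rows)


def _cell_type(row) -> str:
    if row["tms_role"] == "baseline-probe":
        return "baseline"
    if row["trial_type"] == "go":
        return "go"
    return row["outcome"]  # stop-success | stop-fail


def summarize_conditions(measurements: pd.DataFrame, events: pd.DataFrame,
                         mode: str = "exp1",
                         settings: AnalysisSettings | None = None,
                         include_failed_stop: bool = False,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition summaries for one participant.

    Returns ``(summary, measurements)`` where measurements is a copy with
    extreme-trimming applied (single-pulse experiment mode only; trimming runs
    after the rejection filters, within each condition cell).  Summary rows
    cover every (modality x trial type x stim time x pulse type) cell plus the
    pooled active baselines, with baseline-normalized CSE, percent SICI when
    paired-pulse data exist, and mean silent-period duration on manual
    single-pulse cells.
    """
    if mode not in ("exp1", "exp2"):
        raise ValueError(f"unknown mode {mode!r}")
    s = settings or AnalysisSettings()
    meas = measurements.copy()
    missing = set(meas["trial"]) - set(events["trial"])
    if missing:
        raise ValueError(f"measurements reference unknown trials: {sorted(missing)[:5]}")

    df = meas.merge(events, on="trial", how="left", validate="one_to_one")
    df["cell_type"] = df.apply(_cell_type, axis=1)
    df["stim"] = np.where(df["cell_type"] == "baseline", np.nan, df["tms_time_ms"])

    # Trimming (after rejection, within condition cells, per tail floor(n*f))
    if mode == "exp1" and s.trim_fraction > 0:
        for _, grp in df[~df["rejected"]].groupby(
                ["modality", "cell_type", "stim", "pulse_type"], dropna=False):
            keep = trim_extremes(grp["amplitude_mv"].to_numpy(), s.trim_fraction)
            dropped = grp.index[~keep]
            df.loc[dropped, ["rejected", "reject_reason"]] = [True, "trimmed"]
            meas.loc[meas["trial"].isin(df.loc[dropped, "trial"]),
                     ["rejected", "reject_reason"]] = [True, "trimmed"]

    retained = df[~df["rejected"]]

    baseline_means: dict[tuple[str, str], float] = {}
    for (modality, ptype), grp in retained[retained["cell_type"] == "baseline"
                                           ].groupby(["modality", "pulse_type"]):
        baseline_means[(modality, ptype)] = float(grp["amplitude_mv"].mean())

    cell_types = ["go", "stop-success"] + (["stop-fail"] if include_failed_stop else [])
    pulse_types = sorted(df["pulse_type"].dropna().unique())
    stim_times = sorted(df.loc[df["cell_type"] != "baseline", "stim"].dropna().unique())
    modalities = sorted(df["modality"].unique())

    def cell_rows(modality, ctype, stim, ptype):
        if ctype == "baseline":
            return retained[(retained["modality"] == modality)
                            & (retained["cell_type"] == "baseline")
                            & (retained["pulse_type"] == ptype)]
        return retained[(retained["modality"] == modality)
                        & (retained["cell_type"] == ctype)
                        & (retained["stim"] == stim)
                        & (retained["pulse_type"] == ptype)]

    out = []
    cells = [(m, "baseline", np.nan, p) for m in modalities for p in pulse_types]
    cells += [(m, c, t, p) for m in modalities for c in cell_types
              for t in stim_times for p in pulse_types]
    for modality, ctype, stim, ptype in cells:
        grp = cell_rows(modality, ctype, stim, ptype)
        n = len(grp)
        mean_amp = float(grp["amplitude_mv"].mean()) if n else float("nan")
        base = baseline_means.get((modality, ptype))
        norm = (normalize_cse(mean_amp, base)
                if n and base is not None and base > 0 else float("nan"))
        sici = float("nan")
        if ptype == "single" and "paired" in pulse_types and n:
            paired = cell_rows(modality, ctype, stim, "paired")
            if len(paired):
                sici = compute_sici(mean_amp, float(paired["amplitude_mv"].mean()))
        csp_mean, n_csp = float("nan"), 0
        if modality == "manual" and ptype == "single":
            with_csp = grp[grp["csp_present"] == True]  # noqa: E712
            n_csp = len(with_csp)
            if n_csp:
                csp_mean = float(with_csp["csp_duration_ms"].mean())
        out.append({
            "modality": modality, "trial_type": ctype, "stim_time_ms": stim,
            "pulse_type": ptype, "n_meps": n, "mean_amplitude_mv": mean_amp,
            "normalized_cse": norm, "sici_pct": sici,
            "mean_csp_ms": csp_mean, "n_csps": n_csp,
        })
    summary = pd.DataFrame(out)
    return summary, meas


def counts_from_summary(summary: pd.DataFrame,
                        trial_types=("go", "stop-success"),
                        pulse_type: str = "single") -> dict:
    """Condition-cell MEP counts keyed (modality, trial_type, stim_time) for
    inclusion screening."""
    counts = {}
    rows = summary[(summary["pulse_type"] == pulse_type)
                   & (summary["trial_type"].isin(trial_types))]
    for _, r in rows.iterrows():
        counts[(r["modality"], r["trial_type"], r["stim_time_ms"])] = int(r["n_meps"])
    return counts
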