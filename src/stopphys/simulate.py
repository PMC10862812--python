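"""Synthetic study generator: trial sequences, race-model behavior with
adaptive SSD tracking, and per-trial EMG / voice signals with recoverable
ground truth.

The behavioral generator embodies the independent horse-race model: the go
process finishes at an ex-Gaussian time, the stop process at SSD + SSRT, and
the response is withheld iff the stop process both triggers and wins.  The
physiological generator follows a two-process (pause-then-cancel) model of
corticospinal excitability: a broad, early, non-selective Pause bell and a
narrower, later Cancel bell restricted to the responding effector, riding on
a linear go-related facilitation.  Every injected quantity is recorded so
downstream measurement stages can be validated by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    DesignConfig,
    InvalidDesignError,
    PauseCancelParams,
    RaceParams,
    StudyConfig,
    TraceSynthParams,
)

EVENT_COLUMNS = [
    "trial", "block", "modality", "trial_type", "ssd_ms", "rt_ms",
    "outcome", "tms_role", "tms_time_ms", "pulse_type",
]

_MAX_ARRANGEMENT_TRIES = 500


@dataclass
class TrialRecord:
    """One task trial; ``tms_time_ms`` holds the stim-time label (post
    stop-signal latency for task pulses, ITI latency for baseline probes)."""

    trial: int
    block: int
    modality: str
    trial_type: str  # "go" | "stop"
    ssd_ms: float | None = None
    rt_ms: float | None = None
    outcome: str | None = None
    tms_role: str = "none"  # "task-pulse" | "baseline-probe" | "none"
    tms_time_ms: float | None = None
    pulse_type: str | None = None  # "single" | "paired"
    response: int | None = None  # 0/1 choice within modality


def generate_trial_sequence(config: DesignConfig, rng: np.random.Generator | None = None,
                            ) -> list[TrialRecord]:
    """Build the balanced trial skeleton for one participant.

    Per block: exactly ``stop_fraction`` of trials are stop trials, each with a
    task pulse; an equal number of go trials carry task pulses; an equal number
    of go trials (each preceded by another go trial) carry baseline probes in
    the preceding inter-trial interval.  Stim-time labels are balanced exactly
    within each trial type, probe latencies exactly across probes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_stop = config.stop_trials_per_block
    n_go = config.trials_per_block - n_stop
    n_stim = len(config.stim_times_ms)
    n_probe_times = len(config.baseline_probe_times_ms)
    if n_stop % n_stim != 0:
        raise InvalidDesignError(
            f"{n_stop} stop trials per block cannot be split over {n_stim} stim times")
    if n_stop % n_probe_times != 0:
        raise InvalidDesignError(
            f"{n_stop} baseline probes per block cannot be split over "
            f"{n_probe_times} probe times")
    if n_go < 2 * n_stop:
        raise InvalidDesignError(
            "not enough go trials for matched go pulses and baseline probes "
            f"({n_go} go vs {n_stop} stop per block)")

    first = "manual" if config.modality_order == "manual-first" else "vocal"
    second = "vocal" if first == "manual" else "manual"

    records: list[TrialRecord] = []
    trial = 0
    for block in range(config.n_blocks):
        modality = first if block % 2 == 0 else second
        if config.paired_pulse:
            pulse_type = "single" if (block // 2) % 2 == 0 else "paired"
        else:
            pulse_type = "single"

        types = _arrange_block(n_stop, n_go, rng)
        go_pos = [i for i, t in enumerate(types) if t == "go"]
        consec = [i for i in go_pos if i > 0 and types[i - 1] == "go"]
        probe_pos = set(rng.choice(consec, size=n_stop, replace=False).tolist())
        pulse_candidates = [i for i in go_pos if i not in probe_pos]
        go_pulse_pos = set(
            rng.choice(pulse_candidates, size=n_stop, replace=False).tolist())

        stop_labels = _balanced_labels(config.stim_times_ms, n_stop, rng)
        go_labels = _balanced_labels(config.stim_times_ms, n_stop, rng)
        probe_labels = _balanced_labels(config.baseline_probe_times_ms, n_stop, rng)

        stop_it, go_it, probe_it = iter(stop_labels), iter(go_labels), iter(probe_labels)
        for i, ttype in enumerate(types):
            rec = TrialRecord(trial=trial, block=block, modality=modality,
                              trial_type=ttype)
            if ttype == "stop":
                rec.tms_role = "task-pulse"
                rec.tms_time_ms = next(stop_it)
                rec.pulse_type = pulse_type
            elif i in go_pulse_pos:
                rec.tms_role = "task-pulse"
                rec.tms_time_ms = next(go_it)
                rec.pulse_type = pulse_type
            elif i in probe_pos:
                rec.tms_role = "baseline-probe"
                rec.tms_time_ms = next(probe_it)
                rec.pulse_type = pulse_type
            records.append(rec)
            trial += 1
    return records


def _arrange_block(n_stop: int, n_go: int, rng: np.random.Generator) -> list[str]:
    """Random trial-type order with at least ``n_stop`` go-after-go positions
    (needed to host inter-trial baseline probes)."""
    types = ["stop"] * n_stop + ["go"] * n_go
    for _ in range(_MAX_ARRANGEMENT_TRIES):
        rng.shuffle(types)
        consec = sum(1 for i in range(1, len(types))
                     if types[i] == "go" and types[i - 1] == "go")
        if consec >= n_stop:
            return list(types)
    raise InvalidDesignError(
        "could not place baseline probes on consecutive-go positions; "
        "design too stop-dense")


def _balanced_labels(values, total: int, rng: np.random.Generator) -> list[float]:
    labels = np.repeat(np.asarray(values, dtype=float), total // len(values))
    rng.shuffle(labels)
    return labels.tolist()


# ---------------------------------------------------------------------------
# race model and staircase


def sample_go_rt(params: RaceParams, rng: np.random.Generator) -> float:
    """Ex-Gaussian go finishing time (normal + exponential)."""
    return rng.normal(params.go_mu_ms, params.go_sigma_ms) + (
        rng.exponential(params.go_tau_ms) if params.go_tau_ms > 0 else 0.0)


def simulate_race_trial(params: RaceParams, ssd_ms: float | None,
                        rng: np.random.Generator,
                        response_window_ms: float = 1000.0,
                        ) -> tuple[str, float | None]:
    """Run one trial of the independent race.

    Returns ``(outcome, rt_ms)``.  ``ssd_ms=None`` means a go trial.  On stop
    trials the response is withheld iff the stop process triggers (probability
    ``1 - trigger_failure_p``) and ``ssd + ssrt_true`` beats the go finishing
    time; a response is reported only if it lands inside the response window.
    """
    go_ft = sample_go_rt(params, rng)
    if ssd_ms is None:
        if go_ft <= response_window_ms:
            return "go-correct", float(go_ft)
        return "go-omission", None
    if ssd_ms < 0:
        raise ValueError("ssd_ms must be non-negative")
    triggered = rng.random() >= params.trigger_failure_p
    if triggered and ssd_ms + params.ssrt_true_ms < go_ft:
        return "stop-success", None
    if go_ft <= response_window_ms:
        return "stop-fail", float(go_ft)
    return "stop-success", None  # no overt response inside the window


class StaircaseBank:
    """One-up/one-down SSD trackers, one per (modality, response) cell.

    A successful stop raises that cell's SSD by one step, a failed stop lowers
    it, clamped to ``[0, response_window - step]``.
    """

    def __init__(self, config: DesignConfig):
        self._step = config.ssd_step_ms
        self._lo = 0.0
        self._hi = config.response_window_ms - config.ssd_step_ms
        self._ssd: dict[tuple[str, int], float] = {}
        self._init = config.ssd_init_ms

    def current(self, modality: str, response: int) -> float:
        return self._ssd.get((modality, response), self._init)

    def update(self, modality: str, response: int, outcome: str) -> float:
        ssd = self.current(modality, response)
        if outcome == "stop-success":
            ssd += self._step
        elif outcome == "stop-fail":
            ssd -= self._step
        else:
            raise ValueError(f"staircase updates only on stop outcomes, got {outcome!r}")
        ssd = min(max(ssd, self._lo), self._hi)
        self._ssd[(modality, response)] = ssd
        return ssd


# ---------------------------------------------------------------------------
# generative excitability model


def _bell(t: np.ndarray | float, amp: float, peak: float, width: float):
    t = np.asarray(t, dtype=float)
    return amp * np.exp(-((t - peak) ** 2) / (2.0 * width**2))


def cse_ground_truth(trial: TrialRecord, probe_time_ms: float,
                     probed_effector_modality: str,
                     model: PauseCancelParams) -> float:
    """Expected MEP scaling (relative to baseline) at ``probe_time_ms`` after
    go-signal onset.

    ``scaling = 1 + go_facilitation * [probed effector responding]
    - pause(t - ssd) * [stop trial] - cancel(t - ssd) * [stop and responding]``,
    floored at a small positive constant.  Baseline probes sit in the
    inter-trial interval and scale to exactly 1.
    """
    if trial.tms_role == "baseline-probe":
        return 1.0
    if probe_time_ms < 0:
        raise ValueError("probe before go-signal onset")
    responding = trial.modality == probed_effector_modality
    scaling = 1.0
    if responding:
        scaling += model.go_facilitation_slope * probe_time_ms
    if trial.trial_type == "stop":
        if trial.ssd_ms is None:
            raise ValueError("stop trial without an SSD")
        t_stop = probe_time_ms - trial.ssd_ms
        scaling -= _bell(t_stop, model.pause_amp, model.pause_peak_ms,
                         model.pause_width_ms)
        if responding:
            scaling -= _bell(t_stop, model.cancel_amp, model.cancel_peak_ms,
                             model.cancel_width_ms)
    return float(max(scaling, model.floor))


# ---------------------------------------------------------------------------
# trace synthesis


def _render_trace(n_samples: int, pulse_idx: int, fs: float, scaling: float,
                  synth: TraceSynthParams, rng: np.random.Generator, *,
                  tonic: bool, csp_ms: float | None,
                  burst_onset_ms: float | None, mep_cv: float | None = None,
                  ) -> tuple[np.ndarray, dict]:
    """Render one EMG trace around a pulse at sample ``pulse_idx``.

    Returns the trace (mV) and a ground-truth dict of every injected value.
    """
    if pulse_idx >= n_samples or pulse_idx < 0:
        raise ValueError("pulse scheduled outside the trace")
    ms = 1000.0
    cv = synth.mep_cv if mep_cv is None else mep_cv

    trace = (rng.normal(0.0, synth.noise_rms_mv, n_samples)
             if synth.noise_rms_mv > 0 else np.zeros(n_samples))

    mep_off_idx = pulse_idx + int(round(
        (synth.mep_latency_ms + synth.mep_pos_ms + synth.mep_neg_ms) * fs / ms))
    truth: dict = {"scaling": scaling, "pulse_sample_index": pulse_idx,
                   "csp_true_ms": None, "mep_amp_mv": 0.0}

    if tonic and synth.tonic_rms_mv > 0:
        tonic_sig = rng.normal(0.0, synth.tonic_rms_mv, n_samples)
        if csp_ms is not None:
            resume_idx = pulse_idx + int(round(csp_ms * fs / ms))
            sil_lo = min(mep_off_idx, n_samples)
            sil_hi = min(max(resume_idx, sil_lo), n_samples)
            tonic_sig[sil_lo:sil_hi] = 0.0
            truth["csp_true_ms"] = (sil_hi - pulse_idx) / fs * ms if sil_hi > sil_lo else None
        trace += tonic_sig

    # pulse artifact: brief decaying oscillation
    art_n = int(round(synth.artifact_ms * fs / ms))
    if art_n > 0 and synth.artifact_amp_mv > 0:
        tt = np.arange(min(art_n, n_samples - pulse_idx))
        trace[pulse_idx:pulse_idx + len(tt)] += (
            synth.artifact_amp_mv * np.cos(2 * np.pi * tt / max(art_n, 1))
            * np.exp(-3.0 * tt / max(art_n, 1)))

    # biphasic MEP scaled so the sampled peak-to-peak equals the target exactly
    amp_target = synth.mep_base_amp_mv * scaling
    if cv > 0 and amp_target > 0:
        amp_target *= float(rng.lognormal(0.0, cv))
    if amp_target > 0:
        i0 = pulse_idx + int(round(synth.mep_latency_ms * fs / ms))
        n_pos = max(int(round(synth.mep_pos_ms * fs / ms)), 2)
        n_neg = max(int(round(synth.mep_neg_ms * fs / ms)), 2)
        shape = np.concatenate([
            np.sin(np.pi * np.arange(n_pos) / n_pos),
            -0.6 * np.sin(np.pi * np.arange(n_neg) / n_neg),
        ])
        ptp = shape.max() - shape.min()
        shape = shape * (amp_target / ptp)
        hi = min(i0 + len(shape), n_samples)
        if i0 < n_samples:
            trace[i0:hi] += shape[: hi - i0]
            truth["mep_amp_mv"] = float(amp_target)

    if burst_onset_ms is not None and synth.voluntary_amp_mv > 0:
        b0 = int(round(burst_onset_ms * fs / ms))
        b1 = b0 + int(round(synth.voluntary_dur_ms * fs / ms))
        b0, b1 = max(b0, 0), min(b1, n_samples)
        if b1 > b0:
            trace[b0:b1] += rng.normal(0.0, synth.voluntary_amp_mv, b1 - b0)
            truth["burst_onset_ms"] = burst_onset_ms
            # voluntary EMG ends any ongoing silent period at its onset
            if truth["csp_true_ms"] is not None:
                resume_idx = pulse_idx + int(round(truth["csp_true_ms"] * fs / ms))
                if b0 < resume_idx:
                    truth["csp_true_ms"] = ((b0 - pulse_idx) / fs * ms
                                            if b0 > mep_off_idx else None)
    return trace, truth


def synth_emg_trace(trial: TrialRecord, scaling: float, synth: TraceSynthParams,
                    rng: np.random.Generator, *, pulse_trial_time_ms: float,
                    tonic: bool = False, csp_true_ms: float | None = None,
                    mep_cv: float | None = None) -> tuple[np.ndarray, dict]:
    """Synthesize one trial's EMG window around the TMS pulse.

    The trace spans ``pre_ms`` before to ``post_ms`` after the pulse; sample 0
    corresponds to trial time ``pulse_trial_time_ms - pre_ms``.  A voluntary
    burst is added for responding-effector (manual) trials whose response falls
    inside the window.
    """
    synth.validate()
    fs = synth.sampling_rate_hz
    n = int(round((synth.pre_ms + synth.post_ms) * fs / 1000.0))
    pulse_idx = int(round(synth.pre_ms * fs / 1000.0))
    onset_ms = pulse_trial_time_ms - synth.pre_ms

    burst_onset = None
    if trial.modality == "manual" and trial.rt_ms is not None:
        rel = trial.rt_ms - onset_ms
        if rel < n / fs * 1000.0:
            burst_onset = rel
    trace, truth = _render_trace(
        n, pulse_idx, fs, scaling, synth, rng, tonic=tonic, csp_ms=csp_true_ms,
        burst_onset_ms=burst_onset, mep_cv=mep_cv)
    truth.update(trial_index=trial.trial, trace_onset_ms=onset_ms)
    return trace, truth


def synth_voice_envelope(trial: TrialRecord, rng: np.random.Generator, *,
                         fs_hz: float = 1000.0, dur_ms: float = 1200.0,
                         noise_floor: float = 0.02, burst_amp: float = 1.0,
                         ramp_ms: float = 10.0, burst_dur_ms: float = 200.0,
                         ) -> np.ndarray:
    """Amplitude envelope of one vocal trial.

    Bounded sub-threshold noise (uniform on ``[0, noise_floor]``) with a
    supra-threshold burst starting at the trial's response time; successful
    stops and omissions carry no burst.
    """
    n = int(round(dur_ms * fs_hz / 1000.0))
    env = rng.uniform(0.0, noise_floor, n)
    if trial.rt_ms is not None:
        b0 = int(round(trial.rt_ms * fs_hz / 1000.0))
        if b0 < n:
            ramp_n = max(int(round(ramp_ms * fs_hz / 1000.0)), 1)
            b1 = min(b0 + int(round(burst_dur_ms * fs_hz / 1000.0)), n)
            burst = np.full(b1 - b0, burst_amp)
            k = min(ramp_n, len(burst))
            burst[:k] *= np.linspace(1.0 / k, 1.0, k)
            env[b0:b1] = np.maximum(env[b0:b1], burst)
    return env


# ---------------------------------------------------------------------------
# participant-level simulation


@dataclass
class ParticipantData:
    """All synthetic outputs for one participant."""

    events: pd.DataFrame
    truth: pd.DataFrame  # one row per TMS trial, every injected value
    traces: np.ndarray | None = None  # (n_tms_trials, n_samples) mV
    sidecar: dict | None = None
    voice: np.ndarray | None = None  # (n_vocal_trials, n_env_samples)
    voice_trials: list[int] = field(default_factory=list)


def simulate_behavior(config: DesignConfig, race: dict[str, RaceParams],
                      rng: np.random.Generator) -> list[TrialRecord]:
    """Run the race model with staircase tracking over a full trial sequence."""
    records = generate_trial_sequence(config, rng)
    bank = StaircaseBank(config)
    for rec in records:
        rec.response = int(rng.integers(2))
        params = race[rec.modality]
        if rec.trial_type == "stop":
            rec.ssd_ms = bank.current(rec.modality, rec.response)
            rec.outcome, rec.rt_ms = simulate_race_trial(
                params, rec.ssd_ms, rng, config.response_window_ms)
            bank.update(rec.modality, rec.response, rec.outcome)
        else:
            rec.outcome, rec.rt_ms = simulate_race_trial(
                params, None, rng, config.response_window_ms)
            # matched-latency reference for go-trial task pulses
            rec.ssd_ms = None
            if rec.tms_role == "task-pulse":
                rec._virtual_ssd = bank.current(rec.modality, rec.response)  # type: ignore[attr-defined]
    return records


def _pulse_trial_time(rec: TrialRecord, config: DesignConfig) -> float:
    """Absolute pulse time relative to go-signal onset of the trial."""
    if rec.tms_role == "baseline-probe":
        return rec.tms_time_ms - config.iti_ms  # in the preceding ITI
    ref = rec.ssd_ms if rec.trial_type == "stop" else getattr(rec, "_virtual_ssd", config.ssd_init_ms)
    return ref + rec.tms_time_ms


def events_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in EVENT_COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df


def simulate_participant(cfg: StudyConfig, rng: np.random.Generator | int, *,
                         make_traces: bool = True, make_voice: bool = False,
                         mep_cv: float | None = None) -> ParticipantData:
    """Simulate one participant end to end.

    Behavior is always simulated; ``make_traces`` renders per-trial EMG windows
    for every TMS trial (task pulse or baseline probe) plus a JSON-ready
    sidecar, ``make_voice`` renders vocal amplitude envelopes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg.validate()
    records = simulate_behavior(cfg.design, cfg.race, rng)
    events = events_frame(records)

    synth = cfg.trace_synth
    fs = synth.sampling_rate_hz
    tms_records = [r for r in records if r.tms_role != "none"]
    truth_rows = []
    traces = None
    sidecar = None
    if make_traces:
        n_samples = int(round((synth.pre_ms + synth.post_ms) * fs / 1000.0))
        traces = np.empty((len(tms_records), n_samples))
        sidecar = {
            "sampling_rate_hz": fs, "units": "mV",
            "trial_index": [], "pulse_sample_index": [], "trace_onset_ms": [],
        }
    for k, rec in enumerate(tms_records):
        pulse_t = _pulse_trial_time(rec, cfg.design)
        if rec.tms_role == "baseline-probe":
            scaling = 1.0
        else:
            scaling = cse_ground_truth(rec, pulse_t, "manual", cfg.pause_cancel)
        tonic = rec.modality == "manual"
        csp_true = None
        if tonic and synth.tonic_rms_mv > 0:
            csp_true = synth.csp_base_ms + rng.uniform(
                -synth.csp_jitter_ms, synth.csp_jitter_ms)
        atten = synth.paired_attenuation if rec.pulse_type == "paired" else 0.0
        row = {"trial": rec.trial, "scaling": scaling,
               "pulse_trial_time_ms": pulse_t, "csp_true_ms": csp_true,
               "mep_amp_mv": np.nan}
        if make_traces:
            trace, tr_truth = synth_emg_trace(
                rec, scaling * (1.0 - atten), synth, rng,
                pulse_trial_time_ms=pulse_t, tonic=tonic,
                csp_true_ms=csp_true, mep_cv=mep_cv)
            traces[k] = trace
            row["mep_amp_mv"] = tr_truth["mep_amp_mv"]
            row["csp_true_ms"] = tr_truth["csp_true_ms"]
            sidecar["trial_index"].append(int(rec.trial))
            sidecar["pulse_sample_index"].append(tr_truth["pulse_sample_index"])
            sidecar["trace_onset_ms"].append(tr_truth["trace_onset_ms"])
        truth_rows.append(row)

    voice = None
    voice_trials: list[int] = []
    if make_voice:
        vocal = [r for r in records if r.modality == "vocal"]
        env0 = synth_voice_envelope(vocal[0], rng)
        voice = np.empty((len(vocal), env0.shape[0]))
        voice[0] = env0
        voice_trials = [vocal[0].trial]
        for i, rec in enumerate(vocal[1:], start=1):
            voice[i] = synth_voice_envelope(rec, rng)
            voice_trials.append(rec.trial)

    return ParticipantData(events=events, truth=pd.DataFrame(truth_rows),
                           traces=traces, sidecar=sidecar, voice=voice,
                           voice_trials=voice_trials)


def simulate_mep_amplitudes(cfg: StudyConfig, rng: np.random.Generator | int, *,
                            mep_cv: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast amplitude-level simulation (no trace rendering).

    Returns ``(events, amplitudes)`` where amplitudes has one row per TMS
    trial with the injected scaling and a noisy MEP amplitude in mV.  Useful
    for cohort-scale effect-size work where rendering raw EMG is unnecessary.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg.validate()
    records = simulate_behavior(cfg.design, cfg.race, rng)
    events = events_frame(records)
    synth = cfg.trace_synth
    cv = synth.mep_cv if mep_cv is None else mep_cv
    rows = []
    for rec in records:
        if rec.tms_role == "none":
            continue
        pulse_t = _pulse_trial_time(rec, cfg.design)
        scaling = (1.0 if rec.tms_role == "baseline-probe"
                   else cse_ground_truth(rec, pulse_t, "manual", cfg.pause_cancel))
        amp = synth.mep_base_amp_mv * scaling
        if rec.pulse_type == "paired":
            amp *= 1.0 - synth.paired_attenuation
        if cv > 0:
            amp *= float(rng.lognormal(0.0, cv))
        rows.append({"trial": rec.trial, "scaling": scaling,
                     "pulse_trial_time_ms": pulse_t, "amplitude_mv": amp})
    return events, pd.DataFrame(rows)
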