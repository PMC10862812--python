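"""Parameter containers for the stop-signal physiology simulator and pipeline.

Four dataclasses describe a study: :class:`DesignConfig` (trial counts, SSD
staircase, TMS schedule), :class:`RaceParams` (independent horse-race model of
go and stop finishing times), :class:`PauseCancelParams` (the generative
two-process excitability model), and :class:`TraceSynthParams` (EMG trace
rendering).  :class:`AnalysisSettings` collects every measurement threshold
used downstream.  All of them round-trip through a YAML config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class InvalidDesignError(ValueError):
    """Raised when a task design cannot be balanced exactly."""


@dataclass
class DesignConfig:
    """Block/trial structure of the dual manual-vocal stop-signal task.

    Defaults reproduce the single-pulse experiment: 12 alternating blocks of
    90 trials, one third of them stop trials, SSD staircase initialized at
    200 ms moving in 50 ms steps, task TMS at 150/200/250 ms and inter-trial
    baseline probes at 500/700/900 ms.
    """

    n_blocks: int = 12
    trials_per_block: int = 90
    stop_fraction: float = 1.0 / 3.0
    modality_order: str = "manual-first"  # or "vocal-first"
    stim_times_ms: tuple[float, ...] = (150.0, 200.0, 250.0)
    baseline_probe_times_ms: tuple[float, ...] = (500.0, 700.0, 900.0)
    paired_pulse: bool = False
    ssd_init_ms: float = 200.0
    ssd_step_ms: float = 50.0
    response_window_ms: float = 1000.0
    iti_ms: float = 3200.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.stop_fraction < 1.0):
            raise InvalidDesignError("stop_fraction must lie in (0, 1)")
        n_stop = self.trials_per_block * self.stop_fraction
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise InvalidDesignError(
                "trials_per_block * stop_fraction must be an integer "
                f"(got {n_stop})"
            )
        if self.modality_order not in ("manual-first", "vocal-first"):
            raise InvalidDesignError(f"unknown modality_order {self.modality_order!r}")
        if list(self.stim_times_ms) != sorted(self.stim_times_ms):
            raise InvalidDesignError("stim_times_ms must be sorted ascending")
        if self.ssd_step_ms <= 0:
            raise InvalidDesignError("ssd_step_ms must be positive")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise InvalidDesignError("need at least one block and one trial")

    @property
    def stop_trials_per_block(self) -> int:
        return int(round(self.trials_per_block * self.stop_fraction))


def exp2_design(**overrides) -> DesignConfig:
    """Paired-pulse variant: two stim times, single/paired blocks alternating
    every two blocks, slightly longer inter-trial interval."""
    base = dict(
        stim_times_ms=(150.0, 250.0),
        paired_pulse=True,
        iti_ms=3700.0,
    )
    base.update(overrides)
    return DesignConfig(**base)


@dataclass
class RaceParams:
    """Independent race between an ex-Gaussian go process and a constant-latency
    stop process; ``trigger_failure_p`` is the chance the stop process never
    launches."""

    go_mu_ms: float = 480.0
    go_sigma_ms: float = 60.0
    go_tau_ms: float = 80.0
    ssrt_true_ms: float = 220.0
    trigger_failure_p: float = 0.0

    def validate(self) -> None:
        if self.go_sigma_ms <= 0:
            raise ValueError("go_sigma_ms must be positive")
        if self.go_tau_ms < 0:
            raise ValueError("go_tau_ms must be non-negative")
        if self.ssrt_true_ms <= 0:
            raise ValueError("ssrt_true_ms must be positive")
        if not (0.0 <= self.trigger_failure_p < 1.0):
            raise ValueError("trigger_failure_p must lie in [0, 1)")


def default_race_params() -> dict[str, RaceParams]:
    """Per-modality go/stop parameters; vocal responses run faster than manual
    ones, stopping latency is shared."""
    return {
        "manual": RaceParams(480.0, 60.0, 80.0, 220.0, 0.0),
        "vocal": RaceParams(430.0, 55.0, 70.0, 220.0, 0.0),
    }


@dataclass
class PauseCancelParams:
    """Two-process generative model of corticospinal excitability.

    Excitability scaling relative to baseline is
    ``1 + go_facilitation - pause - cancel`` where the Pause bell is broad,
    early and non-selective, the Cancel bell is later, narrower and applies
    only to the responding effector, and go facilitation rises linearly with
    time since the go signal in the responding effector.
    """

    pause_amp: float = 0.25
    pause_peak_ms: float = 150.0
    pause_width_ms: float = 150.0
    cancel_amp: float = 0.35
    cancel_peak_ms: float = 250.0
    cancel_width_ms: float = 50.0
    go_facilitation_slope: float = 0.0005  # gain per ms after go onset
    floor: float = 0.05

    def validate(self) -> None:
        if not self.pause_peak_ms < self.cancel_peak_ms:
            raise ValueError("model assumes the Pause peaks before the Cancel")
        for name in ("pause_amp", "cancel_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("pause_width_ms", "cancel_width_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TraceSynthParams:
    """EMG trace rendering parameters.

    The tonic contraction level sits deliberately below the 0.05 mV pre-pulse
    RMS rejection threshold so that contraction (silent-period) trials survive
    rejection, as real hand-task recordings do.
    """

    sampling_rate_hz: float = 5000.0
    noise_rms_mv: float = 0.01
    tonic_rms_mv: float = 0.04
    mep_base_amp_mv: float = 1.0
    mep_latency_ms: float = 22.0
    mep_pos_ms: float = 6.0  # positive half-wave duration
    mep_neg_ms: float = 9.0  # negative half-wave duration
    mep_cv: float = 0.2  # lognormal sigma of trial-to-trial MEP variability
    artifact_amp_mv: float = 5.0
    artifact_ms: float = 1.5
    paired_attenuation: float = 0.25  # conditioned-MEP reduction on paired pulses
    csp_base_ms: float = 150.0
    csp_jitter_ms: float = 40.0  # uniform +/- jitter of true silent periods
    voluntary_amp_mv: float = 0.3
    voluntary_dur_ms: float = 150.0
    pre_ms: float = 200.0  # trace extent before the pulse
    post_ms: float = 400.0  # trace extent after the pulse

    def validate(self) -> None:
        if self.sampling_rate_hz < 2000:
            raise ValueError(
                "sampling_rate_hz must be >= 2000 to resolve the 10-50 ms MEP window"
            )
        for name in ("noise_rms_mv", "tonic_rms_mv", "mep_base_amp_mv",
                     "artifact_amp_mv", "voluntary_amp_mv", "mep_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AnalysisSettings:
    """Every measurement threshold applied by the extraction pipeline."""

    mep_window_ms: tuple[float, float] = (10.0, 50.0)  # closed on both ends
    min_mep_amp_mv: float = 0.05
    max_prepulse_rms_mv: float = 0.05
    prepulse_span_ms: float = 80.0
    artifact_search_ms: float = 5.0
    artifact_floor_mv: float = 0.5
    trim_fraction: float = 0.05  # per tail, floor(n * fraction) values dropped
    min_meps_exp1: int = 15
    min_meps_exp2: int = 10
    min_failed_stop_meps: int = 10
    min_failed_stop_csps: int = 5
    # silent-period detector (automated stand-in for analyst marking)
    csp_search_start_ms: float = 50.0
    csp_coarse_win_ms: float = 25.0
    csp_fine_win_ms: float = 5.0
    csp_threshold_frac: float = 0.5
    csp_hold_ms: float = 5.0
    csp_min_silence_ms: float = 20.0
    csp_refine_ms: float = 2.0
    csp_max_ms: float = 350.0
    csp_noise_floor_mv: float = 0.02
    # effect-size classification
    d_threshold: float = 0.2
    increase_rule: str = "running-max"  # or "pairwise"


@dataclass
class StudyConfig:
    """Everything needed to simulate and analyse one study."""

    design: DesignConfig = field(default_factory=DesignConfig)
    race: dict[str, RaceParams] = field(default_factory=default_race_params)
    pause_cancel: PauseCancelParams = field(default_factory=PauseCancelParams)
    trace_synth: TraceSynthParams = field(default_factory=TraceSynthParams)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def validate(self) -> None:
        self.design.validate()
        for rp in self.race.values():
            rp.validate()
        self.pause_cancel.validate()
        self.trace_synth.validate()


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj


def study_to_dict(cfg: StudyConfig) -> dict:
    return _as_plain(cfg)


_TUPLE_FIELDS = {"stim_times_ms", "baseline_probe_times_ms", "mep_window_ms"}


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if f.name in _TUPLE_FIELDS and isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
    return cls(**kwargs)


def study_from_dict(data: dict) -> StudyConfig:
    cfg = StudyConfig()
    if "design" in data:
        cfg.design = _from_dict(DesignConfig, data["design"])
    if "race" in data:
        cfg.race = {mod: _from_dict(RaceParams, rp) for mod, rp in data["race"].items()}
    if "pause_cancel" in data:
        cfg.pause_cancel = _from_dict(PauseCancelParams, data["pause_cancel"])
    if "trace_synth" in data:
        cfg.trace_synth = _from_dict(TraceSynthParams, data["trace_synth"])
    if "analysis" in data:
        cfg.analysis = _from_dict(AnalysisSettings, data["analysis"])
    return cfg


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = study_from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(study_to_dict(cfg), fh, sort_keys=False)


def default_config(mode: str = "exp1") -> StudyConfig:
    """Study configuration for the single-pulse (`exp1`) or paired-pulse
    (`exp2`) experiment."""
    if mode == "exp1":
        return StudyConfig()
    if mode == "exp2":
        return StudyConfig(design=exp2_design())
    raise ValueError(f"unknown mode {mode!r}; expected 'exp1' or 'exp2'")
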