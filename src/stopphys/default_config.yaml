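# Default study configuration (single-pulse experiment).
# Every analysis threshold used by the pipeline appears here explicitly.
design:
  n_blocks: 12              # alternating manual/vocal blocks
  trials_per_block: 90      # 12 x 90 = 1080 trials per participant
  stop_fraction: 0.3333333333333333   # one third of trials carry a stop signal
  modality_order: manual-first
  stim_times_ms: [150.0, 200.0, 250.0]      # task TMS latencies after the stop signal
  baseline_probe_times_ms: [500.0, 700.0, 900.0]  # inter-trial baseline probe latencies
  paired_pulse: false       # true = alternate single/paired blocks (SICI design)
  ssd_init_ms: 200.0        # stop-signal delay staircase start
  ssd_step_ms: 50.0         # one-up/one-down staircase step
  response_window_ms: 1000.0
  iti_ms: 3200.0
  seed: 0
race:                       # ex-Gaussian go process + constant stopping latency
  manual: {go_mu_ms: 480.0, go_sigma_ms: 60.0, go_tau_ms: 80.0, ssrt_true_ms: 220.0, trigger_failure_p: 0.0}
  vocal:  {go_mu_ms: 430.0, go_sigma_ms: 55.0, go_tau_ms: 70.0, ssrt_true_ms: 220.0, trigger_failure_p: 0.0}
pause_cancel:               # generative excitability model
  pause_amp: 0.25           # broad, early, non-selective suppression
  pause_peak_ms: 150.0
  pause_width_ms: 150.0
  cancel_amp: 0.35          # later suppression restricted to the responding effector
  cancel_peak_ms: 250.0
  cancel_width_ms: 50.0
  go_facilitation_slope: 0.0005   # excitability gain per ms after go onset
  floor: 0.05
trace_synth:
  sampling_rate_hz: 5000.0
  noise_rms_mv: 0.01
  tonic_rms_mv: 0.04        # background contraction; below the 0.05 mV rejection line
  mep_base_amp_mv: 1.0
  mep_latency_ms: 22.0
  mep_pos_ms: 6.0
  mep_neg_ms: 9.0
  mep_cv: 0.2               # lognormal trial-to-trial MEP variability
  artifact_amp_mv: 5.0
  artifact_ms: 1.5
  paired_attenuation: 0.25  # conditioned-MEP reduction on paired-pulse trials
  csp_base_ms: 150.0
  csp_jitter_ms: 40.0
  voluntary_amp_mv: 0.3
  voluntary_dur_ms: 150.0
  pre_ms: 200.0
  post_ms: 400.0
analysis:
  mep_window_ms: [10.0, 50.0]   # peak-to-peak window after the pulse, endpoints inclusive
  min_mep_amp_mv: 0.05          # MEPs below this are rejected
  max_prepulse_rms_mv: 0.05     # pre-pulse EMG RMS above this rejects the trial
  prepulse_span_ms: 80.0        # RMS span before the pulse
  artifact_search_ms: 5.0
  artifact_floor_mv: 0.5
  trim_fraction: 0.05           # bottom/top tail trimmed per condition (single-pulse mode)
  min_meps_exp1: 15             # per-cell inclusion threshold, single-pulse experiment
  min_meps_exp2: 10             # per-cell inclusion threshold, paired-pulse experiment
  min_failed_stop_meps: 10      # failed-stop CSE analyses
  min_failed_stop_csps: 5       # failed-stop silent-period analyses
  csp_search_start_ms: 50.0
  csp_coarse_win_ms: 25.0
  csp_fine_win_ms: 5.0
  csp_threshold_frac: 0.5
  csp_hold_ms: 5.0
  csp_min_silence_ms: 20.0
  csp_refine_ms: 2.0            # snap to max deflection within +/- 2 ms
  csp_max_ms: 350.0
  csp_noise_floor_mv: 0.02
  d_threshold: 0.2              # Cohen's d cutoff for "shown" suppression / increases
  increase_rule: running-max
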