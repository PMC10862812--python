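"""Synthetic-data generator: sequence balance, race model, staircase,
generative excitability curves, and trace/voice round trips."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import stopphys as sp
from stopphys.emg import detect_csp, extract_mep, prepulse_rms
from stopphys.simulate import (
    _render_trace,
    cse_ground_truth,
    events_frame,
    generate_trial_sequence,
    simulate_behavior,
    simulate_race_trial,
    synth_emg_trace,
    synth_voice_envelope,
)


class TestTrialSequence:
    def test_tiny_design_balance(self, tiny_design):
        recs = generate_trial_sequence(tiny_design)
        assert len(recs) == 9
        stops = [r for r in recs if r.trial_type == "stop"]
        assert len(stops) == 3
        assert Counter(r.tms_time_ms for r in stops) == {150: 1, 200: 1, 250: 1}
        go_pulses = [r for r in recs
                     if r.trial_type == "go" and r.tms_role == "task-pulse"]
        assert Counter(r.tms_time_ms for r in go_pulses) == {150: 1, 200: 1, 250: 1}
        probes = [r for r in recs if r.tms_role == "baseline-probe"]
        assert Counter(r.tms_time_ms for r in probes) == {500: 1, 700: 1, 900: 1}

    def test_probes_sit_on_consecutive_go_positions(self, tiny_design):
        recs = generate_trial_sequence(tiny_design)
        for r in recs:
            if r.tms_role == "baseline-probe":
                assert r.trial_type == "go"
                assert recs[r.trial - 1].trial_type == "go"

    def test_block_structure_alternates_modality(self):
        cfg = sp.DesignConfig(n_blocks=4, trials_per_block=9, seed=1)
        recs = generate_trial_sequence(cfg)
        block_mod = {r.block: r.modality for r in recs}
        assert [block_mod[b] for b in range(4)] == [
            "manual", "vocal", "manual", "vocal"]

    def test_paired_pulse_blocks_alternate_every_two(self):
        cfg = sp.exp2_design(n_blocks=8, trials_per_block=9,
                             stim_times_ms=(150.0, 250.0, 350.0))
        # three stim times keep 3 stop trials per block balanced
        recs = generate_trial_sequence(cfg)
        block_ptype = {r.block: r.pulse_type for r in recs if r.pulse_type}
        assert [block_ptype[b] for b in range(8)] == [
            "single", "single", "paired", "paired"] * 2

    def test_same_seed_reproduces_sequence(self, tiny_design):
        a = generate_trial_sequence(tiny_design)
        b = generate_trial_sequence(tiny_design)
        assert a == b

    @pytest.mark.parametrize("kwargs", [
        dict(trials_per_block=10),           # 10/3 stop trials not integer
        dict(stop_fraction=0.5),             # too few go trials for probes
        dict(trials_per_block=12),           # 4 stops over 3 stim times
        dict(stim_times_ms=(250.0, 150.0)),  # unsorted stim times
        dict(ssd_step_ms=0.0),
    ])
    def test_unbalanced_designs_rejected(self, kwargs):
        fields = {"n_blocks": 1, "trials_per_block": 9, **kwargs}
        cfg = sp.DesignConfig(**fields)
        with pytest.raises(sp.InvalidDesignError):
            generate_trial_sequence(cfg)


class TestRaceModel:
    def test_huge_ssd_means_stop_never_wins(self, rng):
        params = sp.RaceParams()
        for _ in range(50):
            outcome, rt = simulate_race_trial(params, 1e6, rng)
            assert outcome == "stop-fail" and rt is not None

    def test_instant_stop_limit(self, rng):
        params = sp.RaceParams(go_mu_ms=500, go_tau_ms=500,
                               ssrt_true_ms=1e-9, trigger_failure_p=0.25)
        outcomes = [simulate_race_trial(params, 0.0, rng,
                                        response_window_ms=1e9)[0]
                    for _ in range(4000)]
        p_success = outcomes.count("stop-success") / len(outcomes)
        assert p_success == pytest.approx(0.75, abs=0.03)

    def test_stop_success_rate_matches_exgaussian_tail(self, rng):
        # P(stop success) = P(go finishing time > SSD + SSRT), available in
        # closed form from the ex-Gaussian survival function
        mu, sigma, tau, ssrt, ssd = 500.0, 50.0, 50.0, 200.0, 300.0
        params = sp.RaceParams(mu, sigma, tau, ssrt)
        n = 100_000
        wins = sum(simulate_race_trial(params, ssd, rng)[0] == "stop-success"
                   for _ in range(n))
        expected = stats.exponnorm.sf(ssd + ssrt, K=tau / sigma, loc=mu,
                                      scale=sigma)
        assert wins / n == pytest.approx(expected, abs=0.006)

    def test_negative_ssd_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_race_trial(sp.RaceParams(), -1.0, rng)


class TestStaircase:
    def test_one_up_one_down(self):
        bank = sp.StaircaseBank(sp.DesignConfig())
        assert bank.current("manual", 0) == 200.0
        assert bank.update("manual", 0, "stop-success") == 250.0
        assert bank.update("manual", 0, "stop-fail") == 200.0

    def test_floor_clamp(self):
        bank = sp.StaircaseBank(sp.DesignConfig(ssd_init_ms=0.0))
        assert bank.update("manual", 0, "stop-fail") == 0.0

    def test_trackers_are_independent_per_cell(self):
        bank = sp.StaircaseBank(sp.DesignConfig())
        bank.update("manual", 0, "stop-success")
        assert bank.current("manual", 1) == 200.0
        assert bank.current("vocal", 0) == 200.0

    def test_alternation_oscillates(self):
        bank = sp.StaircaseBank(sp.DesignConfig())
        seen = []
        for outcome in ["stop-success", "stop-fail"] * 3:
            seen.append(bank.update("manual", 0, outcome))
        assert seen == [250.0, 200.0] * 3


class TestGroundTruthModel:
    def _stop_trial(self, modality="manual", ssd=300.0):
        return sp.TrialRecord(trial=0, block=0, modality=modality,
                              trial_type="stop", ssd_ms=ssd,
                              tms_role="task-pulse")

    def test_null_model_scales_to_one(self):
        model = sp.PauseCancelParams(pause_amp=0.0, cancel_amp=0.0,
                                     go_facilitation_slope=0.0)
        for t in (150.0, 400.0, 900.0):
            assert cse_ground_truth(self._stop_trial(), t, "manual", model) == 1.0

    def test_nonresponding_effector_ignores_cancel(self):
        trial = self._stop_trial(modality="vocal")
        lo = sp.PauseCancelParams(cancel_amp=0.0)
        hi = sp.PauseCancelParams(cancel_amp=5.0)
        for t in (350.0, 450.0, 550.0):
            assert (cse_ground_truth(trial, t, "manual", lo)
                    == cse_ground_truth(trial, t, "manual", hi))

    def test_responding_suppression_grows_late_nonselective_stays_flat(self):
        model = sp.PauseCancelParams()
        ssd = 300.0
        stim = [150.0, 200.0, 250.0]

        def suppression(modality):
            trial = self._stop_trial(modality=modality)
            go = sp.TrialRecord(trial=1, block=0, modality=modality,
                                trial_type="go", tms_role="task-pulse")
            return [cse_ground_truth(go, ssd + t, "manual", model)
                    - cse_ground_truth(trial, ssd + t, "manual", model)
                    for t in stim]

        responding = suppression("manual")
        assert responding[0] < responding[1] < responding[2]
        nonresponding = suppression("vocal")
        # non-selective suppression is flat up to the spread of the broad
        # Pause bell itself over the probed latencies (closed form)
        pause = [sp.simulate._bell(t, model.pause_amp, model.pause_peak_ms,
                                   model.pause_width_ms) for t in stim]
        curve_tol = (max(pause) - min(pause)) + 1e-12
        assert max(nonresponding) - min(nonresponding) <= curve_tol

    def test_probe_before_go_onset_rejected(self):
        with pytest.raises(ValueError):
            cse_ground_truth(self._stop_trial(), -10.0, "manual",
                             sp.PauseCancelParams())

    def test_floor_bounds_extreme_suppression(self):
        model = sp.PauseCancelParams(pause_amp=5.0)
        assert cse_ground_truth(self._stop_trial(ssd=300.0), 450.0, "manual",
                                model) == model.floor


class TestTraceSynthesis:
    def test_noiseless_round_trip_recovers_exact_amplitude(self, rng):
        synth = replace(sp.TraceSynthParams(), noise_rms_mv=0.0,
                        tonic_rms_mv=0.0, mep_cv=0.0)
        trial = sp.TrialRecord(trial=0, block=0, modality="vocal",
                               trial_type="go", tms_role="task-pulse",
                               tms_time_ms=150.0)
        trace, truth = synth_emg_trace(trial, 0.73, synth, rng,
                                       pulse_trial_time_ms=350.0)
        pulse = truth["pulse_sample_index"]
        amp = extract_mep(trace, pulse, synth.sampling_rate_hz)
        assert amp == pytest.approx(0.73 * synth.mep_base_amp_mv, abs=1e-12)

    def test_zero_scaling_leaves_no_mep(self, rng):
        synth = replace(sp.TraceSynthParams(), noise_rms_mv=0.0,
                        tonic_rms_mv=0.0, mep_cv=0.0)
        trial = sp.TrialRecord(trial=0, block=0, modality="vocal",
                               trial_type="go", tms_role="task-pulse")
        trace, truth = synth_emg_trace(trial, 0.0, synth, rng,
                                       pulse_trial_time_ms=350.0)
        assert truth["mep_amp_mv"] == 0.0
        assert extract_mep(trace, truth["pulse_sample_index"],
                           synth.sampling_rate_hz) == 0.0

    def test_tonic_silence_round_trip(self, rng):
        synth = sp.TraceSynthParams()
        fs = synth.sampling_rate_hz
        n = int((synth.pre_ms + synth.post_ms) * fs / 1000)
        pulse = int(synth.pre_ms * fs / 1000)
        trace, truth = _render_trace(n, pulse, fs, 1.0, synth, rng,
                                     tonic=True, csp_ms=150.0,
                                     burst_onset_ms=None)
        m = detect_csp(trace, pulse, fs, prepulse_rms(trace, pulse, fs))
        assert m.present
        assert m.duration_ms == pytest.approx(truth["csp_true_ms"], abs=2.5)

    def test_pulse_outside_trace_rejected(self, rng):
        synth = sp.TraceSynthParams()
        with pytest.raises(ValueError):
            _render_trace(100, 200, synth.sampling_rate_hz, 1.0, synth, rng,
                          tonic=False, csp_ms=None, burst_onset_ms=None)


class TestVoiceEnvelope:
    def _vocal(self, rt):
        return sp.TrialRecord(trial=0, block=0, modality="vocal",
                              trial_type="go", rt_ms=rt)

    def test_burst_onset_detected_at_true_rt(self, rng):
        env = synth_voice_envelope(self._vocal(420.0), rng)
        rt = sp.detect_voice_onset(env, 0.1, 1000.0)
        assert rt == pytest.approx(420.0, abs=1.0)

    def test_withheld_response_has_no_crossing(self, rng):
        env = synth_voice_envelope(self._vocal(None), rng)
        assert sp.detect_voice_onset(env, 0.1, 1000.0) is None

    def test_bounded_noise_never_fires_early(self, rng):
        # noise floor at 0.9x threshold: no false onsets in 10^4 trials
        threshold = 0.1
        false_onsets = 0
        for _ in range(10_000):
            env = synth_voice_envelope(self._vocal(400.0), rng,
                                       noise_floor=0.9 * threshold)
            rt = sp.detect_voice_onset(env, threshold, 1000.0)
            if rt is not None and rt < 400.0:
                false_onsets += 1
        assert false_onsets == 0


class TestBehavioralSimulation:
    def test_full_determinism_under_fixed_seed(self):
        cfg = sp.default_config("exp1")
        cfg.trace_synth = replace(cfg.trace_synth, post_ms=100.0)
        a = sp.simulate_participant(cfg, np.random.default_rng(5))
        b = sp.simulate_participant(cfg, np.random.default_rng(5))
        assert a.events.equals(b.events)
        assert np.array_equal(a.traces, b.traces)

    def test_stop_trials_have_ssd_and_successes_have_no_rt(self):
        cfg = sp.default_config("exp1")
        ev = events_frame(simulate_behavior(cfg.design, cfg.race,
                                            np.random.default_rng(6)))
        stops = ev[ev.trial_type == "stop"]
        assert stops.ssd_ms.notna().all()
        assert ev.loc[ev.outcome == "stop-success", "rt_ms"].isna().all()
        assert ev.loc[ev.outcome == "stop-fail", "rt_ms"].notna().all()
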