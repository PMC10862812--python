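# Methods

This note documents the generative models, the measurement conventions, the
numerical choices made where the design was genuinely open, and what the
synthetic data do and do not establish about real recordings.

## Task design and trial bookkeeping

A study is 12 blocks of 90 trials alternating between manual and vocal
stop-signal tasks; one third of the trials per block are stop trials. Every
stop trial carries a task TMS pulse; an equal number of go trials carry task
pulses, and an equal number of go trials host baseline probes delivered in the
preceding inter-trial interval (500/700/900 ms after the previous trial ends,
balanced exactly). Stim-time labels (150/200/250 ms post stop signal; 150/250
in the paired-pulse design) are balanced exactly within each trial type.
Baseline probes are placed only on go trials preceded by another go trial;
trial-type orders are resampled (up to 500 shuffles) until enough such
positions exist, and a design whose counts cannot balance raises an explicit
invalid-design error. In the paired-pulse design the stimulation mode switches
between single and paired every two blocks, mimicking a device-setting change.

Counterbalancing in the emulated studies (letter pairings, group-level block
orders) is reduced to a `modality_order` switch and the `paired_pulse` flag;
letter identity has no behavioral or physiological consequence and is not
modeled.

## Behavioral generator

Go finishing times are ex-Gaussian (normal plus exponential), with vocal
responses faster than manual ones (defaults: manual mu/sigma/tau =
480/60/80 ms, vocal 430/55/70 ms). The stopping latency is constant per
participant (default SSRT 220 ms) and the stop process can fail to trigger
with probability `trigger_failure_p` (default 0). A response outside the
1000 ms window is an omission; on stop trials it counts as a successful stop
(no overt response). The stop-signal delay follows a 1-up/1-down staircase in
50 ms steps from 200 ms, clamped to `[0, window − step]`, tracked separately
per (task, response) cell. The direction convention (success → +step) is the
standard tracking rule that drives p(inhibit) to ~0.5, which the simulated
cohorts reproduce (cohort means ≈ .51).

Go pulses need a time reference: task pulses are specified relative to the
stop signal, which go trials lack. We schedule a go trial's pulse at the
current staircase SSD of its response cell plus the stim label, so go and stop
cells are probed at matched post-go latencies. The events table stores the
stim label; absolute pulse time is carried by the trace sidecar
(`trace_onset_ms + pulse_sample_index / fs`), which is exactly the information
a real recording provides.

## Excitability model and EMG synthesis

Excitability scaling relative to baseline is
`1 + f·t·[responding] − Pause(t−SSD)·[stop] − Cancel(t−SSD)·[stop ∧ responding]`,
floored at 0.05. Pause and Cancel are Gaussian bells; the curve family is a
modeling choice (the underlying theory constrains ordering and selectivity,
not shape). Defaults: Pause amplitude .25, peak 150 ms, width 150 ms (broad
and sustained, matching the observation that non-selective suppression is
roughly flat over 150–250 ms); Cancel amplitude .35, peak 250 ms, width 50 ms
(sharply late); facilitation slope 5·10⁻⁴ per ms. Under these defaults
responding-effector suppression grows strictly over 150→200→250 ms while
non-responding suppression varies only within the spread of the Pause bell
itself.

Traces span 200 ms before to 400 ms after the pulse at 5 kHz (configurable;
5 kHz comfortably resolves the 10–50 ms MEP window). Components: Gaussian
instrumentation noise (0.01 mV RMS); a 1.5 ms decaying-cosine pulse artifact
(5 mV); a biphasic MEP at 22 ms latency whose *sampled* peak-to-peak equals
`base × scaling` exactly (the unit waveform is rescaled by its own sampled
peak-to-peak, so noiseless round trips are exact to machine precision);
trial-to-trial MEP variability as a lognormal factor (sigma 0.2); on manual
trials, tonic background EMG at 0.04 mV RMS — deliberately below the 0.05 mV
pre-pulse rejection threshold, since real contraction trials survive that
filter — silenced from MEP offset until the trial's true silent-period end
(150 ± 40 ms after the pulse, uniform); and a voluntary burst (0.3 mV,
150 ms) at the response time of manual trials. A voluntary burst that begins
inside the silent period truncates the ground-truth CSP at its onset — go
trials therefore show shorter silent periods than successful stops, as the
corresponding real measurements do. Paired-pulse trials attenuate the MEP by
a fixed conditioning factor (default 25 %), giving SICI a recoverable truth.

Vocal trials are represented as amplitude envelopes: bounded uniform noise on
`[0, noise_floor]` plus a supra-threshold burst at the true response time.
Bounded noise guarantees zero false onsets whenever the floor sits below the
detection threshold; the default threshold is 5× the noise floor RMS (the
"set amplitude" of the emulated procedure is unreported, so the margin is a
package default).

## Measurement conventions

* MEP amplitude: max − min over 10–50 ms post pulse, both endpoints included;
  ms→samples by rounding to nearest.
* Pre-pulse EMG: RMS over the 80 ms before (and excluding) the pulse sample.
* Rejection, in order of precedence: amplitude < .05 mV (`small-mep`);
  pre-pulse RMS > .05 mV (`prepulse-emg`); response at or before the pulse
  (`rt-at-or-before-pulse` — a response already underway contaminates the MEP
  with movement EMG, which is why fast failed stops drop out preferentially).
* Trimming (single-pulse mode): after rejection, `floor(n × .05)` smallest
  and largest amplitudes per condition cell are discarded; the floor rule is
  a documented choice where rounding was unspecified.
* Normalization: condition mean / active-baseline mean, per task and pulse
  type; SICI per cell is `(TS − CS)/TS × 100` with TS from single-pulse and
  CS from paired-pulse trials, baselines included.
* Inclusion screening: every (task × trial type × stim time) cell must reach
  15 usable MEPs (single-pulse design) or 10 (paired-pulse); failed-stop
  analyses use 10 MEPs / 5 CSPs. Thresholds are configurable.

### Silent-period detection

The analyst's presence judgment and resumption mark are automated: the
pre-pulse RMS serves as the tonic reference (references at or below a
0.02 mV floor are flagged not-contracting — this is what makes vocal-task
hand probes CSP-free); a 25 ms moving-RMS envelope must stay below 50 % of
the reference for ≥ 20 ms and then re-exceed it for ≥ 5 ms; the resumption is
localized with a 5 ms envelope, re-centred by a quarter fine-window (a
centred-RMS crossing systematically leads a step onset by about that much at
the 50 % threshold), and finally snapped to the maximum absolute deflection
within ±2 ms, mirroring the mark-then-refine procedure. Duration is measured
from the pulse (absolute convention) — the pulse time is unambiguous, whereas
MEP offset is noise-sensitive. Only single-pulse manual-task trials with
accepted MEPs are evaluated. On synthetic contraction trials with silent
periods of 80–250 ms the detector's median absolute error is well under 1 ms;
the <3 ms acceptance bound leaves headroom for less favourable
noise-to-contraction ratios. The 25 ms/50 %/5 ms constants are explicit
stand-ins for an unreported human criterion, not a reconstruction of it.

## Effect-size classification

Cohen's d per (task, stim time) contrasts go against successful-stop
amplitudes using the pooled-SD two-sample form — the trial sets are
independent samples within a participant, so the paired-difference variant
would be inappropriate. The vocal-task profile indexes non-selective
suppression; manual minus vocal at the same time indexes additional selective
suppression. A type is "shown" iff some timepoint's d > .2. When both are
shown, each type's characteristic timepoint is the one with the greatest
increase relative to previous timepoints, computed with a running-max rule
(`inc(t) = d(t) − max(0, d(<t))`, first timepoint vs 0); increases ≤ .2
disqualify a timepoint, ties go to the earliest, and if no timepoint
qualifies the plain greatest increase is used so that every finite profile
maps to exactly one category. The rule set (`pairwise` increases, threshold)
is configurable. With two stim times the same rules apply verbatim.

Simulated cohorts recover the intended profiles: pause-only generators
classify predominantly global-only, cancel-only selective-only, and the
default early-pause/late-cancel model global-then-selective. These checks run
on a 48-block amplitude-level simulation (no trace rendering) because at
standard trial counts the sampling error of d (~.25 at 30 trials/cell) is
comparable to the .2 threshold; the enlarged design isolates the
classification logic from that sampling noise, which is a real feature of
per-participant classification at ordinary trial counts, not a defect of the
rules.

## Problem sizes and determinism

The test suite and acceptance script use the full 1080-trial design
throughout: behavioral cohorts of 24 (single-pulse) and 14 (paired-pulse)
participants, 100 participants for SSRT-recovery statistics, single full
participants for trace-level round trips, and 500 trials for silent-period
recovery. All randomness flows through `numpy.random.Generator` seeded from
user-supplied integers; identical config and seed reproduce byte-identical
output tables.

## Limitations

The generator emulates the *structure* of real recordings, not their
biophysics: MEP waveshape is stylized, background EMG is Gaussian rather than
motor-unit structured, the silent period is an abrupt gate rather than a
graded recovery, voice onsets are envelopes without acoustics, and choice
errors are not modeled (responses are always correct when made). Passing
round-trip tests therefore demonstrates that the pipeline recovers what it is
pointed at under controlled conditions — not that the specific thresholds are
optimal for any particular laboratory's recordings. Group-level inferential
statistics (ANOVAs, Bayes factors) are out of scope; the per-condition TSVs
are designed to feed any statistics package.
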