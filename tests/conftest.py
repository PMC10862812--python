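"""Shared fixtures: simulated cohorts and participants reused across tests.

Everything is generated at run time from fixed seeds; session scope keeps the
heavier simulations to one run each.
"""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import stopphys as sp

hypothesis_settings.register_profile("repeatable", derandomize=True)
hypothesis_settings.load_profile("repeatable")
from stopphys.behavior import summarize_behavior
from stopphys.simulate import events_frame, simulate_behavior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_design():
    """Smallest balanced design: one block of 9 trials, 3 stop."""
    return sp.DesignConfig(n_blocks=1, trials_per_block=9, stop_fraction=1 / 3,
                           seed=7)


def _behavior_cohort(mode: str, n_participants: int, seed_tag: int):
    cfg = sp.default_config(mode)
    out = []
    for p in range(n_participants):
        rng = np.random.default_rng([11, seed_tag, p])
        events = events_frame(simulate_behavior(cfg.design, cfg.race, rng))
        out.append(summarize_behavior(events))
    return out


@pytest.fixture(scope="session")
def exp1_cohort():
    """24 simulated participants, single-pulse design: behavioral summaries."""
    return _behavior_cohort("exp1", 24, 0)


@pytest.fixture(scope="session")
def exp2_cohort():
    """14 simulated participants, paired-pulse design: behavioral summaries."""
    return _behavior_cohort("exp2", 14, 1)


@pytest.fixture(scope="session")
def noiseless_participant():
    """Full single-pulse participant with every noise source disabled."""
    cfg = sp.default_config("exp1")
    cfg.trace_synth = replace(cfg.trace_synth, noise_rms_mv=0.0,
                              tonic_rms_mv=0.0, mep_cv=0.0,
                              voluntary_amp_mv=0.0)
    data = sp.simulate_participant(cfg, np.random.default_rng(21),
                                   make_traces=True)
    return cfg, data


@pytest.fixture(scope="session")
def noisy_participant():
    """Full single-pulse participant at default (realistic) noise levels."""
    cfg = sp.default_config("exp1")
    data = sp.simulate_participant(cfg, np.random.default_rng(22),
                                   make_traces=True)
    return cfg, data
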