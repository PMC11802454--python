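"""Shared fixtures: small synthetic sessions generated at test time."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sdchoice.synthetic import (
    TaskConfig, NeuronSpec, LFPSpec, EvokedBurst, SharedThetaSpec, PhaseLock,
    generate_trials, simulate_session, default_lfp_specs,
)


@pytest.fixture(scope="session")
def small_trials() -> pd.DataFrame:
    return generate_trials(TaskConfig(n_trials=200), seed=7)


@pytest.fixture(scope="session")
def spikes_only_session():
    """120-trial session, 6 neurons with mixed tuning, no LFP (fast)."""
    cfg = TaskConfig(n_trials=120)
    specs = [
        NeuronSpec(0, "HPC", baseline_rate=10.0, state_beta={"state": 4.0}),
        NeuronSpec(1, "HPC", baseline_rate=8.0, value_beta=(2.0, 2.0)),
        NeuronSpec(2, "HPC", baseline_rate=8.0),
        NeuronSpec(3, "OFC", baseline_rate=10.0, state_beta={"choice": 4.0}),
        NeuronSpec(4, "OFC", baseline_rate=8.0, value_beta=(2.5, 0.0)),
        NeuronSpec(5, "OFC", baseline_rate=8.0, value_beta=(0.0, 2.5)),
    ]
    return simulate_session(cfg, specs, seed=3)


@pytest.fixture(scope="session")
def lfp_session():
    """Short session with 4 channels (2/area), shared theta lagged 40 ms,
    and two phase-locked units."""
    cfg = TaskConfig(n_trials=60)
    lfp_specs = [
        LFPSpec(channel=0, area="HPC", probe=0, background_amp=4.0,
                evoked=(EvokedBurst(event="fix_on_ms", amp=8.0, rise_ms=120.0,
                                    duration_ms=500.0),),
                shared_weight=1.0),
        LFPSpec(channel=1, area="HPC", probe=0, background_amp=4.0,
                shared_weight=0.5),
        LFPSpec(channel=2, area="OFC", probe=1, background_amp=4.0,
                evoked=(EvokedBurst(event="fix_on_ms", amp=8.0, rise_ms=120.0,
                                    duration_ms=500.0),),
                shared_weight=1.0),
        LFPSpec(channel=3, area="OFC", probe=1, background_amp=4.0,
                shared_weight=0.5),
    ]
    shared = SharedThetaSpec(source_area="HPC", lag_ms=40.0,
                             burst=EvokedBurst(event="cue_on_ms", amp=12.0,
                                               rise_ms=150.0),
                             noise_amp=1.5)
    neurons = [
        NeuronSpec(0, "HPC", probe=0, channel=0, baseline_rate=12.0,
                   state_beta={"state": 4.0},
                   phase_lock=PhaseLock(kappa=(2.0, 0.2))),
        NeuronSpec(1, "HPC", probe=0, channel=1, baseline_rate=10.0),
        NeuronSpec(2, "OFC", probe=1, channel=2, baseline_rate=12.0,
                   state_beta={"choice": 4.0},
                   phase_lock=PhaseLock(kappa=(0.2, 2.0))),
        NeuronSpec(3, "OFC", probe=1, channel=3, baseline_rate=10.0),
    ]
    return simulate_session(cfg, neurons, lfp_specs, shared, seed=5)
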