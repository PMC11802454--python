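"""Generator contracts: determinism, task statistics, planted spike/LFP
structure recoverable by construction-level checks."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sdchoice.synthetic import (
    TaskConfig, NeuronSpec, LFPSpec, EvokedBurst, SharedThetaSpec, PhaseLock,
    generate_trials, generate_lfp, generate_spikes, simulate_session,
    session_duration_s, _burst_waveform,
)
from sdchoice.session import validate_session
from sdchoice.phase import band_phase_amplitude
from sdchoice.stats import circular_mean, rayleigh_test


class TestTrials:
    def test_same_seed_identical_tables(self):
        cfg = TaskConfig(n_trials=300)
        a = generate_trials(cfg, 42)
        b = generate_trials(cfg, 42)
        pd.testing.assert_frame_equal(a, b)

    def test_free_fraction_within_binomial_band(self):
        t = generate_trials(TaskConfig(n_trials=1000), seed=0)
        n_free = (t["trial_type"] == "free").sum()
        lo, hi = sps.binom.ppf([0.025, 0.975], 1000, 0.8)
        assert lo <= n_free <= hi

    def test_infinite_inverse_temperature_gives_perfect_accuracy(self):
        t = generate_trials(TaskConfig(n_trials=400, inverse_temp=1e9), seed=1)
        free = t[t["trial_type"] == "free"]
        assert free["correct"].all()

    def test_offered_values_always_distinct(self, small_trials):
        free = small_trials[small_trials["trial_type"] == "free"]
        assert (free["left_value"] != free["right_value"]).all()

    def test_cue_consistent_with_state(self, small_trials):
        assert (small_trials["cue_id"] // 2 == small_trials["state"]).all()

    def test_event_ordering_and_forced_single_option(self, small_trials):
        ev = small_trials[["fix_on_ms", "cue_on_ms", "choice_on_ms", "response_ms"]]
        assert (ev.diff(axis=1).iloc[:, 1:] > 0).all().all()
        forced = small_trials[small_trials["trial_type"] == "forced"]
        assert forced["right_value"].isna().all()

    @pytest.mark.parametrize("bad", [
        dict(n_trials=0),
        dict(value_levels=(1, 2, 3, 3)),
        dict(p_free=1.5),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_trials(TaskConfig(**bad), seed=0)


class TestSpikes:
    def test_flat_rate_matches_poisson_mean(self):
        cfg = TaskConfig(n_trials=100)
        trials = generate_trials(cfg, 2)
        spec = NeuronSpec(0, "HPC", baseline_rate=10.0)
        spikes = generate_spikes(trials, [spec], seed=3, config=cfg)[0]
        dur = session_duration_s(trials, cfg)
        rate = len(spikes) / dur
        se = np.sqrt(10.0 / dur)
        assert abs(rate - 10.0) < 3 * se

    def test_state_beta_modulates_epoch_rate(self, spikes_only_session):
        sess = spikes_only_session
        from sdchoice.tuning import epoch_rates, DEFAULT_EPOCHS
        ev = sess.event_times_s("cue_on_ms")
        r = epoch_rates(sess.spikes[0], ev, DEFAULT_EPOCHS.state)
        s = sess.trials["state"].to_numpy()
        # planted state beta +4 Hz/code unit => ~8 Hz difference B - A
        assert r[s == 1].mean() - r[s == 0].mean() > 4.0

    def test_negative_baseline_rejected(self, small_trials):
        with pytest.raises(ValueError):
            generate_spikes(small_trials, [NeuronSpec(0, "HPC", baseline_rate=-1.0)],
                            seed=0)

    def test_negative_kappa_rejected(self, small_trials):
        spec = NeuronSpec(0, "HPC", phase_lock=PhaseLock(kappa=(-0.5, 0.0)))
        with pytest.raises(ValueError):
            generate_spikes(small_trials, [spec], seed=0)

    def test_rectification_warning(self, small_trials):
        spec = NeuronSpec(0, "HPC", baseline_rate=0.5,
                          state_beta={"fixation": -4.0, "state": -4.0,
                                      "choice": -4.0})
        with pytest.warns(UserWarning, match="rectification"):
            generate_spikes(small_trials, [spec], seed=0)


class TestPhaseLockedSpikes:
    """Spike phases against the ground-truth von Mises target."""

    @pytest.fixture(scope="class")
    def locked_session(self):
        cfg = TaskConfig(n_trials=150)
        lfp_specs = [LFPSpec(channel=0, area="HPC", background_amp=5.0)]
        neurons = [
            NeuronSpec(0, "HPC", channel=0, baseline_rate=15.0,
                       phase_lock=PhaseLock(mu=(0.0, 0.0), kappa=(2.0, 2.0))),
            NeuronSpec(1, "HPC", channel=0, baseline_rate=15.0),
        ]
        return simulate_session(cfg, neurons, lfp_specs, None, seed=9)

    def _phases(self, sess, nid):
        phase, _ = band_phase_amplitude(sess.lfp[0], (4.0, 8.0), sess.fs)
        t = sess.trials
        starts = sess.event_times_s("cue_on_ms")
        ends = sess.event_times_s("response_ms")
        spk = sess.spikes[nid]
        out = []
        for a, b in zip(starts, ends):
            sel = spk[(spk >= a) & (spk < b)]
            out.append(phase[(sel * sess.fs).astype(int)])
        return np.concatenate(out)

    def test_kappa2_circular_mean_near_preferred_phase(self, locked_session):
        ph = self._phases(locked_session, 0)
        assert len(ph) >= 500
        assert abs(circular_mean(ph)) < 0.2

    def test_kappa0_phases_uniform(self, locked_session):
        ph = self._phases(locked_session, 1)
        _, p = rayleigh_test(ph)
        assert p > 0.01


class TestLFP:
    def test_lag_construction_envelope_peaks(self):
        """Noiseless traces: source-area envelope peak leads the target by
        the configured lag (+/- 1 sample)."""
        cfg = TaskConfig(n_trials=5)
        trials = generate_trials(cfg, 4)
        specs = [LFPSpec(channel=0, area="HPC", background_amp=0.0, shared_weight=1.0),
                 LFPSpec(channel=1, area="OFC", background_amp=0.0, shared_weight=1.0)]
        shared = SharedThetaSpec(source_area="HPC", lag_ms=40.0,
                                 burst=EvokedBurst(amp=10.0, rise_ms=150.0),
                                 noise_amp=0.0)
        lfp = generate_lfp(trials, specs, seed=0, shared=shared, config=cfg)
        fs = 1000.0
        cue = ((trials["t_start_s"] + trials["cue_on_ms"] / 1000.0) * fs).astype(int)
        for c in cue:
            win = slice(c, c + 800)
            p_h = np.argmax(np.abs(sps.zscore(lfp[0][win])))
            p_o = np.argmax(np.abs(sps.zscore(lfp[1][win])))
            assert abs((p_o - p_h) - 40) <= 1

    def test_shared_weight_zero_independent_areas(self):
        cfg = TaskConfig(n_trials=5)
        trials = generate_trials(cfg, 4)
        specs = [LFPSpec(channel=0, area="HPC", background_amp=1.0, shared_weight=0.0),
                 LFPSpec(channel=1, area="OFC", background_amp=1.0, shared_weight=0.0)]
        shared = SharedThetaSpec(noise_amp=2.0, burst=None)
        lfp = generate_lfp(trials, specs, seed=0, shared=shared, config=cfg)
        r = np.corrcoef(lfp[0], lfp[1])[0, 1]
        assert abs(r) < 0.05

    def test_lag_exceeding_burst_duration_rejected(self):
        shared = SharedThetaSpec(lag_ms=900.0,
                                 burst=EvokedBurst(duration_ms=800.0))
        with pytest.raises(ValueError, match="lag"):
            shared.validate()

    def test_burst_waveform_envelope_peak_at_rise(self):
        w = _burst_waveform(EvokedBurst(amp=3.0, rise_ms=150.0, freq_hz=5.0,
                                        phase0=0.0), 1000.0)
        env = np.abs(sps.zscore(w))  # crude: peak cycle should straddle 150 ms
        assert abs(np.argmax(np.abs(w)) - 150) < 110  # within half a cycle


class TestSessionAssembly:
    def test_same_seed_identical_sessions(self):
        cfg = TaskConfig(n_trials=40)
        specs = [NeuronSpec(0, "HPC", baseline_rate=8.0)]
        a = simulate_session(cfg, specs, seed=1)
        b = simulate_session(cfg, specs, seed=1)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert np.array_equal(a.spikes[0], b.spikes[0])

    def test_generated_session_validates(self, lfp_session):
        diag = validate_session(lfp_session)
        assert diag["ok"], diag["problems"]

    def test_ground_truth_sidecar_round_trip(self, tmp_path, spikes_only_session):
        from sdchoice.session import Session
        spikes_only_session.save(tmp_path / "sess")
        loaded = Session.load(tmp_path / "sess")
        assert loaded.ground_truth["task"]["n_trials"] == 120
        assert set(loaded.spikes) == set(spikes_only_session.spikes)
        assert np.allclose(loaded.spikes[0], spikes_only_session.spikes[0], atol=1e-6)

    def test_validate_flags_out_of_bounds_spike(self, spikes_only_session):
        import copy
        sess = copy.copy(spikes_only_session)
        sess.spikes = dict(sess.spikes)
        sess.spikes[0] = np.append(sess.spikes[0], sess.duration_s + 5.0)
        diag = validate_session(sess)
        assert not diag["ok"]
        assert any("outside session bounds" in p for p in diag["problems"])

    def test_low_rate_unit_flagged(self, small_trials):
        cfg = TaskConfig(n_trials=200)
        specs = [NeuronSpec(0, "HPC", baseline_rate=0.3)]
        sess = simulate_session(cfg, specs, seed=2)
        diag = validate_session(sess)
        assert diag["ok"] and any("below" in f for f in diag["flags"])
        assert len(sess.retained_units()) == 0
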