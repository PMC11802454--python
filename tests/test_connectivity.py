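"""Multitaper coherence and MVAR directionality: self-coherence identity,
GPDC bounds on random stable models, constructed-VAR direction recovery,
antisymmetry, Granger calibration and channel selection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sdchoice.connectivity import (
    multitaper_coherogram, select_pair_channels, fit_mvar_gpdc, granger_confirm,
    gpdc_spectrum, select_order, _is_stable, gpdc_window_segments,
)

FS = 1000.0


def simulate_var(a_list, n_trials, t, rng, noise_sd=(1.0, 1.0)):
    """Simulate a bivariate VAR with coefficient matrices ``a_list``."""
    p = len(a_list)
    out = np.zeros((n_trials, t + 50, 2))
    for tr in range(n_trials):
        e = rng.normal(size=(t + 50, 2)) * noise_sd
        for i in range(p, t + 50):
            acc = e[i].copy()
            for k, a in enumerate(a_list, start=1):
                acc += a @ out[tr, i - k]
            out[tr, i] = acc
    return out[:, 50:, :]


VAR_FS = 100.0  # constructed-VAR tests sample at 100 Hz so the 5 Hz
                # resonance is spectrally well separated from DC


def coupled_var(coupling=0.2):
    """x is a 5 Hz resonant AR(2); y is weakly autocorrelated and receives
    lagged input from x."""
    r, f = 0.9, 5.0
    phi1 = 2 * r * np.cos(2 * np.pi * f / VAR_FS)
    phi2 = -r * r
    a1 = np.array([[phi1, 0.0], [coupling, 0.3]])
    a2 = np.array([[phi2, 0.0], [0.0, 0.0]])
    return [a1, a2]


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8000)
        res = multitaper_coherogram(x, x, FS)
        assert np.allclose(res.coherence, 1.0, atol=1e-10)

    def test_independent_noise_matches_shuffle_null(self):
        """Mean coherence of independent trials equals the estimator's
        small-sample bias, estimated by a trial-shuffle null."""
        rng = np.random.default_rng(1)
        n_tr, t = 40, 4000
        x = rng.standard_normal(n_tr * t)
        y = rng.standard_normal(n_tr * t)
        ev = (np.arange(n_tr) * t + 1000) / FS
        res = multitaper_coherogram(x, y, FS, event_times_s=ev, t_range_s=(0.0, 2.0))
        # shuffle: pair each x trial with a rotated y trial
        ev_y = np.roll(ev, 1)
        null = multitaper_coherogram(x, np.concatenate([y[t:], y[:t]]), FS,
                                     event_times_s=ev, t_range_s=(0.0, 2.0))
        assert abs(res.coherence.mean() - null.coherence.mean()) < 0.02

    def test_shared_component_raises_theta_coherence(self, lfp_session):
        sess = lfp_session
        cues = sess.event_times_s("cue_on_ms")
        res = multitaper_coherogram(sess.lfp[0], sess.lfp[2], sess.fs,
                                    event_times_s=cues, t_range_s=(-1.0, 1.5))
        th = (res.freqs >= 4) & (res.freqs <= 8)
        pre = res.coherence[th][:, res.times_s < -0.2].mean()
        post = res.coherence[th][:, res.times_s > 0.2].mean()
        assert post > pre + 0.1

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            multitaper_coherogram(np.zeros(500), np.zeros(500), FS)


class TestGPDC:
    def test_bounds_on_random_stable_models(self):
        """GPDC lies in [0, 1] at every frequency for 100 random stable
        bivariate VAR models."""
        rng = np.random.default_rng(2)
        freqs = np.arange(1.0, 101.0)
        checked = 0
        while checked < 100:
            p = int(rng.integers(1, 4))
            a = [rng.normal(scale=0.3, size=(2, 2)) for _ in range(p)]
            b = np.vstack([ak.T for ak in a])
            if not _is_stable(b, p):
                continue
            sigma = np.diag(rng.uniform(0.5, 2.0, 2))
            g = gpdc_spectrum(b, sigma, p, freqs, FS)
            assert np.all(g >= 0) and np.all(g <= 1 + 1e-12)
            checked += 1

    def test_direction_recovered_from_coupled_var(self):
        rng = np.random.default_rng(3)
        segs = simulate_var(coupled_var(), 60, 200, rng)
        res = fit_mvar_gpdc(segs[:, :, 0], segs[:, :, 1], VAR_FS, n_boot=100,
                            seed=4, freqs=np.arange(1.0, 41.0))
        assert res.net_theta > 0
        assert res.net_theta_ci[0] > 0
        # spectral peak of the net at the planted 5 Hz resonance
        assert res.freqs[np.argmax(res.net)] == pytest.approx(5.0, abs=2.0)

    def test_antisymmetry_under_channel_swap(self):
        rng = np.random.default_rng(5)
        segs = simulate_var(coupled_var(), 30, 200, rng)
        a = fit_mvar_gpdc(segs[:, :, 0], segs[:, :, 1], VAR_FS, order=6, n_boot=5, seed=0)
        b = fit_mvar_gpdc(segs[:, :, 1], segs[:, :, 0], VAR_FS, order=6, n_boot=5, seed=0)
        assert np.allclose(a.net, -b.net, atol=1e-10)

    def test_independent_ar_nets_span_zero(self):
        """Independent AR(2) processes: the bootstrap CI of net theta GPDC
        spans zero in most replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            segs = simulate_var(coupled_var(coupling=0.0), 30, 200, rng)
            res = fit_mvar_gpdc(segs[:, :, 0], segs[:, :, 1], VAR_FS,
                                order=4, n_boot=60, seed=rng.integers(2 ** 31))
            lo, hi = res.net_theta_ci
            hits += lo <= 0 <= hi
        assert hits / n_rep >= 0.8

    def test_zero_variance_input_rejected(self):
        with pytest.raises(ValueError):
            fit_mvar_gpdc(np.zeros((10, 300)), np.random.default_rng(0).normal(size=(10, 300)))


class TestGranger:
    def test_unidirectional_coupling_detected(self):
        rng = np.random.default_rng(7)
        segs = simulate_var(coupled_var(), 50, 200, rng)
        out = granger_confirm(segs[:, :, 0], segs[:, :, 1], order=4)
        assert out["p_x_to_y"] < 0.001
        assert out["F_x_to_y"] > out["F_y_to_x"]

    def test_independent_processes_f_near_one(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(40):
            segs = simulate_var(coupled_var(coupling=0.0), 20, 200, rng)
            out = granger_confirm(segs[:, :, 0], segs[:, :, 1], order=3)
            pvals.append(out["p_x_to_y"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestChannelSelection:
    def _frames(self):
        channels = pd.DataFrame({
            "channel_id": [0, 1, 2, 3], "area": ["HPC", "HPC", "OFC", "OFC"],
            "probe": [0, 0, 1, 1]})
        units = pd.DataFrame({"neuron_id": [0, 1], "area": ["HPC", "OFC"],
                              "probe": [0, 1], "channel": [0, 3]})
        return channels, units

    def test_argmax_among_channels_with_units(self):
        channels, units = self._frames()
        peak_r = {0: 0.3, 1: 0.9, 2: 0.8, 3: 0.5}
        chosen, pairs = select_pair_channels(channels, units, peak_r)
        # channel 1 has higher R but hosts no unit; channel 0 qualifies
        assert chosen == {0: 0, 1: 3}
        assert pairs == [(0, 3)]

    def test_no_units_anywhere_is_error(self):
        channels, units = self._frames()
        units = units.iloc[0:0]
        with pytest.raises(ValueError):
            select_pair_channels(channels, units, {0: 0.5})

    def test_planted_best_channel_selected(self, lfp_session):
        from sdchoice.phase import alignment_series
        sess = lfp_session
        cues = sess.event_times_s("cue_on_ms")
        align = alignment_series(sess.lfp, cues, t_range_s=(-0.3, 0.8), fs=sess.fs)
        theta = align[align["band"] == "theta"]
        peak_r = theta.groupby("channel")["R"].max().to_dict()
        chosen, pairs = select_pair_channels(sess.channels, sess.units, peak_r)
        # channels 0 and 2 carry the full-weight shared burst (planted best)
        assert chosen[0] == 0 and chosen[1] == 2

    def test_gpdc_window_matches_stated_epoch(self, lfp_session):
        sess = lfp_session
        cues = sess.event_times_s("cue_on_ms")
        segs = gpdc_window_segments(sess.lfp[0], cues, sess.fs)
        assert segs.shape == (len(sess.trials), 600)
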