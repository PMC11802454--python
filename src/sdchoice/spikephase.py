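"""Phase modulation of single neurons and its state dependence.

Each spike is assigned the instantaneous band-limited phase of the LFP on the
neuron's own channel; nonuniformity of the resulting phase distribution is
quantified by the Rayleigh statistic Z = n * R**2 (significance p < 0.01).
A neuron's preferred state is the sign of the state coefficient from a
regression of z-scored epoch rates on state (-1/+1) and cue set
(asymmetric -1/2 dummy codes by default; a symmetric option exists).

The group contrast compares Rayleigh Z between preferred and nonpreferred
states (paired t-test) and between the state and fixation epochs, and tests
whether fewer neurons than expected are modulated in *both* states: the
expected both-state count under independence is n * p_A * p_B (the literal
union probability p_A + p_B - p_A p_B is reported alongside), compared to
the observed count with a two-sided binomial test.

Caveat mirrored from the underlying design: a neuron firing in its preferred
state emits more spikes, which alone raises detection power; the optional
spike-count-matched variant subsamples the larger state's spikes to equalise
n before the Rayleigh test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import Session
from .stats import rayleigh_test, circular_mean
from .tuning import DEFAULT_EPOCHS, EpochSpec, epoch_rates
from .phase import band_phase_amplitude, DEFAULT_BANDS, BandSpec

ALPHA_PHASE = 0.01


def spike_phases(
    spike_times_s: np.ndarray, phase: np.ndarray,
    windows_s: np.ndarray, fs: float = 1000.0,
) -> np.ndarray:
    """Band phase at each spike falling inside any of the half-open windows.

    ``windows_s`` is an (n, 2) array of [start, end) times in seconds.
    Returns an empty array when no spikes qualify.
    """
    t = np.asarray(spike_times_s, float)
    windows_s = np.atleast_2d(np.asarray(windows_s, float))
    mask = np.zeros(t.size, dtype=bool)
    for a, b in windows_s:
        mask |= (t >= a) & (t < b)
    idx = np.minimum((t[mask] * fs).astype(int), phase.size - 1)
    return phase[idx]


def preferred_state(
    session: Session, neuron_id: int, epochs: EpochSpec = DEFAULT_EPOCHS,
    cue_coding: str = "asymmetric", epoch: str = "auto",
) -> tuple[int, float, bool]:
    """Preferred state of a neuron from the sign of its state beta.

    z-scored epoch rates are regressed on state (-1/+1) and cue set
    (``cue_coding='asymmetric'`` uses the asymmetric -1/2 dummy codes,
    ``'symmetric'`` uses -1/+1).  ``epoch='auto'`` fits both the state and
    choice epochs and takes the larger-|beta| fit, so neurons whose state
    code emerges only at choice time still get a meaningful label.  Returns
    ``(state 0/1, beta, degenerate_flag)``; an exactly zero beta breaks to
    state A with the flag raised.
    """
    tr = session.trials
    s = tr["state"].to_numpy() * 2 - 1
    cue = tr["cue"].to_numpy()
    c = np.where(cue == 0, -1.0, 2.0) if cue_coding == "asymmetric" else cue * 2 - 1
    wins = {"state": epochs.state, "choice": epochs.choice,
            "fixation": epochs.fixation}
    names = ("state", "choice") if epoch == "auto" else (epoch,)
    best = None
    for name in names:
        win = wins[name]
        ev = session.event_times_s(win.event)
        rates = epoch_rates(session.spikes[neuron_id], ev, win)
        sd = rates.std()
        if sd == 0:
            continue
        z = (rates - rates.mean()) / sd
        x = np.column_stack([np.ones_like(z), s, c])
        beta = float(np.linalg.lstsq(x, z, rcond=None)[0][1])
        if best is None or abs(beta) > abs(best):
            best = beta
    if best is None:
        raise ValueError(f"neuron {neuron_id}: degenerate (constant) rates")
    noise_floor = 1.0 / np.sqrt(len(tr))
    return (1 if best > 0 else 0), best, bool(abs(best) < noise_floor)


def phase_locking_table(
    session: Session, bands: BandSpec = DEFAULT_BANDS,
    epochs: EpochSpec = DEFAULT_EPOCHS, epoch_names: tuple[str, ...] = ("fixation", "state"),
    match_spike_counts: bool = False, seed: int = 0,
    unit_ids: list[int] | None = None, band_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Rayleigh statistics per neuron x band x epoch x state.

    One row per combination with n spikes, Z, p, circular mean phase and the
    neuron's preferred state.  With ``match_spike_counts`` the larger state's
    spike set is subsampled to the smaller state's count before testing.
    """
    rng = np.random.default_rng(seed)
    units = session.retained_units()
    if unit_ids is not None:
        units = units[units["neuron_id"].isin(unit_ids)]
    tr = session.trials
    chan_rows = {int(c): i for i, c in enumerate(session.channels["channel_id"])}
    band_list = [(n, b) for n, b in bands.items()
                 if band_names is None or n in band_names]
    phase_cache: dict[tuple[int, str], np.ndarray] = {}
    rows = []
    for _, u in units.iterrows():
        nid = int(u["neuron_id"])
        ch = int(u["channel"])
        pref, beta, degen = preferred_state(session, nid, epochs)
        for band_name, band in band_list:
            key = (ch, band_name)
            if key not in phase_cache:
                phase_cache[key], _ = band_phase_amplitude(
                    session.lfp[chan_rows[ch]], band, session.fs)
            phi = phase_cache[key]
            for ep_name in epoch_names:
                win: object = getattr(epochs, ep_name)
                ev = session.event_times_s(win.event)
                starts = ev + win.start_ms / 1000.0
                ends = ev + win.end_ms / 1000.0
                state_phases = {}
                for st in (0, 1):
                    sel = tr["state"].to_numpy() == st
                    w = np.column_stack([starts[sel], ends[sel]])
                    state_phases[st] = spike_phases(session.spikes[nid], phi, w, session.fs)
                if match_spike_counts:
                    nmin = min(len(state_phases[0]), len(state_phases[1]))
                    for st in (0, 1):
                        p_ = state_phases[st]
                        if len(p_) > nmin:
                            state_phases[st] = rng.choice(p_, size=nmin, replace=False)
                for st in (0, 1):
                    ph = state_phases[st]
                    if ph.size == 0:
                        z, p, mu = np.nan, np.nan, np.nan
                    else:
                        z, p = rayleigh_test(ph)
                        mu = circular_mean(ph)
                    rows.append({
                        "neuron_id": nid, "area": u["area"], "band": band_name,
                        "epoch": ep_name, "state": st, "n_spikes": int(ph.size),
                        "Z": z, "p": p, "mean_phase": mu,
                        "preferred_state": pref, "state_beta": beta,
                        "preferred_degenerate": degen,
                    })
    return pd.DataFrame(rows)


def state_phase_contrast(
    table: pd.DataFrame, band: str = "theta", alpha: float = ALPHA_PHASE,
) -> dict:
    """Group-level phase-locking contrasts over a phase-locking table.

    Paired t-tests: preferred vs nonpreferred state (state epoch) and state
    vs fixation epoch within the preferred state; binomial test of the
    observed both-state-modulated count against the independence expectation.
    """
    df = table[table["band"] == band]
    state_ep = df[df["epoch"] == "state"]
    wide = state_ep.pivot_table(index="neuron_id", columns="state", values="Z")
    pref = state_ep.groupby("neuron_id")["preferred_state"].first()
    ids = [i for i in wide.index if not wide.loc[i].isna().any()]
    if len(ids) < 2:
        raise ValueError("need at least 2 neurons with spikes in both states")
    z_pref = np.array([wide.loc[i, pref[i]] for i in ids])
    z_non = np.array([wide.loc[i, 1 - pref[i]] for i in ids])
    if np.allclose(z_pref, z_non):
        t_state, p_state = 0.0, 1.0
    else:
        t_state, p_state = sps.ttest_rel(z_pref, z_non)
    out = {"n_neurons": len(ids),
           "z_preferred_mean": float(z_pref.mean()),
           "z_nonpreferred_mean": float(z_non.mean()),
           "t_pref_vs_nonpref": float(t_state), "p_pref_vs_nonpref": float(p_state)}

    # epoch contrast within the preferred state
    fix_ep = df[df["epoch"] == "fixation"]
    if len(fix_ep):
        wide_fix = fix_ep.pivot_table(index="neuron_id", columns="state", values="Z")
        common = [i for i in ids if i in wide_fix.index
                  and not np.isnan(wide_fix.loc[i, pref[i]])]
        z_state = np.array([wide.loc[i, pref[i]] for i in common])
        z_fix = np.array([wide_fix.loc[i, pref[i]] for i in common])
        if len(common) >= 2:
            t_ep, p_ep = (0.0, 1.0) if np.allclose(z_state, z_fix) else \
                sps.ttest_rel(z_state, z_fix)
            out.update({"t_state_vs_fixation": float(t_ep),
                        "p_state_vs_fixation": float(p_ep),
                        "n_epoch_contrast": len(common)})

    sig = state_ep.pivot_table(index="neuron_id", columns="state", values="p")
    sig = sig.loc[ids] < alpha
    p_a = float(sig[0].mean())
    p_b = float(sig[1].mean())
    n = len(ids)
    observed_both = int((sig[0] & sig[1]).sum())
    expected_rate = p_a * p_b
    union_rate = p_a + p_b - p_a * p_b
    binom_p = (sps.binomtest(observed_both, n, expected_rate).pvalue
               if 0 < expected_rate < 1 else np.nan)
    out.update({
        "p_mod_state_A": p_a, "p_mod_state_B": p_b,
        "observed_both": observed_both,
        "expected_both": expected_rate * n,
        "expected_both_union": union_rate * n,
        "binomial_p": float(binom_p) if np.isfinite(binom_p) else np.nan,
    })
    return out
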