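"""Synthetic session generator with planted, recoverable structure.

The generator emulates a two-state, cued value-based choice task recorded
simultaneously from hippocampus (HPC) and orbitofrontal cortex (OFC):

* a trial table with pseudorandomly cued task states (2 cues per state),
  4 juice-drop value levels (2 pictures each), 80% free / 20% forced trials,
  softmax choices and decision times with planted regression structure;
* inhomogeneous-Poisson spike trains whose rates are gated by trial epoch and
  modulated by state, by state-conditional value, and (optionally) by the
  phase of the concurrent band-limited LFP via a von Mises factor;
* LFP traces at 1 kHz built from 1/f background noise, event-evoked theta
  bursts with trial-consistent initial phase, and a shared theta component
  injected into both areas with a configurable lag, which produces interareal
  coherence and net directionality (source leads target).

Every planted parameter is recorded in the session's ground-truth sidecar so
downstream stages can be validated by parameter recovery.  Pseudorandomization
is implemented as counterbalanced shuffling (the standard task-design
practice), which also guarantees at least ``n_trials/40`` forced trials per
state x value cell.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy.special import i0

from .phase import band_phase_amplitude
from .session import Session, code_values

AREAS = ("HPC", "OFC")
EPOCH_GATES = ("fixation", "state", "choice")


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class TaskConfig:
    """Trial-structure and behavioural parameters of the task."""

    n_trials: int = 800
    p_free: float = 0.8
    n_states: int = 2
    cues_per_state: int = 2
    value_levels: tuple[int, ...] = (1, 2, 3, 4)  # juice drops
    inverse_temp: float = 2.5                     # softmax on value difference
    # decision-time model (ms): base + b_absdv*|dv| + b_state*state + b_side*side + noise
    dt_base_ms: float = 300.0
    dt_beta_absdv: float = -15.0     # ms per juice-drop difference
    dt_beta_state: float = -7.0      # ms per state code unit (-1/+1)
    dt_beta_side: float = 0.0
    dt_noise_median_ms: float = 50.0
    dt_noise_sigma: float = 0.45     # lognormal shape (positive, right-skewed)
    # epoch durations (ms)
    fixation_ms: float = 600.0
    cue_ms: float = 600.0
    hold_ms: float = 100.0
    response_hold_ms: float = 300.0
    iti_ms: float = 700.0            # not reported for the task; free parameter
    lead_in_s: float = 2.0
    tail_s: float = 2.0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(set(self.value_levels)) != 4:
            raise ValueError("value_levels must contain 4 distinct values")
        if not 0.0 <= self.p_free <= 1.0:
            raise ValueError("p_free must lie in [0, 1]")


@dataclass
class PhaseLock:
    """Spike-phase coupling to a band of the neuron's LFP channel.

    ``kappa``/``mu`` are per-state (state A, state B); the coupling applies
    inside the listed epoch gates only (the state is unknown to the animal
    before the cue, so fixation is excluded by default).
    """

    band: tuple[float, float] = (4.0, 8.0)
    mu: tuple[float, float] = (0.0, 0.0)
    kappa: tuple[float, float] = (0.0, 0.0)
    gates: tuple[str, ...] = ("state", "choice")

    def validate(self) -> None:
        if min(self.kappa) < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class NeuronSpec:
    """Planted tuning of one unit.

    ``state_beta`` maps epoch gate -> Hz per state-code unit (-1/+1);
    ``value_beta`` is (Hz per coded value unit in state A, same in state B)
    and applies during the choice gate.  Rates are rectified at zero.
    """

    neuron_id: int
    area: str
    probe: int = 0
    channel: int = 0
    baseline_rate: float = 8.0
    state_beta: dict = field(default_factory=dict)
    value_beta: tuple[float, float] = (0.0, 0.0)
    latency_ms: float = 50.0
    phase_lock: PhaseLock | None = None

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be nonnegative")
        if self.area not in AREAS:
            raise ValueError(f"area must be one of {AREAS}")
        for g in self.state_beta:
            if g not in EPOCH_GATES:
                raise ValueError(f"unknown epoch gate {g!r}")
        if self.phase_lock is not None:
            self.phase_lock.validate()


@dataclass
class EvokedBurst:
    """Event-locked damped theta burst with trial-consistent initial phase.

    Envelope ``amp * (t/rise) * exp(1 - t/rise)`` peaks at ``rise_ms`` after
    event onset (+ ``jitter_ms`` of uniform onset jitter, default 0, which
    degrades cross-trial alignment for power studies).
    """

    event: str = "cue_on_ms"
    freq_hz: float = 5.0
    rise_ms: float = 150.0
    duration_ms: float = 800.0
    amp: float = 10.0
    phase0: float = 0.0
    jitter_ms: float = 0.0


@dataclass
class LFPSpec:
    """One LFP channel: 1/f background plus evoked bursts plus a weighted
    copy of the session-wide shared theta component."""

    channel: int
    area: str
    probe: int = 0
    sample_rate: float = 1000.0
    background_amp: float = 5.0
    evoked: tuple[EvokedBurst, ...] = ()
    shared_weight: float = 0.0


@dataclass
class SharedThetaSpec:
    """Shared theta component: injected into source-area channels directly
    and into the other area delayed by ``lag_ms`` (source leads target)."""

    source_area: str = "HPC"
    lag_ms: float = 40.0
    burst: EvokedBurst | None = field(default_factory=EvokedBurst)
    noise_amp: float = 1.5  # tonic shared theta is weak: primate theta is event-evoked
    noise_band: tuple[float, float] = (4.0, 8.0)

    def validate(self) -> None:
        if self.lag_ms < 0:
            raise ValueError("lag must be >= 0 (source leads target)")
        if self.burst is not None and self.lag_ms >= self.burst.duration_ms:
            raise ValueError("lag exceeds the shared burst duration")


# --------------------------------------------------------------------------
# trial generation
# --------------------------------------------------------------------------

def _balanced_shuffled(values: list, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws cycling through `values` as evenly as possible, shuffled."""
    reps = int(np.ceil(n / len(values)))
    arr = np.tile(values, reps)[:n]
    rng.shuffle(arr)
    return arr


def generate_trials(config: TaskConfig, seed: int | np.random.Generator) -> pd.DataFrame:
    """Generate the trial table.

    States, cue identities and free/forced assignment are counterbalanced and
    shuffled across the session (no serial dependence); forced-trial values
    are counterbalanced within state so every state x value cell is sampled.
    Choices on free trials follow a softmax on the state-conditional values;
    the two offered options never share a value.  Decision times are
    base + planted slopes on |value difference|, state and best side, plus
    lognormal noise.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_trials
    levels = np.asarray(config.value_levels)

    state = _balanced_shuffled([0, 1], n, rng)
    cue = _balanced_shuffled([0, 1], n, rng)
    # free/forced split stratified by state so forced-trial value coverage
    # is guaranteed in every state x value cell
    is_free = np.zeros(n, dtype=bool)
    for s in (0, 1):
        idx = np.flatnonzero(state == s)
        n_free_s = int(round(config.p_free * idx.size))
        is_free[rng.choice(idx, size=n_free_s, replace=False)] = True

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    left_value = np.empty(n, dtype=float)
    right_value = np.full(n, np.nan)
    # forced values: balanced within each state
    for s in (0, 1):
        idx = np.flatnonzero((state == s) & ~is_free)
        left_value[idx] = _balanced_shuffled(list(levels), idx.size, rng)
    free_idx = np.flatnonzero(is_free)
    pair_pick = _balanced_shuffled(list(range(len(pairs))), free_idx.size, rng)
    flip = rng.random(free_idx.size) < 0.5
    for j, (ti, pi, fl) in enumerate(zip(free_idx, pair_pick, flip)):
        lo, hi = pairs[pi]
        left_value[ti], right_value[ti] = (hi, lo) if fl else (lo, hi)

    chosen = left_value.copy()
    dv = left_value - right_value  # nan on forced
    with np.errstate(invalid="ignore", over="ignore"):
        p_left = 1.0 / (1.0 + np.exp(-config.inverse_temp * dv))
    choose_left = rng.random(n) < np.nan_to_num(p_left, nan=1.0)
    chosen[free_idx] = np.where(choose_left[free_idx], left_value[free_idx],
                                right_value[free_idx])
    other = np.where(choose_left, right_value, left_value)
    correct = np.where(is_free, chosen > other, True)

    state_code = state * 2 - 1
    best_side = np.where(np.nan_to_num(dv) > 0, -1.0, 1.0)  # -1 left, +1 right
    best_side[~is_free] = np.where(np.isnan(right_value[~is_free]), -1.0, 1.0)
    absdv = np.abs(np.nan_to_num(dv))
    noise = rng.lognormal(mean=np.log(config.dt_noise_median_ms),
                          sigma=config.dt_noise_sigma, size=n)
    dt = (config.dt_base_ms + config.dt_beta_absdv * absdv
          + config.dt_beta_state * state_code + config.dt_beta_side * best_side
          + noise)
    # forced trials: single option, value in place of |dv|
    dt[~is_free] = (config.dt_base_ms
                    + config.dt_beta_absdv * left_value[~is_free]
                    + config.dt_beta_state * state_code[~is_free] + noise[~is_free])

    fix_on = np.zeros(n)
    cue_on = fix_on + config.fixation_ms
    choice_on = cue_on + config.cue_ms + config.hold_ms
    response = choice_on + dt
    trial_len_s = (response + config.response_hold_ms + config.iti_ms) / 1000.0
    t_start = config.lead_in_s + np.concatenate([[0.0], np.cumsum(trial_len_s[:-1])])

    return pd.DataFrame({
        "trial": np.arange(n),
        "state": state,
        "cue": cue,
        "cue_id": state * config.cues_per_state + cue,
        "trial_type": np.where(is_free, "free", "forced"),
        "left_value": left_value,
        "right_value": right_value,
        "chosen_value": chosen,
        "best_side": best_side,
        "correct": correct,
        "dt_ms": dt,
        "t_start_s": t_start,
        "fix_on_ms": fix_on,
        "cue_on_ms": cue_on,
        "choice_on_ms": choice_on,
        "response_ms": response,
    })


def session_duration_s(trials: pd.DataFrame, config: TaskConfig) -> float:
    last = trials["t_start_s"].iloc[-1] + (
        trials["response_ms"].iloc[-1] + config.response_hold_ms) / 1000.0
    return float(last + config.tail_s)


# --------------------------------------------------------------------------
# LFP generation
# --------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator, amp: float) -> np.ndarray:
    """1/f (power) background noise with RMS ``amp``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _burst_waveform(burst: EvokedBurst, fs: float) -> np.ndarray:
    t = np.arange(0.0, burst.duration_ms / 1000.0, 1.0 / fs)
    rise = burst.rise_ms / 1000.0
    env = burst.amp * (t / rise) * np.exp(1.0 - t / rise)
    return env * np.cos(2 * np.pi * burst.freq_hz * t + burst.phase0)


def _add_bursts(trace: np.ndarray, burst: EvokedBurst, event_times_s: np.ndarray,
                fs: float, rng: np.random.Generator) -> None:
    wave = _burst_waveform(burst, fs)
    jit = (rng.uniform(-burst.jitter_ms, burst.jitter_ms, size=len(event_times_s))
           if burst.jitter_ms > 0 else np.zeros(len(event_times_s)))
    starts = np.round((event_times_s + jit / 1000.0) * fs).astype(int)
    for s in starts:
        e = min(s + wave.size, trace.size)
        if s < trace.size and e > max(s, 0):
            trace[max(s, 0):e] += wave[max(-s, 0):e - s]


def generate_lfp(
    trials: pd.DataFrame,
    specs: list[LFPSpec],
    seed: int | np.random.Generator,
    shared: SharedThetaSpec | None = None,
    duration_s: float | None = None,
    config: TaskConfig | None = None,
) -> np.ndarray:
    """Generate the (channels x samples) LFP matrix.

    Each channel is 1/f background + its own evoked bursts (trial-consistent
    initial phase) + ``shared_weight`` times the shared theta component.  The
    shared component reaches the source area at zero delay and the other area
    ``lag_ms`` later, producing interareal theta coherence with net
    source -> target directionality.
    """
    rng = np.random.default_rng(seed)
    fs = specs[0].sample_rate if specs else 1000.0
    if duration_s is None:
        duration_s = session_duration_s(trials, config or TaskConfig(n_trials=len(trials)))
    n = int(round(duration_s * fs))
    events_abs = {
        col: (trials["t_start_s"] + trials[col] / 1000.0).to_numpy()
        for col in ("fix_on_ms", "cue_on_ms", "choice_on_ms")
    }
    if np.any(events_abs["choice_on_ms"] * fs >= n):
        raise ValueError("trial events extend beyond the session span")

    shared_trace = np.zeros(n)
    lag_samples = 0
    if shared is not None:
        shared.validate()
        lag_samples = int(round(shared.lag_ms / 1000.0 * fs))
        if shared.noise_amp > 0:
            sos = sig.butter(4, shared.noise_band, btype="bandpass", fs=fs, output="sos")
            nz = sig.sosfiltfilt(sos, rng.standard_normal(n))
            shared_trace += nz * (shared.noise_amp / nz.std())
        if shared.burst is not None and shared.burst.amp > 0:
            _add_bursts(shared_trace, shared.burst, events_abs[shared.burst.event], fs, rng)
    lagged = np.zeros(n)
    if shared is not None:
        lagged[lag_samples:] = shared_trace[:n - lag_samples]

    lfp = np.empty((len(specs), n))
    for i, spec in enumerate(specs):
        trace = _pink_noise(n, rng, spec.background_amp)
        for burst in spec.evoked:
            _add_bursts(trace, burst, events_abs[burst.event], fs, rng)
        if shared is not None and spec.shared_weight != 0.0:
            src = shared_trace if spec.area == shared.source_area else lagged
            trace += spec.shared_weight * src
        if not np.all(np.isfinite(trace)):
            raise FloatingPointError(f"non-finite LFP trace on channel {spec.channel}")
        lfp[i] = trace
    return lfp


# --------------------------------------------------------------------------
# spike generation
# --------------------------------------------------------------------------

LOCK_NORM_BIN_MS = 20.0  # peri-event resolution of the phase-factor norm


def _rate_vector(spec: NeuronSpec, trials: pd.DataFrame, n_samples: int,
                 fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample nominal rate (Hz) before rectification, per-sample state
    code (0 outside phase-lock gates, else -1/+1), and the peri-cue time bin
    of each gated sample (-1 outside gates)."""
    rate = np.full(n_samples, spec.baseline_rate)
    lock_state = np.zeros(n_samples, dtype=np.int8)
    rel_bin = np.full(n_samples, -1, dtype=np.int32)
    bin_samples = max(1, int(round(LOCK_NORM_BIN_MS / 1000.0 * fs)))
    cue_samples = np.round((trials["t_start_s"].to_numpy()
                            + trials["cue_on_ms"].to_numpy() / 1000.0) * fs).astype(int)
    lat = spec.latency_ms / 1000.0
    codes = trials["state"].to_numpy() * 2 - 1
    values = code_values(trials["chosen_value"].to_numpy())
    t0 = trials["t_start_s"].to_numpy()
    gates = {
        "fixation": (t0 + trials["fix_on_ms"].to_numpy() / 1000.0,
                     t0 + trials["cue_on_ms"].to_numpy() / 1000.0),
        "state": (t0 + trials["cue_on_ms"].to_numpy() / 1000.0,
                  t0 + trials["choice_on_ms"].to_numpy() / 1000.0),
        "choice": (t0 + trials["choice_on_ms"].to_numpy() / 1000.0,
                   t0 + (trials["response_ms"].to_numpy() + 300.0) / 1000.0),
    }
    lock_gates = spec.phase_lock.gates if spec.phase_lock else ()
    for gate, (gs, ge) in gates.items():
        b = spec.state_beta.get(gate, 0.0)
        for i in range(len(trials)):
            s = int(round((gs[i] + lat) * fs))
            e = min(int(round((ge[i] + lat) * fs)), n_samples)
            if e <= s:
                continue
            delta = b * codes[i]
            if gate == "choice":
                delta += spec.value_beta[trials["state"].iat[i]] * values[i]
            if delta != 0.0:
                rate[s:e] += delta
            if gate in lock_gates:
                lock_state[s:e] = codes[i]
                rel_bin[s:e] = (np.arange(s, e) - cue_samples[i]) // bin_samples
    return rate, lock_state, rel_bin


def generate_spikes(
    trials: pd.DataFrame,
    specs: list[NeuronSpec],
    seed: int | np.random.Generator,
    lfp: np.ndarray | None = None,
    lfp_specs: list[LFPSpec] | None = None,
    duration_s: float | None = None,
    fs: float = 1000.0,
    config: TaskConfig | None = None,
) -> dict[int, np.ndarray]:
    """Sample spike trains by thinning a dominating homogeneous Poisson process.

    The intensity is the epoch-gated rectified rate; when a neuron is
    phase-locked (kappa > 0) the intensity is additionally multiplied by
    ``exp(kappa * cos(phi - mu)) / I0(kappa)``, the von Mises density
    normalised to unit mean over uniform phase so the mean rate is preserved.
    """
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = session_duration_s(trials, config or TaskConfig(n_trials=len(trials)))
    n_samples = int(round(duration_s * fs))
    duration_s = n_samples / fs  # keep spike support inside the sampled trace

    # phase of each (channel, band) needed by any locked neuron
    phase_cache: dict[tuple[int, tuple[float, float]], np.ndarray] = {}
    chan_row = {s.channel: i for i, s in enumerate(lfp_specs)} if lfp_specs else {}
    for spec in specs:
        pl = spec.phase_lock
        if pl is None or max(pl.kappa) == 0:
            continue
        key = (spec.channel, tuple(pl.band))
        if key in phase_cache:
            continue
        if lfp is None:
            raise ValueError(f"neuron {spec.neuron_id} is phase-locked but no LFP was given")
        row = chan_row.get(spec.channel, spec.channel)
        phase_cache[key], _ = band_phase_amplitude(lfp[row], pl.band, fs)

    out: dict[int, np.ndarray] = {}
    for spec in specs:
        spec.validate()
        rate, lock_state, rel_bin = _rate_vector(spec, trials, n_samples, fs)
        clipped = np.clip(rate, 0.0, None)
        lost = clipped.sum() - rate.sum()  # negative mass truncated at zero
        if clipped.sum() > 0 and lost > 0.10 * clipped.sum():
            warnings.warn(
                f"neuron {spec.neuron_id}: rectification removed "
                f"{100 * lost / clipped.sum():.1f}% of nominal rate mass",
                stacklevel=2)
        pl = spec.phase_lock
        vm_factor = None
        vm_gain = 1.0
        if pl is not None and max(pl.kappa) > 0:
            # Multiplicative von Mises phase preference, normalised per state
            # and per peri-cue time bin by its cross-trial mean so the
            # peri-event rate profile is preserved: evoked (phase-aligned)
            # theta must not turn a phase code into a rate code.
            phi_all = phase_cache[(spec.channel, tuple(pl.band))]
            vm_factor = np.ones(n_samples)
            for s_val, (mu, kap) in zip((-1, 1), zip(pl.mu, pl.kappa)):
                sel = lock_state == s_val
                if kap == 0 or not np.any(sel):
                    continue
                f = np.exp(kap * np.cos(phi_all[sel] - mu))
                bins = rel_bin[sel]
                uniq, inv = np.unique(bins, return_inverse=True)
                sums = np.bincount(inv, weights=f)
                counts = np.bincount(inv)
                f /= (sums / counts)[inv]
                vm_factor[sel] = f
            vm_gain = float(vm_factor.max())
        m = clipped.max() * vm_gain
        if m <= 0:
            out[spec.neuron_id] = np.empty(0)
            continue
        n_cand = rng.poisson(m * duration_s)
        cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
        idx = np.minimum((cand * fs).astype(int), n_samples - 1)
        lam = clipped[idx].copy()
        if vm_factor is not None:
            lam *= vm_factor[idx]
        keep = rng.random(n_cand) < lam / m
        out[spec.neuron_id] = cand[keep]
    return out


# --------------------------------------------------------------------------
# whole-session assembly and default study populations
# --------------------------------------------------------------------------

def simulate_session(
    config: TaskConfig,
    neuron_specs: list[NeuronSpec],
    lfp_specs: list[LFPSpec] | None = None,
    shared: SharedThetaSpec | None = None,
    seed: int = 0,
) -> Session:
    """Generate a full session (trials, LFP, spikes, ground-truth sidecar).

    Deterministic given ``(config, specs, seed)``: sub-streams for trials,
    LFP and spikes are spawned from one seed sequence in fixed order.
    """
    ss = np.random.SeedSequence(seed)
    s_trials, s_lfp, s_spikes = [np.random.default_rng(c) for c in ss.spawn(3)]
    trials = generate_trials(config, s_trials)
    duration = session_duration_s(trials, config)
    fs = lfp_specs[0].sample_rate if lfp_specs else 1000.0
    if lfp_specs:
        lfp = generate_lfp(trials, lfp_specs, s_lfp, shared=shared,
                           duration_s=duration)
        channels = pd.DataFrame(
            [{"channel_id": s.channel, "area": s.area, "probe": s.probe}
             for s in lfp_specs])
    else:
        lfp = np.zeros((0, int(round(duration * fs))))
        channels = pd.DataFrame(columns=["channel_id", "area", "probe"])
    spikes = generate_spikes(trials, neuron_specs, s_spikes, lfp=lfp if lfp_specs else None,
                             lfp_specs=lfp_specs, duration_s=duration, fs=fs)
    units = pd.DataFrame(
        [{"neuron_id": s.neuron_id, "area": s.area, "probe": s.probe,
          "channel": s.channel} for s in neuron_specs])
    gt = {
        "seed": seed,
        "task": asdict(config),
        "neurons": [asdict(s) for s in neuron_specs],
        "lfp": [asdict(s) for s in (lfp_specs or [])],
        "shared": asdict(shared) if shared is not None else None,
    }
    return Session(trials, units, spikes, lfp, channels, fs=fs, ground_truth=gt)


def rotated_value_population(
    n_neurons: int,
    angle_deg: float,
    seed: int | np.random.Generator,
    area: str = "HPC",
    beta_scale: float = 2.5,
    baseline: float = 8.0,
    id_offset: int = 0,
    channels: tuple[int, ...] = (0,),
) -> list[NeuronSpec]:
    """Population whose state-B value-coding direction is the state-A
    direction rotated by ``angle_deg`` in neuron space.

    ``beta_scale`` is the RMS per-neuron value slope in Hz per coded unit.
    """
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.standard_normal((n_neurons, 2)))[0]
    u, v = basis[:, 0], basis[:, 1]
    th = np.deg2rad(angle_deg)
    amp = beta_scale * np.sqrt(n_neurons)
    beta_a = amp * u
    beta_b = amp * (np.cos(th) * u + np.sin(th) * v)
    specs = []
    for i in range(n_neurons):
        specs.append(NeuronSpec(
            neuron_id=id_offset + i, area=area, probe=0,
            channel=channels[i % len(channels)], baseline_rate=baseline,
            value_beta=(float(beta_a[i]), float(beta_b[i]))))
    return specs


def value_population_specs(
    kind: str,
    n_neurons: int = 40,
    seed: int = 0,
    area: str = "OFC",
    beta_scale: float = 2.5,
    baseline: float = 8.0,
) -> list[NeuronSpec]:
    """Populations for cross-state generalization studies.

    ``kind='invariant'``: every neuron codes value identically in both states.
    ``kind='exclusive'``: disjoint halves code value in exactly one state.
    """
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.6 * beta_scale, 1.4 * beta_scale, n_neurons)
    signs = rng.choice([-1.0, 1.0], n_neurons)
    betas = mags * signs
    specs = []
    for i in range(n_neurons):
        if kind == "invariant":
            vb = (betas[i], betas[i])
        elif kind == "exclusive":
            vb = (betas[i], 0.0) if i < n_neurons // 2 else (0.0, betas[i])
        else:
            raise ValueError("kind must be 'invariant' or 'exclusive'")
        specs.append(NeuronSpec(neuron_id=i, area=area, baseline_rate=baseline,
                                value_beta=vb))
    return specs


def default_lfp_specs(
    background_amp: float = 5.0,
    fix_burst_amp: float = 8.0,
    shared_weights: tuple[float, float] = (1.0, 0.6),
) -> tuple[list[LFPSpec], SharedThetaSpec]:
    """Study-default LFP layout: 2 probes x 2 channels per area.

    Each channel carries an independent fixation-evoked burst (cross-trial
    phase alignment at fixation without interareal lag) and a weighted copy of
    the HPC-sourced shared theta component (cue-evoked burst + band noise,
    OFC delayed by 40 ms).  The first channel of each probe carries the larger
    shared weight, marking it as the planted best coherence channel.
    """
    specs = []
    ch = 0
    for area in AREAS:
        for probe in range(2):
            for k in range(2):
                specs.append(LFPSpec(
                    channel=ch, area=area, probe=probe + (2 if area == "OFC" else 0),
                    background_amp=background_amp,
                    evoked=(EvokedBurst(event="fix_on_ms", freq_hz=5.0, rise_ms=120.0,
                                        duration_ms=500.0, amp=fix_burst_amp,
                                        phase0=0.0),),
                    shared_weight=shared_weights[k]))
                ch += 1
    shared = SharedThetaSpec(
        source_area="HPC", lag_ms=40.0,
        burst=EvokedBurst(event="cue_on_ms", freq_hz=5.0, rise_ms=150.0,
                          duration_ms=800.0, amp=12.0, phase0=0.0),
        noise_amp=1.5)
    return specs, shared


def default_neuron_specs(
    n_per_area: int = 40,
    seed: int = 0,
    hpc_angle_deg: float = 30.0,
    state_beta_hz: float = 4.0,
    value_beta_scale: float = 2.5,
    kappa_preferred: float = 2.0,
    kappa_nonpreferred: float = 0.2,
    n_channels_per_area: int = 4,
    include_low_rate: bool = True,
) -> list[NeuronSpec]:
    """The study-default dual-area population.

    HPC: 40% of neurons carry state tuning in the state epoch (and theta
    phase locking that is strong in their preferred state); half the
    population carries value tuning whose state-B coding direction is the
    state-A direction rotated by ~30 degrees (largely state-general).
    OFC: 40% carry state tuning in the *choice* epoch (with state-epoch theta
    phase locking in the preferred state); value tuning is state-exclusive
    (disjoint halves code value in exactly one state), an orthogonal code.
    One sub-1 Hz unit per area exercises the rate-retention rule.
    """
    rng = np.random.default_rng(seed)
    n_state = int(round(0.4 * n_per_area))
    n_value = n_per_area // 2
    specs: list[NeuronSpec] = []
    nid = 0
    for area in AREAS:
        ch0 = 0 if area == "HPC" else n_channels_per_area
        state_epoch = "state" if area == "HPC" else "choice"
        # state-tuned units (possibly overlapping value tuning below)
        state_ids = list(range(n_state))
        if area == "HPC":
            vp = rotated_value_population(
                n_value, hpc_angle_deg, rng, area=area,
                beta_scale=value_beta_scale, id_offset=0)
            value_betas = [s.value_beta for s in vp]
        else:
            mags = rng.uniform(0.6 * value_beta_scale, 1.4 * value_beta_scale, n_value)
            sg = rng.choice([-1.0, 1.0], n_value)
            value_betas = [
                (mags[i] * sg[i], 0.0) if i < n_value // 2 else (0.0, mags[i] * sg[i])
                for i in range(n_value)
            ]
        for i in range(n_per_area):
            baseline = float(rng.uniform(5.0, 14.0))
            sb = {}
            pl = None
            if i in state_ids:
                sign = -1.0 if i % 2 == 0 else 1.0
                sb = {state_epoch: sign * state_beta_hz}
                pref = 0 if sign < 0 else 1  # state with the higher rate
                kap = [kappa_nonpreferred, kappa_nonpreferred]
                kap[pref] = kappa_preferred
                pl = PhaseLock(mu=(0.0, 0.0), kappa=(kap[0], kap[1]))
            vb = (0.0, 0.0)
            j = i - (n_per_area - n_value)
            if j >= 0:
                vb = (float(value_betas[j][0]), float(value_betas[j][1]))
            specs.append(NeuronSpec(
                neuron_id=nid, area=area,
                probe=(0 if area == "HPC" else 2) + (i % 2),
                channel=ch0 + i % n_channels_per_area,
                baseline_rate=baseline, state_beta=sb, value_beta=vb,
                phase_lock=pl))
            nid += 1
        if include_low_rate:
            specs.append(NeuronSpec(neuron_id=nid, area=area,
                                    probe=(0 if area == "HPC" else 2),
                                    channel=ch0, baseline_rate=0.4))
            nid += 1
    return specs


def make_default_session(seed: int = 0, n_trials: int = 800,
                         n_per_area: int = 40) -> Session:
    """One call producing the full study-default synthetic session."""
    config = TaskConfig(n_trials=n_trials)
    neurons = default_neuron_specs(n_per_area=n_per_area, seed=seed + 1)
    lfp_specs, shared = default_lfp_specs()
    return simulate_session(config, neurons, lfp_specs, shared, seed=seed)
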