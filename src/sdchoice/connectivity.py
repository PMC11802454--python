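"""Interareal multitaper coherence and MVAR-based directionality (GPDC and
time-domain Granger causality).

Coherograms use 3 Slepian tapers (time-bandwidth product 2), 1-s windows and
90% overlap; magnitude-squared coherence is formed from cross/auto spectra
averaged over tapers (and over trials when the analysis is event-aligned) and
z-scored per channel pair across the session for cross-session comparison.

Directionality comes from a bivariate autoregressive (MVAR) model fit by
ensemble least squares over per-trial segments (per-trial means removed;
order by minimum BIC up to a cap).  Generalized partial directed coherence
from source j to target i at frequency f is

    GPDC_{i<-j}(f) = (|A(f)_ij| / s_i) / sqrt(sum_k |A(f)_kj|^2 / s_k^2)

with ``A(f) = I - sum_k A_k exp(-2 pi i f k / fs)`` and s_i the residual
standard deviation of channel i; values are bounded in [0, 1].  Net
directionality is GPDC(x->y) - GPDC(y->x) per frequency, with a CI from the
80%-subsample bootstrap over trials; swapping the channels negates it
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal.windows import dpss

from .stats import boot_ci


# ----------------------------------------------------------------- coherence

@dataclass
class CoherogramResult:
    freqs: np.ndarray
    times_s: np.ndarray
    coherence: np.ndarray        # (freq, time), raw in [0, 1]

    def band_timecourse(self, band: tuple[float, float] = (4.0, 8.0),
                        zscored: bool = True) -> np.ndarray:
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        tc = self.coherence[sel].mean(axis=0)
        if zscored:
            sd = tc.std()
            tc = (tc - tc.mean()) / sd if sd > 0 else tc * 0.0
        return tc


def multitaper_coherogram(
    x: np.ndarray, y: np.ndarray, fs: float = 1000.0,
    window_s: float = 1.0, overlap: float = 0.9, n_tapers: int = 3,
    event_times_s: np.ndarray | None = None,
    t_range_s: tuple[float, float] = (-1.0, 2.0),
) -> CoherogramResult:
    """Multitaper magnitude-squared coherence over time.

    Continuous mode (``event_times_s=None``): windows slide along the whole
    trace and spectra are averaged over tapers.  Event-aligned mode: at each
    peri-event window position spectra are additionally averaged across
    trials, which is what gives the estimator statistical degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    m = int(round(window_s * fs))
    if m > x.size:
        raise ValueError("window longer than trace")
    step = max(1, int(round(m * (1.0 - overlap))))
    tapers = dpss(m, NW=2, Kmax=n_tapers) * np.sqrt(fs)
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)

    def tapered_fft(seg):  # (..., m) -> (..., K, nf)
        return np.fft.rfft(seg[..., None, :] * tapers, axis=-1)

    if event_times_s is None:
        starts = np.arange(0, x.size - m + 1, step)
        segs_x = np.stack([x[s:s + m] for s in starts])
        segs_y = np.stack([y[s:s + m] for s in starts])
        fx = tapered_fft(segs_x)
        fy = tapered_fft(segs_y)
        sxy = (fx * np.conj(fy)).mean(axis=1)
        sxx = (np.abs(fx) ** 2).mean(axis=1)
        syy = (np.abs(fy) ** 2).mean(axis=1)
        coh = np.abs(sxy) ** 2 / np.clip(sxx * syy, 1e-300, None)
        times = (starts + m / 2) / fs
        return CoherogramResult(freqs, times, coh.T)

    ev = np.round(np.asarray(event_times_s) * fs).astype(int)
    rel = np.arange(int(round(t_range_s[0] * fs)),
                    int(round(t_range_s[1] * fs)) - m + 1, step)
    if rel.size == 0:
        raise ValueError("peri-event range shorter than one window")
    if (ev.min() + rel.min()) < 0 or (ev.max() + rel.max() + m) > x.size:
        raise ValueError("peri-event windows extend beyond the trace")
    coh = np.empty((freqs.size, rel.size))
    for j, r in enumerate(rel):
        idx = ev + r
        segs_x = np.stack([x[s:s + m] for s in idx])
        segs_y = np.stack([y[s:s + m] for s in idx])
        fx = tapered_fft(segs_x)   # (trials, K, nf)
        fy = tapered_fft(segs_y)
        sxy = (fx * np.conj(fy)).mean(axis=(0, 1))
        sxx = (np.abs(fx) ** 2).mean(axis=(0, 1))
        syy = (np.abs(fy) ** 2).mean(axis=(0, 1))
        coh[:, j] = np.abs(sxy) ** 2 / np.clip(sxx * syy, 1e-300, None)
    times = (rel + m / 2) / fs
    return CoherogramResult(freqs, times, coh)


# --------------------------------------------------------- channel selection

def select_pair_channels(
    channels: pd.DataFrame, units: pd.DataFrame, peak_r: dict[int, float],
) -> tuple[dict[int, int], list[tuple[int, int]]]:
    """One channel per probe: the highest cross-trial theta alignment among
    channels hosting at least one unit; then all HPC x OFC pairs.

    Returns ``(probe -> channel, [(hpc_channel, ofc_channel), ...])``.
    Probes with no qualifying channel are excluded; an empty selection in
    either area is an error.
    """
    with_units = set(units["channel"].unique())
    chosen: dict[int, int] = {}
    for probe, g in channels.groupby("probe"):
        cands = [c for c in g["channel_id"] if c in with_units and c in peak_r]
        if not cands:
            continue
        chosen[int(probe)] = int(max(cands, key=lambda c: peak_r[c]))
    area_of = channels.set_index("channel_id")["area"].to_dict()
    hpc = [c for c in chosen.values() if area_of[c] == "HPC"]
    ofc = [c for c in chosen.values() if area_of[c] == "OFC"]
    if not hpc or not ofc:
        raise ValueError("no qualifying channel in one or both areas")
    pairs = [(h, o) for h in hpc for o in ofc]
    return chosen, pairs


# ------------------------------------------------------------------ MVAR fit

def _lagged_design(segs: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial lagged design; segs (n_trials, T, 2) ->
    X (n_trials, T-p, 2p) lag-major, Y (n_trials, T-p, 2)."""
    n, t, _ = segs.shape
    if t <= p:
        raise ValueError("segments shorter than the model order")
    lags = [segs[:, p - k:t - k, :] for k in range(1, p + 1)]
    x = np.concatenate(lags, axis=2)
    return x, segs[:, p:, :]


def _trial_moments(segs: np.ndarray, p: int):
    x, y = _lagged_design(segs, p)
    xtx = np.einsum("nti,ntj->nij", x, x)
    xty = np.einsum("nti,ntj->nij", x, y)
    yty = np.einsum("nti,ntj->nij", y, y)
    return xtx, xty, yty, x.shape[1]


def _solve_var(xtx, xty, yty, rows):
    b = np.linalg.solve(xtx, xty)                      # (2p, 2)
    rss = yty - xty.T @ b
    sigma = (rss + rss.T) / 2 / max(rows - xtx.shape[0], 1)
    return b, sigma


def _standardize(segs: np.ndarray) -> np.ndarray:
    segs = np.asarray(segs, float)
    segs = segs - segs.mean(axis=1, keepdims=True)     # per-trial detrend (mean)
    sd = segs.std(axis=(0, 1), keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance input channel")
    return segs / sd


def select_order(segs: np.ndarray, order_max: int = 15) -> int:
    """Minimum-BIC MVAR order, evaluated on a common row set."""
    xtx, xty, yty, _ = _trial_moments(segs, order_max)
    sxx, sxy, syy = xtx.sum(0), xty.sum(0), yty.sum(0)
    rows = segs.shape[0] * (segs.shape[1] - order_max)
    best, best_bic = 1, np.inf
    for p in range(1, order_max + 1):
        k = 2 * p
        b = np.linalg.solve(sxx[:k, :k], sxy[:k])
        rss = syy - sxy[:k].T @ b
        sigma = (rss + rss.T) / 2 / rows
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = logdet + (4 * p) * np.log(rows) / rows
        if bic < best_bic:
            best, best_bic = p, bic
    return best


def _is_stable(b: np.ndarray, p: int) -> bool:
    a = np.stack([b[2 * k:2 * k + 2, :].T for k in range(p)])  # (p, 2, 2)
    comp = np.zeros((2 * p, 2 * p))
    comp[:2, :] = np.concatenate(list(a), axis=1)
    if p > 1:
        comp[2:, :-2] = np.eye(2 * (p - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


def gpdc_spectrum(b: np.ndarray, sigma: np.ndarray, p: int,
                  freqs: np.ndarray, fs: float) -> np.ndarray:
    """GPDC matrix per frequency from stacked VAR coefficients.

    Returns (n_freqs, 2, 2); entry [f, i, j] is GPDC from channel j to i.
    """
    a = np.stack([b[2 * k:2 * k + 2, :].T for k in range(p)])  # A_k, (p,2,2)
    phases = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    abar = np.eye(2)[None, :, :] - np.einsum("fk,kij->fij", phases, a)
    s = np.sqrt(np.clip(np.diag(sigma), 1e-300, None))
    w = np.abs(abar) / s[None, :, None]                # |A_ij| / s_i
    denom = np.sqrt((w ** 2).sum(axis=1, keepdims=True))
    return w / np.clip(denom, 1e-300, None)


@dataclass
class DirectionalityResult:
    freqs: np.ndarray
    gpdc_fwd: np.ndarray         # x -> y
    gpdc_rev: np.ndarray         # y -> x
    net: np.ndarray              # fwd - rev
    net_ci_lo: np.ndarray
    net_ci_hi: np.ndarray
    order: int
    net_theta: float = np.nan    # band-average over 4-8 Hz
    net_theta_ci: tuple[float, float] = (np.nan, np.nan)
    net_5hz: float = np.nan
    net_5hz_ci: tuple[float, float] = (np.nan, np.nan)
    granger: dict = field(default_factory=dict)

    def significant_direction(self) -> str:
        lo, hi = self.net_theta_ci
        if lo > 0:
            return "x->y"
        if hi < 0:
            return "y->x"
        return "none"


def fit_mvar_gpdc(
    x_segments: np.ndarray, y_segments: np.ndarray, fs: float = 1000.0,
    order: int | None = None, order_max: int = 15,
    freqs: np.ndarray | None = None, n_boot: int = 200,
    seed: int | np.random.Generator = 0, theta_band: tuple[float, float] = (4.0, 8.0),
) -> DirectionalityResult:
    """Ensemble MVAR fit over per-trial segments and bootstrap GPDC.

    ``x_segments``/``y_segments`` are (n_trials, n_samples) arrays of the
    analysis window (by default the 600 ms starting 300 ms after the
    state-cue onset, the period of rising theta coherence).  The CI is the 5th/95th percentile over 80%-trial
    subsamples.  An unstable fit is retried at successively lower orders.
    """
    rng = np.random.default_rng(seed)
    segs = _standardize(np.stack([np.asarray(x_segments, float),
                                  np.asarray(y_segments, float)], axis=2))
    if freqs is None:
        freqs = np.arange(1.0, 61.0)
    p = order or select_order(segs, order_max)
    while p >= 1:
        xtx, xty, yty, rows_pt = _trial_moments(segs, p)
        sxx, sxy, syy = xtx.sum(0), xty.sum(0), yty.sum(0)
        b, sigma = _solve_var(sxx, sxy, syy, segs.shape[0] * rows_pt)
        if _is_stable(b, p) or p == 1:
            break
        p -= 1

    def net_from(sxx_, sxy_, syy_, rows_):
        b_, sig_ = _solve_var(sxx_, sxy_, syy_, rows_)
        g = gpdc_spectrum(b_, sig_, p, freqs, fs)
        return g[:, 1, 0] - g[:, 0, 1], g

    net, g_full = net_from(sxx, sxy, syy, segs.shape[0] * rows_pt)
    n = segs.shape[0]
    k = max(2, int(round(0.8 * n)))
    boots = np.empty((n_boot, freqs.size))
    for bi in range(n_boot):
        idx = rng.choice(n, size=k, replace=True)
        boots[bi], _ = net_from(xtx[idx].sum(0), xty[idx].sum(0),
                                yty[idx].sum(0), k * rows_pt)
    lo = np.percentile(boots, 5, axis=0)
    hi = np.percentile(boots, 95, axis=0)
    th = (freqs >= theta_band[0]) & (freqs <= theta_band[1])
    theta_boot = boots[:, th].mean(axis=1)
    f5 = int(np.argmin(np.abs(freqs - 5.0)))
    return DirectionalityResult(
        freqs=freqs, gpdc_fwd=g_full[:, 1, 0], gpdc_rev=g_full[:, 0, 1],
        net=net, net_ci_lo=lo, net_ci_hi=hi, order=p,
        net_theta=float(net[th].mean()), net_theta_ci=boot_ci(theta_boot),
        net_5hz=float(net[f5]), net_5hz_ci=boot_ci(boots[:, f5]))


def granger_confirm(
    x_segments: np.ndarray, y_segments: np.ndarray, order: int | None = None,
    order_max: int = 15,
) -> dict:
    """Time-domain Granger causality: nested-model variance-ratio tests.

    Returns F and p for x->y (past x improves prediction of y) and y->x.
    """
    segs = _standardize(np.stack([np.asarray(x_segments, float),
                                  np.asarray(y_segments, float)], axis=2))
    p = order or select_order(segs, order_max)
    xtx, xty, yty, rows_pt = _trial_moments(segs, p)
    sxx, sxy, syy = xtx.sum(0), xty.sum(0), yty.sum(0)
    rows = segs.shape[0] * rows_pt
    out = {"order": p}
    for target, source, name in ((1, 0, "x_to_y"), (0, 1, "y_to_x")):
        b_full = np.linalg.solve(sxx, sxy[:, target])
        rss_full = syy[target, target] - sxy[:, target] @ b_full
        own = np.array([2 * k + target for k in range(p)])
        b_red = np.linalg.solve(sxx[np.ix_(own, own)], sxy[own, target])
        rss_red = syy[target, target] - sxy[own, target] @ b_red
        dof = rows - 2 * p
        f = max(rss_red - rss_full, 0.0) / p / (rss_full / dof)
        out[f"F_{name}"] = float(f)
        out[f"p_{name}"] = float(sps.f.sf(f, p, dof))
    return out


def gpdc_window_segments(
    lfp_row: np.ndarray, cue_times_s: np.ndarray, fs: float = 1000.0,
    start_ms: float = 300.0, dur_ms: float = 600.0,
) -> np.ndarray:
    """Per-trial segments of the directionality window (600 ms beginning
    300 ms after state-cue onset)."""
    s0 = np.round((np.asarray(cue_times_s) + start_ms / 1000.0) * fs).astype(int)
    n = int(round(dur_ms / 1000.0 * fs))
    if s0.min() < 0 or (s0 + n).max() > lfp_row.size:
        raise ValueError("directionality window extends beyond the trace")
    return np.stack([lfp_row[s:s + n] for s in s0])
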