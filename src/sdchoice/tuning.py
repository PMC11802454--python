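"""Time-resolved and epoch-based single-neuron encoding of task state and
value, and area-level prevalence comparisons.

The sliding analysis counts spikes in 100 ms windows stepped by 25 ms,
aligned separately to the state-cue and choice-option onsets (variable
response times preclude one continuous alignment; the two segments are
concatenated for presentation).  Per window a two-way ANOVA with factors
state (-1/+1) and cue (-1/+1) is fit, and the effect size of each factor is
the partial omega squared

    w2_p = DF * (MS_effect - MS_error)
           / (DF * MS_effect + (N - DF) * MS_error),

a low-bias estimate of the proportion of variance the factor explains.

Epoch models (per neuron, choice-epoch mean rate F):

    F = b0 + b1*state + b2*value + b3*state*value + b4*t        (joint)
    F = b0 + b1*value + b2*t            (per state, chosen-option value)

with state coded -1/+1, value coded -2,-1,1,2 and trial number t z-scored as
a nonstationarity nuisance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .session import Session, code_values
from .stats import fisher_r_to_z

ALPHA_SLIDING = 0.05


@dataclass(frozen=True)
class EpochWindow:
    event: str          # trial-table event column
    start_ms: float
    end_ms: float       # half-open [start, end)

    def validate(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("epoch window must have positive length")


@dataclass(frozen=True)
class EpochSpec:
    """Named fixed analysis windows relative to task events."""

    fixation: EpochWindow = EpochWindow("fix_on_ms", 0.0, 600.0)
    state: EpochWindow = EpochWindow("cue_on_ms", 100.0, 500.0)
    choice: EpochWindow = EpochWindow("choice_on_ms", 100.0, 500.0)


DEFAULT_EPOCHS = EpochSpec()


# --------------------------------------------------------------------- rates

def bin_rates(
    spike_times_s: np.ndarray,
    event_times_s: np.ndarray,
    t_range_s: tuple[float, float],
    width_s: float = 0.100,
    step_s: float = 0.025,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window firing rates aligned to one task event.

    Spikes are counted in half-open windows ``[c - w/2, c + w/2)`` and
    divided by the width.  Returns ``(rates, centers_s)`` with rates of shape
    (n_trials, n_windows) and window centers relative to the event.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    event_times_s = np.asarray(event_times_s, dtype=float)
    centers = np.arange(t_range_s[0] + width_s / 2,
                        t_range_s[1] - width_s / 2 + 1e-9, step_s)
    left = event_times_s[:, None] + centers[None, :] - width_s / 2
    right = left + width_s
    if left.min() < 0 or (duration_s is not None and right.max() > duration_s):
        raise ValueError("analysis window extends beyond the recorded span")
    counts = (np.searchsorted(spike_times_s, right)
              - np.searchsorted(spike_times_s, left))
    return counts / width_s, centers


def epoch_rates(
    spike_times_s: np.ndarray, event_times_s: np.ndarray,
    window: EpochWindow,
) -> np.ndarray:
    """Mean firing rate (Hz) of one neuron in a fixed epoch, per trial."""
    left = np.asarray(event_times_s) + window.start_ms / 1000.0
    right = np.asarray(event_times_s) + window.end_ms / 1000.0
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    counts = (np.searchsorted(spike_times_s, right)
              - np.searchsorted(spike_times_s, left))
    return counts / ((window.end_ms - window.start_ms) / 1000.0)


# --------------------------------------------------------------------- ANOVA

def omega_p2(df_effect: float, ms_effect: float, ms_error: float, n: int) -> float:
    """Partial omega squared of one ANOVA factor (raw, unclipped)."""
    denom = df_effect * ms_effect + (n - df_effect) * ms_error
    if denom == 0:
        return 0.0
    return float(df_effect * (ms_effect - ms_error) / denom)


def _ssr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise residual sum of squares of y on design x (via QR)."""
    q, _ = np.linalg.qr(x)
    proj = q.T @ y
    return np.einsum("ij,ij->j", y, y) - np.einsum("ij,ij->j", proj, proj)


def sliding_anova(
    rates: np.ndarray, state_codes: np.ndarray, cue_codes: np.ndarray,
    centers_s: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-way (state x cue, with interaction) ANOVA per sliding window.

    Effect sums of squares are partial (drop-one-term, equivalent to type III
    with the -1/+1 coding).  Returns one row per window x factor with F, p,
    raw and display-clipped partial omega squared, and the housekeeping
    quantities (DF_effect, MS_effect, MS_error, N).
    """
    y = np.asarray(rates, dtype=float)
    s = np.asarray(state_codes, dtype=float)
    c = np.asarray(cue_codes, dtype=float)
    n = y.shape[0]
    cells = {(a, b): np.sum((s == a) & (c == b)) for a in (-1, 1) for b in (-1, 1)}
    if min(cells.values()) < 2:
        raise ValueError(f"need >=2 trials per state x cue cell, got {cells}")
    inter = s * c
    ones = np.ones(n)
    x_full = np.column_stack([ones, s, c, inter])
    ssr_full = _ssr(x_full, y)
    dfe = n - x_full.shape[1]
    ms_error = ssr_full / dfe
    if centers_s is None:
        centers_s = np.arange(y.shape[1], dtype=float)
    rows = []
    for name, keep in (("state", [0, 2, 3]), ("cue", [0, 1, 3]),
                       ("interaction", [0, 1, 2])):
        ss_eff = _ssr(x_full[:, keep], y) - ssr_full
        ss_eff = np.clip(ss_eff, 0.0, None)  # guard tiny negative round-off
        f = ss_eff / np.where(ms_error > 0, ms_error, np.inf)
        p = sps.f.sf(f, 1, dfe)
        omega = np.array([omega_p2(1.0, ss_eff[w], ms_error[w], n)
                          for w in range(y.shape[1])])
        rows.append(pd.DataFrame({
            "window": np.arange(y.shape[1]), "time_s": centers_s, "factor": name,
            "F": f, "p": p, "omega_p2": omega,
            "omega_p2_clipped": np.clip(omega, 0.0, None),
            "df_effect": 1, "ms_effect": ss_eff, "ms_error": ms_error, "n": n,
        }))
    return pd.concat(rows, ignore_index=True)


def sliding_anova_session(
    session: Session,
    epochs: EpochSpec = DEFAULT_EPOCHS,
    cue_range_s: tuple[float, float] = (-0.7, 1.4),
    choice_range_s: tuple[float, float] = (-0.2, 0.6),
    width_s: float = 0.100,
    step_s: float = 0.025,
) -> pd.DataFrame:
    """Sliding ANOVA for every retained unit, in two aligned segments
    (cue-aligned and choice-aligned) concatenated at presentation."""
    units = session.retained_units()
    s_codes = session.state_codes()
    cue_codes = session.trials["cue"].to_numpy() * 2 - 1
    out = []
    for align, rng_s in (("cue_on_ms", cue_range_s), ("choice_on_ms", choice_range_s)):
        ev = session.event_times_s(align)
        for _, u in units.iterrows():
            nid = int(u["neuron_id"])
            rates, centers = bin_rates(session.spikes[nid], ev, rng_s,
                                       width_s, step_s, session.duration_s)
            res = sliding_anova(rates, s_codes, cue_codes, centers)
            res.insert(0, "alignment", align)
            res.insert(0, "area", u["area"])
            res.insert(0, "neuron_id", nid)
            out.append(res)
    return pd.concat(out, ignore_index=True)


def prevalence_timecourse(
    anova: pd.DataFrame, factor: str = "state", alpha: float = ALPHA_SLIDING,
) -> pd.DataFrame:
    """Fraction of significant neurons per window per area, with binomial CIs
    and a per-window 2x2 chi-square test between areas."""
    df = anova[anova["factor"] == factor]
    areas = sorted(df["area"].unique())
    rows = []
    for (align, win), g in df.groupby(["alignment", "window"], sort=True):
        counts = {}
        for area in areas:
            ga = g[g["area"] == area]
            n = len(ga)
            if n == 0:
                raise ValueError(f"no neurons in area {area}")
            k = int((ga["p"] < alpha).sum())
            lo, hi = proportion_confint(k, n, method="beta")
            counts[area] = (k, n)
            rows.append({"alignment": align, "window": win,
                         "time_s": ga["time_s"].iloc[0], "area": area,
                         "n_sig": k, "n": n, "frac": k / n,
                         "ci_lo": lo, "ci_hi": hi})
        if len(areas) == 2:
            (k1, n1), (k2, n2) = counts[areas[0]], counts[areas[1]]
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if table.sum(axis=0).min() == 0:
                p = 1.0
            else:
                _, p, _, _ = sps.chi2_contingency(table, correction=False)
            for r in rows[-2:]:
                r["chi2_p"] = p
    return pd.DataFrame(rows)


# ------------------------------------------------------------- epoch models

def _multi_ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of many responses on one design; returns (betas, p) each
    (n_params, n_responses)."""
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * sps.t.sf(np.abs(t), dof)
    return beta, p


def fit_choice_epoch_model(
    session: Session, epochs: EpochSpec = DEFAULT_EPOCHS,
    include_forced: bool = True,
) -> pd.DataFrame:
    """Joint state/value/interaction regression on choice-epoch rates."""
    trials = session.trials if include_forced else \
        session.trials[session.trials["trial_type"] == "free"]
    ev = (trials["t_start_s"] + trials[epochs.choice.event] / 1000.0).to_numpy()
    s = trials["state"].to_numpy() * 2 - 1
    v = code_values(trials["chosen_value"].to_numpy())
    # nuisance: recorded trial number (not table position), so fits are
    # invariant to row order
    t = sps.zscore(trials["trial"].to_numpy(dtype=float))
    x = np.column_stack([np.ones_like(s, dtype=float), s, v, s * v, t])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (is only one value present?)")
    units = session.retained_units()
    y = np.column_stack([
        epoch_rates(session.spikes[int(n)], ev, epochs.choice)
        for n in units["neuron_id"]])
    beta, p = _multi_ols(x, y)
    names = ["intercept", "state", "value", "state_x_value", "trial"]
    out = {"neuron_id": units["neuron_id"].to_numpy(), "area": units["area"].to_numpy()}
    for i, nm in enumerate(names):
        out[f"beta_{nm}"] = beta[i]
        out[f"p_{nm}"] = p[i]
    return pd.DataFrame(out)


def state_conditional_value_betas(
    session: Session, epochs: EpochSpec = DEFAULT_EPOCHS,
    min_trials: int = 10, alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron value slope fitted separately within each task state.

    A neuron is labelled value-coding when the slope is significant in at
    least one state.
    """
    units = session.retained_units()
    res = {"neuron_id": units["neuron_id"].to_numpy(),
           "area": units["area"].to_numpy()}
    for s_idx, label in ((0, "A"), (1, "B")):
        tr = session.trials[session.trials["state"] == s_idx]
        if len(tr) < min_trials:
            raise ValueError(f"fewer than {min_trials} trials in state {label}")
        ev = (tr["t_start_s"] + tr[epochs.choice.event] / 1000.0).to_numpy()
        v = code_values(tr["chosen_value"].to_numpy())
        t = sps.zscore(tr["trial"].to_numpy(dtype=float))
        x = np.column_stack([np.ones_like(v), v, t])
        y = np.column_stack([
            epoch_rates(session.spikes[int(n)], ev, epochs.choice)
            for n in units["neuron_id"]])
        beta, p = _multi_ols(x, y)
        res[f"beta_{label}"] = beta[1]
        res[f"p_{label}"] = p[1]
    df = pd.DataFrame(res)
    df["value_coding"] = (df["p_A"] < alpha) | (df["p_B"] < alpha)
    return df


def compare_beta_correlations(
    tuning: pd.DataFrame, area1: str = "HPC", area2: str = "OFC",
) -> dict:
    """Pearson correlation of (beta_A, beta_B) over value-coding neurons per
    area and the Fisher r-to-z comparison between areas."""
    out = {}
    ns = {}
    for area in (area1, area2):
        sub = tuning[(tuning["area"] == area) & tuning["value_coding"]]
        if len(sub) < 4:
            raise ValueError(f"area {area}: need >=4 value-coding neurons, got {len(sub)}")
        if sub["beta_A"].std() == 0 or sub["beta_B"].std() == 0:
            raise ValueError(f"area {area}: degenerate beta variance")
        r, p = sps.pearsonr(sub["beta_A"], sub["beta_B"])
        out[f"r_{area}"] = float(r)
        out[f"p_{area}"] = float(p)
        out[f"n_{area}"] = int(len(sub))
        ns[area] = (float(r), len(sub))
    z, p = fisher_r_to_z(ns[area1][0], ns[area1][1], ns[area2][0], ns[area2][1])
    out["fisher_z"] = z
    out["fisher_p"] = p
    return out
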