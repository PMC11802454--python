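"""Behavioural performance and decision-time regression.

Accuracy is the fraction of free-choice trials on which the higher
state-conditional value was chosen.  Decision times on free trials are
modelled as

    DT = b0 + b1*state + b2*abs(dv) + b3*state*abs(dv) + b4*best_side

where abs(dv) is the absolute value difference between the two offers, state
is coded -1/+1 and best_side -1 (left) / +1 (right).  Continuous predictors
are z-scored before fitting (binary predictors keep their sign codes);
variance inflation factors are reported and checked against a configurable
cap.  The forced-trial variant replaces abs(dv) with the offered value level.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor


@dataclass
class DTRegressionResult:
    params: pd.Series
    pvalues: pd.Series
    vif: pd.Series
    n: int
    standardized: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.params, "p": self.pvalues})


def accuracy_by_state(sessions: pd.DataFrame | list[pd.DataFrame]) -> dict:
    """Per-state accuracy (mean +/- SE across sessions) and a paired
    two-sided t-test across sessions (NaN p for a single session)."""
    tables = [sessions] if isinstance(sessions, pd.DataFrame) else list(sessions)
    per_session = []
    for t in tables:
        free = t[t["trial_type"] == "free"]
        accs = {}
        for s in (0, 1):
            sub = free[free["state"] == s]
            if len(sub) == 0:
                raise ValueError(f"state {s} absent from the trial table")
            accs[s] = float(sub["correct"].mean())
        per_session.append(accs)
    a = np.array([d[0] for d in per_session])
    b = np.array([d[1] for d in per_session])
    if len(tables) > 1:
        tstat, p = sps.ttest_rel(a, b)
    else:
        tstat, p = np.nan, np.nan
    se = lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    return {"state_A_mean": float(a.mean()), "state_A_se": se(a),
            "state_B_mean": float(b.mean()), "state_B_se": se(b),
            "t": float(tstat) if np.isfinite(tstat) else np.nan,
            "p": float(p) if np.isfinite(p) else np.nan,
            "n_sessions": len(tables)}


def _design(trials: pd.DataFrame, standardize: bool) -> pd.DataFrame:
    free = trials[trials["trial_type"] == "free"]
    if free["dt_ms"].isna().any():
        raise ValueError("missing decision times on free trials")
    state = free["state"].to_numpy() * 2 - 1
    absdv = np.abs(free["left_value"] - free["right_value"]).to_numpy(dtype=float)
    side = free["best_side"].to_numpy(dtype=float)
    if standardize:
        absdv = sps.zscore(absdv)
    # interaction always uses the centred continuous term so the binary main
    # effect stays identifiable (keeps variance inflation near 1)
    x = pd.DataFrame({
        "state": state,
        "abs_dv": absdv,
        "state_x_abs_dv": state * (absdv - absdv.mean()),
        "best_side": side,
    }, index=free.index)
    x.insert(0, "const", 1.0)
    return x, free["dt_ms"]


def fit_dt_regression(
    trials: pd.DataFrame, standardize: bool = True, vif_cap: float = 5.0,
) -> DTRegressionResult:
    """OLS of free-choice decision times on state, |value difference|, their
    interaction and best side.  Raises on a rank-deficient design; warns via
    ValueError if any VIF exceeds ``vif_cap``."""
    x, y = _design(trials, standardize)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient decision-time design")
    model = sm.OLS(y.to_numpy(dtype=float), x.to_numpy()).fit()
    vif = pd.Series(
        [variance_inflation_factor(x.to_numpy(), i) for i in range(1, x.shape[1])],
        index=x.columns[1:])
    if (vif > vif_cap).any():
        raise ValueError(f"variance inflation exceeds cap {vif_cap}: {vif.to_dict()}")
    params = pd.Series(model.params, index=x.columns)
    pvals = pd.Series(model.pvalues, index=x.columns)
    return DTRegressionResult(params, pvals, vif, int(model.nobs), standardize)


def fit_forced_rt_regression(trials: pd.DataFrame, standardize: bool = True) -> DTRegressionResult:
    """Forced-trial response-time model: value level in place of |dv|."""
    forced = trials[trials["trial_type"] == "forced"]
    if len(forced) < 10:
        raise ValueError("too few forced trials")
    state = forced["state"].to_numpy() * 2 - 1
    value = forced["left_value"].to_numpy(dtype=float)
    if standardize:
        value = sps.zscore(value)
    x = pd.DataFrame({"state": state, "value": value, "state_x_value": state * value},
                     index=forced.index)
    x.insert(0, "const", 1.0)
    model = sm.OLS(forced["dt_ms"].to_numpy(dtype=float), x.to_numpy()).fit()
    vif = pd.Series(
        [variance_inflation_factor(x.to_numpy(), i) for i in range(1, x.shape[1])],
        index=x.columns[1:])
    return DTRegressionResult(pd.Series(model.params, index=x.columns),
                              pd.Series(model.pvalues, index=x.columns),
                              vif, int(model.nobs), standardize)
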