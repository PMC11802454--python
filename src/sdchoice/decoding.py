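"""Bootstrapped within- and cross-state value decoding with PCA
preprocessing and neuron-dropping curves.

Each bootstrap draws a balanced pseudo-population sample (20 trials x 4
values x 2 states = 160 trials), standardises the choice-epoch spike counts
and reduces them by PCA retaining 95% variance.  The PCA is fit across all
160 trials so every fold shares one PC space; this leaks marginal feature
statistics into the test fold, and a leakage-free per-fold variant is
available via ``pca_on_train=True``.  One linear max-margin multiclass decoder
(one-vs-one, C=1) is trained per state under a stratified leave-one-out
split: one trial of each value level is held out, the state decoder is
trained on the remaining 19 per value (76 trials), within-state accuracy is
scored on its own 4 held-out trials and cross-state accuracy on the other
state's 4 held-out trials.  Chance is 0.25 for 4 value classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .session import Session, code_values
from .stats import boot_ci
from .tuning import DEFAULT_EPOCHS, EpochSpec, epoch_rates

CHANCE = 0.25


@dataclass
class DecodeConfig:
    trials_per_value: int = 20
    n_boot: int = 1000
    var_retained: float = 0.95
    c: float = 1.0
    drop_step: int = 5
    pca_on_train: bool = False


def _epoch_counts(session: Session, epochs: EpochSpec,
                  unit_ids: np.ndarray) -> np.ndarray:
    ev = session.event_times_s(epochs.choice.event)
    return np.column_stack([
        epoch_rates(session.spikes[int(n)], ev, epochs.choice)
        for n in unit_ids])


def _condition_pools(session: Session, trials_per_value: int) -> dict:
    v = code_values(session.trials["chosen_value"].to_numpy())
    s = session.trials["state"].to_numpy()
    pools = {}
    for st in (0, 1):
        for vc in (-2.0, -1.0, 1.0, 2.0):
            rows = np.flatnonzero((s == st) & (v == vc))
            if rows.size < trials_per_value:
                raise ValueError(
                    f"state {st} value {vc}: {rows.size} trials < {trials_per_value}")
            pools[(st, vc)] = rows
    return pools


def _one_bootstrap(
    x: np.ndarray, pools: dict, config: DecodeConfig, rng: np.random.Generator,
) -> dict[str, float]:
    m = config.trials_per_value
    feats, states, labels = [], [], []
    for (st, vc), rows in pools.items():
        pick = rng.choice(rows, size=m, replace=False)
        feats.append(x[pick])
        states.append(np.full(m, st))
        labels.append(np.full(m, vc))
    feats = np.vstack(feats)
    states = np.concatenate(states)
    labels = np.concatenate(labels)
    order = np.arange(feats.shape[0])

    # stratified leave-one-out: hold out one trial of each value in each state
    held = {}
    train_mask = np.ones(feats.shape[0], dtype=bool)
    for st in (0, 1):
        idxs = []
        for vc in (-2.0, -1.0, 1.0, 2.0):
            cand = order[(states == st) & (labels == vc)]
            h = rng.choice(cand)
            idxs.append(h)
            train_mask[h] = False
        held[st] = np.array(idxs)

    if config.pca_on_train:
        scaler = StandardScaler().fit(feats[train_mask])
        z = scaler.transform(feats)
        pca = PCA(n_components=config.var_retained, svd_solver="full").fit(z[train_mask])
    else:
        scaler = StandardScaler().fit(feats)
        z = scaler.transform(feats)
        pca = PCA(n_components=config.var_retained, svd_solver="full").fit(z)
    proj = pca.transform(z)

    out = {}
    models = {}
    for st in (0, 1):
        tr = train_mask & (states == st)
        clf = SVC(kernel="linear", C=config.c, decision_function_shape="ovo")
        clf.fit(proj[tr], labels[tr])
        models[st] = clf
    for st in (0, 1):
        same = held[st]
        other = held[1 - st]
        out[f"within_{st}"] = float(np.mean(models[st].predict(proj[same]) == labels[same]))
        out[f"cross_{st}"] = float(np.mean(models[st].predict(proj[other]) == labels[other]))
    out["within"] = (out["within_0"] + out["within_1"]) / 2
    out["cross"] = (out["cross_0"] + out["cross_1"]) / 2
    return out


def bootstrap_decode(
    session: Session, config: DecodeConfig = DecodeConfig(),
    seed: int | np.random.Generator = 0, epochs: EpochSpec = DEFAULT_EPOCHS,
    unit_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bootstrap within- and cross-state decoding accuracies."""
    rng = np.random.default_rng(seed)
    units = session.retained_units()
    if unit_ids is None:
        unit_ids = units["neuron_id"].to_numpy()
    x = _epoch_counts(session, epochs, unit_ids)
    pools = _condition_pools(session, config.trials_per_value)
    rows = [_one_bootstrap(x, pools, config, rng) for _ in range(config.n_boot)]
    return pd.DataFrame(rows)


def summarize_accuracies(boot: pd.DataFrame) -> dict:
    out = {}
    for key in ("within", "cross"):
        vals = boot[key].to_numpy()
        lo, hi = boot_ci(vals)
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_lo"] = lo
        out[f"{key}_hi"] = hi
    return out


def neuron_dropping(
    session: Session, config: DecodeConfig = DecodeConfig(),
    seed: int | np.random.Generator = 0, epochs: EpochSpec = DEFAULT_EPOCHS,
    max_neurons: int | None = None,
) -> pd.DataFrame:
    """Decoding accuracy as a function of the number of included neurons.

    For each population size N (steps of ``drop_step``) both the neuron
    subset and the trials are re-bootstrapped.  Returns one row per N with
    mean and bootstrap CI for within- and cross-state accuracy.
    """
    rng = np.random.default_rng(seed)
    units = session.retained_units()["neuron_id"].to_numpy()
    if config.drop_step > units.size:
        raise ValueError("drop step exceeds population size")
    x = _epoch_counts(session, epochs, units)
    pools = _condition_pools(session, config.trials_per_value)
    top = units.size if max_neurons is None else min(max_neurons, units.size)
    curve = []
    for n in range(config.drop_step, top + 1, config.drop_step):
        rows = []
        for _ in range(config.n_boot):
            sub = rng.choice(units.size, size=n, replace=False)
            rows.append(_one_bootstrap(x[:, sub], pools, config, rng))
        boot = pd.DataFrame(rows)
        rec = {"n_neurons": n}
        rec.update(summarize_accuracies(boot))
        curve.append(rec)
    return pd.DataFrame(curve)
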