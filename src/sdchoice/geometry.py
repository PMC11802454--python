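"""Population state-space geometry: the state-value PC space, bootstrap
condition means, and alignment of per-state value manifolds by rigid rotation.

The condition-mean matrix holds each neuron's mean choice-epoch rate in the
8 task conditions (state-major, value-minor order).  PCA treats the 8
conditions as observations and neurons as features (column-mean centred; an
optional per-neuron z-scoring exists but is off by default, because scaling
every neuron to unit condition-variance inflates the sampling noise of
untuned neurons until it can bury the value plane) and keeps the smallest
number of components whose cumulative explained variance reaches 95%.

Within each bootstrap the 4 value points of each state are summarised by a
value axis (first principal direction of the 4 points, oriented so projected
value increases).  The rigid rotation is a Givens rotation in the plane
spanned by the two value axes — the unique minimal rotation carrying one axis
onto the other, acting as the identity on the orthogonal complement — applied
to state B's centred value points; the rotation angle is chosen by bounded
1-D search of the RMSE to state A's centred points.  Axis-orientation
ambiguity is removed by folding all angles into [0, 90] degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .session import Session, code_values
from .stats import boot_ci
from .tuning import DEFAULT_EPOCHS, EpochSpec, epoch_rates

VALUE_CODES = (-2.0, -1.0, 1.0, 2.0)
N_CONDITIONS = 8  # 2 states x 4 values, state-major column order


# ----------------------------------------------------------- condition means

def condition_mean_matrix(
    session: Session, epochs: EpochSpec = DEFAULT_EPOCHS,
    trial_subset: np.ndarray | None = None,
) -> np.ndarray:
    """(neurons x 8) mean choice-epoch rates per (state, value) condition."""
    trials = session.trials if trial_subset is None else session.trials.iloc[trial_subset]
    ev = (trials["t_start_s"] + trials[epochs.choice.event] / 1000.0).to_numpy()
    v = code_values(trials["chosen_value"].to_numpy())
    s = trials["state"].to_numpy()
    units = session.retained_units()
    rates = np.column_stack([
        epoch_rates(session.spikes[int(n)], ev, epochs.choice)
        for n in units["neuron_id"]])
    cols = []
    for st in (0, 1):
        for vc in VALUE_CODES:
            sel = (s == st) & (v == vc)
            if not sel.any():
                raise ValueError(f"no trials for state {st}, value code {vc}")
            cols.append(rates[sel].mean(axis=0))
    return np.column_stack(cols)  # neurons x 8


def condition_mean_sems(
    session: Session, epochs: EpochSpec = DEFAULT_EPOCHS,
) -> np.ndarray:
    """(neurons x 8) standard errors of the condition-mean rates."""
    trials = session.trials
    ev = (trials["t_start_s"] + trials[epochs.choice.event] / 1000.0).to_numpy()
    v = code_values(trials["chosen_value"].to_numpy())
    s = trials["state"].to_numpy()
    units = session.retained_units()
    rates = np.column_stack([
        epoch_rates(session.spikes[int(n)], ev, epochs.choice)
        for n in units["neuron_id"]])
    cols = []
    for st in (0, 1):
        for vc in VALUE_CODES:
            sel = (s == st) & (v == vc)
            if sel.sum() < 2:
                raise ValueError(f"state {st}, value {vc}: too few trials for a SEM")
            cols.append(rates[sel].std(axis=0, ddof=1) / np.sqrt(sel.sum()))
    return np.column_stack(cols)


def condition_trial_indices(session: Session) -> dict[tuple[int, float], np.ndarray]:
    v = code_values(session.trials["chosen_value"].to_numpy())
    s = session.trials["state"].to_numpy()
    return {(st, vc): np.flatnonzero((s == st) & (v == vc))
            for st in (0, 1) for vc in VALUE_CODES}


# ------------------------------------------------------------------ PC space

@dataclass
class PCSpace:
    components: np.ndarray      # (k, n_neurons)
    mean: np.ndarray            # feature means of the fitted matrix
    z_mean: np.ndarray          # per-neuron standardisation
    z_std: np.ndarray
    explained_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def project(self, cond_matrix: np.ndarray) -> np.ndarray:
        """Project a (neurons x conditions) matrix; returns (conditions x k)."""
        z = (cond_matrix - self.z_mean[:, None]) / self.z_std[:, None]
        return (z.T - self.mean) @ self.components.T


def build_pc_space(
    cond_matrix: np.ndarray, var_retained: float = 0.95, zscore: bool = False,
    min_components: int = 2, noise_sem: np.ndarray | None = None,
    n_null: int = 200, seed: int | np.random.Generator = 0,
) -> PCSpace:
    """PCA of the condition-mean matrix (conditions as observations).

    Dimensionality: the smallest k reaching ``var_retained`` cumulative
    variance, floored at ``min_components`` (a rotation analysis is undefined
    in fewer than two dimensions).  When ``noise_sem`` (neurons x conditions
    standard errors of the condition means) is given, retention is instead
    decided by parallel analysis: beyond the first component, a PC is kept
    only while its variance also exceeds the 95th percentile of the *top*
    eigenvalue of matched condition-mean noise.  This stops a pure-noise
    dimension (which PCA, by construction, concentrates into the leading
    residual PC) from masquerading as a second value direction, while a
    genuine low-variance signal direction comfortably clears the threshold.
    """
    m = np.asarray(cond_matrix, dtype=float)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    if m.shape[0] < N_CONDITIONS:
        raise ValueError("need at least 8 neurons for the 8-condition space")
    z_mean = m.mean(axis=1)
    z_std = m.std(axis=1, ddof=0)
    if not zscore:
        z_mean = np.zeros(m.shape[0])
        z_std = np.ones(m.shape[0])
    z_std = np.where(z_std > 0, z_std, 1.0)
    z = ((m - z_mean[:, None]) / z_std[:, None]).T  # conditions x neurons
    mean = z.mean(axis=0)
    zc = z - mean
    u, sv, vt = np.linalg.svd(zc, full_matrices=False)
    var = sv ** 2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    k = int(np.searchsorted(np.cumsum(ratio), var_retained) + 1)
    if noise_sem is None:
        k = int(np.clip(k, min_components, len(ratio)))
    else:
        rng = np.random.default_rng(seed)
        sem = np.asarray(noise_sem, dtype=float) / z_std[:, None]
        tops = np.empty(n_null)
        for b in range(n_null):
            e = (rng.standard_normal(sem.shape) * sem).T
            ec = e - e.mean(axis=0)
            tops[b] = np.linalg.svd(ec, compute_uv=False)[0] ** 2
        thresh = np.percentile(tops, 95)
        k = 1
        while k < len(var) and var[k] > thresh:
            k += 1
    return PCSpace(vt[:k], mean, z_mean, z_std, ratio)


def bootstrap_project(
    session: Session, space: PCSpace, n_boot: int = 1000,
    trials_per_cond: int = 20, seed: int | np.random.Generator = 0,
    epochs: EpochSpec = DEFAULT_EPOCHS,
) -> np.ndarray:
    """Bootstrap condition coordinates: per iteration, ``trials_per_cond``
    trials of each condition are drawn (without replacement), averaged and
    projected into the fixed basis.  Returns (n_boot, 8, k)."""
    rng = np.random.default_rng(seed)
    idx = condition_trial_indices(session)
    for cond, rows in idx.items():
        if rows.size < trials_per_cond:
            raise ValueError(
                f"condition {cond} has {rows.size} trials, fewer than {trials_per_cond}")
    units = session.retained_units()
    ev = session.event_times_s(epochs.choice.event)
    rates = np.column_stack([
        epoch_rates(session.spikes[int(n)], ev, epochs.choice)
        for n in units["neuron_id"]])  # trials x neurons
    out = np.empty((n_boot, N_CONDITIONS, space.k))
    conds = [(st, vc) for st in (0, 1) for vc in VALUE_CODES]
    for b in range(n_boot):
        cols = []
        for cond in conds:
            rows = idx[cond]
            pick = rng.choice(rows, size=min(trials_per_cond, rows.size), replace=False)
            cols.append(rates[pick].mean(axis=0))
        out[b] = space.project(np.column_stack(cols))
    return out


# ------------------------------------------------------------- rotation core

def value_axis(points: np.ndarray, definition: str = "fit") -> np.ndarray:
    """Unit vector summarising 4 value points in PC space.

    ``fit``: first principal direction of the points; ``chord``: highest
    minus lowest value point.  Oriented so the projection of value increases.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] != 4:
        raise ValueError("expected 4 value points")
    if np.allclose(pts, pts[0]):
        raise ValueError("coincident value points: axis undefined")
    if definition == "chord":
        axis = pts[-1] - pts[0]
    elif definition == "fit":
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        axis = vt[0]
    else:
        raise ValueError("definition must be 'fit' or 'chord'")
    axis = axis / np.linalg.norm(axis)
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis


def _fold_deg(angle: float) -> float:
    """Fold an angle to [0, 90] degrees (axis-orientation ambiguity)."""
    a = abs(angle) % 180.0
    return min(a, 180.0 - a)


def _plane_rotation(e1: np.ndarray, e2: np.ndarray, phi: float) -> np.ndarray:
    """Givens rotation by ``phi`` (radians) in the plane (e1, e2); identity on
    the orthogonal complement."""
    k = e1.size
    outer11 = np.outer(e1, e1) + np.outer(e2, e2)
    outer21 = np.outer(e2, e1) - np.outer(e1, e2)
    return np.eye(k) + (np.cos(phi) - 1.0) * outer11 + np.sin(phi) * outer21


@dataclass
class RotationFit:
    axis_angle_deg: float        # folded angle between the two value axes
    rotation_deg: float          # folded RMSE-optimal rotation angle
    rotation_signed_deg: float
    rmse_before: float
    rmse_after: float
    axis_a: np.ndarray = field(repr=False, default=None)
    axis_b: np.ndarray = field(repr=False, default=None)


def rigid_align(
    points_a: np.ndarray, points_b: np.ndarray,
    axis_definition: str = "fit", tol_deg: float = 0.1,
) -> RotationFit:
    """Align state-B value points to state-A points by planar rigid rotation.

    Both point sets are centred on their own centroids (a rotation cannot
    absorb the state-mean offset).  The rotation plane is spanned by the two
    value axes; the angle minimising the RMSE between rotated B points and A
    points is located by coarse grid + bounded refinement over
    [-180, 180] degrees to ``tol_deg``.  Post-rotation RMSE can never exceed
    the pre-rotation RMSE (zero rotation is in the search set).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    ax_a = value_axis(a, axis_definition)
    ax_b = value_axis(b, axis_definition)
    cosang = float(np.clip(np.dot(ax_a, ax_b), -1.0, 1.0))
    axis_angle = _fold_deg(np.degrees(np.arccos(cosang)))
    if cosang < 0:  # fold axis B so the plane basis is well conditioned
        ax_b = -ax_b
        cosang = -cosang
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    perp = ax_b - cosang * ax_a
    nperp = np.linalg.norm(perp)
    rmse_before = float(np.sqrt(np.mean(np.sum((bc - ac) ** 2, axis=1))))
    if nperp < 1e-9:
        # axes (anti-)parallel after folding: plane undefined, nothing to rotate
        return RotationFit(axis_angle, 0.0, 0.0, rmse_before, rmse_before, ax_a, ax_b)
    e1, e2 = ax_a, perp / nperp

    def rmse(phi_deg: float) -> float:
        r = _plane_rotation(e1, e2, np.radians(phi_deg))
        return float(np.sqrt(np.mean(np.sum((bc @ r.T - ac) ** 2, axis=1))))

    grid = np.arange(-180.0, 180.0 + 1e-9, 1.0)
    vals = [rmse(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        rmse, bounds=(max(-180.0, g0 - 2.0), min(180.0, g0 + 2.0)),
        method="bounded", options={"xatol": tol_deg / 2})
    phi = float(res.x)
    best = min((rmse(phi), phi), (min(vals), g0), (rmse_before, 0.0))
    rmse_after, phi = best
    return RotationFit(axis_angle, _fold_deg(phi), phi,
                       rmse_before, float(rmse_after), ax_a, ax_b)


def optimal_rotation_closed_form(
    points_a: np.ndarray, points_b: np.ndarray, axis_definition: str = "fit",
) -> float:
    """Closed-form RMSE-optimal planar rotation angle (degrees, signed).

    Independent of the search path in :func:`rigid_align`: the in-plane
    Procrustes solution ``phi* = atan2(c2, c1)`` with
    ``c1 = sum <P b_i, P a_i>`` and ``c2 = sum <Q b_i, P a_i>`` where P
    projects onto the plane and Q is P followed by a 90-degree in-plane turn.
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    ax_a = value_axis(a, axis_definition)
    ax_b = value_axis(b, axis_definition)
    cosang = float(np.clip(np.dot(ax_a, ax_b), -1.0, 1.0))
    if cosang < 0:
        ax_b, cosang = -ax_b, -cosang
    perp = ax_b - cosang * ax_a
    if np.linalg.norm(perp) < 1e-9:
        return 0.0
    e1, e2 = ax_a, perp / np.linalg.norm(perp)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    b1, b2 = bc @ e1, bc @ e2
    a1, a2 = ac @ e1, ac @ e2
    c1 = float(np.sum(b1 * a1 + b2 * a2))
    c2 = float(np.sum(b1 * a2 - b2 * a1))
    return float(np.degrees(np.arctan2(c2, c1)))


# --------------------------------------------------------- session-level API

@dataclass
class ManifoldAlignmentResult:
    space: PCSpace
    per_boot: pd.DataFrame       # axis_angle_deg, rotation_deg, rmse_before/after
    mean_rotation_deg: float
    ci: tuple[float, float]

    def summary(self) -> dict:
        return {"mean_rotation_deg": self.mean_rotation_deg,
                "ci_lo": self.ci[0], "ci_hi": self.ci[1],
                "n_boot": len(self.per_boot), "k": self.space.k}


def align_session_manifolds(
    session: Session, n_boot: int = 1000, trials_per_cond: int = 20,
    seed: int | np.random.Generator = 0, var_retained: float = 0.95,
    axis_definition: str = "fit", zscore: bool = False,
    epochs: EpochSpec = DEFAULT_EPOCHS,
) -> ManifoldAlignmentResult:
    """Full geometry stage for one (sub)session: basis from the full-data
    condition means (with parallel-analysis dimensionality), bootstrap
    projections, rigid alignment per bootstrap."""
    cm = condition_mean_matrix(session, epochs)
    sem = condition_mean_sems(session, epochs)
    space = build_pc_space(cm, var_retained, zscore, noise_sem=sem, seed=seed)
    coords = bootstrap_project(session, space, n_boot, trials_per_cond, seed, epochs)
    rows = []
    for b in range(coords.shape[0]):
        fit = rigid_align(coords[b, :4], coords[b, 4:], axis_definition)
        rows.append({"boot": b, "axis_angle_deg": fit.axis_angle_deg,
                     "rotation_deg": fit.rotation_deg,
                     "rmse_before": fit.rmse_before, "rmse_after": fit.rmse_after})
    per_boot = pd.DataFrame(rows)
    angles = per_boot["rotation_deg"].to_numpy()
    ci = boot_ci(angles) if len(angles) > 1 else (np.nan, np.nan)
    return ManifoldAlignmentResult(space, per_boot, float(angles.mean()), ci)


def compare_rotation_areas(res1: ManifoldAlignmentResult,
                           res2: ManifoldAlignmentResult) -> dict:
    """CI-overlap comparison of rotation angles between two populations."""
    if len(res1.per_boot) != len(res2.per_boot):
        raise ValueError("bootstrap counts differ between areas")
    if len(res1.per_boot) < 2:
        raise ValueError("CI undefined with fewer than 2 bootstraps")
    lo1, hi1 = res1.ci
    lo2, hi2 = res2.ci
    disjoint = hi1 < lo2 or hi2 < lo1
    return {"mean_1": res1.mean_rotation_deg, "ci_1": res1.ci,
            "mean_2": res2.mean_rotation_deg, "ci_2": res2.ci,
            "disjoint": bool(disjoint)}
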