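"""Shared statistical helpers: subsample-bootstrap CIs, circular statistics,
and the Fisher r-to-z comparison of two correlations.

The bootstrap scheme used throughout the package resamples 80% of the data
without replacement in each of ``n_boot`` iterations and reports the 5th and
95th percentiles of the resulting distribution (bootstrap-percentile).
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "boot_ci",
    "subsample_bootstrap",
    "rayleigh_test",
    "resultant_length",
    "circular_mean",
    "fisher_r_to_z",
]


def boot_ci(values: np.ndarray) -> tuple[float, float]:
    """5th/95th percentiles of a bootstrap distribution."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("confidence interval undefined for fewer than 2 bootstrap values")
    return float(np.percentile(values, 5)), float(np.percentile(values, 95))


def subsample_bootstrap(
    data: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    frac: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bootstrap a statistic over draws of ``frac`` of the rows (with
    replacement, i.e. a bootstrap of 80% size under the defaults).

    Returns ``(point_estimate, (ci_lo, ci_hi), boot_values)`` where the point
    estimate is the statistic on the full data and the CI holds the 5th/95th
    percentiles of the resample distribution.
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(data)
    n = data.shape[0]
    k = max(1, int(round(frac * n)))
    boots = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        idx = rng.choice(n, size=k, replace=True)
        boots[b] = statistic(data[idx])
    return float(statistic(data)), boot_ci(boots), boots


def resultant_length(phases: np.ndarray) -> float:
    """Mean resultant vector length R of a set of phase angles (radians)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("R undefined for an empty phase set")
    return float(np.abs(np.exp(1j * phases).mean()))


def circular_mean(phases: np.ndarray) -> float:
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular mean undefined for an empty phase set")
    return float(np.angle(np.exp(1j * phases).mean()))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p)`` with Z = n * R**2 and the standard small-sample
    correction to the p-value (Zar, Biostatistical Analysis):
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with ``Rn = n * R``.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise ValueError("Rayleigh test undefined for zero spikes")
    r = resultant_length(phases)
    z = n * r * r
    rn = n * r
    p = np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's r-to-z.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``; two-sided p.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("Fisher z comparison requires at least 4 observations per group")
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
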