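"""The Session container: trial table, spike trains, LFP traces and the
ground-truth sidecar, plus disk round-tripping and structural validation.

A session is the universal input to every analysis stage.  Times follow one
convention throughout: the session clock is in seconds, per-trial event times
are millisecond offsets from trial start, and every analysis window is
half-open ``[start, end)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RATE_FLOOR_HZ = 1.0  # units below this mean session rate are excluded

TRIAL_EVENT_COLS = ["fix_on_ms", "cue_on_ms", "choice_on_ms", "response_ms"]


@dataclass
class Session:
    """A recorded (or simulated) session.

    Attributes
    ----------
    trials : DataFrame with one row per trial.  Required columns:
        ``trial, state, cue, cue_id, trial_type, left_value, right_value,
        chosen_value, correct, dt_ms, t_start_s`` and the event offsets
        ``fix_on_ms, cue_on_ms, choice_on_ms, response_ms`` (ms from trial
        start).  ``state`` is 0 (A) or 1 (B).
    units : DataFrame with ``neuron_id, area, probe, channel``.
    spikes : dict mapping neuron_id -> sorted spike times in seconds.
    lfp : float array (n_channels, n_samples) at ``fs`` Hz.
    channels : DataFrame with ``channel_id, area, probe``.
    ground_truth : optional sidecar of planted simulation parameters.
    """

    trials: pd.DataFrame
    units: pd.DataFrame
    spikes: dict[int, np.ndarray]
    lfp: np.ndarray
    channels: pd.DataFrame
    fs: float = 1000.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs

    def event_times_s(self, event: str) -> np.ndarray:
        """Absolute session-clock times (s) of a named per-trial event."""
        if event not in TRIAL_EVENT_COLS:
            raise KeyError(f"unknown event column {event!r}")
        return (self.trials["t_start_s"] + self.trials[event] / 1000.0).to_numpy()

    def state_codes(self) -> np.ndarray:
        """Task state coded -1 (state A) / +1 (state B)."""
        return self.trials["state"].to_numpy() * 2 - 1

    def coded_values(self) -> np.ndarray:
        """Chosen-option value on the symmetric -2,-1,1,2 scale."""
        return code_values(self.trials["chosen_value"].to_numpy())

    def mean_rates(self) -> pd.Series:
        dur = self.duration_s
        return pd.Series(
            {nid: len(self.spikes[nid]) / dur for nid in self.units["neuron_id"]},
            name="rate_hz",
        )

    def retained_units(self, floor_hz: float = RATE_FLOOR_HZ) -> pd.DataFrame:
        """Units whose mean session rate reaches the retention floor."""
        rates = self.mean_rates()
        keep = [nid for nid in self.units["neuron_id"] if rates[nid] >= floor_hz]
        return self.units[self.units["neuron_id"].isin(keep)].reset_index(drop=True)

    # ------------------------------------------------------------------ I/O

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.units.to_csv(outdir / "units.csv", index=False)
        self.channels.to_csv(outdir / "channels.csv", index=False)
        rows = []
        for nid, times in self.spikes.items():
            area = self.units.set_index("neuron_id").loc[nid, "area"]
            rows.append(pd.DataFrame({"neuron_id": nid, "area": area, "spike_time_s": times}))
        spikes = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["neuron_id", "area", "spike_time_s"])
        )
        spikes.to_csv(outdir / "spikes.csv", index=False)
        np.save(outdir / "lfp.npy", self.lfp.astype(np.float32))
        meta = {"fs": self.fs, "ground_truth": _jsonable(self.ground_truth)}
        (outdir / "session.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, indir: str | Path) -> "Session":
        indir = Path(indir)
        trials = pd.read_csv(indir / "trials.csv")
        units = pd.read_csv(indir / "units.csv")
        channels = pd.read_csv(indir / "channels.csv")
        spk = pd.read_csv(indir / "spikes.csv")
        spikes = {
            int(nid): np.sort(g["spike_time_s"].to_numpy(dtype=float))
            for nid, g in spk.groupby("neuron_id")
        }
        for nid in units["neuron_id"]:
            spikes.setdefault(int(nid), np.empty(0))
        lfp = np.load(indir / "lfp.npy").astype(float)
        meta = json.loads((indir / "session.json").read_text())
        return cls(trials, units, spikes, lfp, channels,
                   fs=float(meta["fs"]), ground_truth=meta.get("ground_truth", {}))


def code_values(drops: np.ndarray) -> np.ndarray:
    """Map juice-drop amounts (4 ordered levels) to the -2,-1,1,2 code."""
    levels = np.unique(drops[np.isfinite(drops)])
    if levels.size > 4:
        raise ValueError(f"expected at most 4 value levels, got {levels.size}")
    code_of = {1: -2, 2: -1, 3: 1, 4: 2}
    if set(levels).issubset(code_of):
        return np.vectorize(lambda v: code_of[v])(drops).astype(float)
    # generic ordered mapping for nonstandard level sets
    codes = np.array([-2.0, -1.0, 1.0, 2.0])[: levels.size]
    lut = {lv: c for lv, c in zip(levels, codes)}
    return np.vectorize(lut.get)(drops).astype(float)


def validate_session(session: Session, rate_floor_hz: float = RATE_FLOOR_HZ) -> dict:
    """Structural validation; diagnoses, never mutates.

    Checks per-trial event ordering, spike-time bounds, LFP coverage of the
    widest aligned analysis window, and flags units below the rate floor.
    """
    problems: list[str] = []
    flags: list[str] = []
    t = session.trials
    order = np.column_stack([t[c].to_numpy(dtype=float) for c in TRIAL_EVENT_COLS])
    bad = np.where(np.diff(order, axis=1) <= 0)[0]
    for i in np.unique(bad):
        problems.append(f"trial {int(t['trial'].iloc[i])}: event times not strictly ordered")
    dur = session.duration_s
    for nid, times in session.spikes.items():
        if times.size and (times.min() < 0 or times.max() > dur):
            problems.append(f"neuron {nid}: spike time outside session bounds [0, {dur:.3f}] s")
        if times.size > 1 and np.any(np.diff(times) < 0):
            problems.append(f"neuron {nid}: spike times not sorted")
    # aligned-window coverage: 1 s before fixation to 1 s after response
    starts = session.event_times_s("fix_on_ms") - 1.0
    stops = session.event_times_s("response_ms") + 1.0
    if starts.min() < 0 or stops.max() > dur:
        problems.append("trial-aligned windows not fully covered by the continuous LFP trace")
    rates = session.mean_rates()
    for nid, r in rates.items():
        if r < rate_floor_hz:
            flags.append(f"neuron {nid}: mean rate {r:.2f} Hz below {rate_floor_hz} Hz floor, "
                         "flagged for exclusion")
    return {"ok": not problems, "problems": problems, "flags": flags}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
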