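"""Pipeline orchestration: run every analysis stage over one session, with
per-stage seed derivation, failure isolation and a consolidated report.

The report ends with a dissociation scorecard summarising the area contrast
the analyses target: state-coding prevalence by epoch (HPC early, OFC at
choice), per-area value-beta correlations across states, per-area manifold
rotation angles, within/cross-state decoding, net theta directionality and
phase-locking contrasts.
"""
from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, connectivity, decoding, geometry, phase, spikephase, tuning
from .session import Session, validate_session
from .tuning import DEFAULT_EPOCHS, EpochSpec
from .phase import DEFAULT_BANDS, BandSpec

log = logging.getLogger("sdchoice")

STAGES = ("behavior", "tuning", "geometry", "decoding", "lfp", "connectivity",
          "spike_phase")


@dataclass
class RunConfig:
    seed: int = 0
    epochs: EpochSpec = field(default_factory=EpochSpec)
    bands: BandSpec = field(default_factory=BandSpec)
    n_boot_geometry: int = 200
    n_boot_decode: int = 200
    n_boot_gpdc: int = 200
    trials_per_cond: int = 20
    run_neuron_dropping: bool = False
    drop_boot: int = 50
    stages: tuple[str, ...] = STAGES
    out_dir: str | None = None


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def run_pipeline(session: Session, config: RunConfig = RunConfig()) -> dict:
    """Execute all enabled stages in dependency order.

    Every stochastic stage receives a logged sub-seed derived from
    ``config.seed``; a stage failure is recorded (with traceback) and its
    dependents are skipped with a reason.
    """
    seeds = _stage_seeds(config.seed)
    report: dict = {"config": {"seed": config.seed, "stage_seeds": seeds},
                    "stages": {}}
    diag = validate_session(session)
    report["validation"] = diag
    if not diag["ok"]:
        raise ValueError(f"session failed validation: {diag['problems']}")

    def run(name, fn, *deps):
        if name not in config.stages:
            report["stages"][name] = {"status": "skipped", "reason": "toggled off"}
            return None
        for d in deps:
            st = report["stages"].get(d, {})
            if st.get("status") != "ok":
                report["stages"][name] = {
                    "status": "skipped", "reason": f"dependency {d} not available"}
                return None
        try:
            out = fn()
            report["stages"][name] = {"status": "ok", "result": out}
            return out
        except Exception as exc:  # isolate per stage
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc),
                                      "traceback": traceback.format_exc()}
            return None

    run("behavior", lambda: _behavior_stage(session))
    run("tuning", lambda: _tuning_stage(session, config))
    run("geometry", lambda: _geometry_stage(session, config, seeds["geometry"]))
    run("decoding", lambda: _decoding_stage(session, config, seeds["decoding"]))
    lfp_out = run("lfp", lambda: _lfp_stage(session, config))
    run("connectivity",
        lambda: _connectivity_stage(session, config, seeds["connectivity"], lfp_out),
        "lfp")
    run("spike_phase", lambda: _spike_phase_stage(session, config, seeds["spike_phase"]))

    report["scorecard"] = build_scorecard(report)
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


# ------------------------------------------------------------------- stages

def _behavior_stage(session: Session) -> dict:
    acc = behavior.accuracy_by_state(session.trials)
    dt = behavior.fit_dt_regression(session.trials)
    return {"accuracy": acc,
            "dt_regression": {"beta": dt.params.to_dict(),
                              "p": dt.pvalues.to_dict(),
                              "vif": dt.vif.to_dict(), "n": dt.n}}


def _tuning_stage(session: Session, config: RunConfig) -> dict:
    anova = tuning.sliding_anova_session(session, config.epochs)
    prev = tuning.prevalence_timecourse(anova, "state")
    epoch_model = tuning.fit_choice_epoch_model(session, config.epochs)
    sv = tuning.state_conditional_value_betas(session, config.epochs)
    try:
        corr = tuning.compare_beta_correlations(sv)
    except ValueError as exc:  # too few value-coding neurons in an area
        corr = {"error": str(exc)}
    return {"anova": anova, "prevalence": prev, "epoch_model": epoch_model,
            "state_value": sv, "beta_correlations": corr}


def _area_subsession(session: Session, area: str) -> Session:
    units = session.units[session.units["area"] == area].reset_index(drop=True)
    spikes = {int(n): session.spikes[int(n)] for n in units["neuron_id"]}
    return Session(session.trials, units, spikes, session.lfp, session.channels,
                   session.fs, session.ground_truth)


def _geometry_stage(session: Session, config: RunConfig, seed: int) -> dict:
    out = {}
    results = {}
    for i, area in enumerate(("HPC", "OFC")):
        sub = _area_subsession(session, area)
        res = geometry.align_session_manifolds(
            sub, n_boot=config.n_boot_geometry,
            trials_per_cond=config.trials_per_cond, seed=seed + i,
            epochs=config.epochs)
        results[area] = res
        out[area] = res.summary()
        out[area]["per_boot"] = res.per_boot
    out["comparison"] = geometry.compare_rotation_areas(results["HPC"], results["OFC"])
    return out


def _decoding_stage(session: Session, config: RunConfig, seed: int) -> dict:
    dc = decoding.DecodeConfig(trials_per_value=config.trials_per_cond,
                               n_boot=config.n_boot_decode)
    out = {}
    for i, area in enumerate(("HPC", "OFC")):
        sub = _area_subsession(session, area)
        boot = decoding.bootstrap_decode(sub, dc, seed=seed + i, epochs=config.epochs)
        out[area] = decoding.summarize_accuracies(boot)
        if config.run_neuron_dropping:
            dc_drop = decoding.DecodeConfig(
                trials_per_value=config.trials_per_cond, n_boot=config.drop_boot)
            out[area]["dropping"] = decoding.neuron_dropping(
                sub, dc_drop, seed=seed + 10 + i, epochs=config.epochs)
    return out


def _lfp_stage(session: Session, config: RunConfig) -> dict:
    if session.lfp.shape[0] == 0:
        raise ValueError("session has no LFP channels")
    cues = session.event_times_s("cue_on_ms")
    align = phase.alignment_series(session.lfp, cues, config.bands,
                                   t_range_s=(-0.8, 1.2), fs=session.fs)
    # restrict theta-peak analysis to channels hosting at least one unit
    with_units = sorted(set(session.units["channel"]) &
                        set(session.channels["channel_id"]))
    peaks = phase.first_theta_peak(session.lfp, cues, session.fs,
                                   channels=[int(c) for c in with_units])
    areas = session.channels.set_index("channel_id")["area"].to_dict()
    latency = phase.compare_peak_latencies(peaks, areas)
    theta = align[align["band"] == "theta"]
    peak_r = theta.groupby("channel")["R"].max().to_dict()
    return {"alignment": align, "theta_peaks": peaks, "latency": latency,
            "peak_r": peak_r}


def _connectivity_stage(session: Session, config: RunConfig, seed: int,
                        lfp_out: dict) -> dict:
    chosen, pairs = connectivity.select_pair_channels(
        session.channels, session.units, lfp_out["peak_r"])
    cues = session.event_times_s("cue_on_ms")
    rowof = {int(c): i for i, c in enumerate(session.channels["channel_id"])}
    coh_tc = {}
    net = {}
    for h, o in pairs:
        x = session.lfp[rowof[h]]
        y = session.lfp[rowof[o]]
        cg = connectivity.multitaper_coherogram(
            x, y, session.fs, event_times_s=cues, t_range_s=(-1.0, 2.0))
        coh_tc[(h, o)] = {"times_s": cg.times_s,
                          "theta_z": cg.band_timecourse((4.0, 8.0))}
        segs_x = connectivity.gpdc_window_segments(x, cues, session.fs)
        segs_y = connectivity.gpdc_window_segments(y, cues, session.fs)
        res = connectivity.fit_mvar_gpdc(segs_x, segs_y, session.fs,
                                         n_boot=config.n_boot_gpdc, seed=seed)
        res.granger = connectivity.granger_confirm(segs_x, segs_y, order=res.order)
        net[(h, o)] = res
    mean_net_theta = float(np.mean([r.net_theta for r in net.values()]))
    return {"selected": chosen, "pairs": pairs, "coherence": coh_tc,
            "gpdc": net, "mean_net_theta": mean_net_theta}


def _spike_phase_stage(session: Session, config: RunConfig, seed: int) -> dict:
    table = spikephase.phase_locking_table(
        session, config.bands, config.epochs, seed=seed)
    out = {"table": table}
    for area in ("HPC", "OFC"):
        sub = table[table["area"] == area]
        try:
            out[area] = spikephase.state_phase_contrast(sub)
        except ValueError as exc:
            out[area] = {"error": str(exc)}
    return out


# ----------------------------------------------------------------- scorecard

def build_scorecard(report: dict) -> dict:
    """Summary cells of the dual-area dissociation, traceable to the stage
    outputs they are computed from."""
    card: dict = {}
    st = report["stages"]

    if st.get("tuning", {}).get("status") == "ok":
        r = st["tuning"]["result"]
        prev = r["prevalence"]
        epochs = {"state": ("cue_on_ms", 0.1, 0.5), "choice": ("choice_on_ms", 0.1, 0.5)}
        for name, (align, t0, t1) in epochs.items():
            sel = prev[(prev["alignment"] == align) & (prev["time_s"] >= t0)
                       & (prev["time_s"] <= t1)]
            wide = sel.pivot_table(index="window", columns="area", values="frac")
            pvals = sel.groupby("window")["chi2_p"].first()
            diff = (wide["HPC"] - wide["OFC"]).mean()
            n_sig = int((pvals < 0.05).sum())
            card[f"state_prevalence_{name}_epoch"] = {
                "hpc_minus_ofc": float(diff), "n_sig_windows": n_sig,
                "n_windows": int(len(pvals))}
        card["beta_correlations"] = r["beta_correlations"]

    if st.get("geometry", {}).get("status") == "ok":
        g = st["geometry"]["result"]
        card["rotation"] = {
            "hpc_deg": g["HPC"]["mean_rotation_deg"],
            "hpc_ci": (g["HPC"]["ci_lo"], g["HPC"]["ci_hi"]),
            "ofc_deg": g["OFC"]["mean_rotation_deg"],
            "ofc_ci": (g["OFC"]["ci_lo"], g["OFC"]["ci_hi"]),
            "disjoint": g["comparison"]["disjoint"]}

    if st.get("decoding", {}).get("status") == "ok":
        d = st["decoding"]["result"]
        card["decoding"] = {a: {k: d[a][k] for k in
                                ("within_mean", "cross_mean")} for a in d}

    if st.get("lfp", {}).get("status") == "ok":
        card["theta_peak_latency"] = st["lfp"]["result"]["latency"]

    if st.get("connectivity", {}).get("status") == "ok":
        c = st["connectivity"]["result"]
        card["net_theta_gpdc"] = c["mean_net_theta"]

    if st.get("spike_phase", {}).get("status") == "ok":
        s = st["spike_phase"]["result"]
        card["phase_locking"] = {a: s[a] for a in ("HPC", "OFC") if a in s}
    return card


# --------------------------------------------------------------------- I/O

def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = report["stages"]
    if st.get("tuning", {}).get("status") == "ok":
        r = st["tuning"]["result"]
        r["anova"].to_csv(out / "unit_tuning.csv", index=False)
        r["prevalence"].to_csv(out / "prevalence.csv", index=False)
        r["epoch_model"].to_csv(out / "epoch_models.csv", index=False)
        r["state_value"].to_csv(out / "state_value_betas.csv", index=False)
    if st.get("geometry", {}).get("status") == "ok":
        rows = []
        for area in ("HPC", "OFC"):
            pb = st["geometry"]["result"][area]["per_boot"].copy()
            pb.insert(0, "area", area)
            rows.append(pb)
        pd.concat(rows).to_csv(out / "manifold_alignment.csv", index=False)
    if st.get("spike_phase", {}).get("status") == "ok":
        st["spike_phase"]["result"]["table"].to_csv(
            out / "phase_locking.csv", index=False)
    (out / "scorecard.json").write_text(
        json.dumps(_jsonable(report["scorecard"]), indent=1, default=str))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return None
    return obj
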