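"""Pipeline orchestration: simulate -> preprocess -> features -> analyses.

A :class:`PipelineConfig` carries every stage knob, with defaults equal to the
analysis constants used throughout (blink margins 100/150 ms, Gaussian FWHM
35/235 ms, Savitzky-Golay order 2 / 55 ms frame, 30 deg/s saccade threshold,
300-700 ms dilation window, alpha 0.05, FDR q 0.05, cluster-forming p 0.01,
1000 bootstrap draws, %-change exceedance counts 10/3).  ``run_pipeline``
executes the stages in dependency order into a run directory; every output is
stamped with the config hash and seed, so a rerun with the same config is
idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_cohort as sc
from . import timeseries_stats as tss
from .adaptation_model import bootstrap_washout_prediction, percent_change_latency, to_percent_change
from .experiment_analysis import (SETBREAK_BLOCKS, changepoint_lme,
                                  changepoint_table, recall_split,
                                  setbreak_contrast, subgroup_block_lme)
from .signal_preprocess import calibrate_pupil, preprocess_trial
from .trial_features import FeatureConfig, build_trial_table

log = logging.getLogger("pupiladapt")


@dataclass
class PipelineConfig:
    experiment_id: str = "exp1"
    n_participants: int = 28
    seed: int = 0
    # stage toggles
    run_cluster_test: bool = True
    run_two_state: bool = True
    run_latency: bool = True
    run_setbreak: bool = True
    run_changepoints: bool = True
    run_recall_split: bool = False
    write_timeseries: bool = False
    # preprocessing
    blink_pre_ms: float = 100.0
    blink_post_ms: float = 150.0
    fwhm_kin_ms: float = 35.0
    fwhm_pupil_ms: float = 235.0
    sg_frame_ms: float = 55.0
    sg_order: int = 2
    saccade_threshold: float = 30.0
    # features
    baseline_window_s: float = 1.0
    dilation_window_s: tuple = (0.3, 0.7)
    # statistics
    alpha: float = 0.05
    q: float = 0.05
    cluster_alpha: float = 0.01
    n_perm: int = 10000
    n_boot: int = 1000
    n_required_kinematic: int = 10
    n_required_learning: int = 3
    latency_thresholds: tuple = (40, 50, 60, 70, 80)
    n_first_perturbed: int = 5
    align_window: tuple = (-0.5, 1.5)
    # generator overrides (None -> ParticipantParams defaults)
    generator: dict = field(default_factory=dict)

    _KNOWN = None  # populated below

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("dilation_window_s", "latency_thresholds", "align_window"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _participant_params(cfg: PipelineConfig) -> sc.ParticipantParams:
    gen = dict(cfg.generator)
    pupil_over = gen.pop("pupil", {})
    params = sc.ParticipantParams(**gen) if gen else sc.ParticipantParams()
    if pupil_over:
        params.pupil = dataclasses.replace(params.pupil, **pupil_over)
    return params


def preprocess_cohort(cohort: sc.Cohort, cfg: PipelineConfig) -> dict:
    """Preprocess every trial; returns {participant: [PreprocessedTrial, ...]}."""
    kwargs = dict(fwhm_kin_ms=cfg.fwhm_kin_ms, fwhm_pupil_ms=cfg.fwhm_pupil_ms,
                  sg_frame_ms=cfg.sg_frame_ms, sg_order=cfg.sg_order,
                  saccade_threshold=cfg.saccade_threshold,
                  blink_pre=cfg.blink_pre_ms / 1000.0,
                  blink_post=cfg.blink_post_ms / 1000.0)
    out = {}
    for pdat in cohort.participants:
        calib = calibrate_pupil(
            (blk, stim, ts.pupil_mm) for blk, stim, ts in pdat.light_trials)
        out[pdat.participant] = [
            preprocess_trial(ts, calib, pdat.schedule.eye_distance_mm, **kwargs)
            for ts in pdat.trials]
    return out


def perturbation_contrast(cohort: sc.Cohort, preprocessed: dict,
                          cfg: PipelineConfig):
    """Per-subject mean pupil-velocity traces for unperturbed-baseline vs the
    first ``n_first_perturbed`` perturbation trials, movement-onset locked."""
    sched = cohort.schedule
    reaching = sched.reaching
    b = reaching["B"].to_numpy()
    nz = np.nonzero(b != 0)[0]
    if nz.size == 0:
        raise ValueError("schedule has no perturbation trials")
    first_pert = nz[0]
    block1_end = sched.blocks[0][1]
    base_idx = [i for i in range(block1_end)
                if not reaching["is_channel"].iat[i]]
    pert_idx = [i for i in nz[:cfg.n_first_perturbed * 3]
                if not reaching["is_channel"].iat[i]][:cfg.n_first_perturbed]
    t_grid = None
    rows_a, rows_b = [], []
    for pdat in cohort.participants:
        trials = preprocessed[pdat.participant]
        t_grid, mat_a = tss.align_traces([trials[i] for i in base_idx],
                                         window=cfg.align_window)
        _, mat_b = tss.align_traces([trials[i] for i in pert_idx],
                                    window=cfg.align_window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows_a.append(np.nanmean(mat_a, axis=0))
            rows_b.append(np.nanmean(mat_b, axis=0))
    return t_grid, np.asarray(rows_a), np.asarray(rows_b), int(first_pert)


def _learning_index_matrix(table: pd.DataFrame, schedule) -> np.ndarray:
    """(participants x reaching trials) normalized learning indices, NaN
    off-channel."""
    n = schedule.n_reaching
    pids = sorted(table["participant"].unique())
    mat = np.full((len(pids), n), np.nan)
    for r, pid in enumerate(pids):
        sub = table[table["participant"] == pid]
        ch = sub[sub["is_channel"] & sub["learning_index"].notna()]
        mat[r, ch["reach_index"].to_numpy() - 1] = (
            ch["learning_index"].to_numpy() / schedule.b_full)
    return mat


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "config": config.to_dict()}
    summary: dict = {"stamp": stamp}
    stage = "simulate"
    try:
        params = _participant_params(config)
        cohort = sc.generate_cohort(config.experiment_id, config.n_participants,
                                    config.seed, params=params)
        sc.write_schedule(cohort.schedule, out / "schedule.csv")
        if config.write_timeseries:
            sc.simulate_cohort({"experiment_id": config.experiment_id,
                                "n_participants": config.n_participants,
                                "seed": config.seed, "out": out / "raw"})
        stage = "preprocess"
        preprocessed = preprocess_cohort(cohort, config)
        stage = "features"
        fcfg = FeatureConfig(baseline_window=config.baseline_window_s,
                             dilation_window=config.dilation_window_s)
        table = build_trial_table(cohort, fcfg, preprocessed=preprocessed)
        table.to_csv(out / "trials.csv", index=False)
        summary["features"] = {
            "n_trials": int(len(table)),
            "n_participants": int(table["participant"].nunique()),
            "dilation_exclusion_rate": float(
                table["dilation_velocity"].isna().mean()),
        }

        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        sched = cohort.schedule

        if config.run_cluster_test:
            stage = "cluster_test"
            t_grid, base, pert, _ = perturbation_contrast(cohort, preprocessed, config)
            run = tss.running_paired_ttests(pert, base, config.alpha, config.q)
            clus = tss.cluster_mass_permutation(
                pert - base, config.cluster_alpha, config.alpha,
                config.n_perm, rng)
            summary["cluster_test"] = {
                "n_perm": clus.n_perm, "exact": clus.exact,
                "clusters": [dataclasses.asdict(c) for c in clus.clusters],
                "hb_latency_ms": tss.first_significant_latency(run.hb_mask, t_grid),
                "bh_latency_ms": tss.first_significant_latency(run.bh_mask, t_grid),
            }

        if config.run_two_state:
            stage = "two_state"
            li = _learning_index_matrix(table, sched)
            b = sched.reaching["B"].to_numpy()
            f = b / sched.b_full
            is_ch = sched.reaching["is_channel"].to_numpy()
            nz = np.nonzero(f != 0)[0]
            washout_start = int(nz[-1]) + 1 if nz.size else len(f)
            fit = bootstrap_washout_prediction(
                li, f, is_ch, washout_start, n_boot=config.n_boot, rng=rng)
            summary["two_state"] = {
                "point": dataclasses.asdict(fit.point),
                "n_draws": int(len(fit.draws)),
                "longest_below_run": int(fit.longest_below_run),
                "washout_band": {
                    "trial": fit.washout_idx.tolist(),
                    "lower": fit.band_lower.tolist(),
                    "median": fit.band_median.tolist(),
                    "upper": fit.band_upper.tolist(),
                    "actual": fit.actual_mean.tolist(),
                },
            }

        if config.run_latency:
            stage = "latency"
            summary["latency"] = _latency_stage(table, sched, config)

        if config.run_setbreak and config.experiment_id in SETBREAK_BLOCKS:
            stage = "setbreak"
            sb = setbreak_contrast(table, config.experiment_id)
            summary["setbreak"] = sb.to_dict(orient="records")

        if config.run_changepoints and len(sched.change_points) > 0:
            stage = "changepoints"
            records = changepoint_table(table, sched)
            records.to_csv(out / "changepoints.csv", index=False)
            cp_summary = {"n_change_points": int(len(sched.change_points))}
            per_p = records.groupby("participant")["cp_number"].max()
            if len(records) and per_p.mean() >= 3:
                for measure in ("dilation", "baseline"):
                    try:
                        cp_summary[measure] = changepoint_lme(records, measure)
                    except Exception as exc:  # degenerate small runs
                        cp_summary[measure] = {"error": str(exc)}
            summary["changepoints"] = cp_summary

        if config.run_recall_split:
            stage = "recall_split"
            reports = sc.simulate_reports(
                cohort, np.random.default_rng(np.random.SeedSequence([config.seed, 2])))
            reports.to_csv(out / "reports.csv", index=False)
            split = recall_split(reports)
            blocks_res = subgroup_block_lme(table, split, "baseline_pupil")
            summary["recall_split"] = {
                "median": split.median,
                "group_sizes": split.group.value_counts().to_dict(),
                "block_tests": split.block_tests.to_dict(orient="records"),
                "baseline_lme": blocks_res.to_dict(orient="records"),
            }
    except Exception:
        log.error("pipeline stage %r failed", stage)
        (out / "FAILED").write_text(stage)
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return out


def _latency_stage(table: pd.DataFrame, sched, cfg: PipelineConfig) -> dict:
    """Model-free %-change latencies for learning vs washout, on the
    group-mean |PVE| (per trial) and learning index (per cycle)."""
    b = sched.reaching["B"].to_numpy()
    nz = np.nonzero(b != 0)[0]
    if nz.size == 0:
        return {}
    learn_lo, learn_hi = int(nz[0]), int(nz[-1])
    out = {}
    g = table.groupby("reach_index")
    s_pve = g["PVE"].mean().abs().sort_index().to_numpy()
    out.update(_phase_latencies("abs_pve", s_pve, learn_lo, learn_hi,
                                cfg.latency_thresholds,
                                cfg.n_required_kinematic, n_plateau=25))
    cyc = table[table["is_channel"]].groupby("cycle")["learning_index"].mean()
    s = cyc.sort_index().to_numpy()
    lo_c, hi_c = learn_lo // 5, learn_hi // 5
    out.update(_phase_latencies("learning_index", s, lo_c, hi_c,
                                cfg.latency_thresholds,
                                cfg.n_required_learning, n_plateau=5))
    return out


def _phase_latencies(name, s, lo, hi, thresholds, n_req,
                     n_start: int = 2, n_plateau: int = 5) -> dict:
    """%-change latencies for the learning phase and the washout phase.

    Each phase is mapped to %-change units anchored at its own start level
    (mean of the first ``n_start`` samples) and plateau (mean of the last
    ``n_plateau`` samples); the washout phase's plateau is its recovery level,
    which flips a decaying series into a rising %-change index.
    """
    out = {}

    def phase(seg):
        seg = seg[np.isfinite(seg)]
        if len(seg) < max(n_start + n_plateau, n_req):
            return None
        start = float(np.mean(seg[:n_start]))
        plateau = float(np.mean(seg[-n_plateau:]))
        if plateau == start:
            return None
        return percent_change_latency(
            to_percent_change(seg, start, plateau), thresholds, n_req)

    res = phase(s[lo:hi + 1])
    if res is not None:
        out[f"{name}_learning"] = res.latencies
    res_w = phase(s[hi + 1:])
    if res_w is not None:
        out[f"{name}_washout"] = res_w.latencies
    return out


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def make_report(run_dir) -> str:
    """Human-readable report assembled from a completed run's stored outputs
    only (no recomputation).  Writes ``report.txt`` and returns its text."""
    run = Path(run_dir)
    lines = ["pupiladapt run report", "=" * 40]
    spath = run / "summary.json"
    if not spath.exists():
        lines.append("summary: ABSENT")
        text = "\n".join(lines) + "\n"
        (run / "report.txt").write_text(text)
        return text
    summary = json.loads(spath.read_text())
    stamp = summary.get("stamp", {})
    lines.append(f"config hash: {stamp.get('config_hash')}  seed: {stamp.get('seed')}")
    feats = summary.get("features")
    if feats:
        lines.append("")
        lines.append("[features]")
        for k, v in feats.items():
            lines.append(f"  {k}: {v}")
    else:
        lines.append("[features] ABSENT")
    clus = summary.get("cluster_test")
    lines.append("")
    if clus:
        lines.append("[cluster test] perturbed vs baseline pupil velocity")
        lines.append(f"  permutations: {clus['n_perm']} (exact={clus['exact']})")
        for c in clus["clusters"]:
            lines.append(f"  cluster frames {c['start']}-{c['end']}: "
                         f"mass={c['mass']:.2f} p={c['p']:.4f}")
        lines.append(f"  first significant latency HB: {clus['hb_latency_ms']} ms, "
                     f"BH: {clus['bh_latency_ms']} ms")
    else:
        lines.append("[cluster test] ABSENT")
    ts2 = summary.get("two_state")
    lines.append("")
    if ts2:
        p = ts2["point"]
        lines.append("[two-state fit]")
        lines.append(f"  A_f={p['A_f']:.4f} A_s={p['A_s']:.4f} "
                     f"B_f={p['B_f']:.4f} B_s={p['B_s']:.4f}")
        lines.append(f"  bootstrap draws: {ts2['n_draws']}; actual below lower "
                     f"95% bound for {ts2['longest_below_run']} consecutive "
                     f"washout channel trials")
    else:
        lines.append("[two-state fit] ABSENT")
    lat = summary.get("latency")
    lines.append("")
    if lat:
        lines.append("[%-change latency]")
        for k, v in lat.items():
            lines.append(f"  {k}: {v}")
    else:
        lines.append("[%-change latency] ABSENT")
    sb = summary.get("setbreak")
    lines.append("")
    if sb:
        lines.append("[set break] early (trials 1-2) minus late (6-10)")
        for row in sb:
            lines.append(f"  {row['measure']}: delta={row['delta']:.4f} "
                         f"t={row['t']:.2f} p={row['p']:.4g}")
    else:
        lines.append("[set break] ABSENT")
    cp = summary.get("changepoints")
    lines.append("")
    if cp:
        lines.append(f"[change points] n={cp.get('n_change_points')}")
        for m in ("dilation", "baseline"):
            if m in cp and "error" not in cp[m]:
                r = cp[m]
                lines.append(
                    f"  {m}: cp_number slope={r['cp_number']['estimate']:.4f} "
                    f"(p={r['cp_number']['p']:.4g}), lcp slope="
                    f"{r['prev_env_length']['estimate']:.4f} "
                    f"(p={r['prev_env_length']['p']:.4g})")
    else:
        lines.append("[change points] ABSENT")
    rs = summary.get("recall_split")
    lines.append("")
    if rs:
        lines.append(f"[recall split] median={rs['median']} sizes={rs['group_sizes']}")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text


def setup_logging(verbose: int = 0) -> None:
    level = logging.WARNING if verbose == 0 else (
        logging.INFO if verbose == 1 else logging.DEBUG)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")
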