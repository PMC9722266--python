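"""Per-trial scalar features and the analysis trial table.

Reduces each preprocessed trial to the features the statistical analyses run
on: peak-velocity error (PVE, signed lateral deviation at peak tangential
velocity), endpoint error (EPE), the channel-trial learning index (lateral
channel force at peak velocity over peak velocity, viscosity units), baseline
pupil diameter, mean pupil dilation velocity in the 300-700 ms post-onset
window, and reaction/movement times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_preprocess import PreprocessedTrial, calibrate_pupil, preprocess_trial


@dataclass
class FeatureConfig:
    baseline_window: float = 1.0        # s before go cue averaged for baseline
    dilation_window: tuple = (0.3, 0.7)  # s after movement onset
    onset_fraction: float = 0.1          # fraction of peak speed
    min_peak_speed: float = 0.01         # m/s; below -> learning index missing
    cycle_len: int = 5                   # trials per cycle bin


def reach_onset_offset(speed: np.ndarray, t: np.ndarray,
                       fraction: float = 0.1):
    """Reach onset/offset from the tangential speed profile.

    Onset is the first sample at which the speed exceeds ``fraction`` of its
    peak; offset is the first sample after onset below that same threshold.
    If the speed never drops again the last sample is used and flagged.
    Returns ``(onset, offset, offset_flagged)``.
    """
    speed = np.asarray(speed, dtype=float)
    peak = speed.max()
    if peak <= 0:
        raise ValueError("speed profile has no positive peak")
    thr = fraction * peak
    above = np.nonzero(speed > thr)[0]
    i_on = int(above[0])
    after = np.nonzero(speed[i_on:] < thr)[0]
    if after.size:
        return float(t[i_on]), float(t[i_on + int(after[0])]), False
    return float(t[i_on]), float(t[-1]), True


def kinematic_errors(pre: PreprocessedTrial, target_xy,
                     onset: float, offset: float):
    """PVE (signed lateral deviation from the straight start-target line at
    the time of peak tangential speed) and EPE (hand-target distance at
    movement offset), both in meters.

    Returns ``(pve, epe, peak_speed, t_peak, flagged)``; ``flagged`` marks a
    peak-speed time outside [onset, offset] (still computed).
    """
    speed = np.linalg.norm(pre.vel_xy, axis=1)
    ipk = int(np.argmax(speed))
    t_peak = float(pre.t[ipk])
    start = np.zeros(2)
    target = np.asarray(target_xy, dtype=float)
    u = (target - start) / np.linalg.norm(target - start)
    perp = np.array([u[1], -u[0]])  # rightward-positive for a forward reach
    pve = float(np.dot(pre.hand_xy[ipk] - start, perp))
    i_off = int(np.searchsorted(pre.t, offset))
    i_off = min(i_off, len(pre.t) - 1)
    epe = float(np.linalg.norm(pre.hand_xy[i_off] - target))
    flagged = not (onset <= t_peak <= offset)
    return pve, epe, float(speed[ipk]), t_peak, flagged


def learning_index(pre: PreprocessedTrial, min_peak_speed: float = 0.01):
    """Lateral channel force at the time of peak tangential speed divided by
    the peak speed (viscosity units); positive compensates the CW field.
    Returns NaN when the peak speed is below ``min_peak_speed``."""
    speed = np.linalg.norm(pre.vel_xy, axis=1)
    ipk = int(np.argmax(speed))
    vpk = float(speed[ipk])
    if vpk < min_peak_speed:
        return math.nan
    return float(pre.force_xy[ipk, 0]) / vpk


def pupil_features(pre: PreprocessedTrial, onset: float, offset: float,
                   cfg: FeatureConfig = FeatureConfig()):
    """Baseline pupil (%) over the waiting window before the go cue and mean
    dilation velocity (%/s) over the post-onset window; the velocity is
    missing whenever a saccade overlaps the movement period.

    Returns ``(baseline, dilation_velocity, saccade_in_movement,
    waiting_short)``.
    """
    go = pre.events["go_cue"]
    w0 = go - cfg.baseline_window
    waiting_short = (go - pre.t[0]) < 0.5
    bmask = (pre.t >= w0) & (pre.t <= go)
    baseline = float(pre.pupil_norm[bmask].mean()) if bmask.any() else math.nan

    sacc = any(s.start <= offset and s.end >= onset for s in pre.saccades)
    tv = pre.t[:-1]
    d0, d1 = cfg.dilation_window
    dmask = (tv >= onset + d0) & (tv <= onset + d1)
    if sacc or not dmask.any():
        dil = math.nan
    else:
        dil = float(pre.pupil_vel[dmask].mean())
    return baseline, dil, sacc, waiting_short


def compute_trial_row(pre: PreprocessedTrial, entry, target_xy,
                      cfg: FeatureConfig = FeatureConfig()) -> dict:
    """All scalar features for one preprocessed trial (unsigned-flip form)."""
    speed = np.linalg.norm(pre.vel_xy, axis=1)
    onset, offset, off_flag = reach_onset_offset(speed, pre.t, cfg.onset_fraction)
    pve, epe, vpk, t_peak, pk_flag = kinematic_errors(pre, target_xy, onset, offset)
    is_channel = bool(entry["is_channel"])
    li = learning_index(pre, cfg.min_peak_speed) if is_channel else math.nan
    baseline, dil, sacc, wait_flag = pupil_features(pre, onset, offset, cfg)
    rt = pre.events["movement_onset"] - pre.events["go_cue"]
    mt = pre.events["movement_offset"] - pre.events["movement_onset"]
    return dict(reach_index=int(entry["reach_index"]), block=int(entry["block"]),
                B=float(entry["B"]), is_channel=is_channel,
                PVE=pve, EPE=epe, learning_index=li,
                baseline_pupil=baseline, dilation_velocity=dil,
                RT=float(rt), MT=float(mt),
                saccade_in_movement=sacc, offset_flagged=off_flag,
                peak_speed=vpk, waiting_short=wait_flag)


TRIAL_TABLE_COLUMNS = [
    "participant", "reach_index", "block", "cycle", "B", "is_channel",
    "PVE", "EPE", "learning_index", "baseline_pupil", "dilation_velocity",
    "RT", "MT", "saccade_in_movement", "sign_flipped",
    "offset_flagged", "peak_speed", "waiting_short",
]


def build_trial_table(cohort, cfg: FeatureConfig = FeatureConfig(),
                      preprocess_kwargs: dict | None = None,
                      preprocessed: dict | None = None) -> pd.DataFrame:
    """Preprocess every trial of a synthetic cohort and assemble the trial
    table: one row per reaching trial with PVE and learning index sign-flipped
    for CCW-field participants, cycles as 5-trial bins, and a stable column
    order.

    ``preprocessed`` may supply already-conditioned trials per participant
    (as produced by the pipeline) to avoid repeating the preprocessing.
    """
    preprocess_kwargs = preprocess_kwargs or {}
    rows = []
    for pdat in cohort.participants:
        ready = preprocessed.get(pdat.participant) if preprocessed else None
        if ready is None:
            calib = calibrate_pupil(
                (blk, stim, ts.pupil_mm) for blk, stim, ts in pdat.light_trials)
        sched = pdat.schedule
        target = (0.0, sched.amplitude)
        reaching = sched.reaching
        for k, ((_, entry), ts) in enumerate(zip(reaching.iterrows(), pdat.trials)):
            pre = ready[k] if ready is not None else preprocess_trial(
                ts, calib, sched.eye_distance_mm, **preprocess_kwargs)
            row = compute_trial_row(pre, entry, target, cfg)
            if pdat.direction < 0:
                row["PVE"] = -row["PVE"]
                if not math.isnan(row["learning_index"]):
                    row["learning_index"] = -row["learning_index"]
                row["B"] = -row["B"]  # report in CW-convention units
            row["participant"] = pdat.participant
            row["sign_flipped"] = pdat.direction < 0
            row["cycle"] = (row["reach_index"] - 1) // cfg.cycle_len + 1
            rows.append(row)
    table = pd.DataFrame(rows)[TRIAL_TABLE_COLUMNS]
    return table.sort_values(["participant", "reach_index"]).reset_index(drop=True)
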