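"""Synthetic force-field reach-adaptation cohorts with pupillometry.

Generates complete experiments — perturbation schedules, point-mass reach
dynamics under velocity-dependent curl fields and force channels, a two-state
error-driven learner, and a generative pupil model with tonic (uncertainty)
and phasic (surprise) components — so that every downstream analysis stage has
a recoverable ground truth.

Conventions: x is rightward-positive lateral, y is toward-target forward.
A clockwise (CW) field has viscosity B > 0 and pushes the hand rightward while
it moves forward: f_x = B * v_y, f_y = -B * v_x.  All times are seconds, all
signals are sampled at 200 Hz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation_model import TwoStateParams, two_state_simulate

RATE = 200.0  # Hz, sampling rate of all simulated signals


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelConfig:
    """Spring-damper force channel constraining the hand to the straight path."""

    stiffness: float  # N/m
    damping: float    # N/(m/s)

    def __post_init__(self) -> None:
        if not (self.stiffness > 0 and self.damping > 0):
            raise ValueError("channel stiffness and damping must be positive")


@dataclass
class Schedule:
    """Per-trial perturbation plan for one experiment.

    ``trials`` has one row per session trial in order, with columns
    ``trial_index`` (1-based session order), ``reach_index`` (1-based over
    reaching trials, 0 on light-reflex trials), ``block``, ``B`` (signed
    viscosity), ``is_channel``, ``is_light_reflex`` and ``is_change_point``.
    ``change_points`` and ``blocks`` are expressed in reach_index units.
    """

    experiment_id: str
    trials: pd.DataFrame
    change_points: np.ndarray
    blocks: list[tuple[int, int]]
    b_full: float
    amplitude: float
    channel: ChannelConfig
    eye_distance_mm: float

    @property
    def reaching(self) -> pd.DataFrame:
        return self.trials[~self.trials["is_light_reflex"]].reset_index(drop=True)

    @property
    def n_reaching(self) -> int:
        return int((~self.trials["is_light_reflex"]).sum())

    def validate(self) -> None:
        r = self.reaching
        idx = r["reach_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(r) + 1)):
            raise ValueError("reach_index must be contiguous and strictly increasing")
        both = self.trials["is_channel"] & self.trials["is_light_reflex"]
        if both.any():
            raise ValueError("a trial cannot be both channel and light-reflex")
        b = r["B"].to_numpy()
        nz = np.nonzero(b)[0]
        if nz.size and np.any(b[: nz[0]] != 0.0):
            raise ValueError("B must be 0 before the first perturbation trial")
        starts = {s for s, _ in self.blocks}
        for cp in self.change_points:
            blk = next(((s, e) for s, e in self.blocks if s <= cp <= e), None)
            if blk is None or cp == blk[0]:
                raise ValueError(f"change point {cp} is not strictly inside a block")


@dataclass
class PupilParams:
    """Generative pupil model parameters (tonic %, gains per unit surprise)."""

    tonic_floor: float = 30.0        # % of light-reflex range
    novelty_bump: float = 8.0        # % added at block start
    tonic_decay: float = 0.85        # per-trial retention of tonic excess
    surprise_gain: float = 3.0       # % phasic amplitude per unit surprise
    surprise_gain_tonic: float = 2.0  # % tonic increment per unit excess surprise
    habituation_rate: float = 0.3    # per-trial expected-error update rate
    irf_shape: float = 10.1          # gamma-family impulse response shape
    irf_peak_time: float = 0.93      # s after movement onset
    ar_coef: float = 0.95            # AR(1) coefficient of sample noise
    ar_noise_sd: float = 0.5         # % stationary SD of sample noise
    tonic_noise_sd: float = 1.5      # % trial-to-trial tonic jitter
    error_floor: float = 1e-5        # m, floor on expected error
    surprise_cap: float = 6.0        # saturation of the surprise response


@dataclass
class ParticipantParams:
    two_state: TwoStateParams = field(
        default_factory=lambda: TwoStateParams(0.90, 0.99, 0.15, 0.02))
    motor_noise_sd: float = 0.01     # N, lateral force noise
    pupil: PupilParams = field(default_factory=PupilParams)
    blink_rate: float = 0.2          # expected blink events per trial
    saccade_rate: float = 0.15       # P(saccade during movement period)
    calib_min_mm: float = 2.0        # constriction trough (bright stimulus)
    calib_max_mm: float = 6.0        # dilation peak (dark stimulus)
    rt_base: float = 0.30            # s
    rt_tonic_gain: float = 0.005     # s per % tonic excess
    rt_noise_sd: float = 0.02        # s
    mt_base: float = 0.60            # s, movement duration
    mt_tonic_gain: float = 0.002     # s per % tonic excess
    mt_noise_sd: float = 0.01        # s

    def __post_init__(self) -> None:
        if not self.calib_min_mm < self.calib_max_mm:
            raise ValueError("calib_min_mm must be < calib_max_mm")
        p = self.pupil
        for name, v in (("tonic_decay", p.tonic_decay),
                        ("habituation_rate", p.habituation_rate)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class ReachConfig:
    """Plant and timing constants for one experiment's reaches."""

    amplitude: float                  # m
    channel: ChannelConfig
    mass: float = 1.0                 # kg lateral point mass
    feedback_kp: float = 100.0        # N/m lateral PD feedback
    feedback_kd: float = 10.0         # N/(m/s)
    pre_go: float = 2.0               # s of recorded pre-go hold
    post: float = 1.8                 # s recorded after movement offset
    n_substeps: int = 5               # RK4 substeps per 200 Hz sample
    onset_speed: float = 0.035        # m/s online movement-onset trigger
    rate: float = RATE                # Hz


@dataclass
class TrialTimeSeries:
    """200 Hz sampled signals for one trial plus event markers."""

    t: np.ndarray
    hand_xy: np.ndarray    # (n, 2) m
    vel_xy: np.ndarray     # (n, 2) m/s
    force_xy: np.ndarray   # (n, 2) N
    gaze_xy: np.ndarray    # (n, 2) display mm
    pupil_mm: np.ndarray
    events: dict           # go_cue, movement_onset, movement_offset (s)
    blink_intervals: list  # [(start, end)] s
    true_saccades: list    # ground-truth injected saccade intervals, s
    rate: float = RATE

    def validate(self) -> None:
        n = len(self.t)
        for arr in (self.hand_xy, self.vel_xy, self.force_xy, self.gaze_xy,
                    self.pupil_mm):
            if len(arr) != n:
                raise ValueError("all sampled channels must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not self.events["movement_onset"] < self.events["movement_offset"]:
            raise ValueError("movement_onset must precede movement_offset")


# --------------------------------------------------------------------------
# Schedules
# --------------------------------------------------------------------------

_EXP1_CHANNEL = ChannelConfig(7000.0, 30.0)
_EXP234_CHANNEL = ChannelConfig(2500.0, 25.0)

#: CW / CCW reaching-trial sets for the switching-field experiment, as
#: 1-based inclusive ranges over cumulative reaching trials.
EXP2_FIELD_SETS = {
    "exp2A": {
        "cw": [(61, 89), (101, 129), (151, 159), (170, 179), (190, 209), (220, 229)],
        "ccw": [(90, 100), (130, 150), (160, 169), (180, 189), (210, 219), (230, 239)],
    },
    "exp2B": {
        "cw": [(70, 79), (90, 109), (120, 129), (140, 189), (201, 229)],
        "ccw": [(61, 69), (80, 89), (110, 119), (130, 139), (190, 200), (230, 239)],
    },
    "exp2C": {
        "cw": [(61, 159)],
        "ccw": [(160, 170)],
    },
}

EXPERIMENT_IDS = ("exp1", "exp2A", "exp2B", "exp2C", "exp3", "exp4")


def _ranges_to_set(ranges) -> set[int]:
    out: set[int] = set()
    for a, b in ranges:
        out.update(range(a, b + 1))
    return out


def _find_change_points(b: np.ndarray, is_channel: np.ndarray,
                        blocks: list[tuple[int, int]]) -> np.ndarray:
    """Reaching trials where the field sign category flips, strictly inside a
    block and not clamped by a channel (channels hide the kinematic change)."""
    sign = np.sign(b)
    block_starts = {s for s, _ in blocks}
    cps = []
    for i in range(1, len(b)):
        ri = i + 1  # 1-based reach index
        if sign[i] != sign[i - 1] and ri not in block_starts and not is_channel[i]:
            cps.append(ri)
    return np.asarray(cps, dtype=int)


def _place_channels(n_reach: int, eligible: np.ndarray, rng: np.random.Generator,
                    min_gap: int = 1, cycle: int = 5) -> np.ndarray:
    """One channel trial per 5-trial cycle (20% of trials), uniformly placed
    among eligible trials, keeping chosen trials more than ``min_gap`` apart."""
    chosen: list[int] = []
    for start in range(1, n_reach + 1, cycle):
        cand = [i for i in range(start, min(start + cycle, n_reach + 1))
                if eligible[i - 1] and (not chosen or i - chosen[-1] > min_gap)]
        if cand:
            chosen.append(int(rng.choice(cand)))
    flags = np.zeros(n_reach, dtype=bool)
    flags[np.asarray(chosen, dtype=int) - 1] = True
    return flags


def make_schedule(experiment_id, rng: np.random.Generator | int | None = None,
                  channel_min_gap: int = 1) -> Schedule:
    """Build the per-trial perturbation plan for one of the stock experiments
    (``exp1``, ``exp2A``–``exp2C``, ``exp3``, ``exp4``) or for a custom spec.

    A custom spec is a dict with keys ``blocks`` (reaching trials per block),
    ``b_full``, ``cw_trials``/``ccw_trials`` (1-based inclusive ranges),
    ``amplitude``, and optionally ``channel``, ``light_reflex_per_side``,
    ``channel_fraction_range`` and ``eye_distance_mm``.
    """
    rng = np.random.default_rng(rng)
    if isinstance(experiment_id, dict):
        return _custom_schedule(experiment_id, rng, channel_min_gap)
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(f"unknown experiment_id: {experiment_id!r}")

    if experiment_id == "exp1":
        blocks_n = [55, 55, 55, 40, 55]
        b_full, amp, chan, eye = 0.15, 0.12, _EXP1_CHANNEL, 160.0
    elif experiment_id.startswith("exp2"):
        blocks_n = [50] * 5
        b_full, amp, chan, eye = 0.12, 0.10, _EXP234_CHANNEL, 350.0
    elif experiment_id == "exp3":
        blocks_n = [50] * 7
        b_full, amp, chan, eye = 0.12, 0.10, _EXP234_CHANNEL, 440.0
    else:  # exp4
        blocks_n = [50] * 6 + [70]
        b_full, amp, chan, eye = 0.12, 0.10, _EXP234_CHANNEL, 440.0

    n_reach = sum(blocks_n)
    bounds = np.concatenate([[0], np.cumsum(blocks_n)])
    blocks = [(int(bounds[i]) + 1, int(bounds[i + 1])) for i in range(len(blocks_n))]
    b = np.zeros(n_reach)
    idx = np.arange(1, n_reach + 1)

    if experiment_id == "exp1":
        # introduced at 11th reaching trial of block 2, removed at 11th of block 4
        on = blocks[1][0] + 10
        off = blocks[3][0] + 10
        b[(idx >= on) & (idx < off)] = b_full
    elif experiment_id.startswith("exp2"):
        sets = EXP2_FIELD_SETS[experiment_id]
        cw, ccw = _ranges_to_set(sets["cw"]), _ranges_to_set(sets["ccw"])
        if cw & ccw:
            raise ValueError("CW and CCW trial sets overlap")
        b[[i - 1 for i in cw]] = b_full
        b[[i - 1 for i in ccw]] = -b_full
    else:  # exp3 / exp4: gradual ramp, 5% of full strength every 11 trials
        on = blocks[1][0] + 15  # 16th trial of block 2
        for k in range(1, 21):
            lo = on + 11 * (k - 1)
            b[(idx >= lo)] = 0.05 * k * b_full
        if experiment_id == "exp3":
            off = blocks[6][0] + 10  # removed at 11th trial of block 7
            b[idx >= off] = 0.0

    # channel trials
    eligible = np.ones(n_reach, dtype=bool)
    forced = np.zeros(n_reach, dtype=bool)
    random_span = n_reach
    if experiment_id == "exp2C":
        forced[170:] = True          # trials 171..250 all channel
        random_span = 170
    elif experiment_id == "exp4":
        forced[320:] = True          # block 7 trials 21..70 -> reach 321..370
        random_span = 320
    # keep field transitions observable: no channel on a sign-flip trial
    sign = np.sign(b)
    flips = np.zeros(n_reach, dtype=bool)
    flips[1:] = sign[1:] != sign[:-1]
    eligible &= ~flips
    eligible[random_span:] = False
    is_channel = _place_channels(n_reach, eligible, rng, channel_min_gap)
    is_channel |= forced

    cps = _find_change_points(b, is_channel, blocks)
    trials = _assemble_trials(blocks_n, b, is_channel, cps,
                              light_per_side=2)
    sched = Schedule(experiment_id, trials, cps, blocks, b_full, amp, chan, eye)
    sched.validate()
    return sched


def _custom_schedule(spec: dict, rng: np.random.Generator,
                     channel_min_gap: int) -> Schedule:
    blocks_n = list(spec["blocks"])
    n_reach = sum(blocks_n)
    bounds = np.concatenate([[0], np.cumsum(blocks_n)])
    blocks = [(int(bounds[i]) + 1, int(bounds[i + 1])) for i in range(len(blocks_n))]
    b_full = float(spec["b_full"])
    b = np.zeros(n_reach)
    cw = _ranges_to_set(spec.get("cw_trials", []))
    ccw = _ranges_to_set(spec.get("ccw_trials", []))
    if cw & ccw:
        raise ValueError("CW and CCW trial sets overlap")
    b[[i - 1 for i in cw]] = b_full
    b[[i - 1 for i in ccw]] = -b_full
    sign = np.sign(b)
    flips = np.zeros(n_reach, dtype=bool)
    flips[1:] = sign[1:] != sign[:-1]
    is_channel = _place_channels(n_reach, ~flips, rng, channel_min_gap)
    cps = _find_change_points(b, is_channel, blocks)
    trials = _assemble_trials(blocks_n, b, is_channel, cps,
                              light_per_side=int(spec.get("light_reflex_per_side", 2)))
    sched = Schedule("custom", trials, cps, blocks, b_full,
                     float(spec.get("amplitude", 0.10)),
                     spec.get("channel", _EXP234_CHANNEL),
                     float(spec.get("eye_distance_mm", 440.0)))
    sched.validate()
    return sched


def _assemble_trials(blocks_n, b, is_channel, cps, light_per_side=2):
    rows = []
    trial_index = 0
    reach = 0
    cps = set(int(c) for c in cps)
    for bi, n in enumerate(blocks_n, start=1):
        for _ in range(light_per_side):
            trial_index += 1
            rows.append((trial_index, 0, bi, 0.0, False, True, False))
        for _ in range(n):
            trial_index += 1
            reach += 1
            rows.append((trial_index, reach, bi, float(b[reach - 1]),
                         bool(is_channel[reach - 1]), False, reach in cps))
        for _ in range(light_per_side):
            trial_index += 1
            rows.append((trial_index, 0, bi, 0.0, False, True, False))
    return pd.DataFrame(rows, columns=[
        "trial_index", "reach_index", "block", "B", "is_channel",
        "is_light_reflex", "is_change_point"])


# --------------------------------------------------------------------------
# Reach dynamics
# --------------------------------------------------------------------------

def minimal_jerk(amplitude: float, duration: float, t: np.ndarray):
    """Forward position and velocity of a minimal-jerk reach starting at t=0."""
    tau = np.clip(t / duration, 0.0, 1.0)
    y = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vy = amplitude / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    vy = np.where((t >= 0) & (t <= duration), vy, 0.0)
    return y, vy


def _lateral_accel(x, vx, vy_t, b_field, comp, cfg: ReachConfig,
                   is_channel: bool, noise_force: float) -> float:
    f = -comp * vy_t                       # feedforward compensation
    f += -cfg.feedback_kp * x - cfg.feedback_kd * vx
    if is_channel:
        f += -cfg.channel.stiffness * x - cfg.channel.damping * vx
    else:
        f += b_field * vy_t                # curl field (f_x = B * v_y)
    return (f + noise_force) / cfg.mass


def simulate_reach(schedule_entry, learner_compensation: float,
                   params: ParticipantParams | None, rng,
                   cfg: ReachConfig, rt: float | None = None,
                   move_duration: float | None = None,
                   noise_sd: float | None = None) -> TrialTimeSeries:
    """Simulate one trial's hand kinematics and forces.

    ``schedule_entry`` needs keys ``B`` and ``is_channel``.  The lateral
    dynamics are a 1 kg point mass driven by the curl field (or channel
    spring-damper), the learner's feedforward compensation
    (``learner_compensation * v_y`` opposing the field), configurable PD
    feedback and Gaussian motor-force noise, integrated by RK4 substeps.
    The forward profile is a prescribed minimal-jerk reach.

    On channel trials ``force_xy[:, 0]`` records the hand's lateral force on
    the channel (feedforward compensation plus feedback, sign-positive when
    compensating the CW field); otherwise it records the field force.
    """
    B = float(schedule_entry["B"]) if not isinstance(schedule_entry, tuple) else schedule_entry[0]
    is_channel = bool(schedule_entry["is_channel"]) if not isinstance(schedule_entry, tuple) else schedule_entry[1]
    rng = np.random.default_rng(rng)
    if params is not None:
        rt = params.rt_base if rt is None else rt
        move_duration = params.mt_base if move_duration is None else move_duration
        noise_sd = params.motor_noise_sd if noise_sd is None else noise_sd
    rt = 0.3 if rt is None else rt
    T = 0.6 if move_duration is None else move_duration
    noise_sd = 0.0 if noise_sd is None else noise_sd
    if T <= 0:
        raise ValueError("zero-duration reach")
    for v in (B, learner_compensation, rt, T, noise_sd):
        if not np.isfinite(v):
            raise ValueError("non-finite parameter")

    dt = 1.0 / cfg.rate
    go = cfg.pre_go
    t_move0 = go + rt
    total = t_move0 + T + cfg.post
    n = int(round(total * cfg.rate)) + 1
    t = np.arange(n) * dt

    y, vy = minimal_jerk(cfg.amplitude, T, t - t_move0)

    # lateral dynamics, integrated only over the movement span
    x = np.zeros(n)
    vx = np.zeros(n)
    i0 = int(np.searchsorted(t, t_move0))
    i1 = int(np.searchsorted(t, t_move0 + T, side="right"))
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    h = dt / cfg.n_substeps
    xs, vs = 0.0, 0.0
    for i in range(i0, min(i1 + 1, n)):
        if i > i0:
            eta = noise[i - 1]
            tk = t[i - 1]
            for _ in range(cfg.n_substeps):
                xs, vs = _rk4_step(xs, vs, tk, h, B, learner_compensation,
                                   cfg, is_channel, eta, t_move0, T)
                tk += h
        x[i] = xs
        vx[i] = vs
    x[i1 + 1:] = x[min(i1, n - 1)]

    hand = np.column_stack([x, y])
    vel = np.column_stack([vx, vy])
    force = np.zeros((n, 2))
    if is_channel:
        force[:, 0] = (learner_compensation * vy
                       + cfg.feedback_kp * x + cfg.feedback_kd * vx)
    else:
        force[:, 0] = B * vy
        force[:, 1] = -B * vx

    # online threshold-crossing event markers (3.5 cm/s trigger)
    speed = np.hypot(vx, vy)
    above = np.nonzero(speed >= cfg.onset_speed)[0]
    if above.size:
        onset = t[above[0]]
        after = above[-1]
        offset = t[min(after + 1, n - 1)]
    else:
        onset, offset = t_move0, t_move0 + T

    ts = TrialTimeSeries(
        t=t, hand_xy=hand, vel_xy=vel, force_xy=force,
        gaze_xy=np.zeros((n, 2)), pupil_mm=np.zeros(n),
        events={"go_cue": go, "movement_onset": float(onset),
                "movement_offset": float(offset)},
        blink_intervals=[], true_saccades=[])
    ts.validate()
    return ts


def _rk4_step(x, v, tk, h, B, comp, cfg, is_channel, eta, t0, T):
    def acc(xx, vv, tt):
        tau = tt - t0
        if 0.0 <= tau <= T:
            vy = cfg.amplitude / T * (30 * (tau / T)**2 - 60 * (tau / T)**3
                                      + 30 * (tau / T)**4)
        else:
            vy = 0.0
        return _lateral_accel(xx, vv, vy, B, comp, cfg, is_channel, eta)

    k1x, k1v = v, acc(x, v, tk)
    k2x, k2v = v + 0.5 * h * k1v, acc(x + 0.5 * h * k1x, v + 0.5 * h * k1v, tk + 0.5 * h)
    k3x, k3v = v + 0.5 * h * k2v, acc(x + 0.5 * h * k2x, v + 0.5 * h * k2v, tk + 0.5 * h)
    k4x, k4v = v + h * k3v, acc(x + h * k3x, v + h * k3v, tk + h)
    xn = x + h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    vn = v + h / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return xn, vn


# --------------------------------------------------------------------------
# Latent dynamics: surprise, tonic uncertainty, habituation
# --------------------------------------------------------------------------

def update_latents(latents: dict, observed_abs_error: float, block_start: bool,
                   params: PupilParams) -> tuple[dict, float]:
    """Advance the tonic-uncertainty and expected-error latents by one trial.

    Surprise is the observed absolute error relative to the running error
    expectation; tonic relaxes geometrically toward its floor, is bumped by
    excess surprise and by block starts (novelty), and the error expectation
    habituates toward what was observed.
    """
    if observed_abs_error < 0:
        raise ValueError("observed_abs_error must be non-negative")
    tonic = float(latents["tonic"])
    expected = float(latents["expected_error"])
    if not (np.isfinite(tonic) and np.isfinite(expected)):
        raise ValueError("latents must be finite")
    s = observed_abs_error / max(expected, params.error_floor)
    s = min(s, params.surprise_cap)  # arousal responses saturate
    tonic_new = (params.tonic_floor
                 + params.tonic_decay * (tonic - params.tonic_floor)
                 + params.surprise_gain_tonic * max(s - 1.0, 0.0))
    if block_start:
        tonic_new += params.novelty_bump
    expected_new = expected + params.habituation_rate * (observed_abs_error - expected)
    return {"tonic": tonic_new, "expected_error": expected_new}, s


# --------------------------------------------------------------------------
# Pupil traces
# --------------------------------------------------------------------------

def pupil_irf(t_rel: np.ndarray, shape: float, peak_time: float) -> np.ndarray:
    """Gamma-family impulse response, normalized to peak 1 at ``peak_time``."""
    tau = np.maximum(t_rel, 0.0) / peak_time
    k = shape - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(tau > 0, np.exp(k * (np.log(np.maximum(tau, 1e-300)) + 1.0 - tau)), 0.0)
    return h


def pct_to_mm(pct, params: ParticipantParams):
    return params.calib_min_mm + (np.asarray(pct) / 100.0) * (
        params.calib_max_mm - params.calib_min_mm)


def simulate_pupil_trace(t: np.ndarray, movement_onset: float, surprise: float,
                         tonic: float, params: ParticipantParams,
                         rng=None, with_noise: bool = True,
                         blink_rate: float | None = None):
    """Generate one trial's pupil trace in mm.

    pupil(t) maps ``tonic + surprise_gain * s * h(t - onset)`` (percent of the
    light-reflex range, ``h`` the gamma impulse response) onto mm, adds AR(1)
    noise, then draws blink intervals and overwrites them with artifact
    values.  Returns ``(pupil_mm, blink_intervals)``.
    """
    if surprise < 0:
        raise ValueError("surprise must be non-negative")
    if not (t[0] <= movement_onset <= t[-1]):
        raise ValueError("movement onset outside trial window")
    rng = np.random.default_rng(rng)
    p = params.pupil
    pct = tonic + p.surprise_gain * surprise * pupil_irf(
        t - movement_onset, p.irf_shape, p.irf_peak_time)
    if with_noise and p.ar_noise_sd > 0:
        innov = rng.normal(0.0, p.ar_noise_sd * np.sqrt(1 - p.ar_coef**2), len(t))
        noise = np.empty(len(t))
        acc = rng.normal(0.0, p.ar_noise_sd)
        for i, e in enumerate(innov):
            acc = p.ar_coef * acc + e
            noise[i] = acc
        pct = pct + noise
    pupil = pct_to_mm(pct, params)

    blink_rate = params.blink_rate if blink_rate is None else blink_rate
    blinks = []
    if with_noise and blink_rate > 0:
        for _ in range(rng.poisson(blink_rate)):
            dur = rng.uniform(0.08, 0.2)
            start = rng.uniform(t[0], t[-1] - dur)
            blinks.append((float(start), float(start + dur)))
        blinks.sort()
        for s0, s1 in blinks:
            m = (t >= s0) & (t <= s1)
            pupil[m] = 0.3  # tracker-loss artifact value
    return pupil, blinks


def simulate_light_reflex(params: ParticipantParams, rng=None,
                          stimulus_duration: float = 1.5,
                          post_duration: float = 3.5,
                          tau: float = 0.25, noise_sd: float = 0.0):
    """Simulate a (dark, bright) pair of light-reflex calibration trials.

    Each trace follows first-order dynamics from the resting diameter toward
    the dilation peak (dark) or constriction trough (bright) during the
    stimulus, then recovers.  Returns two :class:`TrialTimeSeries`.
    """
    rng = np.random.default_rng(rng)
    rest = 0.5 * (params.calib_min_mm + params.calib_max_mm)
    n = int(round((stimulus_duration + post_duration) * RATE)) + 1
    t = np.arange(n) / RATE
    out = []
    for asym in (params.calib_max_mm, params.calib_min_mm):
        d = np.full(n, rest)
        if stimulus_duration > 0:
            stim = t <= stimulus_duration
            d[stim] = rest + (asym - rest) * (1 - np.exp(-t[stim] / tau))
            d_end = d[stim][-1]
            rec = ~stim
            d[rec] = rest + (d_end - rest) * np.exp(-(t[rec] - stimulus_duration) / tau)
        if noise_sd > 0:
            d = d + rng.normal(0.0, noise_sd, n)
        zeros = np.zeros((n, 2))
        ts = TrialTimeSeries(t=t, hand_xy=zeros, vel_xy=zeros.copy(),
                             force_xy=zeros.copy(), gaze_xy=zeros.copy(),
                             pupil_mm=d,
                             events={"go_cue": 0.0, "movement_onset": 0.0,
                                     "movement_offset": stimulus_duration
                                     + post_duration},
                             blink_intervals=[], true_saccades=[])
        out.append(ts)
    return tuple(out)  # (dark, bright)


def _inject_gaze(ts: TrialTimeSeries, params: ParticipantParams, rng,
                 eye_distance_mm: float, saccade_in_movement: bool,
                 noise_sd_mm: float = 0.4) -> None:
    """Fixation noise around the target plus threshold-crossing saccade pulses."""
    from scipy.ndimage import gaussian_filter1d

    n = len(ts.t)
    if noise_sd_mm > 0:
        # fixation drift is band-limited, not sample-to-sample white
        gaze = gaussian_filter1d(rng.normal(0.0, noise_sd_mm, size=(n, 2)),
                                 sigma=6.0, axis=0, mode="reflect")
        gaze *= noise_sd_mm / max(gaze.std(), 1e-12)
    else:
        gaze = np.zeros((n, 2))
    sacc_times = []
    if saccade_in_movement:
        on, off = ts.events["movement_onset"], ts.events["movement_offset"]
        sacc_times.append(rng.uniform(on + 0.05, max(off - 0.1, on + 0.06)))
    if noise_sd_mm > 0 and rng.random() < 0.3:  # occasional wait saccade
        sacc_times.append(rng.uniform(0.2, ts.events["go_cue"] - 0.3))
    for t0 in sacc_times:
        amp_deg = rng.uniform(2.0, 4.0) * rng.choice([-1.0, 1.0])
        amp_mm = np.tan(np.deg2rad(abs(amp_deg))) * eye_distance_mm * np.sign(amp_deg)
        dur = 0.04
        m = (ts.t >= t0) & (ts.t <= t0 + dur)
        ramp = (ts.t[m] - t0) / dur
        gaze[m, 0] += amp_mm * ramp
        gaze[ts.t > t0 + dur, 0] += amp_mm
        ts.true_saccades.append((float(t0), float(t0 + dur)))
    ts.gaze_xy = gaze
    # blinks also blank the gaze signal
    for s0, s1 in ts.blink_intervals:
        m = (ts.t >= s0) & (ts.t <= s1)
        ts.gaze_xy[m] = -100.0


# --------------------------------------------------------------------------
# Participants and cohorts
# --------------------------------------------------------------------------

@dataclass
class ParticipantData:
    participant: int
    direction: int               # +1 CW, -1 CCW
    params: ParticipantParams
    schedule: Schedule           # with B already sign-flipped for CCW
    trials: list                 # TrialTimeSeries per reaching trial
    light_trials: list           # (block, 'dark'|'bright', TrialTimeSeries)
    truth: pd.DataFrame          # per reaching trial latent ground truth


@dataclass
class Cohort:
    experiment_id: str
    seed: int
    schedule: Schedule           # canonical (CW) schedule
    participants: list


def _flip_schedule(schedule: Schedule) -> Schedule:
    trials = schedule.trials.copy()
    trials["B"] = -trials["B"]
    return dataclasses.replace(schedule, trials=trials)


def simulate_participant(schedule: Schedule, params: ParticipantParams,
                         rng: np.random.Generator, participant: int = 0,
                         direction: int = 1,
                         reach_cfg: ReachConfig | None = None,
                         with_noise: bool = True) -> ParticipantData:
    """Simulate every trial of one participant under ``schedule``.

    The embedded learner updates its fast/slow states from the normalized
    field error (retention-only on channel trials); the pupil latents update
    from the observed absolute lateral error on field trials.
    """
    sched = _flip_schedule(schedule) if direction < 0 else schedule
    cfg = reach_cfg or ReachConfig(amplitude=sched.amplitude,
                                   channel=sched.channel)
    p = params.pupil
    xf = xs = 0.0
    latents = {"tonic": p.tonic_floor + p.novelty_bump,
               "expected_error": 10 * p.error_floor}
    reaching = sched.reaching
    block_start_idx = {s for s, _ in sched.blocks}
    rows, trials = [], []
    noise_sd = params.motor_noise_sd if with_noise else 0.0
    for _, entry in reaching.iterrows():
        ri = int(entry["reach_index"])
        block_start = ri in block_start_idx and ri != 1  # first trial seeded above
        if block_start:
            latents["tonic"] += p.novelty_bump
        tonic_trial = latents["tonic"]
        if with_noise and p.tonic_noise_sd > 0:
            tonic_trial += rng.normal(0.0, p.tonic_noise_sd)
        rt = params.rt_base + params.rt_tonic_gain * (latents["tonic"] - p.tonic_floor)
        mt = params.mt_base + params.mt_tonic_gain * (latents["tonic"] - p.tonic_floor)
        if with_noise:
            rt += rng.normal(0.0, params.rt_noise_sd)
            mt += rng.normal(0.0, params.mt_noise_sd)
        rt, mt = max(rt, 0.15), max(mt, 0.3)

        # learner state tracks the signed field in units of |b_full|, so the
        # same update covers CW, CCW and switching schedules
        b_hat = (xf + xs) * abs(sched.b_full)

        ts = simulate_reach(entry, b_hat, params, rng, cfg, rt=rt,
                            move_duration=mt, noise_sd=noise_sd)

        # observed lateral error at peak tangential velocity (generator truth)
        speed = np.hypot(ts.vel_xy[:, 0], ts.vel_xy[:, 1])
        ipk = int(np.argmax(speed))
        pve_true = float(ts.hand_xy[ipk, 0])

        is_channel = bool(entry["is_channel"])
        if is_channel:
            # channels clamp the error: neutral latent update, retention-only learner
            obs = latents["expected_error"]
            err_field = 0.0
        else:
            obs = abs(pve_true)
            f_n = float(entry["B"]) / abs(sched.b_full)
            err_field = f_n - (xf + xs)
        tsp = params.two_state
        xf = tsp.A_f * xf + tsp.B_f * err_field
        xs = tsp.A_s * xs + tsp.B_s * err_field

        latents, s = update_latents(latents, obs, False, p)
        sacc = with_noise and (rng.random() < params.saccade_rate)
        pupil, blinks = simulate_pupil_trace(
            ts.t, ts.events["movement_onset"], s, tonic_trial, params,
            rng=rng, with_noise=with_noise)
        ts.pupil_mm = pupil
        ts.blink_intervals = blinks
        _inject_gaze(ts, params, rng, sched.eye_distance_mm, sacc,
                     noise_sd_mm=0.4 if with_noise else 0.0)
        trials.append(ts)
        rows.append(dict(reach_index=ri, block=int(entry["block"]),
                         B=float(entry["B"]), is_channel=is_channel,
                         tonic=tonic_trial, surprise=s, x_f=xf, x_s=xs,
                         b_hat=b_hat, pve_true=pve_true, rt=rt, mt=mt,
                         saccade_in_movement=sacc))

    light = []
    noise = 0.01 if with_noise else 0.0
    for blk in range(1, len(sched.blocks) + 1):
        dark, bright = simulate_light_reflex(params, rng, noise_sd=noise)
        light.extend([(blk, "dark", dark), (blk, "bright", bright)])
    return ParticipantData(participant, direction, params, sched, trials,
                           light, pd.DataFrame(rows))


def _directions(experiment_id, n: int) -> np.ndarray:
    if not isinstance(experiment_id, str):
        base = [1, -1]
    elif experiment_id == "exp1":
        base = [1] * 20 + [-1] * 8
    elif experiment_id.startswith("exp2"):
        base = [1] * n
    elif experiment_id == "exp4":
        base = [1] * 19 + [-1] * 15
    else:
        base = [1, -1] * ((n + 1) // 2)
    out = (base * ((n // max(len(base), 1)) + 1))[:n]
    return np.asarray(out, dtype=int)


def generate_cohort(experiment_id: str, n_participants: int, seed: int,
                    params: ParticipantParams | None = None,
                    with_noise: bool = True,
                    reach_cfg: ReachConfig | None = None) -> Cohort:
    """Simulate ``n_participants`` synthetic participants, reproducibly."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    ss = np.random.SeedSequence(seed)
    sched_seed, *part_seeds = ss.spawn(n_participants + 1)
    schedule = make_schedule(experiment_id, np.random.default_rng(sched_seed))
    params = params or ParticipantParams()
    dirs = _directions(experiment_id, n_participants)
    participants = []
    for i in range(n_participants):
        rng = np.random.default_rng(part_seeds[i])
        participants.append(simulate_participant(
            schedule, params, rng, participant=i, direction=int(dirs[i]),
            reach_cfg=reach_cfg, with_noise=with_noise))
    return Cohort(schedule.experiment_id, seed, schedule, participants)


# --------------------------------------------------------------------------
# Disk round trip
# --------------------------------------------------------------------------

def write_schedule(schedule: Schedule, path) -> None:
    schedule.trials.to_csv(path, index=False)


def read_schedule_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def simulate_cohort(config: dict) -> Path:
    """Generate a cohort and write it to disk.

    ``config`` keys: ``experiment_id``, ``n_participants``, ``seed``,
    ``out`` (directory), optional ``with_noise`` and ``write_timeseries``.
    Writes schedule.csv, truth.csv, manifest.json and per-participant
    timeseries.csv / events.csv (long format).  Fully reproducible from seed.
    """
    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config["experiment_id"],
                             int(config["n_participants"]),
                             int(config["seed"]),
                             with_noise=config.get("with_noise", True))
    write_schedule(cohort.schedule, out / "schedule.csv")
    truth = []
    for pd_ in cohort.participants:
        df = pd_.truth.copy()
        df.insert(0, "participant", pd_.participant)
        df.insert(1, "direction", pd_.direction)
        truth.append(df)
    pd.concat(truth, ignore_index=True).to_csv(out / "truth.csv", index=False)
    if config.get("write_timeseries", True):
        for pdat in cohort.participants:
            pdir = out / f"participant_{pdat.participant:03d}"
            pdir.mkdir(exist_ok=True)
            _write_participant_timeseries(pdat, pdir)
    manifest = {
        "experiment_id": cohort.experiment_id,
        "n_participants": len(cohort.participants),
        "seed": cohort.seed,
        "rate_hz": RATE,
        "b_full": cohort.schedule.b_full,
        "amplitude_m": cohort.schedule.amplitude,
        "channel_stiffness": cohort.schedule.channel.stiffness,
        "channel_damping": cohort.schedule.channel.damping,
        "directions": [p.direction for p in cohort.participants],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_participant_timeseries(pdat: ParticipantData, pdir: Path) -> None:
    frames, events = [], []
    for ri, ts in zip(pdat.truth["reach_index"], pdat.trials):
        blink = np.zeros(len(ts.t), dtype=bool)
        for s0, s1 in ts.blink_intervals:
            blink |= (ts.t >= s0) & (ts.t <= s1)
        frames.append(pd.DataFrame({
            "participant": pdat.participant, "reach_index": ri, "t": ts.t,
            "hand_x": ts.hand_xy[:, 0], "hand_y": ts.hand_xy[:, 1],
            "vel_x": ts.vel_xy[:, 0], "vel_y": ts.vel_xy[:, 1],
            "force_x": ts.force_xy[:, 0], "force_y": ts.force_xy[:, 1],
            "gaze_x": ts.gaze_xy[:, 0], "gaze_y": ts.gaze_xy[:, 1],
            "pupil_mm": ts.pupil_mm, "blink": blink}))
        events.append((pdat.participant, ri, ts.events["go_cue"],
                       ts.events["movement_onset"], ts.events["movement_offset"]))
    pd.concat(frames, ignore_index=True).to_csv(pdir / "timeseries.csv", index=False)
    pd.DataFrame(events, columns=["participant", "reach_index", "go_cue",
                                  "movement_onset", "movement_offset"]
                 ).to_csv(pdir / "events.csv", index=False)


def simulate_reports(cohort: Cohort, rng=None,
                     slope: float = 0.6, offset: float = -4.0) -> pd.DataFrame:
    """Per-participant binary perturbation-recall vectors (one flag per block).

    Presence probability in each block is a logistic function of the
    participant's mean tonic latent in that block, so the recall-based split
    analysis has recoverable ground truth.
    """
    rng = np.random.default_rng(rng)
    rows = []
    n_blocks = len(cohort.schedule.blocks)
    for pdat in cohort.participants:
        g = pdat.truth.groupby("block")["tonic"].mean()
        floor = pdat.params.pupil.tonic_floor
        flags = []
        for blk in range(1, n_blocks + 1):
            z = offset + slope * (g.get(blk, floor) - floor)
            prob = 1.0 / (1.0 + np.exp(-z))
            flags.append(int(rng.random() < prob))
        rows.append([pdat.participant] + flags)
    cols = ["participant"] + [f"block{j}" for j in range(1, n_blocks + 1)]
    return pd.DataFrame(rows, columns=cols)
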