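"""Eye, pupil and kinematics conditioning.

Implements the standard pupillometry chain: blink masking with asymmetric
margins and shape-preserving cubic interpolation, Gaussian smoothing,
Savitzky-Golay differentiation, display-to-visual-angle transform, velocity
threshold saccade detection, and light-reflex normalization of pupil diameter
to a 0-100% scale.  Each trial is processed independently; no interpolation
crosses trial boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# --------------------------------------------------------------------------
# Blink handling
# --------------------------------------------------------------------------

def deblink(trace: np.ndarray, t: np.ndarray, blink_intervals,
            pre: float = 0.100, post: float = 0.150):
    """Discard samples from ``pre`` s before to ``post`` s after each blink and
    fill the gaps with a monotone piecewise-cubic (pchip) interpolant through
    the surviving samples.

    Samples outside the masked windows are returned bit-identical.  A blink at
    a trace edge is filled by nearest-value extension and flagged.  Returns
    ``(filled, edge_extended)``.
    """
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    mask = np.zeros(len(t), dtype=bool)
    for s0, s1 in blink_intervals:
        mask |= (t >= s0 - pre) & (t <= s1 + post)
    if not mask.any():
        return trace.copy(), False
    if mask.all():
        raise ValueError("blink mask covers the entire trace; no anchor points")
    out = trace.copy()
    keep = ~mask
    interp = PchipInterpolator(t[keep], trace[keep], extrapolate=False)
    filled = interp(t[mask])
    edge = False
    bad = ~np.isfinite(filled)
    if bad.any():  # masked samples beyond the first/last anchor
        edge = True
        tm = t[mask][bad]
        first, last = t[keep][0], t[keep][-1]
        filled[bad] = np.where(tm < first, trace[keep][0], trace[keep][-1])
    out[mask] = filled
    return out, edge


def detect_blinks_fallback(pupil_mm: np.ndarray, t: np.ndarray,
                           floor: float = 1.0):
    """Fallback blink detector: runs of pupil samples below a plausibility
    floor (mm).  Returns [(start, end)] in seconds."""
    bad = np.asarray(pupil_mm) < floor
    return _runs_to_intervals(bad, t)


def _runs_to_intervals(mask: np.ndarray, t: np.ndarray):
    out = []
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return out
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    for a, b in zip(starts, ends):
        out.append((float(t[a]), float(t[b])))
    return out


# --------------------------------------------------------------------------
# Smoothing and differentiation
# --------------------------------------------------------------------------

def gaussian_smooth(series: np.ndarray, fwhm_ms: float, rate: float) -> np.ndarray:
    """Convolve with a normalized Gaussian of the given FWHM (ms); reflection
    padding at the edges, output length equals input length."""
    if fwhm_ms <= 0:
        raise ValueError("fwhm must be positive")
    series = np.asarray(series, dtype=float)
    sigma = fwhm_ms / 1000.0 * rate * FWHM_TO_SIGMA
    if fwhm_ms / 1000.0 < 1.0 / rate:
        warnings.warn("FWHM shorter than one sample; returning input unchanged")
        return series.copy()
    return gaussian_filter1d(series, sigma, mode="reflect", truncate=8.0)


def savgol_velocity(position: np.ndarray, rate: float, frame_ms: float = 55.0,
                    order: int = 2) -> np.ndarray:
    """Savitzky-Golay filter the position then first-difference it.

    The returned velocity has length n-1; sample i is the forward difference
    between filtered samples i and i+1 times the rate (the derivative at the
    midpoint of that interval).
    """
    position = np.asarray(position, dtype=float)
    window = int(round(frame_ms / 1000.0 * rate))
    if window % 2 == 0:
        window += 1
    window = max(window, 3)
    if len(position) < window:
        raise ValueError(f"series shorter than the {window}-sample frame")
    smoothed = savgol_filter(position, window, order, mode="interp")
    return np.diff(smoothed) * rate


# --------------------------------------------------------------------------
# Gaze geometry and saccades
# --------------------------------------------------------------------------

def to_visual_angle(gaze_xy_mm: np.ndarray, eye_distance_mm: float,
                    center_mm=(0.0, 0.0)) -> np.ndarray:
    """Per-axis visual angle (degrees) of display positions, atan of the
    offset from the screen center over the eye-screen distance."""
    if eye_distance_mm <= 0:
        raise ValueError("eye_distance must be positive")
    g = np.atleast_2d(np.asarray(gaze_xy_mm, dtype=float))
    return np.degrees(np.arctan2(g - np.asarray(center_mm), eye_distance_mm))


@dataclass(frozen=True)
class SaccadeInterval:
    start: float
    end: float
    peak_velocity: float  # deg/s

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("saccade start must precede end")


def detect_saccades(vel_deg: np.ndarray, t: np.ndarray,
                    threshold: float = 30.0,
                    merge_gap: float = 0.010) -> list[SaccadeInterval]:
    """Maximal runs where the angular speed (Euclidean norm over the two axis
    velocities) is at or above ``threshold`` deg/s; runs separated by less
    than ``merge_gap`` s are merged."""
    v = np.atleast_2d(np.asarray(vel_deg, dtype=float))
    if v.shape[0] == 2 and v.shape[1] != 2:
        v = v.T
    speed = np.linalg.norm(v, axis=1) if v.shape[1] == 2 else np.abs(v).ravel()
    t = np.asarray(t, dtype=float)[: len(speed)]
    raw = _runs_to_intervals(speed >= threshold, t)
    merged: list[tuple[float, float]] = []
    for a, b in raw:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        m = (t >= a) & (t <= b)
        end = b if b > a else b + (t[1] - t[0])
        out.append(SaccadeInterval(a, end, float(speed[m].max())))
    return out


# --------------------------------------------------------------------------
# Light-reflex normalization
# --------------------------------------------------------------------------

@dataclass
class PupilCalibration:
    """Pupil limits from the light-reflex trials: constriction trough d_min
    (bright stimulus) and dilation peak d_max (dark stimulus), per block and
    block-averaged."""

    d_min: float
    d_max: float
    per_block: dict = field(default_factory=dict)  # block -> (d_min, d_max)

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("corrupt calibration: d_min >= d_max")


def calibrate_pupil(light_trials) -> PupilCalibration:
    """Average, over blocks, the trough of bright-trial traces and the peak of
    dark-trial traces.

    ``light_trials`` is an iterable of ``(block, stimulus, pupil_mm)`` with
    stimulus 'dark' or 'bright'.
    """
    dark: dict[int, list] = {}
    bright: dict[int, list] = {}
    for block, stim, trace in light_trials:
        store = dark if stim == "dark" else bright
        store.setdefault(block, []).append(np.asarray(trace, dtype=float))
    if not dark or not bright:
        raise ValueError("need at least one dark and one bright trial")
    per_block = {}
    mins, maxs = [], []
    for blk in sorted(set(dark) | set(bright)):
        bmin = np.mean([tr.min() for tr in bright[blk]]) if blk in bright else np.nan
        bmax = np.mean([tr.max() for tr in dark[blk]]) if blk in dark else np.nan
        per_block[blk] = (float(bmin), float(bmax))
        if np.isfinite(bmin):
            mins.append(bmin)
        if np.isfinite(bmax):
            maxs.append(bmax)
    return PupilCalibration(d_min=float(np.mean(mins)), d_max=float(np.mean(maxs)),
                            per_block=per_block)


def normalize_pupil(trace_mm: np.ndarray, calibration: PupilCalibration) -> np.ndarray:
    """Affine map onto percent of the light-reflex range: d_min -> 0,
    d_max -> 100."""
    rng = calibration.d_max - calibration.d_min
    if rng <= 0:
        raise ValueError("degenerate calibration range")
    return 100.0 * (np.asarray(trace_mm, dtype=float) - calibration.d_min) / rng


def pupil_velocity(normalized: np.ndarray, rate: float) -> np.ndarray:
    """Pupil dilation velocity (%/s) by first difference of the normalized
    trace; length n-1."""
    return np.diff(np.asarray(normalized, dtype=float)) * rate


# --------------------------------------------------------------------------
# Per-trial pipeline
# --------------------------------------------------------------------------

@dataclass
class PreprocessedTrial:
    t: np.ndarray
    rate: float
    hand_xy: np.ndarray
    vel_xy: np.ndarray        # smoothed
    force_xy: np.ndarray      # smoothed
    pupil_norm: np.ndarray    # % of light-reflex range, deblinked + smoothed
    pupil_vel: np.ndarray     # %/s, length n-1
    gaze_deg: np.ndarray
    saccades: list
    events: dict
    edge_extended: bool = False


def preprocess_trial(ts, calibration: PupilCalibration,
                     eye_distance_mm: float,
                     fwhm_kin_ms: float = 35.0, fwhm_pupil_ms: float = 235.0,
                     sg_frame_ms: float = 55.0, sg_order: int = 2,
                     saccade_threshold: float = 30.0,
                     blink_pre: float = 0.100, blink_post: float = 0.150
                     ) -> PreprocessedTrial:
    """Full conditioning chain for one trial.

    Kinematics and forces are Gaussian-smoothed (35 ms FWHM).  Gaze is
    deblinked, transformed to visual angle, Savitzky-Golay differentiated
    (order 2, 55 ms frame) and scanned for saccades at 30 deg/s.  Pupil is
    deblinked, smoothed at 235 ms FWHM, normalized to the light-reflex range
    and differentiated to dilation velocity.
    """
    rate = ts.rate
    blinks = ts.blink_intervals
    hand = np.column_stack([gaussian_smooth(ts.hand_xy[:, j], fwhm_kin_ms, rate)
                            for j in range(2)])
    vel = np.column_stack([gaussian_smooth(ts.vel_xy[:, j], fwhm_kin_ms, rate)
                           for j in range(2)])
    force = np.column_stack([gaussian_smooth(ts.force_xy[:, j], fwhm_kin_ms, rate)
                             for j in range(2)])
    gaze_db = np.empty_like(ts.gaze_xy)
    edge = False
    for j in range(2):
        gaze_db[:, j], e = deblink(ts.gaze_xy[:, j], ts.t, blinks,
                                   blink_pre, blink_post)
        edge |= e
    gaze_deg = to_visual_angle(gaze_db, eye_distance_mm)
    ang_vel = np.column_stack([
        savgol_velocity(gaze_deg[:, j], rate, sg_frame_ms, sg_order)
        for j in range(2)])
    saccades = detect_saccades(ang_vel, ts.t, saccade_threshold)

    pupil, e = deblink(ts.pupil_mm, ts.t, blinks, blink_pre, blink_post)
    edge |= e
    pupil = gaussian_smooth(pupil, fwhm_pupil_ms, rate)
    pupil_norm = normalize_pupil(pupil, calibration)
    pvel = pupil_velocity(pupil_norm, rate)
    return PreprocessedTrial(t=ts.t, rate=rate, hand_xy=hand,
                             vel_xy=vel, force_xy=force,
                             pupil_norm=pupil_norm, pupil_vel=pvel,
                             gaze_deg=gaze_deg, saccades=saccades,
                             events=dict(ts.events), edge_extended=edge)
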