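"""Two-state state-space model of motor adaptation and washout statistics.

The learner carries a fast state (high learning rate, low retention) and a
slow state (low learning rate, high retention); their sum is the net
adaptation.  With the field series f(n) normalized to 1 at full strength,

    e(n)      = f(n) - x(n),            x(n) = x_f(n) + x_s(n)
    x_i(n+1)  = A_i x_i(n) + B_i e(n),  i in {fast, slow}

On channel trials the kinematic error is clamped by the channel, so the
update is retention-only (e treated as 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class TwoStateParams:
    """Retention factors A and learning rates B of the fast/slow states."""

    A_f: float
    A_s: float
    B_f: float
    B_s: float

    def __post_init__(self) -> None:
        for name in ("A_f", "A_s", "B_f", "B_s"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.A_s > self.A_f:
            raise ValueError("slow state must retain better (A_s > A_f)")
        if not self.B_f > self.B_s:
            raise ValueError("fast state must learn faster (B_f > B_s)")

    def as_array(self) -> np.ndarray:
        return np.array([self.A_f, self.A_s, self.B_f, self.B_s])


def two_state_simulate(params: TwoStateParams, f: np.ndarray,
                       is_channel: np.ndarray | None = None,
                       x0: tuple[float, float] = (0.0, 0.0),
                       return_states: bool = False):
    """Simulate net adaptation x(n) and error e(n) over a field series.

    ``f`` is the per-trial field in full-strength units; ``is_channel`` marks
    trials whose error is clamped (retention-only update).
    """
    f = np.asarray(f, dtype=float)
    n = len(f)
    ch = np.zeros(n, dtype=bool) if is_channel is None else np.asarray(is_channel, bool)
    xf = np.empty(n + 1)
    xs = np.empty(n + 1)
    xf[0], xs[0] = x0
    e = np.empty(n)
    for i in range(n):
        x = xf[i] + xs[i]
        e[i] = 0.0 if ch[i] else f[i] - x
        xf[i + 1] = params.A_f * xf[i] + params.B_f * e[i]
        xs[i + 1] = params.A_s * xs[i] + params.B_s * e[i]
    x_net = xf[:-1] + xs[:-1]
    if return_states:
        return x_net, e, xf[:-1], xs[:-1]
    return x_net, e


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

_EPS = 1e-4


def _theta_to_params(theta: np.ndarray) -> TwoStateParams:
    """Map an unconstrained-in-ordering box vector onto the invariant region:
    A_s > A_f and B_f > B_s by construction."""
    af, u, bs, w = theta
    a_s = af + (1.0 - af) * u
    b_f = bs + (1.0 - bs) * w
    return TwoStateParams(A_f=af, A_s=min(a_s, 1 - 1e-9),
                          B_f=min(b_f, 1 - 1e-9), B_s=bs)


def _params_to_theta(p: TwoStateParams) -> np.ndarray:
    u = (p.A_s - p.A_f) / (1.0 - p.A_f)
    w = (p.B_f - p.B_s) / (1.0 - p.B_s)
    return np.array([p.A_f, u, p.B_s, w])


@dataclass
class TwoStateFitResult:
    params: TwoStateParams
    cost: float              # sum of squared residuals
    unidentifiable: bool


def two_state_fit(y: np.ndarray, f: np.ndarray, is_channel: np.ndarray,
                  n_starts: int = 20, rng=None,
                  x0: tuple[float, float] = (0.0, 0.0)) -> TwoStateFitResult:
    """Least-squares fit of the two-state model to observed learning indices.

    ``y`` is aligned with the reaching-trial series ``f`` (normalized to full
    field strength) and is NaN wherever no observation exists (non-channel
    trials, excluded trials, the washout phase).  Multi-start box-bounded
    least squares inside the invariant region; returns the best of starts.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    is_channel = np.asarray(is_channel, dtype=bool)
    obs = np.isfinite(y)
    if obs.sum() == 0:
        raise ValueError("all-missing observation series")
    if obs.sum() < 4:
        raise ValueError("fewer observations than parameters")
    rng = np.random.default_rng(rng)

    def resid(theta):
        p = _theta_to_params(np.clip(theta, _EPS, 1 - _EPS))
        x, _ = two_state_simulate(p, f, is_channel, x0=x0)
        return x[obs] - y[obs]

    lo = np.full(4, _EPS)
    hi = np.full(4, 1.0 - _EPS)
    starts = [np.array([0.7, 0.5, 0.05, 0.5])]
    starts += [rng.uniform(0.05, 0.95, 4) for _ in range(max(n_starts - 1, 0))]
    best = None
    for th0 in starts:
        try:
            sol = optimize.least_squares(resid, th0, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")
    params = _theta_to_params(np.clip(best.x, _EPS, 1 - _EPS))
    # flat/degenerate data pins the learning rates at the lower bound
    unident = (params.B_f <= 2 * _EPS and params.B_s <= 2 * _EPS) or (
        np.nanstd(y[obs]) < 1e-12)
    return TwoStateFitResult(params=params, cost=2 * best.cost,
                             unidentifiable=bool(unident))


# --------------------------------------------------------------------------
# Bootstrap washout prediction
# --------------------------------------------------------------------------

@dataclass
class TwoStateFit:
    """Bootstrap fit with washout prediction bands (percentile 2.5/97.5)."""

    point: TwoStateParams
    draws: np.ndarray            # (n_boot, 4) parameter draws
    washout_idx: np.ndarray      # reaching-trial positions (0-based) of the band
    band_lower: np.ndarray
    band_median: np.ndarray
    band_upper: np.ndarray
    actual_mean: np.ndarray      # group-average observed washout series
    below_band: np.ndarray       # actual < lower bound, per washout trial
    longest_below_run: int


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def bootstrap_washout_prediction(li: np.ndarray, f: np.ndarray,
                                 is_channel: np.ndarray, washout_start: int,
                                 n_boot: int = 1000, rng=None,
                                 n_starts: int = 5) -> TwoStateFit:
    """Predict the washout learning-index trajectory from training trials.

    ``li`` is a (participants x reaching trials) matrix of normalized learning
    indices (NaN off-channel); ``washout_start`` is the 0-based reaching-trial
    position of the first washout trial.  Participants are resampled with
    replacement ``n_boot`` times; each resample is refit on the training
    portion and simulated forward through washout.  Reports the per-trial 95%
    percentile band at the washout channel trials and the longest run of
    consecutive such trials where the actual group mean falls below the lower
    bound.
    """
    li = np.asarray(li, dtype=float)
    if li.ndim != 2 or li.shape[0] < 2:
        raise ValueError("need a (participants x trials) matrix with >= 2 rows")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile bands")
    rng = np.random.default_rng(rng)
    n_sub, n_trials = li.shape
    train = np.arange(n_trials) < washout_start
    wash_obs = np.nonzero(~train & np.any(np.isfinite(li), axis=0)
                          & np.asarray(is_channel, bool))[0]

    def fit_mean(rows):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y = np.nanmean(li[rows], axis=0)
        y_train = np.where(train, y, np.nan)
        return two_state_fit(y_train, f, is_channel, n_starts=n_starts, rng=rng)

    point = fit_mean(np.arange(n_sub))
    draws = np.empty((n_boot, 4))
    preds = np.empty((n_boot, len(wash_obs)))
    b = 0
    while b < n_boot:
        rows = rng.integers(0, n_sub, size=n_sub)
        if len(np.unique(rows)) < 2:
            continue  # degenerate resample, draw again
        res = fit_mean(rows)
        draws[b] = res.params.as_array()
        x, _ = two_state_simulate(res.params, f, is_channel)
        preds[b] = x[wash_obs]
        b += 1

    lower = np.percentile(preds, 2.5, axis=0)
    med = np.percentile(preds, 50.0, axis=0)
    upper = np.percentile(preds, 97.5, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        actual = np.nanmean(li[:, wash_obs], axis=0)
    below = actual < lower
    return TwoStateFit(point=point.params, draws=draws, washout_idx=wash_obs,
                       band_lower=lower, band_median=med, band_upper=upper,
                       actual_mean=actual, below_band=below,
                       longest_below_run=_longest_run(below))


# --------------------------------------------------------------------------
# %-change latency
# --------------------------------------------------------------------------

def to_percent_change(series: np.ndarray, start_level: float,
                      plateau_level: float) -> np.ndarray:
    """Affine map to %-change units: 0 at the phase-start level, 100 at the
    plateau.  For washout pass the (flipped) plateau as start and the
    recovery level as plateau."""
    if plateau_level == start_level:
        raise ValueError("plateau equals start level")
    return 100.0 * (np.asarray(series, float) - start_level) / (
        plateau_level - start_level)


@dataclass
class LatencyResult:
    latencies: dict      # threshold (%) -> 1-based index or None
    n_required: int


def percent_change_latency(series: np.ndarray,
                           thresholds=(40, 50, 60, 70, 80),
                           n_required: int = 10) -> LatencyResult:
    """Trial/cycle at which the %-change series has exceeded each threshold
    ``n_required`` times in total (the index of the n-th exceedance)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    out = {}
    for x in thresholds:
        exceed = np.nonzero(series > x)[0]
        out[x] = int(exceed[n_required - 1]) + 1 if len(exceed) >= n_required else None
    return LatencyResult(latencies=out, n_required=n_required)


# --------------------------------------------------------------------------
# Error -> pupil mixed-model prediction test
# --------------------------------------------------------------------------

def lme_error_pupil_predict(train: pd.DataFrame, test: pd.DataFrame) -> dict:
    """Fit dilation ~ |error| with random intercept+slope per participant on
    training pairs, predict each participant's test dilation from their test
    error, and compare actual vs predicted with a two-sided paired t test.

    ``train`` and ``test`` need columns participant, abs_error, dilation.
    A singular random-effects fit falls back to the fixed-effects-only model
    (``singular_fallback`` flag in the result).
    """
    import statsmodels.formula.api as smf

    train = train.dropna(subset=["abs_error", "dilation"])
    test = test.dropna(subset=["abs_error", "dilation"])
    if train["participant"].nunique() < 5:
        raise ValueError("need >= 5 participants with complete pairs")
    singular = False
    re_int = {}
    re_slope = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("dilation ~ abs_error", train,
                             groups=train["participant"],
                             re_formula="~abs_error")
            fit = md.fit(reml=True)
        if not np.all(np.isfinite(fit.fe_params)) or np.any(
                np.linalg.eigvalsh(fit.cov_re) < 1e-12):
            raise np.linalg.LinAlgError("singular random-effects covariance")
        fe_int, fe_slope = fit.fe_params.iloc[0], fit.fe_params.iloc[1]
        for pid, re in fit.random_effects.items():
            re_int[pid] = float(re.iloc[0])
            re_slope[pid] = float(re.iloc[1]) if len(re) > 1 else 0.0
    except Exception:
        singular = True
        ols = smf.ols("dilation ~ abs_error", train).fit()
        fe_int, fe_slope = ols.params.iloc[0], ols.params.iloc[1]

    rows = test.groupby("participant").agg(
        abs_error=("abs_error", "mean"), dilation=("dilation", "mean"))
    predicted, actual = [], []
    for pid, row in rows.iterrows():
        a = fe_int + re_int.get(pid, 0.0)
        b = fe_slope + re_slope.get(pid, 0.0)
        predicted.append(a + b * row["abs_error"])
        actual.append(row["dilation"])
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    tstat, p = stats.ttest_rel(actual, predicted)
    return {"predicted": predicted, "actual": actual,
            "t": float(tstat), "p": float(p), "df": len(actual) - 1,
            "singular_fallback": singular}
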