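"""Frame-wise group inference on event-locked traces.

Running two-sided paired t tests per time frame with Holm-Bonferroni
(family-wise error 0.05) and Benjamini-Hochberg (false discovery rate 0.05)
correction, first-significant-frame latency extraction, and a cluster-mass
sign-flip permutation test (cluster-forming p 0.01, cluster significance
0.05, max-|mass| null, exact enumeration for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


# --------------------------------------------------------------------------
# Event-locked trace alignment
# --------------------------------------------------------------------------

def align_traces(trials, align: str = "movement_onset",
                 window: tuple = (-0.5, 1.5), rate: float = 200.0,
                 signal: str = "pupil_vel") -> tuple[np.ndarray, np.ndarray]:
    """Resample a per-trial signal onto a common event-locked grid.

    Returns ``(t_grid, matrix)`` with one row per trial; samples outside a
    trial's span are NaN.
    """
    t_grid = np.arange(round(window[0] * rate), round(window[1] * rate) + 1) / rate
    rows = []
    for pre in trials:
        t0 = pre.events[align]
        sig = getattr(pre, signal)
        t_sig = pre.t[: len(sig)]
        rows.append(np.interp(t_grid + t0, t_sig, sig,
                              left=np.nan, right=np.nan))
    return t_grid, np.asarray(rows)


# --------------------------------------------------------------------------
# Running paired t tests and corrections
# --------------------------------------------------------------------------

@dataclass
class RunningTestResult:
    t: np.ndarray            # per-frame paired t statistic
    p: np.ndarray            # two-sided p
    df: np.ndarray           # per-frame degrees of freedom
    hb_mask: np.ndarray      # Holm-Bonferroni rejections
    bh_mask: np.ndarray      # Benjamini-Hochberg rejections
    degenerate: np.ndarray = field(default_factory=lambda: np.array([], bool))


def running_paired_ttests(a: np.ndarray, b: np.ndarray,
                          alpha: float = 0.05, q: float = 0.05
                          ) -> RunningTestResult:
    """Frame-wise two-sided paired t tests between two (subjects x frames)
    condition matrices, with HB and BH corrected rejection masks.

    Subjects missing either condition at a frame are dropped pairwise; frames
    with fewer than two complete subjects get NaN statistics.  Zero-variance
    nonzero differences yield p = 0 (the distribution limit) and are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must share shape")
    d = a - b
    valid = np.isfinite(d)
    n = valid.sum(axis=0).astype(float)
    dm = np.where(valid, d, 0.0)
    mean = dm.sum(axis=0) / np.maximum(n, 1)
    ss = (np.where(valid, (d - mean) ** 2, 0.0)).sum(axis=0)
    sd = np.sqrt(ss / np.maximum(n - 1, 1))
    df = n - 1
    degenerate = (sd == 0) & (mean != 0) & (n >= 2)
    trivial = (sd == 0) & (mean == 0) & (n >= 2)  # identical conditions
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, np.inf * np.sign(mean), t)
    t = np.where(trivial, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(degenerate, 0.0, p)
    p = np.where(trivial, 1.0, p)
    bad = n < 2
    t[bad] = np.nan
    p[bad] = np.nan
    ok = np.isfinite(p)
    hb = np.zeros_like(ok)
    bh = np.zeros_like(ok)
    if ok.any():
        hb[ok] = holm_bonferroni(p[ok], alpha)
        bh[ok] = benjamini_hochberg(p[ok], q)
    return RunningTestResult(t=t, p=p, df=df, hb_mask=hb, bh_mask=bh,
                             degenerate=degenerate)


def holm_bonferroni(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down rejection mask: sort ascending and reject while
    p(i) <= alpha / (m - i + 1), stopping at the first failure."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    ok = p[order] <= alpha / (m - np.arange(m))
    k = int(np.argmin(ok)) if not ok.all() else m  # first failure stops
    reject[order[:k]] = True
    return reject


def benjamini_hochberg(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask: reject the k smallest
    p values where k is the largest index with p(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    ok = p[order] <= (np.arange(m) + 1) * q / m
    k = m - int(np.argmax(ok[::-1])) if ok.any() else 0
    reject[order[:k]] = True
    return reject


def first_significant_latency(mask: np.ndarray, t_grid: np.ndarray,
                              onset_time: float = 0.0):
    """Time (ms, relative to ``onset_time``) of the first rejected frame at or
    after the movement onset; None if the mask is empty there."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & (t_grid >= onset_time)
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        return None
    return float((t_grid[idx[0]] - onset_time) * 1000.0)


# --------------------------------------------------------------------------
# Cluster-mass sign-flip permutation test
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int    # frame index, inclusive
    end: int      # frame index, inclusive
    mass: float   # sum of t within the cluster (signed)
    p: float


@dataclass
class ClusterResult:
    clusters: list
    cluster_alpha: float
    alpha: float
    n_perm: int
    exact: bool
    t: np.ndarray

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p < self.alpha]


def _paired_t(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / np.sqrt(n))


def _clusters_from_t(t: np.ndarray, thr: float):
    """Maximal runs of frames with |t| above the cluster-forming threshold;
    positive and negative runs are separate clusters."""
    out = []
    for sign in (1, -1):
        m = (sign * t) > thr
        i = 0
        while i < len(m):
            if m[i]:
                j = i
                while j + 1 < len(m) and m[j + 1]:
                    j += 1
                out.append((i, j, float(t[i:j + 1].sum())))
                i = j + 1
            else:
                i += 1
    return sorted(out)


def _flip_max_masses(d: np.ndarray, signs: np.ndarray, thr: float) -> np.ndarray:
    """Max |cluster mass| for every sign-flip row of ``signs``.

    Uses the identity that the per-frame sum of squares is invariant under
    sign flips, so all permutation t maps come from one matrix product.
    """
    n, _ = d.shape
    sumsq = (d ** 2).sum(axis=0)
    means = signs @ d / n
    var = (sumsq / n - means ** 2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = means / np.sqrt(var / n)
    t_all = np.nan_to_num(t_all, nan=0.0, posinf=0.0, neginf=0.0)
    out = np.zeros(len(signs))
    for k, t_row in enumerate(t_all):
        cl = _clusters_from_t(t_row, thr)
        if cl:
            out[k] = max(abs(c[2]) for c in cl)
    return out


def cluster_mass_permutation(diff: np.ndarray, cluster_alpha: float = 0.01,
                             alpha: float = 0.05, n_perm: int = 10000,
                             rng=None, exact_max_subjects: int = 12
                             ) -> ClusterResult:
    """Cluster-mass sign-flip permutation test on subject difference traces.

    Observed clusters are maximal runs of frames whose paired t exceeds the
    two-sided ``cluster_alpha`` t quantile; the cluster statistic is the sum
    of t within the run.  The null is the max |mass| over sign-flips of the
    subject traces: full 2^n enumeration when n <= ``exact_max_subjects``,
    otherwise ``n_perm`` sampled flips.  Cluster p uses the add-one estimator
    (1 + #{null >= observed}) / (n_used + 1), so it is never 0.
    """
    diff = np.asarray(diff, dtype=float)
    if diff.ndim != 2 or diff.shape[0] < 2:
        raise ValueError("need a (subjects x frames) matrix with >= 2 rows")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    keep = np.all(np.isfinite(diff), axis=0)  # frames missing subjects dropped
    d = diff[:, keep]
    n = d.shape[0]
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1)
    t_obs_kept = _paired_t(np.where(np.isfinite(d), d, 0.0))
    t_obs_kept = np.nan_to_num(t_obs_kept, nan=0.0, posinf=0.0, neginf=0.0)
    obs = _clusters_from_t(t_obs_kept, thr)

    exact = n <= exact_max_subjects
    if exact:
        m = 2 ** n
        signs = 1.0 - 2.0 * ((np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1)
        n_used = m
    else:
        rng = np.random.default_rng(rng)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_used = n_perm
    null = _flip_max_masses(d, signs, thr)

    kept_idx = np.nonzero(keep)[0]
    clusters = []
    for i, j, mass in obs:
        p = (1.0 + float(np.sum(null >= abs(mass)))) / (n_used + 1.0)
        clusters.append(Cluster(start=int(kept_idx[i]), end=int(kept_idx[j]),
                                mass=mass, p=p))
    t_full = np.full(diff.shape[1], np.nan)
    t_full[keep] = t_obs_kept
    return ClusterResult(clusters=clusters, cluster_alpha=cluster_alpha,
                         alpha=alpha, n_perm=n_used, exact=exact, t=t_full)
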