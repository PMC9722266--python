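"""Experiment-level analyses.

Change-point response amplitudes and their mixed-model trends (number of
change points, length of the preceding environment), set-break early/late
contrasts, the recall-based median split with block-wise chi-square tests, and
the subgroup-by-block mixed-model comparison on cycle-binned data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries_stats import benjamini_hochberg, holm_bonferroni

#: blocks whose initial 10 trials are perturbation-free (or nearly so),
#: eligible for the set-break contrast
SETBREAK_BLOCKS = {
    "exp1": (1, 2, 5),
    "exp2A": (1, 2), "exp2B": (1, 2), "exp2C": (1, 2), "exp2": (1, 2),
    "exp3": (1, 2, 3, 4),
    "exp4": (1, 2, 3, 4),
}


# --------------------------------------------------------------------------
# Change points
# --------------------------------------------------------------------------

@dataclass
class ChangePointRecord:
    participant: int
    cp_reach_index: int
    cp_number: int          # ordinal within participant
    prev_env_length: int    # trials in the preceding constant-field run
    measure: str            # 'dilation' or 'baseline'
    pre: float              # mean z over trials [cp-3, cp-1]
    post: float             # z at cp (dilation) or cp+1 (baseline)
    amplitude: float        # post - pre
    abs_pve_cp: float       # |PVE| at the change point
    abs_pve_prev: float     # |PVE| at trial cp-1
    abs_epe_prev: float     # EPE at trial cp-1
    direction: float        # sign of the new field (0 on removal)
    truncated_pre: bool


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=0)
    if s == 0 or not np.isfinite(s):
        return np.full_like(x, np.nan)
    return (x - m) / s


def scan_change_points(b: np.ndarray, blocks) -> np.ndarray:
    """Brute-force scan for field sign-category flips strictly inside blocks
    (1-based reach indices)."""
    sign = np.sign(np.asarray(b, dtype=float))
    starts = {s for s, _ in blocks}
    return np.asarray([i + 1 for i in range(1, len(b))
                       if sign[i] != sign[i - 1] and (i + 1) not in starts],
                      dtype=int)


def prev_env_length(cp: int, b: np.ndarray) -> int:
    """Length of the maximal constant-sign field run immediately before the
    change point (1-based reach index)."""
    sign = np.sign(np.asarray(b, dtype=float))
    j = cp - 2  # 0-based index of the trial before the cp
    run = 0
    while j - run >= 0 and sign[j - run] == sign[j]:
        run += 1
    return run


def changepoint_table(trial_table: pd.DataFrame, schedule,
                      pre_window: int = 3) -> pd.DataFrame:
    """Per-participant change-point response records.

    Dilation velocity and baseline pupil are z-scored within participant over
    all reaching trials; the pre value is the mean z over the ``pre_window``
    trials before the change point, the post value is z at the change point
    (dilation) or the following trial (baseline).
    """
    cps = schedule.change_points
    b = schedule.reaching["B"].to_numpy()
    block_starts = {s for s, _ in schedule.blocks}
    rows = []
    for pid, sub in trial_table.groupby("participant"):
        sub = sub.sort_values("reach_index").set_index("reach_index")
        z_dil = pd.Series(zscore(sub["dilation_velocity"].to_numpy()), index=sub.index)
        z_base = pd.Series(zscore(sub["baseline_pupil"].to_numpy()), index=sub.index)
        pve = sub["PVE"].abs()
        epe = sub["EPE"]
        for k, cp in enumerate(cps, start=1):
            lo = cp - pre_window
            truncated = any(s > lo and s <= cp for s in block_starts)
            lo = max(lo, 1)
            pre_idx = [i for i in range(lo, cp) if i in sub.index]
            for measure, zser, post_idx in (
                    ("dilation", z_dil, cp),
                    ("baseline", z_base, cp + 1)):
                if post_idx not in sub.index:
                    continue
                pre_val = float(zser.loc[pre_idx].mean()) if pre_idx else np.nan
                post_val = float(zser.loc[post_idx])
                rows.append(dict(
                    participant=pid, cp_reach_index=int(cp), cp_number=k,
                    prev_env_length=prev_env_length(int(cp), b),
                    measure=measure, pre=pre_val, post=post_val,
                    amplitude=post_val - pre_val,
                    abs_pve_cp=float(pve.get(cp, np.nan)),
                    abs_pve_prev=float(pve.get(cp - 1, np.nan)),
                    abs_epe_prev=float(epe.get(cp - 1, np.nan)),
                    direction=float(np.sign(b[cp - 1])),
                    truncated_pre=truncated))
    return pd.DataFrame(rows)


def changepoint_lme(records: pd.DataFrame, measure: str = "dilation",
                    group_col: str | None = None) -> dict:
    """Mixed model of change-point response amplitude on the number of change
    points and the length of the preceding environment.

    Fixed effects: intercept, cp_number, prev_env_length, field direction and
    the error-magnitude covariates; random intercept and cp_number slope per
    participant.  The random slope's contribution is assessed by a
    likelihood-ratio test against the intercept-only random structure.
    A singular fit falls back to a random-intercept model, flagged.
    """
    import statsmodels.formula.api as smf

    df = records[records["measure"] == measure].dropna(
        subset=["amplitude", "cp_number", "prev_env_length"]).copy()
    if df.empty:
        raise ValueError("no usable change-point records")
    err_terms = []
    if measure == "dilation" and df["abs_pve_cp"].notna().any():
        err_terms.append("abs_pve_cp")
    if measure == "baseline":
        for c in ("abs_pve_prev", "abs_epe_prev"):
            if df[c].notna().any():
                err_terms.append(c)
    df = df.dropna(subset=err_terms) if err_terms else df
    terms = ["cp_number", "prev_env_length"] + err_terms
    if df["direction"].nunique() > 1:
        terms.append("C(direction)")
    if group_col and group_col in df and df[group_col].nunique() > 1:
        terms.append(f"C({group_col})")
    formula = "amplitude ~ " + " + ".join(terms)

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, df, groups=df["participant"],
                             re_formula=re_formula)
            return md.fit(reml=True)

    singular = False
    try:
        full = _fit("~cp_number")
        if np.any(np.linalg.eigvalsh(full.cov_re) < 1e-10):
            raise np.linalg.LinAlgError
    except Exception:
        singular = True
        full = _fit("1")
    reduced = _fit("1")
    lrt_stat = float(2.0 * (full.llf - reduced.llf)) if not singular else 0.0
    lrt_p = float(stats.chi2.sf(max(lrt_stat, 0.0), df=2)) if not singular else 1.0
    out = {"singular_fallback": singular,
           "lrt_stat": lrt_stat, "lrt_p": lrt_p}
    for term in ("cp_number", "prev_env_length"):
        out[term] = {"estimate": float(full.fe_params[term]),
                     "p": float(full.pvalues[term])}
    return out


# --------------------------------------------------------------------------
# Set breaks
# --------------------------------------------------------------------------

def setbreak_contrast(trial_table: pd.DataFrame, experiment_id: str,
                      measures=("baseline_pupil", "dilation_velocity",
                                "RT", "MT")) -> pd.DataFrame:
    """Early (block trials 1-2) vs late (6-10) contrast after set breaks.

    Uses only blocks whose first 10 trials are perturbation-free for the
    experiment; per participant, measures are averaged over the early and
    late positions pooled across eligible blocks, then compared with a
    two-sided paired t test per measure.  Deltas are early minus late.
    """
    if experiment_id not in SETBREAK_BLOCKS:
        raise ValueError(f"unknown experiment_id: {experiment_id!r}")
    blocks = SETBREAK_BLOCKS[experiment_id]
    df = trial_table[trial_table["block"].isin(blocks)].copy()
    pos = df.groupby(["participant", "block"])["reach_index"].rank("first")
    df["block_pos"] = pos
    early = df[df["block_pos"] <= 2]
    late = df[(df["block_pos"] >= 6) & (df["block_pos"] <= 10)]
    rows = []
    for m in measures:
        e = early.groupby("participant")[m].mean()
        l = late.groupby("participant")[m].mean()
        common = e.index.intersection(l.index)
        e, l = e.loc[common], l.loc[common]
        ok = e.notna() & l.notna()
        if ok.sum() < 2:
            rows.append(dict(measure=m, delta=np.nan, t=np.nan, p=np.nan,
                             df=int(ok.sum()) - 1))
            continue
        tstat, p = stats.ttest_rel(e[ok], l[ok])
        rows.append(dict(measure=m, delta=float((e[ok] - l[ok]).mean()),
                         t=float(tstat), p=float(p), df=int(ok.sum()) - 1))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Recall-based median split
# --------------------------------------------------------------------------

@dataclass
class SubgroupSplit:
    scores: pd.Series        # participant -> total report score (0..n_blocks)
    group: pd.Series         # participant -> 'low' | 'high'
    median: float
    block_tests: pd.DataFrame  # block, chi2, p, present counts per group


def recall_split(reports: pd.DataFrame, continuity: bool = False) -> SubgroupSplit:
    """Median split on the total report score with per-block chi-square tests.

    ``reports`` has a ``participant`` column and one binary column per block.
    Participants strictly below the median score form the low group;
    at-or-above-median participants form the high group (ties go high).  The
    per-block 2x2 (group x present/absent) Pearson chi-square is computed
    without continuity correction by default.
    """
    block_cols = [c for c in reports.columns if c != "participant"]
    scores = reports[block_cols].sum(axis=1)
    scores.index = reports["participant"]
    med = float(scores.median())
    if scores.nunique() == 1:
        raise ValueError("all report scores identical; split undefined")
    group = pd.Series(np.where(scores < med, "low", "high"), index=scores.index)
    rows = []
    for j, col in enumerate(block_cols, start=1):
        present = reports.set_index("participant")[col]
        tab = np.zeros((2, 2))
        for gi, g in enumerate(("low", "high")):
            sel = present[group == g]
            tab[gi, 0] = (sel == 1).sum()
            tab[gi, 1] = (sel == 0).sum()
        if np.any(tab.sum(axis=1) == 0) or np.any(tab.sum(axis=0) == 0):
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=continuity)
        rows.append(dict(block=j, chi2=float(chi2), p=float(p),
                         present_low=int(tab[0, 0]), n_low=int(tab[0].sum()),
                         present_high=int(tab[1, 0]), n_high=int(tab[1].sum())))
    return SubgroupSplit(scores=scores, group=group, median=med,
                         block_tests=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Subgroup x block mixed model
# --------------------------------------------------------------------------

def cycle_bin(trial_table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Average a measure within participant x cycle (5-trial bins)."""
    g = (trial_table.groupby(["participant", "block", "cycle"])[measure]
         .mean().reset_index())
    return g.rename(columns={measure: "value"})


def subgroup_block_lme(trial_table: pd.DataFrame, split: SubgroupSplit,
                       measure: str, exclude_cycles=(),
                       alpha: float = 0.05, q: float = 0.05) -> pd.DataFrame:
    """Per-block subgroup effect on cycle-binned data via a mixed model.

    The model has a per-block intercept, a per-block linear cycle trend
    (cycle centered within block), a random intercept and cycle slope per
    subject, and a per-block subgroup contrast as the effect of interest.
    Per-block contrast p values are corrected with both Holm-Bonferroni and
    Benjamini-Hochberg.  Blocks with one subgroup absent are skipped and
    flagged.
    """
    import statsmodels.formula.api as smf

    data = cycle_bin(trial_table, measure)
    data = data[~data["cycle"].isin(set(exclude_cycles))].copy()
    data = data.dropna(subset=["value"])
    data["group"] = split.group.reindex(data["participant"]).to_numpy()
    data = data.dropna(subset=["group"])
    data["cycle_c"] = data["cycle"] - data.groupby("block")["cycle"].transform("mean")
    keep, skipped = [], []
    for blk, sub in data.groupby("block"):
        if sub["group"].nunique() < 2:
            skipped.append(blk)
        else:
            keep.append(blk)
    data = data[data["block"].isin(keep)]
    data["ishigh"] = (data["group"] == "high").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("value ~ 0 + C(block) + C(block):cycle_c + C(block):ishigh",
                         data, groups=data["participant"], re_formula="~cycle_c")
        fit = md.fit(reml=True)
    rows = []
    for blk in keep:
        name = f"C(block)[{blk}]:ishigh"
        rows.append(dict(block=blk, estimate=float(fit.fe_params[name]),
                         p=float(fit.pvalues[name]), skipped=False))
    for blk in skipped:
        rows.append(dict(block=blk, estimate=np.nan, p=np.nan, skipped=True))
    res = pd.DataFrame(rows).sort_values("block").reset_index(drop=True)
    ok = res["p"].notna()
    res["hb_significant"] = False
    res["bh_significant"] = False
    if ok.any():
        res.loc[ok, "hb_significant"] = holm_bonferroni(res.loc[ok, "p"].to_numpy(), alpha)
        res.loc[ok, "bh_significant"] = benjamini_hochberg(res.loc[ok, "p"].to_numpy(), q)
    return res
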