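"""Luciferase reporter statistics.

Per-well firefly activity is normalized by the co-transfected Renilla
signal; outliers within each (bait, TF) group of normalized ratios are
excluded by the fourth-spread rule (Tukey fences at 1.5x the spread of the
two fourths); the fold change is the ratio of the TF-group mean to the
empty-vector control mean, with a standard error propagated from the two
group SEMs and a two-sided Welch t-test (default; Mann-Whitney optional)
deciding significance at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTROL_TAG = "CONTROL"
DEFAULT_ALPHA = 0.05

WELL_COLUMNS = ["bait_id", "tf_id", "replicate", "firefly", "renilla"]


@dataclass
class FoldChange:
    bait_id: str
    tf_id: str
    n_used: int
    n_excluded: int
    fold: float
    se: float
    pvalue: float
    significant: bool


def read_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"well table missing columns {sorted(missing)}")
    if (df["firefly"] <= 0).any() or (df["renilla"] <= 0).any():
        raise ValueError("firefly and renilla must be positive")
    return df


def fourths(values) -> tuple[float, float]:
    """Tukey's fourths: medians of the lower and upper halves of the sorted
    data, the overall median belonging to both halves when n is odd."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    half = (n + 1) // 2
    return float(np.median(v[:half])), float(np.median(v[n - half:]))


def fourth_spread_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Exclude values outside [lower_fourth - 1.5 d, upper_fourth + 1.5 d],
    where d is the fourth-spread.  Fewer than four values: no filtering
    (warning)."""
    v = np.asarray(values, float)
    if len(v) < 4:
        warnings.warn("fewer than 4 values: fourth-spread filter skipped")
        return v, np.empty(0)
    lo, hi = fourths(v)
    d = hi - lo
    keep = (v >= lo - 1.5 * d) & (v <= hi + 1.5 * d)
    return v[keep], v[~keep]


def fold_change(tf_ratios, control_ratios, bait_id: str = "", tf_id: str = "",
                alpha: float = DEFAULT_ALPHA, test: str = "welch",
                filter_outliers: bool = True) -> FoldChange:
    """Fold change of normalized TF-well ratios over the control group.

    fold = mean(r_TF) / mean(r_CTRL); the standard error follows the usual
    propagation for a ratio of independent means,
    se = fold * sqrt((sem_T/mean_T)^2 + (sem_C/mean_C)^2).
    """
    t = np.asarray(tf_ratios, float)
    c = np.asarray(control_ratios, float)
    n_excluded = 0
    if filter_outliers:
        t, t_out = fourth_spread_filter(t)
        c, _ = fourth_spread_filter(c)
        n_excluded = len(t_out)
    if len(t) == 0 or len(c) == 0:
        raise ValueError("empty group after outlier filtering")
    mean_t, mean_c = t.mean(), c.mean()
    if mean_c == 0:
        raise ValueError("zero control mean")
    fold = mean_t / mean_c
    if len(t) >= 2 and len(c) >= 2:
        sem_t = t.std(ddof=1) / np.sqrt(len(t))
        sem_c = c.std(ddof=1) / np.sqrt(len(c))
        se = fold * np.sqrt((sem_t / mean_t) ** 2 + (sem_c / mean_c) ** 2)
        if test == "welch":
            pvalue = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
        elif test == "mannwhitney":
            pvalue = float(stats.mannwhitneyu(t, c, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
    else:
        se, pvalue = float("nan"), float("nan")
    return FoldChange(bait_id=bait_id, tf_id=tf_id, n_used=len(t),
                      n_excluded=n_excluded, fold=float(fold), se=float(se),
                      pvalue=pvalue,
                      significant=bool(pvalue < alpha) if np.isfinite(pvalue)
                      else False)


def analyze_wells(wells: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                  test: str = "welch") -> pd.DataFrame:
    """Per-(bait, TF) fold changes against each bait's control wells.

    Adds a Benjamini–Hochberg adjusted p-value column for information; the
    significance call itself stays per-interaction at ``alpha``.
    """
    wells = wells.assign(ratio=wells["firefly"] / wells["renilla"])
    results = []
    for bait, sub in wells.groupby("bait_id"):
        ctrl = sub.loc[sub["tf_id"] == CONTROL_TAG, "ratio"].to_numpy()
        if len(ctrl) == 0:
            raise ValueError(f"bait {bait}: no control wells")
        for tf, grp in sub[sub["tf_id"] != CONTROL_TAG].groupby("tf_id"):
            results.append(fold_change(grp["ratio"].to_numpy(), ctrl,
                                       bait_id=bait, tf_id=tf,
                                       alpha=alpha, test=test))
    out = pd.DataFrame([vars(r) for r in results])
    if len(out):
        out["pvalue_bh"] = _benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def _benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    p = np.asarray(pvalues, float)
    n = np.isfinite(p).sum()
    order = np.argsort(np.where(np.isfinite(p), p, np.inf))
    adj = np.full_like(p, np.nan)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[:n][::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj
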