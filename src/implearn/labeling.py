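"""Triple-Response-Time (TRT) labeling of trials from behavioral RTs.

Each trial poses four questions; a hidden rule makes the fourth
answerable from the first, so once a participant has implicitly learned
the rule, the fourth response becomes persistently faster than the
second and third.  The labeling chain:

1. moving median (window 5, centered, truncated at the edges) over each
   question's RT series across trials, to suppress outliers;
2. DRT = smoothed Q4 RT ("determined"); URT = mean of smoothed Q2 and
   Q3 RT ("undetermined");
3. a lower bound of URT against which DRT is judged.  The default rule
   is the 90%-of-URT threshold, bound = confidence x URT; a one-sided
   lower normal confidence limit over a centered rolling window
   (mean - z(conf) * sd / sqrt(n), z(0.90) = 1.2816) is available as
   ``rule="normal_lower"``.  The confidence-limit margin shrinks with
   sqrt(n) and sits well inside the trial-to-trial dispersion of the
   smoothed series, so under the null it fires on a third of trials;
   the fractional threshold keeps the false-mark rate near zero while
   a genuine speed-up of a few hundred milliseconds still crosses it;
4. a trial is "below" when DRT < bound; a TRT mark is given to the third
   and every later trial of each maximal below-run of length >= 3;
5. TRT-marked trials are labeled fast, the rest slow; trials with a
   missing Q2/Q3/Q4 response are excluded.

Classes are then balanced by seeded random down-sampling of the
majority class so classifier training is unbiased.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .io import EventTable

logger = logging.getLogger(__name__)

__all__ = [
    "moving_median",
    "derive_drt_urt",
    "lower_bound",
    "mark_trt",
    "balance_classes",
    "label_trials",
]


def moving_median(series, window: int = 5) -> pd.Series:
    """Centered moving median; edges use the truncated window.

    Missing values are ignored within each window (an all-missing window
    stays missing).  Output length equals input length.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        return s
    return s.rolling(window, center=True, min_periods=1).median()


def _pivot_rt(events: EventTable) -> pd.DataFrame:
    wide = events.df.pivot_table(index="trial", columns="question",
                                 values="rt_s", dropna=False)
    wide = wide.reindex(columns=[1, 2, 3, 4]).sort_index()
    wide.columns = [f"rt{q}" for q in (1, 2, 3, 4)]
    return wide


def derive_drt_urt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add drt / urt columns and mark trials with missing Q2/Q3/Q4.

    Expects smoothed columns mm_rt1..mm_rt4 (see label_trials); DRT is
    the smoothed Q4 RT, URT the mean of smoothed Q2 and Q3.  Trials
    whose raw Q2, Q3 or Q4 response is missing are labeled excluded.
    """
    out = trials.copy()
    out["drt"] = out["mm_rt4"]
    out["urt"] = (out["mm_rt2"] + out["mm_rt3"]) / 2.0
    out["excluded"] = out[["rt2", "rt3", "rt4"]].isna().any(axis=1)
    return out


def lower_bound(trials: pd.DataFrame, confidence: float = 0.90,
                window: int = 5, rule: str = "fraction") -> pd.DataFrame:
    """Lower bound of URT below which DRT counts as fast.

    ``rule="fraction"`` (default): bound = confidence x urt.
    ``rule="normal_lower"``: bound(t) = rolling_mean(urt) -
    z(confidence) * rolling_sd(urt) / sqrt(n_window) over a centered
    window, the one-sided lower normal confidence limit of the URT
    level; windows with fewer than two valid values degenerate to
    bound = urt (logged).
    """
    if not 0 < confidence < 1:
        raise ParameterError(f"confidence must be in (0, 1), got {confidence}")
    out = trials.copy()
    urt = out["urt"]
    if rule == "fraction":
        out["bound"] = confidence * urt
    elif rule == "normal_lower":
        z = float(stats.norm.ppf(confidence))
        roll = urt.rolling(window, center=True, min_periods=1)
        n = roll.count()
        bound = roll.mean() - z * roll.std(ddof=1) / np.sqrt(n)
        degenerate = n < 2
        if degenerate.any():
            logger.info("lower_bound: %d trials with <2 valid window values; "
                        "bound degenerates to urt", int(degenerate.sum()))
        out["bound"] = bound.where(~degenerate, urt)
    else:
        raise ParameterError(f"unknown bound rule {rule!r}")
    out["below"] = (out["drt"] < out["bound"]) & ~out["excluded"]
    out["below"] = out["below"].fillna(False)
    return out


def mark_trt(trials: pd.DataFrame, run_length: int = 3) -> pd.DataFrame:
    """Give TRT marks inside sufficiently long below-runs.

    For every maximal run of consecutive below-true trials of length
    >= run_length, the run_length-th and all later trials of the run are
    marked: the mark is given at the moment the consecutive criterion
    completes.  Marked trials are labeled fast, unmarked slow; excluded
    trials keep the excluded label (and break runs).
    """
    if run_length < 1:
        raise ParameterError(f"run_length must be >= 1, got {run_length}")
    out = trials.copy()
    below = out["below"].to_numpy(dtype=bool)
    trt = np.zeros_like(below)
    streak = 0
    for i, flag in enumerate(below):
        streak = streak + 1 if flag else 0
        if streak >= run_length:
            trt[i] = True
    out["trt"] = trt
    out["label"] = np.where(out["excluded"], "excluded",
                            np.where(trt, "fast", "slow"))
    return out


def balance_classes(trials: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Down-sample the majority class to the minority count (seeded).

    Mirrors the equal-size fast/slow design: the majority class is
    sampled uniformly at random without replacement.  Excluded trials
    are dropped.  Raises if either class is empty.
    """
    labeled = trials[trials["label"].isin(["fast", "slow"])]
    counts = labeled["label"].value_counts()
    for cls in ("fast", "slow"):
        if counts.get(cls, 0) == 0:
            raise ParameterError(f"cannot balance: class {cls!r} is empty")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, grp in labeled.groupby("label"):
        if len(grp) > n_min:
            keep = rng.choice(grp.index.to_numpy(), size=n_min, replace=False)
            grp = grp.loc[np.sort(keep)]
        parts.append(grp)
    out = pd.concat(parts).sort_index()
    logger.info("balance_classes: %s -> %d per class", counts.to_dict(), n_min)
    return out


def label_trials(events: EventTable, window: int = 5, confidence: float = 0.90,
                 run_length: int = 3, rule: str = "fraction") -> pd.DataFrame:
    """Full labeling chain: smoothing, DRT/URT, bound, TRT, labels.

    Returns one row per trial with columns rt1..rt4, mm_rt1..mm_rt4,
    drt, urt, bound, below, trt, excluded, label.
    """
    wide = _pivot_rt(events)
    for q in (1, 2, 3, 4):
        wide[f"mm_rt{q}"] = moving_median(wide[f"rt{q}"].to_numpy(), window).to_numpy()
    out = derive_drt_urt(wide)
    out = lower_bound(out, confidence=confidence, window=window, rule=rule)
    out = mark_trt(out, run_length=run_length)
    return out.reset_index()
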