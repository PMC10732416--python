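"""Behavioral statistics for the go/no-go tasks.

Correctness of a trial is ``action == required_action``.  The
Pavlovian-congruent cue types are go-to-win and no-go-to-avoid (the
instinctive response is also the correct one); the incongruent types are
no-go-to-win and go-to-avoid.  The Pavlovian bias index is the pooled
congruent accuracy minus the pooled incongruent accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .task import CONGRUENT_CUES, CUE_TYPES, GO, INCONGRUENT_CUES

logger = logging.getLogger(__name__)


def _with_correct(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    if out["action"].isna().any():
        raise ValueError("accuracy requires observed actions")
    out["correct"] = (out["action"] == out["required_action"]).astype(float)
    return out


def accuracy_by_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accuracy per cue type, task, and pooled condition.

    Returns a tidy frame (subject_id, task, condition, accuracy) where
    ``condition`` runs over the four cue types plus ``overall``,
    ``congruent`` and ``incongruent`` pooled rows.  Pooled accuracies are
    trial-weighted (equal to the cue-type mean when trial counts are
    equal).  Empty cells yield missing values, never zero.
    """
    t = _with_correct(trials)
    pools = {
        "overall": tuple(CUE_TYPES),
        "congruent": CONGRUENT_CUES,
        "incongruent": INCONGRUENT_CUES,
    }
    rows = []
    for (sid, task), grp in t.groupby(["subject_id", "task"], sort=True):
        by_cue = grp.groupby("cue_type")["correct"].mean()
        for ct in CUE_TYPES:
            rows.append({"subject_id": sid, "task": task, "condition": ct,
                         "accuracy": by_cue.get(ct, np.nan)})
        for label, cues in pools.items():
            sub = grp[grp["cue_type"].isin(cues)]
            rows.append({"subject_id": sid, "task": task, "condition": label,
                         "accuracy": sub["correct"].mean() if len(sub)
                         else np.nan})
    return pd.DataFrame(rows)


def summarize_accuracy(acc: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SEM per task x condition from per-subject accuracies."""
    def sem(x):
        return x.std(ddof=1) / np.sqrt(x.notna().sum())

    return (acc.groupby(["task", "condition"])["accuracy"]
            .agg(mean="mean", sem=sem, n="count").reset_index())


def pavlovian_bias_index(acc: pd.DataFrame) -> pd.DataFrame:
    """Congruent minus incongruent pooled accuracy per subject and task.

    Takes the tidy frame from :func:`accuracy_by_condition`; missing cue
    types propagate to a missing bias.  The index lies in [-1, 1].
    """
    cue_rows = acc[acc["condition"].isin(CUE_TYPES)]
    wide = cue_rows.pivot_table(index=["subject_id", "task"],
                                columns="condition", values="accuracy",
                                dropna=False)
    missing = [ct for ct in CUE_TYPES if ct not in wide.columns]
    for ct in missing:
        wide[ct] = np.nan
    congruent = wide[list(CONGRUENT_CUES)].mean(axis=1, skipna=False)
    incongruent = wide[list(INCONGRUENT_CUES)].mean(axis=1, skipna=False)
    out = (congruent - incongruent).rename("pavlovian_bias").reset_index()
    return out


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges.

    At position i the average runs over a symmetric window of radius
    min((window-1)/2, i, n-1-i), so the first and last points are
    untouched.  A window of 1 is the identity; a window at least twice the
    series length collapses everything to the global mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if window >= 2 * n:
        return np.full(n, x.mean())
    h = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        r = min(h, i, n - 1 - i)
        out[i] = x[i - r: i + r + 1].mean()
    return out


def _presentation_series(grp: pd.DataFrame, cues) -> np.ndarray:
    """Accuracy by cue-presentation index averaged over the given cue types."""
    sub = grp[grp["cue_type"].isin(cues)].copy()
    sub["presentation"] = sub.groupby("cue_type").cumcount() + 1
    series = sub.groupby("presentation")["correct"].mean()
    return series.to_numpy()


def learning_curve(trials: pd.DataFrame, window: int = 5,
                   axis: str = "presentation") -> pd.DataFrame:
    """Smoothed accuracy curves per subject and task.

    With ``axis="presentation"`` (default) the x-axis is the
    cue-presentation index 1..30, accuracy averaged over the four cue
    types before smoothing; ``axis="trial"`` uses the raw trial index.
    Smoothing is the centered moving average of :func:`moving_average`
    (study figure uses window 5).
    """
    t = _with_correct(trials).sort_values(["subject_id", "task",
                                           "trial_index"], kind="stable")
    rows = []
    for (sid, task), grp in t.groupby(["subject_id", "task"], sort=True):
        if axis == "presentation":
            series = _presentation_series(grp, CUE_TYPES)
        elif axis == "trial":
            series = grp["correct"].to_numpy()
        else:
            raise ValueError("axis must be 'presentation' or 'trial'")
        smooth = moving_average(series, window)
        rows.append(pd.DataFrame({
            "subject_id": sid, "task": task,
            "x": np.arange(1, len(series) + 1),
            "accuracy": smooth,
        }))
    return pd.concat(rows, ignore_index=True)


def temporal_pavlovian_bias(
    trials: pd.DataFrame, window: int = 3
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Congruent-minus-incongruent accuracy as a function of presentation.

    Returns the per-subject smoothed bias series (study supplementary
    figure uses window 3) and, per task, the presentation index at which
    the group-mean bias peaks.
    """
    t = _with_correct(trials).sort_values(["subject_id", "task",
                                           "trial_index"], kind="stable")
    rows = []
    for (sid, task), grp in t.groupby(["subject_id", "task"], sort=True):
        con = _presentation_series(grp, CONGRUENT_CUES)
        inc = _presentation_series(grp, INCONGRUENT_CUES)
        n = min(len(con), len(inc))
        bias = moving_average(con[:n] - inc[:n], window)
        rows.append(pd.DataFrame({
            "subject_id": sid, "task": task,
            "x": np.arange(1, n + 1), "bias": bias,
        }))
    table = pd.concat(rows, ignore_index=True)
    peaks = {}
    for task, grp in table.groupby("task"):
        mean_series = grp.groupby("x")["bias"].mean()
        peaks[task] = int(mean_series.idxmax())
    return table, peaks


def quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Partition values into n_bins near-equal groups by sorted position.

    Bin counts differ by at most one.  Ties are ordered by original
    position (stable sort), so earlier trials fall into the lower bin.
    Returns 1-based bin indices.
    """
    values = np.asarray(values)
    n = values.shape[0]
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * n_bins // n + 1
    return bins


def weight_quantile_profiles(
    trials: pd.DataFrame,
    weights: pd.DataFrame,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choice-randomness profiles over action-weight quantiles.

    ``weights`` must align with ``trials`` (columns ``w_go``, ``w_nogo``,
    typically from replaying a fitted model's posterior-median parameters
    over the observed history).  Per subject and task, trials are binned
    into ``n_bins`` quantiles of (w_go - w_nogo) — go-ratio per bin — and
    of |w_go - w_nogo| — accuracy per bin.  Bin edges are computed per
    subject per task from that task's own trials.

    Returns (go_profile, accuracy_profile), tidy frames with one row per
    subject x task x bin.
    """
    t = _with_correct(trials).reset_index(drop=True)
    w = weights.reset_index(drop=True)
    if len(t) != len(w):
        raise ValueError("weights must align with trials row-for-row")
    t["wdiff"] = w["w_go"].to_numpy() - w["w_nogo"].to_numpy()
    t["go"] = (t["action"] == GO).astype(float)

    go_rows, acc_rows = [], []
    for (sid, task), grp in t.groupby(["subject_id", "task"], sort=True):
        d = grp["wdiff"].to_numpy()
        for values, stat_col, rows in (
            (d, "go", go_rows),
            (np.abs(d), "correct", acc_rows),
        ):
            bins = quantile_bins(values, n_bins)
            stat = grp[stat_col].to_numpy()
            for bin_id in range(1, n_bins + 1):
                mask = bins == bin_id
                rows.append({
                    "subject_id": sid, "task": task, "bin": bin_id,
                    "value": stat[mask].mean() if mask.any() else np.nan,
                    "n_trials": int(mask.sum()),
                })
    go_profile = pd.DataFrame(go_rows).rename(columns={"value": "go_ratio"})
    acc_profile = pd.DataFrame(acc_rows).rename(columns={"value": "accuracy"})
    return go_profile, acc_profile


def profile_task_comparison(profile: pd.DataFrame,
                            value_col: str) -> pd.DataFrame:
    """Per-bin paired t-test (GNG vs WMGNG) over subjects of a profile."""
    rows = []
    for bin_id, grp in profile.groupby("bin"):
        wide = grp.pivot(index="subject_id", columns="task",
                         values=value_col).dropna()
        res = paired_t(wide["GNG"].to_numpy(), wide["WMGNG"].to_numpy())
        rows.append({"bin": bin_id, "t": res.t, "df": res.df, "p": res.p,
                     "cohen_d": res.d})
    return pd.DataFrame(rows)


class PairedT(NamedTuple):
    t: float
    df: int
    p: float
    d: float
    undefined: bool = False


def paired_t(x, y) -> PairedT:
    """Classical paired t-test with Cohen's d = mean(diff) / sd(diff).

    Zero-variance differences leave t undefined; the result is flagged
    rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("need two equal-length 1-d samples, n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    n = diff.shape[0]
    if sd == 0.0:
        if np.all(diff == 0.0):
            # no difference anywhere: t = 0 by convention
            return PairedT(0.0, n - 1, 1.0, 0.0)
        return PairedT(np.nan, n - 1, np.nan, np.nan, undefined=True)
    t, p = stats.ttest_rel(x, y)
    return PairedT(float(t), n - 1, float(p), float(diff.mean() / sd))


def rm_anova_2x2(acc: pd.DataFrame) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on accuracy: action x valence.

    ``acc`` is long-format with columns subject_id, action (go/nogo),
    valence (win/avoid), accuracy — one cell per combination per subject.
    Subjects with incomplete cells are dropped (logged).  Returns one row
    per effect (action, valence, interaction) with F, dfs, uncorrected p,
    and generalized eta-squared.
    """
    import pingouin as pg

    required = {"subject_id", "action", "valence", "accuracy"}
    if not required.issubset(acc.columns):
        raise ValueError(f"acc must have columns {sorted(required)}")
    counts = acc.groupby("subject_id").size()
    complete = counts[counts == 4].index
    dropped = set(counts.index) - set(complete)
    if dropped:
        logger.warning("dropping subjects with incomplete cells: %s",
                       sorted(dropped))
    data = acc[acc["subject_id"].isin(complete)]
    if data["subject_id"].nunique() < 2:
        raise ValueError("need at least two complete subjects")
    import warnings

    with warnings.catch_warnings():
        # zero-variance effects divide 0/0; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.rm_anova(data=data, dv="accuracy",
                            within=["action", "valence"],
                            subject="subject_id", effsize="ng2")
    out = table.rename(columns={
        "Source": "effect", "p-unc": "p", "p_unc": "p", "ng2": "eta_sq_gen",
        "ddof1": "df1", "ddof2": "df2",
    })
    # an effect with zero sum of squares has F = 0 by convention (the
    # library leaves 0/0 as NaN)
    if "SS" in table.columns:
        zero = table["SS"].to_numpy() == 0.0
        out.loc[zero & out["F"].isna(), "F"] = 0.0
        out.loc[zero & out["p"].isna(), "p"] = 1.0
    return out[["effect", "F", "df1", "df2", "p", "eta_sq_gen"]]
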