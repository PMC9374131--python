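"""Derived behavioral measures: error rates, satiation quartiles, summaries.

Everything here works on the canonical trial table (one row per trial, the
CSV schema of :mod:`rewardtask.task_model`).  The central products are

* the error-rate table — per (session, reward size[, satiation quartile])
  cell: trial counts, error counts, empirical error rate and mean correct
  reaction time — which feeds both the value-model fits and the ANOVAs; and
* per-session summaries: early/late error ratio and total reward earned.

Satiation is indexed by the normalized cumulative reward Rcum: the reward
consumed *before* each trial divided by the realized session total, so
Rcum in [0, 1) and the series is nondecreasing.  Sessions are divided into
quartiles of Rcum with half-open bins [0.25(q-1), 0.25q) and representative
values 0.125, 0.375, 0.625, 0.875 for quartiles 1-4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task_model import OUTCOMES, Session

__all__ = [
    "ZeroTotalRewardError",
    "QUARTILE_REPRESENTATIVES",
    "normalize_cumulative_reward",
    "assign_quartiles",
    "compute_error_rates",
    "early_late_ratio",
    "total_reward",
    "session_summary",
    "ERROR_RATE_COLUMNS",
]

QUARTILE_REPRESENTATIVES = {1: 0.125, 2: 0.375, 3: 0.625, 4: 0.875}

ERROR_RATE_COLUMNS = [
    "subject_id", "session_id", "treatment", "reward_size", "quartile",
    "quartile_rcum", "n_trials", "n_errors", "error_rate",
    "mean_reaction_time", "low_n",
]


class ZeroTotalRewardError(ValueError):
    """A session with zero total reward has no defined Rcum normalization."""


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, Session):
        return trials.to_frame()
    return trials


def normalize_cumulative_reward(session) -> np.ndarray:
    """Per-trial normalized cumulative reward Rcum for one session.

    For trial i, Rcum_i = (reward delivered on trials 0..i-1) / (session
    total reward): the intake already consumed when the trial is attempted.
    Values lie in [0, 1) and are nondecreasing; adding the final trial's
    delivery closes the series at 1.
    """
    df = _as_frame(session)
    rewards = df["reward_delivered"].to_numpy(float)
    total = rewards.sum()
    if total <= 0:
        raise ZeroTotalRewardError(
            "session delivered no reward; Rcum is undefined")
    prior = np.concatenate([[0.0], np.cumsum(rewards)[:-1]])
    return prior / total


def assign_quartiles(rcum) -> tuple[np.ndarray, np.ndarray]:
    """Map Rcum values to satiation quartiles 1-4 and representative values.

    Quartile q covers the half-open bin [0.25(q-1), 0.25q); its
    representative value is the bin midpoint 0.25(q-1) + 0.125.  An exact
    Rcum of 1.0 (possible only for a hypothetical end-of-session datum)
    falls in quartile 4.
    """
    rcum = np.asarray(rcum, float)
    if np.any((rcum < 0) | (rcum > 1)):
        raise ValueError("Rcum values must lie in [0, 1]")
    q = np.minimum(np.floor(rcum / 0.25).astype(int) + 1, 4)
    rep = 0.25 * (q - 1) + 0.125
    return q, rep


def _check_outcomes(df: pd.DataFrame) -> None:
    bad = ~df["outcome"].isin(OUTCOMES)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"unknown outcome labels at rows {rows}")


def compute_error_rates(trials, by_quartile: bool = False,
                        min_cell_trials: int = 5) -> pd.DataFrame:
    """Error-rate table per (session, reward size[, satiation quartile]).

    An error is an early or late bar release; repeated (post-error) trials
    count as ordinary observations.  ``mean_reaction_time`` averages correct
    trials only (NaN when a cell has none).  Cells with fewer than
    ``min_cell_trials`` trials are retained but flagged ``low_n``; empty
    cells are omitted.
    """
    df = _as_frame(trials)
    if df.empty:
        raise ValueError("trial table is empty")
    _check_outcomes(df)
    df = df.copy()
    df["reward_size"] = df["cue_size"]  # cue names the reward at stake
    df["is_error"] = df["outcome"].isin(["early_error", "late_error"])

    keys = ["subject_id", "session_id", "treatment", "reward_size"]
    if by_quartile:
        parts = []
        for _, grp in df.groupby("session_id", sort=True):
            grp = grp.sort_values("trial_index").copy()
            rcum = normalize_cumulative_reward(grp)
            q, rep = assign_quartiles(rcum)
            grp["quartile"], grp["quartile_rcum"] = q, rep
            parts.append(grp)
        df = pd.concat(parts, ignore_index=True)
        keys = keys + ["quartile", "quartile_rcum"]

    def _agg(grp: pd.DataFrame) -> pd.Series:
        n = len(grp)
        n_err = int(grp["is_error"].sum())
        correct_rt = grp.loc[~grp["is_error"], "reaction_time_ms"]
        return pd.Series({
            "n_trials": n,
            "n_errors": n_err,
            "error_rate": n_err / n,
            "mean_reaction_time": correct_rt.mean() if len(correct_rt) else np.nan,
        })

    out = (df.groupby(keys, sort=True)
             .apply(_agg, include_groups=False)
             .reset_index())
    if not by_quartile:
        out["quartile"] = pd.NA
        out["quartile_rcum"] = np.nan
    out["n_trials"] = out["n_trials"].astype(int)
    out["n_errors"] = out["n_errors"].astype(int)
    out["low_n"] = out["n_trials"] < min_cell_trials
    return out.loc[:, ERROR_RATE_COLUMNS]


def early_late_ratio(trials) -> pd.DataFrame:
    """Per-session ratio of early to late errors.

    NaN when a session has no late errors (ratio undefined).
    """
    df = _as_frame(trials)
    _check_outcomes(df)
    g = df.groupby(["subject_id", "session_id", "treatment"], sort=True)["outcome"]
    out = pd.DataFrame({
        "n_early": g.apply(lambda s: int((s == "early_error").sum())),
        "n_late": g.apply(lambda s: int((s == "late_error").sum())),
    }).reset_index()
    out["early_late_ratio"] = np.where(out["n_late"] > 0,
                                       out["n_early"] / out["n_late"].replace(0, np.nan),
                                       np.nan)
    return out


def total_reward(session, drop_volume: float = 0.1) -> float:
    """Total reward earned in a session, in ml."""
    if isinstance(session, Session):
        drop_volume = session.drop_volume
        df = session.to_frame()
    else:
        df = session
    return float(df["reward_delivered"].sum() * drop_volume)


def session_summary(trials, drop_volume: float = 0.1) -> pd.DataFrame:
    """Per-session summary: trial counts, error ratio, total reward (ml),
    mean correct reaction time."""
    df = _as_frame(trials)
    _check_outcomes(df)
    ratio = early_late_ratio(df)
    g = df.groupby(["subject_id", "session_id", "treatment"], sort=True)
    extra = pd.DataFrame({
        "n_trials": g.size(),
        "total_reward_ml": g["reward_delivered"].sum() * drop_volume,
        "mean_reaction_time": g.apply(
            lambda s: s.loc[s["outcome"] == "correct", "reaction_time_ms"].mean(),
            include_groups=False),
    }).reset_index()
    return ratio.merge(extra, on=["subject_id", "session_id", "treatment"])
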