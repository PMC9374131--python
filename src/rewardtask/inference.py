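"""Nested repeated-measures ANOVA for treatment effects on task performance.

The hypothesis tests mirror an R ``aov(response ~ f1 * f2 + Error(subject))``
call: subjects form a between-unit error stratum, sessions provide the
within-subject replication, and the treatment/reward/satiation effects and
their interactions are tested against the within-subject residual.  The
decomposition is computed by an ordinary least-squares fit with the subject
factor entered first, using sequential (type-I) sums of squares — which
coincide with the other types on the balanced designs the synthetic pipeline
produces; unbalanced data triggers a warning naming the convention.

The canonical designs are

* error rate ~ treatment * reward size           (two-way)
* error rate ~ treatment * reward * satiation    (three-way, quartile factor)
* reaction time ~ treatment * reward size
* early/late error ratio ~ treatment
* total reward earned ~ treatment

Satiation enters as a 4-level categorical quartile factor, not as the
continuous Rcum.  No sphericity correction and no multiple-testing
adjustment are applied; both facts are recorded in the output metadata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .session_metrics import compute_error_rates, session_summary

__all__ = ["AnovaTable", "DesignResults", "rm_anova", "anova_designs",
           "ANOVA_CSV_COLUMNS"]

ANOVA_CSV_COLUMNS = ["effect", "df1", "df2", "SS", "MS", "F", "p"]


@dataclass
class AnovaTable:
    """Effect decomposition (df, SS, MS, F, p) plus design metadata."""

    table: pd.DataFrame  # columns: effect, df1, df2, SS, MS, F, p
    response: str
    factors: list[str]
    subject: str
    n_obs: int
    notes: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ANOVA of {self.response} ~ {' * '.join(self.factors)} "
                f"+ Error({self.subject}), n={self.n_obs}\n"
                + self.table.to_string(index=False))


def _is_balanced(df: pd.DataFrame, factors: list[str]) -> bool:
    counts = df.groupby(factors, sort=False).size()
    return counts.nunique() == 1


def _check_cells(df: pd.DataFrame, factors: list[str]) -> None:
    levels = [sorted(df[f].unique()) for f in factors]
    present = set(map(tuple, df[factors].itertuples(index=False)))
    missing = [cell for cell in itertools.product(*levels) if cell not in present]
    if missing:
        raise ValueError(f"empty design cells for {tuple(factors)}: {missing[:10]}")


def rm_anova(table: pd.DataFrame, factors: list[str], response: str,
             subject: str = "subject_id") -> AnovaTable:
    """Repeated-measures ANOVA with the subject as a nested error stratum.

    ``table`` holds one observation per row (e.g. one session x reward-size
    error-rate cell); ``factors`` are the categorical fixed effects, crossed
    with all interactions.  F for each effect is MS_effect over the
    within-subject residual MS; the subject stratum itself is reported with
    its SS/df but not tested.
    """
    for col in [response, subject, *factors]:
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    df = table.loc[:, [response, subject, *factors]].dropna(subset=[response]).copy()
    n_dropped = len(table) - len(df)
    if df.empty:
        raise ValueError("no non-missing observations")
    for f in [*factors, subject]:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    _check_cells(df, factors)

    notes = ["sequential (type-I) sums of squares",
             "no sphericity correction", "no multiple-testing adjustment"]
    if n_dropped:
        notes.append(f"dropped {n_dropped} rows with missing {response}")
    if not _is_balanced(df, factors):
        msg = ("design is unbalanced; sequential (type-I) sums of squares "
               "depend on factor order")
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    constant_response = np.ptp(df[response].to_numpy(float)) == 0.0

    # safe internal names for the formula interface
    ren = {response: "y", subject: "subj"}
    ren.update({f: f"f{i}" for i, f in enumerate(factors)})
    df = df.rename(columns=ren)
    rhs = " * ".join(f"C(f{i})" for i in range(len(factors)))
    model = smf.ols(f"y ~ C(subj) + {rhs}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on F for the subj row
        aov = anova_lm(model, typ=1)

    resid_ss = float(aov.loc["Residual", "sum_sq"])
    resid_df = float(aov.loc["Residual", "df"])
    ms_err = resid_ss / resid_df

    def _effect_name(term: str) -> str:
        # "C(f0):C(f1)" -> "treatment:reward_size"
        parts = term.replace("C(", "").replace(")", "").split(":")
        inv = {v: k for k, v in ren.items()}
        return ":".join(inv.get(p, p) for p in parts)

    rows = []
    for term in aov.index:
        if term == "Residual":
            continue
        ss = 0.0 if constant_response else float(aov.loc[term, "sum_sq"])
        d1 = float(aov.loc[term, "df"])
        if term == "C(subj)":
            rows.append({"effect": f"{subject} (error stratum)", "df1": d1,
                         "df2": np.nan, "SS": ss, "MS": ss / d1,
                         "F": np.nan, "p": np.nan})
            continue
        if ms_err > 0 and not constant_response:
            F = (ss / d1) / ms_err
        else:
            # degenerate stratum (e.g. constant response): no evidence of effect
            F = 0.0 if np.isclose(ss, 0.0) else np.inf
        p = float(f_dist.sf(F, d1, resid_df))
        rows.append({"effect": _effect_name(term), "df1": d1, "df2": resid_df,
                     "SS": ss, "MS": ss / d1, "F": F, "p": p})
    rows.append({"effect": "Residual", "df1": resid_df, "df2": np.nan,
                 "SS": resid_ss, "MS": ms_err, "F": np.nan, "p": np.nan})
    out = pd.DataFrame(rows, columns=ANOVA_CSV_COLUMNS)
    return AnovaTable(table=out, response=response, factors=list(factors),
                      subject=subject, n_obs=len(df), notes=notes)


@dataclass
class DesignResults:
    """Named ANOVA tables for the canonical designs, plus skip notices."""

    tables: dict[str, AnovaTable]
    skipped: dict[str, str] = field(default_factory=dict)


def _subject_means(cells: pd.DataFrame, factors: list[str], response: str) -> pd.DataFrame:
    keys = ["subject_id", *factors]
    return cells.groupby(keys, sort=True, as_index=False)[response].mean()


def anova_designs(trials: pd.DataFrame, aggregate: str = "session",
                  three_way_aggregate: str = "subject") -> DesignResults:
    """Run the canonical hypothesis tests on a cohort trial table.

    ``aggregate`` controls the observation unit of the two-way designs:
    "session" keeps one row per session x cell (sessions replicate within
    subject); "subject" averages cells over sessions first.  The three-way
    design defaults to subject-level aggregation, whose residual degrees of
    freedom match a 2 x 2 x 4 x 4 subject x treatment x reward x quartile
    mean table; pass ``three_way_aggregate="session"`` for session-level
    cells.  Designs whose factors have a single level (e.g. one treatment)
    are skipped with an explicit notice.
    """
    if aggregate not in ("session", "subject") or three_way_aggregate not in ("session", "subject"):
        raise ValueError("aggregate must be 'session' or 'subject'")
    results: dict[str, AnovaTable] = {}
    skipped: dict[str, str] = {}

    def _try(name, func):
        try:
            results[name] = func()
        except ValueError as exc:
            skipped[name] = str(exc)

    rates = compute_error_rates(trials, by_quartile=False)
    rates_q = compute_error_rates(trials, by_quartile=True)
    summ = session_summary(trials)

    def _maybe_mean(cells, factors, response, level):
        return _subject_means(cells, factors, response) if level == "subject" else cells

    two = _maybe_mean(rates, ["treatment", "reward_size"], "error_rate", aggregate)
    _try("error_two_way",
         lambda: rm_anova(two, ["treatment", "reward_size"], "error_rate"))

    three = _maybe_mean(rates_q, ["treatment", "reward_size", "quartile"],
                        "error_rate", three_way_aggregate)
    _try("error_three_way",
         lambda: rm_anova(three, ["treatment", "reward_size", "quartile"],
                          "error_rate"))

    rt = _maybe_mean(rates, ["treatment", "reward_size"], "mean_reaction_time",
                     aggregate)
    _try("rt_two_way",
         lambda: rm_anova(rt, ["treatment", "reward_size"], "mean_reaction_time"))

    _try("early_late_ratio",
         lambda: rm_anova(summ, ["treatment"], "early_late_ratio"))
    _try("total_reward",
         lambda: rm_anova(summ, ["treatment"], "total_reward_ml"))
    return DesignResults(tables=results, skipped=skipped)
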