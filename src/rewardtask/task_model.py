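"""Domain types and synthetic-session generator for the cued reward-size task.

A monkey initiates a trial by touching a bar; a visual cue signals how many
reward drops (1, 2, 4 or 8; one drop ~0.1 ml) a correctly timed bar release
earns.  A release inside the accept window ([200, 1000] ms after the go
signal) is correct and rewarded; a release before 200 ms is an early error,
after 1000 ms a late error.  Error trials are aborted, and after a 1000 ms
intertrial interval the same cue condition is repeated until completed.
Sessions run up to a fixed duration cap (default 100 min), with the animal
water-restricted beforehand, so satiation builds within a session.

The generator draws each new (non-repeat) cue uniformly from the cue set and
emits an error with the probability given by the satiation-discounted value
model (:mod:`rewardtask.value_model`) at the current normalized cumulative
reward.  The true session total is unknown mid-session, so the generator
normalizes cumulative intake by an expected session total fixed at session
start; the analysis side always re-normalizes by the realized total.
Reaction times are lognormal with a linear reward-size shift on the location
parameter, truncated into the accept window for correct trials and outside
it (early vs late per ``early_error_share``) for errors, so the outcome
labels are self-consistent with the recorded latencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .value_model import ValueModelParams, predict_error_rate_satiation

__all__ = [
    "ACCEPT_WINDOW_MS",
    "TrialRecord",
    "Session",
    "SimConfig",
    "simulate_session",
    "simulate_cohort",
    "simulate_trials_at",
    "cohort_to_frame",
    "write_trial_csv",
    "read_trial_csv",
    "load_sim_config",
]

ACCEPT_WINDOW_MS = (200.0, 1000.0)  # closed interval; outside => error
POST_ERROR_ITI_S = 1.0

OUTCOMES = ("correct", "early_error", "late_error")

TRIAL_CSV_COLUMNS = [
    "subject_id", "session_id", "treatment", "trial_index", "cue_size",
    "outcome", "reaction_time_ms", "reward_delivered", "elapsed_time_s",
]


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``reward_delivered`` equals ``cue_size`` on correct trials and 0 on
    errors; ``elapsed_time`` is seconds from session start at trial end.
    """

    subject_id: str
    session_id: str
    treatment: str
    trial_index: int
    cue_size: int
    outcome: str
    reaction_time: float  # ms
    reward_delivered: int  # drops
    elapsed_time: float  # s

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.reward_delivered not in (0, self.cue_size):
            raise ValueError("reward_delivered must be 0 or cue_size")


@dataclass
class Session:
    """An ordered trial sequence for one subject, treatment and day."""

    subject_id: str
    session_id: str
    treatment: str
    trials: list[TrialRecord]
    session_duration_cap: float  # s
    drop_volume: float = 0.1  # ml per drop

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [t.subject_id for t in self.trials],
                "session_id": [t.session_id for t in self.trials],
                "treatment": [t.treatment for t in self.trials],
                "trial_index": [t.trial_index for t in self.trials],
                "cue_size": [t.cue_size for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "reaction_time_ms": [t.reaction_time for t in self.trials],
                "reward_delivered": [t.reward_delivered for t in self.trials],
                "elapsed_time_s": [t.elapsed_time for t in self.trials],
            }
        )


def _default_params() -> dict[str, ValueModelParams]:
    # study conditions: vehicle shows normal incentive + satiation effects;
    # the disconnection treatment has reduced incentive scale and flattened
    # satiation (smaller c and lambda)
    return {
        "vehicle": ValueModelParams(c=0.2, b=0.05, lambda_=1.0),
        "agonist": ValueModelParams(c=0.1, b=0.05, lambda_=0.3),
    }


@dataclass
class SimConfig:
    """Configuration of the cohort simulator.

    ``reaction_time_model`` is (location, scale, slope): log-latency in
    log-ms is Normal(location - slope * R, scale) before truncation by
    outcome.  ``mean_trial_duration`` is the fixed per-trial time cost in
    seconds (cue onset to reward/abort plus intertrial time); error trials
    additionally cost the 1 s post-error intertrial interval.
    """

    cue_set: list[int] = field(default_factory=lambda: [1, 2, 4, 8])
    params_by_treatment: dict[str, ValueModelParams] = field(default_factory=_default_params)
    mean_trial_duration: float = 20.0  # s -> ~300 trials per 100 min session
    session_duration_cap: float = 6000.0  # s (100 min)
    n_sessions_per_treatment: int = 13
    subjects: list[str] = field(default_factory=lambda: ["m1", "m2"])
    rng_seed: int = 0
    reaction_time_model: tuple[float, float, float] = (6.05, 0.18, 0.012)
    early_error_share: float = 0.5
    drop_volume: float = 0.1

    def __post_init__(self) -> None:
        if not self.cue_set or any(r <= 0 for r in self.cue_set):
            raise ValueError("cue_set must be nonempty with positive reward sizes")
        if self.session_duration_cap <= 0:
            raise ValueError("session_duration_cap must be positive")
        if self.mean_trial_duration <= 0:
            raise ValueError("mean_trial_duration must be positive")
        if not self.subjects:
            raise ValueError("subjects must be nonempty")
        if not 0.0 <= self.early_error_share <= 1.0:
            raise ValueError("early_error_share must be in [0, 1]")


def _truncnorm_ppf(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Quantiles of a standard normal truncated to (lo, hi); stable in tails."""
    if np.isneginf(lo):  # upper truncation
        return ndtri(ndtr(hi) * u)
    if np.isposinf(hi):  # lower truncation: work in the survival tail
        sf = ndtr(-lo)
        return -ndtri(np.clip(sf * (1.0 - u), 1e-300, 1.0))
    plo, phi = ndtr(lo), ndtr(hi)
    return ndtri(plo + u * (phi - plo))


def _sample_reaction_times(config: SimConfig, cues: np.ndarray,
                           outcomes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    loc0, scale, slope = config.reaction_time_model
    mu = loc0 - slope * cues
    lo, hi = np.log(ACCEPT_WINDOW_MS[0]), np.log(ACCEPT_WINDOW_MS[1])
    u = rng.random(len(cues))
    z = np.empty(len(cues))
    for label, (a, b) in (("correct", (lo, hi)),
                          ("early_error", (-np.inf, lo)),
                          ("late_error", (hi, np.inf))):
        m = outcomes == label
        if not m.any():
            continue
        # truncation bounds in standardized units vary with mu (one per cue)
        zm = np.empty(m.sum())
        for mu_val in np.unique(mu[m]):
            sub = mu[m] == mu_val
            a_s = (a - mu_val) / scale if np.isfinite(a) else -np.inf
            b_s = (b - mu_val) / scale if np.isfinite(b) else np.inf
            zm[sub] = _truncnorm_ppf(np.clip(u[m][sub], 1e-12, 1 - 1e-12), a_s, b_s)
        z[m] = zm
    rt = np.exp(mu + scale * z)
    # keep the outcome/latency classification exactly self-consistent at the
    # boundaries despite floating-point truncation error
    lo_ms, hi_ms = ACCEPT_WINDOW_MS
    corr = outcomes == "correct"
    rt[corr] = np.clip(rt[corr], lo_ms, hi_ms)
    early = outcomes == "early_error"
    rt[early] = np.minimum(rt[early], np.nextafter(lo_ms, 0.0))
    late = outcomes == "late_error"
    rt[late] = np.maximum(rt[late], np.nextafter(hi_ms, np.inf))
    return rt


def _expected_session_total(config: SimConfig, params: ValueModelParams) -> float:
    """Expected total drops per session, fixed at session start.

    Used only to normalize cumulative intake during generation: expected
    trial count x mean cue x P(correct), with P(correct) evaluated at the
    session midpoint (Rcum = 0.5) averaged over the cue set.
    """
    cues = np.asarray(config.cue_set, float)
    p_err = float(np.mean(predict_error_rate_satiation(params, cues, 0.5)))
    n_trials = config.session_duration_cap / config.mean_trial_duration
    return max(n_trials * float(np.mean(cues)) * (1.0 - p_err), float(np.min(cues)))


def simulate_session(config: SimConfig, subject: str, treatment: str,
                     seed: int, session_id: str | None = None) -> Session:
    """Simulate one session of the reward-size task.

    Each new trial draws its cue uniformly from ``config.cue_set``; an error
    trial repeats the same cue on the next trial.  The session ends when the
    next trial would exceed the duration cap.
    """
    if treatment not in config.params_by_treatment:
        raise KeyError(f"unknown treatment {treatment!r}; configured: "
                       f"{sorted(config.params_by_treatment)}")
    params = config.params_by_treatment[treatment]
    if session_id is None:
        session_id = f"{subject}-{treatment}-s{seed}"
    rng = np.random.default_rng(seed)
    expected_total = _expected_session_total(config, params)
    cue_set = np.asarray(config.cue_set)

    cues: list[int] = []
    errors: list[bool] = []
    elapsed_ends: list[float] = []
    elapsed = 0.0
    cum_drops = 0.0
    repeat_cue: int | None = None
    while True:
        start_cost = POST_ERROR_ITI_S if (errors and errors[-1]) else 0.0
        if elapsed + start_cost + config.mean_trial_duration > config.session_duration_cap:
            break
        cue = repeat_cue if repeat_cue is not None else int(cue_set[rng.integers(len(cue_set))])
        rcum_gen = min(cum_drops / expected_total, 1.0)
        p_err = float(predict_error_rate_satiation(params, cue, rcum_gen))
        is_err = rng.random() < p_err
        elapsed += start_cost + config.mean_trial_duration
        cues.append(cue)
        errors.append(is_err)
        elapsed_ends.append(elapsed)
        if is_err:
            repeat_cue = cue
        else:
            repeat_cue = None
            cum_drops += cue

    cues_a = np.asarray(cues)
    errors_a = np.asarray(errors)
    outcomes = np.where(errors_a,
                        np.where(rng.random(len(cues_a)) < config.early_error_share,
                                 "early_error", "late_error"),
                        "correct")
    rts = _sample_reaction_times(config, cues_a.astype(float), outcomes, rng)

    trials = [
        TrialRecord(
            subject_id=subject, session_id=session_id, treatment=treatment,
            trial_index=i, cue_size=int(cues_a[i]), outcome=str(outcomes[i]),
            reaction_time=float(rts[i]),
            reward_delivered=0 if errors_a[i] else int(cues_a[i]),
            elapsed_time=float(elapsed_ends[i]),
        )
        for i in range(len(cues_a))
    ]
    return Session(subject_id=subject, session_id=session_id, treatment=treatment,
                   trials=trials, session_duration_cap=config.session_duration_cap,
                   drop_volume=config.drop_volume)


def _session_seed(rng_seed: int, index: int) -> int:
    # deterministic counter scheme: independent child streams per session
    ss = np.random.SeedSequence([int(rng_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(config: SimConfig) -> list[Session]:
    """Simulate every subject x treatment x session of the configured design.

    Per-session seeds are derived deterministically from ``config.rng_seed``
    and a session counter, so cohorts are reproducible and sessions
    independent.
    """
    sessions: list[Session] = []
    idx = 0
    for subject in config.subjects:
        for treatment in sorted(config.params_by_treatment):
            for k in range(config.n_sessions_per_treatment):
                sid = f"{subject}-{treatment}-{k:02d}"
                seed = _session_seed(config.rng_seed, idx)
                sessions.append(simulate_session(config, subject, treatment,
                                                 seed, session_id=sid))
                idx += 1
    return sessions


def simulate_trials_at(params: ValueModelParams, reward_size: int, rcum: float,
                       n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. trial outcomes (True = error) at fixed R and Rcum.

    This is the generative primitive behind :func:`simulate_session`,
    exposed for calibration checks of the trial-outcome model.
    """
    p = float(predict_error_rate_satiation(params, reward_size, rcum))
    return rng.random(n) < p


def cohort_to_frame(sessions: list[Session]) -> pd.DataFrame:
    """Concatenate sessions into one trial table (the canonical CSV schema)."""
    if not sessions:
        return pd.DataFrame(columns=TRIAL_CSV_COLUMNS)
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)


def write_trial_csv(trials: pd.DataFrame | list[Session], path) -> None:
    """Write a trial table to CSV with the documented column order."""
    if isinstance(trials, list):
        trials = cohort_to_frame(trials)
    trials.loc[:, TRIAL_CSV_COLUMNS].to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    bad = ~df["outcome"].isin(OUTCOMES)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"unknown outcome labels at rows {rows}")
    return df


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a flat YAML document.

    ``params_by_treatment`` maps treatment name to {c, b, lambda}.
    """
    if isinstance(path, io.TextIOBase):
        raw = yaml.safe_load(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("simulator config must be a mapping")
    if "params_by_treatment" in raw:
        raw["params_by_treatment"] = {
            name: ValueModelParams(c=float(p["c"]), b=float(p["b"]),
                                   lambda_=float(p.get("lambda", p.get("lambda_", 0.0))))
            for name, p in raw["params_by_treatment"].items()
        }
    if "reaction_time_model" in raw:
        raw["reaction_time_model"] = tuple(float(v) for v in raw["reaction_time_model"])
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
    return SimConfig(**raw)
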