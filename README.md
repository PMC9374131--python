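# rewardtask

Simulation and motivational-value analysis of the cued **reward-size task**,
the operant paradigm used to measure incentive motivation in macaques. A
visual cue announces how many drops of reward (R ∈ {1, 2, 4, 8}) a correctly
timed bar release will earn; releases outside the 200–1000 ms accept window
are errors, and the error rate E is the behavioral index of how much the
animal values the offered outcome. The package is for researchers who run
this task (or re-analyse data from it) and need the full chain from
trial-level records to model parameters and hypothesis tests — plus a
calibrated synthetic-cohort generator for power analysis and method
validation, since trial-level data of this kind are rarely deposited.

## The model

Error rate is inverse in the satiation-discounted value of the offer:

    E(R)        = c / R + b                        (incentive only)
    F(Rcum)     = exp(−λ·Rcum)                     (satiation discount)
    E(R, Rcum)  = c / (R·F(Rcum)) + b              (full model)

where `Rcum` is the normalized cumulative reward already consumed in the
session (a proxy for satiation), `c` scales the incentive effect, `b` is a
baseline lapse rate and `λ` is the satiation rate. Sessions are divided
into quartiles of Rcum (representatives 0.125, 0.375, 0.625, 0.875) and
models are fitted to per-cell empirical error rates by deterministic
sum-of-squares minimization (grid search + bounded refinement). Treatment
effects are tested by repeated-measures ANOVA with subjects as a nested
error stratum: error rate ~ treatment × reward, error rate ~ treatment ×
reward × satiation quartile, plus reaction-time, early/late-error-ratio and
total-reward designs.

## Worked example

```python
import rewardtask as rt

cfg = rt.SimConfig(rng_seed=1)                 # 2 subjects x 2 treatments x 13 sessions
trials = rt.cohort_to_frame(rt.simulate_cohort(cfg))

rates_q = rt.compute_error_rates(trials, by_quartile=True)
for t in ("vehicle", "agonist"):
    res = rt.fit_satiation_model(rates_q[rates_q.treatment == t])
    print(f"{t}: c={res.params.c:.3f} b={res.params.b:.3f} "
          f"lambda={res.params.lambda_:.3f} sse={res.sse:.3f} (n={res.n_points})")

des = rt.anova_designs(trials)
row = des.tables["error_three_way"].table.query("effect=='treatment:quartile'").iloc[0]
print(f"treatment x satiation: F({row.df1:.0f},{row.df2:.0f}) = {row.F:.2f}, p = {row.p:.2e}")
```

prints

```
vehicle: c=0.183 b=0.042 lambda=1.083 sse=3.483 (n=416)
agonist: c=0.110 b=0.047 lambda=0.000 sse=2.133 (n=416)
treatment x satiation: F(3,31) = 23.33, p = 4.31e-08
```

The simulated "vehicle" condition (true c = 0.2, b = 0.05, λ = 1.0) is
recovered as a steep reward-size effect with pronounced satiation; the
disconnection-like "agonist" condition (true c = 0.1, λ = 0.3) comes back
with half the incentive scale and a flattened satiation curve, and the
treatment × satiation interaction — the signature of a satiation-sensitivity
change — is detected against the subject-nested error term. Each fit used
416 cells (52 sessions × 4 reward sizes × 4 quartiles, split by treatment).

The same flow is available from a shell:

```sh
rewardtask simulate --out trials.csv --seed 1
rewardtask metrics  --in trials.csv --out rates.csv --by-quartile
rewardtask fit      --in rates.csv --model satiation --out fit.json
rewardtask anova    --in trials.csv --design three-way --out anova.csv
rewardtask run      --config pipeline.yaml        # everything, with a report bundle
```

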