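# medhabit

Tools for asking whether *when* people meditate predicts whether they
*keep* meditating.  `medhabit` analyses timestamped meditation-app session
logs to test two pieces of common habit-formation advice — meditate in the
morning, and meditate at the same time every day — against short- and
long-term engagement outcomes.  It is aimed at researchers in mobile
health (mHealth) and behavioral science who have per-session event logs
(user id, start timestamp, session type, completion flag, duration) and
want a reproducible pipeline from raw events to engagement statistics.

Because commercial app datasets are proprietary, the package ships a
synthetic event-log generator with known ground truth, so every stage of
the analysis is exercised and validated end-to-end without access to any
real user data.

## The measures and models

Sessions are filtered to completed Meditation-type sessions of 3–60
minutes, indexed by enrollment day *d* (account-creation day = 1), and the
sample is screened to users with ≥ 8 app uses (any type) in their first 60
days.  For each user the pipeline computes:

- **TOD preference** — the proportion *P(xᵢ)* of sessions starting in each
  of four clock windows: morning [04:00, 10:00), midday [10:00, 16:00),
  evening [16:00, 22:00), late night [22:00, 04:00).
- **Temporal consistency** — the Shannon entropy of that distribution,
  *H = −Σᵢ P(xᵢ) ln P(xᵢ)* with 0·ln 0 := 0.  *H* = 0 means a strict
  single-window routine; *H* = ln 4 ≈ 1.386 means no timing preference.
- **M67** — sessions completed in months 6–7 of the account (days
  151–210), a short-term maintenance outcome.
- **LS** — the enrollment day of the last observed session, a long-term
  maintenance outcome, with the account-creation day-of-year (ACD) as a
  horizon covariate.

Three analyses sit on top:

1. **Daily probability curves.**  A logistic additive model
   logit P(y_ud = 1) = f(d) + b_u over days 1–180, with f an 8-knot
   penalized cubic regression spline (cyclic by default, with a natural
   alternative) and b_u a per-user random intercept, fitted by penalized
   IRLS with GCV smoothing selection — overall, per TOD window, and for
   top/bottom outcome quartiles, summarised as the day-1 → day-180 percent
   change.
2. **Per-window regressions.**  For each TOD window, OLS of each outcome
   on session count, entropy and that window's proportion *T* (plus ACD
   for LS); the four proportions sum to 1, so one model per window avoids
   rank deficiency.  Raw (B) and standardized (β) coefficients are
   reported.
3. **Trajectory typologies.**  Each user's first 25 weeks become four
   weekly-probability trajectories (one per window); k-means (k = 4) per
   window yields canonical clusters (1 high-sustained, 2 high-decaying,
   3 moderate, 4 low), combined into an `m-d-e-l` profile — one of
   4⁴ = 256 — then top profiles by mean outcome are aggregated into
   weighted per-window cluster proportions.

## Worked example

```python
import medhabit as mh

cfg = mh.SimConfig(n_users=300, seed=42)
events, truth = mh.simulate(cfg)

eligible = mh.eligibility_filter(events)
events = events[events["user_id"].isin(eligible)]
capped = mh.meditation_sessions(events, max_day=180)
full = mh.meditation_sessions(events, max_day=None)
feats = mh.user_features(capped, full)
print(f"users: {len(feats)}, capped sessions: {len(capped)}")
print(f"mean entropy: {feats['entropy'].mean():.2f}  "
      f"mean morning share: {feats['p_morning'].mean():.2f}")
print(f"mean M67: {feats['m67'].mean():.1f}  mean LS: {feats['ls'].mean():.0f}")

panel = mh.build_daily_panel(capped, window="any", users=set(feats["user_id"]))
fit = mh.fit_gamm(panel, mh.natural_cubic_basis(8))
curve = mh.predict_curve(fit)
print(f"p(1) = {curve[0]:.3f}, p(180) = {curve[-1]:.3f}, "
      f"change = {mh.percent_change(curve):.1f}%")
```

prints

```
users: 300, capped sessions: 17043
mean entropy: 0.94  mean morning share: 0.30
mean M67: 11.8  mean LS: 666
p(1) = 0.413, p(180) = 0.121, change = -70.7%
```

The cohort starts with roughly a 40% chance of meditating on a given day
and decays to about 12% by day 180 (a 71% drop), with session timing
fairly spread across windows (mean entropy 0.94 of a possible 1.39).  The
generator encodes no link between timing and outcomes, so the per-window
regressions on this cohort correctly find no significant TOD-proportion
effects — recovery of *known nonzero* coefficients is exercised by the
generator's regression mode (`mh.simulate_regression`).

The same steps are available as a CLI:

```bash
medhabit simulate --n-users 300 --seed 42 --out events.csv
medhabit run --events events.csv --out-dir results/
```

which writes the six table-shaped CSVs (summary statistics, percent
changes, regressions, cluster counts, top profiles, cluster proportions)
plus a manifest with row counts at every filter stage.

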