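# Methods

This note documents the models, conventions and numerical choices behind
`medhabit`, including the places where the design was genuinely open and
what the synthetic-data results do and do not demonstrate.

## Sessions, sample, and day indexing

An event log has one row per app session: `user_id, account_created,
start, session_type, completed, duration_min`.  Enrollment day is
`d = (calendar date of start − account_created) + 1`, so the creation day
is d = 1 and a session at 00:00 the next day is d = 2.

Sample eligibility counts sessions of *any* type and completion status —
the screen describes account activity, not analysed meditation practice —
and requires ≥ 8 uses with d ≤ 60, boundaries inclusive.  Analysed
meditation sessions must be Meditation-type, completed, and 3–60 minutes
inclusive.  The 180-day cap applies to feature construction and the
probability curves; the maintenance outcomes M67 and LS always use the
uncapped table (a test asserts that reusing the capped table would change
M67, guarding against accidental reuse).  Duplicate rows are kept and no
timezone normalisation is attempted; all timestamps are treated as one
local clock.

## Time-of-day windows and entropy

The four windows are half-open at minute resolution — morning
[04:00, 10:00), midday [10:00, 16:00), evening [16:00, 22:00), late night
[22:00, 04:00) wrapping midnight — so they partition the clock exactly at
any sub-minute precision.  Temporal consistency is Shannon entropy in
nats, H = −Σ pᵢ ln pᵢ with 0·ln 0 := 0, ranging 0 to ln 4 ≈ 1.386.  The
natural log is fixed by that maximum (log₂ would make it 2).  Users with
zero qualifying sessions in the feature window have undefined features;
they are dropped from feature-based analyses and counted in the log.

M67 uses 30-day months: days 151–210, matching the 6 × 30 = 180-day
framing of the rest of the pipeline; a calendar-month alternative is
available via `month_convention="calendar"`.  LS is the maximum observed
d with no censoring model — the log's horizon is the implicit censoring
bound.  The session-count covariate defaults to the 180-day window; a
60-day variant is supported (`feature_window_days=60`) because either
reading is defensible and the choice materially affects only the
covariate's scale.

## Daily probability curves

The panel has exactly 180 rows per user, y(u, d) = 1 iff the user has ≥ 1
qualifying session starting on day d (within a clock window, when one is
requested).  The model is a penalized logistic additive model

    logit P(y_ud = 1) = f(d) + b_u,

with f an 8-knot cubic regression spline and b_u a per-user random
intercept realised as a ridge-penalized offset (the standard
mixed-model-as-penalty identity) — no external mixed-model engine is
involved, keeping the fit deterministic and dependency-free.

**Basis.**  The spline is value-based: coefficients are the function's
values at evenly spaced knots on [1, 180], with the integrated squared
second derivative as the wiggliness penalty (S = D′B⁻¹D from the standard
spline continuity system).  The cyclic variant identifies the first and
last knot and wraps the continuity system, tying the value and first two
derivatives at the two ends; the natural variant zeroes the second
derivative at the boundary knots.  Constants lie in the penalty's null
space in both cases.  Identifiability: the smooth is constrained to sum
to zero over the observed days via a QR null-space reparameterisation
(plain column centering would be rank-deficient, because the constant is
inside the basis span), with the population intercept carried separately.

**A note on the cyclic default.**  A cyclic basis on the enrollment axis
forces f(1) = f(180), so under the cyclic default the day-1 → day-180
percent change is identically zero by construction.  The cyclic basis is
retained as the default for the curve estimates themselves, but any
analysis of the day-1 → day-180 contrast is only informative with the
natural basis (`cyclic=False` / `--no-cyclic`), and the tests of that
contrast use it.  Which basis better matches published decaying-curve
analyses cannot be settled here; both are first-class.

**Fitting.**  Penalized IRLS with step-halving on the penalized deviance;
convergence at 1e-8 relative change, max 200 iterations, with the
deviance trajectory carried in the failure diagnostic.  The per-user
block of each weighted least-squares solve is eliminated by a Schur
complement, so each iteration costs O(n·p) with p = 8.  The intercept
variance σ²_b is updated by an EM fixed-point step in an outer loop
(loose 1e-3 fixed-point tolerance — the variance component needs only a
rough optimum, and the convergence flag reports the IRLS deviance, not
the variance step).  Complete separation is impossible by construction:
the ridge keeps every b_u finite.

**Smoothing selection.**  The penalty is normalised to unit Frobenius
ratio against the smooth block's Gram matrix, making λ dimensionless; λ
is then chosen on a 9-point log grid (10⁻⁶–10²) by deviance-based GCV,
n·D/(n − edf)², with edf the trace of the working-model influence plus
the shrunk random-intercept degrees of freedom.  A fixed λ can be passed
instead.  With only 8 knots the fit is insensitive to λ over a wide
range; the grid covers both effectively-unpenalized and
essentially-constant fits, and the λ → ∞ limit reproduces the
intercept-only GLM probability (verified to < 1e-3).

**Prediction** sets b_u = 0: the curve is the conditional
(median-user) probability, expit(f(d)).  On a heterogeneous population
this is systematically steeper than the marginal average curve (logistic
attenuation); the percent-change test therefore compares the pipeline
against a mean-logit closed form of the generator's daily curves, not
against the marginal pooled frequency.

Quartile subsets (top/bottom of M67 and LS) use the linear-interpolation
quantile with boundary ties included on both sides; degenerate ties can
make the subsets overlap, which is accepted.

## Per-window regressions

OLS (via statsmodels) of each outcome on (n_sessions, H, T_window), plus
ACD when the outcome is LS.  T enters on the 0–1 scale so its coefficient
is the full no-meditation → all-meditation contrast.  Standardized
coefficients are β = B·sd(x)/sd(y); p-values are two-sided t-tests with
n − p − 1 df and no multiple-testing correction;
heteroscedasticity-robust (HC1) SEs are available behind a flag but are
not the default.  Entering all four window proportions at once is
rank-deficient (they sum to 1) and is detected with the collinear columns
named — this is precisely why one model per window is fitted.

## Trajectories, clusters, profiles

Weekly trajectory value = distinct active days in the window that week
/ 7, over weeks 1–25 (days 1–175).  The alternative (share of that week's
sessions) is undefined for zero-session weeks and was rejected.  Users
with all-zero trajectories are still clustered — they belong in the low
cluster, and excluding them would break the cohort partition.

k-means uses k-means++ with 10 restarts behind a fixed seed
(scikit-learn's deterministic implementation); k is fixed at 4, with the
SSE-vs-k elbow curve retained as a diagnostic.  The elbow enforces
monotone SSE by warm-starting each k from the best (k−1) solution
augmented with the farthest point and keeping the better of warm and cold
starts.  Canonical labels formalise the cluster semantics: the two
centroids with the highest week-1–5 mean are "high" (label 1 if the
week-21–25 mean is also high, else 2 for high-decaying); of the rest, the
higher overall mean is 3 (moderate), the lower 4 (low).  Exact ties break
lexicographically and are logged.  Profiles concatenate the four window
labels as `m-d-e-l`; top profiles require ≥ 50 members by default and
rank by mean outcome with ties broken by member count then profile id.
Aggregated cluster proportions round to the nearest integer percent.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes,
not a behavioral model of real meditators.  Per user: an account-creation
date uniform over 2017; a dominant TOD window (default weights
0.32/0.17/0.29/0.22, echoing typical morning/evening dominance); a
mixture concentration κ = 0.35 + 0.6·Beta(2,2) putting weight κ on the
dominant window and the rest spread evenly (this induces a realistic
spread of entropies, mean ≈ 0.9); and an engagement archetype drawn from
the dominant window's mix (defaults: 8% high-sustained, 15%
high-decaying, 52% moderate, 25% low).

Daily meditation is Bernoulli with an archetype-specific curve.  The
moderate curve is a two-parameter normalised-logistic decay from
`p_day1` (default 0.55) at d = 1 to `p_day1·(1 − decay_target)` (default
decay 0.66) at d = 180 — simple, monotone, and sufficient for recovery
tests, since published daily curves are nonparametric.  High archetypes
start at min(0.92, 1.5·p_day1); high-decaying falls to 0.02 by mid-cohort;
low sits at 0.06.  After day 180 every curve tapers exponentially with a
300-day time constant so last-session days spread over the ≥ 730-day
horizon rather than piling at the boundary.  Active days carry 1–3
sessions (1 + Binomial(2, 0.12)), each assigned a window from the user's
mixture, a start time uniform within the 6-hour window (published work
gives no within-day distribution, so uniform is assumed), a lognormal
duration (log-mean 2.6, log-sd 0.45 minutes, truncated at 120) and a
Bernoulli(0.92) completion flag; non-meditation sessions arrive at
Poisson rate 0.25/day.  All randomness flows from per-user
`SeedSequence(seed, spawn_key=(user,))` substreams, so output is
bit-reproducible and growing `n_users` never reshuffles earlier users.

Closed forms used as oracles: the pooled population curve (mixture
average of archetype curves), the conditional expectation of the last
active day under an independent daily-Bernoulli schedule, and — in
regression mode — outcomes built directly as a linear function of drawn
features plus Gaussian noise with stated coefficients.

**What the generator does not emulate:** notification effects,
weekday/weekend or seasonal cycles, within-user autocorrelation beyond
the daily curve, timezone or travel effects, and any causal link between
timing preferences and outcomes.  Passing tests therefore demonstrate
that the estimators recover known structure of these kinds at these
sample sizes — not that the substantive findings would replicate on real
cohorts.

## Problem sizes and test design

Simulation-based tests use cohorts of 60–500 users (the shared fixture
uses 120) and 100-replicate coverage runs at n = 2000 — sizes at which
Monte-Carlo error is well below the asserted tolerances (typically 3
standard errors) while the whole suite stays fast.  Coverage of 95% CIs
is asserted per coefficient at ≥ 90% over 100 replicates; single-draw
sanity checks use 3-SE bands, since a 1.96-SE check on one draw fails 5%
of the time by design.

## Known limitations

- The GAMM reports no confidence bands and supports no tensor smooths or
  residual autocorrelation.
- LS is treated as last-observed with no censoring adjustment.
- GCV here is the deviance-based approximation on a small grid, not a
  full REML/performance-iteration optimisation; with an 8-knot basis the
  practical difference is negligible.
- The canonical cluster-labelling rule formalises informal "qualitatively
  similar" matching and may differ from human judgment on borderline
  centroids.
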