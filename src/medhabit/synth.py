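"""Synthetic meditation-app event-log generator.

Emulates the statistical structure the downstream analysis assumes: a
cohort of users creating accounts through a calendar year, a daily
meditation probability that starts a little above 0.5 and decays over the
first 180 days, per-user time-of-day (TOD) mixtures that induce a spread
of timing entropies, four engagement archetypes (high-sustained,
high-decaying, moderate, low) matching the trajectory-cluster prototypes,
plus non-meditation app uses, durations and completion flags.  Every draw
comes from a per-user substream derived from one master seed, so output is
bit-reproducible and earlier users do not reshuffle when ``n_users`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import TOD_WINDOWS, entropy

ARCHETYPES = ("high_sustained", "high_decaying", "moderate", "low")

#: Non-Meditation session types used for filler app activity.
_OTHER_TYPES = ("Body", "Breathe", "Masterclass", "Mood",
                "Music", "Sleep", "Soundscape", "Spark")

#: Clock hours (start of each 6 h window) used to place session times.
_WINDOW_HOURS = {"morning": 4, "midday": 10, "evening": 16, "late_night": 22}

_LOW_LEVEL = 0.06          # daily probability for the "low" archetype
_DECAYED_FLOOR = 0.02      # where "high_decaying" ends up
_HIGH_CAP = 0.92           # ceiling for the high archetypes


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``p_day1`` and ``decay_target`` anchor the moderate archetype's daily
    meditation probability: it equals ``p_day1`` on day 1 and
    ``p_day1 * (1 - decay_target)`` on day 180, following a two-parameter
    logistic-in-time decay.  ``archetype_mix`` maps each TOD window to a
    probability vector over the four archetypes, applied to users whose
    dominant window it is.  After day 180 all curves taper exponentially
    with time constant ``churn_tau_days`` so last-session days spread out
    over the horizon.
    """

    n_users: int
    seed: int = 0
    year_start: str = "2017-01-01"
    archetype_mix: dict = field(
        default_factory=lambda: {
            w: {"high_sustained": 0.08, "high_decaying": 0.15,
                "moderate": 0.52, "low": 0.25}
            for w in TOD_WINDOWS
        }
    )
    p_day1: float = 0.55
    decay_target: float = 0.66
    other_session_rate: float = 0.25
    duration_log_mean: float = 2.6
    duration_log_sd: float = 0.45
    completion_prob: float = 0.92
    horizon_days: int = 730
    max_sessions_per_day: int = 3
    churn_tau_days: float = 300.0
    dominant_window_weights: tuple = (0.32, 0.17, 0.29, 0.22)

    def __post_init__(self):
        if self.n_users < 1:
            raise ConfigError("n_users must be positive")
        if not 0.0 < self.p_day1 < 1.0:
            raise ConfigError("p_day1 must lie in (0, 1)")
        if not 0.0 <= self.decay_target < 1.0:
            raise ConfigError("decay_target must lie in [0, 1)")
        if not 0.0 <= self.completion_prob <= 1.0:
            raise ConfigError("completion_prob must lie in [0, 1]")
        if self.other_session_rate < 0:
            raise ConfigError("other_session_rate must be nonnegative")
        if self.horizon_days < 1:
            raise ConfigError("horizon_days must be positive")
        for w in TOD_WINDOWS:
            mix = self.archetype_mix[w]
            tot = sum(mix[a] for a in ARCHETYPES)
            if abs(tot - 1.0) > 1e-9 or any(mix[a] < 0 for a in ARCHETYPES):
                raise ConfigError(f"archetype_mix[{w!r}] is not a distribution")


@dataclass(frozen=True)
class TrueParams:
    """Ground truth retained for recovery tests.

    ``users`` has one row per user: dominant window, archetype, TOD-mixture
    concentration ``kappa``, mixture weights, plus per-window archetype
    labels (the dominant window carries the drawn archetype; the other
    windows see only mixture spillover and are labelled ``low``).
    """

    users: pd.DataFrame
    config: SimConfig


def _logistic_weight(d, midpoint: float, tau: float, d_end: float):
    """Normalised decreasing logistic: 1 at d=1, 0 at d=d_end."""
    d = np.asarray(d, dtype=float)
    g = 1.0 / (1.0 + np.exp((d - midpoint) / tau))
    g1 = 1.0 / (1.0 + np.exp((1.0 - midpoint) / tau))
    gend = 1.0 / (1.0 + np.exp((d_end - midpoint) / tau))
    return np.clip((g - gend) / (g1 - gend), 0.0, 1.0)


def _high_level(cfg: SimConfig) -> float:
    return min(_HIGH_CAP, 1.5 * cfg.p_day1)


def daily_curve(archetype: str, days, cfg: SimConfig) -> np.ndarray:
    """True daily meditation probability for an archetype on enrollment
    days ``days`` (taper after day 180 included)."""
    if archetype not in ARCHETYPES:
        raise ConfigError(f"unknown archetype {archetype!r}")
    d = np.asarray(days, dtype=float)
    p_end = cfg.p_day1 * (1.0 - cfg.decay_target)
    hi = _high_level(cfg)
    if archetype == "moderate":
        w = _logistic_weight(d, midpoint=60.0, tau=30.0, d_end=180.0)
        p180 = p_end + (cfg.p_day1 - p_end) * w
        level180 = p_end
    elif archetype == "high_sustained":
        p180 = np.full_like(d, hi)
        level180 = hi
    elif archetype == "high_decaying":
        w = _logistic_weight(d, midpoint=45.0, tau=18.0, d_end=180.0)
        p180 = _DECAYED_FLOOR + (hi - _DECAYED_FLOOR) * w
        level180 = _DECAYED_FLOOR
    else:  # low
        p180 = np.full_like(d, _LOW_LEVEL)
        level180 = _LOW_LEVEL
    taper = np.where(d > 180.0, np.exp(-(d - 180.0) / cfg.churn_tau_days), 1.0)
    return np.where(d <= 180.0, p180, level180 * taper)


def expected_pooled_curve(cfg: SimConfig, days) -> np.ndarray:
    """Closed-form population mean of the daily meditation probability
    under the configured dominant-window and archetype mixes."""
    wts = np.asarray(cfg.dominant_window_weights, dtype=float)
    wts = wts / wts.sum()
    out = np.zeros(np.asarray(days, dtype=float).shape)
    for w, pw in zip(TOD_WINDOWS, wts):
        for a in ARCHETYPES:
            out = out + pw * cfg.archetype_mix[w][a] * daily_curve(a, days, cfg)
    return out


def expected_last_active_day(p: np.ndarray) -> float:
    """E[last day with >= 1 session | >= 1 session] for an independent
    daily-Bernoulli schedule with probabilities ``p`` (days 1..len(p))."""
    p = np.asarray(p, dtype=float)
    # survival[j] = P(no session on any day > j)
    no = 1.0 - p
    tail = np.concatenate([np.cumprod(no[::-1])[::-1], [1.0]])[1:]
    days = np.arange(1, len(p) + 1)
    p_any = 1.0 - np.prod(no)
    return float(np.sum(days * p * tail) / p_any)


def archetype_curve(archetype: str, weeks: int) -> np.ndarray:
    """Weekly-probability prototype for an archetype (cluster-centroid
    shape): high_sustained ~ constant 0.8, high_decaying 0.85 -> ~0,
    moderate ~ constant 0.4, low ~ constant 0.05."""
    if archetype not in ARCHETYPES:
        raise ConfigError(f"unknown archetype {archetype!r}")
    w = np.arange(1, weeks + 1, dtype=float)
    if archetype == "high_sustained":
        return np.full(weeks, 0.80)
    if archetype == "moderate":
        return np.full(weeks, 0.40)
    if archetype == "low":
        return np.full(weeks, 0.05)
    # high_decaying: strictly decreasing from ~0.85 toward ~0
    return 0.85 * np.exp(-0.25 * (w - 1.0)) + 0.0


def _user_rng(seed: int, user_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(user_index,)))


def simulate(cfg: SimConfig) -> tuple[pd.DataFrame, TrueParams]:
    """Generate an event log and its ground truth.

    Per user: an account-creation date uniform over the configured year; a
    dominant TOD window and mixture concentration; an archetype drawn from
    the dominant window's mix; then for every enrollment day a Bernoulli
    meditation indicator at the archetype's daily probability, with 1-3
    sessions on active days, start times uniform within the sampled TOD
    window, truncated-lognormal durations and Bernoulli completion flags;
    plus Poisson non-meditation app uses.  Deterministic for a fixed seed.
    """
    year0 = pd.Timestamp(cfg.year_start)
    window_hours = np.array([_WINDOW_HOURS[w] for w in TOD_WINDOWS])
    dom_w = np.asarray(cfg.dominant_window_weights, dtype=float)
    dom_w = dom_w / dom_w.sum()

    truth_rows = []
    frames = []
    for u in range(cfg.n_users):
        rng = _user_rng(cfg.seed, u)
        uid = f"u{u:05d}"
        created = year0 + pd.Timedelta(days=int(rng.integers(0, 365)))
        dom_idx = int(rng.choice(4, p=dom_w))
        dominant = TOD_WINDOWS[dom_idx]
        kappa = 0.35 + 0.6 * rng.beta(2.0, 2.0)
        pi = np.full(4, (1.0 - kappa) / 3.0)
        pi[dom_idx] = kappa
        mix = cfg.archetype_mix[dominant]
        archetype = str(rng.choice(ARCHETYPES, p=[mix[a] for a in ARCHETYPES]))

        days = np.arange(1, cfg.horizon_days + 1)
        p = daily_curve(archetype, days, cfg)
        active = rng.random(cfg.horizon_days) < p
        active_days = days[active]
        if cfg.max_sessions_per_day > 1:
            extra = rng.binomial(cfg.max_sessions_per_day - 1, 0.12,
                                 size=active_days.size)
        else:
            extra = np.zeros(active_days.size, dtype=int)
        med_days = np.repeat(active_days, 1 + extra)
        n_med = med_days.size

        win = rng.choice(4, size=n_med, p=pi)
        # uniform clock time inside the 6 h window; late-night wraps past
        # midnight but stays on the session's calendar day
        offset_min = rng.integers(0, 360, size=n_med)
        start_min = (window_hours[win] * 60 + offset_min) % (24 * 60)
        med_start = (
            created
            + pd.to_timedelta(med_days - 1, unit="D")
            + pd.to_timedelta(start_min, unit="m")
        )
        dur = np.minimum(
            np.exp(rng.normal(cfg.duration_log_mean, cfg.duration_log_sd,
                              size=n_med)),
            120.0,
        )
        completed = rng.random(n_med) < cfg.completion_prob

        n_other = rng.poisson(
            cfg.other_session_rate
            * np.where(days <= 180, 1.0,
                       np.exp(-(days - 180) / cfg.churn_tau_days))
        )
        other_days = np.repeat(days, n_other)
        n_oth = other_days.size
        oth_start = (
            created
            + pd.to_timedelta(other_days - 1, unit="D")
            + pd.to_timedelta(rng.integers(0, 24 * 60, size=n_oth), unit="m")
        )
        oth_type = rng.choice(_OTHER_TYPES, size=n_oth)
        oth_dur = np.minimum(
            np.exp(rng.normal(cfg.duration_log_mean, cfg.duration_log_sd,
                              size=n_oth)),
            120.0,
        )
        oth_completed = rng.random(n_oth) < 0.7

        frames.append(
            pd.DataFrame(
                {
                    "user_id": uid,
                    "account_created": created,
                    "start": np.concatenate(
                        [med_start.to_numpy(), oth_start.to_numpy()]
                    ),
                    "session_type": np.concatenate(
                        [np.repeat("Meditation", n_med), oth_type]
                    ),
                    "completed": np.concatenate([completed, oth_completed]),
                    "duration_min": np.concatenate([dur, oth_dur]),
                }
            )
        )
        row = {
            "user_id": uid,
            "account_created": created,
            "dominant_window": dominant,
            "archetype": archetype,
            "kappa": kappa,
            "true_entropy": entropy(pi),
        }
        for w, piw in zip(TOD_WINDOWS, pi):
            row[f"pi_{w}"] = piw
            row[f"arch_{w}"] = archetype if w == dominant else "low"
        truth_rows.append(row)

    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["user_id", "start"], kind="mergesort")
    events = events.reset_index(drop=True)
    truth = TrueParams(users=pd.DataFrame(truth_rows), config=cfg)
    return events, truth


def simulate_regression(
    n_users: int,
    coef: dict | None = None,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Regression-recovery mode: draw per-user features directly and build
    an outcome from known coefficients plus Gaussian noise.

    ``coef`` maps predictor names (``const, n_sessions, entropy,
    t_morning`` and optionally ``acd``) to generating values; the default
    is ``{const: 5, n_sessions: 0.4, entropy: -2, t_morning: 2.5}``.
    Returns the feature table (with column ``y``) and the coefficients.
    """
    if coef is None:
        coef = {"const": 5.0, "n_sessions": 0.4, "entropy": -2.0,
                "t_morning": 2.5}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    n_sessions = rng.poisson(25.0, size=n_users).astype(float)
    p = rng.dirichlet((2.0, 1.2, 1.8, 1.4), size=n_users)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    df = pd.DataFrame(
        {
            "n_sessions": n_sessions,
            "entropy": h,
            "t_morning": p[:, 0],
            "t_midday": p[:, 1],
            "t_evening": p[:, 2],
            "t_late_night": p[:, 3],
            "acd": rng.integers(1, 366, size=n_users).astype(float),
        }
    )
    y = np.full(n_users, coef.get("const", 0.0))
    for name, b in coef.items():
        if name != "const":
            y = y + b * df[name].to_numpy()
    df["y"] = y + rng.normal(0.0, noise_sd, size=n_users)
    return df, dict(coef)


def write_event_log(events: pd.DataFrame, path) -> None:
    """Write an event log in the canonical CSV dialect (byte-stable)."""
    out = events.copy()
    out["account_created"] = pd.to_datetime(out["account_created"]).dt.strftime(
        "%Y-%m-%d"
    )
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out["duration_min"] = out["duration_min"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def write_truth(truth: TrueParams, path) -> None:
    """Write the per-user ground-truth sidecar CSV."""
    out = truth.users.copy()
    out["account_created"] = pd.to_datetime(out["account_created"]).dt.strftime(
        "%Y-%m-%d"
    )
    out.to_csv(path, index=False, float_format="%.8f")
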