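"""Per-user engagement features and maintenance outcomes.

Time-of-day (TOD) preference is the proportion of a user's meditation
sessions starting in each of four fixed clock windows; temporal
consistency is the Shannon entropy (nats) of that 4-way distribution,
0 for a single-window user and ln 4 ~ 1.386 for a perfectly even one.
Outcomes are M67 (session count in months 6-7 of the account) and LS
(enrollment day of the last observed session); the account creation date
(ACD, day-of-year 1..365) corrects LS for unequal observation horizons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("medhabit")

#: Window labels in canonical order.
TOD_WINDOWS = ("morning", "midday", "evening", "late_night")

#: Half-open clock boundaries: morning [04:00,10:00), midday [10:00,16:00),
#: evening [16:00,22:00), late_night [22:00,04:00) wrapping midnight.
_WINDOW_START_HOURS = {"morning": 4, "midday": 10, "evening": 16, "late_night": 22}

LN4 = float(np.log(4.0))

# M67 counts sessions in the 6th and 7th 30-day month: d in [151, 210].
M67_FIRST_DAY = 151
M67_LAST_DAY = 210

#: Default window (days) over which P, H and the session count are computed.
FEATURE_WINDOW_DAYS = 180


def assign_tod_window(start):
    """Map session start time(s) to a TOD window label by local clock hour.

    Accepts a single timestamp or a Series; vectorised in the latter case.
    """
    ts = pd.to_datetime(start)
    if isinstance(ts, pd.Series):
        h = ts.dt.hour
        out = pd.Series(
            np.select(
                [(h >= 4) & (h < 10), (h >= 10) & (h < 16), (h >= 16) & (h < 22)],
                ["morning", "midday", "evening"],
                default="late_night",
            ),
            index=ts.index,
        )
        return out
    h = ts.hour
    if 4 <= h < 10:
        return "morning"
    if 10 <= h < 16:
        return "midday"
    if 16 <= h < 22:
        return "evening"
    return "late_night"


def tod_proportions(sessions: pd.DataFrame) -> np.ndarray:
    """Proportion of one user's sessions starting in each TOD window.

    Returns a length-4 vector in window order summing to 1; raises on an
    empty table (the caller is expected to drop feature-less users).
    """
    if len(sessions) == 0:
        raise ValueError("tod_proportions undefined for zero sessions")
    w = assign_tod_window(sessions["start"])
    counts = w.value_counts().reindex(TOD_WINDOWS, fill_value=0)
    return (counts / counts.sum()).to_numpy(dtype=float)


def entropy(p) -> float:
    """Shannon entropy (nats) of a 4-window timing distribution.

    H = -sum_i p_i ln p_i with the 0*ln 0 := 0 convention; ranges from 0
    (all sessions in one window) to ln 4 (uniform over the four windows).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum()) + 0.0


def outcome_m67(
    sessions: pd.DataFrame,
    first_day: int = M67_FIRST_DAY,
    last_day: int = M67_LAST_DAY,
) -> int:
    """Count of one user's sessions in the 6th-7th month (d in [151, 210],
    30-day months), computed on the uncapped session table."""
    d = sessions["d"]
    return int(((d >= first_day) & (d <= last_day)).sum())


def outcome_ls(sessions: pd.DataFrame) -> int:
    """Enrollment day of the user's last observed meditation session."""
    if len(sessions) == 0:
        raise ValueError("outcome_ls undefined for zero sessions")
    return int(sessions["d"].max())


def acd(account_created, year: int = 2017) -> int:
    """Account creation date as day-of-year within the study year."""
    ts = pd.to_datetime(account_created)
    if ts.year != year:
        raise ValueError(f"account created {ts.date()} outside study year {year}")
    return int(ts.dayofyear)


def _m67_calendar(sessions: pd.DataFrame, account_created) -> int:
    # Calendar-month alternative to the default 30-day-month convention.
    created = pd.to_datetime(account_created)
    lo = created + pd.DateOffset(months=5)
    hi = created + pd.DateOffset(months=7)
    s = pd.to_datetime(sessions["start"])
    return int(((s >= lo) & (s < hi)).sum())


def user_features(
    capped: pd.DataFrame,
    all_sessions: pd.DataFrame,
    year: int = 2017,
    month_convention: str = "30day",
) -> pd.DataFrame:
    """Per-user feature/outcome table.

    Parameters
    ----------
    capped
        SessionTable restricted to the feature window (d <= 180 by
        default); source of P, H and n_sessions.
    all_sessions
        Uncapped SessionTable; source of M67 and LS.
    month_convention
        ``"30day"`` (default: M67 counts d in [151, 210]) or
        ``"calendar"`` (sessions in calendar months 6-7 of the account).

    Returns
    -------
    pandas.DataFrame
        One row per user with >= 1 capped session: ``user_id, p_morning,
        p_midday, p_evening, p_late_night, entropy, n_sessions, m67, ls,
        acd``.  Users with no capped sessions are dropped and logged.
    """
    if month_convention not in ("30day", "calendar"):
        raise ValueError(f"unknown month convention {month_convention!r}")

    all_users = pd.Index(all_sessions["user_id"].unique())
    rows = []
    capped_by_user = dict(iter(capped.groupby("user_id", sort=False)))
    for uid, sess_all in all_sessions.groupby("user_id", sort=False):
        sess = capped_by_user.get(uid)
        if sess is None or len(sess) == 0:
            continue
        p = tod_proportions(sess)
        if month_convention == "30day":
            m67 = outcome_m67(sess_all)
        else:
            m67 = _m67_calendar(sess_all, sess_all["account_created"].iloc[0])
        rows.append(
            {
                "user_id": uid,
                "p_morning": p[0],
                "p_midday": p[1],
                "p_evening": p[2],
                "p_late_night": p[3],
                "entropy": entropy(p),
                "n_sessions": len(sess),
                "m67": m67,
                "ls": outcome_ls(sess_all),
                "acd": acd(sess_all["account_created"].iloc[0], year=year),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "user_id", "p_morning", "p_midday", "p_evening", "p_late_night",
            "entropy", "n_sessions", "m67", "ls", "acd",
        ],
    )
    n_dropped = len(all_users) - len(out)
    if n_dropped:
        logger.info(
            "user_features: dropped %d user(s) with no sessions inside the "
            "feature window", n_dropped,
        )
    return out
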