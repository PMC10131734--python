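"""Event-log ingestion, sample-eligibility screening and session filtering.

An event log is one row per app session: who, when, what type, whether it
was completed, and how long it ran.  The analysis sample keeps users who
used the app (any feature, completed or not) at least 8 times in their
first 60 days; the analysed sessions are completed Meditation sessions of
3-60 minutes, indexed by enrollment day ``d`` (account-creation day = 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("medhabit")

#: Column order of the event-log CSV dialect.
EVENT_COLUMNS = [
    "user_id",
    "account_created",
    "start",
    "session_type",
    "completed",
    "duration_min",
]

#: The app's session types.
SESSION_TYPES = frozenset(
    {"Body", "Breathe", "Masterclass", "Meditation", "Mood",
     "Music", "Sleep", "Soundscape", "Spark"}
)

# Session-level filters for analysed meditation sessions.
MIN_DURATION_MIN = 3.0
MAX_DURATION_MIN = 60.0

# Sample-eligibility screen.
ELIGIBILITY_MIN_USES = 8
ELIGIBILITY_WINDOW_DAYS = 60


class EventLogFormatError(ValueError):
    """The file does not conform to the event-log CSV dialect."""


def read_event_log(path) -> pd.DataFrame:
    """Read an event-log CSV into a typed frame.

    Malformed rows (unparseable timestamps, unknown session type, negative
    duration, or a session starting before the account existed) are dropped
    with their row numbers logged; a missing column is a hard error.

    Parameters
    ----------
    path
        CSV with header ``user_id,account_created,start,session_type,
        completed,duration_min`` (ISO-8601 dates/timestamps, UTF-8).

    Returns
    -------
    pandas.DataFrame
        Columns as above with ``account_created`` a date-normalised
        datetime, ``start`` a datetime, ``completed`` boolean and
        ``duration_min`` float.
    """
    raw = pd.read_csv(path, dtype={"user_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise EventLogFormatError(
            f"event log {path!r} is missing required column(s): "
            + ", ".join(missing)
        )
    df = raw.loc[:, EVENT_COLUMNS].copy()

    df["account_created"] = pd.to_datetime(
        df["account_created"], format="%Y-%m-%d", errors="coerce"
    )
    df["start"] = pd.to_datetime(df["start"], errors="coerce")
    df["duration_min"] = pd.to_numeric(df["duration_min"], errors="coerce")
    if df["completed"].dtype != bool:
        df["completed"] = (
            df["completed"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )

    bad = (
        df["user_id"].isna()
        | (df["user_id"].astype(str).str.len() == 0)
        | df["account_created"].isna()
        | df["start"].isna()
        | df["completed"].isna()
        | df["duration_min"].isna()
        | (df["duration_min"] < 0)
        | ~df["session_type"].isin(SESSION_TYPES)
        | (df["start"] < df["account_created"])
    )
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning(
            "read_event_log: rejected %d malformed row(s) (file line numbers "
            "%s%s)", int(bad.sum()), rows[:20], "..." if len(rows) > 20 else ""
        )
        df = df.loc[~bad].reset_index(drop=True)
    df["completed"] = df["completed"].astype(bool)
    return df


def day_index(start, account_created):
    """Enrollment-day index of a session: calendar days since account
    creation, with the creation day counted as day 1.

    Vectorised: accepts scalars or aligned Series of timestamps/dates.
    """
    start = pd.to_datetime(start)
    created = pd.to_datetime(account_created)
    if isinstance(start, pd.Series):
        d = (start.dt.normalize() - created.dt.normalize()).dt.days + 1
        if (d < 1).any():
            raise ValueError("session start precedes account creation")
        return d.astype(np.int64)
    d = (start.normalize() - created.normalize()).days + 1
    if d < 1:
        raise ValueError("session start precedes account creation")
    return int(d)


def eligibility_filter(
    log: pd.DataFrame,
    min_uses: int = ELIGIBILITY_MIN_USES,
    window_days: int = ELIGIBILITY_WINDOW_DAYS,
) -> set:
    """Users who used the app at least ``min_uses`` times within their first
    ``window_days`` days.

    The screen counts sessions of any type and any completion status, since
    it describes account activity rather than analysed meditation practice.
    Day ``window_days`` is included (day 1 = creation day).
    """
    if log.empty:
        return set()
    d = day_index(log["start"], log["account_created"])
    counts = log.loc[(d <= window_days).to_numpy(), "user_id"].value_counts()
    return set(counts.index[counts >= min_uses])


def meditation_sessions(
    log: pd.DataFrame, max_day: int | None = None
) -> pd.DataFrame:
    """Filter to analysable meditation sessions and attach the day index.

    Keeps rows that are (1) Meditation-type, (2) tagged completed, and
    (3) between 3 and 60 minutes inclusive; when ``max_day`` is given,
    additionally drops rows with ``d > max_day``.  The 180-day cap is used
    for feature and probability-curve construction; the maintenance
    outcomes (M67, LS) are computed on the uncapped table.

    Returns the filtered frame with an integer ``d`` column appended.
    """
    keep = (
        (log["session_type"] == "Meditation")
        & log["completed"]
        & (log["duration_min"] >= MIN_DURATION_MIN)
        & (log["duration_min"] <= MAX_DURATION_MIN)
    )
    out = log.loc[keep].copy()
    if "d" not in out.columns:
        out["d"] = (
            day_index(out["start"], out["account_created"])
            if len(out)
            else pd.Series(dtype=np.int64)
        )
    if max_day is not None:
        out = out.loc[out["d"] <= max_day]
    return out.reset_index(drop=True)
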