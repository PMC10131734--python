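import numpy as np
import pandas as pd
import pytest

import medhabit as mh

# Published top-10 profile lists (profile, member count, mean outcome) used
# as printed-table inputs for the profile-aggregation checks.
TABLE5_M67 = [
    ("3-3-3-3", 52, 41.3), ("1-4-4-3", 53, 38.2), ("3-4-4-1", 68, 33.1),
    ("3-4-3-3", 81, 33.1), ("1-3-4-4", 250, 30.2), ("3-3-4-3", 58, 29.6),
    ("3-3-3-4", 191, 29.1), ("1-4-3-4", 87, 28.3), ("4-4-1-3", 220, 27.3),
    ("4-3-3-3", 103, 27.3),
]
TABLE5_LS = [
    ("1-4-4-3", 53, 962.2), ("3-3-3-3", 52, 958.6), ("3-4-3-3", 81, 933.3),
    ("2-3-3-4", 69, 909.9), ("4-4-3-1", 190, 902.6), ("3-4-3-4", 113, 900.3),
    ("4-1-3-4", 159, 891.1), ("4-3-3-3", 103, 891.0), ("1-4-3-4", 87, 881.3),
    ("4-3-1-4", 105, 875.4),
]


def top_profile_frame(rows):
    return pd.DataFrame(rows, columns=["profile", "n", "mean_outcome"])


@pytest.fixture(scope="session")
def sim_small():
    """A small synthetic cohort shared across tests (events + truth)."""
    cfg = mh.SimConfig(n_users=120, seed=11)
    events, truth = mh.simulate(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def sessions_small(sim_small):
    """Capped and uncapped meditation SessionTables for the small cohort."""
    _, events, _ = sim_small
    capped = mh.meditation_sessions(events, max_day=180)
    full = mh.meditation_sessions(events, max_day=None)
    return capped, full


def make_event_log(rows):
    """Build an in-memory event log from (user, created, start, type,
    completed, duration) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["user_id", "account_created", "start", "session_type",
                 "completed", "duration_min"],
    )
    df["account_created"] = pd.to_datetime(df["account_created"])
    df["start"] = pd.to_datetime(df["start"])
    df["duration_min"] = df["duration_min"].astype(float)
    return df


def med_row(user="u1", created="2017-03-01", start="2017-03-01 07:00",
            kind="Meditation", completed=True, duration=10.0):
    return (user, created, start, kind, completed, duration)
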