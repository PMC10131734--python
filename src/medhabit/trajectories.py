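"""Weekly TOD trajectories, k-means typologies and profile aggregation.

Each user's first 175 enrollment days are stratified into 25 weeks; the
weekly value for a TOD window is the number of distinct active days in
that window divided by 7 (a probability of meditating in that window on a
given day of the week).  A separate k-means (k=4) is run per window, its
clusters are relabelled canonically (1 = high sustained, 2 = high
decaying, 3 = moderate, 4 = low), and each user is summarised by the
profile ``m-d-e-l`` of their four window labels — one of 4^4 = 256
possibilities.  Top profiles by mean outcome (with a minimum-membership
threshold) are then aggregated into weighted per-window cluster counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .features import TOD_WINDOWS, assign_tod_window

logger = logging.getLogger("medhabit")

N_WEEKS = 25
TRAJECTORY_MAX_DAY = 7 * N_WEEKS  # 175
N_CLUSTERS = 4
DEFAULT_RESTARTS = 10
MIN_PROFILE_MEMBERS = 50
TOP_K_PROFILES = 10


@dataclass(frozen=True)
class ClusterModel:
    """k-means solution for one window's trajectories."""

    centroids: np.ndarray       # (k, 25)
    assignment: np.ndarray      # raw cluster index per user
    sse: float                  # total within-cluster sum of squares
    users: list

    def canonical_assignment(self) -> np.ndarray:
        label_map = canonical_labels(self)
        return np.array([label_map[a] for a in self.assignment])


def weekly_tod_matrix(sessions: pd.DataFrame) -> np.ndarray:
    """One user's 25-week x 4-window trajectory matrix.

    Entry (w, j) is the number of distinct days in week w (days
    7(w-1)+1 .. 7w) with at least one session starting in window j,
    divided by 7.  Sessions beyond day 175 are ignored.
    """
    out = np.zeros((N_WEEKS, 4))
    sess = sessions.loc[sessions["d"] <= TRAJECTORY_MAX_DAY]
    if len(sess) == 0:
        return out
    win = assign_tod_window(sess["start"])
    widx = win.map({w: i for i, w in enumerate(TOD_WINDOWS)}).to_numpy()
    d = sess["d"].to_numpy()
    for (day, j) in set(zip(d.tolist(), widx.tolist())):
        out[(day - 1) // 7, j] += 1.0 / 7.0
    return out


def trajectory_matrices(sessions: pd.DataFrame, users=None) -> dict:
    """Per-window trajectory matrices for a cohort.

    Returns ``{window: (n_users, 25) array}`` plus the sorted user list
    under key ``"users"``; users without sessions get all-zero rows (they
    are still clustered, landing in the low cluster).
    """
    if users is None:
        users = sessions["user_id"].unique()
    users = sorted(users)
    mats = {w: np.zeros((len(users), N_WEEKS)) for w in TOD_WINDOWS}
    grouped = dict(iter(sessions.groupby("user_id", sort=False)))
    for i, uid in enumerate(users):
        sess = grouped.get(uid)
        if sess is None:
            continue
        m = weekly_tod_matrix(sess)
        for j, w in enumerate(TOD_WINDOWS):
            mats[w][i] = m[:, j]
    mats["users"] = users
    return mats


def kmeans(
    trajectories: np.ndarray,
    k: int = N_CLUSTERS,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    users=None,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ seeding, best of ``restarts`` runs
    by SSE; deterministic given ``seed``."""
    x = np.asarray(trajectories, dtype=float)
    if len(np.unique(x, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct trajectories")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed).fit(x)
    return ClusterModel(
        centroids=km.cluster_centers_.copy(),
        assignment=km.labels_.copy(),
        sse=float(km.inertia_),
        users=list(users) if users is not None else list(range(len(x))),
    )


def elbow_sse(
    trajectories: np.ndarray,
    k_max: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> pd.Series:
    """Total within-cluster SSE for k = 1..k_max (the elbow diagnostic).

    Monotonicity in k is enforced by warm-starting each k from the best
    (k-1)-solution augmented with the point farthest from its centroid,
    and keeping whichever of the warm and cold starts has lower SSE.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    x = np.asarray(trajectories, dtype=float)
    sses = {}
    prev_centers = None
    for k in range(1, k_max + 1):
        if k == 1:
            center = x.mean(axis=0, keepdims=True)
            sse = float(((x - center) ** 2).sum())
            sses[1] = sse
            prev_centers = center
            continue
        cold = KMeans(n_clusters=k, init="k-means++",
                      n_init=restarts, random_state=seed).fit(x)
        d2 = ((x[:, None, :] - prev_centers[None, :, :]) ** 2).sum(-1)
        far = x[np.argmax(d2.min(axis=1))]
        warm_init = np.vstack([prev_centers, far])
        warm = KMeans(n_clusters=k, init=warm_init, n_init=1,
                      random_state=seed).fit(x)
        best = cold if cold.inertia_ <= warm.inertia_ else warm
        sses[k] = float(best.inertia_)
        prev_centers = best.cluster_centers_
    return pd.Series(sses, name="sse")


def canonical_labels(model: ClusterModel) -> dict:
    """Deterministic relabelling of a 4-cluster solution to the canonical
    semantics: 1 high-sustained, 2 high-decaying, 3 moderate, 4 low.

    The two centroids with the highest early mean (weeks 1-5) become
    labels 1 and 2, the one sustaining the higher late mean (weeks 21-25)
    taking 1; of the remaining two, the higher overall mean is 3.  Exact
    ties are broken by lexicographic centroid comparison (logged).
    """
    c = model.centroids
    if c.shape[0] != 4:
        raise ValueError("canonical labelling is defined for k = 4")

    def tie_key(i):
        return tuple(c[i])

    early = c[:, :5].mean(axis=1)
    late = c[:, -5:].mean(axis=1)
    overall = c.mean(axis=1)
    order_early = sorted(range(4), key=lambda i: (-early[i], tie_key(i)))
    if early[order_early[1]] == early[order_early[2]]:
        logger.info("canonical_labels: exact early-mean tie broken "
                    "lexicographically")
    high = order_early[:2]
    rest = order_early[2:]
    high = sorted(high, key=lambda i: (-late[i], tie_key(i)))
    rest = sorted(rest, key=lambda i: (-overall[i], tie_key(i)))
    return {high[0]: 1, high[1]: 2, rest[0]: 3, rest[1]: 4}


def build_profiles(assignments: dict, users=None) -> pd.DataFrame:
    """Combine canonical per-window labels into m-d-e-l profile strings.

    ``assignments`` maps each window to an equal-length vector of
    canonical labels (1..4) in user order.
    """
    missing = [w for w in TOD_WINDOWS if w not in assignments]
    if missing:
        raise ValueError(f"missing window assignment(s): {missing}")
    cols = {w: np.asarray(assignments[w], dtype=int) for w in TOD_WINDOWS}
    n = len(cols["morning"])
    if any(len(v) != n for v in cols.values()):
        raise ValueError("window assignments differ in length")
    profile = [
        "-".join(str(cols[w][i]) for w in TOD_WINDOWS) for i in range(n)
    ]
    return pd.DataFrame(
        {
            "user_id": list(users) if users is not None else list(range(n)),
            **{f"cluster_{w}": cols[w] for w in TOD_WINDOWS},
            "profile": profile,
        }
    )


def top_profiles(
    profiles: pd.DataFrame,
    outcome_col: str,
    min_members: int = MIN_PROFILE_MEMBERS,
    top_k: int = TOP_K_PROFILES,
) -> pd.DataFrame:
    """Profiles with >= ``min_members`` users, ranked by mean outcome.

    Ties are broken by member count (larger first) then profile id.
    Returns columns ``profile, n, mean_outcome``; warns when fewer than
    ``top_k`` profiles qualify.
    """
    g = profiles.groupby("profile")[outcome_col].agg(["size", "mean"])
    g = g.loc[g["size"] >= min_members]
    g = g.sort_values(["mean", "size", "profile"],
                      ascending=[False, False, True])
    if len(g) < top_k:
        logger.warning(
            "top_profiles: only %d profile(s) with >= %d members "
            "(requested top %d)", len(g), min_members, top_k,
        )
    out = g.head(top_k).reset_index()
    out.columns = ["profile", "n", "mean_outcome"]
    out["n"] = out["n"].astype(int)
    return out


def cluster_proportions(top: pd.DataFrame) -> pd.DataFrame:
    """Weighted per-window cluster counts over a top-profile list.

    For each window position of the m-d-e-l profile string, member counts
    are summed by that position's cluster label; percentages are
    count / total membership rounded to the nearest integer percent.
    Returns long-form ``window, cluster, count, pct``.
    """
    total = int(top["n"].sum())
    rows = []
    for pos, w in enumerate(TOD_WINDOWS):
        counts = {c: 0 for c in range(1, 5)}
        for profile, n in zip(top["profile"], top["n"]):
            label = int(profile.split("-")[pos])
            counts[label] += int(n)
        for c in range(1, 5):
            pct = int(round(100.0 * counts[c] / total)) if total else 0
            rows.append({"window": w, "cluster": c,
                         "count": counts[c], "pct": pct})
    return pd.DataFrame(rows)


def cluster_counts(assignments: dict) -> pd.DataFrame:
    """Participants per canonical cluster for each window (cohort-level
    contingency table)."""
    rows = []
    for w in TOD_WINDOWS:
        labels = np.asarray(assignments[w], dtype=int)
        for c in range(1, 5):
            rows.append({"window": w, "cluster": c,
                         "n": int((labels == c).sum())})
    return pd.DataFrame(rows)
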