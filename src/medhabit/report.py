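"""End-to-end pipeline orchestration and reproducibility plumbing.

``run_pipeline`` sequences ingest -> features -> probability curves (all
five windows x five participant subsets) -> per-TOD regressions (two
outcomes x four windows) -> trajectory clustering and profile
aggregation, writing the six table-shaped CSVs plus a run manifest
recording the configuration, seed and row counts at every filter stage.
Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import gamm as gm
from . import ingest
from . import regression as reg
from . import trajectories as traj

logger = logging.getLogger("medhabit")

GAMM_WINDOWS = ("any",) + feat.TOD_WINDOWS
GAMM_SUBSETS = ("all", "m67_bottom", "m67_top", "ls_bottom", "ls_top")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; every default is the analysis-faithful one."""

    events_path: str
    out_dir: str
    feature_window_days: int = 180
    month_convention: str = "30day"
    study_year: int = 2017
    n_knots: int = 8
    cyclic: bool = True
    lambda_select: str = "gcv"
    fixed_lambda: float | None = None
    k_clusters: int = 4
    cluster_seed: int = 17
    restarts: int = 10
    min_members: int = 50
    top_k: int = 10
    min_uses: int = 8
    eligibility_window_days: int = 60
    gamm_windows: tuple = GAMM_WINDOWS
    gamm_subsets: tuple = GAMM_SUBSETS

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def summary_stats(features: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) of each per-user measure."""
    cols = ["p_morning", "p_midday", "p_evening", "p_late_night",
            "entropy", "m67", "ls"]
    rows = []
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
        rows.append({"measure": c, "mean": float(np.mean(x)), "sd": sd})
    return pd.DataFrame(rows)


def _subset_users(subset: str, features_df: pd.DataFrame) -> set:
    if subset == "all":
        return set(features_df["user_id"])
    outcome, which = subset.split("_")
    return gm.quartile_subset(features_df, outcome, which)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle and writes
    every table plus ``manifest.json`` under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_digest": config.digest(),
                "stages": {}}
    stage = "ingest"
    try:
        log = ingest.read_event_log(config.events_path)
        manifest["stages"]["total_sessions"] = int(len(log))
        eligible = ingest.eligibility_filter(
            log, config.min_uses, config.eligibility_window_days
        )
        log = log.loc[log["user_id"].isin(eligible)].reset_index(drop=True)
        manifest["stages"]["eligible_users"] = int(len(eligible))
        manifest["stages"]["eligible_sessions"] = int(len(log))
        sessions_all = ingest.meditation_sessions(log, max_day=None)
        sessions_capped = ingest.meditation_sessions(
            log, max_day=config.feature_window_days
        )
        manifest["stages"]["meditation_sessions_all"] = int(len(sessions_all))
        manifest["stages"]["meditation_sessions_capped"] = int(
            len(sessions_capped)
        )

        stage = "features"
        features_df = feat.user_features(
            sessions_capped, sessions_all, year=config.study_year,
            month_convention=config.month_convention,
        )
        manifest["stages"]["featured_users"] = int(len(features_df))
        features_df.to_csv(out_dir / "features.csv", index=False,
                           float_format="%.8f")
        summary_stats(features_df).to_csv(
            out_dir / "table1_summary.csv", index=False, float_format="%.6f"
        )

        stage = "gamm"
        sessions_180 = ingest.meditation_sessions(log, max_day=gm.MAX_DAY)
        basis = (gm.cyclic_cubic_basis(config.n_knots) if config.cyclic
                 else gm.natural_cubic_basis(config.n_knots))
        lam_kw = (
            {"lambda_select": "fixed", "lam": config.fixed_lambda}
            if config.fixed_lambda is not None
            else {"lambda_select": config.lambda_select}
        )
        curve_rows, change_rows = [], []
        for subset in config.gamm_subsets:
            users = _subset_users(subset, features_df)
            for window in config.gamm_windows:
                panel = gm.build_daily_panel(sessions_180, window=window,
                                             users=users)
                fit = gm.fit_gamm(panel, basis, **lam_kw)
                curve = gm.predict_curve(fit)
                for d, p in zip(fit.days.astype(int), curve):
                    curve_rows.append({"subset": subset, "window": window,
                                       "d": d, "p_hat": p})
                change_rows.append(
                    {
                        "subset": subset, "window": window,
                        "p1": curve[0], "p180": curve[-1],
                        "pct_change": gm.percent_change(curve),
                    }
                )
        pd.DataFrame(curve_rows).to_csv(
            out_dir / "gamm_curves.csv", index=False, float_format="%.8f"
        )
        pd.DataFrame(change_rows).to_csv(
            out_dir / "table2_pct_change.csv", index=False,
            float_format="%.6f",
        )

        stage = "regression"
        reg_tables = [
            reg.regression_table(features_df, outcome,
                                 config.feature_window_days)
            for outcome in ("m67", "ls")
        ]
        pd.concat(reg_tables, ignore_index=True).to_csv(
            out_dir / "table3_regressions.csv", index=False,
            float_format="%.8f",
        )

        stage = "trajectories"
        sessions_175 = ingest.meditation_sessions(
            log, max_day=traj.TRAJECTORY_MAX_DAY
        )
        mats = traj.trajectory_matrices(
            sessions_175, users=features_df["user_id"]
        )
        users = mats["users"]
        assignments = {}
        for window in feat.TOD_WINDOWS:
            model = traj.kmeans(
                mats[window], k=config.k_clusters, seed=config.cluster_seed,
                restarts=config.restarts, users=users,
            )
            assignments[window] = model.canonical_assignment()
        traj.cluster_counts(assignments).to_csv(
            out_dir / "table4_cluster_counts.csv", index=False
        )
        profiles = traj.build_profiles(assignments, users=users)
        profiles = profiles.merge(
            features_df[["user_id", "m67", "ls"]], on="user_id", how="left"
        )
        top_frames, prop_frames = [], []
        for outcome in ("m67", "ls"):
            top = traj.top_profiles(profiles, outcome,
                                    min_members=config.min_members,
                                    top_k=config.top_k)
            top.insert(0, "outcome", outcome)
            top_frames.append(top)
            props = traj.cluster_proportions(top)
            props.insert(0, "outcome", outcome)
            prop_frames.append(props)
        pd.concat(top_frames, ignore_index=True).to_csv(
            out_dir / "table5_top_profiles.csv", index=False,
            float_format="%.4f",
        )
        pd.concat(prop_frames, ignore_index=True).to_csv(
            out_dir / "table6_cluster_proportions.csv", index=False
        )
        manifest["stages"]["profiled_users"] = int(len(profiles))
    except Exception:
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
        logger.error("run_pipeline aborted in stage %r", stage)
        raise

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return {
        "manifest": manifest,
        "features": features_df,
        "curves": pd.DataFrame(curve_rows),
        "pct_change": pd.DataFrame(change_rows),
        "regressions": pd.concat(reg_tables, ignore_index=True),
        "profiles": profiles,
        "top_profiles": pd.concat(top_frames, ignore_index=True),
        "cluster_proportions": pd.concat(prop_frames, ignore_index=True),
    }
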