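"""Per-TOD-window linear regressions of the maintenance outcomes.

Each time-of-day window gets its own multiple regression
``outcome ~ n_sessions + entropy + T_window (+ acd for LS)`` because the
four TOD proportions sum to one and are therefore linearly dependent;
entering them together would be rank-deficient.  The TOD proportion T is
entered on the 0-1 scale, so its coefficient is the contrast between no
and all meditation in that window.  Raw coefficients B come with
classical OLS standard errors and two-sided t-test p-values; the
standardized coefficient is beta = B * sd(x) / sd(y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import TOD_WINDOWS

_T_COLUMNS = {
    "morning": "p_morning",
    "midday": "p_midday",
    "evening": "p_evening",
    "late_night": "p_late_night",
}


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary: per-predictor raw coefficient B, SE, standardized
    beta and p-value, plus n_obs and R^2."""

    table: pd.DataFrame   # index: predictor; columns: B, SE, beta, p
    n_obs: int
    r_squared: float

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "B"])


def _check_rank(x: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for col in x.columns:
            rest = np.column_stack(
                [np.ones(len(x)), x.drop(columns=[col]).to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(col)
        raise RankDeficiencyError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(bad or list(x.columns))
        )
    for col in x.columns:
        if np.ptp(x[col].to_numpy(dtype=float)) == 0:
            raise RankDeficiencyError(f"predictor {col!r} is constant")


def fit_ols(y, x: pd.DataFrame, robust: bool = False) -> RegressionFit:
    """Ordinary least squares of ``y`` on predictors ``x`` (intercept
    added), with standardized coefficients.

    ``robust=True`` switches to HC1 heteroscedasticity-robust standard
    errors; classical SEs are the default.
    """
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("y and X must have the same length")
    if len(y) <= x.shape[1] + 1:
        raise ValueError("need n_obs > n_predictors + 1")
    _check_rank(x)
    design = sm.add_constant(x.astype(float), has_constant="add")
    model = sm.OLS(y, design)
    res = model.fit(cov_type="HC1") if robust else model.fit()

    sd_y = np.std(y, ddof=1)
    rows = {}
    for name in design.columns:
        b = res.params[name]
        if name == "const":
            beta = np.nan
        else:
            beta = b * np.std(x[name].to_numpy(dtype=float), ddof=1) / sd_y
        rows[name] = {
            "B": b, "SE": res.bse[name], "beta": beta, "p": res.pvalues[name],
        }
    table = pd.DataFrame(rows).T[["B", "SE", "beta", "p"]]
    return RegressionFit(table=table, n_obs=int(res.nobs),
                         r_squared=float(res.rsquared))


def tod_regressions(
    features: pd.DataFrame,
    outcome: str,
    tod: str,
    feature_window_days: int = 180,
    robust: bool = False,
) -> RegressionFit:
    """One window's regression: outcome on (n_sessions, entropy, T_window)
    plus ACD when the outcome is LS.

    ``feature_window_days`` is recorded for provenance only; the features
    table must already have been built over the intended window.
    """
    if outcome not in ("m67", "ls"):
        raise ValueError(f"unknown outcome {outcome!r}")
    if tod not in TOD_WINDOWS:
        raise ValueError(f"unknown TOD window {tod!r}")
    cols = ["n_sessions", "entropy", _T_COLUMNS[tod]]
    if outcome == "ls":
        cols.append("acd")
    x = features[cols].copy()
    return fit_ols(features[outcome].to_numpy(dtype=float), x, robust=robust)


def regression_table(
    features: pd.DataFrame, outcome: str, feature_window_days: int = 180
) -> pd.DataFrame:
    """All four per-window regressions for one outcome, stacked in the
    long form ``outcome,tod,predictor,B,SE,beta,p``."""
    frames = []
    for tod in TOD_WINDOWS:
        fit = tod_regressions(features, outcome, tod,
                              feature_window_days=feature_window_days)
        t = fit.table.reset_index(names="predictor")
        t.insert(0, "tod", tod)
        t.insert(0, "outcome", outcome)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
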