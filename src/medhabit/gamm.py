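"""Daily meditation-probability curves via a logistic additive model.

The model is logit P(y_ud = 1) = f(d) + b_u over enrollment days
d = 1..180, where f is a penalized cubic regression spline of the day
(cyclic by default, 8 knots) and b_u is a per-user random intercept.  The
fit maximises the penalized Bernoulli log-likelihood by IRLS, with the
random intercepts realised as ridge-penalized offsets (the standard
mixed-model-as-penalty identity) and the intercept variance updated by an
EM fixed-point step.  The smoothing parameter is chosen by an approximate
GCV grid on the working model unless fixed by the caller.

The spline basis is value-based (coefficients are the function's values at
the knots), with the wiggliness penalty being the integrated squared
second derivative; the cyclic variant ties the value and first two
derivatives at the two ends of the day axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .features import TOD_WINDOWS, assign_tod_window

MAX_DAY = 180
DEFAULT_KNOTS = 8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 200

__all__ = [
    "SplineBasis", "GammFit", "build_daily_panel", "cyclic_cubic_basis",
    "natural_cubic_basis", "fit_gamm", "predict_curve", "percent_change",
    "quartile_subset",
]


class FitError(RuntimeError):
    """IRLS failed to converge; carries the deviance trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# daily panel
# ---------------------------------------------------------------------------

def build_daily_panel(
    sessions: pd.DataFrame,
    window: str = "any",
    users=None,
    max_day: int = MAX_DAY,
) -> pd.DataFrame:
    """Per-user-per-day binary meditation indicators.

    ``y(u, d) = 1`` iff user ``u`` has at least one qualifying session on
    day ``d`` starting in ``window`` ("any" ignores the clock window).
    The result has exactly ``max_day`` rows per user in ``users`` (users
    with no qualifying sessions contribute all-zero rows), ordered by user
    then day.
    """
    if window != "any" and window not in TOD_WINDOWS:
        raise ValueError(f"unknown TOD window {window!r}")
    if users is None:
        users = sessions["user_id"].unique()
    users = sorted(users)
    if len(users) == 0:
        raise ValueError("build_daily_panel needs a nonempty user set")

    sess = sessions.loc[sessions["d"] <= max_day]
    if window != "any":
        sess = sess.loc[assign_tod_window(sess["start"]) == window]

    uidx = {u: i for i, u in enumerate(users)}
    y = np.zeros((len(users), max_day), dtype=np.int8)
    rows = sess.loc[sess["user_id"].isin(uidx)]
    if len(rows):
        i = rows["user_id"].map(uidx).to_numpy()
        j = rows["d"].to_numpy() - 1
        y[i, j] = 1
    return pd.DataFrame(
        {
            "user_id": np.repeat(users, max_day),
            "d": np.tile(np.arange(1, max_day + 1), len(users)),
            "y": y.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# cubic regression spline bases (value-based, integrated-f'' penalty)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """Cubic regression spline basis over the day axis.

    ``F`` maps knot values to fitted values; coefficients are function
    values at the (free) knots.  ``penalty`` is the integrated squared
    second derivative in the same parameterisation; its null space
    contains the constant function.
    """

    knots: np.ndarray          # all knot locations, increasing
    cyclic: bool
    _binv_d: np.ndarray        # maps free knot values -> knot 2nd derivs

    @property
    def n_coef(self) -> int:
        return len(self.knots) - 1 if self.cyclic else len(self.knots)

    @property
    def penalty(self) -> np.ndarray:
        # S = D' B^{-1} D, assembled from the stored B^{-1} D map
        d_mat = self._d_matrix()
        binv_d = self._binv_d if self.cyclic else self._binv_d[1:-1]
        return d_mat.T @ binv_d

    def _d_matrix(self) -> np.ndarray:
        return _difference_matrix(self.knots, self.cyclic)

    def design(self, x, deriv: int = 0) -> np.ndarray:
        """Evaluate the basis (or its first derivative) at points ``x``."""
        x = np.asarray(x, dtype=float)
        k = self.knots
        q = self.n_coef
        lo, hi = k[0], k[-1]
        if (x < lo - 1e-9).any() or (x > hi + 1e-9).any():
            raise ValueError("evaluation points outside the knot range")
        x = np.clip(x, lo, hi)
        j = np.clip(np.searchsorted(k, x, side="right") - 1, 0, len(k) - 2)
        h = k[j + 1] - k[j]
        t = x - k[j]
        s = k[j + 1] - x

        n_m = len(k) - 1 if self.cyclic else len(k)  # knots carrying m rows
        a_f = np.zeros((len(x), q))
        a_m = np.zeros((len(x), n_m))
        left = j % q if self.cyclic else j
        right = (j + 1) % q if self.cyclic else j + 1
        rows = np.arange(len(x))
        if deriv == 0:
            np.add.at(a_f, (rows, left), s / h)
            np.add.at(a_f, (rows, right), t / h)
            np.add.at(a_m, (rows, left % n_m), s**3 / (6 * h) - h * s / 6)
            np.add.at(a_m, (rows, right % n_m), t**3 / (6 * h) - h * t / 6)
        elif deriv == 1:
            np.add.at(a_f, (rows, left), -1.0 / h)
            np.add.at(a_f, (rows, right), 1.0 / h)
            np.add.at(a_m, (rows, left % n_m), -s**2 / (2 * h) + h / 6)
            np.add.at(a_m, (rows, right % n_m), t**2 / (2 * h) - h / 6)
        else:
            raise ValueError("deriv must be 0 or 1")
        return a_f + a_m @ self._binv_d


def _difference_matrix(knots: np.ndarray, cyclic: bool) -> np.ndarray:
    """Second-difference map D with B m = D f (spline continuity system)."""
    h = np.diff(knots)
    if cyclic:
        q = len(knots) - 1
        d_mat = np.zeros((q, q))
        for j in range(q):
            hm, hp = h[(j - 1) % q], h[j % q]
            d_mat[j, (j - 1) % q] += 1.0 / hm
            d_mat[j, j] += -1.0 / hm - 1.0 / hp
            d_mat[j, (j + 1) % q] += 1.0 / hp
        return d_mat
    k = len(knots)
    d_mat = np.zeros((k - 2, k))
    for j in range(1, k - 1):
        d_mat[j - 1, j - 1] = 1.0 / h[j - 1]
        d_mat[j - 1, j] = -1.0 / h[j - 1] - 1.0 / h[j]
        d_mat[j - 1, j + 1] = 1.0 / h[j]
    return d_mat


def _b_matrix(knots: np.ndarray, cyclic: bool) -> np.ndarray:
    h = np.diff(knots)
    if cyclic:
        q = len(knots) - 1
        b = np.zeros((q, q))
        for j in range(q):
            hm, hp = h[(j - 1) % q], h[j % q]
            b[j, (j - 1) % q] += hm / 6.0
            b[j, j] += (hm + hp) / 3.0
            b[j, (j + 1) % q] += hp / 6.0
        return b
    k = len(knots)
    b = np.zeros((k - 2, k - 2))
    for j in range(1, k - 1):
        if j > 1:
            b[j - 1, j - 2] = h[j - 1] / 6.0
        b[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < k - 2:
            b[j - 1, j] = h[j] / 6.0
    return b


def _make_basis(knots: np.ndarray, cyclic: bool) -> SplineBasis:
    b = _b_matrix(knots, cyclic)
    d_mat = _difference_matrix(knots, cyclic)
    binv_d_free = np.linalg.solve(b, d_mat)
    if cyclic:
        binv_d = binv_d_free
    else:
        # natural boundary: zero second derivative at the two end knots
        k = len(knots)
        binv_d = np.zeros((k, k))
        binv_d[1:-1, :] = binv_d_free
    return SplineBasis(knots=np.asarray(knots, dtype=float), cyclic=cyclic,
                       _binv_d=binv_d)


def cyclic_cubic_basis(
    n_knots: int = DEFAULT_KNOTS, lo: float = 1.0, hi: float = MAX_DAY
) -> SplineBasis:
    """Cyclic cubic regression spline with ``n_knots`` even knots on
    [lo, hi]; the smooth and its first two derivatives match at the two
    ends, so the basis has ``n_knots - 1`` coefficients."""
    if n_knots < 4:
        raise ValueError("need at least 4 knots")
    return _make_basis(np.linspace(lo, hi, n_knots), cyclic=True)


def natural_cubic_basis(
    n_knots: int = DEFAULT_KNOTS, lo: float = 1.0, hi: float = MAX_DAY
) -> SplineBasis:
    """Natural (non-cyclic) cubic regression spline, ``n_knots``
    coefficients; provided as the alternative to the cyclic default."""
    if n_knots < 4:
        raise ValueError("need at least 4 knots")
    return _make_basis(np.linspace(lo, hi, n_knots), cyclic=False)


# ---------------------------------------------------------------------------
# penalized IRLS fit
# ---------------------------------------------------------------------------

@dataclass
class GammFit:
    """Fitted logistic additive model with per-user random intercepts."""

    basis: SplineBasis
    beta: np.ndarray           # [intercept, constrained smooth coefficients]
    b: np.ndarray              # per-user intercepts (model order)
    users: list
    sigma2_b: float
    lam: float
    converged: bool
    n_iter: int
    deviance: float
    edf: float
    z_mat: np.ndarray          # sum-to-zero constraint null-space map
    days: np.ndarray

    def linear_predictor(self, days) -> np.ndarray:
        x = self.basis.design(days) @ self.z_mat
        return self.beta[0] + x @ self.beta[1:]


def _panel_arrays(panel: pd.DataFrame, max_day: int = MAX_DAY):
    p = panel.sort_values(["user_id", "d"], kind="mergesort")
    users = p["user_id"].unique().tolist()
    if len(p) != len(users) * max_day:
        raise ValueError(f"panel must hold exactly {max_day} rows per user")
    y = p["y"].to_numpy(dtype=float).reshape(len(users), max_day)
    return users, y


def _irls(y, x_d, s_pad, lam, sigma2_b, estimate_sigma, tol, max_iter):
    """Penalized IRLS at fixed lambda.  y: (U, D); x_d: (D, p)."""
    n_u, n_d = y.shape
    p = x_d.shape[1]
    beta = np.zeros(p)
    beta[0] = logit(min(max(y.mean(), 1e-4), 1 - 1e-4))
    b = np.zeros(n_u)
    pen = lam * s_pad
    trajectory = []

    def objective(eta, beta, b, theta):
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        dev = -2.0 * (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum()
        return dev + beta @ pen @ beta + theta * (b @ b)

    eta = beta[0] + np.zeros_like(y)
    converged = False
    it = 0
    for outer in range(25):
        theta = 1.0 / sigma2_b
        obj = objective(eta, beta, b, theta)
        inner_converged = False
        while it < max_iter:
            it += 1
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w

            g_u = w @ x_d                         # (U, p)
            w_u = w.sum(axis=1)                   # (U,)
            s_u = (w * z).sum(axis=1)             # (U,)
            denom = w_u + theta
            xtwx = x_d.T @ (w.sum(axis=0)[:, None] * x_d)
            xtwz = x_d.T @ (w * z).sum(axis=0)
            m = xtwx - g_u.T @ (g_u / denom[:, None])
            a = m + pen
            rhs = xtwz - g_u.T @ (s_u / denom)
            beta_new = np.linalg.solve(a, rhs)
            b_new = (s_u - g_u @ beta_new) / denom

            # step-halving on the penalized deviance
            step = 1.0
            for _ in range(30):
                beta_try = beta + step * (beta_new - beta)
                b_try = b + step * (b_new - b)
                eta_try = (x_d @ beta_try)[None, :] + b_try[:, None]
                obj_try = objective(eta_try, beta_try, b_try, theta)
                if obj_try <= obj + 1e-12 * (1 + abs(obj)):
                    break
                step *= 0.5
            rel = abs(obj - obj_try) / (1.0 + abs(obj_try))
            beta, b, eta, obj = beta_try, b_try, eta_try, obj_try
            trajectory.append(obj)
            if rel < tol:
                inner_converged = True
                break
        if not estimate_sigma:
            converged = inner_converged
            break
        # EM fixed-point for the intercept variance
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        denom = w.sum(axis=1) + 1.0 / sigma2_b
        sigma2_new = float((b @ b + (1.0 / denom).sum()) / n_u)
        sigma2_new = min(max(sigma2_new, 1e-4), 1e4)
        settled = abs(sigma2_new - sigma2_b) / sigma2_b < 1e-3
        sigma2_b = sigma2_new
        # the variance component needs only a loose fixed point; the flag
        # reports whether the IRLS deviance itself converged
        converged = inner_converged
        if settled:
            break
    if not converged and it >= max_iter:
        raise FitError(
            f"IRLS did not converge in {max_iter} iterations", trajectory
        )

    # effective dof of the fixed part + shrunk random part (working model)
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    theta = 1.0 / sigma2_b
    denom = w.sum(axis=1) + theta
    g_u = w @ x_d
    xtwx = x_d.T @ (w.sum(axis=0)[:, None] * x_d)
    m = xtwx - g_u.T @ (g_u / denom[:, None])
    edf_fixed = float(np.trace(np.linalg.solve(m + pen, m)))
    edf_random = float((w.sum(axis=1) / denom).sum())

    mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
    deviance = float(-2.0 * (y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)).sum())
    n_obs = y.size
    edf = edf_fixed + edf_random
    # deviance-based GCV (the GLM form): n D / (n - edf)^2
    gcv = n_obs * deviance / (n_obs - min(edf, 0.9 * n_obs)) ** 2
    return {
        "beta": beta, "b": b, "sigma2_b": sigma2_b, "converged": converged,
        "n_iter": it, "deviance": deviance, "edf": edf, "gcv": gcv,
        "trajectory": trajectory,
    }


def fit_gamm(
    panel: pd.DataFrame,
    basis: SplineBasis | None = None,
    lambda_select: str = "gcv",
    lam: float | None = None,
    lambda_grid=None,
    sigma2_b: float = 0.5,
    estimate_sigma: bool = True,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> GammFit:
    """Fit logit P(y=1 | u, d) = f(d) + b_u on a daily panel.

    ``lambda_select`` is ``"gcv"`` (approximate GCV over ``lambda_grid``,
    default logspace(-2, 5, 8)) or ``"fixed"`` (requires ``lam``).  The
    smooth is centered over the observed days for identifiability, with
    the population intercept carried separately.  Deterministic.
    """
    if basis is None:
        basis = cyclic_cubic_basis()
    if len(panel) == 0:
        raise ValueError("empty panel")
    users, y = _panel_arrays(panel)

    days = np.arange(1, MAX_DAY + 1, dtype=float)
    f = basis.design(days)
    # sum-to-zero identifiability constraint: reparameterize the smooth on
    # the null space of its column-sum functional (the constant lives in
    # the basis span, so plain centering would be rank deficient)
    c = f.sum(axis=0)
    q, _ = np.linalg.qr(
        np.column_stack([c, np.eye(len(c))]), mode="reduced"
    )
    z_mat = q[:, 1:len(c)]
    x_d = np.column_stack([np.ones(len(days)), f @ z_mat])
    s_z = z_mat.T @ basis.penalty @ z_mat
    # normalize the penalty so lambda is dimensionless: unit Frobenius
    # ratio against the smooth block of the day design's Gram matrix
    gram = x_d[:, 1:].T @ x_d[:, 1:]
    scale = np.linalg.norm(gram) / np.linalg.norm(s_z)
    s_pad = np.zeros((x_d.shape[1], x_d.shape[1]))
    s_pad[1:, 1:] = scale * s_z

    if lambda_select == "fixed":
        if lam is None:
            raise ValueError("lambda_select='fixed' requires lam")
        grid = [float(lam)]
    elif lambda_select == "gcv":
        grid = list(np.logspace(-6, 2, 9) if lambda_grid is None
                    else lambda_grid)
    else:
        raise ValueError(f"unknown lambda_select {lambda_select!r}")

    best = None
    best_lam = None
    for lam_try in grid:
        res = _irls(y, x_d, s_pad, lam_try, sigma2_b, estimate_sigma,
                    tol, max_iter)
        if best is None or res["gcv"] < best["gcv"] - 1e-12:
            best, best_lam = res, lam_try

    return GammFit(
        basis=basis, beta=best["beta"], b=best["b"], users=users,
        sigma2_b=best["sigma2_b"], lam=float(best_lam),
        converged=best["converged"], n_iter=best["n_iter"],
        deviance=best["deviance"], edf=best["edf"], z_mat=z_mat,
        days=days,
    )


def predict_curve(fit: GammFit) -> np.ndarray:
    """Population daily probability curve (random intercept at zero)."""
    return expit(fit.linear_predictor(fit.days))


def percent_change(curve: np.ndarray) -> float:
    """Percent change of the predicted probability from day 1 to day 180."""
    curve = np.asarray(curve, dtype=float)
    if curve[0] <= 0:
        raise ValueError("percent change undefined: p(1) = 0")
    return float(100.0 * (curve[-1] - curve[0]) / curve[0])


def quartile_subset(
    features: pd.DataFrame, outcome: str, which: str
) -> set:
    """Users in the bottom (<= Q1) or top (>= Q3) quartile of an outcome.

    Quartiles use the linear-interpolation quantile; boundary ties are
    included on both sides.
    """
    if outcome not in ("m67", "ls"):
        raise ValueError(f"unknown outcome {outcome!r}")
    if which not in ("bottom", "top"):
        raise ValueError(f"which must be 'bottom' or 'top', got {which!r}")
    if len(features) < 4:
        raise ValueError("need at least 4 users for quartile subsets")
    x = features[outcome].to_numpy(dtype=float)
    if which == "bottom":
        thr = np.quantile(x, 0.25)
        mask = x <= thr
    else:
        thr = np.quantile(x, 0.75)
        mask = x >= thr
    return set(features.loc[mask, "user_id"])
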