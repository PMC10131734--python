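import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import medhabit as mh
import medhabit.gamm as gm

from conftest import make_event_log, med_row


def flat_panel(n_users, p, seed, n_days=180):
    rng = np.random.default_rng(seed)
    y = (rng.random((n_users, n_days)) < p).astype(int)
    return pd.DataFrame({
        "user_id": np.repeat([f"u{i:04d}" for i in range(n_users)], n_days),
        "d": np.tile(np.arange(1, n_days + 1), n_users),
        "y": y.ravel(),
    })


class TestDailyPanel:
    def test_single_morning_session(self):
        log = make_event_log([med_row(start="2017-03-05 07:00")])
        sess = mh.meditation_sessions(log, max_day=180)
        panel = mh.build_daily_panel(sess, window="morning", users={"u1"})
        assert len(panel) == 180
        assert panel.loc[panel["d"] == 5, "y"].item() == 1
        assert panel["y"].sum() == 1

    def test_wrong_window_all_zero(self):
        log = make_event_log([med_row(start="2017-03-05 07:00")])
        sess = mh.meditation_sessions(log, max_day=180)
        panel = mh.build_daily_panel(sess, window="evening", users={"u1"})
        assert panel["y"].sum() == 0

    def test_empty_user_set_rejected(self, sessions_small):
        capped, _ = sessions_small
        with pytest.raises(ValueError):
            mh.build_daily_panel(capped, users=set())

    def test_panel_sums_equal_distinct_active_days(self, sessions_small):
        capped, _ = sessions_small
        users = set(capped["user_id"])
        panel = mh.build_daily_panel(capped, window="any", users=users)
        got = panel.groupby("user_id")["y"].sum()
        for uid, g in capped.groupby("user_id"):
            assert got[uid] == g["d"].nunique()

    def test_any_is_union_of_windows(self, sessions_small):
        capped, _ = sessions_small
        users = set(capped["user_id"])
        any_panel = mh.build_daily_panel(capped, "any", users)
        union = np.zeros(len(any_panel), dtype=int)
        for w in mh.TOD_WINDOWS:
            union |= mh.build_daily_panel(capped, w, users)["y"].to_numpy()
        np.testing.assert_array_equal(any_panel["y"].to_numpy(), union)


class TestSplineBasis:
    def test_cyclic_value_and_derivative_match_at_ends(self):
        b = mh.cyclic_cubic_basis(8)
        ends = np.array([1.0, 180.0])
        x0 = b.design(ends)
        x1 = b.design(ends, deriv=1)
        np.testing.assert_allclose(x0[0], x0[1], atol=1e-8)
        np.testing.assert_allclose(x1[0], x1[1], atol=1e-8)

    @pytest.mark.parametrize("maker", [mh.cyclic_cubic_basis,
                                       mh.natural_cubic_basis])
    def test_constant_in_nullspace_of_penalty(self, maker):
        b = maker(8)
        ones = np.ones(b.n_coef)
        days = np.linspace(1, 180, 73)
        np.testing.assert_allclose(b.design(days) @ ones, 1.0)
        assert abs(ones @ b.penalty @ ones) < 1e-12

    def test_penalty_positive_semidefinite(self):
        b = mh.cyclic_cubic_basis(8)
        eig = np.linalg.eigvalsh(0.5 * (b.penalty + b.penalty.T))
        assert eig.min() > -1e-10

    @pytest.mark.parametrize("maker", [mh.cyclic_cubic_basis,
                                       mh.natural_cubic_basis])
    def test_least_squares_fit_of_periodic_curve(self, maker):
        b = maker(8)
        days = np.arange(1, 181, dtype=float)
        target = np.sin(2 * np.pi * (days - 1) / 179)
        x = b.design(days)
        coef, *_ = np.linalg.lstsq(x, target, rcond=None)
        assert np.abs(x @ coef - target).max() < 0.02

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            mh.cyclic_cubic_basis(3)


class TestFitGamm:
    def test_flat_panel_recovered(self):
        panel = flat_panel(150, 0.3, seed=1)
        fit = mh.fit_gamm(panel)
        curve = mh.predict_curve(fit)
        assert fit.converged
        assert np.abs(curve - 0.3).max() < 0.03

    def test_lambda_to_infinity_matches_intercept_only_glm(self):
        panel = flat_panel(100, 0.25, seed=2)
        fit = mh.fit_gamm(panel, lambda_select="fixed", lam=1e9)
        curve = mh.predict_curve(fit)
        glm = sm.GLM(
            panel["y"].to_numpy(), np.ones((len(panel), 1)),
            family=sm.families.Binomial(),
        ).fit()
        assert np.abs(curve - expit(glm.params[0])).max() < 1e-3

    def test_balanced_duplication_leaves_curve_unchanged(self):
        panel = flat_panel(60, 0.3, seed=3)
        dup = panel.copy()
        dup["user_id"] = "x" + dup["user_id"]
        fit1 = mh.fit_gamm(panel, lambda_select="fixed", lam=1.0,
                           estimate_sigma=False)
        fit2 = mh.fit_gamm(pd.concat([panel, dup], ignore_index=True),
                           lambda_select="fixed", lam=1.0,
                           estimate_sigma=False)
        np.testing.assert_allclose(mh.predict_curve(fit1),
                                   mh.predict_curve(fit2), atol=5e-3)

    def test_sinusoidal_signal_recovered_within_bands(self):
        rng = np.random.default_rng(7)
        n_users, n_days = 500, 180
        days = np.arange(1, n_days + 1, dtype=float)
        eta = -0.5 + 0.8 * np.sin(2 * np.pi * days / 180)
        b_u = rng.normal(0, 0.5, n_users)
        y = (rng.random((n_users, n_days))
             < expit(eta[None, :] + b_u[:, None])).astype(int)
        panel = pd.DataFrame({
            "user_id": np.repeat([f"u{i:04d}" for i in range(n_users)], n_days),
            "d": np.tile(days.astype(int), n_users),
            "y": y.ravel(),
        })
        fit = mh.fit_gamm(panel)
        curve = mh.predict_curve(fit)
        assert np.abs(curve - expit(eta)).max() < 0.04

    def test_penalized_deviance_nonincreasing(self):
        panel = flat_panel(40, 0.3, seed=5)
        _, y = gm._panel_arrays(panel)
        days = np.arange(1, 181, dtype=float)
        basis = mh.cyclic_cubic_basis()
        f = basis.design(days)
        c = f.sum(axis=0)
        q, _ = np.linalg.qr(np.column_stack([c, np.eye(len(c))]))
        z = q[:, 1:len(c)]
        x_d = np.column_stack([np.ones(180), f @ z])
        s_pad = np.zeros((x_d.shape[1], x_d.shape[1]))
        s_pad[1:, 1:] = z.T @ basis.penalty @ z
        res = gm._irls(y, x_d, s_pad, 1.0, 0.5, False, 1e-8, 200)
        assert res["converged"]
        traj = np.asarray(res["trajectory"])
        assert (np.diff(traj) <= 1e-6 * (1 + np.abs(traj[:-1]))).all()

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            mh.fit_gamm(pd.DataFrame(columns=["user_id", "d", "y"]))


class TestPredictAndChange:
    def test_zero_coefficients_give_half(self):
        panel = flat_panel(30, 0.5, seed=8)
        fit = mh.fit_gamm(panel, lambda_select="fixed", lam=1.0)
        fit.beta = np.zeros_like(fit.beta)
        np.testing.assert_allclose(mh.predict_curve(fit), 0.5)

    def test_curve_equals_direct_basis_evaluation(self):
        panel = flat_panel(50, 0.35, seed=9)
        fit = mh.fit_gamm(panel, lambda_select="fixed", lam=10.0)
        direct = expit(
            fit.beta[0]
            + fit.basis.design(fit.days) @ fit.z_mat @ fit.beta[1:]
        )
        np.testing.assert_allclose(mh.predict_curve(fit), direct, atol=1e-12)

    def test_percent_change_examples(self):
        assert mh.percent_change(np.linspace(0.5, 0.25, 180)) == pytest.approx(-50.0)
        assert mh.percent_change(np.full(180, 0.4)) == 0.0
        with pytest.raises(ValueError):
            mh.percent_change(np.concatenate([[0.0], np.full(179, 0.1)]))

    def test_pipeline_percent_change_tracks_generator_truth(self):
        # day-1 -> day-180 contrast requires the untied (natural) basis;
        # oracle: mean-logit closed form of the qualifying daily curves
        cfg = mh.SimConfig(n_users=500, seed=1)
        events, _ = mh.simulate(cfg)
        sess = mh.meditation_sessions(events, max_day=180)
        panel = mh.build_daily_panel(sess, "any", users=set(events["user_id"]))
        fit = mh.fit_gamm(panel, mh.natural_cubic_basis(8))
        got = mh.percent_change(mh.predict_curve(fit))

        # P(>=1 completed session | active day): 1 - E[(1-cp)^(1+extra)]
        q = 1 - (1 - cfg.completion_prob) * (
            (1 - 0.12) + 0.12 * (1 - cfg.completion_prob)
        ) ** 2
        wts = np.asarray(cfg.dominant_window_weights, dtype=float)
        wts = wts / wts.sum()
        mean_logit = np.zeros(2)
        for w, pw in zip(mh.TOD_WINDOWS, wts):
            for a in mh.ARCHETYPES:
                p = np.clip(
                    mh.daily_curve(a, np.array([1.0, 180.0]), cfg) * q,
                    1e-6, 1 - 1e-6,
                )
                mean_logit += pw * cfg.archetype_mix[w][a] * np.log(p / (1 - p))
        oracle = expit(mean_logit)
        oracle_pct = 100 * (oracle[1] - oracle[0]) / oracle[0]
        assert got == pytest.approx(oracle_pct, abs=6.0)
        assert -85.0 < got < -55.0

    def test_window_curves_dominated_by_any(self, sessions_small):
        capped, _ = sessions_small
        users = set(capped["user_id"])
        curves = {}
        for w in ("any",) + mh.TOD_WINDOWS:
            panel = mh.build_daily_panel(capped, w, users)
            fit = mh.fit_gamm(panel, lambda_select="fixed", lam=1.0)
            curves[w] = mh.predict_curve(fit)
        best = np.max([curves[w] for w in mh.TOD_WINDOWS], axis=0)
        assert (curves["any"] >= best - 0.05).all()


class TestQuartileSubset:
    def test_interpolated_quartiles(self):
        feats = pd.DataFrame({"user_id": list("abcd"), "m67": [1, 2, 3, 4],
                              "ls": [1, 1, 1, 1]})
        assert mh.quartile_subset(feats, "m67", "bottom") == {"a"}
        assert mh.quartile_subset(feats, "m67", "top") == {"d"}

    def test_degenerate_ties_include_everyone(self):
        feats = pd.DataFrame({"user_id": list("abcd"), "m67": [5, 5, 5, 5]})
        assert mh.quartile_subset(feats, "m67", "bottom") == set("abcd")
        assert mh.quartile_subset(feats, "m67", "top") == set("abcd")

    def test_subsets_disjoint_unless_degenerate(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({
            "user_id": [f"u{i}" for i in range(40)],
            "ls": rng.permutation(40).astype(float),
        })
        bottom = mh.quartile_subset(feats, "ls", "bottom")
        top = mh.quartile_subset(feats, "ls", "top")
        assert bottom.isdisjoint(top)
        assert bottom | top <= set(feats["user_id"])
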