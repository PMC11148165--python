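"""Mixed models, Kaplan-Meier, Cox partial likelihood, joint model, Fisher."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysbiome.survival import (
    _cox_loglik,
    fisher_association,
    fit_cox,
    fit_joint,
    fit_lmm,
    joint_loglik,
    kaplan_meier,
)


def make_longitudinal(n=200, slope=-0.05, sigma_b=1.0, sigma_e=0.5, seed=0):
    rng = np.random.default_rng(seed)
    b = rng.normal(0, sigma_b, n)
    rows = []
    for i in range(n):
        for day in (2, 5, 9):
            rows.append((f"s{i}", day, 2.0 + slope * day + b[i] + rng.normal(0, sigma_e)))
    return pd.DataFrame(rows, columns=["subject_id", "day", "y"])


def make_joint_cohort(n=150, nu=0.8, seed=0):
    """Longitudinal marker with random intercepts shared into the hazard."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0, 1.0, n)
    rows = []
    for i in range(n):
        for day in (2, 5, 9):
            rows.append((f"s{i}", day, 2.0 - 0.05 * day + b[i] + rng.normal(0, 0.5)))
    long_data = pd.DataFrame(rows, columns=["subject_id", "day", "y"])
    age = rng.normal(60, 10, n)
    lam = 0.006 * np.exp(0.01 * (age - 60) + nu * b)
    t = rng.exponential(1 / lam)
    surv = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "time": np.minimum(t, 60),
            "event": (t <= 60).astype(int),
            "age": age,
        }
    )
    return long_data, surv


class TestLMM:
    def test_degenerate_limit_matches_ols(self):
        """With one observation per subject there is no between/within split;
        fixed effects collapse to ordinary least squares."""
        rng = np.random.default_rng(1)
        n = 120
        day = rng.integers(1, 10, n).astype(float)
        y = 1.0 + 0.3 * day + rng.normal(0, 0.4, n)
        data = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "day": day, "y": y})
        fit = fit_lmm(data, "y", ["day"])
        beta_ols = np.linalg.lstsq(np.column_stack([np.ones(n), day]), y, rcond=None)[0]
        np.testing.assert_allclose(fit.fixed_effects.to_numpy(), beta_ols, atol=1e-5)

    def test_slope_recovery_within_ci(self):
        data = make_longitudinal(seed=2)
        fit = fit_lmm(data, "y", ["day"])
        slope, se = fit.fixed_effects["day"], fit.se["day"]
        assert abs(slope - (-0.05)) < 1.96 * se * 1.5
        assert fit.random_intercept_var == pytest.approx(1.0, rel=0.4)
        assert fit.residual_var == pytest.approx(0.25, rel=0.4)

    def test_unbalanced_panels_fit(self):
        data = make_longitudinal(n=80, seed=3)
        rng = np.random.default_rng(4)
        keep = rng.random(len(data)) > 0.3  # random visit deletion
        fit = fit_lmm(data[keep], "y", ["day"])
        assert fit.converged


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        rec = pd.DataFrame({"time": [60.0] * 8, "event": [0] * 8})
        curves, _ = kaplan_meier(rec)
        assert (curves["all"]["survival"] == 1.0).all()

    def test_two_subject_hand_computation(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        curve = kaplan_meier(rec)[0]["all"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.5)
        assert curve.loc[2.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 50).round(3)
        rec = pd.DataFrame({"time": times, "event": np.ones(50, int)})
        curve = kaplan_meier(rec)[0]["all"]
        for t in (2.0, 5.0, 12.0):
            s_hat = curve.loc[curve["time"] <= t, "survival"].iloc[-1]
            assert s_hat == pytest.approx((times > t).mean(), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(pd.DataFrame({"time": [], "event": []}))


class TestCox:
    rec6 = pd.DataFrame(
        {"time": [2, 3, 5, 7, 11, 13], "event": [1, 1, 0, 1, 1, 0], "x": [1, 0, 1, 0, 1, 0]}
    )

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_grid_search_oracle_tiny_dataset(self, ties):
        fit = fit_cox(self.rec6, ["x"], ties=ties)
        grid = np.linspace(-3, 3, 60001)
        X = self.rec6[["x"]].to_numpy(float)
        t = self.rec6["time"].to_numpy(float)
        e = self.rec6["event"].to_numpy(int)
        lls = [_cox_loglik(np.array([b]), X, t, e, ties)[0] for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert fit.coefficients["x"] == pytest.approx(beta_star, abs=1e-4)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter
        from dysbiome.synthetic import simulate_outcomes

        out = simulate_outcomes(
            np.repeat([1, 2], 150), 0.004, np.array([1.0, 2.5]), 60, seed=6
        )
        out["g"] = (out["cluster"] == 2).astype(int)
        ours = fit_cox(out, ["g"])
        ref = CoxPHFitter().fit(out[["time", "event", "g"]], "time", "event")
        assert ours.coefficients["g"] == pytest.approx(ref.params_["g"], abs=1e-4)
        assert ours.se["g"] == pytest.approx(ref.standard_errors_["g"], abs=1e-4)

    def test_hazard_ratio_recovery(self):
        from dysbiome.synthetic import simulate_outcomes

        out = simulate_outcomes(
            np.repeat([1, 2], 200), 0.005, np.array([1.0, 3.0]), 60, seed=7
        )
        out["g"] = (out["cluster"] == 2).astype(int)
        fit = fit_cox(out, ["g"])
        assert 2.0 <= fit.hr["g"] <= 4.5
        assert fit.ci_lower["g"] < fit.hr["g"] < fit.ci_upper["g"]

    def test_null_covariate_ci_covers_one(self):
        from dysbiome.synthetic import simulate_outcomes

        covered = 0
        for seed in range(20):
            out = simulate_outcomes(
                np.ones(120, dtype=int), 0.008, np.array([1.0]), 60, seed=seed
            )
            rng = np.random.default_rng(seed + 1000)
            out["noise"] = rng.normal(0, 1, len(out))
            fit = fit_cox(out, ["noise"])
            covered += fit.ci_lower["noise"] <= 1.0 <= fit.ci_upper["noise"]
        assert covered >= 17  # ~95% nominal coverage, binomial slack at 20 reps

    def test_constant_covariate_rejected(self):
        rec = self.rec6.assign(flat=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_cox(rec, ["flat"])

    def test_no_events_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(rec, ["x"])

    def test_separation_triggers_penalized_refit(self):
        rec = pd.DataFrame(
            {
                "time": [1, 2, 3, 10, 11, 12],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [1, 1, 1, 0, 0, 0],  # all early deaths in one arm
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_cox(rec, ["x"])
        assert fit.penalized
        assert np.isfinite(fit.coefficients["x"])


class TestJointModel:
    def test_separability_at_zero_association(self):
        """With nu = 0 the marginal likelihood factorizes: joint ll equals the
        mixed-model ll plus the exponential survival ll (quadrature error)."""
        long_data, surv = make_joint_cohort(nu=0.0, seed=2)
        lmm = fit_lmm(long_data, "y", ["day"])
        Z = surv[["age"]].to_numpy()
        t, e = surv["time"].to_numpy(), surv["event"].to_numpy()

        def surv_nll(p):
            eta = p[1] + p[0] * Z[:, 0]
            return -(e * eta - np.exp(eta) * t).sum()

        from scipy.optimize import minimize

        r = minimize(surv_nll, [0.0, np.log(e.sum() / t.sum())], method="Nelder-Mead")
        params = np.concatenate(
            [
                lmm.fixed_effects.to_numpy(),
                [0.5 * np.log(lmm.random_intercept_var), 0.5 * np.log(lmm.residual_var)],
                [r.x[0], r.x[1], 0.0],
            ]
        )
        jl = joint_loglik(long_data, surv, "y", ["day"], ["age"], params)
        assert jl == pytest.approx(lmm.log_likelihood - r.fun, abs=1e-6)

    def test_positive_association_sign_recovered(self):
        long_data, surv = make_joint_cohort(nu=0.8, seed=1)
        fit = fit_joint(long_data, surv, "y", ["day"], ["age"], bootstrap=False)
        assert fit.nu > 0.3
        assert fit.beta["day"] == pytest.approx(-0.05, abs=0.05)
        assert fit.sigma_b == pytest.approx(1.0, rel=0.35)

    def test_bootstrap_ci_deterministic(self):
        long_data, surv = make_joint_cohort(n=80, nu=0.5, seed=3)
        f1 = fit_joint(long_data, surv, "y", ["day"], ["age"], n_boot=10, seed=9)
        f2 = fit_joint(long_data, surv, "y", ["day"], ["age"], n_boot=10, seed=9)
        np.testing.assert_array_equal(f1.boot_nu, f2.boot_nu)

    def test_no_events_rejected(self):
        long_data, surv = make_joint_cohort(n=20, nu=0.0, seed=4)
        surv["event"] = 0
        with pytest.raises(ValueError, match="event"):
            fit_joint(long_data, surv, "y", ["day"], ["age"], bootstrap=False)


class TestFisher:
    def test_sample_odds_ratio(self):
        res = fisher_association([[30, 10], [10, 30]])
        assert res.odds_ratio == pytest.approx(9.0)
        assert not res.corrected

    def test_independence(self):
        res = fisher_association([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_exact_p_matches_hypergeometric_enumeration(self):
        table = np.array([[8, 2], [1, 5]])
        res = fisher_association(table)
        # enumerate all tables with the observed margins
        row0, col0, n = 10, 9, 16
        probs = {
            a: stats.hypergeom.pmf(a, n, row0, col0)
            for a in range(max(0, col0 - (n - row0)), min(row0, col0) + 1)
        }
        p_obs = probs[8]
        p_exact = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_zero_cell_uses_haldane_correction(self):
        res = fisher_association([[5, 0], [2, 7]])
        assert res.corrected
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))
        assert np.isfinite(res.ci[0]) and np.isfinite(res.ci[1])

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            fisher_association([[1, 2, 3], [4, 5, 6]])
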