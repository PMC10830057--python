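"""Cox fitting, exhaustive CV subset search and variance importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cvdval.model_search import (
    PoolEntry,
    _stratified_folds,
    _t,
    cv_subset_search,
    default_candidate_pool,
    fit_cox,
    predict_risk_10y,
    variance_importance,
)
from cvdval.risk_engines import Term, builtin_spec
from cvdval.synthetic_data import generate_covariates, table1_male


def simulate_exponential_cohort(rng, n, betas, rate=0.02, horizon=10.0):
    """Exponential survival with log-hazard x @ betas; admin censoring at horizon."""
    x = rng.normal(size=(n, len(betas)))
    lp = x @ np.asarray(betas)
    t = rng.exponential(1.0 / (rate * np.exp(lp)))
    event = t < horizon
    df = pd.DataFrame(x, columns=[f"x{j}" for j in range(len(betas))])
    df["event"] = event
    df["followup_years"] = np.minimum(t, horizon)
    df["sex"] = "male"
    return df


def identity_terms(k):
    return tuple(_t(f"x{j}", (f"x{j}",), "identity") for j in range(k))


class TestFitCox:
    def test_toy_coefficient_matches_numerical_partial_likelihood(self):
        """6-record toy vs direct maximization of the hand-written Breslow log-PL."""
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([True, True, False, True, False, False])
        df = pd.DataFrame({"x0": x, "followup_years": time, "event": event})

        def neg_logpl(beta):
            ll = 0.0
            for i in range(6):
                if event[i]:
                    risk_set = time >= time[i]
                    ll += beta * x[i] - np.log(np.exp(beta * x[risk_set]).sum())
            return -ll

        oracle = optimize.minimize_scalar(neg_logpl, bounds=(-5, 5), method="bounded").x
        fit = fit_cox(df, identity_terms(1))
        assert fit.coefficients[0] == pytest.approx(oracle, abs=1e-5)
        assert fit.convergence == "converged"

    def test_recovers_known_binary_log_hazard_ratio(self):
        rng = np.random.default_rng(11)
        n = 20_000
        x = (rng.random(n) < 0.4).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(0.7 * x)))
        df = pd.DataFrame(
            {"x0": x, "event": t < 10, "followup_years": np.minimum(t, 10)}
        )
        fit = fit_cox(df, identity_terms(1))
        assert abs(fit.coefficients[0] - 0.7) < 3 * fit.standard_errors[0]

    def test_constant_zero_covariate_is_uninformative(self):
        rng = np.random.default_rng(0)
        df = simulate_exponential_cohort(rng, 500, [0.5])
        df["x1"] = 0.0
        fit = fit_cox(df, identity_terms(2))
        assert fit.coefficients[1] == 0.0
        assert fit.standard_errors[1] == 0.0
        only = fit_cox(df, identity_terms(1))
        assert fit.log_partial_likelihood == pytest.approx(only.log_partial_likelihood, abs=1e-8)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x0": [1.0, 0.0], "event": [False, False], "followup_years": [10.0, 10.0]})
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, identity_terms(1))

    def test_fitted_likelihood_beats_null(self):
        rng = np.random.default_rng(1)
        df = simulate_exponential_cohort(rng, 1000, [0.6, -0.4])
        fit = fit_cox(df, identity_terms(2))
        assert fit.log_partial_likelihood > fit.null_log_partial_likelihood

    def test_matches_lifelines_on_untied_data(self):
        """Independent implementation cross-check (untied times: all tie rules agree)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        df = simulate_exponential_cohort(rng, 2000, [0.5, -0.3])
        fit = fit_cox(df, identity_terms(2))
        cph = CoxPHFitter().fit(
            df[["x0", "x1", "followup_years", "event"]],
            duration_col="followup_years",
            event_col="event",
        )
        assert fit.coefficients == pytest.approx(cph.params_.to_numpy(), abs=1e-4)
        assert fit.standard_errors == pytest.approx(cph.standard_errors_.to_numpy(), rel=1e-3)

    def test_ten_year_risk_tracks_observed_incidence(self):
        rng = np.random.default_rng(2)
        df = simulate_exponential_cohort(rng, 5000, [0.5])
        fit = fit_cox(df, identity_terms(1))
        risk = predict_risk_10y(fit, df)
        assert np.all((risk >= 0) & (risk <= 1))
        assert risk.mean() == pytest.approx(df["event"].mean(), rel=0.05)


class TestSubsetSearch:
    def make_signal_noise_cohort(self, rng, n=5000):
        df = simulate_exponential_cohort(rng, n, [0.8, 0.0])
        return df

    def test_three_term_pool_enumerates_seven_subsets(self):
        rng = np.random.default_rng(3)
        df = simulate_exponential_cohort(rng, 800, [0.7, 0.0, 0.0])
        pool = [PoolEntry(f"x{j}", (_t(f"x{j}", (f"x{j}",), "identity"),)) for j in range(3)]
        res = cv_subset_search(df, pool, folds=3, seed=0)
        assert res.n_subsets == 7
        assert len(res.leaderboard) == 7

    def test_signal_beats_noise(self):
        rng = np.random.default_rng(4)
        df = self.make_signal_noise_cohort(rng)
        pool = [
            PoolEntry("signal", (_t("x0", ("x0",), "identity"),)),
            PoolEntry("noise", (_t("x1", ("x1",), "identity"),)),
        ]
        res = cv_subset_search(df, pool, folds=5, seed=1)
        assert "signal" in res.best_subset

    def test_single_entry_pool_returns_it(self):
        rng = np.random.default_rng(6)
        df = simulate_exponential_cohort(rng, 600, [0.5])
        pool = [PoolEntry("only", (_t("x0", ("x0",), "identity"),))]
        res = cv_subset_search(df, pool, folds=3, seed=0)
        assert res.best_subset == ("only",)
        assert res.n_subsets == 1

    def test_folds_partition_records(self):
        rng = np.random.default_rng(7)
        event = rng.random(503) < 0.2
        fold_id = _stratified_folds(event, 5, seed=9)
        assert len(fold_id) == 503
        assert set(fold_id) == set(range(5))
        # stratification: every fold contains events
        for k in range(5):
            assert event[fold_id == k].sum() > 0

    def test_oversized_pool_refused(self):
        pool = [PoolEntry(f"t{j}", (_t(f"x{j}", (f"x{j}",), "identity"),)) for j in range(21)]
        with pytest.raises(ValueError, match="force"):
            cv_subset_search(pd.DataFrame({"event": [True], "followup_years": [1.0]}), pool)

    def test_default_pool_structure(self):
        pool = default_candidate_pool()
        names = [p.name for p in pool]
        assert "ln_sbp" in names
        sbp = next(p for p in pool if p.name == "ln_sbp")
        assert {t.condition for t in sbp.terms} == {"bp_treated", "not_bp_treated"}
        assert "ln_age_square" in names and "ln_bmi" in names and "ln_ldl" in names


class TestVarianceImportance:
    def test_single_term_share_is_100(self, rng):
        df = simulate_exponential_cohort(rng, 300, [0.5])
        fit = fit_cox(df, identity_terms(1))
        table = variance_importance(fit, df)
        assert table.rows["variance_share"].iloc[0] == pytest.approx(100.0)

    def test_zero_coefficient_share_is_zero(self, rng):
        df = simulate_exponential_cohort(rng, 300, [0.5])
        df["x1"] = rng.normal(size=300)
        fit = fit_cox(df, identity_terms(2))
        object.__setattr__(fit, "coefficients", np.array([fit.coefficients[0], 0.0]))
        table = variance_importance(fit, df)
        assert table.rows.set_index("term").loc["x1", "variance_share"] == pytest.approx(0.0)

    def test_independent_covariates_match_closed_form(self):
        """share(j) = 100 b_j^2 s_j^2 / sum(b^2 s^2) for independent covariates."""
        rng = np.random.default_rng(8)
        n = 200_000
        s1, s2, b1, b2 = 2.0, 0.5, 0.7, -1.1
        df = pd.DataFrame({"x0": rng.normal(0, s1, n), "x1": rng.normal(0, s2, n)})
        df["sex"] = "male"
        from cvdval.risk_engines import RiskEngineSpec, Term

        spec = RiskEngineSpec(
            engine="custom",
            sex="male",
            terms=(
                Term("x0", ("x0",), "identity", beta=b1),
                Term("x1", ("x1",), "identity", beta=b2),
            ),
            mean_lp=0.0,
            baseline_survival=0.9,
        )
        table = variance_importance(spec, df)
        denom = b1**2 * s1**2 + b2**2 * s2**2
        expected = {"x0": 100 * b1**2 * s1**2 / denom, "x1": 100 * b2**2 * s2**2 / denom}
        got = table.rows.set_index("term")["variance_share"]
        # sampling error only: population covariance is exactly diagonal
        assert got["x0"] == pytest.approx(expected["x0"], rel=0.02)
        assert got["x1"] == pytest.approx(expected["x1"], rel=0.02)

    def test_shift_invariance(self, rng):
        df = simulate_exponential_cohort(rng, 400, [0.5, -0.3])
        fit = fit_cox(df, identity_terms(2))
        base = variance_importance(fit, df).rows["variance_share"].to_numpy()
        df2 = df.copy()
        df2["x0"] = df2["x0"] + 5.0
        shifted = variance_importance(fit, df2).rows["variance_share"].to_numpy()
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_engine_spec_rows_include_conditional_sbp_terms(self):
        cohort = generate_covariates(table1_male(), 500, seed=0)
        spec = builtin_spec("framingham", "male")
        table = variance_importance(spec, cohort)
        assert {"ln_sbp_treated", "ln_sbp_untreated"} <= set(table.rows["term"])
        assert len(table.rows) == len(spec.terms)

    def test_degenerate_predictor_rejected(self):
        df = pd.DataFrame({"x0": [1.0, 1.0, 1.0], "sex": "male"})
        from cvdval.risk_engines import RiskEngineSpec, Term

        spec = RiskEngineSpec(
            engine="custom", sex="male",
            terms=(Term("x0", ("x0",), "identity", beta=1.0),),
            mean_lp=0.0, baseline_survival=0.9,
        )
        with pytest.raises(ValueError, match="degenerate"):
            variance_importance(spec, df)
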