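import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.integrate import quad
from scipy.special import expit

from ricurve import inference as inf
from ricurve.reference_tables import REFERENCE_BLOCKS


class TestEnumerate:
    @pytest.mark.parametrize("pool, expected", [
        (("mean_individual_clutch", "population", "sex"), 8),
        (("population",), 2),
        ((), 1),
    ])
    def test_subset_counts(self, pool, expected):
        cands = inf.enumerate_candidates("timescale_binary", fixed_pool=pool)
        assert len(cands) == expected
        assert cands[0].fixed_terms == ()  # intercept-only always present

    def test_families_and_transforms(self):
        binary = inf.enumerate_candidates("timescale_binary", "absolute")[0]
        assert (binary.family, binary.transform) == ("bernoulli_logit", "none")
        log_amp = inf.enumerate_candidates("amplitude_short", "absolute")[0]
        assert (log_amp.family, log_amp.transform) == ("gaussian", "log")
        sqrt_amp = inf.enumerate_candidates("amplitude_long", "centred")[0]
        assert sqrt_amp.transform == "sqrt"


class TestAicc:
    def test_published_row_short_amplitude(self):
        assert inf.aicc(-567.47, 4, 633) == pytest.approx(1143.00, abs=0.005)

    def test_published_row_timescale(self):
        # printed as 1084.80 from the unrounded log-likelihood
        assert inf.aicc(-536.35, 6, 787) == pytest.approx(1084.81, abs=0.005)

    def test_closed_form(self):
        assert inf.aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            inf.aicc(0.0, 5, 6)

    def test_converges_to_aic_for_large_n(self):
        k, ll = 4, -100.0
        aic = -2 * ll + 2 * k
        assert abs(inf.aicc(ll, k, 200_000) - aic) < 1e-3


class TestWeights:
    def test_published_delta_column_reproduces_weights(self):
        deltas = [0.00, 0.52, 0.90, 0.98, 1.78, 2.26, 2.68, 2.76]
        _, w = inf.delta_and_weights(deltas)
        assert np.round(w, 2).tolist() == [0.23, 0.18, 0.15, 0.14, 0.10, 0.08, 0.06, 0.06]

    def test_single_model(self):
        d, w = inf.delta_and_weights([123.4])
        assert d.tolist() == [0.0] and w.tolist() == [1.0]

    def test_equal_aicc_splits_evenly(self):
        _, w = inf.delta_and_weights([10.0, 10.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_weights_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(100, 120, size=7)
        d1, w1 = inf.delta_and_weights(a)
        d2, w2 = inf.delta_and_weights(a + 55.5)  # constant loglik shift
        assert w1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(d1, d2) and np.allclose(w1, w2)


def _binary_data(rng, n=400, sigma2=0.0, beta_pop=0.0, beta_sex=0.0, intercept=0.0,
                 n_years=20):
    pop = rng.integers(0, 2, n)
    sex = rng.integers(0, 2, n)
    years = rng.integers(1990, 1990 + n_years, n)
    b = dict(zip(range(1990, 1990 + n_years),
                 rng.normal(0, np.sqrt(sigma2), n_years) if sigma2 > 0 else np.zeros(n_years)))
    eta = intercept + beta_pop * pop + beta_sex * sex + np.array([b[y] for y in years])
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame({
        "individual_id": [str(i) for i in range(n)],
        "population": np.where(pop == 1, "B", "A"),
        "sex": np.where(sex == 1, "male", "female"),
        "birth_year": years,
        "mean_individual_clutch": rng.normal(8, 1, n),
        "dominant_scale_binary": y,
        "amplitude_short": np.exp(rng.normal(0, 0.5, n)),
        "amplitude_long": np.exp(rng.normal(0.5, 0.5, n)),
    })


class TestFitModel:
    def test_balanced_binary_intercept_near_zero(self):
        rng = np.random.default_rng(0)
        data = _binary_data(rng, n=100)
        data["dominant_scale_binary"] = [0, 1] * 50
        # perfectly balanced within every birth year: zero between-year variance
        data["birth_year"] = np.repeat(np.arange(1990, 2000), 10)
        fit = inf.fit_model(inf.CandidateModel.make("timescale_binary", "absolute", ()), data)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-3)
        assert fit.random_intercept_variance < 1e-3
        assert fit.k_params == 2

    def test_zero_variance_logistic_matches_plain_logit(self):
        rng = np.random.default_rng(1)
        data = _binary_data(rng, n=500, beta_pop=0.8, intercept=-0.2)
        model = inf.CandidateModel.make("timescale_binary", "absolute", ("population",))
        fit = inf.fit_model(model, data, reference_levels={"population": "A"})
        X = np.column_stack([np.ones(len(data)), (data["population"] == "B").astype(float)])
        ref = sm.Logit(data["dominant_scale_binary"].to_numpy(), X).fit(disp=False)
        assert fit.random_intercept_variance < 1e-3
        assert fit.coefficients["intercept"] == pytest.approx(ref.params[0], abs=1e-3)
        assert fit.coefficients["population[B]"] == pytest.approx(ref.params[1], abs=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_marginal_likelihood_matches_quadrature_oracle(self):
        # tiny dataset: brute-force numerical integration of the random
        # intercept vs the Gauss-Hermite marginal log-likelihood
        rng = np.random.default_rng(2)
        n, G = 15, 3
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        groups = np.repeat(np.arange(G), 5)
        y = (rng.random(n) < 0.5).astype(float)
        beta, sigma = np.array([0.3, -0.7]), 0.6

        def oracle():
            tot = 0.0
            for j in range(G):
                idx = groups == j

                def integrand(u):
                    p = expit(X[idx] @ beta + u)
                    lik = np.prod(p ** y[idx] * (1 - p) ** (1 - y[idx]))
                    return lik * np.exp(-u * u / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))

                val, _ = quad(integrand, -8 * sigma, 8 * sigma, limit=200)
                tot += np.log(val)
            return tot

        nodes, wts = np.polynomial.hermite.hermgauss(25)
        from scipy.special import logsumexp
        log_w = np.log(wts) - 0.5 * np.log(np.pi)
        lp = (X @ beta)[:, None] + (np.sqrt(2) * sigma * nodes)[None, :]
        ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
        gll = np.zeros((G, 25))
        np.add.at(gll, groups, ll_obs)
        gh = float(np.sum(logsumexp(gll + log_w[None, :], axis=1)))
        assert gh == pytest.approx(oracle(), abs=1e-8)

    def test_logistic_parameter_recovery(self):
        rng = np.random.default_rng(7)
        data = _binary_data(rng, n=2000, sigma2=0.1, beta_pop=1.0, beta_sex=-0.5,
                            intercept=-0.3)
        model = inf.CandidateModel.make("timescale_binary", "absolute",
                                        ("population", "sex"))
        fit = inf.fit_model(model, data, reference_levels={"population": "A"})
        se = np.sqrt(np.diag(fit.cov))
        names = fit.coef_names
        for name, truth in [("intercept", -0.3), ("population[B]", 1.0),
                            ("sex[male]", -0.5)]:
            i = names.index(name)
            assert abs(fit.coefficients[name] - truth) < 3 * se[i]

    def test_gaussian_zero_group_variance_matches_ols(self):
        rng = np.random.default_rng(4)
        data = _binary_data(rng, n=300)
        model = inf.CandidateModel.make("amplitude_long", "absolute",
                                        ("mean_individual_clutch",))
        fit = inf.fit_model(model, data)
        y = np.log(data["amplitude_long"].to_numpy())
        X = np.column_stack([np.ones(len(data)), data["mean_individual_clutch"]])
        ols = sm.OLS(y, X).fit()
        assert fit.random_intercept_variance < 1e-3
        assert fit.coefficients["intercept"] == pytest.approx(ols.params[0], abs=1e-3)
        assert fit.k_params == 4  # intercept + slope + RE var + residual var

    def test_gaussian_recovers_group_variance(self):
        rng = np.random.default_rng(5)
        n, n_years = 2000, 25
        years = rng.integers(0, n_years, n)
        b = rng.normal(0, 0.5, n_years)
        y = np.exp(1.0 + b[years] + rng.normal(0, 0.4, n))
        data = pd.DataFrame({
            "birth_year": years, "amplitude_long": y,
            "mean_individual_clutch": np.zeros(n),
            "population": "A", "sex": "female",
            "dominant_scale_binary": 0, "amplitude_short": 1.0,
            "individual_id": [str(i) for i in range(n)],
        })
        fit = inf.fit_model(inf.CandidateModel.make("amplitude_long", "absolute", ()), data)
        assert fit.random_intercept_variance == pytest.approx(0.25, rel=0.5)
        assert fit.residual_variance == pytest.approx(0.16, rel=0.2)

    def test_log_transform_rejects_zero_amplitudes(self):
        rng = np.random.default_rng(6)
        data = _binary_data(rng, n=50)
        data.loc[3, "amplitude_short"] = 0.0
        with pytest.raises(inf.ZeroAmplitudeError):
            inf.fit_model(inf.CandidateModel.make("amplitude_short", "absolute", ()), data)


class TestSelectionAndAveraging:
    def _fits(self, logliks, k=2, n=500, coefs=None):
        out = []
        for i, ll in enumerate(logliks):
            c = {"intercept": (coefs[i] if coefs else 0.0)}
            out.append(inf.ModelFit(
                model=inf.CandidateModel.make("timescale_binary", "absolute", ()),
                coef_names=["intercept"], coefficients=c, cov=np.eye(1),
                loglik=ll, k_params=k, n_obs=n, random_intercept_variance=0.0,
                residual_variance=None, converged=True))
        return out

    def test_retained_set_contains_best_and_weights_renormalise(self):
        fits = self._fits([-100.0, -100.5, -103.0])
        table = inf.select_models(fits)
        assert table.retained_indices[0] == 0
        assert len(table.retained_indices) == 2
        assert table.weight.sum() == pytest.approx(1.0, abs=1e-9)
        _, retained = inf.average_within_delta(table)
        assert len(retained) == 2

    def test_averaging_is_convex(self):
        fits = self._fits([-100.0, -100.2], coefs=[0.4, 0.4])
        table = inf.select_models(fits)
        avg, _ = inf.average_within_delta(table)
        assert avg["intercept"] == pytest.approx(0.4, abs=1e-12)

    def test_single_candidate_averages_to_itself(self):
        fits = self._fits([-50.0], coefs=[1.23])
        table = inf.select_models(fits)
        avg, retained = inf.average_within_delta(table)
        assert avg["intercept"] == 1.23 and len(retained) == 1

    def test_conditional_vs_full_averaging(self):
        m1 = inf.ModelFit(
            model=inf.CandidateModel.make("timescale_binary", "absolute", ("sex",)),
            coef_names=["intercept", "sex[male]"],
            coefficients={"intercept": 0.0, "sex[male]": 1.0}, cov=np.eye(2),
            loglik=-99.5, k_params=3, n_obs=500, random_intercept_variance=0.0,
            residual_variance=None, converged=True)
        m2 = inf.ModelFit(
            model=inf.CandidateModel.make("timescale_binary", "absolute", ()),
            coef_names=["intercept"], coefficients={"intercept": 0.0}, cov=np.eye(1),
            loglik=-100.0, k_params=2, n_obs=500, random_intercept_variance=0.0,
            residual_variance=None, converged=True)
        table = inf.select_models([m1, m2])
        cond, _ = inf.average_within_delta(table, method="conditional")
        full, _ = inf.average_within_delta(table, method="full")
        assert cond["sex[male]"] == pytest.approx(1.0)
        assert 0.0 < full["sex[male]"] < 1.0  # shrunk toward zero


class TestMarginalMeans:
    def test_intercept_only_logistic_gives_half(self):
        data = _binary_data(np.random.default_rng(0), n=40)
        fit = inf.ModelFit(
            model=inf.CandidateModel.make("timescale_binary", "absolute", ()),
            coef_names=["intercept"], coefficients={"intercept": 0.0},
            cov=np.array([[0.04]]), loglik=-1.0, k_params=2, n_obs=40,
            random_intercept_variance=0.0, residual_variance=None, converged=True)
        emm = inf.marginal_means(fit, data, "population")
        assert emm["estimate"].iloc[0] == pytest.approx(0.5)
        assert emm["se"].iloc[0] == pytest.approx(0.25 * 0.2)  # p(1-p) * se_eta
        assert "grand mean" in emm["factor_level"].iloc[0]

    def test_log_scale_back_transform(self):
        data = _binary_data(np.random.default_rng(0), n=40)
        fit = inf.ModelFit(
            model=inf.CandidateModel.make("amplitude_long", "absolute", ("population",)),
            coef_names=["intercept", "population[B]"],
            coefficients={"intercept": 0.0, "population[B]": 0.7},
            cov=np.zeros((2, 2)), loglik=-1.0, k_params=4, n_obs=40,
            random_intercept_variance=0.0, residual_variance=0.1, converged=True,
            factor_levels={"population": ["A", "B"]})
        emm = inf.marginal_means(fit, data, "population")
        by_level = dict(zip(emm["factor_level"], emm["estimate"]))
        assert by_level["A"] == pytest.approx(1.0)  # exp(0)
        assert by_level["B"] == pytest.approx(np.exp(0.7))
        assert set(emm["scale_note"]) == {"exp"}

    def test_balanced_two_factor_closed_form(self):
        data = _binary_data(np.random.default_rng(0), n=40)
        beta = {"intercept": -0.2, "population[B]": 0.8, "sex[male]": -0.4}
        fit = inf.ModelFit(
            model=inf.CandidateModel.make("timescale_binary", "absolute",
                                          ("population", "sex")),
            coef_names=list(beta), coefficients=beta, cov=np.zeros((3, 3)),
            loglik=-1.0, k_params=5, n_obs=40, random_intercept_variance=0.0,
            residual_variance=None, converged=True,
            factor_levels={"population": ["A", "B"], "sex": ["female", "male"]})
        emm = inf.marginal_means(fit, data, "population")
        by_level = dict(zip(emm["factor_level"], emm["estimate"]))
        # sex averaged with equal weight on the link scale
        assert by_level["A"] == pytest.approx(float(expit(-0.2 - 0.2)))
        assert by_level["B"] == pytest.approx(float(expit(-0.2 + 0.8 - 0.2)))


class TestReferenceTables:
    def test_every_block_has_eight_models_and_unit_weight(self):
        for block in REFERENCE_BLOCKS:
            assert len(block.rows) == 8
            assert sum(r.weight for r in block.rows) == pytest.approx(1.0, abs=0.02)

    def test_delta_two_rule_on_timescale_absolute_block(self):
        block = REFERENCE_BLOCKS[0]
        retained = [r for r in block.rows if r.delta < 2.0]
        assert len(retained) == 5
        assert max(r.delta for r in retained) == 1.78
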