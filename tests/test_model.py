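"""Inference-engine tests: Pólya-Gamma sampler, non-spatial fits vs grid
oracles, OR summaries, WAIC/DIC, interaction tests and forward selection."""

import numpy as np
import pandas as pd
import pytest

from geostunt import model
from geostunt.model import (
    CategoricalTerm,
    McmcConfig,
    ModelSpec,
    NumericTerm,
    PriorSpec,
    sample_polya_gamma,
)


class TestPolyaGamma:
    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(0)
        b = np.full(20_000, 3.0)
        for c in (0.0, 0.7, 2.5):
            cs = np.full_like(b, c)
            draws = sample_polya_gamma(rng, b, cs)
            expected = 3.0 / 4.0 if c == 0 else 3.0 / (2 * c) * np.tanh(c / 2)
            assert np.mean(draws) == pytest.approx(expected, rel=0.02)

    def test_variance_matches_closed_form(self):
        # Var PG(1, 0) = 1/24
        rng = np.random.default_rng(1)
        draws = sample_polya_gamma(rng, np.ones(200_000), np.zeros(200_000))
        assert np.var(draws) == pytest.approx(1 / 24, rel=0.05)

    def test_positive(self):
        rng = np.random.default_rng(2)
        draws = sample_polya_gamma(
            rng, np.full(1000, 5.0), np.linspace(-3, 3, 1000)
        )
        assert np.all(draws > 0)


class TestNonSpatialFit:
    def test_intercept_only_matches_grid_posterior(self):
        # 10 clusters, each 5/10 stunted; oracle: 1-D grid integration
        df = pd.DataFrame({"y": [5] * 10, "n": [10] * 10})
        spec = ModelSpec()
        fit = model.fit_nonspatial(
            spec, df, method="gibbs", seed=3,
            mcmc=McmcConfig(n_chains=2, n_draws=3000, n_warmup=500),
        )
        from scipy.special import expit

        med = np.median(expit(fit.beta_draws[:, 0]))
        assert 0.45 <= med <= 0.55
        # grid oracle for the posterior median of beta0
        grid = np.linspace(-2, 2, 4001)
        lp = 50 * grid - 100 * np.logaddexp(0, grid) - 0.5 * 1e-6 * grid**2
        post = np.exp(lp - lp.max())
        post /= post.sum()
        cdf = np.cumsum(post)
        grid_med = grid[np.searchsorted(cdf, 0.5)]
        assert np.median(fit.beta_draws[:, 0]) == pytest.approx(grid_med, abs=0.05)

    def test_laplace_close_to_gibbs(self):
        df = pd.DataFrame(
            {"y": [12, 5, 20, 3], "n": [30, 25, 40, 20], "g": ["a", "b", "a", "b"]}
        )
        spec = ModelSpec(covariates=[CategoricalTerm("g", ("a", "b"))])
        fg = model.fit_nonspatial(
            spec, df, method="gibbs", seed=1,
            mcmc=McmcConfig(n_chains=2, n_draws=3000, n_warmup=500),
        )
        fl = model.fit_nonspatial(spec, df, method="laplace", seed=1)
        for j in range(2):
            assert np.median(fl.beta_draws[:, j]) == pytest.approx(
                np.median(fg.beta_draws[:, j]), abs=0.08
            )

    def test_spike_prior_collapses_or_to_one(self):
        df = pd.DataFrame(
            {"y": [12, 5], "n": [30, 25], "g": ["a", "b"]}
        )
        spec = ModelSpec(covariates=[CategoricalTerm("g", ("a", "b"))])
        priors = PriorSpec(coef_precision=1e8)
        fit = model.fit_nonspatial(spec, df, priors=priors, method="laplace", seed=0)
        table = model.summarize_or(fit)
        assert table["or"].iloc[0] == pytest.approx(1.0, abs=0.01)
        assert table["hi95"].iloc[0] - table["lo95"].iloc[0] < 0.01

    def test_recovers_known_odds_ratio_at_scale(self, region):
        # simulate one binary covariate with beta = log 2 at ~5000 children
        from geostunt import synthetic as syn
        from geostunt.spde import MaternParams

        cfg = syn.SimulationConfig(
            n_clusters=350, seed=8, intercept=-1.0,
            covariates=(
                syn.CovariateSpec(
                    "expo", ("no", "yes"), (0.5, 0.5), {"yes": np.log(2.0)}
                ),
            ),
            matern=MaternParams(0.05, 0.0),
        )
        records, truth = syn.simulate_survey(region, cfg, geomask=False)
        assert sum(r.n_children for r in records) > 4000
        spec = ModelSpec(covariates=[CategoricalTerm("expo", ("no", "yes"))])
        fit = model.fit_nonspatial(spec, records, method="laplace", seed=1)
        or_med = model.summarize_or(fit).set_index("term").loc["expo=yes", "or"]
        assert 1.8 <= or_med <= 2.2

    def test_rank_deficiency_warns_not_crashes(self):
        df = pd.DataFrame(
            {"y": [5, 6], "n": [10, 10], "a": ["x", "y"], "b": ["x", "y"]}
        )
        spec = ModelSpec(
            covariates=[CategoricalTerm("a", ("x", "y")), CategoricalTerm("b", ("x", "y"))]
        )
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = model.fit_nonspatial(spec, df, method="laplace", seed=0)
        assert np.all(np.isfinite(fit.beta_draws))


class TestSummarizeOr:
    def test_constant_draws(self):
        fit = model.FitResult(
            method="laplace", beta_names=["intercept", "g=b"],
            beta_draws=np.column_stack(
                [np.zeros(100), np.full(100, np.log(2.0))]
            ),
        )
        table = model.summarize_or(fit)
        assert len(table) == 1  # reference level & intercept absent
        assert table["or"].iloc[0] == pytest.approx(2.0)
        assert table["lo95"].iloc[0] == pytest.approx(2.0)

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(0.3, 0.4, size=(2000, 2))
        fit = model.FitResult(
            method="laplace", beta_names=["intercept", "z"], beta_draws=draws
        )
        table = model.summarize_or(fit)
        ors = np.sort(np.exp(draws[:, 1]))
        lo_oracle = ors[int(np.ceil(0.025 * 2000)) - 1 : int(np.ceil(0.025 * 2000)) + 1].mean()
        assert table["lo95"].iloc[0] == pytest.approx(lo_oracle, rel=0.01)
        assert table["or"].iloc[0] == pytest.approx(
            np.median(np.exp(draws[:, 1])), rel=1e-9
        )


class TestInformationCriteria:
    def test_hand_computed_two_draw_example(self):
        # 2 draws, 2 observations: expand both formulas by hand
        y = np.array([3.0, 7.0])
        n = np.array([10.0, 10.0])
        x = np.ones((2, 1))
        beta = np.array([[-0.2], [0.4]])
        from geostunt.model import _binom_loglik_pointwise

        fit = model.FitResult(
            method="laplace", beta_names=["intercept"], beta_draws=beta,
            _y=y, _n=n, _x=x,
        )
        fit.loglik_pointwise = _binom_loglik_pointwise(
            y[None, :], n[None, :], beta @ x.T
        )
        ll = fit.loglik_pointwise
        dbar = np.mean(-2 * ll.sum(axis=1))
        psi_mean = (beta @ x.T).mean(axis=0)
        dhat = -2 * _binom_loglik_pointwise(y, n, psi_mean).sum()
        expected_dic = dbar + (dbar - dhat)
        assert model.compute_dic(fit) == pytest.approx(expected_dic, rel=1e-12)
        lppd = np.sum(np.log(np.mean(np.exp(ll), axis=0)))
        p_waic = np.sum(np.var(ll, axis=0, ddof=1))
        assert model.compute_waic(fit) == pytest.approx(
            -2 * (lppd - p_waic), rel=1e-12
        )

    def test_degenerate_posterior_point_mass(self):
        y = np.array([4.0])
        n = np.array([9.0])
        x = np.ones((1, 1))
        beta = np.full((50, 1), 0.25)
        from geostunt.model import _binom_loglik_pointwise

        fit = model.FitResult(
            method="laplace", beta_names=["intercept"], beta_draws=beta,
            _y=y, _n=n, _x=x,
        )
        fit.loglik_pointwise = _binom_loglik_pointwise(
            y[None, :], n[None, :], beta @ x.T
        )
        ll_point = _binom_loglik_pointwise(y, n, np.array([0.25])).sum()
        assert model.compute_dic(fit) == pytest.approx(-2 * ll_point, abs=1e-9)
        assert model.compute_waic(fit) == pytest.approx(-2 * ll_point, abs=1e-9)

    def test_too_few_draws_rejected(self):
        fit = model.FitResult(
            method="laplace", beta_names=["intercept"],
            beta_draws=np.zeros((1, 1)),
        )
        fit.loglik_pointwise = np.zeros((1, 3))
        with pytest.raises(ValueError):
            model.compute_waic(fit)


class TestInteractionTest:
    def _rows(self, seed, beta_young, beta_old, n_per=1250):
        rng = np.random.default_rng(seed)
        rows = []
        for g, b in [("0-23", beta_young), ("24-59", beta_old)]:
            for lvl, eff in [("a", 0.0), ("b", b)]:
                p = 1 / (1 + np.exp(-(-0.6 + eff)))
                rows.append(
                    {"y": rng.binomial(n_per, p), "n": n_per,
                     "age_group": g, "f": lvl}
                )
        return pd.DataFrame(rows)

    def test_pvalue_in_unit_interval_and_detects_difference(self):
        df = self._rows(0, beta_young=np.log(1.2), beta_old=np.log(3.0), n_per=4000)
        p = model.interaction_test(df, [CategoricalTerm("f", ("a", "b"))], "age_group")
        assert 0 <= p["f"] < 0.01

    def test_no_interaction_large_p_typical(self):
        df = self._rows(1, beta_young=0.5, beta_old=0.5, n_per=4000)
        p = model.interaction_test(df, [CategoricalTerm("f", ("a", "b"))], "age_group")
        assert p["f"] > 0.01

    def test_single_level_covariate_degenerate(self):
        df = self._rows(2, 0.3, 0.3)
        df["f"] = "only"
        with pytest.raises(ValueError, match="single level"):
            model.interaction_test(
                df, [CategoricalTerm("f", ("only",))], "age_group"
            )

    def test_level_missing_in_one_group_rejected(self):
        df = self._rows(3, 0.3, 0.3)
        df = df[~((df["age_group"] == "0-23") & (df["f"] == "b"))]
        with pytest.raises(ValueError, match="absent in one group"):
            model.interaction_test(
                df, [CategoricalTerm("f", ("a", "b"))], "age_group"
            )

    def test_nonbinary_group_rejected(self):
        df = self._rows(4, 0.3, 0.3)
        df.loc[0, "age_group"] = "60+"
        with pytest.raises(ValueError, match="binary"):
            model.interaction_test(
                df, [CategoricalTerm("f", ("a", "b"))], "age_group"
            )


class TestForwardSelect:
    def _data(self, seed, beta_true=0.8, n_clusters=150):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n_clusters):
            t = rng.choice(["lo", "hi"])
            noise1 = rng.choice(["u", "v"])
            noise2 = rng.choice(["p", "q"])
            p = 1 / (1 + np.exp(-(-0.5 + (beta_true if t == "hi" else 0.0))))
            n = 20
            rows.append(
                {"y": rng.binomial(n, p), "n": n, "t": t,
                 "noise1": noise1, "noise2": noise2}
            )
        return pd.DataFrame(rows)

    CANDIDATES = [
        CategoricalTerm("t", ("lo", "hi")),
        CategoricalTerm("noise1", ("u", "v")),
        CategoricalTerm("noise2", ("p", "q")),
    ]

    def test_true_covariate_selected_first(self):
        hits = 0
        for seed in range(10):
            df = self._data(seed)
            spec, trace = model.forward_select(self.CANDIDATES, df, seed=seed)
            if spec.covariates and spec.covariates[0].name == "t":
                hits += 1
        assert hits >= 8

    def test_no_improvement_keeps_intercept_only(self):
        df = self._data(0, beta_true=0.0)
        spec, trace = model.forward_select(
            [self.CANDIDATES[1], self.CANDIDATES[2]], df, seed=0
        )
        assert spec.covariates == []

    def test_trace_bounded(self):
        df = self._data(1)
        spec, trace = model.forward_select(self.CANDIDATES, df, seed=1)
        assert len(trace) <= len(self.CANDIDATES) + 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            model.forward_select([], self._data(0))
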