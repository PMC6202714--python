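"""Posterior metrics: per-level R², pooling factors, DIC, change tables."""

import warnings

import numpy as np
import pytest

from eivpool import (
    McmcConfig,
    SimParams,
    bayesian_r2,
    compare_models,
    dic,
    fit_model,
    habitat_contrasts,
    metrics_row,
    pooling_factor,
    simulate_survey,
    summarize_changes,
)

from conftest import fake_fit, make_frame


def small_posterior(rng, n_draws, n_plots, hier=False, n_hab=1):
    post = {
        "alpha": rng.standard_normal((1, n_draws, n_plots)),
        "beta": rng.standard_normal((1, n_draws, n_plots)),
        "sigma_species": np.abs(rng.standard_normal((1, n_draws))) + 0.5,
    }
    if hier:
        post["mu_alpha"] = rng.standard_normal((1, n_draws, n_hab))
        post["mu_beta"] = rng.standard_normal((1, n_draws, n_hab))
        post["sigma_alpha"] = np.abs(rng.standard_normal((1, n_draws))) + 0.5
        post["sigma_beta"] = np.abs(rng.standard_normal((1, n_draws))) + 0.5
        post["rho"] = np.zeros((1, n_draws))
    return post


class TestBayesianR2:
    def test_perfect_fit_gives_one(self):
        frame = make_frame([1.0, 2.0, 3.0], ["a", "b", "c"], [1, 1, 1])
        post = {
            "alpha": np.array([[[1.0, 2.0, 3.0]]]),
            "beta": np.zeros((1, 1, 3)),
            "sigma_species": np.ones((1, 1)),
        }
        fit = fake_fit(post, frame, "none")
        assert bayesian_r2(fit, "data").mean == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        # independent direct evaluation of 1 - V(eps)/V(values), per draw
        rng = np.random.default_rng(5)
        frame = make_frame(
            rng.normal(5, 1, 12),
            [f"p{i}" for i in range(6) for _ in (0, 1)],
            [1, 2] * 6,
            habitat=["h1", "h1", "h1", "h1", "h2", "h2", "h2", "h2", "h3", "h3", "h3", "h3"],
        )
        post = small_posterior(rng, n_draws=5, n_plots=6, hier=True, n_hab=3)
        fit = fake_fit(post, frame, "habitat")

        y, x, j = frame.y, frame.x, frame.j
        for level in ("data", "intercepts", "slopes"):
            got = bayesian_r2(fit, level).mean
            per_draw = []
            for s in range(5):
                if level == "data":
                    eps = y - (post["alpha"][0, s][j] + post["beta"][0, s][j] * x)
                    vals = y
                else:
                    name = "alpha" if level == "intercepts" else "beta"
                    mu = post["mu_" + name][0, s][fit.k_of_plot_]
                    vals = post[name][0, s]
                    eps = vals - mu
                per_draw.append(1 - np.var(eps, ddof=1) / np.var(vals, ddof=1))
            assert got == pytest.approx(np.mean(per_draw), abs=1e-12)

    def test_global_pooling_level2_is_zero(self, m2_fit):
        # a constant shift leaves the variance unchanged, so level-2
        # explained variance is structurally zero under global pooling
        assert abs(bayesian_r2(m2_fit, "intercepts").mean) < 1e-12
        assert abs(bayesian_r2(m2_fit, "slopes").mean) < 1e-12

    def test_translation_invariance_of_data_level(self):
        rng = np.random.default_rng(6)
        frame = make_frame(rng.normal(5, 1, 8), [f"p{i // 2}" for i in range(8)],
                           [1, 2] * 4)
        post = small_posterior(rng, 4, 4)
        r2_a = bayesian_r2(fake_fit(post, frame, "none"), "data").mean
        shifted = make_frame(frame.y + 7.0, frame.df["plot"], frame.df["period"])
        post2 = {**post, "alpha": post["alpha"] + 7.0}
        r2_b = bayesian_r2(fake_fit(post2, shifted, "none"), "data").mean
        assert r2_a == pytest.approx(r2_b, abs=1e-12)

    def test_level2_rejected_for_no_pooling(self, m1_fit):
        with pytest.raises(ValueError, match="no-pooling"):
            bayesian_r2(m1_fit, "intercepts")


class TestPoolingFactor:
    def test_complete_pooling_limit(self, quick_mcmc):
        params = SimParams(
            n_habitats=1,
            plots_per_habitat=12,
            species_per_cell=40,
            mu_alpha=(5.0,),
            mu_beta=(0.0,),
            sigma_alpha=0.0,
            sigma_beta=0.0,
            seed=12,
        )
        frame, _ = simulate_survey(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(frame, "M2", mcmc=quick_mcmc)
        assert pooling_factor(fit, "intercepts").value > 0.8

    def test_no_pooling_limit(self):
        params = SimParams(
            n_habitats=1,
            plots_per_habitat=12,
            species_per_cell=200,
            mu_alpha=(5.0,),
            mu_beta=(0.0,),
            sigma_alpha=5.0,
            sigma_beta=0.2,
            seed=13,
        )
        frame, _ = simulate_survey(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(
                frame, "M2", mcmc=McmcConfig(chains=2, warmup=500, draws=600, seed=4)
            )
        assert pooling_factor(fit, "intercepts").value < 0.1

    def test_rejected_for_no_pooling_model(self, m1_fit):
        with pytest.raises(ValueError, match="no-pooling"):
            pooling_factor(m1_fit, "intercepts")

    def test_reported_components_reconstruct_lambda(self, m2_fit):
        pf = pooling_factor(m2_fit, "slopes")
        assert pf.value == pytest.approx(
            1.0 - pf.var_of_mean_errors / pf.mean_var_of_errors, abs=1e-12
        )


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        frame = make_frame([4.0, 5.0, 6.0, 7.0], ["p1", "p1", "p2", "p2"], [1, 2, 1, 2])
        post = {
            "alpha": np.tile([4.0, 6.0], (2, 3, 1)),
            "beta": np.tile([1.0, 1.0], (2, 3, 1)),
            "sigma_species": np.full((2, 3), 1.3),
        }
        fit = fake_fit(post, frame, "none")
        res = dic(fit)
        assert res.pd == pytest.approx(0.0, abs=1e-10)
        assert res.dic == pytest.approx(res.d_at_mean, abs=1e-10)

    def test_brute_force_oracle(self, m1_fit):
        res = dic(m1_fit)
        frame = m1_fit.frame_
        y, x, j = frame.y, frame.x, frame.j
        alpha, beta = m1_fit.flat("alpha"), m1_fit.flat("beta")
        sigma = m1_fit.flat("sigma_species")
        devs = np.array(
            [
                -2.0
                * np.sum(
                    -0.5 * np.log(2 * np.pi)
                    - np.log(sigma[s])
                    - 0.5 * ((y - alpha[s][j] - beta[s][j] * x) / sigma[s]) ** 2
                )
                for s in range(0, len(sigma), 7)
            ]
        )
        got = m1_fit.deviance_draws()[::7]
        assert np.allclose(devs, got, atol=1e-8)
        mu = m1_fit.alpha_[j] + m1_fit.beta_[j] * x
        d_hat = -2.0 * np.sum(
            -0.5 * np.log(2 * np.pi)
            - np.log(m1_fit.sigma_species_)
            - 0.5 * ((y - mu) / m1_fit.sigma_species_) ** 2
        )
        assert res.d_at_mean == pytest.approx(d_hat, abs=1e-8)

    def test_comparison_table(self, m1_fit, m2_fit, m3_fit):
        table = compare_models([m1_fit, m2_fit, m3_fit])
        assert list(table["model"]) == ["M1", "M2", "M3"]
        assert table["dDIC"].min() == 0.0
        assert np.allclose(table["DIC"], table["Dbar"] + table["pD"])


class TestChangeSummaries:
    def test_interval_nesting(self, m3_fit):
        for level in ("plot", "habitat"):
            tab = summarize_changes(m3_fit, level)
            assert ((tab["hi50"] - tab["lo50"]) < (tab["hi95"] - tab["lo95"])).all()
            assert (tab["lo50"] >= tab["lo95"]).all()
            assert (tab["hi50"] <= tab["hi95"]).all()

    def test_exclude_zero_flags_consistent(self, m3_fit):
        tab = summarize_changes(m3_fit, "plot")
        expect = (tab["lo95"] > 0) | (tab["hi95"] < 0)
        assert (tab["excl0_95"] == expect).all()

    def test_habitat_level_requires_habitat_model(self, m2_fit):
        with pytest.raises(ValueError, match="habitat"):
            summarize_changes(m2_fit, "habitat")

    def test_contrast_linearity(self, m3_fit):
        tab = summarize_changes(m3_fit, "habitat").set_index("unit")
        con = habitat_contrasts(m3_fit)
        for _, row in con.iterrows():
            expect = tab.loc[row["habitat_a"], "mean"] - tab.loc[row["habitat_b"], "mean"]
            assert row["mean"] == pytest.approx(expect, abs=1e-10)


def test_metrics_row_schema(m3_fit, m1_fit):
    row = metrics_row(m3_fit)
    assert row["model"] == "M3"
    for key in ("sigma_species", "sigma_alpha", "sigma_beta", "r2_data", "r2_alpha",
                "r2_beta", "lambda_alpha", "lambda_beta", "pD", "DIC"):
        assert np.isfinite(row[key])
    row1 = metrics_row(m1_fit)
    assert np.isnan(row1["sigma_alpha"]) and np.isnan(row1["lambda_beta"])
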