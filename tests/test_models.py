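"""Sampler correctness: closed-form oracles, shrinkage, diagnostics."""

import warnings

import numpy as np
import pytest
from scipy import stats

from eivpool import (
    McmcConfig,
    PriorConfig,
    SimParams,
    check_convergence,
    fit_model,
    plot_raw_means,
    simulate_survey,
)

from conftest import fake_fit, make_frame


def raw_alpha_beta(frame):
    """Per-plot period-1 mean and between-period difference (the
    no-pooling least-squares solution)."""
    raw = plot_raw_means(frame).pivot(index="plot", columns="period", values="mean")
    a = raw[1].loc[frame.plot_ids].to_numpy()
    b = (raw[2] - raw[1]).loc[frame.plot_ids].to_numpy()
    return a, b


class TestNoPooling:
    def test_matches_per_plot_least_squares(self, survey20, m1_fit):
        frame, _ = survey20
        a, b = raw_alpha_beta(frame)
        assert np.abs(m1_fit.alpha_ - a).max() < 0.05
        assert np.abs(m1_fit.beta_ - b).max() < 0.05

    def test_single_period_plot_warns(self):
        frame = make_frame(
            [4, 5, 3, 6, 5, 4], ["p1", "p1", "p1", "p1", "p2", "p2"],
            [1, 1, 2, 2, 1, 1],
        )
        with pytest.warns(UserWarning, match="only one period"):
            fit_model(frame, "M1", mcmc=McmcConfig(chains=2, warmup=100, draws=100, seed=0))


class TestPartialPooling:
    def test_shrinkage_toward_global_mean(self, quick_mcmc):
        # identical true (alpha, beta) across plots: pooling should
        # compress the posterior means relative to the raw plot means
        params = SimParams(
            n_habitats=1,
            plots_per_habitat=15,
            species_per_cell=20,
            mu_alpha=(5.0,),
            mu_beta=(0.2,),
            sigma_alpha=0.0,
            sigma_beta=0.0,
            seed=9,
        )
        frame, _ = simulate_survey(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(frame, "M2", mcmc=quick_mcmc)
        a_raw, _ = raw_alpha_beta(frame)
        assert np.var(fit.alpha_) < np.var(a_raw)
        # every estimate sits between its raw mean and the population mean
        mu = float(fit.mu_alpha_[0])
        lo = np.minimum(a_raw, mu) - 0.05
        hi = np.maximum(a_raw, mu) + 0.05
        assert np.all((fit.alpha_ >= lo) & (fit.alpha_ <= hi))

    def test_reduces_to_no_pooling_when_dispersed(self):
        params = SimParams(
            n_habitats=1,
            plots_per_habitat=12,
            species_per_cell=30,
            mu_alpha=(5.0,),
            mu_beta=(0.0,),
            sigma_alpha=5.0,
            sigma_beta=5.0,
            seed=10,
        )
        frame, _ = simulate_survey(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(
                frame, "M2", mcmc=McmcConfig(chains=2, warmup=500, draws=600, seed=3)
            )
        a_raw, _ = raw_alpha_beta(frame)
        assert np.abs(fit.alpha_ - a_raw).max() < 0.1

    def test_prior_sd_insensitivity(self, quick_mcmc):
        params = SimParams(
            n_habitats=1,
            plots_per_habitat=30,
            species_per_cell=25,
            mu_alpha=(5.0,),
            mu_beta=(0.3,),
            seed=11,
        )
        frame, _ = simulate_survey(params)
        mus = []
        for sd in (100.0, 200.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_model(frame, "M2", PriorConfig(location_sd=sd), quick_mcmc)
            mus.append(float(fit.mu_beta_[0]))
        assert abs(mus[0] - mus[1]) < 0.02


class TestHabitatPooling:
    def test_single_habitat_rejected(self):
        frame = make_frame([1, 2, 3, 4], ["p1", "p1", "p2", "p2"], [1, 2, 1, 2])
        with pytest.raises(ValueError, match="habitat"):
            fit_model(frame, "M3", mcmc=McmcConfig(chains=2, warmup=10, draws=10, seed=0))

    def test_recovers_habitat_means(self, survey20, m3_fit):
        _, truth = survey20
        k = np.array([int(h[-1]) for h in m3_fit.habitats_])
        # posterior habitat means should track the realized habitat means
        # of the plot slopes to within a few posterior sds
        realized = [truth.beta[np.array(truth.habitat_of_plot) == h].mean()
                    for h in m3_fit.habitats_]
        sds = m3_fit.flat("mu_beta").std(axis=0)
        assert np.all(np.abs(m3_fit.mu_beta_ - realized) < 4 * sds + 0.1)


def test_seed_determinism(survey20):
    frame, _ = survey20
    cfg = McmcConfig(chains=2, warmup=100, draws=100, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = fit_model(frame, "M3", mcmc=cfg)
        f2 = fit_model(frame, "M3", mcmc=cfg)
    for name in f1.posterior_:
        assert np.array_equal(f1.posterior_[name], f2.posterior_[name])


class TestConvergenceDiagnostics:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        draws = {"theta": rng.standard_normal((4, 1000))}
        report = check_convergence(draws, ess_threshold=400)
        row = report.table.iloc[0]
        assert abs(row["rhat"] - 1.0) < 0.01
        assert row["ess"] == pytest.approx(4000, rel=0.2)
        assert report.passed

    def test_shifted_chain_fails(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        report = check_convergence({"theta": chains})
        assert report.table.iloc[0]["rhat"] > 1.1
        assert not report.passed

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence({"theta": np.zeros((1, 100))})


class TestPointwiseLogDensity:
    def one_obs_fit(self):
        frame = make_frame([0.0, 1.0], ["p1", "p1"], [1, 2])
        post = {
            "alpha": np.zeros((1, 1, 1)),
            "beta": np.zeros((1, 1, 1)),
            "sigma_species": np.ones((1, 1)),
        }
        return fake_fit(post, frame, "none"), frame

    def test_standard_normal_at_zero(self):
        fit, _ = self.one_obs_fit()
        lpd = fit.pointwise_log_density()
        assert lpd[0, 0] == pytest.approx(-0.9189385332046727, abs=1e-12)

    def test_matches_scipy_norm(self, m1_fit):
        lpd = m1_fit.pointwise_log_density()
        frame = m1_fit.frame_
        s, i = 37, 113
        jj = frame.j[i]
        mu = m1_fit.flat("alpha")[s, jj] + m1_fit.flat("beta")[s, jj] * frame.x[i]
        expected = stats.norm.logpdf(frame.y[i], mu, m1_fit.flat("sigma_species")[s])
        assert lpd[s, i] == pytest.approx(expected, abs=1e-10)

    def test_row_sum_is_total_loglik(self, m1_fit):
        lpd = m1_fit.pointwise_log_density()
        dev = m1_fit.deviance_draws()
        assert np.allclose(-2.0 * lpd.sum(axis=1), dev, atol=1e-6)

    def test_mismatched_frame_rejected(self, m1_fit):
        other = make_frame([1.0, 2.0], ["q1", "q2"], [1, 1])
        with pytest.raises(ValueError, match="do not match"):
            m1_fit.pointwise_log_density(other)


def test_sklearn_param_interface(survey20):
    from eivpool import EIVChangeModel

    model = EIVChangeModel(pooling="M2", draws=50)
    params = model.get_params()
    assert params["pooling"] == "M2"
    model.set_params(draws=100)
    assert model.draws == 100
    clone_params = EIVChangeModel(**params)
    assert clone_params.draws == 50
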