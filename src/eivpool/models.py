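"""Hierarchical Bayesian change models for plot-level indicator values.

Three nested specifications of the same normal data level
``y_i ~ N(alpha_j[i] + beta_j[i] x_i, sigma_species)``:

* ``pooling="none"``    (M1) — every plot's intercept (period-1 mean) and
  slope (between-period change) is estimated independently, equivalent to
  a per-plot regression on the period indicator;
* ``pooling="global"``  (M2) — (alpha_j, beta_j) share a bivariate normal
  population distribution, so sparse plots are shrunk toward the overall
  mean in proportion to their information content;
* ``pooling="habitat"`` (M3) — the population means vary by habitat, so
  plots are shrunk toward their own habitat's mean and habitat-level
  change can be read off directly.

Priors are minimally informative: wide normals on location parameters,
uniform on standard deviations, uniform on the intercept/slope
correlation.  The posterior is simulated by the package's seeded Gibbs
sampler (see ``_gibbs``); results are reproducible given ``random_state``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import _gibbs
from .data import ModelFrame

#: model-id aliases used in outputs and the CLI.
POOLING_OF_MODEL_ID = {"M1": "none", "M2": "global", "M3": "habitat"}
MODEL_ID_OF_POOLING = {v: k for k, v in POOLING_OF_MODEL_ID.items()}

_SCALAR_PARAMS = ("sigma_species", "sigma_alpha", "sigma_beta", "rho")


@dataclass
class PriorConfig:
    """Minimally informative prior settings.

    ``location_sd`` is the sd of the zero-centred normal priors on all
    location parameters (plot effects under no pooling; population means
    under pooling).  ``sigma_upper`` bounds the uniform priors on every
    standard deviation.  The intercept/slope correlation is uniform on
    (-1, 1).
    """

    location_sd: float = 100.0
    sigma_upper: float = 100.0

    def __post_init__(self):
        if self.location_sd <= 0 or self.sigma_upper <= 0:
            raise ValueError("prior scales must be strictly positive")


@dataclass
class McmcConfig:
    """Sampler settings: ``chains`` x (``warmup`` + ``draws`` * ``thin``)."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 0 or self.draws < 1 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")


def _as_model_frame(frame) -> ModelFrame:
    if isinstance(frame, ModelFrame):
        return frame
    if isinstance(frame, pd.DataFrame):
        return ModelFrame(df=frame.copy(), index="N")
    raise TypeError("expected a ModelFrame or a long-format DataFrame")


class EIVChangeModel(BaseEstimator):
    """Sklearn-style estimator for the hierarchical change models.

    Parameters
    ----------
    pooling : {"none", "global", "habitat"}
        Model variant (aliases "M1"/"M2"/"M3" accepted).
    location_prior_sd, sigma_prior_upper : float
        See :class:`PriorConfig`.
    chains, warmup, draws, thin : int
        See :class:`McmcConfig`.
    random_state : int
        Seed for the sampler; fits are bit-reproducible given the same
        data and configuration.

    Attributes (after fit)
    ----------------------
    posterior_ : dict of arrays shaped (chains, draws, ...)
        Raw retained draws keyed ``alpha``, ``beta``, ``sigma_species``
        and, for pooled variants, ``mu_alpha``, ``mu_beta``,
        ``sigma_alpha``, ``sigma_beta``, ``rho``.
    alpha_, beta_ : arrays, one posterior mean per plot.
    sigma_species_ : float posterior mean of the residual sd.
    converged_ : bool, False if any split R-hat exceeded 1.05.
    """

    def __init__(
        self,
        pooling: str = "habitat",
        location_prior_sd: float = 100.0,
        sigma_prior_upper: float = 100.0,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        thin: int = 1,
        random_state: int = 0,
    ):
        self.pooling = pooling
        self.location_prior_sd = location_prior_sd
        self.sigma_prior_upper = sigma_prior_upper
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.thin = thin
        self.random_state = random_state

    # ------------------------------------------------------------------
    @property
    def model_id_(self) -> str:
        return MODEL_ID_OF_POOLING[self._pooling()]

    def _pooling(self) -> str:
        p = POOLING_OF_MODEL_ID.get(self.pooling, self.pooling)
        if p not in ("none", "global", "habitat"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        return p

    def fit(self, frame, y=None) -> "EIVChangeModel":
        """Sample the posterior for the given long-format frame."""
        mf = _as_model_frame(frame)
        pooling = self._pooling()
        PriorConfig(self.location_prior_sd, self.sigma_prior_upper)  # validate
        McmcConfig(self.chains, self.warmup, self.draws, self.thin)  # validate
        if pooling == "habitat" and mf.n_habitats < 2:
            raise ValueError(
                "habitat pooling needs >= 2 habitats; "
                f"frame has {mf.n_habitats}"
            )
        if pooling == "none":
            present = pd.crosstab(mf.df["plot"], mf.df["period"])
            one_period = [
                p
                for p in mf.plot_ids
                if 1 not in present.columns
                or 2 not in present.columns
                or present.loc[p].eq(0).any()
            ]
            if one_period:
                warnings.warn(
                    f"{len(one_period)} plot(s) observed in only one period; "
                    "under no pooling the other period's parameter is "
                    "informed only by its prior",
                    stacklevel=2,
                )
        self.posterior_ = _gibbs.sample_posterior(
            y=mf.y,
            x=mf.x,
            j=mf.j,
            n_plots=mf.n_plots,
            pooling=pooling,
            k_of_plot=mf.k_of_plot,
            location_sd=self.location_prior_sd,
            sigma_upper=self.sigma_prior_upper,
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            thin=self.thin,
            seed=int(self.random_state),
        )
        self.frame_ = mf
        self.plot_ids_ = list(mf.plot_ids)
        self.habitats_ = list(mf.habitats)
        self.k_of_plot_ = mf.k_of_plot.copy()
        self._finalize_summaries()
        if self.chains >= 2:
            report = check_convergence(self)
            self.converged_ = bool(report.passed)
            if not report.passed:
                warnings.warn(
                    "possible non-convergence: max split R-hat "
                    f"{report.table['rhat'].max():.3f}",
                    stacklevel=2,
                )
        else:
            self.converged_ = True
        return self

    def _finalize_summaries(self) -> None:
        post = self.posterior_
        self.alpha_ = post["alpha"].mean(axis=(0, 1))
        self.beta_ = post["beta"].mean(axis=(0, 1))
        self.sigma_species_ = float(post["sigma_species"].mean())
        if "mu_alpha" in post:
            self.mu_alpha_ = post["mu_alpha"].mean(axis=(0, 1))
            self.mu_beta_ = post["mu_beta"].mean(axis=(0, 1))
            self.sigma_alpha_ = float(post["sigma_alpha"].mean())
            self.sigma_beta_ = float(post["sigma_beta"].mean())
            self.rho_ = float(post["rho"].mean())

    @classmethod
    def _from_posterior(cls, posterior: dict, frame: ModelFrame, pooling: str):
        """Build a fitted model around externally supplied draws (tests,
        deserialization).  Arrays must be shaped (chains, draws, ...)."""
        model = cls(pooling=pooling)
        model.posterior_ = posterior
        model.frame_ = frame
        model.plot_ids_ = list(frame.plot_ids)
        model.habitats_ = list(frame.habitats)
        model.k_of_plot_ = frame.k_of_plot.copy()
        model._finalize_summaries()
        model.converged_ = True
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise NotFittedError("call fit() first")

    # ------------------------------------------------------------------
    @property
    def n_draws_(self) -> int:
        self._check_fitted()
        shape = self.posterior_["sigma_species"].shape
        return int(shape[0] * shape[1])

    def flat(self, name: str) -> np.ndarray:
        """Draws of ``name`` flattened over chains: (S,) or (S, dim)."""
        self._check_fitted()
        arr = self.posterior_[name]
        return arr.reshape(-1, *arr.shape[2:])

    def _frame_vectors(self, frame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mf = self.frame_ if frame is None else _as_model_frame(frame)
        if mf.n_plots != len(self.plot_ids_) or list(mf.plot_ids) != self.plot_ids_:
            raise ValueError("frame plots do not match the fitted model")
        return mf.y, mf.x, mf.j

    def predict(self, frame=None) -> np.ndarray:
        """Posterior-mean fitted value per observation row."""
        self._check_fitted()
        _, x, j = self._frame_vectors(frame)
        return self.alpha_[j] + self.beta_[j] * x

    def pointwise_log_density(self, frame=None) -> np.ndarray:
        """Matrix of log p(y_i | draw s): shape (n_draws, n_obs).

        Entry (s, i) is the normal log-density of y_i at mean
        alpha_j[i]^(s) + beta_j[i]^(s) x_i with sd sigma_species^(s).
        """
        self._check_fitted()
        y, x, j = self._frame_vectors(frame)
        alpha = self.flat("alpha")
        beta = self.flat("beta")
        sigma = self.flat("sigma_species")[:, None]
        mu = alpha[:, j] + beta[:, j] * x[None, :]
        z = (y[None, :] - mu) / sigma
        return -0.5 * _gibbs._LOG2PI - np.log(sigma) - 0.5 * z * z

    def deviance_draws(self, frame=None, chunk: int = 512) -> np.ndarray:
        """Per-draw deviance D(theta^(s)) = -2 sum_i log p(y_i|theta^(s)),
        computed in chunks of draws to bound memory."""
        self._check_fitted()
        y, x, j = self._frame_vectors(frame)
        alpha = self.flat("alpha")
        beta = self.flat("beta")
        sigma = self.flat("sigma_species")
        n = len(y)
        out = np.empty(len(sigma))
        for lo in range(0, len(sigma), chunk):
            hi = lo + chunk
            mu = alpha[lo:hi, j] + beta[lo:hi, j] * x[None, :]
            z = (y[None, :] - mu) / sigma[lo:hi, None]
            ll = (
                -0.5 * n * _gibbs._LOG2PI
                - n * np.log(sigma[lo:hi])
                - 0.5 * np.sum(z * z, axis=1)
            )
            out[lo:hi] = -2.0 * ll
        return out

    def deviance_at_posterior_mean(self, frame=None) -> float:
        """D(theta_bar) with theta_bar the posterior mean of each parameter."""
        self._check_fitted()
        y, x, j = self._frame_vectors(frame)
        mu = self.alpha_[j] + self.beta_[j] * x
        sig = self.sigma_species_
        z = (y - mu) / sig
        n = len(y)
        ll = -0.5 * n * _gibbs._LOG2PI - n * np.log(sig) - 0.5 * float(z @ z)
        return -2.0 * ll


@dataclass
class ConvergenceReport:
    """Split R-hat / ESS per parameter with an overall pass flag."""

    table: pd.DataFrame  # columns: parameter, rhat, ess
    rhat_threshold: float
    ess_threshold: float
    passed: bool


def _to_arviz_dict(posterior: dict) -> dict:
    return dict(posterior)


def check_convergence(
    fit,
    rhat_threshold: float = 1.05,
    ess_threshold: float = 400.0,
) -> ConvergenceReport:
    """Split R-hat and bulk effective sample size for every parameter.

    ``fit`` is a fitted :class:`EIVChangeModel` or a dict of draw arrays
    shaped (chain, draw, ...).  Requires at least two chains.
    """
    import arviz as az

    posterior = fit.posterior_ if hasattr(fit, "posterior_") else fit
    n_chains = next(iter(posterior.values())).shape[0]
    if n_chains < 2:
        raise ValueError("convergence diagnostics need >= 2 chains; rerun with more")
    ds = az.convert_to_dataset(_to_arviz_dict(posterior))
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    rows = []
    for name in posterior:
        r = np.atleast_1d(rhat[name].values).ravel()
        e = np.atleast_1d(ess[name].values).ravel()
        for i, (ri, ei) in enumerate(zip(r, e)):
            label = name if r.size == 1 else f"{name}[{i}]"
            rows.append((label, float(ri), float(ei)))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    passed = bool(
        np.all(np.nan_to_num(table["rhat"], nan=1.0) < rhat_threshold)
        and np.all(table["ess"] >= ess_threshold)
    )
    return ConvergenceReport(
        table=table,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
        passed=passed,
    )


def fit_model(
    frame,
    model_id: str = "M3",
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> EIVChangeModel:
    """Functional front end: fit one model variant and return the
    fitted estimator (which carries the posterior draws)."""
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    model = EIVChangeModel(
        pooling=model_id,
        location_prior_sd=priors.location_sd,
        sigma_prior_upper=priors.sigma_upper,
        chains=mcmc.chains,
        warmup=mcmc.warmup,
        draws=mcmc.draws,
        thin=mcmc.thin,
        random_state=mcmc.seed,
    )
    return model.fit(frame)


def pointwise_log_density(fit: EIVChangeModel, frame=None) -> np.ndarray:
    """Module-level alias of :meth:`EIVChangeModel.pointwise_log_density`."""
    return fit.pointwise_log_density(frame)
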