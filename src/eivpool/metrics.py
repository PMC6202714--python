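"""Posterior diagnostics: per-level R², pooling factors, DIC, change tables.

All quantities are computed from raw posterior draws.

Per-level Bayesian R² (Gelman & Pardoe style): for each draw,
``R² = 1 − V(errors) / V(values)`` with V the finite-sample variance
across units at that level.  The data level compares residuals
``y_i − (α_j[i] + β_j[i] x_i)`` against the observed scores; the
intercept level compares ``α_j − μ_α(…)`` against the α_j draws; the
slope level analogously with β.  Under global pooling the level-2 error
is a constant shift of the parameter within each draw, so the level-2 R²
is identically zero — habitat structure is what gives the level-2 model
something to explain.

The pooling factor ``λ = 1 − V_j(E_s[ε_j]) / E_s[V_j(ε_j)]`` summarizes
how strongly level-2 estimates are pulled toward their population mean
(1 = complete pooling, 0 = no pooling).

DIC uses the classic plug-in form: ``pD = D̄ − D(θ̄)`` with θ̄ the
posterior mean of each parameter, and ``DIC = D̄ + pD``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import EIVChangeModel

LEVELS = ("data", "intercepts", "slopes")


@dataclass
class PosteriorScalarSummary:
    """Mean, median and central 50%/95% intervals of a scalar posterior."""

    mean: float
    median: float
    lo50: float
    hi50: float
    lo95: float
    hi95: float

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "PosteriorScalarSummary":
        d = np.asarray(draws, dtype=float).ravel()
        q = np.quantile(d, [0.025, 0.25, 0.5, 0.75, 0.975])
        return cls(
            mean=float(d.mean()),
            median=float(q[2]),
            lo50=float(q[1]),
            hi50=float(q[3]),
            lo95=float(q[0]),
            hi95=float(q[4]),
        )


def _var(a: np.ndarray, axis=None) -> np.ndarray:
    """Finite-sample (ddof=1) variance, the V(·) of the R²/λ formulas."""
    return np.var(a, axis=axis, ddof=1)


def _level2_errors(fit: EIVChangeModel, level: str) -> tuple[np.ndarray, np.ndarray]:
    """(values, errors) draw matrices (S, J) for a level-2 parameter."""
    pooling = fit._pooling()
    if pooling == "none":
        raise ValueError(
            "no-pooling model has no level-2 structure; "
            "only the data level is defined"
        )
    par = fit.flat("alpha" if level == "intercepts" else "beta")
    mu = fit.flat("mu_alpha" if level == "intercepts" else "mu_beta")
    if pooling == "habitat":
        fitted = mu[:, fit.k_of_plot_]
    else:
        fitted = mu  # (S, 1) broadcasts over plots
    return par, par - fitted


def bayesian_r2(fit: EIVChangeModel, level: str = "data") -> PosteriorScalarSummary:
    """Per-draw explained variance at one level, summarized over draws."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if level == "data":
        y, x, j = fit._frame_vectors(None)
        alpha = fit.flat("alpha")
        beta = fit.flat("beta")
        vy = _var(y)
        r2 = np.empty(alpha.shape[0])
        chunk = 512
        for lo in range(0, alpha.shape[0], chunk):
            hi = lo + chunk
            eps = y[None, :] - (alpha[lo:hi, j] + beta[lo:hi, j] * x[None, :])
            r2[lo:hi] = 1.0 - _var(eps, axis=1) / vy
        return PosteriorScalarSummary.from_draws(r2)
    values, errors = _level2_errors(fit, level)
    r2 = 1.0 - _var(errors, axis=1) / _var(values, axis=1)
    return PosteriorScalarSummary.from_draws(r2)


@dataclass
class PoolingFactor:
    """λ with the two variance components that define it."""

    summary: PosteriorScalarSummary
    var_of_mean_errors: float  # V_j(E_s[eps_j])
    mean_var_of_errors: float  # E_s[V_j(eps_j)]

    @property
    def value(self) -> float:
        return self.summary.mean


def pooling_factor(fit: EIVChangeModel, level: str = "slopes") -> PoolingFactor:
    """λ = 1 − V_j(E_s[ε_j]) / E_s[V_j(ε_j)] for intercepts or slopes."""
    if level not in ("intercepts", "slopes"):
        raise ValueError("pooling factor is defined for 'intercepts' or 'slopes'")
    _, errors = _level2_errors(fit, level)
    v_of_mean = float(_var(errors.mean(axis=0)))
    mean_of_v = float(_var(errors, axis=1).mean())
    lam = 1.0 - v_of_mean / mean_of_v
    if not (-0.05 <= lam <= 1.05):
        warnings.warn(
            f"pooling factor {lam:.3f} outside [-0.05, 1.05]; "
            "check convergence or sample size",
            stacklevel=2,
        )
    # Per-draw lambda has no standard definition; report the point value
    # with a Monte-Carlo interval from draw-resampled variance ratios.
    per_draw = 1.0 - v_of_mean / _var(errors, axis=1)
    summary = PosteriorScalarSummary.from_draws(per_draw)
    summary.mean = lam
    return PoolingFactor(
        summary=summary, var_of_mean_errors=v_of_mean, mean_var_of_errors=mean_of_v
    )


@dataclass
class DicResult:
    """Spiegelhalter DIC decomposition for one fitted model."""

    model_id: str
    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def dic(fit: EIVChangeModel, frame=None) -> DicResult:
    """DIC = D̄ + pD with pD = D̄ − D(θ̄), θ̄ the posterior mean."""
    dbar = float(fit.deviance_draws(frame).mean())
    d_hat = float(fit.deviance_at_posterior_mean(frame))
    return DicResult(model_id=fit.model_id_, dbar=dbar, d_at_mean=d_hat)


def compare_models(fits: list[EIVChangeModel], frame=None) -> pd.DataFrame:
    """Table of pD / DIC / ΔDIC-vs-best for several fits of one frame."""
    rows = []
    for fit in fits:
        r = dic(fit, frame)
        rows.append({"model": r.model_id, "pD": r.pd, "DIC": r.dic, "Dbar": r.dbar})
    out = pd.DataFrame(rows)
    out["dDIC"] = out["DIC"] - out["DIC"].min()
    return out


def summarize_changes(fit: EIVChangeModel, level: str = "plot") -> pd.DataFrame:
    """Per-unit between-period change summaries with exclude-zero flags.

    ``level="plot"`` summarizes each plot's slope β_j; ``level="habitat"``
    (habitat pooling only) summarizes the habitat-level mean slopes
    μ_β[k].  Because pooled estimates borrow strength, no multiplicity
    adjustment is applied to these intervals.
    """
    if level == "plot":
        draws = fit.flat("beta")
        units = fit.plot_ids_
    elif level == "habitat":
        if fit._pooling() != "habitat":
            raise ValueError("habitat-level changes need the habitat-pooling model")
        draws = fit.flat("mu_beta")
        units = fit.habitats_
    else:
        raise ValueError("level must be 'plot' or 'habitat'")
    rows = []
    for u, unit in enumerate(units):
        s = PosteriorScalarSummary.from_draws(draws[:, u])
        rows.append(
            {
                "unit": unit,
                "mean": s.mean,
                "median": s.median,
                "lo50": s.lo50,
                "hi50": s.hi50,
                "lo95": s.lo95,
                "hi95": s.hi95,
                "excl0_50": bool(s.lo50 > 0 or s.hi50 < 0),
                "excl0_95": bool(s.lo95 > 0 or s.hi95 < 0),
            }
        )
    return pd.DataFrame(rows)


def habitat_contrasts(fit: EIVChangeModel) -> pd.DataFrame:
    """All pairwise habitat differences in mean change, draw-wise."""
    if fit._pooling() != "habitat":
        raise ValueError("habitat contrasts need the habitat-pooling model")
    draws = fit.flat("mu_beta")
    rows = []
    habs = fit.habitats_
    for a in range(len(habs)):
        for b in range(a + 1, len(habs)):
            d = draws[:, a] - draws[:, b]
            s = PosteriorScalarSummary.from_draws(d)
            rows.append(
                {
                    "habitat_a": habs[a],
                    "habitat_b": habs[b],
                    "mean": s.mean,
                    "lo95": s.lo95,
                    "hi95": s.hi95,
                    "excl0_95": bool(s.lo95 > 0 or s.hi95 < 0),
                }
            )
    return pd.DataFrame(rows)


def metrics_row(fit: EIVChangeModel, frame=None) -> dict:
    """One summary row per (model, index): σ's, per-level R², λ's, pD, DIC.

    Level-2 entries are NaN where the model has no such level.
    """
    pooled = fit._pooling() != "none"
    d = dic(fit, frame)
    row = {
        "model": fit.model_id_,
        "index": fit.frame_.index,
        "sigma_species": fit.sigma_species_,
        "sigma_alpha": fit.sigma_alpha_ if pooled else np.nan,
        "sigma_beta": fit.sigma_beta_ if pooled else np.nan,
        "r2_data": bayesian_r2(fit, "data").mean,
        "r2_alpha": bayesian_r2(fit, "intercepts").mean if pooled else np.nan,
        "r2_beta": bayesian_r2(fit, "slopes").mean if pooled else np.nan,
        "lambda_alpha": pooling_factor(fit, "intercepts").value if pooled else np.nan,
        "lambda_beta": pooling_factor(fit, "slopes").value if pooled else np.nan,
        "pD": d.pd,
        "DIC": d.dic,
    }
    return row
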