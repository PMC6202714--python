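"""Raw-means mixed-model baseline with multiplicity-corrected contrasts.

The traditional analysis treats each plot-period community mean as a
single data point: a linear mixed model of the raw means with
habitat, period and habitat-by-period fixed effects and a plot random
intercept (the repeat-sampling term), all means weighted equally
regardless of how many species they average over.  Habitat-level change
is then a family of K contrasts, and frequentist inference over the
family needs simultaneous (multiplicity-corrected) intervals — either
the single-step max-|z| adjustment over the contrast correlation matrix
or a Bonferroni fallback.

This is deliberately the method being compared against, so its known
weaknesses (equal weighting of plots, no within-plot variance) are kept.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError
import statsmodels.api as sm

from .data import PlotDesign


def _design_matrix(df: pd.DataFrame, habitats: list[str]):
    """Treatment-coded habitat*period design with sorted habitat levels."""
    period2 = (df["period"].to_numpy() == 2).astype(float)
    cols = {"Intercept": np.ones(len(df)), "period2": period2}
    for h in habitats[1:]:
        hd = (df["habitat"] == h).astype(float).to_numpy()
        cols[f"hab[{h}]"] = hd
        cols[f"hab[{h}]:period2"] = hd * period2
    X = pd.DataFrame(cols, index=df.index)
    # reorder: intercept, habitat mains, period, interactions
    order = (
        ["Intercept"]
        + [f"hab[{h}]" for h in habitats[1:]]
        + ["period2"]
        + [f"hab[{h}]:period2" for h in habitats[1:]]
    )
    return X[order]


class RawMeansChangeModel(BaseEstimator):
    """Mixed model on plot-period mean scores (the comparison method).

    Fit takes the raw-means table (columns ``plot``, ``period``,
    ``mean``, ``n``) and a :class:`PlotDesign`; plot means are unweighted
    by ``n``.  Fitted attributes include the per-habitat between-period
    change estimates (``contrasts_``), the plot random-intercept variance
    and the residual variance; habitats observed in only one period are
    dropped from the contrast family with a warning.
    """

    def __init__(self, reml: bool = True):
        self.reml = reml

    def fit(self, raw_means: pd.DataFrame, design: PlotDesign) -> "RawMeansChangeModel":
        df = raw_means.copy()
        df["habitat"] = df["plot"].map(design.table["habitat"])
        if df["habitat"].isna().any():
            missing = sorted(df.loc[df["habitat"].isna(), "plot"].unique())
            raise ValueError(f"plots missing from design table: {missing}")
        if df["habitat"].nunique() < 2:
            raise ValueError("baseline needs >= 2 habitats")
        if set(df["period"].unique()) != {1, 2}:
            raise ValueError("baseline needs both periods present")

        habitats = sorted(df["habitat"].unique())
        per_hab = df.groupby("habitat")["period"].nunique()
        incomplete = sorted(per_hab[per_hab < 2].index)
        if incomplete:
            warnings.warn(
                f"habitat(s) observed in a single period, contrast dropped: "
                f"{incomplete}",
                stacklevel=2,
            )
        X = _design_matrix(df, habitats)
        # an unobserved habitat-period cell leaves an all-zero column
        # (e.g. a habitat recorded in a single period); drop it
        X = X.loc[:, (X != 0).any(axis=0)]
        y = df["mean"].to_numpy(dtype=float)

        resid_ols = y - X.to_numpy() @ np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        degenerate = float(resid_ols @ resid_ols) < 1e-10 * max(len(y), 1)
        if degenerate:
            # Zero residual variance: REML is ill-posed; the least-squares
            # solution is exact.
            ols = sm.OLS(y, X).fit()
            fe = pd.Series(ols.params, index=X.columns)
            cov_fe = np.zeros((X.shape[1], X.shape[1]))
            self.plot_var_ = 0.0
            self.resid_var_ = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = sm.MixedLM(y, X.to_numpy(), groups=df["plot"].to_numpy())
                res = mixed.fit(reml=self.reml)
            fe = pd.Series(res.fe_params, index=X.columns)
            cov_fe = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]
            self.plot_var_ = float(np.asarray(res.cov_re)[0, 0])
            self.resid_var_ = float(res.scale)

        self.fixed_effects_ = fe
        self.cov_fixed_ = cov_fe
        self.habitats_ = habitats

        rows, lvecs = [], []
        for h in habitats:
            if h in incomplete:
                continue
            L = np.zeros(X.shape[1])
            L[X.columns.get_loc("period2")] = 1.0
            if h != habitats[0]:
                L[X.columns.get_loc(f"hab[{h}]:period2")] = 1.0
            est = float(L @ fe.to_numpy())
            se = float(np.sqrt(max(L @ cov_fe @ L, 0.0)))
            rows.append({"habitat": h, "estimate": est, "se": se})
            lvecs.append(L)
        self.contrasts_ = pd.DataFrame(rows)
        self._contrast_vectors_ = np.array(lvecs)
        z = stats.norm.ppf(0.975)
        self.contrasts_["lo95"] = self.contrasts_["estimate"] - z * self.contrasts_["se"]
        self.contrasts_["hi95"] = self.contrasts_["estimate"] + z * self.contrasts_["se"]
        return self

    def _check_fitted(self):
        if not hasattr(self, "contrasts_"):
            raise NotFittedError("call fit() first")


def fit_raw_means_model(
    raw_means: pd.DataFrame, design: PlotDesign, reml: bool = True
) -> RawMeansChangeModel:
    """Functional front end over :class:`RawMeansChangeModel`."""
    return RawMeansChangeModel(reml=reml).fit(raw_means, design)


def _max_abs_z_quantile(corr: np.ndarray, alpha: float) -> float:
    """c with P(max_k |Z_k| <= c) = 1 - alpha for Z ~ MVN(0, corr).

    The single-step adjustment used for simultaneous contrast intervals;
    evaluated through multivariate-normal rectangle probabilities.
    """
    K = corr.shape[0]
    if K == 1:
        return float(stats.norm.ppf(1.0 - alpha / 2.0))
    mvn = stats.multivariate_normal(mean=np.zeros(K), cov=corr, allow_singular=True)

    def coverage(c):
        return float(mvn.cdf(np.full(K, c), lower_limit=np.full(K, -c)))

    lo = stats.norm.ppf(1.0 - alpha / 2.0)  # single-contrast quantile
    hi = stats.norm.ppf(1.0 - alpha / (2.0 * K))  # Bonferroni bound
    target = 1.0 - alpha
    if coverage(hi) < target:  # pragma: no cover - numerical guard
        return float(hi)
    return float(optimize.brentq(lambda c: coverage(c) - target, lo - 1e-9, hi + 1e-9))


def corrected_contrasts(
    fit: RawMeansChangeModel, alpha: float = 0.05, method: str = "single-step"
) -> pd.DataFrame:
    """Family-wise adjusted intervals over the habitat-change contrasts.

    ``method`` is ``"single-step"`` (max-|z| over the estimated contrast
    correlation matrix) or ``"bonferroni"``.  Adjusted intervals are never
    narrower than the unadjusted ones; ``reject`` flags contrasts whose
    adjusted interval excludes zero at family-wise level ``alpha``.
    """
    fit._check_fitted()
    out = fit.contrasts_.copy()
    K = len(out)
    if method == "bonferroni":
        crit = float(stats.norm.ppf(1.0 - alpha / (2.0 * K)))
    elif method == "single-step":
        L = fit._contrast_vectors_
        C = L @ fit.cov_fixed_ @ L.T
        d = np.sqrt(np.clip(np.diag(C), 1e-300, None))
        corr = C / np.outer(d, d)
        crit = _max_abs_z_quantile(corr, alpha)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    crit = max(crit, float(stats.norm.ppf(1.0 - alpha / 2.0)))
    out["lo95_adj"] = out["estimate"] - crit * out["se"]
    out["hi95_adj"] = out["estimate"] + crit * out["se"]
    out["reject"] = (out["lo95_adj"] > 0) | (out["hi95_adj"] < 0)
    out["critical_value"] = crit
    return out
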