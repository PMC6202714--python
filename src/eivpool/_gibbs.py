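"""Gibbs sampler kernels for the normal hierarchical change models.

The three model variants share a normal data level
``y_i ~ N(alpha_j[i] + beta_j[i] * x_i, sigma_species)`` with x the 0/1
period indicator, and differ in what constrains the per-plot pairs
(alpha_j, beta_j):

* no pooling      — independent flat-ish normal priors per plot;
* global pooling  — (alpha_j, beta_j) ~ BVN((mu_a, mu_b), Sigma);
* habitat pooling — BVN means vary by habitat k: (mu_a[k], mu_b[k]).

Because x is binary, the per-plot likelihood reduces to four sufficient
statistics (counts and score sums per period): (alpha_j, beta_j) given
everything else is a conjugate bivariate normal, and sigma_species^2 a
truncated inverse gamma.

Naively alternating the plot effects with their population parameters
mixes poorly (the usual funnel between random effects and their
variance), so the hierarchical variants update the population block
against the *marginal* likelihood with the plot effects integrated out:
the pair of per-plot period means is bivariate normal,
``(ybar0_j, ybar1_j) ~ BVN(T mu_k, T Sigma T' + diag(s2/n0, s2/n1))``
with ``T = [[1, 0], [1, 1]]``.  The covariance — parameterized as
(sigma_a, sigma_b, rho) with uniform priors — takes random-walk
Metropolis steps on the unconstrained scale against that marginal
(scales adapted only during warmup); the population means are conjugate
under the same marginal; the plot effects are then redrawn from their
exact conditional, which keeps the partially collapsed scheme valid.
"""

from __future__ import annotations

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))


def suff_stats(y: np.ndarray, x: np.ndarray, j: np.ndarray, n_plots: int) -> dict:
    """Per-plot sufficient statistics of the binary-regressor data level."""
    is2 = x > 0.5
    n0 = np.bincount(j[~is2], minlength=n_plots).astype(float)
    n1 = np.bincount(j[is2], minlength=n_plots).astype(float)
    s0 = np.bincount(j[~is2], weights=y[~is2], minlength=n_plots)
    s1 = np.bincount(j[is2], weights=y[is2], minlength=n_plots)
    return {
        "n0": n0,
        "n1": n1,
        "s0": s0,
        "s1": s1,
        "sstot": float(y @ y),
        "n": float(len(y)),
    }


def _sample_bvn(p11, p12, p22, lin1, lin2, rng):
    """Vectorized draw from N(P^-1 lin, P^-1) for 2x2 precisions P."""
    det = p11 * p22 - p12 * p12
    c11 = p22 / det
    c12 = -p12 / det
    c22 = p11 / det
    m1 = c11 * lin1 + c12 * lin2
    m2 = c12 * lin1 + c22 * lin2
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 * l21, 1e-300))
    z1 = rng.standard_normal(np.shape(m1))
    z2 = rng.standard_normal(np.shape(m1))
    return m1 + l11 * z1, m2 + l21 * z1 + l22 * z2


def _sample_sigma2(ssr: float, n: float, upper: float, rng) -> float:
    """sigma^2 | rest ~ InvGamma((n-1)/2, SSR/2) truncated to sigma < upper."""
    shape = 0.5 * (n - 1.0)
    for _ in range(1000):
        tau = (0.5 * ssr) / rng.gamma(shape)
        if tau < upper * upper:
            return tau
    return min(tau, upper * upper * 0.99)  # pragma: no cover - bound pathologies


def _marginal_setup(stats: dict, k_idx: np.ndarray) -> dict:
    """Per-plot period means and habitat indices, split by which periods
    a plot was observed in (the marginal likelihood's shape differs)."""
    n0, n1, s0, s1 = stats["n0"], stats["n1"], stats["s0"], stats["s1"]
    both = (n0 > 0) & (n1 > 0)
    o0 = (n0 > 0) & (n1 == 0)
    o1 = (n1 > 0) & (n0 == 0)
    safe0 = np.maximum(n0, 1.0)
    safe1 = np.maximum(n1, 1.0)
    yb0 = s0 / safe0
    yb1 = s1 / safe1
    return {
        "kb": k_idx[both], "y0b": yb0[both], "y1b": yb1[both],
        "in0b": 1.0 / safe0[both], "in1b": 1.0 / safe1[both],
        "k0": k_idx[o0], "y00": yb0[o0], "in00": 1.0 / safe0[o0],
        "k1": k_idx[o1], "y11": yb1[o1], "in11": 1.0 / safe1[o1],
    }


def _marginal_loglik(la, lb, z, tau, mu_a, mu_b, marg, log_upper):
    """Log p(plot period means | mu, Sigma, sigma^2) + transform Jacobians,
    with the plot effects integrated out; the Sigma-block MH target."""
    if la > log_upper or lb > log_upper:
        return -np.inf
    sa2 = np.exp(2.0 * la)
    sb2 = np.exp(2.0 * lb)
    rho = np.tanh(z)
    c = rho * np.sqrt(sa2 * sb2)
    ll = 0.0
    if len(marg["kb"]):
        v11 = sa2 + tau * marg["in0b"]
        v12 = sa2 + c
        v22 = sa2 + 2.0 * c + sb2 + tau * marg["in1b"]
        det = v11 * v22 - v12 * v12
        r0 = marg["y0b"] - mu_a[marg["kb"]]
        r1 = marg["y1b"] - mu_a[marg["kb"]] - mu_b[marg["kb"]]
        quad = (v22 * r0 * r0 - 2.0 * v12 * r0 * r1 + v11 * r1 * r1) / det
        ll += -0.5 * np.sum(np.log(det) + quad)
    if len(marg["k0"]):
        v = sa2 + tau * marg["in00"]
        r0 = marg["y00"] - mu_a[marg["k0"]]
        ll += -0.5 * np.sum(np.log(v) + r0 * r0 / v)
    if len(marg["k1"]):
        v = sa2 + 2.0 * c + sb2 + tau * marg["in11"]
        r1 = marg["y11"] - mu_a[marg["k1"]] - mu_b[marg["k1"]]
        ll += -0.5 * np.sum(np.log(v) + r1 * r1 / v)
    # Jacobians of sigma = exp(l) and rho = tanh(z) under flat priors.
    return ll + la + lb + np.log(1.0 - rho * rho)


def _mu_update(la, lb, z, tau, marg, K, loc_prec, rng):
    """Conjugate draw of the population means under the same marginal."""
    sa2 = np.exp(2.0 * la)
    sb2 = np.exp(2.0 * lb)
    c = np.tanh(z) * np.sqrt(sa2 * sb2)
    P11 = np.full(K, loc_prec)
    P12 = np.zeros(K)
    P22 = np.full(K, loc_prec)
    L1 = np.zeros(K)
    L2 = np.zeros(K)
    if len(marg["kb"]):
        v11 = sa2 + tau * marg["in0b"]
        v12 = sa2 + c
        v22 = sa2 + 2.0 * c + sb2 + tau * marg["in1b"]
        det = v11 * v22 - v12 * v12
        w11, w12, w22 = v22 / det, -v12 / det, v11 / det
        kb = marg["kb"]
        P11 += np.bincount(kb, weights=w11 + 2.0 * w12 + w22, minlength=K)
        P12 += np.bincount(kb, weights=w12 + w22, minlength=K)
        P22 += np.bincount(kb, weights=w22, minlength=K)
        wy1 = w11 * marg["y0b"] + w12 * marg["y1b"]
        wy2 = w12 * marg["y0b"] + w22 * marg["y1b"]
        L1 += np.bincount(kb, weights=wy1 + wy2, minlength=K)
        L2 += np.bincount(kb, weights=wy2, minlength=K)
    if len(marg["k0"]):
        iv = 1.0 / (sa2 + tau * marg["in00"])
        P11 += np.bincount(marg["k0"], weights=iv, minlength=K)
        L1 += np.bincount(marg["k0"], weights=iv * marg["y00"], minlength=K)
    if len(marg["k1"]):
        iv = 1.0 / (sa2 + 2.0 * c + sb2 + tau * marg["in11"])
        k1 = marg["k1"]
        P11 += np.bincount(k1, weights=iv, minlength=K)
        P12 += np.bincount(k1, weights=iv, minlength=K)
        P22 += np.bincount(k1, weights=iv, minlength=K)
        L1 += np.bincount(k1, weights=iv * marg["y11"], minlength=K)
        L2 += np.bincount(k1, weights=iv * marg["y11"], minlength=K)
    return _sample_bvn(P11, P12, P22, L1, L2, rng)


def run_chain(
    stats: dict,
    pooling: str,
    k_of_plot: np.ndarray,
    location_sd: float,
    sigma_upper: float,
    warmup: int,
    draws: int,
    thin: int,
    rng: np.random.Generator,
) -> dict:
    """One MCMC chain; returns arrays of retained draws."""
    n0, n1, s0, s1 = stats["n0"], stats["n1"], stats["s0"], stats["s1"]
    sstot, n_tot = stats["sstot"], stats["n"]
    J = len(n0)
    K = int(k_of_plot.max()) + 1 if pooling == "habitat" else 1
    k_idx = k_of_plot if pooling == "habitat" else np.zeros(J, dtype=np.int64)
    loc_prec = 1.0 / (location_sd * location_sd)
    log_upper = np.log(sigma_upper)

    # Data-driven initials with per-chain jitter for overdispersion.
    grand = (s0.sum() + s1.sum()) / n_tot
    m0 = np.where(n0 > 0, s0 / np.maximum(n0, 1.0), grand)
    m1 = np.where(n1 > 0, s1 / np.maximum(n1, 1.0), m0)
    a = m0 + 0.3 * rng.standard_normal(J)
    b = (m1 - m0) + 0.3 * rng.standard_normal(J)
    resid2 = sstot - np.sum(n0 * m0 * m0 + n1 * m1 * m1)
    tau = max(resid2 / max(n_tot - 2.0 * J, 1.0), 1e-2) * np.exp(
        0.2 * rng.standard_normal()
    )
    mu_a = np.array([a[k_idx == k].mean() for k in range(K)])
    mu_b = np.array([b[k_idx == k].mean() for k in range(K)])
    la = np.log(max(np.std(a), 0.1)) + 0.2 * rng.standard_normal()
    lb = np.log(max(np.std(b), 0.1)) + 0.2 * rng.standard_normal()
    zr = 0.1 * rng.standard_normal()

    hier = pooling in ("global", "habitat")
    n_keep = draws
    out = {
        "alpha": np.empty((n_keep, J)),
        "beta": np.empty((n_keep, J)),
        "sigma_species": np.empty(n_keep),
    }
    if hier:
        out["mu_alpha"] = np.empty((n_keep, K))
        out["mu_beta"] = np.empty((n_keep, K))
        out["sigma_alpha"] = np.empty(n_keep)
        out["sigma_beta"] = np.empty(n_keep)
        out["rho"] = np.empty(n_keep)

    mh_scale = np.array([0.3, 0.3, 0.3])  # per-coordinate proposal sds
    n_iter = warmup + draws * thin
    kept = 0
    nA = n0 + n1
    marg = _marginal_setup(stats, k_idx) if hier else None

    for it in range(n_iter):
        if hier:
            # (sigma_a, sigma_b, rho) | mu, sigma — per-coordinate
            # Metropolis against the marginal likelihood (plot effects
            # integrated out), two sweeps per scan.
            theta = [la, lb, zr]
            cur = _marginal_loglik(*theta, tau, mu_a, mu_b, marg, log_upper)
            for _ in range(2):
                for c3 in range(3):
                    prop_theta = list(theta)
                    prop_theta[c3] += mh_scale[c3] * rng.standard_normal()
                    prop = _marginal_loglik(
                        *prop_theta, tau, mu_a, mu_b, marg, log_upper
                    )
                    accept = np.log(rng.uniform()) < prop - cur
                    if accept:
                        theta, cur = prop_theta, prop
                    if it < warmup:
                        # Robbins-Monro adaptation toward ~44% acceptance.
                        mh_scale[c3] *= np.exp(
                            (float(accept) - 0.44) / (10.0 + it) ** 0.6
                        )
            la, lb, zr = theta

            # (mu_a[k], mu_b[k]) | Sigma, sigma — conjugate under the
            # same marginal.
            mu_a, mu_b = _mu_update(la, lb, zr, tau, marg, K, loc_prec, rng)

            sa = np.exp(la)
            sb = np.exp(lb)
            rho = np.tanh(zr)
            om = 1.0 - rho * rho
            q11 = 1.0 / (sa * sa * om)
            q22 = 1.0 / (sb * sb * om)
            q12 = -rho / (sa * sb * om)
            pm1 = mu_a[k_idx]
            pm2 = mu_b[k_idx]
        else:
            q11 = q22 = loc_prec
            q12 = 0.0
            pm1 = pm2 = 0.0

        # (alpha_j, beta_j) | rest — conjugate bivariate normal per plot.
        inv_tau = 1.0 / tau
        p11 = nA * inv_tau + q11
        p12 = n1 * inv_tau + q12
        p22 = n1 * inv_tau + q22
        lin1 = (s0 + s1) * inv_tau + q11 * pm1 + q12 * pm2
        lin2 = s1 * inv_tau + q12 * pm1 + q22 * pm2
        a, b = _sample_bvn(p11, p12, p22, lin1, lin2, rng)

        # sigma_species | rest.
        ab = a + b
        ssr = sstot - 2.0 * np.sum(a * s0 + ab * s1) + np.sum(n0 * a * a + n1 * ab * ab)
        tau = _sample_sigma2(max(ssr, 1e-12), n_tot, sigma_upper, rng)

        if it >= warmup and (it - warmup) % thin == 0:
            out["alpha"][kept] = a
            out["beta"][kept] = b
            out["sigma_species"][kept] = np.sqrt(tau)
            if hier:
                out["mu_alpha"][kept] = mu_a
                out["mu_beta"][kept] = mu_b
                out["sigma_alpha"][kept] = np.exp(la)
                out["sigma_beta"][kept] = np.exp(lb)
                out["rho"][kept] = np.tanh(zr)
            kept += 1
    return out


def sample_posterior(
    y: np.ndarray,
    x: np.ndarray,
    j: np.ndarray,
    n_plots: int,
    pooling: str,
    k_of_plot: np.ndarray,
    location_sd: float,
    sigma_upper: float,
    chains: int,
    warmup: int,
    draws: int,
    thin: int,
    seed: int,
) -> dict:
    """Run ``chains`` independent chains; stack draws as (chain, draw, ...)."""
    stats = suff_stats(y, x, j, n_plots)
    children = np.random.SeedSequence(seed).spawn(chains)
    per_chain = [
        run_chain(
            stats,
            pooling,
            k_of_plot,
            location_sd,
            sigma_upper,
            warmup,
            draws,
            thin,
            np.random.default_rng(child),
        )
        for child in children
    ]
    return {
        name: np.stack([chain[name] for chain in per_chain], axis=0)
        for name in per_chain[0]
    }
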