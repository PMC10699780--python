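"""Hierarchical normal model with a Gibbs sampler.

The estimator behind the treatment and isotope contrasts: a normal linear
model with any number of crossed or nested random-intercept terms,

    y = X beta + sum_k Z_k u_k + e,    e ~ N(0, sigma^2),
    u_k ~ N(0, sigma_k^2),

with a vague normal prior on ``beta`` and weakly-informative half-normal
priors on the residual and group standard deviations.  The mean layers are
conjugate and sampled by Gibbs; the standard deviations are updated with a
random-walk Metropolis step on the log scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HierarchicalFit", "fit_hierarchical_normal"]


@dataclass
class HierarchicalFit:
    """Posterior draws from :func:`fit_hierarchical_normal`."""

    beta: np.ndarray  # (n_draws, p)
    sigma: np.ndarray  # (n_draws,)
    group_sds: dict = field(default_factory=dict)  # name -> (n_draws,)
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


def _halfnormal_logpdf_term(s: float, scale: float) -> float:
    return -0.5 * (s / scale) ** 2


def fit_hierarchical_normal(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
    *,
    draws: int = 2000,
    burn: int = 500,
    chains: int = 2,
    seed: int | np.random.Generator = 0,
    beta_prior_sd: float = 10.0,
    sd_prior_scale: float = 1.0,
    proposal_scale: float = 0.35,
) -> HierarchicalFit:
    """Sample the posterior of a hierarchical normal model.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effect design (n, p).  Include the
        intercept column explicitly.
    groups
        Mapping from term name to an integer code vector (n,) assigning each
        observation to a group; each term gets i.i.d. normal random
        intercepts with its own half-normal-prior standard deviation.
    draws, burn, chains
        Post-burn-in draws are pooled across chains:
        ``n_draws = chains * (draws - burn)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be 1-D and aligned with X")
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    if burn >= draws:
        raise ValueError("burn must be < draws")
    n, p = X.shape
    groups = groups or {}
    gnames = list(groups)
    codes = {k: np.asarray(v, dtype=np.intp) for k, v in groups.items()}
    sizes = {k: int(codes[k].max()) + 1 if codes[k].size else 0 for k in gnames}
    counts = {k: np.bincount(codes[k], minlength=sizes[k]).astype(float) for k in gnames}

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(int(seed)))
    )

    XtX = X.T @ X
    prior_prec = np.eye(p) / beta_prior_sd**2

    kept = draws - burn
    beta_out = np.empty((chains * kept, p))
    sigma_out = np.empty(chains * kept)
    sds_out = {k: np.empty(chains * kept) for k in gnames}
    accept = {k: 0 for k in ["sigma", *gnames]}
    total_steps = chains * draws

    beta_init, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta_init
    sigma_init = float(np.std(resid0)) or 1.0

    for chain in range(chains):
        beta = beta_init.copy()
        sigma = sigma_init
        u = {k: np.zeros(sizes[k]) for k in gnames}
        sds = {k: 0.5 * sd_prior_scale for k in gnames}
        ranef = np.zeros(n)
        for k in gnames:
            ranef += u[k][codes[k]]

        for it in range(draws):
            inv_s2 = 1.0 / sigma**2
            # --- beta | rest (conjugate normal) ---------------------------
            A = XtX * inv_s2 + prior_prec
            b = X.T @ (y - ranef) * inv_s2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)
            fixed = X @ beta

            # --- group effects | rest (conjugate normal per group) --------
            for k in gnames:
                ranef -= u[k][codes[k]]
                resid = y - fixed - ranef
                s_g = np.bincount(codes[k], weights=resid, minlength=sizes[k])
                var = 1.0 / (counts[k] * inv_s2 + 1.0 / sds[k] ** 2)
                mu_g = var * s_g * inv_s2
                u[k] = mu_g + np.sqrt(var) * rng.standard_normal(sizes[k])
                ranef += u[k][codes[k]]

            # --- residual sd: Metropolis on log sigma ---------------------
            err = y - fixed - ranef
            sse = float(err @ err)

            def logpost_sigma(s: float) -> float:
                return (
                    -n * np.log(s)
                    - 0.5 * sse / s**2
                    + _halfnormal_logpdf_term(s, sd_prior_scale)
                    + np.log(s)  # Jacobian of the log transform
                )

            prop = sigma * np.exp(proposal_scale * rng.standard_normal())
            if np.log(rng.random()) < logpost_sigma(prop) - logpost_sigma(sigma):
                sigma = prop
                accept["sigma"] += 1

            # --- group sds: Metropolis on log sd --------------------------
            for k in gnames:
                m_k = sizes[k]
                ssu = float(u[k] @ u[k])

                def logpost_sd(s: float) -> float:
                    return (
                        -m_k * np.log(s)
                        - 0.5 * ssu / s**2
                        + _halfnormal_logpdf_term(s, sd_prior_scale)
                        + np.log(s)
                    )

                prop = sds[k] * np.exp(proposal_scale * rng.standard_normal())
                if np.log(rng.random()) < logpost_sd(prop) - logpost_sd(sds[k]):
                    sds[k] = prop
                    accept[k] += 1

            if it >= burn:
                row = chain * kept + (it - burn)
                beta_out[row] = beta
                sigma_out[row] = sigma
                for k in gnames:
                    sds_out[k][row] = sds[k]

    return HierarchicalFit(
        beta=beta_out,
        sigma=sigma_out,
        group_sds=sds_out,
        accept_rates={k: v / total_steps for k, v in accept.items()},
    )
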