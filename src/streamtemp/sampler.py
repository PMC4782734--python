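"""Metropolis-within-Gibbs sampler for the hierarchical AR(1) temperature model.

Conditional on the AR coefficients, the model is linear in all regression
blocks after the quasi-differencing transform

    y~_i = y_i - delta_s * y_{prev(i)},   x~_i = x_i - delta_s * x_{prev(i)}

applied to rows whose previous day is observed, so the sampler is almost fully
conjugate:

* all regression blocks (alpha, beta1..11 and every B_y) in one joint
  multivariate normal update — the global and yearly intercepts are
  additively redundant, so blockwise updates would mix slowly
* free components of M: normal update (M[0] is fixed at 0)
* Sigma: inverse-Wishart update
* sd^2: inverse-gamma update (uniform prior on sd, truncated at 10)
* delta_s: truncated-normal update from the site's residual regression
* mu_delta, sd_delta: 1-D slice-sampling steps (the truncated-normal
  normalizer of the delta hierarchy makes these non-conjugate)

Chains are independent and seeded deterministically from (seed, chain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from .model import (
    BETA_PRIOR_SD,
    N_FIXED,
    N_YEAR,
    SD_DELTA_UPPER,
    SD_UPPER,
    WISHART_DF,
    ModelData,
    ModelError,
    Posterior,
)


@dataclass
class MCMCConfig:
    """Chain geometry (defaults mirror the original field analysis) and test constraints.

    ``fix_delta``/``fix_sd``/``no_year_effects`` freeze parts of the model for
    validation against closed-form posteriors; they are not used in ordinary
    fits.
    """

    n_chains: int = 3
    burn_in: int = 1000
    iterations: int = 2500
    thin: int = 5
    fix_delta: float | None = None
    fix_sd: float | None = None
    no_year_effects: bool = False

    @classmethod
    def reduced(cls, n_chains: int = 2, burn_in: int = 300, iterations: int = 500):
        """Desk-scale geometry for experiment batteries (thin 1)."""
        return cls(n_chains=n_chains, burn_in=burn_in, iterations=iterations, thin=1)

    @property
    def n_retained(self) -> int:
        return self.iterations // self.thin


def _trunc_normal(rng, mean, sd, lo, hi):
    """Inverse-CDF draw from N(mean, sd) truncated to (lo, hi)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(a, b)
    x = mean + sd * ndtri(u)
    return float(np.clip(x, lo + 1e-12, hi - 1e-12))


def _slice_sample(rng, x0, logf, lo, hi, w=0.3, max_steps=50):
    """Univariate slice sampler with stepping-out on a bounded support."""
    logy = logf(x0) + np.log(rng.uniform())
    left = max(lo, x0 - w * rng.uniform())
    right = min(hi, left + w)
    for _ in range(max_steps):
        if left <= lo or logf(left) < logy:
            break
        left = max(lo, left - w)
    for _ in range(max_steps):
        if right >= hi or logf(right) < logy:
            break
        right = min(hi, right + w)
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


_LOG_2PI = float(np.log(2 * np.pi))


def _delta_hier_logpdf(delta, mu, sd):
    z = (delta - mu) / sd
    ll = -0.5 * float(z @ z) - len(delta) * (np.log(sd) + 0.5 * _LOG_2PI)
    norm = ndtr((1 - mu) / sd) - ndtr((-1 - mu) / sd)
    return ll - len(delta) * np.log(max(norm, 1e-300))


def sample_posterior(data: ModelData, mcmc: MCMCConfig | None = None, seed: int = 0) -> Posterior:
    """Draw retained posterior samples for every model parameter.

    Fitting uses the observed rows of ``data`` only.  Identical
    (data, config, seed) give bit-identical output.
    """
    if mcmc is None:
        mcmc = MCMCConfig()
    obs = np.where(data.obs_mask)[0]
    if len(obs) < N_FIXED + 2:
        raise ModelError(f"too few observed rows ({len(obs)}) to fit")

    # observed-row views; remap prev_idx into the observed-row frame
    y = data.y[obs]
    Xf = data.X_fixed[obs]
    Xy = data.X_year[obs]
    site_idx = data.site_idx[obs]
    year_idx = data.year_idx[obs]
    pos = -np.ones(data.n_rows, dtype=int)
    pos[obs] = np.arange(len(obs))
    prev = np.where(data.prev_idx[obs] >= 0, pos[data.prev_idx[obs]], -1)

    n = len(y)
    S = len(data.sites)
    Y = len(data.years)
    rows_ar = np.where(prev >= 0)[0]
    prev_ar = prev[rows_ar]
    site_ar = site_idx[rows_ar]
    year_groups = [np.where(year_idx == j)[0] for j in range(Y)]
    ar_site_groups = [np.where(site_ar == s)[0] for s in range(S)]

    no_B = mcmc.no_year_effects
    n_ret = mcmc.n_retained

    out = {
        "alpha": np.empty((mcmc.n_chains, n_ret)),
        "beta": np.empty((mcmc.n_chains, n_ret, N_FIXED - 1)),
        "B": np.empty((mcmc.n_chains, n_ret, Y, N_YEAR)),
        "M": np.empty((mcmc.n_chains, n_ret, N_YEAR)),
        "Sigma": np.empty((mcmc.n_chains, n_ret, N_YEAR, N_YEAR)),
        "delta": np.empty((mcmc.n_chains, n_ret, S)),
        "mu_delta": np.empty((mcmc.n_chains, n_ret)),
        "sd_delta": np.empty((mcmc.n_chains, n_ret)),
        "sd": np.empty((mcmc.n_chains, n_ret)),
    }

    prior_prec = np.eye(N_FIXED) / BETA_PRIOR_SD**2
    I4 = np.eye(N_YEAR)
    p_all = N_FIXED + N_YEAR * Y

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([int(seed) % (2**31), chain])

        # overdispersed start: ridge fit plus prior-scale noise
        A0 = Xf.T @ Xf + np.eye(N_FIXED)
        theta = np.linalg.solve(A0, Xf.T @ y) + rng.normal(0, 0.5, N_FIXED)
        B = np.zeros((Y, N_YEAR)) if no_B else rng.normal(0, 0.5, (Y, N_YEAR))
        M = np.zeros(N_YEAR)
        Sigma = I4.copy()
        if mcmc.fix_delta is not None:
            delta = np.full(S, float(mcmc.fix_delta))
            mu_delta, sd_delta = float(mcmc.fix_delta), 0.1
        else:
            delta = rng.uniform(-0.2, 0.9, S)
            mu_delta = float(np.clip(delta.mean(), -0.95, 0.95))
            sd_delta = rng.uniform(0.1, 0.5)
        sd = float(mcmc.fix_sd) if mcmc.fix_sd is not None else rng.uniform(0.5, 2.0)

        kept = 0
        for it in range(mcmc.burn_in + mcmc.iterations):
            # quasi-differencing under current delta
            d_row = delta[site_ar]
            yt = y.copy()
            yt[rows_ar] -= d_row * y[prev_ar]
            Xft = Xf.copy()
            Xft[rows_ar] -= d_row[:, None] * Xf[prev_ar]
            Xyt = Xy.copy()
            Xyt[rows_ar] -= d_row[:, None] * Xy[prev_ar]

            if no_B:
                # fixed effects only
                A = Xft.T @ Xft / sd**2 + prior_prec
                b = Xft.T @ yt / sd**2
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
                theta = mean + np.linalg.solve(L.T, rng.standard_normal(N_FIXED))
            else:
                # joint draw of (theta, B_1..B_Y): the intercept redundancy
                # between alpha and the yearly intercepts demands it; the
                # normal matrix is assembled from its year-block structure
                P = np.linalg.inv(Sigma)
                PM = P @ M
                A = np.zeros((p_all, p_all))
                b = np.empty(p_all)
                A[:N_FIXED, :N_FIXED] = Xft.T @ Xft / sd**2 + prior_prec
                b[:N_FIXED] = Xft.T @ yt / sd**2
                for j, rows in enumerate(year_groups):
                    sl = slice(N_FIXED + N_YEAR * j, N_FIXED + N_YEAR * (j + 1))
                    Xj = Xyt[rows]
                    C = Xft[rows].T @ Xj / sd**2
                    A[:N_FIXED, sl] = C
                    A[sl, :N_FIXED] = C.T
                    A[sl, sl] = Xj.T @ Xj / sd**2 + P
                    b[sl] = Xj.T @ yt[rows] / sd**2 + PM
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
                draw = mean + np.linalg.solve(L.T, rng.standard_normal(p_all))
                theta = draw[:N_FIXED]
                B = draw[N_FIXED:].reshape(Y, N_YEAR)

            resid_f = yt - Xft @ theta
            if not no_B:
                # hyper layer (M, Sigma): several passes per sweep cost
                # nothing and decorrelate the M <-> Sigma loop
                for _ in range(3):
                    P = np.linalg.inv(Sigma)
                    Arest = Y * P[1:, 1:] + np.eye(N_YEAR - 1) / BETA_PRIOR_SD**2
                    brest = P[1:, :] @ B.sum(axis=0)
                    Lr = np.linalg.cholesky(Arest)
                    mr = np.linalg.solve(Lr.T, np.linalg.solve(Lr, brest))
                    M[1:] = mr + np.linalg.solve(Lr.T, rng.standard_normal(N_YEAR - 1))

                    # covariance of year effects
                    dev = B - M
                    scale = I4 + dev.T @ dev
                    Sigma = stats.invwishart.rvs(
                        df=WISHART_DF + Y, scale=scale, random_state=rng
                    )

            # residual sd (uniform prior on sd, truncated at SD_UPPER)
            if mcmc.fix_sd is None:
                eps = resid_f - np.einsum("ij,ij->i", Xyt, B[year_idx])
                sse = float(eps @ eps)
                for _ in range(100):
                    sd2 = (sse / 2) / rng.gamma((n - 1) / 2)
                    if sd2 < SD_UPPER**2:
                        break
                sd = float(np.sqrt(sd2))

            if mcmc.fix_delta is None:
                # site AR coefficients from the residual regression
                r_full = y - Xf @ theta - np.einsum("ij,ij->i", Xy, B[year_idx])
                a = r_full[prev_ar]
                bb = r_full[rows_ar]
                for s, g in enumerate(ar_site_groups):
                    if len(g) == 0:
                        delta[s] = _trunc_normal(rng, mu_delta, sd_delta, -1, 1)
                        continue
                    prec = a[g] @ a[g] / sd**2 + 1 / sd_delta**2
                    mm = (a[g] @ bb[g] / sd**2 + mu_delta / sd_delta**2) / prec
                    delta[s] = _trunc_normal(rng, mm, 1 / np.sqrt(prec), -1, 1)

                # AR hyper layer: alternate slice steps several times per
                # sweep (the two are tightly coupled given only a few sites)
                for _ in range(3):
                    mu_delta = _slice_sample(
                        rng, mu_delta,
                        lambda m: _delta_hier_logpdf(delta, m, sd_delta),
                        -1.0, 1.0,
                    )
                    sd_delta = _slice_sample(
                        rng, sd_delta,
                        lambda v: _delta_hier_logpdf(delta, mu_delta, v),
                        1e-4, SD_DELTA_UPPER,
                    )

            it_eval = it - mcmc.burn_in
            if it_eval >= 0 and (it_eval + 1) % mcmc.thin == 0 and kept < n_ret:
                out["alpha"][chain, kept] = theta[0]
                out["beta"][chain, kept] = theta[1:]
                out["B"][chain, kept] = B
                out["M"][chain, kept] = M
                out["Sigma"][chain, kept] = Sigma
                out["delta"][chain, kept] = delta
                out["mu_delta"][chain, kept] = mu_delta
                out["sd_delta"][chain, kept] = sd_delta
                out["sd"][chain, kept] = sd
                kept += 1

    return Posterior(
        samples=out,
        sites=data.sites,
        years=data.years,
        std=data.std,
        n_chains=mcmc.n_chains,
        burn_in=mcmc.burn_in,
        iterations=mcmc.iterations,
        thin=mcmc.thin,
        seed=int(seed),
    )
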