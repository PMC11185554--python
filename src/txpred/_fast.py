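"""Numba inner loops for the coordinate-wise samplers and variational passes.

These kernels are deliberately dumb: single-site sweeps with explicit
residual updates, seeded through numba's internal RNG so that a fit is
bit-reproducible given (data, schedule, seed). All model logic
(hyperparameter calibration, summaries, convergence checks) lives in the
calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["spike_slab_gibbs", "vb_spike_slab_pass", "mixture_pass"]


@njit(cache=True)
def spike_slab_gibbs(
    X,
    y,
    group,
    n_groups,
    n_iter,
    burn_in,
    thin,
    df_b,
    S_b,
    df_e,
    S_e,
    a_pi,
    b_pi,
    pi_init,
    fix_pi,
    sb2_init,
    se2_init,
    fix_var,
    seed,
):
    """Single-site Gibbs sampler for (grouped) spike-and-slab regression.

    Every gene j carries an inclusion indicator and an effect; groups have
    their own (pi, slab variance) pairs with Beta / scaled-inverse-chi^2
    full conditionals. Returns posterior-mean accumulators and
    variance-component traces over the retained draws.
    """
    np.random.seed(seed)
    n, m = X.shape
    d = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        d[j] = s

    beta = np.zeros(m)
    r = y.copy()
    sb2 = sb2_init.copy()
    se2 = se2_init
    pi = pi_init.copy()

    n_ret = (n_iter - burn_in) // thin
    effect_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    sb2_trace = np.zeros((n_ret, n_groups))
    se2_trace = np.zeros(n_ret)
    pi_trace = np.zeros((n_ret, n_groups))
    gvar_trace = np.zeros((n_ret, n_groups))
    ret = 0

    k_incl = np.zeros(n_groups, dtype=np.int64)
    ssb = np.zeros(n_groups)
    m_per_group = np.zeros(n_groups, dtype=np.int64)
    for j in range(m):
        m_per_group[group[j]] += 1

    for it in range(n_iter):
        for g in range(n_groups):
            k_incl[g] = 0
            ssb[g] = 0.0
        for j in range(m):
            g = group[j]
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * bj
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * r[i]
            c = d[j] / se2 + 1.0 / sb2[g]
            mu = rhs / (se2 * c)
            if pi[g] >= 1.0:
                p_incl = 1.0
            elif pi[g] <= 0.0:
                p_incl = 0.0
            else:
                logodds = (
                    np.log(pi[g] / (1.0 - pi[g]))
                    - 0.5 * np.log(sb2[g] * c)
                    + 0.5 * mu * mu * c
                )
                if logodds > 35.0:
                    p_incl = 1.0
                elif logodds < -35.0:
                    p_incl = 0.0
                else:
                    p_incl = 1.0 / (1.0 + np.exp(-logodds))
            if np.random.random() < p_incl:
                bnew = mu + np.random.standard_normal() / np.sqrt(c)
                beta[j] = bnew
                k_incl[g] += 1
                ssb[g] += bnew * bnew
                for i in range(n):
                    r[i] -= X[i, j] * bnew
            else:
                beta[j] = 0.0

        if not fix_var:
            for g in range(n_groups):
                sb2[g] = (S_b[g] + ssb[g]) / np.random.chisquare(df_b + k_incl[g])
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            se2 = (S_e + sse) / np.random.chisquare(df_e + n)
        if not fix_pi:
            for g in range(n_groups):
                pi[g] = np.random.beta(
                    a_pi[g] + k_incl[g], b_pi[g] + m_per_group[g] - k_incl[g]
                )

        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            for j in range(m):
                effect_sum[j] += beta[j]
                if beta[j] != 0.0:
                    incl_sum[j] += 1.0
            sb2_trace[ret] = sb2
            se2_trace[ret] = se2
            pi_trace[ret] = pi
            # realized genetic variance per group for this draw
            for g in range(n_groups):
                gv = np.zeros(n)
                for j in range(m):
                    if group[j] == g and beta[j] != 0.0:
                        for i in range(n):
                            gv[i] += X[i, j] * beta[j]
                mean = 0.0
                for i in range(n):
                    mean += gv[i]
                mean /= n
                v = 0.0
                for i in range(n):
                    v += (gv[i] - mean) ** 2
                gvar_trace[ret, g] = v / (n - 1)
            ret += 1

    return effect_sum, incl_sum, sb2_trace, se2_trace, pi_trace, gvar_trace, ret


@njit(cache=True)
def vb_spike_slab_pass(X, d, y, Xr, alpha, mu, s2, sigma2, sa2, logodds_nat):
    """One coordinate-ascent sweep of the mean-field spike-and-slab update.

    ``Xr`` is maintained as X @ (alpha * mu); ``logodds_nat`` is the prior
    log odds of inclusion in natural log units. Updates alpha, mu, s2 and
    Xr in place.
    """
    n, m = X.shape
    for j in range(m):
        s2_j = sigma2 / (d[j] + 1.0 / sa2)
        rj = alpha[j] * mu[j]
        dot = 0.0
        for i in range(n):
            dot += X[i, j] * (y[i] - Xr[i])
        dot += d[j] * rj
        mu_j = s2_j * dot / sigma2
        lo = (
            logodds_nat
            + 0.5 * np.log(s2_j / (sigma2 * sa2))
            + 0.5 * mu_j * mu_j / s2_j
        )
        if lo > 35.0:
            a_j = 1.0
        elif lo < -35.0:
            a_j = 0.0
        else:
            a_j = 1.0 / (1.0 + np.exp(-lo))
        diff = a_j * mu_j - rj
        if diff != 0.0:
            for i in range(n):
                Xr[i] += X[i, j] * diff
        alpha[j] = a_j
        mu[j] = mu_j
        s2[j] = s2_j


@njit(cache=True)
def mixture_pass(
    X, d, y, Xr, b, post_m2, resp, mu_mat, s2_mat, pi, grid_var, sigma2, update_b
):
    """One coordinate-ascent sweep of the mixture-of-normals (VEB) update.

    For each gene the exact single-coordinate posterior under the current
    mixture prior is computed from the residualized OLS estimate; ``b``
    holds posterior-mean effects, ``post_m2`` the posterior second moments,
    ``resp`` the per-gene component responsibilities, and ``mu_mat`` /
    ``s2_mat`` the per-component posterior moments (needed to evaluate the
    ELBO at exactly this variational state). ``Xr`` is maintained as X @ b.
    """
    n, m = X.shape
    K1 = grid_var.shape[0]  # components including the null spike
    logpi = np.empty(K1)
    for k in range(K1):
        logpi[k] = np.log(pi[k]) if pi[k] > 0.0 else -np.inf
    for j in range(m):
        if d[j] <= 0.0:
            continue
        bj = b[j]
        dot = 0.0
        for i in range(n):
            dot += X[i, j] * (y[i] - Xr[i])
        bhat = (dot + d[j] * bj) / d[j]
        v_lik = sigma2 / d[j]
        # log marginal of bhat under each component
        lw = np.empty(K1)
        for k in range(K1):
            v = grid_var[k] + v_lik
            lw[k] = logpi[k] - 0.5 * np.log(2.0 * np.pi * v) - 0.5 * bhat * bhat / v
        mx = lw[0]
        for k in range(1, K1):
            if lw[k] > mx:
                mx = lw[k]
        tot = 0.0
        for k in range(K1):
            lw[k] = np.exp(lw[k] - mx)
            tot += lw[k]
        bnew = 0.0
        m2 = 0.0
        for k in range(K1):
            phi = lw[k] / tot
            resp[j, k] = phi
            if grid_var[k] > 0.0:
                shrink = grid_var[k] / (grid_var[k] + v_lik)
                mu_k = shrink * bhat
                s2_k = shrink * v_lik
                mu_mat[j, k] = mu_k
                s2_mat[j, k] = s2_k
                bnew += phi * mu_k
                m2 += phi * (mu_k * mu_k + s2_k)
            else:
                mu_mat[j, k] = 0.0
                s2_mat[j, k] = 0.0
        post_m2[j] = m2
        if update_b:
            diff = bnew - bj
            if diff != 0.0:
                for i in range(n):
                    Xr[i] += X[i, j] * diff
            b[j] = bnew
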