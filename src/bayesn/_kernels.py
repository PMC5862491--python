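"""Numba-compiled Gibbs sweep kernels.

Same mathematics as the reference updates in ``bayesn.samplers``, written
as tight loops over preallocated arrays. The kernels use numba's internal
legacy RNG, seeded once per chain via :func:`seed_kernel_rng`; all other
draws (variances, mean, pi/Pi) happen on the Python side from a separate
seeded Generator, so a chain is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOGIT_CAP = 35.0


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _col_dot(Z, j, v):
    acc = 0.0
    for i in range(Z.shape[0]):
        acc += Z[i, j] * v[i]
    return acc


@njit(cache=True, inline="always")
def _axpy_col(Z, j, c, v):
    for i in range(Z.shape[0]):
        v[i] += Z[i, j] * c


@njit(cache=True, inline="always")
def _draw_logit(logit):
    if logit > _LOGIT_CAP:
        return 1
    if logit < -_LOGIT_CAP:
        return 0
    p1 = 1.0 / (1.0 + np.exp(-logit))
    return 1 if np.random.random() < p1 else 0


@njit(cache=True, inline="always")
def _locus_step(Z, zz, ycorr, alpha, delta, j, prior_lo, slab_var, sigma2_e):
    """Single-site (delta_j, alpha_j) draw; returns nothing, mutates state."""
    u_old = alpha[j] * delta[j]
    if zz[j] <= 0.0:
        delta[j] = 0
        alpha[j] = np.sqrt(slab_var) * np.random.randn()
        if u_old != 0.0:
            _axpy_col(Z, j, u_old, ycorr)
        return
    rhs = _col_dot(Z, j, ycorr) + zz[j] * u_old
    v = zz[j] * slab_var + sigma2_e
    log_bf = 0.5 * (np.log(sigma2_e / v) + rhs * rhs * slab_var / (sigma2_e * v))
    d = _draw_logit(prior_lo + log_bf)
    if d == 1:
        mean = rhs * slab_var / v
        a_new = mean + np.sqrt(sigma2_e * slab_var / v) * np.random.randn()
        u_new = a_new
    else:
        a_new = np.sqrt(slab_var) * np.random.randn()
        u_new = 0.0
    diff = u_old - u_new
    if diff != 0.0:
        _axpy_col(Z, j, diff, ycorr)
    alpha[j] = a_new
    delta[j] = d


@njit(cache=True, inline="always")
def _prior_logodds(pi):
    if pi <= 0.0:
        return _LOGIT_CAP + 1.0
    if pi >= 1.0:
        return -_LOGIT_CAP - 1.0
    return np.log((1.0 - pi) / pi)


@njit(cache=True)
def bayesb_sweep(Z, zz, ycorr, alpha, delta, slab_var, pi, sigma2_e):
    """One systematic scan of single-site updates (BayesB/BayesC).

    ``slab_var`` is per-locus (BayesB sigma_j^2) or a constant-filled array
    (BayesC sigma_alpha^2).
    """
    prior_lo = _prior_logodds(pi)
    for j in range(Z.shape[1]):
        _locus_step(Z, zz, ycorr, alpha, delta, j, prior_lo, slab_var[j], sigma2_e)


@njit(cache=True)
def bayesn_sweep(
    Z, zz, ycorr, alpha, delta, Delta, offsets, pi_i, Pi, slab_var_win, sigma2_e, rbuf
):
    """One scan of partially-collapsed window updates (BayesN/BayesNC).

    Per window: Delta_i drawn with the included effects integrated out
    (closed-form multivariate normal marginal over the delta=1 subset);
    included effects redrawn jointly, excluded from the prior; then
    single-site sweeps within in-model windows. ``rbuf`` is an n-length
    scratch vector. ``slab_var_win`` is per-window (BayesN) or
    constant-filled (BayesNC).
    """
    n = Z.shape[0]
    Pi_lo = _prior_logodds(Pi)
    for i in range(len(offsets) - 1):
        o0 = offsets[i]
        o1 = offsets[i + 1]
        if o1 <= o0:
            continue
        s2 = slab_var_win[i]
        # collect included members
        m_s = 0
        for j in range(o0, o1):
            if delta[j] == 1:
                m_s += 1
        S = np.empty(m_s, dtype=np.int64)
        c = 0
        for j in range(o0, o1):
            if delta[j] == 1:
                S[c] = j
                c += 1
        # r = ycorr + current window fit
        for t in range(n):
            rbuf[t] = ycorr[t]
        if Delta[i] == 1:
            for c in range(m_s):
                _axpy_col(Z, S[c], alpha[S[c]], rbuf)
        L = np.empty((0, 0))
        x = np.empty(0)
        if m_s > 0:
            G = np.empty((m_s, m_s))
            rhs = np.empty(m_s)
            for a in range(m_s):
                rhs[a] = _col_dot(Z, S[a], rbuf)
                for b in range(a, m_s):
                    acc = 0.0
                    for t in range(n):
                        acc += Z[t, S[a]] * Z[t, S[b]]
                    G[a, b] = acc
                    G[b, a] = acc
            lam = sigma2_e / s2
            for a in range(m_s):
                G[a, a] += lam
            L = np.linalg.cholesky(G)
            # solve L q = rhs (forward), L' x = q (backward)
            q = np.empty(m_s)
            for a in range(m_s):
                acc = rhs[a]
                for b in range(a):
                    acc -= L[a, b] * q[b]
                q[a] = acc / L[a, a]
            x = np.empty(m_s)
            for a in range(m_s - 1, -1, -1):
                acc = q[a]
                for b in range(a + 1, m_s):
                    acc -= L[b, a] * x[b]
                x[a] = acc / L[a, a]
            logdet = 0.0
            for a in range(m_s):
                logdet += 2.0 * np.log(L[a, a])
            quad = 0.0
            for a in range(m_s):
                quad += rhs[a] * x[a]
            log_bf = (
                -0.5 * (m_s * np.log(s2 / sigma2_e) + logdet)
                + 0.5 * quad / sigma2_e
            )
        else:
            log_bf = 0.0
        d_new = _draw_logit(Pi_lo + log_bf)
        Delta[i] = d_new
        if d_new == 1:
            if m_s > 0:
                # alpha_S = x + sqrt(sigma2_e) * solve(L', z)
                zvec = np.empty(m_s)
                for a in range(m_s):
                    zvec[a] = np.random.randn()
                qv = np.empty(m_s)
                for a in range(m_s - 1, -1, -1):
                    acc = zvec[a]
                    for b in range(a + 1, m_s):
                        acc -= L[b, a] * qv[b]
                    qv[a] = acc / L[a, a]
                se = np.sqrt(sigma2_e)
                for t in range(n):
                    ycorr[t] = rbuf[t]
                for a in range(m_s):
                    anew = x[a] + se * qv[a]
                    alpha[S[a]] = anew
                    _axpy_col(Z, S[a], -anew, ycorr)
            else:
                for t in range(n):
                    ycorr[t] = rbuf[t]
            ssd = np.sqrt(s2)
            for j in range(o0, o1):
                if delta[j] == 0:
                    alpha[j] = ssd * np.random.randn()
            prior_lo = _prior_logodds(pi_i[i])
            for j in range(o0, o1):
                _locus_step(Z, zz, ycorr, alpha, delta, j, prior_lo, s2, sigma2_e)
        else:
            for t in range(n):
                ycorr[t] = rbuf[t]
            ssd = np.sqrt(s2)
            p_in = 1.0 - pi_i[i]
            for j in range(o0, o1):
                alpha[j] = ssd * np.random.randn()
                delta[j] = 1 if np.random.random() < p_in else 0


@njit(cache=True)
def ante_sweep(
    Z,
    zz,
    ycorr,
    alpha,
    delta,
    t_coef,
    lambda_t,
    lambda_gamma,
    first_of_chrom,
    pi,
    sigma2_e,
    update_t,
):
    """One antedependence scan in chromosome order, then the t-coefficients.

    alpha_j = t_j alpha_{j-1} + gamma_j; the (delta_j, alpha_j) odds
    integrate gamma_j out and carry the downstream alpha_{j+1} conditional.
    """
    m = Z.shape[1]
    prior_lo = _prior_logodds(pi)
    for j in range(m):
        lam_j = lambda_gamma[j]
        if first_of_chrom[j]:
            prior_mean = 0.0
        else:
            prior_mean = t_coef[j] * alpha[j - 1]
        P0 = 1.0 / lam_j
        b0 = prior_mean / lam_j
        if j + 1 < m and not first_of_chrom[j + 1]:
            tn = t_coef[j + 1]
            ln = lambda_gamma[j + 1]
            P0 += tn * tn / ln
            b0 += tn * alpha[j + 1] / ln
        u_old = alpha[j] * delta[j]
        if zz[j] > 0.0:
            rhs = _col_dot(Z, j, ycorr) + zz[j] * u_old
            P1 = P0 + zz[j] / sigma2_e
            b1 = b0 + rhs / sigma2_e
        else:
            P1 = P0
            b1 = b0
        logit = (
            prior_lo
            + 0.5 * (b1 * b1 / P1 - b0 * b0 / P0)
            - 0.5 * np.log(P1 / P0)
        )
        d = _draw_logit(logit)
        if d == 1:
            a_new = b1 / P1 + np.random.randn() / np.sqrt(P1)
        else:
            a_new = b0 / P0 + np.random.randn() / np.sqrt(P0)
        u_new = a_new * d
        diff = u_old - u_new
        if diff != 0.0:
            _axpy_col(Z, j, diff, ycorr)
        alpha[j] = a_new
        delta[j] = d
    if update_t:
        for j in range(m):
            if first_of_chrom[j]:
                continue
            a_prev = alpha[j - 1]
            P = a_prev * a_prev / lambda_gamma[j] + 1.0 / lambda_t[j]
            b = a_prev * alpha[j] / lambda_gamma[j]
            t_coef[j] = b / P + np.random.randn() / np.sqrt(P)
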