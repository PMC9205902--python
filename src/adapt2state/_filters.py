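"""Numba kernels: exact marginal likelihoods and Metropolis sweeps.

The observation model is y(n) = C x(n) + eps_u with C = [1, 1] (two-state)
or C = 1 (single-state); the state update x(n+1) = A x(n) + B e(n) + eps_x
uses the *observed* error e(n) = p(n) - y(n), so conditioning on the data
turns the dynamics into a linear-Gaussian system with a known exogenous
input and the marginal likelihood factorises through a standard Kalman
filter.  States start at x(1) = 0 exactly (zero initial covariance).

All kernels are scalar-loop implementations so numba compiles them to tight
machine code; they are wrapped with validation in the public modules.
"""

import numpy as np
from numba import njit

_LOG2PI = 1.8378770664093453


@njit(cache=True)
def loglik_two(a_s, a_f, b_s, b_f, sx, su, y, p, pointwise):
    """Marginal log-likelihood of a two-state run; fills `pointwise` (len N)."""
    n_steps = y.shape[0]
    m1 = 0.0
    m2 = 0.0
    p11 = 0.0
    p12 = 0.0
    p22 = 0.0
    vx = sx * sx
    vu = su * su
    total = 0.0
    for n in range(n_steps):
        s_pred = p11 + 2.0 * p12 + p22 + vu
        if s_pred <= 0.0:
            return -np.inf
        resid = y[n] - (m1 + m2)
        term = -0.5 * (_LOG2PI + np.log(s_pred) + resid * resid / s_pred)
        pointwise[n] = term
        total += term
        c1 = p11 + p12
        c2 = p12 + p22
        k1 = c1 / s_pred
        k2 = c2 / s_pred
        m1p = m1 + k1 * resid
        m2p = m2 + k2 * resid
        p11p = p11 - k1 * c1
        p12p = p12 - k1 * c2
        p22p = p22 - k2 * c2
        err = p[n] - y[n]
        m1 = a_s * m1p + b_s * err
        m2 = a_f * m2p + b_f * err
        p11 = a_s * a_s * p11p + vx
        p12 = a_s * a_f * p12p
        p22 = a_f * a_f * p22p + vx
    return total


@njit(cache=True)
def loglik_one(a, b, sx, su, y, p, pointwise):
    """Marginal log-likelihood of a single-state run."""
    n_steps = y.shape[0]
    m = 0.0
    pv = 0.0
    vx = sx * sx
    vu = su * su
    total = 0.0
    for n in range(n_steps):
        s_pred = pv + vu
        if s_pred <= 0.0:
            return -np.inf
        resid = y[n] - m
        term = -0.5 * (_LOG2PI + np.log(s_pred) + resid * resid / s_pred)
        pointwise[n] = term
        total += term
        k = pv / s_pred
        mp = m + k * resid
        pvp = pv - k * pv
        err = p[n] - y[n]
        m = a * mp + b * err
        pv = a * a * pvp + vx
    return total


@njit(cache=True)
def _ok_two(th):
    return (
        th[0] > th[1]
        and th[1] > 0.0
        and th[3] > th[2]
        and th[2] > 0.0
        and th[4] > 0.0
        and th[5] > 0.0
    )


@njit(cache=True)
def _ok_one(th):
    return th[0] > 0.0 and th[1] > 0.0 and th[2] > 0.0 and th[3] > 0.0


@njit(cache=True)
def _logprior_delta(k, prop, old, mu_jk, sd_k, noise_cauchy, cauchy_scale, n_learn):
    """Log prior ratio for one component under the conditional prior.

    Components < n_learn get normal(mu, sd); noise components get either the
    same (hierarchical case) or half-Cauchy(0, scale) (per-run fits).
    """
    if noise_cauchy and k >= n_learn:
        r_new = prop / cauchy_scale
        r_old = old / cauchy_scale
        return -np.log1p(r_new * r_new) + np.log1p(r_old * r_old)
    d_new = (prop - mu_jk) / sd_k
    d_old = (old - mu_jk) / sd_k
    return -0.5 * (d_new * d_new - d_old * d_old)


@njit(cache=True)
def sweep(theta, cur_ll, y, p, mu, sd, noise_cauchy, cauchy_scale,
          scales, z, u, acc, two_state, scratch):
    """One component-wise Metropolis sweep over every run and parameter.

    theta : (R, K) current subject-level parameters, updated in place
    cur_ll: (R,) current marginal log-likelihoods, updated in place
    mu    : (R, K) conditional prior means (population means mapped per run)
    sd    : (K,) conditional prior SDs
    z, u  : (R, K) standard-normal increments / uniforms for this sweep
    acc   : (R, K) int64 acceptance counters
    """
    n_runs, n_par = theta.shape
    n_learn = 4 if two_state else 2
    for j in range(n_runs):
        for k in range(n_par):
            old = theta[j, k]
            prop = old + scales[j, k] * z[j, k]
            theta[j, k] = prop
            if two_state:
                ok = _ok_two(theta[j])
            else:
                ok = _ok_one(theta[j])
            if not ok:
                theta[j, k] = old
                continue
            if two_state:
                new_ll = loglik_two(theta[j, 0], theta[j, 1], theta[j, 2],
                                    theta[j, 3], theta[j, 4], theta[j, 5],
                                    y[j], p, scratch)
            else:
                new_ll = loglik_one(theta[j, 0], theta[j, 1], theta[j, 2],
                                    theta[j, 3], y[j], p, scratch)
            lp = _logprior_delta(k, prop, old, mu[j, k], sd[k], noise_cauchy,
                                 cauchy_scale[k - n_learn] if k >= n_learn else 0.0,
                                 n_learn)
            if np.log(u[j, k]) < new_ll - cur_ll[j] + lp:
                cur_ll[j] = new_ll
                acc[j, k] += 1
            else:
                theta[j, k] = old


@njit(cache=True)
def joint_sweep(theta, cur_ll, y, p, mu, sd, noise_cauchy, cauchy_scale,
                chol, z, u, acc, two_state, scratch):
    """One joint Metropolis update per run using an adapted covariance.

    chol : (R, K, K) lower Cholesky factors of the scaled proposal covariance
    z    : (R, K) standard normals; u : (R,) uniforms; acc : (R,) counters
    """
    n_runs, n_par = theta.shape
    n_learn = 4 if two_state else 2
    step = np.empty(n_par)
    for j in range(n_runs):
        for k in range(n_par):
            acc_v = 0.0
            for m in range(k + 1):
                acc_v += chol[j, k, m] * z[j, m]
            step[k] = acc_v
        old = theta[j].copy()
        for k in range(n_par):
            theta[j, k] = old[k] + step[k]
        if two_state:
            ok = _ok_two(theta[j])
        else:
            ok = _ok_one(theta[j])
        if not ok:
            theta[j] = old
            continue
        if two_state:
            new_ll = loglik_two(theta[j, 0], theta[j, 1], theta[j, 2],
                                theta[j, 3], theta[j, 4], theta[j, 5],
                                y[j], p, scratch)
        else:
            new_ll = loglik_one(theta[j, 0], theta[j, 1], theta[j, 2],
                                theta[j, 3], y[j], p, scratch)
        lp = 0.0
        for k in range(n_par):
            lp += _logprior_delta(k, theta[j, k], old[k], mu[j, k], sd[k],
                                  noise_cauchy,
                                  cauchy_scale[k - n_learn] if k >= n_learn else 0.0,
                                  n_learn)
        if np.log(u[j]) < new_ll - cur_ll[j] + lp:
            cur_ll[j] = new_ll
            acc[j] += 1
        else:
            theta[j] = old


@njit(cache=True)
def pointwise_batch(theta, y, p, out, two_state):
    """Fill out (R, N) with pointwise one-step-ahead log-likelihood terms."""
    n_runs = theta.shape[0]
    for j in range(n_runs):
        if two_state:
            loglik_two(theta[j, 0], theta[j, 1], theta[j, 2], theta[j, 3],
                       theta[j, 4], theta[j, 5], y[j], p, out[j])
        else:
            loglik_one(theta[j, 0], theta[j, 1], theta[j, 2], theta[j, 3],
                       y[j], p, out[j])
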