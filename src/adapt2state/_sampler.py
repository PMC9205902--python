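"""Seeded MCMC engine for the (hierarchical) state-space adaptation models.

Subject-level parameters are updated by component-wise adaptive Metropolis
sweeps plus one joint Metropolis move per iteration whose proposal
covariance is adapted during warmup (Haario-style), both evaluated against
the exact Kalman-filter marginal likelihood (hidden states are never
sampled).  Population hyper-parameters are updated by univariate slice
sampling of their conditional posteriors.  Ordering constraints
(a_s > a_f > 0, b_f > b_s > 0, positive noise scales) are enforced by
proposal rejection, so every retained draw satisfies them exactly.

All randomness flows from one numpy SeedSequence per fit, split per chain;
identical inputs give bit-identical draws.
"""

from __future__ import annotations

import numpy as np

from . import _filters

TWO_STATE_NAMES = ("a_s", "a_f", "b_s", "b_f", "sigma_x", "sigma_u")
ONE_STATE_NAMES = ("a", "b", "sigma_x", "sigma_u")

_INIT_SCALES = {
    True: np.array([0.03, 0.10, 0.02, 0.05, 0.20, 0.40]),
    False: np.array([0.05, 0.05, 0.20, 0.40]),
}


def slice_sample(logf, x0, rng, w=1.0, lower=-np.inf, upper=np.inf, max_out=50):
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logf(x0) - rng.exponential()
    u = rng.random()
    lo = x0 - w * u
    hi = lo + w
    j = int(np.floor(rng.random() * max_out))
    k = max_out - 1 - j
    while j > 0 and lo > lower and logf(lo) > logy:
        lo -= w
        j -= 1
    while k > 0 and hi < upper and logf(hi) > logy:
        hi += w
        k -= 1
    lo = max(lo, lower)
    hi = min(hi, upper)
    for _ in range(200):
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _log_half_cauchy(x, scale):
    return -np.log1p((x / scale) ** 2)


def _init_theta(y_mat, rng, two_state, init_theta=None):
    """Constraint-valid starting values with per-chain jitter.

    ``init_theta`` (R, K), when given, supplies per-run point estimates
    (e.g. from a quick EM pass) so every chain starts in its run's own
    likelihood region; otherwise a shared heuristic is used.
    """
    n_runs = y_mat.shape[0]
    if init_theta is not None:
        theta = np.array(init_theta, dtype=float, copy=True)
        ok = _filters._ok_two if two_state else _filters._ok_one
        for j in range(n_runs):
            for _ in range(20):
                cand = theta[j] * (1.0 + 0.04 * (rng.random(theta.shape[1]) - 0.5))
                if ok(cand):
                    theta[j] = cand
                    break
        return theta
    resid_sd = np.maximum(np.std(np.diff(y_mat, axis=1), axis=1) / np.sqrt(2.0), 0.5)
    if two_state:
        base = np.array([0.90, 0.50, 0.05, 0.15])
        theta = np.empty((n_runs, 6))
        theta[:, :4] = base * (1.0 + 0.1 * (rng.random((n_runs, 4)) - 0.5))
        theta[:, 4] = 1.0 * (1.0 + 0.2 * (rng.random(n_runs) - 0.5))
        theta[:, 5] = resid_sd * (1.0 + 0.2 * (rng.random(n_runs) - 0.5))
    else:
        base = np.array([0.80, 0.15])
        theta = np.empty((n_runs, 4))
        theta[:, :2] = base * (1.0 + 0.1 * (rng.random((n_runs, 2)) - 0.5))
        theta[:, 2] = 1.0 * (1.0 + 0.2 * (rng.random(n_runs) - 0.5))
        theta[:, 3] = resid_sd * (1.0 + 0.2 * (rng.random(n_runs) - 0.5))
    return theta


def _prior_mu_sd(priors, two_state, n_runs, n_planes):
    """Fixed-prior (mu, sd, cauchy scales) arrays for the non-hierarchical case."""
    if two_state:
        mu = np.array([priors.retention_mean[0]] * 2 + [priors.learning_mean[0]] * 2
                      + [0.0, 0.0])
        sd = np.array([priors.retention_mean[1]] * 2 + [priors.learning_mean[1]] * 2
                      + [1.0, 1.0])
    else:
        mu = np.array([priors.retention_mean[0], priors.learning_mean[0], 0.0, 0.0])
        sd = np.array([priors.retention_mean[1], priors.learning_mean[1], 1.0, 1.0])
    return np.tile(mu, (n_runs, 1)), sd


def _hyper_init(theta, plane_idx, n_planes, two_state):
    n_par = theta.shape[1]
    mu = np.empty((n_planes, n_par))
    for pl in range(n_planes):
        mu[pl] = theta[plane_idx == pl].mean(axis=0)
    if two_state:
        sd = np.array([0.05, 0.15, 0.04, 0.08, 0.5, 1.0])
    else:
        sd = np.array([0.10, 0.08, 0.5, 1.0])
    return mu, sd


def _update_hypers(theta, plane_idx, n_planes, hyper_mu, hyper_sd, priors,
                   two_state, rng):
    """Slice-sample population means and SDs given subject-level values."""
    n_par = theta.shape[1]
    n_learn = 4 if two_state else 2
    for k in range(n_par):
        sd_k = hyper_sd[k]
        for pl in range(n_planes):
            v = theta[plane_idx == pl, k]
            if len(v) == 0:
                continue
            n_v, s_v = len(v), v.sum()

            if k < n_learn:
                pm, ps = (priors.retention_mean if k < n_learn // 2
                          else priors.learning_mean)

                def logf(m, n_v=n_v, s_v=s_v, v=v, sd_k=sd_k, pm=pm, ps=ps):
                    return (-0.5 * np.sum((v - m) ** 2) / sd_k ** 2
                            - 0.5 * ((m - pm) / ps) ** 2)

                hyper_mu[pl, k] = slice_sample(
                    logf, hyper_mu[pl, k], rng, w=max(0.05, sd_k))
            else:
                scale = priors.noise_scale

                def logf(m, v=v, sd_k=sd_k, scale=scale):
                    return (-0.5 * np.sum((v - m) ** 2) / sd_k ** 2
                            + _log_half_cauchy(m, scale))

                hyper_mu[pl, k] = slice_sample(
                    logf, hyper_mu[pl, k], rng, w=max(0.05, sd_k), lower=1e-12)
        # shared-across-planes population SD
        resid2 = np.sum((theta[:, k] - hyper_mu[plane_idx, k]) ** 2)
        n_all = theta.shape[0]
        scale = priors.learning_sd_scale if k < n_learn else priors.noise_scale

        def logf_sd(s, resid2=resid2, n_all=n_all, scale=scale):
            return (-n_all * np.log(s) - 0.5 * resid2 / s ** 2
                    + _log_half_cauchy(s, scale))

        hyper_sd[k] = slice_sample(logf_sd, hyper_sd[k], rng,
                                   w=max(0.05, hyper_sd[k]), lower=1e-9)


def _theta_ok(row, two_state):
    return bool(_filters._ok_two(row) if two_state else _filters._ok_one(row))


def _batch_loglik(theta, y_mat, p, two_state, out):
    _filters.pointwise_batch(theta, y_mat, p, out, two_state)
    return out.sum(axis=1)


def _group_moves(theta, cur_ll, y_mat, p, plane_idx, n_planes, hyper_mu,
                 hyper_sd, priors, two_state, rng):
    """Joint translate/scale Metropolis moves over (hyper, subject values).

    The centred hierarchy mixes poorly when a population SD is small (the
    'funnel'): subject values pin the mean, and the mean pins the values.
    Translating a plane's values together with its population mean, and
    rescaling deviations together with the population SD, moves through
    the funnel in one step.  Both moves are exact Metropolis updates (the
    scale move carries its c^(R+1) Jacobian).
    """
    n_par = theta.shape[1]
    n_learn = 4 if two_state else 2
    for k in range(n_par):
        # --- translate: (v_j)_{j in plane} and mu[plane, k] shift together
        for pl in range(n_planes):
            idx = np.where(plane_idx == pl)[0]
            if len(idx) == 0:
                continue
            step = 2.4 * max(hyper_sd[k], 1e-3) / np.sqrt(len(idx))
            delta = rng.normal(0.0, step)
            mu_new = hyper_mu[pl, k] + delta
            if k >= n_learn and mu_new <= 0:
                continue
            prop = theta[idx].copy()
            prop[:, k] += delta
            if not all(_theta_ok(prop[j], two_state) for j in range(len(idx))):
                continue
            if k < n_learn:
                pm, ps = (priors.retention_mean if k < n_learn // 2
                          else priors.learning_mean)
                dprior = (-0.5 * ((mu_new - pm) / ps) ** 2
                          + 0.5 * ((hyper_mu[pl, k] - pm) / ps) ** 2)
            else:
                dprior = (_log_half_cauchy(mu_new, priors.noise_scale)
                          - _log_half_cauchy(hyper_mu[pl, k], priors.noise_scale))
            scratch = np.empty((len(idx), y_mat.shape[1]))
            ll_new = _batch_loglik(prop, y_mat[idx], p, two_state, scratch)
            if np.log(rng.random()) < ll_new.sum() - cur_ll[idx].sum() + dprior:
                theta[idx] = prop
                cur_ll[idx] = ll_new
                hyper_mu[pl, k] = mu_new
        # --- scale: deviations and the population SD rescale together
        c = np.exp(rng.normal(0.0, 0.25))
        sd_new = c * hyper_sd[k]
        prop = theta.copy()
        mus = hyper_mu[plane_idx, k]
        prop[:, k] = mus + c * (theta[:, k] - mus)
        if not all(_theta_ok(prop[j], two_state) for j in range(theta.shape[0])):
            continue
        scale = priors.learning_sd_scale if k < n_learn else priors.noise_scale
        scratch = np.empty_like(y_mat)
        ll_new = _batch_loglik(prop, y_mat, p, two_state, scratch)
        log_acc = (ll_new.sum() - cur_ll.sum()
                   + _log_half_cauchy(sd_new, scale)
                   - _log_half_cauchy(hyper_sd[k], scale)
                   + np.log(c))
        if np.log(rng.random()) < log_acc:
            theta[:, :] = prop
            cur_ll[:] = ll_new
            hyper_sd[k] = sd_new


def _gain_from_theta(theta, two_state):
    vx = theta[:, -2] ** 2
    vu = theta[:, -1] ** 2
    v_plus = 0.5 * (-vx + np.sqrt(vx ** 2 + 4.0 * vx * vu))
    return (v_plus + vx) / (v_plus + vu + vx)


def run_mcmc(y_mat, p, plane_idx, n_planes, priors, *, two_state=True,
             hierarchical=True, chains=4, warmup=1000, draws=1000, seed=0,
             sweeps_per_iter=3, target_accept=0.27, adapt_window=50,
             joint_start=100, init_theta=None):
    """Run the sampler; returns a dict of stacked per-chain draw arrays."""
    y_mat = np.ascontiguousarray(y_mat, dtype=np.float64)
    p = np.ascontiguousarray(p, dtype=np.float64)
    plane_idx = np.asarray(plane_idx, dtype=np.int64)
    n_runs, n_obs = y_mat.shape
    n_par = 6 if two_state else 4
    n_learn = 4 if two_state else 2
    cauchy_scale = np.full(2, float(priors.noise_scale))

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    subj = np.empty((chains, draws, n_runs, n_par))
    gain = np.empty((chains, draws, n_runs))
    pointwise = np.empty((chains, draws, n_runs, n_obs))
    h_mu = np.empty((chains, draws, n_planes, n_par)) if hierarchical else None
    h_sd = np.empty((chains, draws, n_par)) if hierarchical else None
    accept_comp = np.zeros((chains, n_runs, n_par))
    accept_joint = np.zeros((chains, n_runs))

    scratch = np.empty(n_obs)
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = _init_theta(y_mat, rng, two_state, init_theta)
        if hierarchical:
            hyper_mu, hyper_sd = _hyper_init(theta, plane_idx, n_planes, two_state)
            noise_cauchy = False
        else:
            fixed_mu, fixed_sd = _prior_mu_sd(priors, two_state, n_runs, n_planes)
            noise_cauchy = True

        cur_ll = np.empty(n_runs)
        _filters.pointwise_batch(theta, y_mat, p, pointwise[c, 0], two_state)
        cur_ll[:] = pointwise[c, 0].sum(axis=1)

        scales = np.tile(_INIT_SCALES[two_state], (n_runs, 1))
        acc = np.zeros((n_runs, n_par), dtype=np.int64)
        acc_j = np.zeros(n_runs, dtype=np.int64)
        lam = np.full(n_runs, 1.0)
        # Welford running moments for the joint proposal covariance
        w_count = 0
        w_mean = np.zeros((n_runs, n_par))
        w_m2 = np.zeros((n_runs, n_par, n_par))
        chol = np.zeros((n_runs, n_par, n_par))
        for j in range(n_runs):
            chol[j] = np.diag(_INIT_SCALES[two_state])
        joint_active = False
        tot_comp = np.zeros((n_runs, n_par))
        tot_joint = np.zeros(n_runs)
        n_joint_calls = 0

        for it in range(warmup + draws):
            if hierarchical:
                mu_arr = hyper_mu[plane_idx]
                sd_arr = hyper_sd
            else:
                mu_arr = fixed_mu
                sd_arr = fixed_sd
            for _ in range(sweeps_per_iter):
                z = rng.standard_normal((n_runs, n_par))
                u = rng.random((n_runs, n_par))
                _filters.sweep(theta, cur_ll, y_mat, p, mu_arr, sd_arr,
                               noise_cauchy, cauchy_scale, scales, z, u, acc,
                               two_state, scratch)
            if joint_active:
                z = rng.standard_normal((n_runs, n_par))
                u = rng.random(n_runs)
                _filters.joint_sweep(theta, cur_ll, y_mat, p, mu_arr, sd_arr,
                                     noise_cauchy, cauchy_scale,
                                     chol * lam[:, None, None], z, u, acc_j,
                                     two_state, scratch)
                n_joint_calls += 1
            if hierarchical:
                _update_hypers(theta, plane_idx, n_planes, hyper_mu, hyper_sd,
                               priors, two_state, rng)
                _group_moves(theta, cur_ll, y_mat, p, plane_idx, n_planes,
                             hyper_mu, hyper_sd, priors, two_state, rng)

            if it < warmup:
                w_count += 1
                delta = theta - w_mean
                w_mean += delta / w_count
                w_m2 += np.einsum("ri,rj->rij", delta, theta - w_mean)
                if (it + 1) % adapt_window == 0:
                    rate = acc / (adapt_window * sweeps_per_iter)
                    scales *= np.exp(1.2 * (rate - target_accept))
                    np.clip(scales, 1e-5, 5.0, out=scales)
                    tot_comp += acc
                    acc[:] = 0
                    if it + 1 >= joint_start and w_count > n_par + 2:
                        cov = w_m2 / max(w_count - 1, 1)
                        fac = 2.38 ** 2 / n_par
                        for j in range(n_runs):
                            try:
                                chol[j] = np.linalg.cholesky(
                                    fac * (cov[j] + 1e-10 * np.eye(n_par)))
                            except np.linalg.LinAlgError:
                                pass
                        if joint_active:
                            rate_j = acc_j / adapt_window
                            lam *= np.exp(1.0 * (rate_j - 0.25))
                            np.clip(lam, 0.05, 20.0, out=lam)
                        joint_active = True
                        tot_joint += acc_j
                        acc_j[:] = 0
            else:
                d = it - warmup
                subj[c, d] = theta
                gain[c, d] = _gain_from_theta(theta, two_state)
                _filters.pointwise_batch(theta, y_mat, p, pointwise[c, d],
                                         two_state)
                if hierarchical:
                    h_mu[c, d] = hyper_mu
                    h_sd[c, d] = hyper_sd
        accept_comp[c] = (tot_comp + acc) / ((warmup + draws) * sweeps_per_iter)
        accept_joint[c] = (tot_joint + acc_j) / max(n_joint_calls, 1)

    return {
        "subject": subj,
        "gain": gain,
        "pointwise_loglik": pointwise,
        "hyper_mu": h_mu,
        "hyper_sd": h_sd,
        "accept_component": accept_comp,
        "accept_joint": accept_joint,
    }
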