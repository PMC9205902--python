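"""Per-run expectation-maximisation fitter for the two-state model.

Generic constrained linear-dynamical-system EM: the E-step runs a Kalman
filter and Rauch-Tung-Striebel smoother over the two hidden states with
the observed error e(n) = p(n) - y(n) as a deterministic input; the M-step
solves the closed-form regressions for the diagonal retention matrix A and
learning-rate vector B and updates the pooled planning variance and the
measurement variance from smoothed moments.  The unconstrained M-step
optimum is then projected onto the constraint set (relabel the states if
the slow/fast ordering flipped - a likelihood-invariant swap - then clip
to a_s > a_f > 0, b_f > b_s > 0 with small margins).  Without projection
the usual EM monotonicity guarantee applies; a projection step can in
principle lower the likelihood and is therefore reported per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import AdaptationRun, TwoStateParams, run_loglik

_C = np.array([1.0, 1.0])


@dataclass(frozen=True)
class EMConfig:
    max_iter: int = 200
    tol: float = 1e-6
    project: bool = True
    sigma_floor: float = 1e-4


@dataclass
class EMResult:
    params: TwoStateParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


def default_init(run: AdaptationRun) -> TwoStateParams:
    """Package default: canonical slow/fast values, noise from residuals."""
    resid_sd = max(0.5, float(np.std(np.diff(run.y)) / np.sqrt(2.0)))
    return TwoStateParams(a_s=0.95, a_f=0.5, b_s=0.05, b_f=0.2,
                          sigma_x=1.0, sigma_u=resid_sd)


def smooth_states(params: TwoStateParams, run: AdaptationRun):
    """Kalman filter + RTS smoother; returns smoothed means, covariances and
    lag-one covariances Cov(x(n+1), x(n) | y)."""
    y = run.y
    p = run.schedule.p
    n_steps = len(y)
    a = np.array([params.a_s, params.a_f])
    b = np.array([params.b_s, params.b_f])
    q = params.sigma_x ** 2 * np.eye(2)
    r = params.sigma_u ** 2

    m_pred = np.zeros((n_steps, 2))
    p_pred = np.zeros((n_steps, 2, 2))
    m_filt = np.zeros((n_steps, 2))
    p_filt = np.zeros((n_steps, 2, 2))
    for n in range(n_steps):
        if n == 0:
            m_pred[0] = 0.0
            p_pred[0] = 0.0  # x(1) = 0 exactly
        else:
            e = p[n - 1] - y[n - 1]
            m_pred[n] = a * m_filt[n - 1] + b * e
            p_pred[n] = (a[:, None] * p_filt[n - 1]) * a[None, :] + q
        s = _C @ p_pred[n] @ _C + r
        if s <= 0:
            raise ValueError("degenerate innovation variance in the E-step")
        k = p_pred[n] @ _C / s
        resid = y[n] - _C @ m_pred[n]
        m_filt[n] = m_pred[n] + k * resid
        p_filt[n] = p_pred[n] - np.outer(k, _C @ p_pred[n])

    m_smooth = np.zeros((n_steps, 2))
    p_smooth = np.zeros((n_steps, 2, 2))
    lag1 = np.zeros((max(n_steps - 1, 0), 2, 2))
    m_smooth[-1] = m_filt[-1]
    p_smooth[-1] = p_filt[-1]
    for n in range(n_steps - 2, -1, -1):
        pp = p_pred[n + 1]
        # guard: zero predicted covariance (noise-free start) has no smoothing gain
        if np.allclose(pp, 0):
            j = np.zeros((2, 2))
        else:
            j = (p_filt[n] * a[None, :]) @ np.linalg.pinv(pp)
        m_smooth[n] = m_filt[n] + j @ (m_smooth[n + 1] - m_pred[n + 1])
        p_smooth[n] = p_filt[n] + j @ (p_smooth[n + 1] - p_pred[n + 1]) @ j.T
        lag1[n] = p_smooth[n + 1] @ j.T  # Cov(x(n+1), x(n) | all y)
    return m_smooth, p_smooth, lag1


def _project(a_s, a_f, b_s, b_f, eps=1e-6):
    """Project M-step estimates onto the ordering constraint set."""
    if a_f > a_s:  # relabel slow/fast (exact likelihood-invariant swap)
        a_s, a_f = a_f, a_s
        b_s, b_f = b_f, b_s
    a_s = max(a_s, 3 * eps)
    a_f = min(max(a_f, eps), a_s - eps)
    b_f = max(b_f, 3 * eps)
    b_s = min(max(b_s, eps), b_f * (1 - 1e-9))
    return a_s, a_f, b_s, b_f


def em_fit(run: AdaptationRun, init: TwoStateParams | None = None,
           config: EMConfig | None = None) -> EMResult:
    """Constrained LDS-EM point estimation of two-state parameters."""
    if len(run) < 10:
        raise ValueError("EM needs a run of length >= 10")
    config = config or EMConfig()
    params = init or default_init(run)
    y = run.y
    p_in = run.schedule.p
    n_steps = len(y)
    e_obs = p_in - y
    trace = [run_loglik(params, run)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        m, pv, lag1 = smooth_states(params, run)
        ex2 = pv[:, [0, 1], [0, 1]] + m ** 2              # E[x_i(n)^2], (N, 2)
        exy = lag1[:, [0, 1], [0, 1]] + m[1:] * m[:-1]     # E[x_i(n+1) x_i(n)]
        e_head = e_obs[:-1]
        new_ab = np.zeros((2, 2))
        for i in range(2):
            s_xx = ex2[:-1, i].sum()
            s_xe = (m[:-1, i] * e_head).sum()
            s_ee = (e_head ** 2).sum()
            s_yx = exy[:, i].sum()
            s_ye = (m[1:, i] * e_head).sum()
            mat = np.array([[s_xx, s_xe], [s_xe, s_ee]])
            vec = np.array([s_yx, s_ye])
            new_ab[i] = np.linalg.solve(mat + 1e-12 * np.eye(2), vec)
        a_new = new_ab[:, 0]
        b_new = new_ab[:, 1]
        # pooled planning variance over both states and N-1 transitions
        q_sum = 0.0
        for i in range(2):
            q_sum += (ex2[1:, i].sum()
                      + a_new[i] ** 2 * ex2[:-1, i].sum()
                      + b_new[i] ** 2 * (e_head ** 2).sum()
                      - 2 * a_new[i] * exy[:, i].sum()
                      - 2 * b_new[i] * (m[1:, i] * e_head).sum()
                      + 2 * a_new[i] * b_new[i] * (m[:-1, i] * e_head).sum())
        vx_new = max(q_sum / (2 * (n_steps - 1)), config.sigma_floor ** 2)
        # measurement variance from smoothed second moments of C x
        cx_var = pv[:, 0, 0] + 2 * pv[:, 0, 1] + pv[:, 1, 1]
        cx_mean = m[:, 0] + m[:, 1]
        vu_new = max(np.mean((y - cx_mean) ** 2 + cx_var), config.sigma_floor ** 2)

        a_s, a_f = a_new[0], a_new[1]
        b_s, b_f = b_new[0], b_new[1]
        if config.project:
            a_s, a_f, b_s, b_f = _project(a_s, a_f, b_s, b_f)
        params = TwoStateParams(a_s=a_s, a_f=a_f, b_s=b_s, b_f=b_f,
                                sigma_x=float(np.sqrt(vx_new)),
                                sigma_u=float(np.sqrt(vu_new)))
        trace.append(run_loglik(params, run))
        if abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
    return EMResult(params=params, loglik_trace=np.array(trace),
                    converged=converged, n_iter=it)
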