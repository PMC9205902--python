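import numpy as np
import pytest

from adapt2state.model_core import PerturbationSchedule, TwoStateParams


@pytest.fixture(scope="session")
def epoch_schedule():
    return PerturbationSchedule.standard()


@pytest.fixture(scope="session")
def typical_params():
    """Representative two-state parameters at epoch granularity."""
    return TwoStateParams(a_s=0.93, a_f=0.55, b_s=0.06, b_f=0.18,
                          sigma_x=np.sqrt(1.5), sigma_u=np.sqrt(6.0))


def joint_gaussian_loglik(params, run):
    """Independent oracle: log-density of y from the unrolled joint Gaussian.

    Substituting y(n) = C x(n) + eps_u(n) into the state update gives
    x(n+1) = (A - B C) x(n) + B p(n) - B eps_u(n) + eps_x(n), so the
    stacked y vector is an affine map of the iid noise vector
    (eps_x(1..N-1), eps_u(1..N)); its mean vector and covariance matrix
    follow by propagating the coefficients, with no Kalman filtering.
    """
    from scipy import stats

    y = run.y
    p = run.schedule.p
    n = len(y)
    a_mat = np.diag([params.a_s, params.a_f])
    b_vec = np.array([params.b_s, params.b_f])
    c_vec = np.array([1.0, 1.0])
    n_noise = 2 * (n - 1) + n  # eps_x components then eps_u components
    sds = np.concatenate([np.full(2 * (n - 1), params.sigma_x),
                          np.full(n, params.sigma_u)])
    x_coef = np.zeros((2, n_noise))
    x_const = np.zeros(2)
    y_coef = np.zeros((n, n_noise))
    y_mean = np.zeros(n)
    trans = a_mat - np.outer(b_vec, c_vec)
    for step in range(n):
        y_coef[step] = c_vec @ x_coef
        y_coef[step, 2 * (n - 1) + step] += 1.0  # eps_u(step)
        y_mean[step] = c_vec @ x_const
        if step + 1 < n:
            x_coef = trans @ x_coef
            x_coef[:, 2 * step:2 * step + 2] += np.eye(2)  # eps_x(step)
            x_coef[:, 2 * (n - 1) + step] += -b_vec  # -B eps_u(step)
            x_const = a_mat @ x_const + b_vec * (p[step] - y_mean[step])
            # note: A x + B (p - C x - eps_u) = (A - BC) x + B p - B eps_u
    cov = (y_coef * sds ** 2) @ y_coef.T
    return float(stats.multivariate_normal.logpdf(y, mean=y_mean, cov=cov))
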