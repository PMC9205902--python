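"""Post-fit analyses: final adaptation level, parameter-recovery reports,
and Kalman-gain / learning-rate regressions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .model_core import AdaptationRun


def final_adaptation_level(run: AdaptationRun) -> float:
    """Mean observed angle over the last 4 perturbation-phase steps (deg)."""
    pert = np.array([lab == "perturbation" for lab in run.schedule.phase])
    vals = run.y[pert]
    if len(vals) < 4:
        raise ValueError("need at least 4 perturbation-phase steps")
    return float(vals[-4:].mean())


@dataclass
class RecoveryReport:
    """Per-parameter reconstruction quality of one fitting method."""

    method: str
    param_names: tuple
    errors: np.ndarray          # (n_runs, n_params): estimated - truth
    mse: np.ndarray             # (n_params,)
    mse_ci: np.ndarray          # (n_params, 2) bootstrap 95% CI
    corr: np.ndarray            # (n_params,) Pearson r (nan if undefined)
    corr_ci: np.ndarray         # (n_params, 2) Fisher-z 95% CI

    def as_dict(self) -> dict:
        out = {"method": self.method, "parameters": {}}
        for k, name in enumerate(self.param_names):
            out["parameters"][name] = {
                "mean_error": float(self.errors[:, k].mean()),
                "mse": float(self.mse[k]),
                "mse_ci95": [float(v) for v in self.mse_ci[k]],
                "corr": None if np.isnan(self.corr[k]) else float(self.corr[k]),
                "corr_ci95": [None if np.isnan(v) else float(v)
                              for v in self.corr_ci[k]],
            }
        return out


def _fisher_ci(r, n, prob=0.95):
    if n < 4 or not np.isfinite(r) or abs(r) >= 1:
        return np.nan, np.nan
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + prob / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def recovery_report(truths, estimates, method_label: str,
                    param_names=("a_s", "a_f", "b_s", "b_f", "sigma_x", "sigma_u"),
                    n_boot: int = 2000, seed: int = 0) -> RecoveryReport:
    """Errors (estimated minus set parameter), MSE with seeded bootstrap 95%
    CIs, and truth/estimate Pearson correlations with Fisher-z 95% CIs."""
    truths = np.asarray(truths, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if truths.shape != estimates.shape:
        raise ValueError("truths and estimates must have identical shape")
    if truths.ndim != 2 or truths.shape[0] < 3:
        raise ValueError("need aligned (n_runs >= 3, n_params) arrays")
    n_runs, n_par = truths.shape
    if len(param_names) != n_par:
        raise ValueError("param_names does not match the number of columns")
    errors = estimates - truths
    sq = errors ** 2
    mse = sq.mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_runs, size=(n_boot, n_runs))
    boot = sq[idx].mean(axis=1)                      # (n_boot, n_params)
    mse_ci = np.quantile(boot, [0.025, 0.975], axis=0).T
    corr = np.full(n_par, np.nan)
    corr_ci = np.full((n_par, 2), np.nan)
    for k in range(n_par):
        if np.std(truths[:, k]) == 0 or np.std(estimates[:, k]) == 0:
            continue  # correlation undefined for a constant margin
        r = stats.pearsonr(truths[:, k], estimates[:, k]).statistic
        corr[k] = r
        corr_ci[k] = _fisher_ci(r, n_runs)
    return RecoveryReport(method=method_label, param_names=tuple(param_names),
                          errors=errors, mse=mse, mse_ci=mse_ci,
                          corr=corr, corr_ci=corr_ci)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple
    n: int


@dataclass
class GainRegression:
    """OLS of a learning rate on the steady-state Kalman gain."""

    pooled: RegressionFit
    by_plane: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        def rec(f):
            return {"slope": f.slope, "intercept": f.intercept,
                    "r_squared": f.r_squared, "slope_ci95": list(f.slope_ci),
                    "n": f.n}
        return {"pooled": rec(self.pooled),
                "by_plane": {pl: rec(f) for pl, f in self.by_plane.items()}}


def _ols(x, y):
    if np.std(x) == 0:
        raise ValueError("degenerate predictor: Kalman gain is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(slope=float(model.params[1]),
                         intercept=float(model.params[0]),
                         r_squared=float(model.rsquared),
                         slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
                         n=len(x))


def gain_learning_regression(learning_rates, gains, planes=None) -> GainRegression:
    """Regress per-run learning rates (posterior means of b_s or b_f) on
    per-run posterior-mean Kalman gains, pooled and within each plane."""
    b = np.asarray(learning_rates, dtype=float)
    k = np.asarray(gains, dtype=float)
    if b.shape != k.shape or b.ndim != 1:
        raise ValueError("learning_rates and gains must be aligned 1-D arrays")
    if len(b) < 3:
        raise ValueError("need at least 3 runs")
    pooled = _ols(k, b)
    by_plane = {}
    if planes is not None:
        planes = np.asarray(planes)
        for pl in np.unique(planes):
            mask = planes == pl
            if mask.sum() >= 3:
                by_plane[str(pl)] = _ols(k[mask], b[mask])
    return GainRegression(pooled=pooled, by_plane=by_plane)
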