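"""Bayesian fitting of the adaptation models, WAIC, and posterior analyses.

The hierarchical model places, for every parameter (e.g. the slow retention
a_s), a per-plane population normal over the subject x plane values:
a_s,jp ~ N(mu_{a_s,p}, sigma_{a_s}), with the population SD shared across
planes.  Priors are wide: retention means ~ N(1, 9), learning-rate means
~ N(0, 9) (normal parameters are mean and standard deviation), population
SDs of retention/learning ~ half-Cauchy(0, 5), and both the means and SDs
of the noise scales ~ half-Cauchy(0, 15).  Hidden states are marginalised
analytically by forward filtering; the sampler never draws them.  The
per-run (non-hierarchical) fit removes the population level and applies
the hyper-priors directly to the subject-level parameters.

Derived steady-state Kalman gains are recorded per draw from the sampled
noise scales, so posterior uncertainty propagates into K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _sampler
from .model_core import AdaptationRun, TwoStateParams, SingleStateParams

_PARAM_NAMES = {"two": _sampler.TWO_STATE_NAMES, "single": _sampler.ONE_STATE_NAMES}


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-prior specification (normal parameters are mean, SD)."""

    retention_mean: tuple = (1.0, 9.0)
    learning_mean: tuple = (0.0, 9.0)
    learning_sd_scale: float = 5.0
    noise_scale: float = 15.0

    def __post_init__(self):
        if self.retention_mean[1] <= 0 or self.learning_mean[1] <= 0:
            raise ValueError("prior scales must be > 0")
        if self.learning_sd_scale <= 0 or self.noise_scale <= 0:
            raise ValueError("half-Cauchy scales must be > 0")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    sweeps_per_iter: int = 5
    target_accept: float = 0.27
    adapt_window: int = 50
    rhat_threshold: float = 1.05


@dataclass
class PosteriorResult:
    """Joint posterior draws with diagnostics and derived Kalman gains.

    Draw arrays carry a leading (chain, draw) pair of axes: ``subject`` is
    (C, D, R, P), ``gain`` is (C, D, R), ``hyper_mu`` is (C, D, planes, P)
    and ``hyper_sd`` (C, D, P) for hierarchical fits, ``pointwise_loglik``
    is (C, D, R, N).
    """

    model_kind: str
    hierarchical: bool
    param_names: tuple
    run_ids: list
    plane_names: list
    subject: np.ndarray
    gain: np.ndarray
    pointwise_loglik: np.ndarray
    hyper_mu: np.ndarray | None = None
    hyper_sd: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_runs(self):
        return self.subject.shape[2]

    def _pidx(self, param):
        return self.param_names.index(param)

    def subject_means(self) -> np.ndarray:
        """(n_runs, n_params) posterior means of subject-level parameters."""
        return self.subject.mean(axis=(0, 1))

    def gain_means(self) -> np.ndarray:
        """(n_runs,) posterior-mean steady-state Kalman gain per run."""
        return self.gain.mean(axis=(0, 1))

    def hyper_mu_draws(self, param: str, plane: str | None = None) -> np.ndarray:
        if self.hyper_mu is None:
            raise ValueError("non-hierarchical fit has no hyper-parameters")
        pl = 0 if plane is None else self.plane_names.index(plane)
        return self.hyper_mu[:, :, pl, self._pidx(param)].ravel()

    def hyper_mu_mean(self, param: str, plane: str | None = None) -> float:
        return float(self.hyper_mu_draws(param, plane).mean())

    def hyper_mu_interval(self, param: str, plane: str | None = None,
                          prob: float = 0.95):
        draws = self.hyper_mu_draws(param, plane)
        lo, hi = np.quantile(draws, [(1 - prob) / 2, 1 - (1 - prob) / 2])
        return float(lo), float(hi)

    def population_variability_draws(self, param: str,
                                     plane: str | None = None) -> np.ndarray:
        """Posterior draws of the population-mean variability (deg^2).

        The hierarchy places a normal over the noise *scale* sigma, so the
        population mean of sigma^2 is mu^2 + sd_pop^2 (E[X^2] identity);
        reporting mu^2 alone would systematically understate it.
        """
        if param not in ("sigma_x", "sigma_u"):
            raise ValueError("variability is defined for sigma_x / sigma_u")
        if self.hyper_mu is None:
            raise ValueError("non-hierarchical fit has no hyper-parameters")
        pl = 0 if plane is None else self.plane_names.index(plane)
        k = self._pidx(param)
        mu = self.hyper_mu[:, :, pl, k]
        sd = self.hyper_sd[:, :, k]
        return (mu ** 2 + sd ** 2).ravel()

    def to_inference_data(self):
        """arviz InferenceData with posterior and log_likelihood groups."""
        import arviz as az
        post = {"subject": self.subject, "gain": self.gain}
        if self.hyper_mu is not None:
            post["hyper_mu"] = self.hyper_mu
            post["hyper_sd"] = self.hyper_sd
        return az.from_dict(
            posterior=post,
            log_likelihood={"y": self.pointwise_loglik},
        )

    def summary(self) -> dict:
        """JSON-serialisable posterior summary (means, medians, 95% CIs, K)."""
        out = {"model_kind": self.model_kind, "hierarchical": self.hierarchical,
               "runs": {}, "planes": {}, "diagnostics": self.diagnostics}
        flat = self.subject.reshape(-1, self.n_runs, len(self.param_names))
        gain = self.gain.reshape(-1, self.n_runs)
        for j, rid in enumerate(self.run_ids):
            entry = {}
            for k, name in enumerate(self.param_names):
                d = flat[:, j, k]
                lo, hi = np.quantile(d, [0.025, 0.975])
                entry[name] = {"mean": float(d.mean()), "median": float(np.median(d)),
                               "ci95": [float(lo), float(hi)]}
            gd = gain[:, j]
            lo, hi = np.quantile(gd, [0.025, 0.975])
            entry["K"] = {"mean": float(gd.mean()), "median": float(np.median(gd)),
                          "ci95": [float(lo), float(hi)]}
            out["runs"][rid] = entry
        if self.hyper_mu is not None:
            for pl, plane in enumerate(self.plane_names):
                entry = {}
                for k, name in enumerate(self.param_names):
                    d = self.hyper_mu[:, :, pl, k].ravel()
                    lo, hi = np.quantile(d, [0.025, 0.975])
                    entry[f"mu_{name}"] = {"mean": float(d.mean()),
                                           "ci95": [float(lo), float(hi)]}
                out["planes"][plane] = entry
            for k, name in enumerate(self.param_names):
                d = self.hyper_sd[:, :, k].ravel()
                out["planes"].setdefault("population_sd", {})[name] = float(d.mean())
        return out


def _validate_dataset(dataset):
    if len(dataset) < 1:
        raise ValueError("need at least one run")
    gran = {run.granularity for run in dataset}
    if len(gran) != 1:
        raise ValueError("all runs must share step granularity (trial vs epoch)")
    lengths = {len(run) for run in dataset}
    if len(lengths) != 1:
        raise ValueError("all runs must share the same schedule length")
    p0 = dataset[0].schedule.p
    for run in dataset[1:]:
        if not np.array_equal(run.schedule.p, p0):
            raise ValueError("all runs must share the same perturbation schedule")


def _compute_diagnostics(raw, hierarchical, param_names, plane_names, threshold):
    import arviz as az
    diag = {
        "accept_component": float(raw["accept_component"].mean()),
        "accept_joint": float(raw["accept_joint"].mean()),
        "divergences": 0,  # Metropolis/slice moves cannot diverge
    }
    rhats, esss = {}, {}
    n_chains = raw["subject"].shape[0]
    if n_chains < 2:
        diag.update(rhat={}, ess={}, max_rhat=float("nan"), converged=True)
        return diag
    if hierarchical:
        arr = raw["hyper_mu"]
        for pl, plane in enumerate(plane_names):
            for k, name in enumerate(param_names):
                d = arr[:, :, pl, k]
                label = f"mu_{name}[{plane}]"
                rhats[label] = float(az.rhat(az.convert_to_dataset(d))["x"].values)
                esss[label] = float(az.ess(az.convert_to_dataset(d))["x"].values)
    else:
        subj = raw["subject"]
        for k, name in enumerate(param_names):
            d = subj[:, :, :, k].mean(axis=2)
            rhats[name] = float(az.rhat(az.convert_to_dataset(d))["x"].values)
            esss[name] = float(az.ess(az.convert_to_dataset(d))["x"].values)
    diag["rhat"] = rhats
    diag["ess"] = esss
    diag["max_rhat"] = max(rhats.values())
    diag["converged"] = bool(diag["max_rhat"] <= threshold)
    if not diag["converged"]:
        warnings.warn(
            f"max R-hat {diag['max_rhat']:.3f} exceeds {threshold}; "
            "inspect diagnostics before trusting the posterior", RuntimeWarning)
    return diag


def _em_inits(dataset):
    """Quick per-run EM point estimates used to start every chain in its
    run's own likelihood region (a shared heuristic start mixes too slowly
    into runs whose learning rates sit far from the population centre)."""
    from .em_baseline import EMConfig, em_fit
    inits = []
    for run in dataset:
        try:
            inits.append(em_fit(run, config=EMConfig(max_iter=40)).params.as_array())
        except (ValueError, np.linalg.LinAlgError):
            return None
    return np.array(inits)


def _fit(dataset, model_kind, priors, config, hierarchical):
    _validate_dataset(dataset)
    if model_kind not in ("single", "two"):
        raise ValueError("model_kind must be 'single' or 'two'")
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    plane_names = sorted({run.plane for run in dataset})
    plane_idx = np.array([plane_names.index(run.plane) for run in dataset])
    y_mat = np.stack([run.y for run in dataset])
    p = dataset[0].schedule.p
    init_theta = _em_inits(dataset) if model_kind == "two" else None
    raw = _sampler.run_mcmc(
        y_mat, p, plane_idx, len(plane_names), priors,
        two_state=(model_kind == "two"), hierarchical=hierarchical,
        chains=config.chains, warmup=config.warmup, draws=config.draws,
        seed=config.seed, sweeps_per_iter=config.sweeps_per_iter,
        target_accept=config.target_accept, adapt_window=config.adapt_window,
        init_theta=init_theta)
    param_names = _PARAM_NAMES[model_kind]
    diagnostics = _compute_diagnostics(raw, hierarchical, param_names,
                                       plane_names, config.rhat_threshold)
    diagnostics["config"] = asdict(config)
    return PosteriorResult(
        model_kind=model_kind, hierarchical=hierarchical,
        param_names=tuple(param_names),
        run_ids=[run.subject_id for run in dataset], plane_names=plane_names,
        subject=raw["subject"], gain=raw["gain"],
        pointwise_loglik=raw["pointwise_loglik"],
        hyper_mu=raw["hyper_mu"], hyper_sd=raw["hyper_sd"],
        diagnostics=diagnostics)


def fit_hierarchical(dataset, model_kind: str = "two",
                     priors: PriorSpec | None = None,
                     config: SamplerConfig | None = None) -> PosteriorResult:
    """Hierarchical fit of a list of runs grouped by (subject, plane)."""
    return _fit(list(dataset), model_kind, priors, config, hierarchical=True)


def fit_per_run(run: AdaptationRun, model_kind: str = "two",
                priors: PriorSpec | None = None,
                config: SamplerConfig | None = None) -> PosteriorResult:
    """Non-hierarchical fit of a single run (hyper-priors applied directly)."""
    if not isinstance(run, AdaptationRun):
        raise TypeError("fit_per_run expects a single AdaptationRun")
    return _fit([run], model_kind, priors, config, hierarchical=False)


def fit_independent(dataset, model_kind: str = "two",
                    priors: PriorSpec | None = None,
                    config: SamplerConfig | None = None) -> PosteriorResult:
    """Batched convenience: independent per-run fits in one sampler pass.

    Statistically identical to calling :func:`fit_per_run` on each run
    (no parameters are shared); the runs merely share the chain loop.
    """
    return _fit(list(dataset), model_kind, priors, config, hierarchical=False)


@dataclass(frozen=True)
class WaicResult:
    waic: float
    p_waic: float
    lppd: float


def waic(result: PosteriorResult) -> WaicResult:
    """Widely applicable information criterion on the deviance scale.

    WAIC = -2 (lppd - p_waic); lppd sums, over observations, the log of the
    posterior-mean pointwise likelihood; p_waic sums the posterior variance
    of the pointwise log-likelihood.  Lower is better.
    """
    ll = result.pointwise_loglik
    n_draws_total = ll.shape[0] * ll.shape[1]
    if n_draws_total < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    flat = ll.reshape(n_draws_total, -1)
    m = flat.max(axis=0)
    lppd = float(np.sum(np.log(np.mean(np.exp(flat - m), axis=0)) + m))
    p_waic = float(np.sum(flat.var(axis=0, ddof=1)))
    return WaicResult(waic=-2.0 * (lppd - p_waic), p_waic=p_waic, lppd=lppd)


def null_value_probability(delta_draws) -> float:
    """Two-sided posterior tail credibility of zero for a difference.

    Returns 2 * min(P(delta < 0), P(delta > 0)), capped at 1.
    """
    d = np.asarray(delta_draws, dtype=float)
    if d.size == 0:
        raise ValueError("empty draw array")
    frac_neg = np.mean(d < 0)
    frac_pos = np.mean(d > 0)
    return float(min(1.0, 2.0 * min(frac_neg, frac_pos)))


def _deterministic_path(theta, p, two_state):
    """Noise-free forward simulation for an array of parameter draws.

    theta: (D, P) draws; returns (D, N) predicted angle trajectories.
    """
    n_draws = theta.shape[0]
    n_steps = len(p)
    y = np.empty((n_draws, n_steps))
    if two_state:
        x1 = np.zeros(n_draws)
        x2 = np.zeros(n_draws)
        for n in range(n_steps):
            y[:, n] = x1 + x2
            e = p[n] - y[:, n]
            x1 = theta[:, 0] * x1 + theta[:, 2] * e
            x2 = theta[:, 1] * x2 + theta[:, 3] * e
    else:
        x = np.zeros(n_draws)
        for n in range(n_steps):
            y[:, n] = x
            e = p[n] - x
            x = theta[:, 0] * x + theta[:, 1] * e
    return y


def posterior_predicted_path(result: PosteriorResult, run_index: int,
                             p, max_draws: int = 400) -> np.ndarray:
    """Posterior-mean noise-free predicted trajectory for one run."""
    flat = result.subject.reshape(-1, result.n_runs, len(result.param_names))
    step = max(1, flat.shape[0] // max_draws)
    theta = flat[::step, run_index, :]
    return _deterministic_path(theta, np.asarray(p, float),
                               result.model_kind == "two").mean(axis=0)


def rms_residuals(result: PosteriorResult, dataset) -> np.ndarray:
    """Per-run RMS of observed minus posterior-mean predicted angles."""
    dataset = list(dataset)
    if len(dataset) != result.n_runs:
        raise ValueError("dataset does not match the fitted result")
    out = np.empty(len(dataset))
    for j, run in enumerate(dataset):
        pred = posterior_predicted_path(result, j, run.schedule.p)
        out[j] = np.sqrt(np.mean((run.y - pred) ** 2))
    return out


def subject_point_estimates(result: PosteriorResult):
    """Posterior-mean subject-level parameters as typed param objects."""
    means = result.subject_means()
    out = []
    for row in means:
        if result.model_kind == "two":
            out.append(TwoStateParams(a_s=row[0], a_f=row[1], b_s=row[2],
                                      b_f=row[3], sigma_x=row[4], sigma_u=row[5]))
        else:
            out.append(SingleStateParams(a=row[0], b=row[1],
                                         sigma_x=row[2], sigma_u=row[3]))
    return out
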