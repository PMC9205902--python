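"""Generative single- and two-state adaptation dynamics.

The observed movement angle on step (trial or epoch) ``n`` is

    y(n) = C x(n) + eps_u(n),        eps_u ~ N(0, sigma_u)

where ``x`` is the hidden planning state (two components, slow and fast,
with ``C = [1, 1]``, or a scalar for the single-state model).  The state is
updated from the experienced error e(n) = p(n) - y(n), where ``p`` is the
perturbation magnitude (30 deg during perturbed steps, 0 otherwise):

    x(n+1) = A x(n) + B e(n) + eps_x(n),   eps_x ~ N(0, sigma_x) per state

with diagonal retention A = diag(a_s, a_f) under a_s > a_f > 0 and learning
rates B = [b_s, b_f]' under b_f > b_s > 0.  All angles are in degrees;
positive y is compensatory (toward full compensation of the perturbation).

``sigma_x`` and ``sigma_u`` are standard deviations; the corresponding
variabilities are their squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _filters

PLANES = ("sagittal", "horizontal", "coronal")
PHASES = ("baseline", "perturbation", "washout")

OBSERVATION_ROW = np.array([1.0, 1.0])  # C: measured angle = sum of states


class DegenerateLikelihoodError(ValueError):
    """Raised when a noise-free model is inconsistent with the data."""


@dataclass(frozen=True)
class PerturbationSchedule:
    """Per-step perturbation magnitude (deg) and phase labels.

    Phases appear in order baseline -> perturbation -> washout; p is zero
    outside the perturbation phase and a single constant inside it.
    """

    p: np.ndarray
    phase: tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "phase", tuple(self.phase))
        if p.ndim != 1 or len(p) < 1 or len(p) != len(self.phase):
            raise ValueError("p and phase_labels must be equal-length, non-empty")
        if not np.all(np.isfinite(p)):
            raise ValueError("perturbation magnitudes must be finite")
        order = {"baseline": 0, "perturbation": 1, "washout": 2}
        codes = []
        for lab in self.phase:
            if lab not in order:
                raise ValueError(f"unknown phase label {lab!r}")
            codes.append(order[lab])
        if any(b < a for a, b in zip(codes, codes[1:])):
            raise ValueError("phases must appear in order baseline -> perturbation -> washout")
        pert = np.array([lab == "perturbation" for lab in self.phase])
        if np.any(p[~pert] != 0.0):
            raise ValueError("p must be 0 on baseline and washout steps")
        if pert.any() and len(np.unique(p[pert])) != 1:
            raise ValueError("p must be a single constant during the perturbation phase")

    def __len__(self):
        return len(self.p)

    @property
    def magnitude(self) -> float:
        pert = [v for v, lab in zip(self.p, self.phase) if lab == "perturbation"]
        return float(pert[0]) if pert else 0.0

    @classmethod
    def standard(cls, n_baseline: int = 15, n_perturbation: int = 30,
                 n_washout: int = 30, magnitude: float = 30.0) -> "PerturbationSchedule":
        """Default epoch-level design: 15 baseline / 30 perturbation / 30 washout."""
        p = np.concatenate([
            np.zeros(n_baseline),
            np.full(n_perturbation, float(magnitude)),
            np.zeros(n_washout),
        ])
        phase = (("baseline",) * n_baseline + ("perturbation",) * n_perturbation
                 + ("washout",) * n_washout)
        return cls(p=p, phase=phase)

    @classmethod
    def standard_trials(cls, trials_per_epoch: int = 8, **kwargs) -> "PerturbationSchedule":
        """Trial-level counterpart of :meth:`standard` (120/240/240 by default)."""
        ep = cls.standard(**kwargs)
        p = np.repeat(ep.p, trials_per_epoch)
        phase = tuple(np.repeat(ep.phase, trials_per_epoch))
        return cls(p=p, phase=phase)


def _check_sigmas(sigma_x, sigma_u):
    if not (np.isfinite(sigma_x) and np.isfinite(sigma_u)):
        raise ValueError("noise scales must be finite")
    if sigma_x < 0 or sigma_u < 0:
        raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state learning parameters: a_s > a_f > 0, b_f > b_s > 0."""

    a_s: float
    a_f: float
    b_s: float
    b_f: float
    sigma_x: float = 0.0
    sigma_u: float = 0.0

    def __post_init__(self):
        vals = (self.a_s, self.a_f, self.b_s, self.b_f)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("learning parameters must be finite")
        if not (self.a_s > self.a_f > 0):
            raise ValueError("retention constraint a_s > a_f > 0 violated")
        if not (self.b_f > self.b_s > 0):
            raise ValueError("learning-rate constraint b_f > b_s > 0 violated")
        _check_sigmas(self.sigma_x, self.sigma_u)

    @property
    def planning_var(self) -> float:
        return self.sigma_x ** 2

    @property
    def measurement_var(self) -> float:
        return self.sigma_u ** 2

    def as_array(self) -> np.ndarray:
        return np.array([self.a_s, self.a_f, self.b_s, self.b_f,
                         self.sigma_x, self.sigma_u])


@dataclass(frozen=True)
class SingleStateParams:
    """Single-state learning parameters: a > 0, b > 0."""

    a: float
    b: float
    sigma_x: float = 0.0
    sigma_u: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("learning parameters must be finite")
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be > 0")
        _check_sigmas(self.sigma_x, self.sigma_u)

    @property
    def planning_var(self) -> float:
        return self.sigma_x ** 2

    @property
    def measurement_var(self) -> float:
        return self.sigma_u ** 2

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.sigma_x, self.sigma_u])


@dataclass(frozen=True)
class AdaptationRun:
    """Observed angle series with its schedule and labels (the fitting unit)."""

    y: np.ndarray
    schedule: PerturbationSchedule
    subject_id: str = "s01"
    plane: str = "coronal"
    granularity: str = "epoch"

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if len(y) != len(self.schedule):
            raise ValueError("y and schedule must have equal length")
        if not np.all(np.isfinite(y)):
            raise ValueError("observed angles must be finite")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        if self.granularity not in ("trial", "epoch"):
            raise ValueError("granularity must be 'trial' or 'epoch'")

    def __len__(self):
        return len(self.y)


@dataclass(frozen=True)
class StateTrajectory:
    """Hidden-state sequences and the error sequence of one simulated run."""

    x_s: np.ndarray
    e: np.ndarray
    x_f: np.ndarray | None = None


def simulate_run(params, schedule: PerturbationSchedule, seed: int,
                 subject_id: str = "s01", plane: str = "coronal",
                 granularity: str = "epoch"):
    """Simulate one run; returns ``(AdaptationRun, StateTrajectory)``.

    States start at zero; on each step the angle is observed with
    measurement noise, the error e(n) = p(n) - y(n) is computed from the
    *observed* angle, and the state update adds planning noise.  Identical
    (params, schedule, seed) give bit-identical output.
    """
    if len(schedule) < 1:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    p = schedule.p
    n_steps = len(p)
    two = isinstance(params, TwoStateParams)
    if not two and not isinstance(params, SingleStateParams):
        raise TypeError("params must be TwoStateParams or SingleStateParams")
    y = np.empty(n_steps)
    e = np.empty(n_steps)
    if two:
        a = np.array([params.a_s, params.a_f])
        b = np.array([params.b_s, params.b_f])
        x = np.zeros((n_steps, 2))
        for n in range(n_steps):
            y[n] = x[n].sum() + params.sigma_u * rng.standard_normal()
            e[n] = p[n] - y[n]
            if n + 1 < n_steps:
                eps_x = params.sigma_x * rng.standard_normal(2)
                x[n + 1] = a * x[n] + b * e[n] + eps_x
        traj = StateTrajectory(x_s=x[:, 0], x_f=x[:, 1], e=e)
    else:
        x = np.zeros(n_steps)
        for n in range(n_steps):
            y[n] = x[n] + params.sigma_u * rng.standard_normal()
            e[n] = p[n] - y[n]
            if n + 1 < n_steps:
                x[n + 1] = params.a * x[n] + params.b * e[n] \
                    + params.sigma_x * rng.standard_normal()
        traj = StateTrajectory(x_s=x, x_f=None, e=e)
    run = AdaptationRun(y=y, schedule=schedule, subject_id=subject_id,
                        plane=plane, granularity=granularity)
    return run, traj


def deterministic_asymptote(params, p_const: float) -> float:
    """Noise-free fixed-point of the observed angle under constant perturbation.

    Solves y* = p * G / (1 + G) with G = sum_states b / (1 - a); requires
    strict forgetting (every retention factor < 1).
    """
    if isinstance(params, TwoStateParams):
        pairs = [(params.a_s, params.b_s), (params.a_f, params.b_f)]
    elif isinstance(params, SingleStateParams):
        pairs = [(params.a, params.b)]
    else:
        raise TypeError("params must be TwoStateParams or SingleStateParams")
    if any(a >= 1.0 for a, _ in pairs):
        raise ValueError("asymptote undefined: retention factor >= 1")
    gain = sum(b / (1.0 - a) for a, b in pairs)
    return float(p_const) * gain / (1.0 + gain)


def run_loglik(params, run: AdaptationRun, pointwise: bool = False):
    """Exact marginal log-density of ``run.y`` under the model.

    Computed by forward (Kalman) filtering of the conditionally linear
    system; the per-step one-step-ahead predictive terms sum to the total.
    Metadata (subject, plane) does not enter the density.
    """
    y = run.y
    p = run.schedule.p
    pw = np.empty(len(y))
    if isinstance(params, TwoStateParams):
        total = _filters.loglik_two(params.a_s, params.a_f, params.b_s,
                                    params.b_f, params.sigma_x, params.sigma_u,
                                    y, p, pw)
    elif isinstance(params, SingleStateParams):
        total = _filters.loglik_one(params.a, params.b, params.sigma_x,
                                    params.sigma_u, y, p, pw)
    else:
        raise TypeError("params must be TwoStateParams or SingleStateParams")
    if not np.isfinite(total):
        if params.sigma_x == 0 and params.sigma_u == 0:
            raise DegenerateLikelihoodError(
                "noise-free model: data inconsistent with the deterministic path")
        raise DegenerateLikelihoodError("likelihood degenerate for these parameters")
    if pointwise:
        return float(total), pw
    return float(total)


# ---------------------------------------------------------------------------
# CSV round-trip (one file may hold many runs; keyed by subject_id + plane)

RUN_COLUMNS = ["step", "phase", "p_deg", "y_deg", "subject_id", "plane", "granularity"]


def runs_to_frame(runs) -> pd.DataFrame:
    rows = []
    for run in runs:
        for n in range(len(run)):
            rows.append((n + 1, run.schedule.phase[n], run.schedule.p[n],
                         run.y[n], run.subject_id, run.plane, run.granularity))
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


def frame_to_runs(frame: pd.DataFrame):
    missing = set(RUN_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    runs = []
    for (subject, plane), grp in frame.groupby(["subject_id", "plane"], sort=False):
        grp = grp.sort_values("step")
        schedule = PerturbationSchedule(p=grp["p_deg"].to_numpy(),
                                        phase=tuple(grp["phase"]))
        runs.append(AdaptationRun(y=grp["y_deg"].to_numpy(), schedule=schedule,
                                  subject_id=str(subject), plane=str(plane),
                                  granularity=str(grp["granularity"].iloc[0])))
    return runs


def write_runs_csv(runs, path) -> None:
    runs_to_frame(runs).to_csv(path, index=False, float_format="%.12g")


def read_runs_csv(path):
    return frame_to_runs(pd.read_csv(path))
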