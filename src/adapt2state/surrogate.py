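"""Synthetic datasets: surrogate adaptation runs and 3D reach trajectories.

Surrogate runs emulate the validation conditions of the study design: each
run's two-state parameters are drawn from normal distributions centred on
values typical of human visuomotor adaptation at epoch granularity
(a_s ~ N(0.93, 0.03), a_f ~ N(0.55, 0.2), b_s ~ N(0.06, 0.04),
b_f ~ N(0.18, 0.08), planning variability ~ N(1.5, 1) deg^2, measurement
variability ~ N(6, 3) deg^2), re-drawn until the ordering constraints
a_s > a_f > 0 and b_f > b_s > 0 and positivity of the variabilities hold.
A correlated variant ties the slow learning rate to the steady-state
Kalman gain (b_s = factor * K) to test whether fitting pipelines recover,
or spuriously introduce, parameter correlations.

Synthetic 3D centre-out reaches (targets on the corners of a 10 cm cube)
provide ground-truthed input for the trajectory-preprocessing chain; they
are geometric fixtures, not biomechanical simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kalman import steady_state_kalman_gain
from .model_core import (PerturbationSchedule, TwoStateParams,
                         runs_to_frame, frame_to_runs)

TRUTH_COLUMNS = ["run_id", "a_s", "a_f", "b_s", "b_f",
                 "planning_var", "measurement_var"]

#: Corners of a 10 cm cube centred on the start position (cm).
CUBE_TARGETS = {
    tid + 1: 5.0 * np.array(corner, dtype=float)
    for tid, corner in enumerate(
        [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
}

#: Unit normal of each perturbation plane (x right, y anterior, z up).
PLANE_NORMALS = {
    "sagittal": np.array([1.0, 0.0, 0.0]),
    "coronal": np.array([0.0, 1.0, 0.0]),
    "horizontal": np.array([0.0, 0.0, 1.0]),
}


@dataclass(frozen=True)
class ParamDistributionSpec:
    """Normal (mean, sd) per generative parameter; defaults are the study values."""

    a_s: tuple = (0.93, 0.03)
    a_f: tuple = (0.55, 0.2)
    b_s: tuple = (0.06, 0.04)
    b_f: tuple = (0.18, 0.08)
    planning_var: tuple = (1.5, 1.0)
    measurement_var: tuple = (6.0, 3.0)

    def __post_init__(self):
        for name in ("a_s", "a_f", "b_s", "b_f", "planning_var", "measurement_var"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: standard deviation must be >= 0")

    def to_dict(self):
        return {k: list(v) for k, v in asdict(self).items()}


@dataclass(frozen=True)
class TrajectoryRecord:
    """Time-stamped 3D hand positions of one trial."""

    t: np.ndarray
    pos: np.ndarray
    trial: int
    target_id: int
    phase: str = "perturbation"
    plane: str = "coronal"

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        pos = np.asarray(self.pos, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pos", pos)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] != len(t):
            raise ValueError("pos must be (n, 3) aligned with t")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")


@dataclass
class SurrogateDataset:
    runs: list = field(default_factory=list)
    truths: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.runs) != len(self.truths):
            raise ValueError("runs and truths must be aligned")

    def truth_array(self) -> np.ndarray:
        """(n_runs, 6) array: a_s, a_f, b_s, b_f, sigma_x, sigma_u."""
        return np.array([t.as_array() for t in self.truths])


class ConstraintRejectionError(RuntimeError):
    pass


def _draw_pos(rng, mean, sd, cap, what):
    """Normal draw truncated to (0, inf) by rejection."""
    for _ in range(cap):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise ConstraintRejectionError(f"could not draw positive {what} in {cap} attempts")


def draw_params(spec: ParamDistributionSpec, seed, max_attempts: int = 100_000) -> TwoStateParams:
    """One constrained parameter draw; rejection keeps draws unbiased within
    the admissible region (a_s > a_f > 0, b_f > b_s > 0, variabilities > 0)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        a_s = rng.normal(*spec.a_s)
        a_f = rng.normal(*spec.a_f)
        b_s = rng.normal(*spec.b_s)
        b_f = rng.normal(*spec.b_f)
        vx = rng.normal(*spec.planning_var)
        vu = rng.normal(*spec.measurement_var)
        if a_s > a_f > 0 and b_f > b_s > 0 and vx > 0 and vu > 0:
            return TwoStateParams(a_s=a_s, a_f=a_f, b_s=b_s, b_f=b_f,
                                  sigma_x=np.sqrt(vx), sigma_u=np.sqrt(vu))
    raise ConstraintRejectionError(
        "could not satisfy a_s > a_f > 0, b_f > b_s > 0, variabilities > 0 "
        f"in {max_attempts} attempts")


def _spawn_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % np.int64(2 ** 31)]


def generate_surrogate_set(n_runs: int, spec: ParamDistributionSpec | None = None,
                           schedule: PerturbationSchedule | None = None,
                           seed: int = 0, plane: str = "coronal") -> SurrogateDataset:
    """n_runs independent (truth, run) pairs; default schedule 15/30/30 epochs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = spec or ParamDistributionSpec()
    schedule = schedule or PerturbationSchedule.standard()
    seeds = _spawn_seeds(seed, 2 * n_runs)
    runs, truths = [], []
    for i in range(n_runs):
        params = draw_params(spec, seeds[2 * i])
        run, _ = simulate_labelled(params, schedule, seeds[2 * i + 1], i, plane)
        runs.append(run)
        truths.append(params)
    meta = {"kind": "uncorrelated", "n_runs": n_runs, "seed": int(seed),
            "plane": plane, "spec": spec.to_dict(),
            "schedule": {"n_steps": len(schedule), "magnitude": schedule.magnitude}}
    return SurrogateDataset(runs=runs, truths=truths, meta=meta)


def simulate_labelled(params, schedule, seed, index, plane):
    from .model_core import simulate_run
    return simulate_run(params, schedule, seed,
                        subject_id=f"run{index:03d}", plane=plane,
                        granularity="epoch")


def generate_correlated_set(n_runs: int, factor: float = 0.3,
                            spec: ParamDistributionSpec | None = None,
                            schedule: PerturbationSchedule | None = None,
                            seed: int = 0, plane: str = "coronal",
                            max_attempts: int = 100_000) -> SurrogateDataset:
    """Variant with the slow learning rate tied to the Kalman gain.

    Per run: draw positive planning/measurement variabilities, compute the
    steady-state gain K, set b_s = factor * K exactly, then draw a_s, a_f
    and b_f (b_f re-drawn until b_f > b_s).
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    spec = spec or ParamDistributionSpec()
    schedule = schedule or PerturbationSchedule.standard()
    seeds = _spawn_seeds(seed, 2 * n_runs)
    runs, truths = [], []
    for i in range(n_runs):
        rng = np.random.default_rng(seeds[2 * i])
        vx = _draw_pos(rng, *spec.planning_var, max_attempts, "planning_var")
        vu = _draw_pos(rng, *spec.measurement_var, max_attempts, "measurement_var")
        b_s = factor * steady_state_kalman_gain(vx, vu)
        for attempt in range(max_attempts):
            a_s = rng.normal(*spec.a_s)
            a_f = rng.normal(*spec.a_f)
            b_f = rng.normal(*spec.b_f)
            if a_s > a_f > 0 and b_f > b_s:
                break
        else:
            raise ConstraintRejectionError(
                f"b_f > b_s = {b_s:.3f} unattainable under the b_f distribution")
        params = TwoStateParams(a_s=a_s, a_f=a_f, b_s=b_s, b_f=b_f,
                                sigma_x=np.sqrt(vx), sigma_u=np.sqrt(vu))
        run, _ = simulate_labelled(params, schedule, seeds[2 * i + 1], i, plane)
        runs.append(run)
        truths.append(params)
    meta = {"kind": "correlated", "factor": factor, "n_runs": n_runs,
            "seed": int(seed), "plane": plane, "spec": spec.to_dict(),
            "schedule": {"n_steps": len(schedule), "magnitude": schedule.magnitude}}
    return SurrogateDataset(runs=runs, truths=truths, meta=meta)


# ---------------------------------------------------------------------------
# Synthetic 3D centre-out reaches


def _min_jerk(tau):
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _lateral_axis(target, plane):
    normal = PLANE_NORMALS[plane]
    t_hat = target / np.linalg.norm(target)
    lat = np.cross(t_hat, normal)
    norm = np.linalg.norm(lat)
    if norm < 1e-9:
        raise ValueError("target direction is normal to the plane: lateral axis degenerate")
    # sign convention: compensation of a counterclockwise (about +normal)
    # perturbation, i.e. a clockwise re-aim, is positive
    return t_hat, lat / norm


def _smooth_noise(rng, n, dt, sd, knot_dt=0.3):
    """Low-frequency isotropic Gaussian position noise with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros((n, 3))
    t = np.arange(n) * dt
    n_knots = max(4, int(np.ceil(t[-1] / knot_dt)) + 2)
    knots = np.linspace(-knot_dt, t[-1] + knot_dt, n_knots)
    vals = rng.normal(0.0, 1.0, size=(n_knots, 3))
    out = np.column_stack([np.interp(t, knots, vals[:, k]) for k in range(3)])
    return sd * out


def synth_trajectories(n_trials: int, aim_angle: float, plane: str,
                       noise_sd: float = 0.0, seed: int = 0,
                       phase: str = "perturbation", curvature: float = 0.0,
                       hold_time: float = 0.4, move_time: float = 0.8,
                       dt: float = 0.01, start_trial: int = 0):
    """Smooth centre-out reaches with a known injected adaptation angle.

    ``aim_angle`` is the ground-truth adaptation angle (deg) on the
    measurement scale: the path leaves the centre along a direction rotated
    within ``plane`` so that the lateral deviation at half the
    centre-to-target distance equals tan(aim_angle) times that half
    distance, then blends back to the target over the second half.  Each
    trial starts with a stationary hold (speed < 3 cm/s) and carries a
    minimum-jerk longitudinal time profile; optional target-specific
    curvature and smooth position noise emulate real kinematics.

    Consecutive blocks of 8 trials visit each cube-corner target once, in
    seeded pseudo-random order.
    """
    if plane not in PLANE_NORMALS:
        raise ValueError(f"plane must be one of {tuple(PLANE_NORMALS)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    tan_aim = np.tan(np.deg2rad(aim_angle))
    records = []
    order = []
    for i in range(n_trials):
        if not order:
            order = list(rng.permutation(list(CUBE_TARGETS)))
        tid = int(order.pop(0))
        target = CUBE_TARGETS[tid]
        dist = np.linalg.norm(target)
        t_hat, l_hat = _lateral_axis(target, plane)
        n_hold = int(round(hold_time / dt))
        n_move = int(round(move_time / dt)) + 1
        tau = np.linspace(0.0, 1.0, n_move)
        lon = dist * _min_jerk(tau)
        half = dist / 2.0
        lat = np.where(lon <= half, lon * tan_aim,
                       half * tan_aim * 0.5 * (1.0 + np.cos(np.pi * (2 * lon / dist - 1.0))))
        # target-specific baseline curvature (same for every trial to a target)
        lat = lat + curvature * np.sin(np.pi * lon / dist) * (1 if tid % 2 else -1)
        move = lon[:, None] * t_hat[None, :] + lat[:, None] * l_hat[None, :]
        pos = np.vstack([np.zeros((n_hold, 3)), move])
        t = np.arange(len(pos)) * dt
        pos = pos + _smooth_noise(rng, len(pos), dt, noise_sd)
        records.append(TrajectoryRecord(t=t, pos=pos, trial=start_trial + i,
                                        target_id=tid, phase=phase, plane=plane))
    return records


# ---------------------------------------------------------------------------
# Writers (plain-text dialects)

TRAJ_COLUMNS = ["trial", "t_s", "x_cm", "y_cm", "z_cm", "target_id", "phase", "plane"]


def trajectories_to_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        for k in range(len(rec.t)):
            rows.append((rec.trial, rec.t[k], rec.pos[k, 0], rec.pos[k, 1],
                         rec.pos[k, 2], rec.target_id, rec.phase, rec.plane))
    return pd.DataFrame(rows, columns=TRAJ_COLUMNS)


def frame_to_trajectories(frame: pd.DataFrame):
    missing = set(TRAJ_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for trial, grp in frame.groupby("trial", sort=True):
        grp = grp.sort_values("t_s")
        records.append(TrajectoryRecord(
            t=grp["t_s"].to_numpy(),
            pos=grp[["x_cm", "y_cm", "z_cm"]].to_numpy(),
            trial=int(trial), target_id=int(grp["target_id"].iloc[0]),
            phase=str(grp["phase"].iloc[0]), plane=str(grp["plane"].iloc[0])))
    return records


def write_dataset(dataset: SurrogateDataset, runs_path, truths_path, meta_path) -> None:
    """Runs CSV + truths CSV (six parameters per run) + meta JSON."""
    runs_to_frame(dataset.runs).to_csv(runs_path, index=False, float_format="%.12g")
    rows = [(run.subject_id, t.a_s, t.a_f, t.b_s, t.b_f,
             t.planning_var, t.measurement_var)
            for run, t in zip(dataset.runs, dataset.truths)]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        truths_path, index=False, float_format="%.12g")
    with open(meta_path, "w") as fh:
        json.dump(dataset.meta, fh, indent=2, sort_keys=True)


def read_dataset(runs_path, truths_path, meta_path=None) -> SurrogateDataset:
    runs = frame_to_runs(pd.read_csv(runs_path))
    tf = pd.read_csv(truths_path)
    by_id = {row.run_id: TwoStateParams(
        a_s=row.a_s, a_f=row.a_f, b_s=row.b_s, b_f=row.b_f,
        sigma_x=np.sqrt(row.planning_var), sigma_u=np.sqrt(row.measurement_var))
        for row in tf.itertuples()}
    truths = [by_id[r.subject_id] for r in runs]
    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    return SurrogateDataset(runs=runs, truths=truths, meta=meta)
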