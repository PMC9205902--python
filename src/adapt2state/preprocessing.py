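"""Trajectory preprocessing: 3D reaches -> epoch-level adaptation angles.

Pipeline per trial: detect movement onset (speed above 3 cm/s), find the
end (first entry into the target sphere), resample the onset-to-end window
to 50 equally spaced time steps, project onto the centre-to-target axis
(longitudinal) and the orthogonal axis lying in the perturbation plane
(lateral), subtract the per-subject/block/target mean baseline profile,
read off the lateral deviation where half the centre-to-target distance is
travelled and convert it to an angle.  Eight-trial sets (one visit to each
cube-corner target) are averaged into epochs, the model's time step.

Sign convention: a counterclockwise perturbation about the plane normal is
compensated by a clockwise re-aim; the lateral axis is oriented so that
this compensatory deviation is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import AdaptationRun, PerturbationSchedule
from .surrogate import CUBE_TARGETS, PLANE_NORMALS, TrajectoryRecord, _lateral_axis

N_SAMPLES = 50  # normalized-duration resampling length


class NoMovementError(ValueError):
    """Speed never exceeded the onset threshold."""


@dataclass(frozen=True)
class LateralProfile:
    """Lateral deviation (cm) at 50 normalized longitudinal samples."""

    s: np.ndarray
    d: np.ndarray
    target_dist: float
    target_id: int | None = None

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "d", d)
        if len(s) != N_SAMPLES or len(d) != N_SAMPLES:
            raise ValueError(f"profiles must have exactly {N_SAMPLES} samples")
        if not self.target_dist > 0:
            raise ValueError("target_dist must be > 0")


def speeds(traj: TrajectoryRecord) -> np.ndarray:
    """Finite-difference speed (cm/s) at each sample; first sample gets 0."""
    step = np.linalg.norm(np.diff(traj.pos, axis=0), axis=1) / np.diff(traj.t)
    return np.concatenate([[0.0], step])


def detect_onset(traj: TrajectoryRecord, v_thresh: float = 3.0, dwell: int = 3) -> int:
    """Index of the first sample whose speed exceeds ``v_thresh`` and stays
    above it for ``dwell`` consecutive samples."""
    if len(traj.t) < 2:
        raise ValueError("need at least 2 samples")
    v = speeds(traj)
    above = v > v_thresh
    for i in range(len(v)):
        window = above[i:i + dwell]
        if len(window) == dwell and window.all():
            return i
    raise NoMovementError(f"speed never exceeded {v_thresh} cm/s for {dwell} samples")


def detect_end(traj: TrajectoryRecord, target_pos, radius: float = 0.75,
               start: int = 0) -> int:
    """First sample (at or after ``start``) inside the target sphere."""
    dist = np.linalg.norm(traj.pos - np.asarray(target_pos, float), axis=1)
    inside = np.nonzero(dist[start:] <= radius)[0]
    if len(inside) == 0:
        raise ValueError("trajectory never enters the target sphere")
    return start + int(inside[0])


def normalize_trajectory(traj: TrajectoryRecord, onset: int, end: int) -> np.ndarray:
    """Resample the onset..end window at 50 equally spaced times; (50, 3)."""
    if not (0 <= onset < end < len(traj.t)):
        raise ValueError("require 0 <= onset < end within the trajectory")
    if end - onset < 1:
        raise ValueError("window must contain at least 2 samples")
    t_win = traj.t[onset:end + 1]
    grid = np.linspace(t_win[0], t_win[-1], N_SAMPLES)
    return np.column_stack([
        np.interp(grid, t_win, traj.pos[onset:end + 1, k]) for k in range(3)])


def project_to_perturbed_dimension(path: np.ndarray, target_pos, plane: str,
                                   target_id: int | None = None) -> LateralProfile:
    """Project a 50-sample path onto (longitudinal, lateral-in-plane) axes."""
    target = np.asarray(target_pos, dtype=float)
    dist = np.linalg.norm(target)
    if dist == 0:
        raise ValueError("target must not be at the origin")
    if plane not in PLANE_NORMALS:
        raise ValueError(f"plane must be one of {tuple(PLANE_NORMALS)}")
    t_hat, l_hat = _lateral_axis(target, plane)
    return LateralProfile(s=path @ t_hat, d=path @ l_hat, target_dist=dist,
                          target_id=target_id)


def baseline_correct(profile: LateralProfile, baseline_mean: LateralProfile) -> LateralProfile:
    """Subtract the mean baseline lateral profile (same target required)."""
    if (profile.target_id is not None and baseline_mean.target_id is not None
            and profile.target_id != baseline_mean.target_id):
        raise ValueError("baseline profile is for a different target")
    return LateralProfile(s=profile.s, d=profile.d - baseline_mean.d,
                          target_dist=profile.target_dist,
                          target_id=profile.target_id)


def mean_profile(profiles) -> LateralProfile:
    """Pointwise mean of lateral profiles sharing a target."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    tids = {p.target_id for p in profiles}
    if len(tids) != 1:
        raise ValueError("profiles mix targets")
    return LateralProfile(
        s=np.mean([p.s for p in profiles], axis=0),
        d=np.mean([p.d for p in profiles], axis=0),
        target_dist=profiles[0].target_dist, target_id=profiles[0].target_id)


def adaptation_angle(profile: LateralProfile) -> float:
    """Adaptation angle (deg): lateral deviation at half the centre-to-target
    distance, as atan2(d_half, target_dist / 2)."""
    half = profile.target_dist / 2.0
    s = profile.s
    if s[0] > half:
        raise ValueError("trajectory starts beyond half distance")
    cross = np.nonzero(s >= half)[0]
    if len(cross) == 0:
        raise ValueError("trajectory never reaches half the centre-to-target distance")
    i = int(cross[0])
    if i == 0 or s[i] == half:
        d_half = profile.d[i]
    else:
        frac = (half - s[i - 1]) / (s[i] - s[i - 1])
        d_half = profile.d[i - 1] + frac * (profile.d[i] - profile.d[i - 1])
    return float(np.degrees(np.arctan2(d_half, half)))


def epochize(angles, target_ids, phases, trials_per_epoch: int = 8,
             magnitude: float = 30.0, subject_id: str = "s01",
             plane: str = "coronal") -> AdaptationRun:
    """Average consecutive 8-trial sets (each target once) into epochs.

    The epoch inherits its trials' phase label; with the standard block
    design epochs never straddle phases, and straddling is rejected.
    """
    angles = np.asarray(angles, dtype=float)
    target_ids = list(target_ids)
    phases = list(phases)
    n = len(angles)
    if not (n == len(target_ids) == len(phases)):
        raise ValueError("angles, target_ids and phases must be aligned")
    if n == 0 or n % trials_per_epoch != 0:
        raise ValueError(f"trial count must be a positive multiple of {trials_per_epoch}")
    epoch_y, epoch_phase = [], []
    for start in range(0, n, trials_per_epoch):
        sl = slice(start, start + trials_per_epoch)
        tids = target_ids[sl]
        if len(set(tids)) != trials_per_epoch:
            raise ValueError(f"epoch starting at trial {start}: duplicated target")
        labs = set(phases[sl])
        if len(labs) != 1:
            raise ValueError(f"epoch starting at trial {start} straddles phases")
        epoch_y.append(angles[sl].mean())
        epoch_phase.append(labs.pop())
    p = np.array([magnitude if lab == "perturbation" else 0.0 for lab in epoch_phase])
    schedule = PerturbationSchedule(p=p, phase=tuple(epoch_phase))
    return AdaptationRun(y=np.array(epoch_y), schedule=schedule,
                         subject_id=subject_id, plane=plane, granularity="epoch")


def process_trajectories(records, plane: str, targets=None, v_thresh: float = 3.0,
                         dwell: int = 3, target_radius: float = 0.75,
                         trials_per_epoch: int = 8, magnitude: float = 30.0,
                         subject_id: str = "s01") -> AdaptationRun:
    """Full chain: trajectories -> baseline-corrected epoch-level run.

    Baseline mean profiles are computed per target from the baseline-phase
    trials of the block and subtracted from every trial of that target.
    """
    targets = targets or CUBE_TARGETS
    records = sorted(records, key=lambda r: r.trial)
    profiles, tids, phases = [], [], []
    for rec in records:
        onset = detect_onset(rec, v_thresh=v_thresh, dwell=dwell)
        end = detect_end(rec, targets[rec.target_id], radius=target_radius, start=onset)
        path = normalize_trajectory(rec, onset, end)
        profiles.append(project_to_perturbed_dimension(
            path, targets[rec.target_id], plane, target_id=rec.target_id))
        tids.append(rec.target_id)
        phases.append(rec.phase)
    baseline_means = {}
    for tid in set(tids):
        base = [pr for pr, ti, ph in zip(profiles, tids, phases)
                if ti == tid and ph == "baseline"]
        if base:
            baseline_means[tid] = mean_profile(base)
    corrected = [baseline_correct(pr, baseline_means[ti]) if ti in baseline_means else pr
                 for pr, ti in zip(profiles, tids)]
    angles = [adaptation_angle(pr) for pr in corrected]
    return epochize(angles, tids, phases, trials_per_epoch=trials_per_epoch,
                    magnitude=magnitude, subject_id=subject_id, plane=plane)
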