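"""Run configuration, manifests and reproducible pipeline glue.

A RunConfig is a fully serialisable description of one pipeline run: the
schedule, the surrogate parameter distributions, the priors, the sampler
settings and a root seed.  All randomness flows from the root seed, split
deterministically per stage, so a persisted config re-executes to
identical outputs.  Floating-point CSV output is fixed at 12 significant
digits to keep re-runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .inference import PriorSpec, SamplerConfig
from .model_core import PerturbationSchedule
from .surrogate import ParamDistributionSpec


@dataclass
class ScheduleSpec:
    n_baseline: int = 15
    n_perturbation: int = 30
    n_washout: int = 30
    magnitude: float = 30.0
    trials_per_epoch: int = 8
    per_trial: bool = False

    def build(self) -> PerturbationSchedule:
        kwargs = dict(n_baseline=self.n_baseline,
                      n_perturbation=self.n_perturbation,
                      n_washout=self.n_washout, magnitude=self.magnitude)
        if self.per_trial:
            return PerturbationSchedule.standard_trials(
                trials_per_epoch=self.trials_per_epoch, **kwargs)
        return PerturbationSchedule.standard(**kwargs)


@dataclass
class RunConfig:
    seed: int = 0
    n_runs: int = 100
    correlation_factor: float = 0.3
    plane: str = "coronal"
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    distributions: ParamDistributionSpec = field(default_factory=ParamDistributionSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {"seed", "n_runs", "correlation_factor", "plane", "schedule",
                 "distributions", "priors", "sampler"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")

        def build(cls_, kwargs, section):
            valid = {f.name for f in dataclasses.fields(cls_)}
            bad = set(kwargs) - valid
            if bad:
                raise ValueError(
                    f"invalid config keys in [{section}]: {sorted(bad)}")
            return cls_(**kwargs)

        if "schedule" in data:
            data["schedule"] = build(ScheduleSpec, data["schedule"], "schedule")
        if "distributions" in data:
            data["distributions"] = ParamDistributionSpec(
                **{k: tuple(v) for k, v in data["distributions"].items()})
        if "priors" in data:
            pr = dict(data["priors"])
            for key in ("retention_mean", "learning_mean"):
                if key in pr:
                    pr[key] = tuple(pr[key])
            data["priors"] = build(PriorSpec, pr, "priors")
        if "sampler" in data:
            data["sampler"] = build(SamplerConfig, data["sampler"], "sampler")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)


def write_manifest(path, config: RunConfig, command: str, extra=None) -> None:
    import adapt2state
    manifest = {
        "command": command,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"adapt2state": adapt2state.__version__,
                     "numpy": np.__version__},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
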