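"""Run configuration: strict YAML schema, loading, saving.

YAML is the canonical config dialect (JSON being a subset is accepted
too).  The schema is strict — unknown keys are rejected with an error
naming the offending field — because a typo in a prescription silently
changes clinical semantics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .autoplan import LoopConfig, Prescription, default_prostate_prescription
from .dose import KernelConfig
from .fmo import SolverConfig
from .objectives import Model
from .phantom import BeamSpec, PhantomSpec, default_prostate_spec


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_lbfgs_iters: int = 50
    tol: float = 1e-6
    history_size: int = 10

    def to_solver_config(self) -> SolverConfig:
        cfg = SolverConfig(self.max_lbfgs_iters, self.tol, self.history_size)
        cfg.validate()
        return cfg


class KernelSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mu_attenuation: float = 0.005
    sigma_penumbra: float = 3.0
    floor: float = 1e-4

    def to_kernel_config(self) -> KernelConfig:
        cfg = KernelConfig(self.mu_attenuation, self.sigma_penumbra, self.floor)
        cfg.validate()
        return cfg


class RunConfig(BaseModel):
    """Everything needed to reproduce a run."""

    model_config = ConfigDict(extra="forbid")

    phantom: Union[str, PhantomSpec] = "prostate"  # preset name or inline spec
    beams: BeamSpec = Field(default_factory=BeamSpec)
    kernel: KernelSettings = Field(default_factory=KernelSettings)
    prescription: Optional[Prescription] = None  # None -> prostate preset
    model: Model = "dv"
    solver: SolverSettings = Field(default_factory=SolverSettings)
    loop: LoopConfig = Field(default_factory=LoopConfig)
    seed: int = 0
    push_coverage: bool = False

    def resolved_phantom_spec(self) -> PhantomSpec:
        if isinstance(self.phantom, PhantomSpec):
            return self.phantom
        if self.phantom == "prostate":
            return default_prostate_spec(seed=self.seed)
        raise ValueError(f"unknown phantom preset '{self.phantom}'")

    def resolved_prescription(self) -> Prescription:
        return self.prescription or default_prostate_prescription()


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; fail fast on schema errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            " -> ".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({path}): {locs}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
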