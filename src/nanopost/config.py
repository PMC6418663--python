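"""Run configuration: validated YAML blocks for chain, geometry, force
field, simulation and analysis settings.

Unknown keys are rejected, defaults are filled in, and a resolved config
round-trips losslessly through YAML.  The resolved config (plus its hash)
is echoed into every output header so runs are reproducible from their
artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .constants import BEAD_SIZE, SQRT2
from .dynamics import SimulationParams
from .forcefield import ForceFieldParams
from .geometry import PostArrayGeometry

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChainConfig(_Block):
    topology: Literal["linear", "circular"] = "linear"
    N: int = Field(100, ge=3)
    b: float = Field(0.0, ge=0.0)
    orientation: Literal["parallel", "perpendicular"] = "parallel"


class GeometryConfig(_Block):
    """Post array; specify any two of (S_p, d_p, w_p). Omit block for free chains."""

    S_p: Optional[float] = Field(None, gt=0)
    d_p: Optional[float] = Field(None, ge=0)
    w_p: Optional[float] = None
    w: float = Field(BEAD_SIZE, gt=0)

    @model_validator(mode="after")
    def _resolve(self) -> "GeometryConfig":
        given = [v is not None for v in (self.S_p, self.d_p, self.w_p)]
        if sum(given) < 2:
            raise ValueError("geometry needs at least two of (S_p, d_p, w_p)")
        if self.S_p is None:
            self.S_p = self.d_p + self.w_p
        elif self.d_p is None:
            self.d_p = self.S_p - self.w_p
        elif self.w_p is None:
            self.w_p = self.S_p - self.d_p
        elif abs(self.S_p - self.d_p - self.w_p) > 1e-9:
            raise ValueError(
                f"inconsistent geometry: S_p - d_p = {self.S_p - self.d_p} "
                f"but w_p = {self.w_p}"
            )
        if self.d_p > SQRT2 * self.S_p:
            raise ValueError(
                f"d_p = {self.d_p} > sqrt(2)*S_p = {SQRT2 * self.S_p:.6g}: "
                "posts overlap"
            )
        return self

    def build(self) -> PostArrayGeometry:
        return PostArrayGeometry(S_p=self.S_p, d_p=self.d_p, w=self.w)


class ForceFieldConfig(_Block):
    epsilon: float = Field(1.0, gt=0)
    sigma: float = Field(1.0, gt=0)
    kappa: float = Field(30.0, gt=0)
    R_o: float = Field(1.5, gt=0)
    l: float = Field(0.97, gt=0)

    def build(self, b: float) -> ForceFieldParams:
        return ForceFieldParams(
            epsilon=self.epsilon, sigma=self.sigma, kappa=self.kappa,
            R_o=self.R_o, b=b, l=self.l,
        )


class SimulationConfig(_Block):
    dt: float = Field(0.005, gt=0)
    T: float = Field(1.0, gt=0)
    thermostat: Literal["nose_hoover", "langevin", "none"] = "nose_hoover"
    relaxation: float = Field(0.1, gt=0)
    friction: float = Field(1.0, gt=0)
    seed: int = 0
    n_equil: int = Field(100_000, ge=0)
    n_prod: int = Field(1_000_000, ge=1)
    sample_every: int = Field(1000, ge=1)

    def build(self) -> SimulationParams:
        return SimulationParams(
            dt=self.dt, T=self.T, thermostat=self.thermostat,
            relaxation=self.relaxation, friction=self.friction, seed=self.seed,
            n_equil=self.n_equil, n_prod=self.n_prod,
            sample_every=self.sample_every,
        )


class AnalysisConfig(_Block):
    n_blocks: int = Field(10, ge=2)
    q_points: int = Field(200, ge=10)
    persistence_c_min: float = Field(0.6065306597126334, gt=0, lt=1)


class RunConfig(_Block):
    chain: ChainConfig = ChainConfig()
    geometry: Optional[GeometryConfig] = None
    forcefield: ForceFieldConfig = ForceFieldConfig()
    simulation: SimulationConfig = SimulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All validation violations are reported together in the error message.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(raw, source=str(path))


def parse_config(raw: dict, source: str = "<dict>") -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{source}: invalid configuration:\n  " + "\n  ".join(lines))


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.resolved_dict(), sort_keys=False))
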