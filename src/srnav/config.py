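"""Run configuration schema and deterministic seed derivation.

A single YAML-serialisable config captures everything a run depends on:
world-generator parameters, agent hyperparameters, lesion variant, and
scale.  All randomness derives from one master seed through named,
independent streams, so every artifact is reproducible bitwise from
(config, seed).
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .worldgen import GeneratorParams


class AgentConfig(BaseModel):
    """Agent hyperparameters (defaults documented in docs/methods.md)."""

    model_config = ConfigDict(extra="forbid")

    gamma_A: float = Field(0.95, gt=0.0, lt=1.0)   # allocentric SR discount
    gamma_E: float = Field(0.9, gt=0.0, lt=1.0)    # egocentric SR discount
    gamma_Q: float = Field(0.95, gt=0.0, lt=1.0)   # Q-learning discount
    alpha_A: float = Field(0.05, ge=0.0)           # allocentric SR TD rate
    alpha_E: float = Field(0.05, ge=0.0)           # egocentric SR TD rate
    eta: float = Field(1e-3, gt=0.0)               # ADAM step size
    beta1: float = Field(0.9, ge=0.0, lt=1.0)
    beta2: float = Field(0.999, ge=0.0, lt=1.0)
    eps_adam: float = Field(1e-2, gt=0.0)
    epsilon: float = Field(0.1, ge=0.0, le=1.0)    # uniform-exploration prob
    tau: float = Field(0.01, gt=0.0)               # softmax temperature
    horizon: int = Field(2, ge=1)                  # egocentric view depth H
    episode_cap: int = Field(10_000, ge=1)         # primitive-step truncation
    adam_no_sqrt: bool = False                     # literal m-hat/v-hat step
    ego_init_single_world: bool = False            # init from world 0 only


class WorldConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    paradigm: str = "MAIN"
    width: int = Field(20, ge=5)
    height: int = Field(20, ge=5)
    barrier_size: int = Field(4, ge=3)
    barrier_size_min: int = Field(3, ge=3)
    barrier_size_max: int = Field(6, ge=3)
    attempts: int = Field(20, ge=0)
    buffer: int = Field(1, ge=1)
    density: float = Field(0.2, ge=0.0, lt=1.0)
    n_worlds: int = Field(5, ge=1)
    first_reward_corner: str = "TR"

    def to_params(self) -> GeneratorParams:
        return GeneratorParams(
            paradigm=self.paradigm, width=self.width, height=self.height,
            barrier_size=self.barrier_size,
            barrier_size_range=(self.barrier_size_min, self.barrier_size_max),
            attempts=self.attempts, buffer=self.buffer, density=self.density,
            n_worlds=self.n_worlds, first_reward_corner=self.first_reward_corner)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    world: WorldConfig = WorldConfig()
    agent: AgentConfig = AgentConfig()
    lesion: str = "FULL"
    episodes_per_world: int = Field(1000, ge=0)
    n_tasks: int = Field(30, ge=1)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected with
    field-level messages, an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


# ---------------------------------------------------------------------------
# seeding


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode())


def seed_streams(master_seed: int,
                 names: tuple[str, ...] = ("worldgen", "starts", "policy",
                                           "permutation")) -> dict[str, np.random.Generator]:
    """Named independent generators derived from one master seed."""
    return {name: np.random.default_rng(
        np.random.SeedSequence([master_seed, _name_key(name)]))
        for name in names}


def child_seed(master_seed: int, *keys: int | str) -> int:
    """A deterministic 31-bit child seed for (master, keys...)."""
    ints = [master_seed] + [_name_key(k) if isinstance(k, str) else int(k)
                            for k in keys]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2 ** 31))
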