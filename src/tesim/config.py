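"""Run configuration: the single source of truth for one simulation.

Every model parameter of the TE dynamics model lives here: census size ``N``,
per-copy transposition probability ``u``, per-copy selection coefficient ``s``,
the crossover rate ``r`` (per bp per meiosis), the fitness-interaction mode,
the silencing parameters ``a`` (Poisson scale of the silencing magnitude),
``b`` (how strongly silencing inflates selection) and ``k`` (how strongly it
suppresses transposition), the modifier-allele protocol, and the ectopic
recombination model (``r_e``, suppression flag, threshold ``T``).
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

import yaml

FITNESS_MODES = ("additive", "multiplicative", "synergistic")
MODIFIER_DIRECTIONS = ("none", "enhance", "weaken")


class ConfigError(ValueError):
    """A configuration field violates the model's constraints."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters and run controls for one forward simulation.

    Defaults follow the study conditions: two 50-Mb chromosomes, silencing
    scale ``a = 0.02``, modifier introduced at 10% frequency after a
    5000-generation burn-in.
    """

    N: int = 2000
    chrom_length: int = 50_000_000
    n_chroms: int = 2
    u: float = 0.01
    s: float = 1e-3
    r: float = 1e-6
    fitness_mode: str = "additive"
    a: float = 0.02
    b: float = 0.0
    k: float = 0.0
    n0: int = 10
    max_generations: int = 10_000
    burn_in_generations: int = 5000
    modifier_direction: str = "none"
    modifier_init_freq: float = 0.10
    invasion_generations: int = 5000
    modifier_chromosome: int = 0
    modifier_position: int | None = None  # defaults to chrom_length // 2
    r_e: float = 0.0
    ectopic_suppression: bool = False
    T: float = 0.0
    crash_patience: int = 25
    seed: int = 0
    replicates: int = 1
    record_stride: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.N < 2:
            raise ConfigError("N", "need at least 2 individuals")
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length", "must be positive")
        if self.n_chroms < 1:
            raise ConfigError("n_chroms", "must be at least 1")
        if not 0.0 <= self.u <= 1.0:
            raise ConfigError("u", "transposition probability must be in [0, 1]")
        if not 0.0 <= self.s <= 1.0:
            raise ConfigError("s", "selection coefficient must be in [0, 1]")
        if self.r < 0.0:
            raise ConfigError("r", "crossover rate must be non-negative")
        if self.fitness_mode not in FITNESS_MODES:
            raise ConfigError("fitness_mode", f"must be one of {FITNESS_MODES}")
        if self.b < 0.0:
            raise ConfigError("b", "must be non-negative")
        if self.k < 0.0:
            raise ConfigError("k", "must be non-negative")
        if (self.b > 0.0 or self.k > 0.0) and self.a <= 0.0:
            raise ConfigError("a", "must be positive when silencing is active (b > 0 or k > 0)")
        if self.fitness_mode == "synergistic" and (self.b > 0.0 or self.k > 0.0):
            raise ConfigError(
                "fitness_mode",
                "silenced-TE fitness is defined only for additive and multiplicative "
                "modes; synergistic requires b = 0 and k = 0",
            )
        if self.n0 < 0:
            raise ConfigError("n0", "initial copy number must be non-negative")
        if self.n0 > self.n_chroms * self.chrom_length:
            raise ConfigError("n0", "more initial copies than available sites")
        if self.max_generations < 0:
            raise ConfigError("max_generations", "must be non-negative")
        if self.modifier_direction not in MODIFIER_DIRECTIONS:
            raise ConfigError(
                "modifier_direction", f"must be one of {MODIFIER_DIRECTIONS}"
            )
        if not 0.0 <= self.modifier_init_freq <= 1.0:
            raise ConfigError("modifier_init_freq", "must be in [0, 1]")
        if not 0 <= self.modifier_chromosome < self.n_chroms:
            raise ConfigError("modifier_chromosome", "chromosome index out of range")
        if self.modifier_position is not None and not (
            0 <= self.modifier_position < self.chrom_length
        ):
            raise ConfigError("modifier_position", "position outside chromosome")
        if not 0.0 <= self.r_e <= 1.0:
            raise ConfigError("r_e", "per-pair event probability must be in [0, 1]")
        if self.T < 0.0:
            raise ConfigError("T", "silencing threshold must be non-negative")
        if self.crash_patience < 1:
            raise ConfigError("crash_patience", "must be at least 1")
        if self.replicates < 0:
            raise ConfigError("replicates", "must be non-negative")
        if self.record_stride < 1:
            raise ConfigError("record_stride", "must be at least 1")

    # -- convenience ------------------------------------------------------
    @property
    def modifier_locus_position(self) -> int:
        """Modifier locus bp position (middle of the chromosome by default)."""
        if self.modifier_position is not None:
            return self.modifier_position
        return self.chrom_length // 2

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration key")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML or TOML key/value file."""
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("<root>", "config file must be a key/value mapping")
        return cls.from_dict(data)
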