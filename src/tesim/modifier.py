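"""Host modifier alleles of TE silencing and the burn-in/invasion protocol.

A single biallelic modifier locus (middle of a chromosome by default) scales
the silencing parameter ``a`` semi-dominantly: with dosage H = 0, 0.5 or 1
for non-carriers, heterozygotes and homozygotes,

* enhancing allele:  a' = a * (1 + 0.5 * H)
* weakening allele:  a' = a * (1 - 0.5 * H)

The invasion experiment runs the population without the modifier for a
burn-in (default 5000 generations, letting copy number settle at
transposition-selection balance), then places allele copies in randomly
sampled individuals to reach a target frequency (10% by default, one copy
per carrier), and follows the allele through the invasion phase.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .engine import PackedPopulation, init_packed, run_chunk
from .genome import Population


@dataclasses.dataclass
class ModifierSpec:
    direction: str  # "enhance" | "weaken"
    locus_chromosome: int = 0
    locus_position: int = 25_000_000
    init_freq: float = 0.10
    effect_size: float = 0.5  # fraction of a added/removed at homozygosity

    def __post_init__(self) -> None:
        if self.direction not in ("enhance", "weaken"):
            raise ConfigError("direction", "must be 'enhance' or 'weaken'")
        if not 0.0 < self.init_freq < 1.0:
            raise ConfigError("init_freq", "must be in (0, 1)")


def modifier_dosage(individual_or_copies) -> float:
    """Map modifier copies 0/1/2 to dosage H = 0 / 0.5 / 1."""
    copies = getattr(individual_or_copies, "modifier_copies", individual_or_copies)
    if copies not in (0, 1, 2):
        raise ValueError("modifier copies must be 0, 1 or 2")
    return copies * 0.5


def effective_silencing_parameter(a: float, direction: str, H: float,
                                  effect_size: float = 0.5) -> float:
    """a' = a * (1 +/- effect_size * H) for an enhancing/weakening allele."""
    if a <= 0.0:
        raise ValueError("a must be positive")
    sign = 1.0 if direction == "enhance" else -1.0
    return a * (1.0 + sign * effect_size * H)


def effective_silencing_parameter_for(config: SimulationConfig, copies: int
                                      ) -> float:
    """Effective a' for an individual given the configured direction."""
    if config.modifier_direction == "none" or copies == 0:
        return config.a
    return effective_silencing_parameter(
        config.a, config.modifier_direction, modifier_dosage(copies)
    )


def _allele_budget(n_individuals: int, init_freq: float) -> int:
    copies = int(round(2 * n_individuals * init_freq))
    if copies < 1:
        raise ConfigError(
            "modifier_init_freq",
            "frequency corresponds to fewer than one allele copy",
        )
    return copies


def introduce_modifier(population: Population, spec: ModifierSpec,
                       rng: np.random.Generator) -> Population:
    """Place allele copies in randomly sampled individuals at spec.init_freq.

    Carriers receive one copy each (heterozygotes, random homolog) until the
    ``round(2N * init_freq)`` copy budget is met; if the budget exceeds N,
    randomly chosen carriers are upgraded to homozygotes.
    """
    n = population.size
    copies = _allele_budget(n, spec.init_freq)
    het = min(copies, n)
    carriers = rng.choice(n, size=het, replace=False)
    for idx in carriers:
        hom = int(rng.integers(0, 2))
        population.individuals[idx].modifier_homologs = (hom == 0, hom == 1)
    if copies > n:
        extra = rng.choice(carriers, size=copies - n, replace=False)
        for idx in extra:
            population.individuals[idx].modifier_homologs = (True, True)
    return population


def introduce_modifier_packed(state: PackedPopulation, init_freq: float,
                              rng: np.random.Generator) -> PackedPopulation:
    n = state.size
    copies = _allele_budget(n, init_freq)
    het = min(copies, n)
    carriers = rng.choice(n, size=het, replace=False)
    state.mod0[:] = 0
    state.mod1[:] = 0
    homs = rng.integers(0, 2, size=het)
    for idx, hom in zip(carriers, homs):
        if hom == 0:
            state.mod0[idx] = 1
        else:
            state.mod1[idx] = 1
    if copies > n:
        extra = rng.choice(carriers, size=copies - n, replace=False)
        for idx in extra:
            state.mod0[idx] = 1
            state.mod1[idx] = 1
    return state


@dataclasses.dataclass
class InvasionResult:
    """Two-phase trajectory plus the fate of the modifier allele."""

    trajectory: pd.DataFrame  # with a "phase" column
    final_frequency: float
    outcome: str  # "fixed" | "lost" | "segregating" | "aborted"
    burn_in_status: str
    invasion_status: str | None = None


def run_invasion_experiment(config: SimulationConfig, seed: int | None = None
                            ) -> InvasionResult:
    """Burn in without the modifier, introduce it at 10%, follow its fate."""
    if config.modifier_direction == "none":
        raise ConfigError("modifier_direction", "invasion requires enhance or weaken")
    if seed is None:
        seed = config.seed
    seed = int(seed) % 2**31
    state = init_packed(config, (seed * 2 + 1) % 2**31)
    state, pre_traj, pre_status = run_chunk(
        state, config, config.burn_in_generations, seed, have_fitness=False
    )
    pre_traj["phase"] = "pre_invasion"
    if pre_status != "completed":
        pre_traj["status"] = pre_status
        return InvasionResult(pre_traj, 0.0, "aborted", pre_status)

    rng = np.random.default_rng(seed + 7_777_777)
    state = introduce_modifier_packed(state, config.modifier_init_freq, rng)

    # fixation and loss are absorbing (no recurrent modifier mutation), so
    # run the invasion phase in chunks and stop early once absorbed, keeping
    # a short tail to observe the post-fixation copy-number response
    chunk = 250
    tail_after_absorption = min(500, config.invasion_generations)
    remaining = config.invasion_generations
    absorbed_at: int | None = None
    pieces = []
    inv_status = "completed"
    piece_seed = (seed + 99_991) % 2**31
    first = True
    while remaining > 0:
        n_gens = min(chunk, remaining)
        state, piece, inv_status = run_chunk(state, config, n_gens,
                                             piece_seed, have_fitness=True)
        piece_seed = (piece_seed + 104_729) % 2**31
        pieces.append(piece if first else piece.iloc[1:])
        first = False
        remaining -= n_gens
        if inv_status != "completed":
            break
        freq_now = float(state.modifier_frequency())
        if absorbed_at is None and freq_now in (0.0, 1.0):
            absorbed_at = config.invasion_generations - remaining
            remaining = min(remaining, tail_after_absorption)
    inv_traj = pd.concat(pieces, ignore_index=True)
    inv_traj = inv_traj.iloc[1:].reset_index(drop=True)  # entering row repeats
    inv_traj["phase"] = "invasion"
    freq = float(state.modifier_frequency())
    if freq >= 1.0:
        outcome = "fixed"
    elif freq <= 0.0:
        outcome = "lost"
    else:
        outcome = "segregating"
    traj = pd.concat([pre_traj, inv_traj], ignore_index=True)
    traj["status"] = inv_status
    return InvasionResult(traj, freq, outcome, pre_status, inv_status)
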