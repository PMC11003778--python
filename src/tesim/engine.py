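"""Wright-Fisher generation cycle and full simulation runs.

One generation is: fitness-weighted parent sampling (within each sex) ->
gamete formation with recombination -> fusion into N offspring -> per-copy
silencing draw -> transposition -> ectopic-recombination viability ->
fitness. ``step_generation`` implements the cycle on the object-level API
for small populations and tests; ``run_simulation`` runs whole replicates on
the packed numba kernels (same model, vectorized genome representation).

A run terminates at ``max_generations`` (status ``completed``), when the
mean copy number reaches zero (``te_loss``), when mean fitness falls below
0.1% (``population_crash``), or when one sex has no individual with positive
fitness (``extinct``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _kernels
from .config import SimulationConfig
from .ectopic import EctopicConfig, ectopic_viability
from .genome import (FEMALE, MALE, Gamete, Individual, Population,
                     TEInsertion, copy_number, fuse_gametes, init_population,
                     make_gamete)
from .silencing import SilencingState, draw_silencing, individual_fitness

STATUS_NAMES = {
    _kernels.COMPLETED: "completed",
    _kernels.TE_LOSS: "te_loss",
    _kernels.POPULATION_CRASH: "population_crash",
    _kernels.EXTINCT: "extinct",
}

MODE_CODES = {"additive": _kernels.ADDITIVE,
              "multiplicative": _kernels.MULTIPLICATIVE,
              "synergistic": _kernels.SYNERGISTIC}
DIRECTION_CODES = {"none": _kernels.MOD_NONE,
                   "enhance": _kernels.MOD_ENHANCE,
                   "weaken": _kernels.MOD_WEAKEN}


@dataclasses.dataclass
class TrajectoryRecord:
    generation: int
    mean_copy_number: float
    mean_fitness: float
    modifier_frequency: float


@dataclasses.dataclass
class PackedPopulation:
    """CSR-packed population state (see :mod:`tesim._kernels`)."""

    sites: np.ndarray
    homs: np.ndarray
    indptr: np.ndarray
    sex: np.ndarray
    mod0: np.ndarray
    mod1: np.ndarray
    fitness: np.ndarray
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.sex)

    def mean_copy_number(self) -> float:
        return float(self.indptr[-1] / self.size)

    def modifier_frequency(self) -> float:
        return float((self.mod0.sum() + self.mod1.sum()) / (2 * self.size))

    @classmethod
    def from_population(cls, pop: Population, config: SimulationConfig
                        ) -> "PackedPopulation":
        L = config.chrom_length
        sites_l: list[int] = []
        homs_l: list[int] = []
        indptr = np.zeros(pop.size + 1, dtype=np.int64)
        sex = np.zeros(pop.size, dtype=np.uint8)
        mod0 = np.zeros(pop.size, dtype=np.uint8)
        mod1 = np.zeros(pop.size, dtype=np.uint8)
        fitness = np.ones(pop.size, dtype=np.float64)
        for i, ind in enumerate(pop.individuals):
            ins = sorted(ind.insertions)
            sites_l.extend(ins_.chromosome * L + ins_.position for ins_ in ins)
            homs_l.extend(ins_.homolog for ins_ in ins)
            indptr[i + 1] = indptr[i] + len(ins)
            sex[i] = 0 if ind.sex == FEMALE else 1
            mod0[i] = int(ind.modifier_homologs[0])
            mod1[i] = int(ind.modifier_homologs[1])
            fitness[i] = ind.fitness
        return cls(np.asarray(sites_l, dtype=np.int64),
                   np.asarray(homs_l, dtype=np.uint8),
                   indptr, sex, mod0, mod1, fitness, pop.generation)

    def to_population(self, config: SimulationConfig) -> Population:
        L = config.chrom_length
        individuals = []
        for i in range(self.size):
            lo, hi = self.indptr[i], self.indptr[i + 1]
            ins = {
                TEInsertion(int(st // L), int(st % L), int(h))
                for st, h in zip(self.sites[lo:hi], self.homs[lo:hi])
            }
            individuals.append(Individual(
                insertions=ins,
                sex=FEMALE if self.sex[i] == 0 else MALE,
                modifier_homologs=(bool(self.mod0[i]), bool(self.mod1[i])),
                fitness=float(self.fitness[i]),
            ))
        return Population(individuals=individuals, generation=self.generation)


@dataclasses.dataclass
class SimulationResult:
    trajectory: pd.DataFrame
    status: str
    final_state: PackedPopulation | None = None

    @property
    def generations(self) -> int:
        return len(self.trajectory)


class ExtinctionError(RuntimeError):
    """No reproducible parent of one sex (all-zero fitness or sex absent)."""


# ---------------------------------------------------------------------------
# object-level cycle (reference implementation for small populations)
# ---------------------------------------------------------------------------

def select_parents(population: Population, rng: np.random.Generator
                   ) -> list[tuple[Individual, Individual]]:
    """Sample N (mother, father) pairs with probability proportional to W."""
    females = [ind for ind in population.individuals if ind.sex == FEMALE]
    males = [ind for ind in population.individuals if ind.sex == MALE]
    if not females or not males:
        raise ExtinctionError("a sex is absent from the population")
    wf = np.array([ind.fitness for ind in females], dtype=float)
    wm = np.array([ind.fitness for ind in males], dtype=float)
    if wf.sum() <= 0.0 or wm.sum() <= 0.0:
        raise ExtinctionError("all individuals of one sex have zero fitness")
    n = population.size
    mothers = rng.choice(len(females), size=n, p=wf / wf.sum())
    fathers = rng.choice(len(males), size=n, p=wm / wm.sum())
    return [(females[i], males[j]) for i, j in zip(mothers, fathers)]


def transpose_genome(
    offspring: Individual,
    state: SilencingState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Individual:
    """Duplicate each copy i with probability u_i' into a free random site.

    Newborn copies do not transpose in the generation of their birth.
    """
    insertions = sorted(offspring.insertions)
    if state.magnitudes.size != len(insertions):
        raise ValueError("silencing state does not match the individual's insertions")
    occupied = set(offspring.insertions)
    u, k = config.u, config.k
    new_copies: list[TEInsertion] = []
    for ins, m in zip(insertions, state.magnitudes):
        u_eff = max(0.0, u * (1.0 - k * m))
        if u_eff > 0.0 and rng.random() < u_eff:
            while True:
                chrom = int(rng.integers(0, config.n_chroms))
                pos = int(rng.integers(0, config.chrom_length))
                hom = int(rng.integers(0, 2))
                cand = TEInsertion(chrom, pos, hom)
                if cand not in occupied:
                    break
            occupied.add(cand)
            new_copies.append(cand)
    offspring.insertions |= set(new_copies)
    return offspring


def step_generation(population: Population, config: SimulationConfig,
                    rng: np.random.Generator) -> Population:
    """Advance the population exactly one generation (object-level path)."""
    from .modifier import effective_silencing_parameter_for

    pairs = select_parents(population, rng)
    ect = EctopicConfig(r_e=config.r_e, suppression_on=config.ectopic_suppression,
                        T=config.T)
    offspring: list[Individual] = []
    for mother, father in pairs:
        gm = make_gamete(mother, config, rng)
        gp = make_gamete(father, config, rng)
        sex = FEMALE if rng.random() < 0.5 else MALE
        child = fuse_gametes(gm, gp, sex)
        a_eff = effective_silencing_parameter_for(config, child.modifier_copies)
        state = draw_silencing(child, a_eff, rng)
        pre_sorted = sorted(child.insertions)
        child = transpose_genome(child, state, config, rng)
        # newborn copies carry M = 0 in their birth generation
        full_mags = np.zeros(copy_number(child), dtype=np.int64)
        order = {ins: i for i, ins in enumerate(sorted(child.insertions))}
        for ins, m in zip(pre_sorted, state.magnitudes):
            full_mags[order[ins]] = m
        full_state = SilencingState(magnitudes=full_mags, a_eff=a_eff)
        viable = ectopic_viability(child, full_state, ect, rng)
        child.fitness = (
            individual_fitness(child, full_state, config) if viable else 0.0
        )
        offspring.append(child)
    return Population(individuals=offspring, generation=population.generation + 1)


# ---------------------------------------------------------------------------
# packed fast path
# ---------------------------------------------------------------------------

def _kernel_args(config: SimulationConfig) -> tuple:
    mod_site = (config.modifier_chromosome * config.chrom_length
                + config.modifier_locus_position)
    return (
        config.N, config.chrom_length, config.n_chroms,
        float(config.u), float(config.s), float(config.r),
        MODE_CODES[config.fitness_mode], float(config.a), float(config.b),
        float(config.k), DIRECTION_CODES[config.modifier_direction],
        mod_site, float(config.r_e), bool(config.ectopic_suppression),
        float(config.T),
    )


def init_packed(config: SimulationConfig, seed: int) -> PackedPopulation:
    """Found a packed population (same initialization as init_population)."""
    sites, homs, indptr, sex = _kernels.init_population_packed(
        config.N, config.chrom_length, config.n_chroms, config.n0, seed
    )
    n = config.N
    return PackedPopulation(
        sites=sites, homs=homs, indptr=indptr, sex=sex,
        mod0=np.zeros(n, dtype=np.uint8), mod1=np.zeros(n, dtype=np.uint8),
        fitness=np.ones(n, dtype=np.float64), generation=0,
    )


def run_chunk(state: PackedPopulation, config: SimulationConfig,
              n_gens: int, seed: int, have_fitness: bool = False
              ) -> tuple[PackedPopulation, pd.DataFrame, str]:
    """Advance a packed population up to ``n_gens`` generations."""
    rec_n = np.zeros(n_gens + 1, dtype=np.float64)
    rec_w = np.zeros(n_gens + 1, dtype=np.float64)
    rec_m = np.zeros(n_gens + 1, dtype=np.float64)
    (sites, homs, indptr, sex, mod0, mod1, fitness, status, done
     ) = _kernels.simulate_chunk(
        state.sites, state.homs, state.indptr, state.sex,
        state.mod0, state.mod1, state.fitness, have_fitness,
        *_kernel_args(config), n_gens, seed, config.crash_patience,
        rec_n, rec_w, rec_m,
    )
    gen0 = state.generation
    out = PackedPopulation(sites, homs, indptr, sex, mod0, mod1, fitness,
                           generation=gen0 + done - 1)
    stride = config.record_stride
    idx = np.arange(done)
    keep = (idx % stride == 0) | (idx == done - 1)
    traj = pd.DataFrame({
        "generation": gen0 + idx[keep],
        "mean_copy_number": rec_n[:done][keep],
        "mean_fitness": rec_w[:done][keep],
        "modifier_frequency": rec_m[:done][keep],
    })
    return out, traj, STATUS_NAMES[status]


def run_simulation(config: SimulationConfig, seed: int | None = None
                   ) -> SimulationResult:
    """Run one replicate from a fresh population for max_generations."""
    if seed is None:
        seed = config.seed
    init_seed = (seed * 2 + 1) % 2**31
    state = init_packed(config, init_seed)
    state, traj, status = run_chunk(state, config, config.max_generations,
                                    seed % 2**31, have_fitness=False)
    traj["status"] = status
    return SimulationResult(trajectory=traj, status=status, final_state=state)
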