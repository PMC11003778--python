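"""Diploid genomes carrying TE insertions, and recombinant gamete formation.

Individuals carry two homologous copies of each of ``n_chroms`` chromosomes
(50 Mb each by default). A TE insertion is a point location
``(chromosome, position, homolog)``; at most one insertion may occupy a given
triple. Coordinates are 0-based, half-open per chromosome. Meiosis draws a
Poisson number of crossovers per chromosome (mean ``r * chrom_length``, no
interference) with uniform breakpoints, and the gamete takes alternating
homolog segments starting from a uniformly chosen homolog.

This module is the readable, per-individual API; the generation loop used by
long simulations runs on the packed-array kernels in :mod:`tesim._kernels`,
which implement the same model.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .config import ConfigError, SimulationConfig

FEMALE = "female"
MALE = "male"


class TEInsertion(NamedTuple):
    """One TE copy at (chromosome, position, homolog)."""

    chromosome: int
    position: int
    homolog: int


class Gamete(NamedTuple):
    """A haploid product of meiosis: TE sites plus modifier-allele presence."""

    sites: tuple[tuple[int, int], ...]  # sorted (chromosome, position)
    modifier: bool


@dataclasses.dataclass
class Individual:
    """A diploid individual: TE insertions, sex, modifier genotype, fitness.

    ``modifier_homologs`` records on which homolog(s) of the modifier
    chromosome the modifier allele sits, which is what Mendelian transmission
    needs; ``modifier_copies`` is its sum (0, 1 or 2).
    """

    insertions: set[TEInsertion] = dataclasses.field(default_factory=set)
    sex: str = FEMALE
    modifier_homologs: tuple[bool, bool] = (False, False)
    fitness: float = 1.0

    def __post_init__(self) -> None:
        self.insertions = set(TEInsertion(*ins) for ins in self.insertions)
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE!r} or {MALE!r}")

    @property
    def modifier_copies(self) -> int:
        return int(self.modifier_homologs[0]) + int(self.modifier_homologs[1])


@dataclasses.dataclass
class Population:
    """Exactly N individuals at one generation boundary."""

    individuals: list[Individual]
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.individuals)

    def mean_copy_number(self) -> float:
        return float(np.mean([copy_number(ind) for ind in self.individuals]))

    def mean_fitness(self) -> float:
        return float(np.mean([ind.fitness for ind in self.individuals]))

    def modifier_frequency(self) -> float:
        copies = sum(ind.modifier_copies for ind in self.individuals)
        return copies / (2 * self.size) if self.size else 0.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def copy_number(individual: Individual) -> int:
    """Diploid TE copy number n: total insertions across chromosomes/homologs."""
    return len(individual.insertions)


def count_heterozygous(individual: Individual) -> int:
    """Number of insertions with no insertion at the same site on the other homolog."""
    occupied = {(ins.chromosome, ins.position, ins.homolog) for ins in individual.insertions}
    het = 0
    for ins in individual.insertions:
        if (ins.chromosome, ins.position, 1 - ins.homolog) not in occupied:
            het += 1
    return het


def init_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Found a population: each individual gets n0 TEs at distinct random sites.

    Each copy lands at a uniformly chosen distinct (chromosome, position) and
    on one homolog chosen uniformly; placement is independent across
    individuals. Sexes are assigned Bernoulli(1/2); no modifier alleles.
    """
    config.validate()
    individuals: list[Individual] = []
    n_sites = config.n_chroms * config.chrom_length
    for _ in range(config.N):
        if config.n0 > 0:
            # distinct linear sites; collisions at 1e8 sites are vanishingly
            # rare, so rejection sampling terminates immediately in practice
            chosen: set[int] = set()
            while len(chosen) < config.n0:
                chosen.update(
                    int(x)
                    for x in rng.integers(0, n_sites, size=config.n0 - len(chosen))
                )
            homologs = rng.integers(0, 2, size=config.n0)
            insertions = {
                TEInsertion(site // config.chrom_length, site % config.chrom_length, int(h))
                for site, h in zip(sorted(chosen), homologs)
            }
        else:
            insertions = set()
        sex = FEMALE if rng.random() < 0.5 else MALE
        individuals.append(Individual(insertions=insertions, sex=sex))
    return Population(individuals=individuals, generation=0)


def make_gamete(
    individual: Individual,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Gamete:
    """Form one recombinant haploid gamete.

    Per chromosome: crossover count ~ Poisson(r * chrom_length), breakpoint
    positions uniform; the gamete copies alternating homolog segments from a
    uniformly chosen starting homolog; chromosomes assort independently. The
    modifier allele travels with the segment containing its locus.
    """
    sites: list[tuple[int, int]] = []
    modifier = False
    mod_chrom = config.modifier_chromosome
    mod_pos = config.modifier_locus_position
    by_chrom: dict[int, list[TEInsertion]] = {}
    for ins in individual.insertions:
        by_chrom.setdefault(ins.chromosome, []).append(ins)

    for chrom in range(config.n_chroms):
        n_cross = rng.poisson(config.r * config.chrom_length)
        breaks = np.sort(rng.integers(0, config.chrom_length, size=n_cross))
        start = int(rng.integers(0, 2))
        for ins in by_chrom.get(chrom, ()):
            # homolog at position p: start XOR parity of breakpoints <= p
            segment = (start + np.searchsorted(breaks, ins.position, side="right")) % 2
            if ins.homolog == segment:
                sites.append((chrom, ins.position))
        if chrom == mod_chrom:
            segment = (start + np.searchsorted(breaks, mod_pos, side="right")) % 2
            modifier = bool(individual.modifier_homologs[segment])
    return Gamete(sites=tuple(sorted(sites)), modifier=modifier)


def fuse_gametes(maternal: Gamete, paternal: Gamete, sex: str) -> Individual:
    """Union of two gametes: maternal sites on homolog 0, paternal on homolog 1."""
    insertions = {TEInsertion(c, p, 0) for c, p in maternal.sites}
    insertions |= {TEInsertion(c, p, 1) for c, p in paternal.sites}
    return Individual(
        insertions=insertions,
        sex=sex,
        modifier_homologs=(maternal.modifier, paternal.modifier),
    )


def make_test_population(
    layouts: Sequence[Iterable[tuple[int, int, int]]],
    modifier_copies: Sequence[int] | None = None,
    sexes: Sequence[str] | None = None,
) -> Population:
    """Deterministic miniature population for unit tests.

    ``layouts`` lists, per individual, explicit (chromosome, position, homolog)
    triples. Duplicated triples are rejected with the offending individual and
    site named.
    """
    individuals = []
    for idx, layout in enumerate(layouts):
        triples = [tuple(t) for t in layout]
        if len(triples) != len(set(triples)):
            seen: set[tuple[int, int, int]] = set()
            for t in triples:
                if t in seen:
                    raise ConfigError(
                        "layouts", f"individual {idx} has duplicate insertion {t}"
                    )
                seen.add(t)
        copies = 0 if modifier_copies is None else int(modifier_copies[idx])
        if copies not in (0, 1, 2):
            raise ConfigError("modifier_copies", f"individual {idx}: must be 0, 1 or 2")
        sex = sexes[idx] if sexes is not None else (FEMALE if idx % 2 == 0 else MALE)
        individuals.append(
            Individual(
                insertions={TEInsertion(*t) for t in triples},
                sex=sex,
                modifier_homologs=(copies >= 1, copies == 2),
            )
        )
    return Population(individuals=individuals)
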