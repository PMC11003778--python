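"""Dominant-lethal ectopic recombination between heterozygous TE pairs.

Recombination between non-homologous TE copies produces lethal chromosomal
rearrangements. Only heterozygous insertions (no copy at the same site on the
opposite homolog) are at risk, counted genome-wide. ``r_e`` is the
probability per eligible copy per generation of engaging in an ectopic
exchange (its scale is the crossover rate times the few-kb extent of an
element), so an individual carrying h eligible copies -- at least two are
needed to form a pair -- is inviable (fitness set to zero) with probability
1 - (1 - r_e)^h. Epigenetic silencing can optionally exclude a copy from
the risk pool when its magnitude M_i exceeds the threshold ``T``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genome import Individual, TEInsertion
from .silencing import SilencingState


@dataclasses.dataclass
class EctopicConfig:
    r_e: float = 0.0
    suppression_on: bool = False
    T: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_e <= 1.0:
            raise ValueError("r_e must be in [0, 1]")
        if self.T < 0.0:
            raise ValueError("T must be non-negative")


def _sorted_insertions(individual: Individual) -> list[TEInsertion]:
    return sorted(individual.insertions)


def eligible_heterozygous_count(
    individual: Individual,
    state: SilencingState | None,
    ectopic: EctopicConfig,
) -> int:
    """Count ectopic-eligible heterozygous TE copies.

    A copy is eligible when heterozygous and, if suppression is on, when its
    silencing magnitude M_i <= T (``state`` magnitudes follow sorted insertion
    order, matching :class:`SilencingState`).
    """
    insertions = _sorted_insertions(individual)
    occupied = {(i.chromosome, i.position, i.homolog) for i in insertions}
    if ectopic.suppression_on:
        if state is None or state.magnitudes.size != len(insertions):
            raise ValueError("silencing state does not match the individual's insertions")
        mags = state.magnitudes
    else:
        mags = None
    h = 0
    for idx, ins in enumerate(insertions):
        if (ins.chromosome, ins.position, 1 - ins.homolog) in occupied:
            continue
        if mags is not None and mags[idx] > ectopic.T:
            continue
        h += 1
    return h


def eligible_heterozygous_pairs(
    individual: Individual,
    state: SilencingState | None,
    ectopic: EctopicConfig,
) -> int:
    """Unordered pairs of ectopic-eligible heterozygous TEs: h(h-1)/2."""
    h = eligible_heterozygous_count(individual, state, ectopic)
    return h * (h - 1) // 2


def ectopic_viability(
    individual: Individual,
    state: SilencingState | None,
    ectopic: EctopicConfig,
    rng: np.random.Generator,
) -> bool:
    """True if the individual escapes every potential ectopic exchange."""
    if ectopic.r_e <= 0.0:
        return True
    h = eligible_heterozygous_count(individual, state, ectopic)
    if h < 2:  # an exchange needs a partner copy
        return True
    p_inviable = 1.0 - (1.0 - ectopic.r_e) ** h
    return bool(rng.random() >= p_inviable)
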