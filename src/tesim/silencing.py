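"""Copy-number-dependent epigenetic silencing of TEs and host fitness.

Each generation, every TE copy i in an individual with diploid copy number n
receives an integer silencing magnitude M_i ~ Poisson(a' * n), re-drawn every
generation (a' is the individual's effective silencing scale, a times the
modifier effect). Silencing has two consequences, each optional:

* spreading of repressive marks inflates selection, s_i' = s * (1 + b * M_i);
* repression suppresses replication,        u_i' = max(0, u * (1 - k * M_i)).

Fitness W is the probability weight used in parent sampling:

* additive:        W = 1 - s*n          (with b > 0: W = 1 - sum_i s_i')
* multiplicative:  W = (1-s)^n          (with b > 0: W = prod_i (1 - s_i'))
* synergistic:     W = 1 - s*n^2        (defined only without silencing)

W is clamped to [0, 1]; a TE-free genome has W = 1 in every mode.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import SimulationConfig
from .genome import Individual, copy_number


@dataclasses.dataclass
class SilencingState:
    """Per-TE silencing magnitudes for one individual in one generation.

    ``magnitudes[i]`` pairs with ``insertions[i]`` (sorted order); ``a_eff``
    is the effective scale used for the draw.
    """

    magnitudes: np.ndarray  # int64, one entry per insertion
    a_eff: float

    def total(self) -> int:
        return int(self.magnitudes.sum()) if self.magnitudes.size else 0


@dataclasses.dataclass
class EffectiveRates:
    s_prime: np.ndarray
    u_prime: np.ndarray


def draw_silencing(
    individual: Individual, a_eff: float, rng: np.random.Generator
) -> SilencingState:
    """Draw M_i ~ Poisson(a_eff * n) independently for each of the n copies."""
    if a_eff <= 0.0:
        raise ValueError("a_eff must be positive")
    n = copy_number(individual)
    if n == 0:
        return SilencingState(magnitudes=np.zeros(0, dtype=np.int64), a_eff=a_eff)
    return SilencingState(
        magnitudes=rng.poisson(a_eff * n, size=n).astype(np.int64), a_eff=a_eff
    )


def effective_selection_coefficient(s: float, b: float, M_i: float) -> float:
    """s_i' = s * (1 + b * M_i): silencing spreads repressive marks, adding load."""
    return s * (1.0 + b * M_i)


def effective_transposition_rate(u: float, k: float, M_i: float) -> float:
    """u_i' = max(0, u * (1 - k * M_i)): silencing suppresses replication."""
    return max(0.0, u * (1.0 - k * M_i))


def individual_fitness(
    individual: Individual,
    state: SilencingState | None,
    config: SimulationConfig,
) -> float:
    """Fitness W of one individual under the configured interaction mode."""
    n = copy_number(individual)
    if n == 0:
        return 1.0
    mode = config.fitness_mode
    s, b = config.s, config.b
    if mode == "synergistic":
        if b > 0.0:
            raise ValueError(
                "synergistic mode defines no silenced-TE fitness; b must be 0"
            )
        w = 1.0 - s * n * n
    elif b > 0.0:
        if state is None or state.magnitudes.size != n:
            raise ValueError("silencing state does not match the individual's insertions")
        s_eff = s * (1.0 + b * state.magnitudes.astype(np.float64))
        if mode == "additive":
            w = 1.0 - float(s_eff.sum())
        else:  # multiplicative; clamp each factor so W stays a valid weight
            w = float(np.prod(np.maximum(0.0, 1.0 - s_eff)))
    else:
        w = 1.0 - s * n if mode == "additive" else (1.0 - s) ** n
    return float(min(1.0, max(0.0, w)))


def expected_additive_fitness(n: float, s: float, b: float, a_eff: float) -> float:
    """E[W] for additive fitness with silencing: 1 - s*n*(1 + b*a_eff*n)."""
    return 1.0 - s * n * (1.0 + b * a_eff * n)
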