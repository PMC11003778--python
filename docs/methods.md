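# Model and methods

`tesim` is a forward-in-time Wright–Fisher simulator for the population
dynamics of a transposable-element (TE) family whose host silences it
epigenetically in a copy-number-dependent way, together with the analytical
transposition–selection-balance machinery used to validate the simulated
equilibria.

## The model

**Population.** A diploid population of constant census size N with separate
sexes, random mating, and discrete, non-overlapping generations. Each genome
is two chromosomes of 5×10⁷ bp, each present in two homologs. A TE copy is a
point insertion at a (chromosome, position, homolog) triple; coordinates are
0-based and at most one copy may occupy a triple within an individual.

**Generation cycle.** Selection → reproduction → silencing → transposition →
ectopic-recombination viability → fitness:

1. For each of N offspring, a mother and a father are drawn independently,
   with probability proportional to fitness W, from the females and males of
   the parental generation. W is a sampling weight: only relative values
   matter for reproduction.
2. Each parent contributes one recombinant gamete. Crossovers form a Poisson
   process along each chromosome at rate r per bp (count ~ Poisson(rL),
   uniform positions, no interference); the gamete copies alternating
   homolog segments starting from a uniformly chosen homolog, and
   chromosomes assort independently. The maternal gamete becomes homolog 0
   of the offspring, the paternal gamete homolog 1. A single biallelic
   modifier locus is inherited with the chromosome segment containing it.
3. Silencing is re-established every generation: each of the offspring's n
   copies receives an integer magnitude M_i ~ Poisson(a′ n), where
   a′ = a(1 ± 0.5H) is the individual's silencing scale under a modifier of
   dosage H (0/0.5/1). Silencing inflates per-copy selection,
   s_i′ = s(1 + b M_i), and suppresses replication,
   u_i′ = max(0, u(1 − k M_i)).
4. Each copy duplicates with probability u_i′ into a uniformly random
   unoccupied (chromosome, position, homolog); new copies do not transpose,
   and carry M = 0, in the generation of their birth.
5. With ectopic recombination enabled, each *eligible heterozygous* copy
   (no copy at the same position on the other homolog; under suppression
   additionally M_i ≤ T) independently engages in an ectopic exchange with
   probability r_e per generation — the scale of r_e is the crossover rate
   times the few-kb extent of an element. An exchange needs a partner, so an
   individual with h ≥ 2 eligible copies (counted genome-wide) is inviable
   (W = 0, dominant lethal) with probability 1 − (1 − r_e)^h. A per-pair
   reading of r_e would make the published rate range unlivable: at the
   silencing equilibrium the pair count is of order 10⁴, so r_e = 10⁻³
   would kill every carrier genome.
6. Fitness: additive W = 1 − Σ s_i′ (reducing to 1 − sn when b = 0),
   multiplicative W = Π(1 − s_i′), or synergistic W = 1 − s n² (defined only
   without silencing effects). W is clamped to [0, 1]; multiplicative
   factors are clamped at 0 individually. n = 0 gives W = 1 in every mode.

**Termination.** A replicate ends at the generation horizon (`completed`),
when the mean copy number reaches zero (`te_loss`), when a population crash
is detected, or when one sex has no individual with positive fitness
(`extinct`).

## Key parameters

| symbol | meaning | default |
|---|---|---|
| N | census size (diploid individuals) | 2000 (desk scale) |
| u | transposition probability, per copy per generation | 10⁻² |
| s | selection coefficient per copy | 10⁻³ |
| r | crossover rate per bp per meiosis | 10⁻⁶ |
| a | silencing scale: E[M] = a·n | 0.02 |
| b | silencing→selection multiplier (0 = off) | 0 |
| k | silencing→transposition multiplier (0 = off) | 0 |
| n0 | founding copies per individual | 10 |
| r_e | ectopic exchange probability per eligible copy per generation | 0 |
| T | silencing threshold excluding a copy from ectopic risk | 0 |

## Numerical and design choices

**Crash detection.** A crash is runaway accumulation: copy number grows
until the host population's mean fitness collapses. Because W is a relative
weight, a transient dip of mean fitness below the 0.1% threshold during the
overshoot into equilibrium — or a contained plateau held by near-truncation
selection at small absolute fitness — does not stop reproduction. A run is
therefore labelled `population_crash` only when mean fitness stays below
0.1% for `crash_patience` consecutive generations (default 25) *and* the
mean copy number grew by more than 5% over that window. Genuine crashes
(e.g. additive fitness with s ≪ u) grow ≥ u per generation and are caught
within one window.

**Silencing draw order.** M is drawn once per offspring per generation,
before transposition, and the same draw feeds both s_i′ and u_i′; copies
born in that generation have no silencing magnitude yet (M = 0), so they
transpose-silently carry bare s for one generation and are ectopic-eligible.
The alternative (re-drawing after transposition with the enlarged n) differs
only at order u per generation and was not observed to change outcomes
qualitatively.

**Exact-sampling shortcuts.** The packed-array engine avoids per-copy
Poisson draws when their values are not consumed elsewhere, using
distributionally identical aggregates: for additive fitness with b > 0,
Σ M_i ~ Poisson(a′n²); for transposition with k > 0 and b = 0, the
duplication count is Binomial(n, u·E[max(0, 1 − kM)]) with the expectation
evaluated by its finite series (m ≤ ⌊1/k⌋). When both channels are active,
or when ectopic suppression needs per-copy magnitudes, M_i is drawn
explicitly so the M-mediated correlation between fitness and transposition
is preserved.

**Founding.** Each founder receives n0 copies at distinct uniform sites, one
homolog each, independently across individuals. Sweeps cap n0 so the
founding load stays below one half (additive: s·n0 ≤ 0.5; synergistic:
s·n0² ≤ 0.5): without the cap, strong-selection grid cells begin with every
founder at W = 0 and die of founder load instead of exhibiting the model's
initial growth phase. When a single copy is effectively lethal the cell
starts TE-free, which realizes the same immediate-loss outcome.

**Analytic equilibria.** The solver treats copy number as continuous
(infinite-N mean-field) and solves u_eff(n) = −∂ln w̄/∂n with
E[s_i′] = s(1 + b a n) and u_eff = max(0, u(1 − k a n)): closed forms for
the plain modes, quadratics for single-channel silencing (the
transposition-silencing case keeps the smaller root; roots beyond the
u_eff = 0 boundary are rejected), and bracketed `brentq` root-finding for
the combined-channel cubic and the multiplicative-with-b case. Stability is
the sign of d[u_eff + ∂ln w̄/∂n]/dn at the root. Two caveats are inherent to
the mean-field treatment: the discrete-generation fixed point sits at
(u − s(1+u))/(us) rather than the continuous (u − s)/(us) (a 1/(1+u)
relative offset), and near the u_eff clamp the linearized 1 − k a n
understates E[max(0, 1 − kM)], so simulated equilibria exceed the mean-field
n̂ there. `mean_field_trajectory` iterates the deterministic recursion
n′ = n(1 + σ²/n · ∂ln w̄/∂n)(1 + u_eff) with σ² = n (linkage-equilibrium
dispersion) and the exact clamped expectation, and serves as the infinite-N
oracle for simulated trajectories on their approach to equilibrium.

**Outcome classification.** A parameter setting is classified from replicate
trajectories by majority rule: `te_loss` / `population_crash` from terminal
statuses (extinction counts as a crash); otherwise `stable_equilibrium`
requires a plateau, per replicate — ordinary-least-squares slope of mean
copy number over the final window not significant at α = 0.01, or fitted
total drift within 10% of the level (the slope test alone is
anti-conservative on autocorrelated equilibrium fluctuations) — and
among-replicate relative variance (sample variance of final copy numbers
over their mean) below 1/(Ns). The published criterion was partly visual;
this surrogate is the reproducible operationalization. Sweeps additionally
cross-check `unsettled` cells against the solver: when every replicate ran
to the horizon and the final mean lies within 50% of the mean-field
expectation at that generation (or of n̂ where the point-mass map is
unreliable under strong selection), the cell is promoted to stable. This
adjudicates cells that desk-scale runs cannot resolve: drift-dominated cells
(Ns or Nu near 1) and slow cells still on their deterministic approach.

**Sweep horizons.** Equilibration time scales as 1/u, so grid sweeps give
each cell a generation budget by tier (u ≥ 0.5: 300; u ≥ 0.05: 1000;
u ≥ 5×10⁻³: 1600; u ≥ 5×10⁻⁴: 2500; slower: 1200, since no swept s can be
out-replicated there) with the plateau window at half the budget.
Replicate seeds are a stable CRC32 hash of (base seed, cell parameters,
replicate index) so grids can be extended without changing existing streams.

## Problem sizes

The desk profile runs N = 500–2000 with 2–5 replicates over 10³–5×10³
generations; grid classifications and the effective-rate-ratio extremes use
N = 1000 with 2 replicates under the tiered horizons, and the invasion and
ectopic experiments use N = 400–1000 with an 800-generation burn-in.
Fixation and loss of the modifier are absorbing (no recurrent mutation), so
invasion runs proceed in chunks and stop shortly after absorption. The
`paper`-scale profile (N = 10⁴, 100 replicates, ≥10⁴ generations) is
available through the CLI for full-scale reproduction.

## What the simulations do and do not show

The simulator generates all data internally; it emulates an idealized,
single-family TE system: no sequence content or families, no excision, no
demography or spatial structure, no recurrent modifier mutation, and a
silencing magnitude that is conditionally independent across copies given
copy number. Agreement between simulated equilibria and the analytic solver
validates the transposition–selection-balance machinery, not the realism of
those assumptions for any particular organism.

Scale limitations are real and visible: cells whose equilibrium sits within
a few percent of the zero-fitness boundary (e.g. additive with b = 0.2 at
u = 0.1, s ≤ 10⁻³) survive as truncation-held plateaus only when N supplies
enough above-threshold individuals each generation; at desk-scale N the
lottery often empties one sex and the replicate ends `extinct`, so such
cells classify as crashed here even where an N = 10⁴ run can hold the
plateau. Conversely, drift dominates weak cells (N·s < 1) and their labels
rest on the analytic cross-check rather than on the finite run itself.
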