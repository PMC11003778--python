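"""Transposition-selection balance: analytic equilibria and run classification.

In an infinite population the per-generation change of mean copy number n is

    dn/dt = n * [ u_eff(n) + d ln w(n) / dn ]

where ``w(n)`` is the expected fitness of an individual carrying n copies and
``u_eff(n)`` the expected per-copy transposition rate; an equilibrium n_hat
solves ``u_eff(n) = -d ln w / dn`` and is stable when the bracketed net
per-copy growth rate is decreasing at n_hat. With the silencing magnitude
averaged at its mean ``E[M] = a n`` (mean-field), the model variants give

    additive            w = 1 - s n
    multiplicative      w = (1 - s)^n
    synergistic         w = 1 - s n^2
    additive, b > 0     w = 1 - s n (1 + b a n)
    u_eff with k > 0    max(0, u (1 - k a n))

Additive cases reduce to quadratics; the combined b > 0, k > 0 case is a
cubic solved numerically by bracketed root-finding. Roots lying beyond the
u_eff = 0 clamp boundary are rejected.

Finite-population replicate runs are classified with the simulation
criteria: TE loss (mean copy number reached zero), population crash (mean
fitness below 0.1%), or stable equilibrium, requiring both a plateau (no
significant least-squares trend in the final window) and among-replicate
relative variance (variance / mean of final copy numbers) below 1/(N s).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

STABLE = "stable_equilibrium"
LOSS = "te_loss"
CRASH = "population_crash"
UNSETTLED = "unsettled"

_MODE_ALIASES = {
    "additive": "additive",
    "multiplicative": "multiplicative",
    "synergistic": "synergistic",
    "additive+sel_silencing": "additive",
    "additive+transp_silencing": "additive",
    "additive+both": "additive",
}


@dataclasses.dataclass
class EquilibriumSolution:
    n_hat: float | None
    stable: bool | None
    mode: str
    u: float
    s: float
    a: float
    b: float
    k: float
    reason: str = ""


@dataclasses.dataclass
class OutcomeLabel:
    label: str
    relative_variance: float | None
    threshold: float
    details: str = ""


# ---------------------------------------------------------------------------
# analytic equilibria
# ---------------------------------------------------------------------------

def _u_eff(n: float, u: float, k: float, a: float) -> float:
    return max(0.0, u * (1.0 - k * a * n))


def _growth_rate(n: float, mode: str, u: float, s: float, a: float,
                 b: float, k: float) -> float:
    """Per-copy net growth g(n) = u_eff(n) + d ln w / dn (mean-field)."""
    ue = _u_eff(n, u, k, a)
    if mode == "additive":
        w = 1.0 - s * n * (1.0 + b * a * n)
        if w <= 0.0:
            return -1e30  # effectively -inf; keeps brentq endpoints finite
        dw = -s * (1.0 + 2.0 * b * a * n)
        return ue + dw / w
    if mode == "multiplicative":
        f = 1.0 - s * (1.0 + b * a * n)
        if f <= 0.0:
            return -1e30  # effectively -inf; keeps brentq endpoints finite
        # ln w = n ln f; d/dn = ln f - n s b a / f
        return ue + math.log(f) - n * s * b * a / f
    # synergistic
    w = 1.0 - s * n * n
    if w <= 0.0:
        return -1e30  # effectively -inf; keeps brentq endpoints finite
    return ue - 2.0 * s * n / w


def _stability(n_hat: float, mode: str, u: float, s: float, a: float,
               b: float, k: float) -> bool:
    h = max(1e-6, 1e-6 * n_hat)
    gp = (_growth_rate(n_hat + h, mode, u, s, a, b, k)
          - _growth_rate(n_hat - h, mode, u, s, a, b, k)) / (2.0 * h)
    return gp < 0.0


def _solution(mode_tag, u, s, a, b, k, n_hat=None, reason=""):
    stable = None
    if n_hat is not None:
        mode = _MODE_ALIASES[mode_tag]
        stable = _stability(n_hat, mode, u, s, a, b, k)
    return EquilibriumSolution(n_hat=n_hat, stable=stable, mode=mode_tag,
                               u=u, s=s, a=a, b=b, k=k, reason=reason)


def analytic_equilibrium(mode: str, u: float, s: float, a: float = 0.02,
                         b: float = 0.0, k: float = 0.0
                         ) -> EquilibriumSolution:
    """Equilibrium copy number for one model variant (infinite N, mean-field).

    Returns a solution with ``n_hat=None`` (and a reason) when no positive
    equilibrium below the u_eff clamp boundary exists: net growth at small n
    is negative (TE loss predicted) or positive everywhere (unbounded growth
    / population crash predicted).
    """
    if mode not in _MODE_ALIASES:
        raise ValueError(f"unknown mode {mode!r}")
    base = _MODE_ALIASES[mode]
    if base == "synergistic" and (b > 0.0 or k > 0.0):
        raise ValueError("synergistic mode defines no silenced-TE variant")
    for name, val in (("u", u), ("s", s), ("b", b), ("k", k)):
        if val < 0.0:
            raise ValueError(f"{name} must be non-negative")
    if (b > 0.0 or k > 0.0) and a <= 0.0:
        raise ValueError("a must be positive when b > 0 or k > 0")

    clamp = 1.0 / (k * a) if k > 0.0 else math.inf
    if s <= 0.0 and base != "multiplicative":
        reason = ("no selection against copies: "
                  + ("unbounded growth" if u > 0.0 else "pure drift"))
        return EquilibriumSolution(n_hat=None, stable=None, mode=mode,
                                   u=u, s=s, a=a, b=b, k=k, reason=reason)
    if base == "multiplicative" and s <= 0.0:
        return EquilibriumSolution(n_hat=None, stable=None, mode=mode,
                                   u=u, s=s, a=a, b=b, k=k,
                                   reason="no selection against copies")

    if base == "synergistic":
        if u <= 0.0 or s <= 0.0:
            return _solution(mode, u, s, a, b, k, reason="degenerate rates")
        # u (1 - s n^2) = 2 s n  ->  u s n^2 + 2 s n - u = 0
        n_hat = (math.sqrt(s * s + s * u * u) - s) / (u * s)
        return _solution(mode, u, s, a, b, k, n_hat=n_hat)

    if base == "multiplicative":
        if b == 0.0:
            if k == 0.0:
                reason = ("constant per-copy log-fitness gradient: "
                          + ("unbounded growth" if u > -math.log(1.0 - s)
                             else "te_loss"))
                return _solution(mode, u, s, a, b, k, reason=reason)
            # u (1 - k a n) = -ln(1 - s)
            if u <= -math.log(1.0 - s):
                return _solution(mode, u, s, a, b, k,
                                 reason="net loss at all copy numbers")
            n_hat = (u + math.log(1.0 - s)) / (u * k * a)
            return _solution(mode, u, s, a, b, k, n_hat=n_hat)
        return _root_scan(mode, base, u, s, a, b, k, clamp)

    # additive
    if b == 0.0 and k == 0.0:
        if u <= s:
            return _solution(mode, u, s, a, b, k,
                             reason="selection at least as strong as transposition")
        return _solution(mode, u, s, a, b, k, n_hat=(u - s) / (u * s))
    if b > 0.0 and k == 0.0:
        if u <= s:
            return _solution(mode, u, s, a, b, k,
                             reason="selection at least as strong as transposition")
        A = u * s * b * a
        B = s * (u + 2.0 * b * a)
        C = s - u
        n_hat = (-B + math.sqrt(B * B - 4.0 * A * C)) / (2.0 * A)
        return _solution(mode, u, s, a, b, k, n_hat=n_hat)
    if k > 0.0 and b == 0.0:
        if u <= s:
            return _solution(mode, u, s, a, b, k,
                             reason="selection at least as strong as transposition")
        # u (1 - k a n)(1 - s n) = s
        A = u * k * a * s
        B = u * (k * a + s)
        C = u - s
        disc = B * B - 4.0 * A * C
        if disc < 0.0:
            return _solution(mode, u, s, a, b, k,
                             reason="no real balance point")
        root = (B - math.sqrt(disc)) / (2.0 * A)  # smaller root
        if not 0.0 < root < clamp:
            return _solution(
                mode, u, s, a, b, k,
                reason="balance point beyond the u_eff = 0 clamp boundary")
        return _solution(mode, u, s, a, b, k, n_hat=root)
    return _root_scan(mode, base, u, s, a, b, k, clamp)


def _root_scan(mode_tag: str, base: str, u: float, s: float, a: float,
               b: float, k: float, clamp: float) -> EquilibriumSolution:
    """Smallest positive root of g(n) = 0 by log-grid sign scan + brentq."""
    if u <= 0.0 or s <= 0.0:
        return _solution(mode_tag, u, s, a, b, k, reason="degenerate rates")
    n_upper = min(clamp, 1e6)
    grid = np.logspace(-3, math.log10(n_upper), 400)
    g_prev = _growth_rate(grid[0], base, u, s, a, b, k)
    if g_prev <= 0.0:
        return _solution(mode_tag, u, s, a, b, k,
                         reason="net loss already at small copy number")
    for x in grid[1:]:
        g_x = _growth_rate(x, base, u, s, a, b, k)
        if g_x <= 0.0:
            lo = x / (grid[1] / grid[0])
            n_hat = optimize.brentq(
                lambda n: _growth_rate(n, base, u, s, a, b, k), lo, x,
                xtol=1e-9, rtol=1e-12)
            return _solution(mode_tag, u, s, a, b, k, n_hat=float(n_hat))
    return _solution(mode_tag, u, s, a, b, k,
                     reason="net growth positive up to the clamp boundary")


def effective_rate_ratios(solution: EquilibriumSolution, u: float, s: float,
                          a: float, b: float, k: float
                          ) -> tuple[float | None, float | None]:
    """(effective_s / u, s / effective_u) at the equilibrium copy number.

    Effective rates evaluate the silencing formulas at the mean magnitude
    M = a * n_hat. A ratio whose denominator is zero is returned as None.
    """
    if solution.n_hat is None:
        raise ValueError("solution has no equilibrium copy number")
    n_hat = solution.n_hat
    eff_s = s * (1.0 + b * a * n_hat)
    eff_u = max(0.0, u * (1.0 - k * a * n_hat))
    r1 = eff_s / u if u > 0.0 else None
    r2 = s / eff_u if eff_u > 0.0 else None
    return r1, r2


def exact_mean_transposition_factor(k: float, lam: float) -> float:
    """E[max(0, 1 - k M)] for M ~ Poisson(lam): the clamped per-copy factor.

    The mean-field solver uses the linearized 1 - k*lam; this exact
    expectation (a finite series over m <= floor(1/k)) is what per-copy
    sampling realizes, and the two diverge near the u_eff = 0 boundary.
    """
    if k <= 0.0 or lam <= 0.0:
        return 1.0
    m_max = int(1.0 / k)
    pmf = math.exp(-lam)
    acc = 0.0
    m = 0
    while m <= m_max:
        f = 1.0 - k * m
        if f > 0.0:
            acc += f * pmf
        m += 1
        pmf *= lam / m
    return acc


def mean_field_trajectory(mode: str, u: float, s: float, a: float = 0.02,
                          b: float = 0.0, k: float = 0.0, n0: float = 10.0,
                          generations: int = 1000,
                          exact_clamp: bool = True) -> np.ndarray:
    """Deterministic recursion for mean copy number in a large population.

    Per generation the mean responds to selection by the breeder's-equation
    increment sigma^2 * d ln w / dn with sigma^2 = n (linkage-equilibrium,
    Poisson-like dispersion of copies among individuals), then transposition
    multiplies by (1 + u_eff). With ``exact_clamp`` the expected per-copy
    transposition uses the exact clamped Poisson expectation rather than the
    linearized 1 - k a n. Used as the infinite-N oracle for simulated
    trajectories on their approach to equilibrium.
    """
    base = _MODE_ALIASES[mode]
    out = np.empty(generations + 1)
    n = float(n0)
    for t in range(generations + 1):
        out[t] = n
        if n <= 0.0:
            out[t:] = 0.0
            break
        g_sel = _growth_rate(n, base, u, s, a, b, 0.0) - u  # d ln w / dn
        if exact_clamp and k > 0.0:
            ue = u * exact_mean_transposition_factor(k, a * n)
        else:
            ue = _u_eff(n, u, k, a)
        n = max(0.0, n * (1.0 + g_sel)) * (1.0 + ue)
    return out


# ---------------------------------------------------------------------------
# replicate-level classification
# ---------------------------------------------------------------------------

def relative_variance(final_copy_numbers: Sequence[float]) -> float:
    """Sample variance across replicate means divided by their grand mean."""
    values = np.asarray(final_copy_numbers, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two replicates")
    mean = values.mean()
    if mean <= 0.0:
        raise ValueError("undefined at zero mean copy number (label is te_loss)")
    return float(values.var(ddof=1) / mean)


def _plateau(traj: pd.DataFrame, window: int, alpha: float) -> bool:
    """No meaningful copy-number trend over the final window.

    The least-squares slope test alone is anti-conservative here: equilibrium
    fluctuations are mean-reverting and autocorrelated, so tiny slopes reach
    nominal significance. A run therefore also counts as plateaued when the
    fitted total drift over the window stays within 10% of the mean level
    (practical equivalence), which a genuine growth or decline phase exceeds
    by an order of magnitude.
    """
    tail = traj.tail(window)
    y = tail["mean_copy_number"].to_numpy(dtype=float)
    x = tail["generation"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return True
    res = stats.linregress(x, y)
    if res.pvalue >= alpha:
        return True
    drift = abs(res.slope) * (x[-1] - x[0])
    return bool(drift <= 0.1 * y.mean())


def classify_outcome(
    trajectories: Sequence[pd.DataFrame],
    N: int,
    s: float,
    statuses: Sequence[str] | None = None,
    plateau_window: int = 5000,
    alpha: float = 0.01,
) -> OutcomeLabel:
    """Classify one parameter setting from its replicate trajectories.

    Majority rule over replicates: TE loss and population crash are read from
    the terminal statuses (an extinct run counts as a crash); otherwise the
    setting is a stable equilibrium when most replicates plateau (no
    significant copy-number trend over the final ``plateau_window`` recorded
    generations at level ``alpha``) and the relative variance of final copy
    numbers is below 1/(N s). Everything else is unsettled.
    """
    n_rep = len(trajectories)
    if n_rep == 0:
        raise ValueError("no replicates to classify")
    if statuses is None:
        statuses = [
            str(t["status"].iloc[-1]) if "status" in t else "completed"
            for t in trajectories
        ]
    n_loss = sum(st == "te_loss" for st in statuses)
    n_crash = sum(st in ("population_crash", "extinct") for st in statuses)
    threshold = 1.0 / (N * s) if s > 0.0 else math.inf
    if n_loss * 2 > n_rep:
        return OutcomeLabel(LOSS, None, threshold,
                            f"{n_loss}/{n_rep} replicates lost all copies")
    if n_crash * 2 > n_rep:
        return OutcomeLabel(CRASH, None, threshold,
                            f"{n_crash}/{n_rep} replicates crashed")
    completed = [t for t, st in zip(trajectories, statuses) if st == "completed"]
    if 2 * len(completed) <= n_rep:
        return OutcomeLabel(UNSETTLED, None, threshold,
                            "no majority outcome across replicates")
    if any(len(t) < plateau_window for t in completed):
        return OutcomeLabel(
            UNSETTLED, None, threshold,
            f"fewer than {plateau_window} recorded generations for the "
            "plateau test")
    finals = [float(t["mean_copy_number"].iloc[-1]) for t in completed]
    if np.mean(finals) <= 0.0:
        return OutcomeLabel(LOSS, None, threshold, "zero final copy number")
    rv = relative_variance(finals) if len(finals) >= 2 else math.inf
    n_plateau = sum(_plateau(t, plateau_window, alpha) for t in completed)
    if 2 * n_plateau > n_rep and rv < threshold:
        return OutcomeLabel(STABLE, rv, threshold,
                            f"{n_plateau}/{n_rep} replicates plateaued")
    return OutcomeLabel(UNSETTLED, rv, threshold,
                        f"plateau {n_plateau}/{n_rep}, relative variance {rv:.3g}")
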