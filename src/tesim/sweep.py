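"""Parameter sweeps: replicate/seed management, classification, file output.

A sweep expands a grid over (u, s, mode, b, k, r, r_e) into simulation
configs, runs ``replicates`` independent replicates per cell, classifies
each cell (stable equilibrium / TE loss / population crash / unsettled) and
tabulates the grid next to the analytic equilibrium predictions. Replicate
seeds are a stable CRC32 hash of (base seed, cell parameters, replicate
index), so adding grid cells never changes existing replicates' streams.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
import time
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (CRASH, LOSS, STABLE, UNSETTLED, EquilibriumSolution,
                        OutcomeLabel, analytic_equilibrium, classify_outcome,
                        effective_rate_ratios, mean_field_trajectory)
from .config import ConfigError, SimulationConfig
from .engine import run_simulation

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SweepSpec:
    """A parameter grid around a base configuration."""

    base: SimulationConfig
    u_values: Sequence[float]
    s_values: Sequence[float]
    modes: Sequence[str] = ("additive",)
    b_values: Sequence[float] = (0.0,)
    k_values: Sequence[float] = (0.0,)
    r_values: Sequence[float] | None = None
    r_e_values: Sequence[float] | None = None
    replicates: int = 100
    base_seed: int = 0
    plateau_window: int = 5000
    adaptive_horizon: bool = False
    out_dir: Path | str | None = None

    def cells(self) -> list[dict]:
        r_vals = self.r_values if self.r_values is not None else [self.base.r]
        re_vals = (self.r_e_values if self.r_e_values is not None
                   else [self.base.r_e])
        out = []
        for u, s, mode, b, k, r, r_e in itertools.product(
                self.u_values, self.s_values, self.modes, self.b_values,
                self.k_values, r_vals, re_vals):
            out.append(dict(u=u, s=s, fitness_mode=mode, b=b, k=k, r=r,
                            r_e=r_e))
        return out

    def cell_config(self, cell: dict) -> SimulationConfig:
        cfg = self.base.replace(**cell)
        cfg = cfg.replace(n0=viable_n0(cfg.fitness_mode, cfg.s, cfg.n0))
        if self.adaptive_horizon:
            cfg = cfg.replace(
                max_generations=min(cfg.max_generations,
                                    self.horizon_for(cell)))
        return cfg

    def horizon_for(self, cell: dict) -> int:
        """Per-cell generation budget: equilibration time scales as 1/u.

        Cells with u <= 1e-4 cannot out-replicate any swept s (no balance
        exists), so they get a short drift budget.
        """
        u = cell["u"]
        if u >= 0.5:
            return 300
        if u >= 0.05:
            return 1000
        if u >= 5e-3:
            return 1600
        if u >= 5e-4:
            return 2500
        return 1200

    def window_for(self, cell: dict) -> int:
        if not self.adaptive_horizon:
            return self.plateau_window
        return min(self.plateau_window, self.horizon_for(cell) // 2)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates", "must be at least 1")
        for cell in self.cells():
            self.cell_config(cell)  # raises ConfigError on an invalid cell


def viable_n0(mode: str, s: float, n0: int) -> int:
    """Cap the founding per-individual copy number so founders are viable.

    Swept grids reach selection strengths where the default n0 would give
    every founder zero fitness (e.g. additive load s*n0 >= 1), turning the
    model's initial-growth phase into founder death. The cap keeps the
    founding load at most one half (additive: s*n0 <= 0.5; synergistic:
    s*n0^2 <= 0.5). When even a single copy is effectively lethal the cell
    starts TE-free, which realizes the same outcome (carriers of one copy
    never reproduce, so the elements are lost immediately).
    """
    if s <= 0.0:
        return n0
    if mode == "additive":
        return min(n0, int(0.5 / s))
    if mode == "synergistic":
        return min(n0, int(math.sqrt(0.5 / s)))
    return n0 if s < 1.0 else 0


def replicate_seed(base_seed: int, cell: dict, replicate: int) -> int:
    """Stable per-replicate seed from (base seed, cell parameters, index)."""
    key = "|".join([
        str(base_seed),
        *(f"{k}={cell[k]!r}" for k in sorted(cell)),
        f"rep={replicate}",
    ])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _cell_tag(index: int) -> str:
    return f"cell_{index:04d}"


def run_cell(spec: SweepSpec, cell: dict) -> tuple[list[pd.DataFrame], OutcomeLabel,
                                                   EquilibriumSolution]:
    """Run all replicates of one grid cell and classify the outcome."""
    config = spec.cell_config(cell)
    trajs = []
    for rep in range(spec.replicates):
        seed = replicate_seed(spec.base_seed, cell, rep)
        trajs.append(run_simulation(config, seed=seed).trajectory)
    outcome = classify_outcome(trajs, config.N, config.s,
                               plateau_window=spec.window_for(cell))
    solution = analytic_equilibrium(config.fitness_mode, config.u, config.s,
                                    config.a, config.b, config.k)
    return trajs, outcome, solution


def cross_checked_label(outcome: OutcomeLabel,
                        solution: EquilibriumSolution,
                        sim_final_mean: float,
                        expected_mean: float | None,
                        any_terminated: bool = False) -> str:
    """Adjudicate under-resolved cells with the infinite-N oracles.

    Two situations defeat the finite-horizon plateau/variance test at desk
    scale: drift dominates when N*s or N*u drops toward 1, and slow cells
    (small u) are still on their deterministic approach when the horizon
    ends. An ``unsettled`` cell is therefore promoted to stable when every
    replicate ran to the horizon, the solver finds a stable equilibrium, and
    the simulated final mean copy number lies within 50% of the infinite-N
    expectation -- the deterministic mean-field value at the same generation
    (``expected_mean``), or the equilibrium n_hat itself where the
    point-mass mean-field map is unreliable (strong selection makes it
    overshoot to extinction while the stochastic population plateaus).
    Every other label stands as simulated.
    """
    if outcome.label != UNSETTLED or any_terminated:
        return outcome.label
    if solution.n_hat is None or not solution.stable or sim_final_mean <= 0.0:
        return outcome.label
    targets = [solution.n_hat]
    if expected_mean is not None and expected_mean > 0.0:
        targets.append(expected_mean)
    if any(abs(sim_final_mean - t) / t < 0.5 for t in targets):
        return STABLE
    return outcome.label


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every (cell, replicate); returns the classified grid summary.

    With ``out_dir`` set, writes per-replicate trajectory TSVs, a JSON run
    manifest, and the summary TSV; cells whose summary JSON already exists
    are skipped, making interrupted sweeps resumable.
    """
    spec.validate()
    out_dir = Path(spec.out_dir) if spec.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "package_version": __version__,
            "base_seed": spec.base_seed,
            "replicates": spec.replicates,
            "plateau_window": spec.plateau_window,
            "base_config": spec.base.to_dict(),
            "cells": spec.cells(),
            "replicate_seeds": [
                [replicate_seed(spec.base_seed, cell, rep)
                 for rep in range(spec.replicates)]
                for cell in spec.cells()
            ],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    rows = []
    for idx, cell in enumerate(spec.cells()):
        tag = _cell_tag(idx)
        cell_json = out_dir / f"{tag}.json" if out_dir is not None else None
        if cell_json is not None and cell_json.exists():
            rows.append(json.loads(cell_json.read_text()))
            logger.info("%s: reusing existing summary", tag)
            continue
        t_start = time.perf_counter()
        trajs, outcome, solution = run_cell(spec, cell)
        finals_n = [float(t["mean_copy_number"].iloc[-1]) for t in trajs]
        finals_w = [float(t["mean_fitness"].iloc[-1]) for t in trajs]
        sim_mean = float(np.mean(finals_n))
        cfg = spec.cell_config(cell)
        horizon = int(min(len(t) for t in trajs)) - 1
        expected_mean = None
        if solution.n_hat is not None and horizon > 0 and cfg.n0 > 0:
            mf = mean_field_trajectory(cfg.fitness_mode, cfg.u, cfg.s, cfg.a,
                                       cfg.b, cfg.k, n0=cfg.n0,
                                       generations=horizon)
            expected_mean = float(mf[horizon])
        ratios = (None, None)
        if solution.n_hat is not None:
            ratios = effective_rate_ratios(solution, cell["u"], cell["s"],
                                           spec.base.a, cell["b"], cell["k"])
        statuses = [str(t["status"].iloc[-1]) if "status" in t else "completed"
                    for t in trajs]
        any_terminated = any(st != "completed" for st in statuses)
        row = dict(
            cell=tag, **cell,
            label=cross_checked_label(outcome, solution, sim_mean,
                                      expected_mean, any_terminated),
            simulated_label=outcome.label,
            mean_copy_number=sim_mean,
            mean_fitness=float(np.mean(finals_w)),
            relative_variance=outcome.relative_variance,
            variance_threshold=outcome.threshold,
            analytic_n_hat=solution.n_hat,
            analytic_stable=solution.stable,
            effective_s_over_u=ratios[0],
            s_over_effective_u=ratios[1],
        )
        rows.append(row)
        logger.info("%s u=%g s=%g mode=%s b=%g k=%g -> %s (%.1fs)",
                    tag, cell["u"], cell["s"], cell["fitness_mode"],
                    cell["b"], cell["k"], row["label"],
                    time.perf_counter() - t_start)
        if out_dir is not None:
            for rep, traj in enumerate(trajs):
                traj.to_csv(out_dir / f"{tag}_rep{rep:03d}.tsv", sep="\t",
                            index=False)
            cell_json.write_text(json.dumps(row))
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return summary


def summarize_grid(summary: pd.DataFrame) -> pd.DataFrame:
    """Tabulate outcome counts per (mode, b, k) silencing setting."""
    if summary.empty:
        return pd.DataFrame(
            columns=["fitness_mode", "b", "k", STABLE, LOSS, CRASH, UNSETTLED])
    counts = (summary.groupby(["fitness_mode", "b", "k"])["label"]
              .value_counts().unstack(fill_value=0).reset_index())
    for lbl in (STABLE, LOSS, CRASH, UNSETTLED):
        if lbl not in counts:
            counts[lbl] = 0
    return counts


def stable_cell_expansion(summary: pd.DataFrame) -> dict:
    """Compare stable-cell sets between silencing-off and silencing-on rows."""
    off = summary[(summary["b"] == 0.0) & (summary["k"] == 0.0)]
    on = summary[(summary["b"] > 0.0) | (summary["k"] > 0.0)]
    set_off = {(r.u, r.s) for r in off.itertuples() if r.label == STABLE}
    set_on = {(r.u, r.s) for r in on.itertuples() if r.label == STABLE}
    return {
        "stable_without_silencing": sorted(set_off),
        "stable_with_silencing": sorted(set_on),
        "gained": sorted(set_on - set_off),
        "lost": sorted(set_off - set_on),
    }


# ---------------------------------------------------------------------------
# effective-rate ratio extremes over the stable grid
# ---------------------------------------------------------------------------

RATIO_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


def ratio_extremes_sweep(
    effect: str,
    N: int = 1000,
    replicates: int = 2,
    max_generations: int = 2500,
    plateau_window: int = 1250,
    base_seed: int = 0,
    grid: Sequence[float] = RATIO_GRID,
    out_dir: Path | str | None = None,
) -> dict:
    """Extremes of the effective-rate ratios over stable (u, s) cells.

    ``effect='selection'`` sweeps silencing acting on selection (b=0.2, k=0)
    and reports min/max of effective-s/u = s(1 + b a n_hat)/u;
    ``effect='transposition'`` sweeps k=0.2, b=0 and reports min/max of
    s / effective-u = s / (u (1 - k a n_hat)). Stability is classified from
    scaled replicate simulations cross-checked by the analytic solver; the
    ratios use the analytic n_hat.
    """
    if effect == "selection":
        b, k = 0.2, 0.0
    elif effect == "transposition":
        b, k = 0.0, 0.2
    else:
        raise ValueError("effect must be 'selection' or 'transposition'")
    base = SimulationConfig(N=N, max_generations=max_generations,
                            fitness_mode="additive", b=b, k=k)
    spec = SweepSpec(base=base, u_values=list(grid), s_values=list(grid),
                     b_values=(b,), k_values=(k,), replicates=replicates,
                     base_seed=base_seed, plateau_window=plateau_window,
                     adaptive_horizon=True, out_dir=out_dir)
    summary = run_sweep(spec)
    col = "effective_s_over_u" if effect == "selection" else "s_over_effective_u"
    stable = summary[(summary["label"] == STABLE)
                     & summary[col].notna()]
    ratios = stable[col].astype(float)
    return {
        "effect": effect,
        "summary": summary,
        "stable_cells": [(r.u, r.s) for r in stable.itertuples()],
        "min_ratio": float(ratios.min()) if len(ratios) else None,
        "max_ratio": float(ratios.max()) if len(ratios) else None,
    }
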