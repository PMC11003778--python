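"""Analytic equilibria, effective-rate ratios, and outcome classification."""

import math

import numpy as np
import pandas as pd
import pytest

from tesim.analytics import (CRASH, LOSS, STABLE, UNSETTLED,
                             analytic_equilibrium, classify_outcome,
                             effective_rate_ratios, mean_field_trajectory,
                             relative_variance)


def _sign_scan_root(f, lo=1e-3, hi=1e6, n=200_000):
    """Brute-force oracle: first sign change of f on a log grid."""
    xs = np.logspace(math.log10(lo), math.log10(hi), n)
    vals = np.array([f(x) for x in xs])
    idx = np.where(np.diff(np.sign(vals)) != 0)[0]
    return None if idx.size == 0 else (xs[idx[0]], xs[idx[0] + 1])


class TestAnalyticEquilibrium:
    def test_additive_closed_form(self):
        # u (1 - s n) = s  ->  n = (u - s)/(u s)
        sol = analytic_equilibrium("additive", 1e-2, 1e-3)
        assert sol.n_hat == pytest.approx(900.0)
        assert sol.stable

    def test_additive_closed_form_matches_mean_field_recursion(self):
        # the discrete-generation map settles at (u - s(1+u))/(u s) = 899,
        # within one part in a thousand of the continuous-time balance 900
        traj = mean_field_trajectory("additive", 1e-2, 1e-3,
                                     generations=20_000)
        assert traj[-1] == pytest.approx(899.0, rel=1e-6)
        assert traj[-1] == pytest.approx(900.0, rel=2e-3)

    def test_selection_silencing_quadratic(self):
        # root of 4e-8 n^2 + 1.8e-5 n - 0.009 = 0
        sol = analytic_equilibrium("additive", 1e-2, 1e-3, b=0.2)
        assert sol.n_hat == pytest.approx(300.0, rel=1e-9)
        bracket = _sign_scan_root(
            lambda n: 4e-8 * n * n + 1.8e-5 * n - 0.009)
        assert bracket[0] <= sol.n_hat <= bracket[1] * 1.001

    def test_transposition_silencing_takes_smaller_root(self):
        sol = analytic_equilibrium("additive", 1e-2, 1e-3, k=0.2)
        assert sol.n_hat == pytest.approx(218.03, rel=1e-3)
        # the larger quadratic root (~1032) lies past the u_eff = 0 clamp at
        # n = 1/(k a) = 250 and must have been rejected
        assert sol.n_hat < 250.0

    def test_combined_cubic_against_sign_scan(self):
        u, s, a, b, k = 1e-2, 1e-3, 0.02, 0.2, 0.2
        sol = analytic_equilibrium("additive", u, s, a, b, k)

        def g(n):
            w = 1 - s * n - s * b * a * n * n
            return u * (1 - k * a * n) + (-(s + 2 * s * b * a * n)) / w

        bracket = _sign_scan_root(g, hi=1.0 / (k * a) - 1)
        assert bracket is not None
        assert bracket[0] <= sol.n_hat <= bracket[1] * 1.001
        # combined effects: below either single-channel equilibrium
        assert sol.n_hat < 218.1

    def test_multiplicative_without_silencing_never_stabilizes(self):
        for s in (1e-4, 2e-3, 1e-2):
            sol = analytic_equilibrium("multiplicative", 1e-2, s)
            assert sol.n_hat is None

    def test_multiplicative_with_transposition_silencing_stabilizes(self):
        sol = analytic_equilibrium("multiplicative", 1e-2, 1e-3, k=0.2)
        assert sol.n_hat is not None and sol.stable
        # u (1 - k a n) = -ln(1 - s)
        expected = (1e-2 + math.log(1 - 1e-3)) / (1e-2 * 0.2 * 0.02)
        assert sol.n_hat == pytest.approx(expected)

    def test_synergistic_equilibrium(self):
        sol = analytic_equilibrium("synergistic", 1e-2, 2e-5)
        # u s n^2 + 2 s n - u = 0
        n = sol.n_hat
        assert 1e-2 * 2e-5 * n * n + 2 * 2e-5 * n - 1e-2 == \
            pytest.approx(0.0, abs=1e-12)

    def test_loss_predicted_when_selection_dominates(self):
        sol = analytic_equilibrium("additive", 1e-3, 1e-2)
        assert sol.n_hat is None and "selection" in sol.reason

    def test_synergistic_rejects_silencing(self):
        with pytest.raises(ValueError):
            analytic_equilibrium("synergistic", 1e-2, 1e-3, b=0.2)

    def test_additive_monotonicity_in_u_and_s(self):
        n = [analytic_equilibrium("additive", u, 1e-3).n_hat
             for u in (2e-3, 1e-2, 1e-1)]
        assert n[0] < n[1] < n[2]
        m = [analytic_equilibrium("additive", 1e-2, s).n_hat
             for s in (2e-4, 1e-3, 5e-3)]
        assert m[0] > m[1] > m[2]

    def test_silencing_cost_lowers_equilibrium(self):
        for u, s in [(1e-2, 1e-3), (1e-1, 1e-2), (1e-2, 1e-4)]:
            plain = analytic_equilibrium("additive", u, s).n_hat
            costly = analytic_equilibrium("additive", u, s, b=0.2).n_hat
            assert costly < plain


class TestEffectiveRateRatios:
    def test_selection_ratio_at_equilibrium(self):
        sol = analytic_equilibrium("additive", 1e-2, 1e-3, b=0.2)
        r1, r2 = effective_rate_ratios(sol, 1e-2, 1e-3, 0.02, 0.2, 0.0)
        assert r1 == pytest.approx(0.22, rel=1e-6)  # s(1 + b a 300)/u
        assert r2 == pytest.approx(0.1, rel=1e-6)   # k = 0: plain s/u

    def test_transposition_ratio_at_equilibrium(self):
        sol = analytic_equilibrium("additive", 1e-2, 1e-3, k=0.2)
        r1, r2 = effective_rate_ratios(sol, 1e-2, 1e-3, 0.02, 0.0, 0.2)
        assert r1 == pytest.approx(0.1, rel=1e-6)
        assert r2 == pytest.approx(0.782, rel=1e-3)

    def test_without_silencing_both_reduce_to_s_over_u(self):
        sol = analytic_equilibrium("additive", 1e-2, 1e-3)
        assert effective_rate_ratios(sol, 1e-2, 1e-3, 0.02, 0.0, 0.0) == \
            (pytest.approx(0.1), pytest.approx(0.1))


class TestRelativeVariance:
    def test_arithmetic(self):
        assert relative_variance([100, 110, 90]) == pytest.approx(1.0)
        assert relative_variance([7, 7, 7]) == 0.0
        assert relative_variance([10, 1000]) == pytest.approx(490050 / 505)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            relative_variance([100])
        with pytest.raises(ValueError):
            relative_variance([0, 0, 0])


def _traj(values, status="completed"):
    df = pd.DataFrame({
        "generation": np.arange(len(values)),
        "mean_copy_number": values,
        "mean_fitness": np.full(len(values), 0.5),
        "modifier_frequency": np.zeros(len(values)),
    })
    df["status"] = status
    return df


class TestClassifyOutcome:
    def test_majority_loss(self):
        trajs = [_traj([10, 5, 0], "te_loss")] * 3 + [_traj([10] * 3)]
        assert classify_outcome(trajs, 10_000, 1e-3,
                                plateau_window=2).label == LOSS

    def test_majority_crash_includes_extinction(self):
        trajs = [_traj([10, 50, 100], "population_crash"),
                 _traj([10, 60, 120], "extinct"),
                 _traj([10] * 3, "completed")]
        assert classify_outcome(trajs, 10_000, 1e-3,
                                plateau_window=2).label == CRASH

    def test_flat_low_variance_replicates_are_stable(self, rng):
        trajs = [_traj(900 + rng.normal(0, 3, size=6000)) for _ in range(4)]
        out = classify_outcome(trajs, 10_000, 1e-3, plateau_window=5000)
        assert out.label == STABLE
        assert out.relative_variance < out.threshold == pytest.approx(0.1)

    def test_trending_replicates_are_unsettled(self):
        ramp = np.linspace(100, 300, 6000)
        out = classify_outcome([_traj(ramp)] * 3, 10_000, 1e-3,
                               plateau_window=5000)
        assert out.label == UNSETTLED

    def test_high_replicate_scatter_fails_variance_criterion(self, rng):
        # flat plateaus but at wildly different levels: rel var >> 1/(Ns)
        trajs = [_traj(level + rng.normal(0, 2, size=6000))
                 for level in (100, 400, 900)]
        out = classify_outcome(trajs, 10_000, 1e-2, plateau_window=5000)
        assert out.label == UNSETTLED
        assert out.relative_variance > out.threshold

    def test_short_runs_are_unsettled_with_diagnostic(self):
        out = classify_outcome([_traj([5, 5, 5])] * 3, 1000, 1e-3,
                               plateau_window=5000)
        assert out.label == UNSETTLED
        assert "plateau" in out.details
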