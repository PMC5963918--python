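"""Psychometric curve, aggregation, fitting and difference-limen tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import brentq
from scipy.special import expit

from socialtime import (
    DegenerateSlopeError,
    InsufficientDataError,
    LN3,
    ProportionTable,
    PsychometricFit,
    ValidationError,
    aggregate_proportions,
    difference_limen,
    evaluate_curve,
    fit_boltzmann,
    simulate_trials,
)
from socialtime.psychometric import _binomial_loglik

from conftest import (
    DEFAULT_LEVELS,
    binomial_table,
    exact_table,
    grid_best_loglik,
    make_table,
)


class TestEvaluateCurve:
    @pytest.mark.parametrize(
        "x0,omega,x,expected",
        [
            (0.0, 100.0, 0.0, 0.5),  # midpoint = PSE
            (69.3, 150.0, 69.3, 0.5),
            (0.0, 100.0, 100.0 * LN3, 0.75),  # upper quartile at x0 + omega*ln3
            (0.0, 100.0, -100.0 * LN3, 0.25),  # logistic symmetry
            (0.0, 150.0, 600.0, 1 / (1 + math.exp(-4))),
        ],
    )
    def test_known_values(self, x0, omega, x, expected):
        assert evaluate_curve(x0, omega, x) == pytest.approx(expected, abs=1e-12)

    def test_increasing_and_bounded(self):
        x = np.linspace(-2000, 2000, 101)
        y = evaluate_curve(25.0, 120.0, x)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 1))

    def test_zero_omega_raises(self):
        with pytest.raises(DegenerateSlopeError):
            evaluate_curve(0.0, 0.0, 100.0)


class TestAggregateProportions:
    def test_default_design_counts(self, default_design, small_population):
        from socialtime import sample_population

        prof = sample_population(small_population, seed=2)[0]
        trials = simulate_trials(prof, default_design, "upright", seed=2)
        table = aggregate_proportions(trials, "upright")
        assert len(table.levels_ms) == 7
        assert np.all(table.n_total == 20)
        assert table.n_total.sum() == 140

    def test_saturated_responses(self, default_design, small_population):
        from socialtime import sample_population

        prof = sample_population(small_population, seed=2)[0]
        trials = simulate_trials(prof, default_design, "upright", seed=2)
        trials["chose_communicative_longer"] = 1
        table = aggregate_proportions(trials, "upright")
        assert np.array_equal(table.n_chose, table.n_total)

    def test_hand_tally(self):
        # 2 trials per level; responses fixed by hand.
        deltas = np.repeat(DEFAULT_LEVELS, 2)
        responses = [0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 1, 1, 1, 1]
        trials = pd.DataFrame(
            {
                "observer_id": "obs1",
                "condition": "upright",
                "delta_ms": deltas,
                "chose_communicative_longer": responses,
            }
        )
        table = aggregate_proportions(trials, "upright")
        assert np.array_equal(table.n_chose, [0, 1, 0, 1, 2, 2, 2])
        assert np.all(table.n_total == 2)

    def test_empty_and_mixed_observers_rejected(self):
        empty = pd.DataFrame(
            {"observer_id": [], "condition": [], "delta_ms": [],
             "chose_communicative_longer": []}
        )
        with pytest.raises(ValidationError):
            aggregate_proportions(empty, "upright")
        mixed = pd.DataFrame(
            {
                "observer_id": ["a", "b"],
                "condition": ["upright", "upright"],
                "delta_ms": [0.0, 0.0],
                "chose_communicative_longer": [1, 0],
            }
        )
        with pytest.raises(ValidationError):
            aggregate_proportions(mixed, "upright")

    def test_table_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ProportionTable(np.array([0.0, 0.0]), np.array([1, 1]), np.array([2, 2]))
        with pytest.raises(ValidationError):
            make_table([25, 1, 1, 1, 1, 1, 1], n=20)


class TestFitBoltzmann:
    def test_recovers_exact_proportions(self):
        fit = fit_boltzmann(exact_table(50.0, 150.0, n=10**6))
        assert fit.converged
        assert fit.x0_ms == pytest.approx(50.0, abs=1.0)
        assert fit.omega_ms == pytest.approx(150.0, abs=2.0)

    @pytest.mark.parametrize("method", ["mle", "lsq"])
    def test_methods_agree_on_clean_data(self, method):
        fit = fit_boltzmann(exact_table(-30.0, 120.0, n=10**5), method=method)
        assert fit.converged and fit.method == method
        assert fit.x0_ms == pytest.approx(-30.0, abs=2.0)
        assert fit.omega_ms == pytest.approx(120.0, abs=3.0)

    def test_flat_half_proportions_flagged(self):
        with pytest.warns(UserWarning):
            fit = fit_boltzmann(make_table([10] * 7, n=20))
        assert not fit.converged
        assert np.isfinite(fit.x0_ms) and np.isfinite(fit.omega_ms)
        assert fit.omega_ms == 2000.0  # slope diverged to the degenerate regime

    @pytest.mark.parametrize(
        "counts",
        [
            [0] * 7,  # never chose communicative
            [20] * 7,  # always chose communicative
            [0, 0, 0, 20, 20, 20, 20],  # perfect separation
        ],
    )
    def test_degenerate_patterns_flagged_finite(self, counts):
        with pytest.warns(UserWarning):
            fit = fit_boltzmann(make_table(counts, n=20))
        assert not fit.converged
        assert np.isfinite(fit.x0_ms) and np.isfinite(fit.omega_ms)
        assert fit.omega_ms > 0

    def test_insufficient_levels_rejected(self):
        table = make_table([1, 19], n=20, levels=np.array([-200.0, 200.0]))
        with pytest.raises(InsufficientDataError):
            fit_boltzmann(table)

    def test_mle_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            table = binomial_table(rng.uniform(-80, 80), rng.uniform(80, 250), rng)
            fit = fit_boltzmann(table)
            assert fit.converged
            assert fit.loglik >= grid_best_loglik(table) - 1e-6

    def test_mle_matches_glm_oracle(self):
        # Independent route: binomial GLM with logit link (IRLS).
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        for _ in range(5):
            table = binomial_table(rng.uniform(-100, 100), rng.uniform(80, 300), rng)
            fit = fit_boltzmann(table)
            X = sm.add_constant(table.levels_ms)
            glm = sm.GLM(
                np.column_stack([table.n_chose, table.n_total - table.n_chose]),
                X,
                family=sm.families.Binomial(),
            ).fit()
            b0, b1 = glm.params
            assert fit.omega_ms == pytest.approx(1.0 / b1, rel=1e-5)
            assert fit.x0_ms == pytest.approx(-b0 / b1, rel=1e-5, abs=1e-3)

    def test_monotonicity_in_highest_level(self):
        base = [2, 4, 6, 10, 12, 14, 15]
        x0_prev = fit_boltzmann(make_table(base, n=20)).x0_ms
        for bump in range(1, 6):
            counts = list(base)
            counts[-1] = min(counts[-1] + bump, 20)
            x0_new = fit_boltzmann(make_table(counts, n=20)).x0_ms
            assert x0_new <= x0_prev + 1e-9
            x0_prev = x0_new

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        table = binomial_table(20.0, 140.0, rng)
        shift = 250.0
        shifted = ProportionTable(
            table.levels_ms + shift, table.n_chose, table.n_total
        )
        f0 = fit_boltzmann(table)
        f1 = fit_boltzmann(shifted)
        assert f1.x0_ms - f0.x0_ms == pytest.approx(shift, abs=1e-6)
        assert f1.omega_ms == pytest.approx(f0.omega_ms, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=hst.integers(0, 10_000),
        x0=hst.floats(-150, 150),
        omega=hst.floats(60, 400),
    )
    def test_mle_is_local_optimum(self, seed, x0, omega):
        """The fitted likelihood dominates all nearby parameter perturbations."""
        rng = np.random.default_rng(seed)
        table = binomial_table(x0, omega, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_boltzmann(table)
        if not fit.converged:
            return
        for dx in (-5.0, 0.0, 5.0):
            for dw in (-5.0, 0.0, 5.0):
                if fit.omega_ms + dw <= 0:
                    continue
                ll = _binomial_loglik(
                    table.levels_ms, table.n_chose, table.n_total,
                    fit.x0_ms + dx, fit.omega_ms + dw,
                )
                assert fit.loglik >= ll - 1e-9


class TestDifferenceLimen:
    @pytest.mark.parametrize("omega", [10.0, 100.0, 500.0])
    def test_closed_form_matches_quartile_roots(self, omega):
        fit = PsychometricFit(x0_ms=0.0, omega_ms=omega, loglik=0.0,
                              converged=True, method="mle")
        dl = difference_limen(fit)
        span = 20 * omega
        x75 = brentq(lambda x: evaluate_curve(0.0, omega, x) - 0.75,
                     -span, span, xtol=1e-12)
        x25 = brentq(lambda x: evaluate_curve(0.0, omega, x) - 0.25,
                     -span, span, xtol=1e-12)
        assert dl == pytest.approx((x75 - x25) / 2, abs=1e-9)
        assert dl == pytest.approx(omega * LN3, abs=1e-12)

    def test_step_function_limit(self):
        fit = PsychometricFit(x0_ms=0.0, omega_ms=1e-9, loglik=0.0,
                              converged=True, method="mle")
        assert difference_limen(fit) < 1e-6

    def test_nonconverged_propagates_nan(self):
        fit = PsychometricFit(x0_ms=0.0, omega_ms=2000.0, loglik=0.0,
                              converged=False, method="mle")
        with pytest.warns(UserWarning):
            assert math.isnan(difference_limen(fit))


class TestParameterRecoverySmall:
    def test_mean_recovery_unbiased_smoke(self):
        """200 simulated observers at x0=69.3: mean recovered PSE near truth."""
        rng = np.random.default_rng(9)
        ests = []
        for _ in range(200):
            fit = fit_boltzmann(binomial_table(69.3, 150.0, rng))
            if fit.converged:
                ests.append(fit.x0_ms)
        ests = np.asarray(ests)
        assert len(ests) >= 195
        assert ests.mean() == pytest.approx(69.3, abs=10.0)
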