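"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from socialtime import (
    ExperimentDesign,
    PopulationSpec,
    ProportionTable,
    run_experiment,
)

DEFAULT_LEVELS = np.array([-600.0, -400.0, -200.0, 0.0, 200.0, 400.0, 600.0])


def make_table(k, n=20, levels=DEFAULT_LEVELS) -> ProportionTable:
    k = np.asarray(k, dtype=np.int64)
    n = np.full(len(levels), n, dtype=np.int64) if np.isscalar(n) else np.asarray(n)
    return ProportionTable(levels_ms=np.asarray(levels, float), n_chose=k, n_total=n)


def exact_table(x0, omega, n=10**6, levels=DEFAULT_LEVELS) -> ProportionTable:
    """Counts equal to the rounded expected proportions (vanishing noise)."""
    p = expit((levels - x0) / omega)
    return make_table(np.rint(p * n).astype(np.int64), n, levels)


def binomial_table(x0, omega, rng, reps=20, levels=DEFAULT_LEVELS) -> ProportionTable:
    p = expit((levels - x0) / omega)
    return make_table(rng.binomial(reps, p), reps, levels)


def grid_best_loglik(table, x0_range=(-600.0, 600.0), omega_range=(1.0, 1000.0),
                     step=1.0) -> float:
    """Brute-force oracle: densest log-likelihood over the (x0, omega) grid.

    Uses the algebraic form  sum_l k_l eta_l - n_l softplus(eta_l)  with
    eta = (x - x0)/omega, evaluated exhaustively at 1 ms resolution.
    """
    levels = table.levels_ms
    k = table.n_chose.astype(float)
    n = table.n_total.astype(float)
    x0s = np.arange(x0_range[0], x0_range[1] + step / 2, step)
    best = -np.inf
    for omega in np.arange(omega_range[0], omega_range[1] + step / 2, step):
        eta = (levels[None, :] - x0s[:, None]) / omega
        ll = (k * eta - n * np.logaddexp(0.0, eta)).sum(axis=1)
        m = float(ll.max())
        if m > best:
            best = m
    return best


@pytest.fixture(scope="session")
def default_design() -> ExperimentDesign:
    return ExperimentDesign(conditions=("upright",))


@pytest.fixture(scope="session")
def small_population() -> PopulationSpec:
    return PopulationSpec(
        n_observers=5,
        conditions=("upright",),
        pse_intercept_ms=50.0,
        pse_resid_sd_ms=40.0,
    )


@pytest.fixture(scope="session")
def exp1_report():
    """One end-to-end orientation-experiment replicate, shared across tests."""
    return run_experiment("exp1", seed=11)


@pytest.fixture(scope="session")
def exp4_report():
    return run_experiment("exp4", seed=11)
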