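"""Synthetic two-interval duration-comparison observers.

Generates populations of observers with latent psychometric parameters and
simulates their trial-level binary choices, so the whole analysis chain can
be exercised and validated without human data.

Generative model
----------------
Each observer carries an integer trait score (AQ, Autism Spectrum Quotient;
higher = lower social proficiency), drawn from a normal distribution
truncated to a stated range and rounded to integers, and a latent PSE per
condition built from a linear trait link plus Gaussian noise:

    PSE(c) = intercept(c) + slope * AQ + u + eps(c)

where ``u ~ N(0, pse_observer_sd_ms)`` is shared across conditions (it
induces the within-observer correlation between condition PSEs) and
``eps(c) ~ N(0, pse_resid_sd_ms)`` is condition-specific.  The slope
parameter ``omega`` is drawn once per observer and shared across conditions
(temporal sensitivity is modelled as condition-invariant).  On a trial with
duration difference ``delta`` the probability of judging the communicative
sequence longer is

    p = lapse/2 + (1 - lapse) * F(delta; PSE, omega)

with ``F`` the increasing Boltzmann sigmoid of :mod:`socialtime.psychometric`.
The lapse rate defaults to 0 (the fitted curve downstream has no lapse
term); a small lapse is available for robustness testing only.  Presentation
order and standard-assignment flags are recorded on every trial but do not
enter the choice model.

Pharmacological manipulations (oxytocin, its antagonist atosiban, saline)
are modelled purely as an additive shift of the latent PSE, normally
distributed across observers, with ``omega`` untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import truncnorm

from ._util import TRIAL_COLUMNS, ConfigurationError, substream
from .psychometric import evaluate_curve

__all__ = [
    "ObserverProfile",
    "ExperimentDesign",
    "PopulationSpec",
    "sample_population",
    "choice_probability",
    "simulate_trials",
    "apply_drug_effect",
    "calibrate_aq_pse_link",
    "DRUGS",
]

DRUGS = ("none", "oxytocin", "atosiban", "saline")

DEFAULT_LEVELS_MS = (-600.0, -400.0, -200.0, 0.0, 200.0, 400.0, 600.0)


@dataclass(frozen=True)
class ObserverProfile:
    """Latent parameters of one simulated observer."""

    observer_id: str
    aq: int
    pse_ms: dict  # condition -> latent PSE in ms
    omega_ms: float
    lapse: float = 0.0

    def __post_init__(self):
        if self.omega_ms <= 0:
            raise ConfigurationError("omega_ms must be strictly positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ConfigurationError("lapse must lie in [0, 0.1]")


class ExperimentDesign(BaseModel):
    """Method-of-constant-stimuli design: levels, repetitions, conditions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    levels_ms: tuple[float, ...] = DEFAULT_LEVELS_MS
    reps_per_level: int = 20
    conditions: tuple[str, ...] = ("upright", "inverted")
    experiment_id: str = "Exp1"
    n_blocks_per_condition: int = 4

    @model_validator(mode="after")
    def _check(self):
        levels = sorted(self.levels_ms)
        if levels != sorted(-l for l in levels):
            raise ValueError("levels_ms must be symmetric about 0")
        if len(set(levels)) != len(levels):
            raise ValueError("levels_ms must be distinct")
        if self.reps_per_level < 1 or self.n_blocks_per_condition < 1:
            raise ValueError("reps_per_level and n_blocks_per_condition must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition required")
        return self

    @property
    def trials_per_condition(self) -> int:
        return self.reps_per_level * len(self.levels_ms)


class PopulationSpec(BaseModel):
    """Distributional description of a simulated observer population.

    ``pse_intercept_ms`` may be a scalar (applied to every condition) or a
    mapping condition -> intercept.  ``drug_shift_*`` describe the additive
    post-treatment PSE change applied by :func:`apply_drug_effect`.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_observers: int
    conditions: tuple[str, ...] = ("upright",)
    aq_mean: float = 19.5
    aq_sd: float = 6.0
    aq_range: tuple[int, int] = (10, 36)
    pse_intercept_ms: float | dict[str, float] = 0.0
    pse_slope_ms_per_aq: float = 0.0
    pse_observer_sd_ms: float = 0.0
    pse_resid_sd_ms: float = 0.0
    omega_mean_ms: float = 150.0
    omega_sd_ms: float = 30.0
    lapse: float = 0.0
    drug: str = "none"
    drug_shift_mean_ms: float = 0.0
    drug_shift_sd_ms: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.drug not in DRUGS:
            raise ValueError(f"drug must be one of {DRUGS}")
        for name in ("aq_sd", "pse_observer_sd_ms", "pse_resid_sd_ms",
                     "omega_sd_ms", "drug_shift_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        return self

    def intercept_for(self, condition: str) -> float:
        if isinstance(self.pse_intercept_ms, dict):
            try:
                return self.pse_intercept_ms[condition]
            except KeyError:
                raise ConfigurationError(
                    f"no PSE intercept for condition {condition!r}"
                ) from None
        return float(self.pse_intercept_ms)


def _sample_aq(rng: np.random.Generator, n: int, mean: float, sd: float,
               bounds: tuple[int, int]) -> np.ndarray:
    """Integer AQ scores: truncated normal, rounded, clipped to bounds."""
    lo, hi = bounds
    if sd == 0:
        return np.full(n, int(np.clip(round(mean), lo, hi)), dtype=np.int64)
    # Extend the truncation window by 0.5 so edge integers stay reachable.
    a, b = (lo - 0.5 - mean) / sd, (hi + 0.5 - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws), lo, hi).astype(np.int64)


def sample_population(spec: PopulationSpec, seed: int) -> list[ObserverProfile]:
    """Draw ``spec.n_observers`` observer profiles; deterministic per seed."""
    if spec.n_observers < 2:
        raise ConfigurationError("n_observers must be >= 2")
    lo, hi = spec.aq_range
    if lo > hi:
        raise ConfigurationError("aq_range bounds must be ordered")
    for c in spec.conditions:
        spec.intercept_for(c)  # fail fast on missing condition intercepts

    rng = substream(seed, "population")
    n = spec.n_observers
    aq = _sample_aq(rng, n, spec.aq_mean, spec.aq_sd, spec.aq_range)
    u = rng.normal(0.0, spec.pse_observer_sd_ms, size=n)
    omega = np.maximum(rng.normal(spec.omega_mean_ms, spec.omega_sd_ms, size=n), 1.0)
    width = len(str(n))
    profiles = []
    for i in range(n):
        pse = {}
        for c in spec.conditions:
            eps = rng.normal(0.0, spec.pse_resid_sd_ms)
            pse[c] = (
                spec.intercept_for(c)
                + spec.pse_slope_ms_per_aq * aq[i]
                + u[i]
                + eps
            )
        profiles.append(
            ObserverProfile(
                observer_id=f"obs{i + 1:0{width}d}",
                aq=int(aq[i]),
                pse_ms=pse,
                omega_ms=float(omega[i]),
                lapse=spec.lapse,
            )
        )
    return profiles


def choice_probability(profile: ObserverProfile, condition: str, delta_ms):
    """Generating probability of 'communicative judged longer' at delta_ms."""
    pse = profile.pse_ms[condition]
    f = evaluate_curve(pse, profile.omega_ms, delta_ms)
    return profile.lapse / 2.0 + (1.0 - profile.lapse) * f


def simulate_trials(
    profile: ObserverProfile,
    design: ExperimentDesign,
    condition: str,
    seed: int,
) -> pd.DataFrame:
    """Simulate one observer's trials in one condition.

    Returns the trial-level table (one row per trial, columns per
    ``TRIAL_COLUMNS``): ``reps_per_level`` Bernoulli choices per level,
    shuffled into presentation order and divided into blocks.  Deterministic
    for fixed ``(profile, design, condition, seed)``.
    """
    if condition not in profile.pse_ms:
        raise KeyError(f"condition {condition!r} not in profile.pse_ms")
    rng = substream(seed, "trials", profile.observer_id, condition)

    levels = np.asarray(design.levels_ms, dtype=float)
    deltas = np.repeat(levels, design.reps_per_level)
    n = deltas.size
    p = np.asarray(choice_probability(profile, condition, deltas))
    responses = (rng.random(n) < p).astype(np.int8)
    order = rng.permutation(n)
    deltas, responses = deltas[order], responses[order]
    blocks = (np.arange(n) * design.n_blocks_per_condition) // n + 1

    return pd.DataFrame(
        {
            "observer_id": profile.observer_id,
            "experiment_id": design.experiment_id,
            "condition": condition,
            "block": blocks.astype(np.int64),
            "delta_ms": deltas,
            "standard_is_communicative": rng.integers(0, 2, n).astype(np.int8),
            "communicative_first": rng.integers(0, 2, n).astype(np.int8),
            "chose_communicative_longer": responses,
        },
        columns=list(TRIAL_COLUMNS),
    )


def apply_drug_effect(
    profile: ObserverProfile, spec: PopulationSpec, seed: int
) -> ObserverProfile:
    """Post-treatment profile: every condition PSE shifted by one normal draw.

    The shift distribution comes from ``spec.drug_shift_mean_ms`` /
    ``spec.drug_shift_sd_ms`` (e.g. a positive mean for oxytocin in high-AQ
    observers, negative for atosiban, zero for saline).  Temporal sensitivity
    ``omega`` is left untouched.
    """
    if spec.drug == "none":
        raise ConfigurationError("spec.drug must be set to apply a drug effect")
    rng = substream(seed, "drug", profile.observer_id)
    shift = rng.normal(spec.drug_shift_mean_ms, spec.drug_shift_sd_ms)
    new_pse = {c: v + shift for c, v in profile.pse_ms.items()}
    return dataclasses.replace(profile, pse_ms=new_pse)


def calibrate_aq_pse_link(
    target_r: float,
    pse_sd_ms: float,
    aq_mean: float,
    aq_sd: float,
    aq_range: tuple[int, int],
    n_calib: int = 200_000,
) -> dict:
    """Moment-match the AQ->PSE link to a target correlation.

    With ``PSE = intercept + slope*AQ + noise`` the population correlation is
    ``r = slope*sd(AQ) / sqrt(slope^2 sd(AQ)^2 + sd(noise)^2)`` and the PSE
    SD is the denominator.  Because AQ is truncated and rounded its effective
    moments differ from (aq_mean, aq_sd); they are measured on a large fixed
    internal sample, so the returned coefficients are deterministic:

        slope   = target_r * pse_sd / sd_eff(AQ)
        resid   = pse_sd * sqrt(1 - target_r^2)

    Returns slope, residual SD and the effective AQ mean/SD (the latter pair
    lets callers place the intercept to hit a target mean PSE).
    """
    if not -1.0 < target_r < 1.0:
        raise ConfigurationError("target_r must lie in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(2_000_003))
    aq = _sample_aq(rng, n_calib, aq_mean, aq_sd, aq_range)
    sd_eff = float(aq.std(ddof=1))
    return {
        "slope_ms_per_aq": target_r * pse_sd_ms / sd_eff,
        "resid_sd_ms": pse_sd_ms * float(np.sqrt(1.0 - target_r**2)),
        "aq_mean_eff": float(aq.mean()),
        "aq_sd_eff": sd_eff,
    }
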