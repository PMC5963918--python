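"""Psychometric-function estimation for two-interval duration comparison.

The observer's choices ("communicative judged longer") are aggregated into
per-level proportions and fitted with a Boltzmann (logistic) sigmoid

    F(x) = 1 / (1 + exp(-(x - x0) / omega)),   omega > 0,

where ``x`` is the signed duration difference (communicative minus
noncommunicative, in ms), ``x0`` is the point of subjective equality (PSE),
and ``omega`` sets the slope.  Half the interquartile range of the fitted
curve is the difference limen (DL); for this functional form it equals
``omega * ln 3`` in closed form.

Sign convention: the curve is written in its *increasing* form.  The same
family is often printed as ``1/(1+exp((x-x0)/omega))``, which is the
decreasing branch; the two are identical under ``omega -> -omega``, and the
DL is ``|omega| * ln 3`` either way.  Here ``omega`` is kept strictly
positive and the curve rises with ``x``.

The default estimator is maximum likelihood on the per-level binomial
counts.  In the logit parametrisation ``eta = b0 + b1*x`` (with
``b1 = 1/omega`` and ``x0 = -b0/b1``) the negative log-likelihood is convex,
so a safeguarded Newton iteration finds the global optimum without
multi-start; estimates are then mapped back to ``(x0, omega)`` and checked
against the parameter box ``x0 in [-1200, 1200]`` ms, ``omega in (0, 2000]``
ms.  Degenerate data (all responses identical, perfect separation, or a flat
proportion profile) yield finite clamped estimates flagged
``converged=False``; they are never silently dropped.  A least-squares fit
on the proportions is available for sensitivity checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from ._util import (
    DegenerateSlopeError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "ProportionTable",
    "PsychometricFit",
    "evaluate_curve",
    "aggregate_proportions",
    "fit_boltzmann",
    "difference_limen",
    "LN3",
    "X0_BOUNDS_MS",
    "OMEGA_BOUNDS_MS",
]

LN3 = math.log(3.0)

#: Parameter box for the fit; estimates outside are clamped and flagged.
X0_BOUNDS_MS = (-1200.0, 1200.0)
OMEGA_BOUNDS_MS = (1e-6, 2000.0)

_P_CLIP = 1e-12


def evaluate_curve(x0_ms: float, omega_ms: float, x_ms):
    """Choice probability F(x) of the increasing Boltzmann sigmoid.

    Parameters
    ----------
    x0_ms : location (the PSE) in ms.
    omega_ms : slope parameter in ms; must be nonzero.  Positive gives the
        increasing curve used throughout this package.
    x_ms : scalar or array of signed duration differences in ms.
    """
    if omega_ms == 0:
        raise DegenerateSlopeError("omega_ms must be nonzero")
    return expit((np.asarray(x_ms, dtype=float) - x0_ms) / omega_ms)


@dataclass(frozen=True)
class ProportionTable:
    """Per-level counts of 'communicative judged longer' responses."""

    levels_ms: np.ndarray
    n_chose: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels_ms, dtype=float)
        k = np.asarray(self.n_chose, dtype=np.int64)
        n = np.asarray(self.n_total, dtype=np.int64)
        if not (levels.shape == k.shape == n.shape) or levels.ndim != 1:
            raise ValidationError("levels_ms, n_chose, n_total must be 1-D and equal length")
        if levels.size and np.any(np.diff(levels) <= 0):
            raise ValidationError("levels_ms must be strictly increasing")
        if np.any(k < 0) or np.any(k > n):
            raise ValidationError("need 0 <= n_chose <= n_total at every level")
        object.__setattr__(self, "levels_ms", levels)
        object.__setattr__(self, "n_chose", k)
        object.__setattr__(self, "n_total", n)

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_total > 0, self.n_chose / self.n_total, np.nan)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted Boltzmann parameters with derived quantities and diagnostics."""

    x0_ms: float
    omega_ms: float
    loglik: float
    converged: bool
    method: str
    message: str = ""
    dl_ms: float = field(default=np.nan)

    def __post_init__(self):
        if np.isnan(self.dl_ms):
            object.__setattr__(
                self, "dl_ms", self.omega_ms * LN3 if self.converged else np.nan
            )

    @property
    def pse_ms(self) -> float:
        """Alias: the PSE is the location parameter x0."""
        return self.x0_ms


def aggregate_proportions(
    trials: pd.DataFrame, condition: str | None = None
) -> ProportionTable:
    """Tally one observer's trials into per-level choice proportions.

    ``trials`` is the trial-level table (see ``observer_sim``).  If
    ``condition`` is given, rows are filtered to it first; the remaining rows
    must belong to a single observer and a single condition.
    """
    df = trials
    if condition is not None:
        df = df[df["condition"] == condition]
    if len(df) == 0:
        raise ValidationError("no trials to aggregate")
    if len(pd.unique(df["observer_id"])) != 1:
        raise ValidationError("trials mix multiple observers; aggregate one at a time")
    if len(pd.unique(df["condition"])) != 1:
        raise ValidationError("trials mix multiple conditions; pass condition=")
    deltas = df["delta_ms"].to_numpy(dtype=float)
    resp = df["chose_communicative_longer"].to_numpy(dtype=np.int64)
    levels, inverse = np.unique(deltas, return_inverse=True)
    n = np.bincount(inverse)
    k = np.bincount(inverse, weights=resp).astype(np.int64)
    return ProportionTable(levels_ms=levels, n_chose=k, n_total=n)


def _binomial_loglik(levels: np.ndarray, k: np.ndarray, n: np.ndarray,
                     x0: float, omega: float) -> float:
    """Bernoulli log-likelihood of the counts (binomial coefficient omitted)."""
    p = np.clip(evaluate_curve(x0, omega, levels), _P_CLIP, 1 - _P_CLIP)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _moment_init(levels: np.ndarray, phat: np.ndarray) -> tuple[float, float]:
    """Crude (x0, omega) start: level nearest p=0.5 and the 25-75% span."""
    # nearest-to-0.5 level; ties resolve toward the center of the range
    order = np.lexsort((np.abs(levels), np.abs(phat - 0.5)))
    x0 = float(levels[order[0]])
    crossing = np.where((phat[:-1] < 0.75) & (phat[1:] >= 0.75))[0]
    falling = np.where((phat[:-1] < 0.25) & (phat[1:] >= 0.25))[0]
    if crossing.size and falling.size:
        span = levels[crossing[0] + 1] - levels[falling[0]]
        omega = max(float(span) / (2 * LN3), 10.0)
    else:
        omega = 150.0
    return x0, omega


def _newton_logit_mle(levels, k, n, b0, b1, max_iter=100, tol=1e-10):
    """Safeguarded Newton on the convex NLL in (b0, b1); returns (b0, b1, ok)."""

    def nll(b0, b1):
        p = np.clip(expit(b0 + b1 * levels), _P_CLIP, 1 - _P_CLIP)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    f = nll(b0, b1)
    for _ in range(max_iter):
        eta = b0 + b1 * levels
        p = expit(eta)
        w = n * p * (1 - p)
        g0 = float(np.sum(n * p - k))
        g1 = float(np.sum((n * p - k) * levels))
        h00 = float(np.sum(w))
        h01 = float(np.sum(w * levels))
        h11 = float(np.sum(w * levels**2))
        det = h00 * h11 - h01 * h01
        if not np.isfinite(det) or det <= 1e-300:
            return b0, b1, False  # Hessian singular: flat or separated data
        d0 = -(h11 * g0 - h01 * g1) / det
        d1 = -(-h01 * g0 + h00 * g1) / det
        step = 1.0
        for _ in range(40):  # backtracking keeps the NLL monotone
            f_new = nll(b0 + step * d0, b1 + step * d1)
            if f_new <= f + 1e-15:
                break
            step *= 0.5
        else:
            return b0, b1, True  # no further descent possible
        b0, b1 = b0 + step * d0, b1 + step * d1
        improved = f - f_new
        f = f_new
        if improved < tol and max(abs(step * d0), abs(step * d1) * 600) < 1e-8:
            return b0, b1, True
    return b0, b1, False


def _clamp(x0: float, omega: float) -> tuple[float, float, bool]:
    """Force estimates into the parameter box; report whether clamping bit."""
    cx0 = float(np.clip(x0, *X0_BOUNDS_MS))
    comega = float(np.clip(omega, *OMEGA_BOUNDS_MS))
    inside = (cx0 == x0) and (comega == omega)
    return cx0, comega, inside


def _fit_mle(table: ProportionTable) -> PsychometricFit:
    levels, k, n = table.levels_ms, table.n_chose, table.n_total
    phat = k / n

    if np.all(k == 0) or np.all(k == n):
        # All responses identical: the likelihood has no interior optimum.
        x0 = X0_BOUNDS_MS[1] if np.all(k == 0) else X0_BOUNDS_MS[0]
        omega = OMEGA_BOUNDS_MS[1]
        msg = "degenerate data: all responses identical"
        warnings.warn(msg)
        return PsychometricFit(x0, omega, _binomial_loglik(levels, k, n, x0, omega),
                               converged=False, method="mle", message=msg)

    extreme = (k == 0) | (k == n)
    ones = k == n
    if np.all(extreme) and np.all(np.diff(ones.astype(int)) >= 0):
        # Perfect separation (zeros, then ones): the likelihood supremum is
        # approached as omega -> 0 with x0 anywhere in the gap.  Report the
        # gap midpoint and the shallowest step consistent with the data.
        last0 = levels[~ones][-1]
        first1 = levels[ones][0]
        x0, omega, _ = _clamp((last0 + first1) / 2.0, (first1 - last0) / (2 * LN3))
        msg = "degenerate data: perfectly separated responses"
        warnings.warn(msg)
        return PsychometricFit(x0, omega, _binomial_loglik(levels, k, n, x0, omega),
                               converged=False, method="mle", message=msg)

    x0_init, omega_init = _moment_init(levels, phat)
    b1 = 1.0 / omega_init
    b0 = -x0_init * b1
    b0, b1, ok = _newton_logit_mle(levels, k, n, b0, b1)

    if not ok or not np.isfinite(b0) or not np.isfinite(b1) or b1 <= 0:
        # Flat profile (b1 ~ 0 or negative) or separation: finite fallback.
        x0, omega, _ = _clamp(x0_init, 1.0 / b1 if b1 > 0 else OMEGA_BOUNDS_MS[1])
        msg = "degenerate data: slope not identifiable"
        warnings.warn(msg)
        return PsychometricFit(x0, omega, _binomial_loglik(levels, k, n, x0, omega),
                               converged=False, method="mle", message=msg)

    x0_hat, omega_hat = -b0 / b1, 1.0 / b1
    x0, omega, inside = _clamp(x0_hat, omega_hat)
    ll = _binomial_loglik(levels, k, n, x0, omega)
    if not inside:
        msg = "estimate outside parameter bounds (clamped)"
        warnings.warn(msg)
        return PsychometricFit(x0, omega, ll, converged=False, method="mle", message=msg)
    return PsychometricFit(x0, omega, ll, converged=True, method="mle")


def _fit_lsq(table: ProportionTable) -> PsychometricFit:
    levels, k, n = table.levels_ms, table.n_chose, table.n_total
    phat = k / n
    x0_init, omega_init = _moment_init(levels, phat)

    def resid(theta):
        return expit((levels - theta[0]) / theta[1]) - phat

    lb = [X0_BOUNDS_MS[0], OMEGA_BOUNDS_MS[0]]
    ub = [X0_BOUNDS_MS[1], OMEGA_BOUNDS_MS[1]]
    starts = [
        (x0_init, omega_init),
        (0.0, 150.0),
        (x0_init, min(2 * omega_init, 1000.0)),
    ]
    best = None
    for s in starts:
        sol = least_squares(resid, x0=np.clip(s, lb, ub), bounds=(lb, ub), xtol=1e-12)
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    x0, omega = float(best.x[0]), float(best.x[1])
    ll = _binomial_loglik(levels, k, n, x0, omega)
    # Treat an estimate pinned to the box edge as non-identified.
    margin_hit = (
        omega >= 0.999 * OMEGA_BOUNDS_MS[1]
        or omega <= 1e-3
        or abs(x0) >= 0.999 * X0_BOUNDS_MS[1]
    )
    if not best.success or margin_hit:
        msg = "least-squares estimate at or near parameter bounds"
        warnings.warn(msg)
        return PsychometricFit(x0, omega, ll, converged=False, method="lsq", message=msg)
    return PsychometricFit(x0, omega, ll, converged=True, method="lsq")


def fit_boltzmann(table: ProportionTable, method: str = "mle") -> PsychometricFit:
    """Fit the Boltzmann sigmoid to a proportion table.

    ``method="mle"`` (default) maximises the Bernoulli likelihood of the
    per-level counts; ``method="lsq"`` minimises squared error on the
    proportions.  Both are deterministic for fixed input.  Requires at least
    3 levels with observed trials; degenerate response patterns return a
    flagged, finite fit with ``converged=False``.
    """
    informative = int(np.sum(table.n_total > 0))
    if informative < 3:
        raise InsufficientDataError(
            f"need >= 3 informative levels, got {informative}"
        )
    if np.any(table.n_total == 0):
        keep = table.n_total > 0
        table = ProportionTable(
            table.levels_ms[keep], table.n_chose[keep], table.n_total[keep]
        )
    if method == "mle":
        return _fit_mle(table)
    if method == "lsq":
        return _fit_lsq(table)
    raise ValueError(f"unknown method {method!r}; use 'mle' or 'lsq'")


def difference_limen(fit: PsychometricFit) -> float:
    """Difference limen: half the interquartile range of the fitted curve.

    Equals ``omega * ln 3`` in closed form (the quartile abscissae of the
    logistic are ``x0 +/- omega ln 3``).  A non-converged fit propagates a
    flagged NaN rather than a number.
    """
    if not fit.converged:
        warnings.warn("difference limen undefined for non-converged fit; returning NaN")
        return float("nan")
    return fit.omega_ms * LN3
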