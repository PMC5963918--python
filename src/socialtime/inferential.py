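"""Inferential statistics on fitted PSEs and difference limens.

Covers every contrast the duration-compression analyses use: one-sample,
paired and independent t-tests with Cohen's d, the orientation-by-experiment
mixed ANOVA with Cohen's f, Pearson correlation, the AQ median split, and
the bivariate bootstrap of (pre, post) sample means.

Effect-size conventions (fixed by the printed statistics they reproduce):

* one-sample / paired:  d = t / sqrt(n)  (equivalently mean / SD)
* independent (pooled): d = t * sqrt(1/n1 + 1/n2); the test itself uses the
  pooled-variance t (df = n1 + n2 - 2), not Welch
* ANOVA: Cohen's f = sqrt(eta_p^2 / (1 - eta_p^2)) from partial eta squared

All p-values are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError

__all__ = [
    "TTestResult",
    "AnovaResult",
    "CorrelationResult",
    "MedianSplitResult",
    "BootstrapCloud",
    "one_sample_t",
    "paired_t",
    "independent_t",
    "cohens_d_from_t",
    "round_effect_size",
    "cohen_f_from_eta",
    "cohen_f_from_F",
    "mixed_anova_interaction",
    "pearson_r",
    "median_split",
    "bootstrap_bivariate_mean",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    kind: str  # one_sample | paired | independent
    n: int | None = None
    n1: int | None = None
    n2: int | None = None


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    cohen_f: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class MedianSplitResult:
    threshold: float
    low: np.ndarray  # values whose score < threshold
    high: np.ndarray  # values whose score >= threshold
    low_scores: np.ndarray
    high_scores: np.ndarray

    @property
    def n_low(self) -> int:
        return len(self.low)

    @property
    def n_high(self) -> int:
        return len(self.high)


@dataclass(frozen=True)
class BootstrapCloud:
    resampled_means: np.ndarray  # shape (n_boot, 2): (pre mean, post mean)
    seed: int
    n_boot: int


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Classical one-sample t-test against mu0, with d = (mean - mu0)/SD."""
    v = _as_1d(values, "values")
    n = v.size
    if n < 2:
        raise ValidationError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance: t statistic undefined")
    t, p = stats.ttest_1samp(v, mu0)
    return TTestResult(t=float(t), df=n - 1, p=float(p),
                       d=float((v.mean() - mu0) / sd), kind="one_sample", n=n)


def paired_t(pre, post) -> TTestResult:
    """Paired t-test on (post - pre) differences; d = mean(diff)/SD(diff)."""
    a = _as_1d(pre, "pre")
    b = _as_1d(post, "post")
    if a.size != b.size:
        raise ValidationError("pre and post must have equal length")
    diff = b - a
    if diff.size >= 2 and np.all(diff == 0):
        # exactly null difference: t and d are 0 by definition
        return TTestResult(t=0.0, df=diff.size - 1, p=1.0, d=0.0,
                           kind="paired", n=diff.size)
    res = one_sample_t(diff, 0.0)
    return TTestResult(t=res.t, df=res.df, p=res.p, d=res.d, kind="paired", n=res.n)


def independent_t(group1, group2) -> TTestResult:
    """Pooled-variance independent-samples t-test; d = t*sqrt(1/n1 + 1/n2)."""
    g1 = _as_1d(group1, "group1")
    g2 = _as_1d(group2, "group2")
    if g1.size < 2 or g2.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        raise ValidationError("zero variance in both groups: t undefined")
    t, p = stats.ttest_ind(g1, g2, equal_var=True)
    n1, n2 = g1.size, g2.size
    return TTestResult(t=float(t), df=n1 + n2 - 2, p=float(p),
                       d=float(t) * math.sqrt(1 / n1 + 1 / n2),
                       kind="independent", n1=n1, n2=n2)


def cohens_d_from_t(t: float, n: int | None = None, n1: int | None = None,
                    n2: int | None = None, kind: str = "one_sample") -> float:
    """Recover Cohen's d from a t statistic and sample size(s)."""
    if kind in ("one_sample", "paired"):
        if n is None or n <= 0:
            raise ValidationError("kind=one_sample/paired requires positive n")
        return t / math.sqrt(n)
    if kind == "independent":
        if not n1 or not n2 or n1 <= 0 or n2 <= 0:
            raise ValidationError("kind=independent requires positive n1 and n2")
        return t * math.sqrt(1 / n1 + 1 / n2)
    raise ValueError(f"unknown kind {kind!r}")


def round_effect_size(d: float, decimals: int = 2) -> float:
    """Display rounding for effect sizes (the 2-decimal convention)."""
    return float(round(d, decimals))


def cohen_f_from_eta(eta_p2: float) -> float:
    """Cohen's f from partial eta squared."""
    if not 0 <= eta_p2 < 1:
        raise ValidationError("eta_p2 must lie in [0, 1)")
    return math.sqrt(eta_p2 / (1 - eta_p2))


def cohen_f_from_F(F: float, df1: int, df2: int) -> float:
    """Cohen's f recovered from an F statistic via eta_p^2 = F*df1/(F*df1+df2)."""
    eta = F * df1 / (F * df1 + df2)
    return cohen_f_from_eta(eta)


def mixed_anova_interaction(
    data: pd.DataFrame,
    dv: str = "pse_ms",
    within: str = "condition",
    between: str = "experiment",
    subject: str = "observer_id",
) -> AnovaResult:
    """Within-by-between interaction of a two-way mixed-design ANOVA.

    ``data`` is long-format: one row per subject x within-level, plus a
    between-subject group label.  Every subject must have a value at every
    within level (balanced within-subject data).  Returns the interaction F
    with df (k-1)(m-1) and (N-k)(m-1), partial eta squared and Cohen's f.
    """
    counts = data.groupby(subject)[within].nunique()
    m = data[within].nunique()
    if (counts != m).any():
        raise ValidationError("every subject needs a value at every within level")
    if data[between].nunique() < 2:
        raise ValidationError("need at least 2 between-subject groups")
    if data.groupby(subject)[between].nunique().max() > 1:
        raise ValidationError("each subject must belong to exactly one group")

    import pingouin as pg  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin warns on zero-variance toys
        aov = pg.mixed_anova(data=data, dv=dv, within=within,
                             between=between, subject=subject)
    row = aov.set_index("Source").loc["Interaction"]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    df1, df2 = int(row["DF1"]), int(row["DF2"])
    ss_inter = float(row["SS"])
    F = float(row["F"]) if "F" in aov.columns else float("nan")
    if not np.isfinite(F):
        if abs(ss_inter) < 1e-12:
            # No interaction variance at all (e.g. all cells equal): F := 0.
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0,
                               eta_p2=0.0, cohen_f=0.0)
        raise ValidationError("mixed ANOVA produced a non-finite F")
    eta = float(row["np2"])
    return AnovaResult(F=F, df1=df1, df2=df2, p=float(row[p_col]),
                       eta_p2=eta, cohen_f=cohen_f_from_eta(eta))


def pearson_r(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    a = _as_1d(x, "x")
    b = _as_1d(y, "y")
    if a.size != b.size:
        raise ValidationError("x and y must have equal length")
    if a.size < 3:
        raise ValidationError("need at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = stats.pearsonr(a, b)
    return CorrelationResult(r=float(res.statistic), n=a.size, p=float(res.pvalue))


def median_split(scores, values) -> MedianSplitResult:
    """Split observers into low/high trait groups at the sample median.

    The threshold is chosen so that the groups read "score < T" versus
    "score >= T": when the median value is itself attained by some observer,
    T is the smallest integer strictly greater than the median (a median AQ
    of 19 yields groups "< 20" and ">= 20"); otherwise T is the median
    rounded up.  An empty group raises a warning, not an error.
    """
    s = _as_1d(scores, "scores")
    v = _as_1d(values, "values")
    if s.size != v.size:
        raise ValidationError("scores and values must have equal length")
    med = float(np.median(s))
    if np.any(s == med):
        threshold = float(math.floor(med) + 1)
    else:
        threshold = float(math.ceil(med))
    low_mask = s < threshold
    if not low_mask.any() or low_mask.all():
        warnings.warn("median split produced an empty group")
    return MedianSplitResult(
        threshold=threshold,
        low=v[low_mask],
        high=v[~low_mask],
        low_scores=s[low_mask],
        high_scores=s[~low_mask],
    )


def bootstrap_bivariate_mean(pre, post, n_boot: int = 1000,
                             seed: int = 0) -> BootstrapCloud:
    """Bivariate bootstrap cloud of (pre, post) sample means.

    Observers are resampled with replacement as whole pairs; each of the
    ``n_boot`` resamples contributes its (mean pre, mean post) point.
    Deterministic for fixed seed.
    """
    from ._util import substream

    a = _as_1d(pre, "pre")
    b = _as_1d(post, "post")
    if a.size != b.size:
        raise ValidationError("pre and post must have equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 pairs")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = substream(seed, "bootstrap")
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    means = np.column_stack([a[idx].mean(axis=1), b[idx].mean(axis=1)])
    return BootstrapCloud(resampled_means=means, seed=seed, n_boot=n_boot)
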