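"""End-to-end synthetic replications of the six duration-judgment experiments.

Each template encodes one experiment's sample size, conditions and
generating parameters, calibrated to the published group statistics:

* ``exp1``  (n=24, upright/inverted): upright mean PSE 69.3 ms, inverted 0.
* ``exp2``/``exp3`` (n=24 each): communicative intent disrupted (temporal
  lag / spatial swap), both generating means 0.
* ``exp4``  (n=90, upright only): mean PSE 38.5 ms with an AQ-linked
  negative correlation (target r = -0.40) and a median split near AQ 20.
* ``exp5``  (2 x n=40, high-AQ, pre/post): oxytocin arm shifts +36.9 ms,
  atosiban arm -19.1 ms.
* ``exp6``  (2 x n=40, low-AQ, pre/post): atosiban arm shifts -31.1 ms,
  saline arm 0.

Between-observer SDs are back-solved from the published t statistics
(SD = mean * sqrt(n) / t) and are therefore approximations; see
docs/methods.md for the per-template derivations.  A generic two-condition
template (``two_condition``) covers auxiliary designs such as
launching/streaming contrasts.

``run_experiment`` executes simulate -> fit -> analyze for one template and
returns an :class:`ExperimentReport`; ``omnibus_interaction`` pools the
orientation experiments into the orientation-by-experiment mixed ANOVA.
Everything is reproducible from (template, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Any

import numpy as np
import pandas as pd

from ._util import ConfigurationError, ValidationError, derive_seed
from .inferential import (
    AnovaResult,
    BootstrapCloud,
    CorrelationResult,
    TTestResult,
    bootstrap_bivariate_mean,
    independent_t,
    median_split,
    mixed_anova_interaction,
    one_sample_t,
    paired_t,
    pearson_r,
)
from .observer_sim import (
    ExperimentDesign,
    ObserverProfile,
    PopulationSpec,
    apply_drug_effect,
    sample_population,
    simulate_trials,
)
from .psychometric import aggregate_proportions, difference_limen, fit_boltzmann

__all__ = [
    "ExperimentTemplate",
    "ExperimentReport",
    "get_template",
    "template_names",
    "run_experiment",
    "omnibus_interaction",
    "summarize_report",
    "headline_checks",
    "dl_checks",
]

# --- template calibration ---------------------------------------------------
#
# Group SDs are back-solved from the published statistics (SD =
# mean*sqrt(n)/t).  Those are SDs of *fitted* PSEs, which contain
# psychometric-estimation noise on top of true between-observer spread; the
# generating (latent) SDs are therefore deconvolved by subtracting the
# asymptotic sampling variance of one fit,
#
#   var_fit ~= omega^2 / (R * sum_l p_l (1 - p_l)),
#
# (R trials/level, p_l the choice probability at level l), so that the
# *observed* spread of fitted PSEs in a replication matches the published
# value instead of exceeding it.  The published change-score SDs (43-50 ms)
# bound the single-fit noise from above and thereby the slope parameter:
# omega ~ 100 ms (DL ~ 110 ms, a Weber fraction of ~11% at 1 s) keeps the
# fit-noise floor consistent with every printed SD; omega = 150 would
# already exceed some of them on its own.

_OMEGA_MEAN = 100.0
_OMEGA_SD = 20.0
_AQ_CORR_TARGET = -0.40  # published observed correlation (fitted PSE vs AQ)


def _fit_noise_var(omega: float = _OMEGA_MEAN, reps: int = 20,
                   pse: float = 0.0) -> float:
    """Asymptotic variance of one fitted PSE under the default design."""
    from scipy.special import expit

    levels = np.asarray([-600.0, -400.0, -200.0, 0.0, 200.0, 400.0, 600.0])
    p = expit((levels - pse) / omega)
    return omega**2 / (reps * float(np.sum(p * (1 - p))))


def _latent_sd(observed_sd: float, n_fits: int = 1) -> float:
    """Deconvolve fit noise (from n_fits independent fits) out of an observed SD."""
    return float(np.sqrt(max(observed_sd**2 - n_fits * _fit_noise_var(), 0.0)))


# exp1: observed per-condition SD 60.6 (= 69.3*sqrt(24)/5.60) and observed
# upright-inverted difference SD 58.3 (= 69.3*sqrt(24)/5.82) decompose into a
# shared observer component and a condition-specific one.
_EXP1_COND_SD = float(np.sqrt(max(58.3**2 / 2 - _fit_noise_var(), 0.0)))
_EXP1_OBSERVER_SD = float(
    np.sqrt(max(_latent_sd(60.6) ** 2 - _EXP1_COND_SD**2, 0.0))
)
_EXP4_PSE_SD = 60.2  # observed: 38.5*sqrt(90)/6.07


@dataclass(frozen=True)
class ExperimentTemplate:
    """One experiment's design, population arms and analysis kind."""

    name: str
    kind: str  # orientation | aq_correlation | drug | two_condition
    design: ExperimentDesign
    arms: dict  # arm label -> PopulationSpec

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "design": self.design.model_dump(),
            "arms": {k: v.model_dump() for k, v in self.arms.items()},
        }


def _orientation_template(name: str, experiment_id: str,
                          upright_mean: float) -> ExperimentTemplate:
    design = ExperimentDesign(experiment_id=experiment_id,
                              conditions=("upright", "inverted"))
    spec = PopulationSpec(
        n_observers=24,
        conditions=("upright", "inverted"),
        pse_intercept_ms={"upright": upright_mean, "inverted": 0.0},
        pse_observer_sd_ms=_EXP1_OBSERVER_SD,
        pse_resid_sd_ms=_EXP1_COND_SD,
        omega_mean_ms=_OMEGA_MEAN,
        omega_sd_ms=_OMEGA_SD,
    )
    return ExperimentTemplate(name=name, kind="orientation",
                              design=design, arms={"all": spec})


_EXP4_LINK_CACHE: dict = {}


def _exp4_template() -> ExperimentTemplate:
    from .observer_sim import calibrate_aq_pse_link

    aq_mean, aq_sd, aq_range = 19.5, 6.0, (10, 36)
    # The published r = -0.40 relates AQ to *fitted* PSEs; the latent link is
    # correspondingly steeper: cov(AQ, PSE) is untouched by fit noise, so
    # r_latent * sd_latent = r_observed * sd_observed.
    sd_latent = _latent_sd(_EXP4_PSE_SD)
    r_latent = _AQ_CORR_TARGET * _EXP4_PSE_SD / sd_latent
    if "link" not in _EXP4_LINK_CACHE:  # deterministic; computed once
        _EXP4_LINK_CACHE["link"] = calibrate_aq_pse_link(
            r_latent, sd_latent, aq_mean, aq_sd, aq_range
        )
    link = _EXP4_LINK_CACHE["link"]
    intercept = 38.5 - link["slope_ms_per_aq"] * link["aq_mean_eff"]
    design = ExperimentDesign(experiment_id="Exp4", conditions=("upright",))
    spec = PopulationSpec(
        n_observers=90,
        conditions=("upright",),
        aq_mean=aq_mean,
        aq_sd=aq_sd,
        aq_range=aq_range,
        pse_intercept_ms=intercept,
        pse_slope_ms_per_aq=link["slope_ms_per_aq"],
        pse_resid_sd_ms=link["resid_sd_ms"],
        omega_mean_ms=_OMEGA_MEAN,
        omega_sd_ms=_OMEGA_SD,
    )
    return ExperimentTemplate(name="exp4", kind="aq_correlation",
                              design=design, arms={"all": spec})


def _drug_arm(n, aq, baseline_mean, baseline_sd_obs, drug, shift_mean,
              shift_sd_obs):
    """Drug-arm spec; observed SDs are deconvolved to latent ones (a change
    score contains the fit noise of two sessions)."""
    aq_mean, aq_sd, aq_range = aq
    return PopulationSpec(
        n_observers=n,
        conditions=("pre",),
        aq_mean=aq_mean,
        aq_sd=aq_sd,
        aq_range=aq_range,
        pse_intercept_ms=baseline_mean,
        pse_resid_sd_ms=_latent_sd(baseline_sd_obs, n_fits=1),
        omega_mean_ms=_OMEGA_MEAN,
        omega_sd_ms=_OMEGA_SD,
        drug=drug,
        drug_shift_mean_ms=shift_mean,
        drug_shift_sd_ms=_latent_sd(shift_sd_obs, n_fits=2),
    )


def _exp5_template() -> ExperimentTemplate:
    # Observed SDs back-solved from the published t statistics:
    # baselines 13.3*sqrt(40)/1.34 = 62.8 and 9.7*sqrt(40)/1.14 = 53.8;
    # changes 36.9*sqrt(40)/3.68 = 63.4 and 19.1*sqrt(40)/2.24 = 53.9.
    high_aq = (24.9, 4.3, (20, 36))
    design = ExperimentDesign(experiment_id="Exp5", conditions=("pre", "post"))
    arms = {
        "oxytocin": _drug_arm(40, high_aq, 13.3, 62.8, "oxytocin", 36.9, 63.4),
        "atosiban": _drug_arm(40, high_aq, 9.7, 53.8, "atosiban", -19.1, 53.9),
    }
    return ExperimentTemplate(name="exp5", kind="drug", design=design, arms=arms)


def _exp6_template() -> ExperimentTemplate:
    # Observed SDs: baselines 48.6*sqrt(40)/4.32 = 71.1 and
    # 54.5*sqrt(40)/5.94 = 58.0; changes 31.1*sqrt(40)/3.90 = 50.4 and
    # (saline, true shift 0) 43.1 -- the latter is at the two-session
    # fit-noise floor, so its latent shift SD deconvolves to ~0.
    low_aq = (15.5, 2.7, (10, 19))
    design = ExperimentDesign(experiment_id="Exp6", conditions=("pre", "post"))
    arms = {
        "atosiban": _drug_arm(40, low_aq, 48.6, 71.1, "atosiban", -31.1, 50.4),
        "saline": _drug_arm(40, low_aq, 54.5, 58.0, "saline", 0.0, 43.1),
    }
    return ExperimentTemplate(name="exp6", kind="drug", design=design, arms=arms)


def _two_condition_template() -> ExperimentTemplate:
    """Generic two-condition contrast (e.g. launching vs streaming events)."""
    design = ExperimentDesign(experiment_id="TwoCond",
                              conditions=("condition_a", "condition_b"))
    spec = PopulationSpec(
        n_observers=24,
        conditions=("condition_a", "condition_b"),
        pse_intercept_ms={"condition_a": 0.0, "condition_b": 0.0},
        pse_observer_sd_ms=_EXP1_OBSERVER_SD,
        pse_resid_sd_ms=_EXP1_COND_SD,
        omega_mean_ms=_OMEGA_MEAN,
        omega_sd_ms=_OMEGA_SD,
    )
    return ExperimentTemplate(name="two_condition", kind="two_condition",
                              design=design, arms={"all": spec})


_TEMPLATES = {
    "exp1": lambda: _orientation_template("exp1", "Exp1", 69.3),
    "exp2": lambda: _orientation_template("exp2", "Exp2", 0.0),
    "exp3": lambda: _orientation_template("exp3", "Exp3", 0.0),
    "exp4": _exp4_template,
    "exp5": _exp5_template,
    "exp6": _exp6_template,
    "two_condition": _two_condition_template,
}


def template_names() -> tuple:
    return tuple(_TEMPLATES)


def get_template(name: str) -> ExperimentTemplate:
    try:
        return _TEMPLATES[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown experiment template {name!r}; choose from {tuple(_TEMPLATES)}"
        ) from None


@dataclass
class ExperimentReport:
    """Everything one replication produced: fits, contrasts, provenance."""

    experiment_id: str
    template: str
    seed: int
    config_hash: str
    fits: pd.DataFrame  # observer_id, arm, condition, aq, pse_ms, omega_ms, ...
    contrasts: dict
    bootstrap: dict = field(default_factory=dict)  # arm -> BootstrapCloud
    extras: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    n_excluded: int = 0
    trials: pd.DataFrame | None = None  # populated only with keep_trials=True
    created: float = field(default_factory=time.time)  # in-memory only

    def to_dict(self) -> dict:
        """JSON-ready dict.  Deterministic: the timestamp is not serialized."""

        def enc(v: Any) -> Any:
            if isinstance(v, TTestResult):
                return {"type": "t_test", "kind": v.kind, "t": v.t, "df": v.df,
                        "p": v.p, "d": v.d, "d_display": f"{v.d:.2f}",
                        "n": v.n, "n1": v.n1, "n2": v.n2}
            if isinstance(v, AnovaResult):
                return {"type": "anova", "F": v.F, "df1": v.df1, "df2": v.df2,
                        "p": v.p, "eta_p2": v.eta_p2, "cohen_f": v.cohen_f,
                        "cohen_f_display": f"{v.cohen_f:.2f}"}
            if isinstance(v, CorrelationResult):
                return {"type": "correlation", "r": v.r, "n": v.n, "p": v.p}
            return v

        return {
            "experiment_id": self.experiment_id,
            "template": self.template,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_excluded": self.n_excluded,
            "warnings": list(self.warnings),
            "extras": self.extras,
            "contrasts": {k: enc(v) for k, v in self.contrasts.items()},
            "bootstrap": {
                arm: {"seed": c.seed, "n_boot": c.n_boot,
                      "resampled_means": c.resampled_means.tolist()}
                for arm, c in self.bootstrap.items()
            },
            "fits": self.fits.to_dict(orient="records"),
        }


def _config_hash(template: ExperimentTemplate) -> str:
    payload = json.dumps(template.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fit_observer(trials: pd.DataFrame, condition: str, method: str):
    table = aggregate_proportions(trials, condition)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate fits are flagged, not noisy
        fit = fit_boltzmann(table, method=method)
        dl = difference_limen(fit) if fit.converged else np.nan
    return fit, dl

def _simulate_and_fit_arm(
    arm: str,
    spec: PopulationSpec,
    design: ExperimentDesign,
    kind: str,
    seed: int,
    method: str,
    keep_trials: bool = False,
) -> tuple[pd.DataFrame, list]:
    pop_seed = derive_seed(seed, arm, "population")
    trial_seed = derive_seed(seed, arm, "trials")
    drug_seed = derive_seed(seed, arm, "drug")
    profiles = sample_population(spec, pop_seed)
    rows = []
    kept: list = []
    for prof in profiles:
        sessions: list[tuple[str, ObserverProfile]]
        if kind == "drug":
            post = apply_drug_effect(prof, spec, drug_seed)
            post = dc_replace(post, pse_ms={"post": post.pse_ms["pre"]})
            sessions = [("pre", prof), ("post", post)]
        else:
            sessions = [(c, prof) for c in spec.conditions]
        for condition, p in sessions:
            trials = simulate_trials(p, design, condition, trial_seed)
            if keep_trials:
                kept.append(trials)
            fit, dl = _fit_observer(trials, condition, method)
            rows.append({
                "observer_id": prof.observer_id,
                "arm": arm,
                "condition": condition,
                "aq": prof.aq,
                "pse_ms": fit.pse_ms,
                "omega_ms": fit.omega_ms,
                "dl_ms": dl,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "method": fit.method,
            })
    return pd.DataFrame(rows), kept


def _paired_frame(fits: pd.DataFrame, arm: str, c1: str, c2: str) -> pd.DataFrame:
    """Wide observer x (c1, c2) frame of converged PSE/DL values."""
    sub = fits[fits["arm"] == arm]
    wide = sub.pivot(index="observer_id", columns="condition",
                     values=["pse_ms", "dl_ms", "converged"])
    ok = wide["converged"][c1].astype(bool) & wide["converged"][c2].astype(bool)
    return wide[ok]


def _contrasts_orientation(fits: pd.DataFrame) -> tuple[dict, dict]:
    wide = _paired_frame(fits, "all", "upright", "inverted")
    up = wide["pse_ms"]["upright"].to_numpy()
    inv = wide["pse_ms"]["inverted"].to_numpy()
    contrasts = {
        "pse_upright_vs_zero": one_sample_t(up),
        "pse_inverted_vs_zero": one_sample_t(inv),
        "pse_upright_minus_inverted": paired_t(inv, up),
        "dl_upright_minus_inverted": paired_t(
            wide["dl_ms"]["inverted"].to_numpy(),
            wide["dl_ms"]["upright"].to_numpy(),
        ),
    }
    extras = {"n_paired": int(len(wide))}
    return contrasts, extras


def _contrasts_aq(fits: pd.DataFrame) -> tuple[dict, dict]:
    sub = fits[(fits["arm"] == "all") & fits["converged"]]
    pse = sub["pse_ms"].to_numpy()
    dl = sub["dl_ms"].to_numpy()
    aq = sub["aq"].to_numpy(dtype=float)
    split_pse = median_split(aq, pse)
    split_dl = median_split(aq, dl)
    contrasts = {
        "pse_vs_zero": one_sample_t(pse),
        "aq_pse_correlation": pearson_r(aq, pse),
        "pse_low_aq_vs_zero": one_sample_t(split_pse.low),
        "pse_high_aq_vs_zero": one_sample_t(split_pse.high),
        "pse_low_vs_high_aq": independent_t(split_pse.low, split_pse.high),
        "dl_low_vs_high_aq": independent_t(split_dl.low, split_dl.high),
    }
    extras = {
        "median_aq": float(np.median(aq)),
        "split_threshold": split_pse.threshold,
        "n_low_aq": split_pse.n_low,
        "n_high_aq": split_pse.n_high,
    }
    return contrasts, extras


def _contrasts_drug(fits: pd.DataFrame, arms: list, seed: int) -> tuple[dict, dict, dict]:
    contrasts: dict = {}
    clouds: dict = {}
    changes: dict = {}
    for arm in arms:
        wide = _paired_frame(fits, arm, "pre", "post")
        pre = wide["pse_ms"]["pre"].to_numpy()
        post = wide["pse_ms"]["post"].to_numpy()
        contrasts[f"{arm}_pse_pre_vs_zero"] = one_sample_t(pre)
        contrasts[f"{arm}_pse_post_vs_zero"] = one_sample_t(post)
        contrasts[f"{arm}_pse_post_minus_pre"] = paired_t(pre, post)
        contrasts[f"{arm}_dl_post_minus_pre"] = paired_t(
            wide["dl_ms"]["pre"].to_numpy(), wide["dl_ms"]["post"].to_numpy()
        )
        clouds[arm] = bootstrap_bivariate_mean(
            pre, post, n_boot=1000, seed=derive_seed(seed, arm, "bootstrap")
        )
        changes[arm] = post - pre
    a1, a2 = arms
    contrasts[f"change_{a1}_vs_{a2}"] = independent_t(changes[a1], changes[a2])
    extras = {f"n_paired_{arm}": int(len(changes[arm])) for arm in arms}
    return contrasts, clouds, extras


def _contrasts_two_condition(fits: pd.DataFrame, conditions: tuple) -> tuple[dict, dict]:
    c1, c2 = conditions
    wide = _paired_frame(fits, "all", c1, c2)
    v1 = wide["pse_ms"][c1].to_numpy()
    v2 = wide["pse_ms"][c2].to_numpy()
    contrasts = {
        f"pse_{c1}_vs_zero": one_sample_t(v1),
        f"pse_{c2}_vs_zero": one_sample_t(v2),
        f"pse_{c1}_minus_{c2}": paired_t(v2, v1),
        f"dl_{c1}_minus_{c2}": paired_t(
            wide["dl_ms"][c2].to_numpy(), wide["dl_ms"][c1].to_numpy()
        ),
    }
    return contrasts, {"n_paired": int(len(wide))}


def run_experiment(config, seed: int, fit_method: str = "mle",
                   keep_trials: bool = False) -> ExperimentReport:
    """Simulate, fit and analyze one experiment template end to end.

    ``config`` is a template name (``exp1`` ... ``exp6``, ``two_condition``)
    or an :class:`ExperimentTemplate`.  Fully reproducible from
    (config, seed).  ``keep_trials=True`` retains the simulated trial table
    on the report (memory-heavy; off by default).
    """
    template = get_template(config) if isinstance(config, str) else config
    if not isinstance(template, ExperimentTemplate):
        raise ConfigurationError("config must be a template name or ExperimentTemplate")

    report_warnings: list[str] = []
    min_n = min(s.n_observers for s in template.arms.values())
    if min_n < 10 or template.design.reps_per_level < 5:
        report_warnings.append(
            "low power: fewer than 10 observers per arm or fewer than 5 "
            "trials per level; estimates will be unstable"
        )

    fit_frames = []
    trial_frames: list = []
    for arm, spec in template.arms.items():
        arm_fits, arm_trials = _simulate_and_fit_arm(
            arm, spec, template.design, template.kind, seed, fit_method,
            keep_trials=keep_trials,
        )
        fit_frames.append(arm_fits)
        trial_frames.extend(arm_trials)
    fits = pd.concat(fit_frames, ignore_index=True)
    n_excluded = int((~fits["converged"]).sum())
    if n_excluded:
        report_warnings.append(f"{n_excluded} non-converged fits excluded from contrasts")

    clouds: dict = {}
    try:
        if template.kind == "orientation":
            contrasts, extras = _contrasts_orientation(fits)
        elif template.kind == "aq_correlation":
            contrasts, extras = _contrasts_aq(fits)
        elif template.kind == "drug":
            contrasts, clouds, extras = _contrasts_drug(fits, list(template.arms), seed)
        elif template.kind == "two_condition":
            contrasts, extras = _contrasts_two_condition(fits, template.design.conditions)
        else:
            raise ConfigurationError(f"unknown template kind {template.kind!r}")
    except ValidationError as e:
        # Too little usable data for inference (e.g. toy designs where most
        # fits are degenerate): deliver the fits and flag, do not crash.
        contrasts, extras = {}, {}
        report_warnings.append(f"contrasts skipped: {e}")

    return ExperimentReport(
        experiment_id=template.design.experiment_id,
        template=template.name,
        seed=seed,
        config_hash=_config_hash(template),
        fits=fits,
        contrasts=contrasts,
        bootstrap=clouds,
        extras=extras,
        warnings=report_warnings,
        n_excluded=n_excluded,
        trials=pd.concat(trial_frames, ignore_index=True) if trial_frames else None,
    )


def omnibus_interaction(reports) -> AnovaResult:
    """Orientation-by-experiment mixed ANOVA over pooled upright/inverted PSEs.

    ``reports`` are the three orientation-experiment reports; observers are
    the random factor (nested in experiment), orientation is within-subject.
    """
    frames = []
    for rep in reports:
        fits = rep.fits
        for cond in ("upright", "inverted"):
            if not ((fits["condition"] == cond) & fits["converged"]).any():
                raise ValidationError(
                    f"report {rep.experiment_id} lacks converged {cond} fits"
                )
        wide = _paired_frame(fits, "all", "upright", "inverted")
        for cond in ("upright", "inverted"):
            frames.append(pd.DataFrame({
                "observer_id": [f"{rep.experiment_id}:{o}" for o in wide.index],
                "experiment": rep.experiment_id,
                "condition": cond,
                "pse_ms": wide["pse_ms"][cond].to_numpy(dtype=float),
            }))
    pooled = pd.concat(frames, ignore_index=True)
    return mixed_anova_interaction(pooled)


def summarize_report(report: ExperimentReport) -> tuple[str, dict]:
    """Human-readable table plus a JSON-ready summary of one report."""
    fits = report.fits
    desc = (
        fits[fits["converged"]]
        .groupby(["arm", "condition"])["pse_ms"]
        .agg(["count", "mean", "sem"])
        .reset_index()
    )
    summary = {
        "experiment_id": report.experiment_id,
        "template": report.template,
        "seed": report.seed,
        "n_excluded": report.n_excluded,
        "warnings": list(report.warnings),
        "extras": report.extras,
        "group_pse": desc.to_dict(orient="records"),
        "contrasts": report.to_dict()["contrasts"],
    }
    lines = [
        f"Experiment {report.experiment_id} (template {report.template}, "
        f"seed {report.seed})",
        f"excluded non-converged fits: {report.n_excluded}",
    ]
    for w in report.warnings:
        lines.append(f"WARNING: {w}")
    lines.append("")
    lines.append(f"{'arm':<10}{'condition':<12}{'n':>4}{'mean PSE':>10}{'SE':>8}")
    for row in desc.itertuples():
        lines.append(
            f"{row.arm:<10}{row.condition:<12}{row.count:>4}"
            f"{row.mean:>10.1f}{row.sem:>8.1f}"
        )
    lines.append("")
    for name, c in summary["contrasts"].items():
        if c["type"] == "t_test":
            lines.append(
                f"{name}: t({c['df']}) = {c['t']:.2f}, p = {c['p']:.4g}, "
                f"d = {c['d_display']}"
            )
        elif c["type"] == "correlation":
            lines.append(f"{name}: r({c['n']}) = {c['r']:.2f}, p = {c['p']:.4g}")
        else:
            lines.append(
                f"{name}: F({c['df1']}, {c['df2']}) = {c['F']:.2f}, "
                f"p = {c['p']:.4g}, f = {c['cohen_f_display']}"
            )
    return "\n".join(lines), summary


# --- replication-fidelity checks -------------------------------------------
#
# Which contrasts are held to significance (alpha = .05) versus direction
# only follows the power each published effect size affords at the published
# sample size: the weak atosiban change in high-AQ observers (d = -0.35) and
# the exp6 between-group change difference (d = 0.50) cannot clear 5%
# significance in >= 80% of replicates even under their own generating
# effect, so those are directional checks.

ALPHA = 0.05


def headline_checks(report: ExperimentReport) -> dict:
    """Per-contrast booleans: does this replicate reproduce the findings?"""
    c = report.contrasts
    t = report.template
    if t in ("exp1", "exp2", "exp3"):
        if t == "exp1":
            return {
                "upright_positive_sig": c["pse_upright_vs_zero"].t > 0
                and c["pse_upright_vs_zero"].p < ALPHA,
                "inverted_nonsig": c["pse_inverted_vs_zero"].p >= ALPHA,
                "upright_gt_inverted_sig": c["pse_upright_minus_inverted"].t > 0
                and c["pse_upright_minus_inverted"].p < ALPHA,
            }
        return {
            "upright_nonsig": c["pse_upright_vs_zero"].p >= ALPHA,
            "inverted_nonsig": c["pse_inverted_vs_zero"].p >= ALPHA,
        }
    if t == "exp4":
        corr = c["aq_pse_correlation"]
        return {
            "overall_positive_sig": c["pse_vs_zero"].t > 0
            and c["pse_vs_zero"].p < ALPHA,
            "aq_correlation_negative_sig": corr.r < 0 and corr.p < ALPHA,
            "low_gt_high_direction": c["pse_low_vs_high_aq"].t > 0,
        }
    if t == "exp5":
        return {
            "oxytocin_increase_sig": c["oxytocin_pse_post_minus_pre"].t > 0
            and c["oxytocin_pse_post_minus_pre"].p < ALPHA,
            "atosiban_decrease_direction": c["atosiban_pse_post_minus_pre"].t < 0,
            "group_change_diff_sig": c["change_oxytocin_vs_atosiban"].t > 0
            and c["change_oxytocin_vs_atosiban"].p < ALPHA,
        }
    if t == "exp6":
        return {
            "atosiban_decrease_sig": c["atosiban_pse_post_minus_pre"].t < 0
            and c["atosiban_pse_post_minus_pre"].p < ALPHA,
            "saline_flat": c["saline_pse_post_minus_pre"].p >= ALPHA,
            "group_change_diff_direction": c["change_atosiban_vs_saline"].t < 0,
        }
    raise ConfigurationError(f"no headline checks defined for template {t!r}")


def dl_checks(report: ExperimentReport) -> dict:
    """Difference-limen contrasts should stay non-significant (omega shared)."""
    return {
        name: res.p >= ALPHA
        for name, res in report.contrasts.items()
        if name.startswith("dl_") or "_dl_" in name
    }
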