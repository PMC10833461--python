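"""Seeded synthetic oncology cohorts with known missingness mechanisms.

The generator emulates the kind of real-world-evidence cohort the
diagnostics in this package are aimed at: a binary treatment exposure, a
time-to-event outcome from a Weibull proportional-hazards model, a handful
of fully observed baseline covariates, and three prognostic covariates that
are subsequently *amputed* (deliberately masked) under known mechanisms:

* ``ecog`` — performance status, masked completely at random (MCAR);
* ``egfr`` — mutation status, masked at random (MAR): the missingness
  logit depends on observed covariates and the exposure;
* ``pdl1`` — expression in percent, masked not-at-random on its own value
  (MNAR-value): high expression is less likely to be recorded.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so a seed fixes the cohort byte-for-byte across runs and platforms.
Amputation intercepts are solved by bisection on the logit scale so each
POC hits its target missingness proportion in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CohortError, CohortTable, MissingnessMechanism

__all__ = [
    "GenerationConfig",
    "MechanismSpec",
    "AmputationConfig",
    "generate_cohort",
    "ampute",
    "simulate_cohort",
    "default_amputation",
    "true_parameters",
]

_TIME_FLOOR = 1e-12  # follow-up floored here so t_max=0 still yields a valid table


@dataclass
class GenerationConfig:
    """Distributional defaults of the synthetic oncology cohort.

    Continuous covariate weights are per standard deviation of the
    covariate; all weights are on the logit (missingness, exposure, binary
    prevalence) or log-hazard (outcome) scale.
    """

    n: int = 2500
    # fully observed baseline covariates
    age_mean: float = 63.0
    age_sd: float = 9.0
    p_female: float = 0.55
    p_smoking: float = 0.40
    histology_levels: tuple[str, ...] = ("adeno", "squamous", "other")
    histology_probs: tuple[float, ...] = (0.60, 0.25, 0.15)
    ses_levels: tuple[str, ...] = ("low", "medium", "high")
    ses_probs: tuple[float, ...] = (0.30, 0.40, 0.30)
    # prognostic covariates (the future POCs)
    ecog_intercept: float = -0.9
    ecog_age: float = 0.5       # per SD of age
    ecog_smoking: float = 0.6
    egfr_prevalence: float = 0.20
    egfr_smoking: float = -0.8  # mutations enriched in never-smokers
    pdl1_alpha: float = 2.0
    pdl1_beta: float = 2.0      # pdl1 ~ Beta(a, b) * 100 percent
    # exposure model
    exposure_prevalence: float = 0.45
    exposure_age: float = 0.2
    exposure_ecog: float = 0.5
    exposure_histology: Mapping[str, float] = field(
        default_factory=lambda: {"squamous": 0.3, "other": 0.4}
    )
    # Weibull proportional-hazards outcome
    weibull_shape: float = 1.3
    median_survival: float = 2.5  # years, at zero linear predictor
    beta_exposure: float = -0.3   # true exposure log hazard ratio
    beta_age: float = 0.30
    beta_female: float = -0.10
    beta_smoking: float = 0.20
    beta_histology: Mapping[str, float] = field(
        default_factory=lambda: {"squamous": 0.25, "other": 0.35}
    )
    beta_ses: Mapping[str, float] = field(
        default_factory=lambda: {"medium": -0.08, "high": -0.15}
    )
    beta_ecog: float = 0.40
    beta_egfr: float = -0.25
    beta_pdl1: float = 0.35       # per SD of pdl1
    t_max: float = 5.0            # administrative censoring, years

    def __post_init__(self) -> None:
        if self.n < 2:
            raise CohortError("config error: n must be >= 2")
        probs = [
            self.p_female, self.p_smoking, self.egfr_prevalence, self.exposure_prevalence,
            *self.histology_probs, *self.ses_probs,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise CohortError("config error: probabilities must lie in [0, 1]")
        for name, tot in (("histology", self.histology_probs), ("ses", self.ses_probs)):
            if abs(sum(tot) - 1.0) > 1e-9:
                raise CohortError(f"config error: {name} probabilities must sum to 1")
        if self.weibull_shape <= 0 or self.median_survival <= 0:
            raise CohortError("config error: hazard parameters must be > 0")
        if self.age_sd <= 0 or self.pdl1_alpha <= 0 or self.pdl1_beta <= 0:
            raise CohortError("config error: distribution parameters must be > 0")
        if self.t_max < 0:
            raise CohortError("config error: t_max must be >= 0")


@dataclass
class MechanismSpec:
    """How one POC is amputed.

    ``predictors`` (MAR) maps column names to logit weights; continuous
    predictors are standardized internally, binary predictors enter as 0/1,
    and categorical predictors take a nested ``{level: weight}`` map.
    ``self_weight`` (MNAR-value) is the weight per SD of the POC's own
    value; ``latent_weight`` (MNAR-unmeasured) weights a standard-normal
    latent draw that never enters the output table.  ``force_with`` names a
    parent POC whose missingness forces this POC missing too (monotone
    coupling).
    """

    mechanism: MissingnessMechanism
    p_miss: float = 0.35
    predictors: Mapping[str, float | Mapping[str, float]] | None = None
    self_weight: float = 0.8
    latent_weight: float = 1.0
    force_with: str | None = None

    def __post_init__(self) -> None:
        self.mechanism = MissingnessMechanism(self.mechanism)
        if not 0.0 <= self.p_miss <= 1.0:
            raise CohortError("config error: p_miss must lie in [0, 1]")


@dataclass
class AmputationConfig:
    """Per-POC mechanism specifications, applied in insertion order."""

    pocs: dict[str, MechanismSpec]


def default_amputation() -> AmputationConfig:
    """The default three-mechanism study configuration.

    MCAR ecog, MAR egfr (missingness driven by age, sex, smoking,
    histology, socio-economic status, and exposure — treated patients are
    more completely worked up), and MNAR-value pdl1 (high values less
    likely to be recorded).  All three target 35% missingness.
    """
    return AmputationConfig(
        pocs={
            "ecog": MechanismSpec(MissingnessMechanism.MCAR, p_miss=0.35),
            "egfr": MechanismSpec(
                MissingnessMechanism.MAR,
                p_miss=0.35,
                predictors={
                    "age": 0.6,
                    "female": -0.4,
                    "smoking": 0.5,
                    "histology": {"squamous": 0.5, "other": 0.7},
                    "ses": {"high": -0.5},
                    "exposure": 0.4,
                },
            ),
            "pdl1": MechanismSpec(
                MissingnessMechanism.MNAR_VALUE, p_miss=0.35, self_weight=0.8
            ),
        }
    )


def _solve_intercept(lp: np.ndarray, p_miss: float) -> float:
    """Bisection for the intercept making mean(expit(a + lp)) == p_miss."""
    if p_miss <= 0.0:
        return -np.inf
    if p_miss >= 1.0:
        return np.inf
    return brentq(lambda a: float(expit(a + lp).mean()) - p_miss, -40.0, 40.0, xtol=1e-12)


def generate_cohort(config: GenerationConfig | None = None, seed: int = 0) -> CohortTable:
    """Draw a fully observed synthetic cohort.

    Deterministic given ``seed``. The returned table tags ``exposure``,
    ``eventtime``/``status`` (time/event outcome), and everything else as
    fully observed covariates; POC roles appear only after :func:`ampute`.
    """
    cfg = config or GenerationConfig()
    rng = np.random.default_rng(np.random.PCG64(seed))
    n = cfg.n

    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    age_z = (age - cfg.age_mean) / cfg.age_sd
    female = rng.binomial(1, cfg.p_female, n)
    smoking = rng.binomial(1, cfg.p_smoking, n)
    histology = rng.choice(cfg.histology_levels, size=n, p=cfg.histology_probs)
    ses = rng.choice(cfg.ses_levels, size=n, p=cfg.ses_probs)

    ecog_lp = cfg.ecog_intercept + cfg.ecog_age * age_z + cfg.ecog_smoking * smoking
    ecog = rng.binomial(1, expit(ecog_lp))

    egfr_lp = cfg.egfr_smoking * smoking
    egfr = rng.binomial(1, expit(_solve_intercept(egfr_lp, cfg.egfr_prevalence) + egfr_lp))

    pdl1 = rng.beta(cfg.pdl1_alpha, cfg.pdl1_beta, n) * 100.0
    pdl1_sd = 100.0 * np.sqrt(
        cfg.pdl1_alpha * cfg.pdl1_beta
        / ((cfg.pdl1_alpha + cfg.pdl1_beta) ** 2 * (cfg.pdl1_alpha + cfg.pdl1_beta + 1))
    )
    pdl1_mean = 100.0 * cfg.pdl1_alpha / (cfg.pdl1_alpha + cfg.pdl1_beta)
    pdl1_z = (pdl1 - pdl1_mean) / pdl1_sd

    exp_lp = (
        cfg.exposure_age * age_z
        + cfg.exposure_ecog * ecog
        + sum(w * (histology == lvl) for lvl, w in cfg.exposure_histology.items())
    )
    exp_lp = np.asarray(exp_lp, dtype=float)
    exposure = rng.binomial(1, expit(_solve_intercept(exp_lp, cfg.exposure_prevalence) + exp_lp))

    hazard_lp = (
        cfg.beta_exposure * exposure
        + cfg.beta_age * age_z
        + cfg.beta_female * female
        + cfg.beta_smoking * smoking
        + sum(w * (histology == lvl) for lvl, w in cfg.beta_histology.items())
        + sum(w * (ses == lvl) for lvl, w in cfg.beta_ses.items())
        + cfg.beta_ecog * ecog
        + cfg.beta_egfr * egfr
        + cfg.beta_pdl1 * pdl1_z
    )
    hazard_lp = np.asarray(hazard_lp, dtype=float)
    # Weibull PH: S(t) = exp(-lam * t^k * e^lp); lam set by the baseline median
    k = cfg.weibull_shape
    lam = np.log(2.0) / cfg.median_survival**k
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (lam * np.exp(hazard_lp))) ** (1.0 / k)
    status = (t_event <= cfg.t_max).astype(int)
    eventtime = np.maximum(np.minimum(t_event, cfg.t_max), _TIME_FLOOR)

    df = pd.DataFrame(
        {
            "exposure": exposure,
            "age": age,
            "female": female,
            "smoking": smoking,
            "histology": histology,
            "ses": ses,
            "ecog": ecog,
            "egfr": egfr,
            "pdl1": pdl1,
            "eventtime": eventtime,
            "status": status,
        }
    )
    return CohortTable.from_dataframe(
        df, exposure="exposure", time="eventtime", event="status", pocs=()
    )


def _mechanism_logit(
    table: CohortTable, poc: str, spec: MechanismSpec, rng: np.random.Generator
) -> np.ndarray:
    df = table.data
    n = len(df)
    if spec.mechanism == MissingnessMechanism.MCAR:
        return np.zeros(n)
    if spec.mechanism == MissingnessMechanism.MAR:
        if not spec.predictors:
            raise CohortError(f"config error: MAR mechanism for {poc!r} needs predictors")
        lp = np.zeros(n)
        for col, w in spec.predictors.items():
            if col not in df.columns:
                raise CohortError(
                    f"config error: MAR predictor {col!r} for {poc!r} is not a column"
                )
            if isinstance(w, Mapping):
                for lvl, wl in w.items():
                    lp += wl * (df[col] == lvl).to_numpy(dtype=float)
            else:
                x = df[col].to_numpy(dtype=float)
                sd = x.std()
                if np.unique(x).size > 2 and sd > 0:
                    x = (x - x.mean()) / sd
                lp += w * x
        return lp
    if spec.mechanism == MissingnessMechanism.MNAR_VALUE:
        x = df[poc].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        return spec.self_weight * z
    if spec.mechanism == MissingnessMechanism.MNAR_UNMEASURED:
        # latent determinant drawn here and never added to the table
        return spec.latent_weight * rng.standard_normal(n)
    raise CohortError(f"config error: cannot ampute with mechanism {spec.mechanism}")


def ampute(table: CohortTable, config: AmputationConfig, seed: int = 0) -> CohortTable:
    """Mask POC cells according to the configured mechanisms.

    The input table is untouched; a new :class:`CohortTable` is returned
    with the amputed columns tagged as POCs.  Monotone coupling
    (``force_with``) is applied after all marginal draws.
    """
    rng = np.random.default_rng(np.random.PCG64(seed))
    df = table.data
    for poc in config.pocs:
        if poc not in df.columns:
            raise CohortError(f"config error: POC {poc!r} not found in table")
        if df[poc].isna().any():
            raise CohortError(f"POC {poc!r} must be fully observed before amputation")

    masks: dict[str, np.ndarray] = {}
    for poc, spec in config.pocs.items():
        lp = _mechanism_logit(table, poc, spec, rng)
        a = _solve_intercept(lp, spec.p_miss)
        prob = expit(a + lp) if np.isfinite(a) else np.full(len(df), float(spec.p_miss > 0))
        masks[poc] = rng.uniform(size=len(df)) < prob
    for poc, spec in config.pocs.items():
        if spec.force_with is not None:
            if spec.force_with not in masks:
                raise CohortError(
                    f"config error: force_with parent {spec.force_with!r} is not an amputed POC"
                )
            masks[poc] = masks[poc] | masks[spec.force_with]

    out = df.copy()
    for poc, mask in masks.items():
        col = out[poc].astype(float) if out[poc].dtype != object else out[poc].astype(object)
        col[mask] = np.nan
        out[poc] = col

    time_cols = [c for c in table.outcome_cols]
    kw: dict = {"exposure": table.exposure_col}
    if table.outcome_kind == "survival":
        t, e = time_cols[-2], time_cols[-1]
        kw.update(time=t, event=e)
    elif table.outcome_kind in ("binary", "continuous"):
        kw.update(outcome=time_cols[0])
    return CohortTable.from_dataframe(out, pocs=list(masks), **kw)


def simulate_cohort(
    n: int = 2500,
    seed: int = 0,
    generation: GenerationConfig | None = None,
    amputation: AmputationConfig | None = None,
) -> CohortTable:
    """Generate and ampute in one step under the default study conditions."""
    cfg = generation or GenerationConfig(n=n)
    amp = amputation or default_amputation()
    s_gen, s_amp = (int(s) for s in np.random.SeedSequence(seed).generate_state(2) % 2**31)
    return ampute(generate_cohort(cfg, seed=s_gen), amp, seed=s_amp)


def true_parameters(
    generation: GenerationConfig | None = None,
    amputation: AmputationConfig | None = None,
) -> dict:
    """Ground-truth record (mechanisms, weights, coefficients) for harnesses."""
    cfg = generation or GenerationConfig()
    amp = amputation or default_amputation()
    return {
        "generation": asdict(cfg),
        "amputation": {
            poc: {
                "mechanism": spec.mechanism.value,
                "p_miss": spec.p_miss,
                "predictors": dict(spec.predictors) if spec.predictors else None,
                "self_weight": spec.self_weight,
                "latent_weight": spec.latent_weight,
                "force_with": spec.force_with,
            }
            for poc, spec in amp.pocs.items()
        },
        "rng": "numpy PCG64",
    }
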