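"""Generators for complete (pre-missingness) cohorts with known truth.

Two study designs are emulated:

* a hypothetical adolescent cohort relating cannabis use at age 15 (none /
  less than weekly / weekly) to mental health at age 21 — a continuous
  depression symptom score and a binary self-harm indicator — with sex and
  maternal substance use as confounders and two auxiliary childhood
  measures;
* a growth cohort for the linear regression of adult BMI at age 25 on
  weight at age 5, adjusted for birth weight, sex, gestational age,
  parental weights and parental socioeconomic status, with auxiliary
  childhood anthropometry.

Every structural coefficient is a visible, overridable parameter, so the
generating truth is always available to the simulation grid.  The binary
self-harm outcome is produced by thresholding a latent score with standard
logistic noise at zero; the latent score is kept as a hidden ``latent``
column so missingness mechanisms may depend on the continuous propensity
underlying the dichotomized outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Column, Dataset


class ParameterError(ValueError):
    """Invalid generator parameters."""


def _check_simplex(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
        raise ParameterError(f"{name} must be nonnegative and sum to 1")
    return p


def _proxy(target: np.ndarray, rho: float, loc: float, scale: float,
           rng: np.random.Generator) -> np.ndarray:
    """Noisy linear proxy with population correlation ``rho`` to ``target``."""
    if not -1.0 <= rho <= 1.0:
        raise ParameterError("proxy correlation must be in [-1, 1]")
    sd = target.std() if target.size else 0.0
    z = (target - target.mean()) / sd if sd > 0 else np.zeros_like(target)
    eps = rng.standard_normal(target.shape[0])
    return loc + scale * (rho * z + np.sqrt(1.0 - rho ** 2) * eps)


def _ordinal_draw(cutpoints: np.ndarray, lp: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Proportional-odds draw: P(level >= k) = expit(cutpoints[k-1] + lp)."""
    n = lp.shape[0]
    p_ge = 1.0 / (1.0 + np.exp(-(cutpoints[None, :] + lp[:, None])))  # (n, K-1)
    u = rng.uniform(size=n)
    return (u[:, None] < p_ge).sum(axis=1).astype(float)


@dataclass
class CannabisParams:
    """Generating parameters for the adolescent cannabis cohort.

    The depression score is on an arbitrary symptom scale with unit
    residual SD, so slopes read directly as fractions of an outcome SD.
    The weekly-use effect (1.0 SD on depression, log-OR 1.0 on self-harm)
    is deliberately strong so that the selection biases the mechanism
    catalog predicts — including the weak, curvature-driven bias of
    MAR-based imputation under self-dependent missingness — are detectable
    at simulation scale.
    """

    n: int = 1000
    seed: int | None = None
    p_sex: float = 0.5
    p_maternal_substance: float = 0.3
    # ordinal model for cannabis use (none / less than weekly / weekly)
    cannabis_cutpoints: tuple[float, float] = (-0.405, -1.735)
    cannabis_on_sex: float = 0.3
    cannabis_on_maternal: float = 0.7
    # linear model for depression score at 21
    depression_intercept: float = 2.0
    depression_on_cannabis: tuple[float, float] = (0.5, 1.0)  # less-than-weekly, weekly
    depression_on_sex: float = 0.3
    depression_on_maternal: float = 0.5
    residual_sd: float = 1.0
    # latent-logistic model for self-harm
    selfharm_intercept: float = -1.8
    selfharm_on_cannabis: tuple[float, float] = (0.5, 1.0)
    selfharm_on_sex: float = 0.3
    selfharm_on_maternal: float = 0.7
    # auxiliaries
    aux_depression_rho: float = 0.7   # child depression score at 12 ~ outcome proxy
    conduct_intercept: float = -1.5   # conduct disorder ~ cannabis proxy
    conduct_on_cannabis: float = 0.8

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError("n must be >= 0")
        if self.residual_sd < 0:
            raise ParameterError("residual_sd must be >= 0")
        for p in (self.p_sex, self.p_maternal_substance):
            _check_simplex([p, 1.0 - p], "binary probability")


CANNABIS_LEVELS = ("none", "less_than_weekly", "weekly")


def generate_cannabis_population(params: CannabisParams | None = None,
                                 outcome: str = "depression_21") -> Dataset:
    """Generate the complete cannabis cohort (no missing values).

    ``outcome`` selects which variable carries the ``outcome`` role
    ("depression_21" for the linear analysis, "self_harm" for the logistic
    one); both are always generated.
    """
    p = params or CannabisParams()
    p.validate()
    if outcome not in ("depression_21", "self_harm"):
        raise ParameterError(f"unknown outcome {outcome!r}")
    rng = np.random.default_rng(p.seed)
    n = p.n
    sex = (rng.uniform(size=n) < p.p_sex).astype(float)
    maternal = (rng.uniform(size=n) < p.p_maternal_substance).astype(float)
    lp_cu = p.cannabis_on_sex * sex + p.cannabis_on_maternal * maternal
    cannabis = _ordinal_draw(np.asarray(p.cannabis_cutpoints, float), lp_cu, rng)
    d_less, d_week = (cannabis == 1).astype(float), (cannabis == 2).astype(float)

    dep21 = (p.depression_intercept
             + p.depression_on_cannabis[0] * d_less + p.depression_on_cannabis[1] * d_week
             + p.depression_on_sex * sex + p.depression_on_maternal * maternal
             + p.residual_sd * rng.standard_normal(n))
    lp_sh = (p.selfharm_intercept
             + p.selfharm_on_cannabis[0] * d_less + p.selfharm_on_cannabis[1] * d_week
             + p.selfharm_on_sex * sex + p.selfharm_on_maternal * maternal)
    latent = lp_sh + rng.logistic(size=n)
    selfharm = (latent > 0).astype(float)

    dep12 = _proxy(dep21, p.aux_depression_rho, 1.5, 1.0, rng)
    lp_cd = p.conduct_intercept + p.conduct_on_cannabis * cannabis
    conduct = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-lp_cd))).astype(float)

    out_role = {"depression_21": "auxiliary", "self_harm": "auxiliary", outcome: "outcome"}
    cols = [
        Column("sex", "binary", "confounder"),
        Column("maternal_substance_use", "binary", "confounder"),
        Column("depression_12", "continuous", "auxiliary"),
        Column("conduct_disorder", "binary", "auxiliary"),
        Column("cannabis_use", "categorical", "exposure", CANNABIS_LEVELS),
        Column("depression_21", "continuous", out_role["depression_21"]),
        Column("self_harm", "binary", out_role["self_harm"]),
        Column("selfharm_latent", "continuous", "latent"),
    ]
    values = np.column_stack([sex, maternal, dep12, conduct, cannabis,
                              dep21, selfharm, latent])
    return Dataset(cols, values)


GESTATION_LEVELS = ("<39", "39-40", ">41")
SES_LEVELS = ("I/II", "III", "IV/V")


@dataclass
class GrowthParams:
    """Generating parameters for the growth cohort.

    The adult-BMI structural coefficients default to the multiply-imputed
    estimates of the motivating analysis (weight-at-5 slope 0.458 kg/m^2
    per kg, maternal weight 0.0835, etc.), so large-sample recovery checks
    target those published values.  Covariate marginals are chosen to give
    realistic anthropometry (birth weight ~N(3.4, 0.5) kg, adult BMI mean
    near 25 kg/m^2); they are not estimates of the source cohort.
    """

    n: int = 1000
    seed: int | None = None
    p_sex: float = 0.5
    gestation_probs: tuple[float, float, float] = (0.25, 0.55, 0.20)
    ses_probs: tuple[float, float, float] = (0.40, 0.35, 0.25)
    birth_weight_mean: float = 3.4
    birth_weight_sd: float = 0.5
    maternal_weight_mean: float = 62.0
    maternal_weight_sd: float = 10.0
    paternal_weight_mean: float = 78.0
    paternal_weight_sd: float = 11.0
    # structural model for weight at age 5 (kg)
    weight5_intercept: float = 9.0
    weight5_on_birth: float = 1.2
    weight5_on_sex: float = 0.5
    weight5_on_maternal: float = 0.04
    weight5_on_paternal: float = 0.03
    weight5_sd: float = 1.8
    # structural model for adult BMI (kg/m^2)
    bmi_intercept: float = 10.7
    bmi_on_weight5: float = 0.458
    bmi_on_birth: float = -0.788
    bmi_on_sex: float = 0.165
    bmi_on_gestation: tuple[float, float] = (0.150, 0.321)   # <39, >41 vs 39-40
    bmi_on_maternal: float = 0.0835
    bmi_on_paternal: float = 0.0477
    bmi_on_ses: tuple[float, float] = (-0.791, 1.20)         # I/II, IV/V vs III
    residual_sd: float = 3.0
    # auxiliary childhood anthropometry (proxies of the exposure)
    aux_weight45_rho: float = 0.7
    aux_height5_rho: float = 0.5

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError("n must be >= 0")
        if self.residual_sd < 0 or self.weight5_sd < 0:
            raise ParameterError("residual SDs must be >= 0")
        _check_simplex(self.gestation_probs, "gestation_probs")
        _check_simplex(self.ses_probs, "ses_probs")


def generate_growth_cohort(params: GrowthParams | None = None) -> Dataset:
    """Generate the complete growth cohort (no missing values)."""
    p = params or GrowthParams()
    p.validate()
    rng = np.random.default_rng(p.seed)
    n = p.n
    sex = (rng.uniform(size=n) < p.p_sex).astype(float)
    birth = p.birth_weight_mean + p.birth_weight_sd * rng.standard_normal(n)
    gest = rng.choice(3, size=n, p=_check_simplex(p.gestation_probs, "gestation_probs")).astype(float)
    ses = rng.choice(3, size=n, p=_check_simplex(p.ses_probs, "ses_probs")).astype(float)
    mw = p.maternal_weight_mean + p.maternal_weight_sd * rng.standard_normal(n)
    pw = p.paternal_weight_mean + p.paternal_weight_sd * rng.standard_normal(n)
    w5 = (p.weight5_intercept + p.weight5_on_birth * birth + p.weight5_on_sex * sex
          + p.weight5_on_maternal * mw + p.weight5_on_paternal * pw
          + p.weight5_sd * rng.standard_normal(n))
    bmi = (p.bmi_intercept + p.bmi_on_weight5 * w5 + p.bmi_on_birth * birth
           + p.bmi_on_sex * sex
           + p.bmi_on_gestation[0] * (gest == 0) + p.bmi_on_gestation[1] * (gest == 2)
           + p.bmi_on_maternal * mw + p.bmi_on_paternal * pw
           + p.bmi_on_ses[0] * (ses == 0) + p.bmi_on_ses[1] * (ses == 2)
           + p.residual_sd * rng.standard_normal(n))
    w45 = _proxy(w5, p.aux_weight45_rho, 16.0, 1.6, rng)
    h5 = _proxy(w5, p.aux_height5_rho, 109.0, 4.5, rng)

    cols = [
        Column("birth_weight", "continuous", "confounder"),
        Column("sex", "binary", "confounder"),
        Column("gestational_age", "categorical", "confounder", GESTATION_LEVELS),
        Column("maternal_weight", "continuous", "confounder"),
        Column("paternal_weight", "continuous", "confounder"),
        Column("ses", "categorical", "confounder", SES_LEVELS),
        Column("weight_5", "continuous", "exposure"),
        Column("adult_bmi", "continuous", "outcome"),
        Column("weight_4p5", "continuous", "auxiliary"),
        Column("height_5", "continuous", "auxiliary"),
    ]
    values = np.column_stack([birth, sex, gest, mw, pw, ses, w5, bmi, w45, h5])
    return Dataset(cols, values)
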