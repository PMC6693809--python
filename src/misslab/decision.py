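"""Method-selection engine: when is complete-case analysis safe, what do the
incomplete cases offer, and should multiple imputation be preferred?

The bias rules are the selection-model results for regression under
missingness: for linear and logistic regression, CCA is unbiased for the
exposure coefficient whenever the chance of being a complete case does not
depend on the outcome given the covariates — which covers MCAR, covariate-
driven MAR, *and* MNAR mechanisms that involve only the exposure and
confounders.  Logistic regression enjoys three extra exemptions, rooted in
the equality of the disease and exposure odds ratios: completeness may
depend (i) on the outcome only, (ii) on the outcome and confounders, or
(iii) on the outcome and exposure independently (multiplicatively), and the
exposure log-odds-ratio remains unbiased.  None of the three survive when
the binary outcome is a dichotomized continuous score and missingness
tracks the underlying score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .diagnostics import MISSING, MIXED, OBSERVED, PatternTable
from .estimators import FitResult

DEP_TOKENS = ("outcome", "exposure", "confounders", "self")


@dataclass(frozen=True)
class BiasFlags:
    """Special-case switches for the bias rules.

    ``true_exposure_effect_zero``: the generating exposure coefficient is
    truly zero.  ``outcome_exposure_independent``: completeness factorizes
    into separate outcome- and exposure-driven mechanisms.
    ``dichotomized_latent``: the binary outcome dichotomizes a continuous
    score and missingness depends on that score.
    """

    true_exposure_effect_zero: bool = False
    outcome_exposure_independent: bool = False
    dichotomized_latent: bool = False


@dataclass
class Verdict:
    estimand: str
    model: str
    verdict: str            # "unbiased" | "biased"
    rule: str               # rule id applied
    special_cases: list[str]
    rationale: str

    @property
    def unbiased(self) -> bool:
        return self.verdict == "unbiased"


_RULES = {
    "R1": "completeness independent of all data (MCAR): complete cases are representative",
    "R2": "missingness depends on the outcome: linear CCA biased unless the true exposure effect is zero (footnote a)",
    "R3": "missingness depends only on the exposure and/or confounders: conditioning on the covariates blocks every path from the completeness indicator to the outcome",
    "R4": "missingness depends on the outcome and confounders: biased for linear regression; exempt for logistic regression (disease OR = exposure OR)",
    "R5": "missingness depends on the outcome and the exposure: biased, except logistic regression when the two dependences are independent (footnote b)",
}


def cca_bias_verdict(deps: set[str] | frozenset[str], model: str,
                     flags: BiasFlags | None = None) -> Verdict:
    """Bias verdict for the exposure coefficient of a complete-case analysis.

    ``deps`` is the set of analysis-variable groups the chance of being a
    complete case depends on, drawn from {"outcome", "exposure",
    "confounders", "self"}; ``"self"`` (missingness depending on the
    incomplete exposure's own values) acts as exposure dependence for the
    bias rules while also marking the mechanism as MNAR.
    """
    flags = flags or BiasFlags()
    deps = set(deps)
    unknown = deps - set(DEP_TOKENS)
    if unknown:
        raise ValueError(f"unknown dependence tokens {sorted(unknown)}")
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    eff = {("exposure" if d == "self" else d) for d in deps}
    special: list[str] = []

    if not eff:
        rule, verdict = "R1", "unbiased"
    elif eff == {"outcome"}:
        if model == "logistic":
            rule, verdict = "R2", "unbiased"
        elif flags.true_exposure_effect_zero:
            rule, verdict = "R2", "unbiased"
            special.append("footnote-a: true exposure effect is zero")
        else:
            rule, verdict = "R2", "biased"
    elif "outcome" not in eff:
        rule, verdict = "R3", "unbiased"
    elif eff <= {"outcome", "confounders"}:
        rule, verdict = "R4", ("unbiased" if model == "logistic" else "biased")
    else:  # outcome and exposure (and possibly confounders)
        rule = "R5"
        if model == "logistic" and flags.outcome_exposure_independent:
            verdict = "unbiased"
            special.append("footnote-b: outcome- and exposure-dependence are independent")
        else:
            verdict = "biased"

    # the logistic exemptions rely on the outcome being the actual binary
    # variable; a dichotomized latent outcome with score-driven missingness
    # voids them
    if (model == "logistic" and flags.dichotomized_latent
            and "outcome" in eff and verdict == "unbiased"):
        verdict = "biased"
        special.append("dichotomized-latent caveat: missingness tracks the continuous "
                       "score underlying the binary outcome, voiding the logistic exemptions")
    return Verdict("exposure coefficient", model, verdict, rule, special,
                   f"[{rule}] {_RULES[rule]}")


# ------------------------------------------------- incomplete-case information


@dataclass
class InformationReport:
    category: str           # none | minimal | block-limited | substantial
    guidance: str
    thresholds: dict
    evidence: dict


def incomplete_case_information(patterns: PatternTable,
                                block_fraction: float = 0.75,
                                substantial_share: float = 0.10) -> InformationReport:
    """How much the incomplete cases can contribute, by pattern structure.

    Categories: missingness confined to the outcome -> ``none`` (imputing
    the outcome adds no information about the exposure coefficient);
    confined to the exposure -> ``minimal``; incomplete rows losing (almost)
    the whole covariate block at once -> ``block-limited``; scattered
    missingness with many partially observed rows -> ``substantial``.
    Thresholds are reported so the rule is auditable.
    """
    thresholds = {"block_fraction": block_fraction,
                  "substantial_share": substantial_share}
    incomplete = [r for r in patterns.rows if not r.complete]
    n_inc = sum(r.count for r in incomplete)
    groups = list(patterns.groups)
    if n_inc == 0:
        return InformationReport("none", "no incomplete cases", thresholds,
                                 {"incomplete": 0})
    def only(group: str) -> bool:
        return all(r.status.get(group) == MISSING
                   and all(r.status.get(g) == OBSERVED for g in groups if g != group)
                   for r in incomplete)

    if "outcome" in groups and only("outcome"):
        return InformationReport(
            "none",
            "only the outcome is missing: the incomplete cases carry no information "
            "about the regression coefficients, and imputing the outcome only adds "
            "noise; CCA is the best choice",
            thresholds, {"incomplete": n_inc})
    if "exposure" in groups and only("exposure"):
        return InformationReport(
            "minimal",
            "only the exposure is missing: the incomplete cases carry minimal "
            "information about the exposure coefficient (some about the "
            "confounders'); CCA is appropriate if interest is only in the exposure",
            thresholds, {"incomplete": n_inc})
    # rows that lose every non-outcome covariate group at once
    cov_groups = [g for g in groups if g != "outcome"]
    block_rows = sum(r.count for r in incomplete
                     if cov_groups and all(r.status.get(g) == MISSING for g in cov_groups))
    if block_rows / n_inc >= block_fraction:
        return InformationReport(
            "block-limited",
            "incomplete rows tend to lose the whole covariate block at once: they "
            "carry little information and MI is sensitive to imputation-model "
            "misspecification; CCA may be preferred",
            thresholds, {"incomplete": n_inc, "block_rows": block_rows})
    # partially observed rows with observed outcome and exposure are the
    # clearest carriers of information about the exposure coefficient
    partial = sum(r.count for r in incomplete
                  if r.status.get("outcome", OBSERVED) == OBSERVED
                  and r.status.get("exposure", OBSERVED) == OBSERVED)
    if partial / n_inc >= substantial_share or any(
            MIXED in r.status.values() for r in incomplete):
        return InformationReport(
            "substantial",
            f"scattered multi-variable missingness: {partial} incomplete rows with "
            "observed outcome and exposure are likely to contain information about "
            "the exposure coefficient that MI can use",
            thresholds, {"incomplete": n_inc, "partial_outcome_exposure": partial})
    return InformationReport(
        "minimal", "incomplete rows contribute little beyond the complete cases",
        thresholds, {"incomplete": n_inc, "partial_outcome_exposure": partial})


# ------------------------------------------------------------- recommendation


@dataclass
class AuxiliaryReport:
    """What the auxiliary variables offer."""

    available: bool = False
    predicts_missingness: bool = False
    predicts_values: bool = False

    @property
    def informative(self) -> bool:
        return self.available and (self.predicts_missingness or self.predicts_values)


@dataclass
class Recommendation:
    method: str             # "CCA" | "MI" | "either" | "IPW-adjunct"
    checklist: dict         # criterion -> {"passed": bool, "evidence": str}
    caveats: list[str]
    rationale: list[str]


def _outcome_dependent(fit: FitResult | None, outcome_term: str | None) -> tuple[bool, str]:
    if fit is None or outcome_term is None or outcome_term not in fit.terms:
        return False, "no missingness-model evidence for outcome dependence"
    i = fit.terms.index(outcome_term)
    lo, hi = fit.ci_low[i], fit.ci_high[i]
    dep = not (lo <= 0.0 <= hi)  # CI for the log-OR excludes 0 <=> OR CI excludes 1
    ors = fit.odds_ratios()[outcome_term]
    ev = (f"completeness odds ratio per unit outcome {ors['or']:.3g} "
          f"(95% CI {ors['ci'][0]:.3g}, {ors['ci'][1]:.3g})")
    return dep, ev


def recommend_method(verdict: Verdict, info: InformationReport,
                     aux: AuxiliaryReport,
                     missingness_fit: FitResult | None = None,
                     outcome_term: str | None = None,
                     mnar_declared: bool = False) -> Recommendation:
    """Combine the bias verdict, pattern information, auxiliary availability
    and the missingness model into an auditable recommendation.

    Decision order: a declared MNAR mechanism in the covariates with a
    CCA-safe verdict -> CCA with a warning that MAR-based MI would be
    biased; outcome-dependent completeness or informative auxiliaries with
    usable incomplete cases -> MI; a safe verdict with uninformative
    incomplete cases and no auxiliaries -> CCA; otherwise either.
    """
    out_dep, out_ev = _outcome_dependent(missingness_fit, outcome_term)
    checklist = {
        "i_cca_bias_risk": {
            "passed": out_dep or not verdict.unbiased,
            "evidence": f"{out_ev}; bias rule: {verdict.rationale}"},
        "ii_aux_predict_missingness": {
            "passed": aux.predicts_missingness,
            "evidence": "auxiliary variables predict missingness"
            if aux.predicts_missingness else "no auxiliary predictors of missingness"},
        "iii_incomplete_cases_informative": {
            "passed": info.category == "substantial",
            "evidence": f"pattern information category: {info.category} ({info.guidance})"},
        "iv_aux_predict_values": {
            "passed": aux.predicts_values,
            "evidence": "auxiliary variables predict the missing values"
            if aux.predicts_values else "no auxiliary predictors of the missing values"},
        "v_imputation_model_feasible": {
            "passed": info.category != "block-limited",
            "evidence": "enough partially observed data to fit conditional models"
            if info.category != "block-limited"
            else "block-wise missingness leaves conditional models poorly informed"},
    }
    rationale: list[str] = []
    caveats: list[str] = []
    if mnar_declared and verdict.unbiased and not out_dep:
        method = "CCA"
        rationale.append("the declared mechanism is MNAR in the exposure/confounders "
                         "with completeness independent of the outcome: CCA is valid")
        caveats.append("MAR-based MI would be biased here: imputing the MNAR variable "
                       "from observed data misstates its predictive distribution")
    elif out_dep or (aux.informative and info.category != "none"):
        method = "MI"
        if out_dep:
            rationale.append(f"completeness depends on the outcome ({out_ev}): CCA is "
                             "at risk of bias while MI under MAR is valid")
        if aux.informative:
            rationale.append("informative auxiliary variables are available and the "
                             "incomplete cases can contribute: MI gains efficiency")
        if not checklist["v_imputation_model_feasible"]["passed"]:
            caveats.append("block-wise missingness: MI results may be sensitive to "
                           "imputation-model misspecification")
    elif verdict.unbiased and info.category in ("none", "minimal") and not aux.informative:
        method = "CCA"
        rationale.append("CCA is unbiased, the incomplete cases carry little usable "
                         "information and there are no informative auxiliaries: "
                         "imputation would only add noise")
    else:
        method = "either"
        rationale.append("no decisive advantage for CCA or MI under the stated rules; "
                         "report both as a sensitivity analysis")
    return Recommendation(method, checklist, caveats, rationale)
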