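"""End-to-end workflow: diagnose -> decide -> analyse, with a JSON report.

The stages follow the order an applied missing-data analysis takes: first
model the chance of being a complete case on low-missingness analysis
variables (does it depend on the outcome?), then tabulate the missing-data
patterns (do the incomplete cases carry usable information?), then assess
the auxiliary variables, and only then pick and run the analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import __version__
from .dataset import Dataset
from .decision import (AuxiliaryReport, Recommendation, cca_bias_verdict,
                       incomplete_case_information, recommend_method)
from .diagnostics import missingness_model, tabulate_patterns
from .estimators import AnalysisModel, fit_cca, fit_full, fit_ipw, fit_logistic
from .io import load_dataset
from .mi import ImputationConfig, mi_analyze


@dataclass
class RunConfig:
    data: str
    roles: str | None = None
    method: str = "auto"            # auto | cca | ipw | mi
    seed: int = 0
    m: int = 20
    iterations: int = 10
    confounder_missing_max: float = 0.02
    alpha: float = 0.05
    out: str | None = None

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def analysis_model_from_roles(data: Dataset, kind: str | None = None) -> AnalysisModel:
    data.check_analysis_roles()
    roles = data.roles
    outcome = next(n for n, r in roles.items() if r == "outcome")
    exposure = next(n for n, r in roles.items() if r == "exposure")
    confs = tuple(n for n, r in roles.items() if r == "confounder")
    if kind is None:
        kind = "logistic" if data.column(outcome).kind == "binary" else "linear"
    refs = {}
    for name in (exposure,) + confs:
        c = data.column(name)
        if c.kind == "categorical":
            refs[name] = c.levels[0]
    return AnalysisModel(outcome, exposure, confs, kind, refs)


def choose_missingness_predictors(data: Dataset, model: AnalysisModel,
                                  confounder_missing_max: float = 0.02) -> list[str]:
    """Outcome + exposure + confounders with (almost) no missing data.

    High-missingness confounders cannot enter the completeness model
    without discarding most of the incomplete cases from its eligible rows.
    """
    preds = [model.exposure]
    for name in model.confounders:
        frac = float((~data.observed(name)).mean())
        if frac <= confounder_missing_max:
            preds.append(name)
    preds.append(model.outcome)
    return preds


def assess_auxiliaries(data: Dataset, model: AnalysisModel, alpha: float = 0.05,
                       r_min: float = 0.3) -> AuxiliaryReport:
    """Do the auxiliaries predict missingness and/or the missing values?

    Missingness: Wald test of each auxiliary in a univariable logistic
    model of the complete-case indicator.  Values: absolute Pearson
    correlation with each incomplete analysis variable among jointly
    observed rows, against ``r_min``.
    """
    aux = [c.name for c in data.columns if c.role == "auxiliary"]
    if not aux:
        return AuxiliaryReport(False, False, False)
    cc = ~data.missing_any(model.variables)
    predicts_miss = False
    if 0 < cc.sum() < data.n:
        for name in aux:
            rows = data.observed(name)
            y = cc[rows].astype(float)
            if y.min() == y.max():
                continue
            v = data.values(name)[rows]
            try:
                fit = fit_logistic(np.column_stack([np.ones(v.size), v]), y)
            except Exception:
                continue
            p = 2.0 * stats.norm.sf(abs(fit.coef[1] / fit.se[1]))
            if p < alpha:
                predicts_miss = True
                break
    predicts_vals = False
    for target in model.variables:
        if data.observed(target).all():
            continue
        t = data.values(target)
        for name in aux:
            a = data.values(name)
            rows = ~np.isnan(t) & ~np.isnan(a)
            if rows.sum() < 10:
                continue
            r = np.corrcoef(t[rows], a[rows])[0, 1]
            if abs(r) >= r_min:
                predicts_vals = True
                break
        if predicts_vals:
            break
    return AuxiliaryReport(True, predicts_miss, predicts_vals)


def infer_dependence_set(fit, model: AnalysisModel) -> set[str]:
    """Dependence tokens from the missingness-model CIs (log-OR CI excluding 0)."""
    deps: set[str] = set()
    conf_terms = set()
    for name in model.confounders:
        conf_terms.add(name)
    for i, term in enumerate(fit.terms):
        if term == "intercept":
            continue
        sig = not (fit.ci_low[i] <= 0.0 <= fit.ci_high[i])
        if not sig:
            continue
        base = term.split("[")[0]
        if base == model.outcome:
            deps.add("outcome")
        elif base == model.exposure:
            deps.add("exposure")
        elif base in conf_terms:
            deps.add("confounders")
    return deps


def run_workflow(config: RunConfig) -> dict:
    """Execute diagnose -> recommend -> analyse and return the report bundle."""
    data = load_dataset(config.data, config.roles)
    model = analysis_model_from_roles(data)
    bundle: dict = {
        "version": __version__, "seed": config.seed, "config_hash": config.hash(),
        "n_rows": data.n,
        "analysis": {"outcome": model.outcome, "exposure": model.exposure,
                     "confounders": list(model.confounders), "kind": model.kind},
    }
    any_missing = bool(data.missing_any(model.variables).any())
    patterns = tabulate_patterns(data)
    bundle["patterns"] = [{"status": r.status, "count": r.count,
                           "percent": r.percent, "complete": r.complete}
                          for r in patterns.rows]
    if not any_missing:
        bundle["recommendation"] = {
            "method": "full-data fit",
            "rationale": ["no missing values among the analysis variables"]}
        bundle["fit"] = fit_full(data, model).to_dict()
        _maybe_write(bundle, config)
        return bundle

    preds = choose_missingness_predictors(data, model, config.confounder_missing_max)
    diag = missingness_model(data, preds)
    bundle["missingness_model"] = {**diag.to_dict(),
                                   "odds_ratios": diag.odds_ratios(),
                                   "predictors": preds,
                                   "eligible_rows": diag.n_used}
    deps = infer_dependence_set(diag, model)
    verdict = cca_bias_verdict(deps, model.kind)
    info = incomplete_case_information(patterns)
    aux = assess_auxiliaries(data, model, config.alpha)
    rec = recommend_method(verdict, info, aux, diag, outcome_term=model.outcome)
    bundle["verdict"] = {"deps": sorted(deps), "verdict": verdict.verdict,
                         "rule": verdict.rule, "rationale": verdict.rationale}
    bundle["information"] = {"category": info.category, "guidance": info.guidance,
                             "thresholds": info.thresholds, "evidence": info.evidence}
    bundle["auxiliaries"] = {"available": aux.available,
                             "predicts_missingness": aux.predicts_missingness,
                             "predicts_values": aux.predicts_values}
    bundle["recommendation"] = {"method": rec.method, "checklist": rec.checklist,
                                "caveats": rec.caveats, "rationale": rec.rationale}

    method = config.method if config.method != "auto" else rec.method.lower()
    if method not in ("cca", "mi", "ipw"):
        method = "cca"
    bundle["method_run"] = method
    if method == "cca":
        bundle["fit"] = fit_cca(data, model).to_dict()
    elif method == "ipw":
        bundle["fit"] = fit_ipw(data, model, preds[:-1]).to_dict()
    else:
        cfg = ImputationConfig(m=config.m, iterations=config.iterations,
                               seed=config.seed)
        pooled = mi_analyze(data, model, cfg)
        bundle["fit"] = {
            "model": "mi-pooled", "m": pooled.m, "terms": pooled.terms,
            "estimate": pooled.estimate.tolist(), "W": pooled.within.tolist(),
            "B": pooled.between.tolist(), "T": pooled.total.tolist(),
            "df": [None if np.isinf(d) else float(d) for d in pooled.df],
            "fmi": pooled.fmi.tolist(), "ci_low": pooled.ci_low.tolist(),
            "ci_high": pooled.ci_high.tolist(), "meta": pooled.meta}
    _maybe_write(bundle, config)
    return bundle


def _maybe_write(bundle: dict, config: RunConfig) -> None:
    if config.out:
        Path(config.out).write_text(json.dumps(bundle, indent=2, default=float))
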