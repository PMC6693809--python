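"""Regression engines and the complete-case / inverse-probability-weighted stages.

``fit_ols`` and ``fit_logistic`` are deliberately small, explicit engines
(normal equations via QR; iteratively reweighted least squares) so that the
simulation grid can run tens of thousands of fits cheaply and so that
separation and rank deficiency fail loudly instead of producing silent
garbage.  They are cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import Dataset, DatasetError


class RankDeficientError(np.linalg.LinAlgError):
    """The design matrix is not full column rank."""


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation: logistic MLE does not exist."""


class DegenerateOutcomeError(ValueError):
    """Outcome takes a single value; the model is not estimable."""


@dataclass
class FitResult:
    """Coefficients, standard errors and CIs from one regression fit.

    Linear fits use t-based confidence intervals on the residual degrees of
    freedom; logistic fits use Wald (normal) intervals.
    """

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    df_resid: float
    n_used: int
    model: str  # "linear" | "logistic"
    weights_summary: dict | None = None
    cov: np.ndarray | None = field(default=None, repr=False)

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {"coef": float(self.coef[i]), "se": float(self.se[i]),
                "ci": (float(self.ci_low[i]), float(self.ci_high[i]))}

    def odds_ratios(self) -> dict[str, dict]:
        """Exponentiated coefficients with exponentiated CI bounds."""
        return {t: {"or": float(np.exp(self.coef[i])),
                    "ci": (float(np.exp(self.ci_low[i])), float(np.exp(self.ci_high[i])))}
                for i, t in enumerate(self.terms)}

    def to_dict(self) -> dict:
        return {
            "model": self.model, "n_used": self.n_used, "df_resid": self.df_resid,
            "terms": self.terms, "coef": self.coef.tolist(), "se": self.se.tolist(),
            "ci_low": self.ci_low.tolist(), "ci_high": self.ci_high.tolist(),
            "weights": self.weights_summary,
        }


@dataclass(frozen=True)
class AnalysisModel:
    """Declarative analysis spec: outcome ~ exposure + confounders."""

    outcome: str
    exposure: str
    confounders: tuple[str, ...] = ()
    kind: str = "linear"  # "linear" | "logistic"
    references: dict = field(default_factory=dict, hash=False)  # categorical reference levels

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.outcome, self.exposure) + tuple(self.confounders)


def _check_weights(w: np.ndarray | None, n: int) -> np.ndarray | None:
    if w is None:
        return None
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must be a vector matching the rows")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return w


def _solve_xtwx(X: np.ndarray, w: np.ndarray | None):
    """Return (XtWX)^-1 via a rank-checked factorization."""
    Xw = X if w is None else X * np.sqrt(w)[:, None]
    q, r = np.linalg.qr(Xw)
    diag = np.abs(np.diag(r))
    if diag.size and (diag < 1e-10 * max(diag.max(), 1.0)).any():
        raise RankDeficientError("design matrix is rank deficient")
    rinv = np.linalg.solve(r, np.eye(r.shape[0]))
    return rinv @ rinv.T, q, r


def fit_ols(X: np.ndarray, y: np.ndarray, terms: Sequence[str] | None = None,
            weights: np.ndarray | None = None) -> FitResult:
    """(Weighted) least squares with classical or sandwich variance.

    Unweighted fits report the classical variance ``s^2 (X'X)^-1``; weighted
    fits report the HC0 sandwich, since weights are typically estimated
    inverse selection probabilities rather than precision weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(p)]
    w = _check_weights(weights, n)
    xtwx_inv, q, r = _solve_xtwx(X, w)
    if w is None:
        beta = np.linalg.solve(r, q.T @ y)
    else:
        beta = np.linalg.solve(r, q.T @ (np.sqrt(w) * y))
    resid = y - X @ beta
    df = n - p
    if w is None:
        s2 = float(resid @ resid / df) if df > 0 else 0.0
        cov = s2 * xtwx_inv
    else:
        # sandwich: (X'WX)^-1 X' diag(w^2 e^2) X (X'WX)^-1
        meat = (X * ((w * resid) ** 2)[:, None]).T @ X
        cov = xtwx_inv @ meat @ xtwx_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = stats.t.ppf(0.975, df) if df > 0 else np.nan
    ws = None
    if w is not None:
        ws = {"min": float(w.min()), "max": float(w.max()),
              "cv": float(w.std() / w.mean()) if w.mean() > 0 else np.nan}
    return FitResult(terms, beta, se, beta - tq * se, beta + tq * se,
                     float(df), n, "linear", ws, cov)


def fit_logistic(X: np.ndarray, y: np.ndarray, terms: Sequence[str] | None = None,
                 weights: np.ndarray | None = None, tol: float = 1e-8,
                 max_iter: int = 100, trace: list | None = None) -> FitResult:
    """Logistic regression by IRLS with explicit separation detection.

    Convergence: max absolute coefficient change < ``tol``.  Diverging
    coefficients (|beta| beyond ~30, fitted probabilities pinned at 0/1)
    raise :class:`SeparationError` rather than returning silent output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(p)]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic outcome must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome takes a single value")
    w = _check_weights(weights, n)
    base_w = np.ones(n) if w is None else w
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        if trace is not None:  # weighted log-likelihood at the current iterate
            trace.append(float(np.sum(base_w * (y * eta - np.logaddexp(0.0, eta)))))
        irls_w = base_w * mu * (1.0 - mu)
        z = eta + (y - mu) / np.maximum(mu * (1.0 - mu), 1e-12)
        xtwx_inv, q, r = _solve_xtwx(X, irls_w)
        new = np.linalg.solve(r, q.T @ (np.sqrt(irls_w) * z))
        step = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError("coefficients diverging: data are (quasi-)separated")
        if step < tol:
            converged = True
            break
    if not converged:
        raise SeparationError("IRLS failed to converge; possible separation")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    info_inv, _, _ = _solve_xtwx(X, base_w * mu * (1.0 - mu))
    if w is None:
        cov = info_inv
    else:
        score = X * (w * (y - mu))[:, None]
        cov = info_inv @ (score.T @ score) @ info_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    zq = stats.norm.ppf(0.975)
    ws = None
    if w is not None:
        ws = {"min": float(w.min()), "max": float(w.max()),
              "cv": float(w.std() / w.mean()) if w.mean() > 0 else np.nan}
    return FitResult(terms, beta, se, beta - zq * se, beta + zq * se,
                     float(n - p), n, "logistic", ws, cov)


# --------------------------------------------------------------------- design


def build_design(data: Dataset, model: AnalysisModel, rows: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (intercept + exposure + confounders) and outcome vector.

    Categorical variables expand to reference-coded dummies; the reference
    level defaults to the first declared level unless overridden in
    ``model.references``.
    """
    if rows is None:
        rows = np.ones(data.n, dtype=bool)
    cols: list[np.ndarray] = [np.ones(int(rows.sum()))]
    terms: list[str] = ["intercept"]
    for name in (model.exposure,) + tuple(model.confounders):
        c = data.column(name)
        v = data.values(name)[rows]
        if c.kind == "categorical":
            ref = model.references.get(name, c.levels[0])
            if ref not in c.levels:
                raise DatasetError(f"reference level {ref!r} not a level of {name!r}")
            for code, lev in enumerate(c.levels):
                if lev == ref:
                    continue
                cols.append((v == code).astype(float))
                terms.append(f"{name}[{lev}]")
        else:
            cols.append(v)
            terms.append(name)
    y = data.values(model.outcome)[rows]
    return np.column_stack(cols), y, terms


def exposure_terms(data: Dataset, model: AnalysisModel) -> list[str]:
    """Names of the design terms carrying the exposure coefficient(s)."""
    c = data.column(model.exposure)
    if c.kind == "categorical":
        ref = model.references.get(model.exposure, c.levels[0])
        return [f"{model.exposure}[{lev}]" for lev in c.levels if lev != ref]
    return [model.exposure]


def _dispatch(X, y, terms, kind, weights=None) -> FitResult:
    if kind == "linear":
        return fit_ols(X, y, terms, weights)
    if kind == "logistic":
        return fit_logistic(X, y, terms, weights)
    raise ValueError(f"unknown model kind {kind!r}")


def fit_full(data: Dataset, model: AnalysisModel) -> FitResult:
    """Fit on all rows; requires the analysis variables to be complete."""
    if data.missing_any(model.variables).any():
        raise DatasetError("fit_full requires complete analysis variables; use fit_cca")
    X, y, terms = build_design(data, model)
    return _dispatch(X, y, terms, model.kind)


def fit_cca(data: Dataset, model: AnalysisModel) -> FitResult:
    """Complete-case analysis: drop rows missing any analysis variable."""
    keep = ~data.missing_any(model.variables)
    n_cc = int(keep.sum())
    X, y, terms = build_design(data, model, keep)
    if n_cc < X.shape[1] + 2:
        raise DatasetError(f"too few complete cases ({n_cc}) for {X.shape[1]} parameters")
    return _dispatch(X, y, terms, model.kind)


def fit_ipw(data: Dataset, model: AnalysisModel,
            weight_predictors: Sequence[str], prob_floor: float = 0.01) -> FitResult:
    """Inverse-probability-of-complete-case weighted analysis.

    A logistic model for the complete-case indicator is fitted on rows with
    all ``weight_predictors`` observed; complete cases are then reweighted
    by 1/p-hat and analysed with sandwich standard errors (weight-estimation
    uncertainty is ignored, which is conservative).  Probabilities below
    ``prob_floor`` are trimmed to the floor and a warning is emitted.
    """
    cc = ~data.missing_any(model.variables)
    elig = ~data.missing_any(weight_predictors)
    if not (cc & ~elig).sum() == 0 and not elig[cc].all():
        raise DatasetError("weight predictors must be observed on all complete cases")
    Xw_cols = [np.ones(int(elig.sum()))]
    wterms = ["intercept"]
    for name in weight_predictors:
        c = data.column(name)
        v = data.values(name)[elig]
        if c.kind == "categorical":
            for code, lev in enumerate(c.levels[1:], start=1):
                Xw_cols.append((v == code).astype(float))
                wterms.append(f"{name}[{lev}]")
        else:
            Xw_cols.append(v)
            wterms.append(name)
    wfit = fit_logistic(np.column_stack(Xw_cols), cc[elig].astype(float), wterms)
    eta = np.column_stack(Xw_cols) @ wfit.coef
    phat = 1.0 / (1.0 + np.exp(-eta))
    if (phat[cc[elig]] < prob_floor).any():
        warnings.warn(f"complete-case probabilities below {prob_floor} trimmed to the floor",
                      RuntimeWarning, stacklevel=2)
        phat = np.maximum(phat, prob_floor)
    # map fitted probabilities back to the complete cases
    p_full = np.full(data.n, np.nan)
    p_full[elig] = phat
    keep = cc
    w = 1.0 / p_full[keep]
    X, y, terms = build_design(data, model, keep)
    return _dispatch(X, y, terms, model.kind, weights=w)
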