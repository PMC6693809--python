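"""Fully conditional specification multiple imputation and Rubin's-rules pooling.

The imputer cycles over the incomplete variables in column order, refitting
each variable's conditional regression on the currently-completed predictors
(restricted to the rows where the target was genuinely observed) and drawing
fresh imputations from the fitted predictive distribution:

* continuous targets: Bayesian linear regression (draw sigma^2 from its
  scaled inverse chi-square posterior, beta from its conditional normal,
  then add Gaussian noise) or predictive mean matching;
* binary targets: logistic fit with a multivariate-normal perturbation of
  the coefficients (large-sample approximation to a posterior draw), then
  Bernoulli draws;
* categorical targets: multinomial logistic fit with the same perturbation,
  then categorical draws.

Conditional-model failures (separation, rank deficiency) fall back to
predictive mean matching on level codes, with a logged warning.  Pooling
follows Rubin's rules with the large-sample degrees of freedom
``(m-1) (1 + W / ((1+1/m) B))^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import Dataset, DatasetError
from .estimators import (AnalysisModel, FitResult, RankDeficientError,
                         SeparationError, build_design, fit_full)

log = logging.getLogger(__name__)

METHODS = ("bayesian-linear", "logistic-draw", "categorical-draw", "pmm")


@dataclass
class ImputationConfig:
    """Settings for chained-equations imputation.

    ``predictors`` maps each incomplete variable to the columns feeding its
    conditional model; by default every other non-latent variable (analysis
    variables plus all auxiliaries) is used, which in particular guarantees
    the analysis outcome enters every imputation model.  ``passive``
    declares product terms (name, factor_a, factor_b) recomputed after each
    update so declared interactions stay consistent with their factors.
    """

    m: int = 5
    iterations: int = 10
    methods: dict = field(default_factory=dict)      # variable -> method name
    predictors: dict = field(default_factory=dict)   # variable -> list of names
    pmm_donors: int = 5
    passive: tuple = ()
    seed: int | None = None

    def validate(self) -> None:
        if self.m < 2:
            raise DatasetError("m must be >= 2")
        if self.iterations < 1:
            raise DatasetError("iterations must be >= 1")
        for v, meth in self.methods.items():
            if meth not in METHODS:
                raise DatasetError(f"unknown imputation method {meth!r} for {v!r}")


def _default_method(kind: str) -> str:
    return {"continuous": "bayesian-linear", "binary": "logistic-draw",
            "categorical": "categorical-draw"}[kind]


# ----------------------------------------------------------- conditional draws


def draw_bayesian_linear(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Proper Bayesian draw for a normal linear conditional model.

    sigma^2 is drawn from (n-q) s^2 / chi^2_{n-q}; beta from
    N(beta_hat, sigma^2 (X'X)^-1); the imputations are X_mis beta + sigma e.
    """
    n, q = X_obs.shape
    if n <= q + 2:
        raise RankDeficientError("too few observed rows for a Bayesian linear draw")
    qmat, rmat = np.linalg.qr(X_obs)
    diag = np.abs(np.diag(rmat))
    if (diag < 1e-10 * max(diag.max(), 1.0)).any():
        raise RankDeficientError("conditional design is rank deficient")
    beta_hat = np.linalg.solve(rmat, qmat.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    s2 = float(resid @ resid) / (n - q)
    sigma2 = s2 * (n - q) / rng.chisquare(n - q) if s2 > 0 else 0.0
    rinv = np.linalg.solve(rmat, np.eye(q))
    beta = beta_hat + np.sqrt(sigma2) * (rinv @ rng.standard_normal(q))
    return X_mis @ beta + np.sqrt(sigma2) * rng.standard_normal(X_mis.shape[0])


def draw_pmm(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
             donors: int, rng: np.random.Generator) -> np.ndarray:
    """Predictive mean matching: borrow an observed value from a close donor.

    Both observed and missing rows get posterior-draw linear predictions;
    each missing row picks uniformly one of the ``donors`` observed rows
    with the closest predicted value (distance ties broken at random via a
    tiny rng jitter on the ranks).
    """
    if not 1 <= donors <= y_obs.size:
        raise DatasetError("donor pool must satisfy 1 <= donors <= n_obs")
    n, q = X_obs.shape
    qmat, rmat = np.linalg.qr(X_obs)
    diag = np.abs(np.diag(rmat))
    if (diag < 1e-10 * max(diag.max(), 1.0)).any():
        raise RankDeficientError("conditional design is rank deficient")
    beta_hat = np.linalg.solve(rmat, qmat.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dfree = max(n - q, 1)
    s2 = float(resid @ resid) / dfree
    sigma2 = s2 * dfree / rng.chisquare(dfree) if s2 > 0 else 0.0
    rinv = np.linalg.solve(rmat, np.eye(q))
    beta = beta_hat + np.sqrt(sigma2) * (rinv @ rng.standard_normal(q))
    pred_obs = X_obs @ beta_hat          # type-1 matching: LS for donors
    pred_mis = X_mis @ beta              # posterior draw for recipients
    out = np.empty(X_mis.shape[0])
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    for i, pm in enumerate(pred_mis):
        d = np.abs(sorted_pred - pm)
        # random tie-break: jitter equal distances before ranking
        jitter = rng.uniform(0, 1e-12, size=d.size) * (1.0 + np.abs(pm))
        pool = np.argsort(d + jitter, kind="stable")[:donors]
        pick = pool[rng.integers(pool.size)]
        out[i] = y_obs[order[pick]]
    return out


def _perturbed_coef(fit: FitResult, rng: np.random.Generator) -> np.ndarray:
    cov = fit.cov
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    return fit.coef + L @ rng.standard_normal(cov.shape[0])


def draw_logistic(y_obs, X_obs, X_mis, rng) -> np.ndarray:
    """Binary draw from a logistic fit with MVN coefficient perturbation."""
    from .estimators import fit_logistic
    fit = fit_logistic(X_obs, y_obs)
    beta = _perturbed_coef(fit, rng)
    p = 1.0 / (1.0 + np.exp(-np.clip(X_mis @ beta, -30, 30)))
    return (rng.uniform(size=p.size) < p).astype(float)


def _multinomial_fit(X: np.ndarray, y: np.ndarray, K: int,
                     tol: float = 1e-8, max_iter: int = 100):
    """Newton fit of a K-class baseline-category logit; returns (B, cov)."""
    n, p = X.shape
    Y = np.zeros((n, K))
    Y[np.arange(n), y.astype(int)] = 1.0
    nb = p * (K - 1)
    b = np.zeros(nb)
    for _ in range(max_iter):
        eta = np.column_stack([np.zeros(n), (X @ b.reshape(K - 1, p).T)])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        grad = np.concatenate([X.T @ (Y[:, k] - P[:, k]) for k in range(1, K)])
        H = np.zeros((nb, nb))
        for j in range(1, K):
            for k in range(1, K):
                w = P[:, j] * ((j == k) - P[:, k])
                H[(j - 1) * p:j * p, (k - 1) * p:k * p] = -(X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficientError(str(exc)) from exc
        b_new = b - step
        if np.max(np.abs(b_new)) > 30.0:
            raise SeparationError("multinomial coefficients diverging")
        delta = np.max(np.abs(b_new - b))
        b = b_new
        if delta < tol:
            cov = np.linalg.inv(-H)
            return b.reshape(K - 1, p), cov
    raise SeparationError("multinomial IRLS failed to converge")


def draw_categorical(y_obs, X_obs, X_mis, K: int, rng) -> np.ndarray:
    """Categorical draw from a multinomial logit with coefficient perturbation."""
    B, cov = _multinomial_fit(X_obs, y_obs, K)
    flat = B.reshape(-1)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    flat = flat + L @ rng.standard_normal(flat.size)
    B = flat.reshape(B.shape)
    n_mis = X_mis.shape[0]
    eta = np.column_stack([np.zeros(n_mis), X_mis @ B.T])
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n_mis)[:, None]
    return (u > P.cumsum(axis=1)).sum(axis=1).astype(float)


# ------------------------------------------------------------------ FCS cycle


def _predictor_design(data: Dataset, names: list[str], rows: np.ndarray) -> np.ndarray:
    cols = [np.ones(int(rows.sum()))]
    for name in names:
        c = data.column(name)
        v = data.values(name)[rows]
        if c.kind == "categorical":
            for code in range(1, len(c.levels)):
                cols.append((v == code).astype(float))
        else:
            cols.append(v)
    return np.column_stack(cols)


def impute_fcs(data: Dataset, config: ImputationConfig) -> list[Dataset]:
    """Chained-equations imputation; returns ``m`` completed datasets.

    Missing cells are initialized by draws from each variable's observed
    marginal, then ``iterations`` full cycles over the incomplete variables
    (left-to-right column order) refit and redraw each conditional model.
    Observed cells are bit-identical to the input in every completed copy.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    incomplete = [c for c in data.columns
                  if c.role != "latent" and data.mask[:, data.names.index(c.name)].any()]
    for c in incomplete:
        if not data.observed(c.name).any():
            raise DatasetError(f"{c.name!r} has no observed values to learn from")
    usable = [c.name for c in data.columns if c.role != "latent"]
    completed: list[Dataset] = []
    for _ in range(config.m):
        work = data
        # marginal initialization
        for c in incomplete:
            obs_rows = data.observed(c.name)
            pool = data.values(c.name)[obs_rows]
            miss_n = int((~obs_rows).sum())
            work = work.filled(c.name, rng.choice(pool, size=miss_n, replace=True))
        work = _apply_passive(work, config.passive)
        n_iter = config.iterations if incomplete else 0
        for _ in range(n_iter):
            for c in incomplete:
                preds = config.predictors.get(
                    c.name, [v for v in usable if v != c.name])
                obs_rows = data.observed(c.name)
                mis_rows = ~obs_rows
                X_obs = _predictor_design(work, preds, obs_rows)
                X_mis = _predictor_design(work, preds, mis_rows)
                y_obs = work.values(c.name)[obs_rows]
                method = config.methods.get(c.name, _default_method(c.kind))
                try:
                    vals = _draw(method, c, y_obs, X_obs, X_mis, config, rng)
                except (SeparationError, RankDeficientError) as exc:
                    log.warning("conditional model for %s failed (%s); "
                                "falling back to pmm", c.name, exc)
                    vals = draw_pmm(y_obs, X_obs, X_mis,
                                    min(config.pmm_donors, y_obs.size), rng)
                new = work.values(c.name)
                new[mis_rows] = vals
                work = work.with_values(c.name, new)
                work = _apply_passive(work, config.passive)
        completed.append(work)
    return completed


def _draw(method: str, col, y_obs, X_obs, X_mis, config: ImputationConfig,
          rng: np.random.Generator) -> np.ndarray:
    if method == "bayesian-linear":
        return draw_bayesian_linear(y_obs, X_obs, X_mis, rng)
    if method == "pmm":
        return draw_pmm(y_obs, X_obs, X_mis,
                        min(config.pmm_donors, y_obs.size), rng)
    if method == "logistic-draw":
        return draw_logistic(y_obs, X_obs, X_mis, rng)
    if method == "categorical-draw":
        return draw_categorical(y_obs, X_obs, X_mis, len(col.levels), rng)
    raise DatasetError(f"unknown method {method!r}")


def _apply_passive(data: Dataset, passive) -> Dataset:
    for name, a, b in passive:
        data = data.with_values(name, data.values(a) * data.values(b))
    return data


# -------------------------------------------------------------------- pooling


@dataclass
class PooledResult:
    """Rubin's-rules summary across m imputations."""

    terms: list[str]
    estimate: np.ndarray      # Q-bar
    within: np.ndarray        # W
    between: np.ndarray       # B
    total: np.ndarray         # T = W + (1 + 1/m) B
    df: np.ndarray
    fmi: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    m: int
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total)

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {k: float(getattr(self, a)[i]) for k, a in
                [("estimate", "estimate"), ("W", "within"), ("B", "between"),
                 ("T", "total"), ("df", "df"), ("fmi", "fmi"),
                 ("ci_low", "ci_low"), ("ci_high", "ci_high")]}


def pool_rubin(fits: list[FitResult], meta: dict | None = None) -> PooledResult:
    """Combine per-imputation fits by Rubin's rules.

    Q-bar is the mean estimate, W the mean squared SE, B the between-
    imputation sample variance (divisor m-1), T = W + (1+1/m) B, and the
    large-sample df is (m-1)(1 + W/((1+1/m)B))^2.  B = 0 yields infinite
    df and a normal-quantile interval.
    """
    m = len(fits)
    if m < 2:
        raise DatasetError("pooling requires m >= 2 fits")
    terms = fits[0].terms
    if any(f.terms != terms for f in fits):
        raise DatasetError("all fits must share the same term list")
    Q = np.array([f.coef for f in fits])        # (m, p)
    U = np.array([f.se ** 2 for f in fits])
    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore"):
        rel = (1.0 + 1.0 / m) * B
        df = np.where(B > 0, (m - 1) * (1.0 + W / np.where(B > 0, rel, 1.0)) ** 2, np.inf)
        fmi = np.where(T > 0, rel / np.where(T > 0, T, 1.0), 0.0)
    tq = np.where(np.isinf(df), stats.norm.ppf(0.975), stats.t.ppf(0.975, np.maximum(df, 1e-9)))
    se = np.sqrt(T)
    return PooledResult(list(terms), qbar, W, B, T, df, fmi,
                        qbar - tq * se, qbar + tq * se, m, meta or {})


def mi_analyze(data: Dataset, model: AnalysisModel,
               config: ImputationConfig | None = None) -> PooledResult:
    """Impute, fit the analysis model on each completed dataset, and pool."""
    config = config or ImputationConfig()
    completed = impute_fcs(data, config)
    fits = [fit_full(d, model) for d in completed]
    meta = {"m": config.m, "iterations": config.iterations, "seed": config.seed,
            "predictors": {c.name: config.predictors.get(
                c.name, [v for v in data.names
                         if v != c.name and data.column(v).role != "latent"])
                for c in data.columns
                if data.mask[:, data.names.index(c.name)].any()}}
    return pool_rubin(fits, meta)
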