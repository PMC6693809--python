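"""Pre-analysis investigations of the missing data.

Three stages mirror how an applied analysis interrogates incomplete data
before choosing a method: tabulate the missing-data patterns by role group,
model the chance of being a complete case on observed predictors, and try
to refute MCAR by finding observed predictors of missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import Dataset, DatasetError
from .estimators import DegenerateOutcomeError, FitResult, fit_logistic

OBSERVED, MISSING, MIXED = "obs", "miss", "mixed"


@dataclass
class PatternRow:
    pattern: int
    status: dict          # role-group -> "obs" | "miss" | "mixed"
    count: int
    percent: float
    complete: bool


@dataclass
class PatternTable:
    rows: list[PatternRow]
    n: int
    groups: dict          # role-group -> list of variable names

    def counts(self) -> list[int]:
        return [r.count for r in self.rows]

    def percents(self) -> list[float]:
        return [r.percent for r in self.rows]

    def to_markdown(self) -> str:
        heads = list(self.groups)
        sym = {OBSERVED: "+", MISSING: "x", MIXED: "+/x"}
        lines = ["| Pattern | " + " | ".join(heads) + " | n (%) |",
                 "|" + "---|" * (len(heads) + 2)]
        for r in self.rows:
            cells = [sym[r.status[g]] for g in heads]
            lines.append(f"| {r.pattern} | " + " | ".join(cells)
                         + f" | {r.count} ({r.percent:.1f}%) |")
        return "\n".join(lines)


def default_groups(data: Dataset) -> dict:
    """Role groups (outcome / exposure / confounders) over incomplete variables,
    keeping fully observed variables out of the table like omitted columns in
    a published pattern summary, except the outcome and exposure which always
    appear."""
    groups: dict[str, list[str]] = {"outcome": [], "exposure": [], "confounders": []}
    for c in data.columns:
        if c.role == "outcome":
            groups["outcome"].append(c.name)
        elif c.role == "exposure":
            groups["exposure"].append(c.name)
        elif c.role == "confounder":
            groups["confounders"].append(c.name)
    return {k: v for k, v in groups.items() if v}


def tabulate_patterns(data: Dataset, groups: dict | None = None) -> PatternTable:
    """Group-wise missing-data pattern table.

    Each row of the data maps to exactly one pattern of group statuses; a
    group with >= 2 variables shows ``mixed`` when some but not all of its
    members are missing.  Ordering is deterministic: the complete pattern
    first, then descending count (ties by first appearance of the status
    tuple in lexical order).
    """
    if groups is None:
        groups = default_groups(data)
    n = data.n
    status_rows = []
    for g, names in groups.items():
        miss = np.column_stack([~data.observed(v) for v in names])
        nmiss = miss.sum(axis=1)
        st = np.where(nmiss == 0, OBSERVED, np.where(nmiss == len(names), MISSING, MIXED))
        status_rows.append([str(s) for s in st])
    combo = list(zip(*status_rows)) if status_rows else [()] * n
    counts: dict[tuple, int] = {}
    for c in combo:
        counts[c] = counts.get(c, 0) + 1
    rows = []
    complete_key = tuple(OBSERVED for _ in groups)
    ordered = sorted(counts.items(),
                     key=lambda kv: (kv[0] != complete_key, -kv[1], kv[0]))
    for i, (key, cnt) in enumerate(ordered, start=1):
        rows.append(PatternRow(
            pattern=i,
            status=dict(zip(groups, key)),
            count=cnt,
            percent=100.0 * cnt / n if n else 0.0,
            complete=key == complete_key))
    return PatternTable(rows, n, dict(groups))


def missingness_model(data: Dataset, predictors: list[str],
                      analysis_variables: list[str] | None = None) -> FitResult:
    """Logistic regression of the complete-case indicator on observed predictors.

    The fit is restricted to rows where *all* predictors are observed (the
    eligible rows), because the predictors' own values are needed; this
    restriction changes the effective n and is reported via ``n_used``.
    The complete-case indicator refers to ``analysis_variables`` (default:
    all outcome/exposure/confounder columns).
    """
    if analysis_variables is None:
        analysis_variables = [c.name for c in data.columns
                              if c.role in ("outcome", "exposure", "confounder")]
    cc = ~data.missing_any(analysis_variables)
    elig = ~data.missing_any(predictors)
    y = cc[elig].astype(float)
    if y.size == 0 or y.min() == y.max():
        raise DegenerateOutcomeError(
            "need both complete and incomplete cases among eligible rows")
    cols = [np.ones(int(elig.sum()))]
    terms = ["intercept"]
    for name in predictors:
        c = data.column(name)
        v = data.values(name)[elig]
        if c.kind == "categorical":
            for code, lev in enumerate(c.levels[1:], start=1):
                cols.append((v == code).astype(float))
                terms.append(f"{name}[{lev}]")
        else:
            cols.append(v)
            terms.append(name)
    return fit_logistic(np.column_stack(cols), y, terms)


@dataclass
class McarReport:
    variable: str
    alpha: float
    tests: dict            # candidate -> {"estimate","se","z","p","significant"}
    refuted: bool
    bonferroni: bool
    note: str = ("Non-refutation of MCAR cannot distinguish MAR from MNAR: "
                 "dependence on the missing values themselves is unobservable.")


def refute_mcar(data: Dataset, variable: str, candidates: list[str],
                alpha: float = 0.05, bonferroni: bool = False) -> McarReport:
    """Per-candidate Wald tests of association with a variable's missingness.

    Each candidate is tested in a univariable logistic regression of the
    missingness indicator of ``variable`` on the candidate, restricted to
    rows where the candidate is observed.  MCAR is reported as refuted if
    any test is significant at ``alpha`` (Bonferroni-adjusted on request;
    default unadjusted, matching exploratory practice).
    """
    miss = ~data.observed(variable)
    if not miss.any():
        raise DatasetError(f"{variable!r} has no missing values; nothing to test")
    level = alpha / len(candidates) if bonferroni else alpha
    tests = {}
    for cand in candidates:
        rows = data.observed(cand)
        y = miss[rows].astype(float)
        v = data.values(cand)[rows]
        X = np.column_stack([np.ones(v.size), v])
        fit = fit_logistic(X, y, ["intercept", cand])
        est, se = fit.coef[1], fit.se[1]
        z = est / se
        pval = 2.0 * stats.norm.sf(abs(z))
        tests[cand] = {"estimate": float(est), "se": float(se), "z": float(z),
                       "p": float(pval), "significant": bool(pval < level)}
    return McarReport(variable, alpha, tests,
                      refuted=any(t["significant"] for t in tests.values()),
                      bonferroni=bonferroni)
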