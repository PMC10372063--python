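"""Correlation screening, collinearity diagnostics and stepwise regression.

The outcome is the monthly normalized DED index (%); predictors are the
monthly environmental factors.  Screening uses pairwise Pearson correlations
with two-sided p-values from the t transform of r on n - 2 degrees of
freedom.  Model building is forward stepwise selection with backward pruning
on partial F-tests (entry p = 0.05, stay p = 0.10 by default), a final
ordinary-least-squares refit, a global F-test, and variance inflation
factors (VIF_j = 1 / (1 - R²_j)) on the retained terms.

The source analysis labels its multivariate model "logistic" yet reports a
linear equation on the percentage index; this module fits linear regression
(matching the reported equation) and carries the label discrepancy in
:attr:`StepwiseModel.notes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io_timeseries import FACTORS


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r, two-sided p, and paired-observation counts."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class StepwiseEvent:
    action: str  # "add" | "drop"
    term: str
    p_value: float


@dataclass
class StepwiseModel:
    """A selected linear model for the monthly DED index.

    ``terms`` maps selected predictors to coefficients (index % per predictor
    unit).  ``trace`` reconstructs the final term set from the add/drop
    events.
    """

    response: str
    intercept: float
    terms: dict[str, float]
    f_statistic: float | None = None
    f_pvalue: float | None = None
    r_squared: float | None = None
    vifs: dict[str, float] = field(default_factory=dict)
    trace: list[StepwiseEvent] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def equation(self) -> str:
        parts = [f"{self.intercept:.3f}"]
        for name, coef in self.terms.items():
            parts.append(f"{'+' if coef >= 0 else '-'} {abs(coef):.3f}*{name}")
        return f"{self.response} = " + " ".join(parts)


def pearson_matrix(table: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix with significance.

    Constant columns yield undefined r for their pairs, reported as NaN and
    listed in ``undefined`` (never coerced to zero).
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    undefined: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i, k):
            x = table[cols[i]].to_numpy(dtype=float)
            y = table[cols[j]].to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            m = int(mask.sum())
            n[i, j] = n[j, i] = m
            if m < min_n:
                continue
            xs, ys = x[mask], y[mask]
            if np.std(xs) == 0 or np.std(ys) == 0:
                undefined.append((cols[i], cols[j]))
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            rij = float(np.corrcoef(xs, ys)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            r[i, j] = r[j, i] = rij
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((m - 2) / (1.0 - rij * rij))
                pij = 2.0 * stats.t.sf(abs(t), df=m - 2)
            p[i, j] = p[j, i] = pij
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        undefined=undefined,
    )


def vif(table: pd.DataFrame, terms: Sequence[str]) -> dict[str, float]:
    """Variance inflation factor of each term against the others.

    VIF_j = 1/(1 - R²_j) from regressing term j (with intercept) on the
    remaining terms; perfect collinearity reports ``inf`` for the offending
    term.  A single term has VIF 1 by convention.
    """
    terms = list(terms)
    data = table[terms].dropna()
    out: dict[str, float] = {}
    for term in terms:
        others = [t for t in terms if t != term]
        if not others:
            out[term] = 1.0
            continue
        X = sm.add_constant(data[others].to_numpy(dtype=float))
        y = data[term].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        r2 = min(res.rsquared, 1.0)
        out[term] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def _fit_ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _partial_f_pvalue(y: np.ndarray, X_small: np.ndarray | None, X_big: np.ndarray) -> float:
    """p-value of the partial F-test comparing nested OLS models."""
    n = y.size
    big = _fit_ols(y, X_big)
    rss_big = float(big.ssr)
    df_big = int(big.df_resid)
    if X_small is None or X_small.shape[1] == 0:
        rss_small = float(np.sum((y - y.mean()) ** 2))
        df_small = n - 1
    else:
        small = _fit_ols(y, X_small)
        rss_small = float(small.ssr)
        df_small = int(small.df_resid)
    df_num = df_small - df_big
    if df_num <= 0 or df_big <= 0 or rss_big <= 0:
        return 0.0 if rss_small > rss_big else 1.0
    f = ((rss_small - rss_big) / df_num) / (rss_big / df_big)
    return float(stats.f.sf(f, df_num, df_big))


def _ordered(candidates: Sequence[str]) -> list[str]:
    """Candidates in the fixed factor order (unknown names keep input order)."""
    order = {name: i for i, name in enumerate(FACTORS)}
    return sorted(candidates, key=lambda c: (order.get(c, len(order)), c))


def stepwise_select(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    entry_p: float = 0.05,
    stay_p: float = 0.10,
) -> StepwiseModel:
    """Forward stepwise selection with backward pruning on partial F-tests.

    At each step the candidate with the smallest add p-value enters if it
    meets ``entry_p`` (ties broken by the fixed factor order); any retained
    term whose drop p-value exceeds ``stay_p`` is then pruned, worst first.
    The final model is refit by OLS and VIF-checked.  When no candidate ever
    meets ``entry_p`` the intercept-only model is returned (not an error).
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if entry_p > stay_p:
        raise ValueError("entry_p must be <= stay_p")
    candidates = _ordered(candidates)
    data = table[[response, *candidates]].dropna()
    y = data[response].to_numpy(dtype=float)
    notes: list[str] = [
        "model family: linear regression on the percentage index "
        "(reported multivariate equation is linear despite the 'logistic' label)"
    ]
    trace: list[StepwiseEvent] = []

    if np.std(y) == 0:
        return StepwiseModel(response=response, intercept=float(y.mean()), terms={},
                             r_squared=None, trace=trace, notes=notes + ["constant response"])

    selected: list[str] = []

    def design(names: Sequence[str]) -> np.ndarray:
        return data[list(names)].to_numpy(dtype=float) if names else np.empty((y.size, 0))

    while True:
        changed = False
        # forward step
        best_term, best_p = None, np.inf
        for cand in candidates:
            if cand in selected:
                continue
            p_add = _partial_f_pvalue(y, design(selected) if selected else None,
                                      design([*selected, cand]))
            if p_add < best_p - 1e-15:
                best_term, best_p = cand, p_add
        if best_term is not None and best_p <= entry_p:
            selected.append(best_term)
            trace.append(StepwiseEvent("add", best_term, float(best_p)))
            changed = True
        # backward step(s)
        while len(selected) > 0:
            worst_term, worst_p = None, -np.inf
            for term in selected:
                rest = [t for t in selected if t != term]
                p_drop = _partial_f_pvalue(y, design(rest) if rest else None, design(selected))
                if p_drop > worst_p + 1e-15:
                    worst_term, worst_p = term, p_drop
            if worst_term is not None and worst_p > stay_p:
                selected.remove(worst_term)
                trace.append(StepwiseEvent("drop", worst_term, float(worst_p)))
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        return StepwiseModel(response=response, intercept=float(y.mean()), terms={},
                             trace=trace, notes=notes)

    res = _fit_ols(y, design(selected))
    coefs = dict(zip(selected, (float(c) for c in res.params[1:])))
    return StepwiseModel(
        response=response,
        intercept=float(res.params[0]),
        terms=coefs,
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        vifs=vif(data, selected),
        trace=trace,
        notes=notes,
    )


def predict(model: StepwiseModel, values: Mapping[str, float]) -> float:
    """Evaluate a (fitted or externally supplied) linear model at factor values."""
    total = model.intercept
    for name, coef in model.terms.items():
        if name not in values:
            raise KeyError(f"missing value for model term {name!r}")
        total += coef * float(values[name])
    return float(total)


def model_from_coefficients(
    intercept: float, terms: Mapping[str, float], response: str = "DED"
) -> StepwiseModel:
    """Wrap an externally supplied coefficient vector (e.g. a published
    equation) for use with :func:`predict`."""
    return StepwiseModel(response=response, intercept=float(intercept),
                         terms={k: float(v) for k, v in terms.items()},
                         notes=["coefficients supplied externally, not fitted"])
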