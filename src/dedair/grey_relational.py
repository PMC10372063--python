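"""Grey relational analysis (GRA).

GRA scores how closely each comparison series tracks a reference series.
After a dimensionless normalization, the absolute deviation of comparison
``i`` from the reference at time ``k`` is ``delta_i(k)``, and the grey
relational coefficient is

    xi_i(k) = (delta_min + rho * delta_max) / (delta_i(k) + rho * delta_max)

with ``delta_min``/``delta_max`` taken over all comparisons and time points
(global scope) or within each series (per-series scope).  The grey relational
grade of a factor is the arithmetic mean of its coefficients over time;
factors are ranked by decreasing grade.  ``rho`` in (0, 1] is the
distinguishing coefficient moderating the weight of the maximum deviation;
0.5 is the near-universal convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NORMALIZATIONS = ("mean-value", "initial-value", "min-max")
DELTA_SCOPES = ("global", "per-series")


@dataclass(frozen=True)
class GreySettings:
    """GRA conventions: distinguishing coefficient, normalization, delta scope."""

    rho: float = 0.5
    normalization: str = "mean-value"
    delta_scope: str = "global"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.normalization not in (*NORMALIZATIONS, "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.delta_scope not in DELTA_SCOPES:
            raise ValueError(f"unknown delta scope {self.delta_scope!r}")


@dataclass
class GreyResult:
    """Coefficient matrix (time × factor) with per-factor grades and ranks."""

    coefficients: pd.DataFrame
    settings: GreySettings
    grades: pd.Series | None = None
    ranks: pd.Series | None = None


def normalize_series(series: Sequence[float], scheme: str = "mean-value") -> np.ndarray:
    """Normalize one series for GRA.

    mean-value: divide by the series mean; initial-value: divide by the first
    element; min-max: (x - min)/(max - min).  A zero denominator is an error
    naming the scheme.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("series must have length >= 2")
    if scheme == "none":
        return arr.copy()
    if scheme == "mean-value":
        denom = arr.mean()
        if denom == 0:
            raise ValueError("mean-value normalization: series mean is zero")
        return arr / denom
    if scheme == "initial-value":
        if arr[0] == 0:
            raise ValueError("initial-value normalization: first element is zero")
        return arr / arr[0]
    if scheme == "min-max":
        span = arr.max() - arr.min()
        if span == 0:
            raise ValueError("min-max normalization: max equals min")
        return (arr - arr.min()) / span
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def relational_coefficients(
    reference: Sequence[float],
    comparisons: Mapping[str, Sequence[float]] | pd.DataFrame,
    settings: GreySettings | None = None,
    index: Sequence | None = None,
) -> GreyResult:
    """Grey relational coefficients of each comparison series vs the reference."""
    settings = settings or GreySettings()
    ref = np.asarray(reference, dtype=float)
    if isinstance(comparisons, pd.DataFrame):
        names = list(comparisons.columns)
        if index is None:
            index = comparisons.index
        comp_raw = {name: comparisons[name].to_numpy(dtype=float) for name in names}
    else:
        names = list(comparisons)
        comp_raw = {name: np.asarray(comparisons[name], dtype=float) for name in names}
    for name, arr in comp_raw.items():
        if arr.shape != ref.shape:
            raise ValueError(
                f"series {name!r} has length {arr.size}, reference has {ref.size}"
            )

    ref_n = normalize_series(ref, settings.normalization)
    delta = np.empty((ref.size, len(names)))
    for j, name in enumerate(names):
        delta[:, j] = np.abs(ref_n - normalize_series(comp_raw[name], settings.normalization))

    if settings.delta_scope == "global":
        dmin, dmax = delta.min(), delta.max()
        xi = (dmin + settings.rho * dmax) / (delta + settings.rho * dmax)
    else:
        dmin = delta.min(axis=0, keepdims=True)
        dmax = delta.max(axis=0, keepdims=True)
        xi = (dmin + settings.rho * dmax) / (delta + settings.rho * dmax)

    if index is None:
        index = pd.RangeIndex(ref.size)
    coeffs = pd.DataFrame(xi, index=index, columns=names)
    return GreyResult(coefficients=coeffs, settings=settings)


def relational_grades(result: GreyResult) -> GreyResult:
    """Fill grades (mean coefficient per factor) and decreasing-grade ranks.

    Ties are broken by column order (the fixed factor order upstream), so
    rankings are deterministic.
    """
    grades = result.coefficients.mean(axis=0)
    order = np.argsort(-grades.to_numpy(), kind="stable")
    ranks = pd.Series(0, index=grades.index, dtype=int)
    for position, j in enumerate(order, start=1):
        ranks.iloc[j] = position
    return GreyResult(
        coefficients=result.coefficients,
        settings=result.settings,
        grades=grades,
        ranks=ranks,
    )


def grey_relational_analysis(
    reference: Sequence[float],
    comparisons: Mapping[str, Sequence[float]] | pd.DataFrame,
    settings: GreySettings | None = None,
) -> GreyResult:
    """Coefficients, grades and ranks in one call."""
    return relational_grades(relational_coefficients(reference, comparisons, settings))


def sensitivity_sweep(
    reference: Sequence[float],
    comparisons: Mapping[str, Sequence[float]] | pd.DataFrame,
    rho_values: Sequence[float] = (0.3, 0.5, 0.9),
    schemes: Sequence[str] = ("mean-value",),
    delta_scope: str = "global",
) -> pd.DataFrame:
    """Grades and ranks across a grid of GRA conventions.

    One row per (rho, scheme, factor); the ``stable_ranking`` column flags
    whether the rank ordering is identical across the whole grid — the
    diagnostic for conclusions that should not hinge on unstated conventions.
    """
    rho_values = list(rho_values)
    schemes = list(schemes)
    if not rho_values or not schemes:
        raise ValueError("sweep grid must contain at least one rho and one scheme")
    rows = []
    orderings = []
    for scheme in schemes:
        for rho in rho_values:
            settings = GreySettings(rho=rho, normalization=scheme, delta_scope=delta_scope)
            res = grey_relational_analysis(reference, comparisons, settings)
            orderings.append(tuple(res.ranks.sort_values().index))
            for name in res.grades.index:
                rows.append(
                    (rho, scheme, name, float(res.grades[name]), int(res.ranks[name]))
                )
    stable = len(set(orderings)) == 1
    out = pd.DataFrame(rows, columns=["rho", "scheme", "factor", "grade", "rank"])
    out["stable_ranking"] = stable
    return out


def result_to_table(result: GreyResult) -> pd.DataFrame:
    """Published-style layout: coefficient rows per time point, then grade
    and rank rows."""
    if result.grades is None:
        result = relational_grades(result)
    table = result.coefficients.copy()
    table.loc["grade"] = result.grades
    table.loc["rank"] = result.ranks.astype(float)
    return table
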