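"""Bivariate second-order response surfaces for joint exposure effects.

For a factor pair (x, y) the DED index z is fitted to the full quadratic
surface

    z = b0 + b1 x + b2 y + b3 x^2 + b4 y^2 + b5 x y

by least squares; the overall F-test against the intercept-only model and
R² quantify the joint association, and the interaction coefficient b5 with
its t-test quantifies the synergy proper.  The reported surface maximum is
searched on a grid restricted to the convex hull of the observed (x, y)
points — never by extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import Delaunay, QhullError


@dataclass
class SurfaceFit:
    x_name: str
    y_name: str
    coefficients: np.ndarray          # (b0, b1, b2, b3, b4, b5)
    r_squared: float
    f_pvalue: float
    interaction_t: float
    interaction_p: float
    max_location: tuple[float, float]  # within the observed data hull
    max_value: float
    n: int
    degree: int = 2

    def evaluate(self, x, y) -> np.ndarray:
        b = self.coefficients
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return b[0] + b[1] * x + b[2] * y + b[3] * x ** 2 + b[4] * y ** 2 + b[5] * x * y


def _design(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(x), x, y]
    if degree >= 2:
        cols += [x ** 2, y ** 2, x * y]
    return np.column_stack(cols)


def _hull_grid_max(fit_eval, x: np.ndarray, y: np.ndarray, resolution: int = 50):
    """Maximize the fitted surface on a grid clipped to the data hull."""
    gx = np.linspace(x.min(), x.max(), resolution)
    gy = np.linspace(y.min(), y.max(), resolution)
    GX, GY = np.meshgrid(gx, gy)
    points = np.column_stack([GX.ravel(), GY.ravel()])
    try:
        hull = Delaunay(np.column_stack([x, y]))
        inside = hull.find_simplex(points) >= 0
    except QhullError:
        # degenerate geometry (e.g. collinear points): fall back to the data
        points = np.column_stack([x, y])
        inside = np.ones(len(points), dtype=bool)
    candidates = points[inside]
    if candidates.size == 0:
        candidates = np.column_stack([x, y])
    z = fit_eval(candidates[:, 0], candidates[:, 1])
    k = int(np.argmax(z))
    return (float(candidates[k, 0]), float(candidates[k, 1])), float(z[k])


def fit_surface(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    degree: int = 2,
    grid_resolution: int = 50,
) -> SurfaceFit:
    """Least-squares polynomial surface fit of z over (x, y).

    Requires at least two more observations than coefficients; a
    rank-deficient design (for instance a constant x) is an error naming the
    degenerate variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[mask], y[mask], z[mask]
    n_coef = 6 if degree >= 2 else 3
    if x.size < n_coef + 2:
        raise ValueError(f"need at least {n_coef + 2} observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate design: {x_name} is constant")
    if np.ptp(y) == 0:
        raise ValueError(f"degenerate design: {y_name} is constant")
    X = _design(x, y, degree)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design for pair ({x_name}, {y_name})")
    res = sm.OLS(z, X).fit()
    coeffs = np.zeros(6)
    coeffs[: X.shape[1]] = res.params
    if degree >= 2:
        t_int, p_int = float(res.tvalues[5]), float(res.pvalues[5])
    else:
        t_int, p_int = float("nan"), float("nan")

    def surf(px, py):
        b = coeffs
        return (b[0] + b[1] * px + b[2] * py + b[3] * px ** 2
                + b[4] * py ** 2 + b[5] * px * py)

    max_loc, max_val = _hull_grid_max(surf, x, y, grid_resolution)
    return SurfaceFit(
        x_name=x_name, y_name=y_name, coefficients=coeffs,
        r_squared=float(res.rsquared), f_pvalue=float(res.f_pvalue),
        interaction_t=t_int, interaction_p=p_int,
        max_location=max_loc, max_value=max_val, n=int(x.size), degree=degree,
    )


#: Default factor pairs examined for joint effects on the DED index.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("PM10", "AT"), ("PM10", "AP"), ("NO2", "AT"), ("NO2", "AP"),
)


def fit_pairs(
    table: pd.DataFrame,
    response: str = "DED",
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    degree: int = 2,
) -> list[SurfaceFit]:
    return [
        fit_surface(table[a], table[b], table[response], x_name=a, y_name=b, degree=degree)
        for a, b in pairs
    ]


def surface_report(fits: Sequence[SurfaceFit], alpha: float = 0.05) -> pd.DataFrame:
    """Fits ranked by R² with significance flags and maximizing regions."""
    if not fits:
        raise ValueError("need at least one surface fit")
    rows = []
    for fit in fits:
        rows.append({
            "pair": f"{fit.x_name}:{fit.y_name}",
            "r_squared": fit.r_squared,
            "f_pvalue": fit.f_pvalue,
            "significant": fit.f_pvalue < alpha,
            "interaction_t": fit.interaction_t,
            "interaction_p": fit.interaction_p,
            "max_x": fit.max_location[0],
            "max_y": fit.max_location[1],
            "max_response": fit.max_value,
            "n": fit.n,
        })
    out = pd.DataFrame(rows).sort_values("r_squared", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def grid_frame(fit: SurfaceFit, x: Sequence[float], y: Sequence[float], resolution: int = 50) -> pd.DataFrame:
    """Long-form grid (x, y, fitted z) over the bounding box of given data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gx = np.linspace(np.nanmin(x), np.nanmax(x), resolution)
    gy = np.linspace(np.nanmin(y), np.nanmax(y), resolution)
    GX, GY = np.meshgrid(gx, gy)
    Z = fit.evaluate(GX, GY)
    return pd.DataFrame({
        fit.x_name: GX.ravel(), fit.y_name: GY.ravel(), "fitted": Z.ravel(),
    })
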