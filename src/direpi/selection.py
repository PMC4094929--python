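"""Directional epistasis from bidirectional selection-response asymmetry.

Under a constant selection gradient, directional epistasis bends the
phenotype trajectory away from the linear breeder's-equation response: the
expected mean after t generations is

    mu_t = mu_0 - log(1 - 2 * dmu0 * eps * t) / (2 * eps)
         ~ mu_0 + dmu0 * t + eps * dmu0**2 * t**2 + ...

where dmu0 is the initial per-generation response and eps the directional
epistasis coefficient (inverse trait units).  Positive eps accelerates an
upward response and decelerates a downward one, so the average of an
up-selected and a down-selected trajectory grows approximately like
eps * dmu0**2 * t**2.  The estimator here regresses that asymmetry on a
quadratic in t and divides the curvature by the squared initial response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import statsmodels.api as sm

__all__ = [
    "SelectionSeries",
    "ResponseEstimates",
    "TrajectoryDivergenceError",
    "expected_mean",
    "initial_response",
    "asymmetry_series",
    "estimate_epsilon_quadratic",
]

#: |2 dmu0 eps t| below which the closed form hands off to its Taylor series
SERIES_BRANCH_THRESHOLD = 1e-8

#: |dmu0| below which the asymmetry-based epsilon is undefined
SLOPE_TOLERANCE = 1e-12


class TrajectoryDivergenceError(ValueError):
    """The closed-form trajectory blows up in finite time (log argument <= 0)."""


@dataclass
class SelectionSeries:
    """One selection line's trajectory of generation means."""

    generation: np.ndarray
    mean_phenotype: np.ndarray
    line_label: Literal["up", "down"] | str = "up"

    def __post_init__(self) -> None:
        self.generation = np.asarray(self.generation, dtype=float)
        self.mean_phenotype = np.asarray(self.mean_phenotype, dtype=float)
        if self.generation.shape != self.mean_phenotype.shape:
            raise ValueError("generation and mean_phenotype lengths differ")
        if np.any(self.generation < 0):
            raise ValueError("generations must be non-negative")
        order = np.argsort(self.generation)
        self.generation = self.generation[order]
        self.mean_phenotype = self.mean_phenotype[order]
        if np.any(np.diff(self.generation) <= 0):
            raise ValueError("duplicate generations within a line")

    def __len__(self) -> int:
        return len(self.generation)


@dataclass
class ResponseEstimates:
    """Estimates from the up/down asymmetry estimator.

    ``epsilon = quad_coeff / delta0_abs**2`` by construction; standard
    errors are propagated from the two regressions (delta method).
    """

    delta0_up: float
    delta0_down: float
    delta0_abs: float
    quad_coeff: float
    epsilon: float
    se_delta0_up: float
    se_delta0_down: float
    se_delta0_abs: float
    se_quad_coeff: float
    se_epsilon: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def expected_mean(t: float, mu0: float, delta0: float, eps: float) -> float:
    """Expected mean phenotype after ``t`` generations of constant selection.

    Uses the closed form ``mu0 - log(1 - 2 delta0 eps t) / (2 eps)``; when
    the epistatic term is tiny (|2 delta0 eps t| < 1e-8) it switches to the
    second-order Taylor form ``mu0 + delta0 t + eps delta0^2 t^2`` to avoid
    the 0/0 limit at eps -> 0.
    """
    x = 2.0 * delta0 * eps * t
    if abs(x) < SERIES_BRANCH_THRESHOLD:
        return mu0 + delta0 * t + eps * delta0**2 * t**2
    if x >= 1.0:
        raise TrajectoryDivergenceError(
            f"trajectory diverges: 2*delta0*eps*t = {x:.6g} >= 1 "
            "(finite-time blow-up of the constant-gradient model)"
        )
    return mu0 - math.log1p(-x) / (2.0 * eps)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])


def initial_response(series: SelectionSeries, k: int = 20) -> tuple[float, float]:
    """Initial selection response: OLS slope over generations 0..k.

    Returns ``(slope, standard error)`` in trait units per generation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > series.generation.max():
        raise ValueError("k exceeds the span of the series")
    mask = series.generation <= k
    if mask.sum() < 2:
        raise ValueError("fewer than 2 observations within generations 0..k")
    return _ols_slope(series.generation[mask], series.mean_phenotype[mask])


def asymmetry_series(up: SelectionSeries, down: SelectionSeries) -> SelectionSeries:
    """Pointwise average of the up and down trajectories, A(t) = (up+down)/2.

    Additive (and most non-genetic) contributions cancel in the average;
    what remains grows quadratically with t in proportion to directional
    epistasis.
    """
    if not np.array_equal(up.generation, down.generation):
        raise ValueError("up and down series must share the same generation grid")
    return SelectionSeries(
        up.generation.copy(),
        0.5 * (up.mean_phenotype + down.mean_phenotype),
        line_label="asymmetry",
    )


def estimate_epsilon_quadratic(
    up: SelectionSeries, down: SelectionSeries, k: int = 20
) -> ResponseEstimates:
    """Estimate directional epistasis from bidirectional selection responses.

    Procedure: (1) per-line initial slope over generations 0..k by OLS;
    (2) pooled |dmu0| as the arithmetic mean of the absolute slopes;
    (3) quadratic OLS fit ``A(t) = a0 + a1 t + c t^2`` to the up/down
    average; (4) ``eps = c / dmu0^2``.  The intercept and linear terms
    absorb the founding mean and any residual trend from unequal per-line
    initial responses.
    """
    b_up, se_up = initial_response(up, k)
    b_down, se_down = initial_response(down, k)
    d_abs = 0.5 * (abs(b_up) + abs(b_down))
    # SE of the average of two independent absolute slopes
    se_d = 0.5 * math.hypot(se_up, se_down)

    A = asymmetry_series(up, down)
    t = A.generation
    X = np.column_stack([np.ones_like(t), t, t**2])
    res = sm.OLS(A.mean_phenotype, X).fit()
    c, se_c = float(res.params[2]), float(res.bse[2])

    if d_abs < SLOPE_TOLERANCE:
        raise ValueError("initial response indistinguishable from zero; "
                         "epsilon undefined")
    eps = c / d_abs**2
    # delta method: eps = c / d^2
    se_eps = abs(eps) * math.hypot(
        se_c / c if c != 0 else 0.0, 2.0 * se_d / d_abs
    )
    return ResponseEstimates(
        delta0_up=b_up,
        delta0_down=b_down,
        delta0_abs=d_abs,
        quad_coeff=c,
        epsilon=eps,
        se_delta0_up=se_up,
        se_delta0_down=se_down,
        se_delta0_abs=se_d,
        se_quad_coeff=se_c,
        se_epsilon=se_eps,
    )
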