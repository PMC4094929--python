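"""Directional epistasis from line-cross means (P1, P2, F1, F2).

The four population means of a parental-and-intercross design are modelled
with a reference point mu (the F2 mean), an additive effect A separating
the parents by 4A, a dominance effect D, and a unidimensional directional
epistasis coefficient eps:

    P1 = mu - 2A - D + eps*(A^2 + A*D + D^2/4)
    P2 = mu + 2A - D + eps*(A^2 - A*D + D^2/4)
    F1 = mu + D + eps*D^2/4
    F2 = mu

With dominance the system is exactly identified (4 equations, 4 unknowns);
without dominance (D = 0) the 3-parameter model is fit to the 4 means by
equal-weight least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CrossMeans",
    "CrossEstimates",
    "ConvergenceError",
    "predict_cross_means",
    "fit_line_cross",
]


class ConvergenceError(RuntimeError):
    """Nonlinear solver failed to converge; message carries diagnostics."""


@dataclass
class CrossMeans:
    P1: float
    P2: float
    F1: float
    F2: float

    def __post_init__(self) -> None:
        vals = (self.P1, self.P2, self.F1, self.F2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all four means must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.P1, self.P2, self.F1, self.F2], dtype=float)


@dataclass
class CrossEstimates:
    mu: float
    A: float
    D: float
    eps: float
    rss: float = 0.0

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def predict_cross_means(est: CrossEstimates) -> CrossMeans:
    """Evaluate the four-population model at the given parameters."""
    mu, A, D, e = est.mu, est.A, est.D, est.eps
    return CrossMeans(
        P1=mu - 2 * A - D + e * (A * A + A * D + 0.25 * D * D),
        P2=mu + 2 * A - D + e * (A * A - A * D + 0.25 * D * D),
        F1=mu + D + 0.25 * e * D * D,
        F2=mu,
    )


def fit_line_cross(means: CrossMeans, dominance: bool = True) -> CrossEstimates:
    """Fit the line-cross model to four observed means.

    With ``dominance=True`` all four parameters are free and the system is
    exactly identified, so residuals converge to solver tolerance.  With
    ``dominance=False`` the dominance effect is pinned at zero and the
    three remaining parameters are fit by equal-weight least squares.
    """
    obs = means.as_array()

    def residuals(theta: np.ndarray) -> np.ndarray:
        if dominance:
            mu, A, D, e = theta
        else:
            mu, A, e = theta
            D = 0.0
        pred = predict_cross_means(CrossEstimates(mu, A, D, e))
        return pred.as_array() - obs

    mu0 = means.F2
    A0 = (means.P2 - means.P1) / 4.0
    D0 = means.F1 - means.F2
    x0 = np.array([mu0, A0, D0, 0.0]) if dominance else np.array([mu0, A0, 0.0])

    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise ConvergenceError(
            f"line-cross fit did not converge: {sol.message} "
            f"(best candidate {sol.x}, cost {sol.cost:.3g})"
        )
    if dominance:
        mu, A, D, e = sol.x
    else:
        (mu, A, e), D = sol.x, 0.0
    rss = float(np.sum(sol.fun**2))
    return CrossEstimates(float(mu), float(A), float(D), float(e), rss=rss)
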