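"""Directional epistasis from mutation-count regressions.

Two functional, unidimensional models relate a phenotype to a signed count
``m`` of "high" allelic substitutions away from a reference genotype
(``m = 0`` at the reference, e.g. the mean-F2 genotype):

* continuous power model:
    P(m) = mu + alpha * m**beta        for m > 0
         = mu                          for m = 0
         = mu - alpha * |m|**(1/beta)  for m < 0
  beta = 1 means no epistasis, beta > 1 positive (synergistic) epistasis.

* quadratic model:
    P(m) = mu + alpha * m + beta_prime * m**2 / 2
  beta_prime = 0 means no epistasis, beta_prime > 0 positive epistasis.

Both are the quantitative-trait analogues of the log-fitness models used
in mutation-accumulation studies (W = alpha n**beta and the quadratic
W = -(alpha n + beta' n^2 / 2)): the same curves under a relabelled
response.  The power model is monotone in m (no sign epistasis); the
quadratic model changes slope at m = -alpha/beta' (sign epistasis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .qtl import aic_gaussian

__all__ = [
    "MutationCountData",
    "PowerFit",
    "QuadFit",
    "mutation_score",
    "power_predict",
    "quad_predict",
    "substitution_effect",
    "fit_power",
    "fit_quadratic",
]


@dataclass
class MutationCountData:
    """Signed mutation counts and phenotypes, one entry per individual."""

    m: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if self.m.shape != self.phenotype.shape:
            raise ValueError("m and phenotype lengths differ")

    def drop_extremes(self, n_loci: int) -> "MutationCountData":
        """Remove full homozygotes (|m| = number of loci), a robustness
        check against the leverage of extreme genotypes."""
        keep = np.abs(self.m) < n_loci
        return MutationCountData(self.m[keep], self.phenotype[keep])


@dataclass
class PowerFit:
    mu: float
    alpha: float
    beta: float
    se_mu: float = float("nan")
    se_alpha: float = float("nan")
    se_beta: float = float("nan")
    rss: float = float("nan")
    aic: float = float("nan")
    n: int = 0

    def predict(self, m: float | np.ndarray) -> float | np.ndarray:
        return power_predict(self, m)

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "n" else float(v))
                for k, v in self.__dict__.items()}


@dataclass
class QuadFit:
    mu: float
    alpha: float
    beta_prime: float
    se_mu: float = float("nan")
    se_alpha: float = float("nan")
    se_beta_prime: float = float("nan")
    rss: float = float("nan")
    aic: float = float("nan")
    n: int = 0

    def predict(self, m: float | np.ndarray) -> float | np.ndarray:
        return quad_predict(self, m)

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "n" else float(v))
                for k, v in self.__dict__.items()}


def mutation_score(genotypes: np.ndarray) -> np.ndarray:
    """Signed count of extra "high" alleles relative to the all-
    heterozygote reference: ``m = sum_loci (dosage - 1)``.

    Real-valued for expected dosages.
    """
    g = np.asarray(genotypes, dtype=float)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    return (g - 1.0).sum(axis=1)


def power_predict(fit: PowerFit, m: float | np.ndarray) -> float | np.ndarray:
    """Piecewise power-model prediction; P(0) = mu exactly."""
    if not (np.isfinite(fit.alpha) and np.isfinite(fit.beta)) or fit.beta <= 0:
        raise ValueError("alpha and beta must be finite with beta > 0")
    m_arr = np.asarray(m, dtype=float)
    am = np.abs(m_arr)
    out = np.where(
        m_arr > 0,
        fit.mu + fit.alpha * am**fit.beta,
        np.where(m_arr < 0, fit.mu - fit.alpha * am ** (1.0 / fit.beta), fit.mu),
    )
    return float(out) if np.isscalar(m) else out


def quad_predict(fit: QuadFit, m: float | np.ndarray) -> float | np.ndarray:
    """Quadratic-model prediction mu + alpha m + beta' m^2 / 2."""
    m_arr = np.asarray(m, dtype=float)
    out = fit.mu + fit.alpha * m_arr + 0.5 * fit.beta_prime * m_arr**2
    return float(out) if np.isscalar(m) else out


def substitution_effect(
    model: PowerFit | QuadFit, m_from: float, m_to: float
) -> float:
    """Phenotypic effect of moving from ``m_from`` to ``m_to`` substitutions,
    P(m_to) - P(m_from).  Effects toward lower phenotypes are conventionally
    reported as magnitudes by the caller."""
    return float(model.predict(m_to) - model.predict(m_from))


def _start_values(data: MutationCountData) -> tuple[float, float]:
    near_ref = np.abs(data.m) < 0.5
    mu0 = (data.phenotype[near_ref].mean() if near_ref.any()
           else data.phenotype.mean())
    mc = data.m - data.m.mean()
    denom = mc @ mc
    alpha0 = (mc @ (data.phenotype - data.phenotype.mean())) / denom \
        if denom > 0 else 0.0
    return float(mu0), float(alpha0)


def _check_sign_span(data: MutationCountData) -> None:
    if not (np.any(data.m > 0) and np.any(data.m < 0)):
        warnings.warn(
            "mutation counts do not span both signs; the epistasis "
            "exponent is weakly identified",
            stacklevel=3,
        )


def _nls_se(sol, n: int, k: int) -> np.ndarray:
    rss = float(np.sum(sol.fun**2))
    sigma2 = rss / max(n - k, 1)
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def fit_power(data: MutationCountData, n_restarts: int = 5,
              seed: int = 0) -> PowerFit:
    """Nonlinear least-squares fit of the continuous power model.

    beta is optimized on the log scale, which enforces beta > 0 and tames
    the |m|**(1/beta) branch; the kink at m = 0 is handled by the exact
    piecewise evaluation.
    """
    _check_sign_span(data)
    mu0, alpha0 = _start_values(data)
    x0 = np.array([mu0, alpha0 if alpha0 != 0 else 1.0, 0.0])  # log beta = 0

    def residuals(theta: np.ndarray) -> np.ndarray:
        fit = PowerFit(theta[0], theta[1], math.exp(theta[2]))
        return power_predict(fit, data.m) - data.phenotype

    rng = np.random.default_rng(seed)
    sol = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 + 0.1 * rng.standard_normal(3) * \
            np.array([abs(mu0) + 1, abs(alpha0) + 1, 1.0])
        cand = least_squares(residuals, start, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if sol is None or cand.cost < sol.cost:
            sol = cand
        if cand.success:
            break
    if not sol.success:
        raise RuntimeError(
            f"power-model fit failed to converge; best cost {sol.cost:.6g}"
        )
    n, k = len(data.m), 3
    se = _nls_se(sol, n, k)
    beta = math.exp(sol.x[2])
    rss = float(np.sum(sol.fun**2))
    return PowerFit(
        mu=float(sol.x[0]),
        alpha=float(sol.x[1]),
        beta=beta,
        se_mu=float(se[0]),
        se_alpha=float(se[1]),
        se_beta=float(se[2]) * beta,  # delta method from log beta
        rss=rss,
        aic=aic_gaussian(rss, n, k),
        n=n,
    )


def fit_quadratic(data: MutationCountData) -> QuadFit:
    """Least-squares fit of the quadratic model (linear in parameters)."""
    _check_sign_span(data)
    X = np.column_stack([np.ones_like(data.m), data.m, 0.5 * data.m**2])
    coef, _, _, _ = np.linalg.lstsq(X, data.phenotype, rcond=None)
    resid = data.phenotype - X @ coef
    rss = float(resid @ resid)
    n, k = len(data.m), 3
    sigma2 = rss / max(n - k, 1)
    try:
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return QuadFit(
        mu=float(coef[0]),
        alpha=float(coef[1]),
        beta_prime=float(coef[2]),
        se_mu=float(se[0]),
        se_alpha=float(se[1]),
        se_beta_prime=float(se[2]),
        rss=rss,
        aic=aic_gaussian(rss, n, k),
        n=n,
    )
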