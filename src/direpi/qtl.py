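"""Genetic-effect models for genotype-phenotype tables.

Two families of models are fit to tables of individual phenotypes and
per-locus diploid dosages:

* an orthogonal linear model (NOIA-style) with per-locus additive and
  dominance effects and all pairwise interaction effects — the traditional
  decomposition of genetic effects;
* multilinear models in which each pairwise interaction effect is
  constrained to be the product of the marginal genotypic values and a
  directional-epistasis coefficient, either one constant eps or one
  eps_ij per pair.

Model scores use the "statistical" reference: under the observed genotype
frequencies every single-locus additive and dominance column has zero mean
and the two are uncorrelated, so marginal-effect estimates do not shift
when interaction columns enter the model (absent linkage disequilibrium).
Models are compared by AIC computed from the Gaussian likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .core import composite_epsilon

__all__ = [
    "GenoPhenoTable",
    "DesignMatrix",
    "QtlFit",
    "noia_design",
    "fit_additive",
    "fit_linear_pairwise",
    "fit_multilinear",
    "additive_variances",
    "compare_models",
    "aic_gaussian",
]

logger = logging.getLogger("direpi")


@dataclass
class GenoPhenoTable:
    """Phenotypes plus per-locus allele dosages for a set of individuals.

    Dosages count copies of the "high" allele and lie in [0, 2]; real
    values are accepted as expected dosages for uncertain genotypes.
    Individuals with a missing dosage at any locus are dropped (logged).
    """

    phenotype: np.ndarray
    genotypes: np.ndarray
    locus_labels: list[str] = field(default_factory=list)
    het_prob: np.ndarray | None = None  # P(heterozygote), optional

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be individuals x loci")
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise ValueError("phenotype and genotype row counts differ")
        if np.any(np.isnan(self.phenotype)):
            raise ValueError("missing phenotypes are not allowed")
        if not self.locus_labels:
            self.locus_labels = [f"L{i+1}" for i in range(self.genotypes.shape[1])]
        if len(self.locus_labels) != self.genotypes.shape[1]:
            raise ValueError("locus label count differs from locus count")
        keep = ~np.isnan(self.genotypes).any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d individuals with missing genotypes", n_drop)
            self.phenotype = self.phenotype[keep]
            self.genotypes = self.genotypes[keep]
            if self.het_prob is not None:
                self.het_prob = np.asarray(self.het_prob, dtype=float)[keep]
        with np.errstate(invalid="ignore"):
            if np.any((self.genotypes < 0) | (self.genotypes > 2)):
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.phenotype.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class DesignMatrix:
    """Per-locus additive and dominance score columns.

    ``additive[:, i]`` is the centered dosage of locus i; ``dominance[:, i]``
    is the heterozygote contrast made orthogonal (under the reference
    frequencies) to the intercept and the additive column.  Loci without
    heterozygotes have no dominance column (``has_dominance[i]`` False).
    """

    additive: np.ndarray
    dominance: np.ndarray
    has_dominance: np.ndarray
    locus_labels: list[str]
    reference: str

    @property
    def n_loci(self) -> int:
        return self.additive.shape[1]

    def pair_indices(self) -> list[tuple[int, int]]:
        L = self.n_loci
        return [(i, j) for i in range(L) for j in range(i + 1, L)]

    def linear_columns(
        self, interactions: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Stack marginal (and optionally all pairwise product) columns."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        lab = self.locus_labels
        for i in range(self.n_loci):
            cols.append(self.additive[:, i])
            names.append(f"a[{lab[i]}]")
        for i in range(self.n_loci):
            if self.has_dominance[i]:
                cols.append(self.dominance[:, i])
                names.append(f"d[{lab[i]}]")
        if interactions:
            for i, j in self.pair_indices():
                terms = [("a", self.additive[:, i]), ]
                if self.has_dominance[i]:
                    terms.append(("d", self.dominance[:, i]))
                terms_j = [("a", self.additive[:, j])]
                if self.has_dominance[j]:
                    terms_j.append(("d", self.dominance[:, j]))
                for si, ci in terms:
                    for sj, cj in terms_j:
                        cols.append(ci * cj)
                        names.append(f"{si}{sj}[{lab[i]}:{lab[j]}]")
        return np.column_stack(cols), names


def _het_probability(table: GenoPhenoTable) -> np.ndarray:
    """Per-individual heterozygosity probability for each locus.

    Integer dosages give a 0/1 indicator; expected dosages use the supplied
    heterozygote probabilities, falling back to ``2 d (1 - d/2)`` — the
    heterozygosity of a genotype drawn with allele frequency d/2.
    """
    if table.het_prob is not None:
        return np.asarray(table.het_prob, dtype=float)
    g = table.genotypes
    h = np.where(np.isclose(g % 1, 0), (g == 1).astype(float),
                 2.0 * g * (1.0 - g / 2.0))
    return h


def noia_design(
    table: GenoPhenoTable,
    reference: Literal["observed", "f2_theoretical"] = "observed",
) -> DesignMatrix:
    """Build orthogonal additive/dominance scores for each locus.

    ``reference="observed"`` centers and orthogonalizes under the observed
    genotype frequencies (valid without Hardy-Weinberg proportions);
    ``reference="f2_theoretical"`` uses the idealized F2 class frequencies
    (1/4, 1/2, 1/4), giving additive scores (-1, 0, 1) and dominance scores
    (-1/2, 1/2, -1/2).
    """
    g = table.genotypes
    h = _het_probability(table)
    n, L = g.shape
    Sa = np.empty_like(g)
    Sd = np.zeros_like(g)
    has_dom = np.zeros(L, dtype=bool)
    for i in range(L):
        d = g[:, i]
        if np.ptp(d) < 1e-12:
            raise ValueError(
                f"locus {table.locus_labels[i]} is monomorphic; "
                "scores are undefined"
            )
        if reference == "f2_theoretical":
            a = d - 1.0
            dom = h[:, i] - 0.5  # cov(h, d) = 0 under F2 frequencies
        elif reference == "observed":
            a = d - d.mean()
            # residual of the heterozygote contrast on [1, a]
            dom = h[:, i] - h[:, i].mean() - (a @ h[:, i]) / (a @ a) * a
        else:
            raise ValueError(f"unknown reference {reference!r}")
        Sa[:, i] = a
        if np.ptp(dom) > 1e-12 and np.any(h[:, i] > 0):
            Sd[:, i] = dom
            has_dom[i] = True
        else:
            warnings.warn(
                f"locus {table.locus_labels[i]}: no heterozygote signal, "
                "dominance column dropped",
                stacklevel=2,
            )
    return DesignMatrix(Sa, Sd, has_dom, list(table.locus_labels), reference)


@dataclass
class QtlFit:
    """Shared return contract of the genotype-phenotype fits."""

    model: str
    mu: float
    alpha: np.ndarray
    delta: np.ndarray  # zero where no dominance column
    params: pd.DataFrame  # name, estimate, se, p, p_bonferroni (NaN if n/a)
    rss: float
    tss: float
    k: int  # mean-structure parameter count
    n: int
    aic: float
    r2: float
    eps: float | None = None  # constant-eps multilinear
    eps_se: float | None = None
    eps_matrix: np.ndarray | None = None  # per-pair multilinear
    eps_matrix_se: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "mu": float(self.mu),
            "alpha": [float(v) for v in self.alpha],
            "delta": [float(v) for v in self.delta],
            "rss": float(self.rss),
            "k": int(self.k),
            "n": int(self.n),
            "aic": float(self.aic),
            "r2": float(self.r2),
        }
        if self.eps is not None:
            out["eps"] = float(self.eps)
            out["eps_se"] = float(self.eps_se) if self.eps_se is not None else None
        if self.eps_matrix is not None:
            out["eps_matrix"] = [[float(v) for v in row] for row in self.eps_matrix]
        out["params"] = {
            row["name"]: {
                "estimate": float(row["estimate"]),
                "se": float(row["se"]) if np.isfinite(row["se"]) else None,
            }
            for _, row in self.params.iterrows()
        }
        return out


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """AIC under a Gaussian likelihood: ``n ln(RSS/n) + 2 (k + 1)``.

    ``k`` counts mean-structure parameters; the residual variance adds one.
    A perfect fit (zero RSS) has unbounded Gaussian likelihood.
    """
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2.0 * (k + 1)


def _ols_fit(
    y: np.ndarray, X: np.ndarray, names: list[str], model: str,
    design: DesignMatrix,
) -> QtlFit:
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify offending columns by incremental rank
        bad, r = [], 0
        for c in range(k):
            rc = np.linalg.matrix_rank(X[:, : c + 1])
            if rc == r:
                bad.append(names[c])
            r = rc
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    pvals = np.asarray(res.pvalues, dtype=float)
    # Bonferroni across interaction terms only
    inter = np.array([("[" in nm and ":" in nm) for nm in names])
    padj = np.full(k, np.nan)
    m = int(inter.sum())
    if m:
        padj[inter] = np.minimum(pvals[inter] * m, 1.0)
    table = pd.DataFrame(
        {
            "name": names,
            "estimate": np.asarray(res.params, dtype=float),
            "se": np.asarray(res.bse, dtype=float),
            "p": pvals,
            "p_bonferroni": padj,
        }
    )
    L = design.n_loci
    alpha = np.zeros(L)
    delta = np.zeros(L)
    for idx, nm in enumerate(names):
        for i, lab in enumerate(design.locus_labels):
            if nm == f"a[{lab}]":
                alpha[i] = res.params[idx]
            elif nm == f"d[{lab}]":
                delta[i] = res.params[idx]
    return QtlFit(
        model=model,
        mu=float(res.params[0]),
        alpha=alpha,
        delta=delta,
        params=table,
        rss=rss,
        tss=tss,
        k=k,
        n=n,
        aic=aic_gaussian(rss, n, k),
        r2=1.0 - rss / tss if tss > 0 else float("nan"),
    )


def fit_additive(table: GenoPhenoTable, design: DesignMatrix) -> QtlFit:
    """OLS fit with marginal (additive + dominance) effects only."""
    cols, names = design.linear_columns(interactions=False)
    X = np.column_stack([np.ones(table.n_individuals), cols])
    return _ols_fit(table.phenotype, X, ["mu"] + names, "additive", design)


def fit_linear_pairwise(table: GenoPhenoTable, design: DesignMatrix) -> QtlFit:
    """OLS fit with all marginal effects and all pairwise interaction
    effects (additive-by-additive, additive-by-dominance,
    dominance-by-dominance).

    Interaction-effect p-values are reported raw and Bonferroni-adjusted
    across the interaction terms.
    """
    n = table.n_individuals
    cols, names = design.linear_columns(interactions=True)
    if n <= cols.shape[1] + 1:
        raise ValueError("more model columns than individuals")
    X = np.column_stack([np.ones(n), cols])
    return _ols_fit(table.phenotype, X, ["mu"] + names, "pairwise_linear",
                    design)


def _multilinear_predict(
    theta: np.ndarray, design: DesignMatrix, mode: str,
    pair_idx: list[tuple[int, int]],
) -> np.ndarray:
    L = design.n_loci
    mu = theta[0]
    alpha = theta[1 : 1 + L]
    n_dom = int(design.has_dominance.sum())
    delta_free = theta[1 + L : 1 + L + n_dom]
    delta = np.zeros(L)
    delta[design.has_dominance] = delta_free
    y = design.additive * alpha + design.dominance * delta
    pred = mu + y.sum(axis=1)
    if mode == "constant_eps":
        eps_vals = np.full(len(pair_idx), theta[1 + L + n_dom])
    else:
        eps_vals = theta[1 + L + n_dom :]
    for (i, j), e in zip(pair_idx, eps_vals):
        pred = pred + e * y[:, i] * y[:, j]
    return pred


def fit_multilinear(
    table: GenoPhenoTable,
    design: DesignMatrix,
    mode: Literal["constant_eps", "per_pair_eps"] = "constant_eps",
    n_restarts: int = 5,
    seed: int = 0,
) -> QtlFit:
    """Nonlinear least-squares fit of the multilinear model.

    The whole-locus genotypic value ``y_i = alpha_i S_ai + delta_i S_di``
    enters both the marginal sum and the pairwise products, so a single
    eps (or one per pair) governs additive-by-additive, additive-by-
    dominance, and dominance-by-dominance cross-products.  Starting values
    come from the additive OLS fit with eps = 0; on non-convergence the
    start is jittered (seeded) up to ``n_restarts`` times.
    """
    y_obs = table.phenotype
    L = design.n_loci
    n_dom = int(design.has_dominance.sum())
    pair_idx = design.pair_indices()
    if not pair_idx:
        raise ValueError("at least 2 loci are required for an epistasis fit")
    n_eps = 1 if mode == "constant_eps" else len(pair_idx)
    k = 1 + L + n_dom + n_eps
    if table.n_individuals <= k:
        raise ValueError("more parameters than individuals")

    add = fit_additive(table, design)
    x0 = np.concatenate(
        [[add.mu], add.alpha, add.delta[design.has_dominance], np.zeros(n_eps)]
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _multilinear_predict(theta, design, mode, pair_idx) - y_obs

    rng = np.random.default_rng(seed)
    sol = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 * (1 + 0.1 * rng.standard_normal(k))
        cand = least_squares(residuals, start, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if sol is None or cand.cost < sol.cost:
            sol = cand
        if cand.success:
            break
    if not sol.success:
        raise RuntimeError(
            f"multilinear fit failed to converge after {n_restarts} restarts; "
            f"best cost {sol.cost:.6g}, candidate {sol.x}"
        )

    theta = sol.x
    rss = float(np.sum(sol.fun**2))
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    n = table.n_individuals
    # SEs from the Jacobian at the optimum
    J = sol.jac
    sigma2 = rss / max(n - k, 1)
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)

    names = ["mu"] + [f"alpha[{l}]" for l in design.locus_labels]
    names += [f"delta[{l}]" for l, hd in
              zip(design.locus_labels, design.has_dominance) if hd]
    if mode == "constant_eps":
        names += ["eps"]
    else:
        names += [f"eps[{design.locus_labels[i]}:{design.locus_labels[j]}]"
                  for i, j in pair_idx]
    params = pd.DataFrame(
        {"name": names, "estimate": theta, "se": se,
         "p": np.nan, "p_bonferroni": np.nan}
    )

    alpha = theta[1 : 1 + L]
    delta = np.zeros(L)
    delta[design.has_dominance] = theta[1 + L : 1 + L + n_dom]
    fit = QtlFit(
        model=f"multilinear_{mode}",
        mu=float(theta[0]),
        alpha=alpha.copy(),
        delta=delta,
        params=params,
        rss=rss,
        tss=tss,
        k=k,
        n=n,
        aic=aic_gaussian(rss, n, k),
        r2=1.0 - rss / tss if tss > 0 else float("nan"),
    )
    if mode == "constant_eps":
        fit.eps = float(theta[-1])
        fit.eps_se = float(se[-1])
    else:
        em = np.zeros((L, L))
        es = np.zeros((L, L))
        for (i, j), e, s in zip(pair_idx, theta[1 + L + n_dom :],
                                se[1 + L + n_dom :]):
            em[i, j] = em[j, i] = e
            es[i, j] = es[j, i] = s
        fit.eps_matrix = em
        fit.eps_matrix_se = es
    return fit


def additive_variances(fit: QtlFit, design: DesignMatrix) -> np.ndarray:
    """Empirical per-locus additive variances V_Ai = Var(alpha_i S_ai).

    The variance is taken over individuals, i.e. under the observed
    genotype distribution; these are the weights of the composite
    directional-epistasis coefficient.
    """
    contrib = design.additive * fit.alpha
    return np.var(contrib, axis=0)


def composite_from_fit(fit: QtlFit, design: DesignMatrix) -> float:
    """Composite eps_c from a per-pair multilinear fit."""
    if fit.eps_matrix is None:
        raise ValueError("composite epsilon requires a per-pair fit")
    return composite_epsilon(fit.eps_matrix, additive_variances(fit, design))


def compare_models(fits: Sequence[QtlFit]) -> pd.DataFrame:
    """AIC comparison table across fits of the same data.

    Returns one row per model with RSS, parameter count, AIC, delta-AIC
    relative to the best model, and R^2.
    """
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits were not computed on the same number of individuals")
    rows = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.k for f in fits],
            "rss": [f.rss for f in fits],
            "aic": [f.aic for f in fits],
            "r2": [f.r2 for f in fits],
        }
    )
    rows["delta_aic"] = rows["aic"] - rows["aic"].min()
    return rows.sort_values("aic", ignore_index=True)
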