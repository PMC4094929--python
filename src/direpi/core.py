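"""Multilinear genotype-phenotype model and directional-epistasis summaries.

The multilinear model expresses the phenotype of a genotype as a reference
value plus per-locus genotypic effects, with pairwise epistatic deviations
proportional to the product of the interacting effects:

    z = z_R + sum_i y_i + sum_{i<j} y_i y_j eps_ij

The proportionality coefficients ``eps_ij`` (units: inverse trait units)
quantify the strength and direction of epistasis: positive values mean that
effects reinforce each other toward high phenotypes (synergy), negative
values mean antagonism.  The model is linear in each single ``y_i`` holding
the background fixed, hence "multilinear".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MultilinearMap",
    "EpsilonSummary",
    "evaluate_map",
    "epistatic_factor",
    "f_scale",
    "local_epsilon",
    "composite_epsilon",
    "UndefinedEpsilonError",
]

#: below this magnitude a first partial derivative is treated as vanishing,
#: making the derivative-ratio epsilon undefined (trait units per genotypic unit)
DERIVATIVE_TOLERANCE = 1e-10

#: default relative step for central differences
DEFAULT_FD_STEP = 1e-4


class UndefinedEpsilonError(ValueError):
    """Raised when an epsilon coefficient is not defined (vanishing
    derivative or all-zero variance weights)."""


def _symmetrize_check(eps: np.ndarray) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 2 or eps.shape[0] != eps.shape[1]:
        raise ValueError("epsilon must be a square matrix")
    off = ~np.eye(eps.shape[0], dtype=bool)
    if not np.allclose(eps[off], eps.T[off], rtol=0, atol=1e-12):
        raise ValueError("epsilon matrix must be symmetric off the diagonal")
    return eps


@dataclass
class MultilinearMap:
    """A multilinear genotype-phenotype map.

    Parameters
    ----------
    reference_phenotype:
        Phenotype of the reference genotype (all ``y_i = 0``), trait units.
    locus_effects:
        Reference effects of the genotypes of interest at each locus,
        trait units.  Used as the default evaluation point.
    epsilon:
        Symmetric matrix of pairwise directional-epistasis coefficients,
        inverse trait units.  The diagonal is ignored.
    """

    reference_phenotype: float
    locus_effects: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.locus_effects = np.asarray(self.locus_effects, dtype=float)
        self.epsilon = _symmetrize_check(self.epsilon)
        if self.epsilon.shape[0] != self.locus_effects.shape[0]:
            raise ValueError("epsilon dimension must match number of loci")

    @property
    def n_loci(self) -> int:
        return self.locus_effects.shape[0]

    def __call__(self, y: Sequence[float] | None = None) -> float:
        return evaluate_map(self, self.locus_effects if y is None else y)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        n = self.n_loci
        tri = [float(self.epsilon[i, j]) for i in range(n) for j in range(i)]
        return {
            "reference": float(self.reference_phenotype),
            "effects": [float(v) for v in self.locus_effects],
            "epsilon": tri,  # dense lower triangle, row by row
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultilinearMap":
        effects = np.asarray(d["effects"], dtype=float)
        n = effects.shape[0]
        eps = np.zeros((n, n))
        tri = list(d["epsilon"])
        if len(tri) != n * (n - 1) // 2:
            raise ValueError("epsilon triangle length inconsistent with loci")
        k = 0
        for i in range(n):
            for j in range(i):
                eps[i, j] = eps[j, i] = tri[k]
                k += 1
        return cls(float(d["reference"]), effects, eps)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MultilinearMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EpsilonSummary:
    """Pairwise epsilon estimates with their additive-variance weights and
    the resulting composite coefficient."""

    eps_matrix: np.ndarray
    va: np.ndarray
    eps_composite: float = field(init=False)

    def __post_init__(self) -> None:
        self.eps_matrix = _symmetrize_check(self.eps_matrix)
        self.va = np.asarray(self.va, dtype=float)
        if np.any(self.va < 0):
            raise ValueError("additive variances must be non-negative")
        self.eps_composite = composite_epsilon(self.eps_matrix, self.va)


def evaluate_map(map: MultilinearMap, y: Sequence[float]) -> float:
    """Evaluate the multilinear map at genotypic values ``y``.

    Returns ``z_R + sum_i y_i + sum_{i<j} y_i y_j eps_ij``.  Only pairwise
    interaction terms are included; higher orders are out of scope of the
    model as used here.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (map.n_loci,):
        raise ValueError(
            f"genotypic values have length {y.shape}, map has {map.n_loci} loci"
        )
    pair = 0.5 * (y @ map.epsilon @ y - np.sum(np.diag(map.epsilon) * y * y))
    return float(map.reference_phenotype + y.sum() + pair)


def epistatic_factor(eps_ij: float, y_other: float) -> float:
    """Multiplicative change of one locus's effect due to its partner.

    ``f = 1 + y_other * eps_ij``; ``f = 1`` means no epistasis, ``f < 1``
    negative (antagonistic), ``f > 1`` positive (synergistic) epistasis.
    """
    return 1.0 + y_other * eps_ij


def f_scale(eps: float, delta_z: float) -> float:
    """Epistatic factor for a phenotype change of ``delta_z`` trait units.

    This converts an epsilon coefficient (inverse trait units) into the
    dimensionless factor by which allelic effects change when the phenotype
    moves by ``delta_z`` (commonly 100 units, giving an "f_100").
    """
    return 1.0 + delta_z * eps


def local_epsilon(
    g: Callable[..., float],
    ref: Sequence[float],
    i: int,
    j: int,
    step: float | None = None,
) -> float:
    """Local directional epistasis of a smooth genotype-phenotype map.

    The pairwise coefficient is the ratio of the mixed second partial
    derivative to the product of the first partials, all evaluated at the
    reference point:  ``eps_ij = D2_ij / (D_i D_j)``.  Derivatives are
    estimated by central differences.

    Parameters
    ----------
    g:
        Callable accepting ``n`` positional genotypic values.
    ref:
        Reference point (length-``n`` sequence).
    i, j:
        Distinct locus indices.
    step:
        Absolute finite-difference step per coordinate; defaults to
        ``1e-4 * max(1, |ref_k|)``.

    Raises
    ------
    UndefinedEpsilonError
        If either first partial derivative vanishes at the reference.
    """
    if i == j:
        raise ValueError("local epsilon requires two distinct loci")
    ref = np.asarray(ref, dtype=float)

    def h(k: int) -> float:
        if step is not None:
            return float(step)
        return DEFAULT_FD_STEP * max(1.0, abs(ref[k]))

    def at(**shifts: float) -> float:
        point = ref.copy()
        for key, delta in shifts.items():
            point[int(key[1:])] += delta
        return float(g(*point))

    hi, hj = h(i), h(j)
    d_i = (at(**{f"k{i}": hi}) - at(**{f"k{i}": -hi})) / (2 * hi)
    d_j = (at(**{f"k{j}": hj}) - at(**{f"k{j}": -hj})) / (2 * hj)
    if abs(d_i) < DERIVATIVE_TOLERANCE or abs(d_j) < DERIVATIVE_TOLERANCE:
        raise UndefinedEpsilonError(
            "first partial derivative vanishes at the reference; "
            "epsilon (a derivative ratio) is undefined"
        )
    d2_ij = (
        at(**{f"k{i}": hi, f"k{j}": hj})
        - at(**{f"k{i}": hi, f"k{j}": -hj})
        - at(**{f"k{i}": -hi, f"k{j}": hj})
        + at(**{f"k{i}": -hi, f"k{j}": -hj})
    ) / (4 * hi * hj)
    return d2_ij / (d_i * d_j)


def composite_epsilon(eps_matrix: np.ndarray, va: Sequence[float]) -> float:
    """Additive-variance-weighted average of pairwise epsilon coefficients.

    ``eps_c = sum_{i != j} V_Ai V_Aj eps_ij / sum_{i != j} V_Ai V_Aj``.
    Summarizes a multidimensional set of interactions in one directional
    coefficient; pairs involving a locus with no additive variance carry
    no weight.
    """
    eps = np.asarray(eps_matrix, dtype=float)
    va = np.asarray(va, dtype=float)
    if np.any(va < 0):
        raise ValueError("additive variances must be non-negative")
    w = np.outer(va, va)
    np.fill_diagonal(w, 0.0)
    total = w.sum()
    if total <= 0 or not math.isfinite(total):
        raise UndefinedEpsilonError(
            "all pairwise variance weights are zero; composite epsilon undefined"
        )
    return float((w * eps).sum() / total)
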