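"""Seeded generators for every estimator's input.

The generative model is the multilinear genotype-phenotype map applied to
diploid, biallelic, unlinked loci: each locus contributes a genotypic value
``y_i = alpha_i * a_i + delta_i * d_i`` (a = dosage - 1, d = +1/2 for
heterozygotes and -1/2 for homozygotes, the idealized-F2 scores), and the
phenotype is

    z = z_R + sum_i y_i + sum_{i<j} eps_ij y_i y_j + environmental noise.

Generators cover: random-mating (Hardy-Weinberg) genotype-phenotype
tables, individual-based bidirectional truncation-selection trajectories,
closed-form selection trajectories with observation noise, and
mutation-count data.  All draws come from a single explicitly seeded
``numpy.random.Generator`` per call; identical configurations give
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mutcount import MutationCountData, PowerFit, power_predict, mutation_score
from .qtl import GenoPhenoTable
from .selection import SelectionSeries, expected_mean

__all__ = [
    "SimConfig",
    "MultilinearGenotypeMap",
    "make_map",
    "simulate_cross",
    "simulate_selection",
    "simulate_trajectory",
    "simulate_mutcount",
]

logger = logging.getLogger("direpi")


@dataclass
class SimConfig:
    """Parameters of the simulated genetic architecture and breeding design.

    Defaults emulate the reference study conditions: four unlinked diploid
    QTLs at intermediate frequency, unit additive effects, no dominance,
    weak positive epistasis, and a moderately sized selected population.
    """

    n_loci: int = 4
    frequencies: np.ndarray | float = 0.5  # "high"-allele frequency per locus
    alpha: np.ndarray | None = None  # additive effects; default: all 1
    delta: np.ndarray | None = None  # dominance effects; default: all 0
    eps: np.ndarray | float = 0.05  # scalar expands to all pairs
    noise_sd: float = 0.5  # environmental sd, trait units
    pop_size: int = 200
    generations: int = 50
    selected_prop: float = 0.2
    seed: int = 0
    reference_phenotype: float = 0.0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        self.frequencies = np.broadcast_to(
            np.asarray(self.frequencies, dtype=float), (self.n_loci,)
        ).copy()
        if np.any((self.frequencies <= 0) | (self.frequencies >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        self.alpha = (np.ones(self.n_loci) if self.alpha is None
                      else np.asarray(self.alpha, dtype=float))
        self.delta = (np.zeros(self.n_loci) if self.delta is None
                      else np.asarray(self.delta, dtype=float))
        if self.alpha.shape != (self.n_loci,) or self.delta.shape != (self.n_loci,):
            raise ValueError("alpha/delta length must equal n_loci")
        if np.isscalar(self.eps) or np.ndim(self.eps) == 0:
            e = np.full((self.n_loci, self.n_loci), float(self.eps))
            np.fill_diagonal(e, 0.0)
            self.eps = e
        else:
            self.eps = np.asarray(self.eps, dtype=float)
            if self.eps.shape != (self.n_loci, self.n_loci):
                raise ValueError("eps matrix shape must be n_loci x n_loci")
        if not 0 < self.selected_prop < 1:
            raise ValueError("selected proportion must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class MultilinearGenotypeMap:
    """Deterministic genotype (dosage) to phenotype map.

    Evaluates the multilinear model on per-locus genotypic values derived
    from allele dosages with idealized-F2 scores.
    """

    reference_phenotype: float
    alpha: np.ndarray
    delta: np.ndarray
    epsilon: np.ndarray  # symmetric, zero diagonal

    @property
    def n_loci(self) -> int:
        return self.alpha.shape[0]

    def genotypic_values(self, dosages: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(dosages, dtype=float))
        a_score = d - 1.0
        het = np.isclose(d, 1.0)
        d_score = np.where(het, 0.5, -0.5)
        return self.alpha * a_score + self.delta * d_score

    def phenotypes(self, dosages: np.ndarray) -> np.ndarray:
        """Noise-free phenotypes for a matrix of dosages (n x loci)."""
        y = self.genotypic_values(dosages)
        e = self.epsilon.copy()
        np.fill_diagonal(e, 0.0)
        pair = 0.5 * np.einsum("ni,ij,nj->n", y, e, y)
        return self.reference_phenotype + y.sum(axis=1) + pair


def make_map(config: SimConfig) -> MultilinearGenotypeMap:
    """Build the generative map from a simulation configuration."""
    eps = np.array(config.eps, dtype=float)
    np.fill_diagonal(eps, 0.0)
    return MultilinearGenotypeMap(
        reference_phenotype=config.reference_phenotype,
        alpha=config.alpha.copy(),
        delta=config.delta.copy(),
        epsilon=eps,
    )


def _draw_genotypes(rng: np.random.Generator, n: int,
                    freqs: np.ndarray) -> np.ndarray:
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)


def simulate_cross(
    map: MultilinearGenotypeMap,
    n: int,
    noise_sd: float,
    frequencies: np.ndarray | float,
    seed: int,
) -> GenoPhenoTable:
    """Genotype-phenotype table with Hardy-Weinberg genotypes at unlinked
    loci and Gaussian environmental noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.broadcast_to(np.asarray(frequencies, dtype=float),
                            (map.n_loci,))
    g = _draw_genotypes(rng, n, freqs)
    z = map.phenotypes(g) + rng.normal(0.0, noise_sd, size=n)
    return GenoPhenoTable(phenotype=z, genotypes=g)


def _mate(rng: np.random.Generator, parents: np.ndarray, n_off: int) -> np.ndarray:
    """Random mating with free recombination: each offspring draws two
    parents (with replacement) that each transmit one allele per locus."""
    n_par = parents.shape[0]
    sire = parents[rng.integers(n_par, size=n_off)]
    dam = parents[rng.integers(n_par, size=n_off)]
    return (rng.binomial(1, sire / 2.0) + rng.binomial(1, dam / 2.0)).astype(float)


def simulate_selection(
    map: MultilinearGenotypeMap, config: SimConfig
) -> tuple[SelectionSeries, SelectionSeries]:
    """Individual-based bidirectional truncation selection.

    Two replicate populations founded from the same configuration are
    selected in opposite directions: each generation individuals are ranked
    by phenotype and the top (up line) or bottom (down line) fraction is
    bred by random mating with free recombination among unlinked loci.
    Returns the two trajectories of population mean phenotypes on a common
    generation grid.
    """
    n_sel = int(round(config.pop_size * config.selected_prop))
    if n_sel < 2:
        raise ValueError("pop_size * selected_prop must be >= 2")
    rng = np.random.default_rng(config.seed)
    series = {}
    for direction, label in ((+1, "up"), (-1, "down")):
        g = _draw_genotypes(rng, config.pop_size, config.frequencies)
        means = []
        for t in range(config.generations + 1):
            z = map.phenotypes(g) + rng.normal(0.0, config.noise_sd,
                                               size=config.pop_size)
            means.append(z.mean())
            order = np.argsort(direction * z)[::-1]
            selected = g[order[:n_sel]]
            g = _mate(rng, selected, config.pop_size)
        fixed = np.ptp(g, axis=0) < 1e-12
        if fixed.all():
            logger.info("%s line: all loci fixed by generation %d",
                        label, config.generations)
        series[label] = SelectionSeries(
            np.arange(config.generations + 1, dtype=float),
            np.array(means),
            line_label=label,
        )
    return series["up"], series["down"]


def simulate_trajectory(
    mu0: float,
    delta0: float,
    eps: float,
    generations: int,
    noise_sd: float,
    seed: int,
) -> SelectionSeries:
    """Closed-form constant-gradient trajectory plus independent Gaussian
    observation noise on each generation mean."""
    t = np.arange(generations + 1, dtype=float)
    mean = np.array([expected_mean(ti, mu0, delta0, eps) for ti in t])
    rng = np.random.default_rng(seed)
    noisy = mean + rng.normal(0.0, noise_sd, size=len(t))
    return SelectionSeries(t, noisy,
                           line_label="up" if delta0 >= 0 else "down")


def simulate_mutcount(
    power: PowerFit,
    n: int,
    n_loci: int,
    noise_sd: float,
    seed: int,
    frequencies: np.ndarray | float = 0.5,
) -> MutationCountData:
    """Mutation-count data: Hardy-Weinberg genotypes scored as signed
    counts of extra "high" alleles, phenotypes from the continuous power
    model plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    freqs = np.broadcast_to(np.asarray(frequencies, dtype=float), (n_loci,))
    g = _draw_genotypes(rng, n, freqs)
    m = mutation_score(g)
    z = power_predict(power, m) + rng.normal(0.0, noise_sd, size=n)
    return MutationCountData(m, z)
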