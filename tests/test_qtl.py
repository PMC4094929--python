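"""Orthogonal genetic design, linear and multilinear fits, AIC comparison."""

import numpy as np
import pytest

from direpi import (
    GenoPhenoTable,
    SimConfig,
    additive_variances,
    aic_gaussian,
    compare_models,
    composite_epsilon,
    composite_from_fit,
    fit_additive,
    fit_linear_pairwise,
    fit_multilinear,
    make_map,
    noia_design,
    simulate_cross,
)


def random_table(rng, n=400, n_loci=3, probs=(0.5, 0.2, 0.3)):
    """Non-HWE genotype table with noise-only phenotypes."""
    g = rng.choice([0.0, 1.0, 2.0], size=(n, n_loci), p=list(probs))
    return GenoPhenoTable(rng.normal(size=n), g)


class TestNoiaDesign:
    def test_f2_theoretical_scores(self):
        table = GenoPhenoTable([0.0, 0.0, 0.0], [[0.0], [1.0], [2.0]])
        design = noia_design(table, "f2_theoretical")
        np.testing.assert_allclose(design.additive[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(design.dominance[:, 0], [-0.5, 0.5, -0.5])

    def test_additive_column_centered(self, rng):
        design = noia_design(random_table(rng))
        assert np.all(np.abs(design.additive.mean(axis=0)) < 1e-12)

    def test_orthogonality_non_hwe(self, rng):
        """Under the observed-frequency reference, additive and dominance
        columns are uncorrelated within each locus even far from
        Hardy-Weinberg proportions."""
        design = noia_design(random_table(rng, probs=(0.6, 0.1, 0.3)))
        for i in range(design.n_loci):
            a, d = design.additive[:, i], design.dominance[:, i]
            assert abs(np.corrcoef(a, d)[0, 1]) < 1e-10
            assert abs(d.mean()) < 1e-12

    def test_monomorphic_locus_error_names_locus(self):
        table = GenoPhenoTable(
            np.zeros(4), np.column_stack([[0, 1, 2, 1], [2, 2, 2, 2]]),
            locus_labels=["ok", "fixed"],
        )
        with pytest.raises(ValueError, match="fixed"):
            noia_design(table)

    def test_no_heterozygotes_drops_dominance(self):
        g = np.column_stack([[0.0, 2, 0, 2, 0, 2], [0, 1, 2, 0, 1, 2]])
        table = GenoPhenoTable(np.zeros(6), g)
        with pytest.warns(UserWarning, match="dominance"):
            design = noia_design(table)
        assert not design.has_dominance[0]
        assert design.has_dominance[1]

    def test_four_loci_have_24_interaction_columns(self, rng):
        design = noia_design(random_table(rng, n_loci=4, probs=(0.25, 0.5, 0.25)))
        _, names = design.linear_columns(interactions=True)
        inter = [n for n in names if ":" in n]
        assert len(inter) == 24
        kinds = {k: sum(n.startswith(k) for n in inter) for k in
                 ("aa", "ad", "da", "dd")}
        assert kinds["aa"] == 6 and kinds["dd"] == 6
        assert kinds["ad"] + kinds["da"] == 12

    def test_expected_dosages_accepted(self, rng):
        g = rng.uniform(0.1, 1.9, size=(100, 2))
        table = GenoPhenoTable(rng.normal(size=100), g)
        design = noia_design(table)
        for i in range(2):
            a, d = design.additive[:, i], design.dominance[:, i]
            assert abs(np.corrcoef(a, d)[0, 1]) < 1e-10


class TestLinearPairwise:
    def test_noiseless_exact_recovery(self, rng):
        """Data generated from the linear model itself is reproduced with
        zero residuals and exact coefficients."""
        table = random_table(rng, n=300, n_loci=2, probs=(0.25, 0.5, 0.25))
        design = noia_design(table)
        cols, names = design.linear_columns(True)
        beta = np.array([5.0, 1.0, -2.0, 0.5, 0.3, 0.7, -0.2, 0.1, 0.4])
        table2 = GenoPhenoTable(
            np.column_stack([np.ones(300), cols]) @ beta, table.genotypes
        )
        fit = fit_linear_pairwise(table2, noia_design(table2))
        assert fit.rss < 1e-8
        np.testing.assert_allclose(fit.params["estimate"], beta, atol=1e-8)

    def test_marginal_estimates_stable_under_interactions(self, rng):
        """Orthogonality: with zero linkage disequilibrium in the sample
        (a factorial F2 table), adding interaction columns leaves the
        additive and dominance estimates unchanged."""
        # full factorial of genotype classes with exact (1, 2, 1) counts
        # per locus: observed frequencies are F2 and sample LD is zero
        classes = [0.0, 1.0, 1.0, 2.0]
        g = np.array([[a, b, c] for a in classes for b in classes
                      for c in classes])
        table = GenoPhenoTable(rng.normal(size=len(g)), g)
        design = noia_design(table)
        add = fit_additive(table, design)
        pair = fit_linear_pairwise(table, design)
        np.testing.assert_allclose(pair.alpha, add.alpha, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(pair.delta, add.delta, rtol=1e-6, atol=1e-8)

    def test_bonferroni_only_on_interactions(self, rng):
        table = random_table(rng, n=200, n_loci=2, probs=(0.25, 0.5, 0.25))
        fit = fit_linear_pairwise(table, noia_design(table))
        inter = fit.params["name"].str.contains(":")
        assert fit.params.loc[~inter, "p_bonferroni"].isna().all()
        assert (fit.params.loc[inter, "p_bonferroni"] >=
                fit.params.loc[inter, "p"]).all()

    def test_rank_deficiency_reported(self, rng):
        g = rng.choice([0.0, 1.0, 2.0], size=(50, 2))
        g = np.column_stack([g, g[:, 0]])  # duplicated locus
        table = GenoPhenoTable(rng.normal(size=50), g)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_pairwise(table, noia_design(table))


class TestMultilinear:
    def test_per_pair_noiseless_exact(self):
        cfg = SimConfig(n_loci=2, eps=0.07, seed=0)
        table = simulate_cross(make_map(cfg), 300, 0.0, 0.5, 4)
        design = noia_design(table, "f2_theoretical")
        fit = fit_multilinear(table, design, "per_pair_eps")
        assert fit.eps_matrix[0, 1] == pytest.approx(0.07, abs=1e-8)
        assert fit.rss < 1e-16

    def test_constant_eps_recovery_with_noise(self):
        cfg = SimConfig(n_loci=4, eps=0.05, seed=0)
        table = simulate_cross(make_map(cfg), 800, 0.3, 0.5, 12)
        design = noia_design(table, "f2_theoretical")
        fit = fit_multilinear(table, design, "constant_eps")
        assert abs(fit.eps - 0.05) < 2 * fit.eps_se

    def test_additive_data_gives_zero_eps_and_additive_rss(self):
        """On noiseless additive data the multilinear fit collapses onto
        the additive model (nested-model identity at eps = 0)."""
        cfg = SimConfig(n_loci=3, eps=0.0, delta=np.array([0.2, -0.1, 0.3]),
                        seed=0)
        table = simulate_cross(make_map(cfg), 400, 0.0, 0.5, 9)
        design = noia_design(table, "f2_theoretical")
        add = fit_additive(table, design)
        ml = fit_multilinear(table, design, "constant_eps")
        assert ml.eps == pytest.approx(0.0, abs=1e-7)
        assert ml.rss == pytest.approx(add.rss, abs=1e-10)

    def test_nesting_rss_ordering(self):
        """RSS(constant eps) >= RSS(per-pair eps) >= RSS(saturated linear)."""
        cfg = SimConfig(n_loci=3, eps=0.08, delta=np.array([0.3, 0.1, -0.2]),
                        seed=0)
        table = simulate_cross(make_map(cfg), 500, 0.4, 0.5, 21)
        design = noia_design(table)
        const = fit_multilinear(table, design, "constant_eps")
        pairs = fit_multilinear(table, design, "per_pair_eps")
        sat = fit_linear_pairwise(table, design)
        assert const.rss >= pairs.rss - 1e-8
        assert pairs.rss >= sat.rss - 1e-8

    def test_dominance_cross_products_share_eps(self):
        """With dominance effects present, one eps governs the products of
        whole-locus genotypic values; generated data is fit exactly."""
        cfg = SimConfig(n_loci=2, eps=0.05, delta=np.array([0.5, -0.4]), seed=0)
        table = simulate_cross(make_map(cfg), 300, 0.0, 0.5, 31)
        design = noia_design(table, "f2_theoretical")
        fit = fit_multilinear(table, design, "constant_eps")
        assert fit.eps == pytest.approx(0.05, abs=1e-8)
        assert fit.rss < 1e-16


class TestVariancesAndComparison:
    def test_additive_variance_half_at_intermediate_frequency(self):
        # scores (-1, 0, 1) with exact (1/4, 1/2, 1/4) genotype counts
        g = np.array([[0.0]] * 1 + [[1.0]] * 2 + [[2.0]] * 1)
        table = GenoPhenoTable(np.zeros(4), g)
        design = noia_design(table)
        fit = fit_additive(table, design)
        fit.alpha = np.array([1.0])
        assert additive_variances(fit, design)[0] == pytest.approx(0.5)

    def test_additive_variance_scaling(self, rng):
        table = random_table(rng, n=200, n_loci=2)
        design = noia_design(table)
        fit = fit_additive(table, design)
        fit.alpha = np.array([1.0, 2.0])
        va = additive_variances(fit, design)
        fit.alpha = np.array([2.0, 4.0])
        np.testing.assert_allclose(additive_variances(fit, design), 4 * va)
        fit.alpha = np.array([0.0, 0.0])
        np.testing.assert_allclose(additive_variances(fit, design), 0.0)

    def test_composite_equals_constant_when_pairs_equal(self, rng):
        """Composite eps_c from a per-pair fit with all eps_ij equal is
        exactly that common value, whatever the variance weights."""
        eps = np.full((3, 3), 0.04)
        np.fill_diagonal(eps, 0.0)
        va = rng.uniform(0.2, 1.5, size=3)
        assert composite_epsilon(eps, va) == pytest.approx(0.04, rel=1e-12)

    def test_composite_from_per_pair_fit(self):
        cfg = SimConfig(n_loci=3, eps=0.06, seed=0)
        table = simulate_cross(make_map(cfg), 500, 0.0, 0.5, 13)
        design = noia_design(table, "f2_theoretical")
        fit = fit_multilinear(table, design, "per_pair_eps")
        assert composite_from_fit(fit, design) == pytest.approx(0.06, abs=1e-6)

    def test_aic_formula_and_delta(self):
        assert aic_gaussian(100.0, 50, 3) == pytest.approx(
            50 * np.log(2.0) + 8.0
        )

    def test_compare_models_identical_and_nested(self, rng):
        table = random_table(rng, n=300, n_loci=2, probs=(0.25, 0.5, 0.25))
        design = noia_design(table)
        a = fit_additive(table, design)
        b = fit_additive(table, design)
        tab = compare_models([a, b])
        assert tab["delta_aic"].max() == pytest.approx(0.0)
        # same RSS, k differing by one => delta AIC = 2
        b.k += 1
        b.aic = aic_gaussian(b.rss, b.n, b.k)
        tab = compare_models([a, b])
        assert tab["delta_aic"].max() == pytest.approx(2.0)

    def test_compare_models_requires_same_n(self, rng):
        t1 = random_table(rng, n=100, n_loci=2)
        t2 = random_table(rng, n=120, n_loci=2)
        f1 = fit_additive(t1, noia_design(t1))
        f2 = fit_additive(t2, noia_design(t2))
        with pytest.raises(ValueError):
            compare_models([f1, f2])


def test_missing_genotypes_dropped():
    g = np.array([[0.0, 1], [1, np.nan], [2, 0], [1, 2], [0, 1]])
    table = GenoPhenoTable(np.arange(5.0), g)
    assert table.n_individuals == 4


def test_out_of_range_dosage_rejected():
    with pytest.raises(ValueError, match=r"\[0, 2\]"):
        GenoPhenoTable([1.0], [[2.5]])
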