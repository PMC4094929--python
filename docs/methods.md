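# Methods

## The multilinear model and its estimators

`direpi` treats directional epistasis as the curvature of the
genotype–phenotype map.  In the multilinear model the phenotype is
`z = z_R + Σ y_i + Σ_{i<j} ε_ij y_i y_j`: exchanging the genotype at one
locus, background fixed, changes the phenotype linearly, and the pairwise
deviation from additivity is proportional to the product of the two
genotypic values.  Only pairwise interaction terms are modelled; third-
and higher-order products are deliberately excluded (they are rarely
estimable and the estimators below are second-order by construction).
For smooth analytic maps `g(y_1, …, y_n)` the same coefficient is the
derivative ratio `ε_ij = (∂²g/∂y_i∂y_j) / (∂g/∂y_i ∂g/∂y_j)` at the
reference point; `local_epsilon` evaluates it by central differences with
step `1e-4 × max(1, |ref|)` per coordinate (maps built from the model are
polynomial, so truncation error is tightly controlled; the default step
recovers stored coefficients to better than 1e-6 relative).  A first
partial below 1e-10 raises an error rather than returning an unbounded
ratio — ε is a ratio of derivatives and is simply undefined there.

The composite coefficient `ε_c` averages the pairwise matrix with weights
`V_Ai V_Aj`, the product of the additive variances the two loci explain.
Pairs involving a locus without additive variance carry no weight, which
makes ε_c invariant to uniform rescaling of the variances and bounded by
the extreme weighted ε_ij.

Because ε has inverse trait units, reports include the dimensionless
factor `f_Δz = 1 + Δz·ε`, the multiplier applied to allelic effects when
the phenotype moves by Δz (Δz = 100 trait units by default, configurable
with `--fscale-delta`; the choice of 100 is conventional, not
structural).

## Selection-response asymmetry

Under a constant selection gradient with weak directional epistasis the
expected mean follows `μ_t = μ_0 − log(1 − 2Δμ₀εt)/2ε`.  The
implementation switches to the second-order Taylor form
`μ_0 + Δμ₀t + εΔμ₀²t²` when `|2Δμ₀εt| < 1e-8` — the two branches agree to
1e-6 relative well before that point, and the handoff avoids the 0/0
limit at ε → 0.  A non-positive log argument raises a trajectory-
divergence error: the constant-gradient model genuinely blows up in
finite time there and no number should be returned.

The estimator takes an up-selected and a down-selected series on a common
generation grid: per-line initial responses are OLS slopes over
generations 0..k (default k = 20, configurable); the pooled |Δμ₀| is the
arithmetic mean of the absolute slopes; the averaged response
`A(t) = ½(up + down)` is regressed on `a₀ + a₁t + ct²`; and
`ε̂ = c/Δμ₀²`.  The intercept and linear terms are retained because
unequal |Δμ₀| between lines leaves a linear residual trend and a₀ absorbs
the founding mean.  Standard errors propagate by the delta method from
the two regressions.  This is the quadratic approximation only: drift,
inbreeding, linkage disequilibrium, canalization and evolving selection
gradients are out of scope (full-likelihood trajectory models exist
elsewhere for that purpose).

## Line-cross analysis

The four-mean model (reference μ = mean F2, additive A, dominance D,
epistasis ε) is

```
P1 = μ − 2A − D + ε(A² + AD + ¼D²)
P2 = μ + 2A − D + ε(A² − AD + ¼D²)
F1 = μ + D + ¼εD²        F2 = μ.
```

Both variants are solved by the same nonlinear least-squares path
(`scipy.optimize.least_squares`, tolerances 1e-12, starting values
μ = F2, A = (P2−P1)/4, D = F1−F2, ε = 0): with dominance the system is
exactly identified and converges to ~zero residuals; without dominance
(D ≡ 0) the three parameters are fit to the four means with equal
weights.  Equal weighting is the natural choice when only means (no
standard errors or population sizes) are supplied.  One code path keeps
near-degenerate inputs (ε ≈ 0, D ≈ 0) on the same well-conditioned route.
Round-trip recovery is exact away from the `|εA| ≈ 1` regime where the
quadratic terms can mimic a sign flip.

## QTL genotype–phenotype fits

Scores follow the orthogonal ("NOIA"-style statistical) construction.
Per locus, the additive score is the dosage centered under the reference
genotype frequencies; the dominance score is the heterozygote contrast
with the intercept and additive directions projected out *under those
same frequencies*.  The projection form is used deliberately instead of a
transcribed closed formula: it pins exactly the property that matters —
zero mean, zero additive–dominance covariance for arbitrary (including
non-Hardy-Weinberg) genotype frequencies — and reproduces the standard
closed-form scores, e.g. (−1, 0, 1) and (−½, ½, −½) at idealized F2
frequencies.  Expected dosages in [0, 2] are accepted as-is; their
heterozygosity defaults to `2d(1 − d/2)` (the value implied by treating
d/2 as an allele frequency) unless explicit heterozygote probabilities
are supplied.  Orthogonality decouples marginal estimates from
interaction terms only when sample linkage disequilibrium is zero; with
random unlinked loci the residual coupling is O(n^-1/2), which the tests
make exact by using factorial tables.

Three model families share one return contract (estimates, SEs, RSS,
parameter count, AIC, R²):

* **additive** — OLS on intercept + additive + dominance columns;
* **pairwise linear** — OLS adding all pairwise products (for four loci:
  6 additive×additive, 12 additive×dominance, 6 dominance×dominance);
  interaction p-values are reported raw and Bonferroni-corrected across
  the interaction terms (Bonferroni because the terms are few and the
  correction should be conservative);
* **multilinear** — nonlinear least squares on
  `μ + Σ y_i + Σ_{i<j} ε_(ij) y_i y_j` with whole-locus genotypic values
  `y_i = α_i S_ai + δ_i S_di`, so a single ε governs the
  additive×additive, additive×dominance and dominance×dominance
  cross-products of a pair — the direct multi-locus reading of the
  multilinear map.  ε is either one constant or one per pair; the
  per-pair matrix feeds ε_c with empirical weights
  `V_Ai = Var(α_i S_ai)`.  Starting values come from the additive OLS fit
  with ε = 0, with up to 5 seeded jittered restarts; SEs come from the
  Jacobian at the optimum.

Note that ε is defined relative to a reference point: a fit under the
observed-frequency reference and a fit under the idealized-F2 reference
estimate slightly different (reference-shifted) coefficients.  Recovery
tests therefore build the design at the generating reference.

AIC is `n·ln(RSS/n) + 2(k+1)` (Gaussian likelihood; the residual
variance counts as a parameter); a zero-RSS fit returns −∞ by
convention.  `compare_models` tabulates ΔAIC relative to the best model
and R² = 1 − RSS/TSS.

## Mutation-count models

`mutation_score` maps a dosage table to `m = Σ(dosage − 1)`, the signed
count of extra "high" alleles relative to the all-heterozygote reference
(so m spans −L..+L for L loci, real-valued under genotype uncertainty).
The continuous power model is evaluated piecewise (the kink at m = 0 is
analytic, not smoothed); in the fit β is parameterized as `exp(log β)`,
which enforces β > 0 and stabilizes the `|m|^{1/β}` branch.  Starting
values: μ = mean phenotype of |m| < 0.5 individuals (grand mean as
fallback), α = OLS slope on m, β = 1.  The quadratic model is linear in
its parameters and solved directly.  Data covering only one sign of m
leaves β weakly identified and triggers a warning.  `drop_extremes`
removes full homozygotes (|m| = L) for leverage checks.  Both models are
deliberately unidimensional and functional: they summarize the average
curvature of the map, not locus-specific interactions.

## Synthetic-data generator

The generator embodies the multilinear map over diploid, biallelic,
unlinked loci with idealized-F2 genotype scores (`a = dosage − 1`,
`d = ±½`), Gaussian environmental noise, and — for the selection
simulator — individual-based truncation selection with random
(hermaphroditic) mating and free recombination, non-overlapping
generations.  Defaults mirror the reference study conditions: four loci
at frequency ½, unit additive effects, no dominance, ε = 0.05, and for
crosses n = 800 individuals, matching the scale of the F2 mapping
population the methods were designed around; selection runs use 200
individuals, 20% selected, 50 generations, noise sd 0.5 trait units.
All draws come from one `numpy.random.Generator` seeded per call —
identical configurations are bit-reproducible.

What the generator does *not* emulate: linkage and LD between loci,
inbreeding, mutation, overlapping generations, natural-selection
mortality, genotyping error beyond simple expected dosages, and
non-Gaussian environmental effects.  Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to these real-data complications.  In particular the
truncation-selection simulator violates the constant-gradient assumption
behind the closed-form trajectory (the gradient depends on the current
variance), which is why trajectory-level recovery is asserted at the 20%
level rather than the few-percent level achievable on closed-form data.

## Problem sizes and numerical conventions

Recovery studies use 100 replicates of n = 800, four-locus crosses for
the multilinear fit and 200 replicates of 50-generation trajectory pairs
for the selection estimator — large enough for stable rate estimates
while keeping the full suite fast.  Solver tolerances are 1e-12
(`least_squares` xtol/ftol/gtol) throughout; orthogonality is asserted at
1e-10, exact algebraic identities at 1e-6–1e-12 depending on
conditioning.  Degenerate inputs fail loudly: monomorphic loci,
vanishing first derivatives, all-zero composite weights, diverging
trajectories and rank-deficient designs all raise typed errors instead of
returning numbers.

## Known limitations

* ε estimates are reference-dependent; comparisons across populations
  require a common reference (the observed-frequency "statistical"
  reference is population-specific by design).
* The line-cross model uses four populations only; backcross designs and
  variance-based tests are not implemented.
* The selection-response estimator is the quadratic approximation; with
  strong epistasis (`Δμ₀εt` approaching 1) it underestimates curvature.
* The f-factor conversion applies to ε-type coefficients (inverse trait
  units); no analogous conversion is defined here for the power or
  quadratic mutation-count exponents.
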