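# Methods

## The model

A multivariate response matrix `X` (n observations × m features, e.g.
spectra in rows) collected under a crossed factorial design is decomposed
additively into per-effect contribution matrices,

    X = M0 + Σ_f Con_f + E ,

where `M0` carries the intercept, each `Con_f` the contribution of a main
effect or two-way interaction `f`, and `E` the residual. Three estimators
are provided:

* **classical ASCA** — cell-mean estimation: a main-effect row is the level
  mean minus the grand mean, an interaction row the cell mean minus both
  level means plus the grand mean. Exact and orthogonal on balanced
  designs; biased (effect norms overestimated) when cell counts differ.
* **ASCA+** — a multivariate general linear model `X = Dβ + E` with
  *deviation* (sum-to-zero) coding: 0/1 for the first α−1 levels of a
  factor, −1 on the reference (last) level; interactions are products of
  main-effect columns. `β` is estimated by ordinary least squares.
* **WE-ASCA** — the same GLM with *weighted-effect* coding: the reference
  level of a factor carries `−n_level/n_reference`, and an interaction
  column for a non-reference pair (p, q) is supported on four cells,
  `+1` at (p,q), `−n_pq/n_pβ` at (p, ref_B), `−n_pq/n_αq` at (ref_A, q) and
  `+n_pq/n_αβ` at (ref_A, ref_B). Every non-intercept column then sums to
  exactly zero over the observations even under unbalance, so level effects
  are deviations from the observation-weighted mean and the intercept
  estimate equals the column means of `X`.

A factor with α levels always occupies α−1 columns and an interaction
(α−1)(β−1) columns, so each effect is uniquely estimable whenever all
modelled cells are non-empty. On balanced designs the weighted-effect and
deviation matrices are entry-wise identical and all three estimators
coincide.

Per-term contributions are obtained by zeroing all other columns
(including the intercept) of the design matrix and multiplying by the full
parameter matrix: `Con_f = D/f β̂`.

### Numerical choices

* Coding weights are built in exact rational arithmetic
  (`fractions.Fraction`) and converted to float once, so printed count
  ratios (−3/4, −2/3, +1/2) are reproduced bit-exactly, and the zero-sum
  property is exact at the rational level.
* OLS is solved by a rank-revealing orthogonal decomposition
  (`numpy.linalg.lstsq`), never by inverting the normal matrix. A
  rank-deficient design raises an "aliased design" error rather than
  silently pseudo-inverting; a minimum-norm solution is available behind an
  explicit flag.
* Reference level = last level of the declared order; level order defaults
  to first appearance in the design table and can be overridden.
* `M0` is the fitted intercept contribution for GLM schemes. Under
  weighted-effect coding this equals the column-mean matrix; under
  deviation coding on unbalanced data it does not — this is a property of
  the coding, not corrected for.
* Factors with a single level, empty modelled cells, and >2-way
  interactions are rejected with explicit errors.

## Variance partitioning

Effect contributions to the overall variance are reported as percentages of
the corrected total sum of squares `‖X − M0‖²` (column-mean `M0`, all
schemes, so numbers are comparable across estimators):

* **Type III** (GLM schemes): `SS(f) = ‖Ê_f‖² − ‖Ê‖²`, where `Ê_f` is the
  residual of the model refit without term `f`'s columns — all other terms
  retained, including an interaction whose main effect was dropped. Type
  III is invariant to term order and agrees with sequential (type I) sums
  of squares on balanced designs.
* **Naive** (classical ASCA and diagnostics): `SS(f) = ‖Con_f‖²`. On
  unbalanced designs the effect matrices are not orthogonal and the
  percentages may sum to more than 100 — the overestimation the
  weighted-effect scheme is designed to reduce. On matched simulations the
  replicate-mean ordering is classical ≥ WE ≥ deviation.

Tiny negative `SS(f)` from round-off is clipped at zero. A response with
zero corrected variance has nothing to partition; all percentages are
defined as 0 in that degenerate case.

## Permutation test

The statistic for term `f` is the Frobenius sum of squares of the first `l`
score columns of the effect's PCA sub-model; with the default `l = "all"`
this equals `‖Con_f‖²`. `N` random whole-row permutations of `X` against
the fixed design are drawn, the decomposition recomputed under the same
scheme, and

    p(f) = #{ SS_r(f) ≥ SS(f) } / N .

The observed dataset is not counted among the permutations, so `p = 0` is
attainable. Because the design is fixed, `Con_f` of a permuted response is
a precomputed n×n linear map applied to the permuted rows, making the loop
a single matrix product per permutation. Permuted statistics equal to the
observed one up to floating round-off (permutations that merely relabel
observations within levels reproduce the observed statistic exactly in
exact arithmetic) are counted on the ≥ side via a relative tolerance of
1e−9; this makes Monte-Carlo p-values agree with exhaustive enumeration at
small n.

Each term uses an independent seeded generator stream. Two calibration
caveats, both verified by simulation: under a fully null design the p-value
is uniform (≈5% of replicates at p ≤ 0.05); when a *different* strong
effect is present, unrestricted row permutation scatters that effect's
variance into the tested term's null distribution, making the test
conservative for null terms. Restricted/within-stratum permutation is
deliberately not implemented.

## PCA sub-models and score plots

Each `Con_f` is summarized by the SVD of the matrix itself — no additional
centering, since weighted-effect contributions are column-centered by
construction (deviation-coded contributions on unbalanced data may not be;
they are left as estimated). An α-level factor's effect matrix has rank at
most α−1, so a two-level factor's PC1 carries 100% of that matrix's
variance. Loading signs follow the convention that each loading vector's
largest-magnitude entry is positive, making scores reproducible across
platforms. Components requested beyond the numerical rank are returned with
exactly zero variance and flagged. Score plots are augmented with the
residual: `(Con_f + E) P_f` scatters observations around the level scores;
group means and 2-sd covariance ellipses (the plotting default, stated on
the plot helper) summarize each level.

## Effect removal and cross-validated classification

A dominant nuisance factor (typically the individual) is removed by
subtracting its weighted-effect contribution, `X_corr = X − Con_nuisance`,
with the decomposition fitted on the rows being corrected. Refitting on the
corrected matrix leaves (numerically) zero variance for the removed term.

Inside leave-one-group-out cross-validation the removal is fitted on the
training rows of each fold only. The held-out group's rows are never
corrected: a new individual's effect is unobservable, so test spectra enter
the classifier untouched. Classifiers: PCA-LDA (linear discriminant on
leading training-set principal components) and PLS-DA (linear discriminant
on partial-least-squares latent variables regressed on one-hot class
targets), both via scikit-learn, evaluated over a component grid
(default 1–20). All projection and discriminant statistics are computed on
training rows only; a per-fold training checksum is exposed so leakage can
be asserted mechanically.

Mean sensitivity is the unweighted mean of per-class recalls within a
fold, averaged over folds; the reproducibility band is the standard
deviation across folds (a pooled-confusion aggregate is also exposed). LDA
uses the SVD solver by default; a ridge/shrinkage variant is available for
degenerate within-class scatter.

## Synthetic data

The generator emulates an unbalanced factorial spectroscopy experiment:
per-cell observation counts are specified directly; all curves (baseline,
effect profiles) are sums of Gaussian peaks with random centers/widths on a
unit feature axis, so rows look spectra-like and smooth. Ground-truth
contributions are constructed inside the column space of the
weighted-effect coded design (`Con_f = BD/f γ_f`), which guarantees the
weighted zero-sum constraint per term and exact identifiability: with zero
noise the decomposition recovers every contribution to machine precision,
so recovery tests measure estimator error, not parameterization mismatch.
Defaults: m = 200 features, i.i.d. Gaussian noise. Not emulated: Raman
baselines, cosmic spikes, wavenumber-correlated noise, instrument drift —
so passing tests demonstrate estimator correctness on well-specified
additive data, not robustness to real-spectra artifacts.

Tests and the acceptance script use small problem sizes chosen as the
package's own defaults for fast, deterministic checks: m between 10 and 50
features, n between 6 and 120 observations, 20 individuals × 6 spectra for
the cross-validation benchmark, 200 replicates for permutation
calibration.

## Known limitations

* Two-way interactions only; no nested designs, no continuous covariates,
  no mixed/random effects, no missing-cell designs.
* Type II sums of squares and response scaling variants are out of scope.
* The permutation test's unrestricted row shuffling is conservative for a
  null term in the presence of other strong effects (see above).
* The classical-ASCA percentage route on unbalanced data is reported via
  the naive norm ratio; the GLM schemes via type III. Both are exposed.
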