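# Methods

## The joint phenotype/metabolome model

Plot-level phenotypes and feature intensities are modelled jointly.
Conditional on the features, the phenotype equation is

    y = X b1 + Z_m M α + Z_g g1 + Z_g l1 + Z_ig i_g1 + Z_il i_l1 + Z_t t1 + e1

and each of the q feature columns m_j follows

    m_j = X β_j + Z_g g_j,2 + Z_g l_j,2 + Z_ig i_g_j,2 + Z_il i_l_j,2
          + Z_t t_j,2 + e_j,2 .

`M` is the plot × feature matrix of centered and scaled intensities, `α`
the regression effects of features on the phenotype
(`α ~ N(0, I σ²_α)`), `g1` the direct genetic effects, and the remaining
terms line, G × E, line × environment, batch and residual effects.  All
genetic terms have covariance proportional to the VanRaden method-1
genomic relationship matrix G; G × E terms use the block-diagonal
`diag(G, …, G)` over the observed location × year environments.  The
feature equations share one common variance set across j (the common
feature-heritability assumption); a per-feature multiplier hook exists to
probe robustness to its violation.  Breeding values are
`a = Σ_j g_j,2 α_j + g1`.

### Two-step prediction

Step 1 fits the phenotype equation with the aggregated metabolomic effect
`u = Mα`, `u ~ N(0, Q σ²_u)`, `Q = MM′/q`, `σ²_u = q σ²_α`.  Step 2 fits
the same genetic/environmental structure to the predicted `û` with
components scaled by `q σ²_α`, treating `û` as an observed response with
homogeneous residual variance (no propagation of step-1 uncertainty).
The predicted breeding value is `â = ĝ₁ + ĝ₂`, asserted exactly at fit
time.

Under common feature variances and fixed components, the two-step result
equals the posterior mean of `a` given (y, M): conditional on the observed
features the posterior over (α, g1) and over the g_j,2 factorises, so
`E[a | y, M] = ĝ₁ + Σ_j α̂_j ĝ_j,2`, and the `σ²_α` scale cancels between
the step-2 covariances and the step-1 `û = M α̂`.  The test suite verifies
this equivalence against an independent effect-space solver (Henderson
equations with explicit covariance inverses plus per-feature BLUPs) to
1e-4 on instances of 12–15 lines.

## REML

Variance components maximise the restricted likelihood of
`V(θ) = Σ_r θ_r Z_r K_r Z_r′ + θ_e I` by average-information iterations
with step-halving; whenever the AI step is non-ascending or the AI matrix
is not positive definite, an EM step (guaranteed ascent) is taken instead.
Components at the floor (1e-10 × var(y)) with a negative score are held
there for the iteration and re-enter whenever their score turns positive,
so boundary estimates are not locked in prematurely.  Convergence:
maximum relative parameter change < 1e-8 or restricted log-likelihood
change < 1e-9, at most 500 iterations; non-convergence is flagged on the
result, not raised.  Fixed effects use cell-means coding over the observed
location × year × trial cells; the restricted likelihood is invariant to
this choice (tested against an equivalent reference-level coding).

BLUP solutions use the marginal-covariance form
`û_r = θ_r K_r Z_r′ V⁻¹ (y − X b̂)`, which needs no inverse of K — the
VanRaden G is singular by construction (centered allele codes sum to
zero), so Henderson-style systems with G⁻¹ are avoided.  Levels without
records (e.g. unphenotyped lines, or plots with features but masked
phenotypes) are predicted through their covariance with observed levels.
All solvers are dense; the intended scale is up to a few thousand plots.

## Relationship matrices

Marker QC keeps markers with observed minor allele frequency above 0.05
and missingness below 0.20 (both computed on observed calls) and sets
surviving missing calls to the heterozygous code.  Allele frequencies for
the G matrix are always recomputed from the supplied line set.  Feature
standardization uses the population standard deviation (denominator n),
which makes the mean diagonal of Q exactly 1; the convention is
configurable (`ddof`), and zero-variance features are dropped with a
logged count.  Any upstream spectral "adjustment" is left to a
user-supplied preprocessing step — the package only centers and scales.

## Synthetic data

The generator draws from the joint model above with known true
parameters, so estimation and validation can be checked against ground
truth.  Trial designs mimic multi-environment barley testing: each year ×
location environment holds randomised complete block trials of 20–45
lines with 3 replicates, a fixed pair of control lines enters every
trial, and batches (samples malted and mashed together) are contiguous
blocks of plots within trials — the batch-to-plot mapping in real data is
not public, so contiguous blocks are a stand-in.  By default each line is
tested in one environment (matching the sparse line allocation of real
breeding data, about 4–5 plots per line); tests and the acceptance script
set `envs_per_line=None` (every line in every environment) where balanced
designs are wanted.  Genotypes are binomial draws at uniform allele
frequencies; an optional Balding-Nichols family structure (default
20 families at fst 0.3 in the simulation studies) creates the
within-cross relatedness of real breeding lines, which is also what makes
the genomic (g) and line (l) components separable in REML.  Group
assignment can follow years to emulate breeding cycles, giving the
within-year relatedness that makes LOLO prediction more accurate than
LOYO.

Default true variances are chosen so the phenotype roughly matches the
estimated structure of malting-quality traits on the unit scale: a
metabolomic variance ratio near 0.5 (σ²_α = 0.004 with ~120 features),
direct heritability ≈ 0.05, feature heritability ≈ 0.25, total variance
≈ 1.  Fixed effects default to zero (a trial-effect hook can inject
them); the simulation targets variance structure, not fixed-effect
recovery.  Defaults are roughly a one-third scale of a 562-line,
2430-plot, 3-year × 2-location data set; the tests use smaller designs
(20–100 lines) chosen as the smallest sizes at which the Monte-Carlo
properties under test are informative.

What the generator does not emulate: real NMR spectra (peak shapes,
chemical-shift correlations between features — simulated features are
conditionally independent given the design), genetic covariance between
the direct effects and the feature effects, and non-additive genetic
effects.  Passing tests therefore show correctness of the estimators
under the stated model, not robustness to these violations.

## Validation

Cross-validation masks one year (LOYO) or one line (LOLO) per fold; folds
partition the plots.  Predictive correlations and dispersion slopes are
computed on validation observations pooled across folds (per-fold LOLO
metrics over 1–6 plots would be unstable), against phenotypes corrected
for trial fixed effects and batch effects from a full-data GBLUP fit.
Scenario "gm" (features kept, phenotypes masked) is evaluated only through
the LR method, never through the predictive correlation, because shared
environmental effects between features and phenotype would inflate that
correlation.  Variance components in cross-validation are either
re-estimated per fold or reused from the full data; the choice is
recorded in every result (full-data reuse is the default in the pipeline,
and the simulation studies fix them at the generative truth, which is the
regime in which the LR slope has expected value 1).  The
Hotelling-Williams t uses the mean-correlation form with n − 3 degrees of
freedom, n being the pooled validation count.  Accuracy projections
divide the scenario-g correlation by the square root of the heritability
of corrected phenotypes (batch and fixed-effect components excluded from
the denominator, consistent with the correction) and add
(1 − accuracy ratio) × accuracy per LR pair; ratios above 1 are clipped
with a warning.

## Numerical choices and limitations

* Variance floor 1e-10 × var(y); singular fixed-effect designs raise in
  REML and fall back to a pseudo-inverse with a warning in BLUP.
* G/Q are symmetrised and checked for positive semidefiniteness
  (tolerance 1e-8 × largest eigenvalue) before factorisation.
* Ties and degenerate inputs: monomorphic marker sets, all-constant
  features, empty masks and single-year LOYO raise explicit errors.
* Not covered: multi-trait models, heterogeneous residual variances,
  pedigree relationships, sparse solvers, Bayesian per-feature
  heritabilities, and alternative G constructions.
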