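# mgblup — metabolomic-genomic prediction of breeding values

`mgblup` implements genomic BLUP (GBLUP) and two-step metabolomic-genomic
BLUP (MGBLUP) for multi-environment plant-breeding trials, aimed at
quantitative geneticists and breeders who want to combine phenotypes,
SNP genotypes and high-dimensional metabolomic features (e.g. binned
NMR intensities measured on malting-barley wort) in one genetic evaluation.
It covers the whole workflow: a synthetic-data generator with known true
parameters, relationship matrices, REML variance components, heritability
decomposition, and validation of predicted breeding values by
cross-validation and the LR method.

## Models

**GBLUP.** Plot records follow the linear mixed model

    y = Xb + Z_g g + Z_g l + Z_ig i_g + Z_il i_l + Z_t t + e

with trial fixed effects `b` (location × year × trial cells), additive
genomic line effects `g ~ N(0, G σ²_g)` (G is VanRaden's method-1
relationship matrix from the SNP codes), non-genomic line effects
`l ~ N(0, I σ²_l)`, additive G × E effects
`i_g ~ N(0, diag(G, …, G) σ²_ig)` over the location × year environments,
line × environment effects `i_l`, malting-batch effects `t`, and residual
`e`.  The breeding value is `ĝ`.

**MGBLUP.** A joint model adds the metabolome as an intermediate layer:
the phenotype equation carries a per-plot metabolomic effect `u = Mα`
(`M` the standardized plot × feature matrix, `α ~ N(0, I σ²_α)`), while
each feature column follows the same genetic/environmental structure as
the phenotype.  Breeding values are `a = Σ_j g_j,2 α_j + g₁`: a
metabolome-mediated part plus a direct part.  Prediction solves two mixed
model systems in succession — step 1 fits the phenotype equation with
`u ~ N(0, Q σ²_u)`, `Q = MM′/q`; step 2 regresses `û` on the genetic and
environmental structure — and returns `â = ĝ₁ + ĝ₂`.  Heritability
decomposes as

    h² = c²_m · h²_m + h²_d

with `c²_m = Q̄σ²_u / σ²_P1` (metabolomic variance ratio),
`h²_m` the common heritability of the feature intensities (from step 2),
and `h²_d = Ḡσ²_g1 / σ²_P1` the direct heritability.

All variance components are estimated by average-information REML with an
EM fallback.  Validation uses leave-one-year-out (LOYO) and
leave-one-line-out (LOLO) schemes; accuracy is the correlation between
predicted breeding values and corrected phenotypes, dispersion the slope of
their regression, and the LR method compares partial- versus whole-data
predictions (accuracy ratios and dispersion slopes) across the data
scenarios g / gm / gp / gmp (genotypes, ± metabolomics, ± phenotypes on the
validation lines).

## Worked example

```python
import numpy as np
from mgblup import (SimulationConfig, simulate_dataset, fit_gblup, fit_mgblup,
                    standardize_features, gblup_heritability,
                    heritability_decomposition, run_cv)

cfg = SimulationConfig(
    n_lines=30, n_markers=150, n_features=60,
    years=("2014", "2015"), locations=("L1",),
    lines_per_trial=(12, 18), envs_per_line=None,
    plots_per_batch=15, seed=42,
)
ds = simulate_dataset(cfg)

gfit = fit_gblup(ds.plots, ds.G)                      # REML + BLUP
M = standardize_features(ds.features)
mfit = fit_mgblup(ds.plots, ds.G, M)                  # two-step MGBLUP

g_rep = gblup_heritability(gfit.vc, ds.G.mean_diag)
m_rep = heritability_decomposition(mfit.vc1, mfit.vc2,
                                   ds.G.mean_diag, mfit.Q.mean_diag)
print(f"GBLUP : sigma2_P = {g_rep.sigma2_P:.3f}  h2 = {g_rep.h2:.2f}")
print(f"MGBLUP: sigma2_P1 = {m_rep.sigma2_P:.3f}  h2_d = {m_rep.h2_d:.2f}  "
      f"c2_m = {m_rep.c2_m:.2f}  h2_m = {m_rep.h2_m:.2f}  h2 = {m_rep.h2:.2f}")

res = run_cv(ds.plots, ds.G, ds.features, "gblup", "LOYO",
             gblup_vc=gfit.vc, mgblup_vc=(mfit.vc1, mfit.vc2))
print(f"LOYO GBLUP: cor = {res.cor:.2f}, reg = {res.reg:.2f}, n = {res.n}")
```

prints

```
GBLUP : sigma2_P = 0.588  h2 = 0.22
MGBLUP: sigma2_P1 = 0.608  h2_d = 0.00  c2_m = 0.35  h2_m = 0.33  h2 = 0.12
LOYO GBLUP: cor = 0.37, reg = 1.10, n = 192
```

The GBLUP genomic heritability (0.22) absorbs both genetic pathways; the
MGBLUP decomposition shows that on these simulated data most of it is
mediated by the metabolome (`c²_m·h²_m ≈ 0.12`) while the direct part is
near zero.  The LOYO correlation (0.37) measures how well breeding values
of one year's plots are predicted from the other year, and a regression
slope near 1 indicates little dispersion bias.

A `mgblup` command-line tool exposes the same pipeline
(`simulate`, `fit`, `cv`, `lr`, `report` subcommands driven by a YAML
config; see `mgblup --help`).

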