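"""GBLUP and two-step metabolomic-genomic BLUP (MGBLUP).

GBLUP fits the six-term structure g(G) + l + ig(blockG) + il + t + e and the
per-line breeding value is the genomic prediction g_hat.

MGBLUP proceeds in two successive mixed-model solves:

* step 1 adds a per-plot metabolomic effect u ~ N(0, Q sigma2_u) to the GBLUP
  structure, where Q = M M'/q over the standardized feature matrix; u is the
  metabolomic effect on the phenotype (u = M alpha in the underlying joint
  model);
* step 2 regresses the predicted u_hat on the same genetic and environmental
  structure, yielding the metabolome-mediated genetic effect g2_hat.

The predicted breeding value is a_hat = g1_hat + g2_hat.  Step 2 treats
u_hat as an observed response with homogeneous residual variance (no
uncertainty propagation from step 1).

Prediction scenarios for cross-validation name the data available on the
validation population: "g" (genotypes only: phenotypes and features of masked
plots removed), "gm" (features kept, phenotypes masked), and "gp"/"gmp"
(whole data).  Feature standardization is computed once per scenario on the
plots whose features are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError
from .lmm import (
    BLUPSolution,
    DesignMatrices,
    VCEstimates,
    blup_solve,
    build_design,
    gblup_spec,
    mgblup1_spec,
    reml_estimate,
)
from .relationships import FeatureMatrix, GMatrix, QMatrix, compute_Q, \
    standardize_features

SCENARIOS_GBLUP = ("g", "gp", "gmp")
SCENARIOS_MGBLUP = ("g", "gm", "gmp", "gp")


@dataclass
class GBLUPFit:
    vc: VCEstimates
    solution: BLUPSolution
    breeding_values: pd.Series
    design: DesignMatrices


@dataclass
class MGBLUPFit:
    vc1: VCEstimates
    solution1: BLUPSolution
    vc2: VCEstimates
    solution2: BLUPSolution
    breeding_values: pd.Series
    design1: DesignMatrices
    design2: DesignMatrices
    Q: QMatrix


def fit_gblup(
    plots: pd.DataFrame,
    G: GMatrix,
    trait: str = "y",
    vc: VCEstimates | None = None,
    **reml_kw,
) -> GBLUPFit:
    """REML (unless ``vc`` is given) then BLUP for the GBLUP model.

    Breeding values g_hat are returned for every line of G, including lines
    without phenotyped plots (predicted through genomic covariance alone).
    """
    design = build_design(plots, gblup_spec(trait), G=G)
    if vc is None:
        vc = reml_estimate(design, **reml_kw)
    solution = blup_solve(design, vc)
    return GBLUPFit(vc, solution, solution.random["g"].rename("breeding_value"),
                    design)


def fit_mgblup(
    plots: pd.DataFrame,
    G: GMatrix,
    M: FeatureMatrix,
    trait: str = "y",
    vc1: VCEstimates | None = None,
    vc2: VCEstimates | None = None,
    **reml_kw,
) -> MGBLUPFit:
    """Two-step MGBLUP; ``M`` must already be standardized.

    Step 1 uses all plots of ``M`` as levels of the metabolomic term, so
    plots whose phenotype is masked but whose features are present receive a
    u_hat through Q-covariance; step 2 then uses every plot with a u_hat.
    The breeding value is a_hat = g1_hat + g2_hat per line.
    """
    if not M.standardized:
        raise DataFormatError("MGBLUP requires a standardized feature matrix")
    Q = compute_Q(M)
    design1 = build_design(plots, mgblup1_spec(trait), G=G, Q=Q)
    if vc1 is None:
        vc1 = reml_estimate(design1, **reml_kw)
    sol1 = blup_solve(design1, vc1)
    uhat = sol1.random["u"]

    df2 = plots[plots["plot"].isin(Q.plot_ids)].copy()
    if df2.empty:
        raise DataFormatError("no design rows match the Q matrix plots")
    df2["_uhat"] = uhat.reindex(df2["plot"]).to_numpy()
    design2 = build_design(df2, gblup_spec("_uhat"), G=G)
    if vc2 is None:
        vc2 = reml_estimate(design2, **reml_kw)
    sol2 = blup_solve(design2, vc2)

    bv = (sol1.random["g"] + sol2.random["g"]).rename("breeding_value")
    # a_hat = g1_hat + g2_hat must hold exactly by construction
    assert np.allclose(
        bv.to_numpy(),
        sol1.random["g"].to_numpy() + sol2.random["g"].to_numpy(),
    )
    return MGBLUPFit(vc1, sol1, vc2, sol2, bv, design1, design2, Q)


def _check_scenario(model_class: str, scenario: str) -> str:
    if model_class == "gblup":
        if scenario not in SCENARIOS_GBLUP:
            raise ConfigurationError(
                f"scenario {scenario!r} is invalid for GBLUP (no metabolomic "
                f"data in the model); choose one of {SCENARIOS_GBLUP}"
            )
        return "gp" if scenario == "gmp" else scenario
    if model_class == "mgblup":
        if scenario not in SCENARIOS_MGBLUP:
            raise ConfigurationError(
                f"scenario {scenario!r} is invalid for MGBLUP"
            )
        return "gmp" if scenario == "gp" else scenario
    raise ConfigurationError(f"unknown model class {model_class!r}")


def predict_scenario(
    plots: pd.DataFrame,
    G: GMatrix,
    features_raw: FeatureMatrix | None,
    model_class: str,
    masked_plots,
    scenario: str,
    trait: str = "y",
    vc: VCEstimates | None = None,
    vc1: VCEstimates | None = None,
    vc2: VCEstimates | None = None,
    **reml_kw,
) -> pd.Series:
    """Predicted breeding values per line under a validation-data scenario.

    * "g": masked plots are excluded from both phenotypes and features, so
      validation lines are reached through G alone;
    * "gm" (MGBLUP only): masked plots keep their feature rows but their
      phenotypes are masked, so their u_hat comes through Q-covariance;
    * "gp"/"gmp": whole data.
    """
    scenario = _check_scenario(model_class, scenario)
    masked = set(masked_plots)
    is_masked = plots["plot"].isin(masked)
    if scenario in ("g", "gm") and (~is_masked).sum() == 0:
        raise DataFormatError("masking removes every phenotyped plot")

    if model_class == "gblup":
        sub = plots if scenario == "gp" else plots[~is_masked]
        return fit_gblup(sub, G, trait, vc=vc, **reml_kw).breeding_values

    if features_raw is None:
        raise ConfigurationError("MGBLUP scenarios require a feature matrix")
    if scenario == "g":
        sub = plots[~is_masked]
        fkeep = ~np.isin(features_raw.plot_ids, list(masked))
        M = standardize_features(
            FeatureMatrix(features_raw.plot_ids[fkeep],
                          features_raw.intensities[fkeep],
                          features_raw.feature_ids)
        )
        fit = fit_mgblup(sub, G, M, trait, vc1=vc1, vc2=vc2, **reml_kw)
    elif scenario == "gm":
        sub = plots.copy()
        sub.loc[is_masked, trait] = np.nan
        M = standardize_features(features_raw)
        fit = fit_mgblup(sub, G, M, trait, vc1=vc1, vc2=vc2, **reml_kw)
    else:  # gmp
        M = standardize_features(features_raw)
        fit = fit_mgblup(plots, G, M, trait, vc1=vc1, vc2=vc2, **reml_kw)
    return fit.breeding_values
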