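"""Cross-validation, the LR method, and accuracy comparisons.

Two schemes split the plots into training (TP) and validation (VP)
populations: leave-one-year-out (LOYO) masks every plot of one year;
leave-one-line-out (LOLO) masks every plot of one line.

Predictive performance is the correlation between predicted breeding values
and phenotypes corrected for the trial fixed effect and the batch effect
(from a full-data GBLUP fit), pooled over VP plots across folds; dispersion
is the slope of the regression of corrected phenotypes on predicted breeding
values.  Scenario "gm" (phenotypes masked, features kept) is never evaluated
through this predictive correlation — only through the LR method — because
environmental effects shared between features and phenotypes make the
correlation an inappropriate accuracy measure there.

The LR method compares predictions from partial (p) and whole (w) data for
the same VP lines: the correlation cor(a_hat_p, a_hat_w) estimates the ratio
of population accuracies, and the slope of the regression of a_hat_w on
a_hat_p estimates dispersion bias (expected value 1).

Differences between two dependent predictive correlations are tested with
the Hotelling-Williams t (n - 3 degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataFormatError, NumericalError
from .lmm import correct_phenotypes
from .models import fit_gblup, predict_scenario

logger = logging.getLogger(__name__)

LR_PAIRS_DEFAULT = (
    ("gblup", "g", "gp"),
    ("mgblup", "g", "gm"),
    ("mgblup", "gm", "gmp"),
    ("mgblup", "g", "gmp"),
)


@dataclass
class FoldSpec:
    scheme: str
    fold_id: str
    masked_plots: frozenset
    scenario: str = "g"

    def __post_init__(self):
        if not self.masked_plots:
            raise ConfigurationError(f"fold {self.fold_id}: empty masked set")


@dataclass
class ValidationMetrics:
    scheme: str
    model_class: str
    trait: str
    cor: float
    reg: float
    n: int
    vc_mode: str
    per_fold: list = field(default_factory=list)


@dataclass
class LREstimates:
    scheme: str
    model_class: str
    pair: tuple
    ratio: float
    slope: float
    n: int
    trivial: bool = False


def make_folds(plots: pd.DataFrame, scheme: str) -> list:
    """One fold per year (LOYO) or per line (LOLO); folds partition the plots."""
    if scheme == "LOYO":
        years = sorted(plots["year"].astype(str).unique())
        if len(years) < 2:
            raise ConfigurationError("LOYO requires at least two years")
        units = [("year", y) for y in years]
    elif scheme == "LOLO":
        units = [("line", l) for l in sorted(plots["line"].astype(str).unique())]
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    folds = []
    for col, val in units:
        masked = frozenset(plots.loc[plots[col].astype(str) == val, "plot"])
        folds.append(FoldSpec(scheme=scheme, fold_id=val, masked_plots=masked))
    return folds


def _slope(x: np.ndarray, yv: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    yv = np.asarray(yv, dtype=float)
    vx = np.var(x)
    if vx == 0:
        raise NumericalError("regression slope undefined: zero predictor variance")
    return float(np.cov(x, yv, ddof=1)[0, 1] / np.var(x, ddof=1))


def run_cv(
    plots: pd.DataFrame,
    G,
    features_raw,
    model_class: str,
    scheme: str,
    trait: str = "y",
    gblup_vc=None,
    mgblup_vc: tuple | None = None,
    **reml_kw,
) -> ValidationMetrics:
    """Scenario-g cross-validation pooled over VP plots.

    Per fold, the model is fitted on the TP (masked plots excluded from both
    phenotypes and features), breeding values are predicted for the masked
    lines, and evaluated against the full-data corrected phenotypes.  With
    ``gblup_vc`` / ``mgblup_vc`` given, variance components are reused in
    every fold; otherwise they are re-estimated per fold by REML.
    """
    full_fit = fit_gblup(plots, G, trait, vc=gblup_vc, **reml_kw)
    corrected = correct_phenotypes(full_fit.design, full_fit.solution)
    folds = make_folds(plots, scheme)
    vc_mode = "fixed" if (gblup_vc is not None or mgblup_vc is not None) \
        else "reestimated"
    vc1, vc2 = mgblup_vc if mgblup_vc is not None else (None, None)

    preds, obs = [], []
    per_fold = []
    line_of_plot = plots.set_index("plot")["line"]
    for fold in folds:
        vp = [p for p in fold.masked_plots if p in corrected.index]
        if not vp:
            logger.warning("fold %s skipped: no VP phenotypes", fold.fold_id)
            continue
        bv = predict_scenario(
            plots, G, features_raw, model_class, fold.masked_plots, "g",
            trait=trait, vc=gblup_vc, vc1=vc1, vc2=vc2, **reml_kw,
        )
        fold_pred = bv.reindex(line_of_plot.loc[vp]).to_numpy()
        fold_obs = corrected.loc[vp].to_numpy()
        preds.append(fold_pred)
        obs.append(fold_obs)
        per_fold.append({"fold": fold.fold_id, "n_vp": len(vp)})
    if not preds:
        raise DataFormatError("no validation observations in any fold")
    preds = np.concatenate(preds)
    obs = np.concatenate(obs)
    if preds.size < 3:
        raise DataFormatError("fewer than 3 pooled validation observations")
    cor = float(np.corrcoef(preds, obs)[0, 1])
    reg = _slope(preds, obs)
    return ValidationMetrics(scheme, model_class, trait, cor, reg,
                             int(preds.size), vc_mode, per_fold)


def hotelling_williams(r12: float, r13: float, r23: float, n: int):
    """Two-tailed Hotelling-Williams t-test of H0: rho12 = rho13.

    Tests equality of two dependent correlations sharing variable 1, with
    n - 3 degrees of freedom.  Returns (t, p).
    """
    if n < 4:
        raise ConfigurationError("Hotelling-Williams test requires n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ConfigurationError("correlations must lie in [-1, 1]")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise NumericalError("degenerate (non-PSD) correlation matrix")
    detR = float(np.linalg.det(R))
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * (n - 1) / (n - 3) * detR + rbar**2 * (1.0 - r23) ** 3
    if denom <= 0:
        raise NumericalError("degenerate correlation configuration")
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 3))
    return float(t), p


def run_lr(
    plots: pd.DataFrame,
    G,
    features_raw,
    scheme: str,
    pairs=LR_PAIRS_DEFAULT,
    trait: str = "y",
    gblup_vc=None,
    mgblup_vc: tuple | None = None,
    **reml_kw,
) -> list:
    """LR-method ratios of accuracies and dispersion slopes per scenario pair.

    Each pair is (model_class, partial_scenario, whole_scenario) with the
    partial data nested in the whole data.  Per fold, breeding values for the
    VP lines are predicted under both scenarios; the pooled correlation
    estimates the accuracy ratio and the pooled regression slope of whole on
    partial the dispersion bias.
    """
    folds = make_folds(plots, scheme)
    vc1, vc2 = mgblup_vc if mgblup_vc is not None else (None, None)
    results = []
    for model_class, p_scn, w_scn in pairs:
        trivial = p_scn == w_scn
        if trivial:
            logger.warning("identical scenarios %r: LR ratio is trivially 1",
                           p_scn)
        whole_cache = None
        ap_all, aw_all = [], []
        for fold in folds:
            vp_lines = sorted(
                plots.loc[plots["plot"].isin(fold.masked_plots), "line"].unique()
            )
            if not vp_lines:
                continue
            a_p = predict_scenario(
                plots, G, features_raw, model_class, fold.masked_plots, p_scn,
                trait=trait, vc=gblup_vc, vc1=vc1, vc2=vc2, **reml_kw,
            )
            if w_scn in ("gp", "gmp"):
                if whole_cache is None:
                    whole_cache = predict_scenario(
                        plots, G, features_raw, model_class, fold.masked_plots,
                        w_scn, trait=trait, vc=gblup_vc, vc1=vc1, vc2=vc2,
                        **reml_kw,
                    )
                a_w = whole_cache
            else:
                a_w = predict_scenario(
                    plots, G, features_raw, model_class, fold.masked_plots,
                    w_scn, trait=trait, vc=gblup_vc, vc1=vc1, vc2=vc2,
                    **reml_kw,
                )
            ap_all.append(a_p.loc[vp_lines].to_numpy())
            aw_all.append(a_w.loc[vp_lines].to_numpy())
        ap = np.concatenate(ap_all)
        aw = np.concatenate(aw_all)
        ratio = float(np.corrcoef(ap, aw)[0, 1])
        slope = _slope(ap, aw)
        results.append(
            LREstimates(scheme, model_class, (p_scn, w_scn), ratio, slope,
                        int(ap.size), trivial)
        )
    return results


def corrected_phenotype_heritability(vc, g_bar: float) -> float:
    """Genomic heritability of corrected phenotypes.

    The correction removes the trial fixed effects and the batch effect, so
    the batch component is excluded from the denominator.
    """
    comps = vc.as_dict() if hasattr(vc, "as_dict") else dict(vc)
    denom = (g_bar * comps["g"] + comps["l"] + g_bar * comps["ig"]
             + comps["il"] + comps["e"])
    if denom <= 0:
        raise NumericalError("zero denominator for corrected-phenotype h2")
    return g_bar * comps["g"] / denom


def accuracy_projection(
    cor_g: float,
    h2_corrected: float,
    ratio_g_gm: float | None = None,
    ratio_g_gmp: float | None = None,
) -> dict:
    """Projected accuracies from a scenario-g correlation and LR ratios.

    The baseline accuracy is acc_g = cor_g / sqrt(h2_corrected); each
    projected increase is (1 - ratio) * acc_g.  Ratios above 1 are clipped
    (no projected increase) with a warning.
    """
    if not 0.0 < h2_corrected <= 1.0:
        raise ConfigurationError("h2_corrected must lie in (0, 1]")
    acc_g = cor_g / float(np.sqrt(h2_corrected))
    out = {"acc_g": acc_g}
    for label, ratio in (("gm", ratio_g_gm), ("gmp", ratio_g_gmp)):
        if ratio is None:
            continue
        if ratio > 1.0:
            logger.warning("LR ratio %.3f > 1: projection clipped", ratio)
            ratio = 1.0
        inc = (1.0 - ratio) * acc_g
        out[f"increase_{label}"] = inc
        out[f"acc_{label}"] = acc_g + inc
    return out
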