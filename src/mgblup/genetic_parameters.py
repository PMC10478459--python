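"""Phenotypic variances, relative variance components, and heritability.

Total phenotypic variance is the weighted sum of the variance components,
with G-structured terms weighted by G-bar (the mean diagonal of G), the
metabolomic term by Q-bar, and identity-structured terms by 1:

    GBLUP:    sigma2_P  = Gbar s2_g + s2_l + Gbar s2_ig + s2_il + s2_t + s2_e
    MGBLUP_1: sigma2_P1 = Qbar s2_u + Gbar s2_g1 + s2_l1 + Gbar s2_ig1
                          + s2_il1 + s2_t1 + s2_e1

Heritabilities are at plot level.  For GBLUP, h2 = Gbar s2_g / sigma2_P.
For MGBLUP the decomposition is h2 = c2_m * h2_m + h2_d with the direct
heritability h2_d = Gbar s2_g1 / sigma2_P1, the metabolomic variance ratio
c2_m = Qbar s2_u / sigma2_P1, and the common heritability of feature
intensities h2_m taken from the step-2 components.

Full precision is retained internally; formatted tables round to two
decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError
from .lmm import VCEstimates

logger = logging.getLogger(__name__)

# terms whose variance enters sigma2_P weighted by the mean diagonal of G
_G_WEIGHTED = ("g", "ig")
_Q_WEIGHTED = ("u",)


def _components(vc) -> dict:
    if isinstance(vc, VCEstimates):
        return vc.as_dict()
    return dict(vc)


def _weight(name: str, g_bar: float, q_bar: float | None) -> float:
    base = name.rstrip("12_")
    if base in _G_WEIGHTED:
        return g_bar
    if base in _Q_WEIGHTED:
        if q_bar is None:
            raise ConfigurationError(
                "Q-bar is required when a metabolomic term 'u' is present"
            )
        return q_bar
    return 1.0


def total_phenotypic_variance(vc, g_bar: float, q_bar: float | None = None) -> float:
    """Weighted sum of variance components (see module docstring)."""
    comps = _components(vc)
    return float(sum(_weight(nm, g_bar, q_bar) * v for nm, v in comps.items()))


def relative_variance_components(vc, g_bar: float,
                                 q_bar: float | None = None) -> dict:
    comps = _components(vc)
    total = total_phenotypic_variance(comps, g_bar, q_bar)
    if total <= 0:
        raise NumericalError("total phenotypic variance is not positive")
    return {nm: _weight(nm, g_bar, q_bar) * v / total for nm, v in comps.items()}


@dataclass
class HeritabilityReport:
    model: str
    sigma2_P: float
    h2: float
    rvc: dict = field(default_factory=dict)
    h2_d: float | None = None
    c2_m: float | None = None
    h2_m: float | None = None
    genomic_variance: float | None = None      # Gbar * s2_g (or Gbar * s2_g1)
    metabolomic_variance: float | None = None  # Qbar * s2_u

    def __post_init__(self):
        assert abs(sum(self.rvc.values()) - 1.0) < 1e-10


def gblup_heritability(vc, g_bar: float) -> HeritabilityReport:
    """Plot-level genomic heritability h2 = Gbar s2_g / sigma2_P."""
    comps = _components(vc)
    total = total_phenotypic_variance(comps, g_bar)
    if total <= 0:
        raise NumericalError("total phenotypic variance is not positive")
    rvc = relative_variance_components(comps, g_bar)
    return HeritabilityReport(
        model="GBLUP", sigma2_P=total, h2=rvc["g"], rvc=rvc,
        genomic_variance=g_bar * comps["g"],
    )


def heritability_decomposition(
    step1_vc, step2_vc, g_bar: float, q_bar: float
) -> HeritabilityReport:
    """MGBLUP decomposition h2 = c2_m * h2_m + h2_d.

    ``step1_vc`` holds the phenotype-equation components (including 'u');
    ``step2_vc`` the components of the regression of u_hat on the genetic
    and environmental structure, from which the common feature heritability
    h2_m is computed.
    """
    s1 = _components(step1_vc)
    s2 = _components(step2_vc)
    sigma2_P1 = total_phenotypic_variance(s1, g_bar, q_bar)
    if sigma2_P1 <= 0:
        raise NumericalError("total phenotypic variance sigma2_P1 is not positive")
    rvc = relative_variance_components(s1, g_bar, q_bar)
    h2_d = g_bar * s1["g"] / sigma2_P1
    c2_m = q_bar * s1["u"] / sigma2_P1
    denom2 = total_phenotypic_variance(s2, g_bar)
    if denom2 <= 0:
        raise NumericalError("step-2 total variance is not positive")
    h2_m = g_bar * s2["g"] / denom2
    h2 = c2_m * h2_m + h2_d
    return HeritabilityReport(
        model="MGBLUP", sigma2_P=sigma2_P1, h2=h2, rvc=rvc,
        h2_d=h2_d, c2_m=c2_m, h2_m=h2_m,
        genomic_variance=g_bar * s1["g"],
        metabolomic_variance=q_bar * s1["u"],
    )


def heritability_table(reports: dict) -> pd.DataFrame:
    """Tidy table of heritability reports per trait (two-decimal rounding)."""
    rows = []
    for trait, reps in reports.items():
        for rep in reps if isinstance(reps, (list, tuple)) else [reps]:
            rows.append(
                {
                    "trait": trait,
                    "model": rep.model,
                    "genomic_variance": rep.genomic_variance,
                    "h2_direct" if rep.model == "MGBLUP" else "h2": (
                        rep.h2_d if rep.model == "MGBLUP" else rep.h2
                    ),
                    "metabolomic_variance": rep.metabolomic_variance,
                    "c2_m": rep.c2_m,
                    "total": rep.sigma2_P,
                    "h2_m": rep.h2_m,
                    "h2_combined": rep.h2 if rep.model == "MGBLUP" else None,
                }
            )
    return pd.DataFrame(rows).round(2)


def cv_percent(mean: float, variance: float) -> float:
    """Coefficient of phenotypic variation, 100 * sd / mean."""
    if mean == 0:
        logger.warning("CV undefined for zero mean")
        return float("nan")
    return 100.0 * float(np.sqrt(variance)) / mean


def percent_decrease(old: float, new: float) -> float:
    """Percentage decrease from ``old`` to ``new`` (e.g. variance shrinkage)."""
    if old == 0:
        raise NumericalError("percent decrease undefined for zero baseline")
    return 100.0 * (old - new) / old


def descriptive_stats(plots: pd.DataFrame, trait: str) -> dict:
    """n, mean, sample variance, min, max and CV% for one trait."""
    x = plots[trait].dropna().to_numpy(dtype=float)
    if x.size < 2:
        raise ConfigurationError("descriptive statistics need at least 2 records")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    return {
        "n": int(x.size),
        "mean": mean,
        "variance": var,
        "min": float(x.min()),
        "max": float(x.max()),
        "cv_pct": cv_percent(mean, var),
    }
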