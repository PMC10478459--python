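"""Synthetic multi-environment barley-trial data with known true parameters.

The generator draws from the joint phenotype/metabolome model used for
inference, so every downstream stage has a ground-truth test bed:

* phenotype:  y = u + Z_g g1 + Z_g l1 + Z_ig ig1 + Z_il il1 + Z_t t1 + e1,
  with the metabolome-mediated term u = M alpha, alpha ~ N(0, I sigma2_alpha),
  M the standardized feature matrix;
* features:   m_j = Z_g g_j2 + Z_g l_j2 + Z_ig ig_j2 + Z_il il_j2
  + Z_t t_j2 + e_j2 for each feature j, sharing one common variance set
  (the common-heritability assumption);
* breeding values: a = sum_j g_j2 alpha_j + g1.

Genetic terms (g1, g_j2, and their G x E counterparts) are drawn with
covariance proportional to the realized genomic relationship matrix G.
Fixed trial effects default to zero; a config hook can inject them.

Trial design: each year x location environment holds randomised complete
block trials of ``lines_per_trial`` lines with ``replicates_per_line``
replicates; a fixed set of control lines enters every trial; batches (samples
malted and mashed together) are contiguous blocks of plots within trials.
Default sizes are roughly a one-third scale of a three-year, two-location
breeding data set of a few hundred lines; everything is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError
from .relationships import (
    FeatureMatrix,
    GenotypeMatrix,
    GMatrix,
    compute_G,
    standardize_features,
)

__all__ = [
    "PhenotypeVariances",
    "FeatureVariances",
    "SimulationConfig",
    "TrueValues",
    "SimulatedDataset",
    "simulate_design",
    "simulate_genotypes",
    "simulate_features",
    "simulate_phenotypes",
    "simulate_dataset",
]

# salts for per-stage random streams so each stage is reproducible standalone
_DESIGN_SALT, _GENO_SALT, _FEAT_SALT, _PHENO_SALT = 11, 13, 17, 19


@dataclass
class PhenotypeVariances:
    """True variance components of the phenotype equation.

    ``alpha`` is the per-feature variance of the regression effects of
    standardized feature intensities on the phenotype; the implied
    metabolomic variance is sigma2_u = q * sigma2_alpha.
    """

    alpha: float = 0.004
    g1: float = 0.05
    l1: float = 0.05
    ig1: float = 0.05
    il1: float = 0.05
    t1: float = 0.05
    e1: float = 0.30


@dataclass
class FeatureVariances:
    """Common true variance components shared by every feature column."""

    g2: float = 0.25
    l2: float = 0.10
    ig2: float = 0.10
    il2: float = 0.05
    t2: float = 0.05
    e2: float = 0.45


@dataclass
class SimulationConfig:
    n_lines: int = 240
    n_markers: int = 400
    n_features: int = 120
    years: tuple = ("2014", "2015", "2016")
    locations: tuple = ("L1", "L2")
    lines_per_trial: tuple = (20, 45)
    replicates_per_line: int = 3
    n_control_lines: int = 2
    plots_per_batch: int = 40
    envs_per_line: int | None = 1  # None: every line tested in every env
    allele_freq_range: tuple = (0.05, 0.95)
    true_vc_phenotype: PhenotypeVariances = field(default_factory=PhenotypeVariances)
    true_vc_features: FeatureVariances = field(default_factory=FeatureVariances)
    # optional family structure: lines grouped into families whose allele
    # frequencies drift from the base frequencies with differentiation fst
    n_families: int | None = None
    fst: float = 0.0
    # per-feature multipliers on the common feature variances (robustness hook)
    feature_variance_multipliers: tuple | None = None
    # standard deviation of optional nonzero trial fixed effects
    trial_effects_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def n_envs(self) -> int:
        return len(self.years) * len(self.locations)

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ConfigurationError("n_lines must be at least 2")
        if not self.years or not self.locations:
            raise ConfigurationError("need at least one year and one location")
        lo, hi = self.lines_per_trial
        if lo < 1 or hi < lo:
            raise ConfigurationError("lines_per_trial must satisfy 1 <= lo <= hi")
        if lo > self.n_lines:
            raise ConfigurationError(
                f"impossible design: lines_per_trial lower bound {lo} exceeds "
                f"n_lines {self.n_lines}"
            )
        if self.replicates_per_line < 1:
            raise ConfigurationError("replicates_per_line must be >= 1")
        if not 0 <= self.n_control_lines <= self.n_lines:
            raise ConfigurationError("n_control_lines must be in [0, n_lines]")
        if hi <= self.n_control_lines:
            raise ConfigurationError(
                "lines_per_trial upper bound must exceed n_control_lines"
            )
        if self.plots_per_batch < 1:
            raise ConfigurationError("plots_per_batch must be >= 1")
        flo, fhi = self.allele_freq_range
        if not (0.0 < flo <= fhi < 1.0):
            raise ConfigurationError("allele_freq_range must lie inside (0, 1)")
        if self.envs_per_line is not None and not (
            1 <= self.envs_per_line <= self.n_envs
        ):
            raise ConfigurationError("envs_per_line must be in [1, n_envs] or None")
        for name, vcs in (
            ("phenotype", self.true_vc_phenotype),
            ("features", self.true_vc_features),
        ):
            for k, v in asdict(vcs).items():
                if v < 0:
                    raise ConfigurationError(f"negative {name} variance {k}={v}")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError("fst must be in [0, 1)")
        if self.feature_variance_multipliers is not None and len(
            self.feature_variance_multipliers
        ) != self.n_features:
            raise ConfigurationError(
                "feature_variance_multipliers length must equal n_features"
            )


@dataclass
class TrueValues:
    """Ground-truth effects of a simulated data set."""

    line_ids: np.ndarray
    g_j2: np.ndarray | None = None        # (n_lines, k) genetic feature effects
    alpha: np.ndarray | None = None       # (k_retained,)
    g1: np.ndarray | None = None          # (n_lines,) direct genetic effects
    breeding_values: np.ndarray | None = None  # (n_lines,)
    retained_features: np.ndarray | None = None  # bool mask over k


@dataclass
class SimulatedDataset:
    plots: pd.DataFrame
    genotypes: GenotypeMatrix
    G: GMatrix
    features: FeatureMatrix  # raw, not standardized
    truth: TrueValues
    config: SimulationConfig


def _line_ids(config: SimulationConfig) -> np.ndarray:
    return np.array([f"L{i:04d}" for i in range(config.n_lines)])


def simulate_design(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate the plot-level trial design (phenotypes left empty).

    Every line is tested in ``envs_per_line`` environments (all of them if
    None); within each environment its lines are split into randomised
    complete block trials.  Control lines enter every trial.
    """
    if rng is None:
        rng = np.random.default_rng([_DESIGN_SALT, config.seed])
    lines = _line_ids(config)
    controls = lines[: config.n_control_lines]
    regular = lines[config.n_control_lines:]
    envs = [(y, loc) for y in config.years for loc in config.locations]
    n_env = len(envs)

    env_lines: list[list[str]] = [[] for _ in envs]
    if config.envs_per_line is None:
        for el in env_lines:
            el.extend(regular)
    else:
        for line in regular:
            chosen = rng.choice(n_env, size=config.envs_per_line, replace=False)
            for e in chosen:
                env_lines[e].append(line)

    lo, hi = config.lines_per_trial
    reps = config.replicates_per_line
    rows = []
    plot_counter = 0
    batch_counter = 0
    for (year, loc), el in zip(envs, env_lines):
        if not el and config.n_control_lines == 0:
            continue
        env = f"{loc}:{year}"
        el = list(el)
        rng.shuffle(el)
        cap = max(hi - config.n_control_lines, 1)
        n_trials = max(1, math.ceil(len(el) / cap))
        chunks = [list(c) for c in np.array_split(np.array(el, dtype=object),
                                                  n_trials)]
        for t_idx, chunk in enumerate(chunks):
            trial = f"{year}_{loc}_T{t_idx + 1}"
            trial_lines = list(controls) + chunk
            trial_plots = []
            # randomised complete block: each replicate is one block
            for _rep in range(reps):
                order = list(trial_lines)
                rng.shuffle(order)
                trial_plots.extend(order)
            n_batches = max(1, math.ceil(len(trial_plots) / config.plots_per_batch))
            for i, line in enumerate(trial_plots):
                batch_idx = batch_counter + min(i // config.plots_per_batch,
                                                n_batches - 1)
                rows.append(
                    (
                        f"P{plot_counter:06d}",
                        str(line),
                        str(year),
                        str(loc),
                        env,
                        trial,
                        f"B{batch_idx:05d}",
                        line in controls,
                    )
                )
                plot_counter += 1
            batch_counter += n_batches
    plots = pd.DataFrame(
        rows,
        columns=["plot", "line", "year", "location", "env", "trial", "batch",
                 "is_control"],
    )
    present = set(plots["line"])
    missing = [ln for ln in lines if ln not in present]
    if missing:
        raise ConfigurationError(
            f"design left {len(missing)} lines without any trial (first: "
            f"{missing[0]}); increase envs_per_line or adjust trial sizes"
        )
    return plots


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw line x marker codes by binomial sampling at drawn frequencies.

    With ``groups`` (or ``config.n_families``) and ``fst > 0``, each group's
    allele frequencies drift from the base frequencies under a
    Balding-Nichols model, creating within-group relatedness.
    """
    if config.n_markers < 1:
        raise ConfigurationError("n_markers must be >= 1 (G undefined otherwise)")
    if rng is None:
        rng = np.random.default_rng([_GENO_SALT, config.seed])
    lo, hi = config.allele_freq_range
    m = config.n_markers
    nl = config.n_lines
    p = rng.uniform(lo, hi, size=m)
    if groups is None and config.n_families:
        groups = np.arange(nl) * config.n_families // nl
    if groups is not None and config.fst > 0.0:
        groups = np.asarray(groups)
        codes = np.empty((nl, m))
        a = (1.0 - config.fst) / config.fst
        for g in np.unique(groups):
            pg = rng.beta(p * a, (1.0 - p) * a)
            idx = np.flatnonzero(groups == g)
            codes[idx] = rng.binomial(2, pg, size=(idx.size, m))
        return GenotypeMatrix(_line_ids(config), codes)
    codes = rng.binomial(2, p, size=(nl, m)).astype(float)
    return GenotypeMatrix(_line_ids(config), codes)


def _psd_factor(G: GMatrix, name: str = "G") -> np.ndarray:
    vals, vecs = np.linalg.eigh(G.values)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise DataFormatError(f"matrix {name} is not positive semidefinite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _design_index(plots: pd.DataFrame, line_ids: np.ndarray):
    line_pos = pd.Index(line_ids)
    li = line_pos.get_indexer(plots["line"])
    if (li < 0).any():
        bad = plots.loc[li < 0, "line"].iloc[0]
        raise DataFormatError(f"design line {bad!r} not among simulated lines")
    envs = np.sort(plots["env"].unique())
    ei = pd.Index(envs).get_indexer(plots["env"])
    batches = np.sort(plots["batch"].unique())
    bi = pd.Index(batches).get_indexer(plots["batch"])
    return li, ei, len(envs), bi, len(batches)


def simulate_features(
    plots: pd.DataFrame,
    G: GMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureMatrix, TrueValues]:
    """Draw the raw plot x feature matrix from the feature-side model.

    Each feature column is generated independently with genetic effects
    g_j2 ~ N(0, G sigma2_g2), line, G x E, line x env, batch and residual
    terms; fixed feature means default to zero.  Returns the raw matrix and
    a partially filled :class:`TrueValues` (the genetic feature effects).
    """
    if rng is None:
        rng = np.random.default_rng([_FEAT_SALT, config.seed])
    k = config.n_features
    nl = G.line_ids.size
    li, ei, n_env, bi, n_batch = _design_index(plots, G.line_ids)
    L = _psd_factor(G)
    v = config.true_vc_features
    mult = (
        np.sqrt(np.asarray(config.feature_variance_multipliers, dtype=float))
        if config.feature_variance_multipliers is not None
        else np.ones(k)
    )

    g2 = (L @ rng.standard_normal((nl, k))) * np.sqrt(v.g2)
    l2 = rng.standard_normal((nl, k)) * np.sqrt(v.l2)
    ig2 = np.stack(
        [(L @ rng.standard_normal((nl, k))) * np.sqrt(v.ig2) for _ in range(n_env)]
    )
    il2 = rng.standard_normal((n_env, nl, k)) * np.sqrt(v.il2)
    t2 = rng.standard_normal((n_batch, k)) * np.sqrt(v.t2)
    e2 = rng.standard_normal((len(plots), k)) * np.sqrt(v.e2)

    M = (g2[li] + l2[li] + ig2[ei, li] + il2[ei, li] + t2[bi] + e2) * mult
    features = FeatureMatrix(plots["plot"].to_numpy(), M)
    truth = TrueValues(line_ids=G.line_ids.copy(), g_j2=g2 * mult)
    return features, truth


def simulate_phenotypes(
    plots: pd.DataFrame,
    G: GMatrix,
    features_raw: FeatureMatrix,
    truth: TrueValues,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    trait: str = "y",
) -> tuple[pd.DataFrame, TrueValues]:
    """Assemble phenotypes from the metabolome-mediated and direct pathways.

    The raw feature matrix is standardized internally (same convention as
    the Q-matrix construction) before applying the regression effects alpha.
    Completes ``truth`` with alpha, g1 and the breeding values
    a = sum_j g_j2 alpha_j + g1.
    """
    if rng is None:
        rng = np.random.default_rng([_PHENO_SALT, config.seed])
    if len(plots) != features_raw.plot_ids.size or not np.array_equal(
        plots["plot"].to_numpy(), features_raw.plot_ids
    ):
        raise DataFormatError("design rows and feature matrix plots do not match")
    li, ei, n_env, bi, n_batch = _design_index(plots, G.line_ids)
    nl = G.line_ids.size
    L = _psd_factor(G)
    v = config.true_vc_phenotype

    M_std = standardize_features(features_raw)
    kept = np.isin(features_raw.feature_ids, M_std.feature_ids)
    alpha = rng.standard_normal(M_std.n_features) * np.sqrt(v.alpha)
    u = M_std.intensities @ alpha

    g1 = (L @ rng.standard_normal(nl)) * np.sqrt(v.g1)
    l1 = rng.standard_normal(nl) * np.sqrt(v.l1)
    ig1 = np.stack(
        [(L @ rng.standard_normal(nl)) * np.sqrt(v.ig1) for _ in range(n_env)]
    )
    il1 = rng.standard_normal((n_env, nl)) * np.sqrt(v.il1)
    t1 = rng.standard_normal(n_batch) * np.sqrt(v.t1)
    e1 = rng.standard_normal(len(plots)) * np.sqrt(v.e1)

    y = u + g1[li] + l1[li] + ig1[ei, li] + il1[ei, li] + t1[bi] + e1
    if config.trial_effects_sd > 0.0:
        trials = np.sort(plots["trial"].unique())
        ti = pd.Index(trials).get_indexer(plots["trial"])
        trial_eff = rng.standard_normal(trials.size) * config.trial_effects_sd
        y = y + trial_eff[ti]

    out = plots.copy()
    out[trait] = y
    truth.alpha = alpha
    truth.g1 = g1
    truth.retained_features = kept
    truth.breeding_values = truth.g_j2[:, kept] @ alpha + g1
    return out, truth


def true_variance_components(
    config: SimulationConfig, n_features_retained: int | None = None
):
    """The (step-1, step-2) variance components implied by the true values.

    The metabolomic variance is sigma2_u = q * sigma2_alpha over the q
    retained (standardized) features, and each step-2 component is the
    corresponding common feature variance scaled by q * sigma2_alpha.
    Useful for fixed-variance BLUP runs on simulated data.
    """
    from .lmm import VCEstimates

    q = n_features_retained if n_features_retained is not None \
        else config.n_features
    v = config.true_vc_phenotype
    w = config.true_vc_features
    vc1 = VCEstimates.from_dict({
        "u": q * v.alpha, "g": v.g1, "l": v.l1, "ig": v.ig1,
        "il": v.il1, "t": v.t1, "e": v.e1,
    })
    s = q * v.alpha
    vc2 = VCEstimates.from_dict({
        "g": s * w.g2, "l": s * w.l2, "ig": s * w.ig2,
        "il": s * w.il2, "t": s * w.t2, "e": s * w.e2,
    })
    return vc1, vc2


def true_gblup_components(config: SimulationConfig):
    """GBLUP-model components implied by the config (exact when alpha = 0)."""
    from .lmm import VCEstimates

    v = config.true_vc_phenotype
    return VCEstimates.from_dict({
        "g": v.g1, "l": v.l1, "ig": v.ig1, "il": v.il1, "t": v.t1, "e": v.e1,
    })


def simulate_dataset(config: SimulationConfig, trait: str = "y") -> SimulatedDataset:
    """Full generative pipeline: design, genotypes, G, features, phenotypes."""
    plots = simulate_design(config)
    geno = simulate_genotypes(config)
    G = compute_G(geno)
    features, truth = simulate_features(plots, G, config)
    plots, truth = simulate_phenotypes(plots, G, features, truth, config,
                                       trait=trait)
    return SimulatedDataset(plots, geno, G, features, truth, config)
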