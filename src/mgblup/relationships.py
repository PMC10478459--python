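"""Genomic and metabolomic relationship matrices.

The genomic relationship matrix ``G`` between lines is built from SNP codes
with VanRaden's method 1,

    G = Z Z' / (2 * sum_i p_i (1 - p_i)),   Z = codes - 2 p,

with allele frequencies ``p`` always recomputed from the supplied line set.
Markers pass quality control when their minor allele frequency exceeds
``maf_min`` and their missing-call proportion is below ``max_missing``;
surviving missing genotypes are set to the heterozygous code.

The metabolomic similarity matrix ``Q`` between plots (samples) is built from
the standardized feature matrix ``M`` (per-feature mean 0, standard deviation
1) as ``Q = M M' / q`` with ``q`` the number of retained features.  With the
population standard-deviation convention (denominator ``n``) the mean diagonal
of ``Q`` is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataFormatError, NumericalError

logger = logging.getLogger(__name__)

VALID_CODES = (0.0, 1.0, 2.0)
HET_CODE = 1.0


def _as_str_array(ids) -> np.ndarray:
    return np.asarray(ids, dtype=str)


@dataclass
class GenotypeMatrix:
    """Line x marker additive genotype codes in {0, 1, 2}, NaN = missing."""

    line_ids: np.ndarray
    codes: np.ndarray
    marker_ids: np.ndarray | None = None

    def __post_init__(self):
        self.line_ids = _as_str_array(self.line_ids)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2 or self.codes.shape[0] != self.line_ids.size:
            raise DataFormatError(
                f"genotype codes shape {self.codes.shape} does not match "
                f"{self.line_ids.size} line ids"
            )
        if len(set(self.line_ids)) != self.line_ids.size:
            raise DataFormatError("duplicate line ids in genotype matrix")
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, VALID_CODES).all():
            bad = observed[~np.isin(observed, VALID_CODES)][0]
            raise DataFormatError(f"genotype code {bad!r} outside {{0, 1, 2}}")
        if self.marker_ids is None:
            self.marker_ids = np.array(
                [f"M{i:05d}" for i in range(self.codes.shape[1])]
            )
        else:
            self.marker_ids = _as_str_array(self.marker_ids)

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass
class GMatrix:
    """Symmetric line x line genomic relationship matrix."""

    line_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.line_ids = _as_str_array(self.line_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = self.line_ids.size
        if self.values.shape != (n, n):
            raise DataFormatError("G matrix is not square over the line ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataFormatError("G matrix is not symmetric")

    @property
    def mean_diag(self) -> float:
        """Average diagonal element, the G-bar used in heritability formulas."""
        return float(np.mean(np.diag(self.values)))


@dataclass
class FeatureMatrix:
    """Plot x feature intensity matrix (e.g. binned NMR spectra)."""

    plot_ids: np.ndarray
    intensities: np.ndarray
    feature_ids: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self):
        self.plot_ids = _as_str_array(self.plot_ids)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (
            self.intensities.ndim != 2
            or self.intensities.shape[0] != self.plot_ids.size
        ):
            raise DataFormatError(
                f"feature matrix shape {self.intensities.shape} does not match "
                f"{self.plot_ids.size} plot ids"
            )
        if len(set(self.plot_ids)) != self.plot_ids.size:
            raise DataFormatError("duplicate plot ids in feature matrix")
        if self.feature_ids is None:
            self.feature_ids = np.array(
                [f"F{j:05d}" for j in range(self.intensities.shape[1])]
            )
        else:
            self.feature_ids = _as_str_array(self.feature_ids)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]


@dataclass
class QMatrix:
    """Symmetric plot x plot metabolomic similarity matrix Q = MM'/q."""

    plot_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.plot_ids = _as_str_array(self.plot_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = self.plot_ids.size
        if self.values.shape != (n, n):
            raise DataFormatError("Q matrix is not square over the plot ids")

    @property
    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.values)))


def qc_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
) -> GenotypeMatrix:
    """Filter markers on minor allele frequency and missingness.

    Keeps markers with observed MAF strictly above ``maf_min`` and missing
    proportion strictly below ``max_missing`` (both computed on observed
    calls), then sets the surviving missing calls to the heterozygous code.
    """
    codes = geno.codes
    missing = np.isnan(codes)
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(codes, axis=0) / (2.0 * np.maximum(n_obs, 1))
    maf = np.minimum(freq, 1.0 - freq)
    miss_frac = missing.mean(axis=0)
    keep = (n_obs > 0) & (maf > maf_min) & (miss_frac < max_missing)
    n_maf = int(((maf <= maf_min) | (n_obs == 0)).sum())
    n_miss = int((miss_frac >= max_missing).sum())
    if not keep.any():
        raise DataFormatError(
            f"no markers survive QC ({n_maf} failed MAF <= {maf_min}, "
            f"{n_miss} failed missingness >= {max_missing})"
        )
    out = codes[:, keep].copy()
    out[np.isnan(out)] = HET_CODE
    logger.info(
        "marker QC: %d/%d markers retained (%d low MAF, %d high missingness)",
        keep.sum(), codes.shape[1], n_maf, n_miss,
    )
    return GenotypeMatrix(geno.line_ids, out, geno.marker_ids[keep])


def compute_G(geno: GenotypeMatrix) -> GMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Allele frequencies are taken from the supplied lines themselves.  Raises
    if any code is missing (run :func:`qc_markers` first) or if every marker
    is monomorphic (zero denominator).
    """
    codes = geno.codes
    if np.isnan(codes).any():
        raise DataFormatError("genotypes contain missing codes; run qc_markers first")
    if geno.n_lines < 2:
        raise DataFormatError("G requires at least two lines")
    if geno.n_markers == 0:
        raise DataFormatError("G undefined with zero markers")
    p = codes.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise NumericalError("all markers monomorphic: VanRaden denominator is zero")
    Z = codes - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return GMatrix(geno.line_ids, G)


def standardize_features(
    raw: FeatureMatrix, ddof: int = 0
) -> FeatureMatrix:
    """Center and scale each feature to mean 0, standard deviation 1.

    ``ddof=0`` (population convention, the default) makes the mean diagonal of
    the resulting Q matrix exactly 1.  Zero-variance features are dropped with
    a logged count.  Any upstream "adjustment" preprocessing is the caller's
    responsibility; this function only centers and scales.
    """
    if raw.plot_ids.size < 2:
        raise DataFormatError("standardization requires at least two plots")
    x = raw.intensities
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    keep = sd > 0.0
    if not keep.any():
        raise DataFormatError("all features have zero variance")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance features during standardization",
                    n_dropped)
    std = (x[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        raw.plot_ids, std, raw.feature_ids[keep], standardized=True
    )


def compute_Q(M: FeatureMatrix) -> QMatrix:
    """Metabolomic similarity matrix Q = M M' / q over standardized features."""
    if not M.standardized:
        raise DataFormatError("Q requires a standardized feature matrix")
    q = M.n_features
    if q == 0:
        raise DataFormatError("Q undefined with zero features")
    Q = (M.intensities @ M.intensities.T) / q
    Q = 0.5 * (Q + Q.T)
    return QMatrix(M.plot_ids, Q)
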