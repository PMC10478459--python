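"""Readers and writers for the tab-delimited interchange formats.

Phenotypes: one row per plot with the design factors (plot, line, year,
location, trial, batch) and numeric trait columns.  Genotypes: lines x
markers with cells in {0, 1, 2, NA}.  Features: plots x features.  Square
matrices (G, Q) are written with id headers on both axes.  Simulation
configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError
from .relationships import FeatureMatrix, GenotypeMatrix, GMatrix, QMatrix
from .simulate import FeatureVariances, PhenotypeVariances, SimulationConfig

REQUIRED_PLOT_COLUMNS = ("plot", "line", "year", "location", "trial", "batch")
FACTOR_COLUMNS = REQUIRED_PLOT_COLUMNS + ("env", "is_control")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_PLOT_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"phenotype table missing column {col!r}")
    if df["plot"].duplicated().any():
        dup = df.loc[df["plot"].duplicated(), "plot"].iloc[0]
        raise DataFormatError(f"duplicate plot id {dup!r}")
    if "env" not in df.columns:
        df["env"] = df["location"] + ":" + df["year"]
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].isin(("True", "true", "1"))
    trait_cols = [c for c in df.columns if c not in FACTOR_COLUMNS]
    for col in trait_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & ~df[col].str.upper().isin(
            ("NA", "NAN", "")
        )
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise DataFormatError(
                f"non-numeric value {df.loc[bad.idxmax(), col]!r} in trait "
                f"column {col!r} at file row {row}"
            )
        df[col] = parsed
    return df


def write_phenotypes(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise DataFormatError("genotype table has no marker columns")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw = df.to_numpy()
    observed = ~np.isnan(vals)
    bad = observed & ~np.isin(vals, (0.0, 1.0, 2.0))
    missing_tokens = pd.isna(df) | df.astype(str).apply(
        lambda c: c.str.upper().isin(("NA", "NAN", ""))
    )
    invalid = bad | (np.isnan(vals) & ~missing_tokens.to_numpy())
    if invalid.any():
        i, j = np.argwhere(invalid)[0]
        raise DataFormatError(
            f"invalid genotype code {raw[i, j]!r} for line "
            f"{df.index[i]!r}, marker {df.columns[j]!r}"
        )
    return GenotypeMatrix(df.index.to_numpy(dtype=str), vals,
                          df.columns.to_numpy(dtype=str))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    pd.DataFrame(geno.codes, index=geno.line_ids,
                 columns=geno.marker_ids).to_csv(path, sep="\t", na_rep="NA")


def read_features(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise DataFormatError("feature table has no feature columns")
    return FeatureMatrix(df.index.to_numpy(dtype=str),
                         df.to_numpy(dtype=float),
                         df.columns.to_numpy(dtype=str))


def write_features(features: FeatureMatrix, path) -> None:
    pd.DataFrame(features.intensities, index=features.plot_ids,
                 columns=features.feature_ids).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise DataFormatError("matrix table is not square")
    return df


def write_matrix(ids, values, path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


def write_vc_table(fits: dict, path) -> None:
    """Tidy (model, term, estimate) table of variance components."""
    rows = []
    for model, vc in fits.items():
        for term, val in vc.as_dict().items():
            rows.append({"model": model, "term": term, "estimate": val})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_breeding_values(bvs: dict, path) -> None:
    df = pd.DataFrame(bvs)
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def save_sim_config(config: SimulationConfig, path) -> None:
    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_sim_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key, cls in (("true_vc_phenotype", PhenotypeVariances),
                     ("true_vc_features", FeatureVariances)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    for key in ("years", "locations", "lines_per_trial", "allele_freq_range",
                "feature_variance_multipliers"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
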