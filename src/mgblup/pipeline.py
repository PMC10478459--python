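"""End-to-end analysis pipeline and its run configuration.

A run either simulates a data set from a :class:`SimulationConfig` or loads
phenotype/genotype/feature tables, then performs marker QC, builds G and Q,
fits GBLUP and MGBLUP, and (as configured) runs cross-validation and the LR
method.  Results are tab-delimited tables plus a JSON manifest recording the
configuration, seed, convergence flags and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MgblupError
from .genetic_parameters import (
    descriptive_stats,
    gblup_heritability,
    heritability_decomposition,
    heritability_table,
)
from .io import (
    read_features,
    read_genotypes,
    read_phenotypes,
    write_breeding_values,
    write_phenotypes,
    write_features,
    write_genotypes,
    write_matrix,
    write_vc_table,
)
from .models import fit_gblup, fit_mgblup
from .relationships import compute_G, compute_Q, qc_markers, standardize_features
from .simulate import SimulationConfig, simulate_dataset
from .validation import LR_PAIRS_DEFAULT, run_cv, run_lr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulation`` and the three input paths must be given.
    ``vc_mode`` controls cross-validation variance components: "full_data"
    reuses the full-data REML estimates in every fold (recommended for LOLO
    runtime); "reestimate" refits them per fold.
    """

    simulation: SimulationConfig | None = None
    phenotypes_path: str | None = None
    genotypes_path: str | None = None
    features_path: str | None = None
    trait: str = "y"
    models: tuple = ("gblup", "mgblup")
    schemes: tuple = ()
    run_lr_method: bool = False
    lr_pairs: tuple = LR_PAIRS_DEFAULT
    maf_min: float = 0.05
    max_missing: float = 0.20
    reml_max_iter: int = 500
    reml_rtol: float = 1e-8
    vc_mode: str = "full_data"
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        has_paths = any([self.phenotypes_path, self.genotypes_path,
                         self.features_path])
        if (self.simulation is None) == (not has_paths):
            raise ConfigurationError(
                "exactly one of a simulation config or input data paths "
                "must be provided"
            )
        if has_paths and not (self.phenotypes_path and self.genotypes_path):
            raise ConfigurationError(
                "data runs need at least phenotype and genotype paths"
            )
        if self.vc_mode not in ("full_data", "reestimate"):
            raise ConfigurationError(f"unknown vc_mode {self.vc_mode!r}")
        if not 0.0 <= self.maf_min < 0.5:
            raise ConfigurationError("maf_min must be in [0, 0.5)")
        if not 0.0 < self.max_missing <= 1.0:
            raise ConfigurationError("max_missing must be in (0, 1]")
        for m in self.models:
            if m not in ("gblup", "mgblup"):
                raise ConfigurationError(f"unknown model {m!r}")
        for s in self.schemes:
            if s not in ("LOYO", "LOLO"):
                raise ConfigurationError(f"unknown scheme {s!r}")
        for model, p_scn, w_scn in self.lr_pairs:
            from .models import _check_scenario
            _check_scenario(model, p_scn)
            _check_scenario(model, w_scn)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "simulation" in d and d["simulation"] is not None:
        sim = d["simulation"]
        for key in ("years", "locations", "lines_per_trial",
                    "allele_freq_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        from .simulate import FeatureVariances, PhenotypeVariances
        if isinstance(sim.get("true_vc_phenotype"), dict):
            sim["true_vc_phenotype"] = PhenotypeVariances(**sim["true_vc_phenotype"])
        if isinstance(sim.get("true_vc_features"), dict):
            sim["true_vc_features"] = FeatureVariances(**sim["true_vc_features"])
        d["simulation"] = SimulationConfig(**sim)
    for key in ("models", "schemes"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "lr_pairs" in d:
        d["lr_pairs"] = tuple(tuple(p) for p in d["lr_pairs"])
    cfg = RunConfig(**d)
    cfg.validate()
    return cfg


def _stage(name):
    def wrap(fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except MgblupError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> QC -> matrices -> fits -> CV/LR -> reports."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "vc_mode": config.vc_mode,
        "warnings": [],
        "stages": [],
    }

    if config.simulation is not None:
        sim = _stage("simulate")(simulate_dataset, config.simulation,
                                 config.trait)
        plots, geno, G, features = sim.plots, sim.genotypes, sim.G, sim.features
        write_phenotypes(plots, out / "phenotypes.tsv")
        write_genotypes(geno, out / "genotypes.tsv")
        write_features(features, out / "features.tsv")
        manifest["stages"].append("simulate")
    else:
        plots = _stage("read_phenotypes")(read_phenotypes,
                                          config.phenotypes_path)
        geno = _stage("read_genotypes")(read_genotypes, config.genotypes_path)
        geno = _stage("marker_qc")(qc_markers, geno, config.maf_min,
                                   config.max_missing)
        G = _stage("compute_G")(compute_G, geno)
        features = (
            _stage("read_features")(read_features, config.features_path)
            if config.features_path else None
        )
        manifest["stages"].append("load")
    if config.simulation is not None:
        pass  # simulated genotypes have no missing calls; QC not needed
    write_matrix(G.line_ids, G.values, out / "G.tsv")

    reml_kw = {"max_iter": config.reml_max_iter, "rtol": config.reml_rtol}
    trait = config.trait

    stats_rows = [dict(trait=trait, **descriptive_stats(plots, trait))]
    pd.DataFrame(stats_rows).to_csv(out / "descriptive_stats.tsv", sep="\t",
                                    index=False)

    fits: dict = {}
    bvs: dict = {}
    reports: dict = {trait: []}
    gblup_fit = None
    mgblup_fit = None
    if "gblup" in config.models:
        gblup_fit = _stage("fit_gblup")(fit_gblup, plots, G, trait, **reml_kw)
        fits["GBLUP"] = gblup_fit.vc
        bvs["GBLUP"] = gblup_fit.breeding_values
        reports[trait].append(gblup_heritability(gblup_fit.vc, G.mean_diag))
        manifest["gblup_converged"] = gblup_fit.vc.converged
    if "mgblup" in config.models:
        if features is None:
            raise ConfigurationError("MGBLUP requested but no feature data")
        M = _stage("standardize_features")(standardize_features, features)
        mgblup_fit = _stage("fit_mgblup")(fit_mgblup, plots, G, M, trait,
                                          **reml_kw)
        fits["MGBLUP1"] = mgblup_fit.vc1
        fits["MGBLUP2"] = mgblup_fit.vc2
        bvs["MGBLUP"] = mgblup_fit.breeding_values
        reports[trait].append(
            heritability_decomposition(mgblup_fit.vc1, mgblup_fit.vc2,
                                       G.mean_diag, mgblup_fit.Q.mean_diag)
        )
        manifest["mgblup_converged"] = (mgblup_fit.vc1.converged
                                        and mgblup_fit.vc2.converged)
    if fits:
        write_vc_table(fits, out / "variance_components.tsv")
        write_breeding_values(bvs, out / "breeding_values.tsv")
        heritability_table(reports).to_csv(out / "heritability.tsv", sep="\t",
                                           index=False)

    gblup_vc = gblup_fit.vc if (gblup_fit and config.vc_mode == "full_data") \
        else None
    mgblup_vc = (
        (mgblup_fit.vc1, mgblup_fit.vc2)
        if (mgblup_fit and config.vc_mode == "full_data") else None
    )

    cv_rows = []
    for scheme in config.schemes:
        for model in config.models:
            res = _stage(f"cv_{scheme}_{model}")(
                run_cv, plots, G, features, model, scheme, trait,
                gblup_vc=gblup_vc, mgblup_vc=mgblup_vc, **reml_kw,
            )
            cv_rows.append({
                "trait": trait, "scheme": scheme, "model": model,
                "cor": res.cor, "reg": res.reg, "n": res.n,
                "vc_mode": res.vc_mode,
            })
    if cv_rows:
        pd.DataFrame(cv_rows).to_csv(out / "cross_validation.tsv", sep="\t",
                                     index=False)

    lr_rows = []
    if config.run_lr_method:
        for scheme in config.schemes:
            pairs = [p for p in config.lr_pairs if p[0] in config.models]
            for res in _stage(f"lr_{scheme}")(
                run_lr, plots, G, features, scheme, pairs, trait,
                gblup_vc=gblup_vc, mgblup_vc=mgblup_vc, **reml_kw,
            ):
                lr_rows.append({
                    "trait": trait, "scheme": scheme, "model": res.model_class,
                    "pair": f"{res.pair[0]}/{res.pair[1]}",
                    "ratio": res.ratio, "slope": res.slope, "n": res.n,
                })
    if lr_rows:
        pd.DataFrame(lr_rows).to_csv(out / "lr_method.tsv", sep="\t",
                                     index=False)

    cfg_dict = asdict(config)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest["config"] = json.loads(json.dumps(cfg_dict, default=str))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
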