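import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from _helpers import henderson_mme
from mgblup.errors import DataFormatError
from mgblup.lmm import (
    ModelSpec,
    RandomTerm,
    VCEstimates,
    blup_solve,
    build_design,
    correct_phenotypes,
    gblup_spec,
    reml_estimate,
)
from mgblup.models import fit_gblup
from mgblup.relationships import GMatrix
from mgblup.simulate import (
    PhenotypeVariances,
    SimulationConfig,
    simulate_dataset,
    true_gblup_components,
)


def single_obs_design(y=2.0):
    plots = pd.DataFrame({"plot": ["p1"], "line": ["L1"], "y": [y]})
    spec = ModelSpec("y", fixed=(), random_terms=(RandomTerm("g", "line", "G"),))
    G = GMatrix(["L1"], [[1.0]])
    return build_design(plots, spec, G=G)


class TestBlupClosedForm:
    def test_single_observation(self):
        # y = g + e with unit variances: g_hat = (1 + 1)^-1 * y = 1
        design = single_obs_design(2.0)
        vc = VCEstimates.from_dict({"g": 1.0, "e": 1.0})
        sol = blup_solve(design, vc)
        assert sol.random["g"].iloc[0] == pytest.approx(1.0)

    def test_shrinkage_limit(self):
        design = single_obs_design(2.0)
        vc = VCEstimates.from_dict({"g": 1e-12, "e": 1.0})
        sol = blup_solve(design, vc)
        assert abs(sol.random["g"].iloc[0]) < 1e-9


@pytest.fixture(scope="module")
def tiny():
    """Full six-term design on 5 lines x 2 envs x 3 reps = 30 plots.

    The VanRaden G is singular by construction (centered allele codes), so
    it is blended with a small identity part to make Henderson's equations
    (which need K^-1) well defined; both solution routes use the same K.
    """
    cfg = SimulationConfig(
        n_lines=5, n_markers=120, n_features=10, years=("Y1", "Y2"),
        locations=("A",), lines_per_trial=(3, 5), envs_per_line=None,
        n_control_lines=0, plots_per_batch=8, seed=21,
    )
    ds = simulate_dataset(cfg)
    Gr = GMatrix(ds.G.line_ids,
                 0.95 * ds.G.values + 0.05 * np.eye(ds.G.line_ids.size))
    design = build_design(ds.plots, gblup_spec("y"), G=Gr)
    vc = VCEstimates.from_dict(
        {"g": 0.4, "l": 0.2, "ig": 0.15, "il": 0.1, "t": 0.2, "e": 0.5}
    )
    return design, vc


class TestHendersonOracle:
    def test_blup_matches_mme_solution(self, tiny):
        design, vc = tiny
        sol = blup_solve(design, vc)
        beta, random, _, _ = henderson_mme(design, vc)
        np.testing.assert_allclose(sol.fixed.to_numpy(), beta, atol=1e-6)
        for name, u in random.items():
            np.testing.assert_allclose(sol.random[name].to_numpy(), u,
                                       atol=1e-6)

    def test_mme_residual_small(self, tiny):
        design, vc = tiny
        sol = blup_solve(design, vc)
        _, _, C, rhs = henderson_mme(design, vc)
        x = np.concatenate([sol.fixed.to_numpy()]
                           + [sol.random[t.name].to_numpy()
                              for t in design.terms])
        rel = np.linalg.norm(C @ x - rhs) / np.linalg.norm(rhs)
        assert rel < 1e-8


class TestBuildDesign:
    def test_single_trial_fixed_column_of_ones(self):
        plots = pd.DataFrame({
            "plot": ["a", "b", "c"], "line": ["L1"] * 3,
            "year": ["Y"] * 3, "location": ["A"] * 3, "env": ["A:Y"] * 3,
            "trial": ["T1"] * 3, "batch": ["B1"] * 3, "y": [1.0, 2.0, 3.0],
        })
        G = GMatrix(["L1"], [[1.0]])
        d = build_design(plots, gblup_spec("y"), G=G)
        np.testing.assert_array_equal(d.X, np.ones((3, 1)))
        np.testing.assert_array_equal(
            d.terms[0].Z, np.ones((3, 1))
        )

    def test_envblock_dimensions(self, small_dataset):
        d = build_design(small_dataset.plots, gblup_spec("y"),
                         G=small_dataset.G)
        ig = next(t for t in d.terms if t.name == "ig")
        n_env = small_dataset.plots["env"].nunique()
        nl = small_dataset.G.line_ids.size
        assert ig.Z.shape[1] == n_env * nl
        assert ig.K.shape == (n_env * nl, n_env * nl)
        # block-diagonal: cross-environment blocks are zero
        np.testing.assert_array_equal(ig.K[:nl, nl:2 * nl], 0.0)
        np.testing.assert_allclose(ig.K[:nl, :nl], small_dataset.G.values)

    def test_unknown_line_error(self, small_dataset):
        plots = small_dataset.plots.copy()
        plots.loc[plots.index[0], "line"] = "UNKNOWN"
        with pytest.raises(DataFormatError, match="not present in the G"):
            build_design(plots, gblup_spec("y"), G=small_dataset.G)


class TestREML:
    def test_parameter_recovery_two_components(self):
        # 20 replicate data sets: mean estimate within 3 MC SEs of truth
        spec = ModelSpec("y", fixed=(),
                         random_terms=(RandomTerm("g", "line", "G"),))
        r = np.random.default_rng(5)
        nl, reps = 50, 4
        ests = []
        for _ in range(20):
            codes = r.integers(0, 3, size=(nl, 200)).astype(float)
            from mgblup.relationships import GenotypeMatrix, compute_G
            G = compute_G(GenotypeMatrix([f"L{i}" for i in range(nl)], codes))
            L = np.linalg.cholesky(G.values + 1e-8 * np.eye(nl))
            g = L @ r.standard_normal(nl) * np.sqrt(1.0)
            lines = np.repeat(np.arange(nl), reps)
            y = g[lines] + r.standard_normal(nl * reps)
            plots = pd.DataFrame({
                "plot": [f"p{i}" for i in range(nl * reps)],
                "line": [f"L{i}" for i in lines], "y": y,
            })
            d = build_design(plots, spec, G=G)
            vc = reml_estimate(d)
            ests.append([vc.components["g"], vc.residual])
        ests = np.asarray(ests)
        for k, truth in enumerate([1.0, 1.0]):
            mean = ests[:, k].mean()
            se = ests[:, k].std(ddof=1) / np.sqrt(len(ests))
            assert abs(mean - truth) < 3 * se + 1e-9

    def test_null_signal_drives_genomic_variance_to_floor(self, small_dataset):
        plots = small_dataset.plots.copy()
        plots["y"] = np.random.default_rng(0).standard_normal(len(plots))
        fit = fit_gblup(plots, small_dataset.G)
        assert fit.vc.components["g"] < 0.05 * fit.vc.residual

    def test_row_permutation_invariance(self, small_dataset):
        plots = small_dataset.plots
        d1 = build_design(plots, gblup_spec("y"), G=small_dataset.G)
        shuffled = plots.sample(frac=1.0, random_state=1)
        d2 = build_design(shuffled, gblup_spec("y"), G=small_dataset.G)
        vc1, vc2 = reml_estimate(d1), reml_estimate(d2)
        for k in vc1.as_dict():
            assert vc1.as_dict()[k] == pytest.approx(vc2.as_dict()[k],
                                                     rel=1e-5, abs=1e-10)

    def test_loglik_invariant_to_fixed_effect_constraint(self, tiny):
        design, vc = tiny
        theta = np.array([0.3, 0.2, 0.1, 0.1, 0.2, 0.5])
        import copy
        from mgblup.lmm import _reml_core
        Vrs, _, _ = design.vr_stack()
        ll_cellmeans, _, _ = _reml_core(theta, Vrs, design.X, design.y)
        # intercept + treatment dummies span the same column space
        X2 = design.X.copy()
        X2[:, 0] = 1.0
        ll_reference, _, _ = _reml_core(theta, Vrs, X2, design.y)
        assert ll_cellmeans == pytest.approx(ll_reference, abs=1e-6)

    def test_more_fixed_effects_than_observations_error(self):
        plots = pd.DataFrame({
            "plot": ["a"], "line": ["L1"], "year": ["Y"], "location": ["A"],
            "env": ["A:Y"], "trial": ["T1"], "batch": ["B1"], "y": [1.0],
        })
        G = GMatrix(["L1"], [[1.0]])
        d = build_design(plots, gblup_spec("y"), G=G)
        with pytest.raises(DataFormatError, match="more observations"):
            reml_estimate(d)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_reml_matches_lme4_random_intercept(tmp_path):
    """Cross-check the REML core against lme4 on a random-intercept model."""
    r = np.random.default_rng(42)
    n_groups, reps = 30, 5
    groups = np.repeat(np.arange(n_groups), reps)
    y = r.standard_normal(n_groups)[groups] * 1.3 + r.standard_normal(
        n_groups * reps) * 0.8
    df = pd.DataFrame({"plot": [f"p{i}" for i in range(y.size)],
                       "grp": [f"g{i}" for i in groups], "y": y})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ 1 + (1|grp), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[1], vc$vcov[2], sep="\\n")
    """)
    res = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, check=True)
    var_g_r, var_e_r = (float(v) for v in res.stdout.strip().split())

    spec = ModelSpec("y", fixed=("const",),
                     random_terms=(RandomTerm("grp_eff", "grp"),))
    df["const"] = "1"
    d = build_design(df, spec)
    vc = reml_estimate(d)
    assert vc.components["grp_eff"] == pytest.approx(var_g_r, rel=1e-4)
    assert vc.residual == pytest.approx(var_e_r, rel=1e-4)


class TestCorrectPhenotypes:
    def test_constant_trial_shift_absorbed(self, small_dataset):
        plots = small_dataset.plots
        vc = true_gblup_components(small_dataset.config)
        fit = fit_gblup(plots, small_dataset.G, vc=vc)
        base = correct_phenotypes(fit.design, fit.solution)

        shifted = plots.copy()
        trial = shifted["trial"].iloc[0]
        shifted.loc[shifted["trial"] == trial, "y"] += 7.5
        fit2 = fit_gblup(shifted, small_dataset.G, vc=vc)
        moved = correct_phenotypes(fit2.design, fit2.solution)
        np.testing.assert_allclose(base.to_numpy(), moved.to_numpy(),
                                   atol=1e-8)

    def test_corrected_near_zero_mean_per_trial(self, small_dataset):
        fit = fit_gblup(small_dataset.plots, small_dataset.G,
                        vc=true_gblup_components(small_dataset.config))
        corrected = correct_phenotypes(fit.design, fit.solution)
        sd = small_dataset.plots["y"].std()
        means = corrected.groupby(
            small_dataset.plots.set_index("plot")["trial"]).mean()
        assert means.abs().max() < 0.25 * sd

    def test_missing_batch_term_error(self, small_dataset):
        spec = ModelSpec("y", random_terms=(RandomTerm("g", "line", "G"),))
        d = build_design(small_dataset.plots, spec, G=small_dataset.G)
        vc = VCEstimates.from_dict({"g": 0.3, "e": 0.5})
        sol = blup_solve(d, vc)
        with pytest.raises(DataFormatError, match="batch"):
            correct_phenotypes(d, sol)


def test_unphenotyped_lines_predicted_through_covariance(small_dataset):
    plots = small_dataset.plots
    line0 = plots.loc[~plots["is_control"], "line"].iloc[0]
    sub = plots[plots["line"] != line0]
    fit = fit_gblup(sub, small_dataset.G,
                    vc=true_gblup_components(small_dataset.config))
    assert line0 in fit.breeding_values.index
    assert np.isfinite(fit.breeding_values.loc[line0])
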