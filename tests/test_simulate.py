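import numpy as np
import pandas as pd
import pytest

from mgblup.errors import ConfigurationError, DataFormatError
from mgblup.relationships import compute_G
from mgblup.simulate import (
    FeatureVariances,
    PhenotypeVariances,
    SimulationConfig,
    simulate_dataset,
    simulate_design,
    simulate_features,
    simulate_genotypes,
    simulate_phenotypes,
)


def cfg(**kw):
    base = dict(
        n_lines=20, n_markers=60, n_features=25,
        years=("Y1", "Y2"), locations=("A",),
        lines_per_trial=(8, 12), envs_per_line=None,
        plots_per_batch=10, seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestDesign:
    def test_minimal_design(self):
        c = cfg(n_lines=2, years=("Y1",), locations=("A",),
                lines_per_trial=(2, 2), n_control_lines=0)
        plots = simulate_design(c)
        assert len(plots) == 6  # 2 lines x 3 replicates
        assert plots["trial"].nunique() == 1
        assert plots["env"].nunique() == 1

    def test_six_environments_and_replication(self):
        c = cfg(years=("2014", "2015", "2016"), locations=("A", "B"),
                lines_per_trial=(8, 12))
        plots = simulate_design(c)
        assert plots["env"].nunique() == 6
        envs = {f"{l}:{y}" for y in c.years for l in c.locations}
        assert set(plots["env"]) == envs
        # within each trial every line has the configured replicate count
        reps = plots.groupby(["trial", "line"]).size()
        assert (reps == c.replicates_per_line).all()
        # every line tested somewhere
        assert plots["line"].nunique() == c.n_lines

    def test_controls_in_every_trial(self):
        plots = simulate_design(cfg())
        for _, tdf in plots.groupby("trial"):
            assert {"L0000", "L0001"} <= set(tdf["line"])
            assert tdf.loc[tdf["is_control"], "line"].isin(
                ["L0000", "L0001"]
            ).all()

    def test_batches_nested_in_trials(self):
        plots = simulate_design(cfg())
        assert (plots.groupby("batch")["trial"].nunique() == 1).all()

    def test_impossible_design_errors(self):
        with pytest.raises(ConfigurationError, match="impossible design"):
            cfg(lines_per_trial=(50, 60))

    def test_determinism(self):
        a = simulate_design(cfg())
        b = simulate_design(cfg())
        pd.testing.assert_frame_equal(a, b)

    def test_one_env_per_line(self):
        c = cfg(n_lines=40, years=("Y1", "Y2"), locations=("A", "B"),
                lines_per_trial=(5, 12), envs_per_line=1)
        plots = simulate_design(c)
        regular = plots[~plots["is_control"]]
        assert (regular.groupby("line")["env"].nunique() == 1).all()


class TestGenotypes:
    def test_symmetric_frequency_mean(self):
        c = cfg(n_lines=400, n_markers=200, allele_freq_range=(0.5, 0.5))
        g = simulate_genotypes(c)
        assert g.codes.mean() == pytest.approx(1.0, abs=0.05)

    def test_zero_markers_error(self):
        with pytest.raises(ConfigurationError, match="n_markers"):
            simulate_genotypes(cfg(n_markers=0))

    def test_determinism(self):
        np.testing.assert_array_equal(simulate_genotypes(cfg()).codes,
                                      simulate_genotypes(cfg()).codes)

    def test_family_structure_raises_within_group_relationship(self):
        c = cfg(n_lines=60, n_markers=300, n_families=10, fst=0.3)
        G = compute_G(simulate_genotypes(c)).values
        fam = np.arange(60) * 10 // 60
        same = fam[:, None] == fam[None, :]
        off = ~np.eye(60, dtype=bool)
        assert G[same & off].mean() > G[~same].mean() + 0.1


class TestFeatures:
    def test_plots_sharing_line_env_batch_are_identical_without_residual(self):
        c = cfg(true_vc_features=FeatureVariances(e2=0.0))
        plots = simulate_design(c)
        G = compute_G(simulate_genotypes(c))
        M, _ = simulate_features(plots, G, c)
        key = plots["line"] + plots["env"] + plots["batch"]
        dup = key[key.duplicated(keep=False)]
        grp = dup.groupby(dup).groups
        some = next(iter(grp.values()))
        np.testing.assert_allclose(M.intensities[some[0]],
                                   M.intensities[some[1]], atol=1e-12)

    def test_genetic_moment_across_many_features(self):
        # with only genetic variance, the spread of the per-feature line
        # effects matches Gbar * sigma2_g2 over many features
        c = cfg(n_lines=30, n_features=1500, lines_per_trial=(12, 18),
                true_vc_features=FeatureVariances(
                    g2=0.4, l2=0.0, ig2=0.0, il2=0.0, t2=0.0, e2=0.0))
        plots = simulate_design(c)
        G = compute_G(simulate_genotypes(c))
        _, truth = simulate_features(plots, G, c)
        emp = truth.g_j2.var()
        expect = G.mean_diag * 0.4
        assert emp == pytest.approx(expect, rel=0.1)

    def test_null_model_features_are_iid_noise(self):
        c = cfg(true_vc_features=FeatureVariances(
            g2=0, l2=0, ig2=0, il2=0, t2=0, e2=1.0))
        plots = simulate_design(c)
        G = compute_G(simulate_genotypes(c))
        M, _ = simulate_features(plots, G, c)
        line_means = pd.DataFrame(M.intensities).groupby(
            plots["line"].to_numpy()).mean()
        # between-line variance ~ e2 / n_plots_per_line, far below e2
        assert line_means.to_numpy().var() < 0.3


class TestPhenotypes:
    def test_breeding_value_identity(self, small_dataset):
        t = small_dataset.truth
        recomputed = t.g_j2[:, t.retained_features] @ t.alpha + t.g1
        np.testing.assert_allclose(t.breeding_values, recomputed, atol=1e-12)

    def test_all_variances_zero_gives_zero_phenotype(self):
        c = cfg(true_vc_phenotype=PhenotypeVariances(
            alpha=0, g1=0, l1=0, ig1=0, il1=0, t1=0, e1=0))
        ds = simulate_dataset(c)
        np.testing.assert_allclose(ds.plots["y"], 0.0, atol=1e-12)

    def test_gblup_nested_limit_without_metabolomic_effects(self):
        c = cfg(true_vc_phenotype=PhenotypeVariances(
            alpha=0.0, g1=0.3, l1=0, ig1=0, il1=0, t1=0, e1=0.2))
        ds = simulate_dataset(c)
        np.testing.assert_allclose(ds.truth.breeding_values, ds.truth.g1)

    def test_metabolome_mediated_variance_fraction(self):
        c = cfg(n_lines=40, n_features=100, lines_per_trial=(15, 25), seed=2)
        ds = simulate_dataset(c)
        from mgblup.relationships import standardize_features
        M = standardize_features(ds.features)
        u = M.intensities @ ds.truth.alpha
        v = c.true_vc_phenotype
        q = M.n_features
        sigma2_u = q * v.alpha
        total = (sigma2_u + ds.G.mean_diag * (v.g1 + v.ig1)
                 + v.l1 + v.il1 + v.t1 + v.e1)
        ratio = u.var() / ds.plots["y"].var()
        assert ratio == pytest.approx(sigma2_u / total, rel=0.30)

    def test_dimension_mismatch_error(self, small_dataset):
        c = small_dataset.config
        with pytest.raises(DataFormatError, match="do not match"):
            simulate_phenotypes(small_dataset.plots.iloc[:-1], small_dataset.G,
                                small_dataset.features, small_dataset.truth, c)

    def test_trial_effect_hook(self):
        c = cfg(trial_effects_sd=5.0)
        base = simulate_dataset(cfg(trial_effects_sd=0.0))
        shifted = simulate_dataset(c)
        delta = shifted.plots["y"] - base.plots["y"]
        per_trial = delta.groupby(base.plots["trial"]).agg(["std", "mean"])
        assert (per_trial["std"] < 1e-9).all()  # constant shift within trial
        assert per_trial["mean"].abs().max() > 0.5


def test_full_dataset_determinism():
    a = simulate_dataset(cfg())
    b = simulate_dataset(cfg())
    pd.testing.assert_frame_equal(a.plots, b.plots)
    np.testing.assert_array_equal(a.features.intensities,
                                  b.features.intensities)
    np.testing.assert_array_equal(a.truth.breeding_values,
                                  b.truth.breeding_values)
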