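import numpy as np
import pytest

from phylonb.simulate import (
    ScenarioConfig,
    dataset_from_manifest_row,
    run_grid,
    simulate_dataset,
)


class TestSimulateDataset:
    def test_shapes_and_two_families(self):
        cm, fam, cv, truth = simulate_dataset(ScenarioConfig(100, 250, "over", seed=1))
        assert cm.counts.shape == (250, 100)
        assert fam.n_families == 2
        assert set(np.unique(truth.family)) == {1, 2}
        np.testing.assert_array_equal(cm.totals, np.ones(250))
        assert np.isfinite(truth.phi).all()

    def test_family_means_follow_design(self):
        """Realized family means are near (2, 0) for family 1 and
        (2, +-1) for family 2, each drawn with SD 0.1."""
        reps = [simulate_dataset(ScenarioConfig(20, 10, "over", seed=s))[3] for s in range(40)]
        a1 = np.array([t.mu_alpha_fam for t in reps])
        assert abs(a1.mean() - 2.0) < 0.1
        b_null = np.array([t.mu_beta_fam[0] for t in reps])
        b_eff = np.array([t.mu_beta_fam[1] * t.slope_sign for t in reps])
        assert abs(b_null.mean()) < 0.1
        assert abs(b_eff.mean() - 1.0) < 0.1
        signs = {t.slope_sign for t in reps}
        assert signs == {1, -1}

    def test_skewed_covariate_is_squared(self):
        _, _, cv, truth = simulate_dataset(ScenarioConfig(10, 100, "over", True, seed=9))
        assert (cv.values >= 0).all()
        np.testing.assert_allclose(cv.values, truth.x)

    def test_under_regime_replaces_exact_top_fraction(self):
        n = 73  # ceil(0.2 * 73) = 15
        cm, _, _, truth = simulate_dataset(ScenarioConfig(12, n, "under", seed=4))
        assert truth.replacement_mode in ("mean", "zero")
        per_otu = truth.replaced.sum(axis=0)
        np.testing.assert_array_equal(per_otu, np.full(12, int(np.ceil(0.2 * n))))
        assert np.isnan(truth.phi).all()

    def test_under_regime_zero_mode_inflates_zeros(self):
        for seed in range(10):
            cm, _, _, truth = simulate_dataset(ScenarioConfig(10, 50, "under", seed=seed))
            if truth.replacement_mode == "zero":
                zero_frac = (cm.counts == 0).mean(axis=0)
                assert (zero_frac >= 0.2).all()
                return
        pytest.fail("no zero-replacement dataset in 10 seeds")

    def test_dispersion_regimes_move_variance_mean_ratio(self):
        """Over-dispersed counts exceed Poisson variance on average;
        mean-replaced Poisson counts fall below it.  The under-regime
        check is restricted to null-family OTUs: covariate variation
        makes slope-bearing OTUs marginally over-dispersed even when
        the counts are conditionally Poisson."""
        over_ratios, under_ratios = [], []
        for seed in range(8):
            cm, *_ = simulate_dataset(ScenarioConfig(30, 200, "over", seed=seed))
            v = cm.counts.var(axis=0, ddof=1)
            m = cm.counts.mean(axis=0)
            over_ratios.append(np.mean(v / np.maximum(m, 1e-9)))
            cm2, _, _, t2 = simulate_dataset(ScenarioConfig(30, 200, "under", seed=100 + seed))
            if t2.replacement_mode == "mean":
                nulls = t2.family == 1
                v2 = cm2.counts[:, nulls].var(axis=0, ddof=1)
                m2 = cm2.counts[:, nulls].mean(axis=0)
                under_ratios.append(np.mean(v2 / np.maximum(m2, 1e-9)))
        assert np.mean(over_ratios) > 1.0
        assert under_ratios and np.mean(under_ratios) < 1.0

    def test_intercept_slope_correlation_near_design_value(self):
        resid_a, resid_b = [], []
        for seed in range(30):
            _, _, _, t = simulate_dataset(ScenarioConfig(100, 10, "over", seed=seed))
            resid_a.append(t.alpha - t.mu_alpha_fam[t.family - 1])
            resid_b.append(t.beta - t.mu_beta_fam[t.family - 1])
        r = np.corrcoef(np.concatenate(resid_a), np.concatenate(resid_b))[0, 1]
        assert r == pytest.approx(-0.7, abs=0.05)

    def test_counts_track_generating_mean(self):
        cm, _, _, t = simulate_dataset(ScenarioConfig(50, 500, "over", seed=12))
        expected = np.exp(t.alpha[None, :] + t.x[:, None] * t.beta[None, :]).mean(axis=0)
        ratio = cm.counts.mean(axis=0) / expected
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(10, 50, "sideways")


class TestRunGrid:
    def test_full_grid_bookkeeping(self):
        manifest = run_grid(replicates=100, base_seed=1)
        assert len(manifest) == 1800
        assert manifest["scenario"].nunique() == 18
        skew_per_scenario = manifest.groupby("scenario")["skew_x"].sum()
        assert (skew_per_scenario == 50).all()

    def test_single_replicate_grid(self):
        manifest = run_grid(replicates=1, base_seed=0)
        assert len(manifest) == 18
        assert set(manifest["n_otu"]) == {10, 100, 200}
        assert set(manifest["n_subj"]) == {50, 250, 500}

    def test_manifest_deterministic(self):
        a = run_grid(replicates=5, base_seed=7).to_csv()
        b = run_grid(replicates=5, base_seed=7).to_csv()
        assert a == b

    def test_seeds_below_2_31(self):
        manifest = run_grid(replicates=3, base_seed=123)
        assert (manifest["seed"] >= 0).all() and (manifest["seed"] < 2**31).all()

    def test_row_instantiates_matching_dataset(self):
        manifest = run_grid(replicates=2, base_seed=3)
        row = manifest.iloc[5]
        cm, fam, cv, truth = dataset_from_manifest_row(row)
        assert cm.counts.shape == (row["n_subj"], row["n_otu"])
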