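import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from phylonb.hierarchical import (
    HierarchicalNBRegressor,
    ModelSpec,
    PosteriorFit,
    fit_bhm,
    fit_bhm_nophylo,
    significance_threshold,
    summarize_associations,
)

FAST = dict(chains=2, warmup=150, draws=150, thin=2, seed=5)


@pytest.fixture(scope="module")
def tiny_dataset():
    from phylonb.io import CountMatrix, CovariateVector, FamilyMap

    rng = np.random.default_rng(7)
    n, j = 40, 6
    fam = np.array([0, 0, 0, 1, 1, 1])
    x = rng.normal(0, 1, n)
    alpha = rng.normal(2.0, 0.1, j)
    beta = np.where(fam == 0, 0.0, 0.8) + rng.normal(0, 0.1, j)
    mu = np.exp(alpha + np.outer(x, beta))
    counts = rng.poisson(mu)
    sids = [f"s{i}" for i in range(n)]
    oids = [f"o{k}" for k in range(j)]
    return (
        CountMatrix(sids, oids, counts, totals=np.ones(n, dtype=int)),
        FamilyMap({o: f"fam{f}" for o, f in zip(oids, fam)}),
        CovariateVector(sids, x, name="food"),
        {"beta": beta, "fam": fam},
    )


@pytest.fixture(scope="module")
def small_fit(tiny_dataset):
    """One short 2-chain fit on the tiny two-family dataset."""
    import warnings

    cm, fam, cov, truth = tiny_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_bhm(cm, fam, cov, ModelSpec(**FAST))
    return cm, fam, cov, truth, fit


class TestSignificanceThreshold:
    def test_six_batches(self):
        assert significance_threshold(6) == pytest.approx(2.638257, abs=1e-4)

    def test_one_batch_is_usual_two_sided_five_percent(self):
        assert significance_threshold(1) == pytest.approx(1.959964, abs=1e-4)

    def test_invalid(self):
        with pytest.raises(ValueError):
            significance_threshold(0)


class TestSummarizeAssociations:
    def _degenerate_fit(self, const):
        draws = {"beta": np.full((2, 10, 1), const)}
        summary = pd.DataFrame(
            {"mean": [const], "sd": [0.0], "q2.5": [const], "q97.5": [const],
             "rhat": [1.0], "ess": [20.0]},
            index=pd.Index(["beta[0]"], name="param"),
        )
        return PosteriorFit(
            draws=draws, otu_ids=["o1"], family_names=["f"], family_of_otu=["f"],
            food_item="x", spec=ModelSpec(), summary=summary,
        )

    def test_degenerate_draws_flagged_significant(self):
        tab = summarize_associations(self._degenerate_fit(0.7))
        assert np.isinf(tab.loc[0, "z"]) and tab.loc[0, "significant"]

    def test_degenerate_zero_draws_not_significant(self):
        tab = summarize_associations(self._degenerate_fit(0.0))
        assert not tab.loc[0, "significant"]


class TestFittedPosterior:
    def test_summary_quantile_ordering(self, small_fit):
        *_, fit = small_fit
        s = fit.summary
        assert (s["q2.5"] <= s["mean"] + 1e-9).all()
        assert (s["mean"] <= s["q97.5"] + 1e-9).all()

    def test_thinning_rule(self, small_fit):
        *_, fit = small_fit
        assert fit.n_draws_per_chain == FAST["draws"] // FAST["thin"]

    def test_slope_signal_recovered(self, small_fit):
        cm, fam, cov, truth, fit = small_fit
        strong = truth["fam"] == 1
        assert fit.beta_mean()[strong].mean() > 0.5
        assert abs(fit.beta_mean()[~strong].mean()) < 0.3

    def test_association_table_shape(self, small_fit):
        *_, fit = small_fit
        tab = summarize_associations(fit, n_batches=2)
        assert list(tab["otu_id"]) == fit.otu_ids
        assert set(tab.columns) >= {
            "family", "beta_mean", "beta_sd", "z", "ci_lower", "ci_upper",
            "rhat", "ess", "significant",
        }

    def test_seed_determinism(self, tiny_dataset):
        import warnings

        cm, fam, cov, _ = tiny_dataset
        spec = ModelSpec(chains=1, warmup=80, draws=60, thin=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fit_bhm(cm, fam, cov, spec)
            b = fit_bhm(cm, fam, cov, spec)
        np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])


class TestNoPhylogenyComparator:
    def test_matches_collapsed_family_map(self, tiny_dataset):
        """Removing the phylogenetic level is exactly the one-family
        special case: identical seeds give identical draws."""
        import warnings

        cm, fam, cov, _ = tiny_dataset
        spec = ModelSpec(chains=1, warmup=80, draws=60, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fit_bhm_nophylo(cm, fam, cov, spec)
            b = fit_bhm(cm, fam.collapsed(), cov, spec)
        np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])
        assert a.family_names == ["all"]


class TestEstimatorApi:
    def test_get_set_params_and_clone(self):
        est = HierarchicalNBRegressor(chains=2, warmup=10, draws=10)
        est2 = clone(est).set_params(draws=20)
        assert est2.get_params()["draws"] == 20
        assert est.get_params()["draws"] == 10

    def test_input_validation(self):
        est = HierarchicalNBRegressor()
        with pytest.raises(ValueError, match="aligned"):
            est.fit(np.zeros(3), np.zeros((4, 2), dtype=int))
        with pytest.raises(ValueError, match="non-negative"):
            est.fit(np.zeros(3), np.array([[1, -1]] * 3))
        with pytest.raises(ValueError, match="at least 2"):
            est.fit(np.zeros(1), np.ones((1, 2), dtype=int))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            HierarchicalNBRegressor(chains=0, warmup=5, draws=5).fit(
                np.zeros(3), np.ones((3, 2), dtype=int)
            )
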